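# attract-choice

A deterministic model of **facilitation and competition between two
resource species that share consumers** — the canonical case being a
crop and a wildflower strip sharing pollinators ("bees").

Whether a neighbouring species helps or harms a focal one is decided by
the balance of two processes acting at different scales:

* **attraction** — the total number of bees drawn to the patch,
  `N(c, w)`, a function of the amounts `c` (crop) and `w` (wildflowers);
* **choice** — once in the patch, bees ideal-free-distribute by input
  matching, so the fraction visiting the crop is `D(c, w) = c / (c + w)`.

Bees on the crop are `F(c, w) = N(c, w) · D(c, w)`.  Wildflowers
*facilitate* the crop wherever `F(c, w) > F(c, 0)`; they *compete*
wherever `F` falls below that baseline.  No accelerating (Allee-type)
attraction is needed for facilitation — a decelerating `N` already
produces it, because the marginal bee attracted by a rare competitor
exceeds the marginal bee lost to it by choice.

The package is aimed at theoretical ecologists and agroecologists who
want to evaluate, optimize and classify these visit rates for a menu of
attraction functions (linear, linear plus a local pool, weighted linear,
hyperbolic/Michaelis–Menten, exponential saturating, sublinear power,
sigmoid/Holling type III, and a two-species dual hyperbolic form).

## The model in brief

**Independent amounts.**  For fixed `c`, the wildflower amount `w*`
maximizing `F` satisfies the marginal-value (tangent) condition
`∂N/∂w = N / (c + w*)`.  For the hyperbolic form
`N = A·w/(a + w) + N_c` this is a quadratic with the closed root

```
w* = [−2aN_c + √((2aN_c)² − 4(A + N_c)(N_c a² − aAc))] / (2(A + N_c)),
```

positive exactly when `c` exceeds the facilitation threshold
`c₀ = N_c·a/A`.

**Fixed total area.**  A proportion `p` of the area carries wildflowers
(`c = 1 − p`, `w = b·p`, with `b` the relative per-area value).  Crop
"yield" `f(p) = N_p(p) · D_p(p) · (1 − p)` trades bees against area; its
maximizer `p*` always sits below the proportion that maximizes
attraction alone.

## Worked example

With both species identical per unit area (`A_w = A_c = 1`,
`a_w = a_c = 0.4`, `b = 1`), what share of a field should be
wildflowers?

```sh
$ attract-choice optimize-p --Aw 1 --Ac 1 --aw 0.4 --ac 0.4 --b 1
location,objective,method,at_boundary,residual
0.05278517684404396,0.7354209799276552,golden_section,False,8.372371196330164e-08
```

About **5 % of the area** in wildflowers maximizes crop yield
(`p* ≈ 0.053`, `f* ≈ 0.735` versus `0.714` with no wildflowers at all),
even though the species are perfect substitutes to the bees — the log
line notes that total attraction peaks at the even split `p = 0.5`, but
the area cost pulls the yield optimum far to the left.  The near-zero
residual confirms the stationarity condition holds at the reported
location.

The independent-amounts analogue, at the canonical illustrative values
`A = 10`, `a = 0.4`, `N_c = 10`, `c = 10`:

```sh
$ attract-choice optimize-w --form hyperbolic --A 10 --a 0.4 --Nc 10 --c 10
location,objective,method,at_boundary,residual
1.2000000055134215,15.625000000000002,golden_section,False,-1.0768401281779916e-08
```

A wildflower amount `w* = 1.2` lifts bees on the crop from the baseline
`N_c = 10` to `F = 15.625` — facilitation, as guaranteed here because
`c = 10` exceeds `c₀ = N_c·a/A = 0.4`.

From Python the same quantities come from `optimal_p_numeric`,
`optimal_w_analytic` / `optimal_w_numeric`, `facilitation_threshold`,
`regime_profile` (facilitation/neutral/competition labels along a `w`
grid), `allee_scan` (ranges of crop-induced intraspecific facilitation)
and `run_sweep` (the data tables behind the standard scenarios).

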