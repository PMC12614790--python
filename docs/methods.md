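# Methods

## Model

Two resource species occupy one patch: a focal "crop" with amount `c`
and a competitor, "wildflowers", with amount `w`.  Amounts are
dimensionless utilities — the quantity in proportion to which consumers
divide themselves (flower number × nectar value, or any equivalent).  No
unit system is imposed.

Two standard ecological primitives drive everything:

1. **Numerical response (attraction).**  The total number of bees in the
   patch is `N(c, w)`, one of eight functional families (see below).
2. **Ideal free distribution (choice).**  Within the patch, bees divide
   by input matching: the fraction on the crop is
   `D(c, w) = c / (c + w)`, depending only on the ratio of amounts.

Visits to the crop are `F = N·D`; to the wildflowers, `N·(1 − D)`.
The model is static — no plant or pollinator population dynamics, no
seed set or reproduction, no spatial movement; attraction is a
time-independent functional response.  `D` at `c = w = 0` is undefined
and raises an error rather than returning a convention value, so silent
misuse is impossible.

### Attraction families

| form | N(c, w) | behaviour |
|---|---|---|
| `linear_additive` | `g(c + w)` | exactly neutral: `F = gc` for all w |
| `linear_plus_local` | `L + g(c + w)` | contested local pool: strict competition |
| `weighted_linear` | `Agw + gc` | A > 1: wildflowers over-attract, facilitation at all w |
| `hyperbolic` | `Aw/(a + w) + N_c` | decelerating; the analytically tractable focal case |
| `exponential_saturating` | `A(1 − e^(−w/a)) + N_c` | saturating |
| `power` | `Aw^a + N_c`, `0 < a < 1` | sublinear power law |
| `sigmoid` | `(r(c+w))^y / (1 + (r(c+w))^y)` | Holling type III; initially accelerating, joint in c + w |
| `dual_hyperbolic` | `A_w w/(a_w + w) + A_c c/(a_c + c)` | both species decelerating; fixed-area form |

The `power` and `exponential_saturating` families are this package's
generic sublinear and saturating stand-ins; any increasing, decelerating
or saturating form leads to the same qualitative conclusions.  The
sigmoid form is implemented exactly as written, with an optional
multiplicative `amplitude` defaulting to 1.  `N_c` ("bees attracted by
the crop alone") is a scalar parameter; the helper
`crop_attraction_pool(c, A_c, a_c) = A_c·c/(a_c + c)` is provided for
users who want it to vary with `c` consistently with the dual form.

### Optima

At an interior maximum of `F` in `w` the marginal-value (tangent)
condition holds: `∂N/∂w = N/(c + w*)` — the marginal bee attracted
equals the average bees per unit amount.  For the hyperbolic family this
is a quadratic whose positive branch gives `w*` in closed form; the
root is clamped to 0 when nonpositive or complex (the negative branch is
never a maximum of `F`, which the numerical oracle confirms on random
draws).  `w* > 0` exactly when `c > c₀ = N_c·a/A`: a crop that already
attracts many bees (`N_c` large) but offers little local value (`c`
small) cannot be helped.

In the fixed-area variant, a proportion `p` of area carries wildflowers
(`c = 1 − p`, `w = b·p`; `b` is wildflower per-area value relative to
the crop, `total_area` a pure scaling factor).  Crop yield
`f(p) = N_p·D_p·(1 − p)` is shorthand for bees-on-crop weighted
linearly by crop area, not a fruit-production model.  The stationarity
condition `d/dp(N_p D_p) = N_p D_p/(1 − p)` is exposed as a residual,
with the closed-form derivative of the dual attraction
(`D_p' = −b/(1 + (b−1)p)²`) and an optional central finite difference
(step 1e-6).

### Regimes

Wildflowers facilitate the crop at `(c, w)` when
`F(c, w) > F(c, 0)·(1 + ε)`, compete when below the mirrored bound, and
are neutral otherwise.  ε defaults to 1e-9 (relative): the neutral
regime is algebraically exact, so ε only absorbs floating-point noise.
The mirrored wildflower-side classification compares `F_wild(c, w)` to a
crop-absent baseline; for forms carrying the constant `N_c`, that
baseline sets `N_c = 0`, since those bees are defined as attracted by
the crop.

A structural consequence worth knowing: for any attraction additive in
per-species contributions (all families above except the sigmoid),
`F_crop + F_wild = N` equals the sum of the two solo baselines, so
pointwise facilitation is zero-sum — at most one species is facilitated
at any given `(c, w)`.  Mutual pointwise facilitation requires a
non-additive `N`, e.g. the sigmoid.  Each species can still benefit from
*some* amount of the other (both `w*` and its mirror positive), which is
the sense in which facilitation is mutual under decelerating attraction.

**Allee effect operationalization.**  "Conspecific facilitation induced
by a heterospecific" is formalized as a range of `w` where the
per-unit-amount visitation `V(w) = N(c, w)·(1 − D)/w = N/(c + w)`
strictly increases.  `V' = 0` is again the tangent condition, so under
the hyperbolic form the Allee range is exactly `(0, w*)`: nonempty when
`c > c₀`, always empty in a single-species patch (`c = 0`) under
decelerating `N`.  Alternative per-capita quantities (e.g. visits per
flower at fixed nectar value) would move the interval edges; this choice
is the natural per-capita rate under input matching.

## Numerical choices

* All arithmetic in double precision; test comparisons at relative
  tolerance 1e-9 unless a looser bound is stated.
* 1-D maximization: dense grid scan to bracket the global maximum
  (robust for the non-unimodal sigmoid), then scipy bounded scalar
  minimization on the bracketing cell to `xatol = 1e-8`.  Default grids:
  10 001 points over `w ∈ [0, 50]` or `p ∈ [0, 1]` for optimization,
  501 (`w`) / 101 (`p`) points for sweep tables.  These resolutions keep
  every optimizer call well under a second while bracketing any optimum
  the closed forms produce.
* Ties on flat objectives break toward the smallest location (reported
  as a boundary), the conservative recommendation of "no competitor".
  Optimizers warn when the maximum sits at the upper search limit.
* Derivatives: closed form where registered (hyperbolic,
  dual-hyperbolic); otherwise central finite differences with step 1e-6,
  clipped to a forward difference at `w = 0`.
* Allee-interval and regime-interval extraction is grid-based (maximal
  contiguous runs, no sub-grid root polishing); grid density is the
  user's control.
* CSV output: comma-separated, `.` decimal, header row, no index, LF
  endings — identical specs produce byte-identical files.  The tool has
  no randomness anywhere.

## Scenario fixtures

The named scenarios reproduce the model family's canonical illustrative
parameter sets: single-patch scenarios share `a = 0.4`, `A = 10`,
`L = 10`, `r = 0.02`, `y = 3`, `g = 1`; fixed-area scenarios use
`A_w = A_c = 1` (or `A_w = 10` for the attractive-wildflower variant),
`a_w = a_c = 0.4`, `b = 1`.  Two constants are not pinned by those sets
and are package choices: the crop amount `c = 10` and, for the
decelerating/saturating single-patch scenarios, `N_c = 10`.  They place
the system comfortably above the facilitation threshold
(`c₀ = 0.4`) with an interior optimum `w* = 1.2` — a regime where
attraction, choice and the area-free trade-off are all visibly at work —
and match the hand-worked values used throughout the tests.  Attraction
in the qualitative-comparison scenarios is rescaled so `N(c, 50) = 1`;
rescaling by a positive constant provably changes no label and no
argmax, and the optimizers never apply it.

Because the model is deterministic, "synthetic data" here means these
parameter scenarios, not noisy draws: passing tests show the
implementation honours the model's algebra and its qualitative regime
structure, not that any real crop–wildflower system follows these
functional forms or parameter magnitudes.  Field systems add everything
the model abstracts away — pollinator movement and memory, flower
constancy, temporal dynamics, reproduction feedbacks — so empirical
regime boundaries will differ even where the mechanism applies.

## Known limitations

* The fixed-area optimum is found numerically; no closed form for `p*`
  is attempted.  The refined optimum under identical species is
  `p* ≈ 0.0528`; at two-decimal reporting precision this is 0.05, and a
  0.01-resolution sweep peaks at the same value.
* Only two species; no joint optimization over `(c, w)`; no
  game-theoretic or evolutionary stability analysis.
* Figure rendering is out of scope — the tested surface is the data
  tables the CLI emits.
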