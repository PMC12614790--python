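"""Optima of the attraction–choice trade-off.

Two optimization problems arise:

* **independent amounts** — for fixed crop amount c, the wildflower
  amount ``w*`` maximizing bees on the crop F(c, w).  At an interior
  optimum the marginal-value (tangent) condition holds:
  dN/dw = N / (c + w), i.e. the marginal gain in attraction equals the
  average attraction per unit amount.  For the hyperbolic form the
  condition is a quadratic in w with the closed-form positive root

      w* = [-2 a N_c + sqrt((2 a N_c)^2 - 4 (A + N_c)(N_c a^2 - a A c))]
           / (2 (A + N_c)),

  clamped to 0 when no interior optimum exists.  Facilitation by any
  w > 0 requires c above the threshold c0 = N_c * a / A.

* **fixed area** — the proportion ``p*`` of area in wildflowers that
  maximizes crop yield f(p) = N_p(p) * D_p(p) * (1 - p); found
  numerically (grid scan plus bounded refinement), with the analogous
  stationarity condition d/dp(N_p D_p) = N_p D_p / (1 - p) available as
  a residual check.

Numerical optimizers double as independent oracles for the closed forms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import (
    AttractionForm,
    AttractionParams,
    ModelBConfig,
    ParameterError,
    PatchState,
    attraction,
    attraction_values,
    model_b_attraction,
    model_b_choice,
    model_b_yield,
)

__all__ = [
    "OptimumResult",
    "tangent_residual",
    "optimal_w_analytic",
    "optimal_w_numeric",
    "facilitation_threshold",
    "w_star_curve",
    "model_b_stationarity_residual",
    "optimal_p_numeric",
    "argmax_attraction_p",
]

# relative slack used to call two objective values a tie
_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class OptimumResult:
    """Answer of a one-dimensional optimizer.

    Attributes
    ----------
    location : float
        The optimal amount w* (>= 0) or proportion p* (in [0, 1]).
    objective : float
        Value of F or f at the optimum.
    method : str
        One of ``analytic``, ``grid``, ``golden_section``.
    at_boundary : bool
        True when the optimum sits on an endpoint of the search domain
        (w = 0, or p in {0, 1}) rather than at a stationary point.
    residual : float
        Value of the stationarity condition at the reported location;
        near zero for interior optima, generally nonzero on a boundary.
    """

    location: float
    objective: float
    method: str
    at_boundary: bool
    residual: float


def _dN_dw(form: AttractionForm, params: AttractionParams, c: float, w: float, h: float = 1e-6) -> float:
    """Partial derivative of N with respect to w.

    Closed form for the hyperbolic and dual-hyperbolic families; central
    finite difference (step h, clipped at w = 0 to a forward difference)
    otherwise.
    """
    if form is AttractionForm.HYPERBOLIC:
        return params.A * params.a / (params.a + w) ** 2
    if form is AttractionForm.DUAL_HYPERBOLIC:
        return params.A_w * params.a_w / (params.a_w + w) ** 2
    lo = max(w - h, 0.0)
    hi = w + h
    f_lo = attraction_values(form, params, c, lo)
    f_hi = attraction_values(form, params, c, hi)
    return float((f_hi - f_lo) / (hi - lo))


def tangent_residual(
    params: AttractionParams,
    c: float,
    w: float,
    form: AttractionForm | str = AttractionForm.HYPERBOLIC,
) -> float:
    """Stationarity residual dN/dw - N/(c + w) of the tangent condition.

    Zero at an interior maximum of F(c, w): the tangent from -c on the
    amount axis touches N(c, w) exactly at w*.  Closed-form derivative
    for the hyperbolic families; a central finite difference stands in
    for other forms.
    """
    form = AttractionForm.from_name(form)
    if c + w <= 0:
        raise ParameterError("tangent residual requires c + w > 0")
    N = attraction(form, params, PatchState(c=c, w=w))
    return _dN_dw(form, params, c, w) - N / (c + w)


def facilitation_threshold(params: AttractionParams) -> float:
    """Crop amount c0 = N_c * a / A below which w* = 0 (hyperbolic form).

    For c > c0 a strictly positive amount of wildflowers increases bees
    on the crop; at or below c0 the crop already attracts too many bees
    relative to its local value for a competitor to help.

    Raises
    ------
    ZeroDivisionError
        If A = 0 (wildflowers attract nothing; no threshold exists).
    """
    if params.A == 0:
        raise ZeroDivisionError("facilitation threshold undefined for A = 0")
    return params.N_c * params.a / params.A


def optimal_w_analytic(params: AttractionParams, c: float) -> OptimumResult:
    """Closed-form w* for the hyperbolic attraction N = A*w/(a+w) + N_c.

    Solves the quadratic stationarity condition
    w^2 (A + N_c) + w * 2 a N_c + (N_c a^2 - a A c) = 0 on its positive
    branch.  When the root is nonpositive or complex there is no
    interior optimum and F is maximized at w = 0 (reported with
    ``at_boundary=True``).
    """
    if c < 0:
        raise ParameterError(f"c must be >= 0, got {c}")
    A, a, N_c = params.A, params.a, params.N_c
    if A + N_c <= 0:
        raise ParameterError("hyperbolic optimum requires A + N_c > 0")

    disc = (2.0 * a * N_c) ** 2 - 4.0 * (A + N_c) * (N_c * a**2 - a * A * c)
    w_star = -1.0
    if disc >= 0.0:
        w_star = (-2.0 * a * N_c + np.sqrt(disc)) / (2.0 * (A + N_c))

    if w_star <= 0.0:
        # boundary: bees on crop maximal with no wildflowers at all
        objective = N_c if c > 0 else 0.0
        residual = tangent_residual(params, c, 0.0) if c > 0 else np.nan
        return OptimumResult(0.0, float(objective), "analytic", True, float(residual))

    N = attraction(AttractionForm.HYPERBOLIC, params, PatchState(c=c, w=w_star))
    objective = N * c / (c + w_star)
    residual = tangent_residual(params, c, w_star)
    return OptimumResult(float(w_star), float(objective), "analytic", False, float(residual))


def _maximize_1d(fun, grid: np.ndarray, tol: float, residual_fun) -> OptimumResult:
    """Grid scan to bracket the global maximum, then bounded refinement.

    ``fun`` must accept a vector of locations and return objective
    values.  Ties are broken toward the smallest location (np.argmax
    returns the first maximizer), so flat objectives report the left
    endpoint with ``at_boundary=True``.
    """
    values = np.asarray(fun(grid), dtype=float)
    idx = int(np.argmax(values))
    lo = grid[max(idx - 1, 0)]
    hi = grid[min(idx + 1, len(grid) - 1)]

    res = minimize_scalar(
        lambda x: -float(fun(np.asarray(x))),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    loc, obj = float(res.x), float(-res.fun)
    # prefer the grid point if refinement did not genuinely improve on it
    if values[idx] >= obj:
        loc, obj = float(grid[idx]), float(values[idx])

    left, right = float(grid[0]), float(grid[-1])
    tie = _TIE_RTOL * max(1.0, abs(obj))
    f_left = float(fun(np.asarray(left)))
    if f_left >= obj - tie:
        # flat or decreasing objective: the left endpoint is (one of) the maxima
        return OptimumResult(left, f_left, "grid", True, float(residual_fun(left)))
    if idx == len(grid) - 1 or loc >= right * (1.0 - 1e-12):
        warnings.warn(
            f"maximum found at the upper search limit {right}; widen the window",
            stacklevel=3,
        )
        return OptimumResult(right, float(values[-1]), "grid", True, float(residual_fun(right)))
    return OptimumResult(loc, obj, "golden_section", False, float(residual_fun(loc)))


def optimal_w_numeric(
    form: AttractionForm | str,
    params: AttractionParams,
    c: float,
    w_max: float = 50.0,
    tol: float = 1e-8,
    n_grid: int = 10_001,
) -> OptimumResult:
    """Brute-force maximization of F(c, w) over w in [0, w_max].

    A dense grid scan brackets the global maximum (robust for
    non-unimodal forms such as the sigmoid), then bounded scalar
    minimization refines to ``tol``.  Serves as the independent oracle
    for :func:`optimal_w_analytic`.  A warning is issued when the
    maximum sits at ``w_max`` (search window too small).
    """
    form = AttractionForm.from_name(form)
    if w_max <= 0:
        raise ParameterError(f"w_max must be > 0, got {w_max}")
    if tol <= 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    if c < 0:
        raise ParameterError(f"c must be >= 0, got {c}")

    grid = np.linspace(0.0, w_max, n_grid)

    def f_crop(w):
        N = attraction_values(form, params, c, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(c + w > 0, c / (c + w), 0.0)
        return N * D

    def residual(w: float) -> float:
        if c + w <= 0:
            return float("nan")
        return tangent_residual(params, c, w, form=form)

    return _maximize_1d(f_crop, grid, tol, residual)


def w_star_curve(params: AttractionParams, c_grid) -> "pd.DataFrame":
    """Optimal wildflower amount w*(c) along an ascending crop grid.

    Returns a DataFrame with columns ``c`` and ``w_star``; w* is zero up
    to the facilitation threshold c0 and strictly increasing beyond it.
    """
    import pandas as pd

    c_grid = np.asarray(c_grid, dtype=float)
    if c_grid.size == 0:
        raise ParameterError("c_grid must be nonempty")
    if np.any(np.diff(c_grid) < 0):
        raise ParameterError("c_grid must be ascending")
    w = [optimal_w_analytic(params, float(ci)).location for ci in c_grid]
    return pd.DataFrame({"c": c_grid, "w_star": w})


def _d_np_dp(config: ModelBConfig) -> float:
    """Closed-form derivative of the dual-form attraction N_p with p."""
    q, b = config.params, config.b
    p = config.p
    return (
        q.A_w * b * q.a_w / (q.a_w + b * p) ** 2
        - q.A_c * q.a_c / (q.a_c + 1.0 - p) ** 2
    )


def model_b_stationarity_residual(
    config: ModelBConfig, step: float = 1e-6, closed_form: bool = True
) -> float:
    """Residual d/dp(N_p * D_p) - N_p * D_p / (1 - p) at an interior p.

    Vanishes at the proportion p* that maximizes crop yield f(p).  The
    derivative uses the registered closed form for the dual-hyperbolic
    attraction, or a central finite difference of step ``step`` when
    ``closed_form`` is off.
    """
    p = config.p
    if not 0.0 < p < 1.0:
        raise ParameterError(f"stationarity residual defined only for 0 < p < 1, got p={p}")
    N = model_b_attraction(config)
    D = model_b_choice(config)
    if closed_form:
        # D_p = (1-p)/s with s = 1 + (b-1) p, so D_p' = -b / s^2
        s = 1.0 + (config.b - 1.0) * p
        dD = -config.b / s**2
        dN = _d_np_dp(config)
        d_prod = dN * D + N * dD
    else:
        lo = replace(config, p=max(p - step, 0.0))
        hi = replace(config, p=min(p + step, 1.0))
        g_lo = model_b_attraction(lo) * model_b_choice(lo)
        g_hi = model_b_attraction(hi) * model_b_choice(hi)
        d_prod = (g_hi - g_lo) / (hi.p - lo.p)
    return float(d_prod - N * D / (1.0 - p))


def _p_grid_objective(config: ModelBConfig, values_of):
    """Vectorized objective over p for the fixed-area model."""
    q, b, area = config.params, config.b, config.total_area

    def fun(p):
        p = np.asarray(p, dtype=float)
        c = 1.0 - p
        w = b * p
        N = attraction_values(AttractionForm.DUAL_HYPERBOLIC, q, c, w)
        with np.errstate(invalid="ignore", divide="ignore"):
            D = np.where(c + w > 0, c / (c + w), 0.0)
        return values_of(N, D, p) * area

    return fun


def optimal_p_numeric(config: ModelBConfig, tol: float = 1e-8, n_grid: int = 10_001) -> OptimumResult:
    """Proportion p* in [0, 1] maximizing crop yield f(p).

    Grid scan at resolution 1/(n_grid - 1) followed by bounded
    refinement; endpoints are admissible and flagged via
    ``at_boundary``.  The ``p`` field of ``config`` is ignored.
    """
    if tol <= 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    fun = _p_grid_objective(config, lambda N, D, p: N * D * (1.0 - p))

    def residual(p: float) -> float:
        if not 0.0 < p < 1.0:
            return float("nan")
        return model_b_stationarity_residual(replace(config, p=p))

    return _maximize_1d(fun, np.linspace(0.0, 1.0, n_grid), tol, residual)


def argmax_attraction_p(config: ModelBConfig, tol: float = 1e-8, n_grid: int = 10_001) -> OptimumResult:
    """Proportion maximizing total attraction N_p(p) alone (no area cost).

    Under symmetric parameters (A_w = A_c, a_w = a_c, b = 1) this is
    exactly p = 1/2: mixing the two decelerating attractors draws the
    most bees.  The yield optimum p* always sits to the left of it,
    because yield additionally pays for wildflower area.
    """
    if tol <= 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    fun = _p_grid_objective(config, lambda N, D, p: N)

    def residual(p: float) -> float:
        return _d_np_dp(replace(config, p=float(np.clip(p, 0.0, 1.0))))

    return _maximize_1d(fun, np.linspace(0.0, 1.0, n_grid), tol, residual)
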