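"""Classification of facilitation, neutrality and competition.

The operational criterion: wildflowers facilitate the crop at (c, w)
whenever bees on the crop exceed the no-wildflower baseline,
F(c, w) > F(c, 0) = N(c, 0); they compete when F falls below it.  The
same criterion applied with the roles swapped (crop absent as baseline)
classifies the effect of the crop on the wildflowers.

A second, intraspecific question is also answered here: can the presence
of the crop make wildflower visitation *per unit of wildflower* increase
with w — an Allee effect precipitated by a heterospecific?  Under input
matching the per-unit-amount visit rate is

    V(w) = N(c, w) * (1 - D(c, w)) / w = N(c, w) / (c + w),

and an Allee range is any interval where V strictly increases.  With
decelerating attraction this never happens in a single-species patch
(c = 0), but a crop above the facilitation threshold creates one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model_core import (
    AttractionForm,
    AttractionParams,
    ParameterError,
    PatchState,
    attraction_values,
    visit_rates,
)

__all__ = [
    "FACILITATION",
    "NEUTRAL",
    "COMPETITION",
    "RegimeProfile",
    "classify_point",
    "regime_profile",
    "allee_scan",
    "interaction_matrix",
]

FACILITATION = "facilitation"
NEUTRAL = "neutral"
COMPETITION = "competition"

#: Default relative tolerance for calling a point neutral.  The neutral
#: regime (linear additive attraction) is algebraically exact, so only
#: floating-point noise needs absorbing.
DEFAULT_EPSILON = 1e-9


@dataclass(frozen=True)
class RegimeProfile:
    """Per-grid-point regime classification along a wildflower sweep.

    ``facilitation_interval`` is the maximal contiguous run of
    facilitating grid points containing the smallest facilitating w,
    reported as a (w_lo, w_hi) pair, or ``None`` when no point
    facilitates.
    """

    w_grid: np.ndarray
    F_crop_values: np.ndarray
    baseline: float
    labels: tuple
    facilitation_interval: "tuple[float, float] | None"


def _label(F: float, baseline: float, epsilon: float) -> str:
    if F > baseline * (1.0 + epsilon):
        return FACILITATION
    if F < baseline * (1.0 - epsilon):
        return COMPETITION
    return NEUTRAL


def classify_point(
    form,
    params: AttractionParams,
    c: float,
    w: float,
    epsilon: float = DEFAULT_EPSILON,
) -> str:
    """Label the effect of wildflower amount w on crop visits at (c, w).

    Compares F(c, w) against the baseline F(c, 0) with relative
    tolerance ``epsilon``; w = 0 is neutral by construction.
    """
    if c <= 0:
        raise ParameterError(f"classification requires c > 0, got c={c}")
    form = AttractionForm.from_name(form)
    baseline = visit_rates(form, params, PatchState(c=c, w=0.0)).F_crop
    F = visit_rates(form, params, PatchState(c=c, w=w)).F_crop
    return _label(F, baseline, epsilon)


def regime_profile(
    form,
    params: AttractionParams,
    c: float,
    w_grid,
    epsilon: float = DEFAULT_EPSILON,
) -> RegimeProfile:
    """Vectorized classification along an ascending wildflower grid."""
    if c <= 0:
        raise ParameterError(f"classification requires c > 0, got c={c}")
    form = AttractionForm.from_name(form)
    w_grid = np.asarray(w_grid, dtype=float)
    if w_grid.size == 0:
        raise ParameterError("w_grid must be nonempty")
    if np.any(np.diff(w_grid) < 0):
        raise ParameterError("w_grid must be ascending")

    baseline = float(attraction_values(form, params, c, 0.0))  # D(c, 0) = 1
    N = attraction_values(form, params, c, w_grid)
    F = N * c / (c + w_grid)
    labels = tuple(_label(float(Fi), baseline, epsilon) for Fi in F)

    interval = None
    fac = [i for i, lab in enumerate(labels) if lab == FACILITATION]
    if fac:
        start = fac[0]
        end = start
        while end + 1 < len(labels) and labels[end + 1] == FACILITATION:
            end += 1
        interval = (float(w_grid[start]), float(w_grid[end]))

    return RegimeProfile(
        w_grid=w_grid,
        F_crop_values=np.asarray(F, dtype=float),
        baseline=baseline,
        labels=labels,
        facilitation_interval=interval,
    )


def allee_scan(form, params: AttractionParams, c: float, w_grid) -> "list[tuple[float, float]]":
    """Intervals of conspecific facilitation (Allee effect) in w.

    Computes the per-unit-amount visitation V(w) = N(c, w) / (c + w) on
    the grid and returns the maximal contiguous intervals where V is
    strictly increasing (successive differences positive beyond
    floating-point noise).  Empty list when V never increases — the
    case for every decelerating form in a single-species patch (c = 0).
    """
    if c < 0:
        raise ParameterError(f"c must be >= 0, got {c}")
    form = AttractionForm.from_name(form)
    w_grid = np.asarray(w_grid, dtype=float)
    if w_grid.size < 2:
        raise ParameterError("w_grid needs at least two points")
    if np.any(np.diff(w_grid) <= 0):
        raise ParameterError("w_grid must be strictly ascending")
    if np.any(w_grid <= 0) and c == 0:
        raise ParameterError("V undefined at c = w = 0")

    N = attraction_values(form, params, c, w_grid)
    V = N / (c + w_grid)
    dV = np.diff(V)
    rising = dV > 1e-12 * max(1.0, float(np.max(np.abs(V))))

    intervals: list[tuple[float, float]] = []
    i = 0
    while i < len(rising):
        if rising[i]:
            j = i
            while j + 1 < len(rising) and rising[j + 1]:
                j += 1
            intervals.append((float(w_grid[i]), float(w_grid[j + 1])))
            i = j + 1
        i += 1
    return intervals


def interaction_matrix(
    form,
    params: AttractionParams,
    c: float,
    w: float,
    epsilon: float = DEFAULT_EPSILON,
) -> "tuple[str, str]":
    """Ordered pair of labels: (effect of w on crop, effect of c on wildflowers).

    The crop side compares F_crop(c, w) to F_crop(c, 0); the wildflower
    side mirrors it, comparing F_wild(c, w) to F_wild(0, w) — the crop
    absent entirely.  Since the N_c parameter means "bees attracted by
    the crop alone", forms carrying that constant evaluate their
    crop-absent baseline with N_c = 0.

    For attraction forms additive in per-species contributions
    (hyperbolic, dual_hyperbolic, linear families) the two baselines sum
    to N(c, w) exactly, so facilitation is pointwise zero-sum: at most
    one species can be facilitated at any given (c, w).  Mutual
    facilitation requires a non-additive N, e.g. the sigmoid form.
    """
    if c <= 0 or w <= 0:
        raise ParameterError("interaction matrix requires c > 0 and w > 0")
    form = AttractionForm.from_name(form)
    crop_side = classify_point(form, params, c, w, epsilon)

    crop_absent = params
    if form in (
        AttractionForm.HYPERBOLIC,
        AttractionForm.EXPONENTIAL_SATURATING,
        AttractionForm.POWER,
    ):
        crop_absent = replace(params, N_c=0.0)
    baseline_wild = visit_rates(form, crop_absent, PatchState(c=0.0, w=w)).F_wild
    F_wild = visit_rates(form, params, PatchState(c=c, w=w)).F_wild
    wild_side = _label(F_wild, baseline_wild, epsilon)
    return crop_side, wild_side
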