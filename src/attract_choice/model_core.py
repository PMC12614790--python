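"""Core types and primitives of the attraction–choice model.

Two resource species share a patch: a focal "crop" with amount ``c`` and a
potential competitor, "wildflowers", with amount ``w``.  Amounts are
dimensionless utilities — whatever quantity consumers (called "bees"
throughout) use to divide themselves among resources.  Two processes set
the visit rates:

* **attraction** — the total number of bees drawn to the patch,
  ``N(c, w)``, for which several functional forms are supported;
* **choice** — once in the patch, bees ideal-free-distribute by input
  matching, so the fraction on the crop is ``D(c, w) = c / (c + w)``.

Bees on the crop are then ``F = N * D``; bees on the wildflowers are
``N * (1 - D)``.  Whether the wildflowers facilitate or compete with the
crop is entirely a question of how ``N`` grows with ``w`` relative to how
``D`` shrinks — the trade-off this package quantifies.

A second parameterization ("fixed-area" or Model B) divides a fixed total
area between the species: a proportion ``p`` goes to wildflowers, so
``c = 1 - p`` and ``w = b * p`` where ``b`` is the per-area value of
wildflowers relative to the crop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "ModelError",
    "DegeneratePatchError",
    "ParameterError",
    "UnknownFormError",
    "AttractionForm",
    "PatchState",
    "AttractionParams",
    "ModelBConfig",
    "VisitRates",
    "choice_fraction",
    "attraction",
    "attraction_values",
    "visit_rates",
    "crop_attraction_pool",
    "model_b_state",
    "model_b_attraction",
    "model_b_choice",
    "model_b_yield",
    "model_b_wild_yield",
    "normalize_attraction",
]


class ModelError(ValueError):
    """Base class for model-domain errors."""


class DegeneratePatchError(ModelError):
    """Raised when the choice fraction is evaluated at c = w = 0."""


class ParameterError(ModelError):
    """Raised when a parameter violates its bound."""


class UnknownFormError(ModelError):
    """Raised for an unrecognized attraction-form name."""


class AttractionForm(str, Enum):
    """Functional family of the patch attraction N(c, w).

    ``linear_additive``
        N = g*(c + w).  Each plant attracts exactly the bees that choose
        it: neither facilitation nor competition.
    ``linear_plus_local``
        N = L + g*(c + w).  A fixed local pool L is contested, so any
        wildflower presence reduces crop visits.
    ``weighted_linear``
        N = A*g*w + g*c.  Wildflowers disproportionately attractive at a
        distance (A > 1 facilitates the crop).
    ``hyperbolic``
        N = A*w/(a + w) + N_c.  Decelerating (Michaelis–Menten-like)
        attraction; the analytically tractable focal case.
    ``exponential_saturating``
        N = A*(1 - exp(-w/a)) + N_c.  Saturating attraction.
    ``power``
        N = A*w**a + N_c with 0 < a < 1.  Sublinear power-law attraction.
    ``sigmoid``
        N = (r*(c+w))**y / (1 + (r*(c+w))**y).  Holling type III:
        initially accelerating joint attraction.
    ``dual_hyperbolic``
        N = A_w*w/(a_w + w) + A_c*c/(a_c + c).  Both species contribute a
        decelerating term; the fixed-area model's form.
    """

    LINEAR_ADDITIVE = "linear_additive"
    LINEAR_PLUS_LOCAL = "linear_plus_local"
    WEIGHTED_LINEAR = "weighted_linear"
    HYPERBOLIC = "hyperbolic"
    EXPONENTIAL_SATURATING = "exponential_saturating"
    POWER = "power"
    SIGMOID = "sigmoid"
    DUAL_HYPERBOLIC = "dual_hyperbolic"

    @classmethod
    def from_name(cls, name: "str | AttractionForm") -> "AttractionForm":
        if isinstance(name, cls):
            return name
        try:
            return cls(str(name))
        except ValueError:
            valid = ", ".join(f.value for f in cls)
            raise UnknownFormError(
                f"unknown attraction form {name!r}; expected one of: {valid}"
            ) from None


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class PatchState:
    """Amounts (c, w) of crop and wildflowers in the patch.

    Both are nonnegative, dimensionless utilities; at least one must be
    positive wherever the choice fraction is evaluated.
    """

    c: float
    w: float

    def __post_init__(self) -> None:
        _check(math.isfinite(self.c) and self.c >= 0, f"c must be finite and >= 0, got {self.c}")
        _check(math.isfinite(self.w) and self.w >= 0, f"w must be finite and >= 0, got {self.w}")


@dataclass(frozen=True)
class AttractionParams:
    """Constants shaping the patch attraction N(c, w).

    Fields irrelevant to the selected form are ignored at evaluation time
    but validated against their bounds whenever set.

    Parameters
    ----------
    A : float
        Long-range attractiveness scale of the wildflowers (>= 0).
    a : float
        Deceleration / half-saturation constant (> 0).  Reused as the
        exponent of the power form, where 0 < a < 1 is required.
    N_c : float
        Bees attracted by the crop alone, N(c, 0) (>= 0).
    L : float
        Local bee pool present regardless of plant amounts (>= 0).
    r, y : float
        Rate constant and exponent of the sigmoid (type III) form (> 0).
    g : float
        Linear attraction constant (> 0).
    A_w, A_c : float
        Per-species attractiveness scales of the dual form (>= 0).
    a_w, a_c : float
        Per-species deceleration constants of the dual form (> 0).
    amplitude : float
        Optional multiplicative amplitude of the sigmoid form (> 0,
        default 1 as in the plain type III response).
    """

    A: float = 1.0
    a: float = 1.0
    N_c: float = 0.0
    L: float = 0.0
    r: float = 1.0
    y: float = 1.0
    g: float = 1.0
    A_w: float = 1.0
    A_c: float = 1.0
    a_w: float = 1.0
    a_c: float = 1.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        _check(self.A >= 0, f"A must be >= 0, got {self.A}")
        _check(self.a > 0, f"a must be > 0, got {self.a}")
        _check(self.N_c >= 0, f"N_c must be >= 0, got {self.N_c}")
        _check(self.L >= 0, f"L must be >= 0, got {self.L}")
        _check(self.r > 0, f"r must be > 0, got {self.r}")
        _check(self.y > 0, f"y must be > 0, got {self.y}")
        _check(self.g > 0, f"g must be > 0, got {self.g}")
        _check(self.A_w >= 0, f"A_w must be >= 0, got {self.A_w}")
        _check(self.A_c >= 0, f"A_c must be >= 0, got {self.A_c}")
        _check(self.a_w > 0, f"a_w must be > 0, got {self.a_w}")
        _check(self.a_c > 0, f"a_c must be > 0, got {self.a_c}")
        _check(self.amplitude > 0, f"amplitude must be > 0, got {self.amplitude}")


@dataclass(frozen=True)
class ModelBConfig:
    """Fixed-total-area scenario.

    A proportion ``p`` of the area carries wildflowers and ``1 - p``
    carries the crop.  With the crop's per-area value standardized to 1
    and the wildflowers' to ``b``, the induced amounts are exactly
    ``c = 1 - p`` and ``w = b * p``.  ``total_area`` is a pure scaling
    factor on yields and never moves an optimum.
    """

    p: float
    b: float = 1.0
    total_area: float = 1.0
    params: AttractionParams = field(default_factory=AttractionParams)

    def __post_init__(self) -> None:
        _check(0.0 <= self.p <= 1.0, f"p must be in [0, 1], got {self.p}")
        _check(self.b > 0, f"b must be > 0, got {self.b}")
        _check(self.total_area > 0, f"total_area must be > 0, got {self.total_area}")


@dataclass(frozen=True)
class VisitRates:
    """Joint outcome of attraction and choice for one patch state."""

    N: float
    D: float
    F_crop: float
    F_wild: float


def choice_fraction(state: PatchState) -> float:
    """Fraction of patch bees visiting the crop, D = c / (c + w).

    Input matching: bees divide among the two species in proportion to
    their amounts, so D depends only on the ratio c/w.

    Raises
    ------
    DegeneratePatchError
        If c = w = 0, where the fraction is undefined.
    """
    total = state.c + state.w
    if total <= 0.0:
        raise DegeneratePatchError("choice fraction undefined at c = w = 0")
    return state.c / total


def attraction_values(form, params: AttractionParams, c, w):
    """Vectorized patch attraction N(c, w); c and w broadcast as arrays.

    This is the workhorse used by the grid optimizers and sweep runner;
    :func:`attraction` is the scalar, validating front end.
    """
    form = AttractionForm.from_name(form)
    c = np.asarray(c, dtype=float)
    w = np.asarray(w, dtype=float)
    if form is AttractionForm.LINEAR_ADDITIVE:
        return params.g * (c + w)
    if form is AttractionForm.LINEAR_PLUS_LOCAL:
        return params.L + params.g * (c + w)
    if form is AttractionForm.WEIGHTED_LINEAR:
        return params.A * params.g * w + params.g * c
    if form is AttractionForm.HYPERBOLIC:
        return params.A * w / (params.a + w) + params.N_c
    if form is AttractionForm.EXPONENTIAL_SATURATING:
        return params.A * (1.0 - np.exp(-w / params.a)) + params.N_c
    if form is AttractionForm.POWER:
        if not 0.0 < params.a < 1.0:
            raise ParameterError(
                f"power form requires exponent 0 < a < 1 (deceleration), got a={params.a}"
            )
        return params.A * np.power(w, params.a) + params.N_c
    if form is AttractionForm.SIGMOID:
        z = np.power(params.r * (c + w), params.y)
        return params.amplitude * z / (1.0 + z)
    if form is AttractionForm.DUAL_HYPERBOLIC:
        return (
            params.A_w * w / (params.a_w + w)
            + params.A_c * c / (params.a_c + c)
        )
    raise UnknownFormError(f"unhandled form {form!r}")  # pragma: no cover


def attraction(form, params: AttractionParams, state: PatchState) -> float:
    """Total bees attracted to the patch, N(c, w) >= 0, for one form."""
    return float(attraction_values(form, params, state.c, state.w))


def visit_rates(form, params: AttractionParams, state: PatchState) -> VisitRates:
    """Evaluate N, D and the per-species visit rates F = N*D, N*(1-D)."""
    N = attraction(form, params, state)
    D = choice_fraction(state)
    return VisitRates(N=N, D=D, F_crop=N * D, F_wild=N * (1.0 - D))


def crop_attraction_pool(c: float, A_c: float, a_c: float) -> float:
    """Decelerating bees-from-crop-alone helper, N_c(c) = A_c*c/(a_c + c).

    The single-species analogue of the dual form's crop term, for users
    who want the scalar ``N_c`` parameter to vary consistently with c.
    """
    _check(a_c > 0, f"a_c must be > 0, got {a_c}")
    _check(c >= 0, f"c must be >= 0, got {c}")
    return A_c * c / (a_c + c)


def model_b_state(config: ModelBConfig) -> PatchState:
    """Amounts induced by the area split: c = 1 - p, w = b*p."""
    return PatchState(c=1.0 - config.p, w=config.b * config.p)


def model_b_attraction(config: ModelBConfig) -> float:
    """Total bees attracted in the fixed-area model, N_p(p) (dual form)."""
    return attraction(AttractionForm.DUAL_HYPERBOLIC, config.params, model_b_state(config))


def model_b_choice(config: ModelBConfig) -> float:
    """Fraction of bees on the crop, D_p(p) = (1-p) / ((1-p) + b*p)."""
    return choice_fraction(model_b_state(config))


def model_b_yield(config: ModelBConfig) -> float:
    """Crop 'yield' f(p) = N_p(p) * D_p(p) * (1-p) * total_area.

    Yield is shorthand for bees-on-crop weighted by crop area; it assumes
    pollination limitation and linear dependence on area, not any model
    of fruit production.  f(1) = 0 (no crop area, and no bee chooses a
    crop that is absent).
    """
    if config.p >= 1.0:
        return 0.0
    N = model_b_attraction(config)
    D = model_b_choice(config)
    return N * D * (1.0 - config.p) * config.total_area


def model_b_wild_yield(config: ModelBConfig) -> float:
    """Wildflower-side yield, N_p(p) * (1 - D_p(p)) * p * total_area."""
    if config.p <= 0.0:
        return 0.0
    N = model_b_attraction(config)
    D = model_b_choice(config)
    return N * (1.0 - D) * config.p * config.total_area


def normalize_attraction(form, params: AttractionParams, c_fixed: float, w_ref: float = 50.0) -> float:
    """Scaling constant k with k * N(c_fixed, w_ref) = 1.

    Used only to make output tables of different forms comparable on one
    axis; a positive rescaling never moves the argmax of F, so the
    optimizers ignore it.

    Raises
    ------
    ZeroDivisionError
        If N(c_fixed, w_ref) = 0.
    """
    ref = attraction(form, params, PatchState(c=c_fixed, w=w_ref))
    if ref == 0.0:
        raise ZeroDivisionError(
            f"cannot normalize: N(c={c_fixed}, w={w_ref}) = 0 for form {AttractionForm.from_name(form).value}"
        )
    return 1.0 / ref
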