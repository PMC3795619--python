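"""Growth functions for size-at-age modelling of batoids.

Four standard fisheries growth curves, parameterised on disc width (cm):

* ``vbgf``     — three-parameter von Bertalanffy,
  ``W(t) = W_inf * (1 - exp(-k (t - t0)))``
* ``vbgf2``    — two-parameter von Bertalanffy with size at birth fixed,
  ``W(t) = W_inf * (1 - b exp(-k t))`` with ``b = (W_inf - W0) / W_inf``
* ``logistic`` — ``W(t) = W_inf W0 e^{kt} / (W_inf + W0 (e^{kt} - 1))``
* ``gompertz`` — ``W(t) = W_inf * exp(ln(W0 / W_inf) * e^{-kt})``

All four satisfy ``W(t) -> W_inf`` as ``t -> inf``; the three size-at-birth
forms satisfy ``W(0) = W0``.  The logistic and Gompertz rate coefficients are
on a different scale from the von Bertalanffy ``k`` and are not comparable
across models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

MODEL_NAMES = ("vbgf", "vbgf2", "logistic", "gompertz")

#: models whose parameter vector carries a size-at-birth term
W0_MODELS = ("vbgf2", "logistic", "gompertz")


class GrowthModelError(ValueError):
    """Invalid growth-model name or parameter set."""


@dataclass(frozen=True)
class GrowthParams:
    """Parameter vector of one growth function.

    Parameters
    ----------
    model_name
        One of ``vbgf``, ``vbgf2``, ``logistic``, ``gompertz``.
    w_inf
        Asymptotic disc width, cm (> 0).
    k
        Growth coefficient, yr^-1 (> 0).
    t0
        Theoretical age at zero size, yr; required by (and only by) ``vbgf``.
        May be negative.
    w0
        Disc width at age zero, cm; required by the other three models and
        must satisfy ``0 < w0 < w_inf``.
    """

    model_name: str
    w_inf: float
    k: float
    t0: Optional[float] = None
    w0: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_name not in MODEL_NAMES:
            raise GrowthModelError(f"unknown model name {self.model_name!r}")
        if not (self.w_inf > 0):
            raise GrowthModelError("w_inf must be > 0")
        if not (self.k > 0):
            raise GrowthModelError("k must be > 0")
        if self.model_name == "vbgf":
            if self.t0 is None:
                raise GrowthModelError("vbgf requires t0")
            if self.w0 is not None:
                raise GrowthModelError("vbgf does not take w0")
        else:
            if self.t0 is not None:
                raise GrowthModelError(f"{self.model_name} does not take t0")
            if self.w0 is None:
                raise GrowthModelError(f"{self.model_name} requires w0")
            if not (0 < self.w0 < self.w_inf):
                raise GrowthModelError("w0 must satisfy 0 < w0 < w_inf")


@dataclass(frozen=True)
class SizeAtAgeRecord:
    """One animal's estimated age (yr) and disc width (cm), with metadata.

    Ages may sit on a half-year grid: 0.5 yr is added when a band is still
    forming on the centrum edge at capture.  Readability scores run 1 (clear)
    to 3 (unreadable; excluded upstream of any fitting).
    """

    species: str
    age: float
    disc_width: float
    total_length: Optional[float] = None
    sex: Optional[str] = None
    readability: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.age >= 0):
            raise ValueError(f"age must be >= 0, got {self.age}")
        if not (self.disc_width > 0):
            raise ValueError(f"disc_width must be > 0, got {self.disc_width}")
        if self.readability is not None and self.readability not in (1, 2, 3):
            raise ValueError(f"readability must be in {{1,2,3}}, got {self.readability}")
        if self.sex is not None and self.sex not in ("F", "M", "unknown"):
            raise ValueError(f"sex must be F, M or unknown, got {self.sex!r}")


def predict_size(params: GrowthParams, age):
    """Mean disc width (cm) at ``age`` (yr) under ``params``.

    Accepts a scalar or array age; returns the same shape.  Monotone
    non-decreasing in age and approaches ``w_inf`` as age grows, for every
    model and valid parameter set.
    """
    t = np.asarray(age, dtype=float)
    w_inf, k = params.w_inf, params.k
    if params.model_name == "vbgf":
        out = w_inf * (1.0 - np.exp(-k * (t - params.t0)))
    elif params.model_name == "vbgf2":
        b = (w_inf - params.w0) / w_inf
        out = w_inf * (1.0 - b * np.exp(-k * t))
    elif params.model_name == "logistic":
        w0 = params.w0
        ekt = np.exp(k * t)
        out = w_inf * w0 * ekt / (w_inf + w0 * (ekt - 1.0))
    else:  # gompertz
        out = w_inf * np.exp(math.log(params.w0 / w_inf) * np.exp(-k * t))
    return out if out.ndim else float(out)


def vbgf2_equivalent_t0(w_inf: float, k: float, w0: float) -> float:
    """The ``t0`` making the three-parameter curve pass through ``W(0) = w0``."""
    return math.log((w_inf - w0) / w_inf) / k


class FordWalfordError(ValueError):
    """Ford-Walford regression cannot infer an asymptote (slope outside (0, 1))."""


@dataclass(frozen=True)
class FordWalfordResult:
    w_inf: float
    k: float
    slope: float
    intercept: float
    n_pairs: int


def ford_walford(
    mean_size_at_age: Sequence[Tuple[float, float]],
) -> FordWalfordResult:
    """Ford-Walford starting values for (w_inf, k) from mean size at age.

    Regresses mean size at age ``t + 1`` on mean size at age ``t`` across
    consecutive integer ages; under von Bertalanffy growth the slope is
    ``exp(-k)`` and the intercept ``w_inf (1 - exp(-k))``, so

    ``w_inf = intercept / (1 - slope)``,  ``k = -ln(slope)``.

    Non-integer ages are binned to the nearest integer and sizes averaged
    within bins before pairing.

    Raises
    ------
    FordWalfordError
        Fewer than two consecutive-age pairs, degenerate (flat) sizes, or a
        regression slope outside (0, 1) — no asymptote can be inferred and
        the caller should fall back to configured defaults.
    """
    pts = [(float(a), float(s)) for a, s in mean_size_at_age]
    if len(pts) < 3:
        raise FordWalfordError("need at least 3 mean sizes at consecutive ages")
    bins: dict[int, list[float]] = {}
    for a, s in pts:
        bins.setdefault(int(round(a)), []).append(s)
    means = {a: float(np.mean(v)) for a, v in bins.items()}
    x, y = [], []
    for a in sorted(means):
        if a + 1 in means:
            x.append(means[a])
            y.append(means[a + 1])
    if len(x) < 2:
        raise FordWalfordError("need >= 2 consecutive integer-age pairs")
    x_arr, y_arr = np.asarray(x), np.asarray(y)
    sxx = float(np.var(x_arr))
    if sxx <= 1e-12 * max(1.0, float(np.mean(x_arr)) ** 2):
        raise FordWalfordError("sizes do not vary across ages (flat data)")
    slope = float(np.cov(x_arr, y_arr, bias=True)[0, 1] / sxx)
    intercept = float(np.mean(y_arr) - slope * np.mean(x_arr))
    if not (0.0 < slope < 1.0):
        raise FordWalfordError(
            f"Ford-Walford slope {slope:.4f} outside (0, 1); no asymptote inferable"
        )
    w_inf = intercept / (1.0 - slope)
    k = -math.log(slope)
    if not (w_inf > 0 and math.isfinite(w_inf) and math.isfinite(k)):
        raise FordWalfordError("Ford-Walford produced non-finite or non-positive estimates")
    return FordWalfordResult(w_inf=w_inf, k=k, slope=slope, intercept=intercept, n_pairs=len(x))
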