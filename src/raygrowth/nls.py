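"""Nonlinear least-squares growth-model fitting and AICc ranking.

Each growth curve is fitted to size-at-age records by minimising the residual
sum of squares with a bounded trust-region solver, started from Ford-Walford
estimates and re-started from jittered points because NLS on these curves is
sensitive to initial values.  Candidate models are then ranked by the
small-sample bias-corrected Akaike criterion

    AICc = n ln(RSS / n) + 2p + 2p(p + 1) / (n - p - 1)

(the least-squares form, with p counting the estimated growth parameters plus
one error-variance term), and by the differences Delta = AICc - min AICc;
models with Delta <= 2 have the highest support.

The two-parameter von Bertalanffy fixes size at birth (w0) from configuration
and estimates only (w_inf, k), so p = 3; the three-parameter curves estimate
(w_inf, k, t0) or (w_inf, k, w0), so p = 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import (
    FordWalfordError,
    GrowthParams,
    SizeAtAgeRecord,
    ford_walford,
    predict_size,
    vbgf2_equivalent_t0,
)

__all__ = ["NlsFitResult", "aicc", "fit_nls", "rank_models", "NlsError"]

N_RESTARTS = 5


class NlsError(ValueError):
    pass


@dataclass
class NlsFitResult:
    model_name: str
    params: GrowthParams
    rss: float
    n: int
    p: int  # estimated growth parameters + 1 variance term
    aicc: float
    delta_aicc: float = math.nan  # filled by rank_models
    support: str = ""  # "highest" (Delta <= 2) or "lower"
    converged: bool = True


def aicc(rss: float, n: int, p: int) -> float:
    """Bias-corrected AIC for a least-squares fit.

    ``n ln(rss/n) + 2p + 2p(p+1)/(n-p-1)``; requires ``n > p + 1`` and
    ``rss > 0`` (a perfect fit has no finite least-squares AIC and must be
    reported separately).
    """
    if n <= p + 1:
        raise NlsError(f"AICc undefined: n={n} must exceed p+1={p + 1}")
    if not (rss > 0):
        raise NlsError("AICc undefined for rss <= 0 (perfect fit)")
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _free_params(model_name: str) -> int:
    return 2 if model_name == "vbgf2" else 3


def _build_params(model_name: str, theta: np.ndarray, w0: float) -> GrowthParams:
    if model_name == "vbgf":
        return GrowthParams("vbgf", w_inf=theta[0], k=theta[1], t0=theta[2])
    if model_name == "vbgf2":
        return GrowthParams("vbgf2", w_inf=theta[0], k=theta[1], w0=w0)
    return GrowthParams(model_name, w_inf=theta[0], k=theta[1], w0=theta[2])


def _start_and_bounds(model_name, ages, sizes, start, w0):
    """Starting vector and box bounds; Ford-Walford seeds (w_inf, k)."""
    max_obs = float(sizes.max())
    min_age = float(ages.min())
    if start is not None:
        w_inf0, k0 = start.w_inf, start.k
    else:
        try:
            fw = ford_walford(list(zip(ages, sizes)))
            w_inf0, k0 = fw.w_inf, fw.k
        except FordWalfordError:
            w_inf0, k0 = 1.2 * max_obs, 0.2
    lo_w, hi_w = max_obs, 5.0 * max_obs
    w_inf0 = min(max(w_inf0, lo_w * 1.001), hi_w * 0.999)
    k0 = min(max(k0, 1e-3), 49.0)
    if model_name == "vbgf":
        t0_0 = start.t0 if (start is not None and start.t0 is not None) else min(
            0.0, min_age - 0.5
        )
        t0_0 = min(max(t0_0, -9.99), min_age - 1e-6)
        theta0 = np.array([w_inf0, k0, t0_0])
        lo = np.array([lo_w, 1e-4, -10.0])
        hi = np.array([hi_w, 50.0, min_age])
    elif model_name == "vbgf2":
        theta0 = np.array([w_inf0, k0])
        lo = np.array([lo_w, 1e-4])
        hi = np.array([hi_w, 50.0])
    else:
        w0_0 = start.w0 if (start is not None and start.w0 is not None) else w0
        min_obs = float(sizes.min())
        w0_0 = min(max(w0_0, 1e-2), min_obs)
        theta0 = np.array([w_inf0, k0, w0_0])
        lo = np.array([lo_w, 1e-4, 1e-3])
        hi = np.array([hi_w, 50.0, lo_w])  # w0 below every observed size's ceiling
    return theta0, lo, hi


def fit_nls(
    data: Sequence[SizeAtAgeRecord],
    model_name: str,
    w0: float,
    start: Optional[GrowthParams] = None,
    restarts: int = N_RESTARTS,
    seed: int = 0,
) -> NlsFitResult:
    """Fit one growth model to size-at-age records by least squares.

    Parameters
    ----------
    data
        Size-at-age records (readability filtering happens upstream).
    model_name
        ``vbgf``, ``vbgf2``, ``logistic`` or ``gompertz``.
    w0
        Size at birth, cm.  Held fixed for ``vbgf2``; used only as the
        starting value of the estimated w0 for ``logistic``/``gompertz``;
        ignored by ``vbgf``.
    start
        Optional starting parameters; Ford-Walford estimates otherwise.
    restarts
        Jittered restarts around the starting point (best RSS kept).
    """
    ages = np.array([r.age for r in data], dtype=float)
    sizes = np.array([r.disc_width for r in data], dtype=float)
    n = len(ages)
    n_free = _free_params(model_name)
    p = n_free + 1
    if n < n_free + 2:
        raise NlsError(f"need at least {n_free + 2} records to fit {model_name}, got {n}")
    if len(np.unique(ages)) < 2:
        raise NlsError("ages span < 2 distinct values")

    theta0, lo, hi = _start_and_bounds(model_name, ages, sizes, start, w0)

    def resid(theta):
        return predict_size(_build_params(model_name, theta, w0), ages) - sizes

    rng = np.random.default_rng(seed)
    best = None
    any_success = False
    for i in range(max(1, restarts)):
        if i == 0:
            t0 = theta0
        else:
            jitter = rng.normal(0.0, 0.15, size=theta0.shape)
            t0 = np.clip(theta0 * np.exp(jitter), lo + 1e-9, hi - 1e-9)
            if model_name == "vbgf":  # t0 may be <= 0; jitter additively
                t0[2] = np.clip(theta0[2] + rng.normal(0.0, 0.5), lo[2] + 1e-9, hi[2] - 1e-9)
        try:
            sol = least_squares(resid, t0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[0]:
            best = (rss, sol.x, bool(sol.success))
        any_success = any_success or bool(sol.success)
    if best is None:
        raise NlsError(f"optimizer failed for {model_name} from all starts")
    rss, theta, _ = best
    params = _build_params(model_name, theta, w0)
    value = aicc(rss, n, p) if rss > 0 else -math.inf
    return NlsFitResult(
        model_name=model_name,
        params=params,
        rss=rss,
        n=n,
        p=p,
        aicc=value,
        converged=any_success,
    )


def rank_models(fits: Sequence[NlsFitResult]) -> list[NlsFitResult]:
    """Rank fitted models by AICc difference.

    Returns copies sorted ascending by Delta = AICc - min(AICc), with
    ``support`` = "highest" when Delta <= 2 and "lower" otherwise.  Ties in
    AICc (difference < 1e-9) rank the more parsimonious model first.  All
    fits must share the same sample size.
    """
    if len(fits) < 2:
        raise NlsError("need at least 2 fits to rank")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise NlsError(f"fits were made on different sample sizes: {sorted(ns)}")
    best = min(f.aicc for f in fits)
    ranked = []
    for f in fits:
        delta = f.aicc - best
        if delta < 1e-9:
            delta = 0.0
        ranked.append(
            replace(f, delta_aicc=delta, support="highest" if delta <= 2.0 else "lower")
        )
    ranked.sort(key=lambda f: (f.delta_aicc, f.p, f.model_name))
    return ranked
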