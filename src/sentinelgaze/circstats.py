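"""Duration-weighted circular summaries and side-bias inference.

Head orientation per look is a coarse angle (quadrant mid-points 0, 90, 180,
270 degrees; 0 is straight ahead along the body axis, positive angles the
animal's right).  Each focal observation is summarised by the mean angle of
the looks weighted by their durations; a parametric bootstrap under a fitted
von Mises distribution yields a confidence interval, and a side bias is
declared when 0 degrees falls outside it.  Proportions of right- vs
left-biased individuals get exact (Clopper-Pearson) binomial intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from statsmodels.stats.proportion import proportion_confint

from .eventio import LookRecord, ObservationMeta, STATUS_LEVELS

__all__ = [
    "OrientationSummary",
    "weighted_mean_angle",
    "fit_vonmises_weighted",
    "vonmises_bootstrap_ci",
    "classify_bias",
    "exact_binomial_ci",
    "summarize_orientation",
    "build_bias_table",
    "wrap_degrees",
]

_KAPPA_FLOOR = 1e-3  # below this the direction is effectively undefined


def wrap_degrees(a):
    """Wrap angles into (-180, 180]."""
    w = -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)
    return w if np.ndim(a) else float(w)


@dataclass(frozen=True)
class OrientationSummary:
    obs_id: str
    mean_angle: float        # degrees in (-180, 180]
    resultant_length: float  # duration-weighted, in [0, 1]
    kappa: float
    ci_low: float
    ci_high: float
    bias: str                # left | none | right
    n_looks: int
    reliable: bool = True


def weighted_mean_angle(angles, weights) -> tuple[float, float]:
    """Duration-weighted mean direction and resultant length.

    ``theta = atan2(sum w sin, sum w cos)`` in degrees wrapped to
    (-180, 180]; ``R = |resultant| / sum(w)``.  Raises when the resultant is
    numerically zero (antipodal balance leaves the mean undefined).
    """
    th = np.deg2rad(np.asarray(angles, dtype=float))
    w = np.asarray(weights, dtype=float)
    if th.shape != w.shape:
        raise ValueError("angles and weights must have equal length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    C = float(np.sum(w * np.cos(th)))
    S = float(np.sum(w * np.sin(th)))
    R = math.hypot(C, S) / float(np.sum(w))
    if R <= 1e-12:
        raise ValueError("resultant length ~ 0: mean direction undefined")
    return wrap_degrees(math.degrees(math.atan2(S, C))), R


def _kappa_from_R(R: float) -> float:
    """Solve A1(kappa) = I1/I0 (kappa) = R for the von Mises concentration."""
    if R <= 0.0:
        return 0.0
    if R >= 1.0 - 1e-12:
        return 1e8
    f = lambda k: special.i1e(k) / special.i0e(k) - R
    try:
        return float(optimize.brentq(f, 1e-12, 1e8, xtol=1e-12, rtol=1e-12))
    except ValueError:  # pragma: no cover - extreme R handled above
        return 1.0 / (2.0 * (1.0 - R))


def fit_vonmises_weighted(angles, weights) -> tuple[float, float]:
    """Weighted von Mises MLE: (mean direction in degrees, concentration).

    Durations act as frequency weights, so the mean direction is the
    duration-weighted mean angle and the concentration solves
    ``A1(kappa) = R`` with the weighted resultant length ``R``.
    """
    mu, R = weighted_mean_angle(angles, weights)
    return mu, _kappa_from_R(R)


def vonmises_bootstrap_ci(
    angles,
    weights,
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Parametric-bootstrap CI for the duration-weighted mean direction.

    Fits a von Mises distribution to the weighted sample, draws ``B``
    synthetic samples of the same size (paired with the original weights),
    recomputes the weighted mean angle of each, and returns the central
    percentile interval re-centred on the fitted direction.  A near-uniform
    fit (kappa below 1e-3) yields the whole circle.
    """
    if len(angles) < 2:
        raise ValueError("need at least 2 looks for a bootstrap CI")
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(f"B={B} is too small for a reliable CI", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, kappa = fit_vonmises_weighted(angles, weights)
    if kappa < _KAPPA_FLOOR:
        warnings.warn(
            "near-uniform orientation: CI spans the whole circle", stacklevel=2
        )
        return -180.0, 180.0
    w = np.asarray(weights, dtype=float)
    n = w.size
    th = rng.vonmises(math.radians(mu), kappa, size=(B, n))
    C = np.cos(th) @ w
    S = np.sin(th) @ w
    boot = np.degrees(np.arctan2(S, C))
    delta = wrap_degrees(boot - mu)
    alpha = 1.0 - level
    lo, hi = np.percentile(delta, [100 * alpha / 2.0, 100 * (1.0 - alpha / 2.0)])
    return wrap_degrees(mu + lo), wrap_degrees(mu + hi)


def _ci_contains(ci_low: float, ci_high: float, angle: float = 0.0) -> bool:
    """Containment of an angle in a circular interval given in (-180, 180]."""
    a = wrap_degrees(angle)
    if ci_low <= ci_high:
        return ci_low <= a <= ci_high
    return a >= ci_low or a <= ci_high  # interval wraps through 180


def classify_bias(
    ci_low: float, ci_high: float, mean_angle: float | None = None
) -> str:
    """Side-bias label from the bootstrap CI: none when 0 deg is inside.

    Otherwise the side is the sign of the mean angle (positive = right);
    when the mean sits essentially on the axis (|mean| ~ 180) the circular
    midpoint of the CI decides.
    """
    span = (ci_high - ci_low) % 360.0
    if span == 0.0 and ci_low != ci_high:
        warnings.warn("CI spans the full circle; no bias inferred", stacklevel=2)
        return "none"
    if ci_low == -180.0 and ci_high == 180.0:
        return "none"
    if _ci_contains(ci_low, ci_high, 0.0):
        return "none"
    ref = mean_angle
    if ref is None or abs(abs(ref) - 180.0) < 1e-9:
        ref = wrap_degrees(ci_low + span / 2.0)
    return "right" if ref > 0 else "left"


def exact_binomial_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Clopper-Pearson exact binomial interval: (p_hat, ci_low, ci_high)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == n else float(hi)
    return successes / n, lo, hi


def summarize_orientation(
    looks: Sequence[LookRecord],
    B: int = 2000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> OrientationSummary:
    """Full orientation summary of one focal observation."""
    if not looks:
        raise ValueError("no looks")
    angles = [lk.angle for lk in looks]
    weights = [lk.duration for lk in looks]
    mu, R = weighted_mean_angle(angles, weights)
    kappa = _kappa_from_R(R)
    reliable = B >= 100 and len(looks) >= 5
    if kappa < _KAPPA_FLOOR:
        lo, hi, bias = -180.0, 180.0, "none"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lo, hi = vonmises_bootstrap_ci(angles, weights, B=B, level=level, seed=seed)
        bias = classify_bias(lo, hi, mu)
    return OrientationSummary(
        obs_id=looks[0].obs_id,
        mean_angle=mu,
        resultant_length=R,
        kappa=kappa,
        ci_low=lo,
        ci_high=hi,
        bias=bias,
        n_looks=len(looks),
        reliable=reliable,
    )


def build_bias_table(
    summaries: Iterable[OrientationSummary],
    meta: Iterable[ObservationMeta],
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-status bias counts with the exact CI on the right-bias proportion.

    One row per status: counts of left-biased, unbiased and right-biased
    observations, the proportion right among the biased ones and its
    Clopper-Pearson interval (NaN with ``undefined=True`` when no observation
    of that status is biased).
    """
    status_of = {m.obs_id: m.status for m in meta}
    counts = {s: {"left": 0, "none": 0, "right": 0} for s in STATUS_LEVELS}
    for summ in summaries:
        if summ.obs_id not in status_of:
            raise KeyError(f"no metadata for observation {summ.obs_id}")
        status = status_of[summ.obs_id]
        if status not in counts:
            raise ValueError(f"unknown status {status!r}")
        counts[status][summ.bias] += 1
    rows = []
    for status in STATUS_LEVELS:
        c = counts[status]
        n_biased = c["left"] + c["right"]
        if n_biased > 0:
            p, lo, hi = exact_binomial_ci(c["right"], n_biased, level=level)
            undefined = False
        else:
            p = lo = hi = math.nan
            undefined = True
        rows.append(
            {
                "status": status,
                "bias_left": c["left"],
                "no_bias": c["none"],
                "bias_right": c["right"],
                "n": c["left"] + c["none"] + c["right"],
                "prop_right": p,
                "ci_low": lo,
                "ci_high": hi,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
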