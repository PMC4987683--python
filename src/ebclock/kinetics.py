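"""Impulse-model fitting and developmental-clock construction.

Each embryoid body (EB) carries a Brachyury-GFP reporter whose segmented
point count rises, peaks and declines over tens of hours. The count curve
is summarized by a five-parameter impulse model — the product of a rising
and a falling logistic:

    N(t) = A * L(beta1 * (t - t1)) * L(-beta2 * (t - t2)),   L(x) = 1/(1+e^-x)

where ``A`` is the peak point count, ``beta1``/``beta2`` the normalized
progression and recession rates (per hour) and ``t1``/``t2`` approximately
the half-peak times of onset and decline. Onset is read off the fitted
curve as the rising-flank crossing of a fixed point threshold (300 points
by default); developmental age (DevA) of an EB harvested at time ``h`` is
``h - onset``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ImpulseParams",
    "EBTimeSeries",
    "DevClock",
    "NoSignalError",
    "OnsetUndetectedError",
    "impulse_value",
    "fit_impulse",
    "detect_onset",
    "detect_peak",
    "dev_age",
    "cohort_timing_stats",
    "size_dependence",
]

DEFAULT_ONSET_THRESHOLD = 300.0


class NoSignalError(ValueError):
    """Raised when a series never reaches the onset threshold ("no signal")."""


class OnsetUndetectedError(ValueError):
    """Raised when DevA is requested for an EB without a detected onset."""


@dataclass(frozen=True)
class ImpulseParams:
    """Parameters of the double-logistic impulse curve.

    A : peak number of segmented GFP points (amplitude).
    beta1, beta2 : normalized progression / recession rates, 1/h.
    t1, t2 : approximate half-peak times of onset and decline, hours.
    """

    A: float
    beta1: float
    beta2: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        if not (self.A >= 0):
            raise ValueError(f"A must be >= 0, got {self.A}")
        if not (self.beta1 > 0 and self.beta2 > 0):
            raise ValueError("beta1 and beta2 must be positive")
        if not (self.t1 < self.t2):
            raise ValueError(f"t1 must precede t2 (got t1={self.t1}, t2={self.t2})")


@dataclass
class EBTimeSeries:
    """Time-stamped counts of filtered GFP segmentation points for one EB."""

    eb_id: str
    times: np.ndarray  # hours, strictly increasing
    counts: np.ndarray  # non-negative points
    radius_pre_onset: float | None = None  # µm, measured before onset

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValueError("times and counts must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class DevClock:
    """Per-EB event-timing summary: onset/peak from the fitted impulse curve."""

    eb_id: str
    fit: ImpulseParams
    rss: float
    threshold: float = DEFAULT_ONSET_THRESHOLD
    onset_time: float | None = None
    peak_time: float | None = None

    @property
    def onset_to_peak(self) -> float | None:
        if self.onset_time is None or self.peak_time is None:
            return None
        return self.peak_time - self.onset_time


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    # scipy.special.expit, inlined to keep impulse evaluation allocation-light
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def impulse_value(p: ImpulseParams, t: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the impulse curve N(t) = A·L(β1(t−t1))·L(−β2(t−t2)).

    Bounded by 0 ≤ N(t) ≤ A and vanishing at t → ±∞.
    """
    t = np.asarray(t, dtype=float)
    val = p.A * _logistic(p.beta1 * (t - p.t1)) * _logistic(-p.beta2 * (t - p.t2))
    return float(val) if val.ndim == 0 else val


def _impulse_raw(t: np.ndarray, A: float, b1: float, b2: float, t1: float, t2: float) -> np.ndarray:
    return A * _logistic(b1 * (t - t1)) * _logistic(-b2 * (t - t2))


def _init_params(times: np.ndarray, counts: np.ndarray) -> tuple[float, float, float, float, float]:
    """Heuristic start: A₀ = max count, t1₀/t2₀ from raw half-max crossings,
    β₀ = 4 / rise time (logistic slope matched to the observed rise)."""
    a0 = float(counts.max())
    half = a0 / 2.0
    above = counts >= half
    idx = np.nonzero(above)[0]
    i_first, i_last = int(idx[0]), int(idx[-1])
    t1_0 = float(times[i_first])
    t2_0 = float(times[i_last])
    i_peak = int(np.argmax(counts))
    rise = max(times[i_peak] - times[0], 1.0)
    b0 = min(max(4.0 / rise, 1e-2), 5.0)
    if t2_0 - t1_0 < 1.0:
        t2_0 = t1_0 + max(2.0, 2.0 * (times[1] - times[0]))
    return a0, b0, b0, t1_0, t2_0


def fit_impulse(
    s: EBTimeSeries,
    threshold: float = DEFAULT_ONSET_THRESHOLD,
    require_signal: bool = True,
) -> DevClock:
    """Least-squares fit of the impulse model to one EB count curve.

    Smooths measurement/processing noise before event detection; onset and
    peak are then read from the fitted curve. Series whose maximum count
    never reaches ``threshold`` carry no usable signal and are rejected
    (``NoSignalError``) unless ``require_signal`` is False.

    Raises
    ------
    ValueError : fewer than 8 frames.
    NoSignalError : max count below the onset threshold.
    RuntimeError : optimizer failed to converge.
    """
    times, counts = s.times, s.counts
    if times.size < 8:
        raise ValueError(f"need >= 8 frames to fit, got {times.size}")
    if require_signal and counts.max() < threshold:
        raise NoSignalError(
            f"EB {s.eb_id}: max count {counts.max():.0f} below threshold {threshold:.0f}"
        )

    a0, b1_0, b2_0, t1_0, t2_0 = _init_params(times, counts)
    x0 = np.array([a0, b1_0, b2_0, t1_0, t2_0])
    span = times[-1] - times[0]
    lower = np.array([0.0, 1e-3, 1e-3, times[0] - span, times[0] - span])
    upper = np.array([10.0 * max(a0, 1.0), 10.0, 10.0, times[-1] + span, times[-1] + 2 * span])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)

    def resid(x: np.ndarray) -> np.ndarray:
        return _impulse_raw(times, *x) - counts

    res = optimize.least_squares(resid, x0, bounds=(lower, upper), method="trf")
    if not res.success:
        raise RuntimeError(f"EB {s.eb_id}: impulse fit did not converge ({res.message})")
    A, b1, b2, t1, t2 = res.x
    if t1 >= t2:  # enforce parameter ordering; degenerate fits are flagged upstream
        t2 = t1 + 1e-6
    rss = float(np.sum(res.fun**2))
    rss0 = float(np.sum(resid(x0) ** 2))
    if rss > rss0 + 1e-9:  # optimizer must not worsen the start
        raise RuntimeError(f"EB {s.eb_id}: fit worse than initialization")
    params = ImpulseParams(float(A), float(b1), float(b2), float(t1), float(t2))
    clock = DevClock(eb_id=s.eb_id, fit=params, rss=rss, threshold=threshold)
    clock.peak_time = detect_peak(params)
    clock.onset_time = detect_onset(params, threshold)
    return clock


def detect_peak(p: ImpulseParams) -> float:
    """Time of maximal N(t), located numerically on [t1 − 5/β1, t2 + 5/β2].

    For β1 = β2 the curve is symmetric and the peak sits at (t1 + t2)/2;
    the peak time never depends on the amplitude prefactor A.
    """
    lo = p.t1 - 5.0 / p.beta1
    hi = p.t2 + 5.0 / p.beta2
    res = optimize.minimize_scalar(
        lambda t: -impulse_value(p, t), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def detect_onset(
    p: ImpulseParams, threshold: float = DEFAULT_ONSET_THRESHOLD
) -> float | None:
    """Rising-flank crossing N(t) = threshold, or None if the peak stays below.

    The crossing is bracketed between a time far before t1 (where N ≈ 0) and
    the peak, then solved by Brent's method; it is unique on the rising flank
    because N is increasing there.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t_peak = detect_peak(p)
    if impulse_value(p, t_peak) < threshold:
        return None
    lo = p.t1 - 60.0 / p.beta1
    while impulse_value(p, lo) >= threshold:  # pragma: no cover - pathological params
        lo -= 60.0 / p.beta1
    return float(optimize.brentq(lambda t: impulse_value(p, t) - threshold, lo, t_peak, xtol=1e-6))


def dev_age(onset: float | None, harvest: float) -> float:
    """Developmental age: lag between harvest time and Bry-GFP onset (hours).

    Negative values indicate a pre-onset harvest and are returned as-is (the
    caller flags them); an undetected onset is a distinct error condition.
    """
    if onset is None:
        raise OnsetUndetectedError("cannot compute DevA without a detected onset")
    return harvest - onset


def cohort_timing_stats(clocks: Sequence[DevClock]) -> dict:
    """Timing statistics over EBs with detected events.

    Returns onset mean/sd/range and onset-to-peak mean/sd, computed only over
    EBs where the respective event was detected (n_peak may trail n_onset:
    EBs harvested early never reach peak).
    """
    if not clocks:
        raise ValueError("empty cohort")
    onsets = np.array([c.onset_time for c in clocks if c.onset_time is not None])
    o2p = np.array([c.onset_to_peak for c in clocks if c.onset_to_peak is not None])
    if onsets.size == 0:
        raise ValueError("no EB in the cohort has a detected onset")
    return {
        "onset_mean": float(onsets.mean()),
        "onset_sd": float(onsets.std(ddof=1)) if onsets.size > 1 else 0.0,
        "onset_range": (float(onsets.min()), float(onsets.max())),
        "onset_to_peak_mean": float(o2p.mean()) if o2p.size else math.nan,
        "onset_to_peak_sd": float(o2p.std(ddof=1)) if o2p.size > 1 else 0.0,
        "n_onset": int(onsets.size),
        "n_peak": int(o2p.size),
    }


def size_dependence(values: Sequence[float], radii: Sequence[float]) -> dict:
    """Pearson correlation of a kinetic quantity against pre-onset EB radius.

    Used to ask whether onset time, slope or amplitude depend on EB size.
    Constant radii leave the correlation undefined and raise.
    """
    values = np.asarray(values, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if values.size != radii.size or values.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(radii) == 0:
        raise ValueError("radii are constant; correlation undefined")
    r, pval = stats.pearsonr(values, radii)
    return {"r": float(r), "p": float(pval)}
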