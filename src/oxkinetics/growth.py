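"""OD600 growth-curve analysis with stress-induced arrest.

A culture grows exponentially at rate ``lambda_pre`` (per hour) until an
oxidant is added at OD ``od_stress``; growth arrests immediately.  Sublethal
doses give a dose-dependent lag followed by full recovery at ``lambda_post``;
at the threshold dose the biomass plateaus for hours and then declines; above
it the biomass declines immediately.  :class:`GrowthPhaseModel` recovers the
two exponential rates, the lag duration and the recovery/decline
classification from a curve; the lag endpoint is operationalised as the first
*sustained* return of the instantaneous growth rate to >= 90% of the
pre-stress rate (three consecutive sliding windows).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import InconclusiveGrowthError, ValidationError

__all__ = [
    "GrowthCurve",
    "GrowthPhases",
    "GrowthPhaseModel",
    "simulate_growth",
    "instantaneous_growth_rate",
    "fit_exponential",
    "doubling_time",
    "rate_from_doubling",
    "detect_phases",
]

LN2 = math.log(2.0)


@dataclass
class GrowthCurve:
    """An OD600 time series, optionally annotated with the stress time."""

    times_min: np.ndarray
    od600: np.ndarray
    stress_time_min: Optional[float] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.times_min.size != self.od600.size:
            raise ValidationError("times_min and od600 must have equal length")
        if self.times_min.size < 10:
            raise ValidationError("a growth curve needs at least 10 points")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("times_min must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise ValidationError("od600 must be positive everywhere")

    def __len__(self) -> int:
        return int(self.times_min.size)

    @property
    def sampling_min(self) -> float:
        return float(np.median(np.diff(self.times_min)))


@dataclass
class GrowthPhases:
    """Phase decomposition of a stressed growth curve.

    ``lag_min`` and ``lambda_post`` are ``None`` when the culture never
    recovered; ``declining`` flags a sustained negative terminal slope.
    """

    lambda_pre: float
    lambda_post: Optional[float]
    lag_min: Optional[float]
    recovered: bool
    declining: bool
    resume_time_min: Optional[float] = None
    condition: str = ""

    def summary(self) -> str:
        fmt = lambda v, u: f"{v:.3f} {u}" if v is not None else "-"
        return "\n".join(
            [
                "Growth-phase analysis",
                "=" * 40,
                f"condition        : {self.condition or '-'}",
                f"lambda_pre [/h]  : {self.lambda_pre:.3f}",
                f"lambda_post [/h] : {fmt(self.lambda_post, '')}",
                f"lag [min]        : {fmt(self.lag_min, '')}",
                f"recovered        : {self.recovered}",
                f"declining        : {self.declining}",
            ]
        )


def doubling_time(rate: float) -> float:
    """Doubling time in minutes for a per-hour exponential rate."""
    if rate <= 0:
        raise ValidationError("rate must be positive")
    return 60.0 * LN2 / rate


def rate_from_doubling(td_min: float) -> float:
    """Per-hour exponential rate for a doubling time in minutes."""
    if td_min <= 0:
        raise ValidationError("doubling time must be positive")
    return 60.0 * LN2 / td_min


def simulate_growth(
    lambda_pre: float,
    od0: float = 0.02,
    od_stress: float = 0.2,
    lag_min: float = 38.0,
    lambda_post: float = 0.94,
    mode: str = "recovering",
    decline_params: Optional[dict] = None,
    total_min: Optional[float] = None,
    sampling_min: float = 2.0,
    noise_cv: float = 0.0,
    seed: Optional[int] = None,
    condition: str = "",
) -> GrowthCurve:
    """Simulate an OD600 curve with an abrupt stress-induced arrest.

    The culture grows at ``lambda_pre`` until the OD reaches ``od_stress``
    (the stress time, recorded on the returned curve).  Afterwards:

    - ``recovering``: flat for ``lag_min`` minutes, then exponential at
      ``lambda_post``;
    - ``plateau_then_decline``: flat for ``decline_params['plateau_min']``
      (default 180) then exponential decline at
      ``decline_params['decline_rate_per_h']`` (default 0.15/h);
    - ``immediate_decline``: exponential decline right after the stress.

    Noise is multiplicative lognormal with coefficient of variation
    ``noise_cv``.
    """
    if lambda_pre <= 0:
        raise ValidationError("lambda_pre must be positive")
    if od0 <= 0 or od_stress <= od0:
        raise ValidationError("need 0 < od0 < od_stress")
    if mode not in ("recovering", "plateau_then_decline", "immediate_decline"):
        raise ValidationError(f"unknown mode {mode!r}")
    if mode == "recovering":
        if lambda_post <= 0:
            raise ValidationError("lambda_post must be positive in recovering mode")
        if lag_min < 0:
            raise ValidationError("lag_min must be nonnegative")
    params = {"plateau_min": 180.0, "decline_rate_per_h": 0.15}
    if decline_params:
        params.update(decline_params)

    ts_min = 60.0 * math.log(od_stress / od0) / lambda_pre
    if total_min is None:
        if mode == "recovering":
            total_min = ts_min + lag_min + 120.0
        elif mode == "plateau_then_decline":
            total_min = ts_min + params["plateau_min"] + 120.0
        else:
            total_min = ts_min + 180.0
    times = np.arange(0.0, total_min + sampling_min / 2, sampling_min)

    t_h = times / 60.0
    ts_h = ts_min / 60.0
    od = np.empty_like(t_h)
    pre = t_h <= ts_h
    od[pre] = od0 * np.exp(lambda_pre * t_h[pre])
    post = ~pre
    dt_h = t_h[post] - ts_h
    if mode == "recovering":
        lag_h = lag_min / 60.0
        od[post] = np.where(
            dt_h <= lag_h,
            od_stress,
            od_stress * np.exp(lambda_post * np.clip(dt_h - lag_h, 0.0, None)),
        )
    elif mode == "plateau_then_decline":
        plat_h = params["plateau_min"] / 60.0
        rate = params["decline_rate_per_h"]
        od[post] = np.where(
            dt_h <= plat_h,
            od_stress,
            od_stress * np.exp(-rate * np.clip(dt_h - plat_h, 0.0, None)),
        )
    else:  # immediate_decline
        od[post] = od_stress * np.exp(-params["decline_rate_per_h"] * dt_h)

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        od = od * rng.lognormal(-sigma**2 / 2.0, sigma, size=od.size)
    return GrowthCurve(times, od, stress_time_min=ts_min, condition=condition)


def instantaneous_growth_rate(curve: GrowthCurve, window_points: int = 5) -> np.ndarray:
    """Sliding-window instantaneous growth rate, per hour.

    Centered OLS slope of ln(OD) versus time over ``window_points`` samples;
    edge windows are truncated so the result has the curve's length.
    """
    if window_points < 3:
        raise ValidationError("window_points must be >= 3")
    t_h = curve.times_min / 60.0
    ln_od = np.log(curve.od600)
    n = len(curve)
    half = window_points // 2
    rates = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        x = t_h[lo:hi]
        y = ln_od[lo:hi]
        xm = x - x.mean()
        rates[i] = float(xm @ (y - y.mean()) / (xm @ xm))
    return rates


def fit_exponential(curve: GrowthCurve, t_start_min: float, t_end_min: float) -> float:
    """OLS exponential rate (per hour) of ln(OD) over a time window."""
    mask = (curve.times_min >= t_start_min) & (curve.times_min <= t_end_min)
    if mask.sum() < 4:
        raise ValidationError("fit window must contain at least 4 points")
    res = stats.linregress(curve.times_min[mask] / 60.0, np.log(curve.od600[mask]))
    return float(res.slope)


class GrowthPhaseModel:
    """Decompose a stressed growth curve into pre/lag/post phases.

    The lag ends at the first time the instantaneous rate reaches and
    sustains at least ``rate_fraction_threshold * lambda_pre`` for
    ``sustain_windows`` consecutive windows; the sliding-window centre lag is
    corrected by half a window so the reported resume time aligns with the
    kink in ln(OD).  A sustained terminal rate below ``-decline_eps`` flags a
    declining culture.
    """

    def __init__(
        self,
        curve: GrowthCurve,
        stress_time_min: Optional[float] = None,
        rate_fraction_threshold: float = 0.9,
        window_points: int = 5,
        sustain_windows: int = 3,
        decline_eps: float = 0.02,
    ) -> None:
        if stress_time_min is None:
            stress_time_min = curve.stress_time_min
        if stress_time_min is None:
            raise ValidationError("stress_time_min is required (curve carries none)")
        if not (curve.times_min[0] <= stress_time_min <= curve.times_min[-1]):
            raise ValidationError("stress_time_min must lie inside the curve span")
        if not (0 < rate_fraction_threshold <= 1):
            raise ValidationError("rate_fraction_threshold must be in (0, 1]")
        self.curve = curve
        self.stress_time_min = float(stress_time_min)
        self.rate_fraction_threshold = rate_fraction_threshold
        self.window_points = window_points
        self.sustain_windows = sustain_windows
        self.decline_eps = decline_eps

    def fit(self) -> GrowthPhases:
        curve = self.curve
        ts = self.stress_time_min
        t = curve.times_min
        pre_mask = t < ts
        if pre_mask.sum() < 4:
            raise ValidationError("pre-stress window must contain at least 4 points")
        lambda_pre = fit_exponential(curve, t[0], t[pre_mask][-1])

        post_idx = np.nonzero(t > ts)[0]
        if post_idx.size < self.window_points + self.sustain_windows:
            raise InconclusiveGrowthError(
                "curve ends too soon after the stress to classify recovery"
            )
        rates = instantaneous_growth_rate(curve, self.window_points)
        threshold = self.rate_fraction_threshold * lambda_pre

        above = rates >= threshold
        resume_idx: Optional[int] = None
        for i in post_idx:
            j = min(i + self.sustain_windows, len(curve))
            if j - i >= self.sustain_windows and above[i:j].all():
                resume_idx = int(i)
                break

        half_lag = (self.window_points // 2) * curve.sampling_min
        if resume_idx is not None:
            resume_time = max(ts, t[resume_idx] - half_lag)
            lag = resume_time - ts
            post_mask = t >= resume_time
            if post_mask.sum() >= 4:
                lambda_post = fit_exponential(curve, resume_time, t[-1])
            else:
                lambda_post = float(rates[post_mask].mean())
            return GrowthPhases(
                lambda_pre=lambda_pre,
                lambda_post=lambda_post,
                lag_min=float(lag),
                recovered=True,
                declining=False,
                resume_time_min=float(resume_time),
                condition=curve.condition,
            )

        terminal = rates[-self.sustain_windows:]
        declining = bool(np.all(terminal < -self.decline_eps))
        return GrowthPhases(
            lambda_pre=lambda_pre,
            lambda_post=None,
            lag_min=None,
            recovered=False,
            declining=declining,
            condition=curve.condition,
        )


def detect_phases(
    curve: GrowthCurve,
    stress_time_min: Optional[float] = None,
    rate_fraction_threshold: float = 0.9,
    window_points: int = 5,
) -> GrowthPhases:
    """Functional wrapper over :class:`GrowthPhaseModel`."""
    return GrowthPhaseModel(
        curve,
        stress_time_min=stress_time_min,
        rate_fraction_threshold=rate_fraction_threshold,
        window_points=window_points,
    ).fit()
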