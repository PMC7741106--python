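"""Growth-rate estimators: point formula, log-linear exponential fits and
trough-to-peak segment rates.

All rates are continuous per-year rates r; ``rate_percent`` is 100*r and the
annualized alternative 100*(exp(r)-1) is exposed separately.  On cal BP time
axes forward time means decreasing cal BP: a positive rate is growth toward
the present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "GrowthRateEstimate",
    "point_growth_rate",
    "time_to_size",
    "fit_exponential",
    "segment_growth_rates",
]


@dataclass(frozen=True)
class GrowthRateEstimate:
    rate: float
    interval: tuple[float, float]
    method: str
    n_points: int = 2
    rss: float = 0.0
    n_excluded: int = 0
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.rate):
            raise ValueError("rate must be finite")
        if self.interval[0] == self.interval[1]:
            raise ValueError("interval must be non-degenerate")

    @property
    def rate_percent(self) -> float:
        """Printed '%/yr' convention: 100 * continuous rate."""
        return 100.0 * self.rate

    @property
    def annualized_percent(self) -> float:
        """Alternative convention: 100 * (exp(r) - 1)."""
        return 100.0 * (np.exp(self.rate) - 1.0)

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "rate_percent": self.rate_percent,
            "annualized_percent": self.annualized_percent,
            "interval": list(self.interval),
            "method": self.method,
            "n_points": self.n_points,
            "rss": self.rss,
            "n_excluded": self.n_excluded,
        }


def point_growth_rate(n0: float, nt: float, t_years: float) -> GrowthRateEstimate:
    """r = ln(nt / n0) / t for two census points t years apart."""
    if n0 <= 0 or nt <= 0:
        raise ValueError(f"population sizes must be > 0 (got n0={n0}, nt={nt})")
    if t_years <= 0:
        raise ValueError(f"time span must be > 0 years, got {t_years}")
    rate = float(np.log(nt / n0) / t_years)
    return GrowthRateEstimate(rate, (0.0, float(t_years)), "point_formula")


def time_to_size(n0: float, target: float, rate: float) -> float:
    """Years for a population of n0 to reach target at continuous rate r."""
    if n0 <= 0:
        raise ValueError(f"n0 must be > 0, got {n0}")
    if target < n0:
        raise ValueError("target must be >= n0")
    if target == n0:
        return 0.0
    if rate <= 0:
        raise ValueError(f"rate must be > 0 to reach a larger target, got {rate}")
    return float(np.log(target / n0) / rate)


def _forward_time(time: np.ndarray, bp: bool | None) -> tuple[np.ndarray, bool]:
    """Return a forward-running time axis (years toward the present)."""
    time = np.asarray(time, dtype=float)
    if bp is None:
        bp = bool(time.size > 1 and time[0] > time[-1])
    return (-time if bp else time), bp


def fit_exponential(
    time: np.ndarray,
    values: np.ndarray,
    interval: tuple[float, float] | None = None,
    bp: bool | None = None,
) -> GrowthRateEstimate:
    """OLS of ln(value) on forward time; the slope is the growth rate.

    Zero or negative values are excluded (and counted), never floored.
    ``interval`` restricts the fit, given on the original time axis as
    (start, end) with start older than end when the axis is cal BP.
    If ``bp`` is None a decreasing time axis is treated as cal BP.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.shape != values.shape:
        raise ValueError("time and values must have equal length")
    if interval is not None:
        lo, hi = min(interval), max(interval)
        mask = (time >= lo) & (time <= hi)
        time, values = time[mask], values[mask]
    t_fwd, is_bp = _forward_time(time, bp)
    usable = values > 0
    n_excluded = int(np.sum(~usable))
    t_use, v_use = t_fwd[usable], values[usable]
    if t_use.size < 3:
        raise ValueError(
            f"need at least 3 positive points to fit, got {t_use.size} "
            f"({n_excluded} excluded as non-positive)"
        )
    slope, intercept = np.polyfit(t_use, np.log(v_use), 1)
    resid = np.log(v_use) - (slope * t_use + intercept)
    lo, hi = float(time.min()), float(time.max())
    return GrowthRateEstimate(
        float(slope),
        (hi, lo) if is_bp else (lo, hi),
        "exponential_fit",
        n_points=int(t_use.size),
        rss=float(np.sum(resid**2)),
        n_excluded=n_excluded,
        diagnostics={"intercept": float(intercept)},
    )


def segment_growth_rates(
    time: np.ndarray,
    values: np.ndarray,
    prominence: float = 0.1,
    bp: bool | None = None,
) -> list[GrowthRateEstimate]:
    """Trough-to-peak growth rates of a cyclic series.

    Local extrema are detected with prominence ``prominence`` * (max - min);
    each trough is paired with the next peak and the rate is
    ln(peak / trough) / span.  A series with no interior extrema that ends
    higher than it starts is treated as a single whole-series growth phase;
    a constant series yields an empty list.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if time.shape != values.shape:
        raise ValueError("time and values must have equal length")
    if time.size < 3:
        raise ValueError("series must have at least 3 points")
    t_fwd, _ = _forward_time(time, bp)
    order = np.argsort(t_fwd)
    t_fwd, values, time = t_fwd[order], values[order], time[order]
    amplitude = float(values.max() - values.min())
    if amplitude <= 0:
        return []
    prom = prominence * amplitude
    peaks, _ = find_peaks(values, prominence=prom)
    troughs, _ = find_peaks(-values, prominence=prom)
    out: list[GrowthRateEstimate] = []
    if peaks.size == 0 and troughs.size == 0:
        if values[-1] > values[0] and values[0] > 0:
            est = point_growth_rate(values[0], values[-1], t_fwd[-1] - t_fwd[0])
            out.append(
                GrowthRateEstimate(
                    est.rate, (float(time[0]), float(time[-1])), "segment"
                )
            )
        return out
    for t0 in troughs:
        later = peaks[peaks > t0]
        if later.size == 0:
            continue
        t1 = int(later[0])
        if values[t0] <= 0:
            continue
        span = t_fwd[t1] - t_fwd[t0]
        rate = float(np.log(values[t1] / values[t0]) / span)
        out.append(
            GrowthRateEstimate(
                rate,
                (float(time[t0]), float(time[t1])),
                "segment",
                n_points=int(t1 - t0 + 1),
            )
        )
    return out
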