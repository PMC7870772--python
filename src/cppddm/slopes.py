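"""Regression-window selection and ramp-slope covariate extraction.

The group-level regression windows are derived from the grand-average
component waveform with the mid-latency procedure: the peak latency is
summarised as the mean of the two latencies at which the waveform crosses
90% of the peak amplitude on either side (robust to broad or asymmetric
peaks).  For the centro-parietal component the window ends at the
mid-latency and starts where the waveform last crosses 30% of the
waveform's amplitude at that mid-latency; for the biphasic component the
window runs between the mid-latencies of the negative and positive peaks.
Per-participant slopes are ordinary least-squares fits of the average
waveform over the group window, in microvolts per second, and enter the
hierarchical model z-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RegressionWindow",
    "mid_latency",
    "window_component1",
    "window_component2",
    "participant_slope",
    "smooth_waveform",
    "zstandardize",
    "covariate_table",
]


@dataclass(frozen=True)
class RegressionWindow:
    start_ms: float
    end_ms: float
    component: int
    group: str = ""
    provenance: dict = None

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(f"window start {self.start_ms} must precede end {self.end_ms}")


def _interp_crossing(t0, y0, t1, y1, level):
    """Latency where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _crossing_before(time_ms, wave, idx, level, direction):
    """Scan outward from sample ``idx`` for the nearest crossing of
    ``level``; direction -1 scans left, +1 scans right.  Returns the
    interpolated latency or None."""
    i = idx
    while 0 <= i + direction < len(wave):
        j = i + direction
        yi, yj = wave[i], wave[j]
        if np.isnan(yi) or np.isnan(yj):
            return None
        if (yi - level) * (yj - level) <= 0 and yi != yj:
            lo, hi = (j, i) if direction < 0 else (i, j)
            return _interp_crossing(time_ms[lo], wave[lo], time_ms[hi], wave[hi], level)
        i = j
    return None


def mid_latency(
    time_ms: np.ndarray,
    waveform: np.ndarray,
    polarity: str = "positive",
    search_window_ms: tuple | None = None,
):
    """Mid-latency of a peak: mean of the two 90%-amplitude crossing
    latencies either side of the extremum (linear interpolation between
    samples).  Returns (latency_ms, peak_amplitude).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    wave = np.asarray(waveform, dtype=float)
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be 'positive' or 'negative', got {polarity!r}")
    sel = np.ones_like(time_ms, dtype=bool)
    if search_window_ms is not None:
        sel = (time_ms >= search_window_ms[0]) & (time_ms <= search_window_ms[1])
    idx_sel = np.nonzero(sel)[0]
    w = wave[idx_sel]
    if np.all(~np.isfinite(w)) or np.nanmax(w) == np.nanmin(w):
        raise ValueError("waveform is flat or empty in the search window")
    if polarity == "positive":
        pk = idx_sel[int(np.nanargmax(w))]
        if wave[pk] <= 0:
            raise ValueError("no positive extremum in the search window")
    else:
        pk = idx_sel[int(np.nanargmin(w))]
        if wave[pk] >= 0:
            raise ValueError("no negative extremum in the search window")
    level = 0.9 * wave[pk]
    left = _crossing_before(time_ms, wave, pk, level, -1)
    right = _crossing_before(time_ms, wave, pk, level, +1)
    if left is None:
        raise ValueError("no 90%-amplitude crossing on the left of the peak")
    if right is None:
        raise ValueError("no 90%-amplitude crossing on the right of the peak")
    return 0.5 * (left + right), float(wave[pk])


def _value_at(time_ms, wave, t):
    return float(np.interp(t, time_ms, wave))


def window_component1(
    time_ms: np.ndarray, grand_avg: np.ndarray, group: str = ""
) -> RegressionWindow:
    """Window for the centro-parietal ramp component.

    End = mid-latency of the positive peak; start = the latest pre-end
    crossing of 30% of the waveform's amplitude at the mid-latency.
    Thresholds are relative, so any positive rescaling of the waveform
    leaves the window unchanged.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    wave = np.asarray(grand_avg, dtype=float)
    end, peak_amp = mid_latency(time_ms, wave, "positive")
    amp_end = _value_at(time_ms, wave, end)
    level = 0.3 * amp_end
    # scan left from the sample at/just before `end` for the latest crossing
    idx = int(np.searchsorted(time_ms, end))
    idx = min(idx, len(time_ms) - 1)
    start = _crossing_before(time_ms, wave, idx, level, -1)
    if start is None or start >= end:
        raise ValueError("no 30%-amplitude crossing before the window end")
    return RegressionWindow(
        start_ms=float(start),
        end_ms=float(end),
        component=1,
        group=group,
        provenance={"peak_amplitude": peak_amp, "mid_latency_amplitude": amp_end},
    )


def window_component2(
    time_ms: np.ndarray,
    grand_avg: np.ndarray,
    group: str = "",
    search_window_ms: tuple = (-600.0, 100.0),
) -> RegressionWindow:
    """Window for the biphasic component: between the mid-latencies of the
    negative and the positive peak found inside ``search_window_ms``."""
    time_ms = np.asarray(time_ms, dtype=float)
    wave = np.asarray(grand_avg, dtype=float)
    start, neg_amp = mid_latency(time_ms, wave, "negative", search_window_ms)
    end, pos_amp = mid_latency(time_ms, wave, "positive", search_window_ms)
    if not start < end:
        raise ValueError(
            f"negative peak (mid-latency {start:.1f} ms) must precede the "
            f"positive peak ({end:.1f} ms)"
        )
    return RegressionWindow(
        start_ms=float(start),
        end_ms=float(end),
        component=2,
        group=group,
        provenance={"negative_peak": neg_amp, "positive_peak": pos_amp},
    )


def participant_slope(
    time_ms: np.ndarray, waveform: np.ndarray, window: RegressionWindow
) -> float:
    """OLS slope (microvolt/s) of the average waveform over the window.

    NaN samples are dropped; fewer than 3 valid samples give NaN (the
    participant is flagged by the caller).
    """
    time_ms = np.asarray(time_ms, dtype=float)
    wave = np.asarray(waveform, dtype=float)
    sel = (time_ms >= window.start_ms) & (time_ms <= window.end_ms) & np.isfinite(wave)
    if sel.sum() < 3:
        return float("nan")
    t_s = time_ms[sel] / 1000.0
    slope = np.polyfit(t_s, wave[sel], 1)[0]
    return float(slope)


def smooth_waveform(time_ms: np.ndarray, waveform: np.ndarray, fwhm_ms: float = 20.0) -> np.ndarray:
    """Gaussian smoothing of a waveform for peak finding on noisy
    grand averages (small scaled-down cohorts); peak detection on clean or
    hand-built waveforms should use the raw trace."""
    dt = float(np.mean(np.diff(time_ms)))
    sigma = fwhm_ms / 2.355 / dt
    half = int(np.ceil(4 * sigma))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    k /= k.sum()
    pad = np.concatenate([np.full(half, waveform[0]), waveform, np.full(half, waveform[-1])])
    return np.convolve(pad, k, mode="valid")


def zstandardize(values) -> np.ndarray:
    """Z-score with the n-1 denominator; errors on (near-)zero variance."""
    x = np.asarray(values, dtype=float)
    if np.sum(np.isfinite(x)) < 2 or np.nanstd(x) == 0:
        raise ValueError("need at least 2 distinct finite values to standardize")
    return (x - np.nanmean(x)) / np.nanstd(x, ddof=1)


def covariate_table(
    participant_ids,
    ages,
    slopes_c1,
    slopes_c2,
) -> pd.DataFrame:
    """Assemble the model covariate table with z-standardized columns
    (age, eeg1, eeg2) alongside the raw values."""
    df = pd.DataFrame(
        {
            "participant_id": participant_ids,
            "age_years": ages,
            "slope_c1": slopes_c1,
            "slope_c2": slopes_c2,
        }
    )
    df["age"] = zstandardize(df["age_years"])
    df["eeg1"] = zstandardize(df["slope_c1"])
    df["eeg2"] = zstandardize(df["slope_c2"])
    return df
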