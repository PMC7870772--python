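"""EEG cleaning pipeline for epoched data.

Each operation takes and returns an :class:`~cppddm.epochs.EEGEpochArray`
(never mutating its input) and the stages run in a fixed order mirroring
a conventional high-density recipe: DC median correction, outlier
electrode detection and neighbour interpolation, EOG regression, per-trial
re-thresholding, transient censoring, average reference, baseline, and
bad-trial rejection.  Missing data are NaN throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .epochs import EEGEpochArray

__all__ = [
    "dc_median_correct",
    "flag_outlier_electrodes",
    "interpolate_electrodes",
    "regress_out_eog",
    "censor_transients",
    "rereference_and_baseline",
    "drop_bad_trials",
    "epoch_response_locked",
    "preprocess_pipeline",
]


def read_raw_recording(path, fmt: str = "mff"):
    """Reader for vendor EEG recordings (EGI/MFF, EDF): deferred.

    This analysis operates on epoched HDF5 containers
    (:meth:`~cppddm.epochs.EEGEpochArray.from_hdf5`); converting a raw
    continuous recording requires vendor I/O and event parsing that are
    out of scope here.  Convert externally (e.g. with MNE) and export to
    the documented HDF5 layout.
    """
    raise NotImplementedError(
        f"raw {fmt!r} reading is not implemented; epoch externally and use "
        "EEGEpochArray.from_hdf5"
    )


def dc_median_correct(epochs: EEGEpochArray) -> EEGEpochArray:
    """Subtract each trial x electrode median over time (DC offset)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN traces stay NaN
        med = np.nanmedian(epochs.data, axis=2, keepdims=True)
    med = np.where(np.isnan(med), 0.0, med)
    return epochs.copy_with(epochs.data - med)


def flag_outlier_electrodes(
    epochs: EEGEpochArray,
    pct: float = 97.5,
    max_bad_fraction: float = 0.15,
    scope: str = "session",
) -> np.ndarray:
    """Mark electrodes with too many extreme samples.

    The amplitude threshold is the ``pct`` percentile of |amplitude|
    pooled over all trials, electrodes and samples; an electrode is bad
    when >= ``max_bad_fraction`` of its samples (within the scope) exceed
    that threshold.  Returns a boolean mask: (electrodes,) for scope
    'session', (trials, electrodes) for scope 'trial'.
    """
    if scope not in ("session", "trial"):
        raise ValueError(f"scope must be 'session' or 'trial', got {scope!r}")
    absx = np.abs(epochs.data)
    thr = np.nanpercentile(absx, pct)
    exceed = absx > thr
    with np.errstate(invalid="ignore"):
        if scope == "session":
            frac = np.nansum(exceed, axis=(0, 2)) / np.maximum(
                np.sum(~np.isnan(absx), axis=(0, 2)), 1
            )
        else:
            frac = np.nansum(exceed, axis=2) / np.maximum(np.sum(~np.isnan(absx), axis=2), 1)
    return frac >= max_bad_fraction


def interpolate_electrodes(epochs: EEGEpochArray, mask: np.ndarray) -> EEGEpochArray:
    """Replace bad electrodes with the mean of their good neighbours.

    ``mask`` is (electrodes,) or (trials, electrodes).  The montage
    adjacency supplies the 6 (interior) / 4 (perimeter) nearest
    neighbours; neighbours that are themselves bad or missing are skipped.
    An electrode whose neighbours are all bad is set missing with a
    warning.
    """
    data = epochs.data.copy()
    mask = np.atleast_2d(mask)
    if mask.shape[0] == 1:
        mask = np.broadcast_to(mask, (epochs.n_trials, epochs.n_electrodes))
    for t in range(epochs.n_trials):
        bad = np.nonzero(mask[t])[0]
        src = epochs.data[t]
        for e in bad:
            good = [n for n in epochs.neighbours[e] if not mask[t, n]]
            if not good:
                data[t, e] = np.nan
                warnings.warn(f"trial {t}: all neighbours of electrode {e} bad; set missing")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                data[t, e] = np.nanmean(src[good, :], axis=0)
    return epochs.copy_with(data)


def regress_out_eog(
    epochs: EEGEpochArray, heog: np.ndarray, veog: np.ndarray
) -> EEGEpochArray:
    """OLS-remove horizontal and vertical EOG from every electrode.

    ``heog``/``veog`` are (trials, samples) traces time-aligned with the
    epochs.  Coefficients are estimated per electrode across all
    concatenated samples; the residual (plus intercept removal) is
    returned.  Near-collinear EOG channels degenerate to a single
    regressor with a warning.
    """
    h = np.asarray(heog, dtype=float).ravel()
    v = np.asarray(veog, dtype=float).ravel()
    n = epochs.n_trials * epochs.n_samples
    if h.size != n or v.size != n:
        raise ValueError("EOG traces must match trials x samples")
    X = np.column_stack([np.ones(n), h, v])
    hc = h - h.mean()
    vc = v - v.mean()
    denom = np.linalg.norm(hc) * np.linalg.norm(vc)
    if denom == 0 or abs(hc @ vc) / denom > 1 - 1e-10:
        warnings.warn("HEOG and VEOG are collinear; dropping VEOG")
        X = X[:, :2]
    data = epochs.data.reshape(epochs.n_trials, epochs.n_electrodes, -1)
    out = data.copy()
    flat = data.transpose(1, 0, 2).reshape(epochs.n_electrodes, n)
    for e in range(epochs.n_electrodes):
        y = flat[e]
        ok = ~np.isnan(y)
        if ok.sum() < X.shape[1]:
            continue
        coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
        resid = y - X @ coef
        out[:, e, :] = resid.reshape(epochs.n_trials, epochs.n_samples)
    out[np.isnan(epochs.data)] = np.nan
    return epochs.copy_with(out)


def censor_transients(epochs: EEGEpochArray, k_sd: float = 4.0) -> EEGEpochArray:
    """Set samples >= ``k_sd`` standard deviations from the electrode's
    mean to missing.  Zero-SD electrodes are left untouched."""
    data = epochs.data.copy()
    if not np.isfinite(k_sd):
        return epochs.copy_with(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(epochs.data, axis=(0, 2), keepdims=True)
        sd = np.nanstd(epochs.data, axis=(0, 2), keepdims=True)
    with np.errstate(invalid="ignore"):
        bad = (np.abs(epochs.data - mean) >= k_sd * sd) & (sd > 0)
    data[bad] = np.nan
    return epochs.copy_with(data)


def rereference_and_baseline(
    epochs: EEGEpochArray, baseline_window_ms: tuple | None = None
) -> EEGEpochArray:
    """Average-reference every sample, then subtract the per-trace mean
    over the baseline window.

    With no window given the first 100 ms of the epoch are used (the
    stand-in for a pre-evidence baseline when the data are purely
    response-locked).  Trials whose baseline window is fully missing on an
    electrode keep NaN there.
    """
    data = epochs.data.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ref = np.nanmean(data, axis=1, keepdims=True)  # over good electrodes
    data = data - np.where(np.isnan(ref), 0.0, ref)
    if baseline_window_ms is None:
        baseline_window_ms = (epochs.time_ms[0], epochs.time_ms[0] + 100.0)
    lo, hi = baseline_window_ms
    if lo < epochs.time_ms[0] - 1e-9 or hi > epochs.time_ms[-1] + 1e-9:
        raise ValueError("baseline window outside epoch")
    sel = (epochs.time_ms >= lo) & (epochs.time_ms <= hi)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(data[:, :, sel], axis=2, keepdims=True)
    data = data - np.where(np.isnan(base), 0.0, base)
    return epochs.copy_with(data)


def drop_bad_trials(epochs: EEGEpochArray, max_bad_electrodes: int = 19):
    """Drop trials in which >= ``max_bad_electrodes`` electrodes are
    missing (an electrode counts as bad in a trial when more than half its
    samples are NaN).  Returns (epochs, report)."""
    nan_frac = np.mean(np.isnan(epochs.data), axis=2)
    bad_counts = (nan_frac > 0.5).sum(axis=1)
    keep = bad_counts < max_bad_electrodes
    report = pd.DataFrame(
        {
            "trial_index": epochs.trial_index,
            "n_bad_electrodes": bad_counts,
            "kept": keep,
        }
    )
    out = epochs.copy_with(epochs.data[keep], trial_index=epochs.trial_index[keep])
    return out, report


def epoch_response_locked(
    stimulus_epochs: EEGEpochArray,
    rts_s: np.ndarray,
    window_ms: tuple = (-600.0, 198.0),
) -> EEGEpochArray:
    """Re-epoch stimulus-locked data around each trial's response.

    The stimulus-locked time axis must start at (or before) 0 = stimulus
    onset.  Trials whose response window does not fit inside the recording
    are dropped with a warning and noted in ``attrs``.
    """
    rts_s = np.asarray(rts_s, dtype=float)
    if rts_s.shape[0] != stimulus_epochs.n_trials:
        raise ValueError("need one RT per trial")
    fs = stimulus_epochs.sample_rate
    dt_ms = 1000.0 / fs
    lo, hi = window_ms
    n_out = int(round((hi - lo) / dt_ms)) + 1
    time_out = lo + dt_ms * np.arange(n_out)

    t0 = stimulus_epochs.time_ms[0]
    keep, slices = [], []
    for i, rt in enumerate(rts_s):
        resp_idx = int(round((rt * 1000.0 - t0) / dt_ms))
        start = resp_idx + int(round(lo / dt_ms))
        stop = start + n_out
        if start < 0 or stop > stimulus_epochs.n_samples:
            continue
        keep.append(i)
        slices.append((start, stop))
    n_dropped = stimulus_epochs.n_trials - len(keep)
    if n_dropped:
        warnings.warn(f"{n_dropped} trials dropped: response window outside recording")
    data = np.stack(
        [stimulus_epochs.data[i, :, a:b] for i, (a, b) in zip(keep, slices)], axis=0
    ) if keep else np.empty((0, stimulus_epochs.n_electrodes, n_out))
    return EEGEpochArray(
        data=data,
        time_ms=time_out,
        channel_names=stimulus_epochs.channel_names,
        neighbours=stimulus_epochs.neighbours,
        sample_rate=fs,
        trial_index=stimulus_epochs.trial_index[keep],
    )


def preprocess_pipeline(
    epochs: EEGEpochArray,
    heog: np.ndarray | None = None,
    veog: np.ndarray | None = None,
    pct: float = 97.5,
    max_bad_fraction: float = 0.15,
    k_sd: float = 4.0,
    max_bad_electrodes: int = 19,
    baseline_window_ms: tuple | None = None,
):
    """Run the full cleaning recipe in the standard order.

    Returns (cleaned epochs, trial report).  EOG regression is skipped
    when no EOG traces are supplied (synthetic data without ocular
    artefacts).
    """
    out = dc_median_correct(epochs)
    mask = flag_outlier_electrodes(out, pct=pct, max_bad_fraction=max_bad_fraction)
    if mask.any():
        out = interpolate_electrodes(out, mask)
    if heog is not None and veog is not None:
        out = regress_out_eog(out, heog, veog)
    # second, per-trial pass: recompute the percentile and remove (set
    # missing, not interpolate) electrodes that misbehave within a trial
    trial_mask = flag_outlier_electrodes(
        out, pct=pct, max_bad_fraction=max_bad_fraction, scope="trial"
    )
    if trial_mask.any():
        data = out.data.copy()
        data[trial_mask] = np.nan
        out = out.copy_with(data)
    out = censor_transients(out, k_sd=k_sd)
    out = rereference_and_baseline(out, baseline_window_ms=baseline_window_ms)
    return drop_bad_trials(out, max_bad_electrodes=max_bad_electrodes)
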