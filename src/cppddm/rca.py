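"""Reliable components analysis.

RCA finds electrode weightings w that maximise trial-to-trial
reliability: the ratio of the across-trial cross-covariance to the
within-trial covariance,

    rho = (w' R_xy w) / (w' R_xx w),

where R_xy averages the cross-covariance over all ordered pairs of
distinct trials and R_xx pools the within-trial covariance.  The pair
average is computed in O(trials) via the identity

    sum_{i != j} X_i X_j' = S S' - sum_i X_i X_i',     S = sum_i X_i,

after per-trial demeaning over time.  The generalised eigenproblem
R_xy w = rho R_xx w is solved in a reduced principal-component basis of
R_xx for numerical stability, and weights are made interpretable through
the forward-model projection A = R_xx W (W' R_xx W)^-1, whose columns are
the scalp topographies of the recovered components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import EEGEpochArray

__all__ = [
    "RCADecomposition",
    "fit_rca",
    "project_components",
    "forward_model",
    "save_decomposition",
    "load_decomposition",
]


@dataclass
class RCADecomposition:
    weights: np.ndarray  # electrodes x components
    forward_model: np.ndarray  # electrodes x components
    reliability: np.ndarray  # per-component generalised eigenvalue
    explained_reliability_fraction: np.ndarray
    rank_used: int
    pooled_covariance: np.ndarray  # R_xx


def save_decomposition(dec: "RCADecomposition", path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=dec.weights)
        f.create_dataset("forward_model", data=dec.forward_model)
        f.create_dataset("reliability", data=dec.reliability)
        f.create_dataset("explained_reliability_fraction",
                         data=dec.explained_reliability_fraction)
        f.create_dataset("pooled_covariance", data=dec.pooled_covariance)
        f.attrs["rank_used"] = dec.rank_used


def load_decomposition(path) -> "RCADecomposition":
    import h5py

    with h5py.File(path, "r") as f:
        return RCADecomposition(
            weights=f["weights"][...],
            forward_model=f["forward_model"][...],
            reliability=f["reliability"][...],
            explained_reliability_fraction=f["explained_reliability_fraction"][...],
            rank_used=int(f.attrs["rank_used"]),
            pooled_covariance=f["pooled_covariance"][...],
        )


def _trial_covariances(data: np.ndarray):
    """(R_xx, R_xy, effective n) from trials x electrodes x samples data.

    Missing samples are handled pairwise-complete per trial: each trial is
    demeaned over its valid samples and NaNs contribute zero to the cross
    products, with normalisation by the valid-pair counts.
    """
    n_trials, n_el, n_samp = data.shape
    valid = ~np.isnan(data)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        demeaned = data - np.nanmean(data, axis=2, keepdims=True)
    x = np.where(valid, demeaned, 0.0)

    rxx = np.zeros((n_el, n_el))
    counts_xx = np.zeros((n_el, n_el))
    s = np.zeros((n_el, n_samp))
    counts_s = np.zeros((n_el, n_samp))
    for i in range(n_trials):
        rxx += x[i] @ x[i].T
        counts_xx += valid[i].astype(float) @ valid[i].astype(float).T
        s += x[i]
        counts_s += valid[i]
    rxx_norm = rxx / np.maximum(counts_xx - 1, 1)

    total = s @ s.T  # sum over ALL ordered pairs incl. i == j
    cross = total - rxx
    # expected pair count per electrode pair: complete-pair samples x (n-1)
    pair_counts = counts_xx * np.maximum(n_trials - 1, 1)
    rxy = cross / np.maximum(pair_counts - 1, 1)
    rxy = 0.5 * (rxy + rxy.T)
    return rxx_norm, rxy, n_trials


def fit_rca(
    epochs: EEGEpochArray,
    n_components: int = 2,
    rank: int | None = None,
    sign_time_ms: float = 0.0,
) -> RCADecomposition:
    """Fit RCA to epoched data.

    ``rank`` caps the principal-component basis of R_xx used for the
    generalised eigensolve; by default the smallest rank capturing 99% of
    the R_xx variance is used.  Components are sorted by decreasing
    reliability and oriented so the grand-average projection at
    ``sign_time_ms`` (the response, by default) is positive.
    """
    if epochs.n_trials < 2:
        raise ValueError("RCA needs at least 2 trials")
    if rank is not None and rank > epochs.n_electrodes:
        raise ValueError(f"rank {rank} exceeds electrode count {epochs.n_electrodes}")
    rxx, rxy, _ = _trial_covariances(epochs.data)

    evals, evecs = np.linalg.eigh(rxx)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if rank is None:
        frac = np.cumsum(np.maximum(evals, 0)) / np.maximum(np.sum(np.maximum(evals, 0)), 1e-30)
        rank = int(np.searchsorted(frac, 0.99) + 1)
    rank = min(rank, int(np.sum(evals > max(evals.max(), 0) * 1e-12)))

    v = evecs[:, :rank]
    d_inv_sqrt = 1.0 / np.sqrt(evals[:rank])
    # whitened cross-trial covariance; symmetric, so eigendecomposition
    m = (d_inv_sqrt[:, None] * (v.T @ rxy @ v)) * d_inv_sqrt[None, :]
    m = 0.5 * (m + m.T)
    rho, u = np.linalg.eigh(m)
    order = np.argsort(rho)[::-1]
    rho, u = rho[order], u[:, order]

    w_full = v @ (d_inv_sqrt[:, None] * u)  # back-projected weights, all rank comps
    n_components = min(n_components, rank)
    w = w_full[:, :n_components]
    rho_sel = rho[:n_components]

    pos_sum = np.sum(rho[rho > 0])
    explained = rho_sel / pos_sum if pos_sum > 0 else np.zeros_like(rho_sel)

    a = forward_model(w, rxx)

    # sign convention: grand-average projected value at the response > 0
    gavg = np.nanmean(epochs.data, axis=0)  # electrodes x samples
    idx = int(np.argmin(np.abs(epochs.time_ms - sign_time_ms)))
    col = np.where(np.isnan(gavg[:, idx]), 0.0, gavg[:, idx])
    signs = np.sign(w.T @ col)
    signs[signs == 0] = 1.0
    w = w * signs[None, :]
    a = a * signs[None, :]

    return RCADecomposition(
        weights=w,
        forward_model=a,
        reliability=rho_sel,
        explained_reliability_fraction=explained,
        rank_used=rank,
        pooled_covariance=rxx,
    )


def project_components(epochs: EEGEpochArray, weights: np.ndarray) -> np.ndarray:
    """Project epochs through spatial weights.

    Returns trials x components x samples.  Missing electrodes are
    excluded per sample with the weight vector rescaled (by remaining
    squared-weight mass) so projections stay on a comparable scale;
    samples with no valid electrode are missing.
    """
    data = epochs.data
    if weights.ndim == 1:
        weights = weights[:, None]
    if weights.shape[0] != epochs.n_electrodes:
        raise ValueError("weight rows must match electrode count")
    valid = ~np.isnan(data)
    x = np.where(valid, data, 0.0)
    proj = np.einsum("tes,ec->tcs", x, weights)
    w2 = weights**2
    mass = np.einsum("tes,ec->tcs", valid.astype(float), w2)
    total = w2.sum(axis=0)[None, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = proj * np.where(mass > 0, total / mass, np.nan)
    return out


def forward_model(weights: np.ndarray, pooled_covariance: np.ndarray) -> np.ndarray:
    """Haufe-style activation patterns A = R_xx W (W' R_xx W)^-1."""
    w = weights if weights.ndim == 2 else weights[:, None]
    rw = pooled_covariance @ w
    gram = w.T @ rw
    try:
        sol = np.linalg.solve(gram, rw.T).T
    except np.linalg.LinAlgError:
        warnings.warn("singular W' R_xx W; using pseudo-inverse")
        sol = (np.linalg.pinv(gram) @ rw.T).T
    return sol
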