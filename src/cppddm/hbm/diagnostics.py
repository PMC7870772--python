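"""Convergence diagnostics, DIC model comparison and posterior predictives."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..wiener import DiffusionParams, simulate_fpt
from .sampler import PosteriorSamples, total_deviance

__all__ = [
    "gelman_rubin",
    "compute_dic",
    "compare_models",
    "posterior_predictive",
]

RT_QUANTILES = (0.1, 0.3, 0.5, 0.7, 0.9)


def _rhat_scalar(chains: np.ndarray) -> float:
    """Classic (split-free) Gelman–Rubin statistic for one parameter.

    ``chains`` has shape (m chains, n draws).  R-hat is the square root of
    the ratio of the pooled variance estimate to the mean within-chain
    variance.
    """
    m, n = chains.shape
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        return 1.0
    b_over_n = chains.mean(axis=1).var(ddof=1)
    v_hat = (n - 1) / n * w + (1.0 + 1.0 / m) * b_over_n
    return float(np.sqrt(v_hat / w))


def gelman_rubin(samples: PosteriorSamples) -> pd.Series:
    """R-hat per sampled node (vector blocks flattened element-wise)."""
    first = next(iter(samples.draws.values()))
    if first.shape[0] < 2:
        raise ValueError("Gelman-Rubin diagnostic needs at least 2 chains")
    out = {}
    for name, v in samples.draws.items():
        if v.ndim == 2:
            out[name] = _rhat_scalar(v)
        else:
            flat = v.reshape(v.shape[0], v.shape[1], -1)
            for j in range(flat.shape[2]):
                out[f"{name}[{j}]"] = _rhat_scalar(flat[:, :, j])
    return pd.Series(out, name="rhat")


def compute_dic(samples: PosteriorSamples):
    """Deviance information criterion with JAGS-style focus on the
    participant-level parameters.

    p_D = mean(deviance) - deviance(posterior mean of participant-level
    parameters); DIC = mean(deviance) + p_D.  Returns (dic, p_d,
    mean_deviance).
    """
    if samples.deviance is None or samples.deviance.size == 0:
        raise ValueError("no deviance trace recorded")
    if samples.graph is None:
        raise ValueError("samples carry no model graph; refit or attach one")
    mean_dev = float(samples.deviance.mean())
    d_hat = total_deviance(
        samples.graph,
        samples.stacked("alpha").mean(axis=0),
        samples.stacked("beta").mean(axis=0),
        samples.stacked("tau").mean(axis=0),
        samples.stacked("delta").mean(axis=0),
    )
    p_d = mean_dev - d_hat
    return mean_dev + p_d, p_d, mean_dev


def compare_models(results: list) -> pd.DataFrame:
    """DIC comparison table over model fits on identical data.

    Sorted ascending by DIC; delta_dic is the difference from the best
    model.  Residual-variance columns report the posterior mean of the
    squared group SD for each parameter carrying covariates (the variance
    left over after the regression shifts the group mean).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 fitted models to compare")
    hashes = {s.metadata.get("data_hash") for s in results}
    if len(hashes) > 1:
        raise ValueError("model fits are not on identical data")
    sigma_of = {"delta": "sigma_eps", "alpha": "sigma_alpha", "tau": "sigma_tau"}
    rows = []
    for s in results:
        dic, p_d, mean_dev = compute_dic(s)
        row = {
            "model": s.metadata.get("model"),
            "covariates": _covariate_label(s),
            "dic": dic,
            "p_d": p_d,
            "mean_deviance": mean_dev,
        }
        cov_map = s.graph.spec.covariate_map if s.graph is not None else {}
        for par in cov_map:
            row[f"res_var_{par}"] = float(np.mean(s.stacked(sigma_of[par]) ** 2))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    table["delta_dic"] = table["dic"] - table["dic"].min()
    return table


def _covariate_label(s: PosteriorSamples) -> str:
    if s.graph is None:
        return ""
    cm = s.graph.spec.covariate_map
    if not cm:
        return "none"
    return "; ".join(f"{par}: {', '.join(covs)}" for par, covs in sorted(cm.items()))


def posterior_predictive(
    samples: PosteriorSamples,
    data: pd.DataFrame,
    n_rep: int = 50,
    seed: int = 0,
    dt: float = 1e-3,
):
    """Simulate replicated datasets from the posterior and summarise them.

    For each replicate a random retained draw supplies every participant's
    parameters; trial counts and stimulus directions match the observed
    data.  Returns (summary, observed) DataFrames with accuracy and RT
    quantiles per participant x condition; ``summary`` carries one row per
    replicate x cell.
    """
    graph = samples.graph
    if graph is None:
        raise ValueError("samples carry no model graph")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    C, D = samples.deviance.shape
    K = graph.n_conditions

    obs_rows = []
    cells = []
    for p, pid in enumerate(graph.participants):
        for c, cond in enumerate(graph.conditions):
            i0, i1 = graph.ptr[p, c], graph.ptr[p, c + 1]
            if i1 <= i0:
                continue
            rt = graph.rt[i0:i1]
            correct = (graph.upper[i0:i1] == (graph.sign[i0:i1] > 0)).astype(float)
            n_up = int((graph.sign[i0:i1] > 0).sum())
            row = {
                "participant_id": pid,
                "coherence_pct": cond,
                "n": i1 - i0,
                "accuracy": correct.mean(),
            }
            for q in RT_QUANTILES:
                row[f"q{int(q * 100)}"] = np.quantile(rt, q)
            obs_rows.append(row)
            cells.append((p, c, pid, cond, i1 - i0, n_up))
    observed = pd.DataFrame(obs_rows)

    rep_rows = []
    for r in range(n_rep):
        ci = rng.integers(C)
        di = rng.integers(D)
        for p, c, pid, cond, n, n_up in cells:
            pars = DiffusionParams(
                alpha=float(samples.draws["alpha"][ci, di, p]),
                beta=float(samples.draws["beta"][ci, di, p]),
                tau=float(samples.draws["tau"][ci, di, p]),
                delta=float(samples.draws["delta"][ci, di, p, c]),
            )
            sim_rt, sim_corr = _simulate_cell(pars, n, n_up, rng, dt)
            row = {
                "rep": r,
                "participant_id": pid,
                "coherence_pct": cond,
                "accuracy": sim_corr.mean(),
            }
            for q in RT_QUANTILES:
                row[f"q{int(q * 100)}"] = np.quantile(sim_rt, q)
            rep_rows.append(row)
    return pd.DataFrame(rep_rows), observed


def _simulate_cell(pars: DiffusionParams, n: int, n_up: int, rng, dt):
    """Simulate one participant x condition cell; 'down' trials run the
    mirrored process (drift toward the lower boundary, same bias)."""
    out_rt = np.empty(n)
    out_corr = np.empty(n)
    sub_seed = int(rng.integers(2**31 - 1))
    if n_up > 0:
        df = simulate_fpt(pars, n_up, seed=sub_seed, dt=dt)
        out_rt[:n_up] = df["rt_s"]
        out_corr[:n_up] = (df["choice"] == "up").astype(float)
    if n - n_up > 0:
        mirrored = DiffusionParams(pars.alpha, pars.beta, pars.tau, -pars.delta)
        df = simulate_fpt(mirrored, n - n_up, seed=sub_seed + 1, dt=dt)
        out_rt[n_up:] = df["rt_s"]
        out_corr[n_up:] = (df["choice"] == "down").astype(float)
    return out_rt, out_corr
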