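"""Behavioural data screening: structural exclusions, the EWMA fast-guess
filter, and participant-level retention rules.

The EWMA filter treats a participant's RT-sorted accuracy sequence as a
process-control problem: under fast guessing, accuracy is a Bernoulli(0.5)
control process.  The exponentially weighted moving average of accuracy,

    c_s = lambda * x_s + (1 - lambda) * c_{s-1},        c_0 = 0.5,

is compared at every sorted trial s (s = 1, 2, ...) with the upper control
limit

    UCL_s = c_0 + L * sigma_0 * sqrt(lambda / (2 - lambda)
                                     * (1 - (1 - lambda)^(2 s))).

The first sorted trial at which c_s strictly exceeds UCL_s marks the
shortest RT at which responding is credibly above chance; faster trials
are discarded as fast guesses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EWMAConfig",
    "EWMAResult",
    "apply_basic_exclusions",
    "ewma_cutoff",
    "apply_ewma",
    "screen_participants",
]


@dataclass(frozen=True)
class EWMAConfig:
    """Control-chart settings; defaults are the standard fast-guess values
    (chance mean 0.5, Bernoulli SD 0.5, limit width 1.5 SDs, weight 0.1)."""

    lam: float = 0.1
    c0: float = 0.5
    sigma0: float = 0.5
    L: float = 1.5
    keep_cutoff_trial: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lam <= 1:
            raise ValueError(f"lambda must be in (0, 1], got {self.lam}")
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")


@dataclass
class EWMAResult:
    sorted_rts: np.ndarray
    c_trace: np.ndarray
    ucl_trace: np.ndarray
    cutoff_index: int | None  # 1-based sorted-trial index of first crossing
    cutoff_rt: float | None
    retained_fraction: float
    retained_mask: np.ndarray = field(repr=False, default=None)  # original row order


def apply_basic_exclusions(
    dataset: pd.DataFrame,
    excluded_coherences: tuple = (10,),
    rt_timeout_s: float = 2.5,
    expected_coherences: tuple = (10, 30, 50, 75),
):
    """Remove catch trials, timeouts / missing responses, and the excluded
    coherence condition(s).

    Returns the surviving rows and a report with per-participant counts
    per rule; coherence values outside ``expected_coherences`` are noted
    as warnings and their rows kept.
    """
    df = dataset.copy()
    is_catch = df["is_catch"].astype(bool) if "is_catch" in df else pd.Series(False, index=df.index)
    timeout = df["rt_s"].isna() | (df["rt_s"] >= rt_timeout_s)
    excl_coh = df["coherence_pct"].isin(excluded_coherences)
    drop = is_catch | timeout | excl_coh

    known = set(expected_coherences) | {100}
    unknown = sorted(set(df["coherence_pct"].dropna().unique()) - known)
    warnings = [f"unknown coherence value {v!r}: rows kept" for v in unknown]

    grp = df.groupby("participant_id", sort=True)
    report = pd.DataFrame(
        {
            "n_trials": grp.size(),
            "n_catch": is_catch.groupby(df["participant_id"]).sum(),
            "n_timeout": timeout.groupby(df["participant_id"]).sum(),
            "n_excluded_coherence": excl_coh.groupby(df["participant_id"]).sum(),
            "n_removed": drop.groupby(df["participant_id"]).sum(),
        }
    ).fillna(0).astype(int)
    report.attrs["warnings"] = warnings
    return df.loc[~drop].copy(), report


def _sorted_accuracy(trials: pd.DataFrame):
    if "trial_index" in trials:
        order = np.lexsort((np.asarray(trials["trial_index"]), np.asarray(trials["rt_s"])))
    else:
        order = np.argsort(np.asarray(trials["rt_s"]), kind="stable")
    rts = np.asarray(trials["rt_s"], dtype=float)[order]
    if "correct" in trials:
        x = np.asarray(trials["correct"])[order]
    else:
        x = (np.asarray(trials["choice"]) == np.asarray(trials["direction"]))[order]
    x = np.asarray(x, dtype=float)
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("accuracies must be coded 0/1")
    return order, rts, x


def ewma_cutoff(trials: pd.DataFrame, config: EWMAConfig = EWMAConfig()) -> EWMAResult:
    """Run the EWMA control chart over one participant's trials.

    Trials are sorted ascending by RT (ties broken stably by trial_index).
    If the statistic never exceeds the control limit the participant has
    no demonstrably above-chance regime and the retained fraction is 0.
    """
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    order, rts, x = _sorted_accuracy(trials)
    n = len(x)
    lam, c0, s0, L = config.lam, config.c0, config.sigma0, config.L

    s = np.arange(1, n + 1)
    # c_s via the exact linear recursion in closed form
    c = np.empty(n)
    acc = c0
    for i in range(n):
        acc = lam * x[i] + (1 - lam) * acc
        c[i] = acc
    ucl = c0 + L * s0 * np.sqrt(lam / (2 - lam) * (1 - (1 - lam) ** (2 * s)))

    crossing = np.nonzero(c > ucl)[0]
    mask_sorted = np.zeros(n, dtype=bool)
    if crossing.size:
        idx = int(crossing[0])
        cutoff_rt = float(rts[idx])
        if config.keep_cutoff_trial:
            mask_sorted = rts >= cutoff_rt
        else:
            mask_sorted = rts > cutoff_rt
        cutoff_index = idx + 1
    else:
        cutoff_index, cutoff_rt = None, None

    retained = np.zeros(n, dtype=bool)
    retained[order] = mask_sorted
    return EWMAResult(
        sorted_rts=rts,
        c_trace=c,
        ucl_trace=ucl,
        cutoff_index=cutoff_index,
        cutoff_rt=cutoff_rt,
        retained_fraction=float(mask_sorted.mean()),
        retained_mask=retained,
    )


def apply_ewma(dataset: pd.DataFrame, config: EWMAConfig = EWMAConfig()):
    """Apply :func:`ewma_cutoff` per participant.

    Returns (surviving rows, per-participant table with cutoff RT and
    retained fraction).
    """
    keep = np.zeros(len(dataset), dtype=bool)
    rows = []
    for pid, sub in dataset.groupby("participant_id", sort=True):
        res = ewma_cutoff(sub, config)
        keep[dataset.index.get_indexer(sub.index)] = res.retained_mask
        rows.append(
            {
                "participant_id": pid,
                "n_trials": len(sub),
                "cutoff_rt": res.cutoff_rt,
                "retained_fraction": res.retained_fraction,
            }
        )
    report = pd.DataFrame(rows).set_index("participant_id")
    return dataset.loc[keep].copy(), report


def screen_participants(
    dataset: pd.DataFrame,
    ewma_report: pd.DataFrame,
    min_retained: float = 0.6,
    chance_alpha: float = 0.05,
):
    """Drop participants with a low EWMA retention fraction or with overall
    accuracy significantly *below* chance (one-sided binomial test), the
    latter indicating reversed responses that would force negative drift.

    ``dataset`` holds the post-EWMA trials; ``ewma_report`` is the
    per-participant table from :func:`apply_ewma`.
    """
    rows = []
    drop_ids = []
    for pid, sub in dataset.groupby("participant_id", sort=True):
        frac = float(ewma_report.loc[pid, "retained_fraction"]) if pid in ewma_report.index else 0.0
        corr = (
            np.asarray(sub["correct"])
            if "correct" in sub
            else (np.asarray(sub["choice"]) == np.asarray(sub["direction"]))
        )
        k, n = int(corr.sum()), len(corr)
        p_below = stats.binomtest(k, n, 0.5, alternative="less").pvalue if n else 1.0
        below_chance = p_below < chance_alpha
        low_retention = frac < min_retained
        dropped = below_chance or low_retention
        if dropped:
            drop_ids.append(pid)
        rows.append(
            {
                "participant_id": pid,
                "retained_fraction": frac,
                "accuracy": k / n if n else np.nan,
                "below_chance": below_chance,
                "low_retention": low_retention,
                "dropped": dropped,
            }
        )
    # participants wiped out entirely by the EWMA filter never reach the
    # loop above; report them as dropped
    for pid in ewma_report.index.difference(dataset["participant_id"].unique()):
        drop_ids.append(pid)
        rows.append(
            {
                "participant_id": pid,
                "retained_fraction": float(ewma_report.loc[pid, "retained_fraction"]),
                "accuracy": np.nan,
                "below_chance": False,
                "low_retention": True,
                "dropped": True,
            }
        )
    report = pd.DataFrame(rows).set_index("participant_id").sort_index()
    out = dataset.loc[~dataset["participant_id"].isin(drop_ids)].copy()
    return out, report
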