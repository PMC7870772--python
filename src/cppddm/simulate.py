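"""Synthetic cohorts with known ground truth.

Behavioural data follow the same generative model the hierarchical
analysis assumes: each participant's boundary separation, starting point
and non-decision time are truncated-normal draws around group means, the
per-condition drift rates carry sum-to-zero condition effects plus any
age effect, and trials are first-passage samples from the diffusion
process.  A configurable fraction of trials can be replaced by fast
guesses (uniform RT below the participant's fast tail, chance accuracy)
to exercise the EWMA screen.

EEG epochs contain two spatial components with response-locked ramps whose
per-participant slopes are tied linearly to the participant's mean drift
rate, plus spatially correlated low-rank noise.  The slope-map defaults
put the component-1 slope/age correlation near 0.3 in a default child
cohort, with the component-2 link much weaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EEGEpochArray, make_montage
from .hbm.model import BOUNDS, GroupHyperParams, sum_to_zero_design
from .wiener import DiffusionParams, simulate_fpt

__all__ = [
    "SimConfig",
    "EEGSimSpec",
    "CHILD_TRUTH",
    "ADULT_TRUTH",
    "gen_behavior",
    "gen_contaminants",
    "gen_eeg",
]

#: child-like group truth: wide boundaries, slow non-decision time, drift
#: rising with coherence (condition offsets ~ -0.7, 0, +0.7 SD units)
CHILD_TRUTH = GroupHyperParams(
    mu_alpha=1.5, sigma_alpha=0.25,
    mu_beta=0.5, sigma_beta=0.04,
    mu_tau=0.45, sigma_tau=0.08,
    mu_delta=2.0, sigma_eps=0.8,
    theta=sum_to_zero_design(3).T @ np.array([-0.7, 0.0, 0.7]),
)

#: adult-like regime: narrower boundaries, faster non-decision, higher drift
ADULT_TRUTH = GroupHyperParams(
    mu_alpha=1.1, sigma_alpha=0.15,
    mu_beta=0.5, sigma_beta=0.03,
    mu_tau=0.33, sigma_tau=0.05,
    mu_delta=3.4, sigma_eps=0.6,
    theta=sum_to_zero_design(3).T @ np.array([-0.7, 0.0, 0.7]),
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort design.  ``covariate_effects`` maps (parameter, covariate)
    pairs to standardized true weights, e.g. {("delta", "age"): 0.45}."""

    n_participants: int = 40
    ages: tuple = (6.0, 12.9)  # (lo, hi) years; equal => fixed age
    n_trials_per_condition: int = 90
    coherences: tuple = (30, 50, 75)
    group_hyperparams: GroupHyperParams = field(default_factory=lambda: CHILD_TRUTH)
    covariate_effects: dict = field(default_factory=dict)
    contaminant_prop: float = 0.0
    group_label: str = "children"
    dt: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.coherences) != sorted(set(self.coherences)):
            raise ValueError("coherences must be strictly increasing")
        if not 0 <= self.contaminant_prop < 0.5:
            raise ValueError(f"contaminant_prop must be in [0, 0.5), got {self.contaminant_prop}")
        self.group_hyperparams.validate()
        for (par, cov), w in self.covariate_effects.items():
            if par not in ("delta", "alpha", "tau"):
                raise ValueError(f"covariate effect on unsupported parameter {par!r}")


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def gen_behavior(config: SimConfig):
    """Simulate a behavioural cohort.

    Returns (trial table, truth table).  The trial table is tidy with one
    row per decision; the truth table holds every participant's true
    diffusion parameters.  Identical seeds give identical output.
    """
    g = config.group_hyperparams
    K = len(config.coherences)
    rng = np.random.default_rng(config.seed)
    P = config.n_participants

    lo_age, hi_age = config.ages
    ages = np.full(P, lo_age) if hi_age <= lo_age else rng.uniform(lo_age, hi_age, P)
    z_age = (ages - ages.mean()) / ages.std(ddof=1) if P > 1 and hi_age > lo_age else np.zeros(P)

    eff = config.covariate_effects
    b_d = eff.get(("delta", "age"), 0.0)
    b_a = eff.get(("alpha", "age"), 0.0)
    b_t = eff.get(("tau", "age"), 0.0)

    offsets = g.condition_offsets(K)
    m_alpha = g.mu_alpha + g.sigma_alpha * b_a * z_age
    m_tau = g.mu_tau + g.sigma_tau * b_t * z_age
    for name, m in (("alpha", m_alpha), ("tau", m_tau)):
        lo, hi = BOUNDS[name]
        if np.any((m < lo) | (m > hi)):
            raise ValueError(f"true group mean for {name} falls outside bounds [{lo}, {hi}]")

    alpha = _truncnorm(rng, m_alpha, g.sigma_alpha, *BOUNDS["alpha"], size=P)
    beta = _truncnorm(rng, np.full(P, g.mu_beta), g.sigma_beta, *BOUNDS["beta"], size=P)
    tau = _truncnorm(rng, m_tau, g.sigma_tau, *BOUNDS["tau"], size=P)
    m_delta = g.mu_delta + g.sigma_eps * (offsets[None, :] + (b_d * z_age)[:, None])
    lo, hi = BOUNDS["delta"]
    if np.any((m_delta < lo) | (m_delta > hi)):
        raise ValueError(f"true condition drift means fall outside bounds [{lo}, {hi}]")
    delta = _truncnorm(rng, m_delta, g.sigma_eps, lo, hi, size=m_delta.shape)

    pids = [f"{config.group_label[0]}{i + 1:03d}" for i in range(P)]
    frames = []
    for p in range(P):
        rows = []
        for c, coh in enumerate(config.coherences):
            n = config.n_trials_per_condition
            n_up = n // 2
            for direction, count in (("up", n_up), ("down", n - n_up)):
                if count == 0:
                    continue
                drift = delta[p, c] if direction == "up" else -delta[p, c]
                pars = DiffusionParams(alpha[p], beta[p], tau[p], drift)
                sim = simulate_fpt(pars, count, seed=int(rng.integers(2**31 - 1)), dt=config.dt)
                rows.append(
                    pd.DataFrame(
                        {
                            "coherence_pct": coh,
                            "direction": direction,
                            "choice": sim["choice"],
                            "rt_s": sim["rt_s"],
                        }
                    )
                )
        sub = pd.concat(rows, ignore_index=True)
        sub = sub.iloc[rng.permutation(len(sub))].reset_index(drop=True)
        sub.insert(0, "participant_id", pids[p])
        sub.insert(1, "group", config.group_label)
        sub.insert(2, "age_years", ages[p])
        sub["is_catch"] = False
        sub["trial_index"] = np.arange(len(sub))
        frames.append(sub)
    trials = pd.concat(frames, ignore_index=True)
    trials["correct"] = trials["choice"] == trials["direction"]

    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "age_years": ages,
            "z_age": z_age,
            "alpha": alpha,
            "beta": beta,
            "tau": tau,
        }
    )
    for c, coh in enumerate(config.coherences):
        truth[f"delta_{coh}"] = delta[:, c]
    truth["delta_mean"] = delta.mean(axis=1)

    if config.contaminant_prop > 0:
        trials = gen_contaminants(
            trials, config.contaminant_prop, seed=int(rng.integers(2**31 - 1))
        )
    else:
        trials["is_contaminant"] = False
    return trials, truth


def gen_contaminants(
    dataset: pd.DataFrame,
    prop: float,
    guess_rt_bounds: tuple = (0.15, None),
    seed: int = 0,
) -> pd.DataFrame:
    """Replace a fraction of each participant's trials with fast guesses.

    Guesses have uniform RT between ``guess_rt_bounds[0]`` and the
    participant's 10th RT percentile (the upper bound may be overridden)
    and a 50% random choice.  Contaminated rows are flagged in the hidden
    truth column ``is_contaminant``.
    """
    if not 0 <= prop < 0.5:
        raise ValueError(f"prop must be in [0, 0.5), got {prop}")
    out = dataset.copy()
    out["is_contaminant"] = False
    if prop == 0:
        return out
    rng = np.random.default_rng(seed)
    lo = guess_rt_bounds[0]
    for pid, sub in out.groupby("participant_id", sort=True):
        n_replace = int(round(prop * len(sub)))
        if n_replace == 0:
            continue
        hi = guess_rt_bounds[1]
        if hi is None:
            hi = float(np.quantile(sub["rt_s"], 0.10))
        hi = max(hi, lo + 0.01)
        pick = rng.choice(sub.index.to_numpy(), size=n_replace, replace=False)
        out.loc[pick, "rt_s"] = rng.uniform(lo, hi, n_replace)
        out.loc[pick, "choice"] = rng.choice(["up", "down"], n_replace)
        out.loc[pick, "is_contaminant"] = True
    out["correct"] = out["choice"] == out["direction"]
    return out


# --------------------------------------------------------------------------
# EEG generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EEGSimSpec:
    """EEG generator settings.

    ``ramp_slope_map`` ties each participant's component ramp slope
    (microvolt/s) to their mean true drift:
    slope = intercept + per_drift * mean_drift + N(0, noise_sd).
    Component 1 rises linearly from a per-participant onset latency to a
    peak at the response then decays; component 2 is biphasic (negative
    trough, then a rise through zero to a positive peak just before the
    response) whose central rise has the mapped slope.
    """

    n_electrodes: int = 128
    sample_rate: float = 500.0
    epoch_window_ms: tuple = (-600.0, 198.0)
    ramp_slope_map: dict = field(
        default_factory=lambda: {
            "c1": {"intercept": 10.0, "per_drift": 4.0, "noise_sd": 3.2},
            "c2": {"intercept": 12.0, "per_drift": 1.0, "noise_sd": 6.0},
        }
    )
    onset_range_ms: tuple = (-450.0, -300.0)
    noise_sd: float = 5.0
    comp2_lobe_ratio: float = 0.45
    spatial_noise_rank: int = 8
    trial_gain_sd: float = 0.2
    topographies: np.ndarray = None  # (E, 2) unit-norm columns; default built from montage

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window_ms
        if not lo < 0 < hi:
            raise ValueError("epoch window must straddle the response (start < 0 < end)")
        if self.topographies is not None:
            norms = np.linalg.norm(self.topographies, axis=0)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("topography columns must be unit norm")


def default_topographies(n_electrodes: int):
    """Two smooth unit-norm scalp patterns from the synthetic montage: a
    centro-parietal bump (component 1) and an occipital bump (component 2),
    orthogonalised."""
    pos, neighbours = make_montage(n_electrodes)
    t1 = np.exp(-(((pos[:, 0] - 0.0) ** 2 + (pos[:, 1] - 0.45) ** 2) / (2 * 0.35**2)))
    t2 = np.exp(-(((pos[:, 0] - 0.0) ** 2 + (pos[:, 1] + 0.65) ** 2) / (2 * 0.30**2)))
    t1 = t1 / np.linalg.norm(t1)
    t2 = t2 - (t2 @ t1) * t1
    t2 = t2 / np.linalg.norm(t2)
    return np.stack([t1, t2], axis=1), neighbours


def _comp1_wave(t_s, onset_s, slope):
    """Linear rise from onset to the response, then decay to zero by +150 ms."""
    peak = slope * (-onset_s)
    rise = slope * (t_s - onset_s)
    decay = peak * (1.0 - t_s / 0.150)
    w = np.where(t_s < onset_s, 0.0, np.where(t_s <= 0.0, rise, np.maximum(decay, 0.0)))
    return w


def _comp2_wave(t_s, slope, lobe_ratio=0.25):
    """Biphasic: trough -A at -250 ms, central rise at ``slope`` microvolt/s
    to a positive peak of lobe_ratio * A at -20 ms, decay to 0 by +120 ms.

    The asymmetric lobes keep this waveform close to temporally orthogonal
    to the component-1 ramp, so the two sources are separable by a
    reliability decomposition."""
    a = slope * 0.230 / (1.0 + lobe_ratio)
    t1, t2, t3, t4 = -0.450, -0.250, -0.020, 0.120
    w = np.zeros_like(t_s)
    m = (t_s >= t1) & (t_s < t2)
    w[m] = -a * (t_s[m] - t1) / (t2 - t1)
    m = (t_s >= t2) & (t_s < t3)
    w[m] = -a + slope * (t_s[m] - t2)
    m = (t_s >= t3) & (t_s < t4)
    w[m] = lobe_ratio * a * (1.0 - (t_s[m] - t3) / (t4 - t3))
    return w


def gen_eeg(dataset: pd.DataFrame, spec: EEGSimSpec = EEGSimSpec(), seed: int = 0, truth: pd.DataFrame = None):
    """Response-locked EEG epochs for every row of ``dataset``.

    Each trial is topography (x) ramp plus rank-limited spatially
    correlated noise; per-trial multiplicative gain jitter keeps the
    trial-to-trial reliability below 1.  Per-participant true slopes come
    from ``spec.ramp_slope_map`` applied to the participant's mean true
    drift (from ``truth``; falls back to the empirical accuracy-scaled
    values if absent, but the generator is normally called with the truth
    table from :func:`gen_behavior`).

    Returns (EEGEpochArray, slope truth table).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    lo, hi = spec.epoch_window_ms
    if lo > spec.onset_range_ms[0]:
        raise ValueError(
            f"epoch window starts at {lo} ms but ramp onsets extend to "
            f"{spec.onset_range_ms[0]} ms"
        )
    dt_ms = 1000.0 / spec.sample_rate
    time_ms = np.arange(lo, hi + dt_ms / 2, dt_ms)
    t_s = time_ms / 1000.0
    E, S = spec.n_electrodes, len(time_ms)

    if spec.topographies is not None:
        topo = spec.topographies
        _, neighbours = make_montage(E)
    else:
        topo, neighbours = default_topographies(E)

    pids = sorted(dataset["participant_id"].unique())
    if truth is not None and "delta_mean" in truth:
        dmean = truth.set_index("participant_id")["delta_mean"]
    else:
        dmean = pd.Series(
            {p: 2.0 for p in pids}
        )  # neutral fallback: constant mean drift

    rows = []
    waves = {}
    for pid in pids:
        m1, m2 = spec.ramp_slope_map["c1"], spec.ramp_slope_map["c2"]
        s1 = m1["intercept"] + m1["per_drift"] * float(dmean[pid]) + rng.normal(0, m1["noise_sd"])
        s2 = m2["intercept"] + m2["per_drift"] * float(dmean[pid]) + rng.normal(0, m2["noise_sd"])
        onset = rng.uniform(*spec.onset_range_ms) / 1000.0
        w1 = _comp1_wave(t_s, onset, s1)
        w2 = _comp2_wave(t_s, s2, spec.comp2_lobe_ratio)
        waves[pid] = (w1, w2)
        rows.append(
            {"participant_id": pid, "slope_c1_true": s1, "slope_c2_true": s2, "onset_ms": onset * 1000}
        )
    slope_truth = pd.DataFrame(rows)

    # Orthogonalise each participant's biphasic waveform (after
    # time-demeaning, as the reliability decomposition sees the data)
    # against that participant's ramp: zero temporal cross-covariance
    # between the two sources keeps them identifiable by the generalised
    # eigensolve regardless of their power ratio.
    for pid in pids:
        w1, w2 = waves[pid]
        w1d = w1 - w1.mean()
        w2d = w2 - w2.mean()
        denom = float(w1d @ w1d)
        if denom > 0:
            w2 = w2 - (float(w2d @ w1d) / denom) * w1d
        waves[pid] = (w1, w2)

    n_trials = len(dataset)
    data = np.empty((n_trials, E, S))
    B = rng.normal(size=(E, spec.spatial_noise_rank)) / np.sqrt(spec.spatial_noise_rank)
    pid_arr = dataset["participant_id"].to_numpy()
    for i in range(n_trials):
        w1, w2 = waves[pid_arr[i]]
        if spec.trial_gain_sd > 0:
            g1 = rng.lognormal(-spec.trial_gain_sd**2 / 2, spec.trial_gain_sd)
            g2 = rng.lognormal(-spec.trial_gain_sd**2 / 2, spec.trial_gain_sd)
        else:
            g1 = g2 = 1.0
        signal = np.outer(topo[:, 0], g1 * w1) + np.outer(topo[:, 1], g2 * w2)
        if spec.noise_sd > 0:
            eta = rng.normal(size=(spec.spatial_noise_rank, S))
            noise = spec.noise_sd * (
                np.sqrt(0.5) * (B @ eta) + np.sqrt(0.5) * rng.normal(size=(E, S))
            )
        else:
            noise = 0.0
        data[i] = signal + noise

    epochs = EEGEpochArray(
        data=data,
        time_ms=time_ms,
        channel_names=[f"E{e + 1}" for e in range(E)],
        neighbours=neighbours,
        sample_rate=spec.sample_rate,
        trial_index=dataset.index.to_numpy(),
    )
    slope_truth.attrs["topographies"] = topo
    return epochs, slope_truth
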