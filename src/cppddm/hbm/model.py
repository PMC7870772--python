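"""Hierarchical Bayesian diffusion model specification.

Structure (per group, children or adults fitted separately):

* participant level — alpha_p, beta_p, tau_p drawn from truncated normal
  group distributions; drift delta_pc drawn per condition from a truncated
  normal whose mean carries the fixed condition effects and any
  participant-level covariates:

      delta_pc ~ TN( mu_delta + sigma_eps * [ (Q theta)_c + sum_j b_j z_j(p) ],
                     sigma_eps )

  where Q is the orthonormal sum-to-zero projection of the k-1 free
  standardized condition effects theta, and z_j are z-standardized
  covariates (age, EEG ramp slopes).  Covariates on alpha or tau shift the
  group mean by sigma_alpha/tau * sum_j b_j z_j(p) in the same way.

* group level — truncated-normal priors on the group means and half-normal
  priors on the group SDs; standardized weights (theta and b) carry
  Zellner–Siow mixture-of-g priors: weight ~ N(0, g), g ~ InvGamma(1/2, 1/2).

Truncation bounds: alpha in [0.2, 4], beta in [0.001, 0.999],
tau in [0.1, 2], delta in [0, 8].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BOUNDS",
    "PRIORS",
    "GroupHyperParams",
    "ModelSpec",
    "MODEL_TABLE",
    "sum_to_zero_design",
    "build_model",
    "ModelGraph",
]

#: truncation bounds enforced at the hierarchical level
BOUNDS = {
    "alpha": (0.2, 4.0),
    "beta": (0.001, 0.999),
    "tau": (0.1, 2.0),
    "delta": (0.0, 8.0),
}

#: informative group-level priors: (prior mean, prior SD) for the group
#: means, half-normal scale for the group SDs.  Centred on typical values
#: from parameter surveys of simple two-choice tasks.
PRIORS = {
    "mu_alpha": (1.0, 0.5),
    "mu_beta": (0.5, 0.125),
    "mu_tau": (0.4, 0.3),
    "mu_delta": (2.0, 1.5),
    "sigma_alpha": 0.5,
    "sigma_beta": 0.125,
    "sigma_tau": 0.3,
    "sigma_eps": 1.0,
}


def sum_to_zero_design(k: int) -> np.ndarray:
    """Orthonormal projection matrix (k x k-1) mapping k-1 free fixed
    effects to k condition offsets that sum to zero.

    Columns form an orthonormal basis of the centring subspace, so
    Q.T @ Q = I and each column sums to zero.
    """
    if k < 2:
        raise ValueError(f"need at least 2 conditions, got k={k}")
    centering = np.eye(k) - np.full((k, k), 1.0 / k)
    u, s, _ = np.linalg.svd(centering)
    q = u[:, : k - 1]
    # deterministic sign convention: first nonzero entry of each column > 0
    for j in range(q.shape[1]):
        i = np.nonzero(np.abs(q[:, j]) > 1e-12)[0][0]
        if q[i, j] < 0:
            q[:, j] = -q[:, j]
    return q


@dataclass
class GroupHyperParams:
    """Group-level parameters; also used as the ground-truth container for
    the synthetic-data generator."""

    mu_alpha: float = 1.3
    sigma_alpha: float = 0.25
    mu_beta: float = 0.5
    sigma_beta: float = 0.04
    mu_tau: float = 0.45
    sigma_tau: float = 0.08
    mu_delta: float = 2.2
    sigma_eps: float = 0.8
    theta: np.ndarray = field(default_factory=lambda: np.zeros(2))
    b: dict = field(default_factory=dict)  # (param, covariate) -> weight
    g: dict = field(default_factory=dict)  # block -> g-prior scale

    def condition_offsets(self, k: int | None = None) -> np.ndarray:
        """Standardized condition offsets (Q theta); length k, sum zero."""
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        k = k if k is not None else len(theta) + 1
        return sum_to_zero_design(k) @ theta

    def validate(self) -> None:
        for par in ("alpha", "beta", "tau", "delta"):
            mu_name = f"mu_{par}"
            lo, hi = BOUNDS[par]
            v = getattr(self, mu_name)
            if not lo <= v <= hi:
                raise ValueError(f"{mu_name}={v} outside truncation bounds [{lo}, {hi}]")
        for name in ("sigma_alpha", "sigma_beta", "sigma_tau", "sigma_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ModelSpec:
    """Which covariates enter which parameter's group mean.

    ``covariate_map`` maps 'delta' / 'alpha' / 'tau' to covariate column
    names in the covariate table; drift always carries the condition
    effects in addition.
    """

    label: str
    covariate_map: dict

    def __post_init__(self) -> None:
        for par in self.covariate_map:
            if par not in ("delta", "alpha", "tau"):
                raise ValueError(f"covariates not supported on parameter {par!r}")


#: the model family: covariate structure of models 1-12
MODEL_TABLE = {
    "model1": ModelSpec("model1", {}),
    "model2": ModelSpec("model2", {"delta": ["age"], "alpha": ["age"], "tau": ["age"]}),
    "model3": ModelSpec("model3", {"delta": ["age"]}),
    "model4": ModelSpec("model4", {"delta": ["age"], "alpha": ["age"]}),
    "model5": ModelSpec("model5", {"delta": ["age"], "tau": ["age"]}),
    "model6": ModelSpec("model6", {"delta": ["eeg1"]}),
    "model7": ModelSpec("model7", {"delta": ["eeg2"]}),
    "model8": ModelSpec("model8", {"delta": ["eeg1", "eeg2"]}),
    "model9": ModelSpec("model9", {"delta": ["age", "eeg1", "eeg2"]}),
    "model10": ModelSpec("model10", {"delta": ["age", "eeg1", "eeg2"], "alpha": ["age"]}),
    "model11": ModelSpec("model11", {"delta": ["age", "eeg1"], "alpha": ["age"]}),
    "model12": ModelSpec("model12", {"delta": ["age", "eeg2"], "alpha": ["age"]}),
}


class ModelGraph:
    """Assembled generative graph: flat trial arrays grouped by participant
    and condition, covariate designs, bounds and priors.

    Trials are stored sorted by (participant, condition); the slice for
    participant p, condition c is ``ptr[p, c]:ptr[p, c + 1]`` and a
    participant's full range is ``ptr[p, 0]:ptr[p, k]``.
    """

    def __init__(self, spec, rt, upper, sign, ptr, participants, conditions, Z, data_hash):
        self.spec = spec
        self.rt = rt
        self.upper = upper
        self.sign = sign
        self.ptr = ptr
        self.participants = list(participants)
        self.conditions = list(conditions)
        self.Z = Z  # param -> (P, m) design of z-standardized covariates
        self.data_hash = data_hash
        self.n_participants = len(participants)
        self.n_conditions = len(conditions)
        self.Q = sum_to_zero_design(self.n_conditions)
        self.bounds = dict(BOUNDS)
        self.priors = dict(PRIORS)

    # -- bookkeeping -------------------------------------------------------
    def node_names(self) -> list:
        """Names of all sampled nodes (hyperparameters, weights, and the
        participant-level parameter blocks)."""
        names = [
            "mu_alpha", "sigma_alpha", "mu_beta", "sigma_beta",
            "mu_tau", "sigma_tau", "mu_delta", "sigma_eps",
        ]
        names += [f"theta[{n}]" for n in range(self.n_conditions - 1)]
        names += ["g_theta"]
        for par, covs in sorted(self.spec.covariate_map.items()):
            names += [f"b_{par}_{cov}" for cov in covs]
            names += [f"g_{par}"]
        names += ["alpha", "beta", "tau", "delta"]  # vector blocks
        return names

    def n_parameters(self) -> int:
        """Total count of sampled scalars."""
        P, k = self.n_participants, self.n_conditions
        n_hyper = 8 + (k - 1) + 1
        n_b = sum(len(v) for v in self.spec.covariate_map.values())
        n_g = len(self.spec.covariate_map)
        return 3 * P + k * P + n_hyper + n_b + n_g

    # -- conditional means -------------------------------------------------
    def participant_means(self, state: dict):
        """Conditional prior means of the participant-level parameters given
        the group-level state (dict of hyperparameter values)."""
        P, k = self.n_participants, self.n_conditions
        shift = {par: np.zeros(P) for par in ("alpha", "tau", "delta")}
        for par, covs in self.spec.covariate_map.items():
            zb = np.zeros(P)
            for cov in covs:
                zb += state[f"b_{par}_{cov}"] * self.Z[par][cov]
            shift[par] = zb
        m_alpha = state["mu_alpha"] + state["sigma_alpha"] * shift["alpha"]
        m_beta = np.full(P, state["mu_beta"])
        m_tau = state["mu_tau"] + state["sigma_tau"] * shift["tau"]
        offsets = self.Q @ np.asarray([state[f"theta[{n}]"] for n in range(k - 1)])
        m_delta = state["mu_delta"] + state["sigma_eps"] * (
            offsets[None, :] + shift["delta"][:, None]
        )
        return m_alpha, m_beta, m_tau, m_delta

    # -- prior predictive --------------------------------------------------
    def sample_prior_state(self, rng) -> dict:
        """One draw of all group-level nodes from their priors."""
        from scipy import stats

        state = {}
        for par in ("alpha", "beta", "tau", "delta"):
            m0, s0 = self.priors[f"mu_{par}"]
            lo, hi = self.bounds[par]
            state[f"mu_{par}"] = float(
                stats.truncnorm.rvs((lo - m0) / s0, (hi - m0) / s0, m0, s0, random_state=rng)
            )
        for name in ("sigma_alpha", "sigma_beta", "sigma_tau", "sigma_eps"):
            state[name] = float(abs(rng.normal(0.0, self.priors[name])))
        state["g_theta"] = float(1.0 / rng.gamma(0.5, 2.0))
        for n in range(self.n_conditions - 1):
            state[f"theta[{n}]"] = float(rng.normal(0.0, np.sqrt(state["g_theta"])))
        for par, covs in self.spec.covariate_map.items():
            state[f"g_{par}"] = float(1.0 / rng.gamma(0.5, 2.0))
            for cov in covs:
                state[f"b_{par}_{cov}"] = float(rng.normal(0.0, np.sqrt(state[f"g_{par}"])))
        return state

    def prior_predictive(self, rng, n_draws: int = 100, fixed: dict | None = None):
        """Draw participant-level parameters from the prior (optionally with
        some group-level nodes clamped via ``fixed``).

        Returns dict with arrays alpha/beta/tau of shape (n_draws, P) and
        delta of shape (n_draws, P, k).
        """
        from scipy import stats

        P, k = self.n_participants, self.n_conditions
        out = {
            "alpha": np.empty((n_draws, P)),
            "beta": np.empty((n_draws, P)),
            "tau": np.empty((n_draws, P)),
            "delta": np.empty((n_draws, P, k)),
        }
        for d in range(n_draws):
            state = self.sample_prior_state(rng)
            if fixed:
                state.update(fixed)
            m_a, m_b, m_t, m_d = self.participant_means(state)
            for par, m, s in (
                ("alpha", m_a, state["sigma_alpha"]),
                ("beta", m_b, state["sigma_beta"]),
                ("tau", m_t, state["sigma_tau"]),
            ):
                lo, hi = self.bounds[par]
                out[par][d] = stats.truncnorm.rvs(
                    (lo - m) / s, (hi - m) / s, m, s, random_state=rng
                )
            lo, hi = self.bounds["delta"]
            s = state["sigma_eps"]
            out["delta"][d] = stats.truncnorm.rvs(
                (lo - m_d) / s, (hi - m_d) / s, m_d, s, random_state=rng
            )
        return out


def build_model(spec: ModelSpec, data: pd.DataFrame, covariates: pd.DataFrame | None = None):
    """Assemble a :class:`ModelGraph` from screened trial data.

    ``data`` is a tidy trial table (participant_id, coherence_pct,
    direction, choice, rt_s); ``covariates`` indexes participant_id and
    must contain a z-standardized column for every covariate named in the
    spec (mean 0, SD 1 within the analysed group).
    """
    import hashlib

    needed = {c for covs in spec.covariate_map.values() for c in covs}
    if needed:
        if covariates is None:
            raise ValueError(f"model {spec.label} needs covariates {sorted(needed)}")
        cov = covariates.set_index("participant_id") if "participant_id" in covariates else covariates

    participants = sorted(data["participant_id"].unique())
    conditions = sorted(data["coherence_pct"].unique())
    if needed:
        missing = [p for p in participants if p not in cov.index]
        if missing:
            raise ValueError(f"covariates missing for participants: {missing}")
        for c in needed:
            if c not in cov.columns:
                raise ValueError(f"covariate column {c!r} not in table")
            vals = cov.loc[participants, c].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)):
                bad = [p for p, v in zip(participants, vals) if not np.isfinite(v)]
                raise ValueError(f"non-finite covariate {c!r} for participants: {bad}")

    p_code = pd.Categorical(data["participant_id"], categories=participants).codes
    c_code = pd.Categorical(data["coherence_pct"], categories=conditions).codes
    order = np.lexsort((c_code, p_code))
    df = data.iloc[order]
    p_sorted, c_sorted = p_code[order], c_code[order]

    P, K = len(participants), len(conditions)
    rt = df["rt_s"].to_numpy(dtype=np.float64)
    upper = (df["choice"].to_numpy() == "up").astype(np.int64)
    sign = np.where(df["direction"].to_numpy() == "up", 1, -1).astype(np.int64)

    counts = np.zeros((P, K), dtype=np.int64)
    np.add.at(counts, (p_sorted, c_sorted), 1)
    flat = np.concatenate([[0], np.cumsum(counts.ravel())])
    ptr = np.concatenate([flat[:-1].reshape(P, K), flat[K::K].reshape(P, 1)], axis=1)

    Z = {}
    for par, covs in spec.covariate_map.items():
        Z[par] = {c: cov.loc[participants, c].to_numpy(dtype=float) for c in covs}

    h = hashlib.sha256()
    h.update(rt.tobytes())
    h.update(upper.tobytes())
    h.update(sign.tobytes())
    return ModelGraph(spec, rt, upper, sign, ptr, participants, conditions, Z, h.hexdigest())
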