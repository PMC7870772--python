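"""MCMC for the hierarchical diffusion model.

The kernel is adaptive Metropolis-within-Gibbs: every participant-level
parameter and every group-level scalar gets a Gaussian random-walk update
whose proposal scale adapts during burn-in (then freezes, keeping the
chain Markovian afterwards); the g-prior scales are conjugate
inverse-gamma Gibbs draws.  Participant-level updates — the expensive
part, each requiring the Wiener first-passage likelihood over that
participant's trials — run inside a compiled numba kernel with the
per-(participant, condition) log-likelihood cached between updates.

Starting values are drawn from uniform distributions over the admissible
parameter ranges (non-decision time additionally capped below each
participant's fastest response so the initial likelihood is finite).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import ndtr

from ..wiener import SERIES_EPS, _wfpt_logpdf
from .model import BOUNDS, PRIORS, ModelGraph

__all__ = ["SamplerSettings", "PosteriorSamples", "sample_posterior", "total_deviance"]


@dataclass(frozen=True)
class SamplerSettings:
    """Chain configuration.  The default profile matches long production
    runs (3 x 10,000 retained); :meth:`reduced` is the profile used by the
    bundled analyses, and :meth:`smoke` is a fast profile for exercising
    the machinery."""

    n_chains: int = 3
    n_samples: int = 54_000
    n_burnin: int = 4_000
    thin: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= self.n_burnin:
            raise ValueError("n_samples must exceed n_burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_samples - self.n_burnin) // self.thin

    @classmethod
    def reduced(cls, seed: int = 0) -> "SamplerSettings":
        return cls(n_chains=3, n_samples=24_000, n_burnin=4_000, thin=5, seed=seed)

    @classmethod
    def smoke(cls, seed: int = 0) -> "SamplerSettings":
        return cls(n_chains=3, n_samples=2_000, n_burnin=500, thin=1, seed=seed)


@dataclass
class PosteriorSamples:
    """Retained draws: scalars as (chains, draws) arrays, participant
    blocks as (chains, draws, P[, k]) arrays, plus the deviance trace."""

    draws: dict
    deviance: np.ndarray
    metadata: dict = field(default_factory=dict)
    graph: ModelGraph | None = field(default=None, repr=False)

    def scalar_names(self) -> list:
        return [k for k, v in self.draws.items() if v.ndim == 2]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated along the draw axis."""
        v = self.draws[name]
        return v.reshape(-1, *v.shape[2:])

    def summary(self):
        import pandas as pd

        rows = []
        for name in self.scalar_names():
            x = self.stacked(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "q2.5": np.quantile(x, 0.025),
                    "q50": np.quantile(x, 0.5),
                    "q97.5": np.quantile(x, 0.975),
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.create_group("draws")
            for k, v in self.draws.items():
                g.create_dataset(k, data=v)
            f.create_dataset("deviance", data=self.deviance)
            meta = f.create_group("metadata")
            for k, v in self.metadata.items():
                meta.attrs[k] = v if isinstance(v, (int, float, str)) else str(v)

    @classmethod
    def from_hdf5(cls, path) -> "PosteriorSamples":
        import h5py

        with h5py.File(path, "r") as f:
            draws = {k: f["draws"][k][...] for k in f["draws"]}
            dev = f["deviance"][...]
            meta = dict(f["metadata"].attrs)
        return cls(draws=draws, deviance=dev, metadata=meta)


# --------------------------------------------------------------------------
# numba kernels
# --------------------------------------------------------------------------


@njit(cache=True)
def _slice_loglik(rt, upper, sign, i0, i1, alpha, beta, tau, delta):
    out = 0.0
    for i in range(i0, i1):
        out += _wfpt_logpdf(rt[i], upper[i], alpha, beta, tau, delta * sign[i], SERIES_EPS)
        if out == -np.inf:
            return -np.inf
    return out


@njit(cache=True)
def _participant_loglik_row(rt, upper, sign, ptr, p, K, alpha, beta, tau, delta_row, out_row):
    """Log-likelihood of participant p per condition into out_row; returns
    the row sum."""
    tot = 0.0
    for c in range(K):
        ll = _slice_loglik(rt, upper, sign, ptr[p, c], ptr[p, c + 1], alpha, beta, tau, delta_row[c])
        out_row[c] = ll
        tot += ll
    return tot


@njit(cache=True)
def _sweep_participants(
    rt, upper, sign, ptr,
    alpha, beta, tau, delta, ll_pc,
    m_alpha, s_alpha, m_beta, s_beta, m_tau, s_tau, m_delta, s_delta,
    sc_a, sc_b, sc_t, sc_d,
    zs, us,
    acc_a, acc_b, acc_t, acc_d,
    a_lo, a_hi, b_lo, b_hi, t_lo, t_hi, d_lo, d_hi,
):
    P = ptr.shape[0]
    K = ptr.shape[1] - 1
    new_row = np.empty(K)
    for p in range(P):
        cur_row_sum = 0.0
        for c in range(K):
            cur_row_sum += ll_pc[p, c]

        # --- boundary separation -----------------------------------------
        prop = alpha[p] + sc_a[p] * zs[p, 0]
        if a_lo < prop < a_hi:
            new_sum = _participant_loglik_row(
                rt, upper, sign, ptr, p, K, prop, beta[p], tau[p], delta[p], new_row
            )
            logr = (
                new_sum - cur_row_sum
                - ((prop - m_alpha[p]) ** 2 - (alpha[p] - m_alpha[p]) ** 2) / (2.0 * s_alpha**2)
            )
            if logr > 0.0 or np.log(us[p, 0]) < logr:
                alpha[p] = prop
                for c in range(K):
                    ll_pc[p, c] = new_row[c]
                cur_row_sum = new_sum
                acc_a[p] += 1

        # --- starting point ----------------------------------------------
        prop = beta[p] + sc_b[p] * zs[p, 1]
        if b_lo < prop < b_hi:
            new_sum = _participant_loglik_row(
                rt, upper, sign, ptr, p, K, alpha[p], prop, tau[p], delta[p], new_row
            )
            logr = (
                new_sum - cur_row_sum
                - ((prop - m_beta[p]) ** 2 - (beta[p] - m_beta[p]) ** 2) / (2.0 * s_beta**2)
            )
            if logr > 0.0 or np.log(us[p, 1]) < logr:
                beta[p] = prop
                for c in range(K):
                    ll_pc[p, c] = new_row[c]
                cur_row_sum = new_sum
                acc_b[p] += 1

        # --- non-decision time -------------------------------------------
        prop = tau[p] + sc_t[p] * zs[p, 2]
        if t_lo < prop < t_hi:
            new_sum = _participant_loglik_row(
                rt, upper, sign, ptr, p, K, alpha[p], beta[p], prop, delta[p], new_row
            )
            if new_sum > -np.inf:
                logr = (
                    new_sum - cur_row_sum
                    - ((prop - m_tau[p]) ** 2 - (tau[p] - m_tau[p]) ** 2) / (2.0 * s_tau**2)
                )
                if logr > 0.0 or np.log(us[p, 2]) < logr:
                    tau[p] = prop
                    for c in range(K):
                        ll_pc[p, c] = new_row[c]
                    cur_row_sum = new_sum
                    acc_t[p] += 1

        # --- drift rates per condition -----------------------------------
        for c in range(K):
            prop = delta[p, c] + sc_d[p, c] * zs[p, 3 + c]
            if d_lo < prop < d_hi:
                ll_new = _slice_loglik(
                    rt, upper, sign, ptr[p, c], ptr[p, c + 1], alpha[p], beta[p], tau[p], prop
                )
                logr = (
                    ll_new - ll_pc[p, c]
                    - ((prop - m_delta[p, c]) ** 2 - (delta[p, c] - m_delta[p, c]) ** 2)
                    / (2.0 * s_delta**2)
                )
                if logr > 0.0 or np.log(us[p, 3 + c]) < logr:
                    delta[p, c] = prop
                    ll_pc[p, c] = ll_new
                    acc_d[p, c] += 1


@njit(cache=True)
def _full_loglik(rt, upper, sign, ptr, alpha, beta, tau, delta, ll_pc):
    P = ptr.shape[0]
    K = ptr.shape[1] - 1
    tot = 0.0
    for p in range(P):
        tot += _participant_loglik_row(
            rt, upper, sign, ptr, p, K, alpha[p], beta[p], tau[p], delta[p], ll_pc[p]
        )
    return tot


# --------------------------------------------------------------------------
# group-level conditionals
# --------------------------------------------------------------------------


def _tn_logpdf_sum(x, m, s, lo, hi):
    """Summed log-density of truncated normals (normalisation included —
    it depends on the group-level parameters being updated)."""
    z = (x - m) / s
    norm = np.broadcast_to(ndtr((hi - m) / s) - ndtr((lo - m) / s), x.shape)
    if np.any(norm <= 0):
        return -np.inf
    return float(-x.size * np.log(s) - 0.5 * np.sum(z * z) - np.sum(np.log(norm)))


class _Chain:
    """One chain's full state and update machinery."""

    def __init__(self, graph: ModelGraph, rng: np.random.Generator):
        self.graph = graph
        self.rng = rng
        P, K = graph.n_participants, graph.n_conditions
        b = graph.bounds

        # group-level state
        st = {}
        st["mu_alpha"] = rng.uniform(0.6, 2.0)
        st["mu_beta"] = rng.uniform(0.4, 0.6)
        st["mu_tau"] = rng.uniform(0.2, 0.6)
        st["mu_delta"] = rng.uniform(0.5, 4.0)
        st["sigma_alpha"] = rng.uniform(0.1, 0.5)
        st["sigma_beta"] = rng.uniform(0.02, 0.15)
        st["sigma_tau"] = rng.uniform(0.03, 0.3)
        st["sigma_eps"] = rng.uniform(0.3, 1.2)
        st["g_theta"] = 1.0
        for n in range(K - 1):
            st[f"theta[{n}]"] = rng.normal(0, 0.3)
        for par, covs in graph.spec.covariate_map.items():
            st[f"g_{par}"] = 1.0
            for cov in covs:
                st[f"b_{par}_{cov}"] = rng.normal(0, 0.2)
        self.state = st

        # participant-level state
        self.alpha = rng.uniform(0.6, 2.0, P)
        self.beta = rng.uniform(0.4, 0.6, P)
        min_rt = np.array(
            [graph.rt[graph.ptr[p, 0]: graph.ptr[p, K]].min() for p in range(P)]
        )
        hi_tau = np.minimum(0.9 * min_rt, b["tau"][1])
        self.tau = b["tau"][0] + rng.uniform(0.2, 0.8, P) * np.maximum(
            hi_tau - b["tau"][0], 1e-3
        )
        self.delta = rng.uniform(0.5, 4.0, (P, K))
        self.ll_pc = np.empty((P, K))
        _full_loglik(
            graph.rt, graph.upper, graph.sign, graph.ptr,
            self.alpha, self.beta, self.tau, self.delta, self.ll_pc,
        )

        # proposal scales
        self.sc = {
            "alpha": np.full(P, 0.15),
            "beta": np.full(P, 0.05),
            "tau": np.full(P, 0.03),
            "delta": np.full((P, K), 0.3),
        }
        self.hyper_sc = {k: 0.1 for k in st if not k.startswith("g")}
        self.acc = {
            "alpha": np.zeros(P, dtype=np.int64),
            "beta": np.zeros(P, dtype=np.int64),
            "tau": np.zeros(P, dtype=np.int64),
            "delta": np.zeros((P, K), dtype=np.int64),
        }
        self.hyper_acc = {k: 0 for k in self.hyper_sc}
        self._sweep_count = 0

    # -- helpers -----------------------------------------------------------
    def _shifts(self):
        """Covariate shifts Z @ b per parameter (on the standardized scale)."""
        g = self.graph
        P = g.n_participants
        out = {"alpha": np.zeros(P), "tau": np.zeros(P), "delta": np.zeros(P)}
        for par, covs in g.spec.covariate_map.items():
            zb = np.zeros(P)
            for cov in covs:
                zb += self.state[f"b_{par}_{cov}"] * g.Z[par][cov]
            out[par] = zb
        return out

    def _group_logpost(self, st, shifts):
        """Log joint of the group-level state given participant params
        (hyperpriors + truncated-normal level densities)."""
        g = self.graph
        b = g.bounds
        lp = 0.0
        # hyperpriors
        for par in ("alpha", "beta", "tau", "delta"):
            m0, s0 = PRIORS[f"mu_{par}"]
            lo, hi = b[par]
            mu = st[f"mu_{par}"]
            if not lo <= mu <= hi:
                return -np.inf
            lp += -0.5 * ((mu - m0) / s0) ** 2
        for name in ("sigma_alpha", "sigma_beta", "sigma_tau", "sigma_eps"):
            s = st[name]
            if s <= 0:
                return -np.inf
            lp += -0.5 * (s / PRIORS[name]) ** 2
        K = g.n_conditions
        th = np.array([st[f"theta[{n}]"] for n in range(K - 1)])
        lp += -0.5 * np.sum(th * th) / st["g_theta"] - 0.5 * (K - 1) * np.log(st["g_theta"])
        for par, covs in g.spec.covariate_map.items():
            bb = np.array([st[f"b_{par}_{cov}"] for cov in covs])
            lp += -0.5 * np.sum(bb * bb) / st[f"g_{par}"] - 0.5 * len(covs) * np.log(st[f"g_{par}"])
        # level densities
        m_a = st["mu_alpha"] + st["sigma_alpha"] * shifts["alpha"]
        m_t = st["mu_tau"] + st["sigma_tau"] * shifts["tau"]
        offs = g.Q @ th
        m_d = st["mu_delta"] + st["sigma_eps"] * (offs[None, :] + shifts["delta"][:, None])
        lp += _tn_logpdf_sum(self.alpha, m_a, st["sigma_alpha"], *b["alpha"])
        lp += _tn_logpdf_sum(self.beta, np.full_like(self.alpha, st["mu_beta"]), st["sigma_beta"], *b["beta"])
        lp += _tn_logpdf_sum(self.tau, m_t, st["sigma_tau"], *b["tau"])
        lp += _tn_logpdf_sum(self.delta, m_d, st["sigma_eps"], *b["delta"])
        return lp

    # -- one sweep ---------------------------------------------------------
    def sweep(self):
        g = self.graph
        P, K = g.n_participants, g.n_conditions
        st = self.state
        shifts = self._shifts()

        m_a = st["mu_alpha"] + st["sigma_alpha"] * shifts["alpha"]
        m_b = np.full(P, st["mu_beta"])
        m_t = st["mu_tau"] + st["sigma_tau"] * shifts["tau"]
        offs = g.Q @ np.array([st[f"theta[{n}]"] for n in range(K - 1)])
        m_d = st["mu_delta"] + st["sigma_eps"] * (offs[None, :] + shifts["delta"][:, None])

        zs = self.rng.standard_normal((P, 3 + K))
        us = self.rng.random((P, 3 + K))
        lo, hi = zip(*(g.bounds[p] for p in ("alpha", "beta", "tau", "delta")))
        _sweep_participants(
            g.rt, g.upper, g.sign, g.ptr,
            self.alpha, self.beta, self.tau, self.delta, self.ll_pc,
            m_a, st["sigma_alpha"], m_b, st["sigma_beta"],
            m_t, st["sigma_tau"], m_d, st["sigma_eps"],
            self.sc["alpha"], self.sc["beta"], self.sc["tau"], self.sc["delta"],
            zs, us,
            self.acc["alpha"], self.acc["beta"], self.acc["tau"], self.acc["delta"],
            lo[0], hi[0], lo[1], hi[1], lo[2], hi[2], lo[3], hi[3],
        )

        # group-level scalar MH updates
        shifts = self._shifts()
        cur_lp = self._group_logpost(st, shifts)
        for name in sorted(self.hyper_sc):
            prop = dict(st)
            prop[name] = st[name] + self.hyper_sc[name] * self.rng.standard_normal()
            new_shifts = shifts
            if name.startswith("b_"):
                new_shifts = None  # recompute below
            if new_shifts is None:
                saved = st[name]
                st[name] = prop[name]
                new_shifts = self._shifts()
                st[name] = saved
            lp = self._group_logpost(prop, new_shifts)
            if lp - cur_lp > 0 or self.rng.random() < np.exp(min(lp - cur_lp, 0.0)):
                self.state = st = prop
                shifts = new_shifts
                cur_lp = lp
                self.hyper_acc[name] += 1

        # interweaved scale moves: the starting-point SD is funnel-prone
        # (its participant block barely informs the likelihood), so it gets
        # one every sweep; the other families rotate
        self.rescale_move("beta")
        self.rescale_move(("alpha", "tau", "delta")[self._sweep_count % 3])
        self._sweep_count += 1

        # conjugate Gibbs draws for the g-prior scales
        th = np.array([st[f"theta[{n}]"] for n in range(K - 1)])
        a_post = 0.5 * (1 + th.size)
        b_post = 0.5 * (1 + np.sum(th * th))
        st["g_theta"] = b_post / self.rng.gamma(a_post)
        for par, covs in g.spec.covariate_map.items():
            bb = np.array([st[f"b_{par}_{cov}"] for cov in covs])
            a_post = 0.5 * (1 + bb.size)
            b_post = 0.5 * (1 + np.sum(bb * bb))
            st[f"g_{par}"] = b_post / self.rng.gamma(a_post)

    def rescale_move(self, family: str, log_step: float = 0.3):
        """Joint scale move: propose sigma' = sigma * exp(eps) and rescale
        every participant deviation by sigma'/sigma.  Breaks the funnel
        coupling between a group SD and its participant block; the
        truncated-normal kernels and the Jacobian cancel, leaving the
        hyperprior, the truncation normalisations and the trial
        likelihood in the acceptance ratio."""
        g = self.graph
        st = self.state
        b = g.bounds
        shifts = self._shifts()
        K = g.n_conditions
        sig_name = {"alpha": "sigma_alpha", "beta": "sigma_beta",
                    "tau": "sigma_tau", "delta": "sigma_eps"}[family]
        sigma = st[sig_name]
        sigma_new = sigma * np.exp(log_step * self.rng.standard_normal())

        if family == "delta":
            th = np.array([st[f"theta[{n}]"] for n in range(K - 1)])
            offs = g.Q @ th
            base = offs[None, :] + shifts["delta"][:, None]
            m_old = st["mu_delta"] + sigma * base
            m_new = st["mu_delta"] + sigma_new * base
            x = self.delta
            lo, hi = b["delta"]
        else:
            shift = shifts.get(family, np.zeros(g.n_participants))
            if family == "beta":
                shift = np.zeros(g.n_participants)
            m_old = st[f"mu_{family}"] + sigma * shift
            m_new = st[f"mu_{family}"] + sigma_new * shift
            x = {"alpha": self.alpha, "beta": self.beta, "tau": self.tau}[family]
            lo, hi = b[family]
        x_new = m_new + (sigma_new / sigma) * (x - m_old)
        if np.any((x_new <= lo) | (x_new >= hi)):
            return
        # hyperprior (half-normal kernel) difference, plus the asymmetry of
        # the multiplicative proposal
        logr = -0.5 * ((sigma_new / PRIORS[sig_name]) ** 2 - (sigma / PRIORS[sig_name]) ** 2)
        logr += np.log(sigma_new / sigma)
        # truncation normalisation difference (kernels + Jacobian cancel)
        z_old = ndtr((hi - m_old) / sigma) - ndtr((lo - m_old) / sigma)
        z_new = ndtr((hi - m_new) / sigma_new) - ndtr((lo - m_new) / sigma_new)
        if np.any(z_new <= 0):
            return
        logr += float(np.sum(np.log(np.broadcast_to(z_old, x.shape)))
                      - np.sum(np.log(np.broadcast_to(z_new, x.shape))))
        # trial likelihood at the rescaled participant values
        ll_new = np.empty_like(self.ll_pc)
        args = {"alpha": self.alpha, "beta": self.beta, "tau": self.tau,
                "delta": self.delta}
        args[family] = x_new
        tot_new = _full_loglik(
            g.rt, g.upper, g.sign, g.ptr,
            np.ascontiguousarray(args["alpha"]), np.ascontiguousarray(args["beta"]),
            np.ascontiguousarray(args["tau"]), np.ascontiguousarray(args["delta"]),
            ll_new,
        )
        logr += tot_new - self.ll_pc.sum()
        if logr > 0 or self.rng.random() < np.exp(max(logr, -700.0)):
            st[sig_name] = float(sigma_new)
            if family == "delta":
                self.delta = x_new
            elif family == "alpha":
                self.alpha = x_new
            elif family == "beta":
                self.beta = x_new
            else:
                self.tau = x_new
            self.ll_pc = ll_new

    def adapt(self, batch: int, batch_size: int, target: float = 0.35):
        """Robbins–Monro style scale adaptation (burn-in only)."""
        step = min(0.25, 2.0 / np.sqrt(batch + 1))
        for key in ("alpha", "beta", "tau", "delta"):
            rate = self.acc[key] / batch_size
            self.sc[key] *= np.exp(step * (rate - target))
            self.acc[key][...] = 0
        for name in self.hyper_sc:
            rate = self.hyper_acc[name] / batch_size
            self.hyper_sc[name] *= np.exp(step * (rate - target))
            self.hyper_acc[name] = 0


def sample_posterior(graph: ModelGraph, settings: SamplerSettings) -> PosteriorSamples:
    """Run the MCMC and return retained draws.

    Seed-deterministic: chain c uses ``SeedSequence([seed, c])`` and all
    randomness flows through that generator.
    """
    t0 = time.time()
    P, K = graph.n_participants, graph.n_conditions
    C, D = settings.n_chains, settings.n_retained
    scalar_names = [n for n in graph.node_names() if n not in ("alpha", "beta", "tau", "delta")]
    draws = {n: np.empty((C, D)) for n in scalar_names}
    draws["alpha"] = np.empty((C, D, P))
    draws["beta"] = np.empty((C, D, P))
    draws["tau"] = np.empty((C, D, P))
    draws["delta"] = np.empty((C, D, P, K))
    deviance = np.empty((C, D))

    batch_size = 50
    for c in range(C):
        rng = np.random.default_rng(np.random.SeedSequence([settings.seed, c]))
        chain = _Chain(graph, rng)
        d = 0
        for i in range(settings.n_samples):
            chain.sweep()
            if i < settings.n_burnin:
                if (i + 1) % batch_size == 0:
                    chain.adapt((i + 1) // batch_size, batch_size)
            else:
                j = i - settings.n_burnin
                if j % settings.thin == 0 and d < D:
                    for n in scalar_names:
                        draws[n][c, d] = chain.state[n]
                    draws["alpha"][c, d] = chain.alpha
                    draws["beta"][c, d] = chain.beta
                    draws["tau"][c, d] = chain.tau
                    draws["delta"][c, d] = chain.delta
                    deviance[c, d] = -2.0 * chain.ll_pc.sum()
                    d += 1

    meta = {
        "model": graph.spec.label,
        "seed": settings.seed,
        "n_chains": C,
        "n_retained": D,
        "runtime_s": round(time.time() - t0, 2),
        "data_hash": graph.data_hash,
    }
    return PosteriorSamples(draws=draws, deviance=deviance, metadata=meta, graph=graph)


def total_deviance(graph: ModelGraph, alpha, beta, tau, delta) -> float:
    """Deviance (-2 log likelihood) at the given participant-level values."""
    ll_pc = np.empty((graph.n_participants, graph.n_conditions))
    ll = _full_loglik(
        graph.rt, graph.upper, graph.sign, graph.ptr,
        np.ascontiguousarray(alpha, dtype=np.float64),
        np.ascontiguousarray(beta, dtype=np.float64),
        np.ascontiguousarray(tau, dtype=np.float64),
        np.ascontiguousarray(delta, dtype=np.float64),
        ll_pc,
    )
    return -2.0 * ll
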