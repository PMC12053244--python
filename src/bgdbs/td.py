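"""Hierarchical Bayesian temporal-difference modeling of choice data.

A TD learner with softmax action selection assigns each option a Q-value,
updated by the delta rule ``Q_a <- Q_a + alpha (r - Q_a)`` (optionally with
separate learning rates for positive and negative prediction errors), and
chooses option 1 with probability ``p = e^{beta Q1} / (e^{beta Q1} + e^{beta Q2})``.
Choices are Bernoulli in ``p``.

Parameters are estimated per subject and DBS state with a hierarchical,
noncentered parameterization: in logit space,

    theta_{i,j} = theta_max * f(mu + z_i sigma + j (mu_DBS + z_i^DBS sigma_DBS)),
    f(x) = 1 / (1 + e^{-x}),

with normal priors on the group means, exponential priors on the group
scales and standard-normal subject offsets.  Priors are stated in the
original parameter space and mapped to logit space by matching location
exactly and spread to first order (delta method).  Sampling uses an
affine-invariant ensemble MCMC; convergence is assessed with the
Gelman-Rubin statistic (required < 1.1).

The fitted posterior supports reconstruction of expected Q trajectories and
P(Explore) — the per-session proportion of trials on which the chosen
option's expected Q-value is strictly lower than the alternative's — and
model ranking by leave-one-out cross-validated expected log predictive
density.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az
import emcee

from .specs import default_config

__all__ = [
    "ChoiceDataset",
    "TDPriors",
    "TDModel",
    "TDResults",
    "td_simulate",
    "td_loglik",
    "p_explore",
    "compare_models",
]

RHAT_LIMIT = 1.1


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass
class ChoiceDataset:
    """Choice/outcome sequences per subject and DBS state.

    ``choices`` and ``rewards`` are ``(n_subjects, n_states, n_trials)``
    integer arrays (choice index in {0, 1}; reward in {0, 1}); DBS state is
    coded j = 0 (OFF) / 1 (ON) along the second axis.
    """

    choices: np.ndarray
    rewards: np.ndarray

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.int64)
        if self.choices.shape != self.rewards.shape or self.choices.ndim != 3:
            raise ValueError("choices and rewards must both be (subjects, states, trials)")
        if not np.isin(self.choices, [0, 1]).all():
            raise ValueError("choices must be coded 0/1")
        chosen_counts = np.bincount(self.choices.ravel(), minlength=2)
        if chosen_counts.min() == 0:
            raise ValueError("degenerate dataset: one option is never chosen")

    @property
    def n_subjects(self) -> int:
        return self.choices.shape[0]

    @property
    def n_states(self) -> int:
        return self.choices.shape[1]

    @property
    def n_trials(self) -> int:
        return self.choices.shape[2]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ChoiceDataset":
        """Build from a tidy frame with columns subject, dbs_state, trial, choice, reward."""
        df = df.sort_values(["subject", "dbs_state", "trial"])
        subjects = df["subject"].unique()
        states = np.sort(df["dbs_state"].unique())
        trials = df["trial"].nunique()
        shape = (len(subjects), len(states), trials)
        choices = df["choice"].to_numpy().reshape(shape)
        rewards = df["reward"].to_numpy().reshape(shape)
        return cls(choices, rewards)

    @classmethod
    def from_task_results(cls, off_result, on_result) -> "ChoiceDataset":
        """Pair an OFF and an ON :class:`~bgdbs.task.TaskResult` (same seeds)."""
        if not np.array_equal(off_result.seeds, on_result.seeds):
            raise ValueError("paired runs must share seeds")
        choices = np.stack([off_result.choices, on_result.choices], axis=1)
        rewards = np.stack(
            [off_result.rewarded.astype(int), on_result.rewarded.astype(int)], axis=1
        )
        return cls(choices, rewards)

    def to_dataframe(self) -> pd.DataFrame:
        n, j, t = self.choices.shape
        idx = np.indices((n, j, t))
        return pd.DataFrame(
            {
                "subject": idx[0].ravel(),
                "dbs_state": idx[1].ravel(),
                "trial": idx[2].ravel(),
                "choice": self.choices.ravel(),
                "reward": self.rewards.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    mu: float
    sigma_mu: float
    sigma_z: float
    sigma_mu_dbs: float
    sigma_z_dbs: float
    theta_max: float

    def to_logit(self) -> dict[str, float]:
        """Map the original-space prior to logit space.

        The location maps exactly through the inverse scaled sigmoid; spreads
        are scaled by the inverse local derivative of the transform at the
        prior mean (first-order / delta-method matching).
        """
        s = self.mu / self.theta_max
        if not 0 < s < 1:
            raise ValueError("prior mean must lie strictly inside (0, theta_max)")
        mu_t = float(np.log(s / (1 - s)))
        scale = 1.0 / (self.theta_max * s * (1 - s))
        return {
            "mu": mu_t,
            "sigma_mu": self.sigma_mu * scale,
            "sigma_z": self.sigma_z * scale,
            "sigma_mu_dbs": self.sigma_mu_dbs * scale,
            "sigma_z_dbs": self.sigma_z_dbs * scale,
            "theta_max": self.theta_max,
        }


@dataclass(frozen=True)
class TDPriors:
    alpha: PriorSpec
    beta: PriorSpec

    @classmethod
    def default(cls) -> "TDPriors":
        cfg = default_config().td_priors
        return cls(alpha=PriorSpec(**cfg["alpha"]), beta=PriorSpec(**cfg["beta"]))

    def for_param(self, name: str) -> PriorSpec:
        return self.alpha if name.startswith("alpha") else self.beta


# ---------------------------------------------------------------------------
# TD likelihood / simulation
# ---------------------------------------------------------------------------

def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # stable log(1/(1+e^-x))
    return np.where(x >= 0, -np.log1p(np.exp(-np.clip(x, None, 500))),
                    x - np.log1p(np.exp(np.clip(x, None, 500))))


def td_loglik(
    choices: np.ndarray,
    rewards: np.ndarray,
    alpha_plus: np.ndarray | float,
    alpha_minus: np.ndarray | float,
    beta: np.ndarray | float,
    return_pointwise: bool = False,
    return_q: bool = False,
):
    """Log-likelihood of choice sequences under the TD softmax model.

    ``choices``/``rewards`` are ``(..., T)``; the learning-rate and inverse
    temperature arrays broadcast against the leading axes.  Q-values start
    at 0; the chosen option's Q is updated with ``alpha_plus`` for positive
    and ``alpha_minus`` for negative prediction errors.
    """
    choices = np.asarray(choices)
    rewards = np.asarray(rewards)
    T = choices.shape[-1]
    ap = np.asarray(alpha_plus, dtype=float)
    am = np.asarray(alpha_minus, dtype=float)
    b = np.asarray(beta, dtype=float)
    lead = np.broadcast_shapes(choices.shape[:-1], ap.shape, am.shape, b.shape)
    q0 = np.zeros(lead)
    q1 = np.zeros(lead)
    ll_point = np.zeros(lead + (T,)) if return_pointwise else None
    qs = np.zeros(lead + (T, 2)) if return_q else None
    total = np.zeros(lead)
    for t in range(T):
        a = choices[..., t]
        r = rewards[..., t]
        if return_q:
            qs[..., t, 0] = q0
            qs[..., t, 1] = q1
        d = b * (q0 - q1)  # log-odds of choosing option 0
        ll_t = np.where(a == 0, _log_sigmoid(d), _log_sigmoid(-d))
        total += ll_t
        if return_pointwise:
            ll_point[..., t] = ll_t
        q_a = np.where(a == 0, q0, q1)
        delta = r - q_a
        alpha = np.where(delta > 0, ap, am)
        q_new = q_a + alpha * delta
        q0 = np.where(a == 0, q_new, q0)
        q1 = np.where(a == 1, q_new, q1)
    out = [total]
    if return_pointwise:
        out.append(ll_point)
    if return_q:
        out.append(qs)
    return out[0] if len(out) == 1 else tuple(out)


def td_simulate(
    params: Mapping[str, float] | Sequence[float],
    reward_schedule: np.ndarray,
    n_trials: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a TD softmax agent on a pre-drawn reward schedule.

    ``params`` is ``(alpha_plus, alpha_minus, beta)`` (a single-rate agent
    passes equal rates); ``reward_schedule`` is ``(T, 2)`` of 0/1 outcomes
    per (trial, option).  Returns (choices, outcomes).
    """
    if isinstance(params, Mapping):
        ap, am, b = params.get("alpha_plus", params.get("alpha")), None, params["beta"]
        am = params.get("alpha_minus", params.get("alpha"))
    else:
        ap, am, b = params
    if not (0 <= ap <= 1 and 0 <= am <= 1):
        raise ValueError("learning rates must lie in [0, 1]")
    if b < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(rng)
    schedule = np.asarray(reward_schedule)
    T = len(schedule) if n_trials is None else int(n_trials)
    q = np.zeros(2)
    choices = np.zeros(T, dtype=np.int64)
    outcomes = np.zeros(T, dtype=np.int64)
    for t in range(T):
        p1 = 1.0 / (1.0 + np.exp(-b * (q[1] - q[0])))
        a = int(rng.random() < p1)
        r = int(schedule[t, a])
        delta = r - q[a]
        q[a] += (ap if delta > 0 else am) * delta
        choices[t] = a
        outcomes[t] = r
    return choices, outcomes


# ---------------------------------------------------------------------------
# hierarchical model
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class TDModel:
    """Hierarchical TD model over a :class:`ChoiceDataset`.

    ``variant`` selects a single learning rate (``single_rate``) or separate
    rates for positive/negative prediction errors (``dual_rate``).  Call
    :meth:`fit` to sample the posterior.
    """

    def __init__(
        self,
        data: ChoiceDataset,
        variant: str = "dual_rate",
        priors: TDPriors | None = None,
    ):
        if variant not in ("single_rate", "dual_rate"):
            raise ValueError(f"unknown variant {variant!r}")
        self.data = data
        self.variant = variant
        self.priors = priors or TDPriors.default()
        self.param_names = (
            ["alpha_plus", "alpha_minus", "beta"]
            if variant == "dual_rate"
            else ["alpha", "beta"]
        )
        self._logit = {k: self.priors.for_param(k).to_logit() for k in self.param_names}
        N = data.n_subjects
        self._block = 4 + 2 * N  # mu, mu_dbs, log sigma, log sigma_dbs, z, z_dbs
        self.ndim = self._block * len(self.param_names)
        # j index per (subject, state)
        self._j = np.arange(data.n_states)[None, :]

    # -- parameter bookkeeping -------------------------------------------
    def _unpack(self, theta: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Split a (W, ndim) matrix into per-parameter pieces."""
        N = self.data.n_subjects
        out = {}
        for k, name in enumerate(self.param_names):
            blk = theta[:, k * self._block : (k + 1) * self._block]
            out[name] = {
                "mu": blk[:, 0],
                "mu_dbs": blk[:, 1],
                "log_sig": blk[:, 2],
                "log_sig_dbs": blk[:, 3],
                "z": blk[:, 4 : 4 + N],
                "z_dbs": blk[:, 4 + N : 4 + 2 * N],
            }
        return out

    def subject_theta(self, pieces: Mapping[str, np.ndarray], name: str) -> np.ndarray:
        """theta_{i,j} (W, N, n_states) in original parameter space."""
        lg = self._logit[name]
        p = pieces
        sig = np.exp(p["log_sig"])[:, None]
        sig_dbs = np.exp(p["log_sig_dbs"])[:, None]
        base = p["mu"][:, None] + p["z"] * sig  # (W, N)
        shift = p["mu_dbs"][:, None] + p["z_dbs"] * sig_dbs
        x = base[:, :, None] + self._j[None] * shift[:, :, None]
        return lg["theta_max"] * _sigmoid(x)

    def _log_prior(self, pieces: dict[str, dict[str, np.ndarray]]) -> np.ndarray:
        lp = 0.0
        for name in self.param_names:
            lg = self._logit[name]
            p = pieces[name]
            lp = lp - 0.5 * ((p["mu"] - lg["mu"]) / lg["sigma_mu"]) ** 2
            lp = lp - 0.5 * (p["mu_dbs"] / lg["sigma_mu_dbs"]) ** 2
            # exponential prior on sigma, sampled as log sigma (Jacobian = sigma)
            for key, scale in (("log_sig", lg["sigma_z"]), ("log_sig_dbs", lg["sigma_z_dbs"])):
                sig = np.exp(p[key])
                lp = lp - sig / scale + p[key]
            lp = lp - 0.5 * np.sum(p["z"] ** 2, axis=1)
            lp = lp - 0.5 * np.sum(p["z_dbs"] ** 2, axis=1)
        return lp

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized log posterior for a (W, ndim) walker matrix."""
        theta = np.atleast_2d(theta)
        pieces = self._unpack(theta)
        lp = self._log_prior(pieces)
        if self.variant == "dual_rate":
            ap = self.subject_theta(pieces["alpha_plus"], "alpha_plus")
            am = self.subject_theta(pieces["alpha_minus"], "alpha_minus")
        else:
            ap = am = self.subject_theta(pieces["alpha"], "alpha")
        b = self.subject_theta(pieces["beta"], "beta")
        ll = td_loglik(
            self.data.choices[None], self.data.rewards[None], ap, am, b
        )
        return lp + ll.sum(axis=(1, 2))

    # -- sampling ---------------------------------------------------------
    def fit(
        self,
        draws: int = 4000,
        tune: int = 2000,
        chains: int = 4,
        seed: int = 0,
        nwalkers: int | None = None,
        progress: bool = False,
    ) -> "TDResults":
        """Sample the posterior with an affine-invariant ensemble sampler.

        ``chains`` x ``draws`` total posterior draws are kept (the walker
        ensemble is thinned to that budget after discarding ``tune``
        adaptation steps).
        """
        rng = np.random.default_rng(seed)
        W = nwalkers or max(2 * self.ndim + 2, 64)
        p0 = self._init_walkers(W, rng)
        sampler = emcee.EnsembleSampler(
            W, self.ndim, self.log_prob, vectorize=True
        )
        target = chains * draws
        keep_steps = max(int(np.ceil(target / W)), 2)
        state = sampler.run_mcmc(
            p0, tune, progress=progress, skip_initial_state_check=True
        )
        sampler.reset()
        sampler.run_mcmc(
            state, keep_steps, progress=progress, skip_initial_state_check=True
        )
        chain = sampler.get_chain()  # (steps, W, ndim)
        return TDResults(self, chain, chains=chains)

    def _init_walkers(self, W: int, rng: np.random.Generator) -> np.ndarray:
        N = self.data.n_subjects
        p0 = np.empty((W, self.ndim))
        for k, name in enumerate(self.param_names):
            lg = self._logit[name]
            off = k * self._block
            p0[:, off + 0] = lg["mu"] + 0.2 * lg["sigma_mu"] * rng.standard_normal(W)
            p0[:, off + 1] = 0.1 * lg["sigma_mu_dbs"] * rng.standard_normal(W)
            p0[:, off + 2] = np.log(0.5 * lg["sigma_z"]) + 0.1 * rng.standard_normal(W)
            p0[:, off + 3] = np.log(0.5 * lg["sigma_z_dbs"]) + 0.1 * rng.standard_normal(W)
            p0[:, off + 4 : off + 4 + 2 * N] = 0.2 * rng.standard_normal((W, 2 * N))
        return p0


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class TDResults:
    """Posterior samples, convergence diagnostics and derived quantities."""

    def __init__(self, model: TDModel, chain: np.ndarray, chains: int = 4):
        self.model = model
        self.data = model.data
        steps, W, _ = chain.shape
        # fold the walker ensemble into `chains` pseudo-chains for diagnostics
        W_eff = (W // chains) * chains
        folded = chain[:, :W_eff, :].reshape(steps, chains, W_eff // chains, -1)
        self._flat = folded.transpose(1, 0, 2, 3).reshape(chains, steps * (W_eff // chains), -1)
        pieces = model._unpack(self._flat.reshape(-1, model.ndim))
        C, D = self._flat.shape[:2]
        self.theta: dict[str, np.ndarray] = {}
        for name in model.param_names:
            th = model.subject_theta(pieces[name], name)
            self.theta[name] = th.reshape(C, D, *th.shape[1:])
        self.group: dict[str, np.ndarray] = {}
        for name in model.param_names:
            for key in ("mu", "mu_dbs", "log_sig", "log_sig_dbs"):
                self.group[f"{name}_{key}"] = pieces[name][key].reshape(C, D)
        self.rhat = self._compute_rhat()
        self.converged = bool(max(self.rhat.values()) < RHAT_LIMIT)
        if not self.converged:
            warnings.warn(
                f"MCMC convergence not reached (max R-hat = {max(self.rhat.values()):.3f})",
                stacklevel=2,
            )

    # -- diagnostics ------------------------------------------------------
    def _compute_rhat(self) -> dict[str, float]:
        out = {}
        for name, th in self.theta.items():
            r = az.rhat(az.convert_to_dataset(th))
            out[name] = float(np.max(r.to_array().values))
        return out

    @property
    def n_draws(self) -> int:
        return self._flat.shape[0] * self._flat.shape[1]

    def posterior_mean(self, name: str) -> np.ndarray:
        """Posterior-mean theta_{i,j} (subjects x states)."""
        return self.theta[name].mean(axis=(0, 1))

    def credible_interval(self, name: str, prob: float = 0.95) -> np.ndarray:
        lo = (1 - prob) / 2
        flat = self.theta[name].reshape(-1, *self.theta[name].shape[2:])
        return np.quantile(flat, [lo, 1 - lo], axis=0)

    def summary(self) -> pd.DataFrame:
        """Posterior summary per parameter x subject x DBS state."""
        rows = []
        for name in self.model.param_names:
            mean = self.posterior_mean(name)
            ci = self.credible_interval(name)
            for i in range(self.data.n_subjects):
                for j in range(self.data.n_states):
                    rows.append(
                        {
                            "parameter": name,
                            "subject": i,
                            "dbs_state": j,
                            "mean": float(mean[i, j]),
                            "hdi_2.5%": float(ci[0, i, j]),
                            "hdi_97.5%": float(ci[1, i, j]),
                            "r_hat": self.rhat[name],
                        }
                    )
        return pd.DataFrame(rows)

    # -- derived quantities ----------------------------------------------
    def expected_q(self, max_draws: int = 4000) -> np.ndarray:
        """Expected Q trajectories (subjects, states, trials, 2), averaged
        over posterior draws of the learning rates."""
        ap, am = self._rate_draws(max_draws)
        _, qs = td_loglik(
            self.data.choices[None],
            self.data.rewards[None],
            ap,
            am,
            np.ones_like(ap),
            return_q=True,
        )
        return qs.mean(axis=0)

    def _rate_draws(self, max_draws: int) -> tuple[np.ndarray, np.ndarray]:
        names = (
            ("alpha_plus", "alpha_minus")
            if self.model.variant == "dual_rate"
            else ("alpha", "alpha")
        )
        ap = self.theta[names[0]].reshape(-1, self.data.n_subjects, self.data.n_states)
        am = self.theta[names[1]].reshape(-1, self.data.n_subjects, self.data.n_states)
        if len(ap) > max_draws:
            idx = np.linspace(0, len(ap) - 1, max_draws).astype(int)
            ap, am = ap[idx], am[idx]
        return ap, am

    def p_explore(self, session_length: int = 40, max_draws: int = 4000) -> pd.DataFrame:
        """P(Explore) per subject x session x DBS state.

        A trial is exploratory iff the chosen option's expected Q-value is
        strictly lower than the alternative's (ties count as non-exploratory).
        """
        return p_explore(self, session_length=session_length, max_draws=max_draws)

    def pointwise_loglik(self, max_draws: int = 1000) -> np.ndarray:
        """Per-trial pointwise log-likelihood (chain, draw, obs) for LOO."""
        ap, am = self._rate_draws(max_draws)
        b = self.theta["beta"].reshape(-1, self.data.n_subjects, self.data.n_states)
        if len(b) > len(ap):
            idx = np.linspace(0, len(b) - 1, len(ap)).astype(int)
            b = b[idx]
        _, pointwise = td_loglik(
            self.data.choices[None], self.data.rewards[None], ap, am, b,
            return_pointwise=True,
        )
        return pointwise.reshape(1, len(ap), -1)

    def to_inference_data(self, max_draws: int = 1000) -> az.InferenceData:
        ll = self.pointwise_loglik(max_draws)
        return az.from_dict(
            posterior={k: v for k, v in self.group.items()},
            log_likelihood={"choice": ll},
        )

    def loo(self, max_draws: int = 1000):
        """Leave-one-out expected log predictive density (PSIS-LOO)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.loo(self.to_inference_data(max_draws))


def p_explore(
    results: TDResults, session_length: int = 40, max_draws: int = 4000
) -> pd.DataFrame:
    """P(Explore): proportion of low-expected-value choices per session."""
    q = results.expected_q(max_draws)  # (N, J, T, 2)
    data = results.data
    chosen = np.take_along_axis(q, data.choices[..., None], axis=-1)[..., 0]
    other = np.take_along_axis(q, (1 - data.choices)[..., None], axis=-1)[..., 0]
    explore = chosen < other
    T = data.n_trials
    n_sessions = T // session_length
    rows = []
    per_session = explore[..., : n_sessions * session_length].reshape(
        data.n_subjects, data.n_states, n_sessions, session_length
    ).mean(axis=-1)
    for i in range(data.n_subjects):
        for j in range(data.n_states):
            for s in range(n_sessions):
                rows.append(
                    {
                        "subject": i,
                        "dbs_state": j,
                        "session": s + 1,
                        "p_explore": float(per_session[i, j, s]),
                    }
                )
    return pd.DataFrame(rows)


def compare_models(fits: Mapping[str, TDResults], max_draws: int = 1000) -> pd.DataFrame:
    """Rank fitted model variants by PSIS-LOO ELPD (best first)."""
    if len(fits) == 0:
        raise ValueError("no fitted models to compare")
    if len(fits) == 1:
        name = next(iter(fits))
        loo = fits[name].loo(max_draws)
        return pd.DataFrame(
            [{"model": name, "rank": 0, "elpd_loo": float(loo.elpd_loo), "se": float(loo.se)}]
        ).set_index("model")
    idata = {k: v.to_inference_data(max_draws) for k, v in fits.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare(idata, ic="loo")
    return cmp
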