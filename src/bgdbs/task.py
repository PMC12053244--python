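"""The two-choice probabilistic reward reversal learning task and trial loop.

Each trial: a 100 ms relaxation period without input, then both cortical
input neurons are driven (the two stimuli are always co-presented) until a
decision cortex unit crosses the decision threshold (or 3000 ms elapse, in
which case the more active unit is taken).  The chosen option's pre-drawn
reward outcome then gates a 60 ms reward window: the PPN relays reward
delivery to the dopamine unit while the reward-window gate enables phasic
dopamine and therefore basal-ganglia learning.  Reward probabilities are
80:20 for the two options and reverse to 20:80 after trial 60.

The :class:`Simulator` advances a whole batch of independently seeded
simulations in lockstep (each seed runs its own trial state machine), which
is what makes 100-seed condition sweeps cheap.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
import pandas as pd

from .connectome import (
    PH_DECIDE,
    PH_DONE,
    PH_PRE,
    PH_REWARD,
    NetworkState,
    build_default_model,
)
from .dbs import DBSConfig, dbs_variant_config, suppression_current
from .network import DT, relu
from .plasticity import (
    DAPlasticityParams,
    ShortcutPlasticityParams,
    da_update,
    prediction_update,
    shortcut_update,
)
from .specs import NetworkConfig, default_config

__all__ = ["TaskConfig", "TrialRecord", "TaskResult", "Simulator", "run_trial", "run_task", "run_task_batch"]


@dataclass(frozen=True)
class TaskConfig:
    n_trials: int = 120
    session_length: int = 40
    reversal_trial: int = 60
    p_high: float = 0.8
    p_low: float = 0.2
    pre_stimulus_ms: int = 100
    decision_threshold: float = 1.62
    max_decision_ms: int = 3000
    reward_window_ms: int = 60
    reset_between_trials: bool = True

    @classmethod
    def from_config(cls, cfg: NetworkConfig) -> "TaskConfig":
        return cls(**cfg.task)

    @property
    def n_sessions(self) -> int:
        return self.n_trials // self.session_length


@dataclass
class TrialRecord:
    """One trial's outcome plus the traces the downstream analyses need."""

    trial: int
    choice: int
    rewarded: bool
    latency: int
    psp_shortcut: np.ndarray  # (2,) thalamic psp from cortex, decision-epoch mean
    psp_gpi: np.ndarray  # (2,) thalamic psp from GPi, decision-epoch mean
    mean_rates: dict[str, float] = field(default_factory=dict)
    weights: dict[str, np.ndarray] = field(default_factory=dict)  # at trial start


@dataclass
class TaskResult:
    """Batched trial records for a full task run (arrays indexed [sim, trial])."""

    seeds: np.ndarray
    dbs_variant: str
    dbs_on: bool
    shortcut: str
    choices: np.ndarray  # (S, T) int
    rewarded: np.ndarray  # (S, T) bool
    latency: np.ndarray  # (S, T) int
    psp_shortcut: np.ndarray  # (S, T, 2)
    psp_gpi: np.ndarray  # (S, T, 2)
    weights: dict[str, np.ndarray]  # projection -> (S, T, n_pre, n_post) at trial start
    mean_rates: dict[str, np.ndarray]  # population -> (S, T)
    session_length: int = 40
    snapshots: dict[int, dict[str, Any]] = field(default_factory=dict)
    reward_schedule: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.choices.shape[1]

    def records(self, sim: int = 0) -> list[TrialRecord]:
        """Per-trial records for one simulation of the batch."""
        out = []
        for k in range(self.n_trials):
            out.append(
                TrialRecord(
                    trial=k,
                    choice=int(self.choices[sim, k]),
                    rewarded=bool(self.rewarded[sim, k]),
                    latency=int(self.latency[sim, k]),
                    psp_shortcut=self.psp_shortcut[sim, k],
                    psp_gpi=self.psp_gpi[sim, k],
                    mean_rates={p: float(v[sim, k]) for p, v in self.mean_rates.items()},
                    weights={p: w[sim, k] for p, w in self.weights.items()},
                )
            )
        return out

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-trial table (one row per simulation x trial)."""
        S, T = self.choices.shape
        sim, trial = np.meshgrid(np.arange(S), np.arange(T), indexing="ij")
        return pd.DataFrame(
            {
                "sim": sim.ravel(),
                "seed": np.repeat(self.seeds, T),
                "trial": trial.ravel(),
                "session": trial.ravel() // self.session_length + 1,
                "dbs_variant": self.dbs_variant,
                "dbs_on": self.dbs_on,
                "shortcut": self.shortcut,
                "choice": self.choices.ravel(),
                "rewarded": self.rewarded.ravel().astype(int),
                "latency": self.latency.ravel(),
            }
        )


class Simulator:
    """Forward-Euler trial-loop engine over a batch of seeded simulations."""

    def __init__(
        self,
        state: NetworkState,
        dbs: DBSConfig | str = "off",
        dbs_on: bool | None = None,
        task: TaskConfig | None = None,
        record_rates: Iterable[str] | bool = True,
        snapshot_trials: Iterable[int] = (),
    ):
        self.state = state
        cfg = state.cfg
        if isinstance(dbs, str):
            dbs = dbs_variant_config(dbs, cfg)
        self.dbs = dbs
        self.dbs_on = (dbs.variant != "off") if dbs_on is None else bool(dbs_on)
        self.task = task or TaskConfig.from_config(cfg)
        self.snapshot_trials = set(int(k) for k in snapshot_trials)
        if record_rates is True:
            record_rates = [p for p, v in cfg.populations.items() if v.kind != "snc"]
        self.record_pops = [
            p for p in (record_rates or []) if cfg.populations[p].kind != "snc"
        ]
        self._compile()
        self._alloc()

    # -- compilation ------------------------------------------------------
    def _compile(self) -> None:
        """Flatten the network into one state matrix and one signed weight
        matrix for all fixed projections (plastic ones stay separate), so a
        step costs a single BLAS product plus a handful of small batched
        products instead of one call per projection."""
        cfg = self.state.cfg
        st = self.state
        S = st.n_sims
        flag = 1 if self.dbs_on else 0
        axon = self.dbs.axon_rates(flag)
        self.alpha_suppress = self.dbs.alpha_suppress * flag

        # column layout (the dopamine unit is integrated separately; it has
        # no outgoing projections into the rate system)
        self._order = [p for p in cfg.populations if cfg.populations[p].kind != "snc"]
        self._sl: dict[str, slice] = {}
        off = 0
        for p in self._order:
            n = cfg.populations[p].n
            self._sl[p] = slice(off, off + n)
            off += n
        Nf = self._Nf = off
        snc_name = next(p for p, v in cfg.populations.items() if v.kind == "snc")
        self._snc = cfg.populations[snc_name]
        self._snc_name = snc_name

        # flat state; population dicts become column views
        self._mp = np.zeros((S, Nf))
        self._rr = np.zeros((S, Nf))
        for p in self._order:
            self._mp[:, self._sl[p]] = st.mp[p]
            self._rr[:, self._sl[p]] = st.r[p]
            st.mp[p] = self._mp[:, self._sl[p]]
            st.r[p] = self._rr[:, self._sl[p]]

        # per-neuron constants
        self._kvec = np.zeros(Nf)
        self._Bvec = np.zeros(Nf)
        lamvec = np.zeros(Nf)
        self._input_cols: dict[str, slice] = {}
        for p in self._order:
            pop = cfg.populations[p]
            sl = self._sl[p]
            if pop.kind == "input":
                self._input_cols[p] = sl
                continue
            self._kvec[sl] = DT / pop.tau
            self._Bvec[sl] = pop.B
            lamvec[sl] = pop.lam
        noise_cols = [
            np.arange(Nf)[self._sl[p]]
            for p in self._order
            if p in self.state.noise.dims
        ]
        self._noise_cols = np.concatenate(noise_cols) if noise_cols else np.array([], int)
        self._noise_lam = lamvec[self._noise_cols]

        # fixed projections -> one signed matrix; constant axonal drive folds
        # into a bias vector (r_axon is constant while DBS is on)
        W = np.zeros((Nf, Nf))
        self._axon_bias = np.zeros(Nf)
        self._plastic: list[tuple[str, slice, slice, float, float]] = []
        self._snc_pred_name = None
        self._snc_ppn: tuple[np.ndarray, slice] | None = None
        for proj in cfg.projections.values():
            sign = 1.0 if proj.target == "exc" else -1.0
            a = float(axon.get(proj.name, 0.0))
            if proj.post == snc_name:
                if proj.plasticity == "da_snc":
                    self._snc_pred_name = proj.name
                else:
                    w2 = st.w[proj.name]
                    self._snc_ppn = (sign * np.asarray(w2, float), self._sl[proj.pre])
                continue
            pre_sl, post_sl = self._sl[proj.pre], self._sl[proj.post]
            if st.w[proj.name].ndim == 3:  # per-simulation weights (plastic or frozen)
                self._plastic.append((proj.name, pre_sl, post_sl, sign, a))
            else:
                W[pre_sl, post_sl] += sign * st.w[proj.name]
                if a:
                    self._axon_bias[post_sl] += sign * a * st.w[proj.name].sum(axis=0)
        self._Wfix = W
        self._gpi_sl = self._sl["GPi"]
        self._thal_sl = self._sl["Thalamus"]
        self._cordec_sl = self._sl["Cor_dec"]
        self._corin_sl = self._sl["Cor_in"]
        self._ppn_sl = self._sl["PPN"]
        self._strd1_sl = self._sl["StrD1"]
        # thalamic input split for the support traces (fixed parts)
        self._Wthal_exc = np.zeros((Nf, 2))
        self._Wthal_inh = np.zeros((Nf, 2))
        self._thal_axon_exc = np.zeros(2)
        self._thal_axon_inh = np.zeros(2)
        for proj in cfg.projections.values():
            if proj.post != "Thalamus" or st.w[proj.name].ndim == 3:
                continue
            a = float(axon.get(proj.name, 0.0))
            tgt, bias = (
                (self._Wthal_exc, self._thal_axon_exc)
                if proj.target == "exc"
                else (self._Wthal_inh, self._thal_axon_inh)
            )
            tgt[self._sl[proj.pre], :] += st.w[proj.name]
            if a:
                bias += a * st.w[proj.name].sum(axis=0)

        self.shortcut_params = ShortcutPlasticityParams(**cfg.shortcut_plasticity)
        da = cfg.da_plasticity
        self._da_baseline = float(da["da_baseline"])
        self.da_rules: list[tuple[str, slice, slice, DAPlasticityParams]] = []
        for proj in cfg.projections.values():
            if proj.plasticity in ("da_cortical", "da_bg"):
                rule = da["rules"][proj.name]
                self.da_rules.append(
                    (
                        proj.name,
                        self._sl[proj.pre],
                        self._sl[proj.post],
                        DAPlasticityParams(
                            tau=float(rule["tau"]),
                            polarity=int(rule["polarity"]),
                            deviation=str(rule["deviation"]),
                            w_max=float(rule["w_max"]),
                            da_baseline=float(da["da_baseline"]),
                            tau_dip=float(rule.get("tau_dip", rule["tau"])),
                        ),
                    )
                )
        self.shortcut_plastic = cfg.projections["shortcut"].plasticity == "shortcut"
        self.tau_pred = float(da["prediction"]["tau_pred"])
        self.rpe_neg_gain = float(cfg.snc["rpe_neg_gain"])
        self.noise_dims = self.state.noise.dims
        self._pack_for_kernel()

    def _pack_for_kernel(self) -> None:
        """Pack the network into the flat arrays the compiled loop consumes.

        All per-simulation (batched) weight matrices move into one packed
        buffer; the per-projection entries of ``state.w`` become views into
        it, so Python-side code and the kernel share storage.
        """
        cfg = self.state.cfg
        st = self.state
        S = st.n_sims
        da_rules = {name: params for name, _, _, params in self.da_rules}
        flag = 1 if self.dbs_on else 0
        axon = self.dbs.axon_rates(flag)

        entries = []
        for proj in cfg.projections.values():
            if st.w[proj.name].ndim != 3:
                continue
            if proj.plasticity == "shortcut":
                kind = 1
            elif proj.name in da_rules:
                kind = 2
            elif proj.plasticity == "da_snc":
                kind = 3
            else:
                kind = 0  # frozen per-simulation weights
            npre = cfg.populations[proj.pre].n
            npost = 1 if kind == 3 else cfg.populations[proj.post].n
            entries.append((proj, kind, npre, npost))

        P = len(entries)
        self._p_off = np.zeros(P, dtype=np.int64)
        self._p_pre0 = np.zeros(P, dtype=np.int64)
        self._p_pren = np.zeros(P, dtype=np.int64)
        self._p_post0 = np.zeros(P, dtype=np.int64)
        self._p_postn = np.zeros(P, dtype=np.int64)
        self._p_sign = np.zeros(P)
        self._p_axon = np.zeros(P)
        self._p_kind = np.zeros(P, dtype=np.int64)
        self._p_tau = np.ones(P)
        self._p_tau_dip = np.ones(P)
        self._p_pol = np.zeros(P)
        self._p_dev = np.zeros(P, dtype=np.int64)
        self._p_wmax = np.zeros(P)
        self._p_thal_exc = np.zeros(P, dtype=np.int64)
        off = 0
        self._w_offsets: dict[str, tuple[int, int, int]] = {}
        for k, (proj, kind, npre, npost) in enumerate(entries):
            self._p_off[k] = off
            self._p_pre0[k] = self._sl[proj.pre].start
            self._p_pren[k] = npre
            self._p_post0[k] = 0 if kind == 3 else self._sl[proj.post].start
            self._p_postn[k] = npost
            self._p_sign[k] = 1.0 if proj.target == "exc" else -1.0
            self._p_axon[k] = float(axon.get(proj.name, 0.0))
            self._p_kind[k] = kind
            if kind == 2:
                params = da_rules[proj.name]
                self._p_tau[k] = params.tau
                self._p_tau_dip[k] = params.tau_dip
                self._p_pol[k] = params.polarity
                self._p_dev[k] = 0 if params.deviation == "above" else 1
                self._p_wmax[k] = params.w_max
            self._p_thal_exc[k] = int(proj.post == "Thalamus" and proj.target == "exc")
            self._w_offsets[proj.name] = (off, npre, npost)
            off += npre * npost
        self._wtot = off
        self._wbuf = np.zeros((S, off))
        for name, (o, npre, npost) in self._w_offsets.items():
            self._wbuf[:, o : o + npre * npost] = st.w[name].reshape(S, -1)
            st.w[name] = self._wbuf[:, o : o + npre * npost].reshape(S, npre, npost)

        i, j = np.nonzero(self._Wfix)
        self._wf_i = i.astype(np.int64)
        self._wf_j = j.astype(np.int64)
        self._wf_v = self._Wfix[i, j].copy()
        thal0 = self._thal_sl.start
        ei, ej = np.nonzero(self._Wthal_exc)
        self._te_i, self._te_j = ei.astype(np.int64), ej.astype(np.int64)
        self._te_v = self._Wthal_exc[ei, ej].copy()
        ii, ij = np.nonzero(self._Wthal_inh)
        self._ti_i, self._ti_j = ii.astype(np.int64), ij.astype(np.int64)
        self._ti_v = self._Wthal_inh[ii, ij].copy()
        del thal0

        # noise columns must form a contiguous tail for the kernel
        if len(self._noise_cols):
            lo = int(self._noise_cols[0])
            if not np.array_equal(self._noise_cols, np.arange(lo, self._Nf)):
                raise ValueError("noise-bearing populations must be contiguous and last")
            self._noise_lo = lo
        else:
            self._noise_lo = self._Nf
        self._pop_off = np.array(
            [self._sl[p].start for p in self._order] + [self._Nf], dtype=np.int64
        )

    def _alloc(self) -> None:
        S, T = self.state.n_sims, self.task.n_trials
        self.choices = np.full((S, T), -1, dtype=np.int64)
        self.rewarded = np.zeros((S, T), dtype=bool)
        self.latency = np.zeros((S, T), dtype=np.int64)
        self.psp_short = np.zeros((S, T, 2))
        self.psp_gpi = np.zeros((S, T, 2))
        self._acc_short = np.zeros((S, 2))
        self._acc_gpi = np.zeros((S, 2))
        self._acc_steps = np.zeros(S, dtype=np.int64)
        self._rate_out = np.zeros((S, T, len(self._order)))
        self._acc_rate = np.zeros((S, len(self._order)))
        self._acc_rates = {
            p: self._acc_rate[:, self._order.index(p)] for p in self.record_pops
        }
        self.mean_rates = {
            p: self._rate_out[:, :, self._order.index(p)] for p in self.record_pops
        }
        self._wlog = np.zeros((S, T, self._wtot))
        self.weight_log = {
            name: self._wlog[:, :, o : o + npre * npost].reshape(S, T, npre, npost)
            for name, (o, npre, npost) in self._w_offsets.items()
        }
        # per-trial snapshot buffers (filled per seed as each reaches a trial)
        snap_trials = sorted(self.snapshot_trials)
        self._snap_rows = {tr: k for k, tr in enumerate(snap_trials)}
        self._snap_index = np.full(self.task.n_trials, -1, dtype=np.int64)
        for tr, k in self._snap_rows.items():
            if 0 <= tr < self.task.n_trials:
                self._snap_index[tr] = k
        K = len(snap_trials)
        self._snap_mp = np.zeros((K, S, self._Nf))
        self._snap_rr = np.zeros((K, S, self._Nf))
        self._snap_w = np.zeros((K, S, self._wtot))
        self._snap_mp_snc = np.zeros((K, S))
        self._snap_t = np.zeros((K, S), dtype=np.int64)
        self._schedule_u8 = np.ascontiguousarray(
            self.state.reward_schedule.astype(np.uint8)
        )
        self.snapshots: dict[int, dict[str, Any]] = {}
        all_sims = np.arange(S)
        self._log_weights(all_sims, 0)
        if 0 in self.snapshot_trials:
            self._fill_snapshot(0, all_sims)

    def _log_weights(self, sims: np.ndarray, trial: int | np.ndarray) -> None:
        for name, log in self.weight_log.items():
            log[sims, trial] = self.state.w[name][sims]

    def _fill_snapshot(self, trial: int, sims: np.ndarray, t_offset: int = 0) -> None:
        """Record trial-start state for the given simulations.  Seeds reach a
        given trial at different wall-clock steps, so snapshots fill per seed."""
        st = self.state
        snap = self.snapshots.get(trial)
        if snap is None:
            snap = self.snapshots[trial] = {
                "mp": {k: np.zeros_like(v) for k, v in st.mp.items()},
                "r": {k: np.zeros_like(v) for k, v in st.r.items()},
                "w": {k: np.zeros_like(st.w[k]) for k in st.plastic_names()},
                "delta": np.zeros_like(st.delta),
                "alpha_gate": np.zeros_like(st.alpha_gate),
                "t": np.zeros_like(st.t),
                "trial": np.full_like(st.trial, trial),
                "phase": np.full_like(st.phase, PH_PRE),
                "phase_step": np.zeros_like(st.phase_step),
            }
        for k in snap["mp"]:
            snap["mp"][k][sims] = st.mp[k][sims]
            snap["r"][k][sims] = st.r[k][sims]
        for k in snap["w"]:
            snap["w"][k][sims] = st.w[k][sims]
        snap["delta"][sims] = st.delta[sims]
        snap["alpha_gate"][sims] = st.alpha_gate[sims]
        snap["t"][sims] = st.t[sims] + t_offset

    def load_snapshot(self, snap: dict[str, Any]) -> None:
        st = self.state
        for k, v in snap["mp"].items():
            st.mp[k][:] = v
        for k, v in snap["r"].items():
            st.r[k][:] = v
        for k, v in snap["w"].items():
            st.w[k][:] = v
        st.delta[:] = snap["delta"]
        st.alpha_gate[:] = snap["alpha_gate"]
        st.t[:] = snap["t"]
        st.trial[:] = snap["trial"]
        st.phase[:] = snap["phase"]
        st.phase_step[:] = snap["phase_step"]

    # -- stepping ---------------------------------------------------------
    def step(self) -> None:
        """Advance every simulation of the batch by one 1 ms step."""
        st = self.state
        task = self.task
        S = st.n_sims
        mp, rr = self._mp, self._rr

        in_decide = st.phase == PH_DECIDE
        in_reward = st.phase == PH_REWARD
        stim_on = in_decide | in_reward
        # exogenous drives follow the per-seed trial phase
        b_corin = stim_on.astype(float)
        trial_idx = np.minimum(st.trial, task.n_trials - 1)
        rewarded_now = in_reward & self.rewarded[np.arange(S), trial_idx]
        b_ppn = rewarded_now.astype(float)
        st.alpha_gate = in_reward.astype(float)

        rr[:, self._corin_sl] = b_corin[:, None]
        mp[:, self._corin_sl] = b_corin[:, None]
        rr[:, self._ppn_sl] = b_ppn[:, None]
        mp[:, self._ppn_sl] = b_ppn[:, None]

        # summed signed psp: one product for all fixed projections, small
        # batched products for the plastic ones
        psp = rr @ self._Wfix
        psp += self._axon_bias
        w = st.w
        shortcut_psp = None
        for name, pre_sl, post_sl, sign, a in self._plastic:
            r_pre = rr[:, pre_sl]
            if a:
                r_pre = r_pre + a
            part = np.matmul(r_pre[:, None, :], w[name])[:, 0, :]
            if name == "shortcut":
                shortcut_psp = part
            if sign > 0:
                psp[:, post_sl] += part
            else:
                psp[:, post_sl] -= part

        # integrate:  mp += (dt/tau) * (-mp + B + psp + noise + I_dbs)
        drive = psp
        drive -= mp
        drive += self._Bvec
        if len(self._noise_cols):
            draws = st.noise.draw(st.t)
            drive[:, self._noise_cols] += self._noise_lam * draws
        if self.alpha_suppress:
            gmp = mp[:, self._gpi_sl]
            drive[:, self._gpi_sl] += self.alpha_suppress * np.minimum(-1.0 - gmp, 0.0)
        mp += self._kvec * drive
        np.maximum(mp, 0.0, out=rr)
        rr[:, self._corin_sl] = b_corin[:, None]
        rr[:, self._ppn_sl] = b_ppn[:, None]

        # dopamine unit: integrates the reward-prediction error
        ppn_w, ppn_sl = self._snc_ppn
        psp_ppn = (rr[:, ppn_sl] @ ppn_w)[:, 0]
        psp_strd1 = np.matmul(
            rr[:, self._strd1_sl][:, None, :], w[self._snc_pred_name]
        )[:, 0, 0]
        delta = np.where(
            psp_ppn > 0.0,
            relu(1.0 - self._snc.B - psp_strd1),
            -self.rpe_neg_gain * psp_strd1,
        )
        mp_snc = st.mp[self._snc_name]
        mp_snc += (DT / self._snc.tau) * (
            -mp_snc + (st.alpha_gate * delta)[:, None] + self._snc.B
        )
        np.maximum(mp_snc, 0.0, out=st.r[self._snc_name])
        st.delta = delta

        # plasticity (evaluated continuously; the dopamine factor self-gates
        # BG learning to reward windows, so steps at baseline dopamine skip)
        any_stim = bool(stim_on.any())
        da_rate = st.r[self._snc_name][:, 0]
        if self.shortcut_plastic and any_stim:
            r_thal = rr[:, self._thal_sl]
            w["shortcut"][...] = shortcut_update(
                w["shortcut"],
                rr[:, self._corin_sl],
                r_thal,
                np.mean(r_thal, axis=-1, keepdims=True),
                self.shortcut_params,
            )
        if np.any(np.abs(da_rate - self._da_baseline) > 1e-4):
            for name, pre_sl, post_sl, params in self.da_rules:
                w[name][...] = da_update(
                    w[name], rr[:, pre_sl], rr[:, post_sl], da_rate, params
                )
            w[self._snc_pred_name][...] = prediction_update(
                w[self._snc_pred_name],
                rr[:, self._strd1_sl],
                delta,
                st.alpha_gate,
                self.tau_pred,
            )

        # decision-epoch trace accumulation
        if in_decide.any():
            idx = np.nonzero(in_decide)[0]
            thal_exc = rr @ self._Wthal_exc + self._thal_axon_exc
            if shortcut_psp is not None:
                thal_exc += shortcut_psp
            thal_inh = rr @ self._Wthal_inh + self._thal_axon_inh
            self._acc_short[idx] += thal_exc[idx]
            self._acc_gpi[idx] += thal_inh[idx]
            self._acc_steps[idx] += 1
            for p in self.record_pops:
                self._acc_rates[p][idx] += st.r[p][idx].mean(axis=-1)

        self._advance_phases(in_decide, in_reward, trial_idx)
        st.t += 1

    def _advance_phases(self, in_decide, in_reward, trial_idx) -> None:
        st = self.state
        task = self.task
        S = st.n_sims
        st.phase_step += st.phase != PH_DONE

        # PRE -> DECIDE after the relaxation period
        start = (st.phase == PH_PRE) & (st.phase_step >= task.pre_stimulus_ms)
        if np.any(start):
            st.phase[start] = PH_DECIDE
            st.phase_step[start] = 0

        # DECIDE -> REWARD on threshold crossing or timeout
        if np.any(in_decide):
            r_dec = st.r["Cor_dec"]
            crossed = r_dec.max(axis=-1) > task.decision_threshold
            timeout = st.phase_step >= task.max_decision_ms
            decide = in_decide & (crossed | timeout)
            if np.any(decide):
                idx = np.nonzero(decide)[0]
                choice = np.argmax(r_dec[idx], axis=-1)
                tr = trial_idx[idx]
                self.choices[idx, tr] = choice
                self.latency[idx, tr] = st.phase_step[idx]
                self.rewarded[idx, tr] = st.reward_schedule[idx, tr, choice]
                steps = np.maximum(self._acc_steps[idx], 1)[:, None]
                self.psp_short[idx, tr] = self._acc_short[idx] / steps
                self.psp_gpi[idx, tr] = self._acc_gpi[idx] / steps
                for p in self.record_pops:
                    self.mean_rates[p][idx, tr] = self._acc_rates[p][idx] / steps[:, 0]
                self._acc_short[idx] = 0.0
                self._acc_gpi[idx] = 0.0
                self._acc_steps[idx] = 0
                for p in self.record_pops:
                    self._acc_rates[p][idx] = 0.0
                st.phase[idx] = PH_REWARD
                st.phase_step[idx] = 0

        # REWARD -> next trial after the reward window
        ended = in_reward & (st.phase_step >= task.reward_window_ms)
        if np.any(ended):
            idx = np.nonzero(ended)[0]
            if task.reset_between_trials:
                # clear the winner-take-all latch so each trial runs a fresh
                # competition from the baseline state the weights imply; the
                # dopamine unit keeps its tonic baseline (no spurious dip)
                for name in st.mp:
                    st.mp[name][idx] = 0.0
                    st.r[name][idx] = 0.0
                st.mp[self._snc_name][idx] = self._snc.B
                st.r[self._snc_name][idx] = self._snc.B
                st.delta[idx] = 0.0
            st.trial[idx] += 1
            done = st.trial[idx] >= task.n_trials
            st.phase[idx[done]] = PH_DONE
            cont = idx[~done]
            st.phase[cont] = PH_PRE
            st.phase_step[idx] = 0
            if len(cont):
                self._log_weights(cont, st.trial[cont])
                if self.snapshot_trials:
                    trials_cont = st.trial[cont]
                    for k in self.snapshot_trials.intersection(trials_cont.tolist()):
                        # this step consumed noise index t; resuming from the
                        # snapshot must start at t + 1
                        self._fill_snapshot(k, cont[trials_cont == k], t_offset=1)

    # -- drivers ----------------------------------------------------------
    def run(self, until_trial: int | None = None, max_steps: int | None = None) -> None:
        """Run the compiled loop until every simulation has completed
        ``until_trial`` trials (the whole task by default)."""
        from . import _kernel

        task = self.task
        st = self.state
        target = task.n_trials if until_trial is None else int(until_trial)
        if max_steps is None:
            max_steps = (target + 1) * (
                task.pre_stimulus_ms + task.max_decision_ms + task.reward_window_ms
            )
        noise_need = np.zeros(st.n_sims, dtype=np.uint8)
        steps_out = np.zeros(1, dtype=np.int64)
        mp_snc = st.mp[self._snc_name][:, 0]
        r_snc = st.r[self._snc_name][:, 0]
        while steps_out[0] < max_steps:
            st.noise.ensure(st.t)
            noise_need[:] = 0
            rc = _kernel.run_steps(
                self._mp, self._rr,
                mp_snc, r_snc, st.delta, st.alpha_gate,
                st.t, st.trial, st.phase, st.phase_step,
                self._wbuf,
                self._wf_i, self._wf_j, self._wf_v,
                self._axon_bias, self._kvec, self._Bvec,
                self._noise_lo, self._noise_lam,
                self._p_off, self._p_pre0, self._p_pren, self._p_post0, self._p_postn,
                self._p_sign, self._p_axon, self._p_kind,
                self._p_tau, self._p_tau_dip, self._p_pol, self._p_dev, self._p_wmax,
                self._p_thal_exc,
                self.shortcut_params.tau_w if self.shortcut_plastic else np.inf,
                self.shortcut_params.theta_reg, self.shortcut_params.theta_post,
                self.shortcut_params.beta_reg,
                self._snc.B, self._snc.tau, self.rpe_neg_gain, self._da_baseline,
                self.tau_pred,
                self._te_i, self._te_j, self._te_v, self._thal_axon_exc,
                self._ti_i, self._ti_j, self._ti_v, self._thal_axon_inh,
                self._corin_sl.start, self._corin_sl.stop - self._corin_sl.start,
                self._ppn_sl.start,
                self._strd1_sl.start, self._strd1_sl.stop - self._strd1_sl.start,
                self._thal_sl.start, self._thal_sl.stop - self._thal_sl.start,
                self._cordec_sl.start, self._cordec_sl.stop - self._cordec_sl.start,
                self._gpi_sl.start, self._gpi_sl.stop - self._gpi_sl.start,
                float(self._snc_ppn[0][0, 0]), float(self.alpha_suppress),
                self._pop_off,
                task.n_trials, task.pre_stimulus_ms, float(task.decision_threshold),
                task.max_decision_ms, task.reward_window_ms,
                1 if task.reset_between_trials else 0,
                self._schedule_u8,
                st.noise._buf, st.noise._block, noise_need,
                self.choices, self.rewarded, self.latency,
                self.psp_short, self.psp_gpi,
                self._acc_short, self._acc_gpi, self._acc_steps,
                self._rate_out, self._acc_rate,
                self._wlog,
                self._snap_index, self._snap_mp, self._snap_rr, self._snap_w,
                self._snap_mp_snc, self._snap_t,
                target, max_steps - int(steps_out[0]), steps_out,
            )
            if rc == _kernel.RC_DONE:
                self._collect_kernel_snapshots()
                return
            if rc == _kernel.RC_BUDGET:
                break
            # RC_NEED_NOISE: loop refills the flagged blocks and resumes
        raise RuntimeError("simulation did not complete within the step budget")

    def _collect_kernel_snapshots(self) -> None:
        """Convert kernel snapshot buffers into the public per-trial dicts."""
        st = self.state
        for tr, k in self._snap_rows.items():
            if tr == 0 or tr in self.snapshots:
                continue  # trial 0 is captured at initialization
            mp = {p: self._snap_mp[k][:, self._sl[p]].copy() for p in self._order}
            r = {p: self._snap_rr[k][:, self._sl[p]].copy() for p in self._order}
            mp[self._snc_name] = self._snap_mp_snc[k][:, None].copy()
            r[self._snc_name] = np.maximum(mp[self._snc_name], 0.0)
            w = {
                name: self._snap_w[k][:, o : o + npre * npost]
                .reshape(-1, npre, npost)
                .copy()
                for name, (o, npre, npost) in self._w_offsets.items()
            }
            self.snapshots[tr] = {
                "mp": mp,
                "r": r,
                "w": w,
                "delta": np.zeros(st.n_sims),
                "alpha_gate": np.zeros(st.n_sims),
                "t": self._snap_t[k].copy(),
                "trial": np.full(st.n_sims, tr, dtype=np.int64),
                "phase": np.full(st.n_sims, PH_PRE, dtype=np.int64),
                "phase_step": np.zeros(st.n_sims, dtype=np.int64),
            }

    def result(self, shortcut: str | None = None) -> TaskResult:
        if shortcut is None:
            shortcut = (
                "plastic"
                if self.state.cfg.projections["shortcut"].plasticity == "shortcut"
                else "fixed"
            )
        return TaskResult(
            seeds=self.state.seeds.copy(),
            dbs_variant=self.dbs.variant,
            dbs_on=self.dbs_on,
            shortcut=shortcut,
            choices=self.choices,
            rewarded=self.rewarded,
            latency=self.latency,
            psp_shortcut=self.psp_short,
            psp_gpi=self.psp_gpi,
            weights=self.weight_log,
            mean_rates=self.mean_rates,
            session_length=self.task.session_length,
            snapshots=self.snapshots,
            reward_schedule=self.state.reward_schedule.copy(),
        )


def apply_variant(
    state: NetworkState,
    dbs_cfg: DBSConfig | str,
    dbs_on: bool | None = None,
    **kwargs: Any,
) -> Simulator:
    """Wire a DBS variant into a built network and return the simulator.

    Connects the suppression current into the GPi integration and the
    axonal stimulation rates into the matching projections; the ``combined``
    variant applies suppression, efferent and passing-fiber stimulation
    simultaneously.  With the flag off (or the ``off`` variant) trajectories
    are identical to a build without any DBS layer.
    """
    return Simulator(state, dbs=dbs_cfg, dbs_on=dbs_on, **kwargs)


def run_trial(
    state: NetworkState,
    task_cfg: TaskConfig | None = None,
    dbs_cfg: DBSConfig | str = "off",
    dbs_on: bool | None = None,
) -> tuple[NetworkState, list[TrialRecord]]:
    """Run a single trial on an existing state; returns (state, records).

    There is one record per simulation in the batch, all for the trial the
    state currently points at.
    """
    sim = Simulator(state, dbs=dbs_cfg, dbs_on=dbs_on, task=task_cfg)
    target = int(state.trial.min()) + 1
    sim.run(until_trial=target)
    res = sim.result()
    k = target - 1
    return state, [
        TrialRecord(
            trial=k,
            choice=int(res.choices[s, k]),
            rewarded=bool(res.rewarded[s, k]),
            latency=int(res.latency[s, k]),
            psp_shortcut=res.psp_shortcut[s, k],
            psp_gpi=res.psp_gpi[s, k],
        )
        for s in range(state.n_sims)
    ]


def run_task_batch(
    seeds: Iterable[int] | np.ndarray,
    dbs_variant: str = "off",
    shortcut: str = "plastic",
    dbs_on: bool | None = None,
    cfg: NetworkConfig | None = None,
    record_rates: Iterable[str] | bool = True,
    snapshot_trials: Iterable[int] = (),
    dbs_overrides: dict[str, float] | None = None,
) -> TaskResult:
    """Build a batch of models and run the full 120-trial task.

    Paired conditions run with the same seeds share initial weights, noise
    and the reward schedule; only the DBS terms differ.
    """
    if cfg is None:
        cfg = default_config()
    state = build_default_model(np.asarray(list(seeds)), cfg=cfg, shortcut=shortcut)
    dbs = dbs_variant_config(dbs_variant, cfg, **(dbs_overrides or {}))
    sim = Simulator(
        state,
        dbs=dbs,
        dbs_on=dbs_on,
        record_rates=record_rates,
        snapshot_trials=snapshot_trials,
    )
    sim.run()
    return sim.result(shortcut=shortcut)


def run_task(
    seed: int,
    dbs_variant: str = "off",
    shortcut: str = "plastic",
    cfg: NetworkConfig | None = None,
    **kwargs: Any,
) -> list[TrialRecord]:
    """Run one seeded simulation of the full task; returns per-trial records."""
    res = run_task_batch([seed], dbs_variant=dbs_variant, shortcut=shortcut, cfg=cfg, **kwargs)
    return res.records(0)


def run_extended_trial(
    seeds: Iterable[int] | np.ndarray,
    dbs_variant: str = "off",
    dbs_on: bool | None = None,
    cfg: NetworkConfig | None = None,
    duration_ms: int = 3000,
    window: tuple[int, int] = (2500, 3000),
    shortcut: str = "plastic",
) -> dict[str, np.ndarray]:
    """Single untrained-model trial with the stimulus held on for ``duration_ms``.

    No decision is read out; returns per-population mean rates (averaged over
    neurons and the ``window`` of stimulus time) per simulation.  This mirrors
    how the acute activity signatures of the DBS variants are measured.
    """
    if cfg is None:
        cfg = default_config()
    state = build_default_model(np.asarray(list(seeds)), cfg=cfg, shortcut=shortcut)
    task = TaskConfig.from_config(cfg)
    sim = Simulator(state, dbs=dbs_variant if isinstance(dbs_variant, str) else dbs_variant,
                    dbs_on=dbs_on, record_rates=False)
    # hold the phase machine in DECIDE with an unreachable threshold
    sim.task = TaskConfig(
        n_trials=task.n_trials,
        session_length=task.session_length,
        reversal_trial=task.reversal_trial,
        p_high=task.p_high,
        p_low=task.p_low,
        pre_stimulus_ms=task.pre_stimulus_ms,
        decision_threshold=np.inf,
        max_decision_ms=duration_ms + 1,
        reward_window_ms=task.reward_window_ms,
    )
    sums = {p: np.zeros(state.n_sims) for p in cfg.populations}
    lo, hi = window
    for step in range(task.pre_stimulus_ms + duration_ms):
        sim.step()
        stim_t = step - task.pre_stimulus_ms
        if lo <= stim_t < hi:
            for p in sums:
                sums[p] += state.r[p].mean(axis=-1)
    return {p: v / (hi - lo) for p, v in sums.items()}
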