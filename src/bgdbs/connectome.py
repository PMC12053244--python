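"""Build the full circuit from declarative specs; state snapshot/restore.

The model couples the three basal-ganglia pathways (direct Cor_in->StrD1->GPi,
indirect Cor_in->StrD2->GPe->GPi, hyperdirect Cor_in->STN->GPi) with a
thalamo-cortical readout and a plastic cortico-thalamic shortcut that
bypasses the basal ganglia.  All state arrays carry a leading batch axis so
that many independently seeded simulations integrate in lockstep.

Randomness is organized in three named streams derived from each simulation
seed — ``weights`` (initial plastic weights), ``rewards`` (the pre-drawn
reward schedule) and ``noise`` (per-step membrane noise) — so paired
conditions sharing a seed share initial weights and reward contingencies.
Noise is a pure function of (seed, step index), which makes snapshot/restore
bit-exact: restoring a state and resuming reproduces the original trajectory.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .specs import NetworkConfig, ProjectionSpec, default_config

__all__ = ["NetworkState", "build_default_model", "freeze_shortcut", "snapshot", "restore"]

STREAM_WEIGHTS = 0
STREAM_REWARDS = 1
STREAM_NOISE = 2

NOISE_BLOCK = 1024

SNAPSHOT_VERSION = 1

# trial phases
PH_PRE, PH_DECIDE, PH_REWARD, PH_DONE = 0, 1, 2, 3


def _stream_rng(seed: int, stream: int, block: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.Philox(np.random.SeedSequence([int(seed), int(stream), int(block)]))
    )


class NoiseSource:
    """Per-seed membrane noise as a pure function of (seed, step index).

    Uniform(-1, 1) draws are generated in blocks of ``NOISE_BLOCK`` steps from
    a counter-based generator keyed by (seed, stream, block), so the draw for
    any step can be regenerated without replaying the sequence.
    """

    def __init__(self, seeds: np.ndarray, dims: dict[str, slice], total: int):
        self.seeds = np.asarray(seeds, dtype=np.int64)
        self.dims = dims  # population name -> column slice
        self.total = total
        S = len(self.seeds)
        self._buf = np.empty((S, NOISE_BLOCK, total))
        self._block = np.full(S, -1, dtype=np.int64)

    def ensure(self, t: np.ndarray) -> None:
        """Load the noise blocks covering per-seed step indices ``t``."""
        block = t // NOISE_BLOCK
        stale = np.nonzero(block != self._block)[0]
        for s in stale:
            rng = _stream_rng(self.seeds[s], STREAM_NOISE, block[s])
            self._buf[s] = rng.uniform(-1.0, 1.0, (NOISE_BLOCK, self.total))
            self._block[s] = block[s]

    def draw(self, t: np.ndarray) -> np.ndarray:
        """Uniform(-1,1) noise for per-seed step indices ``t`` -> (S, total)."""
        self.ensure(t)
        return self._buf[np.arange(len(self.seeds)), t % NOISE_BLOCK, :]


def _noise_layout(cfg: NetworkConfig) -> tuple[dict[str, slice], int]:
    dims: dict[str, slice] = {}
    off = 0
    for name, pop in cfg.populations.items():
        if pop.kind == "standard" and pop.lam > 0:
            dims[name] = slice(off, off + pop.n)
            off += pop.n
    return dims, off


@dataclass
class NetworkState:
    """Full mutable simulation state for a batch of seeded simulations."""

    cfg: NetworkConfig
    seeds: np.ndarray  # (S,)
    mp: dict[str, np.ndarray]  # population -> (S, n)
    r: dict[str, np.ndarray]
    w: dict[str, np.ndarray]  # plastic: (S, n_pre, n_post); fixed: (n_pre, n_post)
    delta: np.ndarray  # (S,) last reward-prediction error
    alpha_gate: np.ndarray  # (S,) dopamine reward-window gate
    dbs_flag: int
    t: np.ndarray  # (S,) per-seed step counters (noise cursors)
    trial: np.ndarray  # (S,) current trial index
    phase: np.ndarray  # (S,) PH_* codes
    phase_step: np.ndarray  # (S,)
    reward_schedule: np.ndarray  # (S, n_trials, 2) bool
    noise: NoiseSource = field(repr=False)

    @property
    def n_sims(self) -> int:
        return len(self.seeds)

    def plastic_names(self) -> list[str]:
        return [p.name for p in self.cfg.projections.values() if p.is_plastic]

    def copy(self) -> "NetworkState":
        new = NetworkState(
            cfg=self.cfg.copy(),
            seeds=self.seeds.copy(),
            mp={k: v.copy() for k, v in self.mp.items()},
            r={k: v.copy() for k, v in self.r.items()},
            w={k: v.copy() for k, v in self.w.items()},
            delta=self.delta.copy(),
            alpha_gate=self.alpha_gate.copy(),
            dbs_flag=self.dbs_flag,
            t=self.t.copy(),
            trial=self.trial.copy(),
            phase=self.phase.copy(),
            phase_step=self.phase_step.copy(),
            reward_schedule=self.reward_schedule.copy(),
            noise=NoiseSource(self.seeds, *_noise_layout(self.cfg)),
        )
        return new


def _init_weight(spec: ProjectionSpec, n_pre: int, n_post: int,
                 rngs: list[np.random.Generator] | None,
                 include_self: bool) -> np.ndarray:
    """Initial weight matrix; (S, n_pre, n_post) for plastic projections."""
    if spec.pattern == "one_to_one":
        base = np.eye(n_pre) * float(spec.init)
    elif spec.lateral:
        w = np.full((n_pre, n_post), float(spec.init))
        if not include_self:
            np.fill_diagonal(w, 0.0)
        base = w
    elif isinstance(spec.init, tuple):
        lo, hi = spec.init
        assert rngs is not None
        return np.stack([rng.uniform(lo, hi, (n_pre, n_post)) for rng in rngs])
    else:
        base = np.full((n_pre, n_post), float(spec.init))
    if spec.is_plastic:
        assert rngs is not None
        return np.broadcast_to(base, (len(rngs), n_pre, n_post)).copy()
    return base


def _reward_schedule(seed: int, task: dict[str, Any]) -> np.ndarray:
    """Pre-draw reward outcomes per (trial, option) from the rewards stream.

    Option 0 is the initially high-probability choice (p_high before the
    reversal trial, p_low after); option 1 is the complement.
    """
    n, rev = int(task["n_trials"]), int(task["reversal_trial"])
    p_high, p_low = float(task["p_high"]), float(task["p_low"])
    u = _stream_rng(seed, STREAM_REWARDS).random((n, 2))
    p = np.empty((n, 2))
    p[:rev, 0], p[:rev, 1] = p_high, p_low
    p[rev:, 0], p[rev:, 1] = p_low, p_high
    return u < p


def build_default_model(
    seed: int | np.ndarray | list[int],
    cfg: NetworkConfig | None = None,
    shortcut: str = "plastic",
) -> NetworkState:
    """Build the full network for one seed or a batch of seeds.

    ``shortcut='fixed'`` freezes the plastic cortico-thalamic projection at
    its initial value of 0.1 (all else identical to the plastic build).
    """
    if cfg is None:
        cfg = default_config()
    else:
        cfg = cfg.copy()
    seeds = np.atleast_1d(np.asarray(seed, dtype=np.int64))
    if np.any(seeds < 0):
        raise ValueError("seeds must be nonnegative")
    S = len(seeds)
    include_self = bool(cfg.options.get("lateral_include_self", False))
    wrngs = [_stream_rng(s, STREAM_WEIGHTS) for s in seeds]

    w: dict[str, np.ndarray] = {}
    for proj in cfg.projections.values():
        n_pre = cfg.populations[proj.pre].n
        n_post = cfg.populations[proj.post].n
        w[proj.name] = _init_weight(proj, n_pre, n_post, wrngs if proj.is_plastic else None,
                                    include_self)

    mp = {name: np.zeros((S, pop.n)) for name, pop in cfg.populations.items()}
    r = {name: np.zeros((S, pop.n)) for name, pop in cfg.populations.items()}
    schedule = np.stack([_reward_schedule(s, cfg.task) for s in seeds])

    state = NetworkState(
        cfg=cfg,
        seeds=seeds,
        mp=mp,
        r=r,
        w=w,
        delta=np.zeros(S),
        alpha_gate=np.zeros(S),
        dbs_flag=0,
        t=np.zeros(S, dtype=np.int64),
        trial=np.zeros(S, dtype=np.int64),
        phase=np.full(S, PH_PRE, dtype=np.int64),
        phase_step=np.zeros(S, dtype=np.int64),
        reward_schedule=schedule,
        noise=NoiseSource(seeds, *_noise_layout(cfg)),
    )
    if shortcut == "fixed":
        freeze_shortcut(state)
    elif shortcut != "plastic":
        raise ValueError("shortcut must be 'plastic' or 'fixed'")
    return state


def freeze_shortcut(state: NetworkState, name: str = "shortcut") -> NetworkState:
    """Deactivate shortcut plasticity and pin its weights at 0.1 (in place)."""
    spec = state.cfg.projections[name]
    state.cfg.projections[name] = dataclasses.replace(spec, plasticity="none")
    state.w[name] = np.full_like(state.w[name], 0.1)
    return state


def snapshot(state: NetworkState) -> str:
    """Serialize the full state (JSON); round-trips losslessly via :func:`restore`."""
    payload = {
        "version": SNAPSHOT_VERSION,
        "seeds": state.seeds.tolist(),
        "mp": {k: v.tolist() for k, v in state.mp.items()},
        "r": {k: v.tolist() for k, v in state.r.items()},
        "w": {k: v.tolist() for k, v in state.w.items()},
        "w_plastic": state.plastic_names(),
        "delta": state.delta.tolist(),
        "alpha_gate": state.alpha_gate.tolist(),
        "dbs_flag": int(state.dbs_flag),
        "t": state.t.tolist(),
        "trial": state.trial.tolist(),
        "phase": state.phase.tolist(),
        "phase_step": state.phase_step.tolist(),
        "reward_schedule": state.reward_schedule.astype(int).tolist(),
        "frozen_shortcut": state.cfg.projections["shortcut"].plasticity == "none",
    }
    return json.dumps(payload)


def restore(payload: str, cfg: NetworkConfig | None = None) -> NetworkState:
    """Rebuild a :class:`NetworkState` from a snapshot string."""
    try:
        data = json.loads(payload)
        version = data["version"]
    except (json.JSONDecodeError, TypeError, KeyError) as err:
        raise ValueError("corrupt snapshot payload") from err
    if version != SNAPSHOT_VERSION:
        raise ValueError(f"snapshot version mismatch: {version} != {SNAPSHOT_VERSION}")
    if cfg is None:
        cfg = default_config()
    else:
        cfg = cfg.copy()
    try:
        seeds = np.asarray(data["seeds"], dtype=np.int64)
        state = NetworkState(
            cfg=cfg,
            seeds=seeds,
            mp={k: np.asarray(v, dtype=float) for k, v in data["mp"].items()},
            r={k: np.asarray(v, dtype=float) for k, v in data["r"].items()},
            w={k: np.asarray(v, dtype=float) for k, v in data["w"].items()},
            delta=np.asarray(data["delta"], dtype=float),
            alpha_gate=np.asarray(data["alpha_gate"], dtype=float),
            dbs_flag=int(data["dbs_flag"]),
            t=np.asarray(data["t"], dtype=np.int64),
            trial=np.asarray(data["trial"], dtype=np.int64),
            phase=np.asarray(data["phase"], dtype=np.int64),
            phase_step=np.asarray(data["phase_step"], dtype=np.int64),
            reward_schedule=np.asarray(data["reward_schedule"], dtype=bool),
            noise=NoiseSource(np.asarray(data["seeds"], dtype=np.int64), *_noise_layout(cfg)),
        )
        if data.get("frozen_shortcut"):
            spec = state.cfg.projections["shortcut"]
            state.cfg.projections["shortcut"] = dataclasses.replace(spec, plasticity="none")
        if set(state.mp) != set(cfg.populations) or set(state.w) != set(cfg.projections):
            raise KeyError("population/projection mismatch")
    except (KeyError, ValueError) as err:
        raise ValueError("corrupt snapshot payload") from err
    return state
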