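"""Learning rules.

Two families of plasticity shape the circuit during the task:

* The cortico-thalamic shortcut follows a slow Hebbian rule with a
  covariance-style postsynaptic threshold and an Oja-style regularization
  term that only engages once thalamic activity exceeds a threshold
  (``theta_reg``), so baseline activity does not erode the weights:

      tau_w dw/dt = r_pre * v - alpha * v^2 * w
      v = (r_post - mean(r_post) - theta_post)+
      alpha = beta_reg * (r_post - theta_reg)+

* The starred basal-ganglia projections follow dopamine-modulated
  three-factor rules: a dopamine factor kappa (signed deviation of the SNc
  rate from its tonic baseline, with D1-like polarity +1 and D2-like
  polarity -1), the presynaptic rate, and the positive part of the
  postsynaptic deviation from the population mean.  For projections with an
  inhibitory target the deviation is taken *below* the mean: an inhibitory
  pathway acts on the channel it currently silences, so credit must flow to
  synapses onto the suppressed (selected) unit.  Reward-prediction weights
  onto the dopamine unit integrate the prediction error itself during the
  reward window.

All rules are evaluated every 1 ms step; the dopamine factor self-gates
basal-ganglia learning to the reward window because the SNc sits at baseline
otherwise.  Weights are clamped to remain nonnegative (and below per-rule
bounds for the dopamine-modulated rules).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DT, relu

__all__ = ["ShortcutPlasticityParams", "DAPlasticityParams", "shortcut_update", "da_update"]


@dataclass(frozen=True)
class ShortcutPlasticityParams:
    tau_w: float = 150000.0
    theta_reg: float = 0.93
    theta_post: float = 0.1
    beta_reg: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_w <= 0:
            raise ValueError("tau_w must be > 0")


@dataclass(frozen=True)
class DAPlasticityParams:
    """Parameters of one dopamine-modulated projection rule.

    ``tau`` applies while dopamine is above its tonic baseline (phasic
    bursts), ``tau_dip`` while it is below (phasic dips).  Separate rates are
    needed because the dip magnitude saturates — the SNc rate floors at zero
    — while burst amplitude does not, so a single rate would make
    reward-driven updates dwarf omission-driven ones.
    """

    tau: float
    polarity: int  # +1 for D1-like, -1 for D2-like targets
    deviation: str  # 'above' | 'below' the postsynaptic population mean
    w_max: float
    da_baseline: float = 0.1
    tau_dip: float | None = None

    def __post_init__(self) -> None:
        if self.deviation not in ("above", "below"):
            raise ValueError(f"unknown deviation {self.deviation!r}")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.tau_dip is None:
            object.__setattr__(self, "tau_dip", self.tau)


def shortcut_update(
    w: np.ndarray,
    r_pre: np.ndarray,
    r_post: np.ndarray,
    r_post_popmean: np.ndarray,
    params: ShortcutPlasticityParams,
    dt: float = DT,
) -> np.ndarray:
    """One step of the cortico-thalamic shortcut rule; returns new weights.

    ``w`` is ``(..., n_pre, n_post)``; ``r_pre``/``r_post`` are ``(..., n)``;
    ``r_post_popmean`` is the instantaneous mean over the postsynaptic
    population (broadcastable against ``r_post``).
    """
    v = relu(r_post - r_post_popmean - params.theta_post)
    alpha = params.beta_reg * relu(r_post - params.theta_reg)
    hebb = r_pre[..., :, None] * v[..., None, :]
    decay = (alpha * v * v)[..., None, :] * w
    w = w + (dt / params.tau_w) * (hebb - decay)
    return relu(w)


def da_update(
    w: np.ndarray,
    r_pre: np.ndarray,
    r_post: np.ndarray,
    da_rate: np.ndarray | float,
    params: DAPlasticityParams,
    dt: float = DT,
) -> np.ndarray:
    """One step of a dopamine-modulated three-factor rule; returns new weights.

    ``da_rate`` is the SNc firing rate (scalar or per-simulation vector);
    kappa = polarity * (da_rate - baseline) vanishes at baseline dopamine, so
    no learning occurs outside reward windows.
    """
    da = np.asarray(da_rate, dtype=float)
    kappa = params.polarity * (da - params.da_baseline)
    tau = np.where(da >= params.da_baseline, params.tau, params.tau_dip)
    mean_post = np.mean(r_post, axis=-1, keepdims=True)
    if params.deviation == "above":
        dev = relu(r_post - mean_post)
    else:
        dev = relu(mean_post - r_post)
    gain = kappa / tau
    dw = gain[..., None, None] * r_pre[..., :, None] * dev[..., None, :]
    w = w + dt * dw
    return np.clip(w, 0.0, params.w_max)


def prediction_update(
    w: np.ndarray,
    r_pre: np.ndarray,
    delta: np.ndarray | float,
    alpha_gate: np.ndarray | float,
    tau_pred: float,
    dt: float = DT,
) -> np.ndarray:
    """Reward-prediction weights (StrD1 -> SNc): dw = (dt/tau) alpha delta r_pre.

    Gated by the reward window (``alpha_gate``); predictions grow while the
    prediction error is positive and shrink on omitted rewards, when delta is
    negative.  ``w`` is ``(..., n_pre, 1)``.
    """
    gain = np.asarray(alpha_gate, dtype=float) * np.asarray(delta, dtype=float)
    dw = gain[..., None, None] * r_pre[..., :, None]
    return relu(w + (dt / tau_pred) * dw)
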