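"""Rate-coded neuron dynamics: forward-Euler integration at 1 ms resolution.

Every unit is a leaky integrator of its membrane potential ``mp`` with a
rectified-linear transfer to a firing rate ``r``:

    tau dmp/dt = -mp + B + sum(psp_exc) - sum(psp_inh) + lam*U(-1,1) + I_extra
    r = (mp)+

Postsynaptic potentials are linear in the presynaptic rate, ``psp = w * r_pre``
(optionally with an axonal stimulation rate added to ``r_pre``).  The single
dopamine unit integrates a reward-prediction error instead of synaptic input.

All functions are vectorized over a leading batch (simulation/seed) axis and
operate with a fixed step of ``DT`` = 1 ms.
"""
from __future__ import annotations

import numpy as np

from .specs import PopulationSpec

__all__ = ["DT", "euler_step", "compute_psp", "snc_step", "relu"]

DT = 1.0  # ms; fixed integration step


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise positive part (the rate transfer function)."""
    return np.maximum(x, 0.0)


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(f"non-finite input while updating population {name!r}")


def euler_step(
    mp: np.ndarray,
    spec: PopulationSpec,
    exc_input: np.ndarray | float = 0.0,
    inh_input: np.ndarray | float = 0.0,
    noise: np.ndarray | float = 0.0,
    extra_current: np.ndarray | float = 0.0,
    B: np.ndarray | float | None = None,
    out_mp: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance one population by one 1 ms Euler step.

    ``noise`` is the raw uniform draw in [-1, 1] (scaled here by ``spec.lam``);
    ``extra_current`` carries e.g. the DBS suppression current.  ``B`` can
    override the spec baseline (the task clamps cortical/reward input drives).
    Returns ``(mp, r)``.  Input-kind populations are not integrated: their
    rate is set directly to the baseline drive.
    """
    if B is None:
        B = spec.B
    if spec.kind == "input":
        r = np.broadcast_to(np.asarray(B, dtype=float), np.shape(mp)).copy()
        return r, r.copy()
    drive = (
        -mp + B + exc_input - inh_input + spec.lam * np.asarray(noise) + extra_current
    )
    _check_finite(drive, spec.name)
    if out_mp is None:
        out_mp = mp + (DT / spec.tau) * drive
    else:
        np.multiply(drive, DT / spec.tau, out=out_mp)
        out_mp += mp
    return out_mp, relu(out_mp)


def compute_psp(
    w: np.ndarray,
    r_pre: np.ndarray,
    r_axon: float | np.ndarray = 0.0,
) -> np.ndarray:
    """Summed postsynaptic potential ``psp_j = sum_i w_ij (r_pre,i + r_axon)``.

    ``w`` is ``(n_pre, n_post)`` (shared across the batch) or
    ``(S, n_pre, n_post)`` (per-simulation plastic weights); ``r_pre`` is
    ``(S, n_pre)`` or ``(n_pre,)``.  ``r_axon`` models axonal stimulation by
    DBS, which drives terminals independently of the soma.
    """
    w = np.asarray(w, dtype=float)
    r_pre = np.asarray(r_pre, dtype=float)
    r_eff = r_pre + r_axon if np.any(r_axon) else r_pre
    if w.ndim <= 2:
        if w.ndim == 0:
            return w * r_eff
        if r_eff.shape[-1] != w.shape[0]:
            raise ValueError(
                f"shape mismatch: weights {w.shape} vs presynaptic rates {r_eff.shape}"
            )
        return r_eff @ w
    # batched plastic weights: (S, n_pre, n_post) x (S, n_pre)
    if r_eff.ndim == 1:
        r_eff = np.broadcast_to(r_eff, (w.shape[0], w.shape[1]))
    if r_eff.shape != w.shape[:2]:
        raise ValueError(
            f"shape mismatch: weights {w.shape} vs presynaptic rates {r_eff.shape}"
        )
    return np.einsum("sij,si->sj", w, r_eff)


def snc_step(
    mp: np.ndarray,
    spec: PopulationSpec,
    psp_strd1: np.ndarray,
    psp_ppn: np.ndarray,
    alpha_gate: np.ndarray | float,
    rpe_neg_gain: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Advance the dopamine unit one step and return ``(mp, r, delta)``.

    The reward-prediction error contrasts the delivered reward (relayed via
    the PPN) with the striatal prediction:

        delta = (1 - B - sum psp_StrD1)+        if psp_PPN > 0
        delta = -rpe_neg_gain * sum psp_StrD1   otherwise

    and drives the membrane potential only inside the reward window
    (``alpha_gate`` = 1).  Outside the window the unit relaxes to its tonic
    baseline B.
    """
    psp_strd1 = np.asarray(psp_strd1, dtype=float)
    psp_ppn = np.asarray(psp_ppn, dtype=float)
    _check_finite(psp_strd1, spec.name)
    delta = np.where(
        psp_ppn > 0.0,
        relu(1.0 - spec.B - psp_strd1),
        -rpe_neg_gain * psp_strd1,
    )
    mp = mp + (DT / spec.tau) * (-mp + alpha_gate * delta + spec.B)
    return mp, relu(mp), delta
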