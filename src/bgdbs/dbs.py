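"""Mechanistic DBS tissue-effect variants applied to the GPi neighborhood.

Clinical stimulation of the globus pallidus internus can act on distinct
tissue compartments.  Five idealized variants are modeled:

* ``suppression``    — an inhibitory current on the GPi somata that pulls the
  membrane potential toward -1 and saturates there.
* ``afferent``       — axonal stimulation of all projections terminating on
  the GPi (StrD1, STN, GPe and, by default, StrThal terminals).
* ``efferent``       — axonal stimulation of the GPi output to the thalamus.
* ``passing_fibers`` — axonal stimulation of the GPe->STN fibers passing near
  the electrode.
* ``combined``       — suppression + efferent + passing fibers together.

Axonal stimulation adds a rate ``r_axon = alpha_axon * dbs`` to the
presynaptic rate of the affected projections only (the soma is untouched),
reflecting action potentials elicited in axons independently of the soma.
Stimulation is continuous: the ``dbs`` flag holds for the entire simulated
time of an ON run, inter-trial periods included.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .specs import NetworkConfig, default_config

__all__ = ["DBSConfig", "VARIANTS", "suppression_current", "axon_rate", "dbs_variant_config"]

VARIANTS = ("off", "suppression", "afferent", "efferent", "passing_fibers", "combined")

# projection classes touched by axonal stimulation; the GPi's lateral
# collaterals are efferent axons of the stimulated somata, so efferent
# stimulation drives them too
GPI_AFFERENTS = ("StrD1->GPi", "STN->GPi", "GPe->GPi")
GPI_AFFERENT_STRTHAL = "StrThal->GPi"
GPI_EFFERENTS = ("GPi->Thalamus", "GPi->GPi")
PASSING_FIBERS = ("GPe->STN",)


@dataclass(frozen=True)
class DBSConfig:
    """Per-variant stimulation parameters (all rates nonnegative)."""

    variant: str = "off"
    alpha_suppress: float = 0.0
    alpha_axon_afferent: float = 0.0
    alpha_axon_efferent: float = 0.0
    alpha_axon_gpe_stn: float = 0.0
    afferent_includes_strthal: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown DBS variant {self.variant!r}")
        for name in ("alpha_suppress", "alpha_axon_afferent", "alpha_axon_efferent", "alpha_axon_gpe_stn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.variant == "off" and any(
            getattr(self, n) != 0.0
            for n in ("alpha_suppress", "alpha_axon_afferent", "alpha_axon_efferent", "alpha_axon_gpe_stn")
        ):
            raise ValueError("variant 'off' requires all stimulation gains to be 0")

    def axon_rates(self, dbs_flag: float | int = 1) -> dict[str, float]:
        """Map projection name -> axonal rate r_axon for this variant."""
        rates: dict[str, float] = {}
        if self.alpha_axon_afferent:
            targets = list(GPI_AFFERENTS)
            if self.afferent_includes_strthal:
                targets.append(GPI_AFFERENT_STRTHAL)
            for name in targets:
                rates[name] = self.alpha_axon_afferent * dbs_flag
        if self.alpha_axon_efferent:
            for name in GPI_EFFERENTS:
                rates[name] = self.alpha_axon_efferent * dbs_flag
        if self.alpha_axon_gpe_stn:
            for name in PASSING_FIBERS:
                rates[name] = self.alpha_axon_gpe_stn * dbs_flag
        return rates


def dbs_variant_config(
    variant: str,
    cfg: NetworkConfig | None = None,
    **overrides: float,
) -> DBSConfig:
    """Build the :class:`DBSConfig` for a named variant from the network config."""
    if cfg is None:
        cfg = default_config()
    try:
        params = dict(cfg.dbs_variants[variant])
    except KeyError as err:
        raise ValueError(f"unknown DBS variant {variant!r}") from err
    params.update(overrides)
    params.setdefault(
        "afferent_includes_strthal", cfg.options.get("afferent_includes_strthal", True)
    )
    return DBSConfig(variant=variant, **params)


def suppression_current(
    mp: np.ndarray,
    cfg: DBSConfig,
    dbs_flag: float | int | np.ndarray = 1,
) -> np.ndarray:
    """Inhibitory current on the GPi somata: alpha * dbs * (-1 - mp)-.

    Strictly nonpositive, pulls the membrane potential toward -1 and is zero
    once mp <= -1 (the negative-part function saturates the suppression).
    """
    mp = np.asarray(mp, dtype=float)
    return cfg.alpha_suppress * np.asarray(dbs_flag, dtype=float) * np.minimum(-1.0 - mp, 0.0)


def axon_rate(cfg: DBSConfig, projection_class: str, dbs_flag: float | int = 1) -> float:
    """Axonal stimulation rate for a projection class.

    ``projection_class`` is one of ``gpi_afferent``, ``gpi_efferent``,
    ``gpe_stn``.
    """
    alphas = {
        "gpi_afferent": cfg.alpha_axon_afferent,
        "gpi_efferent": cfg.alpha_axon_efferent,
        "gpe_stn": cfg.alpha_axon_gpe_stn,
    }
    try:
        return alphas[projection_class] * dbs_flag
    except KeyError as err:
        raise ValueError(f"unknown projection class {projection_class!r}") from err
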