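"""Declarative network description: populations, projections, parameters.

The full circuit (Figure-1-style cortico-basal-ganglia-thalamo-cortical loop)
is data, not code: populations and projections are read from
``config/network.yaml`` and validated into the dataclasses below.
"""
from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "PopulationSpec",
    "ProjectionSpec",
    "NetworkConfig",
    "load_config",
    "default_config",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One neural population: size, membrane time constant, baseline drive.

    kind
        ``standard`` : leaky rate unit with synaptic input and noise.
        ``input``    : exogenous population (cortical input, reward relay);
                       its rate is set directly to the baseline B, no
                       integration, no noise, no synaptic input.
        ``snc``      : the single dopamine unit whose phasic deviation from
                       baseline encodes the reward prediction error.
    """

    name: str
    n: int
    tau: float
    B: float
    lam: float
    kind: str = "standard"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"population {self.name}: n must be >= 1")
        if self.tau <= 0:
            raise ValueError(f"population {self.name}: tau must be > 0")
        if self.lam < 0:
            raise ValueError(f"population {self.name}: lam must be >= 0")
        if self.kind not in ("standard", "input", "snc"):
            raise ValueError(f"population {self.name}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class ProjectionSpec:
    """One projection between populations.

    Weights are nonnegative; the sign of the effect is carried by ``target``
    (``exc``/``inh``).  ``init`` is either a scalar or a ``(lo, hi)`` tuple of
    uniform bounds.  ``lateral`` marks within-population competition, which
    excludes self-connections by default.
    """

    name: str
    pre: str
    post: str
    pattern: str  # one_to_one | all_to_all
    init: float | tuple[float, float]
    target: str  # exc | inh
    plasticity: str = "none"  # none | shortcut | da_cortical | da_bg | da_snc
    lateral: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in ("one_to_one", "all_to_all"):
            raise ValueError(f"projection {self.name}: bad pattern {self.pattern!r}")
        if self.target not in ("exc", "inh"):
            raise ValueError(f"projection {self.name}: bad target {self.target!r}")
        if self.plasticity not in ("none", "shortcut", "da_cortical", "da_bg", "da_snc"):
            raise ValueError(f"projection {self.name}: bad plasticity {self.plasticity!r}")
        if isinstance(self.init, tuple):
            lo, hi = self.init
            if lo > hi:
                raise ValueError(f"projection {self.name}: uniform bounds need lo <= hi")
            if lo < 0:
                raise ValueError(f"projection {self.name}: weights must be >= 0")
        elif self.init < 0:
            raise ValueError(f"projection {self.name}: weights must be >= 0")

    @property
    def is_plastic(self) -> bool:
        return self.plasticity != "none"


@dataclass
class NetworkConfig:
    """Parsed and validated network + parameter configuration."""

    populations: dict[str, PopulationSpec]
    projections: dict[str, ProjectionSpec]
    shortcut_plasticity: dict[str, float]
    da_plasticity: dict[str, Any]
    snc: dict[str, float]
    dbs_variants: dict[str, dict[str, float]]
    task: dict[str, Any]
    td_priors: dict[str, dict[str, float]]
    options: dict[str, Any] = field(default_factory=dict)

    def copy(self) -> "NetworkConfig":
        return copy.deepcopy(self)

    def validate(self) -> None:
        snc_pops = [p for p in self.populations.values() if p.kind == "snc"]
        if len(snc_pops) != 1:
            raise ValueError("exactly one population of kind 'snc' is required")
        for proj in self.projections.values():
            pre = self.populations.get(proj.pre)
            post = self.populations.get(proj.post)
            if pre is None or post is None:
                raise ValueError(f"projection {proj.name}: unknown population")
            if proj.pattern == "one_to_one" and pre.n != post.n:
                raise ValueError(
                    f"projection {proj.name}: one_to_one requires equal sizes "
                    f"({pre.n} != {post.n})"
                )
            if post.kind == "input":
                raise ValueError(f"projection {proj.name}: input populations take no synaptic input")


def _parse(raw: dict[str, Any]) -> NetworkConfig:
    pops = {
        name: PopulationSpec(name=name, **entry) for name, entry in raw["populations"].items()
    }
    projs: dict[str, ProjectionSpec] = {}
    for entry in raw["projections"]:
        entry = dict(entry)
        init = entry["init"]
        if isinstance(init, list):
            entry["init"] = (float(init[0]), float(init[1]))
        else:
            entry["init"] = float(init)
        spec = ProjectionSpec(**entry)
        if spec.name in projs:
            raise ValueError(f"duplicate projection name {spec.name!r}")
        projs[spec.name] = spec
    cfg = NetworkConfig(
        populations=pops,
        projections=projs,
        shortcut_plasticity=raw["shortcut_plasticity"],
        da_plasticity=raw["da_plasticity"],
        snc=raw["snc"],
        dbs_variants=raw["dbs_variants"],
        task=raw["task"],
        td_priors=raw["td_priors"],
        options=raw.get("options", {}),
    )
    cfg.validate()
    return cfg


def load_config(path: str | None = None) -> NetworkConfig:
    """Load a network configuration from YAML (package default if no path)."""
    if path is None:
        ref = importlib.resources.files("bgdbs") / "config" / "network.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return _parse(raw)


_DEFAULT: NetworkConfig | None = None


def default_config() -> NetworkConfig:
    """A fresh copy of the packaged default configuration."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_config()
    return _DEFAULT.copy()
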