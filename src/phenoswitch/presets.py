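"""Shipped parameter presets.

The source figures mark parameter points inside the bistable region without
printing their coordinates, so every preset here is a documented
reconstruction satisfying the stated constraints (bistability; dimer decay
parameter alpha = 0.5 and 1 with a monomer:dimer decay-rate ratio of 10;
low-state occupancies of 80 and 160 proteins set through the molecule
scale N).  The ``bench-*`` presets are additional benchmark points chosen
in the wide-well regime near the cusp of the bistable region, where both
barriers are moderate and balanced so that exact stochastic first-passage
sampling is affordable; docs/methods.md discusses the choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .params import MotifParams, FullNetworkParams, full_from_motif

__all__ = ["Preset", "list_presets", "load_preset"]


@dataclass(frozen=True)
class Preset:
    """A named parameter set: scaled motif parameters plus the kinetic
    context (timescale ratios) needed to realize them as a full network."""

    name: str
    description: str
    motif_params: MotifParams
    gamma_m_ratio: float
    promoter_timescale: float
    dimer_timescale: float | None = None

    @property
    def full_params(self) -> FullNetworkParams:
        return full_from_motif(
            self.motif_params,
            gamma_m_ratio=self.gamma_m_ratio,
            promoter_timescale=self.promoter_timescale,
            dimer_timescale=self.dimer_timescale,
        )


def _preset_dir():
    return resources.files(__package__) / "presets"


def list_presets() -> list[str]:
    """Names of all shipped presets."""
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> Preset:
    path = _preset_dir() / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(list_presets())}") from None
    mp = MotifParams(
        motif=raw["motif"],
        S0=float(raw["S0"]),
        Sa=float(raw["Sa"]),
        b=float(raw.get("b", 2.0)),
        N=float(raw["N"]),
        c=float(raw.get("c", 0.0)),
        d=float(raw.get("d", 0.0)),
    )
    dt = raw.get("dimer_timescale")
    return Preset(
        name=name,
        description=raw.get("description", ""),
        motif_params=mp,
        gamma_m_ratio=float(raw.get("gamma_m_ratio", 20.0)),
        promoter_timescale=float(raw.get("promoter_timescale", 100.0)),
        dimer_timescale=float(dt) if dt is not None else None,
    )
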