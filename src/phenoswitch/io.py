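"""Configuration loading and provenance-carrying tabular output.

Tables are written as TSV with a ``#``-prefixed header block recording the
package version, the parameters that produced the table and (for stochastic
output) the seed, so every file can be traced back to its run.
``read_table`` round-trips anything ``write_table`` produced.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .params import MotifParams, ParameterError
from .presets import load_preset

__all__ = ["RunConfig", "load_config", "write_table", "read_table"]

_CONFIG_KEYS = {
    "preset", "motif", "S0", "Sa", "b", "N", "c", "d",
    "gamma_m_ratio", "promoter_timescale", "dimer_timescale",
    "seed", "n_replicates", "t_cap", "grid_points", "x_max", "out",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: parameters plus run-level settings."""

    params: MotifParams
    seed: int = 0
    n_replicates: int = 200
    t_cap: float = 1e6
    grid_points: int = 4001
    x_max: float | None = None
    gamma_m_ratio: float = 50.0
    promoter_timescale: float = 100.0
    dimer_timescale: float | None = None
    out: str | None = None
    source_hash: str | None = None

    def provenance(self) -> dict:
        d = {"version": __version__, "seed": self.seed}
        d.update(self.params.to_dict())
        if self.source_hash:
            d["config_sha256"] = self.source_hash
        return d


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    The file either names a ``preset`` or gives motif parameters directly
    (``motif``, ``S0``, ``Sa``, ``N`` at minimum; ``b`` defaults to 2 and
    ``seed`` to 0).  Unknown keys are an error, listed by name.
    """
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ParameterError(f"config {path} must be a YAML mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ParameterError(f"unknown config keys: {', '.join(sorted(unknown))}")

    kinetics = {}
    if "preset" in raw:
        preset = load_preset(raw["preset"])
        base = preset.motif_params.to_dict()
        kinetics = {
            "gamma_m_ratio": preset.gamma_m_ratio,
            "promoter_timescale": preset.promoter_timescale,
            "dimer_timescale": preset.dimer_timescale,
        }
    else:
        base = {"b": 2.0, "c": 0.0, "d": 0.0}
    for key in ("motif", "S0", "Sa", "b", "N", "c", "d"):
        if key in raw:
            base[key] = raw[key]
    for key in ("gamma_m_ratio", "promoter_timescale", "dimer_timescale"):
        if key in raw:
            kinetics[key] = raw[key]
    try:
        params = MotifParams(**base)
    except TypeError as exc:
        raise ParameterError(f"incomplete parameter set in {path}: {exc}") from exc

    return RunConfig(
        params=params,
        seed=int(raw.get("seed", 0)),
        n_replicates=int(raw.get("n_replicates", 200)),
        t_cap=float(raw.get("t_cap", 1e6)),
        grid_points=int(raw.get("grid_points", 4001)),
        x_max=float(raw["x_max"]) if "x_max" in raw else None,
        out=raw.get("out"),
        source_hash=hashlib.sha256(text.encode()).hexdigest(),
        **{k: v for k, v in kinetics.items() if v is not None},
    )


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None, overwrite: bool = False) -> Path:
    """Write a DataFrame as TSV with a commented provenance header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# phenoswitch {__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, sep="\t", comment="#")
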