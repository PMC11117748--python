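"""Run configuration: YAML loaders for concentrations and full pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .context import GimmeConfig
from .scaling import CofactorConcentrations

__all__ = [
    "load_concentrations",
    "packaged_concentrations",
    "concentration_ratios",
    "RunConfig",
    "load_run_config",
]


def load_concentrations(path: str | Path) -> dict[str, CofactorConcentrations]:
    """Read a concentration YAML (``reference`` + per-condition mM maps)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _parse_concentrations(raw, str(path))


def packaged_concentrations() -> dict[str, CofactorConcentrations]:
    """The shipped HEK293 / NAD-depleted concentration table."""
    text = resources.files("nadflux.data").joinpath("concentrations_hek293.yaml").read_text()
    return _parse_concentrations(yaml.safe_load(text), "<packaged>")


def _parse_concentrations(raw: dict, origin: str) -> dict[str, CofactorConcentrations]:
    if not isinstance(raw, dict) or "reference" not in raw or "conditions" not in raw:
        raise ValueError(f"{origin}: need 'reference' and 'conditions' blocks")
    ref = {str(k): float(v) for k, v in raw["reference"].items()}
    out = {}
    for name, comps in raw["conditions"].items():
        conc = {str(k): float(v) for k, v in comps.items()}
        out[str(name)] = CofactorConcentrations(conc, ref)
    return out


def concentration_ratios(conc: CofactorConcentrations) -> dict[str, float]:
    """Percent of the reference concentration remaining, per compartment."""
    return {comp: 100.0 * conc.ratio(comp) for comp in conc.concentration}


@dataclass
class RunConfig:
    """Everything a four-scenario run needs, loadable from one YAML file."""

    model: str  # SBML path, or "toy" for the synthetic fixture
    proteomics: dict[str, str]  # cell-line label -> abundance table path
    km_table: str
    concentrations: str  # YAML path, or "packaged"
    output_dir: str = "nadflux_out"
    id_map: Optional[str] = None
    cofactor_ids: Optional[list[str]] = None
    gimme_objective_fraction: float = 0.8
    gimme_activity_threshold: Optional[float] = None  # None -> median of medians
    keep_unscored: bool = True
    fva_fraction: float = 0.5
    pfba_fraction: float = 1.0
    tighten_all: bool = False
    cap_at_fva: bool = False
    sigma_min_pathway: float = 0.01
    sigma_min_reaction: float = 0.01
    percent_change_cap: float = 1000.0
    pathway_merges: dict[str, str] = field(default_factory=dict)
    pathway_exclude: list[str] = field(default_factory=list)
    reference_scenario: Optional[str] = None  # default: "<first proteome>_high"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gimme_objective_fraction", "fva_fraction", "pfba_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not self.proteomics:
            raise ValueError("at least one proteomics table is required")

    @property
    def gimme(self) -> GimmeConfig:
        if self.gimme_activity_threshold is None:
            raise ValueError("activity threshold not resolved yet")
        return GimmeConfig(
            activity_threshold=self.gimme_activity_threshold,
            objective_fraction=self.gimme_objective_fraction,
            keep_unscored=self.keep_unscored,
        )


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)
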