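"""Orchestration of the four-scenario experiment.

Two proteomes (e.g. parental and NAD-depleted cell lines) are integrated
into context models; each context model is then parameterized for two free
NAD concentration sets (high = parental, low = depleted), giving four
scenarios whose parsimonious flux distributions are aggregated into pathway
and reaction change tables against the (first proteome, high) reference.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path
from typing import Optional

import cobra
import pandas as pd

from . import __version__
from .config import RunConfig, load_concentrations, packaged_concentrations
from .context import (
    GimmeConfig,
    average_replicates,
    gimme,
    gimme_threshold,
    map_protein_ids,
    read_abundance_table,
    read_id_map,
    score_reactions,
)
from .lp import FluxResult, fba, write_flux_table
from .model import load_sbml
from .report import (
    changed_pathways,
    pathway_map_from_model,
    pathway_summary_frame,
    reaction_change_table,
    summarize_pathways,
)
from .scaling import read_km_table, run_scenario

__all__ = ["run_all", "scan_fraction", "build_context_models"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the CLI."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_model(cfg: RunConfig) -> cobra.Model:
    if cfg.model == "toy":
        from .fixtures import ToyModelSpec, make_toy_model

        return make_toy_model(ToyModelSpec(seed=cfg.seed))
    return load_sbml(cfg.model)


def _load_concentrations(cfg: RunConfig):
    if cfg.concentrations == "packaged":
        return packaged_concentrations()
    return load_concentrations(cfg.concentrations)


def build_context_models(
    cfg: RunConfig, model: Optional[cobra.Model] = None
) -> tuple[dict[str, cobra.Model], float]:
    """GIMME context model per proteome; returns (models, activity threshold)."""
    if model is None:
        model = _load_model(cfg)
    id_map = read_id_map(cfg.id_map) if cfg.id_map else None
    scores = {}
    for line, path in cfg.proteomics.items():
        table = read_abundance_table(path)
        gene_values = map_protein_ids(average_replicates(table), id_map)
        scores[line] = score_reactions(model, gene_values)
    if cfg.gimme_activity_threshold is not None:
        threshold = cfg.gimme_activity_threshold
    else:
        labels = list(scores)
        if len(labels) != 2:
            raise ValueError(
                "median-of-medians threshold needs exactly two proteomes; "
                "set gimme_activity_threshold explicitly otherwise"
            )
        threshold = gimme_threshold(scores[labels[0]], scores[labels[1]])
    gcfg = GimmeConfig(
        activity_threshold=threshold,
        objective_fraction=cfg.gimme_objective_fraction,
        keep_unscored=cfg.keep_unscored,
    )
    models = {line: gimme(model, s, gcfg) for line, s in scores.items()}
    return models, threshold


def run_all(cfg: RunConfig) -> dict:
    """Run the full four-scenario experiment and write the report bundle.

    Outputs under ``cfg.output_dir``: one ``fluxes_<scenario>.csv`` per
    scenario, ``pathway_summary.csv``, ``changed_pathways.csv``,
    ``reaction_changes.csv``, and ``manifest.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        model = _load_model(cfg)
    except Exception as exc:
        raise StageError("load_model", exc)
    try:
        km_table = read_km_table(cfg.km_table)
        concentrations = _load_concentrations(cfg)
    except Exception as exc:
        raise StageError("load_inputs", exc)
    try:
        context_models, threshold = build_context_models(cfg, model)
    except Exception as exc:
        raise StageError("build_context", exc)

    scenario_fluxes: dict[str, FluxResult] = {}
    scenario_models: dict[str, cobra.Model] = {}
    for line, ctx_model in context_models.items():
        for level, conc in concentrations.items():
            label = f"{line}_{level}"
            try:
                result = run_scenario(
                    ctx_model,
                    km_table,
                    conc,
                    fva_fraction=cfg.fva_fraction,
                    pfba_fraction=cfg.pfba_fraction,
                    cofactor_ids=cfg.cofactor_ids,
                    tighten_all=cfg.tighten_all,
                    cap_at_fva=cfg.cap_at_fva,
                )
            except Exception as exc:
                raise StageError(f"scenario:{label}", exc)
            if not result.ok:
                raise StageError(
                    f"scenario:{label}", RuntimeError(f"LP status {result.status}")
                )
            scenario_fluxes[label] = result
            scenario_models[label] = ctx_model
            write_flux_table(result, ctx_model, out / f"fluxes_{label}.csv")

    reference = cfg.reference_scenario or f"{next(iter(context_models))}_high"
    if reference not in scenario_fluxes:
        raise StageError(
            "report", KeyError(f"reference scenario {reference!r} not produced")
        )

    pmap = pathway_map_from_model(
        model, merges=cfg.pathway_merges, excluded=cfg.pathway_exclude
    )
    summaries = summarize_pathways(
        scenario_fluxes, pmap, reference, cap=cfg.percent_change_cap
    )
    pathway_summary_frame(summaries).to_csv(out / "pathway_summary.csv", index=False)
    pathway_summary_frame(
        changed_pathways(summaries, cfg.sigma_min_pathway)
    ).to_csv(out / "changed_pathways.csv", index=False)
    reaction_change_table(
        scenario_fluxes, reference, cfg.sigma_min_reaction, cfg.percent_change_cap
    ).to_csv(out / "reaction_changes.csv", index=False)

    manifest = {
        "package_version": __version__,
        "cobra_version": cobra.__version__,
        "python_version": platform.python_version(),
        "scenarios": sorted(scenario_fluxes),
        "reference_scenario": reference,
        "gimme_activity_threshold": threshold,
        "context_model_reactions": {
            line: len(m.reactions) for line, m in context_models.items()
        },
        "objective_values": {
            label: fr.objective_value for label, fr in scenario_fluxes.items()
        },
        "config": {k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def scan_fraction(cfg: RunConfig, fractions: list[float]) -> pd.DataFrame:
    """Rerun the context extraction over a grid of GIMME objective fractions.

    Reports submodel sizes and attained objectives so threshold stability
    can be inspected; an empty grid yields an empty table.
    """
    rows = []
    model = _load_model(cfg)
    for frac in fractions:
        scan_cfg = RunConfig(**{
            **{k: getattr(cfg, k) for k in cfg.__dataclass_fields__},
            "gimme_objective_fraction": frac,
        })
        models, threshold = build_context_models(scan_cfg, model)
        for line, sub in models.items():
            rows.append({
                "objective_fraction": frac,
                "cell_line": line,
                "n_reactions": len(sub.reactions),
                "objective": fba(sub).objective_value,
                "activity_threshold": threshold,
            })
    return pd.DataFrame(rows, columns=[
        "objective_fraction", "cell_line", "n_reactions", "objective",
        "activity_threshold",
    ])
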