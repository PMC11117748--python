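"""Pathway-level aggregation of scenario flux distributions.

Fluxes are grouped by pathway annotation, summarized as the mean absolute
flux per pathway, compared across scenarios via a population standard
deviation σ, and expressed as percent change against a reference scenario,
with large relative increases capped (a pathway silent in the reference
would otherwise yield an infinite change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import cobra
import numpy as np
import pandas as pd

from .lp import FluxResult

__all__ = [
    "PathwayMap",
    "PathwaySummary",
    "PERCENT_CHANGE_CAP",
    "pathway_map_from_model",
    "pathway_mean_abs_flux",
    "percent_change",
    "summarize_pathways",
    "changed_pathways",
    "reaction_change_table",
]

log = logging.getLogger(__name__)

#: Upper cap on percent changes (handles reference flux = 0).
PERCENT_CHANGE_CAP = 1000.0


@dataclass
class PathwayMap:
    """Pathway name → member reaction ids, with optional merge/exclude edits."""

    pathways: dict[str, list[str]]
    merges: Mapping[str, str] = field(default_factory=dict)  # old name -> new name
    excluded: frozenset[str] = frozenset()

    def effective(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, rids in self.pathways.items():
            name = self.merges.get(name, name)
            if name in self.excluded:
                continue
            out.setdefault(name, []).extend(rids)
        return out


def pathway_map_from_model(
    model: cobra.Model,
    merges: Optional[Mapping[str, str]] = None,
    excluded: Sequence[str] = (),
) -> PathwayMap:
    """Build a pathway map from the model's subsystem annotations."""
    pathways: dict[str, list[str]] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            pathways.setdefault(rxn.subsystem, []).append(rxn.id)
    return PathwayMap(pathways, merges or {}, frozenset(excluded))


def pathway_mean_abs_flux(flux: FluxResult, pmap: PathwayMap) -> dict[str, float]:
    """Mean of |v_r| over each pathway's reactions.

    Reactions missing from the flux vector contribute 0 (logged); a pathway
    empty after filtering is omitted with a warning.
    """
    out: dict[str, float] = {}
    for name, rids in pmap.effective().items():
        if not rids:
            log.warning("pathway %r has no reactions after filtering; omitted", name)
            continue
        vals = []
        for rid in rids:
            if rid not in flux.fluxes:
                log.info("pathway %r: reaction %s absent from solution, counted as 0", name, rid)
                vals.append(0.0)
            else:
                vals.append(abs(flux.fluxes[rid]))
        out[name] = float(np.mean(vals))
    return out


def percent_change(v: float, v_prime: float, cap: float = PERCENT_CHANGE_CAP) -> float:
    """100·(v′ − v)/v, clamped from above at ``cap``.

    v = 0 with v′ > 0 maps to the cap; v = v′ = 0 maps to 0. Decreases are
    never clamped (they are bounded below by −100 for nonnegative inputs).
    """
    if v < 0 or v_prime < 0:
        raise ValueError("percent_change expects nonnegative magnitudes")
    if v == 0:
        return cap if v_prime > 0 else 0.0
    return min(100.0 * (v_prime - v) / v, cap)


@dataclass
class PathwaySummary:
    pathway: str
    mean_abs_flux: dict[str, float]  # scenario label -> mean |v|
    sigma: float  # population std across scenarios
    percent_change: dict[str, float]  # scenario label -> % change vs reference


def summarize_pathways(
    fluxes: Mapping[str, FluxResult],
    pmap: PathwayMap,
    reference: str,
    cap: float = PERCENT_CHANGE_CAP,
) -> list[PathwaySummary]:
    """Per-pathway mean |flux| for every scenario, σ across scenarios, and
    percent change of each scenario against ``reference``."""
    if reference not in fluxes:
        raise KeyError(f"reference scenario {reference!r} not among {sorted(fluxes)}")
    per_scenario = {label: pathway_mean_abs_flux(fr, pmap) for label, fr in fluxes.items()}
    names = sorted({n for d in per_scenario.values() for n in d})
    out = []
    for name in names:
        means = {label: per_scenario[label].get(name, 0.0) for label in fluxes}
        sigma = float(np.std(list(means.values())))  # population std
        changes = {
            label: percent_change(means[reference], means[label], cap) for label in fluxes
        }
        out.append(PathwaySummary(name, means, sigma, changes))
    return out


def changed_pathways(
    summaries: Sequence[PathwaySummary], sigma_min: float = 0.01
) -> list[PathwaySummary]:
    """Pathways whose σ strictly exceeds ``sigma_min``, most variable first."""
    return sorted(
        (s for s in summaries if s.sigma > sigma_min),
        key=lambda s: s.sigma,
        reverse=True,
    )


def reaction_change_table(
    fluxes: Mapping[str, FluxResult],
    reference: str,
    sigma_min: float = 0.01,
    cap: float = PERCENT_CHANGE_CAP,
) -> pd.DataFrame:
    """Per-reaction |flux| across scenarios with σ ≥ ``sigma_min``.

    Note the boundary is inclusive here (reactions *at* the threshold are
    shown) while pathway selection is strict.
    """
    if reference not in fluxes:
        raise KeyError(f"reference scenario {reference!r} not among {sorted(fluxes)}")
    labels = list(fluxes)
    rids = sorted({rid for fr in fluxes.values() for rid in fr.fluxes})
    rows = []
    for rid in rids:
        mags = {label: abs(fluxes[label].fluxes.get(rid, 0.0)) for label in labels}
        sigma = float(np.std(list(mags.values())))
        if sigma < sigma_min:
            continue
        row = {"reaction_id": rid, "sigma": sigma}
        for label in labels:
            row[f"flux_{label}"] = fluxes[label].fluxes.get(rid, 0.0)
            row[f"pct_change_{label}"] = percent_change(mags[reference], mags[label], cap)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.sort_values("sigma", ascending=False).reset_index(drop=True)
    return frame


def pathway_summary_frame(summaries: Sequence[PathwaySummary]) -> pd.DataFrame:
    """Flatten summaries into a CSV-ready frame."""
    rows = []
    for s in summaries:
        row: dict = {"pathway": s.pathway, "sigma": s.sigma}
        for label, v in s.mean_abs_flux.items():
            row[f"mean_abs_flux_{label}"] = v
        for label, c in s.percent_change.items():
            row[f"pct_change_{label}"] = c
        rows.append(row)
    return pd.DataFrame(rows)
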