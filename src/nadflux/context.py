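"""Proteomics integration: reaction scoring and GIMME context-model extraction.

Protein abundance ratios (replicate table) are averaged per protein, mapped
onto reactions through the GPR rules (AND → min, OR → max over scored
children), and integrated with a GIMME linear program that minimizes
penalized flux through low-evidence reactions while preserving a fraction of
the optimal objective.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import cobra
import pandas as pd

from .lp import FEASIBILITY_TOL, fba

__all__ = [
    "GimmeConfig",
    "UNSCORED",
    "read_abundance_table",
    "read_id_map",
    "average_replicates",
    "map_protein_ids",
    "score_reactions",
    "gimme_threshold",
    "gimme",
]

log = logging.getLogger(__name__)

#: Marker distinguishing "no expression evidence" from a zero score.
UNSCORED = None

#: |flux| above this in the penalty solution keeps a below-threshold reaction.
FLUX_KEEP_TOL = 1e-6


@dataclass(frozen=True)
class GimmeConfig:
    """GIMME knobs: expression activity threshold and minimum objective fraction."""

    activity_threshold: float
    objective_fraction: float = 0.8
    keep_unscored: bool = True  # retain reactions with no expression evidence

    def __post_init__(self) -> None:
        if self.activity_threshold < 0:
            raise ValueError("activity_threshold must be ≥ 0")
        if not 0 < self.objective_fraction <= 1:
            raise ValueError("objective_fraction must be in (0, 1]")


def read_abundance_table(path: str | Path) -> pd.DataFrame:
    """Read a protein abundance-ratio table (TSV/CSV: id, rep1..repN).

    Ratios must be positive where present; missing replicate cells are allowed.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need an id column plus ≥1 replicate column")
    frame = frame.set_index(frame.columns[0])
    if (frame <= 0).any().any():
        raise ValueError(f"{path}: abundance ratios must be > 0")
    return frame


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping protein ids to model gene ids."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(frame[0], frame[1]))


def average_replicates(table: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean ratio per protein; missing replicates are skipped."""
    if table.empty:
        raise ValueError("empty abundance table")
    return table.mean(axis=1, skipna=True).to_dict()


def map_protein_ids(
    values: Mapping[str, float], id_map: Optional[Mapping[str, str]] = None
) -> dict[str, float]:
    """Translate protein ids to model gene ids, dropping unmapped proteins.

    With no map, ids are assumed to already be model gene ids. The number of
    dropped proteins is logged, never raised — partial proteome coverage is
    the normal case.
    """
    if id_map is None:
        return dict(values)
    mapped = {id_map[p]: v for p, v in values.items() if p in id_map}
    log.info("mapped %d of %d proteins to model genes", len(mapped), len(values))
    return mapped


def _eval_gpr(node: ast.AST, gene_values: Mapping[str, float]) -> Optional[float]:
    # AND → min, OR → max over *scored* children; unscored children are
    # dropped; a node with no scored child is itself unscored.
    if isinstance(node, ast.Name):
        return gene_values.get(node.id)
    if isinstance(node, ast.BoolOp):
        child = [_eval_gpr(c, gene_values) for c in node.values]
        scored = [v for v in child if v is not None]
        if not scored:
            return None
        return min(scored) if isinstance(node.op, ast.And) else max(scored)
    if isinstance(node, ast.Expression):
        return _eval_gpr(node.body, gene_values)
    raise ValueError(f"unsupported GPR node: {ast.dump(node)}")


def score_reactions(
    model: cobra.Model, gene_values: Mapping[str, float]
) -> dict[str, Optional[float]]:
    """GPR-aggregate gene values into reaction scores.

    Returns a mapping reaction id → score, with :data:`UNSCORED` (``None``)
    for reactions without a GPR or without any scored gene.
    """
    scores: dict[str, Optional[float]] = {}
    for rxn in model.reactions:
        body = rxn.gpr.body if rxn.gpr is not None else None
        scores[rxn.id] = _eval_gpr(body, gene_values) if body is not None else UNSCORED
    return scores


def gimme_threshold(
    scores_a: Mapping[str, Optional[float]], scores_b: Mapping[str, Optional[float]]
) -> float:
    """Activity threshold: median of each table's scored values, then the
    median (= mean, for two values) of those two medians."""
    medians = []
    for scores in (scores_a, scores_b):
        vals = sorted(v for v in scores.values() if v is not None)
        if not vals:
            raise ValueError("score table has no scored reaction")
        medians.append(float(pd.Series(vals).median()))
    return float(pd.Series(medians).median())


def gimme(
    model: cobra.Model,
    scores: Mapping[str, Optional[float]],
    cfg: GimmeConfig,
) -> cobra.Model:
    """Extract a context-specific submodel (GIMME).

    Solves ``min Σ_r (threshold − score_r)·|v_r|`` over scored reactions
    below the activity threshold, subject to steady state, bounds, and
    objective ≥ ``objective_fraction`` × optimum; keeps every above-threshold
    and (by default) unscored reaction, plus penalized reactions that carry
    |flux| > tolerance in the penalty-minimizing solution.
    """
    base = fba(model)
    if not base.ok or base.objective_value <= 0:
        raise ValueError(
            f"GIMME needs a solvable model with positive objective "
            f"(status={base.status}, objective={base.objective_value})"
        )

    penalized = {
        rid: cfg.activity_threshold - s
        for rid, s in scores.items()
        if s is not None and s < cfg.activity_threshold
    }

    with model as m:
        m.solver = "glpk"
        m.tolerance = FEASIBILITY_TOL
        from cobra.util.solver import fix_objective_as_constraint

        try:
            fix_objective_as_constraint(m, fraction=cfg.objective_fraction)
        except Exception as exc:  # pragma: no cover - solver-level failure
            raise ValueError(
                f"objective fraction {cfg.objective_fraction} not attainable"
            ) from exc
        aux_vars = []
        constraints = []
        obj_terms = []
        for rid, weight in penalized.items():
            rxn = m.reactions.get_by_id(rid)
            a = m.problem.Variable(f"gimme_abs_{rid}", lb=0)
            c_pos = m.problem.Constraint(
                a - rxn.flux_expression, lb=0, name=f"gimme_pos_{rid}"
            )
            c_neg = m.problem.Constraint(
                a + rxn.flux_expression, lb=0, name=f"gimme_neg_{rid}"
            )
            aux_vars.append(a)
            constraints.extend([c_pos, c_neg])
            obj_terms.append(weight * a)
        m.add_cons_vars(aux_vars + constraints)
        m.objective = m.problem.Objective(sum(obj_terms) if obj_terms else 0, direction="min")
        sol = m.optimize()
        if sol.status != "optimal":
            raise ValueError(f"GIMME penalty LP not optimal: {sol.status}")
        penalty_fluxes = {r.id: float(sol.fluxes[r.id]) for r in model.reactions}

    drop = [rid for rid in penalized if abs(penalty_fluxes[rid]) <= FLUX_KEEP_TOL]
    if not cfg.keep_unscored:
        drop += [
            rid
            for rid, s in scores.items()
            if s is None and abs(penalty_fluxes[rid]) <= FLUX_KEEP_TOL
        ]
    sub = model.copy()
    sub.remove_reactions([sub.reactions.get_by_id(r) for r in drop], remove_orphans=True)
    return sub
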