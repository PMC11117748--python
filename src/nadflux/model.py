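"""Model I/O and structural queries for compartmentalized stoichiometric models.

The in-memory container is :class:`cobra.Model`; this module adds the pieces
the concentration-scaling pipeline needs on top of plain SBML I/O: pathway
(subsystem) labels that survive a write/read cycle, explicit GPR parsing, and
identification of cofactor-dependent reactions by metabolite id.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Iterable, Optional, Sequence

import cobra
from cobra.core import Group
from cobra.core.gene import GPR

__all__ = [
    "DEFAULT_COFACTOR_BASES",
    "load_sbml",
    "write_sbml",
    "parse_gpr",
    "serialize_gpr",
    "default_cofactor_ids",
    "cofactor_reactions",
]

#: Base metabolite identifiers (BiGG-style, compartment suffix stripped) that
#: make up the free NAD(P)(H) pool. Bound/prosthetic forms are deliberately
#: excluded; override the resolved id set explicitly to change this.
DEFAULT_COFACTOR_BASES: tuple[str, ...] = ("nad", "nadh", "nadp", "nadph")


def load_sbml(path: str | Path) -> cobra.Model:
    """Read an SBML (Level 3 + FBC, or legacy COBRA-notes dialect) model.

    Pathway labels are restored from SBML groups where present. Raises
    ``FileNotFoundError`` for a missing file and ``ValueError`` for a model
    that parses but declares no objective.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SBML file not found: {path}")
    model = cobra.io.read_sbml_model(str(path))
    if not _objective_reactions(model):
        raise ValueError(
            f"model {model.id!r} has no objective reaction; "
            "set an FBC objective (or COBRA notes objective) before use"
        )
    return model


def write_sbml(model: cobra.Model, path: str | Path) -> None:
    """Write ``model`` as SBML L3+FBC, encoding subsystems as groups.

    Refuses to write a model without an objective so that every file this
    package produces is loadable by :func:`load_sbml`.
    """
    if not _objective_reactions(model):
        raise ValueError("refusing to write a model without an objective reaction")
    model = model.copy()
    _sync_subsystem_groups(model)
    for group in model.groups:
        # cobra stores members as a set; order them so output is reproducible
        group._members = _OrderedMembers(sorted(group.members, key=lambda m: m.id))
    cobra.io.write_sbml_model(model, str(path))


class _OrderedMembers(list):
    """List with the set-ops cobra expects, preserving iteration order."""

    def update(self, items) -> None:
        known = {id(x) for x in self}
        self.extend(x for x in items if id(x) not in known)

    def difference_update(self, items) -> None:
        gone = {id(x) for x in items}
        self[:] = [x for x in self if id(x) not in gone]


def _objective_reactions(model: cobra.Model) -> dict[str, float]:
    from cobra.util.solver import linear_reaction_coefficients

    return {r.id: c for r, c in linear_reaction_coefficients(model).items() if c}


def _sync_subsystem_groups(model: cobra.Model) -> None:
    # cobra only serializes groups, not the per-reaction subsystem string
    existing = {g.id for g in model.groups}
    by_subsystem: dict[str, list] = {}
    for rxn in model.reactions:
        if rxn.subsystem:
            by_subsystem.setdefault(rxn.subsystem, []).append(rxn)
    new = [
        Group(id=name.replace(" ", "_"), name=name, members=members, kind="partonomy")
        for name, members in by_subsystem.items()
        if name.replace(" ", "_") not in existing
    ]
    if new:
        model.add_groups(new)


def parse_gpr(text: str) -> GPR:
    """Parse a gene-protein-reaction rule into a boolean expression tree.

    ``and`` binds tighter than ``or``; keywords are case-insensitive; gene ids
    are opaque strings. An empty/whitespace rule yields the no-GPR marker
    (a :class:`GPR` whose ``body`` is ``None``), not an error.
    """
    if text is None or not text.strip():
        return GPR()
    import re
    import warnings

    text = re.sub(r"\b(and|or)\b", lambda m: m.group(1).lower(), text, flags=re.IGNORECASE)

    with warnings.catch_warnings():
        warnings.simplefilter("error", SyntaxWarning)
        try:
            gpr = GPR.from_string(text)
        except SyntaxWarning as exc:
            raise ValueError(f"malformed GPR rule {text!r}") from exc
    if gpr.body is None:
        raise ValueError(f"malformed GPR rule {text!r}")
    return gpr


def serialize_gpr(gpr: GPR) -> str:
    """Inverse of :func:`parse_gpr`; ``parse ∘ serialize`` is a fixed point."""
    return gpr.to_string()


def default_cofactor_ids(model: cobra.Model, bases: Sequence[str] = DEFAULT_COFACTOR_BASES) -> set[str]:
    """Resolve ``<base>_<compartment>`` cofactor metabolite ids present in ``model``."""
    candidates = {
        f"{base}_{comp}" for base in bases for comp in model.compartments
    }
    return {m.id for m in model.metabolites if m.id in candidates}


def cofactor_reactions(
    model: cobra.Model,
    cofactor_ids: Optional[Iterable[str]] = None,
) -> list[tuple[str, set[str]]]:
    """List reactions touching at least one cofactor metabolite.

    Parameters
    ----------
    cofactor_ids
        Metabolite ids to treat as the cofactor pool. Defaults to the free
        NAD(P)(H) species resolved by :func:`default_cofactor_ids`. Unknown
        ids raise ``KeyError`` naming them.

    Returns
    -------
    ``[(reaction_id, {participating cofactor metabolite ids}), ...]`` in
    model reaction order.
    """
    if cofactor_ids is None:
        ids = default_cofactor_ids(model)
    else:
        ids = set(cofactor_ids)
        known = {m.id for m in model.metabolites}
        unknown = sorted(ids - known)
        if unknown:
            raise KeyError(f"cofactor metabolite ids not in model: {unknown}")
    out: list[tuple[str, set[str]]] = []
    for rxn in model.reactions:
        hits = {m.id for m in rxn.metabolites if m.id in ids}
        if hits:
            out.append((rxn.id, hits))
    return out


def gpr_genes(gpr: GPR) -> set[str]:
    """Gene ids appearing in a GPR tree (empty set for the no-GPR marker)."""
    if gpr.body is None:
        return set()
    return {n.id for n in ast.walk(gpr.body) if isinstance(n, ast.Name)}
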