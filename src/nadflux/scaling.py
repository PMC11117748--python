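"""Cofactor-concentration parameterization of flux bounds.

The central idea: a reaction using free NAD(P)(H) cannot run faster than its
Michaelis–Menten occupancy allows. Given a feasible flux range [v_, v̄] from
FVA, a measured cofactor concentration C, a reference (wild-type)
concentration C0, and the enzyme's Km for the cofactor, the new bounds are

    v̄_C = v̄ · C/(Km + C) · s,     v_C = v_ · C/(Km + C) · s,

with the normalization factor s = (Km + C0)/C0 chosen so the bounds are
exactly the FVA bounds when C = C0. Lower Km (higher affinity) gives a
factor closer to 1 at C < C0, i.e. a weaker constraint — selecting the
minimum Km per reaction is therefore the conservative choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import cobra
import pandas as pd

from .lp import FluxRange, FluxResult, fva, pfba
from .model import cofactor_reactions, default_cofactor_ids

__all__ = [
    "KmRecord",
    "CofactorConcentrations",
    "ScalingContext",
    "ScaledBounds",
    "ORGANISM_PRIORITY",
    "read_km_table",
    "select_km",
    "scale_factor",
    "scale_bounds",
    "apply_concentrations",
    "run_scenario",
]

log = logging.getLogger(__name__)

#: Mammalian fallback order when no human Km is curated: closest-available
#: large mammals first.
ORGANISM_PRIORITY: tuple[str, ...] = ("human", "pig", "cow", "rat", "mouse")

_ORGANISM_SYNONYMS = {
    "homo sapiens": "human",
    "human": "human",
    "sus scrofa domesticus": "pig",
    "sus scrofa": "pig",
    "pig": "pig",
    "bos taurus": "cow",
    "cow": "cow",
    "rattus norvegicus": "rat",
    "rat": "rat",
    "mus musculus": "mouse",
    "mouse": "mouse",
}


def canonical_organism(name: str) -> str:
    try:
        return _ORGANISM_SYNONYMS[name.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown organism {name!r}; known: {sorted(set(_ORGANISM_SYNONYMS))}"
        ) from None


@dataclass(frozen=True)
class KmRecord:
    """One curated Michaelis constant: reaction × cofactor × organism, in mM."""

    reaction_id: str
    cofactor_id: str
    organism: str
    km: float  # mM
    source: str = ""

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError(f"{self.reaction_id}: Km must be > 0, got {self.km}")
        object.__setattr__(self, "organism", canonical_organism(self.organism))


@dataclass(frozen=True)
class CofactorConcentrations:
    """Per-compartment cofactor concentrations (mM): measured C and reference C0."""

    concentration: Mapping[str, float]  # compartment -> C
    reference: Mapping[str, float]  # compartment -> C0

    def __post_init__(self) -> None:
        for comp, c0 in self.reference.items():
            if c0 <= 0:
                raise ValueError(f"reference concentration must be > 0 ({comp}: {c0})")
        for comp, c in self.concentration.items():
            if c < 0:
                raise ValueError(f"concentration must be ≥ 0 ({comp}: {c})")

    def ratio(self, compartment: str) -> float:
        """C/C0 for one compartment (the 'fraction remaining')."""
        return self.concentration[compartment] / self.reference[compartment]


@dataclass(frozen=True)
class ScalingContext:
    """Inputs of the bound-scaling formula for one reaction/cofactor/compartment."""

    C: float
    C0: float
    km: float

    @property
    def s(self) -> float:
        """Normalization factor (Km + C0)/C0; s·C0/(Km + C0) = 1 exactly."""
        return (self.km + self.C0) / self.C0


@dataclass(frozen=True)
class ScaledBounds:
    reaction_id: str
    v_lower_scaled: float
    v_upper_scaled: float

    def __post_init__(self) -> None:
        if self.v_lower_scaled > self.v_upper_scaled + 1e-12:
            raise ValueError(f"{self.reaction_id}: scaled lower bound exceeds upper")


def read_km_table(path: str | Path) -> list[KmRecord]:
    """Read a Km CSV: reaction_id, cofactor_id, organism, km_mM[, source]."""
    frame = pd.read_csv(path)
    required = {"reaction_id", "cofactor_id", "organism", "km_mM"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        KmRecord(
            reaction_id=row.reaction_id,
            cofactor_id=row.cofactor_id,
            organism=row.organism,
            km=float(row.km_mM),
            source=str(getattr(row, "source", "")),
        )
        for row in frame.itertuples(index=False)
    ]


def select_km(
    records: Iterable[KmRecord], reaction_id: str, cofactor_id: str
) -> Optional[float]:
    """Pick the Km for one reaction/cofactor pair.

    The highest-priority organism present wins (human > pig > cow > rat >
    mouse); within that organism the minimum Km is used. Returns ``None``
    when no record matches — absence is a modeled state, not an error.
    """
    matching = [
        r for r in records if r.reaction_id == reaction_id and r.cofactor_id == cofactor_id
    ]
    for organism in ORGANISM_PRIORITY:
        kms = [r.km for r in matching if r.organism == organism]
        if kms:
            return min(kms)
    return None


def scale_factor(ctx: ScalingContext) -> float:
    """Dimensionless bound multiplier f = s · C/(Km + C); f = 1 at C = C0."""
    if ctx.C0 <= 0:
        raise ValueError("reference concentration C0 must be > 0")
    if ctx.km <= 0:
        raise ValueError("Km must be > 0")
    if ctx.C < 0:
        raise ValueError("concentration C must be ≥ 0")
    return ctx.s * ctx.C / (ctx.km + ctx.C)


def scale_bounds(flux_range: FluxRange, ctx: ScalingContext) -> ScaledBounds:
    """Multiply both ends of an FVA range by the scaling factor.

    A [0, 0] range stays [0, 0]: a reaction blocked by the model constraints
    stays blocked regardless of cofactor availability.
    """
    f = scale_factor(ctx)
    return ScaledBounds(
        reaction_id=flux_range.reaction_id,
        v_lower_scaled=flux_range.v_lower * f,
        v_upper_scaled=flux_range.v_upper * f,
    )


def _reaction_factor(
    rxn_cofactors: set[str],
    metabolite_compartment: Mapping[str, str],
    km_by_cofactor: Mapping[str, float],
    conc: CofactorConcentrations,
    rxn_id: str,
) -> Optional[float]:
    # most-limiting rule: min factor over participating cofactor species
    # (and hence over compartments, for transport reactions)
    factors = []
    for cid in sorted(rxn_cofactors):
        km = km_by_cofactor.get(cid)
        if km is None:
            continue
        comp = metabolite_compartment[cid]
        if comp not in conc.concentration or comp not in conc.reference:
            raise KeyError(
                f"reaction {rxn_id}: no configured concentration for compartment "
                f"{comp!r} of cofactor {cid}"
            )
        factors.append(scale_factor(ScalingContext(
            C=conc.concentration[comp], C0=conc.reference[comp], km=km
        )))
    return min(factors) if factors else None


def apply_concentrations(
    model: cobra.Model,
    km_table: Sequence[KmRecord],
    conc: CofactorConcentrations,
    fva_fraction: float = 0.5,
    cofactor_ids: Optional[Iterable[str]] = None,
    tighten_all: bool = False,
    cap_at_fva: bool = False,
) -> cobra.Model:
    """Return a copy of ``model`` with cofactor-reaction bounds rescaled.

    Runs FVA at ``fva_fraction`` of the optimum, then for every
    cofactor-dependent reaction with at least one selected Km replaces its
    bounds by the Michaelis–Menten-scaled FVA range; cofactor reactions
    without a Km — and, unless ``tighten_all`` is set, all non-cofactor
    reactions — keep their prior bounds. ``cap_at_fva`` clamps factors > 1
    (possible when C > C0) back to 1. The input model is never mutated.
    """
    ids = set(cofactor_ids) if cofactor_ids is not None else default_cofactor_ids(model)
    ranges = {fr.reaction_id: fr for fr in fva(model, fraction_of_optimum=fva_fraction)}
    met_comp = {m.id: m.compartment for m in model.metabolites}
    scaled = model.copy()

    for rid, cofs in cofactor_reactions(model, ids):
        km_by_cof = {
            cid: km
            for cid in cofs
            if (km := select_km(km_table, rid, cid)) is not None
        }
        factor = _reaction_factor(cofs, met_comp, km_by_cof, conc, rid)
        if factor is None:
            continue  # no curated Km: bounds left as-is
        if factor > 1:
            if cap_at_fva:
                factor = 1.0
            else:
                log.info("reaction %s: factor %.4g > 1 (C above reference)", rid, factor)
        fr = ranges[rid]
        lo, hi = fr.v_lower * factor, fr.v_upper * factor
        rxn = scaled.reactions.get_by_id(rid)
        rxn.bounds = (min(lo, hi), max(lo, hi))

    if tighten_all:
        touched = {rid for rid, _ in cofactor_reactions(model, ids)}
        for fr in ranges.values():
            if fr.reaction_id not in touched:
                rxn = scaled.reactions.get_by_id(fr.reaction_id)
                rxn.bounds = (fr.v_lower, fr.v_upper)
    return scaled


def run_scenario(
    context_model: cobra.Model,
    km_table: Sequence[KmRecord],
    conc: CofactorConcentrations,
    fva_fraction: float = 0.5,
    pfba_fraction: float = 1.0,
    **apply_kwargs,
) -> FluxResult:
    """Parameterize a context model for one concentration set and run pFBA."""
    scaled = apply_concentrations(
        context_model, km_table, conc, fva_fraction=fva_fraction, **apply_kwargs
    )
    return pfba(scaled, fraction_of_optimum=pfba_fraction)
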