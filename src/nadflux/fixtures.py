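"""Synthetic fixtures: toy models, proteomics tables, and Km tables.

The flagship fixture is a two-compartment (cytosol/mitochondrion) network
with the redox architecture the concentration-scaling method assumes:
glucose is oxidized by an NAD⁺-consuming glycolysis proxy, cytosolic NADH is
reoxidized either by a lactate branch or a malate–aspartate-style shuttle,
pyruvate feeds an NAD-coupled TCA proxy, and an electron-transport-chain
proxy reoxidizes mitochondrial NADH to drive an ATP-demand objective. All
NAD species are interconverted only (no moiety synthesis or breakdown), so
the steady-state assumption holds and depleting a compartment's free NAD can
only act through the Michaelis–Menten bound scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from cobra import Metabolite, Model, Reaction

from .scaling import CofactorConcentrations, KmRecord

__all__ = [
    "ToyModelSpec",
    "make_toy_model",
    "make_t1_model",
    "make_toy_proteomics",
    "make_toy_km_table",
    "make_random_network",
    "make_random_branched_model",
    "toy_concentrations",
]

#: Reference (parental) free NAD concentrations of the toy, mM per compartment.
TOY_REFERENCE_MM = {"c": 0.11, "m": 0.23}
#: Depleted concentrations: 60% remaining in cytosol, 10% in mitochondria.
TOY_DEPLETED_MM = {"c": 0.066, "m": 0.023}

#: Genes of the lactate branch / shuttle (up in the compensated proteome)
#: and of the ETC proxy (down).
COMPENSATION_UP = ("gLDH", "gMCT", "gSHUT")
COMPENSATION_DOWN = ("gETC",)

#: Baseline abundance-ratio means. The redox-overflow genes (lactate branch,
#: shuttle) sit clearly above the median so the context extraction never
#: drops the overflow routes on noise alone; the futile oxidase decoys sit
#: clearly below it and are the reactions the extraction should remove.
_BASELINE_MEAN = {"gLDH": 3.0, "gMCT": 3.0, "gSHUT": 3.0, "gAOX": 0.2, "gNOX": 0.2}
_DEFAULT_MEAN = 2.0


@dataclass(frozen=True)
class ToyModelSpec:
    """Parameters of the toy network generator."""

    n_glycolysis_steps: int = 1
    include_lactate_branch: bool = True
    include_etc_proxy: bool = True
    nad_km_mM: Optional[float] = None  # None -> per-compartment reference conc.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_glycolysis_steps < 1:
            raise ValueError("n_glycolysis_steps must be ≥ 1")
        if self.nad_km_mM is not None and self.nad_km_mM <= 0:
            raise ValueError("nad_km_mM must be > 0")


def _add(model: Model, rid: str, stoich, lb, ub, gpr="", subsystem="") -> Reaction:
    rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites(stoich)
    if gpr:
        rxn.gene_reaction_rule = gpr
    rxn.subsystem = subsystem
    return rxn


def make_toy_model(spec: ToyModelSpec = ToyModelSpec()) -> Model:
    """Build the two-compartment NAD-coupled toy network.

    Deterministic for a fixed spec (there is no structural randomness; the
    seed only flows into the companion proteomics/Km generators).
    """
    m = Model("nad_toy")
    m.compartments = {"c": "cytosol", "m": "mitochondrion", "e": "extracellular"}

    met = {
        mid: Metabolite(mid, compartment=mid.rsplit("_", 1)[1])
        for mid in [
            "glc_e", "glc_c", "pyr_c", "pyr_m", "lac_c", "lac_e",
            "nad_c", "nadh_c", "nad_m", "nadh_m", "atp_c", "atp_m",
        ]
    }

    _add(m, "EX_glc_e", {met["glc_e"]: -1}, -10, 0, subsystem="Exchange")
    _add(m, "GLCt", {met["glc_e"]: -1, met["glc_c"]: 1}, 0, 1000,
         gpr="gGLCT", subsystem="Transport")

    # glycolysis proxy: optional 1:1 chain, NAD/ATP coupling on the last step
    prev = met["glc_c"]
    for i in range(1, spec.n_glycolysis_steps):
        inter = Metabolite(f"gly{i}_c", compartment="c")
        _add(m, f"GLY{i}", {prev: -1, inter: 1}, 0, 1000,
             gpr=f"gGLY{i}", subsystem="Glycolysis")
        prev = inter
    _add(m, f"GLY{spec.n_glycolysis_steps}",
         {prev: -1, met["nad_c"]: -2,
          met["pyr_c"]: 2, met["nadh_c"]: 2, met["atp_c"]: 2},
         0, 1000, gpr=f"gGLY{spec.n_glycolysis_steps}", subsystem="Glycolysis")

    if spec.include_lactate_branch:
        _add(m, "LDH", {met["pyr_c"]: -1, met["nadh_c"]: -1,
                        met["lac_c"]: 1, met["nad_c"]: 1},
             0, 1000, gpr="gLDH", subsystem="Lactate metabolism")
        _add(m, "LACt", {met["lac_c"]: -1, met["lac_e"]: 1}, 0, 1000,
             gpr="gMCT", subsystem="Transport")
        _add(m, "EX_lac_e", {met["lac_e"]: -1}, 0, 1000, subsystem="Exchange")

    _add(m, "PYRt", {met["pyr_c"]: -1, met["pyr_m"]: 1}, 0, 1000,
         gpr="gMPC", subsystem="Transport")
    _add(m, "TCA", {met["pyr_m"]: -1, met["nad_m"]: -4, met["nadh_m"]: 4},
         0, 1000, gpr="gTCA", subsystem="TCA cycle")

    if spec.include_etc_proxy:
        _add(m, "ETC", {met["nadh_m"]: -1, met["nad_m"]: 1, met["atp_m"]: 2.5},
             0, 1000, gpr="gETC", subsystem="Oxidative phosphorylation")
        _add(m, "ATPt", {met["atp_m"]: -1, met["atp_c"]: 1}, 0, 1000,
             gpr="gANT", subsystem="Transport")

    _add(m, "SHUTTLE", {met["nadh_c"]: -1, met["nad_m"]: -1,
                        met["nad_c"]: 1, met["nadh_m"]: 1},
         0, 1000, gpr="gSHUT", subsystem="Malate-aspartate shuttle")

    # futile NADH oxidase decoys: dissipate reducing equivalents without ATP
    # yield; low-expressed, so context extraction should prune them
    _add(m, "AOX", {met["nadh_m"]: -1, met["nad_m"]: 1}, 0, 1000,
         gpr="gAOX", subsystem="Futile oxidases")
    _add(m, "NOX", {met["nadh_c"]: -1, met["nad_c"]: 1}, 0, 1000,
         gpr="gNOX", subsystem="Futile oxidases")

    _add(m, "DM_atp_c", {met["atp_c"]: -1}, 0, 10000, subsystem="ATP demand")
    m.objective = "DM_atp_c"
    return m


def make_t1_model() -> Model:
    """Diamond network with one direct and one two-step route A→B.

    FBA optimum is 10 (uptake-limited); at 100% of the optimum the FVA range
    of each internal branch is [2, 8] and the parsimonious solution routes
    8 units through the direct edge.
    """
    m = Model("t1")
    A = Metabolite("A", compartment="c")
    B = Metabolite("B", compartment="c")
    C = Metabolite("C", compartment="c")
    _add(m, "EX_A", {A: 1}, 0, 10)
    _add(m, "R1", {A: -1, B: 1}, 0, 8, gpr="g1")
    _add(m, "R2a", {A: -1, C: 1}, 0, 8, gpr="g2")
    _add(m, "R2b", {C: -1, B: 1}, 0, 8, gpr="g3")
    _add(m, "EX_B", {B: -1}, 0, 100)
    m.objective = "EX_B"
    return m


def toy_concentrations() -> dict[str, CofactorConcentrations]:
    """'high' (parental) and 'low' (depleted) concentration sets for the toy."""
    return {
        "high": CofactorConcentrations(dict(TOY_REFERENCE_MM), dict(TOY_REFERENCE_MM)),
        "low": CofactorConcentrations(dict(TOY_DEPLETED_MM), dict(TOY_REFERENCE_MM)),
    }


def make_toy_proteomics(
    model: Model,
    condition: str,
    seed: int = 0,
    n_replicates: int = 3,
    noise_sigma: float = 0.1,
    n_extra_genes: int = 0,
) -> pd.DataFrame:
    """Triplicate protein abundance ratios for the toy genes.

    ``condition`` is ``"parental"`` (all means 1) or ``"compensated"``
    (lactate-branch and shuttle genes up 2×, ETC proxy down 2× — the
    expression compensation a chronically NAD-depleted line develops).
    Ratios carry multiplicative lognormal noise; ``n_extra_genes`` appends
    background genes absent from the model, for distributional checks and to
    exercise partial proteome coverage.
    """
    if condition not in ("parental", "compensated"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    genes = sorted(g.id for g in model.genes)
    genes += [f"bg{i:04d}" for i in range(n_extra_genes)]
    rows = {}
    for g in genes:
        mean = _BASELINE_MEAN.get(g, _DEFAULT_MEAN) if not g.startswith("bg") else 1.0
        if condition == "compensated":
            if g in COMPENSATION_UP:
                mean *= 2.0
            elif g in COMPENSATION_DOWN:
                mean *= 0.5
        rows[g] = mean * rng.lognormal(mean=0.0, sigma=noise_sigma, size=n_replicates)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=[f"rep{i+1}" for i in range(n_replicates)])
    frame.index.name = "protein_id"
    return frame


def make_toy_km_table(
    model: Model,
    seed: int = 0,
    coverage: float = 1.0,
    km_mM: Optional[float] = None,
    decoys: bool = True,
) -> list[KmRecord]:
    """Curated-style Km records for the toy's NAD-coupled reactions.

    For each covered reaction and each participating cofactor species, one
    canonical human record is emitted with Km equal to the compartment's
    reference concentration (or ``km_mM`` if given), so the worked
    bound-scaling factors apply exactly. ``decoys`` adds larger human
    duplicates and smaller lower-priority-organism records that the
    selection rules must ignore. ``coverage`` < 1 leaves a deterministic
    subset of reactions unmapped, as a curated table would.
    """
    from .model import cofactor_reactions

    if not 0 <= coverage <= 1:
        raise ValueError("coverage must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pairs = cofactor_reactions(model)
    n_keep = int(np.floor(coverage * len(pairs)))
    keep_idx = sorted(rng.choice(len(pairs), size=n_keep, replace=False))
    records: list[KmRecord] = []
    comp_of = {m.id: m.compartment for m in model.metabolites}
    for i in keep_idx:
        rid, cofs = pairs[i]
        for cid in sorted(cofs):
            km = km_mM if km_mM is not None else TOY_REFERENCE_MM[comp_of[cid]]
            records.append(KmRecord(rid, cid, "human", km, source="synthetic"))
            if decoys:
                if rng.random() < 0.5:
                    records.append(KmRecord(
                        rid, cid, "human", km * rng.uniform(1.5, 3.0),
                        source="synthetic decoy (larger duplicate)"))
                if rng.random() < 0.5:
                    records.append(KmRecord(
                        rid, cid, rng.choice(["pig", "cow", "rat", "mouse"]),
                        km * rng.uniform(0.2, 0.8),
                        source="synthetic decoy (lower-priority organism)"))
    return records


def make_random_network(seed: int, max_reactions: int = 6, max_metabolites: int = 4) -> Model:
    """Small random stoichiometric network with finite bounds.

    Coefficients are integers in [−2, 2]; every reaction's bounds straddle 0,
    so v = 0 is always feasible and the LP is bounded — suitable for
    brute-force cross-checks of the LP layer.
    """
    rng = np.random.default_rng(seed)
    n_r = int(rng.integers(2, max_reactions + 1))
    n_m = int(rng.integers(1, max_metabolites + 1))
    model = Model(f"rand{seed}")
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_m)]
    for j in range(n_r):
        while True:
            col = rng.integers(-2, 3, size=n_m)
            if np.any(col):
                break
        lb = float(rng.integers(-10, 1))
        ub = float(rng.integers(0, 11))
        _add(model, f"r{j}", {mets[i]: int(col[i]) for i in range(n_m) if col[i]}, lb, ub)
    obj = int(rng.integers(0, n_r))
    model.objective = f"r{obj}"
    return model


def make_random_branched_model(seed: int) -> Model:
    """Randomized diamond-plus-bypass network with a positive FBA optimum.

    Structure: uptake → two parallel routes (one direct, one two-step) →
    export objective; capacities are drawn so the export optimum is strictly
    positive. Used for property checks of the context-extraction LP.
    """
    rng = np.random.default_rng(seed)
    m = Model(f"branch{seed}")
    A = Metabolite("A", compartment="c")
    B = Metabolite("B", compartment="c")
    C = Metabolite("C", compartment="c")
    supply = float(rng.integers(4, 15))
    c1 = float(rng.integers(1, 12))
    c2 = float(rng.integers(1, 12))
    _add(m, "EX_A", {A: 1}, 0, supply)
    _add(m, "R1", {A: -1, B: 1}, 0, c1, gpr="g1")
    _add(m, "R2a", {A: -1, C: 1}, 0, c2, gpr="g2")
    _add(m, "R2b", {C: -1, B: 1}, 0, c2, gpr="g3")
    _add(m, "EX_B", {B: -1}, 0, 1000)
    m.objective = "EX_B"
    return m
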