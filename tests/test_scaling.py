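"""Km selection and Michaelis–Menten flux-bound scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nadflux.fixtures import (
    ToyModelSpec,
    make_toy_km_table,
    make_toy_model,
    toy_concentrations,
)
from nadflux.lp import FluxRange, fva, pfba
from nadflux.model import cofactor_reactions
from nadflux.scaling import (
    CofactorConcentrations,
    KmRecord,
    ScalingContext,
    apply_concentrations,
    read_km_table,
    run_scenario,
    scale_bounds,
    scale_factor,
    select_km,
)


def _rec(org, km, rid="R", cid="nad_c"):
    return KmRecord(rid, cid, org, km)


class TestSelectKm:
    def test_min_within_best_organism(self):
        records = [_rec("human", 0.08), _rec("human", 0.05), _rec("rat", 0.01)]
        assert select_km(records, "R", "nad_c") == pytest.approx(0.05)

    def test_organism_priority_over_value(self):
        records = [_rec("rat", 0.2), _rec("pig", 0.4)]
        assert select_km(records, "R", "nad_c") == pytest.approx(0.4)

    def test_full_priority_chain(self):
        records = [_rec(o, k) for o, k in
                   [("mouse", 1.0), ("rat", 2.0), ("cow", 3.0), ("pig", 4.0)]]
        assert select_km(records, "R", "nad_c") == pytest.approx(4.0)

    def test_no_record_is_none(self):
        assert select_km([], "R", "nad_c") is None
        assert select_km([_rec("human", 0.1, cid="nadh_c")], "R", "nad_c") is None

    def test_latin_names_accepted(self):
        records = [_rec("Rattus norvegicus", 0.2), _rec("Sus scrofa domesticus", 0.4)]
        assert select_km(records, "R", "nad_c") == pytest.approx(0.4)

    def test_unknown_organism_rejected(self):
        with pytest.raises(ValueError, match="organism"):
            _rec("zebrafish", 0.1)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValueError):
            _rec("human", 0.0)


class TestScaleFactor:
    def test_identity_at_reference_concentration(self):
        assert scale_factor(ScalingContext(C=0.11, C0=0.11, km=0.11)) == pytest.approx(1.0, abs=1e-12)

    def test_cytosolic_depletion_factor(self):
        # 60% of reference remaining, Km at the reference concentration
        f = scale_factor(ScalingContext(C=0.066, C0=0.11, km=0.11))
        assert f == pytest.approx(0.75, abs=1e-12)

    def test_mitochondrial_depletion_factor(self):
        # 10% remaining
        f = scale_factor(ScalingContext(C=0.023, C0=0.23, km=0.23))
        assert f == pytest.approx(0.023 / 0.253 * 2, abs=1e-12)
        assert f == pytest.approx(0.18182, abs=1e-5)

    @given(
        km=st.floats(1e-4, 10),
        c0=st.floats(1e-4, 10),
    )
    def test_identity_holds_across_km_c0_grid(self, km, c0):
        assert scale_factor(ScalingContext(C=c0, C0=c0, km=km)) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_in_concentration(self):
        grid = np.linspace(0.0, 0.3, 7)
        factors = [scale_factor(ScalingContext(C=c, C0=0.11, km=0.2)) for c in grid]
        assert all(b > a for a, b in zip(factors, factors[1:]))

    def test_lower_km_is_less_constraining_under_depletion(self):
        # higher affinity -> occupancy changes less -> weaker constraint
        f_small = scale_factor(ScalingContext(C=0.05, C0=0.11, km=0.01))
        f_large = scale_factor(ScalingContext(C=0.05, C0=0.11, km=1.0))
        assert f_small > f_large

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            scale_factor(ScalingContext(C=0.1, C0=0.0, km=0.1))
        with pytest.raises(ValueError):
            scale_factor(ScalingContext(C=0.1, C0=0.1, km=0.0))


class TestScaleBounds:
    def test_both_ends_scaled(self):
        ctx = ScalingContext(C=0.066, C0=0.11, km=0.11)  # f = 0.75
        sb = scale_bounds(FluxRange("R", -5.0, 10.0), ctx)
        assert sb.v_upper_scaled == pytest.approx(7.5)
        assert sb.v_lower_scaled == pytest.approx(-3.75)

    def test_blocked_range_stays_blocked(self):
        ctx = ScalingContext(C=0.001, C0=0.11, km=0.11)
        sb = scale_bounds(FluxRange("R", 0.0, 0.0), ctx)
        assert sb.v_lower_scaled == sb.v_upper_scaled == 0.0

    def test_reference_concentration_is_identity(self):
        ctx = ScalingContext(C=0.23, C0=0.23, km=0.5)
        sb = scale_bounds(FluxRange("R", 2.0, 8.0), ctx)
        assert (sb.v_lower_scaled, sb.v_upper_scaled) == pytest.approx((2.0, 8.0))


class TestApplyConcentrations:
    def test_reference_concentrations_leave_bounds_unchanged(self):
        model = make_toy_model()
        km = make_toy_km_table(model)
        high = toy_concentrations()["high"]
        ranges = {fr.reaction_id: fr for fr in fva(model, 0.5)}
        scaled = apply_concentrations(model, km, high, fva_fraction=0.5)
        for rid, _ in cofactor_reactions(model):
            rxn = scaled.reactions.get_by_id(rid)
            assert rxn.lower_bound == pytest.approx(ranges[rid].v_lower, abs=1e-9)
            assert rxn.upper_bound == pytest.approx(ranges[rid].v_upper, abs=1e-9)

    def test_per_compartment_factors(self):
        model = make_toy_model()
        km = make_toy_km_table(model, decoys=False)
        low = toy_concentrations()["low"]
        ranges = {fr.reaction_id: fr for fr in fva(model, 0.5)}
        scaled = apply_concentrations(model, km, low, fva_fraction=0.5)
        f_c, f_m = 0.75, 0.023 / 0.253 * 2
        # purely mitochondrial reaction scales with the mitochondrial factor
        etc = scaled.reactions.get_by_id("ETC")
        assert etc.upper_bound == pytest.approx(ranges["ETC"].v_upper * f_m, rel=1e-9)
        # purely cytosolic reaction scales with the cytosolic factor
        gly = scaled.reactions.get_by_id("GLY1")
        assert gly.upper_bound == pytest.approx(ranges["GLY1"].v_upper * f_c, rel=1e-9)
        # the shuttle touches both compartments: most-limiting factor wins
        sh = scaled.reactions.get_by_id("SHUTTLE")
        assert sh.upper_bound == pytest.approx(ranges["SHUTTLE"].v_upper * min(f_c, f_m), rel=1e-9)

    def test_unmapped_cofactor_reaction_keeps_prior_bounds(self):
        model = make_toy_model()
        km = [r for r in make_toy_km_table(model, decoys=False)
              if r.reaction_id != "LDH"]
        low = toy_concentrations()["low"]
        scaled = apply_concentrations(model, km, low, fva_fraction=0.5)
        assert scaled.reactions.get_by_id("LDH").bounds == model.reactions.get_by_id("LDH").bounds

    def test_partial_species_mapping_uses_mapped_species_only(self):
        model = make_toy_model()
        # only the oxidized cytosolic species mapped for GLY1
        km = [KmRecord("GLY1", "nad_c", "human", 0.11)]
        low = toy_concentrations()["low"]
        ranges = {fr.reaction_id: fr for fr in fva(model, 0.5)}
        scaled = apply_concentrations(model, km, low, fva_fraction=0.5)
        gly = scaled.reactions.get_by_id("GLY1")
        assert gly.upper_bound == pytest.approx(ranges["GLY1"].v_upper * 0.75, rel=1e-9)

    def test_non_cofactor_reactions_untouched_by_default(self):
        model = make_toy_model()
        km = make_toy_km_table(model)
        low = toy_concentrations()["low"]
        scaled = apply_concentrations(model, km, low, fva_fraction=0.5)
        for rid in ("GLCt", "PYRt", "ATPt", "EX_glc_e"):
            assert scaled.reactions.get_by_id(rid).bounds == model.reactions.get_by_id(rid).bounds

    def test_tighten_all_resets_non_cofactor_bounds_to_fva(self):
        model = make_toy_model()
        km = make_toy_km_table(model)
        low = toy_concentrations()["low"]
        ranges = {fr.reaction_id: fr for fr in fva(model, 0.5)}
        scaled = apply_concentrations(model, km, low, fva_fraction=0.5, tighten_all=True)
        glct = scaled.reactions.get_by_id("GLCt")
        assert glct.lower_bound == pytest.approx(ranges["GLCt"].v_lower, abs=1e-9)
        assert glct.upper_bound == pytest.approx(ranges["GLCt"].v_upper, abs=1e-9)

    def test_missing_compartment_concentration_errors(self):
        model = make_toy_model()
        km = make_toy_km_table(model)
        broken = CofactorConcentrations({"c": 0.066}, {"c": 0.11})
        with pytest.raises(KeyError, match="compartment 'm'"):
            apply_concentrations(model, km, broken, fva_fraction=0.5)

    def test_input_model_never_mutated(self):
        model = make_toy_model()
        before = {r.id: r.bounds for r in model.reactions}
        apply_concentrations(model, make_toy_km_table(model),
                             toy_concentrations()["low"], fva_fraction=0.5)
        assert {r.id: r.bounds for r in model.reactions} == before

    def test_supraphysiological_concentration_relaxes_unless_capped(self):
        model = make_toy_model()
        km = make_toy_km_table(model, decoys=False)
        high_c = CofactorConcentrations({"c": 0.5, "m": 1.0}, {"c": 0.11, "m": 0.23})
        ranges = {fr.reaction_id: fr for fr in fva(model, 0.5)}
        relaxed = apply_concentrations(model, km, high_c, fva_fraction=0.5)
        assert relaxed.reactions.get_by_id("ETC").upper_bound > ranges["ETC"].v_upper
        capped = apply_concentrations(model, km, high_c, fva_fraction=0.5, cap_at_fva=True)
        assert capped.reactions.get_by_id("ETC").upper_bound == pytest.approx(
            ranges["ETC"].v_upper, abs=1e-9)


class TestScenario:
    def test_reference_scenario_matches_plain_pfba(self):
        model = make_toy_model()
        km = make_toy_km_table(model)
        res = run_scenario(model, km, toy_concentrations()["high"], fva_fraction=0.5)
        plain = pfba(model, 1.0)
        assert res.objective_value == pytest.approx(plain.objective_value, abs=1e-6)

    def test_depletion_lowers_objective(self):
        model = make_toy_model()
        km = make_toy_km_table(model)
        conc = toy_concentrations()
        hi = run_scenario(model, km, conc["high"], fva_fraction=0.5)
        lo = run_scenario(model, km, conc["low"], fva_fraction=0.5)
        assert lo.objective_value < hi.objective_value - 1e-6

    def test_objective_nonincreasing_as_concentration_drops(self):
        model = make_toy_model()
        km = make_toy_km_table(model, decoys=False)
        ref = {"c": 0.11, "m": 0.23}
        objectives = []
        for frac in (1.0, 0.8, 0.6, 0.4, 0.2):
            conc = CofactorConcentrations(
                {k: v * frac for k, v in ref.items()}, dict(ref))
            objectives.append(
                run_scenario(model, km, conc, fva_fraction=0.5).objective_value)
        assert all(b <= a + 1e-6 for a, b in zip(objectives, objectives[1:]))


def test_km_table_csv_round_trip(tmp_path):
    path = tmp_path / "km.csv"
    path.write_text(
        "reaction_id,cofactor_id,organism,km_mM,source\n"
        "GLY1,nad_c,human,0.11,curated\n"
        "GLY1,nad_c,rat,0.05,curated\n"
    )
    records = read_km_table(path)
    assert len(records) == 2
    assert select_km(records, "GLY1", "nad_c") == pytest.approx(0.11)


def test_km_table_missing_columns(tmp_path):
    path = tmp_path / "km.csv"
    path.write_text("reaction_id,km_mM\nR,0.1\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_km_table(path)
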