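"""Relative-affinity estimators, prerequisite validation, site judgment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mixscreen.equilibrium import (
    BindingSystem,
    LigandSpecies,
    TargetPreparation,
    solve_equilibrium,
)
from mixscreen.estimation import (
    DepletionError,
    EstimationError,
    RelativeAffinityModel,
    estimated_binding_ratio,
    judge_binding_site,
    relative_affinity_eq5,
    relative_affinity_eq6,
    validate_prerequisites,
)
from mixscreen.measurement import (
    LinearResponse,
    PeakRecord,
    PeakTable,
    ProcessingProtocol,
    RecoveryProfile,
    simulate_peak_table,
)

from conftest import single_candidate_model, single_candidate_table


class TestBindingRatio:
    def test_direct_arithmetic(self):
        assert estimated_binding_ratio(500.0, 1000.0, 0.5, 50.0) == pytest.approx(0.02)

    def test_zero_bound_area(self):
        assert estimated_binding_ratio(0.0, 1000.0, 0.5, 50.0) == 0.0

    def test_zero_total_area_is_undefined(self):
        with pytest.raises(EstimationError):
            estimated_binding_ratio(500.0, 0.0, 0.5, 50.0)

    def test_forward_simulation_round_trip(self, single_fixtures):
        """Noiseless forward model with ideal (zero-intercept) channels
        reproduces the equilibrium binding ratios to 1e-6."""
        system, _, _ = single_candidate_table("BCHA", 2.0e-6, single_fixtures)
        state = solve_equilibrium(system)
        resp = {lid: LinearResponse(slope=100.0, intercept=0.0, linear_upper=1e9)
                for lid in ("BCHA", "BMPL")}
        rr = RecoveryProfile(RR={"BCHA": 0.47, "BMPL": 1.0})
        protocol = ProcessingProtocol()
        table = simulate_peak_table(
            state, system, protocol, resp, rr, noise_cv=0.0, duplicates=1
        )
        for lid in ("BCHA", "BMPL"):
            br = estimated_binding_ratio(
                table.area(lid, "extract"), table.area(lid, "pmfs"),
                rr[lid], protocol.CR,
            )
            assert br == pytest.approx(state.BR[lid], abs=1e-6)


class TestDiluteForm:
    def test_identity(self):
        assert relative_affinity_eq6(1000, 1000, 500, 500, 0.8, 0.8) == pytest.approx(1.0)

    def test_doubled_bound_area(self):
        assert relative_affinity_eq6(1000, 1000, 500, 1000, 0.8, 0.8) == pytest.approx(2.0)

    def test_role_swap_gives_reciprocal(self):
        fwd = relative_affinity_eq6(900, 1100, 400, 700, 0.9, 0.5)
        rev = relative_affinity_eq6(1100, 900, 700, 400, 0.5, 0.9)
        assert fwd * rev == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scale_x=st.floats(0.1, 10.0),
        scale_a=st.floats(0.1, 10.0),
        a_ta=st.floats(100.0, 1e5),
        a_tx=st.floats(100.0, 1e5),
        a_ba=st.floats(100.0, 1e5),
        a_bx=st.floats(100.0, 1e5),
    )
    def test_invariant_to_per_ligand_rescaling(self, scale_x, scale_a, a_ta, a_tx, a_ba, a_bx):
        """Rescaling both areas of one ligand by a common factor (a different
        detector sensitivity) leaves the estimate unchanged - the estimate is
        slope-free and CR-free."""
        base = relative_affinity_eq6(a_ta, a_tx, a_ba, a_bx, 0.8, 0.6)
        scaled = relative_affinity_eq6(
            a_ta * scale_a, a_tx * scale_x, a_ba * scale_a, a_bx * scale_x, 0.8, 0.6
        )
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_zero_area_rejected(self):
        with pytest.raises(EstimationError):
            relative_affinity_eq6(1000, 0.0, 500, 500, 0.8, 0.8)


class TestRatioForm:
    def test_symmetric_inputs(self):
        assert relative_affinity_eq5(1000, 1000, 500, 500, 0.8, 0.8, 50.0) == pytest.approx(1.0)

    def test_converges_to_dilute_form_at_vanishing_br(self):
        # both binding ratios at 1e-4: relative gap below 1e-3
        CR, rr = 50.0, 1.0
        A_T = 1.0e4
        A_B = 1e-4 * rr * CR * A_T
        dilute = relative_affinity_eq6(A_T, A_T, A_B, A_B, rr, rr)
        corrected = relative_affinity_eq5(A_T, A_T, A_B, A_B, rr, rr, CR)
        assert abs(dilute / corrected - 1.0) < 1e-3

    def test_exact_depletion_relation(self):
        """dilute = ratio_form * (1 - BR_X) / (1 - BR_A), exactly, on ideal
        areas."""
        CR = 50.0
        rr_a, rr_x = 1.0, 0.5
        br_a, br_x = 0.08, 0.25
        A_TA, A_TX = 2.0e4, 1.5e4
        A_BA = br_a * rr_a * CR * A_TA
        A_BX = br_x * rr_x * CR * A_TX
        dilute = relative_affinity_eq6(A_TA, A_TX, A_BA, A_BX, rr_a, rr_x)
        corrected = relative_affinity_eq5(A_TA, A_TX, A_BA, A_BX, rr_a, rr_x, CR)
        assert dilute == pytest.approx(corrected * (1 - br_x) / (1 - br_a), rel=1e-12)

    def test_recovers_truth_at_high_binding_ratio(self):
        """True K_X/K_A = 3 with BR_X ~ 0.3: the depletion-corrected form
        recovers the truth while the dilute form deviates (downward, by the
        depletion factor)."""
        system = BindingSystem(
            volume=2.0,
            target=TargetPreparation(suspension_volume=50.0, site_density=4.2),
            ligands=[
                LigandSpecies(id="A", role="reference", K=1e13, total_conc=0.2e-6),
                LigandSpecies(id="X", K=3e13, total_conc=0.267e-6),
            ],
        )
        state = solve_equilibrium(system)
        assert state.BR["X"] == pytest.approx(0.3, abs=0.05)
        resp = {lid: LinearResponse(slope=100.0, intercept=0.0, linear_upper=1e9)
                for lid in ("A", "X")}
        rr = RecoveryProfile(RR={"A": 1.0, "X": 1.0})
        protocol = ProcessingProtocol()
        table = simulate_peak_table(state, system, protocol, resp, rr,
                                    noise_cv=0.0, duplicates=1)
        args = (table.area("A", "pmfs"), table.area("X", "pmfs"),
                table.area("A", "extract"), table.area("X", "extract"), 1.0, 1.0)
        corrected = relative_affinity_eq5(*args, protocol.CR)
        dilute = relative_affinity_eq6(*args)
        assert corrected == pytest.approx(3.0, rel=1e-6)
        assert dilute < corrected  # depletion bias, toward zero

    def test_depletion_error_on_overconsumed_total(self):
        with pytest.raises(DepletionError):
            relative_affinity_eq5(1000, 100, 500, 50_000, 1.0, 1.0, 50.0)


def build_table(areas, protocol=None):
    protocol = protocol or ProcessingProtocol()
    records = tuple(
        PeakRecord(ligand_id=lid, kind=kind, area=area)
        for (lid, kind), area in areas.items()
    )
    return PeakTable(records=records, protocol=protocol)


class TestPrerequisites:
    resp = {
        "X": LinearResponse(slope=100.0, intercept=100.0, linear_upper=1000.0),
        "A": LinearResponse(slope=100.0, intercept=100.0, linear_upper=1000.0),
    }
    rr = RecoveryProfile(RR={"X": 0.5, "A": 1.0})

    def make(self, overrides=None):
        areas = {
            ("A", "pmfs"): 600.0,
            ("A", "extract"): 600.0,
            ("X", "pmfs"): 600.0,
            ("X", "extract"): 600.0,
        }
        areas.update(overrides or {})
        return build_table(areas)

    def test_all_satisfied(self):
        # all areas at 6x|intercept|; BRs = 600/(RR*50*600) = 4% and 2%
        report = validate_prerequisites(self.make(), self.resp, self.rr, "A", "X")
        assert report.valid
        assert report.failures() == []

    def test_low_extract_area_fails_intercept_rule(self):
        table = self.make({("X", "extract"): 300.0})  # 3x|intercept|
        report = validate_prerequisites(table, self.resp, self.rr, "A", "X")
        assert not report.valid
        assert any("intercept" in f for f in report.failures())
        # the dilute-form estimate is still computable
        model = RelativeAffinityModel(table, self.resp, self.rr, "A",
                                      candidate_ids=["X"])
        est = model.estimate_pair("X", "eq6")
        assert est.ratio > 0 and not est.valid

    def test_high_binding_ratio_fails(self):
        table = self.make({("X", "extract"): 4500.0})  # BR_X = 0.15
        report = validate_prerequisites(table, self.resp, self.rr, "A", "X")
        assert report.br_below_limit["X"] is False
        assert not report.valid

    def test_out_of_linear_range_fails(self):
        table = self.make({("A", "pmfs"): 2.0e5})
        report = validate_prerequisites(table, self.resp, self.rr, "A", "X")
        assert report.in_linear_range[("A", "pmfs")] is False
        assert not report.valid

    def test_missing_records_listed(self):
        table = build_table({("A", "pmfs"): 600.0, ("A", "extract"): 600.0,
                             ("X", "pmfs"): 600.0})
        with pytest.raises(EstimationError, match="extract"):
            validate_prerequisites(table, self.resp, self.rr, "A", "X")

    def test_refuted_same_site_invalidates(self):
        report = validate_prerequisites(
            self.make(), self.resp, self.rr, "A", "X", same_site_evidence="refuted"
        )
        assert not report.valid


class TestBindingSiteJudgment:
    rr = RecoveryProfile(RR={"B1": 0.5, "N1": 0.5})

    def tables(self, reduction, denatured_frac, ns_change=0.0, ns_denat=1.0):
        def table(b1_extract, n1_extract):
            return build_table({
                ("B1", "pmfs"): 1000.0, ("B1", "extract"): b1_extract,
                ("N1", "pmfs"): 1000.0, ("N1", "extract"): n1_extract,
            })

        base = table(2000.0, 500.0)
        comp = table(2000.0 * (1 - reduction), 500.0 * (1 + ns_change))
        denat = table(2000.0 * denatured_frac, 500.0 * ns_denat)
        return base, comp, denat

    def test_specific_pattern(self):
        base, comp, denat = self.tables(reduction=0.45, denatured_frac=0.0)
        verdict = judge_binding_site(base, comp, denat, self.rr)
        assert verdict["B1"] == "specific"

    def test_nonspecific_pattern(self):
        base, comp, denat = self.tables(reduction=0.45, denatured_frac=0.0,
                                        ns_change=-0.02, ns_denat=1.0)
        verdict = judge_binding_site(base, comp, denat, self.rr)
        assert verdict["N1"] == "nonspecific"

    def test_intermediate_reduction_is_indeterminate(self):
        base, comp, denat = self.tables(reduction=0.20, denatured_frac=0.0)
        verdict = judge_binding_site(base, comp, denat, self.rr)
        assert verdict["B1"] == "indeterminate"

    def test_mismatched_ligand_sets_error(self):
        base, comp, denat = self.tables(reduction=0.45, denatured_frac=0.0)
        broken = build_table({("B1", "pmfs"): 1000.0, ("B1", "extract"): 1000.0})
        with pytest.raises(EstimationError):
            judge_binding_site(base, broken, denat, self.rr)


class TestModelResults:
    def test_fit_and_summary(self, single_fixtures):
        _, truth, table = single_candidate_table("BCHA", 2.0e-6, single_fixtures)
        model = single_candidate_model(table, single_fixtures, "BCHA")
        res = model.fit()
        assert "BCHA" in res.summary()
        assert res.ratios["BCHA"] == pytest.approx(truth.true_ratios["BCHA"], rel=0.15)
        frame = res.to_frame()
        assert bool(frame.loc[frame.candidate_id == "BCHA", "valid"].iloc[0])

    def test_auto_method_switches_to_ratio_form(self, single_fixtures):
        # low candidate concentration: BR_X > 10%, auto picks the corrected form
        _, _, table = single_candidate_table("BCHA", 0.25e-6, single_fixtures)
        model = single_candidate_model(table, single_fixtures, "BCHA")
        res = model.fit(method="auto")
        assert res.estimates[0].method == "eq5"

    def test_json_report_carries_checksums_and_thresholds(self, single_fixtures, tmp_path):
        import json

        _, _, table = single_candidate_table("BCHA", 2.0e-6, single_fixtures)
        model = single_candidate_model(table, single_fixtures, "BCHA")
        payload = json.loads(model.fit().to_json())
        assert "peak_table_sha256" in payload["metadata"]
        assert payload["metadata"]["thresholds"]["br_limit"] == 0.10

    def test_missing_reference_rejected(self, single_fixtures):
        table = build_table({("X", "pmfs"): 600.0, ("X", "extract"): 600.0})
        with pytest.raises(EstimationError, match="BMPL"):
            RelativeAffinityModel(
                table, single_fixtures.responses, single_fixtures.recovery, "BMPL"
            )
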