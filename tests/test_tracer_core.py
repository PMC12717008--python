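"""Isotope-dilution inversion: anthropometry, mixing-model round trips,
absorption algebra and eligibility screening."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ferrotrace import tracer_core as tc

NAT = tc.NATURAL_ABUNDANCE
TRACERS = tc.DEFAULT_TRACER_PATTERNS


def forward_mix(baseline, q_by_label, total_mol):
    """Independent forward oracle for the mixing model."""
    q = np.array(list(q_by_label.values()))
    t = np.stack([TRACERS[lb].as_array() for lb in q_by_label])
    mixed = ((total_mol - q.sum()) * baseline.as_array() + q @ t) / total_mol
    return tc.IsotopePattern.from_array(mixed, renormalize=True)


class TestAnthropometry:
    @pytest.mark.parametrize(
        "height,weight,expected",
        [(160.0, 55.0, 3.461), (170.0, 60.0, 3.918)],
    )
    def test_blood_volume_regression(self, height, weight, expected):
        assert tc.blood_volume(height, weight) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("height,weight", [(0, 55), (160, -1)])
    def test_blood_volume_rejects_nonpositive(self, height, weight):
        with pytest.raises(ValueError):
            tc.blood_volume(height, weight)

    def test_blood_volume_unknown_formula(self):
        with pytest.raises(ValueError, match="unknown"):
            tc.blood_volume(160, 55, formula="nosuch")

    @pytest.mark.parametrize(
        "bv,hb,expected",
        [(3.461, 130.0, 1561.3), (1.0, 100.0, 347.0), (2.5, 0.0, 0.0)],
    )
    def test_circulating_iron(self, bv, hb, expected):
        assert tc.circulating_iron(bv, hb) == pytest.approx(expected, abs=0.05)

    def test_circulating_iron_rejects_negative(self):
        with pytest.raises(ValueError):
            tc.circulating_iron(-1.0, 130.0)


class TestIsotopePattern:
    def test_pure_isotope_molar_mass(self):
        assert tc.pattern_molar_mass(tc.IsotopePattern(0, 1, 0, 0)) == pytest.approx(55.9349)

    def test_natural_molar_mass(self):
        assert tc.pattern_molar_mass(NAT) == pytest.approx(55.845, abs=0.01)

    def test_unnormalized_pattern_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tc.IsotopePattern(0.2, 0.4, 0.1, 0.1)

    def test_ratio_representation_round_trips(self):
        p = tc.IsotopePattern.from_ratios_to_56(NAT.ratios_to_56())
        assert np.allclose(p.as_array(), NAT.as_array(), atol=1e-15)


class TestSolveTracerIncrements:
    TOTAL = 0.028  # mol, a typical circulating iron pool

    def test_no_shift_gives_zero(self):
        sol = tc.solve_tracer_increments(NAT, NAT, {"57Fe": TRACERS["57Fe"]}, self.TOTAL)
        assert sol.q_mol["57Fe"] == pytest.approx(0.0, abs=1e-15)

    def test_single_tracer_round_trip(self):
        q = {"57Fe": 0.01 * self.TOTAL}
        measured = forward_mix(NAT, q, self.TOTAL)
        sol = tc.solve_tracer_increments(measured, NAT, {"57Fe": TRACERS["57Fe"]}, self.TOTAL)
        assert sol.q_mol["57Fe"] == pytest.approx(q["57Fe"], rel=1e-10)

    @pytest.mark.parametrize("space", ["ratio", "abundance"])
    def test_three_tracer_round_trip(self, space):
        q = {"54Fe": 1e-5, "57Fe": 2e-5, "58Fe": 3e-6}
        measured = forward_mix(NAT, q, self.TOTAL)
        sol = tc.solve_tracer_increments(measured, NAT, TRACERS, self.TOTAL, space=space)
        for label, true_q in q.items():
            assert sol.q_mol[label] == pytest.approx(true_q, rel=1e-8)

    def test_solver_spaces_agree_noiseless(self):
        q = {"54Fe": 5e-6, "57Fe": 1e-5, "58Fe": 2e-6}
        measured = forward_mix(NAT, q, self.TOTAL)
        a = tc.solve_tracer_increments(measured, NAT, TRACERS, self.TOTAL, space="ratio")
        b = tc.solve_tracer_increments(measured, NAT, TRACERS, self.TOTAL, space="abundance")
        for label in q:
            assert a.q_mol[label] == pytest.approx(b.q_mol[label], rel=1e-6)

    def test_scale_homogeneity(self):
        """Doubling the pool size doubles every increment for a fixed
        measured/baseline pair."""
        q = {"57Fe": 1e-5, "58Fe": 4e-6}
        measured = forward_mix(NAT, q, self.TOTAL)
        tr = {k: TRACERS[k] for k in q}
        s1 = tc.solve_tracer_increments(measured, NAT, tr, self.TOTAL)
        s2 = tc.solve_tracer_increments(measured, NAT, tr, 2 * self.TOTAL)
        for label in q:
            assert s2.q_mol[label] == pytest.approx(2 * s1.q_mol[label], rel=1e-12)

    def test_zero_contribution_tracer_is_inert(self):
        q = {"57Fe": 1e-5, "58Fe": 4e-6}
        measured = forward_mix(NAT, q, self.TOTAL)
        partial = tc.solve_tracer_increments(
            measured, NAT, {k: TRACERS[k] for k in q}, self.TOTAL
        )
        full = tc.solve_tracer_increments(measured, NAT, TRACERS, self.TOTAL)
        assert full.q_mol["54Fe"] == pytest.approx(0.0, abs=1e-8 * self.TOTAL)
        for label in q:
            assert full.q_mol[label] == pytest.approx(partial.q_mol[label], rel=1e-8)

    def test_normalization_invariance(self):
        """A common multiplicative perturbation of all abundances before
        renormalization leaves the inversion unchanged."""
        q = {"57Fe": 1e-5}
        measured = forward_mix(NAT, q, self.TOTAL)
        scaled = tc.IsotopePattern.from_array(measured.as_array() * 1.0 + 0.0, renormalize=True)
        doubled = tc.IsotopePattern.from_array(2.0 * measured.as_array(), renormalize=True)
        s1 = tc.solve_tracer_increments(scaled, NAT, {"57Fe": TRACERS["57Fe"]}, self.TOTAL)
        s2 = tc.solve_tracer_increments(doubled, NAT, {"57Fe": TRACERS["57Fe"]}, self.TOTAL)
        assert s1.q_mol["57Fe"] == pytest.approx(s2.q_mol["57Fe"], rel=1e-12)

    def test_ill_conditioned_system_rejected(self):
        with pytest.raises(ValueError, match="ill-conditioned"):
            tc.solve_tracer_increments(NAT, NAT, {"x": NAT}, self.TOTAL)


class TestFiaAlgebra:
    def _dose(self):
        return tc.TracerDose("57Fe", 4.0, TRACERS["57Fe"], day=1, condition_id="c")

    def test_zero_increment_zero_fia(self):
        assert tc.fia_from_increment(0.0, self._dose()).fia == 0.0

    def test_algebraic_inversion(self):
        dose = self._dose()
        cfg = tc.AbsorptionModelConfig(incorporation_factor=0.8)
        q = 0.8 * 0.20 * dose.fe_mol
        est = tc.fia_from_increment(q, dose, cfg)
        assert est.fia == pytest.approx(0.20, rel=1e-12)
        assert not est.out_of_range

    def test_out_of_range_flagged_not_clipped(self):
        dose = self._dose()
        q = 0.8 * 1.2 * dose.fe_mol
        est = tc.fia_from_increment(q, dose)
        assert est.fia == pytest.approx(1.2, rel=1e-12)
        assert est.out_of_range

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            tc.TracerDose("57Fe", 0.0, TRACERS["57Fe"], day=1, condition_id="c")


class TestProcessTrial:
    def test_full_trial_emits_312_records(self, noiseless_bundle):
        assert len(noiseless_bundle["fia"]) == 312

    def test_noiseless_fia_matches_truth(self, noiseless_bundle):
        merged = noiseless_bundle["fia"].merge(
            noiseless_bundle["truth"],
            on=["participant_id", "condition_id", "tracer", "phase"],
        )
        rel = (merged["fia"] - merged["true_fia"]).abs() / merged["true_fia"]
        assert rel.max() < 1e-9

    def test_missing_sampling_day_skips_phase(self, noiseless_bundle):
        meas = noiseless_bundle["measurements"]
        pid = meas["participant_id"].iloc[0]
        dropped = meas[~((meas["participant_id"] == pid) & (meas["day"] == 37))]
        fia, skipped = tc.process_trial(
            dropped, noiseless_bundle["design"], noiseless_bundle["cohort"]
        )
        assert len(fia[fia["participant_id"] == pid]) == 3
        assert (pid, "missing day 37") in skipped
        assert len(fia) == 312 - 3


ELIGIBLE = dict(sf_ug_l=40.0, hb_g_l=125.0, height_cm=165.0, weight_kg=60.0,
                age_y=25.0, crp_mg_l=1.0)  # BMI 22.0


class TestEligibility:
    def test_clean_record_eligible(self):
        decision = tc.check_eligibility(ELIGIBLE)
        assert decision.eligible and decision.reasons == []

    @pytest.mark.parametrize(
        "field,value,reason",
        [
            ("sf_ug_l", 55.0, "SF"),
            ("hb_g_l", 119.9, "anaemia"),
            ("weight_kg", 75.0, "weight"),
            ("age_y", 17.0, "age"),
            ("crp_mg_l", 6.0, "CRP"),
            ("height_cm", 140.0, "BMI"),
        ],
    )
    def test_single_violation_named(self, field, value, reason):
        record = dict(ELIGIBLE, **{field: value})
        decision = tc.check_eligibility(record)
        assert not decision.eligible
        assert reason in decision.reasons

    def test_missing_field_rejected(self):
        record = dict(ELIGIBLE)
        del record["crp_mg_l"]
        with pytest.raises(ValueError, match="crp"):
            tc.check_eligibility(record)

    @given(
        sf=st.floats(0, 100), hb=st.floats(80, 180), weight=st.floats(35, 100),
        age=st.floats(10, 60), crp=st.floats(0, 20), height=st.floats(140, 190),
    )
    def test_worsening_never_rescues(self, sf, hb, weight, age, crp, height):
        """Eligibility is monotone: degrading any single marker never turns
        an excluded record eligible."""
        record = dict(sf_ug_l=sf, hb_g_l=hb, weight_kg=weight, age_y=age,
                      crp_mg_l=crp, height_cm=height)
        base = tc.check_eligibility(record)
        # markers whose degradation cannot improve any other criterion
        # (weight is excluded: raising it can repair an underweight BMI)
        worse_by = {"sf_ug_l": 10, "hb_g_l": -10, "crp_mg_l": 5}
        for field, delta in worse_by.items():
            worse = tc.check_eligibility(dict(record, **{field: record[field] + delta}))
            if not base.eligible:
                assert not worse.eligible
                assert set(base.reasons) <= set(worse.reasons)
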