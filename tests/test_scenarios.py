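"""Scenario comparison, uplift rule, coverage scaling and config loading."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmfootprint import (
    CohortSpec,
    FeedingPrevalence,
    FootprintResult,
    ScenarioSpec,
    ValidationError,
    apply_uplift,
    avoided_under_coverage,
    compare,
    compute_footprint,
    extinction,
    load_comparison_config,
    normalize_prevalence,
    round_half_up,
    scale_coverage,
    scenario_from_config,
)


def spec(cohort: CohortSpec) -> ScenarioSpec:
    return ScenarioSpec(cohort=cohort)


class TestCompare:
    def test_china_difference_row(self, china_baseline, china_counterfactual):
        cmp = compare(spec(china_baseline), spec(china_counterfactual))
        assert round_half_up(cmp.difference.ghg_low) == -319.0
        assert round_half_up(cmp.difference.ghg_high) == -406.0
        assert cmp.difference.water == pytest.approx(-137_833, rel=1e-3)
        assert round_half_up(cmp.difference.lost_milk) == -38.3
        assert cmp.prevalence_delta["ebf_pbf"] == pytest.approx(28.7)
        assert cmp.prevalence_delta["partial"] == pytest.approx(-24.2)

    def test_identical_scenarios_zero_difference(self, china_baseline):
        cmp = compare(spec(china_baseline), spec(china_baseline))
        assert all(v == 0.0 for v in cmp.difference.as_dict().values())
        assert all(v == 0.0 for v in cmp.prevalence_delta.values())

    def test_canada_water_saving(self, canada_before, canada_after):
        cmp = compare(spec(canada_before), spec(canada_after))
        assert round_half_up(cmp.difference.water) == -1_661.7
        # differences are exact fieldwise deltas at full precision; the
        # published GHG deltas (3.9-4.9) subtract the *rounded* row values
        assert cmp.difference.ghg_low == pytest.approx(-3.846, abs=1e-3)
        assert cmp.difference.ghg_high == pytest.approx(-4.895, abs=1e-3)

    def test_differing_births_warn(self, china_baseline):
        other = CohortSpec("alt", 12_000_000, china_baseline.prevalence)
        with pytest.warns(UserWarning, match="different annual_births"):
            compare(spec(china_baseline), spec(other))

    @given(
        ebf_a=st.floats(0, 100), split_a=st.floats(0, 1),
        ebf_b=st.floats(0, 100), split_b=st.floats(0, 1),
    )
    def test_antisymmetry(self, ebf_a, split_a, ebf_b, split_b):
        """Swapping baseline and counterfactual flips every difference sign."""
        def cohort(ebf, split):
            rest = 100 - ebf
            return CohortSpec(
                "x", 1e6, FeedingPrevalence(ebf, rest * split, rest * (1 - split))
            )

        a, b = spec(cohort(ebf_a, split_a)), spec(cohort(ebf_b, split_b))
        ab = compare(a, b).difference.as_dict()
        ba = compare(b, a).difference.as_dict()
        for k in ab:
            assert ab[k] == pytest.approx(-ba[k], abs=1e-12)


class TestApplyUplift:
    def test_indonesia_ten_points(self):
        base = normalize_prevalence(ebf_pbf=58.2, partial=29.9)
        up = apply_uplift(base, 10)
        assert round_half_up(up.ebf_pbf) == 68.2
        assert round_half_up(up.partial) == 21.2
        assert round_half_up(up.non_bf) == 10.6

    def test_indonesia_fifteen_points(self):
        base = normalize_prevalence(ebf_pbf=58.2, partial=29.9)
        up = apply_uplift(base, 15)
        assert round_half_up(up.ebf_pbf) == 73.2
        assert round_half_up(up.partial) == 17.9
        assert round_half_up(up.non_bf) == 8.9

    def test_zero_uplift_fixed_point(self):
        """A prevalence already on the two-thirds rule is unchanged."""
        base = FeedingPrevalence(70.0, 20.0, 10.0)
        up = apply_uplift(base, 0)
        assert up.as_tuple() == pytest.approx(base.as_tuple())

    def test_uplift_beyond_100_rejected(self):
        with pytest.raises(ValidationError):
            apply_uplift(FeedingPrevalence(95, 5, 0), 10)

    @given(ebf=st.floats(0, 100), inc=st.floats(0, 100))
    def test_two_thirds_split_holds(self, ebf, inc):
        """Partial is always twice non-breastfed after an uplift."""
        if ebf + inc > 100:
            return
        base = FeedingPrevalence(ebf, (100 - ebf) * 2 / 3, (100 - ebf) / 3)
        up = apply_uplift(base, inc)
        if up.non_bf > 1e-9:
            assert up.partial / up.non_bf == pytest.approx(2.0, rel=1e-9)


class TestScaleCoverage:
    SCENARIO = FootprintResult(
        cmf_kg=13_572_865, ghg_low=149.3, ghg_high=190.0,
        water=64_488.2, lost_milk=22.1,
    )

    def test_five_percent_coverage_row(self):
        scaled, covered = scale_coverage(self.SCENARIO, 0.05, 4_435_250)
        assert round_half_up(scaled.ghg_low) == 7.5
        assert round_half_up(scaled.ghg_high) == 9.5
        assert covered == pytest.approx(221_762.5)

    def test_ten_percent_water(self):
        scaled, _ = scale_coverage(self.SCENARIO, 0.10, 4_435_250)
        assert round_half_up(scaled.water) == 6_448.8

    def test_full_coverage_unchanged(self):
        scaled, covered = scale_coverage(self.SCENARIO, 1.0, 1000)
        assert scaled == self.SCENARIO
        assert covered == 1000

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValidationError):
            scale_coverage(self.SCENARIO, bad, 1000)

    @given(c1=st.floats(0.01, 1), c2=st.floats(0.01, 1))
    def test_multiplicative_composition(self, c1, c2):
        """Scaling by c1 then c2 equals scaling by c1*c2, linearly per field."""
        once, _ = scale_coverage(self.SCENARIO, c1 * c2, 1000)
        twice, _ = scale_coverage(scale_coverage(self.SCENARIO, c1, 1000).result,
                                  c2, 1000)
        for k, v in once.as_dict().items():
            assert twice.as_dict()[k] == pytest.approx(v, rel=1e-12)

    def test_avoided_under_coverage_is_scaled_difference(
        self, china_baseline, china_counterfactual
    ):
        cmp = compare(spec(china_baseline), spec(china_counterfactual))
        avoided = avoided_under_coverage(cmp, 0.25)
        for k, v in cmp.difference.as_dict().items():
            assert avoided.as_dict()[k] == pytest.approx(0.25 * v)


class TestExtinction:
    def test_prevalence_replaced(self, china_baseline):
        ext = extinction(china_baseline)
        assert ext.effective_prevalence.as_tuple() == (0.0, 0.0, 100.0)
        assert ext.annual_births == china_baseline.annual_births

    def test_downstream_upper_carbon(self, lmic_extinct):
        ext = extinction(lmic_extinct)
        r = compute_footprint(ext)
        assert round_half_up(r.ghg_high) == 36_788.2

    def test_idempotent(self, lmic_extinct):
        assert extinction(extinction(lmic_extinct)) == extinction(lmic_extinct)
        assert extinction(lmic_extinct) == lmic_extinct

    def test_zero_births_zero_footprint(self):
        z = extinction(CohortSpec("z", 0, FeedingPrevalence(100, 0, 0)))
        r = compute_footprint(z)
        assert all(v == 0.0 for v in r.as_dict().values())


class TestScenarioConfig:
    def test_direct_prevalence(self):
        s = scenario_from_config(
            {"births": 11_501_936, "prevalence": {"ebf_pbf": 61.3, "partial": 32.2}}
        )
        assert s.cohort.effective_prevalence.non_bf == pytest.approx(6.5)
        assert s.coverage == 1.0

    def test_uplift_inherits_births(self):
        base = scenario_from_config(
            {"births": 4_435_250, "prevalence": {"ebf_pbf": 58.2, "partial": 29.9}}
        )
        cf = scenario_from_config(
            {"uplift": 10, "coverage": 0.05},
            base_prevalence=base.cohort.effective_prevalence,
            inherit_births=base.cohort.annual_births,
        )
        assert cf.cohort.annual_births == 4_435_250
        assert round_half_up(cf.cohort.effective_prevalence.partial) == 21.2
        assert cf.coverage == 0.05

    def test_uplift_without_base_rejected(self):
        with pytest.raises(ValidationError):
            scenario_from_config({"births": 1000, "uplift": 10})

    def test_both_prevalence_and_uplift_rejected(self):
        with pytest.raises(ValidationError):
            scenario_from_config(
                {"births": 1000, "uplift": 10,
                 "prevalence": {"ebf_pbf": 50, "partial": 30}}
            )

    def test_comparison_file_roundtrip(self, tmp_path):
        cfg = tmp_path / "cmp.yaml"
        cfg.write_text(
            """
baseline:
  label: Indonesia 2018
  births: 4435250
  prevalence: {ebf_pbf: 58.2, partial: 29.9}
counterfactual:
  label: BFHI +10
  uplift: 10
coverages: [0.05, 0.10]
diet: {pattern: mixed, mothers: 1000}
"""
        )
        cc = load_comparison_config(cfg)
        assert cc.baseline.cohort.annual_births == 4_435_250
        assert cc.counterfactual.cohort.annual_births == 4_435_250
        assert round_half_up(cc.counterfactual.cohort.effective_prevalence.ebf_pbf) == 68.2
        assert cc.coverages == (0.05, 0.10)
        assert cc.diet_pattern == "mixed"
        assert cc.diet_mothers == 1000

    def test_bad_keys_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            load_comparison_config(
                {"baseline": {"births": 1, "prevalence": {"ebf_pbf": 50, "partial": 50}},
                 "counterfactual": {"uplift": 1}, "extra": 1}
            )

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValidationError):
            load_comparison_config(
                {"baseline": {"births": 1000,
                              "prevalence": {"ebf_pbf": 50, "partial": 50}},
                 "counterfactual": {"uplift": 1},
                 "coverages": [1.5]}
            )
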