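"""Generator: geometry, calibration, determinism, sensory link."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tpafish import (
    ATTRIBUTE_NAMES, CohortSpec, FilletParams, GroupSpec, ProbeProtocol,
    SensoryLink, extract_profile, fresh_frozen_group, ground_truth_profile,
    iqf_group, sensory_link, simulate_cohort, simulate_curve,
)
from tpafish.stats import aggregate_fish


class TestGroundTruthGeometry:
    def test_recovered_height_sets_springiness(self, protocol):
        # recovered surface at 0.869 x initial height -> second travel is
        # 0.369/0.5 = 73.8% of the first
        f = FilletParams(recovery_fraction=0.738, noise_sd=0.0)
        truth = ground_truth_profile(protocol, f)
        assert truth.springiness == pytest.approx(73.8, rel=1e-3)
        assert truth.thickness_2 / truth.thickness_1 == pytest.approx(
            0.738, rel=1e-3)

    def test_perfectly_elastic_sample(self, protocol):
        # identical cycles: full recovery, same peak, same shape
        f = FilletParams(recovery_fraction=1.0, second_peak_fraction=1.0,
                         stiffness_shape2=12.0, noise_sd=0.0)
        truth = ground_truth_profile(protocol, f)
        assert truth.cohesiveness == pytest.approx(1.0, abs=1e-12)
        assert truth.springiness == pytest.approx(100.0, abs=1e-9)

    def test_resilience_equals_decompression_fraction(self, protocol):
        f = FilletParams(decompression_fraction=0.235, noise_sd=0.0)
        truth = ground_truth_profile(protocol, f)
        assert truth.resilience == pytest.approx(23.5, rel=1e-3)

    def test_adhesion_dip_closed_form(self, protocol):
        f = FilletParams(adhesion_force_n=0.9, adhesion_duration_s=2.0)
        truth = ground_truth_profile(protocol, f)
        assert truth.adhesiveness == pytest.approx(-2 * 0.9 * 2 / np.pi)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(thick=st.floats(6.0, 25.0), rf=st.floats(0.4, 1.0),
           scale=st.floats(50.0, 400.0))
    def test_thickness_springiness_identity(self, thick, rf, scale):
        # thickness-2 = thickness-1 * springiness/100, exactly by formula
        truth = ground_truth_profile(
            ProbeProtocol(),
            FilletParams(thickness_mm=thick, recovery_fraction=rf,
                         stiffness_scale=scale, noise_sd=0.0))
        assert truth.thickness_2 == pytest.approx(
            truth.thickness_1 * truth.springiness / 100.0, rel=1e-12)

    def test_rejects_unreachable_trigger(self, protocol):
        # peak force below the 5 g trigger: no contact possible
        with pytest.raises(ValueError):
            ground_truth_profile(protocol,
                                 FilletParams(stiffness_scale=0.04))


class TestRoundTrip:
    @pytest.mark.parametrize("noise_sd,tol", [(0.0, 0.005), (0.02, 0.01)])
    def test_extractor_recovers_ground_truth(self, protocol, noise_sd, tol):
        fillet = FilletParams(noise_sd=noise_sd)
        curve, truth = simulate_curve(protocol, fillet, seed=11)
        profile, _, _ = extract_profile(curve)
        for name in ATTRIBUTE_NAMES:
            assert profile[name] == pytest.approx(truth[name], rel=tol), name

    def test_default_hardness_lands_on_iqf_calibration(self, protocol):
        # defaults are calibrated to the IQF cohort: a 15.73 mm fillet
        # should give hardness-1 within 3 published SDs of 200.34 N
        curve, _ = simulate_curve(
            protocol, FilletParams(thickness_mm=15.73), seed=3)
        profile, _, _ = extract_profile(curve)
        assert abs(profile.hardness_1 - 200.34) < 3 * 42.19


class TestSensoryLink:
    def test_direct_evaluation(self):
        link = SensoryLink(intercept=0.0, coefs={"hardness_1": 0.02},
                           noise_sd=0.0)
        assert sensory_link({"hardness_1": 200.0}, link) == pytest.approx(4.0)

    def test_clipping_to_intensity_ceiling(self):
        link = SensoryLink(intercept=20.0, coefs={}, noise_sd=0.0)
        assert sensory_link({}, link) == 15.0

    def test_zero_link_returns_intercept(self):
        link = SensoryLink(intercept=5.5, coefs={"hardness_1": 0.0},
                           noise_sd=0.0)
        assert sensory_link({"hardness_1": 123.0}, link) == pytest.approx(5.5)

    def test_unknown_attribute_rejected(self):
        link = SensoryLink(intercept=0.0, coefs={"bogus": 1.0}, noise_sd=0.0)
        with pytest.raises(KeyError, match="bogus"):
            sensory_link({"hardness_1": 1.0}, link)


class TestCohort:
    def test_moments_converge_to_targets(self):
        spec = CohortSpec(groups=(iqf_group(500), fresh_frozen_group(500)),
                          seed=1234)
        agg = aggregate_fish(simulate_cohort(spec).tpa)
        for group, target in (("iqf", 69.77), ("fresh_frozen", 73.84)):
            mean = agg.loc[agg.treatment == group, "springiness"].mean()
            assert abs(mean - target) < 0.2

    def test_sd_of_fish_means_matches_target(self):
        spec = CohortSpec(groups=(iqf_group(500), fresh_frozen_group(500)),
                          seed=1234)
        agg = aggregate_fish(simulate_cohort(spec).tpa)
        sd = agg.loc[agg.treatment == "iqf", "springiness"].std(ddof=1)
        assert sd == pytest.approx(2.51, rel=0.10)

    def test_deterministic_from_seed(self):
        spec = CohortSpec(groups=(iqf_group(5), fresh_frozen_group(4)),
                          seed=99)
        a, b = simulate_cohort(spec), simulate_cohort(spec)
        pd.testing.assert_frame_equal(a.tpa, b.tpa)
        pd.testing.assert_frame_equal(a.sensory, b.sensory)

    def test_zero_noise_sensory_equals_link_mean(self):
        # all-zero coefficients, zero noise: every score is the intercept
        links = {"firmness": SensoryLink(intercept=4.2, coefs={},
                                         noise_sd=0.0)}
        spec = CohortSpec(groups=(iqf_group(4, sensory_links=links),),
                          seed=5)
        cohort = simulate_cohort(spec)
        assert (cohort.sensory["firmness"] == 4.2).all()

    def test_study_design_row_counts(self):
        spec = CohortSpec(groups=(iqf_group(60), fresh_frozen_group(34)),
                          seed=0)
        cohort = simulate_cohort(spec)
        assert cohort.sensory.shape[0] == 94
        assert cohort.tpa.shape[0] == 94 * 8

    def test_rejects_impossible_targets(self):
        with pytest.raises(ValueError):
            iqf_group(10, cohesiveness=(1.2, 0.02))
        with pytest.raises(ValueError):
            iqf_group(1)
        with pytest.raises(ValueError):
            GroupSpec(name="x", n_fish=5, springiness=(120.0, 1.0))

    def test_thicker_fillets_read_harder(self):
        # compression work rises with thickness across fish: the
        # relationship residualization exists to remove
        spec = CohortSpec(groups=(iqf_group(200),), seed=6)
        agg = aggregate_fish(simulate_cohort(spec).tpa)
        r = np.corrcoef(agg["hardness_1b"], agg["thickness_2"])[0, 1]
        assert r > 0.3

    def test_curve_mode_attaches_traces(self):
        spec = CohortSpec(groups=(iqf_group(2, points_per_fillet=2),), seed=8)
        cohort = simulate_cohort(spec, return_curves=True)
        assert len(cohort.curves) == 4
        assert cohort.curves[0].meta["fish_id"] == "iqf_001"
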