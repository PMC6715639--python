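"""Synthetic community generator: CLDs, attributes, calibrated communities,
recovery-report mechanics."""

import numpy as np
import pytest

from mergm.netdata import ValidationError, descriptive_summary
from mergm.synthgen import (
    COMMUNITY_1_ATTRIBUTES,
    CommunityProfile,
    community_1_profile,
    generate_attributes,
    generate_cld,
    generate_community,
    recovery_experiment,
)
from mergm.estimator import EstimationSettings
from mergm.sampler import ModelSpec
from mergm.configs import default_specs

from conftest import actors_only_net


class TestCld:
    def test_tiny_complete_case(self):
        B = generate_cld(2, 1.0, seed=0)
        assert B[0, 1] == 1 and B[1, 0] == 1 and B.trace() == 0

    def test_expected_arc_count(self):
        n, dens = 58, 0.03
        counts = [generate_cld(n, dens, hub_bias=1.0, seed=s).sum() for s in range(30)]
        expected = dens * n * (n - 1)
        se = np.sqrt(n * (n - 1) * dens * (1 - dens) / 30)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_no_self_loops_and_binary(self):
        B = generate_cld(20, 0.2, hub_bias=2.0, seed=1)
        assert B.trace() == 0 and set(np.unique(B)) <= {0, 1}

    def test_hub_bias_zero_matches_uniform_placement(self):
        # without bias, in-degree variance is consistent with a G(n, m) draw
        n, dens, reps = 25, 0.1, 40
        var_unbiased = np.mean([
            generate_cld(n, dens, 0.0, seed=s).sum(axis=0).var() for s in range(reps)
        ])
        p = dens
        binom_var = (n - 1) * p * (1 - p)
        assert var_unbiased == pytest.approx(binom_var, rel=0.25)

    def test_hub_bias_inflates_in_degree_variance(self):
        var0 = np.mean([generate_cld(30, 0.08, 0.0, seed=s).sum(axis=0).var()
                        for s in range(20)])
        var5 = np.mean([generate_cld(30, 0.08, 5.0, seed=s).sum(axis=0).var()
                        for s in range(20)])
        assert var5 > 1.5 * var0

    def test_invalid_density_rejected(self):
        with pytest.raises(ValueError):
            generate_cld(10, 1.2)


class TestAttributes:
    def test_degenerate_probabilities(self):
        probs = {"gender": {"female": 1.0, "male": 0.0}}
        table = generate_attributes(12, probs, seed=0)
        assert (table["gender"] == "female").all()

    def test_multinomial_frequencies_at_large_n(self):
        n = 10_000
        table = generate_attributes(n, COMMUNITY_1_ATTRIBUTES, seed=1)
        for cat, p in COMMUNITY_1_ATTRIBUTES["organisation"].items():
            freq = (table["organisation"] == cat).mean()
            se = np.sqrt(max(p * (1 - p), 1e-9) / n)
            assert abs(freq - p) < max(4 * se, 1e-12), cat

    def test_one_record_per_actor(self):
        table = generate_attributes(18, COMMUNITY_1_ATTRIBUTES, seed=2)
        assert len(table) == 18 and table["id"].is_unique


@pytest.fixture(scope="module")
def small_profile():
    # reduced-scale profile so generation stays fast in the suite
    return CommunityProfile(
        invited=18, respondents=12, n_variables=20,
        mean_out_degree=4.0, mean_actions=3.0, seed=9,
    )


class TestCommunity:
    def test_calibrated_means_within_15_percent(self, small_profile):
        net = generate_community(small_profile)
        s = descriptive_summary(net, small_profile.invited)
        assert abs(s["out_degree"]["mean"] - 4.0) / 4.0 <= 0.15
        assert abs(s["actions_per_member"]["mean"] - 3.0) / 3.0 <= 0.15

    def test_same_seed_same_community(self, small_profile):
        assert generate_community(small_profile).equal_layers(
            generate_community(small_profile))

    def test_generated_network_satisfies_data_invariants(self, small_profile):
        net = generate_community(small_profile)  # constructor validates
        assert net.A.trace() == 0 and net.B.trace() == 0
        assert net.n_actors == 12 and net.n_variables == 20
        assert set(net.Y.columns) == {"organisation", "education", "gender"}

    def test_published_scale_profile_targets(self):
        profile = community_1_profile(seed=3)
        net = generate_community(profile)
        s = descriptive_summary(net, profile.invited)
        assert s["n_respondents"] == 18 and s["n_cld_variables"] == 58
        assert s["response_rate_pct"] == 67
        assert abs(s["out_degree"]["mean"] - 7.1) / 7.1 <= 0.15
        assert abs(s["actions_per_member"]["mean"] - 5.4) / 5.4 <= 0.15

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValidationError):
            CommunityProfile(invited=10, respondents=12)
        with pytest.raises(ValidationError):
            CommunityProfile(attribute_probs={"gender": {"female": 0.5, "male": 0.4}})


class TestRecovery:
    def test_two_replicate_shape_check(self):
        model = ModelSpec(tuple(default_specs(["Density"])), np.array([-1.0]))
        report = recovery_experiment(
            (actors_only_net(8), model), 2,
            est_settings=EstimationSettings(
                phase1_samples=50, iters_per_subphase=20, phase3_samples=50),
            seed=1,
        )
        assert report.estimates.shape == (2, 1)
        records = report.to_records()
        assert len(records) == 1
        assert {"bias", "coverage_2se", "mc_se"} <= set(records[0])

    def test_rejects_single_replicate(self):
        model = ModelSpec(tuple(default_specs(["Density"])), np.array([-1.0]))
        with pytest.raises(ValueError):
            recovery_experiment((actors_only_net(8), model), 1)
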