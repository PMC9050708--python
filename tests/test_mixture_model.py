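import numpy as np
import pytest

from nucleofoot.footprint import N_BINS, DistanceHistogram
from nucleofoot.mixture_model import (
    ClassProfiles,
    MixtureSettings,
    estimate_nucleosome_score,
    log_posterior,
    pooled_theta,
    rhat,
    train_class_profiles,
)
from nucleofoot.synthetic import make_m_profiles, sample_distance_histogram


def random_profiles(rng, concentration=50.0):
    a = rng.dirichlet(np.full(N_BINS, concentration))
    b = rng.dirichlet(np.full(N_BINS, concentration))
    return ClassProfiles(a, b)


class TestPooledTheta:
    def test_normalized_counts_single_sample(self):
        np.testing.assert_allclose(
            pooled_theta([np.array([1, 2, 1])], alpha=0.0),
            [0.25, 0.5, 0.25],
        )

    def test_pooling_across_samples(self):
        np.testing.assert_allclose(
            pooled_theta([np.array([1, 0]), np.array([0, 1])], alpha=0.0),
            [0.5, 0.5],
        )

    def test_empty_bin_with_zero_alpha_is_error(self):
        with pytest.raises(ValueError, match="alpha"):
            pooled_theta([np.array([1, 0, 1])], alpha=0.0)

    def test_smoothing_limit_uniform(self):
        np.testing.assert_allclose(
            pooled_theta([np.zeros(N_BINS)], alpha=1.0), np.full(N_BINS, 1 / N_BINS)
        )


class TestTrainClassProfiles:
    def test_recovers_generating_profiles(self, profiles):
        hists, labels = [], []
        for lab, lam in (("healthy", 0.0), ("HGSOC", 1.0)):
            for s in range(3):
                hists.append(
                    sample_distance_histogram(
                        profiles, lam, 200_000, seed=s + (0 if lam == 0 else 50)
                    )
                )
                labels.append(lab)
        trained = train_class_profiles(hists, labels)
        assert trained.theta_healthy.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.max(np.abs(trained.theta_healthy - profiles.theta_healthy)) < 5e-4
        assert np.max(np.abs(trained.theta_hgsoc - profiles.theta_hgsoc)) < 5e-4

    def test_missing_class_is_error(self, profiles):
        h = sample_distance_histogram(profiles, 0.0, 100, seed=1)
        with pytest.raises(ValueError, match="HGSOC"):
            train_class_profiles([h], ["healthy"])

    def test_zero_counts_requires_explicit_flag(self):
        empty = DistanceHistogram(np.zeros(N_BINS, dtype=int))
        with pytest.raises(ValueError, match="zero total"):
            train_class_profiles([empty, empty], ["healthy", "HGSOC"])
        trained = train_class_profiles(
            [empty, empty], ["healthy", "HGSOC"], allow_empty_counts=True
        )
        np.testing.assert_allclose(trained.theta_healthy, 1 / N_BINS)


class TestLogPosterior:
    def test_endpoint_is_pure_class_likelihood(self, profiles, rng):
        y = sample_distance_histogram(profiles, 0.3, 10_000, seed=4)
        assert log_posterior(0.0, y, profiles) == pytest.approx(
            float(y.counts @ np.log(profiles.theta_healthy))
        )
        assert log_posterior(1.0, y, profiles) == pytest.approx(
            float(y.counts @ np.log(profiles.theta_hgsoc))
        )

    def test_constant_when_profiles_identical(self, profiles):
        same = ClassProfiles(
            profiles.theta_healthy.copy(), profiles.theta_healthy.copy()
        )
        y = sample_distance_histogram(profiles, 0.0, 10_000, seed=5)
        vals = [log_posterior(l, y, same) for l in (0.0, 0.3, 0.7, 1.0)]
        assert np.ptp(vals) < 1e-9

    def test_matches_term_by_term_summation(self, rng):
        prof = random_profiles(rng)
        y = rng.integers(0, 50, N_BINS)
        lam = 0.3
        want = sum(
            yi * np.log(lam * th + (1 - lam) * thh)
            for yi, th, thh in zip(y, prof.theta_hgsoc, prof.theta_healthy)
        )
        got = log_posterior(lam, DistanceHistogram(y), prof)
        assert got == pytest.approx(want, rel=1e-10)

    def test_lambda_outside_unit_interval_is_error(self, profiles):
        y = sample_distance_histogram(profiles, 0.0, 100, seed=6)
        with pytest.raises(ValueError):
            log_posterior(1.5, y, profiles)


class TestEstimate:
    def test_recovery_at_intermediate_truth(self, profiles):
        y = sample_distance_histogram(profiles, 0.4, 10**6, seed=7)
        res = estimate_nucleosome_score(y, profiles)
        assert abs(res.score - 0.4) < 0.02
        assert res.ci_low < res.score < res.ci_high

    def test_label_swap_antisymmetry(self, profiles):
        y = sample_distance_histogram(profiles, 0.3, 10**5, seed=8)
        a = estimate_nucleosome_score(y, profiles).score
        b = estimate_nucleosome_score(y, profiles.swapped()).score
        assert abs((1.0 - a) - b) < 0.005

    def test_credible_interval_concentrates_with_n(self, profiles):
        widths = []
        for n in (10**4, 10**6):
            y = sample_distance_histogram(profiles, 0.5, n, seed=9)
            r = estimate_nucleosome_score(y, profiles)
            widths.append(r.ci_high - r.ci_low)
        assert widths[1] < widths[0] / 3

    def test_unidentifiable_profiles_flagged_uniform_posterior(self, profiles):
        same = ClassProfiles(
            profiles.theta_healthy.copy(), profiles.theta_healthy.copy()
        )
        y = sample_distance_histogram(profiles, 0.0, 10_000, seed=10)
        r = estimate_nucleosome_score(y, same)
        assert not r.identifiable
        assert r.score == pytest.approx(0.5, abs=1e-3)
        assert r.ci_high - r.ci_low == pytest.approx(0.95, abs=0.001)

    def test_empty_histogram_is_error(self, profiles):
        with pytest.raises(ValueError, match="empty"):
            estimate_nucleosome_score(
                DistanceHistogram(np.zeros(N_BINS, dtype=int)), profiles
            )

    def test_mcmc_requires_seed_and_agrees_with_quadrature(self, profiles):
        y = sample_distance_histogram(profiles, 0.6, 10**5, seed=11)
        with pytest.raises(ValueError, match="seed"):
            estimate_nucleosome_score(
                y, profiles, MixtureSettings(sampler="mcmc")
            )
        quad = estimate_nucleosome_score(y, profiles)
        mc = estimate_nucleosome_score(
            y, profiles, MixtureSettings(sampler="mcmc", seed=3)
        )
        assert abs(mc.score - quad.score) <= 0.005
        assert mc.rhat is not None and mc.converged

    def test_monotone_in_truth(self, profiles):
        means = []
        for k, lam in enumerate((0.0, 0.25, 0.5, 0.75, 1.0)):
            vals = [
                estimate_nucleosome_score(
                    sample_distance_histogram(
                        profiles, lam, 10**5, seed=100 * k + s
                    ),
                    profiles,
                    MixtureSettings(grid_size=20_001),
                ).score
                for s in range(3)
            ]
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)


class TestRhat:
    def test_constant_chains_are_unity_by_convention(self):
        assert rhat(np.ones((4, 50))) == 1.0

    def test_separated_chains_diverge(self, rng):
        chains = np.vstack(
            [rng.normal(0, 1, 300), rng.normal(10, 1, 300)]
        )
        assert rhat(chains) > 1.1

    def test_well_mixed_chains_converge(self, rng):
        chains = rng.normal(0, 1, (4, 300))
        assert rhat(chains) < 1.05

    def test_single_chain_is_error(self):
        with pytest.raises(ValueError, match="chains"):
            rhat(np.zeros((1, 100)))
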