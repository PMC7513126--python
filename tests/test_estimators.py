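import numpy as np
import pytest

from nzest import (
    EstimatorSpec,
    SampleCounts,
    default_grid,
    estimate,
    make_test_distribution,
    sample_counts,
)
from nzest.estimators import (
    addone_estimate,
    addp_estimate,
    bayes_estimate,
    bincount_estimate,
    kds_estimate,
    nonzero_estimate,
)


def counts_of(values, k=None):
    arr = np.array(values, dtype=np.int64)
    return SampleCounts(default_grid(k or len(arr)), arr)


class TestBincount:
    def test_direct_normalization(self):
        est = bincount_estimate(counts_of([3, 0, 1]))
        assert np.allclose(est.probs, [0.75, 0.0, 0.25])

    def test_point_mass_and_uniform(self):
        assert bincount_estimate(counts_of([0, 7, 0])).probs[1] == 1.0
        assert np.allclose(bincount_estimate(counts_of([1, 1, 1, 1])).probs, 0.25)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            bincount_estimate(counts_of([0, 0, 0]))


class TestAddOne:
    def test_fills_only_empty_bins(self):
        assert np.allclose(addone_estimate(counts_of([3, 0, 1])).probs, [0.6, 0.2, 0.2])

    def test_single_observation_gives_uniform(self):
        assert np.allclose(addone_estimate(counts_of([1, 0, 0, 0, 0, 0])).probs, 1 / 6)

    def test_empty_sample_gives_uniform(self):
        assert np.allclose(addone_estimate(counts_of([0, 0, 0, 0])).probs, 0.25)


class TestBayes:
    def test_posterior_mean_flat_prior(self):
        assert np.allclose(bayes_estimate(counts_of([3, 0, 1])).probs, [4 / 7, 1 / 7, 2 / 7])
        assert np.allclose(
            bayes_estimate(counts_of([1, 0, 0, 0, 0, 0])).probs,
            [2 / 7] + [1 / 7] * 5,
        )

    def test_prior_mean_on_empty_sample(self):
        assert np.allclose(bayes_estimate(counts_of([0] * 5)).probs, 0.2)

    def test_agrees_with_addone_only_when_all_bins_empty(self):
        empty = counts_of([0, 0, 0])
        assert np.allclose(addone_estimate(empty).probs, bayes_estimate(empty).probs)
        occupied = counts_of([2, 0, 1])
        assert not np.allclose(addone_estimate(occupied).probs, bayes_estimate(occupied).probs)

    def test_rejects_nonpositive_prior(self):
        with pytest.raises(ValueError):
            bayes_estimate(counts_of([1, 0]), prior_count=0.0)


class TestAddP:
    def test_formula(self):
        est = addp_estimate(counts_of([3, 0, 1]), add_mass=1e-4)
        assert np.allclose(est.probs, np.array([0.75, 1e-4, 0.25]) / 1.0001)

    def test_no_empty_bins_reduces_to_bincount(self):
        c = counts_of([2, 3, 5])
        assert np.allclose(addp_estimate(c).probs, bincount_estimate(c).probs)

    def test_zero_bin_mass_independent_of_n(self):
        # the filled-in probability stays ~add_mass no matter the sample size
        small = addp_estimate(counts_of([5, 0, 5]), add_mass=1e-4).probs[1]
        large = addp_estimate(counts_of([5000, 0, 5000]), add_mass=1e-4).probs[1]
        assert small == pytest.approx(large, rel=1e-9)
        assert small == pytest.approx(1e-4, rel=1e-3)


class TestKds:
    def test_dirac_sample_positive_everywhere_mode_preserved(self, truths):
        c = sample_counts(truths["dirac"], 5, 0)
        est, bw = kds_estimate(c)
        assert np.all(est.probs > 0.0)
        assert est.probs.argmax() == 4
        assert bw >= 0.05

    def test_dirac_output_identical_for_every_n(self, truths):
        # the sample is the same point set regardless of its multiplicity
        outs = []
        for n in (1, 10, 100):
            c = sample_counts(truths["dirac"], n, 0)
            est, bw = kds_estimate(c)
            outs.append((est.probs, bw))
        for probs, bw in outs[1:]:
            assert np.array_equal(probs, outs[0][0])
            assert bw == outs[0][1]

    def test_large_uniform_sample_close_to_uniform_up_to_boundary_bias(self, truths, rng):
        # kernel mass leaking across the outcome-at-upper-edge embedding gives a
        # systematic ~1/9 L1 boundary bias; the interior matches uniform closely
        c = sample_counts(truths["uniform"], 10_000, rng)
        est, _ = kds_estimate(c)
        assert np.abs(est.probs - 1 / 9).sum() < 0.15
        assert np.abs(est.probs[1:-1] - 1 / 9).max() < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            kds_estimate(counts_of([0] * 9))

    def test_bandwidth_cap_raises(self, truths):
        c = sample_counts(truths["dirac"], 1, 0)
        with pytest.raises(RuntimeError, match="cap"):
            kds_estimate(c, bw0=0.001, bw_step=0.001, bw_cap=0.002)


class TestNonzero:
    def test_worked_single_observation_example(self):
        est = nonzero_estimate(counts_of([1, 0, 0, 0, 0, 0]), level=0.95)
        assert np.allclose(np.round(est.probs, 4), [0.1737] + [0.1653] * 5)

    def test_empty_sample_exact_uniform(self):
        est = nonzero_estimate(counts_of([0, 0, 0, 0]))
        assert np.array_equal(est.probs, np.full(4, 0.25))

    def test_large_sample_matches_truth_within_ci_widths(self):
        # at n=10^4 the narrow intervals pin the estimate near (0.9, 0.1)
        est = nonzero_estimate(counts_of([9000, 1000]), level=0.95)
        assert np.all(np.abs(est.probs - [0.9, 0.1]) < 0.005)

    def test_observed_bin_dominates_unobserved(self, rng):
        # CP midpoints are monotone in x at fixed n
        for _ in range(20):
            k = int(rng.integers(2, 12))
            c = rng.multinomial(int(rng.integers(1, 30)), np.full(k, 1 / k))
            est = nonzero_estimate(SampleCounts(default_grid(k), c))
            observed = c > 0
            if observed.any() and (~observed).any():
                assert est.probs[observed].min() >= est.probs[~observed].max()

    def test_converges_to_bincount(self, truths, rng):
        c = sample_counts(truths["normal_wide"], 50_000, rng)
        nz = nonzero_estimate(c).probs
        bc = bincount_estimate(c).probs
        assert np.abs(nz - bc).max() < 0.01

    def test_rejects_bad_level(self):
        with pytest.raises(ValueError):
            nonzero_estimate(counts_of([1, 0]), level=1.5)


class TestDispatcher:
    @pytest.mark.parametrize("method", ["bincount", "addone", "bayes", "addp", "kds", "nonzero"])
    def test_dispatch_and_normalization(self, method):
        c = counts_of([4, 0, 1, 0, 0, 2, 0, 0, 0], k=9)
        est = estimate(EstimatorSpec(method), c)
        assert abs(est.probs.sum() - 1.0) < 1e-9
        if method != "bincount":
            assert np.all(est.probs > 0.0)

    def test_aliases_accepted(self):
        assert EstimatorSpec("NZ").method == "nonzero"
        assert EstimatorSpec("AO").method == "addone"

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            EstimatorSpec("wald")

    def test_degenerate_single_bin(self):
        c = counts_of([3])
        for method in ("bincount", "addone", "bayes", "addp", "kds", "nonzero"):
            assert estimate(EstimatorSpec(method), c).probs[0] == pytest.approx(1.0)
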