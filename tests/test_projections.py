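import numpy as np
import pytest

from enscircuit.projections import (
    classify_orientation,
    compare_proportions,
    fit_bimodal,
    split_by_cutoff,
)
from enscircuit.synthetic import SimProjectionConfig, generate_projections

ORAL = (-1.0, 0.0)


def _vec(theta_deg):
    t = np.deg2rad(theta_deg)
    # rotate the oral direction by theta
    return (-np.cos(t), np.sin(t))


class TestClassifyOrientation:
    @pytest.mark.parametrize(
        "theta, expected",
        [
            (0.0, "oral"),
            (45.0, "oral"),
            (90.0, "circumferential"),
            (135.0, "aboral"),
            (180.0, "aboral"),
        ],
    )
    def test_sector_rule(self, theta, expected):
        assert classify_orientation(_vec(theta), ORAL) == expected

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation((0.0, 0.0), ORAL)

    def test_sectors_partition_half_circle(self):
        labels = {classify_orientation(_vec(t), ORAL) for t in np.linspace(0, 180, 361)}
        assert labels == {"oral", "aboral", "circumferential"}


class TestFitBimodal:
    def _pooled_lengths(self, n=2000, seed=7):
        cfg = SimProjectionConfig(
            n_per_region={"pooled": n},
            orientation_props={
                "pooled": {"oral": 0.5, "aboral": 0.5, "circumferential": 0.0, "untraceable": 0.0}
            },
        )
        neurons, truth = generate_projections(cfg, seed)
        return np.array([m.length_mm for m in neurons]), truth

    def test_recovers_generative_means_and_trough(self):
        lengths, truth = self._pooled_lengths()
        fit = fit_bimodal(lengths, seed=0)
        m1, m2 = truth.mixture["means_mm"]
        assert fit.bimodal and fit.converged
        assert fit.means[0] == pytest.approx(m1, abs=0.15)
        assert fit.means[1] == pytest.approx(m2, abs=0.15)
        assert m1 < fit.trough_mm < m2

    def test_unimodal_sample_not_bimodal(self):
        rng = np.random.default_rng(1)
        fit = fit_bimodal(rng.normal(3.0, 0.5, 800).clip(0.01), seed=0)
        assert fit.bimodal is False
        assert fit.trough_mm is None

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_bimodal([1.0, 2.0, 3.0])

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            fit_bimodal([1.0, -2.0, 3.0, 4.0])

    def test_component_order_normalized(self):
        lengths, _ = self._pooled_lengths(n=500, seed=3)
        fit = fit_bimodal(lengths, seed=5)
        assert fit.means[0] <= fit.means[1]
        assert fit.weights[0] + fit.weights[1] == pytest.approx(1.0)

    def test_recovery_improves_with_sample_size(self):
        bias = {}
        for n in (100, 2000):
            errs = []
            for seed in range(20):
                lengths, truth = self._pooled_lengths(n=n, seed=100 + seed)
                fit = fit_bimodal(lengths, seed=seed)
                m = truth.mixture["means_mm"]
                errs.append(abs(fit.means[0] - m[0]) + abs(fit.means[1] - m[1]))
            bias[n] = np.mean(errs)
        assert bias[2000] < bias[100]


class TestSplitByCutoff:
    def test_basic_split(self):
        short, long_ = split_by_cutoff([1.0, 2.0, 4.0, 5.0], 3.1)
        assert list(short) == [1.0, 2.0]
        assert list(long_) == [4.0, 5.0]

    def test_empty_input(self):
        short, long_ = split_by_cutoff([], 3.1)
        assert len(short) == len(long_) == 0

    def test_cutoff_value_goes_long(self):
        short, long_ = split_by_cutoff([3.1], 3.1)
        assert len(short) == 0 and list(long_) == [3.1]

    def test_partition_sizes(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0.1, 8.0, 57)
        short, long_ = split_by_cutoff(x, 3.1)
        assert len(short) + len(long_) == len(x)


class TestCompareProportions:
    def test_identical_proportions(self):
        chi2, p = compare_proportions(10, 20, 10, 20)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_table(self):
        # [[30,10],[10,30]]: all expected cells 20 -> chi2 = 4 * 100/20 = 20
        chi2, _ = compare_proportions(30, 40, 10, 40)
        assert chi2 == pytest.approx(20.0)

    def test_extreme_table(self):
        chi2, p = compare_proportions(0, 10, 10, 10)
        assert chi2 > 10
        assert p < 0.01

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            compare_proportions(0, 0, 1, 10)


class TestGenerator:
    def test_region_sample_sizes(self):
        neurons, _ = generate_projections(SimProjectionConfig(), seed=1)
        regions = [m.region for m in neurons]
        assert regions.count("proximal") == 57
        assert regions.count("distal") == 61

    def test_single_component_weights(self):
        cfg = SimProjectionConfig(mixture_weights=(1.0, 0.0))
        neurons, _ = generate_projections(cfg, seed=1)
        lengths = np.array([m.length_mm for m in neurons if m.length_mm is not None])
        # all lengths from component 1: N(1.5, 0.4) truncated at 0
        assert lengths.max() < 3.5

    def test_lengths_positive_and_untraceable_lengthless(self):
        neurons, _ = generate_projections(SimProjectionConfig(), seed=2)
        for m in neurons:
            if m.orientation == "untraceable":
                assert m.length_mm is None
            else:
                assert m.length_mm > 0

    def test_seed_determinism(self):
        a, _ = generate_projections(SimProjectionConfig(), seed=5)
        b, _ = generate_projections(SimProjectionConfig(), seed=5)
        assert [(m.orientation, m.length_mm) for m in a] == [
            (m.orientation, m.length_mm) for m in b
        ]

    def test_bad_sd_rejected(self):
        with pytest.raises(ValueError):
            generate_projections(SimProjectionConfig(mixture_sds_mm=(0.4, 0.0)), seed=1)
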