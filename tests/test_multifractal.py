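import numpy as np
import pytest

import speechmf as smf
from speechmf.multifractal import default_scales

# analytic singularity-exponent endpoints of a binomial cascade with weight p
# are -log2(max(p, 1-p)) and -log2(min(p, 1-p))
CASCADE_07_WIDTH = -np.log2(0.3) + np.log2(0.7)  # 1.2224


class TestBinProportions:
    @pytest.mark.parametrize(
        "u, L, expected",
        [
            ([1, 2, 3, 4], 2, [0.3, 0.7]),
            ([1, 1, 1, 1], 1, [0.25, 0.25, 0.25, 0.25]),
            ([0, 0, 2, 2], 2, [1.0]),  # zero bin excluded, renormalized
        ],
    )
    def test_examples(self, u, L, expected):
        np.testing.assert_allclose(smf.bin_proportions(np.array(u, float), L), expected)

    def test_trailing_remainder_discarded(self):
        # only the first two full bins of size 2 enter
        P = smf.bin_proportions(np.array([1.0, 1.0, 2.0, 2.0, 99.0]), 2)
        np.testing.assert_allclose(P, [1 / 3, 2 / 3])

    def test_errors(self):
        with pytest.raises(ValueError, match="no mass"):
            smf.bin_proportions(np.zeros(8), 2)
        with pytest.raises(ValueError, match="out of range"):
            smf.bin_proportions(np.ones(4), 8)


class TestMassDistribution:
    @pytest.mark.parametrize(
        "P, q, expected",
        [
            ([0.3, 0.7], 1.0, [0.3, 0.7]),
            ([0.3, 0.7], 0.0, [0.5, 0.5]),
            ([0.3, 0.7], 2.0, [0.09 / 0.58, 0.49 / 0.58]),
        ],
    )
    def test_examples(self, P, q, expected):
        np.testing.assert_allclose(smf.mass_distribution(np.array(P), q), expected)

    @pytest.mark.parametrize("q", [-300.0, 300.0])
    def test_extreme_q_finite_and_normalized(self, q, rng):
        P = smf.bin_proportions(rng.uniform(0.01, 1.0, size=1024), 4)
        mu = smf.mass_distribution(P, q)
        assert np.all(np.isfinite(mu))
        assert np.sum(mu) == pytest.approx(1.0, abs=1e-10)

    def test_mu_sums_to_one_across_q_and_scales(self, cascade_07):
        for L in (16, 64, 256):
            P = smf.bin_proportions(cascade_07, L)
            for q in (-300.0, -7.0, 0.0, 1.0, 2.0, 300.0):
                assert np.sum(smf.mass_distribution(P, q)) == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            smf.mass_distribution(np.array([0.0, 1.0]), 2.0)


class TestCJSpectrum:
    def test_constant_series_is_monofractal(self):
        spec = smf.cj_spectrum(np.full(2**12, 0.5))
        assert spec.width <= 0.02
        kept = spec.retained
        np.testing.assert_allclose(spec.alpha[kept], 1.0, atol=0.02)
        np.testing.assert_allclose(spec.f[kept], 1.0, atol=0.02)

    def test_cascade_width_matches_closed_form(self, cascade_07):
        spec = smf.cj_spectrum(cascade_07)
        assert spec.width == pytest.approx(CASCADE_07_WIDTH, abs=0.15)
        # extreme retained alpha agree with the analytic endpoints
        kept_alpha = spec.alpha[spec.retained]
        assert kept_alpha.min() == pytest.approx(-np.log2(0.7), abs=0.1)
        assert kept_alpha.max() == pytest.approx(-np.log2(0.3), abs=0.1)

    def test_uniform_cascade_is_monofractal(self):
        flat = smf.binomial_cascade(smf.CascadeSpec(p=0.5, levels=14, seed=0))
        assert smf.cj_spectrum(flat).width <= 0.05

    def test_spectrum_is_downward_opening(self, cascade_07):
        spec = smf.cj_spectrum(cascade_07)
        kept = spec.retained
        peak_q = spec.q[kept][np.argmax(spec.f[kept])]
        assert abs(peak_q) <= 5  # maximum f near q = 0
        assert spec.f[kept].max() <= 1.0 + 0.02  # support dimension of a 1-D series

    def test_iid_noise_narrower_than_cascade(self):
        cfg = smf.CJConfig(scales=default_scales(2**14))
        for seed in range(10):
            noise = np.random.default_rng(seed).uniform(0.0, 1.0, size=2**14)
            cascade = smf.binomial_cascade(smf.CascadeSpec(p=0.7, levels=14, seed=seed))
            assert smf.cj_spectrum(noise, cfg).width < smf.cj_spectrum(cascade, cfg).width

    @pytest.mark.parametrize("c", [2.0, 0.25, 1024.0])
    def test_power_of_two_rescaling_bit_exact(self, cascade_07, c):
        base = smf.cj_spectrum(cascade_07)
        scaled = smf.cj_spectrum(c * cascade_07)
        assert scaled.width == base.width
        assert np.array_equal(scaled.alpha, base.alpha)

    def test_arbitrary_rescaling_invariant_to_fp_noise(self, cascade_07):
        base = smf.cj_spectrum(cascade_07)
        scaled = smf.cj_spectrum(3.7 * cascade_07)
        assert scaled.width == pytest.approx(base.width, abs=1e-9)

    def test_width_increases_away_from_uniform_weight(self):
        widths = []
        for p in (0.55, 0.65, 0.75):
            cas = smf.binomial_cascade(smf.CascadeSpec(p=p, levels=14, seed=11))
            widths.append(smf.cj_spectrum(cas).width)
        assert widths[0] < widths[1] < widths[2]

    def test_too_few_scales_rejected(self):
        with pytest.raises(ValueError, match="3 scales"):
            smf.cj_spectrum(np.ones(64), smf.CJConfig(scales=np.array([4, 8])))

    def test_q_grid_must_contain_0_and_1(self):
        with pytest.raises(ValueError, match="contain 0 and 1"):
            smf.CJConfig(q_grid=np.array([-2.0, 0.0, 2.0]))


class TestSpectrumWidth:
    def test_max_minus_min_of_retained_alpha(self, cascade_07):
        spec = smf.cj_spectrum(cascade_07)
        kept = spec.alpha[spec.retained]
        assert smf.spectrum_width(spec) == kept.max() - kept.min()
        # degenerate retained set: a single q gives zero width
        spec.retained = np.zeros_like(spec.retained)
        spec.retained[0] = True
        assert smf.spectrum_width(spec) == 0.0

    def test_empty_retained_set_raises(self, cascade_07):
        spec = smf.cj_spectrum(cascade_07)
        spec.retained = np.zeros_like(spec.retained)
        with pytest.raises(ValueError, match="no retained q"):
            smf.spectrum_width(spec)
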