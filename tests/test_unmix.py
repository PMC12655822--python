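import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from serscyto import (
    REPORTER_ORDER,
    AxisSpec,
    RamanSpectrum,
    ReferenceLibrary,
    cls_unmix,
    mix_spectra,
    pearson_with_slope_p,
    ratios_to_fractions,
    recovery_correlation,
    unmix_spectra,
)


class TestRatiosToFractions:
    def test_dominant_tag_design(self):
        assert np.allclose(ratios_to_fractions((1, 6, 1, 1, 1)), [0.1, 0.6, 0.1, 0.1, 0.1])

    def test_symmetry(self):
        assert np.allclose(ratios_to_fractions((2,) * 5), 0.2)

    def test_one_hot(self):
        assert np.allclose(ratios_to_fractions((0, 0, 5, 0, 0)), [0, 0, 1, 0, 0])

    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1, 1), (0, 0, 0, 0, 0)])
    def test_negative_or_all_zero_rejected(self, bad):
        with pytest.raises(ValueError):
            ratios_to_fractions(bad)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=10).filter(lambda r: sum(r) > 0))
    def test_fractions_sum_to_one(self, ratios):
        assert abs(ratios_to_fractions(ratios).sum() - 1.0) < 1e-12


def _normal_equation_oracle(matrix, y):
    return np.linalg.solve(matrix.T @ matrix, matrix.T @ y)


class TestClsUnmix:
    def test_pure_reference_identity(self, library):
        spec = library.references["QSY21"]
        prof = cls_unmix(spec, library)
        expected = {r: (1.0 if r == "QSY21" else 0.0) for r in REPORTER_ORDER}
        for r in REPORTER_ORDER:
            assert prof.weights[r] == pytest.approx(expected[r], abs=1e-9)
        assert prof.residual_norm == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["ols", "nnls"])
    def test_two_component_mixture(self, library, mode):
        spec = mix_spectra(library, [0.3, 0.7, 0, 0, 0])
        prof = cls_unmix(spec, library, mode=mode)
        assert np.allclose(prof.as_array(), [0.3, 0.7, 0, 0, 0], atol=1e-9)
        # independent oracle: solve the normal equations directly
        oracle = _normal_equation_oracle(library.matrix(), spec.intensities)
        assert np.allclose(cls_unmix(spec, library, "ols").as_array(), oracle, atol=1e-9)

    @settings(derandomize=True, max_examples=25)
    @given(w=st.lists(st.floats(0, 1), min_size=5, max_size=5))
    def test_noiseless_recovery_of_any_nonnegative_weights(self, w, library):
        spec = mix_spectra(library, w)
        for mode in ("ols", "nnls"):
            assert np.allclose(cls_unmix(spec, library, mode).as_array(), w, atol=1e-9)

    def test_ols_matches_normal_equation_oracle_on_noisy_input(self, library, rng):
        for _ in range(10):
            y = library.matrix() @ rng.uniform(0, 1, 5) + rng.normal(0, 0.05, library.wavenumbers.size)
            spec = RamanSpectrum(library.wavenumbers, y)
            oracle = _normal_equation_oracle(library.matrix(), y)
            assert np.allclose(cls_unmix(spec, library, "ols").as_array(), oracle, atol=1e-9)

    def test_nnls_equals_ols_when_ols_is_nonnegative(self, library, rng):
        checked = 0
        for _ in range(100):
            spec = mix_spectra(
                library, rng.uniform(0.05, 1, 5), noise_sd=0.005, rng=rng
            )
            ols = cls_unmix(spec, library, "ols").as_array()
            if np.all(ols >= 0):
                nnls = cls_unmix(spec, library, "nnls").as_array()
                assert np.allclose(ols, nnls, atol=1e-9)
                checked += 1
        assert checked > 50

    def test_scale_covariance_of_ols(self, library):
        spec = mix_spectra(library, [0.2, 0.1, 0.4, 0.05, 0.25])
        w1 = cls_unmix(spec, library, "ols").as_array()
        w3 = cls_unmix(spec.copy_with(3.0 * spec.intensities), library, "ols").as_array()
        assert np.allclose(w3, 3.0 * w1, atol=1e-9)

    def test_axis_mismatch_is_error(self, library):
        other = AxisSpec(250, 3000, 14)
        spec = RamanSpectrum(other.grid(), np.zeros(other.n_points))
        with pytest.raises(ValueError, match="axes differ"):
            cls_unmix(spec, library)

    def test_rank_deficient_library_names_collinear_reporters(self, library):
        refs = dict(library.references)
        dup = refs["SiNC"].copy_with(refs["SiNC"].intensities.copy())
        dup.meta["name"] = "DTDC"
        # DTDC reference replaced by a copy of SiNC's shape centred elsewhere
        refs["DTDC"] = refs["SiNC"].copy_with(refs["SiNC"].intensities * 0.5)
        lib2 = ReferenceLibrary.__new__(ReferenceLibrary)
        lib2.axis_spec = library.axis_spec
        lib2.references = refs
        lib2.provenance = "simulated"
        spec = mix_spectra(library, [0.2] * 5)
        with pytest.raises(ValueError, match="SiNC"):
            cls_unmix(spec, lib2)

    def test_relative_residual_definition(self, library, rng):
        spec = mix_spectra(library, [0.2, 0.3, 0.1, 0.05, 0.2], noise_sd=0.02, seed=0)
        prof = cls_unmix(spec, library)
        assert prof.relative_residual == pytest.approx(
            prof.residual_norm / np.linalg.norm(spec.intensities)
        )


class TestUnmixSpectra:
    def test_batch_matches_single(self, library):
        specs = [mix_spectra(library, [0.1, 0.2, 0.3, 0.2, 0.1])] * 2
        frame = unmix_spectra(specs, library)
        assert len(frame) == 2
        single = cls_unmix(specs[0], library)
        # columns are integrin-named; DTDC weight appears under beta5
        assert frame.loc[0, "beta5"] == pytest.approx(single.weights["DTDC"])


class TestPearson:
    def test_exact_linearity(self):
        res = pearson_with_slope_p([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)

    def test_hand_computed_r(self):
        # cov = 0.75, var_x = var_y = 1.25 -> r = 0.6
        assert pearson_with_slope_p([1, 2, 3, 4], [2, 1, 4, 3]).r == pytest.approx(0.6)

    def test_matches_textbook_formulas(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = x + np.array([0.1, -0.1, 0.1, -0.1, 0.1])
        res = pearson_with_slope_p(x, y)
        # brute-force Pearson and slope-t oracle
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        n = len(x)
        resid = y - (y.mean() + slope * (x - x.mean()))
        se = np.sqrt(np.sum(resid**2) / (n - 2) / np.sum((x - x.mean()) ** 2))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(slope / se), n - 2)
        assert res.r == pytest.approx(r)
        assert res.p == pytest.approx(p)

    def test_constant_input_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_with_slope_p([1, 2, 3, 4], [5, 5, 5, 5])

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            pearson_with_slope_p([1, 2], [1, 2])


class TestRecoveryCorrelation:
    def test_perfect_recovery(self):
        pairs = [([0.1, 0.6, 0.1, 0.1, 0.1], [0.1, 0.6, 0.1, 0.1, 0.1]),
                 ([0.2] * 5, [0.2] * 5),
                 ([0.5, 0.2, 0.1, 0.1, 0.1], [0.5, 0.2, 0.1, 0.1, 0.1])]
        assert recovery_correlation(pairs).r == pytest.approx(1.0)

    def test_recovered_weights_renormalised_before_comparison(self):
        # recovered = 2x the true fractions; renormalisation makes it perfect
        pairs = [([0.1, 0.6, 0.1, 0.1, 0.1], [0.2, 1.2, 0.2, 0.2, 0.2]),
                 ([0.3, 0.3, 0.2, 0.1, 0.1], [0.6, 0.6, 0.4, 0.2, 0.2])]
        res = recovery_correlation(pairs)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_affine_invariance_of_r(self, rng):
        x = rng.uniform(0, 1, 20)
        y = x + rng.normal(0, 0.1, 20)
        r0 = pearson_with_slope_p(x, y).r
        r1 = pearson_with_slope_p(2.5 * x + 1.0, y).r
        assert r1 == pytest.approx(r0)
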