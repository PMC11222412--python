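"""Radiomics features: first-order statistics, GLCM/GLRLM textures against
hand enumeration, wavelet sub-bands, and matrix assembly."""

import numpy as np
import pytest

from srstroke.radiomics import (
    FIRST_ORDER_NAMES,
    GLCM_NAMES,
    GLRLM_NAMES,
    FeatureMatrix,
    FeatureVector,
    RadiomicsConfig,
    extract_case_features,
    extract_channel_features,
    first_order_features,
    glcm_features,
    glrlm_features,
    normalize_features,
    wavelet_channels,
)

FO = {n: i for i, n in enumerate(FIRST_ORDER_NAMES)}
GC = {n: i for i, n in enumerate(GLCM_NAMES)}
GR = {n: i for i, n in enumerate(GLRLM_NAMES)}


class TestFirstOrder:
    def test_constant_region(self):
        img = np.full((2, 5, 1), 5.0)
        f = first_order_features(img, np.ones_like(img, bool))
        assert f[FO["mean"]] == 5 and f[FO["variance"]] == 0
        assert f[FO["entropy"]] == 0 and f[FO["uniformity"]] == 1

    def test_hand_computed_quartet(self):
        img = np.array([1.0, 2.0, 3.0, 4.0]).reshape(4, 1, 1)
        f = first_order_features(img, np.ones((4, 1, 1), bool))
        assert f[FO["mean"]] == 2.5
        assert f[FO["variance"]] == 1.25      # population convention
        assert f[FO["range"]] == 3
        assert f[FO["energy"]] == 1 + 4 + 9 + 16
        assert f[FO["median"]] == 2.5

    def test_moments_of_standard_normal(self, rng):
        x = rng.normal(size=10_000).reshape(100, 100, 1)
        f = first_order_features(x, np.ones_like(x, bool))
        assert f[FO["skewness"]] == pytest.approx(0.0, abs=0.15)
        assert f[FO["kurtosis"]] == pytest.approx(0.0, abs=0.25)  # excess
        assert f[FO["standard_deviation"]] == pytest.approx(1.0, abs=0.05)

    def test_too_few_voxels(self):
        mask = np.zeros((3, 3, 1), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError):
            first_order_features(np.ones((3, 3, 1)), mask)


class TestGLCM:
    def test_checkerboard(self):
        """2-level checkerboard with in-plane unit offsets: every pair
        crosses levels, so P = [[0,.5],[.5,0]] (hand-built matrix)."""
        x, y = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        img = ((x + y) % 2).astype(float)[..., None]
        f = glcm_features(img, np.ones_like(img, bool), n_levels=2,
                          offsets=((1, 0, 0), (0, 1, 0)))
        assert f[GC["contrast"]] == pytest.approx(1.0)
        assert f[GC["maximum_probability"]] == pytest.approx(0.5)
        assert f[GC["correlation"]] == pytest.approx(-1.0)

    def test_constant_fallbacks(self):
        img = np.full((3, 3, 1), 7.0)
        f = glcm_features(img, np.ones_like(img, bool))
        assert f[GC["contrast"]] == 0 and f[GC["joint_energy"]] == 1
        assert f[GC["correlation"]] == 0 and f[GC["joint_entropy"]] == 0

    def test_matches_hand_enumeration_on_toy(self):
        """Contrast/dissimilarity/energy from an explicitly enumerated
        co-occurrence matrix on a 4x4 toy (oracle: pair loop)."""
        img = np.array([[1, 1, 2, 3],
                        [2, 2, 3, 3],
                        [4, 2, 1, 1],
                        [1, 3, 4, 4]], dtype=float)[..., None]
        mask = np.ones_like(img, bool)
        offset = (1, 0, 0)
        counts = np.zeros((4, 4))
        for i in range(3):
            for j in range(4):
                a, b = int(img[i, j, 0]) - 1, int(img[i + 1, j, 0]) - 1
                counts[a, b] += 1
        p = counts + counts.T
        p /= p.sum()
        ii, jj = np.meshgrid(np.arange(1, 5), np.arange(1, 5), indexing="ij")
        f = glcm_features(img, mask, n_levels=4, offsets=(offset,))
        assert f[GC["contrast"]] == pytest.approx(((ii - jj) ** 2 * p).sum())
        assert f[GC["dissimilarity"]] == pytest.approx((np.abs(ii - jj) * p).sum())
        assert f[GC["joint_energy"]] == pytest.approx((p**2).sum())
        assert f[GC["autocorrelation"]] == pytest.approx((ii * jj * p).sum())
        assert f[GC["maximum_probability"]] == pytest.approx(p.max())


class TestGLRLM:
    def test_single_long_run(self):
        """One constant line of length L along the run direction:
        LRE = L^2 and RP = 1/L (oracle: explicit run enumeration)."""
        L = 6
        img = np.full((1, L, 1), 3.0)
        f = glrlm_features(img, np.ones_like(img, bool), n_levels=4,
                           directions=((0, 1, 0),))
        assert f[GR["long_run_emphasis"]] == pytest.approx(L**2)
        assert f[GR["run_percentage"]] == pytest.approx(1 / L)

    def test_alternating_levels_all_unit_runs(self):
        img = np.array([1, 2, 1, 2, 1, 2], dtype=float).reshape(1, 6, 1)
        f = glrlm_features(img, np.ones_like(img, bool), n_levels=2,
                           directions=((0, 1, 0),))
        assert f[GR["short_run_emphasis"]] == pytest.approx(1.0)
        assert f[GR["run_percentage"]] == pytest.approx(1.0)

    def test_run_count_matches_enumeration(self, rng):
        """Total matrix mass equals the hand-enumerated number of maximal
        runs along the direction."""
        vals = rng.integers(1, 4, size=12).astype(float)
        img = vals.reshape(1, 12, 1)
        mask = np.ones_like(img, bool)
        # oracle: count maximal constant segments
        n_runs = 1 + int((np.diff(vals) != 0).sum())
        f = glrlm_features(img, mask, n_levels=3, directions=((0, 1, 0),))
        assert f[GR["run_percentage"]] * 12 == pytest.approx(n_runs)


class TestWavelet:
    def test_constant_image(self):
        bands = wavelet_channels(np.full((8, 8, 8), 2.0))
        assert set(bands) == {"LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"}
        np.testing.assert_allclose(bands["LLL"], 2.0 * 2 ** 1.5, atol=1e-10)
        for k, b in bands.items():
            if k != "LLL":
                np.testing.assert_allclose(b, 0.0, atol=1e-10)

    def test_parseval_identity(self, rng):
        img = rng.normal(size=(8, 10, 6))
        bands = wavelet_channels(img)
        total = sum((b**2).sum() for b in bands.values())
        assert total == pytest.approx((img**2).sum(), rel=1e-10)

    def test_inverse_roundtrip(self, rng):
        import pywt

        img = rng.normal(size=(8, 8, 8))
        coeffs = pywt.dwtn(img, "db4", mode="periodization")
        back = pywt.idwtn(coeffs, "db4", mode="periodization")
        np.testing.assert_allclose(back, img, atol=1e-10)

    def test_too_small_axis_rejected(self):
        with pytest.raises(ValueError):
            wavelet_channels(np.zeros((4, 4)))


class TestChannelFeatures:
    def test_dimensionality_and_names(self, noiseless_patient):
        p = noiseless_patient
        fv = extract_channel_features(p.swi, p.dwi_mask, channel="SWI")
        assert len(fv.values) == 513
        assert len(set(fv.names)) == 513
        assert all(n.startswith("SWI.") for n in fv.names)

    def test_constant_image_is_deterministic_and_finite(self):
        img = np.full((16, 16, 16), 3.0)
        mask = np.zeros_like(img, bool)
        mask[4:9, 4:9, 4:9] = True
        a = extract_channel_features(img, mask)
        b = extract_channel_features(img, mask)
        np.testing.assert_array_equal(a.values, b.values)
        assert np.isfinite(a.values).all()

    def test_intensity_shift_invariance(self, noiseless_patient):
        """Adding a constant leaves variance/entropy/texture unchanged
        (min-max quantization) and shifts mean/median by that constant."""
        p = noiseless_patient
        a = extract_channel_features(p.swi, p.dwi_mask, channel="SWI")
        b = extract_channel_features(p.swi + 17.0, p.dwi_mask, channel="SWI")
        def v(fv, name):
            return fv.values[fv.names.index(name)]
        for name in ("variance", "entropy", "uniformity", "standard_deviation"):
            assert v(b, f"SWI.original.firstorder.{name}") == pytest.approx(
                v(a, f"SWI.original.firstorder.{name}"), rel=1e-9)
        for name in GLCM_NAMES:
            assert v(b, f"SWI.original.glcm.{name}") == pytest.approx(
                v(a, f"SWI.original.glcm.{name}"), rel=1e-9)
        for name in ("mean", "median"):
            assert v(b, f"SWI.original.firstorder.{name}") - v(
                a, f"SWI.original.firstorder.{name}") == pytest.approx(17.0, abs=1e-9)

    def test_first_order_permutation_invariance(self, rng):
        mask = np.zeros((6, 6, 2), bool)
        mask[1:5, 1:5, :] = True
        vals = rng.normal(size=mask.sum())
        a = np.zeros(mask.shape)
        b = np.zeros(mask.shape)
        a[mask] = vals
        b[mask] = rng.permutation(vals)
        fa = first_order_features(a, mask)
        fb = first_order_features(b, mask)
        np.testing.assert_allclose(fa, fb, rtol=1e-12)


class TestCaseFeatures:
    def test_modality_dimensions(self, noiseless_patient):
        from srstroke.pipeline import RunConfig, build_case_rois

        p = noiseless_patient
        rois = build_case_rois(p.dwi_mask, RunConfig())
        swi_only = extract_case_features(p, rois, modalities=("SWI",))
        assert len(swi_only.values) == 513
        both = extract_case_features(p, rois, modalities=("SWI", "CTP"))
        assert len(both.values) == 4 * 513 == 2052
        assert len(set(both.names)) == 2052
        prefixes = {n.split(".")[0] for n in both.names}
        assert prefixes == {"SWI", "TTP", "CBV", "CBF"}

    def test_missing_roi_names_modality(self, noiseless_patient):
        with pytest.raises(ValueError, match="SWI"):
            extract_case_features(noiseless_patient, {}, modalities=("SWI",))


class TestNormalization:
    def test_train_statistics_and_constant_columns(self, rng):
        x = rng.normal(size=(10, 4))
        x[:, 2] = 3.0  # constant
        names = ("a", "b", "c", "d")
        tr = FeatureMatrix(matrix=x, labels=np.zeros(10, int), names=names)
        te = FeatureMatrix(matrix=x + 1.0, labels=np.zeros(10, int), names=names)
        trn, ten = normalize_features(tr, te)
        np.testing.assert_allclose(trn.matrix.mean(0)[[0, 1, 3]], 0, atol=1e-12)
        np.testing.assert_allclose(trn.matrix.std(0)[[0, 1, 3]], 1, atol=1e-12)
        assert (trn.matrix[:, 2] == 0).all() and (ten.matrix[:, 2] == 0).all()
        assert trn.normalization["constant_columns"] == ["c"]
        # test uses TRAIN statistics (oracle: manual recomputation)
        manual = (te.matrix[:, 0] - x[:, 0].mean()) / x[:, 0].std()
        np.testing.assert_allclose(ten.matrix[:, 0], manual, rtol=1e-12)

    def test_column_mismatch_rejected(self):
        a = FeatureMatrix(matrix=np.ones((2, 2)), labels=[0, 1], names=("a", "b"))
        b = FeatureMatrix(matrix=np.ones((2, 2)), labels=[0, 1], names=("a", "c"))
        with pytest.raises(ValueError):
            normalize_features(a, b)


def test_feature_vector_rejects_nan():
    with pytest.raises(ValueError):
        FeatureVector(values=np.array([1.0, np.nan]), names=("a", "b"), channel="X")
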