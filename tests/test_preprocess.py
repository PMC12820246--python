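"""Preprocessing contracts: scaling, clipping, encoding, PCA, filtering,
PSD features, volume normalisation, bias correction, patch extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofuse.preprocess import (band_powers, band_psd_features,
                                  bandpass_filter, clip_outliers_zscore,
                                  correct_bias_field, extract_patches,
                                  impute_genotypes, minmax_scale_columns,
                                  normalize_volume, one_hot_genotypes,
                                  pca_reduce)
from neurofuse.synthetic import bias_field, plant_bias_field, _base_volume


# -- min-max -----------------------------------------------------------------


@pytest.mark.parametrize("col,expected", [
    ([2, 4, 6], [0, 0.5, 1]),
    ([5, 5, 5], [0, 0, 0]),          # constant-column convention
    ([-1, 0, 3], [0, 0.25, 1]),
])
def test_minmax_scaling(col, expected):
    scaled, params = minmax_scale_columns(np.array(col, dtype=float)[:, None])
    np.testing.assert_allclose(scaled[:, 0], expected)


def test_minmax_params_reused_on_heldout():
    X = np.array([[0.0], [10.0]])
    _, params = minmax_scale_columns(X)
    held, _ = minmax_scale_columns(np.array([[5.0], [20.0]]), params)
    np.testing.assert_allclose(held[:, 0], [0.5, 1.0])  # clipped into range


def test_minmax_idempotent(rng):
    X = rng.normal(size=(20, 4))
    once, _ = minmax_scale_columns(X)
    twice, _ = minmax_scale_columns(once)
    np.testing.assert_allclose(once, twice, atol=1e-12)


def test_minmax_rejects_missing():
    with pytest.raises(ValueError, match="impute"):
        minmax_scale_columns(np.array([[1.0], [np.nan]]))


# -- clipping ----------------------------------------------------------------


def test_clipping_truncates_at_three_sd():
    col = np.array([0.0] * 12 + [100.0])   # outlier z = 3.33 > 3
    clipped, (mean, sd) = clip_outliers_zscore(col[:, None])
    bound = mean[0] + 3 * sd[0]
    assert clipped.max() == pytest.approx(bound)
    np.testing.assert_array_equal(clipped[:12, 0], 0.0)


def test_clipping_is_noop_within_bounds(rng):
    X = rng.normal(size=(50, 3))
    X = (X - X.mean(0)) / X.std(0)   # everything within ~3 sd
    clipped, _ = clip_outliers_zscore(X)
    np.testing.assert_allclose(clipped, X)
    huge, _ = clip_outliers_zscore(X, threshold=np.inf)
    np.testing.assert_allclose(huge, X)


def test_clipping_idempotent_and_degenerate(rng):
    X = rng.standard_cauchy(size=(40, 2))
    once, params = clip_outliers_zscore(X)
    twice, _ = clip_outliers_zscore(once, params=params)
    np.testing.assert_allclose(once, twice)
    const = np.full((5, 1), 3.0)
    out, _ = clip_outliers_zscore(const)
    np.testing.assert_array_equal(out, const)


# -- genotype encoding -------------------------------------------------------


def test_one_hot_layout_and_row_sums():
    G = np.array([[0, 1], [2, 2]])
    H = one_hot_genotypes(G)
    assert H.shape == (2, 6)
    np.testing.assert_array_equal(H[0], [1, 0, 0, 0, 1, 0])  # AA then AG
    np.testing.assert_array_equal(H[1], [0, 0, 1, 0, 0, 1])  # GG twice
    np.testing.assert_array_equal(H.sum(axis=1), [2, 2])


def test_one_hot_rejects_out_of_range():
    with pytest.raises(ValueError, match="locus 1"):
        one_hot_genotypes(np.array([[0, 3]]))


def test_mode_imputation():
    G = np.array([[0, 2], [0, -1], [1, 2], [-1, 2]])
    filled, modes = impute_genotypes(G)
    np.testing.assert_array_equal(modes, [0, 2])
    np.testing.assert_array_equal(filled[:, 0], [0, 0, 1, 0])
    np.testing.assert_array_equal(filled[:, 1], [2, 2, 2, 2])


# -- PCA ---------------------------------------------------------------------


def test_pca_rank_one_needs_single_component(rng):
    u = rng.normal(size=(50, 1))
    v = rng.normal(size=(1, 8))
    res = pca_reduce(u @ v, variance_target=0.95)
    assert res.n_components == 1
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_white_noise_needs_nearly_all_components(rng):
    X = rng.normal(size=(5000, 10))
    res = pca_reduce(X, variance_target=0.95, max_components=None)
    assert res.n_components == 10   # ceil(0.95 * 10) with equal eigenvalues


def test_pca_target_one_keeps_rank(rng):
    X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 9))
    res = pca_reduce(X, variance_target=1.0, max_components=None)
    assert res.n_components == np.linalg.matrix_rank(X)


def test_pca_cap_and_orthonormal_loadings(rng):
    X = rng.normal(size=(40, 12))
    res = pca_reduce(X, variance_target=0.99, max_components=3)
    assert res.n_components == 3
    np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(3),
                               atol=1e-10)
    np.testing.assert_allclose(res.transform(X), res.scores, atol=1e-10)


def test_pca_invalid_target():
    with pytest.raises(ValueError):
        pca_reduce(np.eye(3), variance_target=1.5)


# -- EEG ---------------------------------------------------------------------


def test_bandpass_preserves_passband_and_kills_stopband():
    sr = 200.0
    t = np.arange(2000) / sr
    tone = np.sin(2 * np.pi * 10 * t)
    out = bandpass_filter(tone, sr)
    assert 0.95 <= out.std() / tone.std() <= 1.05
    sr2 = 250.0
    t2 = np.arange(2500) / sr2
    fast = np.sin(2 * np.pi * 90 * t2)
    # steady-state attenuation (zero-phase filtering has edge transients)
    steady = bandpass_filter(fast, sr2)[250:-250]
    assert steady.std() <= 0.1 * fast.std()
    np.testing.assert_array_equal(bandpass_filter(np.zeros(500), sr),
                                  np.zeros(500))


def test_bandpass_rejects_bad_cutoffs():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass_filter(np.zeros(100), sample_rate=64.0, high=40.0)


def test_alpha_tone_concentrates_in_alpha_band():
    sr = 128.0
    rec = np.sin(2 * np.pi * 10 * np.arange(1024) / sr)[:, None]
    bp = band_powers(rec, sr)
    assert bp[2, 0] / bp.sum() >= 0.90


def test_band_features_zscore_and_determinism(rng):
    recs = rng.normal(size=(6, 512, 3))
    recs[5] = recs[4]
    feats, params = band_psd_features(recs, sample_rate=128.0)
    np.testing.assert_allclose(feats.mean(axis=0), 0, atol=1e-9)
    np.testing.assert_allclose(feats.std(axis=0), 1, atol=1e-9)
    np.testing.assert_array_equal(feats[4], feats[5])
    held, _ = band_psd_features(recs[:2], 128.0, params=params)
    assert held.shape == (2, 12)


def test_band_features_reject_short_recordings(rng):
    with pytest.raises(ValueError, match="Welch"):
        band_powers(rng.normal(size=(100, 2)), sample_rate=128.0)


# -- volumes -----------------------------------------------------------------


def test_normalize_volume_contracts(rng):
    V = rng.uniform(10, 20, size=(6, 6, 6))
    out = normalize_volume(V)
    assert out.min() == 0.0 and out.max() == 1.0
    np.testing.assert_allclose(out, (V - V.min()) / (V.max() - V.min()))
    np.testing.assert_array_equal(normalize_volume(np.full((3, 3, 3), 7.0)),
                                  np.zeros((3, 3, 3)))
    ready = normalize_volume(out)
    np.testing.assert_allclose(ready, out, atol=1e-12)


def test_bias_correction_identity_on_clean_plateau():
    """A homogeneous phantom passes through within 1% RMS."""
    grids = np.meshgrid(*[np.linspace(-1, 1, 24)] * 3, indexing="ij")
    r = np.sqrt(sum(g ** 2 for g in grids))
    V = 0.8 / (1 + np.exp((r - 0.8) / 0.05)) + 0.02
    corrected, field = correct_bias_field(V)
    rms = np.sqrt(np.mean((corrected - V) ** 2)) / np.sqrt(np.mean(V ** 2))
    assert rms < 0.01
    tissue = V > 0.5 * V.max()
    assert np.abs(field - 1)[tissue].max() < 0.05


def test_bias_correction_recovers_planted_field(rng):
    """Planted amplitude-0.3 quadratic bias is mostly removed."""
    base = _base_volume((32, 32, 32))
    V = np.clip(base + 0.05 * rng.normal(size=base.shape), 0, None)
    corr0, field0 = correct_bias_field(V)
    plateau = V > 0.6 * V.max()
    direct = []
    for seed in range(11, 16):
        true_field = bias_field(V.shape, 0.3, seed)
        Vb = V * true_field
        corrb, fieldb = correct_bias_field(Vb)
        # field recovery: anatomy component cancels in fieldb / field0
        resid = true_field / (fieldb / field0)
        assert (np.std(resid[plateau])
                <= 0.5 * np.std(true_field[plateau])), seed
        ru = (Vb / V)[plateau]
        rc = (corrb / V)[plateau]
        direct.append(1 - (rc.std() / rc.mean()) / (ru.std() / ru.mean()))
    assert np.mean(direct) >= 0.5


def test_bias_correction_zero_volume_warns():
    with pytest.warns(UserWarning):
        out, field = correct_bias_field(np.zeros((5, 5, 5)))
    np.testing.assert_array_equal(out, 0)


# -- patches -----------------------------------------------------------------


@pytest.mark.parametrize("shape,patch,stride,count,last", [
    ((64, 64, 64), (32, 32, 32), (32, 32, 32), 8, (32, 32, 32)),
    ((64, 64, 64), (64, 64, 64), (64, 64, 64), 1, (0, 0, 0)),
    ((70, 70, 70), (32, 32, 32), (32, 32, 32), 27, (38, 38, 38)),
])
def test_patch_counts_and_clamping(shape, patch, stride, count, last):
    grid = extract_patches(np.zeros(shape), patch, stride)
    assert len(grid) == count
    assert tuple(grid.starts[-1]) == last
    assert grid.patches.shape[1:] == patch


def test_patch_identity_case(rng):
    V = rng.normal(size=(10, 10, 10))
    grid = extract_patches(V, (10, 10, 10), (10, 10, 10))
    np.testing.assert_array_equal(grid.patches[0], V)


def test_patch_too_large_rejected():
    with pytest.raises(ValueError, match="larger"):
        extract_patches(np.zeros((8, 8, 8)), (9, 8, 8), (1, 1, 1))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(L=st.integers(6, 20), p=st.integers(2, 6), s=st.integers(1, 6))
def test_patches_cover_every_voxel_when_stride_le_patch(L, p, s):
    s = min(s, p)   # coverage guaranteed for stride <= patch
    V = np.zeros((L, 6, 6))
    grid = extract_patches(V, (p, 6, 6), (s, 6, 6))
    covered = np.zeros(L, dtype=bool)
    for (a, _, _) in grid.starts:
        covered[a:a + p] = True
    assert covered.all()
    assert len(set(map(tuple, grid.starts))) == len(grid)
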