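"""Per-modality preprocessing: scaling, clipping, genotype encoding and
PCA, EEG filtering and band power-spectral-density features, volume
normalisation, simplified polynomial bias correction, and patch
extraction.

Every fit-style operation returns the statistics it estimated so that
held-out data can be transformed with training-set parameters only
(leakage guard). Conventions for degenerate inputs: a constant column
under min-max scaling maps to zeros (the 0/0 case of the scaling
formula); a zero-variance column is returned unchanged by outlier
clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sp_signal

from .config import BANDS, BAND_EDGES
from .io_formats import MISSING

__all__ = [
    "minmax_scale_columns", "clip_outliers_zscore", "impute_genotypes",
    "one_hot_genotypes", "pca_reduce", "PCAResult",
    "bandpass_filter", "band_psd_features", "band_powers",
    "normalize_volume", "correct_bias_field", "extract_patches", "PatchGrid",
]


# -- tabular -----------------------------------------------------------------


def minmax_scale_columns(X: np.ndarray, params: tuple | None = None):
    """Min-max scale each column to [0, 1].

    Returns ``(scaled, (mins, maxs))``; pass ``params`` back in to apply
    training-set scaling to held-out rows (clipped into [0, 1]).
    Constant columns map to all zeros.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X contains missing values; impute before scaling")
    if params is None:
        mins, maxs = X.min(axis=0), X.max(axis=0)
    else:
        mins, maxs = params
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (X - mins) / safe
    scaled[:, span <= 0] = 0.0
    if params is not None:
        scaled = np.clip(scaled, 0.0, 1.0)
    return scaled, (mins, maxs)


def clip_outliers_zscore(X: np.ndarray, threshold: float = 3.0,
                         params: tuple | None = None):
    """Truncate values beyond ``mean +/- threshold * sd`` per column."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    X = np.asarray(X, dtype=float)
    if params is None:
        mean, sd = X.mean(axis=0), X.std(axis=0)
    else:
        mean, sd = params
    lo = np.where(sd > 0, mean - threshold * sd, -np.inf)
    hi = np.where(sd > 0, mean + threshold * sd, np.inf)
    return np.clip(X, lo, hi), (mean, sd)


def impute_genotypes(G: np.ndarray, modes: np.ndarray | None = None):
    """Replace missing genotype calls (-1) with the per-locus mode.

    Returns ``(imputed, modes)``; modes estimated on the given matrix
    unless supplied (training-set reuse). All-missing loci impute to 0.
    """
    G = np.asarray(G)
    if modes is None:
        modes = np.zeros(G.shape[1], dtype=G.dtype)
        for j in range(G.shape[1]):
            col = G[:, j]
            present = col[col != MISSING]
            if present.size:
                vals, counts = np.unique(present, return_counts=True)
                modes[j] = vals[np.argmax(counts)]
    out = G.copy()
    mask = out == MISSING
    out[mask] = np.broadcast_to(modes, out.shape)[mask]
    return out, modes


def one_hot_genotypes(G: np.ndarray) -> np.ndarray:
    """Expand an (n, p) count matrix to (n, 3p) one-hot columns.

    Per-locus column order is (AA, AG, GG) i.e. counts (0, 1, 2).
    """
    G = np.asarray(G)
    bad = ~np.isin(G, (0, 1, 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"genotype {G[i, j]} out of range at subject {i}, "
                         f"locus {j}; impute missing values first")
    n, p = G.shape
    out = np.zeros((n, 3 * p))
    rows = np.repeat(np.arange(n), p)
    cols = 3 * np.tile(np.arange(p), n) + G.ravel()
    out[rows, cols] = 1.0
    return out


@dataclass
class PCAResult:
    scores: np.ndarray              # (n, k)
    loadings: np.ndarray            # (k, p), orthonormal rows
    explained_variance_ratio: np.ndarray
    n_components: int
    mean: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) @ self.loadings.T


def pca_reduce(X: np.ndarray, variance_target: float = 0.95,
               max_components: int | None = 200) -> PCAResult:
    """PCA keeping the smallest k with cumulative explained variance
    >= ``variance_target``, then applying the hard component cap."""
    from sklearn.decomposition import PCA

    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    model = PCA(svd_solver="full").fit(X)
    evr = model.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    k = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    k = min(k, len(evr))
    if max_components is not None:
        k = min(k, max_components)
    scores = model.transform(X)[:, :k]
    return PCAResult(scores=scores, loadings=model.components_[:k],
                     explained_variance_ratio=evr[:k], n_components=k,
                     mean=model.mean_)


# -- EEG ---------------------------------------------------------------------


def bandpass_filter(data: np.ndarray, sample_rate: float, low: float = 0.5,
                    high: float = 40.0, order: int = 4,
                    axis: int = 0) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis."""
    nyquist = sample_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz must be below the Nyquist "
                         f"frequency {nyquist} Hz")
    sos = sp_signal.butter(order, [low, high], btype="bandpass",
                           fs=sample_rate, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=axis)


def band_powers(recording: np.ndarray, sample_rate: float,
                welch_window_s: float = 2.0,
                welch_overlap: float = 0.5) -> np.ndarray:
    """Welch band powers of a (T, c) recording.

    Returns a (4, c) array of absolute powers integrated over the delta
    [0.5, 4), theta [4, 8), alpha [8, 13) and beta [13, 30) Hz bands.
    """
    recording = np.atleast_2d(np.asarray(recording, dtype=float))
    if recording.ndim != 2:
        raise ValueError("recording must be (T, c)")
    nperseg = int(round(welch_window_s * sample_rate))
    if recording.shape[0] < nperseg:
        raise ValueError(
            f"recording of {recording.shape[0]} samples is shorter than one "
            f"Welch window ({nperseg} samples)")
    freqs, psd = sp_signal.welch(
        recording, fs=sample_rate, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * welch_overlap), axis=0)
    df = freqs[1] - freqs[0]
    out = np.empty((len(BANDS), recording.shape[1]))
    for b, band in enumerate(BANDS):
        lo, hi = BAND_EDGES[band]
        sel = (freqs >= lo) & (freqs < hi)
        out[b] = psd[sel].sum(axis=0) * df
    return out


def band_psd_features(recordings, sample_rate: float,
                      welch_window_s: float = 2.0, welch_overlap: float = 0.5,
                      params: tuple | None = None):
    """Log-z band-power feature matrix, one row per recording.

    ``recordings`` is an (n, T, c) array or a list of (T, c) arrays.
    Powers are integrated per band and channel, log-transformed, then
    z-scored per feature column across subjects (training statistics
    are returned for reuse). Feature layout is band-major:
    column ``b * c + ch`` is band ``b`` of channel ``ch``.
    Returns ``(features, (mean, sd))``.
    """
    rows = [band_powers(r, sample_rate, welch_window_s,
                        welch_overlap).ravel() for r in recordings]
    logp = np.log(np.maximum(np.stack(rows), 1e-300))
    if params is None:
        mean, sd = logp.mean(axis=0), logp.std(axis=0)
    else:
        mean, sd = params
    safe = np.where(sd > 0, sd, 1.0)
    feats = (logp - mean) / safe
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite PSD features")
    return feats, (mean, sd)


# -- volumes -----------------------------------------------------------------


def normalize_volume(V: np.ndarray) -> np.ndarray:
    """Min-max normalise a volume to [0, 1]; constant volumes map to 0."""
    V = np.asarray(V, dtype=float)
    lo, hi = V.min(), V.max()
    if hi <= lo:
        return np.zeros_like(V)
    return (V - lo) / (hi - lo)


def _poly_design(shape: tuple[int, int, int], order: int,
                 mask: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape],
                        indexing="ij")
    cols = [np.ones(int(mask.sum()))]
    monomials = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                if 0 < i + j + k <= order:
                    monomials.append((i, j, k))
    x, y, z = (g[mask] for g in grids)
    for i, j, k in monomials:
        cols.append(x ** i * y ** j * z ** k)
    return np.stack(cols, axis=1)


def correct_bias_field(V: np.ndarray, poly_order: int = 2,
                       tissue_frac: float = 0.5):
    """Simplified multiplicative bias correction.

    Fits a polynomial of ``poly_order`` to the log-intensity of tissue
    voxels (above ``tissue_frac`` of the maximum), exponentiates the
    mean-centred fit into a smooth field, divides it out and rescales to
    preserve the original mean. Returns ``(corrected, estimated_field)``.
    This is a stand-in for iterative bias-field methods and assumes
    tissue intensities are roughly homogeneous.
    """
    V = np.asarray(V, dtype=float)
    vmax = V.max()
    if vmax <= 0:
        warnings.warn("all-zero volume; bias correction skipped")
        return V.copy(), np.ones_like(V)
    tissue = V > tissue_frac * vmax
    # erode away the partial-volume boundary shell so the fit sees the
    # homogeneous interior only; keep the original mask if erosion
    # removes too much (small volumes)
    eroded = ndimage.binary_erosion(tissue, iterations=3)
    if eroded.sum() >= 50:
        tissue = eroded
    design_t = _poly_design(V.shape, poly_order, tissue)
    coeffs, *_ = np.linalg.lstsq(design_t, np.log(V[tissue]), rcond=None)
    full = np.ones(V.shape, dtype=bool)
    design_full = _poly_design(V.shape, poly_order, full)
    log_field = (design_full @ coeffs).reshape(V.shape)
    log_field -= log_field[tissue].mean()
    field = np.exp(log_field)
    corrected = V / field
    corrected *= V.mean() / corrected.mean()
    return corrected, field


@dataclass
class PatchGrid:
    """Sub-volumes at half-open windows ``[start, start + patch)``."""
    patches: np.ndarray                      # (k, p_h, p_w, p_d)
    starts: np.ndarray                       # (k, 3) window origins
    patch_size: tuple[int, int, int]
    stride: tuple[int, int, int]
    source_shape: tuple[int, int, int]

    def __len__(self) -> int:
        return self.patches.shape[0]


def _axis_starts(length: int, patch: int, stride: int) -> list[int]:
    n = int(np.ceil((length - patch) / stride)) + 1
    return [min(i * stride, length - patch) for i in range(n)]


def extract_patches(V: np.ndarray, patch: tuple[int, int, int],
                    stride: tuple[int, int, int]) -> PatchGrid:
    """Extract (possibly overlapping) sub-volumes on a strided grid.

    The final window on each axis is clamped to the end of the volume so
    the last voxel is always covered; per-axis patch count is
    ``ceil((L - p) / s) + 1``.
    """
    V = np.asarray(V)
    patch = tuple(int(p) for p in patch)
    stride = tuple(int(s) for s in stride)
    if any(p > L for p, L in zip(patch, V.shape)):
        raise ValueError(f"patch {patch} larger than volume {V.shape}")
    if any(s < 1 for s in stride):
        raise ValueError("stride entries must be >= 1")
    axes_starts = [_axis_starts(L, p, s)
                   for L, p, s in zip(V.shape, patch, stride)]
    starts, patches = [], []
    for a in axes_starts[0]:
        for b in axes_starts[1]:
            for c in axes_starts[2]:
                starts.append((a, b, c))
                patches.append(V[a:a + patch[0], b:b + patch[1],
                                 c:c + patch[2]])
    return PatchGrid(patches=np.stack(patches), starts=np.array(starts),
                     patch_size=patch, stride=stride,
                     source_shape=tuple(V.shape))
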