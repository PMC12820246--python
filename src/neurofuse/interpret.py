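"""Gradient-based saliency and the uncertainty separation report.

Saliency is the absolute input gradient of a target class logit,
max-normalised to [0, 1] (identically-zero maps are left as zeros).
Volume saliency is mapped back onto the input voxel grid (overlapping
patches averaged); EEG saliency is aggregated over feature windows into
a bands x channels grid. The uncertainty report contrasts the
epistemic / aleatoric / total uncertainty of correctly and incorrectly
predicted subjects with a one-sided Mann-Whitney test (incorrect >
correct).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import BANDS, CLASSES
from .model import TriModalClassifier
from .nn import Tensor

__all__ = ["volume_saliency", "eeg_saliency", "uncertainty_report",
           "normalize_map"]


def normalize_map(m: np.ndarray) -> np.ndarray:
    """Max-normalise a nonnegative map; zero maps stay zero."""
    m = np.abs(np.asarray(m, dtype=float))
    peak = m.max()
    return m / peak if peak > 0 else m


def _input_gradient(model: TriModalClassifier, batch: dict, key: str,
                    target_class: int) -> np.ndarray:
    if not 0 <= target_class < len(CLASSES):
        raise ValueError(f"target class {target_class} out of range")
    model.eval()
    tensors = {k: Tensor(np.asarray(v, dtype=float)) for k, v in batch.items()
               if k != "mask"}
    tensors[key].requires_grad = True
    tensors["mask"] = batch.get("mask")
    logits = model(tensors)
    grad_seed = np.zeros(logits.shape)
    grad_seed[:, target_class] = 1.0
    logits.backward(grad_seed)
    g = tensors[key].grad
    return np.zeros(tensors[key].data.shape) if g is None else g


def volume_saliency(model: TriModalClassifier, batch: dict,
                    target_class: int,
                    grid_starts: np.ndarray | None = None,
                    volume_shape: tuple | None = None) -> np.ndarray:
    """|d logit_c / d voxel| for one subject's volume patches.

    ``batch`` holds a single sample (leading dimension 1). Returns the
    normalised per-voxel map on the source grid when ``grid_starts`` and
    ``volume_shape`` are given, else the per-patch map stack.
    """
    g = np.abs(_input_gradient(model, batch, "mri", target_class))[0]
    if grid_starts is None or volume_shape is None:
        return normalize_map(g)
    out = np.zeros(volume_shape)
    counts = np.zeros(volume_shape)
    p = g.shape[1:]
    for patch_map, (a, b, c) in zip(g, np.asarray(grid_starts)):
        out[a:a + p[0], b:b + p[1], c:c + p[2]] += patch_map
        counts[a:a + p[0], b:b + p[1], c:c + p[2]] += 1
    out = np.divide(out, counts, out=out, where=counts > 0)
    return normalize_map(out)


def eeg_saliency(model: TriModalClassifier, batch: dict, target_class: int,
                 n_channels: int) -> np.ndarray:
    """Band x channel saliency grid for one subject's recording features.

    Gradients are averaged (as magnitudes) over the feature windows and
    reshaped to (4 bands, c channels) following the band-major feature
    layout.
    """
    g = np.abs(_input_gradient(model, batch, "eeg", target_class))[0]
    per_feature = g.mean(axis=0)
    if per_feature.size != len(BANDS) * n_channels:
        raise ValueError(
            f"feature count {per_feature.size} is not 4 x {n_channels}")
    return normalize_map(per_feature.reshape(len(BANDS), n_channels))


def uncertainty_report(subjects: pd.DataFrame,
                       columns=("epistemic", "aleatoric", "u_final")):
    """Summarise uncertainty grouped by prediction correctness.

    ``subjects`` needs a boolean ``correct`` column plus the uncertainty
    columns. Returns ``(summary_frame, p_value)``; the Mann-Whitney p
    (one-sided, incorrect > correct on ``u_final``) is None when either
    group is empty, and the summary flags the skipped test.
    """
    if "correct" not in subjects:
        raise ValueError("subjects frame needs a 'correct' column")
    rows = []
    for flag, name in ((True, "correct"), (False, "incorrect")):
        grp = subjects[subjects["correct"] == flag]
        for col in columns:
            if col not in subjects:
                continue
            vals = grp[col].to_numpy(dtype=float)
            rows.append({
                "group": name, "measure": col, "n": len(vals),
                "mean": float(vals.mean()) if len(vals) else np.nan,
                "median": float(np.median(vals)) if len(vals) else np.nan,
                "iqr": float(np.subtract(*np.percentile(vals, [75, 25])))
                if len(vals) else np.nan,
            })
    summary = pd.DataFrame(rows)
    inc = subjects.loc[~subjects["correct"], columns[-1]].to_numpy(dtype=float)
    cor = subjects.loc[subjects["correct"], columns[-1]].to_numpy(dtype=float)
    if len(inc) == 0 or len(cor) == 0:
        summary.attrs["test"] = "skipped: a group is empty"
        return summary, None
    stat = sp_stats.mannwhitneyu(inc, cor, alternative="greater")
    summary.attrs["test"] = f"mann-whitney U={stat.statistic:.1f}"
    return summary, float(stat.pvalue)
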