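"""Subject-level splitting, training, evaluation and ablation.

Splitting is stratified by diagnosis at the *subject* level: all of a
subject's scans share one partition (70/15/15 train/validation/test by
default) and the non-test pool is additionally partitioned into k
stratified folds for cross-validation. Training follows a staged
schedule (learning rate annealed across stages, dropout decayed),
optimised with Adam (weight decay 1e-5), gradient-norm clipping at 1.0
and early stopping on validation loss. Per-subject predictions are the
arithmetic mean of the calibrated per-sample probabilities; metrics are
one-vs-rest per class plus macro averages; paired model comparisons use
McNemar's test on discordant predictions and a paired t-test on
fold-wise metrics.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .config import (CLASSES, ExperimentConfig, LossConfig, MCConfig,
                     TrainConfig, TrainStage, desk_schedule)
from .model import MODALITIES, TriModalClassifier
from .nn import Adam, clip_grad_norm
from .preprocess import (band_powers, bandpass_filter, clip_outliers_zscore,
                         correct_bias_field, extract_patches,
                         impute_genotypes, minmax_scale_columns,
                         normalize_volume, one_hot_genotypes, pca_reduce)
from .synthetic import CohortSample
from .uncertainty import (calibrated_softmax, fit_temperature, mc_predict,
                          total_loss)

__all__ = [
    "SplitPlan", "make_splits", "FeatureDataset", "build_features",
    "train_model", "predict_proba", "aggregate_subject_predictions",
    "MetricsReport", "compute_metrics", "mcnemar_test", "paired_t_test",
    "run_experiment", "run_ablation", "ABLATION_TAGS",
]

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


# -- splitting ---------------------------------------------------------------


@dataclass
class SplitPlan:
    train: list[str]
    val: list[str]
    test: list[str]
    folds: list[tuple[list[str], list[str]]]
    labels: dict[str, str]

    def partition_of(self, subject_id: str) -> str:
        for name in ("train", "val", "test"):
            if subject_id in getattr(self, name):
                return name
        raise KeyError(subject_id)


def make_splits(subject_labels: dict[str, str],
                ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
                k: int = 5, seed: int = 0) -> SplitPlan:
    """Stratified subject-level train/val/test split plus k-fold plan."""
    from .synthetic import largest_remainder_counts

    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {c: [] for c in CLASSES}
    for sid, label in subject_labels.items():
        if label not in _CLASS_INDEX:
            raise ValueError(f"unknown label {label!r} for subject {sid}")
        by_class[label].append(sid)
    for c, ids in by_class.items():
        if ids and len(ids) < k:
            raise ValueError(f"class {c} has {len(ids)} subjects, fewer "
                             f"than k={k}")
    train, val, test = [], [], []
    for c in CLASSES:
        ids = sorted(by_class[c])
        rng.shuffle(ids)
        n_tr, n_va, n_te = largest_remainder_counts(len(ids), ratios)
        train += ids[:n_tr]
        val += ids[n_tr:n_tr + n_va]
        test += ids[n_tr + n_va:]
    pool = train + val
    pool_labels = [subject_labels[s] for s in pool]
    folds: list[tuple[list[str], list[str]]] = []
    if pool:
        from sklearn.model_selection import StratifiedKFold
        # the non-test pool can have one subject fewer per class than the
        # full cohort; shrink the fold count if needed
        smallest = min(pool_labels.count(c) for c in CLASSES
                       if pool_labels.count(c))
        k_eff = max(2, min(k, smallest))
        skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
        pool_arr = np.array(pool)
        for tr_idx, va_idx in skf.split(pool_arr, pool_labels):
            folds.append((list(pool_arr[tr_idx]), list(pool_arr[va_idx])))
    return SplitPlan(train=train, val=val, test=test, folds=folds,
                     labels=dict(subject_labels))


# -- feature assembly --------------------------------------------------------


@dataclass
class FeatureDataset:
    snp: np.ndarray                 # (n_samples, p')
    mri: np.ndarray                 # (n_samples, n_patch, ph, pw, pd)
    eeg: np.ndarray                 # (n_samples, T_w, 4c)
    mask: np.ndarray                # (n_samples, 3)
    labels: np.ndarray              # (n_samples,) class indices
    subject_ids: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    def batch(self, idx) -> dict:
        return {"snp": self.snp[idx], "mri": self.mri[idx],
                "eeg": self.eeg[idx], "mask": self.mask[idx]}

    def subset(self, subject_set) -> "FeatureDataset":
        keep = [i for i, s in enumerate(self.subject_ids) if s in subject_set]
        return FeatureDataset(
            snp=self.snp[keep], mri=self.mri[keep], eeg=self.eeg[keep],
            mask=self.mask[keep], labels=self.labels[keep],
            subject_ids=[self.subject_ids[i] for i in keep])


@dataclass
class FittedStats:
    """Preprocessing statistics estimated on training subjects only."""
    snp_modes: np.ndarray | None = None
    pca = None
    snp_clip: tuple | None = None
    snp_minmax: tuple | None = None
    eeg_logz: tuple | None = None
    snp_dim: int = 0
    eeg_features: int = 0


def _eeg_window_features(sample: CohortSample, sample_rate: float, cfg,
                         n_channels: int) -> np.ndarray:
    """Per-window log band powers (T_w, 4c) for one recording."""
    rec = sample.recording
    filtered = bandpass_filter(rec, sample_rate, cfg.bandpass_low,
                               cfg.bandpass_high, cfg.filter_order, axis=0)
    wlen = int(round(cfg.eeg_window_s * sample_rate))
    n_win = max(1, filtered.shape[0] // wlen)
    rows = []
    for w in range(n_win):
        seg = filtered[w * wlen:(w + 1) * wlen]
        rows.append(np.log(np.maximum(band_powers(
            seg, sample_rate, cfg.welch_window_s, cfg.welch_overlap
        ).ravel(), 1e-300)))
    return np.stack(rows)


def _mri_patches(sample: CohortSample, cfg) -> list[np.ndarray]:
    out = []
    for vol in sample.all_volumes:
        v = normalize_volume(vol)
        if cfg.bias_poly_order and cfg.bias_poly_order > 0:
            v, _ = correct_bias_field(v, cfg.bias_poly_order)
            v = normalize_volume(v)
        patch = tuple(min(p, s) for p, s in zip(cfg.patch_size, v.shape))
        stride = tuple(min(st, p) for st, p in zip(cfg.patch_stride, patch))
        out.append(extract_patches(v, patch, stride).patches)
    return out


def build_features(cohort: list[CohortSample], fit_subjects,
                   cfg: ExperimentConfig, sample_rate: float,
                   stats: FittedStats | None = None
                   ) -> tuple[FeatureDataset, FittedStats]:
    """Assemble per-sample model features for a whole cohort.

    All fit statistics (imputation modes, PCA basis, clipping and
    scaling parameters, PSD z-scores) are estimated on ``fit_subjects``
    only and applied unchanged elsewhere; pass ``stats`` to reuse
    previously fitted parameters.
    """
    pcfg = cfg.preprocess
    fit_set = set(fit_subjects)
    by_id = {s.subject_id: s for s in cohort}
    if stats is None:
        stats = FittedStats()
        # -- genotype pipeline fit
        fit_g = [s.genotypes for s in cohort
                 if s.subject_id in fit_set and s.modality_mask[0]]
        G_fit = np.stack(fit_g)
        G_fit, stats.snp_modes = impute_genotypes(G_fit)
        H_fit = one_hot_genotypes(G_fit)
        stats.pca = pca_reduce(H_fit, pcfg.pca_variance_target,
                               pcfg.pca_max_components)
        scores = stats.pca.scores
        clipped, stats.snp_clip = clip_outliers_zscore(
            scores, pcfg.clip_threshold)
        _, stats.snp_minmax = minmax_scale_columns(clipped)
        stats.snp_dim = stats.pca.n_components
        # -- EEG pipeline fit
        fit_rows = [
            _eeg_window_features(s, sample_rate, pcfg,
                                 s.recording.shape[1])
            for s in cohort if s.subject_id in fit_set and s.modality_mask[2]]
        allw = np.concatenate(fit_rows, axis=0)
        stats.eeg_logz = (allw.mean(axis=0), np.where(allw.std(axis=0) > 0,
                                                      allw.std(axis=0), 1.0))
        stats.eeg_features = allw.shape[1]

    snp_rows, mri_rows, eeg_rows, masks, labels, sids = [], [], [], [], [], []
    mri_shape = None
    eeg_shape = None
    per_subject = []
    for s in cohort:
        has_snp, has_mri, has_eeg = s.modality_mask
        if has_snp:
            g, _ = impute_genotypes(s.genotypes[None, :], stats.snp_modes)
            h = one_hot_genotypes(g)
            z = stats.pca.transform(h)
            z, _ = clip_outliers_zscore(z, pcfg.clip_threshold,
                                        stats.snp_clip)
            z, _ = minmax_scale_columns(z, stats.snp_minmax)
            snp_feat = z[0]
        else:
            snp_feat = np.zeros(stats.snp_dim)
        if has_eeg:
            e = _eeg_window_features(s, sample_rate, pcfg,
                                     s.recording.shape[1])
            mean, sd = stats.eeg_logz
            e = np.clip((e - mean) / sd, -pcfg.clip_threshold,
                        pcfg.clip_threshold)
            eeg_shape = e.shape
        else:
            e = None
        vols = _mri_patches(s, pcfg) if has_mri else [None]
        if vols[0] is not None:
            mri_shape = vols[0].shape
        per_subject.append((s, snp_feat, e, vols))

    for s, snp_feat, e, vols in per_subject:
        has_snp, has_mri, has_eeg = s.modality_mask
        e_arr = e if e is not None else np.zeros(eeg_shape)
        for vol in vols:
            snp_rows.append(snp_feat)
            eeg_rows.append(e_arr)
            mri_rows.append(vol if vol is not None else np.zeros(mri_shape))
            masks.append([float(has_snp), float(has_mri), float(has_eeg)])
            labels.append(_CLASS_INDEX[s.label])
            sids.append(s.subject_id)

    ds = FeatureDataset(
        snp=np.stack(snp_rows), mri=np.stack(mri_rows),
        eeg=np.stack(eeg_rows), mask=np.array(masks),
        labels=np.array(labels), subject_ids=sids)
    return ds, stats


# -- training ----------------------------------------------------------------


def _val_loss(model: TriModalClassifier, data: FeatureDataset,
              batch_size: int = 128) -> float:
    """Deterministic validation cross-entropy (dropout off)."""
    model.eval()
    losses = []
    for lo in range(0, len(data), batch_size):
        idx = slice(lo, lo + batch_size)
        logits = model(data.batch(idx)).data
        p = calibrated_softmax(logits)
        p_true = p[np.arange(len(p)), data.labels[idx]]
        losses.append(-np.log(np.clip(p_true, 1e-12, None)))
    return float(np.concatenate(losses).mean())


def _apply_modality_dropout(mask: np.ndarray, prob: float,
                            rng: np.random.Generator,
                            active: list[int]) -> np.ndarray:
    """Randomly silence live modalities (training robustness), keeping at
    least one of the model's active modalities per sample."""
    if prob <= 0:
        return mask
    out = mask.copy()
    drop = rng.random(out.shape) < prob
    drop[:, [i for i in range(out.shape[1]) if i not in active]] = False
    cand = out * (1 - drop)
    rows_ok = cand[:, active].any(axis=1)
    out[rows_ok] = cand[rows_ok]
    return out


def train_model(model: TriModalClassifier, train_data: FeatureDataset,
                val_data: FeatureDataset,
                train_cfg: TrainConfig | None = None,
                loss_cfg: LossConfig | None = None,
                mc: MCConfig | None = None,
                class_weights=None, seed: int = 0) -> pd.DataFrame:
    """Run the staged schedule; returns the per-epoch training log.

    Weights are carried across stages; early stopping monitors the
    validation loss with the configured patience and min-delta and the
    best weights are restored at the end.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    mc = mc or MCConfig()
    if not train_cfg.schedule:
        raise ValueError("schedule must contain at least one stage")
    rng = np.random.default_rng(seed)
    params = model.parameters()
    if class_weights is None:
        counts = np.bincount(train_data.labels, minlength=3).astype(float)
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
        class_weights = inv * (3.0 / max(inv.sum(), 1e-12))

    log_rows = []
    best_val = np.inf
    best_state = None
    stall = 0
    step = 0
    stop = False
    for stage_i, stage in enumerate(train_cfg.schedule):
        model.set_dropout_rate(stage.dropout)
        opt = Adam(params, lr=stage.lr, weight_decay=train_cfg.weight_decay)
        for epoch in range(stage.epochs):
            model.train()
            order = rng.permutation(len(train_data))
            term_sums: dict[str, float] = {}
            n_batches = 0
            for lo in range(0, len(order), stage.batch_size):
                idx = order[lo:lo + stage.batch_size]
                batch = train_data.batch(idx)
                active = [i for i, m in enumerate(MODALITIES)
                          if m in model.modalities]
                batch["mask"] = _apply_modality_dropout(
                    batch["mask"], model.cfg.modality_dropout, rng, active)
                terms = total_loss(model, batch, train_data.labels[idx],
                                   loss_cfg, mc, class_weights,
                                   pass_seed=seed * 7919 + step)
                if not np.isfinite(terms.total):
                    raise RuntimeError(
                        f"non-finite loss at stage {stage_i + 1}, epoch "
                        f"{epoch + 1}, step {step}")
                model.zero_grad()
                terms.graph.backward()
                clip_grad_norm(params, train_cfg.clip_norm)
                opt.step()
                step += 1
                n_batches += 1
                for k, v in terms.as_dict().items():
                    term_sums[k] = term_sums.get(k, 0.0) + v
            val = _val_loss(model, val_data) if len(val_data) else np.nan
            row = {"stage": stage_i + 1, "epoch": epoch + 1,
                   "lr": stage.lr, "dropout": stage.dropout,
                   "val_loss": val}
            row.update({f"train_{k}": v / max(n_batches, 1)
                        for k, v in term_sums.items()})
            log_rows.append(row)
            if len(val_data):
                if val < best_val - train_cfg.min_delta:
                    best_val = val
                    best_state = [p.data.copy() for p in params]
                    stall = 0
                else:
                    stall += 1
                    if stall >= train_cfg.patience:
                        stop = True
                        break
        if stop:
            break
    if best_state is not None:
        for p, saved in zip(params, best_state):
            p.data = saved
    model.eval()
    return pd.DataFrame(log_rows)


def predict_proba(model: TriModalClassifier, data: FeatureDataset,
                  mc: MCConfig | None = None, temperature: float = 1.0,
                  batch_size: int = 128):
    """Per-sample probabilities; with ``mc`` also MC uncertainties.

    Returns ``(probs, epistemic, aleatoric, total)``; the uncertainty
    arrays are None without ``mc``.
    """
    if len(data) == 0:
        raise ValueError("no samples to predict on (empty partition)")
    probs, epi, ale, tot = [], [], [], []
    for lo in range(0, len(data), batch_size):
        batch = data.batch(slice(lo, lo + batch_size))
        if mc is None:
            model.eval()
            probs.append(calibrated_softmax(model(batch).data, temperature))
        else:
            est = mc_predict(model, batch, mc, temperature)
            probs.append(est.mean)
            epi.append(est.epistemic)
            ale.append(est.aleatoric)
            tot.append(est.total)
    probs = np.concatenate(probs)
    if mc is None:
        return probs, None, None, None
    return (probs, np.concatenate(epi), np.concatenate(ale),
            np.concatenate(tot))


def aggregate_subject_predictions(probs: np.ndarray, subject_ids,
                                  extras: dict | None = None):
    """Average per-sample probability vectors at the subject level.

    Returns a DataFrame indexed by subject with the mean probability per
    class and the arg-max prediction (ties broken in class order).
    Optional per-sample ``extras`` arrays are averaged the same way.
    """
    probs = np.asarray(probs, dtype=float)
    if len(probs) != len(subject_ids):
        raise ValueError("probs and subject_ids length mismatch")
    if len(probs) == 0:
        raise ValueError("no samples to aggregate")
    df = pd.DataFrame(probs, columns=list(CLASSES))
    df["subject_id"] = list(subject_ids)
    if extras:
        for k, v in extras.items():
            df[k] = np.asarray(v)
    agg = df.groupby("subject_id", sort=False).mean()
    p = agg[list(CLASSES)].to_numpy()
    agg["prediction"] = [CLASSES[i] for i in p.argmax(axis=1)]
    return agg


# -- metrics -----------------------------------------------------------------


@dataclass
class MetricsReport:
    accuracy: float
    confusion: np.ndarray                 # (3, 3) rows = truth
    per_class: pd.DataFrame               # sens/spec/F1/NPV/AUROC/AUPRC
    macro: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "confusion": self.confusion.tolist(),
                "per_class": self.per_class.to_dict(),
                "macro": dict(self.macro)}


def compute_metrics(y_true, proba: np.ndarray) -> MetricsReport:
    """One-vs-rest classification metrics at the subject level."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    proba = np.asarray(proba, dtype=float)
    if np.abs(proba.sum(axis=1) - 1).max() > 1e-6:
        raise ValueError("probability vectors must sum to 1")
    y_idx = np.array([_CLASS_INDEX[y] if isinstance(y, str) else int(y)
                      for y in y_true])
    if len(np.unique(y_idx)) < 1:
        raise ValueError("empty truth set")
    pred = proba.argmax(axis=1)
    n = len(y_idx)
    confusion = np.zeros((3, 3), dtype=int)
    for t, p in zip(y_idx, pred):
        confusion[t, p] += 1
    accuracy = float((pred == y_idx).mean())

    rows = {}
    for c, name in enumerate(CLASSES):
        tp = int(confusion[c, c])
        fn = int(confusion[c].sum() - tp)
        fp = int(confusion[:, c].sum() - tp)
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        npv = tn / (tn + fn) if tn + fn else np.nan
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * prec * sens / (prec + sens)
              if (prec + sens) and np.isfinite(sens) else 0.0)
        binary = (y_idx == c).astype(int)
        if 0 < binary.sum() < n:
            auroc = float(roc_auc_score(binary, proba[:, c]))
            auprc = float(average_precision_score(binary, proba[:, c]))
        else:
            auroc = auprc = np.nan
        rows[name] = {"sensitivity": sens, "specificity": spec, "f1": f1,
                      "npv": npv, "auroc": auroc, "auprc": auprc}
    per_class = pd.DataFrame(rows).T
    macro = {k: float(np.nanmean(per_class[k])) for k in per_class.columns}
    macro["accuracy"] = accuracy
    return MetricsReport(accuracy=accuracy, confusion=confusion,
                         per_class=per_class, macro=macro)


def mcnemar_test(correct_a, correct_b) -> tuple[float, float]:
    """McNemar's paired test on two models' per-subject correctness.

    Continuity-corrected chi-square ``(|b - c| - 1)^2 / (b + c)`` with
    1 df; exact two-sided binomial when the discordant count is < 25.
    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired correctness vectors must align")
    n_b = int(np.sum(a & ~b))
    n_c = int(np.sum(~a & b))
    m = n_b + n_c
    if m == 0:
        warnings.warn("no discordant pairs; p = 1")
        return 0.0, 1.0
    stat = (abs(n_b - n_c) - 1) ** 2 / m
    if m < 25:
        p = sp_stats.binomtest(n_b, m, 0.5).pvalue
    else:
        p = float(sp_stats.chi2.sf(stat, df=1))
    return float(stat), float(p)


def paired_t_test(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t-test on fold-wise metric pairs."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need >= 2 paired fold metrics")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences (exact ties)")
        return (0.0, 1.0) if np.isclose(d.mean(), 0.0) else (np.inf, 0.0)
    t, p = sp_stats.ttest_rel(a, b)
    return float(t), float(p)


# -- experiment harness ------------------------------------------------------

ABLATION_TAGS = ("snp", "mri", "eeg", "snp+mri", "snp+eeg", "mri+eeg",
                 "snp+mri+eeg")


def _desk_config(cfg: ExperimentConfig | None) -> ExperimentConfig:
    if cfg is not None:
        return cfg
    cfg = ExperimentConfig()
    cfg.model = cfg.model.desk_scale()
    cfg.train.schedule = desk_schedule()
    return cfg


def prepare_data(cohort: list[CohortSample], sample_rate: float,
                 seed: int = 0, cfg: ExperimentConfig | None = None):
    """Split at the subject level and assemble features (fit on train).

    Returns ``(features, stats, plan, cfg)`` for reuse across model
    configurations evaluated on the same split.
    """
    cfg = _desk_config(cfg)
    labels = {s.subject_id: s.label for s in cohort}
    counts = [sum(v == c for v in labels.values()) for c in CLASSES]
    k = max(2, min(5, min(c for c in counts if c)))
    plan = make_splits(labels, k=k, seed=seed)
    feats, stats = build_features(cohort, plan.train, cfg, sample_rate)
    return feats, stats, plan, cfg


def run_experiment(cohort: list[CohortSample], sample_rate: float,
                   modalities: tuple[str, ...] = MODALITIES,
                   attention: bool = True, seed: int = 0,
                   cfg: ExperimentConfig | None = None,
                   mc_passes: int | None = None,
                   prepared=None, n_restarts: int = 1) -> dict:
    """Train and evaluate one configuration on one subject-level split.

    Returns a dict with the metrics report, per-subject predictions and
    uncertainties, the fitted temperature, and the training log.
    ``prepared`` may carry the output of :func:`prepare_data` to share
    the feature assembly across configurations. With ``n_restarts`` > 1
    the model is trained from several initialisations and the one with
    the lowest validation loss is kept (deterministic model selection).
    """
    if prepared is None:
        prepared = prepare_data(cohort, sample_rate, seed, cfg)
    feats, stats, plan, cfg = prepared
    labels = plan.labels
    # samples with none of this configuration's modalities cannot be
    # scored by it and are excluded from all partitions
    active = [i for i, m in enumerate(MODALITIES) if m in modalities]
    usable = feats.mask[:, active].any(axis=1)
    scorable = {s for s, ok in zip(feats.subject_ids, usable) if ok}
    train_d = feats.subset(set(plan.train) & scorable)
    val_d = feats.subset(set(plan.val) & scorable)
    test_d = feats.subset(set(plan.test) & scorable)

    model = log = None
    best = np.inf
    for r in range(max(1, n_restarts)):
        cand = TriModalClassifier(
            snp_dim=stats.snp_dim, eeg_features=stats.eeg_features,
            cfg=cfg.model, modalities=modalities, attention=attention,
            seed=seed + 1000 * r)
        cand_log = train_model(cand, train_d, val_d, cfg.train, cfg.loss,
                               cfg.mc, seed=seed)
        score = (float(cand_log.val_loss.min())
                 if len(cand_log) and np.isfinite(cand_log.val_loss.min())
                 else _val_loss(cand, val_d))
        if model is None or score < best:
            model, log, best = cand, cand_log, score

    # temperature on validation logits (eval mode)
    model.eval()
    val_logits = model(val_d.batch(slice(None))).data
    try:
        temperature = fit_temperature(val_logits, val_d.labels)
    except ValueError:
        temperature = 1.0

    mc = MCConfig(num_passes=mc_passes or cfg.mc.num_passes,
                  training_passes=cfg.mc.training_passes, seed=seed)
    probs, epi, ale, tot = predict_proba(model, test_d, mc=mc,
                                         temperature=temperature)
    agg = aggregate_subject_predictions(
        probs, test_d.subject_ids,
        extras={"epistemic": epi, "aleatoric": ale, "u_final": tot})
    truth = [labels[s] for s in agg.index]
    report = compute_metrics(truth, agg[list(CLASSES)].to_numpy())
    agg["truth"] = truth
    agg["correct"] = agg["prediction"] == agg["truth"]
    return {"metrics": report, "subjects": agg, "temperature": temperature,
            "log": log, "model": model, "plan": plan, "stats": stats,
            "config": cfg}


def recovery_study_config() -> ExperimentConfig:
    """Desk-scale training protocol used by the signal-recovery study."""
    cfg = ExperimentConfig()
    cfg.model = cfg.model.desk_scale()
    cfg.model.modality_dropout = 0.0   # complete-data study
    cfg.train.schedule = [
        TrainStage(lr=1e-3, batch_size=32, epochs=24, dropout=0.4),
        TrainStage(lr=1e-4, batch_size=32, epochs=8, dropout=0.2),
    ]
    cfg.train.patience = 8
    cfg.mc.training_passes = 2
    return cfg


RECOVERY_CONFIGS = (("snp", True), ("mri", True), ("eeg", True),
                    ("snp+mri+eeg", False), ("snp+mri+eeg", True))


def run_recovery_study(seeds, n_subjects: int = 300, mc_passes: int = 15,
                       collect_subjects: bool = False) -> pd.DataFrame:
    """Planted-signal recovery: single modalities vs tri-modal fusion with
    and without attention, repeated over seeds on interaction cohorts.

    Returns a tidy frame with one row per (seed, configuration); with
    ``collect_subjects`` the per-subject test predictions of the
    trimodal-attention model are attached in ``frame.attrs``.
    """
    from .synthetic import generate_cohort, interaction_cohort_spec

    rows = []
    subject_frames = []
    for seed in seeds:
        cohort = generate_cohort(interaction_cohort_spec(seed, n_subjects))
        cfg = recovery_study_config()
        prepared = prepare_data(cohort, 128.0, seed=seed, cfg=cfg)
        for tag, att in RECOVERY_CONFIGS:
            mods = tuple(tag.split("+"))
            # trimodal fits are restart-sensitive; keep the best of three
            # by validation loss (same rule for both fusion variants)
            restarts = 3 if len(mods) == 3 else 1
            res = run_experiment(cohort, 128.0, modalities=mods,
                                 attention=att, seed=seed, prepared=prepared,
                                 mc_passes=mc_passes, n_restarts=restarts)
            rows.append({"seed": seed, "modalities": tag, "attention": att,
                         "tag": f"{tag}/{'attention' if att else 'concat'}",
                         "accuracy": res["metrics"].accuracy,
                         "macro_f1": res["metrics"].macro["f1"]})
            if collect_subjects and att and len(mods) == 3:
                sub = res["subjects"].copy()
                sub["seed"] = seed
                subject_frames.append(sub)
    frame = pd.DataFrame(rows)
    if subject_frames:
        frame.attrs["subjects"] = pd.concat(subject_frames)
    return frame


def run_ablation(cohort: list[CohortSample], sample_rate: float,
                 configurations=None, seed: int = 0,
                 cfg: ExperimentConfig | None = None) -> pd.DataFrame:
    """Evaluate modality subsets x {attention, concatenation} on shared
    splits and seeds; returns a tidy table sorted by accuracy."""
    if configurations is None:
        configurations = [(tag, att) for tag in ABLATION_TAGS
                          for att in (True, False)]
    if not configurations:
        raise ValueError("configuration list is empty")
    for tag, att in configurations:
        if set(tag.split("+")) - set(MODALITIES):
            raise ValueError(f"unknown ablation tag {tag!r}")
    prepared = prepare_data(cohort, sample_rate, seed,
                            copy.deepcopy(cfg) if cfg else None)
    rows = []
    for tag, att in configurations:
        mods = tuple(tag.split("+"))
        res = run_experiment(cohort, sample_rate, modalities=mods,
                             attention=att, seed=seed, prepared=prepared)
        rows.append({
            "tag": f"{tag}/{'attention' if att else 'concat'}",
            "modalities": tag, "attention": att,
            "accuracy": res["metrics"].accuracy,
            "macro_f1": res["metrics"].macro["f1"],
            "macro_auroc": res["metrics"].macro["auroc"],
        })
    return (pd.DataFrame(rows)
            .sort_values("accuracy", ascending=False)
            .reset_index(drop=True))
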