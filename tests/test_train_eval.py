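"""Splitting, leakage guards, training mechanics, metrics and statistics."""

import numpy as np
import pandas as pd
import pytest

from neurofuse.config import (CLASSES, ExperimentConfig, LossConfig, MCConfig,
                              TrainConfig, TrainStage, reference_schedule)
from neurofuse.model import TriModalClassifier
from neurofuse.synthetic import CohortSpec, generate_cohort
from neurofuse.train_eval import (aggregate_subject_predictions, run_ablation,
                                  build_features, compute_metrics,
                                  make_splits, mcnemar_test, paired_t_test,
                                  prepare_data, run_experiment, train_model)


def subject_labels(n_per_class=20):
    labels = {}
    for c_i, c in enumerate(CLASSES):
        for j in range(n_per_class):
            labels[f"{c}-{j:03d}"] = c
    return labels


# -- splits ------------------------------------------------------------------


def test_split_sizes_and_stratification():
    plan = make_splits(subject_labels(20), seed=0)
    assert len(plan.train) == 42 and len(plan.val) == 9 and len(plan.test) == 9
    for part in (plan.train, plan.val, plan.test):
        counts = [sum(plan.labels[s] == c for s in part) for c in CLASSES]
        assert max(counts) - min(counts) <= 1
    # partitions are disjoint and cover everyone
    all_ids = plan.train + plan.val + plan.test
    assert len(set(all_ids)) == len(all_ids) == 60


def test_split_determinism_and_fold_partition():
    a = make_splits(subject_labels(15), seed=3)
    b = make_splits(subject_labels(15), seed=3)
    assert a.train == b.train and a.val == b.val and a.test == b.test
    seen = []
    for tr, va in a.folds:
        assert not set(tr) & set(va)
        seen.extend(va)
    assert sorted(seen) == sorted(a.train + a.val)   # each subject once
    # per-fold class proportions within one subject of balance
    for _, va in a.folds:
        counts = [sum(a.labels[s] == c for s in va) for c in CLASSES]
        assert max(counts) - min(counts) <= 1


def test_split_rejects_class_smaller_than_k():
    labels = subject_labels(4)
    with pytest.raises(ValueError, match="fewer"):
        make_splits(labels, k=5)


def test_multi_scan_subjects_stay_in_one_partition(desk_cfg):
    spec = CohortSpec(n_subjects=15, volume_shape=(8, 8, 8), n_channels=2,
                      n_timesteps=512, n_snps=20, scans_per_subject=3,
                      frac_complete=1.0, seed=5)
    cohort = generate_cohort(spec)
    feats, stats, plan, _ = prepare_data(cohort, spec.sample_rate, seed=0,
                                         cfg=desk_cfg)
    assert len(feats) == 45   # 3 samples per subject
    for sid in set(feats.subject_ids):
        parts = {plan.partition_of(sid)}
        assert len(parts) == 1


def test_fit_statistics_come_from_training_subjects_only(small_cohort,
                                                         desk_cfg):
    labels = {s.subject_id: s.label for s in small_cohort}
    train_ids = list(labels)[:8]
    _, stats = build_features(small_cohort, train_ids, desk_cfg, 128.0)
    # refitting on the training rows reproduces the stored statistics
    _, stats2 = build_features(small_cohort, train_ids, desk_cfg, 128.0)
    np.testing.assert_array_equal(stats.snp_modes, stats2.snp_modes)
    np.testing.assert_allclose(stats.eeg_logz[0], stats2.eeg_logz[0])
    # transforming held-out subjects with the fitted stats is unchanged
    feats_a, _ = build_features(small_cohort, train_ids, desk_cfg, 128.0,
                                stats=stats)
    feats_b, _ = build_features(small_cohort, list(labels), desk_cfg, 128.0,
                                stats=stats)
    np.testing.assert_allclose(feats_a.snp, feats_b.snp)
    np.testing.assert_allclose(feats_a.eeg, feats_b.eeg)


# -- training ----------------------------------------------------------------


def test_reference_schedule_matches_published_stages():
    sched = reference_schedule()
    assert len(sched) == 10
    assert sched[0].lr == 0.001 and sched[-1].lr == 0.00001
    assert sched[0].batch_size == 32 and sched[-1].batch_size == 16
    assert sched[0].dropout == 0.5 and sched[-1].dropout == 0.2
    assert sched[0].epochs == 10 and sched[-1].epochs == 50
    assert sched[0].kernel == 3 and sched[-1].kernel == 5
    assert [s.filters for s in sched] == [64, 64, 128, 128, 128, 128, 128,
                                          256, 256, 256]


def test_training_loss_decreases_on_small_cohort():
    """One stage at lr 1e-3, 2 epochs, 50 subjects: epoch-2 training loss
    is below epoch-1 in at least 8 of 10 seeds."""
    spec = CohortSpec(n_subjects=50, volume_shape=(8, 8, 8), n_channels=2,
                      n_timesteps=512, n_snps=30, frac_complete=1.0, seed=2)
    cohort = generate_cohort(spec)
    cfg0 = ExperimentConfig()
    cfg0.model = cfg0.model.desk_scale()
    cfg0.model.modality_dropout = 0.0
    cfg0.mc.training_passes = 2
    wins = 0
    for seed in range(10):
        feats, stats, plan, cfg = prepare_data(cohort, spec.sample_rate,
                                               seed=seed, cfg=cfg0)
        model = TriModalClassifier(stats.snp_dim, stats.eeg_features,
                                   cfg=cfg.model, seed=seed)
        tc = TrainConfig(schedule=[TrainStage(lr=1e-3, batch_size=16,
                                              epochs=2, dropout=0.3)])
        log = train_model(model, feats, feats.subset(set(plan.val)), tc,
                          cfg.loss, cfg.mc, seed=seed)
        if log.train_total.iloc[-1] < log.train_total.iloc[0]:
            wins += 1
    assert wins >= 8


def test_gradient_clipping_bounds_update_norm():
    """An injected exploding gradient is clipped to norm <= 1."""
    from neurofuse.nn import Tensor, clip_grad_norm
    params = [Tensor(np.zeros((4, 4)), requires_grad=True)]
    params[0].grad = np.full((4, 4), 1e6)
    clip_grad_norm(params, 1.0)
    assert np.sqrt((params[0].grad ** 2).sum()) <= 1.0 + 1e-6


def test_empty_schedule_rejected(desk_cfg, small_cohort):
    feats, stats, plan, cfg = prepare_data(small_cohort, 128.0, seed=0,
                                           cfg=desk_cfg)
    model = TriModalClassifier(stats.snp_dim, stats.eeg_features,
                               cfg=cfg.model)
    with pytest.raises(ValueError, match="schedule"):
        train_model(model, feats, feats, TrainConfig(schedule=[]))


# -- aggregation -------------------------------------------------------------


def test_subject_aggregation_rules():
    probs = np.array([[1.0, 0.0, 0.0],
                      [0.0, 1.0, 0.0],
                      [0.2, 0.3, 0.5]])
    agg = aggregate_subject_predictions(probs, ["a", "a", "b"])
    np.testing.assert_allclose(agg[list(CLASSES)].loc["a"].to_numpy(dtype=float),
                               [0.5, 0.5, 0.0])
    assert agg.loc["a", "prediction"] == "AD"   # tie broken by class order
    assert agg.loc["b", "prediction"] == "HC"
    single = aggregate_subject_predictions(probs[:1], ["x"])
    np.testing.assert_array_equal(
        single[list(CLASSES)].loc["x"].to_numpy(dtype=float), probs[0])
    with pytest.raises(ValueError):
        aggregate_subject_predictions(np.empty((0, 3)), [])


def test_three_sample_mean_by_hand(rng):
    p = rng.dirichlet(np.ones(3), size=3)
    agg = aggregate_subject_predictions(p, ["s", "s", "s"])
    np.testing.assert_allclose(agg[list(CLASSES)].loc["s"].to_numpy(dtype=float),
                               p.mean(axis=0))


# -- metrics -----------------------------------------------------------------


def test_perfect_predictions_metrics():
    y = [CLASSES[i % 3] for i in range(30)]
    proba = np.zeros((30, 3))
    for i, label in enumerate(y):
        proba[i, CLASSES.index(label)] = 1.0
    rep = compute_metrics(y, proba)
    assert rep.accuracy == 1.0
    assert np.all(np.diag(rep.confusion) == 10)
    assert rep.confusion.sum() == 30
    assert (rep.per_class["f1"] == 1.0).all()


def test_binary_reduction_counts_match_closed_form():
    """Confusion [[8,2],[1,9]] mapped into the AD-vs-PD corner."""
    y, proba = [], []
    for truth, pred, n in (("AD", "AD", 8), ("AD", "PD", 2),
                           ("PD", "AD", 1), ("PD", "PD", 9)):
        for _ in range(n):
            y.append(truth)
            p = np.full(3, 0.0)
            p[CLASSES.index(pred)] = 1.0
            proba.append(p)
    rep = compute_metrics(y, np.array(proba))
    assert rep.per_class.loc["AD", "sensitivity"] == pytest.approx(0.8)
    sens, prec = 8 / 10, 8 / 9
    assert rep.per_class.loc["AD", "f1"] == pytest.approx(
        2 * prec * sens / (prec + sens))
    assert rep.per_class.loc["PD", "sensitivity"] == pytest.approx(0.9)


def test_metrics_match_exhaustive_counting_oracle(rng):
    """Sens/spec/NPV against brute-force counting on random small inputs."""
    for _ in range(25):
        n = int(rng.integers(6, 20))
        y = rng.integers(0, 3, size=n)
        proba = rng.dirichlet(np.ones(3), size=n)
        rep = compute_metrics(y, proba)
        pred = proba.argmax(axis=1)
        for c in range(3):
            tp = sum(1 for t, p in zip(y, pred) if t == c and p == c)
            fn = sum(1 for t, p in zip(y, pred) if t == c and p != c)
            fp = sum(1 for t, p in zip(y, pred) if t != c and p == c)
            tn = n - tp - fn - fp
            row = rep.per_class.iloc[c]
            if tp + fn:
                assert row["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert row["specificity"] == pytest.approx(tn / (tn + fp))
            if tn + fn:
                assert row["npv"] == pytest.approx(tn / (tn + fn))


def test_random_predictions_have_chance_auroc(rng):
    n = 600
    y = rng.integers(0, 3, size=n)
    proba = rng.dirichlet(np.ones(3), size=n)
    rep = compute_metrics(y, proba)
    assert abs(rep.macro["auroc"] - 0.5) < 0.07


def test_metrics_reject_unnormalised_probabilities():
    with pytest.raises(ValueError, match="sum"):
        compute_metrics(["AD"], np.array([[0.5, 0.2, 0.1]]))


# -- statistical tests -------------------------------------------------------


def test_mcnemar_closed_forms():
    # b = c = 10: continuity-corrected statistic (|0|-1)^2/20 = 0.05
    a = np.array([True] * 10 + [False] * 10 + [True] * 30)
    b = np.array([False] * 10 + [True] * 10 + [True] * 30)
    stat, p = mcnemar_test(a, b)
    assert stat == pytest.approx(0.05)
    assert p > 0.8
    # b=10, c=2 -> chi2 = 49/12, but with 12 discordant pairs the exact
    # binomial applies
    a2 = np.array([True] * 10 + [False] * 2 + [True] * 20)
    b2 = np.array([False] * 10 + [True] * 2 + [True] * 20)
    stat2, p2 = mcnemar_test(a2, b2)
    assert stat2 == pytest.approx(49 / 12)
    assert p2 < 0.05


def test_mcnemar_chi2_branch_and_degenerate():
    from scipy import stats as sp_stats
    a = np.array([True] * 20 + [False] * 10 + [True] * 10)
    b = np.array([False] * 20 + [True] * 10 + [True] * 10)
    stat, p = mcnemar_test(a, b)   # 30 discordant pairs -> chi-square
    assert p == pytest.approx(float(sp_stats.chi2.sf(stat, 1)))
    with pytest.warns(UserWarning):
        stat0, p0 = mcnemar_test(np.array([True, False]),
                                 np.array([True, False]))
    assert p0 == 1.0


def test_paired_t_closed_form_and_symmetry():
    diffs = np.array([0.02, 0.03, 0.01, 0.02, 0.02])
    base = np.full(5, 0.8)
    t, p = paired_t_test(base + diffs, base)
    expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
    assert t == pytest.approx(expected_t, abs=1e-9)
    t2, p2 = paired_t_test(base, base + diffs)
    assert t2 == pytest.approx(-t) and p2 == pytest.approx(p)
    with pytest.warns(UserWarning):
        t3, p3 = paired_t_test(base, base)
    assert p3 == 1.0


# -- experiment harness ------------------------------------------------------


def test_run_ablation_bookkeeping(desk_cfg):
    spec = CohortSpec(n_subjects=24, volume_shape=(8, 8, 8), n_channels=2,
                      n_timesteps=512, n_snps=20, frac_complete=1.0, seed=9)
    cohort = generate_cohort(spec)
    table = run_ablation(cohort, spec.sample_rate,
                         configurations=[("snp+mri+eeg", True),
                                         ("snp", False)],
                         seed=0, cfg=desk_cfg)
    assert list(table.columns[:3]) == ["tag", "modalities", "attention"]
    assert (table["tag"] == "snp+mri+eeg/attention").sum() == 1
    assert table["accuracy"].is_monotonic_decreasing
    with pytest.raises(ValueError, match="empty"):
        run_ablation(cohort, spec.sample_rate, configurations=[], seed=0)
    with pytest.raises(ValueError, match="unknown"):
        run_ablation(cohort, spec.sample_rate,
                     configurations=[("pet", True)], seed=0)


def test_run_experiment_returns_consistent_report(desk_cfg):
    spec = CohortSpec(n_subjects=24, volume_shape=(8, 8, 8), n_channels=2,
                      n_timesteps=512, n_snps=20, frac_complete=1.0, seed=8)
    cohort = generate_cohort(spec)
    res = run_experiment(cohort, spec.sample_rate, seed=0, cfg=desk_cfg,
                         mc_passes=5)
    agg = res["subjects"]
    assert res["metrics"].confusion.sum() == len(agg)
    assert set(agg["prediction"]) <= set(CLASSES)
    assert (agg["u_final"] >= 0).all()
    np.testing.assert_allclose(agg["u_final"],
                               agg["epistemic"] + agg["aleatoric"],
                               atol=1e-12)
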