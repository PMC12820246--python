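"""MC-dropout identities, calibration, and composite-loss reduction cases."""

import numpy as np
import pytest

from neurofuse.config import LossConfig, MCConfig, ModelConfig
from neurofuse.model import TriModalClassifier
from neurofuse.uncertainty import (calibrated_softmax, cross_entropy,
                                   decompose_uncertainty, fit_temperature,
                                   focal_loss, mc_predict, total_loss)


def tiny_model(dropout=0.3, seed=0):
    cfg = ModelConfig(fusion_dim=8, d_k=4, snp_embed_dim=16,
                      snp_token_width=8, lstm_hidden=4, cnn_filters=(2,),
                      cnn_kernel=3, fc_units=8, dropout=dropout,
                      modality_dropout=0.0)
    return TriModalClassifier(snp_dim=6, eeg_features=8, cfg=cfg, seed=seed)


def tiny_batch(rng, n=4):
    return {"snp": rng.random((n, 6)),
            "mri": rng.random((n, 1, 6, 6, 6)),
            "eeg": rng.random((n, 3, 8)),
            "mask": np.ones((n, 3))}


# -- decomposition identities ------------------------------------------------


def test_two_sample_decomposition_by_hand():
    samples = np.array([[1.0, 0.0], [0.0, 1.0]])
    epi, ale, total = decompose_uncertainty(samples)
    assert epi == pytest.approx(0.25)     # class-mean of (0.25, 0.25)
    assert ale == pytest.approx(0.0)
    assert total == pytest.approx(0.25)


def test_certain_one_hot_samples_have_zero_uncertainty():
    samples = np.tile([1.0, 0.0, 0.0], (5, 1))
    epi, ale, total = decompose_uncertainty(samples)
    assert epi == ale == total == 0.0


def test_uniform_samples_are_purely_aleatoric():
    samples = np.tile([1 / 3, 1 / 3, 1 / 3], (7, 1))
    epi, ale, total = decompose_uncertainty(samples)
    assert epi == pytest.approx(0.0)
    assert ale == pytest.approx(2 / 3)     # 3 * (1/3)(2/3)
    assert total == pytest.approx(2 / 3)


def test_single_sample_variance_is_zero(rng):
    p = rng.dirichlet(np.ones(3))
    epi, ale, total = decompose_uncertainty(p[None, :])
    assert epi == 0.0
    assert total == pytest.approx(ale)


def test_additive_identity_always_holds(rng):
    samples = rng.dirichlet(np.ones(4), size=(20, 6))   # (T, n, C)
    epi, ale, total = decompose_uncertainty(samples)
    np.testing.assert_allclose(total, epi + ale)       # exact identity
    assert (epi >= 0).all() and (ale >= 0).all()


def test_non_probability_samples_rejected():
    with pytest.raises(ValueError):
        decompose_uncertainty(np.array([[0.9, 0.3]]))


# -- MC prediction -----------------------------------------------------------


def test_zero_dropout_collapses_posterior(rng):
    model = tiny_model(dropout=0.0)
    batch = tiny_batch(rng)
    est = mc_predict(model, batch, MCConfig(num_passes=5, seed=3))
    np.testing.assert_array_equal(est.variance, 0.0)
    np.testing.assert_array_equal(est.epistemic, 0.0)
    model.eval()
    ref = calibrated_softmax(model(batch).data)
    np.testing.assert_allclose(est.mean, ref)


def test_mc_predict_is_replayable_and_stochastic(rng):
    model = tiny_model(dropout=0.5)
    batch = tiny_batch(rng)
    est1 = mc_predict(model, batch, MCConfig(num_passes=6, seed=9))
    est2 = mc_predict(model, batch, MCConfig(num_passes=6, seed=9))
    np.testing.assert_array_equal(est1.samples, est2.samples)
    assert est1.epistemic.max() > 0      # dropout produces spread
    np.testing.assert_allclose(est1.mean.sum(axis=1), 1.0, atol=1e-9)


def test_mc_mean_stabilises_with_more_passes(rng):
    """The posterior-mean estimator concentrates ~ 1/sqrt(T)."""
    model = tiny_model(dropout=0.5)
    batch = tiny_batch(rng, n=2)
    small = mc_predict(model, batch, MCConfig(num_passes=30, seed=1))
    large = mc_predict(model, batch, MCConfig(num_passes=300, seed=2))
    se = np.sqrt(large.variance.mean(axis=1) / 30).reshape(-1, 1)
    assert np.all(np.abs(small.mean - large.mean) <= 3 * se + 1e-6)


def test_zero_passes_rejected():
    with pytest.raises(ValueError):
        MCConfig(num_passes=0)


# -- calibrated softmax ------------------------------------------------------


def test_softmax_symmetry_and_closed_form():
    np.testing.assert_allclose(calibrated_softmax([0.0, 0.0, 0.0], 7.0),
                               np.full(3, 1 / 3))
    np.testing.assert_allclose(calibrated_softmax([np.log(2), 0.0], 1.0),
                               [2 / 3, 1 / 3])
    # T = 1000 on logits (5,0,0): exact max deviation from uniform is
    # (e^0.005 - 1) * 2/(3 (2 + e^0.005)) ~ 1.11e-3; ~uniform within 2e-3
    near_uniform = calibrated_softmax([5.0, 0.0, 0.0], 1000.0)
    np.testing.assert_allclose(near_uniform, 1 / 3, atol=2e-3)
    exact = calibrated_softmax([5.0, 0.0, 0.0], 10000.0)
    np.testing.assert_allclose(exact, 1 / 3, atol=2e-4)
    with pytest.raises(ValueError):
        calibrated_softmax([1.0], 0.0)


def test_temperature_recovered_from_simulated_logits(rng):
    """Calibrated logits -> T ~ 1; doubled logits -> T ~ 2."""
    n = 20000
    probs = rng.dirichlet((4, 4, 4), size=n)
    labels = (rng.random(n)[:, None] > probs.cumsum(axis=1)).sum(axis=1)
    logits = np.log(probs)
    assert fit_temperature(logits, labels) == pytest.approx(1.0, abs=0.05)
    assert fit_temperature(2 * logits, labels) == pytest.approx(2.0, abs=0.1)


def test_fitted_temperature_never_hurts_nll(rng):
    from neurofuse.uncertainty import _nll
    for trial in range(5):
        logits = rng.normal(size=(50, 3)) * (trial + 1)
        labels = rng.integers(0, 3, size=50)
        t = fit_temperature(logits, labels)
        assert _nll(logits, labels, t) <= _nll(logits, labels, 1.0) + 1e-12
    with pytest.raises(ValueError):
        fit_temperature(rng.normal(size=(10, 3)), np.zeros(10, dtype=int))


# -- losses ------------------------------------------------------------------


def test_cross_entropy_closed_forms():
    assert cross_entropy([1.0, 0.0, 0.0], 0) == pytest.approx(0.0, abs=1e-9)
    assert cross_entropy([1 / 3] * 3, 1) == pytest.approx(np.log(3), abs=1e-9)
    assert cross_entropy([0.5, 0.25, 0.25], 0) == pytest.approx(np.log(2),
                                                                abs=1e-9)
    with pytest.raises(ValueError):
        cross_entropy([0.5, 0.5], np.array([[1, 1]]))


def test_focal_reduces_to_cross_entropy_at_gamma_zero(rng):
    for _ in range(100):
        p = rng.dirichlet(np.ones(3))
        y = int(rng.integers(0, 3))
        assert focal_loss(p, y, gamma=0.0) == pytest.approx(
            cross_entropy(p, y), abs=1e-9)


def test_focal_closed_form_and_monotonicity():
    assert focal_loss([1.0, 0.0], 0, gamma=3.0) == pytest.approx(0.0,
                                                                 abs=1e-9)
    assert focal_loss([0.5, 0.5], 0, gamma=2.0) == pytest.approx(
        0.25 * np.log(2), abs=1e-9)
    vals = [focal_loss([p, 1 - p], 0, gamma=2.0)
            for p in np.linspace(0.05, 0.95, 10)]
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        focal_loss([0.5, 0.5], 0, gamma=-1.0)


def test_total_loss_reduces_to_cross_entropy(rng):
    model = tiny_model(dropout=0.0)
    batch = tiny_batch(rng)
    labels = np.array([0, 1, 2, 0])
    cfg = LossConfig(lam=0, alpha=0, kl_coeff=0, uncertainty_weight=0,
                     focal_weight=0)
    terms = total_loss(model, batch, labels, cfg, MCConfig(training_passes=3))
    model.eval()
    probs = calibrated_softmax(model(batch).data)
    assert terms.total == pytest.approx(cross_entropy_rows(probs, labels),
                                        abs=1e-9)
    assert terms.uncertainty == 0.0
    assert terms.l2 == terms.l1 == terms.kl == terms.focal == 0.0


def cross_entropy_rows(probs, labels):
    return float(np.mean([cross_entropy(p, int(y))
                          for p, y in zip(probs, labels)]))


def test_total_loss_terms_nonnegative_and_additive(rng):
    model = tiny_model(dropout=0.4)
    batch = tiny_batch(rng)
    labels = np.array([0, 1, 2, 1])
    cfg = LossConfig()
    terms = total_loss(model, batch, labels, cfg, MCConfig(), pass_seed=5)
    d = terms.as_dict()
    assert all(v >= 0 for v in d.values())
    assert terms.total == pytest.approx(
        d["ce"] + d["uncertainty"] + d["l2"] + d["l1"] + d["kl"] + d["focal"],
        abs=1e-9)
    assert terms.total >= terms.ce
    # zeroing one coefficient removes exactly that term
    cfg2 = LossConfig(alpha=0.0)
    terms2 = total_loss(model, batch, labels, cfg2, MCConfig(), pass_seed=5)
    assert terms2.total == pytest.approx(terms.total - terms.l1, abs=1e-9)


def test_total_loss_zero_weights_kill_penalties(rng):
    model = tiny_model(dropout=0.0)
    for p in model.parameters():
        p.data[:] = 0.0
    terms = total_loss(model, tiny_batch(rng), np.array([0, 1, 2, 0]),
                       LossConfig(), MCConfig())
    assert terms.l2 == terms.l1 == terms.kl == 0.0


def test_l2_coefficient_single_weight(rng):
    """lambda = 0.1 on a lone weight of 2 contributes 0.1 * 2^2 = 0.4."""
    model = tiny_model(dropout=0.0)
    for p in model.parameters():
        p.data[:] = 0.0
    model.head.classify.W.data[0, 0] = 2.0
    cfg = LossConfig(lam=0.1, alpha=0, kl_coeff=0, uncertainty_weight=0,
                     focal_weight=0)
    terms = total_loss(model, tiny_batch(rng), np.array([0, 1, 2, 0]),
                       cfg, MCConfig())
    assert terms.l2 == pytest.approx(0.4, abs=1e-9)


def test_negative_coefficient_rejected(rng):
    model = tiny_model()
    with pytest.raises(ValueError):
        total_loss(model, tiny_batch(rng), np.array([0, 1, 2, 0]),
                   LossConfig(lam=-1.0), MCConfig())
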