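"""Estimator contracts: null model, evaluation metric, leakage guard,
determinism, persistence, and the Double composition."""

import numpy as np
import pytest

from qtst.dataset_builder import QDatasetRow
from qtst.errors import LeakageError, ValidationError
from qtst.estimators import (
    EstimatorBundle,
    NetworkSpec,
    evaluate,
    fit_null_model,
    predict_double,
    predict_qest,
    predict_qests,
    train_qest,
    train_qests,
)

TINY = NetworkSpec(hidden_layers=(16,), max_iter=60, seed=0)


def _rows(inv_t, log_q, rid="r0"):
    return [
        QDatasetRow(structure_id=f"s{i}", reaction_id=rid, role="reactant",
                    inverse_temperature=it, log_q=q)
        for i, (it, q) in enumerate(zip(inv_t, log_q))
    ]


class TestNullModel:
    def test_exact_recovery_noiseless(self):
        inv_t = np.linspace(1 / 2000, 1 / 50, 100)
        rows = _rows(inv_t, 5000.0 * inv_t + 3.0)
        model = fit_null_model(rows)
        assert model.slope == pytest.approx(5000.0, abs=1e-8)
        assert model.intercept == pytest.approx(3.0, abs=1e-8)

    def test_constant_targets(self):
        inv_t = np.linspace(1 / 2000, 1 / 50, 50)
        model = fit_null_model(_rows(inv_t, np.full_like(inv_t, 7.5)))
        assert model.slope == pytest.approx(0.0, abs=1e-8)
        assert model.intercept == pytest.approx(7.5, abs=1e-10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError):
            fit_null_model(_rows([0.01, 0.01], [1.0, 2.0]))


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate([1.0, 2.0], [1.0, 2.0])
        assert rep.mae == 0.0
        assert rep.mae_pct_of_std == 0.0

    def test_mean_predictor_folded_normal(self, rng):
        truths = rng.standard_normal(200_000)
        rep = evaluate(np.zeros_like(truths), truths)
        assert rep.mae_pct_of_std == pytest.approx(100.0 * np.sqrt(2 / np.pi), abs=1.0)

    def test_binned_maes_recombine_to_overall(self, rng):
        n = 5000
        preds = rng.normal(size=n)
        truths = rng.normal(size=n)
        inv_t = rng.uniform(1 / 2000, 1 / 50, n)
        rep = evaluate(preds, truths, inv_t, n_bins=10)
        weighted = sum(mae * cnt for _, _, mae, cnt in rep.per_bin) / n
        assert weighted == pytest.approx(rep.mae, rel=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            evaluate([], [])


class TestLeakageGuard:
    def test_test_rows_abort_qest_training(self, planted_setup):
        split = planted_setup["split"]
        leaked = [r for r in planted_setup["rows"]][:50]  # includes dev rows
        leaked += [r for r in planted_setup["rows"] if r.reaction_id in split.test_ids][:1]
        with pytest.raises(LeakageError):
            train_qest(planted_setup["structures"], leaked, split, planted_setup["fcfg"], TINY)

    def test_test_rows_abort_qests_training(self, planted_setup):
        split = planted_setup["split"]
        rows = [r for r in planted_setup["rows"] if r.reaction_id in split.test_ids][:10]
        with pytest.raises(LeakageError):
            train_qests(planted_setup["reactions"], rows, split, planted_setup["fcfg"], TINY)


@pytest.fixture(scope="module")
def tiny_trained(planted_setup):
    """A deliberately small Qest/QesTS pair for contract tests."""
    split = planted_setup["split"]
    dev = [r for r in planted_setup["rows"] if r.reaction_id not in split.test_ids]
    dev_small = dev[: len(dev) // 4]
    qest = train_qest(planted_setup["structures"], dev_small, split, planted_setup["fcfg"], TINY)
    qests = train_qests(planted_setup["reactions"], dev_small, split, planted_setup["fcfg"], TINY)
    return qest, qests


class TestPredictionContracts:
    def test_inference_deterministic(self, tiny_trained, planted_setup):
        qest, _ = tiny_trained
        s = planted_setup["reactions"][0].reactant
        assert predict_qest(qest, s, 300.0) == predict_qest(qest, s, 300.0)

    def test_prediction_smooth_in_temperature(self, tiny_trained, planted_setup):
        qest, _ = tiny_trained
        s = planted_setup["reactions"][0].reactant
        a = predict_qest(qest, s, 300.0)
        b = predict_qest(qest, s, 300.3)
        assert abs(a - b) < 1.0

    def test_training_seed_deterministic(self, planted_setup):
        split = planted_setup["split"]
        dev = [r for r in planted_setup["rows"] if r.reaction_id not in split.test_ids][:400]
        b1 = train_qest(planted_setup["structures"], dev, split, planted_setup["fcfg"], TINY)
        b2 = train_qest(planted_setup["structures"], dev, split, planted_setup["fcfg"], TINY)
        s = planted_setup["reactions"][0].reactant
        assert predict_qest(b1, s, 500.0) == predict_qest(b2, s, 500.0)

    def test_bundle_save_load_identical_predictions(self, tiny_trained, planted_setup, tmp_path):
        qest, _ = tiny_trained
        qest.save(tmp_path / "bundle")
        loaded = EstimatorBundle.load(tmp_path / "bundle")
        s = planted_setup["reactions"][1].reactant
        for t in (100.0, 700.0, 1900.0):
            assert predict_qest(loaded, s, t) == pytest.approx(predict_qest(qest, s, t), abs=1e-10)

    def test_wrong_bundle_kind_rejected(self, tiny_trained, planted_setup):
        qest, qests = tiny_trained
        r = planted_setup["reactions"][0]
        with pytest.raises(ValidationError):
            predict_qest(qests, r.reactant, 300.0)
        with pytest.raises(ValidationError):
            predict_qests(qest, r.reactant, r.product, 1.0, 1.0, 300.0)

    def test_double_composes_qest_into_qests(self, tiny_trained, planted_setup):
        """Double == QesTS fed with Qest's own reactant/product predictions."""
        qest, qests = tiny_trained
        r = planted_setup["reactions"][0]
        t = 400.0
        lq_r = predict_qest(qest, r.reactant, t)
        lq_p = predict_qest(qest, r.product, t)
        manual = predict_qests(qests, r.reactant, r.product, lq_r, lq_p, t)
        assert predict_double(qest, qests, r.reactant, r.product, t) == pytest.approx(manual, abs=1e-12)

    def test_double_needs_no_transition_state(self, tiny_trained, planted_setup):
        """The Double interface touches only reactant and product objects."""
        import inspect

        sig = inspect.signature(predict_double)
        assert "ts" not in sig.parameters
        assert {"reactant", "product"} <= set(sig.parameters)
        qest, qests = tiny_trained
        r = planted_setup["reactions"][2]
        value = predict_double(qest, qests, r.reactant, r.product, 600.0)
        assert np.isfinite(value)

    def test_qests_with_identical_reactant_product(self, tiny_trained, planted_setup):
        """Zero difference vector: prediction depends only on (lnQ_R, lnQ_P, 1/T)."""
        _, qests = tiny_trained
        r = planted_setup["reactions"][0]
        a = predict_qests(qests, r.reactant, r.reactant, 10.0, 10.0, 500.0)
        b = predict_qests(qests, r.product, r.product, 10.0, 10.0, 500.0)
        assert a == pytest.approx(b, abs=1e-9)
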