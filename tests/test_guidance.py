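"""Triage classifiers: recurrence arithmetic, metrics, padding, cross-validation."""

import numpy as np
import pytest

from medtriage._nn import LSTMState, LSTMWeights, sigmoid
from medtriage.guidance import (
    ClassifierConfig,
    ConfusionMatrix,
    compute_max_len,
    confusion_matrix_from_predictions,
    cross_validate,
    evaluate_classifier,
    lstm_step,
    metrics_from_confusion,
    pad_or_truncate,
    train_classifier,
)
from medtriage.preprocess import TokenizedDocument


def _doc(doc_id, tokens):
    return TokenizedDocument(doc_id, tuple(tokens), len(tokens))


# ---------------------------------------------------------------------------
# LSTM recurrence


def _lstm_step_oracle(x, h_prev, c_prev, W, b):
    """Scalar-loop recomputation of the gate equations, independent of the
    vectorized implementation."""
    H = len(h_prev)
    hx = list(h_prev) + list(x)
    z = [sum(hx[j] * W[j][k] for j in range(len(hx))) + b[k] for k in range(4 * H)]
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    g = [sig(z[k]) for k in range(H)]
    i = [sig(z[H + k]) for k in range(H)]
    ct = [np.tanh(z[2 * H + k]) for k in range(H)]
    c = [g[k] * c_prev[k] + i[k] * ct[k] for k in range(H)]
    o = [sig(z[3 * H + k]) for k in range(H)]
    h = [o[k] * np.tanh(c[k]) for k in range(H)]
    return np.array(h), np.array(c)


class TestLSTMStep:
    def test_zero_weights_closed_form(self):
        # all gates sigmoid(0)=0.5 and candidate tanh(0)=0, so c = 0.5*c_prev
        # and h = 0.5*tanh(0.5*c_prev)
        H, D = 4, 3
        w = LSTMWeights(W=np.zeros((H + D, 4 * H)), b=np.zeros(4 * H))
        c_prev = np.array([0.2, -0.4, 1.0, 0.0])
        out = lstm_step(np.ones(D), LSTMState(h=np.zeros(H), c=c_prev), w)
        np.testing.assert_allclose(out.c, 0.5 * c_prev, atol=1e-15)
        np.testing.assert_allclose(out.h, 0.5 * np.tanh(0.5 * c_prev), atol=1e-15)

    def test_all_zero_input_gives_zero_hidden(self):
        H, D = 3, 2
        w = LSTMWeights(W=np.zeros((H + D, 4 * H)), b=np.zeros(4 * H))
        out = lstm_step(np.zeros(D), LSTMState(h=np.zeros(H), c=np.zeros(H)), w)
        np.testing.assert_array_equal(out.h, np.zeros(H))

    def test_matches_equation_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            H, D = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            W = rng.normal(scale=0.5, size=(H + D, 4 * H))
            b = rng.normal(scale=0.5, size=4 * H)
            x = rng.normal(size=D)
            h_prev, c_prev = rng.normal(size=H), rng.normal(size=H)
            out = lstm_step(x, LSTMState(h=h_prev, c=c_prev), LSTMWeights(W, b))
            h_exp, c_exp = _lstm_step_oracle(x, h_prev, c_prev, W, b)
            np.testing.assert_allclose(out.h, h_exp, atol=1e-10)
            np.testing.assert_allclose(out.c, c_exp, atol=1e-10)

    def test_shape_mismatch_errors(self):
        w = LSTMWeights(W=np.zeros((5, 12)), b=np.zeros(12))
        with pytest.raises(ValueError):
            lstm_step(np.zeros(4), LSTMState(h=np.zeros(3), c=np.zeros(3)), w)


class TestBackpropGradients:
    """Analytic gradients match central differences on tie-free fixtures."""

    @pytest.mark.parametrize("net_kind", ["lstm", "textcnn"])
    def test_gradient_check(self, net_kind):
        from medtriage._nn import LSTMClassifier, TextCNNClassifier

        rng = np.random.default_rng(5)
        V, d, T, B, K = 30, 4, 6, 4, 3
        E = np.vstack([np.zeros(d), rng.normal(size=(V - 1, d))])
        # distinct tokens per row -> no duplicated conv windows (no pool ties)
        X = np.array([rng.permutation(np.arange(1, V))[:T] for _ in range(B)])
        X[0, 4:] = 0
        y = rng.integers(0, K, size=B)
        if net_kind == "lstm":
            net = LSTMClassifier(E, K, units=5, dense_units=6, dropout=0.0, seed=1)
        else:
            net = TextCNNClassifier(E, K, filter_size=2, n_filters=5,
                                    dense_units=6, dropout=0.0, seed=1)

        def loss():
            probs, _ = net._forward(X, train=False)
            return -np.mean(np.log(probs[np.arange(B), y] + 1e-12))

        probs, cache = net._forward(X, train=False)
        dlog = probs.copy()
        dlog[np.arange(B), y] -= 1
        dlog /= B
        grads = net._backward(dlog, cache)
        eps = 1e-6
        for p, g in zip(net.params(), grads):
            flat_idx = rng.integers(0, p.size, size=3)
            for fi in flat_idx:
                idx = np.unravel_index(fi, p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(num, abs=1e-6, rel=1e-4)


# ---------------------------------------------------------------------------
# Sequence preparation


class TestComputeMaxLen:
    def test_uniform_1_to_100_gives_75(self):
        docs = [_doc(str(i), ["t"] * i) for i in range(1, 101)]
        assert compute_max_len(docs) == 75

    def test_constant_lengths(self):
        docs = [_doc(str(i), ["t"] * 7) for i in range(10)]
        assert compute_max_len(docs) == 7

    def test_empty_doc_list_errors(self):
        with pytest.raises(ValueError):
            compute_max_len([])


class TestPadOrTruncate:
    INDEX = {f"t{i}": i for i in range(10)}  # token t_i -> stored index i+1

    def test_short_doc_post_padded(self):
        seq = pad_or_truncate(_doc("d", ["t0", "t1", "t2"]), 5, self.INDEX)
        np.testing.assert_array_equal(seq, [1, 2, 3, 0, 0])

    def test_long_doc_truncated_at_tail(self):
        seq = pad_or_truncate(_doc("d", [f"t{i}" for i in range(7)]), 5, self.INDEX)
        np.testing.assert_array_equal(seq, [1, 2, 3, 4, 5])

    def test_empty_doc_all_pad(self):
        np.testing.assert_array_equal(pad_or_truncate(_doc("d", []), 4, self.INDEX),
                                      [0, 0, 0, 0])


# ---------------------------------------------------------------------------
# Metrics


def _metrics_oracle(y_true, y_pred):
    """Brute-force counting of per-class one-vs-rest precision/recall/F1."""
    out = {}
    for cls in sorted(set(y_true)):
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        out[cls] = (prec, rec, f1)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / len(y_true)
    return out, acc


class TestMetrics:
    def test_binary_8_2_2_8_case(self):
        # one-vs-rest counts TP=8, FP=2, FN=2, TN=8 for class "pos"
        y_true = ["pos"] * 10 + ["neg"] * 10
        y_pred = ["pos"] * 8 + ["neg"] * 2 + ["pos"] * 2 + ["neg"] * 8
        cm = confusion_matrix_from_predictions(y_true, y_pred)
        rep = metrics_from_confusion(cm)
        pc = rep.per_class["pos"]
        assert pc["precision"] == pytest.approx(0.8)
        assert pc["recall"] == pytest.approx(0.8)
        assert pc["f1"] == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.8)

    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a", "b", "c"]
        cm = confusion_matrix_from_predictions(y, y)
        assert np.array_equal(cm.counts, np.diag([2, 2, 2]))
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0

    def test_random_three_class_matches_counting_oracle(self):
        rng = np.random.default_rng(9)
        classes = ["a", "b", "c"]
        y_true = [classes[i] for i in rng.integers(0, 3, size=200)]
        y_pred = [classes[i] for i in rng.integers(0, 3, size=200)]
        cm = confusion_matrix_from_predictions(y_true, y_pred)
        rep = metrics_from_confusion(cm)
        oracle, acc = _metrics_oracle(y_true, y_pred)
        for cls, (p, r, f1) in oracle.items():
            assert rep.per_class[cls]["precision"] == pytest.approx(p)
            assert rep.per_class[cls]["recall"] == pytest.approx(r)
            assert rep.per_class[cls]["f1"] == pytest.approx(f1)
        assert rep.accuracy == pytest.approx(acc)
        assert rep.macro_f1 == pytest.approx(
            np.mean([f for (_, _, f) in oracle.values()]))

    def test_accuracy_invariant_under_consistent_label_permutation(self):
        rng = np.random.default_rng(10)
        classes = ["a", "b", "c"]
        y_true = [classes[i] for i in rng.integers(0, 3, size=120)]
        y_pred = [classes[i] for i in rng.integers(0, 3, size=120)]
        perm = {"a": "c", "b": "a", "c": "b"}
        rep1 = metrics_from_confusion(confusion_matrix_from_predictions(y_true, y_pred))
        rep2 = metrics_from_confusion(confusion_matrix_from_predictions(
            [perm[t] for t in y_true], [perm[p] for p in y_pred]))
        assert rep1.accuracy == pytest.approx(rep2.accuracy)
        assert rep1.macro_f1 == pytest.approx(rep2.macro_f1)

    def test_absent_class_excluded_from_macro_with_nan(self, caplog):
        cm = confusion_matrix_from_predictions(["a", "a"], ["a", "b"],
                                               labels=["a", "b", "ghost"])
        with caplog.at_level("WARNING"):
            rep = metrics_from_confusion(cm)
        assert np.isnan(rep.per_class["ghost"]["precision"])
        assert not np.isnan(rep.macro_precision)

    def test_confusion_matrix_row_normalization(self):
        cm = ConfusionMatrix(labels=["a", "b"], counts=np.array([[3, 1], [0, 0]]))
        norm = cm.normalized()
        np.testing.assert_allclose(norm[0], [0.75, 0.25])
        np.testing.assert_array_equal(norm[1], [0.0, 0.0])


# ---------------------------------------------------------------------------
# Training protocols


class TestTrainClassifier:
    def test_knn_on_separated_vectors_fits_training_set(self, separated_corpus,
                                                        separated_model):
        _, docs, labels = separated_corpus
        cfg = ClassifierConfig(seed=0).scaled_down()
        clf = train_classifier("knn", docs[:200], labels[:200], separated_model, cfg)
        _, rep = evaluate_classifier(clf, docs[:200], labels[:200])
        assert rep.accuracy == 1.0

    def test_svm_accepts_study_hyperparameters(self, separated_corpus, separated_model):
        _, docs, labels = separated_corpus
        cfg = ClassifierConfig(seed=0, svm_C=0.3, svm_kernel="poly", svm_gamma=0.2)
        clf = train_classifier("svm", docs[:200], labels[:200], separated_model, cfg)
        svc = clf.inner.named_steps["svc"]
        assert (svc.C, svc.kernel, svc.gamma) == (0.3, "poly", 0.2)

    def test_unknown_kind_errors(self, separated_corpus, separated_model):
        _, docs, labels = separated_corpus
        with pytest.raises(ValueError):
            train_classifier("boost", docs[:50], labels[:50], separated_model)

    def test_single_class_errors(self, separated_corpus, separated_model):
        _, docs, _ = separated_corpus
        with pytest.raises(ValueError):
            train_classifier("knn", docs[:20], ["same"] * 20, separated_model)

    def test_lstm_trains_and_logs_history(self, separated_corpus, separated_model):
        _, docs, labels = separated_corpus
        cfg = ClassifierConfig(seed=0).scaled_down(epochs=2, max_len=15)
        clf = train_classifier("lstm", docs[:120], labels[:120], separated_model, cfg,
                               val_docs=docs[120:160], val_labels=labels[120:160])
        assert len(clf.history) == 2
        assert {"epoch", "train_loss", "train_accuracy", "val_loss",
                "val_accuracy"} <= set(clf.history[0])


class TestCrossValidate:
    def test_two_fold_average_matches_fold_reports(self, separated_corpus,
                                                   separated_model):
        _, docs, labels = separated_corpus
        from sklearn.model_selection import StratifiedKFold

        cfg = ClassifierConfig(seed=4)
        n = 80
        rep = cross_validate("knn", docs[:n], labels[:n], separated_model, cfg,
                             folds=2, repeats=1)
        # recompute the two fold accuracies independently
        skf = StratifiedKFold(n_splits=2, shuffle=True, random_state=4000)
        accs = []
        for tr, te in skf.split(np.zeros(n), labels[:n]):
            clf = train_classifier("knn", [docs[i] for i in tr],
                                   [labels[i] for i in tr], separated_model, cfg)
            _, r = evaluate_classifier(clf, [docs[i] for i in te],
                                       [labels[i] for i in te])
            accs.append(r.accuracy)
        assert rep.accuracy == pytest.approx(np.mean(accs))

    def test_repeats_with_same_seed_are_deterministic(self, separated_corpus,
                                                      separated_model):
        _, docs, labels = separated_corpus
        cfg = ClassifierConfig(seed=4)
        r1 = cross_validate("knn", docs[:80], labels[:80], separated_model, cfg,
                            folds=2, repeats=2)
        r2 = cross_validate("knn", docs[:80], labels[:80], separated_model, cfg,
                            folds=2, repeats=2)
        assert r1.accuracy == r2.accuracy
        assert r1.macro_f1 == r2.macro_f1

    def test_too_small_class_for_folds_errors(self, separated_corpus, separated_model):
        _, docs, labels = separated_corpus
        with pytest.raises(ValueError, match="stratify"):
            cross_validate("knn", docs[:9], labels[:9], separated_model,
                           ClassifierConfig(seed=0), folds=9, repeats=1)

    def test_study_protocol_shape_accepted(self):
        # folds=10, repeats=5 is the reference protocol; validate the guardrails
        cfg = ClassifierConfig(seed=0)
        assert cfg.train_fraction == 0.7
        with pytest.raises(ValueError):
            ClassifierConfig(train_fraction=1.5)
        with pytest.raises(ValueError):
            ClassifierConfig(dropout=1.5)
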