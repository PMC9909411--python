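"""Department triage as multi-class classification of complaint text.

The headline model is an LSTM over frozen pre-trained embeddings; TextCNN,
random forest, KNN and SVM serve as baselines. The recurrent models consume
padded token-index matrices; the classical models consume mean document
vectors. Evaluation is the usual one-vs-rest confusion-matrix bookkeeping
with per-class and macro/micro precision, recall and F1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._nn import LSTMClassifier, LSTMState, LSTMWeights, TextCNNClassifier, lstm_step
from .embedding import EmbeddingModel, embed_document
from .preprocess import TokenizedDocument

logger = logging.getLogger(__name__)

ClassifierKind = Literal["lstm", "textcnn", "random_forest", "knn", "svm"]

__all__ = [
    "ClassifierConfig", "ConfusionMatrix", "MetricsReport", "FittedClassifier",
    "LSTMState", "LSTMWeights", "lstm_step", "compute_max_len", "pad_or_truncate",
    "train_classifier", "evaluate_classifier", "cross_validate",
]


@dataclass
class ClassifierConfig:
    """Hyperparameters for all five classifier kinds (defaults at study scale)."""

    max_len: int = 110
    embedding_dim: int = 256
    lstm_units: int = 256
    dense_units: int = 512
    cnn_filter_size: int = 2
    cnn_filter_num: int = 256
    cnn_layers: int = 1
    batch_size: int = 32
    epochs: int = 15
    dropout: float = 0.5
    learning_rate: float = 1e-2  # Adam step size for the lstm/textcnn trainers
    rf_n_estimators: int = 100
    knn_k: int = 5
    svm_C: float = 0.3
    svm_gamma: float = 0.2
    svm_kernel: str = "poly"
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must be in [0, 1]")

    def scaled_down(self, **overrides) -> "ClassifierConfig":
        """A small-corpus preset: dim 32, 32 units, 5 epochs."""
        base = replace(self, embedding_dim=32, lstm_units=32, dense_units=64,
                       cnn_filter_num=32, epochs=5)
        return replace(base, **overrides)


def compute_max_len(docs: Sequence[TokenizedDocument]) -> int:
    """Nearest-rank 75th percentile of the token-length distribution."""
    if not docs:
        raise ValueError("need at least one document")
    lengths = sorted(len(d.tokens) for d in docs)
    rank = math.ceil(0.75 * len(lengths))  # 1-indexed nearest rank
    return lengths[rank - 1]


def pad_or_truncate(doc: TokenizedDocument, max_len: int,
                    index: dict[str, int]) -> np.ndarray:
    """Map tokens to 1-based indices, truncate the tail, post-pad with 0."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    ids = [index[t] + 1 for t in doc.tokens if t in index][:max_len]
    out = np.zeros(max_len, dtype=np.int64)
    out[: len(ids)] = ids
    return out


def _padded_matrix(docs, model, max_len):
    return np.vstack([pad_or_truncate(d, max_len, model.index) for d in docs])


def _embedding_table(model: EmbeddingModel) -> np.ndarray:
    """Lookup table with a zero pad row prepended at index 0."""
    table = np.zeros((model.matrix.shape[0] + 1, model.dim))
    table[1:] = model.matrix.astype(np.float64)
    return table


def _mean_vectors(docs, model):
    return np.vstack([embed_document(d, model).vector for d in docs])


@dataclass
class ConfusionMatrix:
    """Square count matrix: rows are true classes, columns predictions."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        """Row-normalized matrix (rows with no samples stay zero)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sums > 0, self.counts / sums, 0.0)
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.counts, index=self.labels, columns=self.labels).to_csv(path)


@dataclass
class MetricsReport:
    """Per-class and averaged precision/recall/F1 plus overall accuracy.

    Classes absent from the test set get ``nan`` entries and are excluded
    from the macro averages.
    """

    labels: list[str]
    per_class: dict[str, dict[str, float]]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    accuracy: float

    def headline(self, averaging: Literal["macro", "micro"] = "macro") -> dict[str, float]:
        if averaging == "macro":
            return {"precision": self.macro_precision, "recall": self.macro_recall,
                    "f1": self.macro_f1, "accuracy": self.accuracy}
        return {"precision": self.micro_precision, "recall": self.micro_recall,
                "f1": self.micro_f1, "accuracy": self.accuracy}


def confusion_matrix_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str] | None = None
) -> ConfusionMatrix:
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    labels = list(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(labels=labels, counts=counts)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest TP/FP/FN per class; F1 is the harmonic mean of P and R."""
    counts = cm.counts
    tp = np.diag(counts).astype(float)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1)

    per_class: dict[str, dict[str, float]] = {}
    precs, recs, f1s = [], [], []
    for i, lab in enumerate(cm.labels):
        if support[i] == 0:
            logger.warning("class %r absent from test set; excluded from macro averages", lab)
            per_class[lab] = {"precision": float("nan"), "recall": float("nan"),
                              "f1": float("nan"), "support": 0}
            continue
        p = tp[i] / (tp[i] + fp[i]) if tp[i] + fp[i] > 0 else 0.0
        r = tp[i] / (tp[i] + fn[i]) if tp[i] + fn[i] > 0 else 0.0
        f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
        per_class[lab] = {"precision": p, "recall": r, "f1": f1, "support": int(support[i])}
        precs.append(p)
        recs.append(r)
        f1s.append(f1)

    total = counts.sum()
    micro_tp = tp.sum()
    micro_p = micro_tp / (micro_tp + fp.sum()) if total else 0.0
    micro_r = micro_tp / (micro_tp + fn.sum()) if total else 0.0
    micro_f1 = (2 * micro_p * micro_r / (micro_p + micro_r)) if micro_p + micro_r > 0 else 0.0
    return MetricsReport(
        labels=cm.labels,
        per_class=per_class,
        macro_precision=float(np.mean(precs)) if precs else 0.0,
        macro_recall=float(np.mean(recs)) if recs else 0.0,
        macro_f1=float(np.mean(f1s)) if f1s else 0.0,
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f1),
        accuracy=float(micro_tp / total) if total else 0.0,
    )


class FittedClassifier:
    """Uniform predict-on-documents wrapper around all five model kinds."""

    def __init__(self, kind: ClassifierKind, inner, model: EmbeddingModel,
                 config: ClassifierConfig, classes: list[str], max_len: int | None):
        self.kind = kind
        self.inner = inner
        self.model = model
        self.config = config
        self.classes = classes
        self.max_len = max_len

    @property
    def history(self) -> list[dict]:
        """Per-epoch train/validation loss and accuracy (neural kinds only)."""
        return getattr(self.inner, "history", [])

    def predict(self, docs: Sequence[TokenizedDocument]) -> list[str]:
        if self.kind in ("lstm", "textcnn"):
            X = _padded_matrix(docs, self.model, self.max_len)
            idx = self.inner.predict(X)
            return [self.classes[i] for i in idx]
        X = _mean_vectors(docs, self.model)
        return list(self.inner.predict(X))


def train_classifier(
    kind: ClassifierKind,
    docs: Sequence[TokenizedDocument],
    labels: Sequence[str],
    model: EmbeddingModel,
    config: ClassifierConfig | None = None,
    val_docs: Sequence[TokenizedDocument] | None = None,
    val_labels: Sequence[str] | None = None,
) -> FittedClassifier:
    """Fit one classifier kind on tokenized documents.

    lstm/textcnn consume padded index matrices over the frozen embedding;
    random_forest/knn/svm consume mean document vectors. Per-epoch loss and
    accuracy for the neural kinds are recorded on ``.history`` (and logged).
    """
    config = config or ClassifierConfig()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")

    if kind in ("lstm", "textcnn"):
        max_len = config.max_len
        X = _padded_matrix(docs, model, max_len)
        y = np.array([classes.index(l) for l in labels])
        table = _embedding_table(model)
        if kind == "lstm":
            net = LSTMClassifier(table, len(classes), units=config.lstm_units,
                                 dense_units=config.dense_units,
                                 dropout=config.dropout, seed=config.seed)
        else:
            net = TextCNNClassifier(table, len(classes),
                                    filter_size=config.cnn_filter_size,
                                    n_filters=config.cnn_filter_num,
                                    dense_units=config.dense_units,
                                    dropout=config.dropout, seed=config.seed)
        Xv = yv = None
        if val_docs is not None:
            Xv = _padded_matrix(val_docs, model, max_len)
            yv = np.array([classes.index(l) for l in val_labels])
        net.fit(X, y, epochs=config.epochs, batch_size=config.batch_size,
                X_val=Xv, y_val=yv, lr=config.learning_rate,
                log=lambda rec: logger.info("%s %s", kind, rec))
        return FittedClassifier(kind, net, model, config, classes, max_len)

    X = _mean_vectors(docs, model)
    y = list(labels)
    if kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        inner = RandomForestClassifier(n_estimators=config.rf_n_estimators,
                                       random_state=config.seed)
    elif kind == "knn":
        from sklearn.neighbors import KNeighborsClassifier

        inner = KNeighborsClassifier(n_neighbors=config.knn_k)
    elif kind == "svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC

        # mean embedding vectors have tiny magnitudes; the kernel SVM needs
        # standardized features to see any structure at all
        inner = make_pipeline(
            StandardScaler(),
            SVC(C=config.svm_C, kernel=config.svm_kernel,
                gamma=config.svm_gamma, random_state=config.seed),
        )
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    inner.fit(X, y)
    return FittedClassifier(kind, inner, model, config, classes, None)


def evaluate_classifier(
    clf: FittedClassifier,
    docs: Sequence[TokenizedDocument],
    labels: Sequence[str],
) -> tuple[ConfusionMatrix, MetricsReport]:
    preds = clf.predict(docs)
    all_labels = sorted(set(clf.classes) | set(labels))
    cm = confusion_matrix_from_predictions(list(labels), preds, labels=all_labels)
    return cm, metrics_from_confusion(cm)


def train_test_evaluate(
    kind: ClassifierKind,
    docs: Sequence[TokenizedDocument],
    labels: Sequence[str],
    model: EmbeddingModel,
    config: ClassifierConfig | None = None,
) -> tuple[FittedClassifier, ConfusionMatrix, MetricsReport]:
    """The headline protocol: one stratified train/test split (default 70/30)."""
    from sklearn.model_selection import train_test_split

    config = config or ClassifierConfig()
    idx = np.arange(len(docs))
    tr, te = train_test_split(idx, train_size=config.train_fraction,
                              random_state=config.seed, stratify=list(labels))
    docs_tr = [docs[i] for i in tr]
    docs_te = [docs[i] for i in te]
    y_tr = [labels[i] for i in tr]
    y_te = [labels[i] for i in te]
    clf = train_classifier(kind, docs_tr, y_tr, model, config,
                           val_docs=docs_te, val_labels=y_te)
    cm, report = evaluate_classifier(clf, docs_te, y_te)
    return clf, cm, report


def cross_validate(
    kind: ClassifierKind,
    docs: Sequence[TokenizedDocument],
    labels: Sequence[str],
    model: EmbeddingModel,
    config: ClassifierConfig | None = None,
    folds: int = 10,
    repeats: int = 5,
) -> MetricsReport:
    """Repeated stratified k-fold: metrics averaged over folds, then repeats.

    Per-repeat seeds derive deterministically from the config's master seed.
    """
    from sklearn.model_selection import StratifiedKFold

    config = config or ClassifierConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    label_list = list(labels)
    min_class = min(label_list.count(c) for c in set(label_list))
    if min_class < folds:
        raise ValueError(
            f"smallest class has {min_class} samples; cannot stratify into {folds} folds"
        )

    repeat_reports: list[MetricsReport] = []
    for r in range(repeats):
        rep_seed = (config.seed * 1000 + r) % (2**31)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        fold_reports = []
        for tr, te in skf.split(np.zeros(len(docs)), label_list):
            cfg = replace(config, seed=rep_seed)
            clf = train_classifier(kind, [docs[i] for i in tr],
                                   [label_list[i] for i in tr], model, cfg)
            _, rep = evaluate_classifier(clf, [docs[i] for i in te],
                                         [label_list[i] for i in te])
            fold_reports.append(rep)
        repeat_reports.append(_average_reports(fold_reports))
    return _average_reports(repeat_reports)


def _average_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    labels = reports[0].labels

    def avg(vals):
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    per_class = {
        lab: {
            m: avg([r.per_class.get(lab, {}).get(m, float("nan")) for r in reports])
            for m in ("precision", "recall", "f1")
        }
        for lab in labels
    }
    return MetricsReport(
        labels=labels,
        per_class=per_class,
        macro_precision=avg([r.macro_precision for r in reports]),
        macro_recall=avg([r.macro_recall for r in reports]),
        macro_f1=avg([r.macro_f1 for r in reports]),
        micro_precision=avg([r.micro_precision for r in reports]),
        micro_recall=avg([r.micro_recall for r in reports]),
        micro_f1=avg([r.micro_f1 for r in reports]),
        accuracy=avg([r.accuracy for r in reports]),
    )
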