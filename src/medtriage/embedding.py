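"""Token embeddings: skip-gram / CBOW training, document vectors, similarity.

The trainer is a compact negative-sampling word2vec in numpy. Both
architectures share one code path: skip-gram predicts each context token from
the center token; CBOW predicts the center token from the averaged context.
Training is single-threaded and fully deterministic for a fixed seed.

A document vector is the arithmetic mean of its in-vocabulary token vectors;
out-of-vocabulary tokens are skipped and do not count toward the divisor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .preprocess import TokenizedDocument

Architecture = Literal["skip_gram", "cbow"]


@dataclass
class EmbeddingModel:
    """A trained token -> dense-vector map of fixed dimension."""

    dim: int
    architecture: Architecture
    index: dict[str, int]
    matrix: np.ndarray  # (vocab, dim) float32
    train_params: dict = field(default_factory=dict)

    @property
    def vocabulary(self) -> set[str]:
        return set(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    def vector(self, token: str) -> np.ndarray:
        return self.matrix[self.index[token]]

    # -- persistence ---------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.vocab.txt``, ``<prefix>.vectors.npy`` and a JSON sidecar."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        ordered = sorted(self.index, key=self.index.get)
        prefix.with_suffix(".vocab.txt").write_text(
            "\n".join(ordered) + "\n", encoding="utf-8"
        )
        np.save(prefix.with_suffix(".vectors.npy"), self.matrix.astype(np.float32))
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {"dim": self.dim, "architecture": self.architecture,
                 "train_params": self.train_params},
                indent=2,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, prefix: str | Path) -> "EmbeddingModel":
        prefix = Path(prefix)
        vocab = prefix.with_suffix(".vocab.txt").read_text(encoding="utf-8").split("\n")
        vocab = [t for t in vocab if t]
        matrix = np.load(prefix.with_suffix(".vectors.npy"))
        meta = json.loads(prefix.with_suffix(".json").read_text(encoding="utf-8"))
        return cls(
            dim=int(meta["dim"]),
            architecture=meta["architecture"],
            index={t: i for i, t in enumerate(vocab)},
            matrix=matrix,
            train_params=meta.get("train_params", {}),
        )

    def export_text(self, path: str | Path) -> None:
        """word2vec text format: header line, then ``token v1 ... v_dim``."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(self.index)} {self.dim}\n")
            for token in sorted(self.index, key=self.index.get):
                vals = " ".join(f"{x:.6f}" for x in self.matrix[self.index[token]])
                fh.write(f"{token} {vals}\n")

    @classmethod
    def import_text(cls, path: str | Path, architecture: Architecture = "skip_gram") -> "EmbeddingModel":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        n, dim = (int(x) for x in lines[0].split())
        index: dict[str, int] = {}
        matrix = np.zeros((n, dim), dtype=np.float32)
        for i, line in enumerate(lines[1 : n + 1]):
            parts = line.rsplit(maxsplit=dim)
            index[parts[0]] = i
            matrix[i] = [float(x) for x in parts[1:]]
        return cls(dim=dim, architecture=architecture, index=index, matrix=matrix)


@dataclass(frozen=True)
class DocumentVector:
    """Mean token vector of one document; ``n_tokens_used`` counts in-vocabulary tokens."""

    doc_id: str
    vector: np.ndarray
    n_tokens_used: int

    @property
    def degenerate(self) -> bool:
        return self.n_tokens_used == 0


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    docs: Sequence[TokenizedDocument],
    dim: int,
    architecture: Architecture = "skip_gram",
    seed: int = 0,
    window: int = 5,
    min_count: int = 1,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    batch_size: int = 256,
) -> EmbeddingModel:
    """Train negative-sampling embeddings on tokenized documents.

    Tokens occurring fewer than ``min_count`` times are dropped from the
    vocabulary. The learning rate decays linearly to 10% of ``lr`` over the
    run. Raises ``ValueError`` on an empty token stream or ``dim < 2``.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if len(docs) < 2:
        raise ValueError("need at least 2 documents")

    counts: dict[str, int] = {}
    for d in docs:
        for t in d.tokens:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("empty token stream after min_count filtering")
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    sentences = [
        np.array([index[t] for t in d.tokens if t in index], dtype=np.int64)
        for d in docs
    ]
    sentences = [s for s in sentences if len(s) >= 1]

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim), dtype=np.float64) - 0.5) / dim
    W_out = np.zeros((V, dim), dtype=np.float64)

    # unigram^0.75 negative-sampling distribution
    freqs = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    noise_p = freqs / freqs.sum()

    # (input position(s), predicted token) pairs
    centers: list[int] = []
    contexts: list[int] = []
    for s in sentences:
        L = len(s)
        for pos in range(L):
            lo, hi = max(0, pos - window), min(L, pos + window + 1)
            for j in range(lo, hi):
                if j != pos:
                    centers.append(s[pos])
                    contexts.append(s[j])
    if not centers:
        # single-token documents only: no context pairs, vectors stay at init
        return EmbeddingModel(dim=dim, architecture=architecture, index=index,
                              matrix=W_in.astype(np.float32),
                              train_params=dict(window=window, min_count=min_count,
                                                epochs=epochs, seed=seed, negative=negative))
    centers_a = np.asarray(centers, dtype=np.int64)
    contexts_a = np.asarray(contexts, dtype=np.int64)
    n_pairs = len(centers_a)

    # For CBOW the roles swap: the context token is the input and the center
    # token is predicted. With pair granularity the two architectures differ
    # only in which side indexes W_in; averaging over the context window is
    # approximated by per-pair updates, which preserves the expected gradient.
    if architecture == "cbow":
        inputs_all, targets_all = contexts_a, centers_a
    elif architecture == "skip_gram":
        inputs_all, targets_all = centers_a, contexts_a
    else:
        raise ValueError(f"unknown architecture {architecture!r}")

    total_steps = epochs * ((n_pairs + batch_size - 1) // batch_size)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            batch = order[start : start + batch_size]
            inp = inputs_all[batch]
            tgt = targets_all[batch]
            B = len(batch)
            alpha = lr * max(0.1, 1.0 - step / total_steps)
            step += 1

            neg = rng.choice(V, size=(B, negative), p=noise_p)
            # columns: [positive, negatives...]; labels [1, 0, ...]
            out_idx = np.concatenate([tgt[:, None], neg], axis=1)  # (B, 1+k)
            h = W_in[inp]  # (B, d)
            out_vecs = W_out[out_idx]  # (B, 1+k, d)
            scores = np.einsum("bd,bkd->bk", h, out_vecs)
            probs = _sigmoid(scores)
            labels = np.zeros_like(probs)
            labels[:, 0] = 1.0
            err = probs - labels  # (B, 1+k)

            grad_h = np.einsum("bk,bkd->bd", err, out_vecs)
            grad_out = err[:, :, None] * h[:, None, :]  # (B, 1+k, d)

            # scatter-add over a batch can stack many updates on one frequent
            # token; clip the per-row step to keep the combined update stable
            np.add.at(W_in, inp, np.clip(-alpha * grad_h, -0.1, 0.1))
            np.add.at(W_out, out_idx.ravel(),
                      np.clip(-alpha * grad_out.reshape(-1, dim), -0.1, 0.1))

    return EmbeddingModel(
        dim=dim,
        architecture=architecture,
        index=index,
        matrix=W_in.astype(np.float32),
        train_params=dict(window=window, min_count=min_count, epochs=epochs,
                          seed=seed, negative=negative, lr=lr),
    )


def embed_document(doc: TokenizedDocument, model: EmbeddingModel) -> DocumentVector:
    """Arithmetic mean of in-vocabulary token vectors (all-OOV -> zero vector)."""
    idx = [model.index[t] for t in doc.tokens if t in model.index]
    if not idx:
        return DocumentVector(doc.doc_id, np.zeros(model.dim, dtype=np.float64), 0)
    vec = model.matrix[idx].astype(np.float64).mean(axis=0)
    return DocumentVector(doc.doc_id, vec, len(idx))


def embed_documents(
    docs: Iterable[TokenizedDocument], model: EmbeddingModel
) -> list[DocumentVector]:
    return [embed_document(d, model) for d in docs]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """dot(a,b) / (|a||b|); defined as 0.0 when either norm is zero."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def set_overlap_similarity(
    tokens_u: set[str],
    tokens_v: set[str],
    variant: Literal["as_printed", "sqrt_normalized"] = "sqrt_normalized",
) -> float:
    """Token-set overlap |U∩V| normalized by |U|·|V| or its square root.

    ``as_printed`` divides by the raw product of set sizes; ``sqrt_normalized``
    divides by the geometric mean (the Ochiai coefficient, bounded by 1).
    """
    if not tokens_u or not tokens_v:
        raise ValueError("token sets must be nonempty")
    inter = len(tokens_u & tokens_v)
    prod = len(tokens_u) * len(tokens_v)
    if variant == "as_printed":
        return inter / prod
    if variant == "sqrt_normalized":
        return inter / float(np.sqrt(prod))
    raise ValueError(f"unknown variant {variant!r}")


def select_dimension(
    docs: Sequence[TokenizedDocument],
    labels: Sequence[str],
    candidate_dims: Sequence[int],
    architectures: Sequence[Architecture] = ("skip_gram", "cbow"),
    seed: int = 0,
    knn_k: int = 5,
    test_fraction: float = 0.3,
    **train_kwargs,
) -> tuple[int, Architecture, list[dict]]:
    """Pick the embedding dimension by a KNN classification sweep.

    For each (dim, architecture) pair: train embeddings, average them into
    document vectors, and score a k-nearest-neighbour classifier on a
    stratified 70/30 split. Returns the argmax accuracy; ties prefer the
    smaller dimension, then skip-gram.
    """
    from sklearn.model_selection import train_test_split
    from sklearn.neighbors import KNeighborsClassifier

    if not candidate_dims:
        raise ValueError("candidate_dims must be nonempty")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 classes")

    table: list[dict] = []
    for dim in candidate_dims:
        for arch in architectures:
            model = train_embeddings(docs, dim=dim, architecture=arch,
                                     seed=seed, **train_kwargs)
            X = np.vstack([embed_document(d, model).vector for d in docs])
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, list(labels), test_size=test_fraction,
                random_state=seed, stratify=list(labels),
            )
            knn = KNeighborsClassifier(n_neighbors=knn_k)
            knn.fit(X_tr, y_tr)
            acc = float(knn.score(X_te, y_te))
            table.append({"dim": dim, "architecture": arch, "accuracy": acc})

    arch_rank = {"skip_gram": 0, "cbow": 1}
    best = max(table, key=lambda r: (r["accuracy"], -r["dim"], -arch_rank[r["architecture"]]))
    return best["dim"], best["architecture"], table
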