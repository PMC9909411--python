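"""Physician recommendation: similar patients, similar physicians, hybrid.

Strategy A (similar patients): find patients whose complaint vectors are
within a cosine threshold of the target's, average those similarities per
consulting physician, and take the top of that ranking. Strategy B (similar
physicians): profile each physician by the mean vector of their top TF-IDF
keywords and rank physicians by cosine to the profile of the physician the
target actually consulted. The hybrid keeps strategy-A physicians that also
appear in strategy B's list, backfilling deleted slots from the extended
strategy-A ranking.

Ties are broken everywhere by score descending, then physician id ascending.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .corpus import Corpus
from .embedding import DocumentVector, EmbeddingModel, embed_document
from .preprocess import PreprocessConfig, TokenizedDocument, preprocess_document
from .corpus import ComplaintRecord

logger = logging.getLogger(__name__)

Strategy = Literal["similar_patient", "similar_physician", "hybrid"]


class ColdStartError(Exception):
    """The target has no consultation history to recommend from."""


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise-cosine matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric")
        self._pos = {pid: i for i, pid in enumerate(self.ids)}

    def sim(self, id_a: str, id_b: str) -> float:
        return float(self.values[self._pos[id_a], self._pos[id_b]])

    def row(self, id_a: str) -> np.ndarray:
        return self.values[self._pos[id_a]]


@dataclass
class PhysicianProfile:
    """Top TF-IDF keywords plus their unweighted mean embedding vector."""

    physician_id: str
    keywords: list[tuple[str, float]]
    vector: np.ndarray
    degenerate: bool = False


@dataclass
class RecommendationList:
    """Ranked physicians for one target patient under one strategy."""

    target_patient_id: str
    strategy: Strategy
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        ids = [pid for pid, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate physician in recommendation list")
        scores = [s for _, s in self.entries]
        if any(a < b - 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")

    @property
    def physician_ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]


def build_patient_similarity(doc_vectors: Sequence[DocumentVector]) -> SimilarityMatrix:
    """Pairwise cosine of mean complaint vectors.

    Degenerate (zero) vectors get similarity 0 to everyone and 1 to self.
    """
    if len(doc_vectors) < 2:
        raise ValueError("need at least 2 patients")
    X = np.vstack([dv.vector for dv in doc_vectors]).astype(np.float64)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = X / safe[:, None]
    values = unit @ unit.T
    zero = norms == 0
    values[zero, :] = 0.0
    values[:, zero] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip(values, -1.0, 1.0)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(ids=[dv.doc_id for dv in doc_vectors], values=values)


def _rank(scores: dict[str, float]) -> list[tuple[str, float]]:
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def similar_patient_ranking(
    target: str, sim: SimilarityMatrix, corpus: Corpus, beta: float
) -> list[tuple[str, float]]:
    """Full physician ranking for the similar-patient strategy.

    Candidates are all patients (the target included, anchoring its own
    physician at similarity 1.0) with cosine >= beta to the target; each
    physician consulted by at least one candidate is scored by the mean
    similarity of its candidate patients.
    """
    if not 0 < beta <= 1:
        raise ValueError("beta must be in (0, 1]")
    row = sim.row(target)
    per_physician: dict[str, list[float]] = {}
    for pid, s in zip(sim.ids, row):
        if s >= beta:
            phys = corpus.patient_to_physician.get(pid)
            if phys is not None:
                per_physician.setdefault(phys, []).append(float(s))
    scores = {phys: float(np.mean(sims)) for phys, sims in per_physician.items()}
    return _rank(scores)


def similar_patient_recommend(
    target: str,
    sim: SimilarityMatrix,
    corpus: Corpus,
    beta: float = 0.8,
    list_size: int = 10,
) -> RecommendationList:
    ranking = similar_patient_ranking(target, sim, corpus, beta)
    if not ranking:
        logger.warning("cold start: no patient within beta=%.3f of %s", beta, target)
    return RecommendationList(target, "similar_patient", ranking[:list_size])


def tfidf_keywords(
    physician_docs: dict[str, Sequence[str]], top_k: int = 15
) -> dict[str, list[tuple[str, float]]]:
    """Rank each physician's tokens by tf·idf and keep the top ``top_k``.

    One concatenated document per physician; tf is the within-document token
    frequency and idf = ln((1+N)/(1+df)) + 1 over the physician documents.
    Ties break by raw term count, then lexicographically.
    """
    n_docs = len(physician_docs)
    df: dict[str, int] = {}
    counts: dict[str, dict[str, int]] = {}
    for phys, tokens in physician_docs.items():
        if not tokens:
            raise ValueError(f"physician {phys!r} has an empty document")
        c: dict[str, int] = {}
        for t in tokens:
            c[t] = c.get(t, 0) + 1
        counts[phys] = c
        for t in c:
            df[t] = df.get(t, 0) + 1

    idf = {t: math.log((1 + n_docs) / (1 + d)) + 1.0 for t, d in df.items()}
    out: dict[str, list[tuple[str, float]]] = {}
    for phys, c in counts.items():
        total = sum(c.values())
        scored = [(t, (n / total) * idf[t], n) for t, n in c.items()]
        scored.sort(key=lambda r: (-r[1], -r[2], r[0]))
        out[phys] = [(t, w) for t, w, _ in scored[:top_k]]
    return out


def physician_token_docs(
    corpus: Corpus, config: PreprocessConfig | None = None
) -> dict[str, list[str]]:
    """One concatenated token document per physician from its consulted texts."""
    out: dict[str, list[str]] = {}
    for p in corpus.physicians:
        tokens: list[str] = []
        for i, text in enumerate(p.consulted_texts):
            rec = ComplaintRecord(
                patient_id=f"{p.physician_id}#{i}", text=text,
                disease="", department=p.department,
            )
            tokens.extend(preprocess_document(rec, config).tokens)
        out[p.physician_id] = tokens
    return out


def build_physician_profiles(
    keywords: dict[str, list[tuple[str, float]]], model: EmbeddingModel
) -> list[PhysicianProfile]:
    """Unweighted mean of in-vocabulary keyword vectors per physician."""
    profiles = []
    for phys, kws in keywords.items():
        idx = [model.index[t] for t, _ in kws if t in model.index]
        if idx:
            vec = model.matrix[idx].astype(np.float64).mean(axis=0)
            degenerate = False
        else:
            vec = np.zeros(model.dim)
            degenerate = True
            logger.warning("physician %r: all keywords out of vocabulary", phys)
        profiles.append(PhysicianProfile(phys, list(kws), vec, degenerate))
    return profiles


def similar_physician_recommend(
    target: str,
    profiles: Sequence[PhysicianProfile],
    corpus: Corpus,
    list_size: int = 10,
) -> RecommendationList:
    """Rank the pool by cosine to the consulted physician's profile.

    The consulted physician itself is excluded from the list; degenerate
    (all-OOV) profiles never enter the ranking.
    """
    consulted = corpus.patient_to_physician.get(target)
    if consulted is None:
        raise ColdStartError(f"patient {target!r} has no consulted physician")
    by_id = {p.physician_id: p for p in profiles}
    if consulted not in by_id:
        raise ColdStartError(f"consulted physician {consulted!r} has no profile")
    anchor = by_id[consulted]
    anchor_norm = np.linalg.norm(anchor.vector)
    scores: dict[str, float] = {}
    for p in profiles:
        if p.physician_id == consulted or p.degenerate:
            continue
        n = np.linalg.norm(p.vector)
        if anchor_norm == 0 or n == 0:
            scores[p.physician_id] = 0.0
        else:
            scores[p.physician_id] = float(anchor.vector @ p.vector / (anchor_norm * n))
    return RecommendationList(target, "similar_physician", _rank(scores)[:list_size])


def hybrid_recommend(
    list_a: RecommendationList,
    list_b: RecommendationList,
    full_ranking: Sequence[tuple[str, float]],
    corpus: Corpus | None = None,
    list_size: int = 10,
) -> RecommendationList:
    """Filter the similar-patient list by similar-physician membership.

    Walk the extended similar-patient ranking (which begins with list A) in
    rank order, keeping physicians that are members of list B — or that are
    the target's own consulted physician — until ``list_size`` entries are
    collected or candidates run out. Retained entries keep their A-scores.
    """
    target = list_a.target_patient_id
    if list_b.target_patient_id != target:
        raise ValueError("lists A and B must be for the same target")
    own = corpus.patient_to_physician.get(target) if corpus is not None else None
    b_members = set(list_b.physician_ids)

    merged: list[tuple[str, float]] = list(list_a.entries)
    present = set(list_a.physician_ids)
    for pid, score in full_ranking:
        if pid not in present:
            merged.append((pid, score))
            present.add(pid)

    entries: list[tuple[str, float]] = []
    for pid, score in merged:
        if pid in b_members or pid == own:
            entries.append((pid, score))
            if len(entries) == list_size:
                break
    return RecommendationList(target, "hybrid", entries)
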