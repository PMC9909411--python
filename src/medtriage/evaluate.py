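"""Recommendation evaluation: precision, service quality, and composite RP.

A recommended physician counts as a success when at least a fraction gamma of
their consulted texts lie within cosine threshold beta of the target's
complaint. Precision A is the fraction of successful physicians on the list.
Text (B) and voice (C) service quality are the fractions of recommended
physicians whose mean reply length / voice duration strictly exceed the pool
average. The composite score is RP = tau1*A + tau2*B + tau3*C, default
weights (0.8, 0.1, 0.1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .corpus import Corpus, PhysicianRecord
from .embedding import DocumentVector, EmbeddingModel, embed_document
from .preprocess import PreprocessConfig, preprocess_corpus, preprocess_document
from .corpus import ComplaintRecord
from .recommend import (
    RecommendationList,
    Strategy,
    build_patient_similarity,
    build_physician_profiles,
    hybrid_recommend,
    physician_token_docs,
    similar_patient_ranking,
    similar_patient_recommend,
    similar_physician_recommend,
    tfidf_keywords,
)

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (0.8, 0.1, 0.1)


@dataclass(frozen=True)
class RPWeights:
    """Linear weights for precision, text quality and voice quality."""

    tau1: float = 0.8
    tau2: float = 0.1
    tau3: float = 0.1

    def __post_init__(self) -> None:
        if min(self.tau1, self.tau2, self.tau3) < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.tau1 + self.tau2 + self.tau3 - 1.0) > 1e-9:
            logger.warning("RP weights sum to %.4f, not 1",
                           self.tau1 + self.tau2 + self.tau3)


@dataclass(frozen=True)
class ServiceBaseline:
    """Pool averages of per-physician mean reply length and voice duration."""

    mean_text_length: float
    mean_voice_duration: float
    n_physicians: int = 0


@dataclass
class RPResult:
    """One evaluation cell: (A, B, C, RP) at a given (beta, gamma)."""

    strategy: Strategy
    beta: float
    gamma: float
    A: float
    B: float
    C: float
    RP: float
    n_targets: int
    empty_cell: bool = False

    def __post_init__(self) -> None:
        pass  # RP linearity is asserted where the result is computed


def compute_service_baseline(physicians: Sequence[PhysicianRecord]) -> ServiceBaseline:
    """Average the per-physician means over the whole department pool."""
    if not physicians:
        raise ValueError("empty physician pool")
    return ServiceBaseline(
        mean_text_length=float(np.mean([p.mean_reply_length for p in physicians])),
        mean_voice_duration=float(np.mean([p.mean_voice_duration for p in physicians])),
        n_physicians=len(physicians),
    )


def _physician_text_vectors(
    physician: PhysicianRecord, model: EmbeddingModel,
    config: PreprocessConfig | None = None,
) -> np.ndarray:
    vecs = []
    for i, text in enumerate(physician.consulted_texts):
        rec = ComplaintRecord(patient_id=f"{physician.physician_id}#{i}", text=text,
                              disease="", department=physician.department)
        doc = preprocess_document(rec, config)
        vecs.append(embed_document(doc, model).vector)
    return np.vstack(vecs) if vecs else np.zeros((0, model.dim))


def _cosine_fractions(target_vec: np.ndarray, text_matrix: np.ndarray,
                      beta: float) -> float:
    """Fraction of rows whose cosine to the target is >= beta."""
    if len(text_matrix) == 0:
        return 0.0
    tn = np.linalg.norm(target_vec)
    if tn == 0:
        return 0.0
    norms = np.linalg.norm(text_matrix, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    cos = (text_matrix @ target_vec) / (safe * tn)
    cos = np.where(norms > 0, cos, 0.0)
    return float(np.mean(cos >= beta))


def recommendation_success(
    target_complaint_vec: np.ndarray,
    physician: PhysicianRecord,
    model: EmbeddingModel,
    beta: float,
    gamma: float,
    preprocess: PreprocessConfig | None = None,
) -> bool:
    """True iff >= gamma of the physician's texts are within beta of the target."""
    if not physician.consulted_texts:
        raise ValueError(f"physician {physician.physician_id!r} has no consulted texts")
    frac = _cosine_fractions(
        np.asarray(target_complaint_vec, dtype=np.float64),
        _physician_text_vectors(physician, model, preprocess),
        beta,
    )
    return frac >= gamma


def precision_A(
    recs: RecommendationList,
    corpus: Corpus,
    model: EmbeddingModel,
    target_vec: np.ndarray,
    beta: float,
    gamma: float,
    preprocess: PreprocessConfig | None = None,
) -> float:
    """Fraction of recommended physicians judged successful."""
    if not recs.entries:
        logger.warning("empty recommendation list for %s: A = 0", recs.target_patient_id)
        return 0.0
    n_ok = sum(
        recommendation_success(target_vec, corpus.physician(pid), model, beta, gamma,
                               preprocess)
        for pid in recs.physician_ids
    )
    return n_ok / len(recs.entries)


def text_service_quality(
    recs: RecommendationList, corpus: Corpus, baseline: ServiceBaseline
) -> float:
    """Fraction of recommended physicians with mean reply length above the pool mean.

    Strictly above; a physician with no replies counts as below.
    """
    if not recs.entries:
        return 0.0
    above = sum(
        corpus.physician(pid).mean_reply_length > baseline.mean_text_length
        for pid in recs.physician_ids
    )
    return above / len(recs.entries)


def voice_service_quality(
    recs: RecommendationList, corpus: Corpus, baseline: ServiceBaseline
) -> float:
    """As :func:`text_service_quality`, on mean voice durations."""
    if not recs.entries:
        return 0.0
    above = sum(
        corpus.physician(pid).mean_voice_duration > baseline.mean_voice_duration
        for pid in recs.physician_ids
    )
    return above / len(recs.entries)


def compute_rp(A: float, B: float, C: float,
               weights: RPWeights | None = None) -> float:
    weights = weights or RPWeights()
    return weights.tau1 * A + weights.tau2 * B + weights.tau3 * C


class SweepEngine:
    """Precomputes everything beta/gamma-independent for the parameter sweep.

    Holds the patient-similarity matrix, per-physician consulted-text vectors
    (as cosine rows against every patient complaint) and the service-quality
    flags, so each (strategy, beta, gamma) cell reduces to thresholding.
    """

    def __init__(self, corpus: Corpus, model: EmbeddingModel,
                 preprocess: PreprocessConfig | None = None,
                 list_size: int = 10, top_k_keywords: int = 15):
        self.corpus = corpus
        self.model = model
        self.list_size = list_size
        docs = preprocess_corpus(corpus.complaints, preprocess)
        self.doc_vectors = [embed_document(d, model) for d in docs]
        self.vec_by_patient = {dv.doc_id: dv.vector for dv in self.doc_vectors}
        self.sim = build_patient_similarity(self.doc_vectors)

        # physician profiles for strategy B (independent of beta/gamma)
        keywords = tfidf_keywords(
            {k: v for k, v in physician_token_docs(corpus, preprocess).items() if v},
            top_k=top_k_keywords,
        )
        self.profiles = build_physician_profiles(keywords, model)

        self.baseline = compute_service_baseline(corpus.physicians)
        self.text_above = {
            p.physician_id: p.mean_reply_length > self.baseline.mean_text_length
            for p in corpus.physicians
        }
        self.voice_above = {
            p.physician_id: p.mean_voice_duration > self.baseline.mean_voice_duration
            for p in corpus.physicians
        }

        # cosine of every physician consulted text against every patient vector
        self._text_cos: dict[str, np.ndarray] = {}
        P = np.vstack([self.vec_by_patient[c.patient_id] for c in corpus.complaints])
        pnorm = np.linalg.norm(P, axis=1)
        psafe = np.where(pnorm > 0, pnorm, 1.0)
        self._patient_order = [c.patient_id for c in corpus.complaints]
        self._patient_row = {pid: i for i, pid in enumerate(self._patient_order)}
        for phys in corpus.physicians:
            T = _physician_text_vectors(phys, model, preprocess)
            if len(T) == 0:
                self._text_cos[phys.physician_id] = np.zeros((len(P), 0))
                continue
            tnorm = np.linalg.norm(T, axis=1)
            tsafe = np.where(tnorm > 0, tnorm, 1.0)
            cos = (P @ T.T) / np.outer(psafe, tsafe)
            cos[pnorm == 0, :] = 0.0
            cos[:, tnorm == 0] = 0.0
            self._text_cos[phys.physician_id] = cos

    # -- per-cell pieces -----------------------------------------------------

    def success(self, target: str, physician_id: str, beta: float,
                gamma: float) -> bool:
        cos = self._text_cos[physician_id][self._patient_row[target]]
        if cos.size == 0:
            return False
        return float(np.mean(cos >= beta)) >= gamma

    def recommend(self, target: str, strategy: Strategy,
                  beta: float) -> RecommendationList:
        if strategy == "similar_patient":
            return similar_patient_recommend(target, self.sim, self.corpus, beta,
                                             self.list_size)
        if strategy == "similar_physician":
            return similar_physician_recommend(target, self.profiles, self.corpus,
                                               self.list_size)
        if strategy == "hybrid":
            ranking = similar_patient_ranking(target, self.sim, self.corpus, beta)
            a = RecommendationList(target, "similar_patient", ranking[: self.list_size])
            b = similar_physician_recommend(target, self.profiles, self.corpus,
                                            self.list_size)
            return hybrid_recommend(a, b, ranking, self.corpus, self.list_size)
        raise ValueError(f"unknown strategy {strategy!r}")

    def evaluate_cell(self, strategy: Strategy, beta: float, gamma: float,
                      weights: RPWeights | None = None,
                      targets: Sequence[str] | None = None) -> RPResult:
        """Average A, B, C over every target patient and combine into RP."""
        weights = weights or RPWeights()
        targets = list(targets) if targets is not None else list(self._patient_order)
        A_vals, B_vals, C_vals = [], [], []
        any_rec = False
        for target in targets:
            recs = self.recommend(target, strategy, beta)
            if recs.entries:
                any_rec = True
                m = len(recs.entries)
                n_ok = sum(self.success(target, pid, beta, gamma)
                           for pid in recs.physician_ids)
                A_vals.append(n_ok / m)
                B_vals.append(sum(self.text_above[p] for p in recs.physician_ids) / m)
                C_vals.append(sum(self.voice_above[p] for p in recs.physician_ids) / m)
            else:
                A_vals.append(0.0)
                B_vals.append(0.0)
                C_vals.append(0.0)
        A = float(np.mean(A_vals))
        B = float(np.mean(B_vals))
        C = float(np.mean(C_vals))
        rp = compute_rp(A, B, C, weights)
        if not any_rec:
            logger.warning("cell (%s, beta=%.2f, gamma=%.2f): no recommendations",
                           strategy, beta, gamma)
        return RPResult(strategy=strategy, beta=beta, gamma=gamma, A=A, B=B, C=C,
                        RP=rp, n_targets=len(targets), empty_cell=not any_rec)


def parameter_sweep(
    corpus: Corpus,
    model: EmbeddingModel,
    strategies: Sequence[Strategy] = ("similar_patient", "similar_physician", "hybrid"),
    betas: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    gammas: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    weights: RPWeights | None = None,
    list_size: int = 10,
    preprocess: PreprocessConfig | None = None,
    targets: Sequence[str] | None = None,
) -> list[RPResult]:
    """Evaluate every (strategy, beta, gamma) cell of the grid.

    Recommendations are regenerated at each beta; success is re-judged at
    each gamma; A/B/C are averaged over all target patients.
    """
    if not betas or not gammas or not strategies:
        raise ValueError("strategies, betas and gammas must be nonempty")
    engine = SweepEngine(corpus, model, preprocess, list_size=list_size)
    results = []
    for strategy in strategies:
        for beta in betas:
            for gamma in gammas:
                results.append(engine.evaluate_cell(strategy, beta, gamma, weights,
                                                    targets))
    return results


def sweep_to_dataframe(results: Iterable[RPResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {"strategy": r.strategy, "beta": r.beta, "gamma": r.gamma,
             "A": r.A, "B": r.B, "C": r.C, "RP": r.RP, "n_targets": r.n_targets}
            for r in results
        ]
    )
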