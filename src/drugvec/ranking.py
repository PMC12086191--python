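"""Analogy scoring and candidate ranking by centered cosine similarity.

Given a query drug d, a relation vector v and a candidate gene set, each
candidate g is scored with

    cos(u_d − c + v,  u_g − c)

where c is the mean embedding of the candidate search space (centering;
``c = 0`` when centering is off).  Candidates are ranked by descending
score with deterministic lexicographic tie-breaking.  The reverse task
(gene → drug) mirrors this with −v and centering over drug candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .embeddings import EmbeddingStore
from .estimators import RelationVector

__all__ = ["RankedPrediction", "analogy_score", "rank_candidates", "reverse_rank"]

logger = logging.getLogger(__name__)


class RankingError(ValueError):
    pass


@dataclass(frozen=True)
class RankedPrediction:
    """A full candidate ranking for one query.

    ``ranking`` is ordered by descending score, ties broken by ascending
    candidate id; ``rank_of`` is 1-based.  Candidates whose centered vector
    had zero norm receive score −inf and are counted in
    ``n_degenerate`` rather than silently reordered.
    """

    query_id: str
    direction: str  # "drug->gene" or "gene->drug"
    ranking: tuple[tuple[str, float], ...]
    center_used: np.ndarray | None = None
    n_degenerate: int = 0

    def rank_of(self, candidate_id: str) -> int | None:
        for i, (cid, _) in enumerate(self.ranking, start=1):
            if cid == candidate_id:
                return i
        return None

    def first_correct_rank(self, answers: Iterable[str]) -> int | None:
        """1-based rank of the best-ranked candidate in ``answers``."""
        answers = set(answers)
        for i, (cid, _) in enumerate(self.ranking, start=1):
            if cid in answers:
                return i
        return None

    def top(self, k: int) -> list[str]:
        return [cid for cid, _ in self.ranking[:k]]


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise RankingError("degenerate cosine: zero-norm operand")
    return float(np.dot(a, b) / (na * nb))


def analogy_score(store: EmbeddingStore, query_id: str, v: RelationVector,
                  candidate_id: str,
                  center: np.ndarray | None = None) -> float:
    """Centered cosine between the shifted query and one candidate."""
    c = 0.0 if center is None else np.asarray(center, dtype=np.float64)
    q = store.vector(query_id) - c + v.vector
    u = store.vector(candidate_id) - c
    return _cosine(q, u)


def _rank(store: EmbeddingStore, query_id: str, v: RelationVector,
          candidates: Iterable[str], center_on: str,
          direction: str) -> RankedPrediction:
    cand = sorted(set(candidates))
    if not cand:
        raise RankingError("empty candidate set")
    missing = store.missing(cand + [query_id])
    if missing:
        raise RankingError(f"concepts without embeddings: {missing[:10]}")
    if center_on == "candidates":
        center = store.mean_vector(cand)
    elif center_on == "none" or center_on is None:
        center = None
    else:
        raise RankingError(f"center_on must be 'candidates' or 'none', got {center_on!r}")

    c = 0.0 if center is None else center
    q = store.vector(query_id) - c + v.vector
    qn = np.linalg.norm(q)
    if qn == 0.0:
        raise RankingError("degenerate cosine: shifted query has zero norm")
    mat = store.vectors(cand) - c
    norms = np.linalg.norm(mat, axis=1)
    degenerate = norms == 0.0
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.warning("%d candidate(s) with zero centered norm scored -inf", n_deg)
    with np.errstate(invalid="ignore"):
        scores = mat @ q / (norms * qn)
    scores[degenerate] = -np.inf
    # descending score, ascending id: candidates are pre-sorted by id, so a
    # stable sort on -score realises the tie-break.
    order = np.argsort(-scores, kind="stable")
    ranking = tuple((cand[i], float(scores[i])) for i in order)
    return RankedPrediction(query_id, direction, ranking,
                            None if center is None else np.asarray(center),
                            n_deg)


def rank_candidates(store: EmbeddingStore, query_id: str, v: RelationVector,
                    candidates: Iterable[str],
                    center_on: str = "candidates") -> RankedPrediction:
    """Rank gene candidates for a drug query by cos(u_d − c + v, u_g − c)."""
    return _rank(store, query_id, v, candidates, center_on, "drug->gene")


def reverse_rank(store: EmbeddingStore, gene_query: str, v: RelationVector,
                 drug_candidates: Iterable[str],
                 center_on: str = "candidates") -> RankedPrediction:
    """Rank drug candidates for a gene query: the relation is applied
    backwards (−v) and centering is over the drug search space."""
    return _rank(store, gene_query, -v, drug_candidates, center_on, "gene->drug")
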