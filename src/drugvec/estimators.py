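"""Relation-vector estimators.

A drug-gene relation is represented as a direction v in embedding space
such that u_d + v ≈ u_g for related pairs (d, g).  Two estimators:

* naive — difference of the mean embeddings of two concept sets,
  E_G{u_g} − E_D{u_d}, which mixes in unrelated drugs and genes;
* pair mean — the mean of the per-pair differences over a relation set,
  (1/|R|) Σ (u_g − u_d), equivalently E_R{u_g} − E_R{u_d}, which uses only
  actually related pairs and is the estimator of record here.

Year- or pathway-restricted variants are not separate code paths: apply
``pair_mean_estimator`` to the restricted relation set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .embeddings import EmbeddingStore
from .relations import (PathwayCatalog, RelationSet, restrict_to_pathway)

__all__ = [
    "RelationVector",
    "naive_estimator",
    "pair_mean_estimator",
    "pathway_estimators",
    "save_relation_vector",
    "load_relation_vector",
]

logger = logging.getLogger(__name__)


class EstimatorError(ValueError):
    pass


@dataclass(frozen=True)
class RelationVector:
    """An estimated relation vector with its provenance.

    Attributes
    ----------
    vector : ndarray, shape (K,)
    estimator_kind : {"naive", "pair_mean"}
    source : str
        Description of the subset used (global R, a pathway, a year slice).
    n_pairs : int
        Pairs averaged (pair_mean) or 0 for the naive estimator.
    n_dropped : int
        Pairs dropped because a member lacked an embedding.
    """

    vector: np.ndarray
    estimator_kind: str
    source: str = "R"
    n_pairs: int = 0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=np.float64)
        if v.ndim != 1 or not np.isfinite(v).all():
            raise EstimatorError("relation vector must be a finite 1-d array")
        object.__setattr__(self, "vector", v)

    @property
    def dim(self) -> int:
        return self.vector.shape[0]

    def __neg__(self) -> "RelationVector":
        return RelationVector(-self.vector, self.estimator_kind,
                              self.source, self.n_pairs, self.n_dropped)


def naive_estimator(store: EmbeddingStore, drugs: Iterable[str],
                    genes: Iterable[str], source: str = "D,G") -> RelationVector:
    """E_G{u_g} − E_D{u_d} over whole concept sets, related or not."""
    drugs, genes = set(drugs), set(genes)
    if not drugs or not genes:
        raise EstimatorError("naive estimator needs non-empty drug and gene sets")
    missing = store.missing(drugs | genes)
    if missing:
        raise EstimatorError(f"concepts without embeddings: {missing[:10]}")
    v = store.mean_vector(genes) - store.mean_vector(drugs)
    return RelationVector(v, "naive", source, n_pairs=0)


def pair_mean_estimator(store: EmbeddingStore, relations: RelationSet,
                        source: str = "R",
                        on_missing: str = "drop") -> RelationVector:
    """Mean of u_g − u_d over the pairs of ``relations``.

    Parameters
    ----------
    on_missing : {"drop", "error"}
        Pairs whose drug or gene has no embedding are dropped with a logged
        count, or raise.
    """
    if len(relations) == 0:
        raise EstimatorError("no relations: cannot estimate a relation vector")
    usable, dropped = [], 0
    for d, g in sorted(relations.pairs):
        if d in store and g in store:
            usable.append((d, g))
        else:
            dropped += 1
    if dropped:
        if on_missing == "error":
            raise EstimatorError(
                f"{dropped} pair(s) reference concepts without embeddings")
        logger.warning("dropped %d/%d pairs lacking embeddings (%s)",
                       dropped, len(relations), source)
    if not usable:
        raise EstimatorError("no relations with embeddings on both sides")
    du = store.vectors([d for d, _ in usable])
    gu = store.vectors([g for _, g in usable])
    v = (gu - du).mean(axis=0)
    return RelationVector(v, "pair_mean", source, n_pairs=len(usable),
                          n_dropped=dropped)


def pathway_estimators(store: EmbeddingStore, relations: RelationSet,
                       catalog: PathwayCatalog, pathways: Iterable[str],
                       on_missing: str = "drop"
                       ) -> tuple[dict[str, RelationVector], list[str]]:
    """Per-pathway pair-mean estimators over each R_p.

    Returns (estimators, empty_pathways); pathways whose restricted
    relation set is empty are reported, never silently skipped.  Raises if
    every requested pathway is empty.
    """
    estimators: dict[str, RelationVector] = {}
    empty: list[str] = []
    for pid in pathways:
        view = restrict_to_pathway(relations, catalog, pid)
        if len(view) == 0:
            empty.append(pid)
            continue
        estimators[pid] = pair_mean_estimator(
            store, view.as_relation_set(), source=f"R_p[{pid}]",
            on_missing=on_missing)
    if not estimators:
        raise EstimatorError("no pathway has any relations to estimate from")
    return estimators, empty


# -- persistence -------------------------------------------------------------


def save_relation_vector(rv: RelationVector, path) -> None:
    """Write the vector as one TSV row of K floats plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(f"{x:.17g}" for x in rv.vector) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"estimator_kind": rv.estimator_kind, "source": rv.source,
                   "n_pairs": rv.n_pairs, "n_dropped": rv.n_dropped,
                   "dim": rv.dim}, fh, indent=2)


def load_relation_vector(path) -> RelationVector:
    path = Path(path)
    vec = np.loadtxt(path, delimiter="\t", ndmin=1)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta: Mapping = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return RelationVector(vec, meta.get("estimator_kind", "pair_mean"),
                          meta.get("source", "R"), meta.get("n_pairs", 0),
                          meta.get("n_dropped", 0))
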