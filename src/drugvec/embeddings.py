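"""Concept embedding storage and centered views.

Embeddings map opaque concept identifiers (PubTator-style IDs or readable
names) to K-dimensional real vectors.  Two on-disk dialects are supported:

* word2vec text — header line ``"<count> <dim>"`` followed by one
  space-separated row per concept (the BioConceptVec distribution format);
* headerless TSV — ``id\\tx1\\t...\\txK`` rows, convenient for fixtures.

Either may be gzip-compressed (detected by a ``.gz`` suffix).  Vectors are
held as 64-bit floats regardless of file precision so that cosine
comparisons are deterministic.
"""

from __future__ import annotations

import gzip
import io
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "EmbeddingStore",
    "CenteredView",
    "load_embeddings",
    "save_embeddings",
]


class EmbeddingError(ValueError):
    """Raised for malformed embedding files or invalid lookups."""


class EmbeddingStore:
    """An ordered vocabulary of concept IDs with a dense vector matrix.

    Parameters
    ----------
    ids : sequence of str
        Unique, non-empty concept identifiers in file order.
    matrix : array-like, shape (len(ids), K)
        Row ``i`` is the embedding of ``ids[i]``.  Stored as float64.
    """

    def __init__(self, ids: Sequence[str], matrix) -> None:
        ids = list(ids)
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise EmbeddingError("matrix must be 2-dimensional")
        if len(ids) != matrix.shape[0]:
            raise EmbeddingError(
                f"{len(ids)} ids but {matrix.shape[0]} matrix rows"
            )
        if any(not i for i in ids):
            raise EmbeddingError("empty identifier")
        index: dict[str, int] = {}
        for pos, cid in enumerate(ids):
            if cid in index:
                raise EmbeddingError(f"duplicate identifier: {cid!r}")
            index[cid] = pos
        if not np.isfinite(matrix).all():
            raise EmbeddingError("non-finite embedding values")
        self.ids = ids
        self.matrix = matrix
        self._index = index

    # -- basic access -----------------------------------------------------

    @property
    def dim(self) -> int:
        """Embedding dimension K."""
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._index

    def vector(self, concept_id: str) -> np.ndarray:
        """Return the stored vector for ``concept_id`` (a view, do not mutate)."""
        try:
            return self.matrix[self._index[concept_id]]
        except KeyError:
            raise EmbeddingError(f"unknown identifier: {concept_id!r}") from None

    def vectors(self, concept_ids: Iterable[str]) -> np.ndarray:
        """Stack vectors for ``concept_ids`` in the given order."""
        idx: list[int] = []
        missing: list[str] = []
        for c in concept_ids:
            r = self._index.get(c)
            if r is None:
                missing.append(c)
            else:
                idx.append(r)
        if missing:
            raise EmbeddingError(f"unknown identifiers: {sorted(missing)}")
        return self.matrix[idx]

    def missing(self, concept_ids: Iterable[str]) -> list[str]:
        """Identifiers from ``concept_ids`` absent from the vocabulary."""
        return sorted(c for c in set(concept_ids) if c not in self._index)

    # -- aggregation ------------------------------------------------------

    def mean_vector(self, concept_ids: Iterable[str]) -> np.ndarray:
        """Arithmetic mean of the vectors of ``concept_ids``.

        The sample mean E_S{u_w} over a concept set S; permutation
        invariant.  Raises on an empty set or unknown identifiers.
        """
        ids = sorted(set(concept_ids))
        if not ids:
            raise EmbeddingError("empty mean: no identifiers given")
        return self.vectors(ids).mean(axis=0)

    def centered_view(self, candidate_ids: Iterable[str]) -> "CenteredView":
        """A view in which the mean of ``candidate_ids`` is the origin.

        Centering subtracts the mean candidate embedding (e.g. E_G{u_g}
        over the gene search space) from every requested vector — including
        non-candidates such as the query drug — so that cosine similarity
        no longer depends on the global origin of the embedding space.
        """
        return CenteredView(self, self.mean_vector(candidate_ids))


class CenteredView:
    """Accessor returning ``u_x - center`` for any stored concept ``x``."""

    def __init__(self, store: EmbeddingStore, center: np.ndarray) -> None:
        self.store = store
        self.center = np.asarray(center, dtype=np.float64)

    def __call__(self, concept_id: str) -> np.ndarray:
        return self.store.vector(concept_id) - self.center

    def matrix_for(self, concept_ids: Sequence[str]) -> np.ndarray:
        return self.store.vectors(concept_ids) - self.center


# -- I/O -------------------------------------------------------------------


def _open_text(path: Path, mode: str = "rt") -> io.TextIOBase:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def load_embeddings(path, format: str | None = None) -> EmbeddingStore:
    """Load an :class:`EmbeddingStore` from disk.

    Parameters
    ----------
    path : path-like
        File in word2vec text format or headerless TSV; ``.gz`` accepted.
    format : {"word2vec-text", "tsv", None}
        ``None`` autodetects: a first line of exactly two integer tokens is
        treated as a word2vec header.
    """
    path = Path(path)
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise EmbeddingError(f"{path}: empty embedding file")

    header_tokens = lines[0].split()
    looks_w2v = len(header_tokens) == 2 and all(
        t.lstrip("+").isdigit() for t in header_tokens
    )
    if format is None:
        format = "word2vec-text" if looks_w2v else "tsv"

    if format == "word2vec-text":
        if not looks_w2v:
            raise EmbeddingError(
                f"{path}: line 1: expected header '<count> <dim>', got {lines[0]!r}"
            )
        count, dim = int(header_tokens[0]), int(header_tokens[1])
        body = lines[1:]
        if len(body) != count:
            raise EmbeddingError(
                f"{path}: header declares {count} rows but file has {len(body)}"
            )
        start = 2
    elif format == "tsv":
        body = lines
        dim = None
        start = 1
    else:
        raise EmbeddingError(f"unknown embedding format: {format!r}")

    ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(body, start=start):
        tokens = line.split("\t") if format == "tsv" else line.split()
        if format == "tsv" and len(tokens) == 1:
            tokens = line.split()
        if len(tokens) < 2:
            raise EmbeddingError(f"{path}: line {lineno}: malformed row")
        cid, values = tokens[0], tokens[1:]
        try:
            vec = np.array([float(v) for v in values], dtype=np.float64)
        except ValueError as exc:
            raise EmbeddingError(f"{path}: line {lineno}: {exc}") from None
        if dim is None:
            dim = vec.size
        if vec.size != dim:
            raise EmbeddingError(
                f"{path}: line {lineno}: expected {dim} values, got {vec.size}"
            )
        ids.append(cid)
        rows.append(vec)
    try:
        return EmbeddingStore(ids, np.vstack(rows))
    except EmbeddingError as exc:
        raise EmbeddingError(f"{path}: {exc}") from None


def save_embeddings(store: EmbeddingStore, path, format: str = "word2vec-text",
                    precision: int = 8) -> None:
    """Write ``store`` to ``path`` in word2vec text or TSV format."""
    path = Path(path)
    sep = "\t" if format == "tsv" else " "
    with _open_text(path, "wt") as fh:
        if format == "word2vec-text":
            fh.write(f"{len(store)} {store.dim}\n")
        elif format != "tsv":
            raise EmbeddingError(f"unknown embedding format: {format!r}")
        for cid, row in zip(store.ids, store.matrix):
            vals = sep.join(f"{x:.{precision}g}" for x in row)
            fh.write(f"{cid}{sep}{vals}\n")
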