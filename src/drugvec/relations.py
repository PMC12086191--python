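"""Drug-gene relation sets, pathway catalogs, and year annotations.

The ground-truth interactions form a set R of (drug, gene) pairs inside
universes D_all x G_all.  Derived objects used throughout:

* projections ``D = pi_D(R)`` and ``G = pi_G(R)`` — drugs/genes with at
  least one relation;
* answer sets ``[d] = {g : (d,g) in R}`` and ``[g] = {d : (d,g) in R}``;
* pathway restrictions ``R_p = R ∩ (D_p x G_p)`` for curated pathway
  memberships (KEGG-style);
* year restrictions ``R^y`` keeping pairs whose drug and gene both first
  appeared in the literature by year ``y``, and the known/unknown split of
  ``R^y`` by the pair's first co-appearance year.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "RelationSet",
    "PathwayCatalog",
    "PathwayRelationView",
    "YearAnnotations",
    "load_relations",
    "load_pathways",
    "load_concept_years",
    "load_pair_years",
    "restrict_to_pathway",
    "eligible_pathways",
    "restrict_by_year",
    "split_known_unknown",
    "relation_statistics",
]


class RelationDataError(ValueError):
    pass


@dataclass(frozen=True)
class RelationSet:
    """A deduplicated set of (drug, gene) pairs with their universes."""

    pairs: frozenset[tuple[str, str]]
    drug_universe: frozenset[str]
    gene_universe: frozenset[str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]],
                   drug_universe: Iterable[str] | None = None,
                   gene_universe: Iterable[str] | None = None) -> "RelationSet":
        ps = frozenset((str(d), str(g)) for d, g in pairs)
        drugs = frozenset(drug_universe) if drug_universe is not None else \
            frozenset(d for d, _ in ps)
        genes = frozenset(gene_universe) if gene_universe is not None else \
            frozenset(g for _, g in ps)
        bad = [(d, g) for d, g in ps if d not in drugs or g not in genes]
        if bad:
            raise RelationDataError(
                f"pairs outside the declared universes: {sorted(bad)[:5]}"
            )
        return cls(ps, drugs, genes)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    # -- projections and answer sets --------------------------------------

    @property
    def drugs_related(self) -> frozenset[str]:
        """D = pi_D(R): drugs with at least one relation."""
        return frozenset(d for d, _ in self.pairs)

    @property
    def genes_related(self) -> frozenset[str]:
        """G = pi_G(R): genes with at least one relation."""
        return frozenset(g for _, g in self.pairs)

    def answer_sets(self) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
        """Return ([d] for each related drug, [g] for each related gene)."""
        by_drug: dict[str, set[str]] = {}
        by_gene: dict[str, set[str]] = {}
        for d, g in self.pairs:
            by_drug.setdefault(d, set()).add(g)
            by_gene.setdefault(g, set()).add(d)
        return (
            {d: frozenset(gs) for d, gs in by_drug.items()},
            {g: frozenset(ds) for g, ds in by_gene.items()},
        )

    def genes_of(self, drug: str) -> frozenset[str]:
        return frozenset(g for d, g in self.pairs if d == drug)

    def drugs_of(self, gene: str) -> frozenset[str]:
        return frozenset(d for d, g in self.pairs if g == gene)


@dataclass(frozen=True)
class PathwayEntry:
    pathway_id: str
    name: str
    drugs: frozenset[str]
    genes: frozenset[str]


class PathwayCatalog:
    """Per-pathway drug and gene memberships (D_p, G_p)."""

    def __init__(self, entries: Iterable[PathwayEntry]) -> None:
        self._entries: dict[str, PathwayEntry] = {}
        for e in entries:
            if e.pathway_id in self._entries:
                raise RelationDataError(f"duplicate pathway id: {e.pathway_id}")
            self._entries[e.pathway_id] = e

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pathway_id: str) -> bool:
        return pathway_id in self._entries

    def __getitem__(self, pathway_id: str) -> PathwayEntry:
        try:
            return self._entries[pathway_id]
        except KeyError:
            raise RelationDataError(f"unknown pathway id: {pathway_id!r}") from None

    @property
    def pathway_ids(self) -> list[str]:
        return sorted(self._entries)


@dataclass(frozen=True)
class PathwayRelationView:
    """R restricted to one pathway, with its derived projections."""

    pathway_id: str
    pairs: frozenset[tuple[str, str]]
    member_drugs: frozenset[str]   # D_p (catalog membership)
    member_genes: frozenset[str]   # G_p (catalog membership)

    @property
    def drugs_related(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.pairs)

    @property
    def genes_related(self) -> frozenset[str]:
        return frozenset(g for _, g in self.pairs)

    def answer_sets(self) -> tuple[dict[str, frozenset[str]], dict[str, frozenset[str]]]:
        return RelationSet.from_pairs(
            self.pairs, self.member_drugs, self.member_genes
        ).answer_sets()

    def as_relation_set(self) -> RelationSet:
        return RelationSet.from_pairs(self.pairs, self.member_drugs, self.member_genes)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class YearAnnotations:
    """First-appearance years for concepts and pair co-appearance years.

    ``drug_year[d]`` / ``gene_year[g]`` give the year a concept first
    appeared in the literature; ``pair_year[(d, g)]`` the year the two
    first appeared together.  A pair with no recorded co-appearance year is
    treated as never having co-appeared (effectively year +inf), so it can
    only ever fall on the "unknown" side of a split.
    """

    drug_year: dict[str, int] = field(default_factory=dict)
    gene_year: dict[str, int] = field(default_factory=dict)
    pair_year: dict[tuple[str, str], int] = field(default_factory=dict)

    def validate(self) -> None:
        for (d, g), y in self.pair_year.items():
            yd = self.drug_year.get(d)
            yg = self.gene_year.get(g)
            if yd is not None and yg is not None and max(yd, yg) > y:
                raise RelationDataError(
                    f"pair ({d}, {g}) co-appears in {y}, before concept years "
                    f"({yd}, {yg})"
                )


# -- loaders ---------------------------------------------------------------


def _read_tsv(path) -> list[tuple[int, list[str]]]:
    path = Path(path)
    out = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            out.append((lineno, [c.strip() for c in row]))
    return out


def load_relations(path, drug_universe: Iterable[str] | None = None,
                   gene_universe: Iterable[str] | None = None) -> RelationSet:
    """Load a two-column (drug_id, gene_id) TSV; optional header; dedup."""
    rows = _read_tsv(path)
    pairs: list[tuple[str, str]] = []
    for i, (lineno, row) in enumerate(rows):
        if len(row) < 2:
            raise RelationDataError(f"{path}: line {lineno}: expected 2 columns")
        d, g = row[0], row[1]
        if i == 0 and {d.lower(), g.lower()} & {"drug", "drug_id"}:
            continue  # header row
        if not d or not g:
            raise RelationDataError(f"{path}: line {lineno}: empty identifier")
        pairs.append((d, g))
    return RelationSet.from_pairs(pairs, drug_universe, gene_universe)


def load_pathways(path) -> PathwayCatalog:
    """Load a pathway TSV: pathway_id, name, member_id, member_type."""
    drugs: dict[str, set[str]] = {}
    genes: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for lineno, row in _read_tsv(path):
        if len(row) < 4:
            raise RelationDataError(f"{path}: line {lineno}: expected 4 columns")
        pid, name, member, kind = row[0], row[1], row[2], row[3].lower()
        if lineno == 1 and kind in {"member_type", "type"}:
            continue
        names.setdefault(pid, name)
        if kind == "drug":
            drugs.setdefault(pid, set()).add(member)
        elif kind == "gene":
            genes.setdefault(pid, set()).add(member)
        else:
            raise RelationDataError(
                f"{path}: line {lineno}: member_type must be drug or gene, "
                f"got {kind!r}"
            )
    return PathwayCatalog(
        PathwayEntry(pid, names[pid],
                     frozenset(drugs.get(pid, ())), frozenset(genes.get(pid, ())))
        for pid in sorted(names)
    )


def load_concept_years(path) -> YearAnnotations:
    """Load concept years TSV: id, kind in {drug, gene}, year."""
    ann = YearAnnotations()
    for lineno, row in _read_tsv(path):
        if len(row) < 3:
            raise RelationDataError(f"{path}: line {lineno}: expected 3 columns")
        cid, kind, year = row[0], row[1].lower(), row[2]
        if lineno == 1 and kind in {"kind", "type"}:
            continue
        try:
            y = int(year)
        except ValueError:
            raise RelationDataError(
                f"{path}: line {lineno}: bad year {year!r}") from None
        if kind == "drug":
            ann.drug_year[cid] = y
        elif kind == "gene":
            ann.gene_year[cid] = y
        else:
            raise RelationDataError(
                f"{path}: line {lineno}: kind must be drug or gene")
    return ann


def load_pair_years(path, into: YearAnnotations | None = None) -> YearAnnotations:
    """Load pair co-appearance years TSV: drug_id, gene_id, year."""
    ann = into if into is not None else YearAnnotations()
    for lineno, row in _read_tsv(path):
        if len(row) < 3:
            raise RelationDataError(f"{path}: line {lineno}: expected 3 columns")
        d, g, year = row[0], row[1], row[2]
        if lineno == 1 and {d.lower()} & {"drug", "drug_id"}:
            continue
        try:
            ann.pair_year[(d, g)] = int(year)
        except ValueError:
            raise RelationDataError(
                f"{path}: line {lineno}: bad year {year!r}") from None
    return ann


# -- restriction operations -------------------------------------------------


def restrict_to_pathway(relations: RelationSet, catalog: PathwayCatalog,
                        pathway_id: str) -> PathwayRelationView:
    """R_p: pairs of R whose drug is in D_p and gene is in G_p."""
    entry = catalog[pathway_id]
    pairs = frozenset(
        (d, g) for d, g in relations.pairs
        if d in entry.drugs and g in entry.genes
    )
    return PathwayRelationView(pathway_id, pairs, entry.drugs, entry.genes)


def eligible_pathways(relations: RelationSet, catalog: PathwayCatalog,
                      min_drugs: int = 2, min_genes: int = 2) -> list[str]:
    """Pathways with at least ``min_drugs`` distinct related drugs and
    ``min_genes`` distinct related genes in R_p.

    Pathways where only a single drug or a single gene carries relations are
    excluded: the restricted analogy task there would be degenerate.
    """
    keep = []
    for pid in catalog.pathway_ids:
        view = restrict_to_pathway(relations, catalog, pid)
        if (len(view.drugs_related) >= min_drugs
                and len(view.genes_related) >= min_genes):
            keep.append(pid)
    return keep


def restrict_by_year(relations: RelationSet, years: YearAnnotations,
                     year: int) -> RelationSet:
    """R^y: pairs whose drug and gene both first appeared by ``year``.

    Universes shrink to the concepts with first-appearance year <= year.
    Every concept in R must carry a year annotation.
    """
    missing = sorted(
        {d for d, _ in relations.pairs if d not in years.drug_year}
        | {g for _, g in relations.pairs if g not in years.gene_year}
    )
    if missing:
        raise RelationDataError(f"concepts without year annotation: {missing[:10]}")
    drugs = frozenset(d for d in relations.drug_universe
                      if years.drug_year.get(d, year + 1) <= year)
    genes = frozenset(g for g in relations.gene_universe
                      if years.gene_year.get(g, year + 1) <= year)
    pairs = frozenset((d, g) for d, g in relations.pairs
                      if d in drugs and g in genes)
    return RelationSet(pairs, drugs, genes)


def split_known_unknown(relations_y: RelationSet, years: YearAnnotations,
                        year: int) -> tuple[RelationSet, RelationSet]:
    """Partition R^y into known (co-appeared by ``year``) and unknown.

    A pair whose co-appearance year is absent counts as unknown (it has
    never been seen together, so it cannot be "known" at any cutoff).
    The two parts are disjoint and their union is ``relations_y``.
    """
    known, unknown = set(), set()
    for pair in relations_y.pairs:
        y_pair = years.pair_year.get(pair)
        if y_pair is not None and y_pair <= year:
            known.add(pair)
        else:
            unknown.add(pair)
    mk = RelationSet(frozenset(known), relations_y.drug_universe,
                     relations_y.gene_universe)
    mu = RelationSet(frozenset(unknown), relations_y.drug_universe,
                     relations_y.gene_universe)
    return mk, mu


# -- summary statistics ------------------------------------------------------


def relation_statistics(relations: RelationSet) -> dict[str, float]:
    """Aggregate composition statistics for a relation set.

    Returns the universe sizes |D_all|, |G_all|, the relation count |R|,
    the related counts |D|, |G|, and the mean answer-set sizes
    E_{d in D}{|[d]|} = |R|/|D| and E_{g in G}{|[g]|} = |R|/|G| (each pair
    contributes once to exactly one drug's and one gene's answer set).
    """
    by_drug, by_gene = relations.answer_sets()
    n = len(relations)
    stats = {
        "n_drug_universe": len(relations.drug_universe),
        "n_gene_universe": len(relations.gene_universe),
        "n_relations": n,
        "n_drugs_related": len(by_drug),
        "n_genes_related": len(by_gene),
        "mean_genes_per_drug": (n / len(by_drug)) if by_drug else float("nan"),
        "mean_drugs_per_gene": (n / len(by_gene)) if by_gene else float("nan"),
    }
    return stats


def mean_answer_sizes(n_relations: int, n_drugs_related: int,
                      n_genes_related: int) -> tuple[float, float]:
    """Mean answer-set sizes implied by a printed composition.

    Since the answer sets [d] partition R by drug and [g] partition R by
    gene, E{|[d]|} = |R|/|D| and E{|[g]|} = |R|/|G| hold exactly.
    """
    if n_drugs_related <= 0 or n_genes_related <= 0:
        raise RelationDataError("related counts must be positive")
    return n_relations / n_drugs_related, n_relations / n_genes_related
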