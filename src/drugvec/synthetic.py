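"""Synthetic benchmarks with planted relation structure.

The generator emulates the geometry the analogy method assumes: related
gene embeddings sit at the mean of their related drugs' embeddings plus a
planted relation vector (optionally pathway-specific) plus isotropic
noise, so that u_d + v* ≈ u_g holds up to noise.  Distractor genes are
drawn from the same marginal but carry no relations.  Concept and pair
years are stamped so that year restriction and the known/unknown split
are non-degenerate at mid-range cutoffs.

Everything is driven by one integer seed; the same config and seed always
produce identical objects and files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .embeddings import EmbeddingStore, save_embeddings
from .relations import (PathwayCatalog, PathwayEntry, RelationSet,
                        YearAnnotations)

__all__ = ["SyntheticConfig", "SyntheticBenchmark", "generate_benchmark",
           "write_benchmark"]


class SyntheticConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted benchmark.

    Defaults give 200 drugs, 400 genes (75% of them related), dimension 50
    and mild noise — a scale at which every evaluation setting exercises a
    non-trivial search space while remaining fast.

    Attributes
    ----------
    n_drugs, n_genes : int
        Universe sizes; related genes are ``int(related_gene_frac * n_genes)``.
    dim : int
        Embedding dimension K.
    degree_choices : tuple of int
        A related gene links to ``rng.choice(degree_choices)`` drugs of its
        pathway (the per-gene drug-degree distribution).
    relation_norm : float
        Magnitude of each planted relation vector v*.
    noise_scale : float
        Isotropic noise σ added to each related gene embedding.
    n_pathways : int
    pathway_shifts : {"distinct", "shared"}
        Independent v* per pathway, or one v* shared by all.
    year_range : (int, int)
        Concept first-appearance years drawn uniformly in this range.
    pair_year_max_lag : int
        Pair co-appearance year = max(concept years) + Uniform{0..lag}.
    seed : int
    """

    n_drugs: int = 200
    n_genes: int = 400
    dim: int = 50
    degree_choices: tuple[int, ...] = (1, 2, 3)
    related_gene_frac: float = 0.75
    relation_norm: float = 3.0
    noise_scale: float = 0.05
    n_pathways: int = 4
    pathway_shifts: str = "distinct"
    year_range: tuple[int, int] = (1975, 2023)
    pair_year_max_lag: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_drugs, self.n_genes, self.dim, self.n_pathways) < 1:
            raise SyntheticConfigError("counts must be positive")
        if self.noise_scale < 0:
            raise SyntheticConfigError("noise scale must be >= 0")
        if not 0 < self.related_gene_frac <= 1:
            raise SyntheticConfigError("related_gene_frac must be in (0, 1]")
        if self.pathway_shifts not in ("distinct", "shared"):
            raise SyntheticConfigError(
                "pathway_shifts must be 'distinct' or 'shared'")
        n_related = int(self.related_gene_frac * self.n_genes)
        if n_related * max(self.degree_choices) > self.n_drugs * self.n_genes:
            raise SyntheticConfigError("more relations requested than "
                                       "n_drugs * n_genes allows")
        if self.year_range[0] > self.year_range[1]:
            raise SyntheticConfigError("empty year range")


@dataclass(frozen=True)
class SyntheticBenchmark:
    """A generated benchmark plus the planted ground truth."""

    store: EmbeddingStore
    relations: RelationSet
    catalog: PathwayCatalog
    years: YearAnnotations
    truth: dict

    def __iter__(self):
        return iter((self.store, self.relations, self.catalog,
                     self.years, self.truth))


def _unit(rng: np.random.Generator, dim: int) -> np.ndarray:
    v = rng.normal(size=dim)
    return v / np.linalg.norm(v)


def generate_benchmark(config: SyntheticConfig | None = None,
                       **overrides) -> SyntheticBenchmark:
    """Generate embeddings, relations, pathways, years and planted truth.

    Drug embeddings are standard normal draws.  Each related gene g picks
    its drugs within one pathway p and receives

        u_g = mean(u_d for d related to g) + v*_p + sigma * noise,

    so the pair-mean estimator over R_p targets v*_p exactly in the
    noise-free limit.  Distractor genes get a fresh drug-marginal draw
    plus their pathway's shift (no relations).
    """
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = SyntheticConfig(**{**asdict(config), **overrides})
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_related = max(1, int(config.related_gene_frac * config.n_genes))
    drug_ids = [f"D{i:04d}" for i in range(config.n_drugs)]
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]

    drug_mat = rng.normal(size=(config.n_drugs, config.dim))

    # planted relation vectors per pathway
    if config.pathway_shifts == "shared":
        shared = _unit(rng, config.dim) * config.relation_norm
        shifts = [shared.copy() for _ in range(config.n_pathways)]
    else:
        shifts = [_unit(rng, config.dim) * config.relation_norm
                  for _ in range(config.n_pathways)]

    # pathway membership: drugs and genes split round-robin after a shuffle
    drug_perm = rng.permutation(config.n_drugs)
    gene_perm = rng.permutation(config.n_genes)
    drug_pathway = {drug_ids[j]: int(i % config.n_pathways)
                    for i, j in enumerate(drug_perm)}
    gene_pathway = {gene_ids[j]: int(i % config.n_pathways)
                    for i, j in enumerate(gene_perm)}
    drugs_in = [[d for d in drug_ids if drug_pathway[d] == p]
                for p in range(config.n_pathways)]

    related_genes = {gene_ids[j] for j in gene_perm[:n_related]}
    drug_index = {d: i for i, d in enumerate(drug_ids)}
    gene_rows = np.empty((config.n_genes, config.dim))
    pairs: list[tuple[str, str]] = []
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for g in gene_ids:
        p = gene_pathway[g]
        if g in related_genes and drugs_in[p]:
            k = int(rng.choice(config.degree_choices))
            k = min(k, len(drugs_in[p]))
            chosen = list(rng.choice(drugs_in[p], size=k, replace=False))
            base = drug_mat[[drug_index[d] for d in chosen]].mean(axis=0)
            pairs.extend((d, g) for d in chosen)
        else:
            base = rng.normal(size=config.dim)  # distractor: drug marginal
        noise = rng.normal(size=config.dim) * config.noise_scale
        gene_rows[gene_index[g]] = base + shifts[p] + noise

    store = EmbeddingStore(drug_ids + gene_ids,
                           np.vstack([drug_mat, gene_rows]))
    relations = RelationSet.from_pairs(pairs, drug_ids, gene_ids)
    catalog = PathwayCatalog(
        PathwayEntry(f"P{p:02d}", f"synthetic pathway {p}",
                     frozenset(drugs_in[p]),
                     frozenset(g for g in gene_ids if gene_pathway[g] == p))
        for p in range(config.n_pathways))

    # year stamps: concept years uniform in range; pair year = max + lag,
    # which enforces max(y_d, y_g) <= y_(d,g) by construction
    y0, y1 = config.year_range
    years = YearAnnotations()
    for d in drug_ids:
        years.drug_year[d] = int(rng.integers(y0, y1 + 1))
    for g in gene_ids:
        years.gene_year[g] = int(rng.integers(y0, y1 + 1))
    for d, g in sorted(relations.pairs):
        lag = int(rng.integers(0, config.pair_year_max_lag + 1))
        years.pair_year[(d, g)] = max(years.drug_year[d],
                                      years.gene_year[g]) + lag
    years.validate()

    truth = {
        "relation_vectors": {f"P{p:02d}": shifts[p].tolist()
                             for p in range(config.n_pathways)},
        "shared_shift": config.pathway_shifts == "shared",
        "noise_scale": config.noise_scale,
        "config": asdict(config),
    }
    return SyntheticBenchmark(store, relations, catalog, years, truth)


def write_benchmark(bench: SyntheticBenchmark, out_dir) -> dict[str, Path]:
    """Write a benchmark in the formats the loaders read, plus truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "embeddings": out / "embeddings.w2v.txt",
        "relations": out / "relations.tsv",
        "pathways": out / "pathways.tsv",
        "concept_years": out / "concept_years.tsv",
        "pair_years": out / "pair_years.tsv",
        "truth": out / "truth.json",
    }
    save_embeddings(bench.store, paths["embeddings"], precision=17)
    with open(paths["relations"], "w") as fh:
        for d, g in sorted(bench.relations.pairs):
            fh.write(f"{d}\t{g}\n")
    with open(paths["pathways"], "w") as fh:
        for pid in bench.catalog.pathway_ids:
            e = bench.catalog[pid]
            for d in sorted(e.drugs):
                fh.write(f"{pid}\t{e.name}\t{d}\tdrug\n")
            for g in sorted(e.genes):
                fh.write(f"{pid}\t{e.name}\t{g}\tgene\n")
    with open(paths["concept_years"], "w") as fh:
        for d, y in sorted(bench.years.drug_year.items()):
            fh.write(f"{d}\tdrug\t{y}\n")
        for g, y in sorted(bench.years.gene_year.items()):
            fh.write(f"{g}\tgene\t{y}\n")
    with open(paths["pair_years"], "w") as fh:
        for (d, g), y in sorted(bench.years.pair_year.items()):
            fh.write(f"{d}\t{g}\t{y}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(bench.truth, fh, indent=2, sort_keys=True)
    return paths
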