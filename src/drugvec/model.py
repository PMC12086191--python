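"""Model/Results facade over the analogy toolkit.

``DrugGeneAnalogy`` bundles an embedding store with relation data the way
a statsmodels model bundles endog/exog; ``fit`` estimates the relation
vector(s) and returns a ``DrugGeneAnalogyResults`` object that carries the
estimates with their uncertainties and exposes prediction, evaluation and
a text summary.

Example
-------
>>> from drugvec.synthetic import generate_benchmark
>>> from drugvec.model import DrugGeneAnalogy
>>> bench = generate_benchmark(seed=0)
>>> res = DrugGeneAnalogy(bench.store, bench.relations,
...                       pathways=bench.catalog, years=bench.years).fit()
>>> report = res.evaluate(setting="G")
>>> round(report.top1, 3)  # doctest: +SKIP
1.0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embeddings import EmbeddingStore, load_embeddings
from .estimators import (RelationVector, naive_estimator, pair_mean_estimator,
                         pathway_estimators)
from .evaluation import EvaluationReport, evaluate_setting, random_baseline
from .ranking import RankedPrediction, rank_candidates, reverse_rank
from .relations import (PathwayCatalog, RelationSet, YearAnnotations,
                        eligible_pathways, load_concept_years,
                        load_pair_years, load_pathways, load_relations,
                        relation_statistics)

__all__ = ["DrugGeneAnalogy", "DrugGeneAnalogyResults"]


class DrugGeneAnalogy:
    """Analogy model: u_d + v ≈ u_g over a set of related (drug, gene) pairs.

    Parameters
    ----------
    embeddings : EmbeddingStore
    relations : RelationSet
        Ground-truth drug-gene pairs with their universes.
    pathways : PathwayCatalog, optional
        Required for the pathway-wise settings (P1, P2 and their year
        variants).
    years : YearAnnotations, optional
        Required for the year settings (Y1, Y2 and pathway variants).
    """

    def __init__(self, embeddings: EmbeddingStore, relations: RelationSet,
                 pathways: PathwayCatalog | None = None,
                 years: YearAnnotations | None = None) -> None:
        self.embeddings = embeddings
        self.relations = relations
        self.pathways = pathways
        self.years = years

    @classmethod
    def from_files(cls, embeddings_path, relations_path,
                   pathways_path=None, concept_years_path=None,
                   pair_years_path=None) -> "DrugGeneAnalogy":
        """Build a model from the standard on-disk formats."""
        store = load_embeddings(embeddings_path)
        relations = load_relations(relations_path)
        catalog = load_pathways(pathways_path) if pathways_path else None
        years = None
        if concept_years_path:
            years = load_concept_years(concept_years_path)
            if pair_years_path:
                load_pair_years(pair_years_path, into=years)
            years.validate()
        return cls(store, relations, pathways=catalog, years=years)

    def fit(self, estimator: str = "pair_mean",
            fit_pathways: bool = True) -> "DrugGeneAnalogyResults":
        """Estimate the global (and, when available, per-pathway) relation
        vectors and return a results object.

        The pair-mean estimator averages u_g − u_d over related pairs; its
        per-dimension standard error is the empirical standard deviation of
        the differences divided by sqrt(n_pairs).
        """
        store, rel = self.embeddings, self.relations
        if estimator == "pair_mean":
            rv = pair_mean_estimator(store, rel, source="R")
        elif estimator == "naive":
            rv = naive_estimator(
                store,
                [d for d in rel.drug_universe if d in store],
                [g for g in rel.gene_universe if g in store],
                source="D,G")
        else:
            raise ValueError(f"unknown estimator: {estimator!r}")

        # uncertainty of the mean difference (pair-mean only)
        stderr = None
        if estimator == "pair_mean":
            usable = sorted((d, g) for d, g in rel.pairs
                            if d in store and g in store)
            diffs = (store.vectors([g for _, g in usable])
                     - store.vectors([d for d, _ in usable]))
            if len(usable) > 1:
                stderr = diffs.std(axis=0, ddof=1) / np.sqrt(len(usable))

        pathway_vectors: dict[str, RelationVector] = {}
        empty_pathways: list[str] = []
        if fit_pathways and self.pathways is not None and estimator == "pair_mean":
            eligible = eligible_pathways(rel, self.pathways)
            if eligible:
                pathway_vectors, empty_pathways = pathway_estimators(
                    store, rel, self.pathways, eligible)

        return DrugGeneAnalogyResults(
            model=self, relation_vector=rv, stderr=stderr,
            estimator_kind=estimator, pathway_vectors=pathway_vectors,
            empty_pathways=empty_pathways)


@dataclass
class DrugGeneAnalogyResults:
    """Fitted relation vector(s) with uncertainties and diagnostics."""

    model: DrugGeneAnalogy
    relation_vector: RelationVector
    stderr: np.ndarray | None
    estimator_kind: str
    pathway_vectors: dict[str, RelationVector] = field(default_factory=dict)
    empty_pathways: list[str] = field(default_factory=list)

    @property
    def params(self) -> np.ndarray:
        """The estimated global relation vector (statsmodels convention)."""
        return self.relation_vector.vector

    @property
    def n_pairs(self) -> int:
        return self.relation_vector.n_pairs

    def predict(self, query_id: str, direction: str = "drug->gene",
                pathway: str | None = None, top_k: int | None = 10,
                center: bool = True) -> RankedPrediction:
        """Rank candidate targets for one query concept.

        Candidates are the full gene universe (or drug universe for the
        reverse direction) restricted to embedded concepts; ``pathway``
        selects a per-pathway relation vector instead of the global one.
        """
        store = self.model.embeddings
        rv = self.pathway_vectors[pathway] if pathway else self.relation_vector
        center_on = "candidates" if center else "none"
        if direction == "drug->gene":
            cands = [g for g in self.model.relations.gene_universe if g in store]
            pred = rank_candidates(store, query_id, rv, cands, center_on)
        elif direction == "gene->drug":
            cands = [d for d in self.model.relations.drug_universe if d in store]
            pred = reverse_rank(store, query_id, rv, cands, center_on)
        else:
            raise ValueError(f"unknown direction: {direction!r}")
        if top_k is not None:
            pred = RankedPrediction(pred.query_id, pred.direction,
                                    pred.ranking[:top_k], pred.center_used,
                                    pred.n_degenerate)
        return pred

    def evaluate(self, setting: str = "G", year: int | None = None,
                 k_list: Sequence[int] = (1, 10), center: bool = True,
                 direction: str = "drug->gene") -> EvaluationReport:
        """Evaluate the fitted estimator kind under one setting."""
        return evaluate_setting(
            self.model.embeddings, self.model.relations,
            catalog=self.model.pathways, years=self.model.years,
            setting=setting, year=year, estimator_kind=self.estimator_kind,
            k_list=k_list, center=center, direction=direction)

    def baseline(self, n_repeats: int = 10, seed: int = 0,
                 k_list: Sequence[int] = (1, 10)) -> EvaluationReport:
        """Weighted random baseline on the same relation data."""
        return random_baseline(self.model.relations, n_repeats=n_repeats,
                               seed=seed, k_list=k_list)

    def summary(self) -> str:
        """Text summary of the data composition and the fitted vector."""
        stats = relation_statistics(self.model.relations)
        v = self.relation_vector.vector
        lines = [
            "Drug-Gene Analogy Model Results",
            "=" * 46,
            f"{'Estimator:':<28}{self.estimator_kind}",
            f"{'Embedding dimension K:':<28}{self.model.embeddings.dim}",
            f"{'|R| relations used:':<28}{self.n_pairs or stats['n_relations']}",
            f"{'|D_all| x |G_all|:':<28}"
            f"{stats['n_drug_universe']} x {stats['n_gene_universe']}",
            f"{'|D| related drugs:':<28}{stats['n_drugs_related']}",
            f"{'|G| related genes:':<28}{stats['n_genes_related']}",
            f"{'mean |[d]| (genes/drug):':<28}{stats['mean_genes_per_drug']:.3f}",
            f"{'mean |[g]| (drugs/gene):':<28}{stats['mean_drugs_per_gene']:.3f}",
            f"{'||v_hat|| relation norm:':<28}{np.linalg.norm(v):.4f}",
        ]
        if self.stderr is not None:
            lines.append(f"{'mean stderr per dim:':<28}"
                         f"{float(np.mean(self.stderr)):.4f}")
        if self.pathway_vectors:
            lines.append(f"{'pathway vectors fitted:':<28}"
                         f"{len(self.pathway_vectors)}")
        if self.empty_pathways:
            lines.append(f"{'pathways without pairs:':<28}"
                         f"{len(self.empty_pathways)}")
        lines.append("=" * 46)
        return "\n".join(lines)
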