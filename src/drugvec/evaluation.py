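"""Evaluation of analogy predictions: settings, ranking metrics, baseline.

Nine evaluation settings are supported, differing in how the relation
vector is estimated, which drugs are queried, and which genes count as
correct.  The candidate search space is always the full gene universe of
the (possibly year-restricted) relation data, never a pathway subset:

====  ==========================================================
G     global: estimator from R, queries d in D, answers [d]
P1    per pathway p: estimator from R_p, queries d in D_p,
      answers [d]_p (only same-pathway genes are correct)
P2    predictions as P1, queries d in (pathway drugs ∩ D),
      answers [d] (any related gene is correct)
Y1    setting G on the year slice R^y
Y2    estimator from the known part of R^y; only pairs first
      co-appearing after y count as correct
P1Y1, P2Y1, P1Y2, P2Y2 — pathway analogues of Y1/Y2
====  ==========================================================

Metrics are top-k accuracy (a query is a hit if any of the k highest-
ranked candidates is in its answer set) and mean reciprocal rank.  The
weighted random baseline ranks the related genes G by sampling without
replacement with probability proportional to the answer-set size |[g]|.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .embeddings import EmbeddingStore
from .estimators import (RelationVector, naive_estimator, pair_mean_estimator)
from .ranking import RankedPrediction, rank_candidates, reverse_rank
from .relations import (PathwayCatalog, RelationSet, YearAnnotations,
                        eligible_pathways, restrict_by_year,
                        restrict_to_pathway, split_known_unknown)

__all__ = [
    "EvaluationReport",
    "QueryOutcome",
    "topk_accuracy",
    "mean_reciprocal_rank",
    "evaluate_setting",
    "random_baseline",
    "SETTINGS",
]

SETTINGS = ("G", "P1", "P2", "Y1", "Y2", "P1Y1", "P2Y1", "P1Y2", "P2Y2")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class QueryOutcome:
    """Outcome for one query instance (a drug, possibly within a pathway)."""

    query_id: str
    pathway_id: str | None
    answer_set_size: int
    first_correct_rank: int | None


@dataclass
class EvaluationReport:
    """Per-query outcomes and aggregate metrics for one setting."""

    setting_id: str
    direction: str
    per_query: list[QueryOutcome]
    topk: dict[int, float]
    mrr: float
    skipped: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    @property
    def n_queries(self) -> int:
        return len(self.per_query)

    @property
    def top1(self) -> float:
        return self.topk.get(1, float("nan"))

    @property
    def top10(self) -> float:
        return self.topk.get(10, float("nan"))

    def to_dict(self) -> dict:
        return {
            "setting": self.setting_id,
            "direction": self.direction,
            "n_queries": self.n_queries,
            "topk": {str(k): v for k, v in sorted(self.topk.items())},
            "mrr": self.mrr,
            "skipped": dict(self.skipped),
            "config": dict(self.config),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def per_query_rows(self) -> list[tuple]:
        return [(q.query_id, q.pathway_id or "", q.answer_set_size,
                 q.first_correct_rank if q.first_correct_rank is not None else "")
                for q in self.per_query]


# -- metrics -----------------------------------------------------------------


def _ranks(per_query: Sequence[QueryOutcome | int | None]) -> list[int | None]:
    out = []
    for q in per_query:
        if isinstance(q, QueryOutcome):
            out.append(q.first_correct_rank)
        else:
            out.append(q)
    return out


def topk_accuracy(per_query: Sequence, k: int) -> float:
    """Fraction of queries whose first correct candidate ranks within k.

    Accepts QueryOutcome objects or raw ranks (``None`` = never correct).
    """
    if k < 1:
        raise EvaluationError("k must be >= 1")
    ranks = _ranks(per_query)
    if not ranks:
        raise EvaluationError("no queries")
    return sum(1 for r in ranks if r is not None and r <= k) / len(ranks)


def mean_reciprocal_rank(per_query: Sequence) -> float:
    """Mean of 1/rank of the first correct candidate; 0 when never correct."""
    ranks = _ranks(per_query)
    if not ranks:
        raise EvaluationError("no queries")
    return sum(1.0 / r for r in ranks if r is not None) / len(ranks)


# -- setting enumeration -----------------------------------------------------


@dataclass(frozen=True)
class _Task:
    query_id: str
    pathway_id: str | None
    relation_vector: RelationVector
    answers: frozenset[str]


def _estimator(store: EmbeddingStore, relations: RelationSet,
               kind: str, source: str) -> RelationVector:
    if kind == "pair_mean":
        return pair_mean_estimator(store, relations, source=source)
    if kind == "naive":
        rv = naive_estimator(
            store,
            [d for d in relations.drug_universe if d in store],
            [g for g in relations.gene_universe if g in store],
            source=source)
        return rv
    raise EvaluationError(f"unknown estimator kind: {kind!r}")


def _setting_tasks(store: EmbeddingStore, relations: RelationSet,
                   catalog: PathwayCatalog | None,
                   years: YearAnnotations | None,
                   setting: str, year: int | None,
                   estimator_kind: str,
                   skipped: dict[str, int]) -> tuple[list[_Task], RelationSet]:
    """Enumerate (query, estimator, answers) per setting; return the
    year-restricted relation set actually evaluated against."""
    setting = setting.upper()
    if setting not in SETTINGS:
        raise EvaluationError(f"unknown setting: {setting!r}")
    pathway_like = setting.startswith("P")
    year_like = "Y" in setting
    unknown_like = setting.endswith("Y2") or setting == "Y2"

    if pathway_like and catalog is None:
        raise EvaluationError(f"setting {setting} requires a pathway catalog")
    if year_like and (years is None or year is None):
        raise EvaluationError(f"setting {setting} requires year annotations "
                              "and a cutoff year")

    ry = restrict_by_year(relations, years, year) if year_like else relations
    if unknown_like:
        known, unknown = split_known_unknown(ry, years, year)
    else:
        known = unknown = None

    tasks: list[_Task] = []

    def add(query: str, pid: str | None, rv: RelationVector,
            answers: frozenset[str]) -> None:
        if not answers:
            skipped["empty_answer_set"] = skipped.get("empty_answer_set", 0) + 1
            return
        if query not in store:
            skipped["query_missing_embedding"] = \
                skipped.get("query_missing_embedding", 0) + 1
            return
        tasks.append(_Task(query, pid, rv, answers))

    if not pathway_like:
        if unknown_like:  # Y2
            if len(known) == 0:
                raise EvaluationError("setting Y2: no known relations at "
                                      f"year {year} to estimate from")
            rv = _estimator(store, known, estimator_kind, f"R^{year}|known")
            unk_by_drug, _ = unknown.answer_sets()
            for d in sorted(ry.drugs_related):
                add(d, None, rv, unk_by_drug.get(d, frozenset()))
        else:  # G or Y1
            src = f"R^{year}" if year_like else "R"
            rv = _estimator(store, ry, estimator_kind, src)
            by_drug, _ = ry.answer_sets()
            for d in sorted(by_drug):
                add(d, None, rv, by_drug[d])
        return tasks, ry

    # pathway-wise settings
    p2_like = setting.startswith("P2")
    global_by_drug, _ = ry.answer_sets()
    if unknown_like:
        global_unknown_by_drug, _ = unknown.answer_sets()
    for pid in eligible_pathways(ry, catalog):
        view = restrict_to_pathway(ry, catalog, pid)
        rp = view.as_relation_set()
        if unknown_like:
            known_p, unknown_p = split_known_unknown(rp, years, year)
            if len(known_p) == 0:
                skipped["pathway_no_known_relations"] = \
                    skipped.get("pathway_no_known_relations", 0) + 1
                continue
            rv = _estimator(store, known_p, estimator_kind,
                            f"R_p[{pid}]^{year}|known")
            if p2_like:  # P2Y2: answers are global unknown relations
                queries = sorted(catalog[pid].drugs & ry.drugs_related)
                for d in queries:
                    add(d, pid, rv, global_unknown_by_drug.get(d, frozenset()))
            else:        # P1Y2: answers are within-pathway unknown relations
                unk_by_drug, _ = unknown_p.answer_sets()
                for d in sorted(rp.drugs_related):
                    add(d, pid, rv, unk_by_drug.get(d, frozenset()))
        else:
            src = f"R_p[{pid}]" + (f"^{year}" if year_like else "")
            rv = _estimator(store, rp, estimator_kind, src)
            if p2_like:  # P2 / P2Y1: pathway predictions, global answers
                queries = sorted(catalog[pid].drugs & ry.drugs_related)
                for d in queries:
                    add(d, pid, rv, global_by_drug.get(d, frozenset()))
            else:        # P1 / P1Y1
                by_drug, _ = rp.answer_sets()
                for d in sorted(by_drug):
                    add(d, pid, rv, by_drug[d])
    return tasks, ry


def evaluate_setting(store: EmbeddingStore, relations: RelationSet,
                     catalog: PathwayCatalog | None = None,
                     years: YearAnnotations | None = None,
                     setting: str = "G", year: int | None = None,
                     estimator_kind: str = "pair_mean",
                     k_list: Sequence[int] = (1, 10),
                     center: bool = True,
                     direction: str = "drug->gene") -> EvaluationReport:
    """Run one evaluation setting end to end and aggregate metrics.

    The search space is the full gene universe of the (year-restricted)
    relation data, restricted to embedded concepts; centering subtracts
    its mean embedding from every operand.  Aggregates are micro-averages
    over query instances — in pathway settings a drug queried in several
    pathways contributes once per pathway.

    For ``direction="gene->drug"`` (global-type settings only) the roles
    mirror: queries are related genes, candidates the drug universe, and
    the relation vector is applied with opposite sign.
    """
    setting = setting.upper()
    skipped: dict[str, int] = {}
    if direction not in ("drug->gene", "gene->drug"):
        raise EvaluationError(f"unknown direction: {direction!r}")
    if direction == "gene->drug" and setting.startswith("P"):
        raise EvaluationError("gene->drug direction is defined for the "
                              "global-type settings (G, Y1, Y2) only")

    if direction == "gene->drug":
        tasks, ry = _setting_tasks(
            store, _mirror(relations), catalog,
            _mirror_years(years) if years is not None else None,
            setting, year, estimator_kind, skipped)
    else:
        tasks, ry = _setting_tasks(store, relations, catalog, years,
                                   setting, year, estimator_kind, skipped)

    candidates = sorted(c for c in ry.gene_universe if c in store)
    n_missing = len(ry.gene_universe) - len(candidates)
    if n_missing:
        skipped["candidates_missing_embedding"] = n_missing
    if not candidates:
        raise EvaluationError("no embedded candidates in the search space")
    if not tasks:
        raise EvaluationError(
            f"setting {setting}: no eligible queries (skipped: {skipped})")

    center_on = "candidates" if center else "none"
    outcomes: list[QueryOutcome] = []
    for t in tasks:
        pred = rank_candidates(store, t.query_id, t.relation_vector,
                               candidates, center_on=center_on)
        outcomes.append(QueryOutcome(
            t.query_id, t.pathway_id, len(t.answers),
            pred.first_correct_rank(t.answers)))

    topk = {int(k): topk_accuracy(outcomes, int(k)) for k in k_list}
    report = EvaluationReport(
        setting_id=setting, direction=direction, per_query=outcomes,
        topk=topk, mrr=mean_reciprocal_rank(outcomes), skipped=skipped,
        config={"estimator": estimator_kind, "center": center,
                "year": year, "k_list": [int(k) for k in k_list],
                "n_candidates": len(candidates)})
    return report


def _mirror(relations: RelationSet) -> RelationSet:
    """Swap drug and gene roles: pairs (g, d), universes exchanged."""
    return RelationSet(frozenset((g, d) for d, g in relations.pairs),
                       relations.gene_universe, relations.drug_universe)


def _mirror_years(years: YearAnnotations) -> YearAnnotations:
    return YearAnnotations(
        drug_year=dict(years.gene_year), gene_year=dict(years.drug_year),
        pair_year={(g, d): y for (d, g), y in years.pair_year.items()})


# -- random baseline ---------------------------------------------------------


def weighted_ranking(gene_weights: Mapping[str, int | float],
                     rng: np.random.Generator) -> list[str]:
    """One full ranking of the genes by successive sampling without
    replacement with probability proportional to weight.

    Uses exponential sort keys (Efraimidis-Spirakis), which reproduces the
    distribution of renormalized successive draws exactly.
    """
    genes = sorted(gene_weights)
    w = np.array([float(gene_weights[g]) for g in genes])
    if not len(genes) or w.sum() <= 0:
        raise EvaluationError("zero total weight: cannot sample a ranking")
    if (w < 0).any():
        raise EvaluationError("negative weight")
    keys = np.full(len(genes), np.inf)
    pos = w > 0
    keys[pos] = rng.exponential(size=int(pos.sum())) / w[pos]
    order = np.argsort(keys, kind="stable")
    return [genes[i] for i in order]


def random_baseline(relations: RelationSet, n_repeats: int = 10,
                    seed: int = 0, k_list: Sequence[int] = (1, 10),
                    per_query_sampling: bool = False) -> EvaluationReport:
    """Weighted random baseline over the related genes G.

    Genes are ranked by sampling without replacement with probability
    proportional to |[g]| (the number of drugs related to each gene); by
    default one ranking per repeat is shared across every query, or one
    per query with ``per_query_sampling=True``.  Aggregates are the mean
    over ``n_repeats`` repeats (repeat r seeds its generator with
    ``seed + r``); ``per_query`` records the outcomes of the first repeat.
    """
    by_drug, by_gene = relations.answer_sets()
    if not by_gene:
        raise EvaluationError("no related genes to rank")
    weights = {g: len(ds) for g, ds in by_gene.items()}
    queries = sorted(by_drug)

    per_repeat_topk: list[dict[int, float]] = []
    per_repeat_mrr: list[float] = []
    first_repeat: list[QueryOutcome] = []
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        shared = None if per_query_sampling else weighted_ranking(weights, rng)
        outcomes = []
        for d in queries:
            ranking = weighted_ranking(weights, rng) if per_query_sampling \
                else shared
            answers = by_drug[d]
            rank = next((i for i, g in enumerate(ranking, start=1)
                         if g in answers), None)
            outcomes.append(QueryOutcome(d, None, len(answers), rank))
        per_repeat_topk.append({int(k): topk_accuracy(outcomes, int(k))
                                for k in k_list})
        per_repeat_mrr.append(mean_reciprocal_rank(outcomes))
        if r == 0:
            first_repeat = outcomes

    topk = {k: float(np.mean([t[k] for t in per_repeat_topk]))
            for k in per_repeat_topk[0]}
    return EvaluationReport(
        setting_id="random-baseline", direction="drug->gene",
        per_query=first_repeat, topk=topk,
        mrr=float(np.mean(per_repeat_mrr)),
        config={"n_repeats": n_repeats, "seed": seed,
                "per_query_sampling": per_query_sampling,
                "per_repeat_top1": [t.get(1) for t in per_repeat_topk]})


def baseline_first_draw_expectation(relations: RelationSet) -> dict[str, float]:
    """Closed-form top-1 probability of the weighted baseline per query.

    The first draw picks gene g with probability |[g]| / |R| (total weight
    Σ_g |[g]| = |R|), so P(hit for drug d) = Σ_{g in [d]} |[g]| / |R|.
    """
    by_drug, by_gene = relations.answer_sets()
    total = len(relations)
    return {d: sum(len(by_gene[g]) for g in gs) / total
            for d, gs in by_drug.items()}
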