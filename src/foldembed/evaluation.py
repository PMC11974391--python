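"""Retrieval benchmark: sensitivity up to the first incorrect fold.

Every query is searched against the full database (query included) and
the ranked hit list is scanned from the top. The scan stops at the
first hit whose *fold* differs from the query's fold; the metric is the
fraction of available true positives (TPs) found before that point.
TPs are defined per level:

* family: same family;
* superfamily: same superfamily and **not** same family;
* fold: same fold and **not** same superfamily.

The stopping rule is purely fold-based at every level: a hit that is
not a TP for the evaluated level neither counts nor stops the scan
unless its fold differs from the query's. The self-hit is a family
TP and, sharing the query's fold, can never stop the scan.

Also reported: the fraction of the top-20 hits sharing the query's
fold, and per-query length/contact-order/class fields for stratified
summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .features import contact_order, featurize
from .model import GraphBatch, Model
from .training import ClassificationLabel, LabeledDomain

logger = logging.getLogger(__name__)

__all__ = [
    "Level",
    "BenchmarkRecord",
    "BenchmarkSummary",
    "is_true_positive",
    "sensitivity_up_to_first_fp",
    "top_k_fold_fraction",
    "count_true_positives",
    "run_benchmark",
    "write_benchmark_tsv",
]

Level = Literal["family", "superfamily", "fold"]
LEVELS: tuple[Level, ...] = ("family", "superfamily", "fold")

#: default stratification bins (residues / contact order)
LENGTH_BINS = (0, 100, 200, 300, 10**9)
CONTACT_ORDER_BINS = (0.0, 0.1, 0.15, 0.2, 1.0)


@dataclass
class BenchmarkRecord:
    query_id: str
    sensitivity_family: float
    sensitivity_superfamily: float
    sensitivity_fold: float
    top20_fraction_same_fold: float
    length: int
    contact_order: float
    class_id: str


@dataclass
class BenchmarkSummary:
    n_queries: int
    mean_sensitivity_family: float
    mean_sensitivity_superfamily: float
    mean_sensitivity_fold: float
    mean_top20_fraction_same_fold: float
    self_hit_rank1_fraction: float


def is_true_positive(
    query: ClassificationLabel, hit: ClassificationLabel, level: Level
) -> bool:
    """Whether ``hit`` counts as a true positive for ``query`` at the
    given recognition level (deeper-level matches are excluded at the
    shallower levels)."""
    if level == "family":
        return query.same_family(hit)
    if level == "superfamily":
        return query.same_superfamily(hit) and not query.same_family(hit)
    if level == "fold":
        return query.same_fold(hit) and not query.same_superfamily(hit)
    raise ValueError(f"unknown level {level!r}")


def sensitivity_up_to_first_fp(
    ranked_hit_labels: Sequence[ClassificationLabel],
    query_label: ClassificationLabel,
    level: Level,
    total_tps: int,
) -> float:
    """Fraction of the ``total_tps`` available true positives ranked
    above the first hit from a different fold.

    ``total_tps`` must be the number of database entries that are TPs
    for this query at this level (benchmark queries are chosen to have
    at least one TP at every level).
    """
    if total_tps <= 0:
        raise ValueError("query has no true positives at this level")
    found = 0
    for hit in ranked_hit_labels:
        if not query_label.same_fold(hit):
            break
        if is_true_positive(query_label, hit, level):
            found += 1
    return found / total_tps


def top_k_fold_fraction(
    ranked_hit_labels: Sequence[ClassificationLabel],
    query_label: ClassificationLabel,
    k: int = 20,
) -> float:
    """Fraction of the top-``k`` hits sharing the query's fold. Falls
    back to the available length with a warning for shorter lists."""
    if len(ranked_hit_labels) < k:
        logger.warning(
            "ranked list has %d hits (< %d); using all of them",
            len(ranked_hit_labels),
            k,
        )
        k = len(ranked_hit_labels)
    top = ranked_hit_labels[:k]
    return sum(query_label.same_fold(hit) for hit in top) / k


def count_true_positives(
    query_label: ClassificationLabel,
    database_labels: Sequence[ClassificationLabel],
    level: Level,
) -> int:
    return sum(is_true_positive(query_label, lab, level) for lab in database_labels)


def run_benchmark(
    queries: list[LabeledDomain],
    database: list[LabeledDomain],
    model: Model,
    batch_size: int = 64,
) -> tuple[list[BenchmarkRecord], BenchmarkSummary]:
    """Embed queries and database, rank every query against the full
    database by cosine similarity (query included when present), and
    compute per-query retrieval metrics plus their means.

    Every query must have at least one TP in the database at each of
    the family, superfamily and fold levels.
    """
    if not queries or not database:
        raise ValueError("queries and database must be non-empty")

    def _embed(items: list[LabeledDomain]) -> np.ndarray:
        rows = []
        for start in range(0, len(items), batch_size):
            graphs = [featurize(it.structure) for it in items[start : start + batch_size]]
            rows.append(model.forward(GraphBatch(graphs)))
        return np.vstack(rows)

    db_z = _embed(database)
    db_labels = [it.label for it in database]
    db_ids = [it.domain_id for it in database]
    # identical objects shared between queries and database are reused
    shared = {id(it): k for k, it in enumerate(database)}

    records: list[BenchmarkRecord] = []
    self_hits = 0
    for item in queries:
        k = shared.get(id(item))
        z = db_z[k] if k is not None else _embed([item])[0]
        sims = db_z @ z
        order = np.argsort(-sims, kind="stable")
        ranked = [db_labels[j] for j in order]
        if db_ids[order[0]] == item.domain_id:
            self_hits += 1
        sens = {}
        for level in LEVELS:
            total = count_true_positives(item.label, db_labels, level)
            if total == 0:
                raise ValueError(
                    f"query {item.domain_id} has no {level}-level true "
                    "positives in the database"
                )
            sens[level] = sensitivity_up_to_first_fp(ranked, item.label, level, total)
        struct = item.structure
        records.append(
            BenchmarkRecord(
                query_id=item.domain_id,
                sensitivity_family=sens["family"],
                sensitivity_superfamily=sens["superfamily"],
                sensitivity_fold=sens["fold"],
                top20_fraction_same_fold=top_k_fold_fraction(ranked, item.label),
                length=struct.L,
                contact_order=(
                    contact_order(struct).contact_order if struct.L >= 2 else 0.0
                ),
                class_id=item.label.class_id,
            )
        )

    summary = BenchmarkSummary(
        n_queries=len(records),
        mean_sensitivity_family=float(
            np.mean([r.sensitivity_family for r in records])
        ),
        mean_sensitivity_superfamily=float(
            np.mean([r.sensitivity_superfamily for r in records])
        ),
        mean_sensitivity_fold=float(np.mean([r.sensitivity_fold for r in records])),
        mean_top20_fraction_same_fold=float(
            np.mean([r.top20_fraction_same_fold for r in records])
        ),
        self_hit_rank1_fraction=self_hits / len(records),
    )
    return records, summary


def stratify(
    records: list[BenchmarkRecord],
    by: Literal["class", "length", "contact_order"],
) -> dict[str, float]:
    """Mean fold-level sensitivity per stratum (class, length bin, or
    contact-order bin)."""
    groups: dict[str, list[float]] = {}
    for r in records:
        if by == "class":
            key = r.class_id
        elif by == "length":
            edges = LENGTH_BINS
            i = np.searchsorted(edges, r.length, side="right") - 1
            key = f"{edges[i]}-{edges[i + 1]}" if edges[i + 1] < 10**9 else f">={edges[i]}"
        elif by == "contact_order":
            edges = CONTACT_ORDER_BINS
            i = min(np.searchsorted(edges, r.contact_order, side="right") - 1,
                    len(edges) - 2)
            key = f"{edges[i]:.2f}-{edges[i + 1]:.2f}"
        else:
            raise ValueError(f"unknown stratification {by!r}")
        groups.setdefault(key, []).append(r.sensitivity_fold)
    return {k: float(np.mean(v)) for k, v in sorted(groups.items())}


def write_benchmark_tsv(
    records: list[BenchmarkRecord], summary: BenchmarkSummary, per_query_path, summary_path
) -> None:
    with open(per_query_path, "w") as fh:
        fh.write(
            "query\tsensitivity_family\tsensitivity_superfamily\t"
            "sensitivity_fold\ttop20_fraction_same_fold\tlength\t"
            "contact_order\tclass\n"
        )
        for r in records:
            fh.write(
                f"{r.query_id}\t{r.sensitivity_family:.6f}\t"
                f"{r.sensitivity_superfamily:.6f}\t{r.sensitivity_fold:.6f}\t"
                f"{r.top20_fraction_same_fold:.6f}\t{r.length}\t"
                f"{r.contact_order:.6f}\t{r.class_id}\n"
            )
    with open(summary_path, "w") as fh:
        fh.write("metric\tvalue\n")
        for name, value in vars(summary).items():
            fh.write(f"{name}\t{value:.6f}\n")
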