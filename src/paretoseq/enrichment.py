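"""Gene-set enrichment of prioritized gene lists.

The score is deliberately plain: for a gene set G and an annotation term i
with annotated gene set GO_i, the enrichment score is the fraction

    f_i = |G intersect GO_i| / |G|,

an exact rational in [0, 1].  Applied cumulatively over Pareto fronts
(fronts 1..i pooled) it traces how quickly a functional category is
recovered as the ranking is descended.  No hypergeometric testing or
ontology-graph propagation is performed; term membership comes from a
user-supplied two-column table.
"""

from __future__ import annotations

from typing import Mapping, Set

import pandas as pd

from .errors import FormatError, ValidationError
from .pareto import ParetoRanking

__all__ = [
    "read_gene_sets",
    "enrichment_score",
    "cumulative_front_scores",
]

#: term_id -> set of gene_ids
GeneSetAnnotation = Mapping[str, Set[str]]


def read_gene_sets(path) -> dict[str, set[str]]:
    """Read a 2-column TSV (term_id, gene_id) into term -> gene set."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: gene-set annotation needs 2 columns (term_id, gene_id)")
    if df.iloc[0, 0] in ("term_id", "term"):
        df = df.iloc[1:]
    annotation: dict[str, set[str]] = {}
    for term, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        annotation.setdefault(term, set()).add(gene)
    return annotation


def enrichment_score(genes: Set[str], annotation: GeneSetAnnotation, term: str) -> float:
    """Fraction of ``genes`` annotated with ``term``: |G ∩ GO_i| / |G|."""
    if not genes:
        raise ValidationError("enrichment_score: empty gene set")
    if term not in annotation:
        raise ValidationError(f"enrichment_score: unknown term {term!r}")
    return len(set(genes) & set(annotation[term])) / len(genes)


def cumulative_front_scores(
    ranking: ParetoRanking, annotation: GeneSetAnnotation, term: str
) -> list[tuple[int, float]]:
    """Enrichment of the pooled fronts 1..i, for every i.

    Returns one (cumulative gene count, score) point per front, mirroring
    the enrichment-vs-list-depth curves used to compare rankings.
    """
    if len(ranking.table) == 0:
        raise ValidationError("cumulative_front_scores: empty ranking")
    points: list[tuple[int, float]] = []
    pooled: set[str] = set()
    for i in range(1, ranking.n_fronts() + 1):
        pooled |= set(ranking.front(i))
        points.append((len(pooled), enrichment_score(pooled, annotation, term)))
    return points
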