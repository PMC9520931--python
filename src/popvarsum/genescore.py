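"""Cohort-level gene mutation scores and tumor-vs-healthy differences.

For a cohort *c* (a donor population defined by a filter) and a gene *G*,
the gene score is the cohort's variant burden in the gene normalized by
cohort size:

    S(G, c) = (sum of occurrences of every variant in G's region) / size(c)

where a variant's occurrence is summed over donors (each contributing 0,
1 or 2 chromosome copies).  Scores are then rank-normalized within each
cohort by dividing by the cohort's maximum gene score, so the top gene
scores 1.0 and the others scale proportionally.  The differential
ranking orders candidate genes by the difference of their normalized
scores between a tumor and a healthy cohort; the gene mutating most
disproportionately in tumors comes first.

This deliberately replaces per-donor mutational profiles (and
distribution-comparison statistics such as the unidirectional Earth
Mover's Difference) with a single aggregate score per gene and cohort:
only cohort-level counts are consumed, never individual genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import PopvarsumError
from .popquery import PopulationFilter, QueryEngine, RegionSpec

__all__ = [
    "GeneScoreRecord",
    "DiffResult",
    "gene_score",
    "rank_normalize",
    "differential_gene_ranking",
]


@dataclass(frozen=True)
class GeneScoreRecord:
    gene: str
    score: float  # S = sum of variant occurrences / cohort size
    n_variants: int
    cohort_size: int
    normalized: float | None = None


@dataclass(frozen=True)
class DiffResult:
    gene: str
    score_tumor: float
    score_healthy: float
    normalized_tumor: float
    normalized_healthy: float
    diff: float


def _as_region(engine: QueryEngine, gene) -> tuple[str, RegionSpec]:
    if isinstance(gene, RegionSpec):
        name = gene.gene or f"{gene.chrom}:{gene.start}-{gene.stop}"
        return name, gene
    return str(gene), RegionSpec(gene=str(gene))


def gene_score(engine: QueryEngine, cohort: PopulationFilter, gene) -> GeneScoreRecord:
    """Score one gene for one cohort: total occurrences of the gene's
    variants in the cohort divided by the cohort size."""
    name, region = _as_region(engine, gene)
    population = engine.select_population(cohort)
    if not population:
        raise PopvarsumError(f"cohort for gene {name} selects no donors")
    variants = engine.variants_in_region(cohort, region)
    total = sum(v["occurrence"] for v in variants)
    return GeneScoreRecord(
        gene=name,
        score=total / len(population),
        n_variants=len(variants),
        cohort_size=len(population),
    )


def rank_normalize(scores: list[GeneScoreRecord]) -> list[GeneScoreRecord]:
    """Fill ``normalized``: each score divided by the maximum, so the top
    gene gets 1.0 (ties share it); all zeros stay zero."""
    if not scores:
        raise PopvarsumError("no gene scores to normalize")
    top = max(r.score for r in scores)
    if top == 0:
        return [replace(r, normalized=0.0) for r in scores]
    return [replace(r, normalized=r.score / top) for r in scores]


def differential_gene_ranking(
    engine: QueryEngine,
    tumor: PopulationFilter,
    healthy: PopulationFilter,
    genes,
) -> list[DiffResult]:
    """Per-gene difference of normalized scores between the two cohorts,
    sorted by diff descending (gene name ascending on ties)."""
    tumor_scores = rank_normalize([gene_score(engine, tumor, g) for g in genes])
    healthy_scores = rank_normalize([gene_score(engine, healthy, g) for g in genes])
    out = [
        DiffResult(
            gene=t.gene,
            score_tumor=t.score,
            score_healthy=h.score,
            normalized_tumor=t.normalized,
            normalized_healthy=h.normalized,
            diff=t.normalized - h.normalized,
        )
        for t, h in zip(tumor_scores, healthy_scores)
    ]
    out.sort(key=lambda r: (-r.diff, r.gene))
    return out
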