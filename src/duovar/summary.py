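"""CNV summaries, gene overlap and GO-term enrichment.

Per-chromosome CNV statistics (count, total length, percent of chromosome,
mean/median/min/max) with a genome total row; interval intersection of
calls with gene models; and one-sided Fisher enrichment of GO terms among
CNV-overlapped genes against an annotated background, corrected with
Benjamini-Yekutieli (valid under arbitrary dependence between terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


class SummaryError(ValueError):
    pass


@dataclass(frozen=True)
class ChromosomeSummary:
    chrom: str
    chrom_length: int
    n_cnv: int
    total_cnv_length: int
    pct_length_in_cnv: float
    mean_length: float
    median_length: float
    max_length: int
    min_length: int


def _summary(chrom: str, chrom_length: int, lengths: np.ndarray) -> ChromosomeSummary:
    n = len(lengths)
    total = int(lengths.sum()) if n else 0
    return ChromosomeSummary(
        chrom=chrom,
        chrom_length=int(chrom_length),
        n_cnv=n,
        total_cnv_length=total,
        pct_length_in_cnv=100.0 * total / chrom_length if chrom_length else 0.0,
        mean_length=total / n if n else 0.0,
        median_length=float(np.median(lengths)) if n else 0.0,
        max_length=int(lengths.max()) if n else 0,
        min_length=int(lengths.min()) if n else 0,
    )


def summarize_by_chromosome(
    cnvs: pd.DataFrame, chrom_lengths: dict[str, int]
) -> list[ChromosomeSummary]:
    """Per-chromosome rows (zeros for CNV-free chromosomes) plus a TOTAL row.

    ``cnvs`` needs chrom, start, end (0-based half-open).  Calls on unknown
    chromosomes or beyond chromosome bounds raise.
    """
    unknown = set(cnvs["chrom"]) - set(chrom_lengths)
    if unknown:
        raise SummaryError(f"calls on unknown chromosome(s): {sorted(unknown)}")
    for r in cnvs.itertuples():
        if r.start < 0 or r.end > chrom_lengths[r.chrom]:
            raise SummaryError(f"call outside {r.chrom} bounds")
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = cnvs[cnvs["chrom"] == chrom]
        rows.append(_summary(chrom, length, (sub["end"] - sub["start"]).to_numpy()))
    all_lengths = (cnvs["end"] - cnvs["start"]).to_numpy()
    rows.append(_summary("TOTAL", sum(chrom_lengths.values()), all_lengths))
    return rows


def aggregate_totals(
    per_chrom: pd.DataFrame,
) -> dict:
    """Genome total row from per-chromosome (chrom_length, total_cnv_length,
    n_cnv) counts alone — mean and genome fraction follow arithmetically;
    the median needs raw call lengths and is not derivable here."""
    genome_length = int(per_chrom["chrom_length"].sum())
    total = int(per_chrom["total_cnv_length"].sum())
    n = int(per_chrom["n_cnv"].sum())
    return {
        "chrom_length": genome_length,
        "total_cnv_length": total,
        "n_cnv": n,
        "mean_length": total / n if n else 0.0,
        "pct_length_in_cnv": 100.0 * total / genome_length,
    }


def summaries_to_frame(rows: list[ChromosomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def overlap_genes(
    cnvs: pd.DataFrame, genes: pd.DataFrame
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Intersect CNV calls with gene intervals (>= 1 bp overlap).

    ``cnvs``: id, chrom, start, end; ``genes``: gene_id, chrom, start, end —
    both 0-based half-open.  Returns (cnv -> genes, gene -> cnvs), each
    list sorted and duplicate-free.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples():
        trees.setdefault(g.chrom, IntervalTree())[g.start : g.end] = g.gene_id
    cnv_to_genes: dict[str, list[str]] = {}
    gene_to_cnvs: dict[str, list[str]] = {}
    for c in cnvs.itertuples():
        hits = trees.get(c.chrom, IntervalTree()).overlap(c.start, c.end)
        names = sorted({iv.data for iv in hits})
        if names:
            cnv_to_genes[c.id] = names
        for name in names:
            gene_to_cnvs.setdefault(name, []).append(c.id)
    for name in gene_to_cnvs:
        gene_to_cnvs[name] = sorted(set(gene_to_cnvs[name]))
    return cnv_to_genes, gene_to_cnvs


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_count: int
    study_total: int
    population_count: int
    population_total: int
    p_fisher: float
    p_adjusted: float


def go_enrichment(
    study_genes: set[str],
    population_genes: set[str],
    annotation: pd.DataFrame,
) -> list[EnrichmentResult]:
    """One-sided (enrichment) Fisher test per GO term, BY-corrected.

    ``annotation`` maps gene -> term (columns gene, term); terms are taken
    as annotated, with no ontology-graph propagation.  Only terms observed
    in the study set are tested; results are sorted by adjusted p.
    """
    if not study_genes:
        return []
    if not study_genes <= population_genes:
        raise SummaryError("study genes must be a subset of the population")
    anno = annotation[annotation["gene"].isin(population_genes)]
    term_to_genes = anno.groupby("term")["gene"].agg(set)
    n_study = len(study_genes)
    n_pop = len(population_genes)
    rows = []
    for term, genes_with in term_to_genes.items():
        a = len(genes_with & study_genes)
        if a == 0:
            continue
        k = len(genes_with)
        table = [[a, n_study - a], [k - a, (n_pop - k) - (n_study - a)]]
        _, p = fisher_exact(table, alternative="greater")
        rows.append((term, a, k, float(p)))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_by")
    results = [
        EnrichmentResult(
            term=term,
            study_count=a,
            study_total=n_study,
            population_count=k,
            population_total=n_pop,
            p_fisher=p,
            p_adjusted=float(pa),
        )
        for (term, a, k, p), pa in zip(rows, p_adj)
    ]
    return sorted(results, key=lambda r: (r.p_adjusted, r.p_fisher, r.term))


def fold_coverage(total_mapped_bases: float, genome_length: float) -> float:
    """Mapped bases over genome length, in matching units."""
    if genome_length <= 0:
        raise SummaryError("genome length must be positive")
    return total_mapped_bases / genome_length
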