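"""Post-calling SNP filters: depth-percentile cap and flank-uniqueness.

High-depth calls (deeper than the per-animal 95th percentile) are removed
as likely collapsed-repeat artifacts; calls whose flanking sequence cannot
be placed uniquely on the reference are removed as ambiguous.  The
built-in uniqueness oracle is an exact, strand-aware substring search of
the flank+allele sequence, pluggable so an external aligner can stand in.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Mapping

import pandas as pd

from .annotation import reverse_complement

logger = logging.getLogger(__name__)


def depth_percentile_filter(
    snps: pd.DataFrame, percentile: float = 95.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition SNPs into (kept, removed) by a nearest-rank depth cutoff.

    The cutoff is the nearest-rank percentile of all input depths; records
    strictly deeper than it are removed.
    """
    if snps.empty:
        return snps.copy(), snps.copy()
    depths = snps["depth"].to_numpy()
    n = len(depths)
    rank = max(1, math.ceil(percentile / 100.0 * n))
    cutoff = sorted(depths)[min(rank, n) - 1]
    keep = snps["depth"] <= cutoff
    removed = snps.loc[~keep].copy()
    removed["filter_reason"] = f"depth>{cutoff}"
    return snps.loc[keep].copy(), removed


def count_occurrences(haystack: str, needle: str) -> int:
    """Overlap-aware substring occurrence count."""
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def exact_uniqueness_oracle(reference: Mapping[str, str]) -> Callable[[str], int]:
    """Placement counter: occurrences of a query on both reference strands."""
    seqs = {name: str(reference[name]).upper() for name in reference.keys()}

    def placements(query: str) -> int:
        query = query.upper()
        rc = reverse_complement(query)
        total = 0
        for seq in seqs.values():
            total += count_occurrences(seq, query)
            if rc != query:
                total += count_occurrences(seq, rc)
        return total

    return placements


def uniqueness_filter(
    snps: pd.DataFrame,
    reference: Mapping[str, str],
    flank_length: int = 100,
    predicate: Callable[[str], int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep SNPs whose flank+/-allele sequence places exactly once.

    The query is the reference sequence from ``flank_length`` bases before
    to after the site (truncated and logged near contig edges).  ``predicate``
    maps a query sequence to its placement count; the default is exact
    double-strand substring search of the supplied reference.
    """
    if snps.empty:
        return snps.copy(), snps.copy()
    oracle = predicate or exact_uniqueness_oracle(reference)
    keep_mask = []
    for r in snps.itertuples():
        chrom_seq = str(reference[r.chrom])
        pos0 = int(r.pos) - 1
        lo = max(0, pos0 - flank_length)
        hi = min(len(chrom_seq), pos0 + flank_length + 1)
        if lo != pos0 - flank_length or hi != pos0 + flank_length + 1:
            logger.warning(
                "flank truncated at contig edge for %s:%d", r.chrom, r.pos
            )
        query = chrom_seq[lo:hi]
        keep_mask.append(oracle(query) == 1)
    keep = pd.Series(keep_mask, index=snps.index)
    removed = snps.loc[~keep].copy()
    removed["filter_reason"] = "ambiguous_placement"
    return snps.loc[keep].copy(), removed


def apply_filters(
    snps: pd.DataFrame,
    reference: Mapping[str, str],
    depth_percentile: float = 95.0,
    flank_length: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Depth filter then uniqueness filter; removed rows carry a reason."""
    kept, removed_depth = depth_percentile_filter(snps, depth_percentile)
    kept, removed_uniq = uniqueness_filter(kept, reference, flank_length)
    removed = pd.concat([removed_depth, removed_uniq], ignore_index=True)
    return kept, removed
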