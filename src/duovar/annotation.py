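"""SNP functional-class assignment and orthologue conservation scoring.

Each variant is classified against a set of gene models into a single
consequence class (synonymous/nonsynonymous coding, stop gained/lost,
splice site, UTR, intronic, up/downstream, intergenic, ...), resolving
overlapping transcripts by a severity precedence.  Nonsynonymous variants
additionally receive an "alignment score change" (ASC): the mean BLOSUM62
score of the variant residue against a panel of orthologous residues minus
the mean score of the reference residue against the same panel.  Negative
values mark variants that break cross-species conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
CODON_TO_AA = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))  # the 61 non-stop codons


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


class FunctionalClass(str, Enum):
    ESSENTIAL_SPLICE_SITE = "essential_splice_site"
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    NONSYNONYMOUS_CODING = "nonsynonymous_coding"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS_CODING = "synonymous_coding"
    UTR5 = "utr5"
    UTR3 = "utr3"
    WITHIN_MATURE_MIRNA = "within_mature_mirna"
    WITHIN_NONCODING_GENE = "within_noncoding_gene"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


#: Most severe first; one class per SNP after reduction across transcripts.
SEVERITY_ORDER: tuple[FunctionalClass, ...] = (
    FunctionalClass.ESSENTIAL_SPLICE_SITE,
    FunctionalClass.STOP_GAINED,
    FunctionalClass.STOP_LOST,
    FunctionalClass.NONSYNONYMOUS_CODING,
    FunctionalClass.SPLICE_SITE,
    FunctionalClass.SYNONYMOUS_CODING,
    FunctionalClass.UTR5,
    FunctionalClass.UTR3,
    FunctionalClass.WITHIN_MATURE_MIRNA,
    FunctionalClass.WITHIN_NONCODING_GENE,
    FunctionalClass.INTRONIC,
    FunctionalClass.UPSTREAM,
    FunctionalClass.DOWNSTREAM,
    FunctionalClass.INTERGENIC,
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

# Ensembl-style intronic splice windows: first/last 2 intronic bases are
# essential, bases 3-8 from either exon boundary are splice_site.
ESSENTIAL_SPLICE_BP = 2
SPLICE_SITE_BP = 8
DEFAULT_FLANK_WINDOW = 5000  # up/downstream window in bp


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon structure plus genomic CDS intervals.

    Coordinates are 0-based half-open; ``exons`` and ``cds`` are sorted by
    genomic start regardless of strand.  Non-coding transcripts have an
    empty ``cds``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError("exon end must exceed start")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        """CDS in translation order (reverse-complemented on minus strand)."""
        chrom_seq = reference[self.chrom]
        seq = "".join(str(chrom_seq[s:e]) for s, e in self.cds)
        return reverse_complement(seq) if self.strand == "-" else seq

    def cds_offset(self, pos0: int) -> int | None:
        """Translation-order CDS offset of genomic position, or None."""
        off = 0
        for s, e in self.cds:
            if s <= pos0 < e:
                plus_off = off + (pos0 - s)
                if self.strand == "+":
                    return plus_off
                return self.cds_length - 1 - plus_off
            off += e - s
        return None


@lru_cache(maxsize=1)
def blosum62() -> dict[tuple[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    return {
        (a, b): float(mat[a, b]) for a in AMINO_ACIDS for b in AMINO_ACIDS
    }


@dataclass(frozen=True)
class AscInput:
    """Residues entering the alignment-score-change computation."""

    ref_aa: str
    var_aa: str
    orthologues: tuple[str, ...]
    snp_id: str = ""

    def __post_init__(self) -> None:
        for res in (self.ref_aa, self.var_aa, *self.orthologues):
            if res not in AMINO_ACIDS:
                raise AnnotationError(f"nonstandard residue {res!r}")


@dataclass(frozen=True)
class AscScore:
    a: float
    n_orthologues: int
    defined: bool


def asc(inp: AscInput, matrix: Mapping[tuple[str, str], float] | None = None) -> AscScore:
    """Mean matrix score of variant-vs-orthologues minus reference-vs-orthologues.

    Undefined (not zero) with an empty orthologue panel; exactly zero when
    the variant residue equals the reference residue.
    """
    n = len(inp.orthologues)
    if n == 0:
        return AscScore(a=float("nan"), n_orthologues=0, defined=False)
    s = blosum62() if matrix is None else matrix
    sum_v = sum(s[inp.var_aa, o] for o in inp.orthologues)
    sum_r = sum(s[inp.ref_aa, o] for o in inp.orthologues)
    return AscScore(a=(sum_v - sum_r) / n, n_orthologues=n, defined=True)


def _coding_consequence(
    model: GeneModel, cds_seq: str, cds_off: int, alt: str
) -> tuple[FunctionalClass, bool]:
    """Consequence of substituting ``alt`` (forward-strand base) into the CDS.

    Returns (class, ref_matches_codon).
    """
    codon_idx, within = divmod(cds_off, 3)
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_tx = alt if model.strand == "+" else complement_base(alt)
    ref_ok = True  # caller checks genomic base; codon internally consistent
    new_codon = codon[:within] + alt_tx + codon[within + 1 :]
    old_stop = codon in STOP_CODONS
    new_stop = new_codon in STOP_CODONS
    if old_stop and new_stop:
        return FunctionalClass.SYNONYMOUS_CODING, ref_ok
    if old_stop:
        return FunctionalClass.STOP_LOST, ref_ok
    if new_stop:
        return FunctionalClass.STOP_GAINED, ref_ok
    if CODON_TO_AA[codon] == CODON_TO_AA[new_codon]:
        return FunctionalClass.SYNONYMOUS_CODING, ref_ok
    return FunctionalClass.NONSYNONYMOUS_CODING, ref_ok


def classify_in_transcript(
    pos0: int,
    alt: str,
    model: GeneModel,
    reference: Mapping[str, str],
    window: int = DEFAULT_FLANK_WINDOW,
) -> FunctionalClass | None:
    """Class of a forward-strand substitution relative to one transcript.

    Returns None when the position is outside the transcript and its
    up/downstream window.
    """
    start, end = model.start, model.end
    if pos0 < start or pos0 >= end:
        if pos0 < start and start - pos0 <= window:
            before = True
        elif pos0 >= end and pos0 - end < window:
            before = False
        else:
            return None
        upstream_side = before if model.strand == "+" else not before
        return FunctionalClass.UPSTREAM if upstream_side else FunctionalClass.DOWNSTREAM

    for i, (s, e) in enumerate(model.exons):
        if s <= pos0 < e:
            return _classify_exonic(pos0, alt, model, reference)
        if pos0 < s:  # in intron between exon i-1 and exon i
            intron_start = model.exons[i - 1][1]
            intron_end = s
            offset = min(pos0 - intron_start, intron_end - 1 - pos0) + 1
            if offset <= ESSENTIAL_SPLICE_BP:
                return FunctionalClass.ESSENTIAL_SPLICE_SITE
            if offset <= SPLICE_SITE_BP:
                return FunctionalClass.SPLICE_SITE
            return FunctionalClass.INTRONIC
    raise AssertionError("unreachable: position inside span but unplaced")


def _classify_exonic(
    pos0: int, alt: str, model: GeneModel, reference: Mapping[str, str]
) -> FunctionalClass:
    if model.biotype == "miRNA":
        return FunctionalClass.WITHIN_MATURE_MIRNA
    if not model.cds:
        return FunctionalClass.WITHIN_NONCODING_GENE
    cds_off = model.cds_offset(pos0)
    if cds_off is None:
        cds_start = model.cds[0][0]
        five_prime = pos0 < cds_start if model.strand == "+" else pos0 >= model.cds[-1][1]
        return FunctionalClass.UTR5 if five_prime else FunctionalClass.UTR3
    cds_seq = model.cds_sequence(reference)
    cls, _ = _coding_consequence(model, cds_seq, cds_off, alt)
    return cls


def classify_snp(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
    window: int = DEFAULT_FLANK_WINDOW,
) -> FunctionalClass:
    """Single consequence class for a SNP (1-based position, forward-strand
    alleles), reduced across overlapping transcripts by severity."""
    pos0 = pos - 1
    genome_base = str(reference[chrom][pos0 : pos0 + 1]).upper()
    if genome_base and genome_base != ref.upper():
        logger.warning(
            "ref allele %s disagrees with reference base %s at %s:%d; "
            "classifying against the reference codon",
            ref, genome_base, chrom, pos,
        )
    hits = []
    for m in models:
        if m.chrom != chrom:
            continue
        cls = classify_in_transcript(pos0, alt, m, reference, window=window)
        if cls is not None:
            hits.append(cls)
    if not hits:
        return FunctionalClass.INTERGENIC
    return min(hits, key=_SEVERITY_RANK.__getitem__)


def classify_table(
    snps: pd.DataFrame,
    models: Sequence[GeneModel],
    reference: Mapping[str, str],
    window: int = DEFAULT_FLANK_WINDOW,
) -> pd.DataFrame:
    """Vector wrapper: adds a ``functional_class`` column to a SNP table."""
    out = snps.copy()
    out["functional_class"] = [
        str(classify_snp(r.chrom, int(r.pos), r.ref, r.alt, models, reference, window))
        for r in snps.itertuples()
    ]
    return out


def tabulate_classes(
    annotated_a: pd.DataFrame, annotated_b: pd.DataFrame
) -> pd.DataFrame:
    """Per-class counts for two animals, their intersection and union.

    The intersection is keyed on (chrom, pos, alt); the union count is
    enforced by inclusion-exclusion per class and for the total row.
    Percentages (of each column total) are reported to one decimal.
    """
    key = ["chrom", "pos", "alt"]
    inter = annotated_a.merge(annotated_b[key], on=key, how="inner")
    rows = []
    for cls in SEVERITY_ORDER:
        name = cls.value
        ca = int((annotated_a["functional_class"] == name).sum())
        cb = int((annotated_b["functional_class"] == name).sum())
        ci = int((inter["functional_class"] == name).sum())
        rows.append(summarize_class_counts(name, ca, cb, ci))
    df = pd.DataFrame(rows)
    total = {
        "functional_class": "total",
        "count_a": df["count_a"].sum(),
        "count_b": df["count_b"].sum(),
        "count_intersection": df["count_intersection"].sum(),
    }
    total["count_union"] = (
        total["count_a"] + total["count_b"] - total["count_intersection"]
    )
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    for col in ("count_a", "count_b", "count_intersection", "count_union"):
        denom = df[col].iloc[-1]
        df["pct_" + col[6:]] = (
            (100.0 * df[col] / denom).round(1) if denom else 0.0
        )
    return df


def summarize_class_counts(
    name: str, count_a: int, count_b: int, count_intersection: int
) -> dict:
    """One tabulation row; union derived by inclusion-exclusion."""
    if count_intersection > min(count_a, count_b):
        raise AnnotationError("intersection exceeds a per-animal count")
    return {
        "functional_class": name,
        "count_a": count_a,
        "count_b": count_b,
        "count_intersection": count_intersection,
        "count_union": count_a + count_b - count_intersection,
    }


@dataclass
class AscProfile:
    """Histogram of ASC values in fixed-width bins anchored at zero."""

    bin_edges: np.ndarray
    counts: np.ndarray
    proportion_heterozygous: np.ndarray
    proportion_shared: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
                "proportion_heterozygous": self.proportion_heterozygous,
                "proportion_shared": self.proportion_shared,
            }
        )


def asc_bin_profile(records: pd.DataFrame, bin_width: float = 3.0) -> AscProfile:
    """Bin nonsynonymous SNPs by ASC (columns: asc, zygosity, shared).

    Bins have the given width with zero as a bin edge; per-bin heterozygous
    and shared-with-other-animal proportions accompany the counts.
    """
    if records.empty:
        empty = np.array([])
        return AscProfile(np.array([0.0]), empty, empty, empty)
    vals = records["asc"].to_numpy(dtype=float)
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    idx = np.clip(np.digitize(vals, edges) - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    counts = np.bincount(idx, minlength=n_bins)
    het = (records["zygosity"].to_numpy() == "het").astype(float)
    shared = records["shared"].to_numpy().astype(float)
    with np.errstate(invalid="ignore"):
        prop_het = np.bincount(idx, weights=het, minlength=n_bins) / counts
        prop_shared = np.bincount(idx, weights=shared, minlength=n_bins) / counts
    return AscProfile(edges, counts, prop_het, prop_shared)


def load_orthologue_panels(path) -> list[AscInput]:
    """Read panels from TSV: snp_id, ref_aa, var_aa, comma-separated residues."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    panels = []
    for r in df.itertuples():
        orth = tuple(x for x in r.orthologue_residues.split(",") if x)
        panels.append(
            AscInput(ref_aa=r.ref_aa, var_aa=r.var_aa, orthologues=orth, snp_id=r.snp_id)
        )
    return panels


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Load transcripts from a GFF3 file (1-based inclusive on disk)."""
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for tx in db.features_of_type(("mRNA", "transcript", "ncRNA", "miRNA")):
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start - 1, f.end) for f in db.children(tx, featuretype="CDS"))
        )
        biotype = tx.attributes.get("biotype", [None])[0] or (
            "protein_coding" if cds else
            ("miRNA" if tx.featuretype == "miRNA" else "noncoding")
        )
        models.append(
            GeneModel(
                gene_id=tx.attributes.get("Parent", [tx.id])[0],
                transcript_id=tx.id,
                chrom=tx.seqid,
                strand=tx.strand,
                exons=exons,
                cds=cds,
                biotype=biotype,
            )
        )
    return models
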