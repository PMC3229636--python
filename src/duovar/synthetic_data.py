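"""Synthetic inputs with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here with known truth:

* read placements for two samples along a reference, Poisson per base pair,
  with planted copy-number segments (expected count scales with copy/2);
* SNP truth sets with an array callset (complete, correct), a sequencing
  callset with zygosity-dependent miss rates and an allele-drop branch, and
  a custom-panel validation table with planted monomorphic (false) SNPs;
* orthologue residue panels with tunable conservation;
* multi-exon gene models with frame-complete CDS written into a random
  reference sequence, plus SNPs planted with known consequence classes;
* qPCR Ct replicate tables with Gaussian cycle noise.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AMINO_ACIDS,
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    AscInput,
    FunctionalClass,
    GeneModel,
    reverse_complement,
)

BASES = "ACGT"


class SyntheticDataError(ValueError):
    pass


class SegmentOutOfBoundsError(SyntheticDataError):
    pass


class PackingError(SyntheticDataError):
    pass


@dataclass(frozen=True)
class GenomeSpec:
    """Reference layout: chromosome names, lengths (bp) and a seed."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise SyntheticDataError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise SyntheticDataError("names and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise SyntheticDataError("chromosome lengths must be positive")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


@dataclass(frozen=True)
class CnvSegment:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    copy_number_a: float
    copy_number_b: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise SyntheticDataError("segment end must exceed start")
        if self.copy_number_a < 0 or self.copy_number_b < 0:
            raise SyntheticDataError("copy numbers must be non-negative")


@dataclass(frozen=True)
class CnvPlan:
    """Planted copy states; copy number is 2/2 outside the segments."""

    segments: tuple[CnvSegment, ...] = ()

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CnvSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise SyntheticDataError("segments overlap within a chromosome")

    def validate_against(self, genome: GenomeSpec) -> None:
        lengths = genome.chrom_lengths
        for seg in self.segments:
            if seg.chrom not in lengths:
                raise SegmentOutOfBoundsError(f"unknown chromosome {seg.chrom}")
            if seg.start < 0 or seg.end > lengths[seg.chrom]:
                raise SegmentOutOfBoundsError(
                    f"segment {seg.chrom}:{seg.start}-{seg.end} outside chromosome"
                )


Placements = dict[str, np.ndarray]  # chrom -> sorted 1-based read start positions


def _regions(plan: CnvPlan, chrom: str, length: int):
    """Yield (start, end, cn_a, cn_b) tiling the chromosome."""
    segs = sorted((s for s in plan.segments if s.chrom == chrom), key=lambda s: s.start)
    cursor = 0
    for seg in segs:
        if seg.start > cursor:
            yield cursor, seg.start, 2.0, 2.0
        yield seg.start, seg.end, seg.copy_number_a, seg.copy_number_b
        cursor = seg.end
    if cursor < length:
        yield cursor, length, 2.0, 2.0


def simulate_read_placements(
    genome: GenomeSpec,
    plan: CnvPlan,
    mean_depth_a: float,
    mean_depth_b: float,
    window_hint: int,
    seed: int,
) -> tuple[Placements, Placements, CnvPlan]:
    """Draw single-base read starts for two samples.

    ``mean_depth_*`` is the expected read count per ``window_hint`` bp at
    copy number 2; within a planted segment the local rate scales by
    copy_number/2.  Returns (placements_a, placements_b, truth plan).
    """
    if mean_depth_a <= 0 or mean_depth_b <= 0:
        raise SyntheticDataError("mean depths must be positive")
    plan.validate_against(genome)
    rng = np.random.default_rng(seed)
    out_a: Placements = {}
    out_b: Placements = {}
    for chrom, length in genome.chrom_lengths.items():
        parts_a, parts_b = [], []
        for start, end, cn_a, cn_b in _regions(plan, chrom, length):
            span = end - start
            for parts, depth, cn in (
                (parts_a, mean_depth_a, cn_a),
                (parts_b, mean_depth_b, cn_b),
            ):
                rate = depth / window_hint * cn / 2.0
                n = rng.poisson(rate * span)
                if n:
                    parts.append(rng.integers(start, end, size=n) + 1)
        out_a[chrom] = np.sort(np.concatenate(parts_a)) if parts_a else np.empty(0, int)
        out_b[chrom] = np.sort(np.concatenate(parts_b)) if parts_b else np.empty(0, int)
    return out_a, out_b, plan


def write_placements(placements: Placements, path) -> None:
    """TSV with one ``chrom<TAB>position`` (1-based) row per read."""
    with open(path, "w") as fh:
        for chrom in placements:
            for pos in placements[chrom]:
                fh.write(f"{chrom}\t{pos}\n")


def read_placements(path) -> Placements:
    df = pd.read_csv(path, sep="\t", names=["chrom", "position"], dtype={"chrom": str})
    return {
        chrom: np.sort(sub["position"].to_numpy())
        for chrom, sub in df.groupby("chrom", sort=False)
    }


# ---------------------------------------------------------------------------
# SNP truth / callset simulation


@dataclass(frozen=True)
class SnpTruthConfig:
    n_sites: int
    fraction_heterozygous: float = 0.5
    miss_rate_hom: float = 0.0
    miss_rate_het: float = 0.0
    allele_drop_fraction: float = 0.0
    monomorphic_fraction: float = 0.0
    seed: int = 0
    mean_depth: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "fraction_heterozygous",
            "miss_rate_hom",
            "miss_rate_het",
            "allele_drop_fraction",
            "monomorphic_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticDataError(f"{name} must lie in [0, 1], got {v}")
        if self.n_sites < 0:
            raise SyntheticDataError("n_sites must be non-negative")


@dataclass
class SnpCallsets:
    truth: pd.DataFrame
    sequencing: pd.DataFrame
    array: pd.DataFrame
    panel: pd.DataFrame


def simulate_snp_callsets(cfg: SnpTruthConfig, genome: GenomeSpec) -> SnpCallsets:
    """Truth sites plus array, sequencing and custom-panel callsets.

    The array table contains every truth site with its correct genotype.
    The sequencing table misses hom-alt sites with ``miss_rate_hom`` and het
    sites with ``miss_rate_het``; of the missed hets, ``allele_drop_fraction``
    are instead emitted as homozygous calls for the alternate allele (the
    single-allele discordance mode), the remainder are omitted.  The panel
    table flags ``monomorphic_fraction`` of the reported SNPs as monomorphic
    false positives.
    """
    if cfg.n_sites > genome.total_length:
        raise SyntheticDataError("more sites requested than genome positions")
    rng = np.random.default_rng(cfg.seed)
    offsets = rng.choice(genome.total_length, size=cfg.n_sites, replace=False)
    offsets.sort()
    bounds = np.cumsum([0] + list(genome.lengths))
    chrom_idx = np.searchsorted(bounds, offsets, side="right") - 1
    chroms = np.array(genome.names, dtype=object)[chrom_idx]
    pos = offsets - bounds[chrom_idx] + 1  # 1-based

    ref_i = rng.integers(0, 4, cfg.n_sites)
    alt_i = (ref_i + rng.integers(1, 4, cfg.n_sites)) % 4
    base_arr = np.frombuffer(BASES.encode(), dtype="S1").astype("U1")
    ref = base_arr[ref_i]
    alt = base_arr[alt_i]
    het = rng.random(cfg.n_sites) < cfg.fraction_heterozygous
    zyg = np.where(het, "het", "hom_alt")

    truth = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": ref, "alt": alt, "zygosity": zyg}
    )

    array = pd.DataFrame(
        {
            "marker": [f"mk{i}" for i in range(cfg.n_sites)],
            "chrom": chroms,
            "pos": pos,
            "allele1": ref,
            "allele2": alt,
            "call": np.where(het, np.char.add(ref, alt), np.char.add(alt, alt)),
            "unambiguous": True,
        }
    )

    u = rng.random(cfg.n_sites)
    missed = np.where(het, u < cfg.miss_rate_het, u < cfg.miss_rate_hom)
    dropped = missed & het & (rng.random(cfg.n_sites) < cfg.allele_drop_fraction)
    emitted = ~missed | dropped
    seq_zyg = np.where(dropped, "hom_alt", zyg)
    depth = rng.poisson(cfg.mean_depth, cfg.n_sites) + 1
    sequencing = pd.DataFrame(
        {
            "chrom": chroms[emitted],
            "pos": pos[emitted],
            "ref": ref[emitted],
            "alt": alt[emitted],
            "zygosity": seq_zyg[emitted],
            "depth": depth[emitted],
        }
    ).reset_index(drop=True)

    n_rep = len(sequencing)
    mono = rng.random(n_rep) < cfg.monomorphic_fraction
    panel = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(n_rep)],
            "chrom": sequencing["chrom"],
            "pos": sequencing["pos"],
            "status": np.where(mono, "monomorphic", "polymorphic"),
        }
    )

    truth["missed_by_sequencing"] = missed
    truth["allele_dropped"] = dropped
    return SnpCallsets(truth=truth, sequencing=sequencing, array=array, panel=panel)


# ---------------------------------------------------------------------------
# Orthologue panels


@dataclass(frozen=True)
class OrthologuePanelConfig:
    n_snps: int
    n_species: int = 10
    conservation: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 0:
            raise SyntheticDataError("n_species must be non-negative")
        if not 0.0 <= self.conservation <= 1.0:
            raise SyntheticDataError("conservation must lie in [0, 1]")


def simulate_orthologue_panels(cfg: OrthologuePanelConfig) -> list[AscInput]:
    """Panels with reference/variant residues and orthologues that equal the
    reference residue with probability ``conservation``."""
    rng = np.random.default_rng(cfg.seed)
    aas = list(AMINO_ACIDS)
    panels = []
    for i in range(cfg.n_snps):
        r = aas[rng.integers(20)]
        v = aas[(aas.index(r) + rng.integers(1, 20)) % 20]
        orth = tuple(
            r if rng.random() < cfg.conservation else aas[rng.integers(20)]
            for _ in range(cfg.n_species)
        )
        panels.append(AscInput(ref_aa=r, var_aa=v, orthologues=orth, snp_id=f"snp{i}"))
    return panels


def write_orthologue_panels(panels: Sequence[AscInput], path) -> None:
    pd.DataFrame(
        {
            "snp_id": [p.snp_id for p in panels],
            "ref_aa": [p.ref_aa for p in panels],
            "var_aa": [p.var_aa for p in panels],
            "orthologue_residues": [",".join(p.orthologues) for p in panels],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneSet:
    genes: list[GeneModel]
    reference: dict[str, str]

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in self.genes:
                ftype = {"protein_coding": "mRNA", "miRNA": "miRNA"}.get(
                    m.biotype, "transcript"
                )
                fh.write(
                    f"{m.chrom}\tduovar\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}"
                    f"\t.\tID={m.gene_id};biotype={m.biotype}\n"
                )
                fh.write(
                    f"{m.chrom}\tduovar\t{ftype}\t{m.start + 1}\t{m.end}\t.\t{m.strand}"
                    f"\t.\tID={m.transcript_id};Parent={m.gene_id};biotype={m.biotype}\n"
                )
                for s, e in m.exons:
                    fh.write(
                        f"{m.chrom}\tduovar\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"Parent={m.transcript_id}\n"
                    )
                for s, e in m.cds:
                    fh.write(
                        f"{m.chrom}\tduovar\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"Parent={m.transcript_id}\n"
                    )

    def write_reference_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def write_cds_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for m in self.genes:
                if not m.cds:
                    continue
                seq = m.cds_sequence(self.reference)
                fh.write(f">{m.transcript_id}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


MIN_INTRON = 60
GENE_GAP = 12_000  # keeps 5 kb up/downstream windows of neighbours disjoint


def simulate_gene_models(
    genome: GenomeSpec,
    n_genes: int,
    seed: int,
    *,
    min_codons: int = 40,
    max_codons: int = 200,
    noncoding_fraction: float = 0.1,
    mirna_fraction: float = 0.05,
) -> GeneSet:
    """Random reference sequence with packed multi-exon genes.

    Protein-coding CDS are frame-complete (start ATG, end stop, no internal
    stop), flanked by UTRs, with introns of at least 60 bp; genes are spaced
    so neighbouring up/downstream windows never overlap.  Raises
    PackingError when the genome cannot host ``n_genes`` at that spacing.
    """
    rng = np.random.default_rng(seed)
    reference = {
        name: list(_random_seq(rng, length)) for name, length in genome.chrom_lengths.items()
    }
    genes: list[GeneModel] = []
    cursors = {name: GENE_GAP for name in genome.names}
    chrom_cycle = list(genome.names)
    gi = 0
    attempts = 0
    while gi < n_genes:
        attempts += 1
        if attempts > n_genes * 10 + len(chrom_cycle):
            raise PackingError("cannot pack requested genes into the genome")
        chrom = chrom_cycle[gi % len(chrom_cycle)]
        u = rng.random()
        if u < mirna_fraction:
            biotype = "miRNA"
        elif u < mirna_fraction + noncoding_fraction:
            biotype = "noncoding"
        else:
            biotype = "protein_coding"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        utr5 = int(rng.integers(50, 201))
        utr3 = int(rng.integers(50, 301))
        if biotype == "protein_coding":
            n_codons = int(rng.integers(min_codons, max_codons + 1))
            cds_seq = (
                "ATG"
                + "".join(
                    SENSE_CODONS[i]
                    for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)
                )
                + sorted(STOP_CODONS)[rng.integers(3)]
            )
            tx_seq = _random_seq(rng, utr5) + cds_seq + _random_seq(rng, utr3)
            cds_tx = (utr5, utr5 + len(cds_seq))
        elif biotype == "miRNA":
            tx_seq = _random_seq(rng, int(rng.integers(60, 120)))
            n_exons = 1
            cds_tx = None
        else:
            tx_seq = _random_seq(rng, int(rng.integers(200, 800)))
            cds_tx = None

        # split the transcript into exon chunks of >= 20 bp each
        tx_len = len(tx_seq)
        n_exons = min(n_exons, tx_len // 20)
        n_exons = max(n_exons, 1)
        cuts = sorted(rng.choice(np.arange(20, tx_len - 19), size=n_exons - 1, replace=False)) if n_exons > 1 else []
        chunk_bounds = [0, *cuts, tx_len]
        chunks = list(zip(chunk_bounds[:-1], chunk_bounds[1:]))
        introns = [int(rng.integers(MIN_INTRON, 401)) for _ in range(n_exons - 1)]
        span = tx_len + sum(introns)

        start = cursors[chrom]
        end = start + span
        if end + GENE_GAP > genome.chrom_lengths[chrom]:
            # chromosome full: drop it from rotation
            if chrom in chrom_cycle:
                chrom_cycle.remove(chrom)
            if not chrom_cycle:
                raise PackingError("cannot pack requested genes into the genome")
            continue
        cursors[chrom] = end + GENE_GAP

        # genomic exon layout (transcript order on plus strand; reversed on minus)
        order = chunks if strand == "+" else chunks[::-1]
        exon_iv = []
        g = start
        for k, (ts, te) in enumerate(order):
            exon_iv.append((g, g + (te - ts), ts, te))
            g += te - ts
            if k < n_exons - 1:
                g += introns[k]
        chrom_seq = reference[chrom]
        for (gs, ge, ts, te) in exon_iv:
            piece = tx_seq[ts:te]
            if strand == "-":
                piece = reverse_complement(piece)
            chrom_seq[gs:ge] = list(piece)
        for (gs0, ge0, _, _), (gs1, _, _, _), ilen in zip(
            exon_iv, exon_iv[1:], introns if strand == "+" else introns[::-1]
        ):
            intron_seq = list(_random_seq(rng, gs1 - ge0))
            donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
            intron_seq[:2] = list(donor)
            intron_seq[-2:] = list(acceptor)
            chrom_seq[ge0:gs1] = intron_seq

        exons = tuple(sorted((gs, ge) for gs, ge, _, _ in exon_iv))
        cds_iv: list[tuple[int, int]] = []
        if cds_tx is not None:
            cs, ce = cds_tx
            for gs, ge, ts, te in exon_iv:
                lo, hi = max(cs, ts), min(ce, te)
                if hi > lo:
                    if strand == "+":
                        cds_iv.append((gs + (lo - ts), gs + (hi - ts)))
                    else:
                        cds_iv.append((ge - (hi - ts), ge - (lo - ts)))
        genes.append(
            GeneModel(
                gene_id=f"gene{gi}",
                transcript_id=f"tx{gi}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=tuple(sorted(cds_iv)),
                biotype=biotype,
            )
        )
        gi += 1

    return GeneSet(
        genes=genes, reference={k: "".join(v) for k, v in reference.items()}
    )


def plant_snps(gene_set: GeneSet, n_snps: int, seed: int, window: int = 5000) -> pd.DataFrame:
    """Plant SNPs with consequence classes known by construction.

    Coding picks record the class implied by the genetic code for the chosen
    codon substitution; positional picks (introns, splice windows, UTRs,
    up/downstream, intergenic, non-coding exons) record the class implied by
    the generator's own layout bookkeeping.  Both labels are independent of
    the classifier's code path.
    """
    rng = np.random.default_rng(seed)
    ref = gene_set.reference
    coding = [g for g in gene_set.genes if g.cds]
    rows = []
    guard = 0
    while len(rows) < n_snps:
        guard += 1
        if guard > n_snps * 200:
            raise SyntheticDataError("could not plant requested SNPs")
        if rng.random() < 0.5 and coding:
            m = coding[rng.integers(len(coding))]
            cds_seq = m.cds_sequence(ref)
            cds_off = int(rng.integers(len(cds_seq)))
            codon_idx, within = divmod(cds_off, 3)
            codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            alt_tx = BASES[rng.integers(4)]
            if alt_tx == codon[within]:
                continue
            new = codon[:within] + alt_tx + codon[within + 1 :]
            if codon in STOP_CODONS:
                cls = (
                    FunctionalClass.SYNONYMOUS_CODING
                    if new in STOP_CODONS
                    else FunctionalClass.STOP_LOST
                )
            elif new in STOP_CODONS:
                cls = FunctionalClass.STOP_GAINED
            elif CODON_TO_AA[codon] == CODON_TO_AA[new]:
                cls = FunctionalClass.SYNONYMOUS_CODING
            else:
                cls = FunctionalClass.NONSYNONYMOUS_CODING
            pos0 = _cds_offset_to_genomic(m, cds_off)
            alt = alt_tx if m.strand == "+" else reverse_complement(alt_tx)
        else:
            m = gene_set.genes[rng.integers(len(gene_set.genes))]
            pick = rng.integers(9)
            res = _positional_pick(rng, m, int(pick), window, gene_set)
            if res is None:
                continue
            pos0, cls = res
            base = ref[m.chrom][pos0]
            alt = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
        rows.append(
            {
                "chrom": m.chrom,
                "pos": pos0 + 1,
                "ref": ref[m.chrom][pos0],
                "alt": alt,
                "truth_class": str(cls),
            }
        )
    return pd.DataFrame(rows)


def _cds_offset_to_genomic(m: GeneModel, cds_off: int) -> int:
    plus_off = cds_off if m.strand == "+" else m.cds_length - 1 - cds_off
    off = 0
    for s, e in m.cds:
        if plus_off < off + (e - s):
            return s + (plus_off - off)
        off += e - s
    raise AssertionError("CDS offset out of range")


def _positional_pick(rng, m: GeneModel, pick: int, window: int, gene_set: GeneSet):
    introns = [
        (a[1], b[0]) for a, b in zip(m.exons, m.exons[1:])
    ]
    if pick == 0:  # intronic, clear of both splice windows
        deep = [iv for iv in introns if iv[1] - iv[0] > 2 * 8 + 2]
        if not deep:
            return None
        s, e = deep[rng.integers(len(deep))]
        return int(rng.integers(s + 8, e - 8)), FunctionalClass.INTRONIC
    if pick == 1:  # splice_site: 3..8 bp into an intron
        if not introns:
            return None
        s, e = introns[rng.integers(len(introns))]
        off = int(rng.integers(3, 9))
        pos0 = s + off - 1 if rng.random() < 0.5 else e - off
        return pos0, FunctionalClass.SPLICE_SITE
    if pick == 2:  # essential splice: first/last 2 intronic bases
        if not introns:
            return None
        s, e = introns[rng.integers(len(introns))]
        off = int(rng.integers(1, 3))
        pos0 = s + off - 1 if rng.random() < 0.5 else e - off
        return pos0, FunctionalClass.ESSENTIAL_SPLICE_SITE
    if pick in (3, 4):  # UTRs (coding transcripts only)
        if not m.cds:
            return None
        tx_pos = _utr_tx_position(rng, m, five_prime=(pick == 3))
        if tx_pos is None:
            return None
        cls = FunctionalClass.UTR5 if pick == 3 else FunctionalClass.UTR3
        return _tx_to_genomic(m, tx_pos), cls
    if pick == 5:  # upstream
        d = int(rng.integers(1, window + 1))
        pos0 = m.start - d if m.strand == "+" else m.end - 1 + d
        return pos0, FunctionalClass.UPSTREAM
    if pick == 6:  # downstream
        d = int(rng.integers(1, window + 1))
        pos0 = m.end - 1 + d if m.strand == "+" else m.start - d
        return pos0, FunctionalClass.DOWNSTREAM
    if pick == 7:  # intergenic: midway between this gene's window and the next
        pos0 = m.end + window + int(rng.integers(1, GENE_GAP - 2 * window - 100))
        if pos0 >= len(gene_set.reference[m.chrom]):
            return None
        others = [
            g for g in gene_set.genes if g.chrom == m.chrom and g is not m
        ]
        if any(g.start - window <= pos0 < g.end + window for g in others):
            return None
        return pos0, FunctionalClass.INTERGENIC
    # non-coding exon
    if m.cds:
        return None
    s, e = m.exons[rng.integers(len(m.exons))]
    cls = (
        FunctionalClass.WITHIN_MATURE_MIRNA
        if m.biotype == "miRNA"
        else FunctionalClass.WITHIN_NONCODING_GENE
    )
    return int(rng.integers(s, e)), cls


def _utr_tx_position(rng, m: GeneModel, five_prime: bool):
    exon_len = sum(e - s for s, e in m.exons)
    cds_tx_start = _genomic_to_tx(m, m.cds[0][0] if m.strand == "+" else m.cds[-1][1] - 1)
    cds_tx_end = cds_tx_start + m.cds_length
    if five_prime:
        return int(rng.integers(0, cds_tx_start)) if cds_tx_start > 0 else None
    return int(rng.integers(cds_tx_end, exon_len)) if cds_tx_end < exon_len else None


def _genomic_to_tx(m: GeneModel, pos0: int) -> int:
    off = 0
    order = m.exons if m.strand == "+" else m.exons[::-1]
    for s, e in order:
        if s <= pos0 < e:
            return off + (pos0 - s if m.strand == "+" else e - 1 - pos0)
        off += e - s
    raise AssertionError("position not exonic")


def _tx_to_genomic(m: GeneModel, tx_pos: int) -> int:
    off = 0
    order = m.exons if m.strand == "+" else m.exons[::-1]
    for s, e in order:
        if tx_pos < off + (e - s):
            d = tx_pos - off
            return s + d if m.strand == "+" else e - 1 - d
        off += e - s
    raise AssertionError("transcript position out of range")


# ---------------------------------------------------------------------------
# qPCR


@dataclass(frozen=True)
class QpcrPlan:
    """True copy numbers per sample for one assay."""

    true_copy_numbers: Mapping[str, float]
    calibrator_copy_number: float = 2.0
    replicates: int = 4
    ct_noise_sd: float = 0.1
    reference_gene_ct: float = 20.0
    assay: str = "assay1"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise SyntheticDataError("replicates must be >= 1")
        if self.ct_noise_sd < 0:
            raise SyntheticDataError("noise sd must be non-negative")
        if any(cn < 0 for cn in self.true_copy_numbers.values()):
            raise SyntheticDataError("copy numbers must be non-negative")


def simulate_qpcr(
    plan: QpcrPlan, amplification_efficiency: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """Ct replicate table under exponential amplification.

    Target Ct = reference Ct - log2(copy/2)/log2(1+efficiency) + noise per
    replicate; a copy number of zero yields censored (empty) target Ct
    values, modelling complete absence of the segment.
    """
    if not 0.9 < amplification_efficiency <= 1.1:
        raise SyntheticDataError("amplification efficiency must lie in (0.9, 1.1]")
    rng = np.random.default_rng(seed)
    rows = []
    per_cycle = np.log2(1.0 + amplification_efficiency)
    for sample, cn in plan.true_copy_numbers.items():
        ref_ct = plan.reference_gene_ct + rng.normal(0, plan.ct_noise_sd, plan.replicates)
        if cn == 0:
            tgt_ct = np.full(plan.replicates, np.nan)
        else:
            true_ct = plan.reference_gene_ct - np.log2(cn / 2.0) / per_cycle
            tgt_ct = true_ct + rng.normal(0, plan.ct_noise_sd, plan.replicates)
        row = {"sample": sample, "assay": plan.assay}
        for i in range(plan.replicates):
            row[f"target_ct_rep{i + 1}"] = tgt_ct[i]
            row[f"reference_ct_rep{i + 1}"] = ref_ct[i]
        rows.append(row)
    return pd.DataFrame(rows)
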