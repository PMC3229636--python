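"""Consequence classification, ASC scoring, tabulation and ASC profiles."""

import numpy as np
import pandas as pd
import pytest
from Bio.Data import CodonTable

from duovar import annotation as ann
from duovar import synthetic_data as sd

STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]


def _mini_gene(codon: str, strand: str):
    """Single-exon transcript: 6 bp UTR5 + ATG <codon> TAA + 6 bp UTR3.

    Returns (model, reference, genomic positions of the codon bases in
    transcript order, and a transcript->genomic base mapper for alts).
    """
    pad = "ACAACC" * 5  # A/C-only padding, no start codons
    tx = "AACCAA" + "ATG" + codon + "TAA" + "CCAACC"
    exon_start = len(pad)
    genomic = tx if strand == "+" else ann.reverse_complement(tx)
    ref = {"c": pad + genomic + pad}
    model = ann.GeneModel(
        gene_id="g",
        transcript_id="t",
        chrom="c",
        strand=strand,
        exons=((exon_start, exon_start + len(tx)),),
        cds=((exon_start + 6, exon_start + 15),),
    )
    positions = []
    for cds_off in (3, 4, 5):  # the middle codon
        plus_off = cds_off if strand == "+" else 8 - cds_off
        positions.append(exon_start + 6 + plus_off)
    return model, ref, positions


def _oracle_class(codon: str, j: int, alt_tx: str) -> str:
    new = codon[:j] + alt_tx + codon[j + 1 :]
    old_stop = codon in STANDARD.stop_codons
    new_stop = new in STANDARD.stop_codons
    if old_stop and new_stop:
        return "synonymous_coding"
    if old_stop:
        return "stop_lost"
    if new_stop:
        return "stop_gained"
    if STANDARD.forward_table[codon] == STANDARD.forward_table[new]:
        return "synonymous_coding"
    return "nonsynonymous_coding"


@pytest.mark.parametrize("strand", ["+", "-"])
def test_classifier_matches_codon_enumeration_oracle(strand):
    """Every single-base substitution in every sense codon, both strands,
    classifies identically to direct genetic-code enumeration."""
    codons = list(ann.SENSE_CODONS) + sorted(STANDARD.stop_codons)
    for codon in codons:
        model, ref, positions = _mini_gene(codon, strand)
        for j in range(3):
            for alt_tx in "ACGT":
                if alt_tx == codon[j]:
                    continue
                pos0 = positions[j]
                alt = alt_tx if strand == "+" else ann.complement_base(alt_tx)
                got = ann.classify_snp(
                    "c", pos0 + 1, ref["c"][pos0], alt, [model], ref
                )
                assert str(got) == _oracle_class(codon, j, alt_tx), (
                    codon, j, alt_tx, strand,
                )


class TestClassifierRegions:
    def test_named_codon_examples(self):
        # GCT -> GCC : third-position wobble
        model, ref, pos = _mini_gene("GCT", "+")
        assert ann.classify_snp("c", pos[2] + 1, "T", "C", [model], ref) is \
            ann.FunctionalClass.SYNONYMOUS_CODING
        # CGA -> TGA : arginine to stop
        model, ref, pos = _mini_gene("CGA", "+")
        assert ann.classify_snp("c", pos[0] + 1, "C", "T", [model], ref) is \
            ann.FunctionalClass.STOP_GAINED

    def test_upstream_window_boundary(self, gene_set):
        model = next(g for g in gene_set.genes if g.strand == "+")
        ref = gene_set.reference
        near = model.start - 4999
        far = model.start - 5001
        assert ann.classify_snp(
            model.chrom, near + 1, ref[model.chrom][near], "A", [model], ref
        ) is ann.FunctionalClass.UPSTREAM
        assert ann.classify_snp(
            model.chrom, far + 1, ref[model.chrom][far], "A", [model], ref
        ) is ann.FunctionalClass.INTERGENIC

    def test_planted_snps_recover_truth_classes(self, gene_set):
        snps = sd.plant_snps(gene_set, 400, seed=17)
        for r in snps.itertuples():
            got = ann.classify_snp(
                r.chrom, r.pos, r.ref, r.alt, gene_set.genes, gene_set.reference
            )
            assert str(got) == r.truth_class, (r.chrom, r.pos, r.truth_class, str(got))

    def test_ref_mismatch_logged_but_classified(self, caplog):
        model, ref, pos = _mini_gene("GCT", "+")
        with caplog.at_level("WARNING"):
            got = ann.classify_snp("c", pos[2] + 1, "G", "C", [model], ref)
        assert "disagrees" in caplog.text
        assert got is ann.FunctionalClass.SYNONYMOUS_CODING


class TestAsc:
    def test_hand_lookup_example(self):
        # s(D,D)=6, s(A,D)=-2 under BLOSUM62
        score = ann.asc(ann.AscInput(ref_aa="A", var_aa="D", orthologues=("D", "D")))
        assert score.a == pytest.approx(8.0)
        assert score.defined and score.n_orthologues == 2

    def test_variant_equals_reference_is_zero_everywhere(self):
        for r in ann.AMINO_ACIDS:
            s = ann.asc(ann.AscInput(ref_aa=r, var_aa=r, orthologues=tuple("ACD")))
            assert s.a == 0.0

    def test_antisymmetry_exhaustive(self):
        orth = tuple("WYK")
        for r in ann.AMINO_ACIDS:
            for v in ann.AMINO_ACIDS:
                a1 = ann.asc(ann.AscInput(ref_aa=r, var_aa=v, orthologues=orth)).a
                a2 = ann.asc(ann.AscInput(ref_aa=v, var_aa=r, orthologues=orth)).a
                assert a1 == pytest.approx(-a2)

    def test_empty_panel_undefined(self):
        s = ann.asc(ann.AscInput(ref_aa="A", var_aa="D", orthologues=()))
        assert not s.defined and np.isnan(s.a)

    def test_fully_conserved_panel_never_rewards_the_variant(self):
        """With all orthologues equal to the reference, ASC = s(v,r) - s(r,r),
        which BLOSUM62 keeps <= 0 for every v != r (diagonal dominance)."""
        m = ann.blosum62()
        for r in ann.AMINO_ACIDS:
            for v in ann.AMINO_ACIDS:
                if v == r:
                    continue
                s = ann.asc(ann.AscInput(ref_aa=r, var_aa=v, orthologues=(r,) * 4))
                assert s.a == pytest.approx(m[v, r] - m[r, r])
                assert s.a <= 0

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ann.AnnotationError, match="B"):
            ann.AscInput(ref_aa="B", var_aa="D", orthologues=("D",))


class TestTabulation:
    @staticmethod
    def _annotated(rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "functional_class"])

    def test_inclusion_exclusion_on_overlapping_sets(self):
        a = self._annotated(
            [("c", 1, "A", "intronic"), ("c", 2, "G", "intergenic"), ("c", 3, "T", "intronic")]
        )
        b = self._annotated(
            [("c", 1, "A", "intronic"), ("c", 9, "C", "intergenic")]
        )
        tab = ann.tabulate_classes(a, b).set_index("functional_class")
        assert tab.loc["intronic", "count_union"] == 2 + 1 - 1
        assert tab.loc["total", "count_union"] == 3 + 2 - 1

    def test_disjoint_and_identical_sets(self):
        a = self._annotated([("c", 1, "A", "intronic")])
        b = self._annotated([("c", 5, "A", "intronic")])
        tab = ann.tabulate_classes(a, b).set_index("functional_class")
        assert tab.loc["intronic", "count_intersection"] == 0
        assert tab.loc["intronic", "count_union"] == 2
        same = ann.tabulate_classes(a, a).set_index("functional_class")
        assert same.loc["intronic", "count_union"] == 1
        assert same.loc["intronic", "count_intersection"] == 1


class TestAscProfile:
    def test_counts_sum_and_all_het_bins(self):
        df = pd.DataFrame(
            {
                "asc": np.linspace(-7, 7, 40),
                "zygosity": "het",
                "shared": False,
            }
        )
        prof = ann.asc_bin_profile(df)
        assert prof.counts.sum() == 40
        assert np.allclose(prof.proportion_heterozygous[prof.counts > 0], 1.0)
        # zero is a bin edge
        assert np.any(np.isclose(prof.bin_edges, 0.0))
        assert np.allclose(np.diff(prof.bin_edges), 3.0)

    def test_planted_shared_trend_across_bins(self):
        """Variants planted so that negative-ASC records are less often
        shared reproduce a positive ASC/shared-rate association."""
        rng = np.random.default_rng(8)
        asc_vals = rng.uniform(-9, 9, 4000)
        p_shared = 0.2 + 0.6 * (asc_vals + 9) / 18
        df = pd.DataFrame(
            {
                "asc": asc_vals,
                "zygosity": np.where(rng.random(4000) < 0.5, "het", "hom_alt"),
                "shared": rng.random(4000) < p_shared,
            }
        )
        prof = ann.asc_bin_profile(df)
        keep = prof.counts > 30
        mids = (prof.bin_edges[:-1] + prof.bin_edges[1:])[keep] / 2
        from scipy.stats import spearmanr

        rho, _ = spearmanr(mids, prof.proportion_shared[keep])
        assert rho > 0

    def test_empty_profile(self):
        prof = ann.asc_bin_profile(pd.DataFrame(columns=["asc", "zygosity", "shared"]))
        assert prof.counts.size == 0


def test_gff3_round_trip(gene_set, tmp_path):
    """Models written as GFF3 and re-loaded classify identically."""
    gff = tmp_path / "genes.gff3"
    gene_set.write_gff3(gff)
    loaded = ann.load_gene_models(gff)
    assert len(loaded) == len(gene_set.genes)
    by_id = {m.transcript_id: m for m in loaded}
    for orig in gene_set.genes:
        back = by_id[orig.transcript_id]
        assert back.exons == orig.exons
        assert back.cds == orig.cds
        assert back.strand == orig.strand
        assert back.biotype == orig.biotype
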