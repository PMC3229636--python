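"""Array-vs-sequencing concordance and panel-based false-positive rate.

Array genotypes at sites that are not homozygous-reference define the set
of variants sequencing should have detected; the fraction not concordantly
recovered is the false-negative rate, split by zygosity.  Non-concordant
heterozygous sites are further classified: the characteristic sequencing
failure mode is a homozygous call for one of the two array alleles
(allele drop-out).  A custom genotyping panel run on a population
estimates the false-positive rate as the fraction of reported SNPs that
prove monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConcordanceTable:
    n_hom_detectable: int
    n_hom_called: int
    n_hom_concordant: int
    n_het_detectable: int
    n_het_called: int
    n_het_concordant: int

    def __post_init__(self) -> None:
        for z in ("hom", "het"):
            det = getattr(self, f"n_{z}_detectable")
            cal = getattr(self, f"n_{z}_called")
            con = getattr(self, f"n_{z}_concordant")
            if not con <= cal <= det:
                raise EvaluationError("need concordant <= called <= detectable")

    @property
    def detection_rates(self) -> tuple[float, float]:
        """(hom, het) percent of detectable sites present in the seq set."""
        return (
            100.0 * self.n_hom_called / self.n_hom_detectable,
            100.0 * self.n_het_called / self.n_het_detectable,
        )

    @property
    def concordance_rates(self) -> tuple[float, float]:
        return (
            100.0 * self.n_hom_concordant / self.n_hom_detectable,
            100.0 * self.n_het_concordant / self.n_het_detectable,
        )


@dataclass(frozen=True)
class DiscordanceBreakdown:
    """Non-concordant detectable het sites: allele drop-out vs everything else.

    ``n_single_allele`` counts sites where sequencing reported a homozygous
    genotype for one of the two array alleles; ``n_other`` covers sites
    missed outright or reported with incompatible alleles.
    """

    n_discordant_het: int
    n_single_allele: int
    n_other: int

    def __post_init__(self) -> None:
        if self.n_single_allele + self.n_other != self.n_discordant_het:
            raise EvaluationError("single_allele + other must equal discordant")

    @property
    def single_allele_fraction(self) -> float:
        if self.n_discordant_het == 0:
            return float("nan")
        return self.n_single_allele / self.n_discordant_het


@dataclass(frozen=True)
class PanelValidation:
    n_tested: int
    n_polymorphic: int
    n_monomorphic: int

    def __post_init__(self) -> None:
        if self.n_polymorphic + self.n_monomorphic != self.n_tested:
            raise EvaluationError("polymorphic + monomorphic must equal tested")


def _genotype(a1: str, a2: str) -> tuple[str, str]:
    return tuple(sorted((a1, a2)))


def build_concordance(
    array_calls: pd.DataFrame,
    seq_calls: pd.DataFrame,
    reference_alleles: pd.DataFrame,
) -> tuple[ConcordanceTable, DiscordanceBreakdown]:
    """Compare array genotypes to sequencing SNP calls.

    ``array_calls``: marker, chrom, pos, allele1, allele2, call (two-letter
    genotype), optional boolean ``unambiguous``.  ``seq_calls``: chrom, pos,
    ref, alt, zygosity.  ``reference_alleles``: chrom, pos, ref.  Detectable
    sites are array calls that are not homozygous-reference; "called" means
    position overlap with the sequencing set, "concordant" requires
    genotype equality (unordered alleles plus zygosity).
    """
    arr = array_calls.copy()
    if "unambiguous" in arr.columns:
        arr = arr[arr["unambiguous"].astype(bool)]
    for df, what in ((arr, "array"), (seq_calls, "sequencing")):
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise EvaluationError(f"duplicate positions in {what} calls")

    merged = arr.merge(
        reference_alleles[["chrom", "pos", "ref"]], on=["chrom", "pos"], how="left"
    )
    if merged["ref"].isna().any():
        raise EvaluationError("reference allele missing for some array sites")
    merged = merged.merge(
        seq_calls[["chrom", "pos", "ref", "alt", "zygosity"]].rename(
            columns={"ref": "seq_ref", "alt": "seq_alt", "zygosity": "seq_zygosity"}
        ),
        on=["chrom", "pos"],
        how="left",
    )

    counts = {
        "hom": {"detectable": 0, "called": 0, "concordant": 0},
        "het": {"detectable": 0, "called": 0, "concordant": 0},
    }
    n_single = 0
    n_discordant_het = 0
    for r in merged.itertuples():
        call_gt = _genotype(r.call[0], r.call[1])
        if call_gt == _genotype(r.ref, r.ref):
            continue  # homozygous reference: not detectable by SNP calling
        zyg = "het" if call_gt[0] != call_gt[1] else "hom"
        counts[zyg]["detectable"] += 1
        called = isinstance(r.seq_zygosity, str)
        if called:
            counts[zyg]["called"] += 1
            seq_gt = (
                _genotype(r.seq_ref, r.seq_alt)
                if r.seq_zygosity == "het"
                else _genotype(r.seq_alt, r.seq_alt)
            )
            concordant = seq_gt == call_gt
        else:
            concordant = False
        if concordant:
            counts[zyg]["concordant"] += 1
        elif zyg == "het":
            n_discordant_het += 1
            if (
                called
                and r.seq_zygosity != "het"
                and r.seq_alt in (r.allele1, r.allele2)
            ):
                n_single += 1

    table = ConcordanceTable(
        n_hom_detectable=counts["hom"]["detectable"],
        n_hom_called=counts["hom"]["called"],
        n_hom_concordant=counts["hom"]["concordant"],
        n_het_detectable=counts["het"]["detectable"],
        n_het_called=counts["het"]["called"],
        n_het_concordant=counts["het"]["concordant"],
    )
    breakdown = DiscordanceBreakdown(
        n_discordant_het=n_discordant_het,
        n_single_allele=n_single,
        n_other=n_discordant_het - n_single,
    )
    return table, breakdown


def false_negative_rates(t: ConcordanceTable) -> tuple[float, float]:
    """Percent of detectable sites not concordantly recovered, (hom, het)."""
    if t.n_hom_detectable == 0 or t.n_het_detectable == 0:
        raise EvaluationError("false-negative rate undefined with no detectable sites")
    return (
        (1.0 - t.n_hom_concordant / t.n_hom_detectable) * 100.0,
        (1.0 - t.n_het_concordant / t.n_het_detectable) * 100.0,
    )


def false_positive_rate(p: PanelValidation) -> float:
    """Percent of panel-tested SNPs that proved monomorphic."""
    if p.n_tested == 0:
        raise EvaluationError("false-positive rate undefined with no tested SNPs")
    return 100.0 * p.n_monomorphic / p.n_tested


def panel_from_table(panel: pd.DataFrame) -> PanelValidation:
    """Build a PanelValidation from a table with a ``status`` column."""
    mono = int((panel["status"] == "monomorphic").sum())
    return PanelValidation(
        n_tested=len(panel), n_polymorphic=len(panel) - mono, n_monomorphic=mono
    )


def report(table: ConcordanceTable, breakdown: DiscordanceBreakdown) -> dict:
    """JSON-ready summary with integer percentages alongside exact values."""
    det = table.detection_rates
    con = table.concordance_rates
    fn = false_negative_rates(table)
    return {
        "hom_detectable": table.n_hom_detectable,
        "het_detectable": table.n_het_detectable,
        "hom_detection_pct": round(det[0]),
        "het_detection_pct": round(det[1]),
        "hom_concordance_pct": round(con[0]),
        "het_concordance_pct": round(con[1]),
        "fn_hom_pct": round(fn[0]),
        "fn_het_pct": round(fn[1]),
        "fn_hom_pct_exact": fn[0],
        "fn_het_pct_exact": fn[1],
        "discordant_het": breakdown.n_discordant_het,
        "single_allele_fraction": breakdown.single_allele_fraction,
    }
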