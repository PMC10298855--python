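"""Pileup-based automation of manual IGV review of candidate somatic calls.

Manual review of read alignments in a genome browser is the de facto final
arbiter of somatic calls in small cohorts.  This module reproduces that
review as a deterministic classifier over 20 bp pileup windows centered on
each candidate.  A call is a true positive ("pass") iff all four criteria
hold:

(i)   clean biallelic configuration — no third allele at the center
      supported by ≥2 reads (singleton stray bases are tolerated as
      sequencing error);
(ii)  dual-strand support — at least one alt read on each strand;
(iii) clean 20 bp window — an alt read carrying ≥2 mismatches inside the
      window (the variant base included) is discounted; the site needs at
      least one clean alt read and a clean fraction ≥ 0.5;
(iv)  alt counts — ≥3 alt reads in the tumor and <3 in the normal pileup.

The verdict is a pure function of the two pileups and the variant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger("cfsomatic")


@dataclass
class ValidationConfig:
    width_bp: int = 20
    min_third_allele_reads: int = 2   # criterion (i) tolerance
    min_clean_fraction: float = 0.5   # criterion (iii) site-level threshold
    min_tumor_alt: int = 3            # criterion (iv)
    max_normal_alt: int = 3           # criterion (iv): normal_alt >= 3 fails
    window_rule: str = "per_read"     # or "per_column" (aggregate variant)


@dataclass
class PileupRead:
    read_id: str
    strand: str      # "fwd" / "rev" / "unknown"
    base: str        # base at the window center ("-" for a gap)
    mismatches: int  # non-reference aligned bases in the window, center excluded


@dataclass
class PileupWindow:
    """Per-read evidence in a window centered on a candidate variant."""

    sample_role: str  # "tumor" / "normal"
    chrom: str
    center_pos: int   # 1-based
    reads: list
    width_bp: int = 20

    def __post_init__(self):
        if self.width_bp < 2 or self.width_bp % 2:
            raise ValueError("width_bp must be even and >= 2")

    def base_counts(self) -> dict:
        counts: dict = {}
        for r in self.reads:
            counts[r.base] = counts.get(r.base, 0) + 1
        return counts

    def alt_reads(self, alt: str) -> list:
        return [r for r in self.reads if r.base == alt]


@dataclass
class IGVVerdict:
    key: str
    verdict: str  # "pass" / "non_pass" / "untestable"
    criteria: tuple  # (allele_config, strand_support, window_clean, alt_counts)
    detail: str = ""


# ---------------------------------------------------------------------------
# The four criteria
# ---------------------------------------------------------------------------

def check_allele_config(tumor_pileup: PileupWindow, ref: str, alt: str,
                        config: ValidationConfig = ValidationConfig()) -> bool:
    """(i) Biallelic cleanliness: no third allele supported by ≥2 reads."""
    for base, n in tumor_pileup.base_counts().items():
        if base not in (ref, alt) and n >= config.min_third_allele_reads:
            return False
    return True


def check_strand_support(tumor_pileup: PileupWindow, alt: str,
                         config: ValidationConfig = ValidationConfig()) -> bool:
    """(ii) At least one alt read on each of the forward and reverse strands.

    If every alt read is strand-unknown the criterion is untestable and
    passes (consistent with the strand-exemption policy of the caller
    dialects), with a logged note.
    """
    alt_reads = tumor_pileup.alt_reads(alt)
    strands = {r.strand for r in alt_reads}
    if alt_reads and strands <= {"unknown"}:
        log.debug("strand support untestable at %s:%d (all reads strand-unknown)",
                  tumor_pileup.chrom, tumor_pileup.center_pos)
        return True
    return "fwd" in strands and "rev" in strands


def check_window_clean(tumor_pileup: PileupWindow, alt: str,
                       config: ValidationConfig = ValidationConfig()) -> bool:
    """(iii) Mismatch cleanliness of alt-supporting reads in the 20 bp window.

    A read whose total mismatch count in the window — the candidate base
    itself included — reaches 2 (i.e. ≥1 *extra* mismatch) is dirty.  Under
    the default ``per_read`` rule the site passes iff ≥1 alt read is clean
    and the clean fraction is ≥ ``min_clean_fraction``.  The ``per_column``
    variant is an aggregate approximation: the mean number of extra
    mismatches per alt read must be < 1.
    """
    alt_reads = tumor_pileup.alt_reads(alt)
    if not alt_reads:
        return False
    if config.window_rule == "per_column":
        mean_extra = sum(r.mismatches for r in alt_reads) / len(alt_reads)
        return mean_extra < 1.0
    clean = sum(1 for r in alt_reads if r.mismatches == 0)
    return clean >= 1 and clean / len(alt_reads) >= config.min_clean_fraction


def check_alt_counts(tumor_pileup: PileupWindow, normal_pileup: PileupWindow,
                     alt: str, config: ValidationConfig = ValidationConfig()) -> bool:
    """(iv) ≥3 alt reads in the tumor pileup and <3 in the normal pileup."""
    t = len(tumor_pileup.alt_reads(alt))
    n = len(normal_pileup.alt_reads(alt))
    return t >= config.min_tumor_alt and n < config.max_normal_alt


def classify_variant_igv(variant, tumor_pileup: PileupWindow | None,
                         normal_pileup: PileupWindow | None,
                         config: ValidationConfig = ValidationConfig()) -> IGVVerdict:
    """Apply the four criteria to one candidate variant.

    ``variant`` needs ``key``, ``ref`` and ``alt`` attributes (a
    MergedVariant or CallerVariant).  A missing pileup, or a non-SNV
    candidate (whose center-base representation is undefined), yields an
    ``untestable`` verdict, which callers exclude from pass-rate
    denominators.
    """
    if tumor_pileup is None or normal_pileup is None:
        return IGVVerdict(variant.key, "untestable", (None,) * 4, "missing pileup")
    if len(variant.ref) != 1 or len(variant.alt) != 1:
        return IGVVerdict(variant.key, "untestable", (None,) * 4, "not an SNV")
    c1 = check_allele_config(tumor_pileup, variant.ref, variant.alt, config)
    c2 = check_strand_support(tumor_pileup, variant.alt, config)
    c3 = check_window_clean(tumor_pileup, variant.alt, config)
    c4 = check_alt_counts(tumor_pileup, normal_pileup, variant.alt, config)
    verdict = "pass" if (c1 and c2 and c3 and c4) else "non_pass"
    return IGVVerdict(variant.key, verdict, (c1, c2, c3, c4))


# ---------------------------------------------------------------------------
# Per-gene summaries
# ---------------------------------------------------------------------------

def gene_fp_summary(verdicts: Iterable[IGVVerdict],
                    gene_assignment: Mapping[str, str]) -> pd.DataFrame:
    """Per-gene pass / non-pass table from classifier verdicts.

    Untestable verdicts are excluded from the denominators and counted in a
    separate column.  Percentages are rounded to one decimal; rows sorted by
    non-pass percentage descending.
    """
    rows: dict = {}
    n_untestable_total = 0
    for v in verdicts:
        gene = gene_assignment.get(v.key, "NA")
        r = rows.setdefault(gene, {"gene": gene, "total": 0, "n_pass": 0,
                                   "n_non_pass": 0, "n_untestable": 0})
        if v.verdict == "untestable":
            r["n_untestable"] += 1
            n_untestable_total += 1
            continue
        r["total"] += 1
        if v.verdict == "pass":
            r["n_pass"] += 1
        else:
            r["n_non_pass"] += 1
    if n_untestable_total:
        log.info("gene_fp_summary: %d untestable verdicts excluded from "
                 "denominators", n_untestable_total)
    df = pd.DataFrame(rows.values())
    return summarize_gene_counts(df)


def summarize_gene_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Add non-pass counts and rounded percentages to a (gene, total, n_pass)
    table — e.g. the bundled published review counts — and sort by non-pass
    percentage descending."""
    df = df.copy()
    if "n_non_pass" not in df.columns:
        df["n_non_pass"] = df["total"] - df["n_pass"]
    with pd.option_context("mode.chained_assignment", None):
        nonzero = df["total"].where(df["total"] > 0, 1)
        df["pct_pass"] = (100.0 * df["n_pass"] / nonzero).round(1)
        df["pct_non_pass"] = (100.0 * df["n_non_pass"] / nonzero).round(1)
    df.loc[df["total"] == 0, ["pct_pass", "pct_non_pass"]] = 0.0
    return df.sort_values("pct_non_pass", ascending=False, kind="mergesort",
                          ignore_index=True)


def fp_burden_correlation(gene_table: pd.DataFrame):
    """Spearman correlation of total mutation count vs non-pass count across
    genes (tie-corrected).  Requires ≥3 genes."""
    from .cohort_stats import spearman_corr

    if len(gene_table) < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    return spearman_corr(gene_table["total"].to_numpy(),
                         gene_table["n_non_pass"].to_numpy())


# ---------------------------------------------------------------------------
# Pileup TSV interchange
# ---------------------------------------------------------------------------

_PILEUP_COLUMNS = ["key", "sample_role", "chrom", "center_pos", "read_id",
                   "strand", "base", "mismatches"]


def write_pileups(pileups: Mapping[str, Mapping[str, PileupWindow]], path) -> None:
    """Write pileup windows as a flat TSV, one row per read per window.

    ``pileups`` maps variant key -> {"tumor": window, "normal": window}.
    The format is a deliberately simple interchange that standard alignment
    pileup tools can be post-processed into.
    """
    rows = []
    for key, pair in pileups.items():
        for role, window in pair.items():
            if window is None:
                continue
            for r in window.reads:
                rows.append((key, role, window.chrom, window.center_pos,
                             r.read_id, r.strand, r.base, r.mismatches))
    pd.DataFrame(rows, columns=_PILEUP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pileups(path, width_bp: int = 20) -> dict:
    """Read a pileup TSV back into PileupWindow pairs keyed by variant."""
    df = pd.read_csv(path, sep="\t", dtype={"key": str, "base": str})
    out: dict = {}
    for (key, role), grp in df.groupby(["key", "sample_role"], sort=False):
        first = grp.iloc[0]
        reads = [PileupRead(str(r.read_id), r.strand, r.base, int(r.mismatches))
                 for r in grp.itertuples()]
        out.setdefault(key, {})[role] = PileupWindow(
            sample_role=role, chrom=first["chrom"],
            center_pos=int(first["center_pos"]), reads=reads, width_bp=width_bp)
    return out
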