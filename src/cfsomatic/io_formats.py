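"""Readers and writers for every external format the pipeline touches.

Five somatic callers emit VCFs in five FORMAT dialects; this module maps each
dialect onto a single normalized record type (:class:`CallerVariant`) carrying
the tumor/normal depths, alt-supporting read counts, strand split and VAF that
the downstream filters consume.  It also reads the capture-target BED, the
clinical covariate table, and writes/reads the per-variant report TSV.

Coordinate conventions: VCF positions are 1-based inclusive and kept 1-based
internally; BED intervals are 0-based half-open.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("cfsomatic")

#: The five supported callers, in the consolidation priority order used by
#: caller_merge (descending completeness of count/strand/orientation fields).
CALLERS = ("mutect2", "strelka2", "vardict", "muse", "somaticsniper")

#: Megabases of the whole-exome capture design (SureSelect Human All Exon
#: v6 + UTR) used as the default mutation-burden denominator when no BED is
#: supplied.
DEFAULT_TARGET_MB = 91.08


class FormatError(ValueError):
    """A file does not conform to the expected external format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CallerVariant:
    """One caller's normalized somatic call for one tumor/normal pair.

    ``alt_fwd``/``alt_rev`` are the tumor alt-supporting reads per sequencing
    strand; callers that do not report strand (muse, somaticsniper, strelka2)
    get an even imputed split and ``strand_known=False``, which exempts the
    record from strand-dependent checks rather than auto-failing it.
    ``fr_orientation`` is the (F1R2, F2R1) alt read-pair orientation split,
    reported only by Mutect2 and used by the oxoG artifact filter.
    ``ref_fwd``/``ref_rev`` are reference-allele strand counts where the
    dialect provides them (vardict RD, mutect2 SB); when ``None`` the
    strand-bias test assumes a balanced reference split.
    """

    caller_name: str
    sample_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    tumor_depth: int
    tumor_alt: int
    normal_depth: int
    normal_alt: int
    alt_fwd: int
    alt_rev: int
    vaf: float
    site_flags: frozenset = frozenset()
    fr_orientation: tuple | None = None
    ref_fwd: int | None = None
    ref_rev: int | None = None
    strand_known: bool = True

    @property
    def key(self) -> str:
        """Sample–locus–allele merge key, e.g. ``P01-chr1-123-A-T``."""
        return f"{self.sample_id}-{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def site_key(self) -> str:
        """Position-only key (the merge key without alleles)."""
        return f"{self.sample_id}-{self.chrom}-{self.pos}"

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def validate(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.key}: ref == alt")
        if self.tumor_alt > self.tumor_depth:
            raise ValueError(f"{self.key}: tumor_alt > tumor_depth")
        if self.normal_alt > self.normal_depth:
            raise ValueError(f"{self.key}: normal_alt > normal_depth")
        if self.alt_fwd + self.alt_rev != self.tumor_alt:
            raise ValueError(f"{self.key}: alt_fwd + alt_rev != tumor_alt")
        if self.tumor_depth > 0:
            expect = self.tumor_alt / self.tumor_depth
            if abs(self.vaf - expect) > 1e-6:
                raise ValueError(f"{self.key}: vaf inconsistent with counts")


@dataclass
class TargetRegions:
    """Capture-target intervals (0-based half-open) and their total size.

    ``intervals=None`` means "no BED supplied": the whole design is assumed
    covered (``contains`` is always true) and ``total_mb`` defaults to the
    91.08 Mb exome+UTR design.
    """

    intervals: list | None
    total_mb: float

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple]) -> "TargetRegions":
        """Build from raw (chrom, start, end) triples, merging overlaps."""
        merged = merge_intervals(intervals)
        total = sum(e - s for _, s, e in merged)
        return cls(intervals=merged, total_mb=total / 1e6)

    @classmethod
    def default(cls) -> "TargetRegions":
        return cls(intervals=None, total_mb=DEFAULT_TARGET_MB)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based position lies in the target."""
        if self.intervals is None:
            return True
        z = pos - 1  # to 0-based
        for c, s, e in self.intervals:
            if c == chrom and s <= z < e:
                return True
        return False


def merge_intervals(intervals: Iterable[tuple]) -> list:
    """Union of (chrom, start, end) half-open intervals via a sorted sweep.

    Adjacent intervals (end == next start) are merged.  Idempotent.
    """
    out: list = []
    for chrom, start, end in sorted(intervals):
        if start >= end:
            raise FormatError(f"malformed interval {chrom}:{start}-{end} (start >= end)")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, start, end))
    return out


@dataclass
class ClinicalRecord:
    """Patient covariates with the dichotomizations used throughout.

    ``age`` in years, ``os_time`` in days; ``event`` is death.  Stage fields
    use the dichotomies of the clinical-association analysis: T1–3 vs T4,
    N0 vs N+, stage I–III vs IV, age ≤60 vs >60.
    """

    patient_id: str
    age: float
    sex: str  # "male" / "female"
    t_stage: str  # "T1-3" / "T4"
    n_stage: str  # "N0" / "N+"
    clinical_stage: str  # "I-III" / "IV"
    metastasis: bool
    perineural_invasion: bool
    lymphovascular_invasion: bool
    p16: bool
    os_time: float
    event: bool

    @property
    def age_group(self) -> str:
        return "<=60" if self.age <= 60 else ">60"

    def __post_init__(self):
        if self.os_time < 0:
            raise ValueError(f"{self.patient_id}: negative os_time")


#: Clinical dichotomies: parameter -> (accessor, (group0 label, group1 label)).
CLINICAL_DICHOTOMIES = {
    "age": (lambda r: r.age > 60, ("<=60", ">60")),
    "sex": (lambda r: r.sex == "female", ("male", "female")),
    "t_stage": (lambda r: r.t_stage == "T4", ("T1-3", "T4")),
    "n_stage": (lambda r: r.n_stage == "N+", ("N0", "N+")),
    "clinical_stage": (lambda r: r.clinical_stage == "IV", ("I-III", "IV")),
    "metastasis": (lambda r: r.metastasis, ("no", "yes")),
    "perineural_invasion": (lambda r: r.perineural_invasion, ("no", "yes")),
    "lymphovascular_invasion": (lambda r: r.lymphovascular_invasion, ("no", "yes")),
    "p16": (lambda r: r.p16, ("negative", "positive")),
}


# ---------------------------------------------------------------------------
# VCF reading (five caller dialects)
# ---------------------------------------------------------------------------

@dataclass
class VcfReadResult:
    """Variants successfully extracted plus per-record extraction errors."""

    variants: list
    errors: list = field(default_factory=list)  # (record_index, message)


def _fmt(variant, tag):
    """A sample-by-value array for a FORMAT tag, or None if absent."""
    try:
        arr = variant.format(tag)
    except KeyError:
        return None
    return arr


def _ad_counts(variant, idx):
    ad = _fmt(variant, "AD")
    if ad is None:
        raise KeyError("AD")
    row = np.asarray(ad[idx]).ravel()
    ref_n, alt_n = int(row[0]), int(row[1])
    return max(ref_n, 0), max(alt_n, 0)


_STRELKA_BASE_TAG = {"A": "AU", "C": "CU", "G": "GU", "T": "TU"}


def _extract_mutect2(v, ti, ni):
    t_ref, t_alt = _ad_counts(v, ti)
    n_ref, n_alt = _ad_counts(v, ni)
    depth_t, depth_n = t_ref + t_alt, n_ref + n_alt
    fr = None
    f1 = _fmt(v, "F1R2")
    f2 = _fmt(v, "F2R1")
    if f1 is not None and f2 is not None:
        fr = (int(np.ravel(f1[ti])[-1]), int(np.ravel(f2[ti])[-1]))
    ref_fwd = ref_rev = None
    alt_fwd, alt_rev = _even_split(t_alt)
    strand_known = False
    sb = _fmt(v, "SB")
    if sb is not None:
        row = np.ravel(sb[ti])
        ref_fwd, ref_rev, alt_fwd, alt_rev = (int(x) for x in row[:4])
        strand_known = True
    return dict(tumor_depth=depth_t, tumor_alt=t_alt, normal_depth=depth_n,
                normal_alt=n_alt, alt_fwd=alt_fwd, alt_rev=alt_rev,
                ref_fwd=ref_fwd, ref_rev=ref_rev, fr_orientation=fr,
                strand_known=strand_known)


def _extract_strelka2(v, ti, ni):
    ref, alt = v.REF, v.ALT[0]
    if len(ref) == 1 and len(alt) == 1:
        def tier1(idx, base):
            arr = _fmt(v, _STRELKA_BASE_TAG[base])
            if arr is None:
                raise KeyError(_STRELKA_BASE_TAG[base])
            return int(np.ravel(arr[idx])[0])
        t_alt, t_ref = tier1(ti, alt), tier1(ti, ref)
        n_alt, n_ref = tier1(ni, alt), tier1(ni, ref)
    else:
        tar, tir = _fmt(v, "TAR"), _fmt(v, "TIR")
        if tar is None or tir is None:
            raise KeyError("TAR/TIR")
        t_ref, t_alt = int(np.ravel(tar[ti])[0]), int(np.ravel(tir[ti])[0])
        n_ref, n_alt = int(np.ravel(tar[ni])[0]), int(np.ravel(tir[ni])[0])
    alt_fwd, alt_rev = _even_split(t_alt)
    return dict(tumor_depth=t_ref + t_alt, tumor_alt=t_alt,
                normal_depth=n_ref + n_alt, normal_alt=n_alt,
                alt_fwd=alt_fwd, alt_rev=alt_rev, strand_known=False)


def _extract_vardict(v, ti, ni):
    t_ref, t_alt = _ad_counts(v, ti)
    n_ref, n_alt = _ad_counts(v, ni)
    ald, rd = _fmt(v, "ALD"), _fmt(v, "RD")
    if ald is not None:
        row = np.ravel(ald[ti])
        alt_fwd, alt_rev = int(row[0]), int(row[1])
        strand_known = True
    else:
        alt_fwd, alt_rev = _even_split(t_alt)
        strand_known = False
    ref_fwd = ref_rev = None
    if rd is not None:
        row = np.ravel(rd[ti])
        ref_fwd, ref_rev = int(row[0]), int(row[1])
    return dict(tumor_depth=t_ref + t_alt, tumor_alt=t_alt,
                normal_depth=n_ref + n_alt, normal_alt=n_alt,
                alt_fwd=alt_fwd, alt_rev=alt_rev,
                ref_fwd=ref_fwd, ref_rev=ref_rev, strand_known=strand_known)


def _extract_ad_dp(v, ti, ni):
    """muse / somaticsniper: AD and DP only, strand unknown."""
    t_ref, t_alt = _ad_counts(v, ti)
    n_ref, n_alt = _ad_counts(v, ni)
    alt_fwd, alt_rev = _even_split(t_alt)
    return dict(tumor_depth=t_ref + t_alt, tumor_alt=t_alt,
                normal_depth=n_ref + n_alt, normal_alt=n_alt,
                alt_fwd=alt_fwd, alt_rev=alt_rev, strand_known=False)


def _even_split(n: int) -> tuple:
    return (n - n // 2, n // 2)


_DIALECTS = {
    "mutect2": _extract_mutect2,
    "strelka2": _extract_strelka2,
    "vardict": _extract_vardict,
    "muse": _extract_ad_dp,
    "somaticsniper": _extract_ad_dp,
}


def _locate_samples(samples: Sequence[str]):
    """Indices of the tumor and normal sample columns."""
    names = {s.upper(): i for i, s in enumerate(samples)}
    if "TUMOR" in names and "NORMAL" in names:
        return names["TUMOR"], names["NORMAL"]
    t = [i for i, s in enumerate(samples) if s.endswith("_T")]
    n = [i for i, s in enumerate(samples) if s.endswith("_N")]
    if len(t) == 1 and len(n) == 1:
        return t[0], n[0]
    raise FormatError(f"cannot identify tumor/normal sample columns in {samples}")


def read_caller_vcf(path, caller_name: str, sample_id: str | None = None) -> VcfReadResult:
    """Read one caller's VCF into normalized :class:`CallerVariant` records.

    ``caller_name`` selects the FORMAT-field dialect.  Multi-allelic rows are
    split into one record per alt allele with the ``multiallelic`` site flag
    set.  Records whose count fields cannot be extracted are reported in
    ``result.errors`` (with their record index) rather than silently dropped.
    """
    from cyvcf2 import VCF

    if caller_name not in _DIALECTS:
        raise ValueError(f"unknown caller {caller_name!r}; expected one of {CALLERS}")
    extract = _DIALECTS[caller_name]
    vcf = VCF(str(path))
    if len(vcf.samples) < 2:
        raise FormatError(f"{path}: expected tumor and normal sample columns, "
                          f"found {vcf.samples}")
    ti, ni = _locate_samples(vcf.samples)
    if sample_id is None:
        sample_id = Path(path).name.split(".")[0]

    result = VcfReadResult(variants=[])
    for i, v in enumerate(vcf):
        alts = v.ALT
        flags = frozenset({"multiallelic"}) if len(alts) > 1 else frozenset()
        for alt in alts:
            try:
                fields = extract(v, ti, ni)
            except (KeyError, IndexError, TypeError) as exc:
                result.errors.append((i, f"record {i} ({v.CHROM}:{v.POS}): "
                                         f"field extraction failed: {exc}"))
                continue
            depth = fields["tumor_depth"]
            vaf = fields["tumor_alt"] / depth if depth > 0 else 0.0
            cv = CallerVariant(
                caller_name=caller_name, sample_id=sample_id,
                chrom=v.CHROM, pos=v.POS, ref=v.REF.upper(), alt=alt.upper(),
                vaf=vaf, site_flags=flags, **fields)
            result.variants.append(cv)
    return result


# ---------------------------------------------------------------------------
# BED / clinical / report tables
# ---------------------------------------------------------------------------

def read_target_regions(path=None) -> TargetRegions:
    """Read a BED3+ file into merged :class:`TargetRegions`.

    With no file, the default 91.08 Mb design is assumed (no interval list).
    """
    if path is None:
        return TargetRegions.default()
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED line with <3 columns: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise FormatError(f"{path}: malformed interval {chrom}:{start}-{end}")
            intervals.append((chrom, start, end))
    if not intervals:
        return TargetRegions(intervals=[], total_mb=0.0)
    return TargetRegions.from_intervals(intervals)


_CLINICAL_BOOLS = {"true": True, "yes": True, "1": True, "positive": True,
                   "false": False, "no": False, "0": False, "negative": False}


def read_clinical_table(path) -> list:
    """Read the clinical TSV into :class:`ClinicalRecord` objects.

    Expected columns: patient_id, age, sex, t_stage, n_stage, clinical_stage,
    metastasis, perineural_invasion, lymphovascular_invasion, p16, os_time,
    event.  Raw stage labels (e.g. "T2", "III", "N1") are dichotomized here;
    unknown category labels raise naming the row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["patient_id", "age", "sex", "t_stage", "n_stage", "clinical_stage",
                "metastasis", "perineural_invasion", "lymphovascular_invasion",
                "p16", "os_time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing clinical columns {missing}")

    def bools(row_i, col, raw):
        key = str(raw).strip().lower()
        if key not in _CLINICAL_BOOLS:
            raise FormatError(f"{path} row {row_i} column {col!r}: "
                              f"unknown category label {raw!r}")
        return _CLINICAL_BOOLS[key]

    records = []
    for i, row in df.iterrows():
        t_raw = row["t_stage"].strip().upper()
        if t_raw in {"T1", "T2", "T3", "T1-3"}:
            t_stage = "T1-3"
        elif t_raw == "T4":
            t_stage = "T4"
        else:
            raise FormatError(f"{path} row {i} column 't_stage': "
                              f"unknown category label {t_raw!r}")
        n_raw = row["n_stage"].strip().upper()
        if n_raw == "N0":
            n_stage = "N0"
        elif n_raw in {"N1", "N2", "N3", "N+"}:
            n_stage = "N+"
        else:
            raise FormatError(f"{path} row {i} column 'n_stage': "
                              f"unknown category label {n_raw!r}")
        s_raw = row["clinical_stage"].strip().upper()
        if s_raw in {"I", "II", "III", "I-III"}:
            stage = "I-III"
        elif s_raw == "IV":
            stage = "IV"
        else:
            raise FormatError(f"{path} row {i} column 'clinical_stage': "
                              f"unknown category label {s_raw!r}")
        sex = row["sex"].strip().lower()
        if sex not in {"male", "female"}:
            raise FormatError(f"{path} row {i} column 'sex': "
                              f"unknown category label {row['sex']!r}")
        records.append(ClinicalRecord(
            patient_id=row["patient_id"],
            age=float(row["age"]), sex=sex,
            t_stage=t_stage, n_stage=n_stage, clinical_stage=stage,
            metastasis=bools(i, "metastasis", row["metastasis"]),
            perineural_invasion=bools(i, "perineural_invasion", row["perineural_invasion"]),
            lymphovascular_invasion=bools(i, "lymphovascular_invasion",
                                          row["lymphovascular_invasion"]),
            p16=bools(i, "p16", row["p16"]),
            os_time=float(row["os_time"]),
            event=bools(i, "event", row["event"]),
        ))
    return records


def write_clinical_table(records: Sequence[ClinicalRecord], path) -> None:
    """Write clinical records in the TSV layout ``read_clinical_table`` expects."""
    rows = [{
        "patient_id": r.patient_id, "age": r.age, "sex": r.sex,
        "t_stage": r.t_stage, "n_stage": r.n_stage,
        "clinical_stage": r.clinical_stage,
        "metastasis": "yes" if r.metastasis else "no",
        "perineural_invasion": "yes" if r.perineural_invasion else "no",
        "lymphovascular_invasion": "yes" if r.lymphovascular_invasion else "no",
        "p16": "positive" if r.p16 else "negative",
        "os_time": r.os_time, "event": "1" if r.event else "0",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_population_af(path) -> dict:
    """Population allele-frequency TSV (chrom, pos, ref, alt, af) into the
    allele-keyed lookup the common-polymorphism filter uses."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return {f"{r.chrom}-{r.pos}-{r.ref}-{r.alt}": float(r.af)
            for r in df.itertuples()}


def read_pon_sites(path) -> frozenset:
    """Panel-of-normals site list TSV (chrom, pos, ref, alt) into an
    allele-level key set."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return frozenset(f"{r.chrom}-{r.pos}-{r.ref}-{r.alt}" for r in df.itertuples())


_REPORT_COLUMNS = ["key", "sample_id", "chrom", "pos", "ref", "alt", "callers",
                   "gene", "consequence", "tumor_depth", "tumor_alt",
                   "normal_depth", "normal_alt", "vaf", "filters_fired",
                   "igv_verdict"]


def write_variant_report(variants, trace, path) -> None:
    """Write merged variants with their filter trace to a TSV report.

    One row per variant; ``filters_fired`` is a comma-joined list of cascade
    filters that fired (empty for kept variants); stable column order.
    """
    rows = []
    for mv in variants:
        fired = trace.fired_filters(mv.key) if trace is not None else []
        c = mv.consolidated
        rows.append({
            "key": mv.key, "sample_id": mv.sample_id, "chrom": mv.chrom,
            "pos": mv.pos, "ref": mv.ref, "alt": mv.alt,
            "callers": ",".join(sorted(mv.caller_support)),
            "gene": mv.gene or "", "consequence": mv.consequence or "",
            "tumor_depth": c.tumor_depth, "tumor_alt": c.tumor_alt,
            "normal_depth": c.normal_depth, "normal_alt": c.normal_alt,
            "vaf": round(c.vaf, 6), "filters_fired": ",".join(fired),
            "igv_verdict": mv.igv_verdict,
        })
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_variant_report(path) -> pd.DataFrame:
    """Re-read a variant report written by :func:`write_variant_report`."""
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       dtype={"filters_fired": str, "gene": str,
                              "consequence": str, "callers": str})


# ---------------------------------------------------------------------------
# Bundled reference table
# ---------------------------------------------------------------------------

def load_igv_gene_counts() -> pd.DataFrame:
    """IGV manual-review counts for the 25 most frequently mutated genes in a
    50-patient OSCC plasma cfDNA cohort (columns: gene, total, n_pass).

    Used as a worked input for the per-gene false-positive summary and its
    burden/false-positive rank correlation.
    """
    p = Path(__file__).parent / "data" / "igv_gene_counts.tsv"
    return pd.read_csv(p, sep="\t")
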