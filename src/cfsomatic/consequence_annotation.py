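"""Codon-level consequence classification against a minimal gene model.

A deliberately small stand-in for a full effect predictor: one transcript
per gene, whole exons coding, and the full consequence ontology collapsed to
nine categories: synonymous, missense, splicing_site, frameshift, in_frame,
start_lost, stop_gained, stop_lost, stop_retained.  Splice sites are the
canonical ±2 intronic bases flanking each exon.  Classification is performed
on the coding strand, so a gene model on the minus strand and its variants
give the same calls as their reverse-complement mirror.

A consequence column already present on the input (e.g. from real annotation
output) bypasses classification.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

CONSEQUENCE_TYPES = ("synonymous", "missense", "splicing_site", "frameshift",
                     "in_frame", "start_lost", "stop_gained", "stop_lost",
                     "stop_retained")

#: Consequence types that leave the protein unchanged.
SYNONYMOUS_TYPES = frozenset({"synonymous", "stop_retained"})

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class NotClassifiableError(ValueError):
    """Variant lies outside all exons and splice margins of its gene model."""


@dataclass
class GeneModel:
    """Single-transcript gene model with 1-based inclusive exons."""

    symbol: str
    chrom: str
    strand: str  # "+" / "-"
    exons: list  # [(start, end)] sorted, non-overlapping, 1-based inclusive
    splice_margin: int = 2

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.symbol}: overlapping exons")

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_splice_margin(self, pos: int) -> bool:
        """Intronic position within ``splice_margin`` bp of an exon edge."""
        if self.contains_exonic(pos):
            return False
        m = self.splice_margin
        for i, (s, e) in enumerate(self.exons):
            if i > 0 and s - m <= pos < s:  # acceptor side (intronic)
                return True
            if i < len(self.exons) - 1 and e < pos <= e + m:  # donor side
                return True
        return False

    def cds_sequence(self, reference: Mapping[str, str]) -> str:
        seq = str(reference[self.chrom])
        cds = "".join(seq[s - 1:e] for s, e in self.exons).upper()
        if self.strand == "-":
            cds = cds.translate(_COMPLEMENT)[::-1]
        return cds

    def genomic_to_cds(self, pos: int) -> int:
        """0-based index into the coding-strand CDS for a genomic position."""
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                idx_fwd = offset + (pos - s)
                if self.strand == "-":
                    return self.cds_length - 1 - idx_fwd
                return idx_fwd
            offset += e - s + 1
        raise NotClassifiableError(f"{self.symbol}: position {pos} not exonic")


def classify_consequence(v, model: GeneModel, reference: Mapping[str, str]) -> str:
    """Assign one of the nine consequence categories to a variant.

    ``v`` needs ``pos``, ``ref`` and ``alt`` attributes (minimal
    representation).  Indels are classified by net length change
    (frameshift vs in_frame); SNVs by codon comparison on the coding strand.
    """
    pos = v.pos
    if not model.contains_exonic(pos):
        if model.in_splice_margin(pos):
            return "splicing_site"
        raise NotClassifiableError(
            f"{model.symbol}: {v.ref}>{v.alt} at {pos} outside exons and "
            f"splice margins")
    if len(v.ref) != len(v.alt):
        net = abs(len(v.ref) - len(v.alt))
        return "frameshift" if net % 3 else "in_frame"
    if len(v.ref) != 1:
        # multi-base substitution: classify by its first changed base
        for i, (r, a) in enumerate(zip(v.ref, v.alt)):
            if r != a:
                sub = type("V", (), {"pos": pos + i, "ref": r, "alt": a})
                return classify_consequence(sub, model, reference)

    cds = model.cds_sequence(reference)
    i = model.genomic_to_cds(pos)
    alt = v.alt.upper()
    if model.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    codon_idx = i // 3
    ref_codon = cds[codon_idx * 3: codon_idx * 3 + 3]
    alt_codon = (ref_codon[: i % 3] + alt + ref_codon[i % 3 + 1:])
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    if aa_ref == "*" and aa_alt == "*":
        return "stop_retained"
    if aa_ref == "*":
        return "stop_lost"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == aa_alt:
        return "synonymous"
    return "missense"


def is_nonsynonymous(consequence: str) -> bool:
    """True for every category that alters the protein (all but synonymous
    and stop_retained)."""
    if consequence not in CONSEQUENCE_TYPES:
        raise ValueError(f"unknown consequence {consequence!r}")
    return consequence not in SYNONYMOUS_TYPES


# ---------------------------------------------------------------------------
# Gene lookup and batch annotation
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval lookup from genomic position to gene model (spans padded by
    the splice margin so splice-site variants resolve to their gene)."""

    def __init__(self, models: Iterable[GeneModel]):
        self._by_chrom: dict = {}
        for m in models:
            s, e = m.span
            self._by_chrom.setdefault(m.chrom, []).append(
                (s - m.splice_margin, e + m.splice_margin, m))
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: t[0])
        self._starts = {c: [t[0] for t in lst] for c, lst in self._by_chrom.items()}

    def lookup(self, chrom: str, pos: int) -> GeneModel | None:
        lst = self._by_chrom.get(chrom)
        if not lst:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos) - 1
        if i >= 0:
            s, e, m = lst[i]
            if s <= pos <= e:
                return m
        return None


def annotate_variants(variants, models: Iterable[GeneModel] | GeneIndex,
                      reference: Mapping[str, str],
                      skip_unresolved: bool = True) -> list:
    """Fill ``gene`` and ``consequence`` on merged variants in place.

    Variants with a pre-assigned consequence are left untouched.  Variants
    resolving to no gene model are left unannotated (or raise when
    ``skip_unresolved`` is false).  Returns the input list.
    """
    index = models if isinstance(models, GeneIndex) else GeneIndex(models)
    for v in variants:
        if v.consequence is not None:
            continue
        m = index.lookup(v.chrom, v.pos)
        if m is None:
            if not skip_unresolved:
                raise NotClassifiableError(f"{v.key}: no gene model")
            continue
        v.gene = m.symbol
        v.consequence = classify_consequence(v, m, reference)
    return list(variants)


def consequence_counts(variants) -> pd.Series:
    """Counts of the nine consequence categories over classified variants."""
    counts = {t: 0 for t in CONSEQUENCE_TYPES}
    for v in variants:
        if v.consequence is not None:
            counts[v.consequence] += 1
    return pd.Series(counts)


# ---------------------------------------------------------------------------
# Gene-model interchange (flat GFF-like TSV)
# ---------------------------------------------------------------------------

def write_gene_models(models: Iterable[GeneModel], path) -> None:
    """One row per gene: symbol, chrom, strand, exons as ``start-end;...``."""
    with open(path, "w") as fh:
        fh.write("symbol\tchrom\tstrand\texons\tsplice_margin\n")
        for m in models:
            exons = ";".join(f"{s}-{e}" for s, e in m.exons)
            fh.write(f"{m.symbol}\t{m.chrom}\t{m.strand}\t{exons}\t{m.splice_margin}\n")


def read_gene_models(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    models = []
    for r in df.itertuples():
        exons = [tuple(int(x) for x in part.split("-"))
                 for part in r.exons.split(";")]
        models.append(GeneModel(symbol=r.symbol, chrom=r.chrom, strand=r.strand,
                                exons=exons, splice_margin=int(r.splice_margin)))
    return models


# ---------------------------------------------------------------------------
# Patient x gene matrix
# ---------------------------------------------------------------------------

@dataclass
class GeneMutationMatrix:
    """Patients × genes boolean presence matrix of nonsynonymous mutations."""

    presence: pd.DataFrame  # bool, index=patients, columns=genes

    @property
    def counts(self) -> pd.Series:
        return self.presence.sum(axis=0)

    @property
    def frequency(self) -> pd.Series:
        n = len(self.presence)
        return self.counts / n if n else self.counts.astype(float)


def build_gene_matrix(variants, patients: Sequence[str]) -> GeneMutationMatrix:
    """Presence matrix: cell true iff the patient carries ≥1 nonsynonymous
    annotated variant in the gene (presence, not count)."""
    genes = sorted({v.gene for v in variants
                    if v.gene and v.consequence and is_nonsynonymous(v.consequence)})
    df = pd.DataFrame(False, index=list(patients), columns=genes, dtype=bool)
    for v in variants:
        if (v.gene and v.consequence and is_nonsynonymous(v.consequence)
                and v.sample_id in df.index):
            df.loc[v.sample_id, v.gene] = True
    return GeneMutationMatrix(presence=df)


def top_mutated_genes(matrix: GeneMutationMatrix, n: int) -> list:
    """Top ``n`` genes by patient frequency, ties broken lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    freq = matrix.frequency
    order = sorted(freq.index, key=lambda g: (-freq[g], g))
    return order[:n]
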