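"""Normalization and consensus merging of the five per-caller call sets.

Calls are merged by a sample–locus–allele key (union semantics: a variant
called by any caller enters the merged set).  The key includes ref and alt —
not position alone — so distinct alt alleles at one site are never conflated;
position-only grouping is kept as a site-level annotation for the
multiallelic filter.  For each merged record one "consolidated" evidence
record supplies the counts used downstream, chosen by caller priority
(mutect2 > strelka2 > vardict > muse > somaticsniper, i.e. descending
completeness of count/strand/orientation fields); strand and read-pair
orientation evidence missing from the consolidated record is backfilled from
any other caller that reported it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import CALLERS, CallerVariant

log = logging.getLogger("cfsomatic")

#: Consolidation priority (first match wins); config-overridable via the
#: ``priority`` argument of :func:`merge_callers`.
DEFAULT_PRIORITY = CALLERS


class ReferenceMismatchError(ValueError):
    """A variant's REF allele disagrees with the reference sequence."""


@dataclass
class MergedVariant:
    """Consensus record for one sample–locus–allele across callers."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    caller_support: frozenset
    evidence: dict  # caller_name -> CallerVariant
    consolidated: CallerVariant
    gene: str | None = None
    consequence: str | None = None
    igv_verdict: str = "untested"

    @property
    def key(self) -> str:
        return f"{self.sample_id}-{self.chrom}-{self.pos}-{self.ref}-{self.alt}"

    @property
    def site_key(self) -> str:
        return f"{self.sample_id}-{self.chrom}-{self.pos}"


def _ref_base(reference, chrom: str, pos: int) -> str:
    """1-based single-base lookup on a dict-of-strings or FASTA-like object."""
    seq = reference[chrom]
    return str(seq[pos - 1]).upper()


def normalize_variant(v: CallerVariant, reference: Mapping[str, str] | None = None) -> CallerVariant:
    """Left-align and trim a variant to its minimal representation.

    Shared suffix bases are trimmed first (extending left through the
    reference when an allele would empty), then shared prefix bases; SNVs
    already minimal are returned unchanged (idempotent).  With a reference,
    the REF allele is checked against it and a
    :class:`ReferenceMismatchError` raised on disagreement.
    """
    ref, alt, pos = v.ref, v.alt, v.pos
    if not ref or not alt:
        raise ValueError(f"{v.key}: empty allele")
    if reference is not None:
        seq = str(reference[v.chrom])
        if seq[pos - 1: pos - 1 + len(ref)].upper() != ref:
            raise ReferenceMismatchError(
                f"{v.key}: REF {ref!r} disagrees with reference")
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (ref[-1] == alt[-1] and len(ref) != len(alt)
              and reference is not None and pos > 1):
            # pure indel with shared last base: shift left through reference
            base = _ref_base(reference, v.chrom, pos - 1)
            ref, alt, pos = base + ref[:-1], base + alt[:-1], pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    if (ref, alt, pos) == (v.ref, v.alt, v.pos):
        return v
    return replace(v, ref=ref, alt=alt, pos=pos)


def merge_callers(callsets: Mapping[str, Sequence[CallerVariant]] | Sequence[Sequence[CallerVariant]],
                  priority: Sequence[str] = DEFAULT_PRIORITY) -> list:
    """Merge per-caller call sets into consensus :class:`MergedVariant`\\ s.

    ``callsets`` is a mapping caller -> variants (or a sequence of lists,
    each list homogeneous in ``caller_name``).  Inputs must already be
    normalized.  The same caller reporting the same key twice raises a
    duplicate-record warning in the log; the first record is kept.  Output
    order is deterministic (sorted by key) and therefore invariant to caller
    input order.
    """
    if not isinstance(callsets, Mapping):
        named: dict = {}
        for lst in callsets:
            for v in lst:
                named.setdefault(v.caller_name, []).append(v)
        callsets = named

    by_key: dict = {}
    for caller, variants in callsets.items():
        seen = set()
        for v in variants:
            if v.caller_name != caller:
                raise ValueError(f"callset {caller!r} contains a record from "
                                 f"{v.caller_name!r}")
            if v.key in seen:
                log.warning("duplicate record from %s for %s; first kept", caller, v.key)
                continue
            seen.add(v.key)
            by_key.setdefault(v.key, {})[caller] = v

    rank = {c: i for i, c in enumerate(priority)}
    merged = []
    for key in sorted(by_key):
        evidence = by_key[key]
        support = frozenset(evidence)
        lead_caller = min(evidence, key=lambda c: rank.get(c, len(rank)))
        consolidated = _consolidate(evidence[lead_caller], evidence.values())
        v0 = evidence[lead_caller]
        flags = frozenset().union(*(e.site_flags for e in evidence.values()))
        consolidated = replace(consolidated, site_flags=flags)
        merged.append(MergedVariant(
            sample_id=v0.sample_id, chrom=v0.chrom, pos=v0.pos,
            ref=v0.ref, alt=v0.alt, caller_support=support,
            evidence=evidence, consolidated=consolidated))
    return merged


def _consolidate(lead: CallerVariant, evidence: Iterable[CallerVariant]) -> CallerVariant:
    """Backfill strand/orientation fields the lead record lacks."""
    out = lead
    if not out.strand_known:
        for e in evidence:
            if e.strand_known and e.tumor_alt == out.tumor_alt:
                out = replace(out, alt_fwd=e.alt_fwd, alt_rev=e.alt_rev,
                              ref_fwd=e.ref_fwd, ref_rev=e.ref_rev,
                              strand_known=True)
                break
        else:
            for e in evidence:
                if e.strand_known:
                    out = replace(out, tumor_alt=e.tumor_alt,
                                  tumor_depth=e.tumor_depth,
                                  vaf=e.vaf,
                                  alt_fwd=e.alt_fwd, alt_rev=e.alt_rev,
                                  ref_fwd=e.ref_fwd, ref_rev=e.ref_rev,
                                  strand_known=True)
                    break
    if out.fr_orientation is None:
        for e in evidence:
            if e.fr_orientation is not None:
                out = replace(out, fr_orientation=e.fr_orientation)
                break
    return out


def support_histogram(merged: Sequence[MergedVariant]) -> dict:
    """Counts by caller and by support level.

    Returns ``{"per_caller": {...}, "per_support_level": {1: n1, ...},
    "union": N}``; per-caller counts equal the deduplicated input list
    lengths, the union count the merged total.
    """
    per_caller = {c: 0 for c in CALLERS}
    per_level: dict = {}
    for mv in merged:
        k = len(mv.caller_support)
        per_level[k] = per_level.get(k, 0) + 1
        for c in mv.caller_support:
            per_caller[c] = per_caller.get(c, 0) + 1
    return {"per_caller": per_caller, "per_support_level": per_level,
            "union": len(merged)}
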