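"""The six-rule somatic filter cascade plus the recurrent-FP gene blacklist.

Candidate somatic calls surviving the caller merge are filtered by, in order:

(i)   common polymorphisms — population minor allele frequency > 1%;
(ii)  panel-of-normals membership (allele-level site list);
(iii) 8-oxoguanine artifacts — C>A/G>T calls whose alt-supporting read-pair
      orientation (F1R2/F2R1) is almost entirely one-sided;
(iv)  site artifacts — multiallelic sites, clustered events (≥3 same-sample
      variants within 100 bp) and strand bias (one-sided exact test on the
      ref/alt × fwd/rev 2×2 table, p < 0.005);
(v)   allele support — <4 alt reads in cfDNA or ≥4 alt reads in the normal;
(vi)  VAF < 5% in the cfDNA sample;
plus the MUC16/MUC19 blacklist of recurrently false-positive genes.

Every filter is evaluated for every variant (no short-circuit) so the trace
supports per-filter attrition reporting; a variant is kept iff no filter
fired.  Records from strand-unknown callers are exempt from the strand-bias
sub-check, and calls without orientation counts from the oxoG check
(exemptions logged) — this avoids biasing removal against callers that do
not report those fields.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy.stats import hypergeom

from .caller_merge import MergedVariant

log = logging.getLogger("cfsomatic")

FILTER_ORDER = ("population_af", "panel_of_normals", "oxog", "site_artifacts",
                "allele_support", "vaf", "blacklist_genes")


@dataclass
class FilterConfig:
    """Thresholds of the cascade; defaults reproduce the published rules."""

    max_population_af: float = 0.01   # filter (i): AF strictly greater fires
    min_tumor_alt: int = 4            # filter (v): tumor_alt < 4 fires
    max_normal_alt: int = 4           # filter (v): normal_alt >= 4 fires
    min_vaf: float = 0.05             # filter (vi): vaf < 0.05 fires
    clustered_window_bp: int = 100
    clustered_min_events: int = 3
    strand_bias_p: float = 0.005
    oxog_min_ratio: float = 0.9
    oxog_min_reads: int = 3
    blacklist_genes: frozenset = frozenset({"MUC16", "MUC19"})


@dataclass
class FilterTrace:
    """Ordered per-variant record of every filter evaluation.

    ``entries[key]`` is the ordered list of ``(filter_name, fired, detail)``
    triples; a dropped variant has at least one fired entry, a kept variant
    none.
    """

    entries: dict = field(default_factory=dict)

    def add(self, key: str, filter_name: str, fired: bool, detail: str = "") -> None:
        self.entries.setdefault(key, []).append((filter_name, fired, detail))

    def fired_filters(self, key: str) -> list:
        return [name for name, fired, _ in self.entries.get(key, []) if fired]

    def dropped(self, key: str) -> bool:
        return bool(self.fired_filters(key))

    def attrition(self) -> dict:
        """Number of variants on which each filter fired."""
        counts = {name: 0 for name in FILTER_ORDER}
        for events in self.entries.values():
            for name, fired, _ in events:
                if fired:
                    counts[name] = counts.get(name, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Individual filters.  Each returns (fired, detail).
# ---------------------------------------------------------------------------

def filter_population_af(v: MergedVariant, af_lookup: Mapping[str, float],
                         config: FilterConfig = FilterConfig()):
    """(i) Common polymorphisms: population AF strictly above 1% fires."""
    allele = f"{v.chrom}-{v.pos}-{v.ref}-{v.alt}"
    af = af_lookup.get(allele, 0.0) if af_lookup else 0.0
    fired = af > config.max_population_af
    return fired, f"population_af={af:g}"


def filter_panel_of_normals(v: MergedVariant, pon_sites,
                            config: FilterConfig = FilterConfig()):
    """(ii) Allele-level membership in the panel-of-normals site list."""
    allele = f"{v.chrom}-{v.pos}-{v.ref}-{v.alt}"
    fired = bool(pon_sites) and allele in pon_sites
    return fired, "in panel of normals" if fired else ""


def filter_oxog(v: MergedVariant, config: FilterConfig = FilterConfig()):
    """(iii) 8-oxoguanine: C>A/G>T with one-sided F1R2/F2R1 orientation.

    Fires iff the substitution is C>A or G>T and
    ``max(F1R2, F2R1) / (F1R2 + F2R1) >= oxog_min_ratio`` with at least
    ``oxog_min_reads`` orientation-informative reads.  Other substitution
    classes never fire; missing orientation counts are logged untestable.
    """
    c = v.consolidated
    if not ((v.ref, v.alt) in {("C", "A"), ("G", "T")}):
        return False, ""
    if c.fr_orientation is None:
        log.debug("oxog untestable for %s: no orientation counts", v.key)
        return False, "untestable: no orientation counts"
    f1r2, f2r1 = c.fr_orientation
    total = f1r2 + f2r1
    if total < config.oxog_min_reads:
        return False, f"untestable: only {total} orientation-informative reads"
    ratio = max(f1r2, f2r1) / total
    fired = ratio >= config.oxog_min_ratio
    return fired, f"orientation ratio {ratio:.3f} (F1R2={f1r2}, F2R1={f2r1})"


def strand_bias_p(ref_fwd: int, ref_rev: int, alt_fwd: int, alt_rev: int) -> float:
    """One-sided exact p for strand imbalance of alt vs ref reads.

    The smaller tail of the hypergeometric distribution of forward alt reads
    given the table margins (equivalently a one-sided Fisher test on the
    ref/alt × fwd/rev 2×2 table, taken in the observed direction).
    """
    n_alt = alt_fwd + alt_rev
    n_fwd = ref_fwd + alt_fwd
    n = ref_fwd + ref_rev + alt_fwd + alt_rev
    if n == 0 or n_alt == 0:
        return 1.0
    rv = hypergeom(n, n_fwd, n_alt)
    return float(min(rv.cdf(alt_fwd), rv.sf(alt_fwd - 1)))


def filter_site_artifacts(v: MergedVariant,
                          neighborhood: Sequence[int] | None = None,
                          site_alt_count: int = 1,
                          config: FilterConfig = FilterConfig(),
                          strand_p: float | None = None):
    """(iv) Multiallelic sites, clustered events and strand bias.

    ``neighborhood`` is the sorted list of same-sample variant positions on
    the variant's chromosome (including the variant itself);
    ``site_alt_count`` the number of distinct alt alleles observed at the
    site across callers.  Fires if any sub-check fires; the detail string
    names the sub-flags.  Strand-unknown evidence skips the strand sub-check.
    """
    c = v.consolidated
    flags = []
    if "multiallelic" in c.site_flags or site_alt_count > 1:
        flags.append("multiallelic")
    if neighborhood:
        lo = bisect.bisect_left(neighborhood, v.pos - config.clustered_window_bp)
        hi = bisect.bisect_right(neighborhood, v.pos + config.clustered_window_bp)
        if hi - lo >= config.clustered_min_events:
            flags.append("clustered")
    if c.strand_known:
        if strand_p is not None:
            p = strand_p
        else:
            if c.ref_fwd is not None and c.ref_rev is not None:
                ref_fwd, ref_rev = c.ref_fwd, c.ref_rev
            else:
                n_ref = c.tumor_depth - c.tumor_alt
                ref_fwd, ref_rev = n_ref - n_ref // 2, n_ref // 2
            p = strand_bias_p(ref_fwd, ref_rev, c.alt_fwd, c.alt_rev)
        if p < config.strand_bias_p:
            flags.append(f"strand_bias(p={p:.2g})")
    else:
        log.debug("strand-bias check skipped for %s: strand unknown", v.key)
    return bool(flags), ",".join(flags)


def filter_allele_support(v: MergedVariant, config: FilterConfig = FilterConfig()):
    """(v) Fires iff tumor alt reads < 4 or normal alt reads ≥ 4."""
    c = v.consolidated
    fired = c.tumor_alt < config.min_tumor_alt or c.normal_alt >= config.max_normal_alt
    return fired, f"tumor_alt={c.tumor_alt}, normal_alt={c.normal_alt}"


def filter_vaf(v: MergedVariant, config: FilterConfig = FilterConfig()):
    """(vi) Fires iff cfDNA VAF < 5% (exactly 5% survives)."""
    c = v.consolidated
    if c.tumor_depth == 0:
        return True, "no coverage"
    fired = c.vaf < config.min_vaf
    return fired, f"vaf={c.vaf:.4f}"


def filter_blacklist_genes(v: MergedVariant, config: FilterConfig = FilterConfig()):
    """Recurrent false-positive gene blacklist (MUC16/MUC19 by default)."""
    fired = v.gene is not None and v.gene in config.blacklist_genes
    return fired, f"gene={v.gene}" if fired else ""


def _batch_strand_p(merged: Sequence[MergedVariant]):
    """Vectorized strand-bias p for every variant (None if strand-unknown).

    Identical to :func:`strand_bias_p` per record; computed in one
    hypergeometric batch for speed on large merged sets.
    """
    import numpy as np
    from scipy.stats import hypergeom as hg

    out = [None] * len(merged)
    idx, rf, rr, af, ar = [], [], [], [], []
    for i, v in enumerate(merged):
        c = v.consolidated
        if not c.strand_known:
            continue
        if c.ref_fwd is not None and c.ref_rev is not None:
            f, r = c.ref_fwd, c.ref_rev
        else:
            n_ref = c.tumor_depth - c.tumor_alt
            f, r = n_ref - n_ref // 2, n_ref // 2
        idx.append(i)
        rf.append(f); rr.append(r); af.append(c.alt_fwd); ar.append(c.alt_rev)
    if not idx:
        return out
    rf, rr, af, ar = (np.array(x) for x in (rf, rr, af, ar))
    n = rf + rr + af + ar
    n_fwd = rf + af
    n_alt = af + ar
    lower = hg.cdf(af, n, n_fwd, n_alt)
    upper = hg.sf(af - 1, n, n_fwd, n_alt)
    p = np.minimum(np.minimum(lower, upper), 1.0)
    p[(n == 0) | (n_alt == 0)] = 1.0
    for i, pi in zip(idx, p):
        out[i] = float(pi)
    return out


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

def apply_cascade(merged: Sequence[MergedVariant],
                  config: FilterConfig = FilterConfig(),
                  af_lookup: Mapping[str, float] | None = None,
                  pon_sites=None):
    """Run filters (i)–(vi) plus the gene blacklist over the merged set.

    Returns ``(kept, trace)`` with ``kept`` the variants on which no filter
    fired.  All filters are evaluated for every variant, in the fixed order,
    so the trace records every firing; conservation holds by construction
    (|kept| + |dropped| = |input|).
    """
    af_lookup = af_lookup or {}
    pon_sites = pon_sites or frozenset()

    # site-level context: same-sample variant positions per chromosome, and
    # distinct alt alleles per site
    positions: dict = {}
    site_alts: dict = {}
    for v in merged:
        positions.setdefault((v.sample_id, v.chrom), []).append(v.pos)
        site_alts.setdefault(v.site_key, set()).add(v.alt)
    for lst in positions.values():
        lst.sort()

    strand_p = _batch_strand_p(merged)
    trace = FilterTrace()
    kept = []
    for i, v in enumerate(merged):
        neighborhood = positions[(v.sample_id, v.chrom)]
        n_alts = len(site_alts[v.site_key])
        checks = (
            ("population_af", filter_population_af(v, af_lookup, config)),
            ("panel_of_normals", filter_panel_of_normals(v, pon_sites, config)),
            ("oxog", filter_oxog(v, config)),
            ("site_artifacts", filter_site_artifacts(v, neighborhood, n_alts,
                                                     config, strand_p[i])),
            ("allele_support", filter_allele_support(v, config)),
            ("vaf", filter_vaf(v, config)),
            ("blacklist_genes", filter_blacklist_genes(v, config)),
        )
        any_fired = False
        for name, (fired, detail) in checks:
            trace.add(v.key, name, fired, detail)
            any_fired = any_fired or fired
        if not any_fired:
            kept.append(v)
    return kept, trace
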