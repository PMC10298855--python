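"""Boundary behavior and invariants of the six-rule filter cascade."""
from math import comb

import numpy as np
import pytest

from cfsomatic.filter_cascade import (FilterConfig, apply_cascade,
                                      filter_allele_support,
                                      filter_blacklist_genes, filter_oxog,
                                      filter_population_af,
                                      filter_panel_of_normals,
                                      filter_site_artifacts, filter_vaf,
                                      strand_bias_p)

from conftest import make_merged


CFG = FilterConfig()


class TestPopulationAf:
    @pytest.mark.parametrize("af,fired", [(0.02, True), (0.01, False), (0.0, False)])
    def test_strict_one_percent_boundary(self, af, fired):
        v = make_merged()
        lookup = {f"{v.chrom}-{v.pos}-{v.ref}-{v.alt}": af}
        assert filter_population_af(v, lookup, CFG)[0] is fired

    def test_absent_site_treated_as_zero(self):
        assert filter_population_af(make_merged(), {}, CFG)[0] is False


class TestPanelOfNormals:
    def test_allele_level_membership(self):
        v = make_merged()
        allele = f"{v.chrom}-{v.pos}-{v.ref}-{v.alt}"
        assert filter_panel_of_normals(v, {allele}, CFG)[0] is True
        assert filter_panel_of_normals(v, {allele.replace("-T", "-G")}, CFG)[0] is False
        assert filter_panel_of_normals(v, frozenset(), CFG)[0] is False


class TestOxog:
    def test_wrong_substitution_class_never_fires(self):
        v = make_merged(ref="T", alt="C", fr_orientation=(20, 0))
        assert filter_oxog(v, CFG)[0] is False

    def test_total_orientation_imbalance_fires(self):
        v = make_merged(ref="C", alt="A", fr_orientation=(10, 0))
        assert filter_oxog(v, CFG)[0] is True

    def test_balanced_orientation_does_not_fire(self):
        v = make_merged(ref="G", alt="T", fr_orientation=(11, 9))
        assert filter_oxog(v, CFG)[0] is False

    def test_missing_or_thin_orientation_untestable(self):
        v = make_merged(ref="C", alt="A", fr_orientation=None)
        fired, detail = filter_oxog(v, CFG)
        assert fired is False and "untestable" in detail
        v = make_merged(ref="C", alt="A", fr_orientation=(2, 0))
        assert filter_oxog(v, CFG)[0] is False


def exact_tail_by_enumeration(ref_fwd, ref_rev, alt_fwd, alt_rev):
    """One-sided hypergeometric tail computed from binomial coefficients."""
    n = ref_fwd + ref_rev + alt_fwd + alt_rev
    n_fwd = ref_fwd + alt_fwd
    n_alt = alt_fwd + alt_rev
    denom = comb(n, n_alt)

    def pmf(k):
        if k < 0 or k > n_alt or k > n_fwd or n_alt - k > n - n_fwd:
            return 0.0
        return comb(n_fwd, k) * comb(n - n_fwd, n_alt - k) / denom

    lower = sum(pmf(k) for k in range(alt_fwd + 1))
    upper = sum(pmf(k) for k in range(alt_fwd, n_alt + 1))
    return min(lower, upper)


class TestSiteArtifacts:
    def test_multiallelic_site_flag(self):
        v = make_merged(site_flags=frozenset({"multiallelic"}))
        fired, detail = filter_site_artifacts(v, config=CFG)
        assert fired and "multiallelic" in detail

    def test_second_alt_allele_at_site(self):
        fired, detail = filter_site_artifacts(make_merged(), site_alt_count=2,
                                              config=CFG)
        assert fired and "multiallelic" in detail

    def test_clustered_window_against_scan_oracle(self):
        rng = np.random.default_rng(9)
        positions = sorted(int(p) for p in rng.integers(1000, 4000, size=30))
        for pos in positions:
            v = make_merged(pos=pos, alt_fwd=10, alt_rev=10,
                            ref_fwd=30, ref_rev=30)
            fired, detail = filter_site_artifacts(v, positions, config=CFG)
            n_win = sum(1 for q in positions if abs(q - pos) <= 100)
            assert ("clustered" in detail) == (n_win >= 3)

    def test_three_events_within_100bp_fire(self):
        v = make_merged(pos=1050, alt_fwd=10, alt_rev=10, ref_fwd=30, ref_rev=30)
        fired, detail = filter_site_artifacts(v, [1000, 1050, 1099], config=CFG)
        assert fired and "clustered" in detail

    def test_one_sided_strand_bias_fires(self):
        v = make_merged(tumor_depth=80, tumor_alt=20, alt_fwd=20, alt_rev=0,
                        ref_fwd=30, ref_rev=30)
        fired, detail = filter_site_artifacts(v, config=CFG)
        assert fired and "strand_bias" in detail

    def test_strand_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            rf, rr = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            af, ar = int(rng.integers(0, 25)), int(rng.integers(0, 25))
            if af + ar == 0:
                continue
            assert strand_bias_p(rf, rr, af, ar) == pytest.approx(
                exact_tail_by_enumeration(rf, rr, af, ar), abs=1e-10)

    def test_strand_unknown_evidence_skips_strand_check(self):
        v = make_merged(caller="muse", tumor_alt=20, alt_fwd=20, alt_rev=0,
                        strand_known=False)
        fired, _ = filter_site_artifacts(v, config=CFG)
        assert fired is False


class TestAlleleSupportAndVaf:
    @pytest.mark.parametrize("t_alt,n_alt,fired", [
        (3, 0, True),    # <4 tumor alt reads
        (4, 4, True),    # >=4 normal alt reads
        (4, 3, False),   # both boundaries satisfied
    ])
    def test_allele_support_boundaries(self, t_alt, n_alt, fired):
        v = make_merged(tumor_alt=t_alt, normal_alt=n_alt)
        assert filter_allele_support(v, CFG)[0] is fired

    @pytest.mark.parametrize("alt,depth,fired", [(4, 100, True), (5, 100, False)])
    def test_vaf_boundary_five_percent(self, alt, depth, fired):
        v = make_merged(tumor_depth=depth, tumor_alt=alt)
        assert filter_vaf(v, CFG)[0] is fired

    def test_zero_coverage_fires_with_detail(self):
        v = make_merged(tumor_depth=0, tumor_alt=0)
        fired, detail = filter_vaf(v, CFG)
        assert fired and detail == "no coverage"

    def test_two_percent_profile_keeps_low_vaf_variant(self):
        v = make_merged(tumor_depth=100, tumor_alt=3)
        assert filter_vaf(v, CFG)[0] is True
        assert filter_vaf(v, FilterConfig(min_vaf=0.02))[0] is False


class TestBlacklist:
    @pytest.mark.parametrize("gene,fired", [("MUC16", True), ("MUC19", True),
                                            ("TTN", False), (None, False)])
    def test_default_blacklist(self, gene, fired):
        v = make_merged()
        v.gene = gene
        assert filter_blacklist_genes(v, CFG)[0] is fired

    def test_emptied_blacklist(self):
        v = make_merged()
        v.gene = "MUC16"
        cfg = FilterConfig(blacklist_genes=frozenset())
        assert filter_blacklist_genes(v, cfg)[0] is False


def _random_merged(rng, n=300):
    out = []
    for i in range(n):
        depth = int(rng.integers(20, 120))
        alt = int(rng.integers(0, depth + 1))
        out.append(make_merged(pos=int(rng.integers(1, 10 ** 6)),
                               tumor_depth=depth, tumor_alt=alt,
                               normal_depth=80,
                               normal_alt=int(rng.integers(0, 8)),
                               ref_fwd=(depth - alt) // 2,
                               ref_rev=depth - alt - (depth - alt) // 2))
    return out


class TestCascade:
    def test_all_clean_fixture_kept_entirely(self):
        vs = [make_merged(pos=1000 * i, tumor_alt=20) for i in range(1, 6)]
        kept, trace = apply_cascade(vs)
        assert kept == vs
        assert all(not trace.fired_filters(v.key) for v in vs)

    def test_conservation_and_trace_completeness(self):
        vs = _random_merged(np.random.default_rng(4))
        kept, trace = apply_cascade(vs)
        dropped = [v for v in vs if trace.dropped(v.key)]
        assert len(kept) + len(dropped) == len(vs)
        for v in dropped:
            assert trace.fired_filters(v.key)
        for v in kept:
            assert not trace.fired_filters(v.key)

    def test_trace_replay_reproduces_drop_decision(self):
        vs = _random_merged(np.random.default_rng(8))
        kept, trace = apply_cascade(vs)
        kept_keys = {v.key for v in kept}
        for v in vs:
            assert (v.key in kept_keys) == (not trace.dropped(v.key))

    def test_raising_thresholds_never_grows_kept_set(self):
        vs = _random_merged(np.random.default_rng(15))
        base_kept = {v.key for v in apply_cascade(vs)[0]}
        for cfg in (FilterConfig(min_vaf=0.10), FilterConfig(min_tumor_alt=8)):
            tighter = {v.key for v in apply_cascade(vs, cfg)[0]}
            assert tighter <= base_kept

    def test_filters_are_independent_predicates(self):
        """The kept set equals the conjunction of individually evaluated
        filters, so evaluation order cannot matter."""
        vs = _random_merged(np.random.default_rng(23))
        kept, trace = apply_cascade(vs)
        attrition = trace.attrition()
        assert sum(attrition.values()) >= len(vs) - len(kept)
        for v in vs:
            events = dict((name, fired)
                          for name, fired, _ in trace.entries[v.key])
            assert len(events) == 7
            assert (v in kept) == (not any(events.values()))
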