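"""Burden computation and the statistical battery, against small oracles."""
import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest

from cfsomatic.cohort_stats import (BCAA_CATABOLISM, HYPOXIA_RELATED, GeneSet,
                                    adjusted_linear_model, bonferroni_alpha,
                                    bonferroni_alpha_display, categorical_test,
                                    compute_pmb, gene_clinical_association,
                                    geneset_status, km_logrank, mann_whitney,
                                    mutation_type_table, power_sample_size,
                                    spearman_corr)
from cfsomatic.consequence_annotation import GeneMutationMatrix
from cfsomatic.io_formats import ClinicalRecord, TargetRegions

from conftest import make_merged


def clin(pid, metastasis=False, age=55, stage="I-III", os_time=100., event=False):
    return ClinicalRecord(pid, age, "male", "T4", "N0", stage, metastasis,
                          False, False, False, os_time, event)


class TestPmb:
    def test_counts_per_megabase(self):
        vs = [make_merged(pos=100 + 3 * i, tumor_depth=100, tumor_alt=10)
              for i in range(9108 // 4)]  # scaled instance of the arithmetic
        t = TargetRegions(None, 91.08)
        (b,) = compute_pmb(vs, t).values()
        assert b.pmb == pytest.approx(len(vs) / 91.08)

    def test_zero_variants_zero_burden(self):
        res = compute_pmb([], TargetRegions(None, 91.08), patients=["P1"])
        assert res["P1"].pmb == 0.0

    def test_vaf_threshold_and_target_membership(self):
        inside_hi = make_merged(pos=50, tumor_depth=100, tumor_alt=10)
        inside_lo = make_merged(pos=53, tumor_depth=100, tumor_alt=4)   # VAF 4%
        outside = make_merged(chrom="chr2", pos=50, tumor_depth=100, tumor_alt=10)
        t = TargetRegions([("chr1", 0, 1000)], 0.001)
        res = compute_pmb([inside_hi, inside_lo, outside], t)
        assert res["P01"].qualifying_mutations == 1

    def test_scale_consistency(self):
        vs = [make_merged(pos=100 + 3 * i, tumor_depth=100, tumor_alt=10)
              for i in range(40)]
        a = compute_pmb(vs, TargetRegions(None, 10.0))["P01"].pmb
        b = compute_pmb(vs, TargetRegions(None, 20.0))["P01"].pmb
        assert a == pytest.approx(2 * b)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_exact_branch_matches_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for n1, n2 in [(3, 3), (4, 5), (6, 6)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u_obs, p = mann_whitney(x, y)
            # enumerate the U distribution over all group assignments
            pooled = np.concatenate([x, y])
            us = []
            for idx in itertools.combinations(range(n1 + n2), n1):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                us.append(sum((xi > yj) for xi in xs for yj in ys))
            us = np.array(us, float)
            lower = np.mean(us <= u_obs)
            upper = np.mean(us >= u_obs)
            assert p == pytest.approx(min(1.0, 2 * min(lower, upper)), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestSpearman:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_corr(x, x)
        assert rho == pytest.approx(1.0)

    def test_classical_formula_no_ties(self):
        rng = np.random.default_rng(8)
        x = rng.permutation(5).astype(float)
        y = rng.permutation(5).astype(float)
        rho, _ = spearman_corr(x, y)
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = np.sum((rx - ry) ** 2)
        assert rho == pytest.approx(1 - 6 * d2 / (5 * 24), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, _ = spearman_corr(x, y)
        rho2, _ = spearman_corr(np.exp(3 * x), y ** 3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 1, 1], [1, 2, 3])


class TestCategorical:
    def test_diagonal_table_fisher_exact_value(self):
        p, method = categorical_test([[9, 0], [0, 9]])
        assert method == "fisher"
        # hypergeometric enumeration: only the two diagonal tables are as
        # extreme; each has probability 1/C(18,9)
        assert p == pytest.approx(2 / comb(18, 9), rel=1e-9)

    def test_expected_exactly_five_routes_chi_square(self):
        # the routing rule is strict: expected *below* 5 -> Fisher, and the
        # diagonal 10/10 table has every expected cell exactly 5
        _, method = categorical_test([[10, 0], [0, 10]])
        assert method == "chi-square"

    def test_balanced_table_no_association(self):
        p, method = categorical_test([[25, 25], [25, 25]])
        assert method == "chi-square" and p == pytest.approx(1.0)

    def test_expected_cell_routing(self):
        _, method = categorical_test([[2, 8], [3, 7]])
        assert method == "fisher"
        _, method = categorical_test([[20, 30], [28, 22]])
        assert method == "chi-square"

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            categorical_test([[0, 0], [0, 0]])


class TestAdjustedModel:
    def test_degenerate_covariate_reduces_to_group_difference(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        x = (rng.random(30) < 0.5).astype(float)
        B, p = adjusted_linear_model(y, x, np.full(30, 55.0))
        # with both z-scored and no covariate, B is the Pearson correlation
        assert B == pytest.approx(float(np.corrcoef(y, x)[0, 1]), abs=1e-10)

    def test_null_coefficient_centered_at_zero(self):
        rng = np.random.default_rng(5)
        bs = []
        for _ in range(300):
            y = rng.normal(size=40)
            x = (rng.random(40) < 0.4).astype(float)
            age = rng.normal(60, 8, size=40)
            B, _ = adjusted_linear_model(y, x, age)
            bs.append(B)
        assert abs(np.mean(bs)) < 3 * np.std(bs) / np.sqrt(len(bs))

    def test_collinear_rejected(self):
        x = np.array([0, 1] * 10, float)
        with pytest.raises(ValueError):
            adjusted_linear_model(np.arange(20.0), x, 2 * x + 1)


class TestBonferroni:
    @pytest.mark.parametrize("m,display", [(9, 0.006), (2, 0.025), (1, 0.05)])
    def test_family_thresholds(self, m, display):
        assert bonferroni_alpha_display(0.05, m) == display
        assert bonferroni_alpha(0.05, m) == pytest.approx(0.05 / m)

    def test_zero_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestGeneAssociation:
    def _matrix(self, data, patients):
        return GeneMutationMatrix(pd.DataFrame(data, index=patients))

    def test_extreme_table_flagged(self):
        patients = [f"P{i}" for i in range(20)]
        met = [i < 6 for i in range(20)]
        m = self._matrix({"HIT": met, "NOISE": [i % 2 == 0 for i in range(20)]},
                         patients)
        clinical = [clin(p, metastasis=b) for p, b in zip(patients, met)]
        out = gene_clinical_association(m, clinical, "metastasis").set_index("gene")
        assert out.loc["HIT", "p"] < out.loc["NOISE", "p"]
        assert out.loc["HIT", "significant_after_correction"]
        assert out.loc["HIT", "bonferroni_alpha"] == pytest.approx(0.025)

    def test_permuted_labels_control_familywise_error(self):
        rng = np.random.default_rng(30)
        patients = [f"P{i}" for i in range(30)]
        data = {f"G{j}": rng.random(30) < 0.4 for j in range(10)}
        m = self._matrix(data, patients)
        fw_errors = 0
        reps = 200
        for _ in range(reps):
            labels = rng.permutation(np.arange(30) < 10)
            clinical = [clin(p, metastasis=bool(b))
                        for p, b in zip(patients, labels)]
            out = gene_clinical_association(m, clinical, "metastasis")
            fw_errors += out["significant_after_correction"].any()
        rate = fw_errors / reps
        assert rate <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / reps)


class TestGenesetStatus:
    def test_union_matches_per_patient_or_oracle(self):
        rng = np.random.default_rng(7)
        patients = [f"P{i}" for i in range(25)]
        genes = ["ARNT", "EPAS1", "PAK3", "RAF1", "TFE3", "OTHER"]
        df = pd.DataFrame(rng.random((25, 6)) < 0.2, index=patients, columns=genes)
        status, frac = geneset_status(GeneMutationMatrix(df), HYPOXIA_RELATED)
        for p in patients:
            assert status[p] == any(df.loc[p, g] for g in HYPOXIA_RELATED.genes)
        assert frac == pytest.approx(status.mean())

    def test_absent_members_warn_but_work(self, caplog):
        df = pd.DataFrame({"AUH": [True, False]}, index=["P1", "P2"])
        with caplog.at_level("WARNING", logger="cfsomatic"):
            status, frac = geneset_status(GeneMutationMatrix(df), BCAA_CATABOLISM)
        assert frac == 0.5
        assert any("absent" in r.message for r in caplog.records)

    def test_no_overlap_rejected(self):
        df = pd.DataFrame({"TTN": [True]}, index=["P1"])
        with pytest.raises(ValueError):
            geneset_status(GeneMutationMatrix(df), BCAA_CATABOLISM)

    def test_empty_geneset_rejected(self):
        with pytest.raises(ValueError):
            GeneSet("empty", set())


class TestSurvival:
    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(11)
        times = rng.exponential(100, size=30)
        events = np.ones(30, bool)
        groups = np.arange(30) < 15
        curves, _, _ = km_logrank(times, events, groups)
        for label in (False, True):
            t_g = np.sort(times[groups == label])
            sf = curves[label]
            for i, t in enumerate(t_g):
                # S(t) = fraction strictly surviving beyond t
                emp = np.mean(t_g > t)
                assert sf.loc[t].iloc[0] == pytest.approx(emp, abs=1e-10)

    def test_identical_groups_statistic_zero(self):
        times = np.array([10., 20., 30., 10., 20., 30.])
        events = np.ones(6, bool)
        groups = np.array([True, True, True, False, False, False])
        _, stat, p = km_logrank(times, events, groups)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([1.0, 2.0], [True, True], [True, True])


class TestPower:
    def test_zero_effect_power_is_alpha(self):
        power, n = power_sample_size(10, 5, 10, 5, n1=20, n2=20, alpha=0.05)
        assert power == pytest.approx(0.05, abs=1e-9)
        assert n == float("inf")

    def test_large_effect_asymptote(self):
        power, _ = power_sample_size(0, 1, 3.5, 1, n1=20, n2=20)
        assert power > 0.999

    def test_closed_form_matches_monte_carlo(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(19)
        m1, m2, sd, n = 0.0, 0.7, 1.0, 30
        power, _ = power_sample_size(m1, sd, m2, sd, n1=n, n2=n)
        x = rng.normal(m1, sd, size=(10000, n))
        y = rng.normal(m2, sd, size=(10000, n))
        p = ttest_ind(x, y, axis=1).pvalue
        assert power == pytest.approx(np.mean(p < 0.05), abs=0.02)


class TestMutationTypeTable:
    def test_three_patient_hand_computation(self, small_cohort):
        from cfsomatic.cohort_stats import BurdenResult
        from cfsomatic.consequence_annotation import CONSEQUENCE_TYPES

        counts = {"P1": 2, "P2": 4, "P3": 10}
        burdens = {}
        for pid, c in counts.items():
            tc = {t: 0 for t in CONSEQUENCE_TYPES}
            tc["missense"] = c
            burdens[pid] = BurdenResult(pid, c, 0.0, tc)
        clinical = [clin("P1"), clin("P2"), clin("P3", metastasis=True)]
        out = mutation_type_table(burdens, clinical, "metastasis")
        row = out.set_index("mutation_type").loc["missense"]
        assert row["mean_no"] == pytest.approx(3.0)
        assert row["sd_no"] == pytest.approx(np.std([2, 4], ddof=1))
        assert row["mean_yes"] == pytest.approx(10.0)
        assert row["sd_yes"] == 0.0

    def test_empty_group_rejected(self):
        from cfsomatic.cohort_stats import BurdenResult
        from cfsomatic.consequence_annotation import CONSEQUENCE_TYPES

        b = {"P1": BurdenResult("P1", 0, 0.0, {t: 0 for t in CONSEQUENCE_TYPES})}
        with pytest.raises(ValueError):
            mutation_type_table(b, [clin("P1")], "metastasis")
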