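"""Plasma mutation burden and the cohort-level statistical battery.

Plasma mutation burden (PMB) is the number of kept somatic mutations with
VAF ≥ 5% inside the capture target, per megabase of target (91.08 Mb for the
whole-exome + UTR design).  Burdens and per-consequence-type counts are
compared across clinical dichotomies with Mann–Whitney U tests, categorical
gene–clinical associations use chi-square or Fisher's exact test (routing by
the minimum-expected-cell < 5 rule), burden–metastasis associations are
additionally age-adjusted by linear regression on standardized variables,
gene-set mutation status is tested against overall survival with
Kaplan–Meier / log-rank, and families of tests are Bonferroni-corrected
(family sizes follow the analysis design: 9 clinical dichotomies, 2 gene
sets, or the number of genes actually tested).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consequence_annotation import CONSEQUENCE_TYPES, GeneMutationMatrix
from .io_formats import CLINICAL_DICHOTOMIES, ClinicalRecord, TargetRegions

log = logging.getLogger("cfsomatic")


# ---------------------------------------------------------------------------
# Burden
# ---------------------------------------------------------------------------

@dataclass
class BurdenResult:
    """Per-patient plasma mutation burden and consequence-type counts."""

    patient_id: str
    qualifying_mutations: int
    pmb: float  # mutations per Mb
    type_counts: dict = field(default_factory=dict)


def compute_pmb(variants, target: TargetRegions,
                patients: Sequence[str] | None = None,
                pmb_min_vaf: float = 0.05) -> dict:
    """PMB per patient over kept (post-cascade) variants.

    Only variants with VAF ≥ ``pmb_min_vaf`` and position inside the target
    intervals qualify.  ``patients`` fixes the result keys (patients with no
    variants get PMB 0); by default the patients observed in ``variants``.
    Refuses to divide by a zero-size target.
    """
    if target.total_mb <= 0:
        raise ValueError("target size is 0 Mb; refusing to compute per-Mb burden")
    ids = list(patients) if patients is not None else sorted({v.sample_id for v in variants})
    results = {p: BurdenResult(p, 0, 0.0, {t: 0 for t in CONSEQUENCE_TYPES})
               for p in ids}
    for v in variants:
        r = results.get(v.sample_id)
        if r is None:
            continue
        c = v.consolidated if hasattr(v, "consolidated") else v
        if c.vaf < pmb_min_vaf or not target.contains(v.chrom, v.pos):
            continue
        r.qualifying_mutations += 1
        if v.consequence is not None:
            r.type_counts[v.consequence] += 1
    for r in results.values():
        r.pmb = r.qualifying_mutations / target.total_mb
    return results


def mutation_type_table(burdens: Mapping[str, BurdenResult],
                        clinical: Sequence[ClinicalRecord],
                        parameter: str) -> pd.DataFrame:
    """Group mean ± SD of each consequence-type count for one clinical
    dichotomy, with a Mann–Whitney p per type.

    Rows: the nine consequence types; columns: per-group n/mean/sd and p.
    """
    accessor, labels = CLINICAL_DICHOTOMIES[parameter]
    groups = {labels[0]: [], labels[1]: []}
    for rec in clinical:
        if rec.patient_id in burdens:
            groups[labels[int(bool(accessor(rec)))]].append(rec.patient_id)
    if not groups[labels[0]] or not groups[labels[1]]:
        raise ValueError(f"clinical dichotomy {parameter!r} has an empty group")
    rows = []
    for ctype in CONSEQUENCE_TYPES:
        x = np.array([burdens[p].type_counts[ctype] for p in groups[labels[0]]], float)
        y = np.array([burdens[p].type_counts[ctype] for p in groups[labels[1]]], float)
        _, p = mann_whitney(x, y)
        rows.append({
            "mutation_type": ctype,
            f"n_{labels[0]}": len(x), f"mean_{labels[0]}": x.mean(),
            f"sd_{labels[0]}": x.std(ddof=1) if len(x) > 1 else 0.0,
            f"n_{labels[1]}": len(y), f"mean_{labels[1]}": y.mean(),
            f"sd_{labels[1]}": y.std(ddof=1) if len(y) > 1 else 0.0,
            "p": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def mann_whitney(x, y):
    """Two-sided Mann–Whitney U: ``(U, p)`` for the first sample.

    Exact enumeration when both samples are small (n1 + n2 ≤ 12) and tie-free;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group in Mann-Whitney test")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_corr(x, y):
    """Tie-corrected Spearman rank correlation ``(rho, p)``.

    Pearson correlation of mid-ranks with a t-approximation p-value; raises
    on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: correlation undefined")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def categorical_test(table) -> tuple:
    """Association p-value for a 2×2 count table: ``(p, method)``.

    Fisher's exact (two-sided) when any expected cell count is below 5,
    otherwise chi-square without continuity correction.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    expected = stats.contingency.expected_freq(t)
    if expected.min() < 5:
        _, p = stats.fisher_exact(t, alternative="two-sided")
        return float(p), "fisher"
    chi2 = stats.chi2_contingency(t, correction=False)
    return float(chi2.pvalue), "chi-square"


def adjusted_linear_model(y, predictor, covariate):
    """Age-adjusted association of a binary predictor with burden.

    OLS of standardized ``y`` on the standardized binary predictor and the
    standardized covariate; returns ``(B, p)`` — the standardized coefficient
    of the predictor and its two-sided p.  A constant covariate degrades
    gracefully to the two-predictor model without it; collinear
    predictor/covariate raises.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x1 = np.asarray(predictor, float)
    x2 = np.asarray(covariate, float)
    if y.size <= 3:
        raise ValueError("need more than 3 observations")
    if np.std(x1) == 0:
        raise ValueError("constant predictor")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    cols = [z(x1)]
    names = ["predictor"]
    if np.std(x2) > 0:
        x2z = z(x2)
        if abs(np.corrcoef(x1, x2)[0, 1]) > 1 - 1e-12:
            raise ValueError("predictor and covariate are collinear")
        cols.append(x2z)
        names.append("covariate")
    X = sm.add_constant(np.column_stack(cols))
    model = sm.OLS(z(y), X).fit()
    return float(model.params[1]), float(model.pvalues[1])


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def bonferroni_alpha_display(alpha: float, m: int) -> float:
    """The threshold as reported in text, rounded to 3 decimals
    (0.05/9 -> 0.006, 0.05/2 -> 0.025)."""
    return round(bonferroni_alpha(alpha, m), 3)


# ---------------------------------------------------------------------------
# Gene- and gene-set-level association
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    test: str
    n0: int
    n1: int
    statistic: float | None
    p: float
    bonferroni_alpha: float
    significant_after_correction: bool
    method: str = ""
    B: float | None = None  # standardized coefficient, regression only


@dataclass
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self):
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


#: Gene sets tested against overall survival (family of 2).
BCAA_CATABOLISM = GeneSet("BCAA catabolism",
                          {"HMGCS2", "AUH", "ACAT1", "ACADSB", "EHHADH"})
HYPOXIA_RELATED = GeneSet("Hypoxia-related",
                          {"ARNT", "EPAS1", "PAK3", "RAF1", "TFE3"})


def gene_clinical_association(matrix: GeneMutationMatrix,
                              clinical: Sequence[ClinicalRecord],
                              parameter: str,
                              genes: Sequence[str] | None = None,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene 2×2 association between mutation presence and a clinical
    dichotomy, Bonferroni-corrected over the genes actually tested."""
    accessor, labels = CLINICAL_DICHOTOMIES[parameter]
    genes = list(genes) if genes is not None else list(matrix.presence.columns)
    group1 = {r.patient_id for r in clinical if accessor(r)}
    threshold = bonferroni_alpha(alpha, len(genes))
    rows = []
    for g in genes:
        mut = matrix.presence[g]
        in1 = mut.index.isin(group1)
        a = int((mut & in1).sum())         # mutated, group1
        b = int((mut & ~in1).sum())        # mutated, group0
        c = int((~mut & in1).sum())
        d = int((~mut & ~in1).sum())
        p, method = categorical_test([[a, b], [c, d]])
        rows.append({"gene": g, f"mutated_{labels[1]}": a,
                     f"mutated_{labels[0]}": b, "p": p, "method": method,
                     "bonferroni_alpha": threshold,
                     "significant_after_correction": p < threshold})
    return pd.DataFrame(rows).sort_values("p", ignore_index=True)


def geneset_status(matrix: GeneMutationMatrix, geneset: GeneSet):
    """Per-patient mutation status of a gene set (any member mutated).

    Returns ``(status, fraction)`` — a boolean Series over patients and the
    mutated fraction.  Members absent from the matrix are ignored with a
    warning; an empty intersection raises.
    """
    present = [g for g in sorted(geneset.genes) if g in matrix.presence.columns]
    absent = sorted(geneset.genes - set(present))
    if absent:
        log.warning("gene set %s: members absent from matrix ignored: %s",
                    geneset.name, absent)
    if not present:
        raise ValueError(f"gene set {geneset.name!r} has no members in the matrix")
    status = matrix.presence[present].any(axis=1)
    return status, float(status.mean())


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def km_logrank(times, events, groups):
    """Kaplan–Meier curves and the two-group log-rank test.

    ``groups`` is a boolean/binary vector.  Returns ``(curves, statistic,
    p)`` where ``curves`` maps group label -> survival-function DataFrame
    (product-limit estimate).  Each group must be non-empty.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups).astype(bool)
    curves = {}
    for label in (False, True):
        mask = groups == label
        if not mask.any():
            raise ValueError(f"survival group {label} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(label))
        curves[label] = kmf.survival_function_
    res = logrank_test(times[groups], times[~groups],
                       event_observed_A=events[groups],
                       event_observed_B=events[~groups])
    return curves, float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def power_sample_size(mean1: float, sd1: float, mean2: float, sd2: float,
                      n1: int, n2: int, alpha: float = 0.05,
                      target_power: float = 0.8):
    """Two-sample normal-approximation power and required sample size.

    Uses the pooled standardized difference d = |mean1 - mean2| / s_pooled
    and the two-sided z-test power formula.  Returns ``(power, total_n)``:
    achieved power at the stated group sizes and the total N (both groups,
    same allocation ratio) required for ``target_power``.  A zero effect has
    no finite N (``total_n = inf``).
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    s_pooled = np.sqrt(((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2))
    d = abs(mean1 - mean2) / s_pooled
    z_a = stats.norm.ppf(1 - alpha / 2)
    se_factor = np.sqrt(1 / n1 + 1 / n2)
    ncp = d / se_factor
    power = float(stats.norm.sf(z_a - ncp) + stats.norm.cdf(-z_a - ncp))
    if d == 0:
        return power, float("inf")
    z_b = stats.norm.ppf(target_power)
    ratio = n2 / n1
    # per-group n1' for a (1 : ratio) allocation
    n1_req = (z_a + z_b) ** 2 * (1 + 1 / ratio) / d ** 2
    total_n = float(np.ceil(n1_req) + np.ceil(n1_req * ratio))
    return power, total_n
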