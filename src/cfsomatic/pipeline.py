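"""End-to-end orchestration: merge → annotate → filter → validate → burden.

Thin glue over the stage modules, used by the CLI, the acceptance harness
and tests.  Works either from an in-memory synthetic cohort or from files
on disk.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .caller_merge import merge_callers, normalize_variant, support_histogram
from .cohort_stats import compute_pmb
from .consequence_annotation import annotate_variants
from .filter_cascade import FilterConfig, apply_cascade
from .io_formats import TargetRegions
from .read_validation import ValidationConfig, classify_variant_igv


@dataclass
class PipelineResult:
    merged: list
    kept: list
    trace: object
    histogram: dict
    burdens: dict
    verdicts: dict = field(default_factory=dict)


def run_pipeline(callsets: Mapping[str, Sequence],
                 reference: Mapping[str, str] | None = None,
                 gene_models=None,
                 target: TargetRegions | None = None,
                 patients: Sequence[str] | None = None,
                 population_af: Mapping[str, float] | None = None,
                 pon_sites=None,
                 pileups: Mapping[str, Mapping] | None = None,
                 filter_config: FilterConfig = FilterConfig(),
                 validation_config: ValidationConfig = ValidationConfig(),
                 pmb_min_vaf: float = 0.05) -> PipelineResult:
    """Run the post-calling pipeline over per-caller call sets.

    ``callsets`` maps caller name -> CallerVariant list.  Annotation runs
    when gene models and a reference are supplied; IGV-style validation when
    pileup windows are supplied (verdicts are recorded on the merged
    records but do not remove variants — review is an audit, not a filter).
    """
    normalized = {c: [normalize_variant(v, reference) for v in lst]
                  for c, lst in callsets.items()}
    merged = merge_callers(normalized)
    if gene_models is not None and reference is not None:
        annotate_variants(merged, gene_models, reference)
    kept, trace = apply_cascade(merged, filter_config,
                                af_lookup=population_af, pon_sites=pon_sites)
    target = target or TargetRegions.default()
    burdens = compute_pmb(kept, target, patients=patients,
                          pmb_min_vaf=pmb_min_vaf)
    verdicts = {}
    if pileups:
        for mv in merged:
            pair = pileups.get(mv.key)
            if pair is None:
                continue
            verdict = classify_variant_igv(mv, pair.get("tumor"),
                                           pair.get("normal"), validation_config)
            mv.igv_verdict = verdict.verdict
            verdicts[mv.key] = verdict
    return PipelineResult(merged=merged, kept=kept, trace=trace,
                          histogram=support_histogram(merged),
                          burdens=burdens, verdicts=verdicts)


def run_synthetic(cohort, filter_config: FilterConfig = FilterConfig(),
                  validation_config: ValidationConfig = ValidationConfig(),
                  with_pileups: bool = True) -> PipelineResult:
    """Run the full pipeline on an in-memory synthetic cohort."""
    from .synthetic_cohort import build_pileups, caller_records

    pileups = build_pileups(cohort) if with_pileups else None
    patients = [c.patient_id for c in cohort.clinical]
    return run_pipeline(
        caller_records(cohort), reference=cohort.reference,
        gene_models=cohort.gene_index, target=cohort.target,
        patients=patients, population_af=cohort.population_af,
        pon_sites=cohort.pon_sites, pileups=pileups,
        filter_config=filter_config, validation_config=validation_config)
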