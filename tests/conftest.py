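import numpy as np
import pytest

from cfsomatic.io_formats import CallerVariant
from cfsomatic.synthetic_cohort import SimulationConfig, simulate_cohort


def small_config(seed=7, **kw):
    """A desk-scale study: 8 patients, reduced rates, 300-gene exome."""
    defaults = dict(seed=seed, n_patients=8, lambda_nonmet=2.0, lambda_met=5.0,
                    n_genes=300, germline_per_patient=30,
                    artifacts_per_patient=25, n_population_sites=500,
                    n_pon_sites=60, max_pileup_sites=2500)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config())


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    from cfsomatic.pipeline import run_synthetic

    return run_synthetic(small_cohort)


def make_variant(caller="mutect2", sample="P01", chrom="chr1", pos=100,
                 ref="A", alt="T", tumor_depth=80, tumor_alt=20,
                 normal_depth=80, normal_alt=0, alt_fwd=None, alt_rev=None,
                 **kw):
    if alt_fwd is None:
        alt_fwd = tumor_alt - tumor_alt // 2
    if alt_rev is None:
        alt_rev = tumor_alt - alt_fwd
    vaf = tumor_alt / tumor_depth if tumor_depth else 0.0
    return CallerVariant(caller_name=caller, sample_id=sample, chrom=chrom,
                         pos=pos, ref=ref, alt=alt, tumor_depth=tumor_depth,
                         tumor_alt=tumor_alt, normal_depth=normal_depth,
                         normal_alt=normal_alt, alt_fwd=alt_fwd,
                         alt_rev=alt_rev, vaf=vaf, **kw)


def make_merged(**kw):
    from cfsomatic.caller_merge import merge_callers

    v = make_variant(**kw)
    return merge_callers({v.caller_name: [v]})[0]
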