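"""Seeded generator of a complete synthetic cfDNA tumor/normal study.

Produces, from one integer seed, everything the pipeline consumes — a small
synthetic exome (a few Mb of gene models over six chromosomes, using real
OSCC-relevant gene symbols so the blacklist and gene-set machinery is
exercised), per-patient true somatic variants with group-dependent burden
(metastatic patients carry more), germline SNPs tied to a population
allele-frequency table, five caller call sets with caller-specific
sensitivity and false-positive profiles, pileup windows with planted
artifact classes, and a clinical table whose survival times are coupled to
gene-set mutation status — together with a truth manifest that labels every
emitted record by origin.

The per-Mb somatic rate λ is the rate of *detectable* (VAF ≥ 5%) mutations,
so the planted group rates are recovered directly as group mean plasma
mutation burden; the defaults (λ = 14 vs 38 mutations/Mb for 41 + 9
patients) echo the group means of the motivating clinical cohort.  Genomic
positions live in a small exon space (~4 Mb) while the burden denominator
stays at the 91.08 Mb design size, keeping runtime at desk scale without
changing the statistic's scale.

Each artifact class violates exactly one filter or review criterion:
``oxog`` (one-sided F1R2/F2R1 orientation, always emitted by the one caller
dialect that reports orientation), ``strand_bias`` (all alt reads on one
strand, always emitted by a strand-aware caller), ``clustered`` (≥3 events
within 100 bp, alt reads carrying extra window mismatches), ``low_support``
(<3 tumor alt reads or ≥3 normal alt reads), ``pon`` (drawn from the
recurrent panel-of-normals site list) and ``blacklist`` (placed in
MUC16/MUC19).  Identical config + seed gives byte-identical outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .caller_merge import MergedVariant
from .cohort_stats import HYPOXIA_RELATED
from .consequence_annotation import (GeneIndex, GeneModel, classify_consequence,
                                     is_nonsynonymous)
from .io_formats import CALLERS, CallerVariant, ClinicalRecord, TargetRegions
from .read_validation import PileupRead, PileupWindow

log = logging.getLogger("cfsomatic")

ARTIFACT_CLASSES = ("oxog", "strand_bias", "clustered", "low_support",
                    "pon", "blacklist")

#: Which cascade filter is expected to remove each planted origin class.
INTENDED_FILTER = {
    "germline": "population_af",
    "oxog": "oxog",
    "strand_bias": "site_artifacts",
    "clustered": "site_artifacts",
    "low_support": "allele_support",
    "pon": "panel_of_normals",
    "blacklist": "blacklist_genes",
}

#: Named genes with fixed coding lengths (bp, multiples of 3).  Sizes are
#: graded so the most frequently mutated genes of a real OSCC cfDNA cohort
#: stay the most frequently hit here; the survival gene-set members are kept
#: small so their per-patient mutation probability lands near the 20-30%
#: range reported for such sets.
NAMED_GENE_SIZES = {
    "TTN": 9000, "MUC16": 7500, "SYNE1": 6600, "OBSCN": 6000, "KMT2D": 4800,
    "RYR3": 4800, "MUC19": 4500, "UBR4": 4500, "MACF1": 4200, "SYNE2": 4200,
    "PLEC": 3900, "RYR1": 3900, "DNAH1": 3900, "DMD": 3600, "HECTD4": 3600,
    "LRP1B": 3300, "LRP1": 3300, "MYCBP2": 3000, "DNAH11": 3000, "USH2A": 3000,
    "DNHD1": 2700, "ATM": 2700, "FAT4": 2700, "INTS1": 2400, "NBEAL1": 2100,
    # survival gene sets (BCAA catabolism + hypoxia-related)
    "HMGCS2": 300, "AUH": 300, "ACAT1": 300, "ACADSB": 300, "EHHADH": 300,
    "ARNT": 300, "EPAS1": 300, "PAK3": 300, "RAF1": 300, "TFE3": 300,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHROMS = tuple(f"chr{i}" for i in range(1, 7))

#: Callers whose VCF representation of indels carries an extra shared
#: suffix base (exercises cross-caller normalization).
PAD_INDEL_CALLERS = frozenset({"vardict", "somaticsniper"})


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort."""

    seed: int = 0
    n_patients: int = 50
    metastatic_fraction: float = 9 / 50
    lambda_nonmet: float = 14.0   # detectable somatic mutations per Mb
    lambda_met: float = 38.0
    target_mb: float = 91.08      # burden denominator (capture design size)
    n_genes: int = 3000
    indel_fraction: float = 0.02
    splice_fraction: float = 0.01
    germline_per_patient: int = 150
    n_population_sites: int = 4000
    n_pon_sites: int = 300
    artifacts_per_patient: float = 40.0
    artifact_class_props: dict = field(default_factory=lambda: {
        "oxog": 0.20, "strand_bias": 0.20, "clustered": 0.15,
        "low_support": 0.20, "pon": 0.15, "blacklist": 0.10})
    caller_sensitivity: dict = field(default_factory=lambda: {
        "mutect2": 0.95, "strelka2": 0.90, "vardict": 0.85,
        "muse": 0.75, "somaticsniper": 0.70})
    caller_fp_rate: dict = field(default_factory=lambda: {
        "mutect2": 0.35, "strelka2": 0.50, "vardict": 0.55,
        "muse": 0.40, "somaticsniper": 0.50})
    germline_leak_rate: float = 0.4
    vaf_alpha: float = 2.0
    vaf_beta: float = 6.0
    vaf_floor: float = 0.10       # detection floor of the planted VAF mixture
    mean_depth: float = 90.0      # matches the ~90x coverage of cfDNA WES
    normal_noise_vaf: float = 0.002
    window_error_rate: float = 0.02  # P(extra mismatch per read per 20bp window)
    stray_allele_rate: float = 0.03
    metastasis_gene: str = "KMT2D"
    metastasis_gene_extra: float = 4.0  # extra mutations in met patients
    survival_geneset: frozenset = frozenset(HYPOXIA_RELATED.genes)
    hazard_ratio: float = 3.0
    baseline_hazard: float = np.log(2) / 1500.0  # per day; WT median OS 1500 d
    followup_min_days: float = 300.0
    followup_max_days: float = 2500.0
    max_pileup_sites: int = 4000

    def lam(self, metastatic: bool) -> float:
        return self.lambda_met if metastatic else self.lambda_nonmet


@dataclass
class TruthManifest:
    """Ground-truth labels for every emitted record.

    ``variants`` has one row per planted variant (origin: somatic, germline
    or an artifact class; the caller membership columns say which call sets
    carry it); ``per_patient`` holds true burdens, gene-set status and the
    survival parameters.
    """

    variants: pd.DataFrame
    per_patient: pd.DataFrame


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    manifest: TruthManifest
    clinical: list
    gene_models: list
    gene_index: GeneIndex
    reference: dict           # chrom -> str
    target: TargetRegions
    population_af: dict       # "chrom-pos-ref-alt" -> AF
    pon_sites: frozenset
    exon_bed: list            # (chrom, start0, end0) of the synthetic exons


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _gene_sizes(config: SimulationConfig, rng) -> list:
    sizes = list(NAMED_GENE_SIZES.items())
    n_filler = max(config.n_genes - len(sizes), 0)
    raw = rng.lognormal(mean=np.log(1300.0), sigma=0.5, size=n_filler)
    raw = np.clip(raw, 300, 4200)
    for i, s in enumerate(raw):
        sizes.append((f"GENE{i + 1:04d}", int(round(s / 3.0)) * 3))
    return sizes


def _build_genome(config: SimulationConfig, rng):
    """Lay out gene models over six chromosomes and draw the reference."""
    sizes = _gene_sizes(config, rng)
    order = rng.permutation(len(sizes))
    total_cds = sum(s for _, s in sizes)
    per_chrom_target = total_cds * 1.35 / len(_CHROMS)

    models, layouts = [], {c: [] for c in _CHROMS}
    chrom_i, cursor = 0, 1000
    cursors = {c: 1000 for c in _CHROMS}
    for idx in order:
        symbol, cds_len = sizes[idx]
        chrom = _CHROMS[chrom_i]
        pos = cursors[chrom]
        n_exons = 1 if cds_len < 400 else int(rng.integers(2, 4))
        cuts = np.sort(rng.integers(60, cds_len - 60, size=n_exons - 1)) \
            if n_exons > 1 else np.array([], dtype=int)
        exon_lens = np.diff(np.concatenate([[0], cuts, [cds_len]]))
        if (exon_lens < 30).any():  # re-split degenerate cuts evenly
            exon_lens = np.full(n_exons, cds_len // n_exons)
            exon_lens[-1] += cds_len - exon_lens.sum()
        exons = []
        for el in exon_lens:
            exons.append((pos, pos + int(el) - 1))
            pos += int(el) + int(rng.integers(60, 200))  # intron
        strand = "+" if rng.random() < 0.5 else "-"
        models.append(GeneModel(symbol=symbol, chrom=chrom, strand=strand,
                                exons=exons))
        cursors[chrom] = exons[-1][1] + int(rng.integers(150, 400))
        if cursors[chrom] - 1000 > per_chrom_target:
            chrom_i = min(chrom_i + 1, len(_CHROMS) - 1)

    chrom_lens = {c: cursors[c] + 1000 for c in _CHROMS}
    ref_arrays = {c: _BASES[rng.integers(0, 4, size=chrom_lens[c])].copy()
                  for c in _CHROMS}

    # patch start (ATG) and stop (TGA) codons onto each CDS
    for m in models:
        L = m.cds_length
        for cds_i, base in list(zip(range(3), b"ATG")) + \
                list(zip(range(L - 3, L), b"TGA")):
            gpos, flip = _cds_to_genomic(m, cds_i)
            b = base
            if flip:
                b = {65: 84, 84: 65, 67: 71, 71: 67}[base]  # complement
            ref_arrays[m.chrom][gpos - 1] = b

    reference = {c: arr.tobytes().decode("ascii") for c, arr in ref_arrays.items()}
    return models, reference, ref_arrays


def _cds_to_genomic(model: GeneModel, cds_i: int):
    """Genomic 1-based position of a coding-strand CDS index, and whether
    the stored reference base is the complement."""
    idx_fwd = cds_i if model.strand == "+" else model.cds_length - 1 - cds_i
    offset = 0
    for s, e in model.exons:
        n = e - s + 1
        if idx_fwd < offset + n:
            return s + (idx_fwd - offset), model.strand == "-"
        offset += n
    raise IndexError(cds_i)


def _exon_position_table(models):
    """Flat arrays (chrom_code, pos, gene_idx) of every exonic base."""
    chrom_code = {c: i for i, c in enumerate(_CHROMS)}
    codes, positions, gene_idx = [], [], []
    for gi, m in enumerate(models):
        for s, e in m.exons:
            n = e - s + 1
            positions.append(np.arange(s, e + 1, dtype=np.int64))
            codes.append(np.full(n, chrom_code[m.chrom], dtype=np.int16))
            gene_idx.append(np.full(n, gi, dtype=np.int32))
    return (np.concatenate(codes), np.concatenate(positions),
            np.concatenate(gene_idx))


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimulationConfig = SimulationConfig(),
                    detail: str = "full") -> SyntheticCohort:
    """Generate the synthetic study.

    ``detail="burdens"`` skips variant placement, caller assignment and the
    genome (used for replicate studies of burden statistics); the manifest
    then carries only the per-patient table.  Deterministic under the
    config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_genome, s_clinical, s_somatic, s_germline, s_artifact,
     s_caller, s_survival, s_pileup) = ss.spawn(8)
    rng_clin = np.random.default_rng(s_clinical)
    rng_som = np.random.default_rng(s_somatic)

    n = config.n_patients
    patients = [f"P{i + 1:02d}" for i in range(n)]
    n_met = int(round(config.metastatic_fraction * n))
    met_mask = np.zeros(n, dtype=bool)
    if n:
        met_mask[rng_clin.choice(n, size=n_met, replace=False)] = True

    counts = np.array([rng_som.poisson(config.lam(m) * config.target_mb)
                       for m in met_mask], dtype=int)

    per_patient = pd.DataFrame({
        "patient_id": patients, "metastasis": met_mask,
        "n_somatic": counts, "pmb_true": counts / config.target_mb,
    })

    if detail == "burdens" or n == 0:
        per_patient["geneset_mutated"] = False
        clinical = _draw_clinical(config, per_patient, rng_clin,
                                  np.random.default_rng(s_survival))
        manifest = TruthManifest(variants=pd.DataFrame(), per_patient=per_patient)
        return SyntheticCohort(config=config, manifest=manifest,
                               clinical=clinical, gene_models=[],
                               gene_index=GeneIndex([]), reference={},
                               target=TargetRegions(None, config.target_mb),
                               population_af={}, pon_sites=frozenset(),
                               exon_bed=[])

    models, reference, ref_arrays = _build_genome(config, np.random.default_rng(s_genome))
    chrom_of = np.array(_CHROMS)
    exp_code, exp_pos, exp_gene = _exon_position_table(models)
    n_expos = exp_pos.size
    symbols = [m.symbol for m in models]
    gi_by_symbol = {s: i for i, s in enumerate(symbols)}

    # --- true somatic variants -------------------------------------------
    frames = []
    ref_code_arrays = {c: np.searchsorted(_BASES, arr) for c, arr in ref_arrays.items()}
    for pi, pid in enumerate(patients):
        k = counts[pi]
        extra = int(rng_som.poisson(config.metastasis_gene_extra)) if met_mask[pi] else 0
        idx = _sample_distinct(rng_som, n_expos, k)
        if extra:
            gene_i = gi_by_symbol[config.metastasis_gene]
            pool = np.flatnonzero(exp_gene == gene_i)
            idx = np.unique(np.concatenate(
                [idx, rng_som.choice(pool, size=min(extra, pool.size), replace=False)]))
        frames.append(pd.DataFrame({
            "sample_id": pid,
            "chrom": chrom_of[exp_code[idx]],
            "pos": exp_pos[idx],
            "gene_idx": exp_gene[idx],
        }))
    som = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    m_tot = len(som)
    code = np.searchsorted(np.array(_CHROMS), som["chrom"].to_numpy())
    ref_idx = np.array([ref_code_arrays[c][p - 1]
                        for c, p in zip(som["chrom"], som["pos"])], dtype=int)
    alt_idx = (ref_idx + rng_som.integers(1, 4, size=m_tot)) % 4
    base_str = "ACGT"
    som["ref"] = [base_str[i] for i in ref_idx]
    som["alt"] = [base_str[i] for i in alt_idx]
    som["origin"] = "somatic"

    # truncated Beta VAFs (floor = detection limit of the planted mixture)
    a, b = config.vaf_alpha, config.vaf_beta
    u = rng_som.uniform(beta_dist.cdf(config.vaf_floor, a, b), 1.0, size=m_tot)
    som["true_vaf"] = beta_dist.ppf(u, a, b)

    # a small fraction become indels / splice-site variants
    _make_indels(som, reference, rng_som, config)
    splice_rows = _splice_variants(som, models, reference, rng_som, config,
                                   gi_by_symbol)
    if splice_rows is not None and len(splice_rows):
        som = pd.concat([som, splice_rows], ignore_index=True)

    # --- germline SNPs and population AF table ---------------------------
    rng_germ = np.random.default_rng(s_germline)
    pop_idx = _sample_distinct(rng_germ, n_expos, config.n_population_sites)
    pop = pd.DataFrame({
        "chrom": chrom_of[exp_code[pop_idx]], "pos": exp_pos[pop_idx],
        "gene_idx": exp_gene[pop_idx],
    })
    p_ref = np.array([ref_code_arrays[c][p - 1]
                      for c, p in zip(pop["chrom"], pop["pos"])], dtype=int)
    p_alt = (p_ref + rng_germ.integers(1, 4, size=len(pop))) % 4
    pop["ref"] = [base_str[i] for i in p_ref]
    pop["alt"] = [base_str[i] for i in p_alt]
    pop["af"] = rng_germ.uniform(0.02, 0.5, size=len(pop))
    population_af = {f"{r.chrom}-{r.pos}-{r.ref}-{r.alt}": float(r.af)
                     for r in pop.itertuples()}

    germ_frames = []
    n_g = min(config.germline_per_patient, len(pop))
    for pid in patients:
        pick = rng_germ.choice(len(pop), size=n_g, replace=False)
        g = pop.iloc[np.sort(pick)][["chrom", "pos", "gene_idx", "ref", "alt"]].copy()
        g["sample_id"] = pid
        g["origin"] = "germline"
        g["true_vaf"] = np.clip(rng_germ.normal(0.5, 0.05, size=len(g)), 0.05, 0.95)
        germ_frames.append(g)
    germ = pd.concat(germ_frames, ignore_index=True) if germ_frames else pd.DataFrame()

    # --- panel-of-normals site list and artifacts ------------------------
    rng_art_master = np.random.default_rng(s_artifact)
    class_seeds = s_artifact.spawn(len(ARTIFACT_CLASSES))
    class_rngs = {cls: np.random.default_rng(cs)
                  for cls, cs in zip(ARTIFACT_CLASSES, class_seeds)}

    pon_idx = _sample_distinct(rng_art_master, n_expos, config.n_pon_sites)
    pon = pd.DataFrame({
        "chrom": chrom_of[exp_code[pon_idx]], "pos": exp_pos[pon_idx],
        "gene_idx": exp_gene[pon_idx],
    })
    q_ref = np.array([ref_code_arrays[c][p - 1]
                      for c, p in zip(pon["chrom"], pon["pos"])], dtype=int)
    q_alt = (q_ref + rng_art_master.integers(1, 4, size=len(pon))) % 4
    pon["ref"] = [base_str[i] for i in q_ref]
    pon["alt"] = [base_str[i] for i in q_alt]
    pon_sites = frozenset(f"{r.chrom}-{r.pos}-{r.ref}-{r.alt}"
                          for r in pon.itertuples())

    art = _plant_artifacts(config, patients, models, reference, ref_code_arrays,
                           exp_code, exp_pos, exp_gene, chrom_of, pon,
                           class_rngs, rng_art_master, som)

    variants = pd.concat([som, germ, art], ignore_index=True)
    variants["gene"] = [symbols[i] if i >= 0 else "" for i in variants["gene_idx"]]

    # --- sequencing counts -----------------------------------------------
    _draw_counts(variants, config, rng_som)

    # --- caller membership ------------------------------------------------
    rng_call = np.random.default_rng(s_caller)
    _assign_callers(variants, config, rng_call)

    variants["key"] = (variants["sample_id"] + "-" + variants["chrom"] + "-"
                       + variants["pos"].astype(str) + "-" + variants["ref"]
                       + "-" + variants["alt"])
    # a germline draw can land on a somatic allele; keep one manifest entry
    # per key (somatic rows first) so every emitted record traces uniquely
    variants = variants.drop_duplicates(subset="key", keep="first",
                                        ignore_index=True)
    variants["intended_filter"] = variants["origin"].map(INTENDED_FILTER).fillna("")
    variants["igv_expected"] = np.select(
        [variants["origin"].eq("somatic") & (variants["ref"].str.len() == 1)
         & (variants["alt"].str.len() == 1),
         variants["origin"].isin(["strand_bias", "clustered", "low_support"])],
        ["pass", "non_pass"], default="")

    # --- gene-set status and survival ------------------------------------
    gene_index = GeneIndex(models)
    set_genes = set(config.survival_geneset)
    status = {p: False for p in patients}
    sel = variants[(variants["origin"] == "somatic")
                   & variants["gene"].isin(set_genes)]
    for r in sel.itertuples():
        if status[r.sample_id]:
            continue
        model = models[r.gene_idx]
        v = type("V", (), {"pos": r.pos, "ref": r.ref, "alt": r.alt,
                           "key": r.key})
        try:
            cons = classify_consequence(v, model, reference)
        except Exception:
            continue
        if is_nonsynonymous(cons):
            status[r.sample_id] = True
    per_patient["geneset_mutated"] = [status[p] for p in patients]

    clinical = _draw_clinical(config, per_patient, rng_clin,
                              np.random.default_rng(s_survival))
    per_patient["os_time"] = [c.os_time for c in clinical]
    per_patient["event"] = [c.event for c in clinical]

    exon_bed = sorted((m.chrom, s - 1, e) for m in models for s, e in m.exons)
    manifest = TruthManifest(variants=variants, per_patient=per_patient)
    return SyntheticCohort(config=config, manifest=manifest, clinical=clinical,
                           gene_models=models, gene_index=gene_index,
                           reference=reference,
                           target=TargetRegions(None, config.target_mb),
                           population_af=population_af, pon_sites=pon_sites,
                           exon_bed=exon_bed)


def _sample_distinct(rng, n_pop: int, k: int) -> np.ndarray:
    """k distinct indices in [0, n_pop) (sorted), cheap for k << n_pop."""
    k = min(k, n_pop)
    out = np.unique(rng.integers(0, n_pop, size=int(k * 1.05) + 16))
    while out.size < k:
        out = np.unique(np.concatenate(
            [out, rng.integers(0, n_pop, size=k - out.size + 16)]))
    if out.size > k:
        out = rng.choice(out, size=k, replace=False)
        out.sort()
    return out


def _make_indels(som: pd.DataFrame, reference, rng, config) -> None:
    mask = rng.random(len(som)) < config.indel_fraction
    for i in np.flatnonzero(mask):
        chrom, pos = som.at[i, "chrom"], int(som.at[i, "pos"])
        seq = reference[chrom]
        length = int(rng.integers(1, 4))
        anchor = seq[pos - 1]
        if rng.random() < 0.5 and pos - 1 + 1 + length <= len(seq):  # deletion
            som.at[i, "ref"] = seq[pos - 1: pos + length]
            som.at[i, "alt"] = anchor
        else:  # insertion
            ins = "".join("ACGT"[j] for j in rng.integers(0, 4, size=length))
            som.at[i, "ref"] = anchor
            som.at[i, "alt"] = anchor + ins


def _splice_variants(som, models, reference, rng, config, gi_by_symbol):
    """Extra intronic variants at canonical splice positions."""
    multi = [i for i, m in enumerate(models) if len(m.exons) > 1]
    if not multi:
        return None
    rows = []
    for pid, grp in som.groupby("sample_id", sort=False):
        n_s = rng.poisson(config.splice_fraction * len(grp))
        for _ in range(n_s):
            gi = int(rng.choice(multi))
            m = models[gi]
            # a donor/acceptor position of a random internal boundary
            bi = int(rng.integers(0, len(m.exons) - 1))
            if rng.random() < 0.5:
                pos = m.exons[bi][1] + int(rng.integers(1, m.splice_margin + 1))
            else:
                pos = m.exons[bi + 1][0] - int(rng.integers(1, m.splice_margin + 1))
            refb = reference[m.chrom][pos - 1]
            alt = "ACGT"[("ACGT".index(refb) + int(rng.integers(1, 4))) % 4]
            rows.append({"sample_id": pid, "chrom": m.chrom, "pos": pos,
                         "gene_idx": gi, "ref": refb, "alt": alt,
                         "origin": "somatic",
                         "true_vaf": float(np.clip(rng.beta(
                             config.vaf_alpha, config.vaf_beta), config.vaf_floor, 1))})
    return pd.DataFrame(rows)


def _plant_artifacts(config, patients, models, reference, ref_code_arrays,
                     exp_code, exp_pos, exp_gene, chrom_of, pon, class_rngs,
                     rng_master, som) -> pd.DataFrame:
    """Per-patient artifact calls, one planted class per record."""
    base_str = "ACGT"
    classes = list(config.artifact_class_props)
    probs = np.array([config.artifact_class_props[c] for c in classes], float)
    probs = probs / probs.sum()
    taken = {(r.sample_id, r.chrom, r.pos) for r in som.itertuples()}

    bl_models = [(i, m) for i, m in enumerate(models)
                 if m.symbol in ("MUC16", "MUC19")]
    rows = []
    n_expos = exp_pos.size
    for pid in patients:
        n_art = rng_master.poisson(config.artifacts_per_patient)
        draw = rng_master.choice(len(classes), size=n_art, p=probs)
        for ci in draw:
            cls = classes[ci]
            rng = class_rngs[cls]
            if cls == "pon":
                r = pon.iloc[int(rng.integers(0, len(pon)))]
                entries = [(r.chrom, int(r.pos), r.ref, r.alt, int(r.gene_idx))]
            elif cls == "blacklist":
                gi, m = bl_models[int(rng.integers(0, len(bl_models)))]
                s, e = m.exons[int(rng.integers(0, len(m.exons)))]
                pos = int(rng.integers(s, e + 1))
                refb = reference[m.chrom][pos - 1]
                alt = base_str[(base_str.index(refb) + int(rng.integers(1, 4))) % 4]
                entries = [(m.chrom, pos, refb, alt, gi)]
            elif cls == "oxog":
                # C>A or G>T substitution at a matching reference base
                for _ in range(50):
                    j = int(rng.integers(0, n_expos))
                    chrom = chrom_of[exp_code[j]]
                    refb = base_str[ref_code_arrays[chrom][exp_pos[j] - 1]]
                    if refb in "CG":
                        break
                alt = "A" if refb == "C" else "T"
                entries = [(chrom, int(exp_pos[j]), refb, alt, int(exp_gene[j]))]
            elif cls == "clustered":
                # three events within one 100 bp window, inside one exon
                for _ in range(50):
                    gi = int(rng.integers(0, len(models)))
                    m = models[gi]
                    s, e = max(m.exons, key=lambda x: x[1] - x[0])
                    if e - s >= 120:
                        break
                start = int(rng.integers(s, e - 95))
                offs = [0, 30 + int(rng.integers(0, 15)), 62 + int(rng.integers(0, 25))]
                entries = []
                for o in offs:
                    pos = start + o
                    refb = reference[m.chrom][pos - 1]
                    alt = base_str[(base_str.index(refb) + int(rng.integers(1, 4))) % 4]
                    entries.append((m.chrom, pos, refb, alt, gi))
            else:  # strand_bias, low_support: anywhere exonic
                j = int(rng.integers(0, n_expos))
                chrom = chrom_of[exp_code[j]]
                refb = base_str[ref_code_arrays[chrom][exp_pos[j] - 1]]
                alt = base_str[(base_str.index(refb) + int(rng.integers(1, 4))) % 4]
                entries = [(chrom, int(exp_pos[j]), refb, alt, int(exp_gene[j]))]
            for chrom, pos, refb, alt, gi in entries:
                if (pid, chrom, pos) in taken:
                    continue  # artifact positions never collide with truth keys
                taken.add((pid, chrom, pos))
                rows.append({"sample_id": pid, "chrom": chrom, "pos": pos,
                             "gene_idx": gi, "ref": refb, "alt": alt,
                             "origin": cls, "true_vaf": np.nan})
    return pd.DataFrame(rows)


def _draw_counts(variants: pd.DataFrame, config, rng) -> None:
    """Tumor/normal depths, alt counts, strand and orientation splits."""
    m = len(variants)
    depth = np.maximum(rng.poisson(config.mean_depth, size=m), 20)
    ndepth = np.maximum(rng.poisson(config.mean_depth, size=m), 20)
    origin = variants["origin"].to_numpy()
    vaf = variants["true_vaf"].to_numpy(float)

    alt = np.zeros(m, dtype=int)
    nalt = np.zeros(m, dtype=int)
    is_som = origin == "somatic"
    is_germ = origin == "germline"
    alt[is_som] = np.maximum(rng.binomial(depth[is_som], vaf[is_som]), 1)
    nalt[is_som] = rng.binomial(ndepth[is_som], config.normal_noise_vaf)
    alt[is_germ] = np.maximum(rng.binomial(depth[is_germ], vaf[is_germ]), 1)
    nalt[is_germ] = rng.binomial(ndepth[is_germ], vaf[is_germ])

    for cls, lo in (("oxog", 6), ("clustered", 6), ("pon", 6), ("blacklist", 6)):
        mask = origin == cls
        alt[mask] = lo + rng.poisson(4, size=mask.sum())
        nalt[mask] = rng.binomial(ndepth[mask], config.normal_noise_vaf)
    mask = origin == "strand_bias"
    alt[mask] = 10 + rng.poisson(5, size=mask.sum())
    nalt[mask] = rng.binomial(ndepth[mask], config.normal_noise_vaf)
    mask = origin == "low_support"
    n_ls = mask.sum()
    tumor_side = rng.random(n_ls) < 0.5
    a = np.where(tumor_side, rng.integers(1, 3, size=n_ls),
                 10 + rng.poisson(4, size=n_ls))
    na = np.where(tumor_side, rng.binomial(ndepth[mask], config.normal_noise_vaf),
                  4 + rng.poisson(2, size=n_ls))
    alt[mask], nalt[mask] = a, na

    alt = np.minimum(alt, depth)
    nalt = np.minimum(nalt, ndepth)

    alt_fwd = rng.binomial(alt, 0.5)
    sb_mask = origin == "strand_bias"
    one_side = rng.random(sb_mask.sum()) < 0.5
    alt_fwd[sb_mask] = np.where(one_side, alt[sb_mask], 0)
    ref_n = depth - alt
    ref_fwd = rng.binomial(ref_n, 0.5)

    f1r2 = rng.binomial(alt, 0.5)
    ox_mask = origin == "oxog"
    ox_side = rng.random(ox_mask.sum()) < 0.5
    f1r2[ox_mask] = np.where(ox_side, alt[ox_mask], 0)

    variants["tumor_depth"] = depth
    variants["tumor_alt"] = alt
    variants["normal_depth"] = ndepth
    variants["normal_alt"] = nalt
    variants["alt_fwd"] = alt_fwd
    variants["alt_rev"] = alt - alt_fwd
    variants["ref_fwd"] = ref_fwd
    variants["ref_rev"] = ref_n - ref_fwd
    variants["f1r2"] = f1r2
    variants["f2r1"] = alt - f1r2
    variants["vaf"] = np.where(depth > 0, alt / depth, 0.0)


def _assign_callers(variants: pd.DataFrame, config, rng) -> None:
    """Bernoulli caller membership with the forcing rules described above."""
    m = len(variants)
    origin = variants["origin"].to_numpy()
    member = np.zeros((m, len(CALLERS)), dtype=bool)
    for j, caller in enumerate(CALLERS):
        p = np.where(origin == "somatic", config.caller_sensitivity[caller],
                     np.where(origin == "germline", config.germline_leak_rate,
                              config.caller_fp_rate[caller]))
        member[:, j] = rng.random(m) < p
    # every record must be called by someone
    none = ~member.any(axis=1)
    member[none, rng.integers(0, len(CALLERS), size=none.sum())] = True
    # orientation evidence requires mutect2; strand evidence a strand-aware caller
    mut_j = CALLERS.index("mutect2")
    vd_j = CALLERS.index("vardict")
    member[origin == "oxog", mut_j] = True
    sb = origin == "strand_bias"
    member[sb & ~member[:, mut_j] & ~member[:, vd_j], vd_j] = True
    for j, caller in enumerate(CALLERS):
        variants[f"caller_{caller}"] = member[:, j]


def _draw_clinical(config, per_patient: pd.DataFrame, rng, rng_surv) -> list:
    """Clinical covariates and survival outcomes.

    Covariate prevalences mirror a male-predominant OSCC cohort (96% male,
    ~74% T4, ~44% node-positive, ~78% stage IV with all metastatic patients
    stage IV, ~8% p16-positive).  Survival is exponential with hazard
    multiplied by the planted ratio for gene-set-mutated patients; censoring
    is uniform administrative follow-up.
    """
    n = len(per_patient)
    records = []
    if n == 0:
        return records
    met = per_patient["metastasis"].to_numpy()
    ages = np.clip(np.round(rng.normal(59.6, 10.0, size=n)), 40, 89)

    def pick(k, eligible=None):
        chosen = np.zeros(n, dtype=bool)
        pool = np.flatnonzero(eligible) if eligible is not None else np.arange(n)
        k = min(k, pool.size)
        if k > 0:
            chosen[rng.choice(pool, size=k, replace=False)] = True
        return chosen

    female = pick(max(1, round(0.04 * n))) if n > 2 else np.zeros(n, bool)
    t4 = pick(round(0.74 * n))
    nplus = pick(round(0.44 * n))
    stage4 = met.copy()
    need = round(0.78 * n) - stage4.sum()
    if need > 0:
        stage4 |= pick(int(need), eligible=~stage4)
    pni = pick(round(0.34 * n))
    lvi = pick(round(0.22 * n))
    p16 = pick(round(0.08 * n))

    status = per_patient["geneset_mutated"].to_numpy() \
        if "geneset_mutated" in per_patient else np.zeros(n, bool)
    hazard = config.baseline_hazard * np.where(status, config.hazard_ratio, 1.0)
    t_event = rng_surv.exponential(1.0 / hazard)
    censor = rng_surv.uniform(config.followup_min_days, config.followup_max_days, size=n)
    os_time = np.minimum(t_event, censor)
    event = t_event <= censor

    for i, pid in enumerate(per_patient["patient_id"]):
        records.append(ClinicalRecord(
            patient_id=pid, age=float(ages[i]),
            sex="female" if female[i] else "male",
            t_stage="T4" if t4[i] else "T1-3",
            n_stage="N+" if nplus[i] else "N0",
            clinical_stage="IV" if stage4[i] else "I-III",
            metastasis=bool(met[i]), perineural_invasion=bool(pni[i]),
            lymphovascular_invasion=bool(lvi[i]), p16=bool(p16[i]),
            os_time=float(np.round(os_time[i], 1)), event=bool(event[i])))
    return records


# ---------------------------------------------------------------------------
# Caller record materialization and VCF emission
# ---------------------------------------------------------------------------

def _padded_alleles(caller: str, ref: str, alt: str, chrom: str, pos: int,
                    reference) -> tuple:
    """Caller-specific (non-minimal) indel representation."""
    if caller in PAD_INDEL_CALLERS and len(ref) != len(alt):
        seq = reference[chrom]
        end = pos - 1 + len(ref)
        if end < len(seq):
            b = seq[end]
            return ref + b, alt + b
    return ref, alt


def caller_records(cohort: SyntheticCohort) -> dict:
    """In-memory per-caller :class:`CallerVariant` call sets.

    Counts are shared across callers (the same reads underlie every call);
    only the fields each dialect reports differ: strand split for mutect2
    and vardict, read-pair orientation for mutect2 only, an even imputed
    strand split (``strand_known=False``) elsewhere.  Indels are emitted in
    a right-padded representation by some callers.
    """
    out = {c: [] for c in CALLERS}
    v = cohort.manifest.variants
    if v.empty:
        return out
    member_cols = {c: v[f"caller_{c}"].to_numpy() for c in CALLERS}
    rows = list(v.itertuples())
    for caller in CALLERS:
        mem = member_cols[caller]
        records = out[caller]
        for i, r in enumerate(rows):
            if not mem[i]:
                continue
            ref, alt = _padded_alleles(caller, r.ref, r.alt, r.chrom, r.pos,
                                       cohort.reference)
            kwargs = dict(caller_name=caller, sample_id=r.sample_id,
                          chrom=r.chrom, pos=r.pos, ref=ref, alt=alt,
                          tumor_depth=int(r.tumor_depth), tumor_alt=int(r.tumor_alt),
                          normal_depth=int(r.normal_depth), normal_alt=int(r.normal_alt),
                          vaf=float(r.vaf))
            if caller == "mutect2":
                records.append(CallerVariant(
                    alt_fwd=int(r.alt_fwd), alt_rev=int(r.alt_rev),
                    ref_fwd=int(r.ref_fwd), ref_rev=int(r.ref_rev),
                    fr_orientation=(int(r.f1r2), int(r.f2r1)),
                    strand_known=True, **kwargs))
            elif caller == "vardict":
                records.append(CallerVariant(
                    alt_fwd=int(r.alt_fwd), alt_rev=int(r.alt_rev),
                    ref_fwd=int(r.ref_fwd), ref_rev=int(r.ref_rev),
                    strand_known=True, **kwargs))
            else:
                ta = int(r.tumor_alt)
                records.append(CallerVariant(
                    alt_fwd=ta - ta // 2, alt_rev=ta // 2,
                    strand_known=False, **kwargs))
    return out


_VCF_FORMATS = {
    "mutect2": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
         '##FORMAT=<ID=F1R2,Number=R,Type=Integer,Description="F1R2 pair counts">',
         '##FORMAT=<ID=F2R1,Number=R,Type=Integer,Description="F2R1 pair counts">',
         '##FORMAT=<ID=SB,Number=4,Type=Integer,Description="Per-sample strand table">'],
        "GT:AD:DP:F1R2:F2R1:SB"),
    "strelka2": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
         '##FORMAT=<ID=AU,Number=2,Type=Integer,Description="A tier1,tier2 counts">',
         '##FORMAT=<ID=CU,Number=2,Type=Integer,Description="C tier1,tier2 counts">',
         '##FORMAT=<ID=GU,Number=2,Type=Integer,Description="G tier1,tier2 counts">',
         '##FORMAT=<ID=TU,Number=2,Type=Integer,Description="T tier1,tier2 counts">',
         '##FORMAT=<ID=TAR,Number=2,Type=Integer,Description="Ref tier counts">',
         '##FORMAT=<ID=TIR,Number=2,Type=Integer,Description="Indel tier counts">'],
        None),  # per-record FORMAT
    "vardict": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Allele frequency">',
         '##FORMAT=<ID=RD,Number=2,Type=Integer,Description="Ref fwd,rev">',
         '##FORMAT=<ID=ALD,Number=2,Type=Integer,Description="Alt fwd,rev">'],
        "GT:DP:AD:AF:RD:ALD"),
    "muse": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'],
        "GT:AD:DP"),
    "somaticsniper": (
        ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
         '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
         '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">'],
        "GT:AD:DP"),
}


def _vcf_sample_fields(caller: str, r: CallerVariant) -> tuple:
    """(FORMAT string, tumor column, normal column) for one record."""
    t_ref = r.tumor_depth - r.tumor_alt
    n_ref = r.normal_depth - r.normal_alt
    if caller == "mutect2":
        f1, f2 = r.fr_orientation if r.fr_orientation else (0, 0)
        rf = r.ref_fwd if r.ref_fwd is not None else t_ref - t_ref // 2
        rr = r.ref_rev if r.ref_rev is not None else t_ref // 2
        t = (f"0/1:{t_ref},{r.tumor_alt}:{r.tumor_depth}:"
             f"{t_ref - t_ref // 2},{f1}:{t_ref // 2},{f2}:"
             f"{rf},{rr},{r.alt_fwd},{r.alt_rev}")
        nn = (f"0/0:{n_ref},{r.normal_alt}:{r.normal_depth}:"
              f"{n_ref - n_ref // 2},0:{n_ref // 2},{r.normal_alt}:"
              f"{n_ref - n_ref // 2},{n_ref // 2},{r.normal_alt},0")
        return "GT:AD:DP:F1R2:F2R1:SB", t, nn
    if caller == "strelka2":
        if r.is_snv:
            counts_t = {b: 0 for b in "ACGT"}
            counts_t[r.ref] = r.tumor_depth - r.tumor_alt
            counts_t[r.alt] = r.tumor_alt
            counts_n = {b: 0 for b in "ACGT"}
            counts_n[r.ref] = n_ref
            counts_n[r.alt] = r.normal_alt
            fmt = "GT:DP:AU:CU:GU:TU"
            t = "0/1:%d:%s" % (r.tumor_depth, ":".join(
                f"{counts_t[b]},{counts_t[b]}" for b in "ACGT"))
            nn = "0/0:%d:%s" % (r.normal_depth, ":".join(
                f"{counts_n[b]},{counts_n[b]}" for b in "ACGT"))
            return fmt, t, nn
        fmt = "GT:DP:TAR:TIR"
        t = f"0/1:{r.tumor_depth}:{t_ref},{t_ref}:{r.tumor_alt},{r.tumor_alt}"
        nn = f"0/0:{r.normal_depth}:{n_ref},{n_ref}:{r.normal_alt},{r.normal_alt}"
        return fmt, t, nn
    if caller == "vardict":
        rf = r.ref_fwd if r.ref_fwd is not None else t_ref - t_ref // 2
        rr = r.ref_rev if r.ref_rev is not None else t_ref // 2
        t = (f"0/1:{r.tumor_depth}:{t_ref},{r.tumor_alt}:{r.vaf:.4f}:"
             f"{rf},{rr}:{r.alt_fwd},{r.alt_rev}")
        nn = (f"0/0:{r.normal_depth}:{n_ref},{r.normal_alt}:"
              f"{(r.normal_alt / r.normal_depth) if r.normal_depth else 0:.4f}:"
              f"{n_ref - n_ref // 2},{n_ref // 2}:{r.normal_alt},0")
        return "GT:DP:AD:AF:RD:ALD", t, nn
    t = f"0/1:{t_ref},{r.tumor_alt}:{r.tumor_depth}"
    nn = f"0/0:{n_ref},{r.normal_alt}:{r.normal_depth}"
    return "GT:AD:DP", t, nn


def emit_caller_vcfs(cohort: SyntheticCohort, outdir) -> list:
    """Write one VCF per patient per caller; returns the file paths.

    Files are named ``<patient>.<caller>.vcf`` with TUMOR/NORMAL sample
    columns, records sorted by position.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_order = {c: i for i, c in enumerate(_CHROMS)}
    records = caller_records(cohort)
    contigs = [f"##contig=<ID={c},length={len(cohort.reference[c])}>"
               for c in _CHROMS if c in cohort.reference]
    paths = []
    patients = [c.patient_id for c in cohort.clinical]
    for caller in CALLERS:
        per_patient: dict = {p: [] for p in patients}
        for r in records[caller]:
            per_patient.setdefault(r.sample_id, []).append(r)
        header_extra, _ = _VCF_FORMATS[caller]
        for pid in patients:
            path = outdir / f"{pid}.{caller}.vcf"
            lines = ["##fileformat=VCFv4.2", f"##source={caller}"]
            lines += contigs + header_extra
            lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                         "\tTUMOR\tNORMAL")
            recs = sorted(per_patient.get(pid, []),
                          key=lambda r: (chrom_order.get(r.chrom, 99), r.pos))
            for r in recs:
                fmt, t, nn = _vcf_sample_fields(caller, r)
                lines.append(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t"
                             f"PASS\t.\t{fmt}\t{t}\t{nn}")
            path.write_text("\n".join(lines) + "\n")
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Pileup emission
# ---------------------------------------------------------------------------

def build_pileups(cohort: SyntheticCohort, keys: Iterable[str] | None = None) -> dict:
    """Tumor/normal :class:`PileupWindow` pairs for a subset of variants.

    By default: every IGV-evaluable planted record (clean somatic SNVs and
    the pileup-level artifact classes), capped at ``max_pileup_sites`` with
    artifacts kept preferentially so each class stays well represented.
    Clean reads carry window mismatches at the sequencing-error rate; the
    ``clustered`` artifact class plants ≥1 extra mismatch on every alt read;
    occasional stray third-allele singleton reads exercise the biallelic
    tolerance rule.
    """
    cfg = cohort.config
    v = cohort.manifest.variants
    if v.empty:
        return {}
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed).spawn(8)[7])
    if keys is None:
        evaluable = v[v["igv_expected"] != ""]
        art = evaluable[evaluable["origin"] != "somatic"]
        som = evaluable[evaluable["origin"] == "somatic"]
        n_som = max(cfg.max_pileup_sites - len(art), 0)
        if len(som) > n_som:
            pick = rng.choice(len(som), size=n_som, replace=False)
            som = som.iloc[np.sort(pick)]
        subset = pd.concat([art, som])
    else:
        keyset = set(keys)
        subset = v[v["key"].isin(keyset)]

    out = {}
    for r in subset.itertuples():
        clustered = r.origin == "clustered"
        reads_t = []
        for i in range(int(r.tumor_alt)):
            strand = "fwd" if i < r.alt_fwd else "rev"
            mm = (1 + rng.poisson(0.5)) if clustered \
                else int(rng.random() < cfg.window_error_rate)
            reads_t.append(PileupRead(f"t{i}", strand, r.alt[0], mm))
        n_ref = int(r.tumor_depth - r.tumor_alt)
        for i in range(n_ref):
            strand = "fwd" if i < r.ref_fwd else "rev"
            mm = int(rng.random() < cfg.window_error_rate)
            reads_t.append(PileupRead(f"t{int(r.tumor_alt) + i}", strand,
                                      r.ref[0], mm))
        if rng.random() < cfg.stray_allele_rate:
            third = "ACGT"["ACGT".index(r.ref[0]) - 1]
            if third != r.alt[0]:
                reads_t.append(PileupRead("stray0", "fwd", third, 0))
        reads_n = []
        for i in range(int(r.normal_depth)):
            base = r.alt[0] if i < r.normal_alt else r.ref[0]
            strand = "fwd" if i % 2 == 0 else "rev"
            mm = int(rng.random() < cfg.window_error_rate)
            reads_n.append(PileupRead(f"n{i}", strand, base, mm))
        out[r.key] = {
            "tumor": PileupWindow("tumor", r.chrom, int(r.pos), reads_t),
            "normal": PileupWindow("normal", r.chrom, int(r.pos), reads_n),
        }
    return out


def emit_pileups(cohort: SyntheticCohort, path,
                 keys: Iterable[str] | None = None) -> dict:
    """Build pileups and write them as the flat interchange TSV."""
    from .read_validation import write_pileups

    pileups = build_pileups(cohort, keys)
    write_pileups(pileups, path)
    return pileups


# ---------------------------------------------------------------------------
# Whole-cohort file emission and pipeline evaluation
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir) -> dict:
    """Write every study file (VCFs, pileups, clinical, BED, gene models,
    reference FASTA, AF/PoN tables, truth manifest) under ``outdir``."""
    from .consequence_annotation import write_gene_models
    from .io_formats import write_clinical_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"vcfs": emit_caller_vcfs(cohort, outdir / "vcf")}

    p = outdir / "pileups.tsv"
    emit_pileups(cohort, p)
    paths["pileups"] = p

    p = outdir / "clinical.tsv"
    write_clinical_table(cohort.clinical, p)
    paths["clinical"] = p

    p = outdir / "targets.bed"
    with open(p, "w") as fh:
        for chrom, s, e in cohort.exon_bed:
            fh.write(f"{chrom}\t{s}\t{e}\n")
    paths["bed"] = p

    p = outdir / "genes.tsv"
    write_gene_models(cohort.gene_models, p)
    paths["genes"] = p

    p = outdir / "reference.fa"
    with open(p, "w") as fh:
        for chrom, seq in cohort.reference.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    paths["reference"] = p

    p = outdir / "population_af.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for key in sorted(cohort.population_af):
            chrom, pos, ref, alt = key.rsplit("-", 3)
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{cohort.population_af[key]:.6f}\n")
    paths["population_af"] = p

    p = outdir / "pon_sites.tsv"
    with open(p, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for key in sorted(cohort.pon_sites):
            chrom, pos, ref, alt = key.rsplit("-", 3)
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    paths["pon"] = p

    p = outdir / "truth_manifest.tsv"
    cohort.manifest.variants.to_csv(p, sep="\t", index=False)
    paths["manifest"] = p
    return paths


@dataclass
class PipelineEvaluation:
    sensitivity: float
    fdr: float
    n_true_somatic: int
    n_kept: int
    n_kept_true: int
    per_class_removal: dict      # origin -> fraction removed overall
    per_class_intended: dict     # origin -> fraction removed by intended filter
    igv_accuracy: float | None = None


def evaluate_pipeline(cohort: SyntheticCohort, kept: Sequence[MergedVariant],
                      trace=None, verdicts: Mapping[str, object] | None = None
                      ) -> PipelineEvaluation:
    """Score a pipeline run against the truth manifest.

    Sensitivity = kept true somatics / true somatics; FDR = kept
    non-somatics / kept.  With a filter trace, per-origin removal is
    attributed to the intended filter; with IGV verdicts, classifier
    accuracy against the planted expected labels is added.
    """
    v = cohort.manifest.variants
    truth_samples = set(v["sample_id"]) if not v.empty else set()
    kept_samples = {k.sample_id for k in kept}
    if kept_samples - truth_samples:
        raise ValueError("kept variants contain samples absent from the manifest")

    somatic_keys = set(v.loc[v["origin"] == "somatic", "key"])
    kept_keys = {k.key for k in kept}
    n_true = len(somatic_keys)
    n_kept = len(kept_keys)
    n_kept_true = len(kept_keys & somatic_keys)
    sensitivity = n_kept_true / n_true if n_true else 1.0
    fdr = (n_kept - n_kept_true) / n_kept if n_kept else 0.0

    per_removal, per_intended = {}, {}
    for origin, grp in v.groupby("origin"):
        keys = grp["key"]
        removed = ~keys.isin(kept_keys)
        per_removal[origin] = float(removed.mean())
        if trace is not None and origin != "somatic":
            intended = INTENDED_FILTER.get(origin)
            hit = [intended in trace.fired_filters(k) for k in keys]
            per_intended[origin] = float(np.mean(hit)) if hit else float("nan")

    igv_acc = None
    if verdicts is not None:
        exp = v[v["igv_expected"] != ""]
        scored = [(verdicts[k].verdict == e)
                  for k, e in zip(exp["key"], exp["igv_expected"])
                  if k in verdicts and verdicts[k].verdict != "untestable"]
        igv_acc = float(np.mean(scored)) if scored else None

    return PipelineEvaluation(
        sensitivity=sensitivity, fdr=fdr, n_true_somatic=n_true,
        n_kept=n_kept, n_kept_true=n_kept_true,
        per_class_removal=per_removal, per_class_intended=per_intended,
        igv_accuracy=igv_acc)
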