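"""Synthetic cohort generator for end-to-end pipeline validation.

Emulates, on a toy two-chromosome exome (~170 kb of flanked target), the
statistical structure the validation design assumes:

* a truth catalogue of SNVs and short indels uniform over the target
  (a stand-in for a platinum-style reference call set);
* per-sample, per-material call sets: blood nearly equal to truth, FFPE
  with higher planted false-positive/false-negative rates, both spatially
  enriched inside designated problematic regions;
* three caller call sets per material, each dropping calls at a private
  miss rate and adding a small private false-positive set, so a 2-of-3
  consensus recovers the material set with fewer private errors than any
  single caller;
* per-base coverage from a negative binomial whose mean decays and whose
  overdispersion grows with the sample's qPCR amplification score, placing
  the expected %>=20X at 90% exactly at qPCR = 10;
* a sample QC table drawn from the reported ranges (qPCR 0.8-14.8, DIN
  1.2-6.1, fragment length 266-3296 bp), negatively coupled so the
  qPCR-success correlation is recoverable.

Error placement is sequence-context free (no C>T deamination bias is
planted by default); every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import (
    CallSet,
    CoverageTrack,
    GenomicInterval,
    RegionSet,
    SampleQC,
    VariantAnnotations,
    VariantCall,
    VariantKey,
    normalize_variant,
)
from .regions import flank_target, intersect, subtract
from .triage import Panel

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedCohort",
    "simulate_truth",
    "simulate_callsets",
    "simulate_coverage",
    "simulate_qc_table",
    "simulate_cohort",
    "write_simdir",
    "load_simdir",
]

_NT = np.array(list("ACGT"))
# transitions partner for ti/tv draws
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "C": ("A", "G"),
    "G": ("C", "T"),
    "T": ("A", "G"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    FFPE error rates default to the matched-pair calibration of the real
    cohort (fp 784/33,330, fn 1,023/33,569); blood rates are an order of
    magnitude cleaner. Problematic regions cover ~5% of the target with a
    x100 error-rate multiplier, concentrating most discordance in a small
    excludable fraction of the exome.
    """

    seed: int = 0
    genome: tuple = (("chr1", 140_000), ("chr2", 140_000))
    n_exons: int = 1000
    exon_length: int = 150
    flank_bp: int = 10
    exons_per_gene: int = 5
    n_truth_variants: int = 10_000
    titv_ratio: float = 2.8
    indel_fraction: float = 0.10
    max_indel_len: int = 3
    # planted per-material error rates (vs the truth catalogue)
    fp_rate: dict = field(
        default_factory=lambda: {"blood": 0.005, "ffpe": 784 / 33_330}
    )
    fn_rate: dict = field(
        default_factory=lambda: {"blood": 0.001, "ffpe": 1_023 / 33_569}
    )
    n_problematic_regions: int = 50
    problematic_enrichment: float = 100.0
    caller_labels: tuple = ("gatk", "samtools", "freebayes")
    caller_miss_rates: dict = field(
        default_factory=lambda: {"gatk": 0.010, "samtools": 0.015, "freebayes": 0.020}
    )
    caller_private_fp_rate: float = 0.005
    # cohort composition: first n_matched_pairs FFPE cases have a blood mate
    n_samples: int = 35
    n_matched_pairs: int = 13
    # coverage model: NB mean = depth_scale * exp(-depth_decay * qpcr),
    # size = max(size_min, size_base - size_slope * qpcr); calibrated so the
    # expected %>=20X crosses 90% at qPCR 10 (the predicted-failure rule)
    depth_scale: float = 220.0
    depth_decay: float = 0.18
    size_base: float = 20.0
    size_slope: float = 1.2
    size_min: float = 2.0
    # per-sample library efficiency: mean-one lognormal multiplier on the
    # expected depth, reproducing the scatter real cohorts show around the
    # qPCR trend
    depth_noise_sd: float = 0.4
    blood_mean_depth: float = 100.0
    blood_size: float = 25.0
    # capture-poor regions: probe inefficiency shared by all samples and
    # materials, the substrate joint low-coverage detection looks for
    n_capture_poor_regions: int = 5
    capture_poor_multiplier: float = 0.02
    # QC-table ranges (the cohort's reported ranges)
    qpcr_range: tuple = (0.8, 14.8)
    din_range: tuple = (1.2, 6.1)
    fragment_range: tuple = (266.0, 3296.0)
    # clinical findings planted in the FFPE cohort (strict/inclusive yield
    # structure of the study: pathogenic hits and phenotype-relevant
    # likely-pathogenic/VUS findings)
    p_case_pathogenic: float = 0.125
    p_case_relevant_vus: float = 0.167
    # exclusion stratifications without special enrichment (fractions of target)
    background_exclusion_fracs: tuple = (
        ("tandem_repeats_homopolymers", 0.02),
        ("low_mappability", 0.02),
        ("bad_promoters", 0.005),
    )
    confident_frac: float = 0.98

    def __post_init__(self) -> None:
        for d in (self.fp_rate, self.fn_rate, self.caller_miss_rates):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rates must lie in [0,1], got {v}")
        if self.problematic_enrichment < 1.0:
            raise ValueError("problematic_enrichment must be >= 1")


@dataclass
class SimulatedTruth:
    """Reference, region structure and truth catalogue of the toy exome."""

    reference: dict  # chrom -> str
    exons: RegionSet
    target: RegionSet
    confident: RegionSet
    exclusions: dict  # label -> RegionSet
    problematic: RegionSet
    capture_poor: RegionSet  # systematically under-captured target regions
    gene_map: dict  # gene -> RegionSet
    truth: CallSet

    def reference_lookup(self, chrom: str, start: int, end: int) -> str:
        return self.reference[chrom][start:end]


@dataclass
class SimulatedCohort:
    cfg: SimulationConfig
    truth: SimulatedTruth
    qc: list  # SampleQC per FFPE case (n_samples)
    coverage: dict  # (sample_id, material) -> CoverageTrack
    material_sets: dict  # (sample_id, material) -> CallSet (pre-caller ideal set)
    caller_sets: dict  # (sample_id, material) -> {caller -> CallSet}
    planted_findings: dict  # sample_id -> assertion planted ("pathogenic"|...)|None
    panels: dict  # name -> Panel (from the simulated gene map)

    @property
    def matched_sample_ids(self) -> list:
        return [q.sample_id for q in self.qc[: self.cfg.n_matched_pairs]]

    @property
    def sample_ids(self) -> list:
        return [q.sample_id for q in self.qc]


# ---------------------------------------------------------------------------
# Truth catalogue
# ---------------------------------------------------------------------------

def _target_bases(target: RegionSet) -> list:
    return [(iv.chrom, pos) for iv in target for pos in range(iv.start, iv.end)]


def simulate_truth(cfg: SimulationConfig, rng: Optional[np.random.Generator] = None) -> SimulatedTruth:
    """Generate the toy exome: reference, targets, stratifications, truth variants."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    chroms = dict(cfg.genome)
    reference = {
        chrom: "".join(rng.choice(_NT, size=length)) for chrom, length in cfg.genome
    }

    # evenly spaced exons, split between chromosomes
    per_chrom = cfg.n_exons // len(chroms)
    exon_ivs = []
    for chrom, length in cfg.genome:
        spacing = length // per_chrom
        if spacing <= cfg.exon_length + 2 * cfg.flank_bp:
            raise ValueError("genome too small for the requested exon layout")
        for i in range(per_chrom):
            start = i * spacing + cfg.flank_bp + 1
            exon_ivs.append(GenomicInterval(chrom, start, start + cfg.exon_length))
    exons = RegionSet("exons", exon_ivs)
    target = flank_target(exons, cfg.flank_bp, name="target")

    # genes: consecutive runs of exons
    gene_map = {}
    flanked = [
        GenomicInterval(iv.chrom, iv.start - cfg.flank_bp, iv.end + cfg.flank_bp)
        for iv in exon_ivs
    ]
    n_genes = math.ceil(len(flanked) / cfg.exons_per_gene)
    width = len(str(n_genes))
    for g in range(n_genes):
        ivs = flanked[g * cfg.exons_per_gene : (g + 1) * cfg.exons_per_gene]
        gene_map[f"G{g + 1:0{width}d}"] = RegionSet(f"G{g + 1:0{width}d}", ivs)

    # problematic regions: whole flanked exons, drawn without replacement
    prob_idx = rng.choice(len(flanked), size=cfg.n_problematic_regions, replace=False)
    problematic = RegionSet("problematic", [flanked[i] for i in sorted(prob_idx)])

    # capture-poor regions: may overlap any genomic context
    poor_idx = rng.choice(len(flanked), size=cfg.n_capture_poor_regions, replace=False)
    capture_poor = RegionSet("capture_poor", [flanked[i] for i in sorted(poor_idx)])

    # background exclusion stratifications: random exon subsets, no enrichment
    exclusions = {}
    remaining = [i for i in range(len(flanked)) if i not in set(prob_idx.tolist())]
    for label, frac in cfg.background_exclusion_fracs:
        k = max(1, int(round(frac * len(flanked))))
        take = rng.choice(remaining, size=min(k, len(remaining)), replace=False)
        exclusions[label] = RegionSet(label, [flanked[i] for i in sorted(take)])
    exclusions["internal"] = problematic

    # confident region: target minus a small random slice
    n_drop = max(1, int(round((1.0 - cfg.confident_frac) * len(flanked))))
    drop = rng.choice(remaining, size=min(n_drop, len(remaining)), replace=False)
    confident = subtract(
        target, RegionSet("nonconfident", [flanked[i] for i in sorted(drop)]), name="confident"
    )

    truth = CallSet("platinum", "truth", "catalogue")
    if cfg.n_truth_variants > target.total_bases:
        raise ValueError("more truth variants requested than target bases")
    bases = _target_bases(target)
    picks = rng.choice(len(bases), size=cfg.n_truth_variants, replace=False)
    lookup = lambda c, s, e: reference[c][s:e]
    p_ti = cfg.titv_ratio / (1.0 + cfg.titv_ratio)
    for i in sorted(picks):
        chrom, pos0 = bases[i]
        key = _draw_variant(reference, chrom, pos0, cfg, rng, p_ti)
        if key is None:
            continue
        key = normalize_variant(key, lookup)
        if key in truth.calls or not target.contains_pos(key.chrom, key.anchor0):
            continue  # collision or left-shifted off target: skip
        truth.add(VariantCall(key=key, genotype=None, callers=frozenset(["catalogue"])))
    return SimulatedTruth(
        reference=reference,
        exons=exons,
        target=target,
        confident=confident,
        exclusions=exclusions,
        problematic=problematic,
        capture_poor=capture_poor,
        gene_map=gene_map,
        truth=truth,
    )


def _draw_variant(
    reference: dict,
    chrom: str,
    pos0: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    p_ti: float,
) -> Optional[VariantKey]:
    seq = reference[chrom]
    ref_base = seq[pos0]
    if rng.random() >= cfg.indel_fraction:
        if rng.random() < p_ti:
            alt = _TRANSITION[ref_base]
        else:
            alt = _TRANSVERSIONS[ref_base][rng.integers(2)]
        return VariantKey(chrom, pos0 + 1, ref_base, alt)
    length = int(rng.integers(1, cfg.max_indel_len + 1))
    if rng.random() < 0.5:  # deletion: anchor + deleted bases
        if pos0 + 1 + length > len(seq):
            return None
        return VariantKey(chrom, pos0 + 1, seq[pos0 : pos0 + 1 + length], ref_base)
    ins = "".join(rng.choice(_NT, size=length))
    return VariantKey(chrom, pos0 + 1, ref_base, ref_base + ins)


# ---------------------------------------------------------------------------
# Call sets
# ---------------------------------------------------------------------------

def _base_weights(truth: SimulatedTruth, enrichment: float) -> tuple:
    """(bases, weights) over the target, enriched inside problematic regions."""
    bases = _target_bases(truth.target)
    weights = np.array(
        [
            enrichment if truth.problematic.contains_pos(c, p) else 1.0
            for c, p in bases
        ]
    )
    return bases, weights


def _material_set(
    truth: SimulatedTruth,
    sample_id: str,
    material: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    bases: list,
    weights: np.ndarray,
) -> CallSet:
    """Truth minus FN draws plus novel FP draws, spatially enriched."""
    fn_rate = cfg.fn_rate[material]
    fp_rate = cfg.fp_rate[material]
    E = cfg.problematic_enrichment
    out = CallSet(sample_id, material, "material")

    # false negatives: per-variant drop probability, enriched inside
    # problematic regions, scaled to the overall planted rate
    keys = sorted(truth.truth.calls)
    w = np.array(
        [
            E if truth.problematic.contains_pos(k.chrom, k.anchor0) else 1.0
            for k in keys
        ]
    )
    p_drop = np.minimum(1.0, fn_rate * w / w.mean())
    drops = rng.random(len(keys)) < p_drop
    for key, dropped in zip(keys, drops):
        if not dropped:
            out.add(
                VariantCall(
                    key=key,
                    genotype=(key.ref, key.alt),
                    quality=float(np.round(rng.uniform(30, 90), 2)),
                    callers=frozenset(["material"]),
                )
            )

    # false positives: novel SNVs at weighted positions off the truth set
    n_fp = rng.binomial(len(keys), fp_rate)
    truth_pos = {(k.chrom, k.anchor0) for k in keys}
    probs = weights / weights.sum()
    lookup = truth.reference_lookup
    placed = 0
    pool = iter(())
    while placed < n_fp:
        i = next(pool, None)
        if i is None:
            pool = iter(rng.choice(len(bases), size=max(64, 2 * n_fp), p=probs))
            continue
        chrom, pos0 = bases[int(i)]
        if (chrom, pos0) in truth_pos:
            continue
        ref_base = truth.reference[chrom][pos0]
        alts = [b for b in "ACGT" if b != ref_base]
        key = VariantKey(chrom, pos0 + 1, ref_base, alts[rng.integers(3)])
        key = normalize_variant(key, lookup)
        if key in out.calls or key in truth.truth.calls:
            continue
        out.add(
            VariantCall(
                key=key,
                genotype=(key.ref, key.alt),
                quality=float(np.round(rng.uniform(20, 60), 2)),
                callers=frozenset(["material"]),
            )
        )
        truth_pos.add((chrom, pos0))
        placed += 1
    return out


def _caller_sets(
    material_set: CallSet,
    truth: SimulatedTruth,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    bases: list,
) -> dict:
    """Per-caller views: drop at the caller miss rate, add private FPs."""
    out = {}
    lookup = truth.reference_lookup
    for caller in cfg.caller_labels:
        miss = cfg.caller_miss_rates[caller]
        cs = CallSet(material_set.sample_id, material_set.material, caller)
        for key, call in material_set.calls.items():
            if rng.random() >= miss:
                cs.add(
                    VariantCall(
                        key=key,
                        genotype=call.genotype,
                        quality=call.quality,
                        callers=frozenset([caller]),
                    )
                )
        n_private = rng.binomial(len(material_set), cfg.caller_private_fp_rate)
        added = 0
        while added < n_private:
            chrom, pos0 = bases[rng.integers(len(bases))]
            ref_base = truth.reference[chrom][pos0]
            alts = [b for b in "ACGT" if b != ref_base]
            key = VariantKey(chrom, pos0 + 1, ref_base, alts[rng.integers(3)])
            key = normalize_variant(key, lookup)
            if key in cs.calls or key in material_set.calls:
                continue
            cs.add(
                VariantCall(
                    key=key,
                    genotype=(key.ref, key.alt),
                    quality=float(np.round(rng.uniform(10, 40), 2)),
                    callers=frozenset([caller]),
                )
            )
            added += 1
        out[caller] = cs
    return out


def simulate_callsets(
    truth: SimulatedTruth,
    cfg: SimulationConfig,
    sample_id: str,
    materials: Sequence[str] = ("ffpe",),
    rng: Optional[np.random.Generator] = None,
) -> tuple:
    """(material_sets, caller_sets) for one sample.

    Returns ``({material: CallSet}, {material: {caller: CallSet}})``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    bases, weights = _base_weights(truth, cfg.problematic_enrichment)
    material_sets, caller_sets = {}, {}
    for material in materials:
        ms = _material_set(truth, sample_id, material, cfg, rng, bases, weights)
        material_sets[material] = ms
        caller_sets[material] = _caller_sets(ms, truth, cfg, rng, bases)
    return material_sets, caller_sets


# ---------------------------------------------------------------------------
# Coverage and QC
# ---------------------------------------------------------------------------

def depth_model(cfg: SimulationConfig, qpcr: float) -> tuple:
    """(mean, size) of the negative-binomial per-base depth for one sample."""
    mean = cfg.depth_scale * math.exp(-cfg.depth_decay * qpcr)
    size = max(cfg.size_min, cfg.size_base - cfg.size_slope * qpcr)
    return mean, size


def simulate_coverage(
    cfg: SimulationConfig,
    qc: SampleQC,
    target: RegionSet,
    rng: Optional[np.random.Generator] = None,
    material: str = "ffpe",
    capture_poor: Optional[RegionSet] = None,
) -> CoverageTrack:
    """Negative-binomial per-base depth.

    FFPE depth decays with the qPCR score; every sample additionally draws
    a mean-one lognormal library-efficiency multiplier. Bases inside
    ``capture_poor`` regions have their expected depth scaled down for all
    samples and materials, mimicking probe inefficiency.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if material == "blood":
        mean, size = cfg.blood_mean_depth, cfg.blood_size
    else:
        mean, size = depth_model(cfg, qc.qpcr_value)
    sd = cfg.depth_noise_sd
    mean = mean * float(rng.lognormal(-0.5 * sd * sd, sd))
    means = np.full(target.total_bases, mean)
    if capture_poor is not None and len(capture_poor):
        probe = CoverageTrack(qc.sample_id, target, np.zeros(target.total_bases, dtype=np.int64))
        means[probe.region_mask(capture_poor)] *= cfg.capture_poor_multiplier
    p = size / (size + means)
    depths = rng.negative_binomial(size, p, size=target.total_bases)
    return CoverageTrack(qc.sample_id, target, depths)


def simulate_qc_table(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list:
    """Draw the FFPE cohort's pre-library QC table.

    qPCR is uniform over the reported range; DIN and fragment length are
    negatively coupled to qPCR (degraded samples amplify poorly), and the
    mapped-read yield decays with qPCR.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    out = []
    lo, hi = cfg.qpcr_range
    for i in range(cfg.n_samples):
        qpcr = float(rng.uniform(lo, hi))
        din_lo, din_hi = cfg.din_range
        din = float(
            np.clip(
                din_hi - (din_hi - din_lo) * (qpcr - lo) / (hi - lo) + rng.normal(0, 0.6),
                din_lo,
                din_hi,
            )
        )
        fr_lo, fr_hi = cfg.fragment_range
        frag = float(
            np.clip(
                fr_hi - (fr_hi - fr_lo) * (qpcr - lo) / (hi - lo) + rng.normal(0, 350),
                fr_lo,
                fr_hi,
            )
        )
        reads = int(8e7 * math.exp(-0.15 * qpcr) * rng.lognormal(0, 0.2))
        out.append(
            SampleQC(
                sample_id=f"S{i + 1:02d}",
                qpcr_value=round(qpcr, 2),
                din=round(din, 2),
                fragment_length_bp=round(frag, 0),
                mapped_reads=reads,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Clinical annotations
# ---------------------------------------------------------------------------

def annotate_callset(
    callset: CallSet,
    gene_map: Mapping[str, RegionSet],
    rng: np.random.Generator,
    planted_assertion: Optional[str] = None,
    planted_genes: Optional[Sequence[str]] = None,
) -> Optional[VariantKey]:
    """Attach gene / population-AF / pathogenicity annotations in place.

    AF follows a mixture (most variants common, a minority rare); at most
    one variant inside ``planted_genes`` receives ``planted_assertion``
    with a rare AF, standing in for the case's clinically relevant finding.
    Returns the planted key, if any.
    """
    import bisect

    by_chrom: dict = {}
    for gene, region in gene_map.items():
        for iv in region:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gene))
    for ivs in by_chrom.values():
        ivs.sort()

    def gene_of(key: VariantKey) -> Optional[str]:
        ivs = by_chrom.get(key.chrom)
        if not ivs:
            return None
        i = bisect.bisect_right(ivs, (key.anchor0, float("inf"), "")) - 1
        if i >= 0 and key.anchor0 < ivs[i][1]:
            return ivs[i][2]
        return None

    planted_key = None
    candidates = []
    for call in callset.sorted_calls():
        gene = gene_of(call.key)
        u = rng.random()
        if u < 0.70:
            af = float(rng.uniform(0.05, 0.5))
        elif u < 0.85:
            af = float(rng.uniform(0.01, 0.05))
        else:
            af = float(rng.uniform(0.0, 0.01))
        call.annotations = VariantAnnotations(gene=gene, population_af=af)
        if planted_assertion and planted_genes and gene in set(planted_genes):
            candidates.append(call)
    if planted_assertion and candidates:
        call = candidates[int(rng.integers(len(candidates)))]
        call.annotations = VariantAnnotations(
            gene=call.annotations.gene,
            population_af=float(rng.uniform(0.0, 0.005)),
            pathogenicity=planted_assertion,
        )
        planted_key = call.key
    return planted_key


def panels_from_gene_map(gene_map: Mapping[str, RegionSet]) -> dict:
    """Panels over the simulated gene namespace (CDGP 84 c SDGP 166; aorta 27)."""
    genes = sorted(gene_map)
    if len(genes) < 193:
        raise ValueError("gene map too small to carve the default panels")
    return {
        "cdgp": Panel("cdgp", frozenset(genes[:84])),
        "sdgp": Panel("sdgp", frozenset(genes[:166])),
        "aorta": Panel("aorta", frozenset(genes[166:193])),
    }


# ---------------------------------------------------------------------------
# Whole cohort
# ---------------------------------------------------------------------------

def simulate_cohort(cfg: SimulationConfig) -> SimulatedCohort:
    """Generate everything the pipeline consumes, deterministically from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_truth(cfg, rng)
    qc = simulate_qc_table(cfg, rng)
    panels = panels_from_gene_map(truth.gene_map)

    coverage, material_sets, caller_sets, planted = {}, {}, {}, {}
    bases, weights = _base_weights(truth, cfg.problematic_enrichment)
    for i, sample_qc in enumerate(qc):
        sid = sample_qc.sample_id
        mats = ("ffpe", "blood") if i < cfg.n_matched_pairs else ("ffpe",)
        for material in mats:
            ms = _material_set(truth, sid, material, cfg, rng, bases, weights)
            material_sets[(sid, material)] = ms
            caller_sets[(sid, material)] = _caller_sets(ms, truth, cfg, rng, bases)
            coverage[(sid, material)] = simulate_coverage(
                cfg, sample_qc, truth.target, rng,
                material=material, capture_poor=truth.capture_poor,
            )
        # clinical finding planted in the FFPE material set and all callers
        u = rng.random()
        if u < cfg.p_case_pathogenic:
            planted[sid] = "pathogenic"
        elif u < cfg.p_case_pathogenic + cfg.p_case_relevant_vus:
            planted[sid] = "vus"
        else:
            planted[sid] = None
    return SimulatedCohort(
        cfg=cfg,
        truth=truth,
        qc=qc,
        coverage=coverage,
        material_sets=material_sets,
        caller_sets=caller_sets,
        planted_findings=planted,
        panels=panels,
    )


# ---------------------------------------------------------------------------
# On-disk form
# ---------------------------------------------------------------------------

def write_simdir(cohort: SimulatedCohort, outdir) -> None:
    """Write the cohort in the plain-text formats the other modules read."""
    from . import io as fio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = dict(cohort.cfg.genome)
    fio.write_bed(cohort.truth.exons, outdir / "exons.bed")
    fio.write_bed(cohort.truth.target, outdir / "target.bed")
    fio.write_bed(cohort.truth.confident, outdir / "confident.bed")
    fio.write_bed(cohort.truth.problematic, outdir / "problematic.bed")
    fio.write_bed(cohort.truth.capture_poor, outdir / "capture_poor.bed")
    for label, rs in cohort.truth.exclusions.items():
        fio.write_bed(rs, outdir / f"exclusion.{label}.bed")
    fio.write_vcf(cohort.truth.truth, outdir / "truth.vcf", contigs)
    fio.write_qc_table(cohort.qc, outdir / "qc.tsv")
    with open(outdir / "genes.bed", "w") as fh:
        for gene in sorted(cohort.truth.gene_map):
            for iv in cohort.truth.gene_map[gene]:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\n")
    for (sid, material), track in cohort.coverage.items():
        fio.write_coverage(track, outdir / f"{sid}.{material}.cov.bedgraph")
    for (sid, material), callers in cohort.caller_sets.items():
        for caller, cs in callers.items():
            fio.write_vcf(cs, outdir / f"{sid}.{material}.{caller}.vcf", contigs)


def load_simdir(indir) -> dict:
    """Read back the parts of a simulation directory needed by the pipeline."""
    from . import io as fio

    indir = Path(indir)
    target = fio.read_bed(indir / "target.bed", "target")
    out = {
        "target": target,
        "confident": fio.read_bed(indir / "confident.bed", "confident"),
        "problematic": fio.read_bed(indir / "problematic.bed", "problematic"),
        "truth": fio.read_vcf(indir / "truth.vcf", "platinum", "truth", "catalogue"),
        "qc": fio.read_qc_table(indir / "qc.tsv"),
        "exclusions": {},
        "coverage": {},
        "caller_vcfs": {},
    }
    for path in sorted(indir.glob("exclusion.*.bed")):
        label = path.name.split(".", 1)[1].rsplit(".", 1)[0]
        out["exclusions"][label] = fio.read_bed(path, label)
    for path in sorted(indir.glob("*.cov.bedgraph")):
        sid, material = path.name.split(".")[:2]
        out["coverage"][(sid, material)] = fio.read_coverage(path, target, sid)
    for path in sorted(indir.glob("*.vcf")):
        parts = path.name.split(".")
        if len(parts) == 4:  # sid.material.caller.vcf
            sid, material, caller = parts[:3]
            out["caller_vcfs"].setdefault((sid, material), {})[caller] = fio.read_vcf(
                path, sid, material, caller
            )
    return out
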