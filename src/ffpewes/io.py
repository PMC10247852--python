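"""Readers and writers for the plain-text formats the pipeline exchanges.

VCF 4.2 (read through cyvcf2, written as plain text), BED3+, coverage as
bedGraph runs or a 3-column (chrom, pos1, depth) table, the sample QC table
as TSV, and the variant annotation table as TSV with columns
(chrom, pos, ref, alt, gene, af, assertion).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CallSet,
    CoverageTrack,
    GenomicInterval,
    RegionSet,
    SampleQC,
    VariantAnnotations,
    VariantCall,
    VariantKey,
    canonical_contig,
    normalize_variant,
    trim_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_coverage",
    "write_coverage",
    "read_qc_table",
    "write_qc_table",
    "read_annotations",
    "write_annotations",
    "apply_annotations",
]


class VcfParseError(ValueError):
    """Malformed VCF content, naming the offending location when known."""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path,
    sample_id: str,
    material: str,
    provenance: str,
    contigs: Optional[Sequence[str]] = None,
    reference_lookup: Optional[Callable[[str, int, int], str]] = None,
    aliases: Optional[dict] = None,
) -> CallSet:
    """Read one VCF into a :class:`CallSet`.

    Multiallelic records are split into one call per alternate allele.
    Keys are normalized: left-aligned against ``reference_lookup`` when one
    is given, otherwise parsimony-trimmed (reference-free). Records on
    contigs outside ``contigs`` (after alias mapping) are dropped with a
    logged warning.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises on malformed headers
        raise VcfParseError(f"{path}: cannot parse VCF header (line 1): {exc}") from exc

    allowed = set(contigs) if contigs is not None else None
    callset = CallSet(sample_id, material, provenance)
    dropped: set[str] = set()
    for record in vcf:
        chrom = canonical_contig(record.CHROM, aliases)
        if allowed is not None and chrom not in allowed:
            dropped.add(record.CHROM)
            continue
        callers = frozenset(
            str(record.INFO.get("CALLERS")).split(",")
            if record.INFO.get("CALLERS")
            else [provenance]
        )
        af = record.INFO.get("POPAF")
        annotations = VariantAnnotations(
            gene=record.INFO.get("GENE"),
            population_af=float(af) if af is not None else None,
            pathogenicity=str(record.INFO.get("PATHO") or "none"),
        )
        gt = None
        if len(vcf.samples) >= 1 and record.genotypes:
            alleles = [record.REF] + list(record.ALT)
            idx = [i for i in record.genotypes[0][:-1] if isinstance(i, int) and i >= 0]
            if idx:
                gt = tuple(alleles[i] for i in idx)
        for alt in record.ALT:
            try:
                key = VariantKey(chrom, record.POS, record.REF.upper(), alt.upper())
                if reference_lookup is not None:
                    key = normalize_variant(key, reference_lookup)
                else:
                    key = trim_key(key)
            except ValueError as exc:
                raise VcfParseError(
                    f"{path}: bad record at {record.CHROM}:{record.POS}: {exc}"
                ) from exc
            callset.add(
                VariantCall(
                    key=key,
                    genotype=gt,
                    quality=record.QUAL,
                    callers=callers,
                    annotations=annotations,
                )
            )
    if dropped:
        logger.warning(
            "%s: dropped records on contigs outside the configured list: %s",
            path,
            ", ".join(sorted(dropped)),
        )
    return callset


def _format_info(call: VariantCall) -> str:
    parts = [f"CALLERS={','.join(sorted(call.callers))}"]
    ann = call.annotations
    if ann.gene is not None:
        parts.append(f"GENE={ann.gene}")
    if ann.population_af is not None:
        parts.append(f"POPAF={ann.population_af:.6g}")
    if ann.pathogenicity != "none":
        parts.append(f"PATHO={ann.pathogenicity}")
    return ";".join(parts)


def _vcf_header(contigs: Optional[dict], samples: Sequence[str]) -> list:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Supporting variant callers">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=PATHO,Number=1,Type=String,Description="Pathogenicity assertion">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if samples:
        cols += "\tFORMAT\t" + "\t".join(samples)
    lines.append(cols)
    return lines


def _gt_string(call: VariantCall) -> str:
    if call.genotype is None:
        return "./."
    alleles = {call.key.ref: 0, call.key.alt: 1}
    try:
        return "/".join(str(alleles[a]) for a in call.genotype)
    except KeyError:
        return "./."


def write_vcf(callset: CallSet, path, contigs: Optional[dict] = None) -> None:
    """Write a CallSet as a sorted single-sample plain-text VCF."""
    lines = _vcf_header(contigs, [callset.sample_id])
    for call in callset.sorted_calls():
        k = call.key
        qual = f"{call.quality:.6g}" if call.quality is not None else "."
        lines.append(
            f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t{qual}\tPASS\t"
            f"{_format_info(call)}\tGT\t{_gt_string(call)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path, name: str, aliases: Optional[dict] = None) -> RegionSet:
    """Read a BED3+ file (0-based half-open) into a normalized RegionSet."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = canonical_contig(fields[0], aliases)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            intervals.append(GenomicInterval(chrom, start, end))
    return RegionSet(name, intervals)


def write_bed(region: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in region:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------

def read_coverage(path, target: RegionSet, sample_id: str,
                  aliases: Optional[dict] = None) -> CoverageTrack:
    """Read per-base depth over the target.

    Accepts bedGraph runs (chrom, start0, end0, depth) or a 3-column table
    (chrom, pos1, depth). Target bases absent from the file get depth 0;
    positions outside the target are logged and ignored.
    """
    depths = np.zeros(target.total_bases, dtype=np.int64)
    track = CoverageTrack(sample_id, target, depths)
    n_outside = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            chrom = canonical_contig(fields[0], aliases)
            if len(fields) == 3:
                pos0, depth = int(fields[1]) - 1, int(fields[2])
                idx = track.index_of(chrom, pos0)
                if idx is None:
                    n_outside += 1
                else:
                    depths[idx] = depth
            elif len(fields) >= 4:
                start, end, depth = int(fields[1]), int(fields[2]), int(float(fields[3]))
                for pos0 in range(start, end):
                    idx = track.index_of(chrom, pos0)
                    if idx is None:
                        n_outside += 1
                    else:
                        depths[idx] = depth
            else:
                raise ValueError(f"{path}:{lineno}: expected 3 or 4 columns")
    if n_outside:
        logger.warning("%s: ignored %d positions outside the target", path, n_outside)
    return track


def write_coverage(track: CoverageTrack, path) -> None:
    """Write a coverage track as bedGraph runs (compact, lossless)."""
    with open(path, "w") as fh:
        cum = 0
        for iv in track.target.intervals:
            sub = track.depths[cum : cum + len(iv)]
            edges = np.flatnonzero(np.diff(sub)) + 1
            bounds = np.concatenate(([0], edges, [len(sub)]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                fh.write(f"{iv.chrom}\t{iv.start + int(a)}\t{iv.start + int(b)}\t{int(sub[a])}\n")
            cum += len(iv)


# ---------------------------------------------------------------------------
# QC table
# ---------------------------------------------------------------------------

_QC_COLUMNS = ["sample_id", "qpcr", "din", "fragment_length", "mapped_reads", "pct_ge_20x"]


def read_qc_table(path) -> list:
    df = pd.read_csv(path, sep="\t")
    missing = {c for c in _QC_COLUMNS[:5] if c not in df.columns}
    if missing:
        raise ValueError(f"{path}: missing QC columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        pct = getattr(row, "pct_ge_20x", None)
        out.append(
            SampleQC(
                sample_id=str(row.sample_id),
                qpcr_value=float(row.qpcr),
                din=float(row.din),
                fragment_length_bp=float(row.fragment_length),
                mapped_reads=int(row.mapped_reads),
                pct_ge_20x=None if pct is None or pd.isna(pct) else float(pct),
            )
        )
    return out


def write_qc_table(qcs: Iterable[SampleQC], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "qpcr": q.qpcr_value,
                "din": q.din,
                "fragment_length": q.fragment_length_bp,
                "mapped_reads": q.mapped_reads,
                "pct_ge_20x": q.pct_ge_20x,
            }
            for q in qcs
        ],
        columns=_QC_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

_ANN_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "af", "assertion"]


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = {c for c in _ANN_COLUMNS if c not in df.columns}
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return df


def write_annotations(callset: CallSet, path) -> None:
    rows = []
    for call in callset.sorted_calls():
        k, a = call.key, call.annotations
        rows.append(
            {
                "chrom": k.chrom,
                "pos": k.pos,
                "ref": k.ref,
                "alt": k.alt,
                "gene": a.gene,
                "af": a.population_af,
                "assertion": a.pathogenicity,
            }
        )
    pd.DataFrame(rows, columns=_ANN_COLUMNS).to_csv(path, sep="\t", index=False)


def apply_annotations(callset: CallSet, table: pd.DataFrame) -> int:
    """Attach gene/AF/pathogenicity annotations to matching calls.

    Returns the number of calls annotated. Unmatched table rows are ignored.
    """
    lookup = {}
    for row in table.itertuples(index=False):
        key = VariantKey(canonical_contig(str(row.chrom)), int(row.pos), row.ref, row.alt)
        lookup[key] = VariantAnnotations(
            gene=None if pd.isna(row.gene) else str(row.gene),
            population_af=None if pd.isna(row.af) else float(row.af),
            pathogenicity="none" if pd.isna(row.assertion) else str(row.assertion),
        )
    n = 0
    for call in callset:
        ann = lookup.get(call.key)
        if ann is not None:
            call.annotations = ann
            n += 1
    return n
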