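"""Ensemble consensus across variant callers.

The pipeline keeps a variant when at least ``min_callers`` of the
independent callers report it (default 2 of 3: GATK, SAMtools, freebayes in
the real workflow). Consensus is at the variant level: genotype
disagreement does not drop a site; the genotype of the first supporting
caller (in configured caller order) is retained, and the maximum quality
across supporting callers is kept so the result is order independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import CallSet, VariantAnnotations, VariantCall

__all__ = ["EnsembleConfig", "consensus_calls", "build_multisample", "extract_sample"]

DEFAULT_CALLERS = ("gatk", "samtools", "freebayes")


@dataclass(frozen=True)
class EnsembleConfig:
    min_callers: int = 2
    caller_labels: tuple = DEFAULT_CALLERS

    def __post_init__(self) -> None:
        if self.min_callers < 1:
            raise ValueError("min_callers must be >= 1")
        if self.min_callers > len(self.caller_labels):
            raise ValueError(
                f"min_callers ({self.min_callers}) exceeds the number of "
                f"callers ({len(self.caller_labels)})"
            )


def consensus_calls(per_caller: Sequence[CallSet], cfg: EnsembleConfig) -> CallSet:
    """Merge per-caller call sets for one sample into the ensemble set.

    A key is retained iff it appears in at least ``cfg.min_callers`` input
    sets. The retained call records the union of supporting caller labels;
    annotations merge with first-non-missing-wins in ``cfg.caller_labels``
    order.
    """
    if not per_caller:
        raise ValueError("need at least one per-caller CallSet")
    sample_ids = {cs.sample_id for cs in per_caller}
    materials = {cs.material for cs in per_caller}
    if len(sample_ids) != 1 or len(materials) != 1:
        raise ValueError(
            f"per-caller call sets must share sample and material, got "
            f"samples={sorted(sample_ids)} materials={sorted(materials)}"
        )
    order = {label: i for i, label in enumerate(cfg.caller_labels)}
    ranked = sorted(per_caller, key=lambda cs: order.get(cs.provenance, len(order)))

    support: dict = {}
    for cs in ranked:
        for key, call in cs.calls.items():
            support.setdefault(key, []).append(call)

    out = CallSet(ranked[0].sample_id, ranked[0].material, "ensemble")
    for key, calls in support.items():
        if len(calls) < cfg.min_callers:
            continue
        callers = frozenset().union(*(c.callers for c in calls))
        quality = max((c.quality for c in calls if c.quality is not None), default=None)
        annotations = VariantAnnotations()
        for c in calls:  # first non-missing wins (calls are in caller order)
            annotations = annotations.merged_with(c.annotations)
        out.add(
            VariantCall(
                key=key,
                genotype=calls[0].genotype,
                quality=quality,
                callers=callers,
                annotations=annotations,
            )
        )
    return out


def build_multisample(callsets: Sequence[CallSet]) -> pd.DataFrame:
    """Assemble ensemble call sets into one multisample table.

    Rows are variant keys (union across samples), columns are sample ids;
    cells hold the sample's :class:`VariantCall` or NaN. Sample material
    and provenance travel in ``DataFrame.attrs`` so extraction is lossless.
    """
    if not callsets:
        raise ValueError("need at least one CallSet")
    ids = [cs.sample_id for cs in callsets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in multisample table")
    all_keys = sorted(set().union(*(cs.keys() for cs in callsets)))
    data = {
        cs.sample_id: [cs.calls.get(key) for key in all_keys] for cs in callsets
    }
    index = pd.Index(all_keys, tupleize_cols=False, name="variant_key")
    table = pd.DataFrame(data, index=index)
    table.attrs["material"] = {cs.sample_id: cs.material for cs in callsets}
    table.attrs["provenance"] = {cs.sample_id: cs.provenance for cs in callsets}
    return table


def extract_sample(table: pd.DataFrame, sample_id: str) -> CallSet:
    """Recover one sample's CallSet from a multisample table (exact round trip)."""
    if sample_id not in table.columns:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    cs = CallSet(
        sample_id,
        table.attrs["material"][sample_id],
        table.attrs["provenance"][sample_id],
    )
    for call in table[sample_id]:
        if call is not None and not (isinstance(call, float) and pd.isna(call)):
            cs.add(call)
    return cs
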