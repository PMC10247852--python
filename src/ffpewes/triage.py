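"""Clinical triage of exome variants for sudden-death case work.

Implements the interpretation funnel applied after variant calling: a
population allele-frequency filter (5% prefilter, then <1% with rescue of
established pathogenic variants), gene-panel subsetting, and the four
referral categories of increasing breadth:

1. familial_variant - a single genomic position is queried; a failed exome
   can still answer it when the local depth suffices.
2. specified_gene   - frequency filter, then restriction to the named genes.
3. disease_panel    - frequency filter, then a targeted panel (e.g. aorta).
4. general_scd      - two tiers: the cardio diagnostic gene panel (CDGP)
   first, and only if it yields nothing pathogenic the expanded sudden
   death gene panel (SDGP).

Pathogenicity is consumed as an input annotation (ACMG classification is
performed upstream by human reviewers); a variant with no annotated
population frequency is treated as rare (AF 0), mirroring the clinical
practice of retaining variants unseen in population databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

from .concordance import round_half_up
from .core import CallSet, CoverageTrack, VariantKey
from .coverage import QCThresholds

__all__ = [
    "Panel",
    "ReferralRequest",
    "CaseReport",
    "frequency_filter",
    "panel_subset",
    "run_referral",
    "cohort_yield",
    "load_panel",
    "builtin_panels",
]

PATHOGENIC = frozenset({"pathogenic", "likely_pathogenic"})

REFERRAL_CATEGORIES = ("familial_variant", "specified_gene", "disease_panel", "general_scd")

# enforced sizes of the shipped placeholder panels
PANEL_SIZES = {"cdgp": 84, "sdgp": 166, "aorta": 27}


@dataclass(frozen=True)
class Panel:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(g.upper() for g in self.genes))
        if not self.genes:
            raise ValueError("panel must contain at least one gene")


@dataclass(frozen=True)
class ReferralRequest:
    case_id: str
    category: str
    payload: object  # VariantKey | sequence of genes | panel name

    def __post_init__(self) -> None:
        if self.category not in REFERRAL_CATEGORIES:
            raise ValueError(f"unknown referral category {self.category!r}")
        if self.category == "familial_variant" and not isinstance(self.payload, VariantKey):
            raise TypeError("familial_variant referral needs a VariantKey payload")
        if self.category == "specified_gene" and isinstance(self.payload, (str, VariantKey)):
            raise TypeError("specified_gene referral needs a sequence of gene symbols")
        if self.category == "disease_panel" and not isinstance(self.payload, str):
            raise TypeError("disease_panel referral needs a panel name")


@dataclass
class CaseReport:
    case_id: str
    retained: list = field(default_factory=list)  # (tier label, VariantCall)
    familial_variant_status: Optional[str] = None  # present | absent | uncovered
    yield_category: str = "negative"  # positive | vus_only | negative | failed

    def retained_assertions(self) -> set:
        return {call.annotations.pathogenicity for _tier, call in self.retained}


def frequency_filter(
    calls: CallSet, af_cutoff_primary: float = 0.05, af_cutoff_secondary: float = 0.01
) -> CallSet:
    """Two-stage population-frequency filter with pathogenic rescue.

    Stage 1 removes variants at AF >= ``af_cutoff_primary`` with no
    pathogenic/likely-pathogenic assertion; stage 2 keeps variants at
    AF < ``af_cutoff_secondary`` plus asserted pathogenic variants of any
    frequency. Missing AF counts as 0 (rare until proven common). The
    filter is idempotent.
    """
    kept = {}
    for key, call in calls.calls.items():
        af = call.annotations.population_af or 0.0
        pathogenic = call.annotations.pathogenicity in PATHOGENIC
        if af >= af_cutoff_primary and not pathogenic:
            continue  # stage 1: common and unremarkable
        if af < af_cutoff_secondary or pathogenic:
            kept[key] = call  # stage 2: rare, or rescued as established pathogenic
    return CallSet(calls.sample_id, calls.material, calls.provenance, kept)


def panel_subset(calls: CallSet, panel: Panel) -> CallSet:
    """Keep calls whose annotated gene is in the panel; unannotated calls drop."""
    import logging

    kept, unannotated = {}, 0
    for key, call in calls.calls.items():
        gene = call.annotations.gene
        if gene is None:
            unannotated += 1
        elif gene.upper() in panel.genes:
            kept[key] = call
    if unannotated:
        logging.getLogger(__name__).info(
            "%s: dropped %d calls without gene annotation", panel.name, unannotated
        )
    return CallSet(calls.sample_id, calls.material, calls.provenance, kept)


def _classify(report: CaseReport, likely_pathogenic_is_positive: bool) -> str:
    assertions = report.retained_assertions()
    positive = {"pathogenic"} | (
        {"likely_pathogenic"} if likely_pathogenic_is_positive else set()
    )
    if report.familial_variant_status == "present":
        return "positive"
    if assertions & positive:
        return "positive"
    if assertions & {"likely_pathogenic", "vus"}:
        return "vus_only"
    return "negative"


def run_referral(
    request: ReferralRequest,
    calls: CallSet,
    coverage: Optional[CoverageTrack],
    panels: Mapping[str, Panel],
    qc: QCThresholds = QCThresholds(),
    failed_sequencing: bool = False,
    likely_pathogenic_is_positive: bool = False,
) -> CaseReport:
    """Resolve one referral into a case report.

    A familial-variant query never applies the whole-exome success rule:
    even in a failed exome the presence/absence of one position is reported
    whenever its local depth reaches ``qc.local_depth`` (else "uncovered").
    For the broader categories a failed-sequencing case reports
    ``yield_category="failed"``.
    """
    report = CaseReport(case_id=request.case_id)

    if request.category == "familial_variant":
        key: VariantKey = request.payload
        depth = coverage.depth_at(key.chrom, key.anchor0) if coverage is not None else None
        if depth is None or depth < qc.local_depth:
            report.familial_variant_status = "uncovered"
        elif key in calls:
            report.familial_variant_status = "present"
            report.retained.append(("familial", calls.calls[key]))
        else:
            report.familial_variant_status = "absent"
        report.yield_category = _classify(report, likely_pathogenic_is_positive)
        return report

    if failed_sequencing:
        report.yield_category = "failed"
        return report

    filtered = frequency_filter(calls)

    if request.category == "specified_gene":
        wanted = frozenset(g.upper() for g in request.payload)
        subset = panel_subset(filtered, Panel("specified_genes", wanted))
        report.retained = [("specified_gene", c) for c in subset.sorted_calls()]
    elif request.category == "disease_panel":
        if request.payload not in panels:
            raise KeyError(f"unknown panel {request.payload!r}")
        subset = panel_subset(filtered, panels[request.payload])
        report.retained = [(request.payload, c) for c in subset.sorted_calls()]
    else:  # general_scd: two-tier CDGP -> SDGP strategy
        tier1 = panel_subset(filtered, panels["cdgp"])
        report.retained = [("cdgp", c) for c in tier1.sorted_calls()]
        tier1_hit = any(
            c.annotations.pathogenicity in PATHOGENIC for c in tier1
        )
        if not tier1_hit:  # expand only when the first tier is unrevealing
            tier2 = panel_subset(filtered, panels["sdgp"])
            tier1_keys = tier1.keys()
            report.retained += [
                ("sdgp", c) for c in tier2.sorted_calls() if c.key not in tier1_keys
            ]

    report.yield_category = _classify(report, likely_pathogenic_is_positive)
    return report


def cohort_yield(reports: Sequence[CaseReport]) -> dict:
    """Diagnostic-yield arithmetic over a cohort of case reports.

    Failed-sequencing cases are excluded from the denominator. The strict
    yield counts positive cases; the inclusive yield adds cases whose
    finding is a likely-pathogenic variant or a phenotype-relevant VUS.
    Percentages are rounded half-up, strict to 1 decimal, inclusive to an
    integer.
    """
    ok = [r for r in reports if r.yield_category != "failed"]
    if not ok:
        raise ValueError("no successfully sequenced cases in the cohort")
    n_success = len(ok)
    n_positive = sum(r.yield_category == "positive" for r in ok)
    n_vus_relevant = sum(r.yield_category == "vus_only" for r in ok)
    return {
        "n_success": n_success,
        "n_positive": n_positive,
        "yield_strict_pct": round_half_up(100.0 * n_positive / n_success, 1),
        "n_vus_relevant": n_vus_relevant,
        "yield_inclusive_pct": round_half_up(
            100.0 * (n_positive + n_vus_relevant) / n_success, 0
        ),
    }


def load_panel(path, name: str, expected_size: Optional[int] = None) -> Panel:
    """Load a panel from a text file of gene symbols (one per line, # comments)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.upper())
    if expected_size is not None and len(genes) != expected_size:
        raise ValueError(
            f"panel {name!r}: expected {expected_size} genes, found {len(genes)}"
        )
    return Panel(name, frozenset(genes))


def builtin_panels() -> dict:
    """The shipped placeholder panels (synthetic gene lists, enforced sizes).

    The real panel contents are laboratory-specific; these lists carry
    plausible cardiac/aorta gene symbols purely so the triage logic can be
    exercised, and should be replaced with curated lists for real use.
    CDGP is a subset of SDGP by construction.
    """
    panels = {}
    for name, size in PANEL_SIZES.items():
        ref = resources.files("ffpewes").joinpath(f"panels/{name}.synthetic.txt")
        with resources.as_file(ref) as path:
            panels[name] = load_panel(path, name, expected_size=size)
    return panels
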