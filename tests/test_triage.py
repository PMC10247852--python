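"""Frequency filtering, panel subsetting, referral resolution and yield."""

import numpy as np
import pytest

from ffpewes.core import (
    CallSet,
    CoverageTrack,
    GenomicInterval,
    RegionSet,
    VariantAnnotations,
    VariantCall,
    VariantKey,
)
from ffpewes.triage import (
    CaseReport,
    Panel,
    ReferralRequest,
    builtin_panels,
    cohort_yield,
    frequency_filter,
    panel_subset,
    run_referral,
)

PANELS = {
    "cdgp": Panel("cdgp", frozenset({"MYBPC3", "KCNQ1"})),
    "sdgp": Panel("sdgp", frozenset({"MYBPC3", "KCNQ1", "CALM2"})),
    "aorta": Panel("aorta", frozenset({"FBN1"})),
}


def call(pos, gene=None, af=None, assertion="none"):
    return VariantCall(
        VariantKey("chr1", pos, "A", "G"),
        callers=frozenset(["ensemble"]),
        annotations=VariantAnnotations(gene=gene, population_af=af, pathogenicity=assertion),
    )


def callset(calls):
    cs = CallSet("case", "ffpe", "ensemble")
    for c in calls:
        cs.add(c)
    return cs


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "af,assertion,kept",
        [
            (0.004, "none", True),    # rare
            (0.06, "none", False),    # above the 5% prefilter
            (0.02, "none", False),    # between 1% and 5%, unremarkable
            (0.02, "pathogenic", True),  # pathogenic rescue above 1%
            (0.10, "likely_pathogenic", True),
            (None, "none", True),     # missing AF treated as rare
            (0.5, "benign", False),
        ],
    )
    def test_retention_rules(self, af, assertion, kept):
        out = frequency_filter(callset([call(10, af=af, assertion=assertion)]))
        assert (len(out) == 1) == kept

    def test_idempotent_and_predicate_holds_exhaustively(self, rng):
        calls = []
        assertions = ["none", "pathogenic", "likely_pathogenic", "vus", "benign"]
        for pos in range(1, 400):
            calls.append(
                call(
                    pos,
                    af=None if rng.random() < 0.1 else float(rng.random() * 0.6),
                    assertion=assertions[rng.integers(5)],
                )
            )
        once = frequency_filter(callset(calls))
        twice = frequency_filter(once)
        assert once.keys() == twice.keys()
        for c in once:
            af = c.annotations.population_af or 0.0
            assert af < 0.01 or c.annotations.pathogenicity in (
                "pathogenic",
                "likely_pathogenic",
            )


class TestPanelSubset:
    def test_membership(self):
        cs = callset([call(1, gene="MYBPC3"), call(2, gene="TTN"), call(3, gene=None)])
        out = panel_subset(cs, PANELS["cdgp"])
        assert out.keys() == {VariantKey("chr1", 1, "A", "G")}

    def test_full_panel_is_identity(self):
        cs = callset([call(1, gene="MYBPC3"), call(2, gene="KCNQ1")])
        assert panel_subset(cs, PANELS["cdgp"]).keys() == cs.keys()

    def test_random_fixture_matches_membership_oracle(self, rng):
        genes = [f"GENE{i}" for i in range(30)]
        panel = Panel("p", frozenset(genes[:10]))
        cs = callset(
            [call(pos, gene=genes[rng.integers(30)]) for pos in range(1, 200)]
        )
        out = panel_subset(cs, panel)
        want = {k for k, c in cs.calls.items() if c.annotations.gene in panel.genes}
        assert out.keys() == want

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            Panel("empty", frozenset())


class TestBuiltinPanels:
    def test_shipped_sizes_and_nesting(self):
        panels = builtin_panels()
        assert len(panels["cdgp"].genes) == 84
        assert len(panels["sdgp"].genes) == 166
        assert len(panels["aorta"].genes) == 27
        assert panels["cdgp"].genes <= panels["sdgp"].genes
        # tier monotonicity: the SDGP subset always contains the CDGP subset
        cs = callset([call(i, gene=g) for i, g in enumerate(sorted(panels["sdgp"].genes), 1)])
        assert panel_subset(cs, panels["cdgp"]).keys() <= panel_subset(cs, panels["sdgp"]).keys()


def low_coverage_track(hot_pos0, hot_depth=25, n=1000):
    """An exome failing the 90% rule (14% at 20X) but deep at one position."""
    depths = np.zeros(n, dtype=int)
    depths[:140] = 30
    depths[hot_pos0] = hot_depth
    target = RegionSet("t", [GenomicInterval("chr1", 0, n)])
    return CoverageTrack("case", target, depths)


class TestRunReferral:
    def test_familial_variant_answered_despite_failed_exome(self):
        key = VariantKey("chr1", 501, "A", "G")
        coverage = low_coverage_track(hot_pos0=500)
        request = ReferralRequest("case", "familial_variant", key)
        cs = callset([])
        cs.add(VariantCall(key, callers=frozenset(["ensemble"])))
        present = run_referral(request, cs, coverage, PANELS, failed_sequencing=True)
        assert present.familial_variant_status == "present"
        assert present.yield_category == "positive"
        absent = run_referral(request, callset([]), coverage, PANELS, failed_sequencing=True)
        assert absent.familial_variant_status == "absent"
        assert absent.yield_category == "negative"

    def test_familial_variant_uncovered_below_local_depth(self):
        key = VariantKey("chr1", 501, "A", "G")
        coverage = low_coverage_track(hot_pos0=500, hot_depth=12)
        report = run_referral(
            ReferralRequest("case", "familial_variant", key),
            callset([]),
            coverage,
            PANELS,
            failed_sequencing=True,
        )
        assert report.familial_variant_status == "uncovered"

    def test_general_scd_short_circuits_on_tier1_hit(self):
        cs = callset(
            [
                call(1, gene="MYBPC3", af=0.0001, assertion="pathogenic"),
                call(2, gene="CALM2", af=0.0001, assertion="vus"),
            ]
        )
        report = run_referral(
            ReferralRequest("case", "general_scd", None), cs, None, PANELS
        )
        tiers = {tier for tier, _ in report.retained}
        assert tiers == {"cdgp"}
        assert report.yield_category == "positive"

    def test_general_scd_expands_to_sdgp_when_tier1_empty(self):
        cs = callset([call(2, gene="CALM2", af=0.0001, assertion="likely_pathogenic")])
        report = run_referral(
            ReferralRequest("case", "general_scd", None), cs, None, PANELS
        )
        assert [tier for tier, _ in report.retained] == ["sdgp"]
        # likely-pathogenic counts toward the inclusive yield by default
        assert report.yield_category == "vus_only"
        strict = run_referral(
            ReferralRequest("case", "general_scd", None), cs, None, PANELS,
            likely_pathogenic_is_positive=True,
        )
        assert strict.yield_category == "positive"

    def test_specified_gene_and_disease_panel(self):
        cs = callset(
            [
                call(1, gene="FBN1", af=0.0001, assertion="vus"),
                call(2, gene="MYBPC3", af=0.0001),
            ]
        )
        gene_report = run_referral(
            ReferralRequest("case", "specified_gene", ("FBN1",)), cs, None, PANELS
        )
        assert [c.annotations.gene for _t, c in gene_report.retained] == ["FBN1"]
        panel_report = run_referral(
            ReferralRequest("case", "disease_panel", "aorta"), cs, None, PANELS
        )
        assert [c.annotations.gene for _t, c in panel_report.retained] == ["FBN1"]
        with pytest.raises(KeyError):
            run_referral(
                ReferralRequest("case", "disease_panel", "nope"), cs, None, PANELS
            )

    def test_failed_sequencing_blocks_panel_analysis(self):
        cs = callset([call(1, gene="MYBPC3", af=0.0001, assertion="pathogenic")])
        report = run_referral(
            ReferralRequest("case", "general_scd", None), cs, None, PANELS,
            failed_sequencing=True,
        )
        assert report.yield_category == "failed"

    def test_payload_type_checked(self):
        with pytest.raises(TypeError):
            ReferralRequest("c", "familial_variant", "chr1:1:A:G")


class TestCohortYield:
    @staticmethod
    def reports(n_positive, n_vus, n_negative, n_failed=0):
        out = []
        for i in range(n_positive):
            out.append(CaseReport(f"p{i}", yield_category="positive"))
        for i in range(n_vus):
            out.append(CaseReport(f"v{i}", yield_category="vus_only"))
        for i in range(n_negative):
            out.append(CaseReport(f"n{i}", yield_category="negative"))
        for i in range(n_failed):
            out.append(CaseReport(f"f{i}", yield_category="failed"))
        return out

    def test_zero_positive_cohort(self):
        y = cohort_yield(self.reports(0, 0, 10))
        assert y["yield_strict_pct"] == 0.0

    def test_failed_cases_leave_denominator(self):
        y = cohort_yield(self.reports(1, 0, 3, n_failed=4))
        assert y["n_success"] == 4
        assert y["yield_strict_pct"] == 25.0

    def test_all_failed_raises(self):
        with pytest.raises(ValueError):
            cohort_yield(self.reports(0, 0, 0, n_failed=3))
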