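"""Coverage metrics, success rule, joint low-coverage criteria and QC advisories."""

import numpy as np
import pytest

from ffpewes.core import CoverageTrack, GenomicInterval, RegionSet, SampleQC
from ffpewes.coverage import (
    QCThresholds,
    gene_coverage_curve,
    is_successful,
    joint_low_coverage,
    lab_advisories,
    pool_cohort,
    qc_correlation,
    sample_metrics,
)


def track(depths, sample="s"):
    depths = np.asarray(depths)
    target = RegionSet("t", [GenomicInterval("chr1", 0, len(depths))])
    return CoverageTrack(sample, target, depths)


class TestSampleMetrics:
    def test_uniform_track(self):
        m = sample_metrics(track(np.full(500, 30)))
        assert m.mean_depth == 30
        assert m.pct_ge[20] == 100.0 and m.pct_ge[30] == 100.0
        assert m.pct_zero == 0.0
        assert m.fold80 == 1.0  # perfectly uniform coverage

    def test_nearest_rank_fold80(self):
        # 20th percentile of [10,10,10,10,100] is 10; mean 28 -> fold80 2.8
        m = sample_metrics(track([10, 10, 10, 10, 100]))
        assert m.mean_depth == 28
        assert m.fold80 == pytest.approx(2.8)

    def test_fold80_undefined_when_d20_is_zero(self):
        m = sample_metrics(track([0, 0, 5, 5, 5]))
        assert m.fold80 is None

    def test_random_track_matches_full_sort_oracle(self, rng):
        for _ in range(20):
            depths = rng.integers(0, 100, size=int(rng.integers(5, 400)))
            m = sample_metrics(track(depths))
            n = len(depths)
            assert m.mean_depth == pytest.approx(depths.mean())
            for t in (10, 20, 30):
                assert m.pct_ge[t] == pytest.approx(100.0 * (depths >= t).sum() / n)
            assert m.pct_zero == pytest.approx(100.0 * (depths == 0).sum() / n)
            d20 = sorted(depths)[int(np.ceil(0.2 * n)) - 1]
            if d20 > 0:
                assert m.fold80 == pytest.approx(depths.mean() / d20)
            else:
                assert m.fold80 is None

    def test_pct_ge_monotone_in_threshold(self, rng):
        m = sample_metrics(track(rng.integers(0, 60, size=300)), thresholds=range(0, 60, 5))
        vals = [m.pct_ge[t] for t in sorted(m.pct_ge)]
        assert vals == sorted(vals, reverse=True)


class TestSuccessRule:
    def test_boundary_is_inclusive(self):
        n = 1000
        depths = np.full(n, 30)
        depths[: n // 10] = 0  # exactly 90.0% at >=20X
        assert is_successful(sample_metrics(track(depths)))
        depths[n // 10] = 0  # 89.9%
        assert not is_successful(sample_metrics(track(depths)))

    def test_missing_20x_entry_raises(self):
        m = sample_metrics(track(np.full(10, 30)), thresholds=(10, 30))
        with pytest.raises(KeyError):
            is_successful(m)

    def test_synthetic_cohort_success_count_matches_hand_count(self, small_cohort):
        flags = [
            is_successful(sample_metrics(small_cohort.coverage[(q.sample_id, "ffpe")]))
            for q in small_cohort.qc
        ]
        hand = [
            (small_cohort.coverage[(q.sample_id, "ffpe")].depths >= 20).mean() >= 0.9
            for q in small_cohort.qc
        ]
        assert flags == hand


class TestJointLowCoverage:
    def test_quarter_zero_coverage_criterion(self):
        # one base at zero depth in exactly 6 of 24 samples is flagged
        depth = np.full((24, 50), 100)
        depth[:6, 10] = 0
        tracks = [track(row, f"s{i}") for i, row in enumerate(depth)]
        flagged = joint_low_coverage(tracks)
        assert [(iv.start, iv.end) for iv in flagged] == [(10, 11)]
        depth[5, 10] = 100  # only 5/24 -> below 25%, no longer flagged
        tracks = [track(row, f"s{i}") for i, row in enumerate(depth)]
        assert joint_low_coverage(tracks).total_bases == 0

    def test_all_well_covered_gives_empty_set(self):
        tracks = [track(np.full(80, 100), f"s{i}") for i in range(24)]
        assert joint_low_coverage(tracks).total_bases == 0

    @pytest.mark.parametrize(
        "column,expect",
        [
            (np.full(24, 19), True),   # max < 20
            (np.full(24, 20), False),  # max == 20: criterion is strict
            (np.array([3] * 24), True),  # sum 72 < 100 and median < 20
            (np.array([30] * 11 + [19] * 13), True),  # median below 20
            (np.array([30] * 12 + [19] * 12), False),  # median == 24.5
        ],
    )
    def test_individual_criteria(self, column, expect):
        depth = np.full((24, 3), 200)
        depth[:, 1] = column
        tracks = [track(row, f"s{i}") for i, row in enumerate(depth)]
        flagged = joint_low_coverage(tracks)
        assert (flagged.total_bases > 0) == expect

    def test_random_matrix_matches_per_base_oracle(self, rng):
        qc = QCThresholds()
        for _ in range(30):
            n_samples = int(rng.integers(2, 30))
            depth = rng.integers(0, 40, size=(n_samples, 120))
            tracks = [track(row, f"s{i}") for i, row in enumerate(depth)]
            flagged = joint_low_coverage(tracks, qc)
            mask = np.zeros(120, dtype=bool)
            for j in range(120):
                col = depth[:, j]
                mask[j] = (
                    (col == 0).sum() / n_samples >= qc.low_cov_sample_frac_zero
                    or col.max() < qc.low_cov_max
                    or col.sum() < qc.low_cov_sum
                    or float(np.median(col)) < qc.low_cov_median
                )
            assert np.array_equal(tracks[0].region_mask(flagged), mask)

    def test_mismatched_targets_raise(self):
        with pytest.raises(ValueError):
            joint_low_coverage([track(np.zeros(5)), track(np.zeros(6))])


class TestGeneCoverageCurve:
    def _genes(self, n_genes=10, gene_len=50):
        return {
            f"G{i}": RegionSet(f"G{i}", [GenomicInterval("chr1", i * gene_len, (i + 1) * gene_len)])
            for i in range(n_genes)
        }

    def test_uniform_coverage_saturates_curve(self):
        genes = self._genes()
        curve = gene_coverage_curve(track(np.full(500, 30)), genes)
        assert (curve[10] == 1.0).all() and (curve[30] == 1.0).all()

    def test_half_covered_gene_boundary(self):
        genes = {"G": RegionSet("G", [GenomicInterval("chr1", 0, 100)])}
        depths = np.concatenate([np.full(50, 25), np.zeros(50)])
        curve = gene_coverage_curve(
            track(depths), genes, fraction_grid=[0.5, 0.51]
        )
        assert curve.loc[0.5, 20] == 1.0
        assert curve.loc[0.51, 20] == 0.0

    def test_monotone_in_fraction_and_depth(self, rng):
        genes = self._genes()
        curve = gene_coverage_curve(track(rng.integers(0, 50, size=500)), genes)
        for d in (10, 20, 30):
            assert (np.diff(curve[d].to_numpy()) <= 1e-12).all()
        assert (curve[10] >= curve[20]).all() and (curve[20] >= curve[30]).all()

    def test_matches_per_gene_counting_oracle(self, rng):
        genes = self._genes()
        depths = rng.integers(0, 50, size=500)
        grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        curve = gene_coverage_curve(track(depths), genes, fraction_grid=grid)
        for d in (10, 20, 30):
            for f in grid:
                covered = 0
                for i in range(10):
                    gene_depths = depths[i * 50 : (i + 1) * 50]
                    if (gene_depths >= d).sum() >= f * 50 - 1e-9:
                        covered += 1
                assert curve.loc[f, d] == pytest.approx(covered / 10)

    def test_gene_without_target_bases_is_excluded(self):
        genes = self._genes(2)
        genes["off"] = RegionSet("off", [GenomicInterval("chr9", 0, 10)])
        curve = gene_coverage_curve(track(np.full(100, 30)), genes, fraction_grid=[1.0])
        assert curve.loc[1.0, 20] == 1.0  # 2 of 2 on-target genes counted


class TestQcCorrelation:
    def _qc(self, qpcr, pct):
        return SampleQC(f"s{qpcr:.3f}", qpcr, 3.0, 800.0, 10_000, pct_ge_20x=pct)

    def test_perfectly_decreasing_gives_rho_minus_one(self):
        qcs = [self._qc(float(q), 99.0 - 3 * q) for q in range(10)]
        out = qc_correlation(qcs)
        assert out.loc["qpcr", "rho"] == pytest.approx(-1.0)
        assert 0 < out.loc["qpcr", "r2"] <= 1

    def test_independent_metric_has_small_rho(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            qcs = [
                self._qc(float(rng.uniform(1, 14)), float(rng.uniform(10, 99)))
                for _ in range(100)
            ]
            assert abs(qc_correlation(qcs).loc["qpcr", "rho"]) < 0.3

    def test_constant_metric_reports_missing(self):
        qcs = [self._qc(5.0, 50.0 + i) for i in range(6)]
        assert np.isnan(qc_correlation(qcs).loc["qpcr", "rho"])

    def test_needs_four_samples(self):
        with pytest.raises(ValueError):
            qc_correlation([self._qc(1.0, 90.0)] * 3)


class TestLabAdvisories:
    def test_qpcr_above_ten_predicts_failure(self):
        qc = SampleQC("s", 10.1, 2.0, 500, 1000)
        assert not lab_advisories(qc).predicted_success
        assert lab_advisories(SampleQC("s", 10.0, 2.0, 500, 1000)).predicted_success

    @pytest.mark.parametrize(
        "frag,din,protocol",
        [
            (1200.0, 2.0, "frag"),   # long fragments alone select fragmentation
            (500.0, 3.5, "frag"),    # intact DNA (DIN) alone selects it too
            (500.0, 2.0, "nofrag"),
            (1000.0, 3.0, "nofrag"),  # thresholds are strict inequalities
        ],
    )
    def test_protocol_branch(self, frag, din, protocol):
        assert lab_advisories(SampleQC("s", 5.0, din, frag, 1000)).protocol == protocol

    def test_pooling_chunks_by_qpcr(self):
        qcs = [SampleQC(f"s{i}", float(16 - i), 3.0, 800, 1000) for i in range(16)]
        pools = pool_cohort(qcs)
        assert len(pools) == 16
        assert {a.pool_id for a in pools} == {0, 1}
        # pools are sorted: every pool-0 sample amplifies better than pool-1
        q_of = {q.sample_id: q.qpcr_value for q in qcs}
        pool0 = [q_of[a.sample_id] for a in pools if a.pool_id == 0]
        pool1 = [q_of[a.sample_id] for a in pools if a.pool_id == 1]
        assert max(pool0) <= min(pool1)
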