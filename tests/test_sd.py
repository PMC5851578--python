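import numpy as np
import pytest

from carp.annotate import ResolvedHit
from carp.consensus import ConsensusRecord
from carp.sd import (
    CopyNumberRecord,
    copy_number_table,
    coverage_profile,
    loglog_regression,
    triage_unclassified,
)
from carp.seqio import GenomeInterval
from oracles import ols_loglog


def _hit(lib, g_start, g_end, q_start=0, q_end=None):
    q_end = q_end if q_end is not None else g_end - g_start
    return ResolvedHit(
        lib, "Unclassified", GenomeInterval("c", g_start, g_end),
        q_start, q_end, 0.9, 100,
    )


class TestCopyNumberTable:
    def test_counts_resolved_hits_per_consensus(self):
        cons = [
            ConsensusRecord("family000001", "A" * 500, []),
            ConsensusRecord("family000002", "C" * 300, []),
        ]
        hits = [
            _hit("family000001", 0, 500),
            _hit("family000001", 5000, 5500),
            _hit("other", 9000, 9100),
        ]
        table = {r.consensus_id: r for r in copy_number_table(hits, cons)}
        assert table["family000001"].copies == 2
        assert table["family000002"].copies == 0
        assert table["family000001"].length == 500


class TestLogLogRegression:
    def test_exact_line_recovered_with_zero_se(self):
        # log10(c) = 2 + 0.5 * log10(L), chosen so copies are exact
        lengths = [100, 10_000, 1_000_000]
        copies = [1000, 10_000, 100_000]
        records = [
            CopyNumberRecord(f"c{i}", L, c)
            for i, (L, c) in enumerate(zip(lengths, copies))
        ]
        result = loglog_regression(records)
        assert result.slope == pytest.approx(0.5, abs=1e-6)
        assert result.intercept == pytest.approx(2.0, abs=1e-6)
        assert result.slope_se == pytest.approx(0.0, abs=1e-6)
        assert result.intercept_se == pytest.approx(0.0, abs=1e-6)

    def test_matches_normal_equation_oracle(self, rng):
        lengths = rng.integers(200, 50_000, size=40)
        copies = np.maximum(
            1, (lengths**0.4 * 10 ** rng.normal(0, 0.3, 40)).astype(int)
        )
        records = [
            CopyNumberRecord(f"c{i}", int(L), int(c))
            for i, (L, c) in enumerate(zip(lengths, copies))
        ]
        result = loglog_regression(records)
        slope, intercept, slope_se, intercept_se = ols_loglog(lengths, copies)
        assert result.slope == pytest.approx(slope, abs=1e-9)
        assert result.intercept == pytest.approx(intercept, abs=1e-9)
        assert result.slope_se == pytest.approx(slope_se, abs=1e-9)
        assert result.intercept_se == pytest.approx(intercept_se, abs=1e-9)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        lengths = rng.integers(500, 20_000, size=25)
        copies = rng.integers(1, 3000, size=25)
        records = [
            CopyNumberRecord(f"c{i}", int(L), int(c))
            for i, (L, c) in enumerate(zip(lengths, copies))
        ]
        result = loglog_regression(records)
        X = sm.add_constant(np.log10(lengths))
        fit = sm.OLS(np.log10(copies), X).fit()
        assert result.intercept == pytest.approx(fit.params[0], abs=1e-9)
        assert result.slope == pytest.approx(fit.params[1], abs=1e-9)
        assert result.slope_se == pytest.approx(fit.bse[1], abs=1e-9)
        assert result.p_slope == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_zero_copy_records_excluded(self):
        records = [CopyNumberRecord(f"c{i}", 500 * (i + 1), c) for i, c in
                   enumerate([0, 10, 20, 40])]
        result = loglog_regression(records)
        assert result.n == 3

    def test_too_few_records_error(self):
        records = [CopyNumberRecord("a", 100, 5), CopyNumberRecord("b", 200, 9)]
        with pytest.raises(ValueError):
            loglog_regression(records)


class TestCoverageProfile:
    def test_single_hit_depth_and_peak(self):
        cons = ConsensusRecord("family000001", "A" * 200, [])
        profile = coverage_profile(cons, [_hit("family000001", 0, 100, 0, 100)])
        assert profile.depth[:100].tolist() == [1] * 100
        assert profile.depth[100:].sum() == 0
        assert profile.peaks == [(0, 100, 1)]

    def test_overlapping_hits_stack(self):
        cons = ConsensusRecord("family000001", "A" * 200, [])
        profile = coverage_profile(
            cons,
            [
                _hit("family000001", 0, 100, 0, 100),
                _hit("family000001", 500, 600, 50, 150),
            ],
        )
        assert (profile.depth[50:100] == 2).all()
        assert (profile.depth[0:50] == 1).all()

    def test_depth_conservation(self, rng):
        cons = ConsensusRecord("family000001", "A" * 300, [])
        hits = []
        total = 0
        for _ in range(20):
            s = int(rng.integers(0, 250))
            e = s + int(rng.integers(30, 50))
            hits.append(_hit("family000001", s * 7, s * 7 + (e - s), s, e))
            total += e - s
        profile = coverage_profile(cons, hits)
        assert profile.depth.sum() == total

    def test_uniform_full_length_single_peak(self):
        cons = ConsensusRecord("family000001", "A" * 250, [])
        hits = [_hit("family000001", i * 300, i * 300 + 250, 0, 250)
                for i in range(30)]
        profile = coverage_profile(cons, hits)
        assert len(profile.peaks) == 1
        start, end, depth = profile.peaks[0]
        assert (start, end) == (0, 250)
        assert depth == 30


class TestTriage:
    def _records(self):
        return [
            CopyNumberRecord("sd_like", 8000, 2),
            CopyNumberRecord("boundary", 500, 2000),
            CopyNumberRecord("novel_te", 400, 2500),
        ]

    def test_high_copy_strictly_above_threshold(self):
        result = triage_unclassified(self._records())
        assert [r.consensus_id for r in result.high_copy_review] == ["novel_te"]
        assert {r.consensus_id for r in result.sd_candidates} == {
            "sd_like", "boundary",
        }

    def test_partition_is_complete(self):
        records = self._records()
        result = triage_unclassified(records)
        assert len(result.sd_candidates) + len(result.high_copy_review) == len(
            records
        )

    def test_profiles_attached_for_high_copy(self):
        cons = {"novel_te": ConsensusRecord("novel_te", "A" * 400, [])}
        hits = [_hit("novel_te", i * 500, i * 500 + 400, 0, 400) for i in range(5)]
        result = triage_unclassified(
            self._records(), hits, cons
        )
        assert "novel_te" in result.profiles
        assert result.profiles["novel_te"].depth.max() == 5
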