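"""Summaries, exact Wilcoxon signed-rank engine, cohort comparison, report."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon

from icpulse.similarity import DIRecord
from icpulse.stats import (
    build_report,
    compare_periods,
    summarize,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(x, y):
    """Independent oracle: full enumeration of all 2^n sign assignments."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    r = rankdata(np.abs(d))
    w = min(r[d > 0].sum(), r[d < 0].sum())
    total = r.sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=d.size):
        wp = float(np.dot(r, signs))
        if wp <= w + 1e-9 or wp >= total - w - 1e-9:
            count += 1
    return float(w), count / 2.0**d.size


class TestSummarize:
    def test_order_statistics_example(self):
        s = summarize([1, 2, 3, 4, 5], "DI", "baseline")
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        assert s.n == 5

    def test_single_value(self):
        s = summarize([7.5])
        assert s.q1 == s.median == s.q3 == 7.5

    @given(st.integers(0, 2**31 - 1))
    def test_matches_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(1, 60)))
        s = summarize(x)
        xs = np.sort(x)

        def q(p):  # linear interpolation between order statistics
            h = (xs.size - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, xs.size - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        assert s.q1 == pytest.approx(q(0.25), abs=1e-12)
        assert s.median == pytest.approx(q(0.5), abs=1e-12)
        assert s.q3 == pytest.approx(q(0.75), abs=1e-12)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            summarize([])
        with pytest.raises(ValueError):
            summarize([1.0, np.nan])


class TestWilcoxon:
    def test_five_concordant_pairs(self):
        res = wilcoxon_signed_rank([2.0, 3, 4, 5, 6], [1.0, 1, 1, 1, 1])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.0625)
        assert res.method == "exact"

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2, 3, 4, 5], [1.0, 2, 3, 4, 5])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2, 3], [0.0, 0, 0])

    @pytest.mark.parametrize("n", [5, 8, 10, 12])
    def test_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            x = rng.normal(0.4, 1, n)
            y = rng.normal(0.0, 1, n)
            res = wilcoxon_signed_rank(x, y)
            w_b, p_b = brute_force_wilcoxon(x, y)
            assert res.statistic == pytest.approx(w_b)
            assert res.p_value == pytest.approx(p_b, abs=1e-12)

    def test_ties_handled_exactly(self):
        x = np.array([2.0, 3.0, 5.0, 6.0, 9.0, 10.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0, 7.0])  # |d| has triple ties
        res = wilcoxon_signed_rank(x, y)
        w_b, p_b = brute_force_wilcoxon(x, y)
        assert res.statistic == pytest.approx(w_b)
        assert res.p_value == pytest.approx(p_b, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_scipy_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 26))
        x = rng.normal(0.3, 1, n)
        y = rng.normal(0.0, 1, n)
        res = wilcoxon_signed_rank(x, y)
        ref = scipy_wilcoxon(x, y, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_invariant_under_common_shift(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank(x + 100.0, y + 100.0)
        assert a.statistic == b.statistic and a.p_value == b.p_value

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0.5, 1, 40)
        y = rng.normal(0.0, 1, 40)
        res = wilcoxon_signed_rank(x, y)
        assert res.method == "normal-approximation"
        ref = scipy_wilcoxon(x, y, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def make_records(n_waves, base_di, plat_di, per_period=5, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for w in range(n_waves):
        for i in range(per_period):
            records.append(
                DIRecord(
                    di=base_di + w + jitter * rng.standard_normal(),
                    n_compared=200,
                    wave_id=f"w{w:02d}",
                    period_label="baseline",
                    onset_time=float(i),
                )
            )
            records.append(
                DIRecord(
                    di=plat_di + w + jitter * rng.standard_normal(),
                    n_compared=200,
                    wave_id=f"w{w:02d}",
                    period_label="plateau",
                    onset_time=300.0 + i,
                )
            )
    return records


class TestComparePeriods:
    def test_programmed_shift_detected(self):
        records = make_records(10, base_di=30.0, plat_di=20.0, jitter=0.5)
        out = compare_periods(records)
        assert out.test.p_value < 0.05
        assert out.summaries["plateau"].median < out.summaries["baseline"].median
        assert len(out.per_wave) == 10

    def test_wave_missing_period_excluded_with_warning(self, caplog):
        import logging

        records = make_records(6, 30.0, 20.0, jitter=0.5)
        records = [
            r for r in records if not (r.wave_id == "w00" and r.period_label == "plateau")
        ]
        with caplog.at_level(logging.WARNING, logger="icpulse.stats"):
            out = compare_periods(records)
        assert len(out.per_wave) == 5
        assert any("missing a period" in r.message for r in caplog.records)

    def test_n_pairs_bounded_by_waves(self):
        out = compare_periods(make_records(15, 30.0, 20.0, jitter=0.5))
        assert out.test.n_pairs <= 15

    def test_pooled_mode_runs(self):
        out = compare_periods(make_records(6, 30.0, 20.0, jitter=1.0), pairing="pooled")
        assert out.test.n_pairs > 6

    def test_unlabeled_only_rejected(self):
        with pytest.raises(ValueError):
            compare_periods(
                [DIRecord(di=1.0, n_compared=10, wave_id="w", period_label=None)]
            )


class TestBuildReport:
    def test_one_row_per_wave_and_deterministic(self):
        out = compare_periods(make_records(7, 30.0, 20.0, jitter=0.5))
        r1 = build_report(out, config_echo={"alpha": 0.05})
        r2 = build_report(out, config_echo={"alpha": 0.05})
        assert r1 == r2
        wave_rows = [ln for ln in r1.splitlines() if ln.strip().startswith("w0")]
        assert len(wave_rows) == 7
        assert "alpha: 0.05" in r1
        assert "Wilcoxon" in r1

    def test_report_written_to_disk(self, tmp_path):
        out = compare_periods(make_records(5, 30.0, 20.0, jitter=0.5))
        path = tmp_path / "report.txt"
        text = build_report(out, path=path)
        assert path.read_text() == text
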