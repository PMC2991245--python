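import warnings

import numpy as np
import pytest

from recombscan.aggregate import (
    CallerConfig,
    aggregate_detections,
    build_recotypes,
    call_events,
    call_from_records,
    filter_phasing_artifacts,
    run_all,
    sequence_distributions,
)
from recombscan.genealogy import DetectionRecord
from recombscan.io import HaplotypeMatrix, PopulationMap
from recombscan.model import RecombinationScan


def rec(rows, a, b, run=(10, 1, "forward")):
    return DetectionRecord(frozenset(rows), (a, b), run)


class TestCallerConfig:
    def test_total_runs_default_is_seventy(self):
        cfg = CallerConfig()
        assert cfg.grains == (20, 10, 5)
        assert cfg.total_runs == 70
        assert cfg.resolved_threshold == 42

    @pytest.mark.parametrize(
        "grains,directions,expected",
        [((10,), "forward", 10), ((5,), "both", 10), ((20, 10, 5), "both", 70)],
    )
    def test_total_runs(self, grains, directions, expected):
        cfg = CallerConfig(grains=grains, directions=directions, threshold=1)
        assert cfg.total_runs == expected

    def test_threshold_fraction(self):
        cfg = CallerConfig(threshold=None, threshold_frac=0.6)
        assert cfg.resolved_threshold == 42

    def test_invalid(self):
        with pytest.raises(ValueError):
            CallerConfig(grains=(10, 10))
        with pytest.raises(ValueError):
            CallerConfig(grains=(10,), directions="forward", threshold=11)


def test_run_all_executes_every_offset(splice_matrix):
    log = []
    run_all(splice_matrix, CallerConfig(grains=(10, 5), threshold=1), log=log)
    assert len(log) == 30
    assert len(set(log)) == 30
    assert (5, 3, "reverse") in log


class TestAggregateDetections:
    def test_single_record_indicator(self):
        dists = aggregate_detections([rec({1}, 3, 8)], 12)
        assert len(dists) == 1
        np.testing.assert_array_equal(
            dists[0].counts, [0, 0, 0, 1, 1, 1, 1, 1, 0, 0, 0, 0]
        )

    def test_overlap_accumulates(self):
        dists = aggregate_detections([rec({1}, 3, 8), rec({1}, 5, 12)], 12)
        counts = dists[0].counts
        assert counts[5:8].tolist() == [2, 2, 2]
        assert counts[3:5].tolist() == [1, 1]

    def test_distinct_sets_distinct_lines(self):
        dists = aggregate_detections([rec({1}, 3, 8), rec({2}, 3, 8)], 12)
        assert len(dists) == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        records = []
        for _ in range(40):
            a = int(rng.integers(0, 10))
            b = int(rng.integers(a + 1, 15))
            records.append(rec({int(rng.integers(0, 4))}, a, b))
        dists = aggregate_detections(records, 15)
        total = sum(int(d.counts.sum()) for d in dists)
        assert total == sum(r.interval[1] - r.interval[0] for r in records)


class TestCallEvents:
    def cfg(self, T):
        return CallerConfig(grains=(10,), directions="forward", threshold=T)

    def test_below_threshold_no_events(self):
        dists = aggregate_detections([rec({1}, 3, 8)], 12)
        assert call_events(dists, self.cfg(2)) == []

    def test_odd_plateau_midpoint(self):
        records = [rec({1}, 10, 15)] * 3
        dists = aggregate_detections(records, 20)
        (ev,) = call_events(dists, self.cfg(3))
        assert ev.breakpoint == 12.0
        assert ev.maximum_interval == (10, 15)

    def test_even_plateau_midpoint(self):
        records = [rec({1}, 10, 14)] * 3
        dists = aggregate_detections(records, 20)
        (ev,) = call_events(dists, self.cfg(3))
        assert ev.breakpoint == 11.5

    def test_discontiguous_region_keeps_argmax_segment(self):
        records = [rec({1}, 2, 5), rec({1}, 2, 5), rec({1}, 8, 12),
                   rec({1}, 8, 12), rec({1}, 9, 12)]
        dists = aggregate_detections(records, 14)
        (ev,) = call_events(dists, self.cfg(2))
        assert ev.peak_count == 3
        assert ev.threshold_interval == (8, 12)


class TestCallFromRecords:
    def haps(self, n_seq=6, n_snps=30):
        return HaplotypeMatrix(
            np.zeros((n_seq, n_snps), dtype=np.int16) + np.arange(n_seq)[:, None] % 2,
            np.arange(n_snps) * 10.0,
            [f"r{i}" for i in range(n_seq)],
            [f"s{j}" for j in range(n_snps)],
        )

    def test_single_junction_single_event(self):
        records = [rec({1, 2}, 5, 15)] * 4
        events = call_from_records(records, self.haps(), self.cfg(3))
        assert len(events) == 1
        assert events[0].rows == {1, 2}
        assert events[0].breakpoint == 9.5

    def cfg(self, T):
        return CallerConfig(grains=(10,), directions="forward", threshold=T)

    def test_two_junctions_one_sequence(self):
        records = [rec({1}, 2, 8)] * 3 + [rec({1}, 18, 26)] * 3
        events = call_from_records(records, self.haps(), self.cfg(3))
        assert len(events) == 2
        assert {int(np.floor(e.breakpoint)) for e in events} == {4, 21}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        records = []
        for _ in range(120):
            row = int(rng.integers(0, 6))
            a = int(rng.integers(0, 20))
            b = int(rng.integers(a + 2, 30))
            records.append(rec({row}, a, b))
        lo = call_from_records(records, self.haps(), self.cfg(4))
        hi = call_from_records(records, self.haps(), self.cfg(8))
        called_lo = {(r, int(e.breakpoint)) for e in lo for r in e.rows}
        called_hi = {(r, int(e.breakpoint)) for e in hi for r in e.rows}
        # every sequence called at the stricter threshold is called at the
        # looser one at a nearby position
        for r, b in called_hi:
            assert any(r2 == r and abs(b2 - b) <= 2 for r2, b2 in called_lo)


class TestRecotypes:
    def test_no_events(self, splice_matrix):
        recm = build_recotypes([], splice_matrix)
        assert recm.matrix.shape == (8, 0)

    def test_membership_column(self, splice_matrix):
        res = RecombinationScan(splice_matrix, grains=(10, 5),
                                threshold_frac=0.5).fit()
        recm = res.recotypes
        assert recm.n_events >= 1
        splice_row = splice_matrix.row_index("F")
        assert recm.matrix[splice_row].sum() >= 1
        sums = recm.matrix.sum(axis=0)
        for j, ev in enumerate(
            sorted(res.events, key=lambda e: (e.breakpoint, sorted(e.rows)))
        ):
            assert sums[j] == len(ev.rows)


class TestPhasingFilter:
    def make_events(self, positions):
        res = []
        from recombscan.aggregate import RecombinationEvent

        for row, bk in positions:
            b = int(bk)
            res.append(
                RecombinationEvent(
                    rows=frozenset({row}), peak_count=10,
                    maximum_interval=(b, b + 1), breakpoint=float(bk),
                    threshold_interval=(max(b - 1, 0), b + 2),
                )
            )
        return res

    def pairing(self):
        return PopulationMap(
            populations={"A|0": "p", "A|1": "p", "B|0": "p", "B|1": "p"},
            pairs={"A": ("A|0", "A|1"), "B": ("B|0", "B|1")},
        )

    def haps(self):
        return HaplotypeMatrix(
            np.arange(4)[:, None] % 2 + np.zeros((4, 30), dtype=np.int16),
            np.arange(30) * 10.0,
            ["A|0", "A|1", "B|0", "B|1"],
            [f"s{j}" for j in range(30)],
        )

    def test_reciprocal_pair_within_six_snps_removed(self):
        events = self.make_events([(0, 10.0), (1, 14.0)])
        kept, removed = filter_phasing_artifacts(events, self.haps(), self.pairing())
        assert kept == [] and len(removed) == 2

    def test_boundary_six_and_beyond_kept(self):
        events = self.make_events([(0, 10.0), (1, 16.0)])
        kept, removed = filter_phasing_artifacts(events, self.haps(), self.pairing())
        assert len(kept) == 2 and removed == []

    def test_different_individuals_kept(self):
        events = self.make_events([(0, 10.0), (2, 12.0)])
        kept, removed = filter_phasing_artifacts(events, self.haps(), self.pairing())
        assert len(kept) == 2

    def test_missing_pairing_warns(self):
        events = self.make_events([(0, 10.0)])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            kept, removed = filter_phasing_artifacts(events, self.haps(), None)
        assert kept == events and removed == []
        assert caught


def test_sequence_distributions_credit_members():
    records = [rec({0, 2}, 1, 5), rec({2}, 3, 8)]
    counts = sequence_distributions(records, 4, 10)
    assert counts[0, 1:5].tolist() == [1, 1, 1, 1]
    assert counts[2, 3:5].tolist() == [2, 2]
    assert counts[1].sum() == 0
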