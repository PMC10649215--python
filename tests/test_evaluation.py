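"""Scoring: tolerance matching, S/P/DER metrics, realignment, pooling."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from hypothesis import given, settings, strategies as st

import parafit as pf
from parafit.evaluation import AnnotationSet, MatchResult
from parafit.parabolic import SignalRecord


def optimal_tp(det: np.ndarray, ref: np.ndarray, tol: int) -> int:
    """Maximum one-to-one matching within tolerance, via optimal assignment."""
    if len(det) == 0 or len(ref) == 0:
        return 0
    feasible = np.abs(ref[:, None].astype(int) - det[None, :].astype(int)) <= tol
    rows, cols = linear_sum_assignment(np.where(feasible, 0, 1))
    return int(feasible[rows, cols].sum())


class TestMatch:
    def test_identical_lists(self):
        ref = np.arange(0, 5000, 250)
        m = pf.match(ref, ref, tolerance=10)
        assert (m.TP, m.FN, m.FP) == (ref.size, 0, 0)

    def test_empty_detections(self):
        m = pf.match(np.array([], dtype=int), np.arange(0, 1000, 100), tolerance=10)
        assert (m.TP, m.FN, m.FP) == (0, 10, 0)

    def test_everything_out_of_tolerance(self):
        ref = np.arange(100, 2000, 200)
        m = pf.match(ref + 11, ref, tolerance=10)
        assert (m.TP, m.FN, m.FP) == (0, ref.size, ref.size)

    def test_one_to_one_no_double_matching(self):
        # Two detections near one reference: only one may match.
        m = pf.match(np.array([98, 103]), np.array([100]), tolerance=10)
        assert (m.TP, m.FN, m.FP) == (1, 0, 1)
        assert m.pairs == ((100, 98),)  # earliest unmatched wins

    def test_matches_brute_force_on_small_cases(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            ref = np.sort(rng.choice(200, size=rng.integers(0, 6), replace=False))
            det = np.sort(rng.choice(200, size=rng.integers(0, 6), replace=False))
            tol = int(rng.integers(0, 30))
            m = pf.match(det, ref, tolerance=tol)
            assert m.TP == optimal_tp(det, ref, tol)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            pf.match(np.array([5, 3]), np.array([1, 2]), tolerance=1)

    def test_tolerance_conversion(self):
        assert pf.tolerance_samples(250.0) == 10
        assert pf.tolerance_samples(360.0) == 14
        assert pf.tolerance_samples(250.0, tolerance_ms=0) == 0


class TestMetrics:
    def test_qt_database_totals(self):
        """Pooled QT-database counts give S=99.95, P=99.88, DER=0.17."""
        r = pf.metrics(MatchResult(TP=86_953, FN=42, FP=105))
        assert round(r.S, 2) == 99.95
        assert round(r.P, 2) == 99.88
        assert round(r.DER, 2) == 0.17

    def test_mit_database_totals(self):
        """Pooled MIT-BIH counts give S=P=99.66, DER=0.68."""
        r = pf.metrics(MatchResult(TP=109_120, FN=373, FP=373))
        assert round(r.S, 2) == 99.66
        assert round(r.P, 2) == 99.66
        assert round(r.DER, 2) == 0.68

    def test_perfect_detection(self):
        r = pf.metrics(MatchResult(TP=42, FN=0, FP=0))
        assert (r.S, r.P, r.DER) == (100.0, 100.0, 0.0)

    def test_undefined_ratios_are_none(self):
        r = pf.metrics(MatchResult(TP=0, FN=0, FP=3))
        assert r.S is None and r.DER is None
        assert r.P == 0.0
        r2 = pf.metrics(MatchResult(TP=0, FN=3, FP=0))
        assert r2.P is None and r2.S == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            MatchResult(TP=-1, FN=0, FP=0)


class TestPool:
    def test_single_record_is_identity(self):
        r = pf.metrics(MatchResult(TP=10, FN=2, FP=1), record_id="a")
        p = pf.pool([r])
        assert p.counts == MatchResult(TP=10, FN=2, FP=1)

    def test_micro_average_not_mean_of_percentages(self):
        a = pf.metrics(MatchResult(TP=10, FN=0, FP=0))
        b = pf.metrics(MatchResult(TP=0, FN=10, FP=0))
        assert pf.pool([a, b]).S == pytest.approx(50.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pf.pool([])


class TestRealignment:
    def _apex_record(self, apex=500):
        t = np.arange(2500) / 250.0
        y = np.exp(-0.5 * ((t - apex / 250.0) / 0.010) ** 2)
        return SignalRecord(y, fs=250)

    def test_annotation_at_apex_unchanged(self):
        rec = self._apex_record()
        ann = AnnotationSet(np.array([500]), labels=("N",))
        out = pf.realign_annotations(rec, ann, search_ms=40)
        assert out.indices[0] == 500

    def test_offset_annotation_snaps_to_apex(self):
        rec = self._apex_record()
        ann = AnnotationSet(np.array([495]), labels=("N",))
        out = pf.realign_annotations(rec, ann, search_ms=40)
        assert out.indices[0] == 500

    def test_zero_search_is_identity(self):
        rec = self._apex_record()
        ann = AnnotationSet(np.array([495]), labels=("N",))
        out = pf.realign_annotations(rec, ann, search_ms=0)
        assert out.indices[0] == 495

    def test_downward_peak_also_found(self):
        rec = SignalRecord(-self._apex_record().samples + 0.5, fs=250)
        ann = AnnotationSet(np.array([493]), labels=("N",))
        out = pf.realign_annotations(rec, ann, search_ms=40)
        assert out.indices[0] == 500

    def test_non_beat_labels_untouched(self):
        rec = self._apex_record()
        ann = AnnotationSet(np.array([493, 495]), labels=("+", "N"))
        out = pf.realign_annotations(rec, ann, search_ms=40)
        assert out.indices[0] == 493 and out.indices[1] == 500

    def test_edge_annotation_uses_truncated_window(self):
        rec = self._apex_record(apex=3)
        ann = AnnotationSet(np.array([1]), labels=("N",))
        out = pf.realign_annotations(rec, ann, search_ms=40)
        assert 0 <= out.indices[0] <= 13


class TestBeatFiltering:
    def test_non_beat_annotations_ignored_in_scoring(self):
        ref = AnnotationSet(
            np.array([100, 200, 300, 400]), labels=("N", "+", "V", "~")
        )
        assert list(ref.beats_only().indices) == [100, 300]
        m = pf.match(np.array([100, 300]), ref, tolerance=5)
        assert (m.TP, m.FN, m.FP) == (2, 0, 0)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    nd=st.integers(0, 25),
    nr=st.integers(0, 25),
    tol=st.integers(0, 40),
)
def test_matching_invariants(seed, nd, nr, tol):
    """Count conservation, FN/FP symmetry under swapping, and TP
    monotonicity in the tolerance."""
    rng = np.random.default_rng(seed)
    det = np.sort(rng.choice(2000, size=nd, replace=False))
    ref = np.sort(rng.choice(2000, size=nr, replace=False))
    m = pf.match(det, ref, tolerance=tol)
    assert m.TP + m.FN == nr
    assert m.TP + m.FP == nd
    swapped = pf.match(ref, det, tolerance=tol)
    assert (swapped.FN, swapped.FP) == (m.FP, m.FN)
    wider = pf.match(det, ref, tolerance=tol + 5)
    assert wider.TP >= m.TP


# Per-record (TP, FN, FP) counts of the full 82-record QT benchmark; their
# micro-average must reproduce the pooled totals row exactly.
QT_PER_RECORD_COUNTS = [
    ("sel100",1134,0,0), ("sel16420",1063,0,0), ("sel102",1088,0,0), ("sel16483",1087,0,0),
    ("sel103",1048,0,0), ("sel16539",922,0,0), ("sel104",1109,0,0), ("sel16773",1008,0,1),
    ("sel114",862,0,4), ("sel16786",925,0,0), ("sel116",1185,0,1), ("sel16795",761,0,0),
    ("sel117",766,0,0), ("sel17152",1628,0,0), ("sel123",756,0,0), ("sel17453",1047,0,0),
    ("sel213",1641,1,0), ("sele0104",804,0,0), ("sel221",1236,11,0), ("sele0106",896,0,3),
    ("sel223",1308,1,0), ("sele0107",812,0,4), ("sel230",1077,0,0), ("sele0110",872,0,4),
    ("sel231",732,0,0), ("sele0111",907,0,0), ("sel232",865,0,2), ("sele0112",684,0,1),
    ("sel233",1532,1,0), ("sele0114",698,1,0), ("sel301",1351,0,2), ("sele0116",558,0,4),
    ("sel302",1500,0,1), ("sele0121",1429,7,1), ("sel306",1040,0,0), ("sele0122",1414,1,0),
    ("sel307",853,0,0), ("sele0124",1121,0,0), ("sel308",1289,5,12), ("sele0126",945,0,1),
    ("sel310",2012,0,0), ("sele0129",670,1,29), ("sel803",1026,0,0), ("sele0133",840,0,0),
    ("sel808",903,0,3), ("sele0136",809,0,0), ("sel811",704,0,0), ("sele0166",813,0,0),
    ("sel820",1159,0,0), ("sele0170",897,0,0), ("sel821",1557,0,0), ("sele0203",1246,0,6),
    ("sel840",1180,0,0), ("sele0210",1063,0,0), ("sel847",801,0,12), ("sele0211",1575,0,0),
    ("sel853",1113,0,0), ("sele0303",1044,1,2), ("sel871",917,0,1), ("sele0405",1216,0,0),
    ("sel872",990,0,0), ("sele0406",959,0,0), ("sel873",859,0,0), ("sele0409",1737,0,0),
    ("sel883",892,0,1), ("sele0411",1202,0,1), ("sel891",1267,0,3), ("sele0509",1028,0,0),
    ("sel14046",1259,1,0), ("sele0603",869,1,0), ("sel14157",1081,0,0), ("sele0604",1031,0,0),
    ("sel14172",663,0,0), ("sele0606",1442,0,0), ("sel15814",1028,8,4), ("sele0607",1184,0,1),
    ("sel16265",1031,0,0), ("sele0609",1126,1,0), ("sel16272",851,0,0), ("sele0612",751,0,0),
    ("sel16273",1112,0,0), ("sele0704",1093,1,1),
]


class TestPoolFullDatabase:
    def test_pooling_82_qt_records_reproduces_totals(self):
        results = [
            pf.metrics(MatchResult(TP=tp, FN=fn, FP=fp), record_id=name)
            for name, tp, fn, fp in QT_PER_RECORD_COUNTS
        ]
        pooled = pf.pool(results)
        assert pooled.counts == MatchResult(TP=86_953, FN=42, FP=105)
        assert round(pooled.S, 2) == 99.95
        assert round(pooled.P, 2) == 99.88
        assert round(pooled.DER, 2) == 0.17
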