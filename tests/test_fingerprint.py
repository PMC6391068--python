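import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enscircuit.fingerprint import (
    SignatureRecord,
    amplitude_ratio,
    build_aot,
    classify_signature,
    ratio_histogram,
    summarize_classes,
)
from enscircuit.transients import NeuronResponse, RecordingMovie, RoiEllipse, StimEpoch


def _record(ratio=None, cls="III", prep_id=0, condition="Ctrl-Ctrl"):
    return SignatureRecord(0, 0.4, 0.4, ratio, cls, condition, prep_id)


class TestAmplitudeRatio:
    def test_basic_quotient(self):
        assert amplitude_ratio(0.4, 0.2) == pytest.approx(0.5)

    def test_identity(self):
        assert amplitude_ratio(0.3, 0.3) == pytest.approx(1.0)

    def test_zero_es1_inconsistent(self):
        with pytest.raises(ValueError):
            amplitude_ratio(0.0, 0.2)


class TestClassifySignature:
    @pytest.mark.parametrize(
        "r1, r2, ratio, expected",
        [
            (True, False, None, "I"),
            (False, True, None, "V"),
            (True, True, 0.5, "II"),
            (True, True, 1.0, "III"),
            (True, True, 0.8, "III"),  # boundary values belong to "unchanged"
            (True, True, 1.2, "III"),
            (True, True, 1.5, "IV"),
        ],
    )
    def test_five_class_partition(self, r1, r2, ratio, expected):
        assert classify_signature(r1, r2, ratio) == expected

    def test_double_non_responder_rejected(self):
        with pytest.raises(ValueError):
            classify_signature(False, False)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=100.0, allow_nan=False))
    def test_every_ratio_gets_exactly_one_class(self, ratio):
        assert classify_signature(True, True, ratio) in {"II", "III", "IV"}


class TestBuildAot:
    def _movie_and_rois(self):
        movie = RecordingMovie(
            np.ones((6, 30, 30)), 2.0, 1.0, [StimEpoch(2, 3)]
        )
        rois = [
            RoiEllipse(0, (10.0, 10.0), 8.0, 6.0),
            RoiEllipse(1, (12.0, 10.0), 8.0, 6.0),  # overlaps roi 0
        ]
        return movie, rois

    def test_responder_pixels_carry_amplitude(self):
        movie, rois = self._movie_and_rois()
        resp = [NeuronResponse(0, 0, 1.0, np.ones(6), 0.4, True)]
        aot = build_aot(movie, resp, rois, 0)
        assert aot.max() == pytest.approx(0.4)
        assert np.allclose(aot[aot > 0], 0.4)

    def test_no_responders_all_zero(self):
        movie, rois = self._movie_and_rois()
        resp = [NeuronResponse(0, 0, 1.0, np.ones(6), 0.01, False)]
        assert build_aot(movie, resp, rois, 0).max() == 0.0

    def test_overlap_takes_max(self):
        movie, rois = self._movie_and_rois()
        resp = [
            NeuronResponse(0, 0, 1.0, np.ones(6), 0.3, True),
            NeuronResponse(1, 0, 1.0, np.ones(6), 0.5, True),
        ]
        aot = build_aot(movie, resp, rois, 0)
        # pixels covered by both ellipses show the larger amplitude
        assert aot[10, 11] == pytest.approx(0.5)

    def test_epoch_out_of_range(self):
        movie, rois = self._movie_and_rois()
        with pytest.raises(IndexError):
            build_aot(movie, [], rois, 3)


class TestRatioHistogram:
    def test_binning_by_0p2(self):
        records = [_record(r) for r in (0.5, 1.0, 1.0, 1.5)]
        hist = ratio_histogram(records)
        by_edge = dict(zip(np.round(hist.edges, 10), hist.percentages))
        assert by_edge[0.4] == pytest.approx(25.0)
        assert by_edge[1.0] == pytest.approx(50.0)
        assert by_edge[1.4] == pytest.approx(25.0)

    def test_blocked_categorical_bin(self):
        hist = ratio_histogram([_record(None, "I")])
        assert hist.blocked_pct == 100.0
        assert hist.percentages.sum() == 0.0

    def test_boundary_ratio_falls_in_upper_bin(self):
        hist = ratio_histogram([_record(0.8)])
        idx = int(np.argmax(hist.percentages))
        assert hist.edges[idx] == pytest.approx(0.8)

    def test_cap_pools_large_ratios(self):
        hist = ratio_histogram([_record(7.0)])
        assert hist.percentages[-1] == 100.0

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        records = [_record(float(r)) for r in rng.uniform(0.05, 3.0, 50)]
        records += [_record(None, "I"), _record(None, "V")]
        assert ratio_histogram(records).total_pct == pytest.approx(100.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ratio_histogram([])


class TestSummarizeClasses:
    def test_single_preparation_fraction(self):
        records = [_record(None, "I")] * 3 + [_record(1.0, "III")] * 7
        df = summarize_classes(records)
        blocked = df[df.cls == "I"].iloc[0]
        assert blocked.mean_pct == pytest.approx(30.0)

    def test_sem_across_preparations(self):
        records = [_record(None, "I", prep_id=0)] + [_record(1.0, "III", prep_id=0)] * 9
        records += [_record(None, "I", prep_id=1)] * 3 + [_record(1.0, "III", prep_id=1)] * 7
        df = summarize_classes(records)
        blocked = df[df.cls == "I"].iloc[0]
        assert blocked.mean_pct == pytest.approx(20.0)
        assert blocked.sem_pct == pytest.approx(10.0)

    def test_class_counts_partition_responders(self, noise_free_small):
        records = noise_free_small["records"]
        df = summarize_classes(records)
        assert df.mean_pct.sum() == pytest.approx(100.0)
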