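"""Decoder training, bounded scoring, arbitration and accuracy statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from gripdecode import decoder as dec
from gripdecode.features import FeatureMatrix
from gripdecode.synth import REST, CueSchedule


def _schedule(labels_durs):
    labels, durs = zip(*labels_durs)
    ends = np.cumsum(durs).astype(float)
    return CueSchedule(tuple(labels), ends - np.asarray(durs, float), ends)


def _trace(times, states, movements):
    scores = np.zeros((len(times), len(movements)))
    for i, s in enumerate(states):
        if s != REST:
            scores[i, movements.index(s)] = 0.5
    return dec.DecodeTrace(np.asarray(times, float), scores,
                           np.asarray(states, dtype=object), tuple(movements))


class TestAssembleTrainingSet:
    def test_bin_takes_label_of_containing_interval(self):
        sched = _schedule([(REST, 1.0), ("peg", 1.0), (REST, 1.0)])
        fm = FeatureMatrix(np.array([0.95, 1.0, 1.95, 2.0]),
                           np.zeros((4, 96)))
        lb = dec.assemble_training_set(fm, sched)
        # half-open [start, end): a bin starting exactly at a boundary
        # belongs to the interval that begins there
        assert list(lb.labels) == [REST, "peg", "peg", REST]

    def test_bin_outside_schedule_is_rest(self):
        sched = _schedule([("peg", 1.0)])
        fm = FeatureMatrix(np.array([0.5, 5.0]), np.zeros((2, 96)))
        lb = dec.assemble_training_set(fm, sched)
        assert list(lb.labels) == ["peg", REST]

    def test_block_bin_count_matches_enumeration(self, sim3k, default_session):
        """7 movements x 3 cues x ~3.5 s at 10 bins/s -> ~735 movement bins."""
        schedules, fms, _ = default_session
        counts = []
        for sched, fm in zip(schedules, fms):
            labels = sched.labels_for_times(fm.bin_starts_s)
            counts.append(int(np.sum(labels != REST)))
            # oracle: direct enumeration of bin starts inside movement cues
            expect = sum(
                int(np.sum((fm.bin_starts_s >= s) & (fm.bin_starts_s < e)))
                for lab, s, e in zip(sched.labels, sched.starts, sched.ends)
                if lab != REST
            )
            assert counts[-1] == expect
        assert 600 <= np.mean(counts) <= 870      # 735 +/- cue-length spread

    def test_eight_states_present(self, sim3k, default_session):
        schedules, fms, _ = default_session
        labels = schedules[0].labels_for_times(fms[0].bin_starts_s)
        assert set(labels) == set(sim3k.movements) | {REST}


class TestTrain:
    def test_training_set_accuracy_high_on_separable_fixture(
            self, sim3k, short_session, short_model):
        schedules, fms, _ = short_session
        for sched, fm in zip(schedules[:2], fms[:2]):
            trace = dec.decode(short_model, fm)
            for m in sim3k.movements:
                assert dec.individual_accuracy(trace, sched, m) >= 99.0

    def test_missing_movement_rejected(self, short_session):
        _, fms, _ = short_session
        y = np.full(fms[0].n_bins, REST, dtype=object)
        y[:20] = "peg"
        with pytest.raises(dec.DecoderError, match="hand_open"):
            dec.train(dec.LabeledBins(fms[0], y),
                      movements=("peg", "hand_open"))

    def test_binary_reduction_single_movement(self, sim3k, short_session):
        """One movement vs rest behaves as a detector for that movement."""
        schedules, fms, _ = short_session
        y = schedules[0].labels_for_times(fms[0].bin_starts_s)
        y = np.where(y == "peg", "peg", REST).astype(object)
        model = dec.train(dec.LabeledBins(fms[0], y), movements=("peg",))
        trace = dec.decode(model, fms[0])
        cue = schedules[0].labels_for_times(fms[0].bin_starts_s)
        on_peg = np.mean(trace.states[cue == "peg"] == "peg")
        on_other = np.mean(trace.states[cue != "peg"] == "peg")
        assert on_peg > 0.9 and on_other < 0.05

    def test_determinism(self, sim3k, short_session):
        schedules, fms, _ = short_session
        y = schedules[0].labels_for_times(fms[0].bin_starts_s)
        lb = dec.LabeledBins(fms[0], y)
        m1 = dec.train(lb, movements=sim3k.movements, seed=3)
        m2 = dec.train(lb, movements=sim3k.movements, seed=3)
        X = fms[0].values[:50]
        assert np.array_equal(dec.score_bins(m1, X), dec.score_bins(m2, X))


class TestScoring:
    def test_scores_bounded(self, short_model):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((1000, 96)) * 10
        s = dec.score_bins(short_model, X)
        assert np.all(np.abs(s) <= 1.0)

    def test_prototype_scores_own_class_highest(self, sim3k, short_session,
                                                short_model):
        schedules, fms, _ = short_session
        cue = schedules[2].labels_for_times(fms[2].bin_starts_s)
        for k, m in enumerate(sim3k.movements):
            proto = fms[2].values[cue == m].mean(axis=0)
            s = dec.score_bin(short_model, proto)
            assert short_model.movements[int(np.argmax(s))] == m

    def test_nonfinite_input_rejected(self, short_model):
        bad = np.full(96, np.nan)
        with pytest.raises(dec.DecoderError):
            dec.score_bin(short_model, bad)


class TestArbitrate:
    MOVS = ("a", "b", "c")

    def test_all_nonpositive_gives_rest(self):
        assert dec.arbitrate(np.array([-0.1, 0.0, -1.0]), self.MOVS) == REST

    def test_highest_positive_wins(self):
        assert dec.arbitrate(np.array([0.4, 0.7, -0.2]), self.MOVS) == "b"

    def test_tie_goes_to_first_label(self):
        assert dec.arbitrate(np.array([0.5, 0.5, 0.1]), self.MOVS) == "a"

    @given(hnp.arrays(float, 3, elements=st.floats(-1, 1)))
    @settings(max_examples=200, deadline=None)
    def test_exclusivity(self, scores):
        out = dec.arbitrate(scores, self.MOVS)
        assert out in self.MOVS or out == REST
        if out != REST:
            assert scores[self.MOVS.index(out)] > 0


class TestAccuracy:
    def test_perfect_decode_is_100(self):
        sched = _schedule([(REST, 0.5), ("a", 0.5), (REST, 0.5)])
        times = np.arange(15) * 0.1
        states = sched.labels_for_times(times)
        trace = _trace(times, states, ["a"])
        assert dec.individual_accuracy(trace, sched, "a") == 100.0

    def test_always_rest_counting_oracle(self):
        """Decoder stuck at rest, movement cued 10% of bins -> 90%."""
        sched = _schedule([("a", 1.0), (REST, 9.0)])
        times = np.arange(100) * 0.1
        trace = _trace(times, [REST] * 100, ["a"])
        assert dec.individual_accuracy(trace, sched, "a") == pytest.approx(90.0)

    def test_accuracy_100_iff_indicators_identical(self):
        sched = _schedule([("a", 1.0), (REST, 1.0)])
        times = np.arange(20) * 0.1
        states = list(sched.labels_for_times(times))
        states[3] = REST                     # one disagreement
        trace = _trace(times, states, ["a"])
        assert dec.individual_accuracy(trace, sched, "a") == pytest.approx(95.0)

    def test_absent_movement_rejected(self):
        sched = _schedule([(REST, 1.0)])
        trace = _trace([0.0], [REST], ["a"])
        with pytest.raises(dec.DecoderError):
            dec.individual_accuracy(trace, sched, "a")


class TestResponseProbabilities:
    def test_perfect_decode_identity_rows(self):
        sched = _schedule([("a", 1.0), (REST, 1.0), ("b", 1.0)])
        times = np.arange(30) * 0.1
        trace = _trace(times, sched.labels_for_times(times), ["a", "b"])
        summ = dec.response_probabilities(trace, sched)
        assert np.allclose(summ.response_probability.to_numpy(), np.eye(2))

    def test_mixed_activation_tally(self):
        """9 active bins of A and 1 of B inside A's cue -> row (0.9, 0.1)."""
        sched = _schedule([("a", 1.0)])
        times = np.arange(10) * 0.1
        states = ["a"] * 9 + ["b"]
        trace = _trace(times, states, ["a", "b"])
        summ = dec.response_probabilities(trace, sched)
        assert summ.response_probability.loc["a", "a"] == pytest.approx(0.9)
        assert summ.response_probability.loc["a", "b"] == pytest.approx(0.1)

    def test_rows_sum_to_one(self, sim3k, short_session, short_model):
        schedules, fms, _ = short_session
        trace = dec.decode(short_model, fms[2])
        summ = dec.response_probabilities(trace, schedules[2])
        sums = summ.response_probability.dropna().sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_cue_without_activation_flagged(self):
        sched = _schedule([("a", 1.0), ("b", 1.0)])
        times = np.arange(20) * 0.1
        states = [REST] * 10 + ["b"] * 10
        trace = _trace(times, states, ["a", "b"])
        summ = dec.response_probabilities(trace, sched)
        assert summ.undefined_cues == ("a",)
        assert summ.response_probability.loc["a"].isna().all()
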