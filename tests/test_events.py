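"""Epoch features, threshold decay and the event-labeling rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ergoload.emg import MuscleThresholds, RmsSeries
from ergoload.errors import ConfigurationError
from ergoload.events import (
    EpochFeatures,
    count_events,
    epoch_features,
    export_event_log,
    label_events,
    modified_threshold,
)
from ergoload.kinematics import InclinationSeries
from oracles import naive_label_events

MUSCLES = ["TrpR", "TrpL", "ESR", "ESL"]


def make_thresholds(base=100.0):
    ref = {m: float(base) for m in MUSCLES}
    return MuscleThresholds(
        muscles=list(MUSCLES),
        mve_mv={m: 4 * base for m in MUSCLES},
        ref_p90_mv={m: {"morning": base} for m in MUSCLES},
        base={
            "ref100": dict(ref),
            "ref150": {m: 1.5 * base for m in MUSCLES},
            "mvc50": {m: 2.0 * base for m in MUSCLES},
        },
    )


def feat(levels, fwd=0.0, side=0.0, valid=True, idx=0):
    return EpochFeatures(
        epoch_index=idx,
        start_s=idx * 10.0,
        p90_rms_mv={m: float(v) for m, v in zip(MUSCLES, levels)},
        fwd_deg=fwd,
        side_deg=side,
        valid=valid,
    )


def constant_rms(level, duration_s, step_s=0.4):
    t = np.arange(0.0, duration_s, step_s)
    return {m: RmsSeries(values=np.full(len(t), level), times=t) for m in MUSCLES}


def flat_incl(duration_s, fs=100.0, fwd=None):
    n = int(duration_s * fs)
    f = np.zeros(n) if fwd is None else fwd
    return InclinationSeries(
        times=np.arange(n) / fs,
        forward_deg=f,
        sideways_deg=np.zeros(n),
        total_deg=np.abs(f),
        valid=np.ones(n, dtype=bool),
        fs=fs,
    )


class TestEpochFeatures:
    def test_thirty_seconds_three_epochs(self):
        feats = epoch_features(constant_rms(5.0, 30.0), flat_incl(30.0), (0.0, 30.0))
        assert len(feats) == 3
        for f in feats:
            assert f.valid
            assert all(v == pytest.approx(5.0) for v in f.p90_rms_mv.values())
            assert f.fwd_deg == 0.0 and f.side_deg == 0.0

    def test_trailing_partial_epoch_dropped(self):
        feats = epoch_features(constant_rms(5.0, 38.0), flat_incl(38.0), (0.0, 38.0))
        assert len(feats) == 3

    def test_inclination_p90_captures_brief_flexion(self):
        """9 s at 0 degrees and 1 s at 90: the P90 summary lands on 90."""
        fs = 100.0
        fwd = np.zeros(int(10 * fs))
        fwd[-int(1 * fs):] = 90.0
        feats = epoch_features(constant_rms(5.0, 10.0), flat_incl(10.0, fs, fwd), (0.0, 10.0))
        assert feats[0].fwd_deg == pytest.approx(90.0)

    def test_too_few_rms_windows_invalidates(self):
        t = np.array([0.0, 0.4, 0.8])  # only 3 windows in the epoch
        rms = {m: RmsSeries(values=np.full(3, 5.0), times=t) for m in MUSCLES}
        feats = epoch_features(rms, flat_incl(10.0), (0.0, 10.0))
        assert not feats[0].valid

    def test_empty_interval(self):
        assert epoch_features(constant_rms(5.0, 10.0), None, (10.0, 10.0)) == []


class TestModifiedThreshold:
    @pytest.mark.parametrize(
        "fwd,side,expected",
        [
            (0.0, 0.0, 100.0),
            (90.0, 0.0, 50.0),
            (120.0, 0.0, 50.0),
            (45.0, 0.0, 75.0),
            (45.0, 15.0, 75.0),
            (0.0, 30.0, 50.0),
            (0.0, 45.0, 50.0),
            (-45.0, 0.0, 75.0),
        ],
    )
    def test_closed_form(self, fwd, side, expected):
        assert modified_threshold(100.0, fwd, side) == expected

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            modified_threshold(0.0, 10.0, 10.0)

    @given(st.floats(1e-3, 1e3), st.floats(-180, 180), st.floats(-180, 180))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_monotonicity(self, base, fwd, side):
        t = modified_threshold(base, fwd, side)
        assert base / 2 - 1e-12 <= t <= base + 1e-12
        # more inclination never raises the threshold
        t2 = modified_threshold(base, min(abs(fwd) * 1.5, 180), side)
        assert t2 <= t + 1e-12


class TestLabelEvents:
    def test_all_below_no_event(self):
        es = label_events([feat([50, 50, 50, 50])], make_thresholds(), "ref100")
        assert es.count == 0

    def test_two_muscle_rule(self):
        es = label_events([feat([110, 110, 50, 50])], make_thresholds(), "ref100")
        assert es.count == 1 and es.rule_trace[0] == "two_muscle"

    def test_single_muscle_insufficient(self):
        es = label_events([feat([110, 50, 50, 50])], make_thresholds(), "ref100")
        assert es.count == 0

    def test_modified_es_rule_under_flexion(self):
        # ESR at 60 % of base is below base but above the half threshold at 90 deg
        es = label_events([feat([50, 50, 60, 50], fwd=90.0)], make_thresholds(), "ref100")
        assert es.count == 1 and es.rule_trace[0] == "modified_es"

    def test_modified_rule_disabled_by_switch(self):
        es = label_events(
            [feat([50, 50, 60, 50], fwd=90.0)], make_thresholds(), "ref100",
            two_muscle_rule_only=True,
        )
        assert es.count == 0

    def test_tie_is_not_event(self):
        es = label_events([feat([100, 100, 100, 100])], make_thresholds(), "ref100")
        assert es.count == 0

    def test_invalid_epoch_never_event(self):
        es = label_events([feat([500, 500, 500, 500], valid=False)], make_thresholds(), "ref100")
        assert es.count == 0 and es.n_valid == 0

    def test_missing_threshold_raises(self):
        th = make_thresholds()
        del th.base["ref100"]["ESL"]
        with pytest.raises(ConfigurationError):
            label_events([feat([0, 0, 0, 0])], th, "ref100")


@st.composite
def feature_tables(draw):
    n = draw(st.integers(1, 30))
    feats = []
    for i in range(n):
        levels = [draw(st.floats(0, 250)) for _ in MUSCLES]
        feats.append(
            feat(
                levels,
                fwd=draw(st.floats(-180, 180)),
                side=draw(st.floats(0, 180)),
                valid=draw(st.booleans()),
                idx=i,
            )
        )
    return feats


class TestRuleProperties:
    @given(feature_tables(), st.sampled_from(["ref100", "ref150", "mvc50"]), st.booleans())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_oracle_equivalence(self, feats, mode, only_two):
        """label_events agrees epoch-for-epoch with the naive reimplementation."""
        th = make_thresholds()
        es = label_events(feats, th, mode, two_muscle_rule_only=only_two)
        assert list(es.labels) == naive_label_events(feats, th, mode, only_two)

    @given(feature_tables())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mode_ordering(self, feats):
        """Under shared calibration, ref150 events are a subset of ref100 events."""
        th = make_thresholds()
        e100 = label_events(feats, th, "ref100").labels
        e150 = label_events(feats, th, "ref150").labels
        assert not (e150 & ~e100).any()

    @given(feature_tables(), st.floats(1.0, 3.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_amplitude_and_inclination(self, feats, factor):
        """Raising amplitudes or inclination never cancels an event."""
        th = make_thresholds()
        before = label_events(feats, th, "ref100").labels
        boosted = [
            feat(
                [f.p90_rms_mv[m] * factor for m in MUSCLES],
                fwd=min(abs(f.fwd_deg) * factor, 180),
                side=min(f.side_deg * factor, 180),
                valid=f.valid,
                idx=f.epoch_index,
            )
            for f in feats
        ]
        after = label_events(boosted, th, "ref100").labels
        assert not (before & ~after).any()


class TestCountAndExport:
    def test_count_and_rate(self):
        feats = [feat([110, 110, 0, 0], idx=i) for i in range(3)]
        feats += [feat([0, 0, 0, 0], idx=i + 3) for i in range(357)]
        es = label_events(feats, make_thresholds(), "ref100")
        n, rate = count_events(es)
        assert n == 3 and rate == pytest.approx(3.0)  # 360 epochs = 1 h

    def test_empty_series(self):
        es = label_events([], make_thresholds(), "ref100")
        assert count_events(es) == (0, 0.0)

    def test_export_rows_and_trace(self, tmp_path):
        feats = [
            feat([110, 110, 0, 0], idx=0),
            feat([0, 0, 0, 0], idx=1),
            feat([0, 0, 60, 0], fwd=90.0, idx=2),
        ]
        th = make_thresholds()
        es = label_events(feats, th, "ref100")
        out = tmp_path / "events.csv"
        export_event_log(es, feats, out, th)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 events
        assert lines[1].startswith("0.0,ref100,two_muscle")
        assert "modified_es" in lines[2]

    def test_no_events_header_only(self, tmp_path):
        feats = [feat([0, 0, 0, 0])]
        es = label_events(feats, make_thresholds(), "ref100")
        out = tmp_path / "events.csv"
        export_event_log(es, feats, out)
        assert len(out.read_text().strip().splitlines()) == 1
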