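"""Gesture taxonomy, stroke segmentation, rule-based coding and sheets."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from touchtrace import synthetic
from touchtrace.state_table import expand
from touchtrace.tpa_coding import (
    ADMISSIBLE_SCALES,
    ActionLabel,
    GestureCode,
    Hand,
    RuleParams,
    TimeScale,
    auto_code,
    classify_duration,
    classify_stroke,
    detailed_coding,
    detect_inter_stroke,
    detect_span,
    export_coding,
    first_pass_coding,
    gesture_time_budget,
    import_coding,
    is_admissible,
    mins_secs,
    segment_strokes,
)


class TestTimeScale:
    @pytest.mark.parametrize(
        "d,expected",
        [
            (300, TimeScale.SHORT),
            (499, TimeScale.SHORT),
            (500, TimeScale.MEDIUM),  # boundary inclusive
            (2000, TimeScale.MEDIUM),  # boundary inclusive
            (2001, TimeScale.LONG),
            (60000, TimeScale.LONG),
        ],
    )
    def test_thresholds(self, d, expected):
        assert classify_duration(d) is expected

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            classify_duration(-1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e7, allow_nan=False))
    def test_classes_partition_positive_durations(self, d):
        assert classify_duration(d) in TimeScale

    def test_every_label_has_admissible_scales(self):
        for label in ActionLabel:
            assert ADMISSIBLE_SCALES[label]
        assert is_admissible(ActionLabel.TAP, 80)
        assert not is_admissible(ActionLabel.FIX, 80)
        assert is_admissible(ActionLabel.TRACE, 5000)


class TestSegmentation:
    def render(self, stim, script, sigma=0.0):
        log, truth = synthetic.render_script(script, stim, jitter_sigma=sigma, seed=3)
        return expand(log), truth

    def test_down_moves_up_is_one_stroke(self, stim_aois):
        stim, _ = stim_aois
        rows, _ = self.render(stim, [synthetic.Primitive("fix", ("SQUARE-A",), 1000, 200)])
        strokes = segment_strokes(rows)
        assert len(strokes) == 1
        assert strokes[0].duration == 200

    def test_id_reuse_gives_two_strokes(self, stim_aois):
        stim, _ = stim_aois
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 300),
            synthetic.Primitive("fix", ("SQUARE-B",), 3000, 300),
        ]
        rows, _ = self.render(stim, script)
        strokes = segment_strokes(rows)
        # two disjoint runs of the same ID are two separate touches
        assert len(strokes) == 2
        assert strokes[0].input_id == strokes[1].input_id == 0

    def test_overload_closes_and_flags_stroke(self, stim_aois):
        stim, _ = stim_aois
        log, _ = synthetic.render_script(
            [synthetic.Primitive("fix", ("SQUARE-A",), 1000, 2000)], stim
        )
        log = synthetic.inject_overload(log, at=1800, duration=300)
        strokes = segment_strokes(expand(log))
        assert len(strokes) == 2
        assert strokes[0].overload_closed and not strokes[1].overload_closed

    def test_path_length_bounds_net_displacement(self, demo_corpus):
        _stim, _aois, _log, _truth, rows = demo_corpus
        for s in segment_strokes(rows):
            assert s.path_length >= s.net_displacement - 1e-9
            assert s.duration >= 0


class TestClassifier:
    def classify_primitive(self, stim_aois, kind, targets, duration, **kw):
        stim, aois = stim_aois
        script = [synthetic.Primitive(kind, targets, 1000, duration, **kw)]
        log, _ = synthetic.render_script(script, stim, jitter_sigma=0.0)
        strokes = segment_strokes(expand(log))
        assert len(strokes) >= 1
        return classify_stroke(strokes[0], aois)

    def test_perimeter_following_is_trace(self, stim_aois):
        label, _ = self.classify_primitive(stim_aois, "trace", ("SQUARE-A",), 1200)
        assert label is ActionLabel.TRACE

    def test_back_and_forth_is_brush(self, stim_aois):
        label, _ = self.classify_primitive(stim_aois, "brush", ("PENTAGON-A",), 1000)
        assert label is ActionLabel.BRUSH

    def test_momentary_point_touch_is_tap(self, stim_aois):
        label, conf = self.classify_primitive(stim_aois, "tap", ("Circle-a",), 80)
        assert label is ActionLabel.TAP and conf > 0.9

    def test_stationary_hold_is_fix(self, stim_aois):
        label, _ = self.classify_primitive(stim_aois, "fix", ("SQUARE-B",), 1500)
        assert label is ActionLabel.FIX

    def test_direct_between_objects_is_slide_to(self, stim_aois):
        label, _ = self.classify_primitive(
            stim_aois, "slide_to", ("SQUARE-A", "TRIANGLE-A"), 450
        )
        assert label is ActionLabel.SLIDE_TO

    def test_ordered_traversal_with_pauses_is_scan(self, stim_aois):
        label, _ = self.classify_primitive(
            stim_aois, "scan", ("SQUARE-A", "TRIANGLE-A", "Circle-a"), 1800
        )
        assert label is ActionLabel.SCAN

    def test_empty_stroke_rejected(self, stim_aois):
        from touchtrace.tpa_coding import Stroke

        _stim, aois = stim_aois
        with pytest.raises(ValueError):
            classify_stroke(Stroke(input_id=0, samples=[]), aois)


class TestInterStroke:
    def events_for(self, stim_aois, script):
        stim, aois = stim_aois
        log, _ = synthetic.render_script(script, stim, jitter_sigma=0.0)
        strokes = segment_strokes(expand(log))
        return detect_inter_stroke(strokes, aois)

    def test_short_gap_to_other_cell_is_jump(self, stim_aois):
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 600),
            synthetic.Primitive("fix", ("TRIANGLE-B",), 1800, 600),  # 200 ms airborne
        ]
        events = self.events_for(stim_aois, script)
        assert [e.label for e in events] == [ActionLabel.JUMP_TO]
        assert events[0].duration == 200

    def test_long_lift_same_object_is_hover(self, stim_aois):
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 600),
            synthetic.Primitive("fix", ("SQUARE-A",), 2500, 600),  # 900 ms, no translation
        ]
        events = self.events_for(stim_aois, script)
        assert [e.label for e in events] == [ActionLabel.HOVER]

    def test_very_long_gap_is_indeterminate_candidate(self, stim_aois):
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 600),
            synthetic.Primitive("fix", ("Circle-a",), 12000, 600),  # 10.4 s off-surface
        ]
        events = self.events_for(stim_aois, script)
        assert len(events) == 1
        assert events[0].label is None  # park vs break unobservable from the log
        assert "unobservable" in events[0].note


class TestSpan:
    def test_anchor_plus_stretch_is_span(self, stim_aois):
        stim, aois = stim_aois
        script = [synthetic.Primitive("span", ("SQUARE-A", "TRIANGLE-A"), 1000, 550,
                                      digit=0, digit2=1)]
        log, _ = synthetic.render_script(script, stim)
        spans = detect_span(segment_strokes(expand(log)), aois)
        assert len(spans) == 1
        assert spans[0].anchor_id != spans[0].mover_id

    def test_two_distant_digits_no_span(self, stim_aois):
        stim, aois = stim_aois
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 800, digit=0),
            synthetic.Primitive("slide_to", ("PENTAGON-B", "Diamond-a"), 1200, 450, digit=1),
        ]
        log, _ = synthetic.render_script(script, stim)
        assert detect_span(segment_strokes(expand(log)), aois) == []

    def test_single_stroke_never_span(self, stim_aois):
        stim, aois = stim_aois
        script = [synthetic.Primitive("slide_to", ("SQUARE-A", "TRIANGLE-A"), 1000, 450)]
        log, _ = synthetic.render_script(script, stim)
        assert detect_span(segment_strokes(expand(log)), aois) == []


class TestFirstPass:
    def test_boundaries_coincide_with_occupancy_changes(self, demo_corpus):
        """Line starts must equal the brute-force AOI change points."""
        _stim, aois, _log, _truth, rows = demo_corpus
        from touchtrace.geometry import assign_aoi

        codes = first_pass_coding(rows, aois)
        occ_prev, change_points = None, []
        for row in rows:
            occ = frozenset(
                (cell.object_name, cell.location)
                for d in row.digits_in_use()
                if (cell := assign_aoi(aois, row.positions[d])) is not None
            )
            if occ != occ_prev:
                change_points.append((row.t, occ))
                occ_prev = occ
        # a zero-length empty change at the very last row closes the
        # protocol rather than opening a line
        if change_points and change_points[-1] == (rows[-1].t, frozenset()):
            change_points.pop()
        assert [c.time for c in codes] == [t for t, _ in change_points]

    def test_lifting_all_digits_starts_a_new_line(self, stim_aois):
        stim, aois = stim_aois
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 500),
            synthetic.Primitive("fix", ("SQUARE-A",), 2500, 500),
        ]
        log, _ = synthetic.render_script(script, stim)
        codes = first_pass_coding(expand(log), aois)
        objects = [c.object_name for c in codes]
        assert objects == ["SQUARE-A", "", "SQUARE-A"]  # empty line while lifted

    def test_two_simultaneous_objects_on_one_line(self, stim_aois):
        stim, aois = stim_aois
        script = [
            synthetic.Primitive("fix", ("SQUARE-A",), 1000, 800, digit=0),
            synthetic.Primitive("fix", ("PENTAGON-A",), 1000, 800, digit=1),
        ]
        log, _ = synthetic.render_script(script, stim)
        codes = first_pass_coding(expand(log), aois)
        both = [c for c in codes if "+" in c.object_name]
        assert both and both[0].object_name == "SQUARE-A+PENTAGON-A"
        assert both[0].location == ((1, 1), (2, 1))

    def test_single_dwell_single_line(self, stim_aois):
        stim, aois = stim_aois
        log, _ = synthetic.render_script(
            [synthetic.Primitive("fix", ("SQUARE-A",), 1000, 900)], stim
        )
        codes = first_pass_coding(expand(log), aois)
        assert len(codes) == 1
        assert codes[0].duration == 900


class TestDetailed:
    def test_levels_from_spatial_extent(self, stim_aois):
        stim, aois = stim_aois
        script = [
            synthetic.Primitive("trace", ("SQUARE-A",), 1000, 1200),  # whole shape
            synthetic.Primitive("trace", ("SQUARE-B",), 4000, 800, fraction=0.3),  # part
            synthetic.Primitive("fix", ("PENTAGON-A",), 7000, 900),  # one spot
        ]
        log, _ = synthetic.render_script(script, stim)
        rows = expand(log)
        codes = detailed_coding(rows, aois, [(0, 10000)])
        by_obj = {c.object_name: c for c in codes if c.action is ActionLabel.TRACE}
        assert by_obj["SQUARE-A"].level == 1  # whole perimeter
        assert by_obj["SQUARE-B"].level == 2  # part of the shape
        fix = [c for c in codes if c.action is ActionLabel.FIX][0]
        assert fix.level == 3  # an individual spot/edge only

    def test_codes_clip_to_parent_lines_with_continuation(self, demo_corpus):
        _stim, aois, _log, _truth, rows = demo_corpus
        first = first_pass_coding(rows, aois)
        span = (rows[0].t, rows[-1].t)
        codes = detailed_coding(rows, aois, [span], first_pass=first)
        for code in codes:
            parents = [l for l in first if l.time <= code.time and code.t_end <= l.t_end]
            assert parents, f"code at {code.time} extends outside its parent line"
        assert any(c.comment.startswith("//") for c in codes)  # continuations marked

    def test_selection_outside_span_rejected(self, demo_corpus):
        _stim, aois, _log, _truth, rows = demo_corpus
        with pytest.raises(ValueError, match="outside trial span"):
            detailed_coding(rows, aois, [(10**9, 10**9 + 1)])


class TestBudgetAndSheets:
    def make_codes(self):
        return [
            GestureCode(time=0, action=ActionLabel.TRACE, duration=30000),
            GestureCode(time=30000, action=ActionLabel.FIX, duration=10000),
        ]

    def test_single_label_is_all_of_budget(self):
        codes = [GestureCode(time=0, action=ActionLabel.BRUSH, duration=5000)]
        assert gesture_time_budget(codes) == {ActionLabel.BRUSH: 1.0}

    def test_thirty_plus_ten_in_forty(self):
        budget = gesture_time_budget(self.make_codes(), window=(0, 40000))
        assert budget[ActionLabel.TRACE] == pytest.approx(0.75)
        assert budget[ActionLabel.FIX] == pytest.approx(0.25)

    def test_empty_window_empty_budget(self):
        assert gesture_time_budget(self.make_codes(), window=(50000, 60000)) == {}

    def test_mins_secs_format(self):
        assert mins_secs(78000) == "1:18"
        assert mins_secs(0) == "0:00"
        assert mins_secs(191000) == "3:11"

    def test_export_import_round_trip(self, demo_codes):
        text = export_coding(demo_codes)
        back = import_coding(text)
        assert back == demo_codes
        assert len(text.splitlines()) == len(demo_codes) + 1

    def test_import_error_names_line(self):
        text = export_coding(self.make_codes())
        bad = text + "garbage\n"
        with pytest.raises(ValueError, match="line 4"):
            import_coding(bad)

    def test_hand_defaults_unknown(self, demo_codes):
        assert all(c.hand is Hand.UNKNOWN for c in demo_codes)


class TestRecovery:
    def score_at(self, stim, aois, sigma, seed=11):
        script = synthetic.build_demo_script(stim)
        log, truth = synthetic.render_script(script, stim, jitter_sigma=sigma, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            codes = auto_code(expand(log), aois)
        return synthetic.recovery_score(truth, codes), truth, codes

    def test_scripted_corpus_recovered_at_low_jitter(self, stim_aois):
        """trace/fix/tap/brush/slideTo/jumpTo/hover/span recovered >= 90%
        at jitter sigma <= 2 px."""
        stim, aois = stim_aois
        for sigma in (0.0, 2.0):
            score, _, _ = self.score_at(stim, aois, sigma)
            assert score >= 0.9

    def test_recovery_degrades_monotonically_with_jitter(self, stim_aois):
        stim, aois = stim_aois
        scores = [self.score_at(stim, aois, s)[0] for s in (0.0, 2.0, 8.0, 32.0)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_corpus_labels_admissible_time_scales(self, stim_aois):
        """On the scripted corpus every emitted label's duration falls in a
        class the taxonomy admits for that label."""
        stim, aois = stim_aois
        _, _, codes = self.score_at(stim, aois, 2.0)
        for code in codes:
            if code.action is None or not code.duration:
                continue
            assert is_admissible(code.action, code.duration), (code.action, code.duration)
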