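"""Position -> sound mapping: pitch ladder, board fields, event streams."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from moveson.simulate import Trajectory, gen_trajectory
from moveson.sonification import (DEFAULT_TUNING, FrameGeometry, TaskSpec,
                                  field_center, locate, map_pitch,
                                  note_height, sonify, sound_params,
                                  task_events)

GEOM = FrameGeometry()


def _flat_trajectory(y, x=10.0, z=10.0, duration=10.0, rate=60.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    arr = np.full_like(t, y) if np.isscalar(y) else np.asarray(y)
    return Trajectory(t=t, x=np.full_like(t, x), y=arr,
                      z=np.full_like(t, z), valid=np.ones_like(t, bool),
                      rate_hz=rate)


class TestPitchMapping:
    @pytest.mark.parametrize("height,expected_pitch,expected_freq", [
        (2.0, 1, 226.6),     # bottom interval plays c'
        (50.0, 6, 440.0),    # top interval plays a'
        (51.0, 6, 440.0),    # the very top is closed into interval 6
        (0.0, 1, 226.6),
        (8.5, 2, 293.66),    # boundaries are half-open [low, high)
    ])
    def test_height_to_pitch(self, height, expected_pitch, expected_freq):
        pitch, freq = map_pitch(height, GEOM, DEFAULT_TUNING)
        assert pitch == expected_pitch
        assert freq == pytest.approx(expected_freq)

    @pytest.mark.parametrize("height", [-0.1, 51.5, 1e6])
    def test_out_of_frame_heights_emit_nothing(self, height):
        assert map_pitch(height, GEOM) is None

    def test_tuning_table_must_be_increasing(self):
        with pytest.raises(ValueError, match="increasing"):
            map_pitch(10.0, GEOM, (440, 400, 350, 330, 290, 220))

    @given(st.floats(min_value=0.0, max_value=51.0,
                     allow_nan=False, allow_infinity=False))
    def test_every_in_frame_height_maps_to_one_interval(self, height):
        pitch, freq = map_pitch(height, GEOM)
        assert 1 <= pitch <= 6
        assert freq == DEFAULT_TUNING[pitch - 1]

    def test_frequency_monotone_in_pitch_index(self):
        freqs = [map_pitch(note_height(k), GEOM)[1] for k in range(1, 7)]
        assert freqs == sorted(freqs)
        assert len(set(freqs)) == 6


class TestLocate:
    def test_center_of_board_is_field_five(self):
        field, timbre, _ = locate((25.5, 0.0, 25.5), GEOM)
        assert field == 5
        assert timbre == "saxophone"

    @pytest.mark.parametrize("x,expected", [
        (5.0, "clarinet"), (25.0, "saxophone"), (45.0, "bowed")])
    def test_timbre_from_x_thirds(self, x, expected):
        assert locate((x, 0.0, 10.0), GEOM)[1] == expected

    def test_loudness_ramp(self):
        # proximal edge is loudest (0 dB), attenuation grows with z
        assert locate((10, 0, 0.0), GEOM)[2] == 0.0
        louds = [locate((10, 0, z), GEOM)[2] for z in (0, 10, 30, 51)]
        assert all(a > b for a, b in zip(louds, louds[1:]))
        assert louds[-1] == pytest.approx(-GEOM.loudness_range_db)

    def test_out_of_frame_positions(self):
        assert locate((-1.0, 0, 10.0), GEOM) is None
        assert locate((10.0, 0, 52.0), GEOM) is None

    def test_field_numbering_row_major(self):
        # field 1 near-left, field 3 near-right, field 9 far-right
        assert locate((5, 0, 5), GEOM)[0] == 1
        assert locate((45, 0, 5), GEOM)[0] == 3
        assert locate((45, 0, 45), GEOM)[0] == 9

    @given(st.floats(0, 51), st.floats(0, 51), st.floats(0, 51))
    def test_partition_every_position_has_one_triple(self, x, y, z):
        p = sound_params((x, y, z), GEOM)
        assert p is not None
        assert 1 <= p.field_index <= 9
        assert 1 <= p.pitch_index <= 6
        assert p.timbre_zone in ("clarinet", "saxophone", "bowed")
        assert p.loudness_db <= 0.0


class TestSonify:
    def test_full_vertical_sweep_yields_six_ascending_notes(self):
        y = np.linspace(0, 51, 1200)
        stream = sonify(_flat_trajectory(y, duration=20.0))
        assert len(stream) == 6
        freqs = stream.frequencies()
        assert freqs == sorted(freqs)
        assert stream.pitch_sequence() == [1, 2, 3, 4, 5, 6]

    def test_stationary_hand_sustains_one_event(self):
        stream = sonify(_flat_trajectory(20.0, duration=10.0))
        assert len(stream) == 1
        assert stream.events[0].duration_s == pytest.approx(10.0, abs=0.05)

    def test_empty_trajectory_gives_empty_stream(self):
        tr = Trajectory(t=np.array([]), x=np.array([]), y=np.array([]),
                        z=np.array([]), valid=np.array([], bool), rate_hz=60)
        assert len(sonify(tr)) == 0

    def test_boundary_jitter_is_debounced_to_one_event(self):
        # oscillation of +-(hysteresis/2) interval around the c'/d' boundary
        # must not re-trigger; brute-force event-count oracle
        t = np.arange(0, 10, 1 / 60.0)
        for frac, cycles in [(0.05, 2), (0.2, 3)]:
            amp = (frac / 2) * GEOM.interval_height
            y = 8.5 + amp * np.sin(2 * np.pi * cycles * t / 10.0)
            stream = sonify(_flat_trajectory(y), hysteresis_fraction=frac)
            assert len(stream) == 1

    def test_without_hysteresis_boundary_jitter_chatters(self):
        t = np.arange(0, 10, 1 / 60.0)
        y = 8.5 + 0.2 * np.sin(2 * np.pi * 3 * t / 10.0)
        assert len(sonify(_flat_trajectory(y), hysteresis_fraction=0.0)) > 1

    def test_invalid_hysteresis_rejected(self):
        with pytest.raises(ValueError):
            sonify(_flat_trajectory(10.0), hysteresis_fraction=0.7)

    def test_round_trip_task_trajectory_reproduces_pitch_sequence(self):
        def collapse(seq):
            out = []
            for v in seq:
                if not out or out[-1] != v:
                    out.append(v)
            return out

        for reps in (1, 2):
            task = TaskSpec.scale(repetitions=reps)
            ideal = gen_trajectory(task, corruption=0.0, dialect="inertial",
                                   seed=0)
            got = collapse(sonify(ideal).pitch_sequence())
            want = collapse(task_events(task).pitch_sequence())
            assert got == want


class TestTaskEvents:
    def test_scale_task_has_eleven_events(self):
        # six ascending plus five descending, a' shared at the turn
        stream = task_events(TaskSpec.scale(repetitions=1))
        assert stream.pitch_sequence() == [1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1]

    def test_interval_task_has_two_events(self):
        assert len(task_events(TaskSpec.interval(6, repetitions=1))) == 2

    @pytest.mark.parametrize("reps", [2, 4])
    def test_repetitions_scale_event_count(self, reps):
        single = len(task_events(TaskSpec.scale(repetitions=1)))
        assert len(task_events(TaskSpec.scale(repetitions=reps))) == reps * single

    def test_task_validation(self):
        with pytest.raises(ValueError):
            TaskSpec(note_sequence=(1, 7))
        with pytest.raises(ValueError):
            TaskSpec(repetitions=0)
        with pytest.raises(ValueError):
            TaskSpec(position_field=10)


def test_field_centers_stay_inside_their_cells():
    for f in range(1, 10):
        cx, cz = field_center(f, GEOM)
        assert locate((cx, 0, cz), GEOM)[0] == f


def test_planar_sweep_touches_all_nine_fields():
    fields = set()
    for x in np.linspace(0.5, 50.5, 30):
        for z in np.linspace(0.5, 50.5, 30):
            fields.add(locate((x, 0, z), GEOM)[0])
    assert fields == set(range(1, 10))
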