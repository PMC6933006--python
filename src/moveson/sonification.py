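"""Movement-to-music mapping for the sonification training frame.

The training apparatus is a 51 x 51 cm board divided into nine numbered
fields (3 x 3), with 51 cm vertical bars marked into six equally spaced
intervals labelled with the first six notes of the C major scale
(c' at the bottom up to a' at the top).  Hand position inside the frame
is mapped to sound:

* height (y)  -> pitch, one of six scale notes,
* left-right (x) -> timbre (clarinet / saxophone / bowed string),
* depth (z)   -> loudness (proximal = loud).

This module reproduces that mapping deterministically and discretises a
continuous hand trajectory into a stream of note events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FrameGeometry",
    "SoundParams",
    "Event",
    "EventStream",
    "TaskSpec",
    "DEFAULT_TUNING",
    "TIMBRE_ZONES",
    "map_pitch",
    "locate",
    "sonify",
    "task_events",
]

#: Default tuning table (Hz), index 1..6.  The endpoints are the values the
#: training software used (c' = 226.6 Hz, a' = 440 Hz); interior notes are
#: equal-temperament anchored at a' = 440.  Note the c' endpoint is *not*
#: equal-tempered c' (261.63 Hz); the printed endpoint is kept deliberately
#: and the table is fully configurable.
DEFAULT_TUNING: tuple[float, ...] = (226.6, 293.66, 329.63, 349.23, 392.00, 440.0)

TIMBRE_ZONES: tuple[str, str, str] = ("clarinet", "saxophone", "bowed")

#: General-MIDI program numbers used when exporting events to MIDI.
GM_PROGRAMS = {"clarinet": 71, "saxophone": 66, "bowed": 40}


@dataclass(frozen=True)
class FrameGeometry:
    """Geometry of the training frame.

    Axis convention (documented; the physical setup fixes none numerically):
    x runs left->right across the board (timbre axis), y is vertical
    (pitch axis), z runs proximal->distal away from the patient
    (loudness axis).  Origin at the patient-side left board corner.
    """

    board_size: float = 51.0  # cm, square board edge
    bar_height: float = 51.0  # cm
    n_fields: int = 9  # 3 x 3 grid
    n_pitch_intervals: int = 6
    loudness_range_db: float = 20.0  # attenuation at the far board edge

    def __post_init__(self) -> None:
        side = round(self.n_fields ** 0.5)
        if side * side != self.n_fields:
            raise ValueError("n_fields must be a perfect square")
        if self.n_pitch_intervals < 2:
            raise ValueError("need at least 2 pitch intervals")
        if self.board_size <= 0 or self.bar_height <= 0:
            raise ValueError("frame dimensions must be positive")

    @property
    def grid_side(self) -> int:
        return round(self.n_fields ** 0.5)

    @property
    def interval_height(self) -> float:
        return self.bar_height / self.n_pitch_intervals


@dataclass(frozen=True)
class SoundParams:
    """Discrete sound parameters for one hand position."""

    field_index: int  # 1..9, row-major from the patient's near-left corner
    pitch_index: int  # 1..6
    frequency: float  # Hz
    timbre_zone: str  # clarinet | saxophone | bowed
    loudness_db: float  # attenuation, <= 0


@dataclass(frozen=True)
class Event:
    onset_s: float
    offset_s: float
    params: SoundParams

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventStream:
    """Ordered, non-overlapping note events from one trajectory."""

    events: list[Event] = field(default_factory=list)
    source_id: str | None = None

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def pitch_sequence(self) -> list[int]:
        return [e.params.pitch_index for e in self.events]

    def frequencies(self) -> list[float]:
        return [e.params.frequency for e in self.events]

    def to_jsonl(self) -> str:
        lines = []
        for e in self.events:
            p = e.params
            lines.append(json.dumps({
                "onset_s": round(e.onset_s, 6),
                "offset_s": round(e.offset_s, 6),
                "field": p.field_index,
                "pitch": p.pitch_index,
                "frequency_hz": p.frequency,
                "timbre": p.timbre_zone,
                "loudness_db": round(p.loudness_db, 4),
            }))
        return "\n".join(lines) + ("\n" if lines else "")


@dataclass(frozen=True)
class TaskSpec:
    """A training task: a note sequence played at one board field.

    The standard scale task is four upward and downward legato C major
    scales restricted to the first six notes (c'-d'-e'-f'-g'-a' and
    g'-f'-e'-d'-c').
    """

    position_field: int = 1
    note_sequence: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1)
    repetitions: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.position_field <= 9:
            raise ValueError("position_field must be in 1..9")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if not self.note_sequence:
            raise ValueError("note_sequence must be non-empty")
        if any(not 1 <= n <= 6 for n in self.note_sequence):
            raise ValueError("pitch indices must be in 1..6")

    @classmethod
    def scale(cls, position_field: int = 1, repetitions: int = 4) -> "TaskSpec":
        """The four-scales task used as the first task of every session."""
        return cls(position_field=position_field,
                   note_sequence=(1, 2, 3, 4, 5, 6, 5, 4, 3, 2, 1),
                   repetitions=repetitions)

    @classmethod
    def interval(cls, top_note: int, position_field: int = 1,
                 repetitions: int = 4) -> "TaskSpec":
        """Musical interval task c' -> top note."""
        return cls(position_field=position_field,
                   note_sequence=(1, top_note), repetitions=repetitions)


def _validate_tuning(tuning: Sequence[float], n: int) -> tuple[float, ...]:
    t = tuple(float(f) for f in tuning)
    if len(t) != n:
        raise ValueError(f"tuning table must have {n} entries, got {len(t)}")
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError("tuning table frequencies must be strictly increasing")
    return t


def map_pitch(height: float, geometry: FrameGeometry = FrameGeometry(),
              tuning: Sequence[float] = DEFAULT_TUNING) -> tuple[int, float] | None:
    """Map a hand height (cm) to (pitch_index, frequency).

    Intervals are half-open [low, high) with the very top of the bar closed
    into the highest interval.  Heights outside [0, bar_height] are
    out-of-frame and return None (no event).
    """
    tuning = _validate_tuning(tuning, geometry.n_pitch_intervals)
    if not 0.0 <= height <= geometry.bar_height:
        return None
    k = int(height // geometry.interval_height) + 1
    k = min(k, geometry.n_pitch_intervals)  # close the top boundary
    return k, tuning[k - 1]


def locate(position: tuple[float, float, float],
           geometry: FrameGeometry = FrameGeometry()
           ) -> tuple[int, str, float] | None:
    """Map an (x, y, z) position to (field_index, timbre_zone, loudness_db).

    The 3x3 field grid is numbered row-major starting at the patient's
    near-left corner (field 1 = near-left, field 3 = near-right,
    field 9 = far-right).  Timbre comes from x-thirds, loudness is a
    linear dB ramp along z with 0 dB at the proximal edge.
    """
    x, _y, z = position
    s = geometry.board_size
    if not (0.0 <= x <= s and 0.0 <= z <= s):
        return None
    side = geometry.grid_side
    cell = s / side
    col = min(int(x // cell), side - 1)
    row = min(int(z // cell), side - 1)
    field_index = row * side + col + 1
    third = min(int(x // (s / 3)), 2)
    timbre = TIMBRE_ZONES[third]
    loudness_db = -(z / s) * geometry.loudness_range_db
    return field_index, timbre, loudness_db


def sound_params(position: tuple[float, float, float],
                 geometry: FrameGeometry = FrameGeometry(),
                 tuning: Sequence[float] = DEFAULT_TUNING) -> SoundParams | None:
    """Full position -> sound mapping; None when out of frame."""
    x, y, z = position
    pitch = map_pitch(y, geometry, tuning)
    loc = locate(position, geometry)
    if pitch is None or loc is None:
        return None
    k, f = pitch
    field_index, timbre, loud = loc
    return SoundParams(field_index, k, f, timbre, loud)


def sonify(trajectory, geometry: FrameGeometry = FrameGeometry(),
           tuning: Sequence[float] = DEFAULT_TUNING,
           hysteresis_fraction: float = 0.05) -> EventStream:
    """Discretise a trajectory into a note-event stream.

    A new event is emitted whenever the pitch interval, timbre zone or
    board field changes; the previous event is closed at that sample.  To
    avoid chatter at interval boundaries, a pitch change is only registered
    once the hand has moved past the boundary by ``hysteresis_fraction`` of
    one interval height (anti-chatter dead band).  A stationary hand
    sustains a single event.

    Parameters
    ----------
    trajectory
        Object with ``t`` (s), ``x``, ``y``, ``z`` (cm) and ``valid``
        boolean arrays (see :class:`moveson.simulate.Trajectory`).
    """
    if not 0.0 <= hysteresis_fraction < 0.5:
        raise ValueError("hysteresis_fraction must be in [0, 0.5)")
    tuning = _validate_tuning(tuning, geometry.n_pitch_intervals)
    stream = EventStream(source_id=getattr(trajectory, "source_id", None))
    t = np.asarray(trajectory.t, dtype=float)
    if t.size == 0:
        return stream
    xs = np.asarray(trajectory.x, dtype=float)
    ys = np.asarray(trajectory.y, dtype=float)
    zs = np.asarray(trajectory.z, dtype=float)
    valid = np.asarray(getattr(trajectory, "valid", np.ones_like(t, bool)), bool)

    h = geometry.interval_height
    band = hysteresis_fraction * h

    cur: SoundParams | None = None
    cur_onset = 0.0
    last_t = float(t[-1])

    def close(at: float) -> None:
        nonlocal cur
        if cur is not None and at > cur_onset:
            stream.events.append(Event(cur_onset, at, cur))
        cur = None

    for i in range(t.size):
        if not valid[i]:
            close(float(t[i]))
            continue
        pos = (float(xs[i]), float(ys[i]), float(zs[i]))
        p = sound_params(pos, geometry, tuning)
        if p is None:
            close(float(t[i]))
            continue
        if cur is None:
            cur = p
            cur_onset = float(t[i])
            continue
        pitch_changed = p.pitch_index != cur.pitch_index
        if pitch_changed and band > 0.0:
            # only accept the new interval once past the boundary by `band`
            if p.pitch_index > cur.pitch_index:
                boundary = cur.pitch_index * h
                pitch_changed = pos[1] >= boundary + band
            else:
                boundary = (cur.pitch_index - 1) * h
                pitch_changed = pos[1] <= boundary - band
        if (pitch_changed or p.timbre_zone != cur.timbre_zone
                or p.field_index != cur.field_index):
            close(float(t[i]))
            cur = p
            cur_onset = float(t[i])
    close(last_t)
    return stream


def task_events(task: TaskSpec, geometry: FrameGeometry = FrameGeometry(),
                tuning: Sequence[float] = DEFAULT_TUNING,
                note_duration_s: float = 0.4) -> EventStream:
    """Idealised event stream for a task (reference rendering).

    Consecutive repeated notes inside one repetition are merged (legato
    no-repeat rule: the turning note of a scale sounds once); repetitions
    are re-articulated, so a task with ``repetitions=r`` has exactly
    ``r`` times the single-repetition event count.
    """
    tuning = _validate_tuning(tuning, geometry.n_pitch_intervals)
    stream = EventStream(source_id=f"task-field{task.position_field}")
    cx, cz = field_center(task.position_field, geometry)
    t0 = 0.0
    for _rep in range(task.repetitions):
        merged: list[int] = []
        for n in task.note_sequence:
            if not merged or merged[-1] != n:
                merged.append(n)
        for n in merged:
            y = note_height(n, geometry)
            p = sound_params((cx, y, cz), geometry, tuning)
            assert p is not None
            stream.events.append(Event(t0, t0 + note_duration_s, p))
            t0 += note_duration_s
    return stream


def note_height(pitch_index: int, geometry: FrameGeometry = FrameGeometry()) -> float:
    """Target hand height (cm) for a note: the centre of its interval."""
    if not 1 <= pitch_index <= geometry.n_pitch_intervals:
        raise ValueError("pitch index outside tuning range")
    return (pitch_index - 0.5) * geometry.interval_height


def field_center(field_index: int, geometry: FrameGeometry = FrameGeometry()
                 ) -> tuple[float, float]:
    """Board-plane centre (x, z) of a numbered field."""
    side = geometry.grid_side
    if not 1 <= field_index <= geometry.n_fields:
        raise ValueError("field index outside board")
    row, col = divmod(field_index - 1, side)
    cell = geometry.board_size / side
    return (col + 0.5) * cell, (row + 0.5) * cell
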