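"""Target melodies, scrambled mismatch foils, and rhythm-flattened variants.

A MINT target is a short (3-4 s) monophonic melody of 4-7 notes at
120 beats/min.  Mismatch foils reuse the target's pitches and note
durations in a different order, avoiding permutations that begin or end
on the melody's own pitch extremes (those endpoints are too salient and
would make mismatches trivially detectable).  The Rhythm condition uses
melodies collapsed onto a single pitch, so only temporal structure
distinguishes match from mismatch.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConstraintError,
    EmptyInputError,
    PitchRangeError,
    UnscramblableMelodyError,
)

__all__ = [
    "Note",
    "Melody",
    "MelodyPair",
    "MelodyParams",
    "generate_melody",
    "scramble_melody",
    "valid_scramble_orders",
    "flatten_to_rhythm",
    "make_pair",
    "melody_to_dict",
    "melody_from_dict",
    "save_melody_json",
    "load_melody_json",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Note:
    """A single note: onset and duration in beats, MIDI pitch, 0-1 velocity."""

    onset_beats: float
    duration_beats: float
    pitch: int
    velocity: float = 0.8

    def __post_init__(self) -> None:
        if self.duration_beats <= 0:
            raise ValueError("duration_beats must be positive")
        if self.onset_beats < 0:
            raise ValueError("onset_beats must be non-negative")
        if not 0 <= int(self.pitch) <= 127:
            raise PitchRangeError(f"MIDI pitch {self.pitch} outside 0-127")
        if not 0 <= self.velocity <= 1:
            raise ValueError("velocity must be in [0, 1]")


@dataclass(frozen=True)
class Melody:
    """An ordered, monophonic sequence of notes at a fixed tempo."""

    notes: tuple[Note, ...]
    tempo_bpm: float = 120.0
    id: str = ""

    def __post_init__(self) -> None:
        if self.tempo_bpm <= 0:
            raise ValueError("tempo_bpm must be positive")
        onsets = [n.onset_beats for n in self.notes]
        if onsets != sorted(onsets):
            raise ValueError("notes must be sorted by onset")
        for a, b in zip(self.notes, self.notes[1:]):
            if a.onset_beats + a.duration_beats > b.onset_beats + _EPS:
                raise ValueError("melody must be monophonic (no overlaps)")

    def __len__(self) -> int:
        return len(self.notes)

    @property
    def total_beats(self) -> float:
        """Notated span in beats (end of the last note)."""
        if not self.notes:
            return 0.0
        last = self.notes[-1]
        return last.onset_beats + last.duration_beats

    @property
    def duration_seconds(self) -> float:
        """Notated span in seconds at ``tempo_bpm``."""
        return self.total_beats * 60.0 / self.tempo_bpm

    @property
    def pitches(self) -> tuple[int, ...]:
        return tuple(n.pitch for n in self.notes)

    @property
    def durations(self) -> tuple[float, ...]:
        return tuple(n.duration_beats for n in self.notes)


@dataclass(frozen=True)
class MelodyPair:
    """A target melody and its scrambled mismatch foil."""

    target: Melody
    foil: Melody
    is_valid_foil: bool = True

    def __post_init__(self) -> None:
        if sorted(self.target.pitches) != sorted(self.foil.pitches):
            raise ValueError("foil must preserve the target pitch multiset")
        if sorted(self.target.durations) != sorted(self.foil.durations):
            raise ValueError("foil must preserve the target duration multiset")


@dataclass(frozen=True)
class MelodyParams:
    """Generation constraints for MINT target melodies.

    Defaults give 4-7 notes from a {eighth, quarter, dotted-quarter, half}
    duration alphabet at 120 bpm, filling a 3-4 s window in the C4-C6
    register.
    """

    pitch_low: int = 60
    pitch_high: int = 84
    duration_alphabet: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    tempo_bpm: float = 120.0
    min_notes: int = 4
    max_notes: int = 7
    total_seconds: tuple[float, float] = (3.0, 4.0)
    max_interval: int = 12  # largest melodic leap, semitones
    velocity: float = 0.8

    @property
    def total_beats_window(self) -> tuple[float, float]:
        lo, hi = self.total_seconds
        return lo * self.tempo_bpm / 60.0, hi * self.tempo_bpm / 60.0

    def validate(self) -> None:
        if self.pitch_low > self.pitch_high:
            raise ConstraintError("pitch_low exceeds pitch_high")
        if not (0 <= self.pitch_low and self.pitch_high <= 127):
            raise ConstraintError("pitch range outside MIDI 0-127")
        if self.min_notes < 2 or self.max_notes < self.min_notes:
            raise ConstraintError("need max_notes >= min_notes >= 2")
        if not self.duration_alphabet or min(self.duration_alphabet) <= 0:
            raise ConstraintError("duration alphabet must be positive")
        lo, hi = self.total_beats_window
        if self.min_notes * min(self.duration_alphabet) > hi:
            raise ConstraintError(
                "total-duration window unreachable: even min_notes of the "
                "shortest duration exceed the upper bound"
            )
        if self.max_notes * max(self.duration_alphabet) < lo:
            raise ConstraintError(
                "total-duration window unreachable: even max_notes of the "
                "longest duration fall short of the lower bound"
            )


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_melody(params: MelodyParams | None = None, seed: int = 0) -> Melody:
    """Draw a random target melody satisfying every ``MelodyParams`` bound.

    Deterministic in ``(params, seed)``.  Note count and durations are drawn
    by rejection sampling on the total-duration window; pitches follow a
    bounded random walk (leaps capped at ``max_interval`` semitones) and are
    redrawn if all notes land on one pitch, so a scrambled foil always
    exists for generated targets.
    """
    params = params or MelodyParams()
    params.validate()
    rng = _rng(seed)
    lo_beats, hi_beats = params.total_beats_window
    alphabet = np.asarray(params.duration_alphabet, dtype=float)

    durations = None
    for _ in range(100_000):
        n = int(rng.integers(params.min_notes, params.max_notes + 1))
        cand = alphabet[rng.integers(0, len(alphabet), size=n)]
        if lo_beats - _EPS <= cand.sum() <= hi_beats + _EPS:
            durations = cand
            break
    if durations is None:  # pragma: no cover - guarded by validate()
        raise ConstraintError("rejection sampling failed to hit the duration window")

    n = len(durations)
    for _ in range(1000):
        pitches = [int(rng.integers(params.pitch_low, params.pitch_high + 1))]
        for _ in range(n - 1):
            lo = max(params.pitch_low, pitches[-1] - params.max_interval)
            hi = min(params.pitch_high, pitches[-1] + params.max_interval)
            pitches.append(int(rng.integers(lo, hi + 1)))
        if len(set(pitches)) > 1:
            break

    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    notes = tuple(
        Note(float(o), float(d), p, params.velocity)
        for o, d, p in zip(onsets, durations, pitches)
    )
    return Melody(notes=notes, tempo_bpm=params.tempo_bpm, id=f"mel-{seed}")


def _tokens(m: Melody) -> tuple[tuple[int, float, float], ...]:
    return tuple((n.pitch, n.duration_beats, n.velocity) for n in m.notes)


def _melody_from_tokens(tokens, tempo_bpm: float, id_: str) -> Melody:
    onset = 0.0
    notes = []
    for pitch, dur, vel in tokens:
        notes.append(Note(onset, dur, pitch, vel))
        onset += dur
    return Melody(notes=tuple(notes), tempo_bpm=tempo_bpm, id=id_)


def _endpoints_ok(tokens, pmin: int, pmax: int) -> bool:
    return tokens[0][0] not in (pmin, pmax) and tokens[-1][0] not in (pmin, pmax)


def valid_scramble_orders(m: Melody) -> list[tuple]:
    """Enumerate every admissible foil note order for ``m`` by brute force.

    Returns distinct (pitch, duration, velocity) sequences that differ from
    the original order, restricted to those avoiding the melody's pitch
    extremes at both endpoints whenever at least one such order exists.
    Intended as an exact oracle and as the fallback for degenerate melodies.
    """
    orig = _tokens(m)
    pmin, pmax = min(m.pitches), max(m.pitches)
    seen = set()
    distinct, strict = [], []
    for perm in itertools.permutations(orig):
        if perm == orig or perm in seen:
            continue
        seen.add(perm)
        distinct.append(perm)
        if _endpoints_ok(perm, pmin, pmax):
            strict.append(perm)
    return strict if strict else distinct


def scramble_melody(m: Melody, seed: int = 0) -> Melody:
    """Reorder the notes of ``m`` into a mismatch foil.

    The foil keeps the pitch multiset and duration multiset of the target,
    differs from it in note order, starts at onset 0 with contiguous
    onsets recomputed from the permuted durations, and — whenever any such
    order exists — neither begins nor ends on the melody's own minimum or
    maximum pitch.  Rejection sampling (10 000 attempts) handles the common
    case; degenerate melodies fall back to exact enumeration.

    Raises
    ------
    UnscramblableMelodyError
        If every permutation reproduces the original order (all notes
        identical in pitch, duration and velocity).
    """
    if len(m) < 2:
        raise UnscramblableMelodyError("need at least 2 notes to scramble")
    orig = _tokens(m)
    pmin, pmax = min(m.pitches), max(m.pitches)
    rng = _rng(seed)
    idx = np.arange(len(orig))
    for _ in range(10_000):
        perm = tuple(orig[i] for i in rng.permutation(idx))
        if perm != orig and _endpoints_ok(perm, pmin, pmax):
            return _melody_from_tokens(perm, m.tempo_bpm, f"{m.id}-foil")
    candidates = valid_scramble_orders(m)
    if not candidates:
        raise UnscramblableMelodyError(
            "no distinct note order exists (all notes identical)"
        )
    perm = candidates[int(rng.integers(0, len(candidates)))]
    return _melody_from_tokens(perm, m.tempo_bpm, f"{m.id}-foil")


def flatten_to_rhythm(
    m: Melody, fixed_pitch: int, pitch_range: tuple[int, int] = (60, 84)
) -> Melody:
    """Collapse every note of ``m`` onto ``fixed_pitch``, keeping its timing.

    Idempotent; used to build Rhythm-condition stimuli where only temporal
    structure carries information.
    """
    lo, hi = pitch_range
    if not lo <= fixed_pitch <= hi:
        raise PitchRangeError(f"fixed_pitch {fixed_pitch} outside [{lo}, {hi}]")
    notes = tuple(replace(n, pitch=fixed_pitch) for n in m.notes)
    return Melody(notes=notes, tempo_bpm=m.tempo_bpm, id=f"{m.id}-flat{fixed_pitch}")


def make_pair(
    params: MelodyParams | None = None,
    seed: int = 0,
    *,
    rhythm_pitch: int | None = None,
) -> MelodyPair:
    """Generate a target and its scrambled foil from one seed.

    With ``rhythm_pitch`` set, both members are flattened to that pitch
    (Rhythm condition); generation retries until the flattened target has
    at least two distinct durations so a foil exists.
    """
    params = params or MelodyParams()
    for attempt in range(1000):
        gen_seed = (seed + 7_919 * attempt) % (2**31)
        target = generate_melody(params, gen_seed)
        if rhythm_pitch is not None:
            target = flatten_to_rhythm(
                target, rhythm_pitch, (params.pitch_low, params.pitch_high)
            )
            if len(set(target.durations)) < 2:
                continue
        foil = scramble_melody(target, seed=(gen_seed + 1) % (2**31))
        return MelodyPair(target=target, foil=foil)
    raise ConstraintError("could not generate a scramblable melody")  # pragma: no cover


# ---------------------------------------------------------------------------
# serialization

def melody_to_dict(m: Melody) -> dict:
    return {
        "id": m.id,
        "tempo_bpm": m.tempo_bpm,
        "notes": [
            {
                "onset_beats": n.onset_beats,
                "duration_beats": n.duration_beats,
                "pitch": n.pitch,
                "velocity": n.velocity,
            }
            for n in m.notes
        ],
    }


def melody_from_dict(d: dict) -> Melody:
    notes = tuple(
        Note(x["onset_beats"], x["duration_beats"], int(x["pitch"]), x.get("velocity", 0.8))
        for x in d["notes"]
    )
    return Melody(notes=notes, tempo_bpm=d.get("tempo_bpm", 120.0), id=d.get("id", ""))


def save_melody_json(m: Melody, path) -> None:
    if not m.notes:
        raise EmptyInputError("refusing to save an empty melody")
    with open(path, "w") as fh:
        json.dump(melody_to_dict(m), fh, indent=1)


def load_melody_json(path) -> Melody:
    with open(path) as fh:
        return melody_from_dict(json.load(fh))
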