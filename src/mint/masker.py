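"""Multi-music noise: the MINT's informational masker.

The masker bed mixes several independently generated streams of
polyphonic instrumental music into 46 s of "multi-music noise" — the
musical analogue of multi-talker babble.  Streams occupy staggered
registers so the bed's spectrum extends both below and above the target
melodies' register, giving energetic as well as informational masking.
Per-trial masker excerpts 1 s longer than the paired melody are cut from
the bed at random offsets and tapered with 10 ms raised-cosine ramps.

The original task drew its masker from published classical scores; here
a seeded procedural generator produces the polyphonic streams instead,
which keeps the toolkit self-contained.  The masker's function depends
on its statistical character (overlapping tonal streams, broad spectrum),
not on the identity of the pieces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .audio import (
    DEFAULT_SAMPLE_RATE,
    SynthParams,
    Waveform,
    apply_raised_cosine_ramp,
    normalize_peak,
    render_notes,
)
from .errors import BedTooShortError, CoverageError
from .melody import Note

__all__ = [
    "MaskerConfig",
    "MaskerStream",
    "MaskerBed",
    "MaskerExcerpt",
    "generate_masker_source",
    "build_masker_bed",
    "extract_excerpt",
    "make_masker_bed",
]

DEFAULT_BED_SECONDS = 46.0
EXCERPT_MARGIN_S = 1.0
RAMP_MS = 10.0

# Staggered registers (MIDI) and timbres for up to six streams; the first
# four are the defaults.  Lowest stream reaches below C4 and the highest
# above C6 so the union strictly contains the target register [60, 84].
_REGISTERS = [(36, 62), (48, 74), (62, 90), (76, 103), (43, 67), (55, 85)]
_TIMBRES = [
    SynthParams((1.0, 0.7, 0.5, 0.35, 0.25, 0.15), decay_s=0.6),
    SynthParams((1.0, 0.4, 0.6, 0.2, 0.3, 0.1), decay_s=0.35),
    SynthParams((1.0, 0.2, 0.5, 0.15, 0.35, 0.25, 0.1), decay_s=0.5),
    SynthParams((1.0, 0.8, 0.3, 0.4, 0.1), decay_s=0.25),
    SynthParams((1.0, 0.5, 0.25, 0.12), decay_s=0.45),
    SynthParams((1.0, 0.3, 0.45, 0.3, 0.2), decay_s=0.3),
]
_TEMPI = [88.0, 104.0, 120.0, 132.0, 96.0, 112.0]


@dataclass(frozen=True)
class MaskerConfig:
    """Masker construction parameters (defaults reproduce the task's bed)."""

    bed_seconds: float = DEFAULT_BED_SECONDS
    stream_count: int = 4
    target_pitch_range: tuple[int, int] = (60, 84)
    chord_size: tuple[int, int] = (2, 4)  # simultaneous notes per event
    # sanity bound on loudness uniformity: max/min RMS over 1 s windows
    rms_uniformity_bound: float = 4.0
    # each flank band must hold at least this fraction of bed energy
    band_floor_fraction: float = 0.01
    low_band_hz: float = 200.0
    high_band_hz: float = 2500.0


@dataclass(frozen=True)
class MaskerStream:
    """One polyphonic stream: its notes, register, tempo, and timbre."""

    notes: tuple[Note, ...]
    pitch_range: tuple[int, int]
    tempo_bpm: float
    synth: SynthParams


@dataclass
class MaskerBed:
    waveform: Waveform
    stream_count: int
    band: tuple[float, float]
    seed: int

    @property
    def duration(self) -> float:
        return self.waveform.duration


@dataclass
class MaskerExcerpt:
    waveform: Waveform
    source_offset: float
    duration: float


def _stream_notes(
    rng: np.random.Generator,
    register: tuple[int, int],
    tempo_bpm: float,
    duration_s: float,
    chord_size: tuple[int, int],
) -> tuple[Note, ...]:
    """A chordal random walk: chords of 2-4 notes every 0.5-2 beats."""
    lo, hi = register
    beats_total = duration_s * tempo_bpm / 60.0
    notes: list[Note] = []
    onset = 0.0
    center = float(rng.integers(lo + 4, hi - 4))
    while onset < beats_total:
        step = float(rng.choice([0.5, 1.0, 1.0, 1.5, 2.0]))
        center = float(np.clip(center + rng.integers(-5, 6), lo + 3, hi - 3))
        k = int(rng.integers(chord_size[0], chord_size[1] + 1))
        offsets = rng.choice([-12, -7, -5, -4, -3, 0, 3, 4, 5, 7, 12], size=k, replace=False)
        dur = step * float(rng.choice([1.0, 1.0, 2.0]))
        for off in offsets:
            pitch = int(np.clip(center + off, lo, hi))
            notes.append(Note(onset, dur, pitch, float(rng.uniform(0.5, 0.9))))
        onset += step
    return tuple(notes)


def generate_masker_source(
    seed: int,
    stream_count: int = 4,
    config: MaskerConfig | None = None,
) -> list[MaskerStream]:
    """Generate ``stream_count`` polyphonic streams with staggered registers.

    Deterministic in ``seed``.  Raises :class:`CoverageError` if the union
    of stream registers fails to extend strictly below and above the target
    melody register.
    """
    config = config or MaskerConfig(stream_count=stream_count)
    if stream_count < 2:
        raise CoverageError("need at least 2 masker streams")
    if stream_count > len(_REGISTERS):
        raise CoverageError(f"at most {len(_REGISTERS)} streams supported")
    registers = _REGISTERS[:stream_count]
    t_lo, t_hi = config.target_pitch_range
    if min(r[0] for r in registers) >= t_lo or max(r[1] for r in registers) <= t_hi:
        raise CoverageError(
            "stream registers do not strictly contain the target pitch range"
        )
    streams = []
    for i in range(stream_count):
        rng = np.random.default_rng([seed, i])
        streams.append(
            MaskerStream(
                notes=_stream_notes(
                    rng, registers[i], _TEMPI[i], config.bed_seconds, config.chord_size
                ),
                pitch_range=registers[i],
                tempo_bpm=_TEMPI[i],
                synth=_TIMBRES[i],
            )
        )
    return streams


def build_masker_bed(
    streams: list[MaskerStream],
    duration_s: float = DEFAULT_BED_SECONDS,
    seed: int = 0,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> MaskerBed:
    """Render streams, mix at equal RMS, and peak-normalize to [-1, 1]."""
    if not streams:
        raise BedTooShortError("no streams to build a bed from")
    if duration_s < 5.0:
        raise BedTooShortError("bed must be at least 5 s (melody + margin)")
    mix = np.zeros(int(round(duration_s * sample_rate)))
    for s in streams:
        w = render_notes(s.notes, s.tempo_bpm, s.synth, sample_rate, total_seconds=duration_s)
        r = w.rms()
        if r > 0:
            mix += w.samples / r  # equal-RMS contribution
    bed_wave = normalize_peak(Waveform(mix, sample_rate))
    band = _spectral_support(bed_wave)
    return MaskerBed(waveform=bed_wave, stream_count=len(streams), band=band, seed=seed)


def _spectral_support(w: Waveform, frac: float = 0.005) -> tuple[float, float]:
    """(low, high) Hz bounding the central 99% of spectral energy."""
    spec = np.abs(np.fft.rfft(w.samples)) ** 2
    freqs = np.fft.rfftfreq(w.n_samples, 1.0 / w.sample_rate)
    cum = np.cumsum(spec) / spec.sum()
    low = float(freqs[np.searchsorted(cum, frac)])
    high = float(freqs[np.searchsorted(cum, 1 - frac)])
    return (low, high)


def rms_uniformity(w: Waveform, window_s: float = 1.0) -> float:
    """Max/min ratio of RMS over non-overlapping ``window_s`` windows."""
    n = int(w.sample_rate * window_s)
    k = w.n_samples // n
    vals = [
        float(np.sqrt(np.mean(w.samples[i * n : (i + 1) * n] ** 2))) for i in range(k)
    ]
    vals = [v for v in vals if v > 0]
    return max(vals) / min(vals)


def make_masker_bed(
    seed: int,
    config: MaskerConfig | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    max_attempts: int = 5,
) -> MaskerBed:
    """Source + bed in one call, regenerating if loudness is too non-uniform.

    The original clip was chosen by ear to sound "relatively uniform"; that
    selection is operationalized as an RMS max/min bound over 1 s windows,
    regenerating from a derived seed on failure (attempt count recorded).
    """
    config = config or MaskerConfig()
    for attempt in range(max_attempts):
        attempt_seed = (seed + 1_000_003 * attempt) % (2**31)
        streams = generate_masker_source(attempt_seed, config.stream_count, config)
        bed = build_masker_bed(streams, config.bed_seconds, attempt_seed, sample_rate)
        if rms_uniformity(bed.waveform) <= config.rms_uniformity_bound:
            bed.waveform.meta["uniformity_attempts"] = attempt + 1
            return bed
    bed.waveform.meta["uniformity_attempts"] = max_attempts
    bed.waveform.meta["uniformity_failed"] = True
    return bed


def extract_excerpt(
    bed: MaskerBed,
    melody_duration: float,
    seed: int = 0,
    margin_s: float = EXCERPT_MARGIN_S,
    ramp_ms: float = RAMP_MS,
    offset: float | None = None,
) -> MaskerExcerpt:
    """Cut a tapered excerpt ``melody_duration + margin_s`` long from the bed.

    The source offset is drawn uniformly over the feasible range (seeded),
    or pinned with ``offset`` when reproducing a manifest.
    """
    duration = melody_duration + margin_s
    max_offset = bed.duration - duration
    if max_offset < 0:
        raise BedTooShortError(
            f"bed of {bed.duration:.2f} s cannot supply a {duration:.2f} s excerpt"
        )
    if offset is None:
        rng = np.random.default_rng(seed)
        offset = float(rng.uniform(0.0, max_offset))
    elif offset > max_offset + 1e-9:
        raise BedTooShortError("requested offset leaves too little bed")
    sr = bed.waveform.sample_rate
    i0 = int(round(offset * sr))
    n = int(round(duration * sr))
    cut = Waveform(bed.waveform.samples[i0 : i0 + n].copy(), sr)
    return MaskerExcerpt(
        waveform=apply_raised_cosine_ramp(cut, ramp_ms),
        source_offset=i0 / sr,
        duration=n / sr,
    )
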