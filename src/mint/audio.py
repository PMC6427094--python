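"""Waveform container, additive synthesis, and level/SNR primitives.

All downstream mixing is built on four small operations — peak
normalization, raised-cosine ramps, dB gain, and windowed RMS SNR
measurement — so the level contracts of the task (0 to -9 dB SNR steps,
the 6 dB interaural level difference of the Spatial cue) can be verified
directly on rendered audio.

SNR convention: 0 dB means equal RMS between target and masker measured
over the target's support window; this is the standard psychoacoustic
operationalization and makes ``measure_snr`` an exact verification tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .errors import (
    DegenerateSignalError,
    EmptyInputError,
    RampTooLongError,
    UndefinedSNRError,
)
from .melody import Melody

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "Waveform",
    "SynthParams",
    "midi_to_hz",
    "render_notes",
    "render_melody",
    "normalize_peak",
    "apply_raised_cosine_ramp",
    "change_level",
    "measure_snr",
    "band_energy_fraction",
    "write_wav",
    "read_wav",
]

DEFAULT_SAMPLE_RATE = 44100


@dataclass
class Waveform:
    """Mono ``(n,)`` or stereo ``(n, 2)`` float samples in [-1, 1] at a fixed rate."""

    samples: np.ndarray
    sample_rate: int = DEFAULT_SAMPLE_RATE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D (mono) or 2-D (n, channels)")
        if self.samples.ndim == 2 and self.samples.shape[1] not in (1, 2):
            raise ValueError("at most two channels supported")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return 1 if self.samples.ndim == 1 else self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, i: int) -> "Waveform":
        if self.samples.ndim == 1:
            if i != 0:
                raise IndexError("mono waveform has a single channel")
            return Waveform(self.samples.copy(), self.sample_rate)
        return Waveform(self.samples[:, i].copy(), self.sample_rate)

    def slice_seconds(self, start: float, end: float) -> "Waveform":
        i0 = max(0, int(round(start * self.sample_rate)))
        i1 = min(self.n_samples, int(round(end * self.sample_rate)))
        return Waveform(self.samples[i0:i1].copy(), self.sample_rate)

    def rms(self, window: tuple[float, float] | None = None) -> float:
        x = self.samples if window is None else self.slice_seconds(*window).samples
        if x.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(np.square(x))))

    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if self.samples.size else 0.0

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.sample_rate, dict(self.meta))


@dataclass(frozen=True)
class SynthParams:
    """Parametric harmonic-tone timbre: partial weights plus envelope times.

    A configurable additive synth with exponential decay stands in for a
    sampled piano timbre; the task logic is timbre-agnostic.
    """

    partial_amplitudes: tuple[float, ...] = (1.0, 0.5, 0.33, 0.25, 0.2, 0.12)
    decay_s: float = 0.4
    attack_s: float = 0.005
    release_s: float = 0.02

    def __post_init__(self) -> None:
        if not any(a != 0 for a in self.partial_amplitudes):
            raise ValueError("need at least one nonzero partial")
        if self.decay_s <= 0:
            raise ValueError("decay_s must be positive")


def midi_to_hz(pitch: float) -> float:
    """Equal-tempered fundamental: 440 Hz at MIDI 69."""
    return 440.0 * 2.0 ** ((pitch - 69) / 12.0)


def _tone(f0: float, dur_s: float, synth: SynthParams, sr: int) -> np.ndarray:
    n = int(round(dur_s * sr))
    t = np.arange(n) / sr
    env = np.exp(-t / synth.decay_s)
    na = int(round(synth.attack_s * sr))
    if na > 1:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(min(na, n)) / na))
        env[: len(ramp)] *= ramp
    nr = int(round(synth.release_s * sr))
    if 1 < nr < n:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        env[n - nr :] *= ramp[::-1]
    x = np.zeros(n)
    nyq = sr / 2
    for k, amp in enumerate(synth.partial_amplitudes, start=1):
        if amp and k * f0 < nyq:
            x += amp * np.sin(2 * np.pi * k * f0 * t)
    return x * env


def render_notes(
    notes,
    tempo_bpm: float,
    synth: SynthParams | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    total_seconds: float | None = None,
) -> Waveform:
    """Additively render a (possibly polyphonic) note list to mono audio.

    Each note receives a ``release_s`` raised-cosine tail beyond its notated
    duration to avoid offset clicks; the buffer is extended accordingly
    unless ``total_seconds`` pins its length.
    """
    synth = synth or SynthParams()
    if not notes:
        raise EmptyInputError("cannot render an empty note list")
    beat_s = 60.0 / tempo_bpm
    span = max(n.onset_beats + n.duration_beats for n in notes) * beat_s
    length_s = total_seconds if total_seconds is not None else span + synth.release_s
    buf = np.zeros(int(round(length_s * sample_rate)))
    for note in notes:
        i0 = int(round(note.onset_beats * beat_s * sample_rate))
        tone = note.velocity * _tone(
            midi_to_hz(note.pitch),
            note.duration_beats * beat_s + synth.release_s,
            synth,
            sample_rate,
        )
        seg = tone[: max(0, len(buf) - i0)]
        buf[i0 : i0 + len(seg)] += seg
    peak = np.max(np.abs(buf))
    if peak > 0:
        buf *= 0.9 / peak  # headroom before downstream gain staging
    return Waveform(buf, sample_rate)


def render_melody(
    m: Melody,
    synth: SynthParams | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> Waveform:
    """Render a monophonic melody; duration = notated span + one release tail."""
    if not m.notes:
        raise EmptyInputError("cannot render an empty melody")
    return render_notes(m.notes, m.tempo_bpm, synth, sample_rate)


def normalize_peak(w: Waveform) -> Waveform:
    """Scale so the maximum absolute sample is exactly 1."""
    peak = w.peak()
    if peak == 0:
        raise DegenerateSignalError("cannot peak-normalize an all-zero signal")
    return Waveform(w.samples / peak, w.sample_rate, dict(w.meta))


def apply_raised_cosine_ramp(w: Waveform, ramp_ms: float = 10.0) -> Waveform:
    """Taper onset and offset with raised-cosine ramps of ``ramp_ms``.

    gain(t) = 0.5 * (1 - cos(pi * t / ramp)) rising over the onset ramp and
    mirrored at the offset; samples strictly between the ramps are untouched.
    """
    n = int(round(ramp_ms / 1000.0 * w.sample_rate))
    if 2 * n > w.n_samples:
        raise RampTooLongError(
            f"{ramp_ms} ms ramps exceed half of a {w.duration:.4f} s waveform"
        )
    gain = np.ones(w.n_samples)
    if n > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n) / n))
        gain[:n] = ramp
        gain[-n:] = ramp[::-1]
    samples = w.samples * (gain if w.samples.ndim == 1 else gain[:, None])
    return Waveform(samples, w.sample_rate, dict(w.meta))


def change_level(w: Waveform, gain_db: float) -> Waveform:
    """Apply a broadband gain of ``gain_db`` dB (amplitude factor 10^(g/20)).

    Resulting samples outside [-1, 1] are not an error; a clipping flag is
    recorded in the waveform metadata instead so gain staging can respond.
    """
    out = Waveform(w.samples * 10.0 ** (gain_db / 20.0), w.sample_rate, dict(w.meta))
    if out.peak() > 1.0:
        out.meta["clipped"] = True
    return out


def measure_snr(
    target: Waveform,
    masker: Waveform,
    window: tuple[float, float] | None = None,
) -> float:
    """RMS signal-to-noise ratio in dB over ``window`` (whole overlap if None).

    Returns ``-inf`` for a zero-energy target; a zero-energy masker makes
    the ratio undefined and raises :class:`UndefinedSNRError`.
    """
    if target.sample_rate != masker.sample_rate:
        raise ValueError("sample rates differ")
    if window is None:
        end = min(target.duration, masker.duration)
        window = (0.0, end)
    rt = target.rms(window)
    rm = masker.rms(window)
    if rm == 0:
        raise UndefinedSNRError("masker has zero energy in the window")
    if rt == 0:
        return float("-inf")
    return 20.0 * np.log10(rt / rm)


def band_energy_fraction(w: Waveform, low_hz: float, high_hz: float) -> float:
    """Fraction of total spectral energy falling in [low_hz, high_hz]."""
    x = w.samples if w.samples.ndim == 1 else w.samples.mean(axis=1)
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1.0 / w.sample_rate)
    total = spec.sum()
    if total == 0:
        raise DegenerateSignalError("zero-energy signal has no band fractions")
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    return float(spec[mask].sum() / total)


def write_wav(path, w: Waveform, subtype: str = "float32") -> None:
    """Write a RIFF WAV file (``float32`` default, ``int16`` optional)."""
    data = w.samples
    if subtype == "float32":
        wavfile.write(path, w.sample_rate, data.astype(np.float32))
    elif subtype == "int16":
        clipped = np.clip(data, -1.0, 1.0)
        wavfile.write(path, w.sample_rate, np.round(clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unsupported WAV subtype: {subtype}")


def read_wav(path) -> Waveform:
    """Read a WAV file into a float :class:`Waveform` scaled to [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data / 32767.0
    elif data.dtype == np.int32:
        data = data / 2147483647.0
    elif data.dtype == np.uint8:
        data = (data.astype(np.float64) - 128) / 127.0
    data = np.asarray(data, dtype=np.float64)
    if np.max(np.abs(data)) > 1.0 + 1e-9:
        warnings.warn("WAV samples exceed [-1, 1]; keeping values as read")
    return Waveform(data, int(sr))
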