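"""Minimal Standard MIDI File (format 0) I/O for monophonic melodies.

Writes a single-track SMF with a tempo meta event and note on/off pairs,
and reads such files back into :class:`~mint.melody.Melody`.  Only the
subset of the SMF spec needed for MINT melody exchange is supported:
format 0, one channel, no running-status writing (though reading handles
running status), metrical division.
"""

from __future__ import annotations

import struct

from .errors import EmptyInputError, MintError
from .melody import Melody, Note

__all__ = ["save_melody_midi", "load_melody_midi"]

TICKS_PER_BEAT = 480


def _vlq(value: int) -> bytes:
    """Encode a MIDI variable-length quantity."""
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def save_melody_midi(m: Melody, path) -> None:
    """Write ``m`` as a format-0 single-track standard MIDI file."""
    if not m.notes:
        raise EmptyInputError("refusing to save an empty melody")
    tempo_us = round(60_000_000 / m.tempo_bpm)
    events = bytearray()
    events += _vlq(0) + b"\xff\x51\x03" + struct.pack(">I", tempo_us)[1:]
    tick = 0
    for n in m.notes:
        on = round(n.onset_beats * TICKS_PER_BEAT)
        off = round((n.onset_beats + n.duration_beats) * TICKS_PER_BEAT)
        vel = max(1, min(127, round(n.velocity * 127)))
        events += _vlq(on - tick) + bytes([0x90, n.pitch, vel])
        events += _vlq(off - on) + bytes([0x80, n.pitch, 0])
        tick = off
    events += _vlq(0) + b"\xff\x2f\x00"

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, TICKS_PER_BEAT))
        fh.write(b"MTrk" + struct.pack(">I", len(events)) + bytes(events))


def _read_vlq(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        b = data[pos]
        pos += 1
        value = (value << 7) | (b & 0x7F)
        if not b & 0x80:
            return value, pos


def load_melody_midi(path) -> Melody:
    """Read a monophonic format-0 (or single-track format-1) MIDI file."""
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise MintError("not a standard MIDI file")
    _, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if division & 0x8000:
        raise MintError("SMPTE time division is not supported")
    if ntrks < 1:
        raise MintError("MIDI file contains no tracks")
    pos = 14
    if data[pos : pos + 4] != b"MTrk":
        raise MintError("missing MTrk chunk")
    (length,) = struct.unpack(">I", data[pos + 4 : pos + 8])
    track = data[pos + 8 : pos + 8 + length]

    tempo_bpm = 120.0
    tick = 0
    p = 0
    status = 0
    pending: dict[int, tuple[int, int]] = {}  # pitch -> (onset tick, velocity)
    notes: list[Note] = []
    while p < len(track):
        delta, p = _read_vlq(track, p)
        tick += delta
        b = track[p]
        if b & 0x80:
            status = b
            p += 1
        if status == 0xFF:  # meta
            meta_type = track[p]
            mlen, p = _read_vlq(track, p + 1)
            if meta_type == 0x51:
                us = int.from_bytes(track[p : p + 3], "big")
                tempo_bpm = 60_000_000 / us
            p += mlen
            if meta_type == 0x2F:
                break
        elif status in (0xF0, 0xF7):  # sysex
            mlen, p = _read_vlq(track, p)
            p += mlen
        else:
            kind = status & 0xF0
            if kind in (0x80, 0x90, 0xA0, 0xB0, 0xE0):
                d1, d2 = track[p], track[p + 1]
                p += 2
            else:
                d1, d2 = track[p], 0
                p += 1
            if kind == 0x90 and d2 > 0:
                pending[d1] = (tick, d2)
            elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                if d1 in pending:
                    onset, vel = pending.pop(d1)
                    notes.append(
                        Note(
                            onset / division,
                            max((tick - onset) / division, 1e-6),
                            d1,
                            vel / 127,
                        )
                    )
    notes.sort(key=lambda n: n.onset_beats)
    return Melody(notes=tuple(notes), tempo_bpm=tempo_bpm)
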