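"""Trial assembly: SNR mixing, condition cues, blocks, and task versions.

A MINT trial presents two intervals separated by 0.5 s: a target melody
embedded in multi-music noise starting 0.5 s after noise onset, and a
comparison melody in silence that either matches the target or is its
scrambled foil.  Five noise conditions differ in the cue available —

* baseline    noise-first, no extra cue
* rhythm      as baseline but single-pitch (temporal cues only)
* prediction  silence-first, so the target can be held in memory
* spatial     the melody is lateralized: +3 dB in the attended ear and
              -3 dB in the other, with the inverse applied to the noise,
              giving the target a 6 dB interaural level difference
* visual      a piano-roll cue scrolls during the in-noise interval

plus a control block with both intervals in silence.  A session version
packs 20 trials per condition (10 match / 10 mismatch, each of the four
SNRs 0/-3/-6/-9 dB five times) behind 4 familiarization trials per
condition; four versions re-randomize the SNR-stimulus pairing.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .audio import (
    DEFAULT_SAMPLE_RATE,
    SynthParams,
    Waveform,
    measure_snr,
    render_melody,
    write_wav,
)
from .errors import GeometryError, InputError, PoolError
from .masker import (
    EXCERPT_MARGIN_S,
    MaskerBed,
    MaskerConfig,
    MaskerExcerpt,
    extract_excerpt,
    make_masker_bed,
)
from .melody import (
    Melody,
    MelodyPair,
    MelodyParams,
    make_pair,
    melody_from_dict,
    melody_to_dict,
)

__all__ = [
    "NOISE_CONDITIONS",
    "CONTROL",
    "ALL_CONDITIONS",
    "SNR_LEVELS",
    "SessionConfig",
    "StereoMix",
    "PianoRollCue",
    "Trial",
    "TrialAudio",
    "SessionVersion",
    "mix_target_in_noise",
    "apply_spatial_cue",
    "measured_target_ild",
    "make_visual_cue",
    "assemble_trial",
    "build_session",
    "render_trial",
    "render_session",
    "session_to_json",
    "session_from_json",
    "session_to_frame",
    "validate_session",
]

NOISE_CONDITIONS = ("baseline", "rhythm", "prediction", "spatial", "visual")
CONTROL = "control"
ALL_CONDITIONS = NOISE_CONDITIONS + (CONTROL,)
SNR_LEVELS = (0.0, -3.0, -6.0, -9.0)

EMBED_OFFSET_S = 0.5
ISI_S = 0.5
SPATIAL_GAIN_DB = 3.0
SILENT_INTERVAL_RMS = 0.1  # reference playback level for the in-silence melody


@dataclass(frozen=True)
class SessionConfig:
    """Everything needed to rebuild a session deterministically."""

    snr_levels: tuple[float, ...] = SNR_LEVELS
    trials_per_block: int = 20
    familiarization_trials: int = 4
    embed_offset_s: float = EMBED_OFFSET_S
    isi_s: float = ISI_S
    excerpt_margin_s: float = EXCERPT_MARGIN_S
    sample_rate: int = DEFAULT_SAMPLE_RATE
    melody: MelodyParams = field(default_factory=MelodyParams)
    masker: MaskerConfig = field(default_factory=MaskerConfig)

    def __post_init__(self) -> None:
        if self.trials_per_block % (2 * len(self.snr_levels)) != 0 and (
            self.trials_per_block % len(self.snr_levels) != 0
            or self.trials_per_block % 2 != 0
        ):
            raise PoolError(
                "trials_per_block must divide evenly over SNR levels and "
                "into match/mismatch halves"
            )


# ---------------------------------------------------------------------------
# mixing


@dataclass
class StereoMix:
    """A two-channel mixture with its target and masker components retained.

    ``mixture = target_track + masker_track`` holds sample-exactly per
    channel; keeping the decomposition makes every level contract (SNR,
    spatial ILD) directly measurable after the fact.
    """

    target_track: np.ndarray  # (n, 2)
    masker_track: np.ndarray  # (n, 2)
    sample_rate: int
    snr_db: float
    embed_offset: float
    target_support: tuple[float, float]
    metadata: dict = field(default_factory=dict)

    @property
    def mixture(self) -> np.ndarray:
        return self.target_track + self.masker_track

    @property
    def waveform(self) -> Waveform:
        return Waveform(self.mixture, self.sample_rate)

    def target_channel(self, ear: int) -> Waveform:
        return Waveform(self.target_track[:, ear].copy(), self.sample_rate)

    def masker_channel(self, ear: int) -> Waveform:
        return Waveform(self.masker_track[:, ear].copy(), self.sample_rate)

    def measured_snr(self, ear: int | None = None) -> float:
        """Re-measure RMS SNR over the target's support window."""
        if ear is None:
            t = Waveform(self.target_track, self.sample_rate)
            m = Waveform(self.masker_track, self.sample_rate)
        else:
            t, m = self.target_channel(ear), self.masker_channel(ear)
        return measure_snr(t, m, self.target_support)


def mix_target_in_noise(
    target: Waveform,
    excerpt: MaskerExcerpt,
    snr_db: float,
    embed_offset: float = EMBED_OFFSET_S,
) -> StereoMix:
    """Embed a rendered melody in a masker excerpt at an exact RMS SNR.

    The masker is left unscaled; the target is scaled so that the RMS
    ratio over the target's support window equals ``snr_db``, then placed
    ``embed_offset`` seconds after noise onset.  Output is diotic (both
    channels identical) until a spatial cue is applied.
    """
    sr = excerpt.waveform.sample_rate
    if target.sample_rate != sr:
        raise ValueError("sample rates differ")
    n = excerpt.waveform.n_samples
    i0 = int(round(embed_offset * sr))
    nt = target.n_samples
    if i0 + nt > n:
        raise GeometryError(
            f"target of {target.duration:.2f} s does not fit in a "
            f"{excerpt.duration:.2f} s excerpt at offset {embed_offset} s"
        )
    support = (i0 / sr, (i0 + nt) / sr)
    masker_mono = excerpt.waveform.samples
    rms_m = float(np.sqrt(np.mean(masker_mono[i0 : i0 + nt] ** 2)))
    rms_t = target.rms()
    if rms_t == 0 or rms_m == 0:
        raise GeometryError("degenerate target or masker in the support window")
    gain = 10.0 ** (snr_db / 20.0) * rms_m / rms_t
    target_mono = np.zeros(n)
    target_mono[i0 : i0 + nt] = target.samples * gain
    return StereoMix(
        target_track=np.column_stack([target_mono, target_mono]),
        masker_track=np.column_stack([masker_mono, masker_mono]),
        sample_rate=sr,
        snr_db=snr_db,
        embed_offset=i0 / sr,
        target_support=support,
        metadata={
            "target_gain_db": 20.0 * float(np.log10(gain)),
            "ear_gains_db": {"target": [0.0, 0.0], "masker": [0.0, 0.0]},
            "side": None,
        },
    )


def apply_spatial_cue(mix: StereoMix, side: str) -> StereoMix:
    """Lateralize the target: +3 dB target / -3 dB masker in the attended ear,
    inverted in the other ear, so the target carries a 6 dB interaural level
    difference (and the masker the opposite one).

    A ``side`` descriptor is attached for the pre-trial attention icon.
    """
    if side not in ("left", "right"):
        import warnings

        warnings.warn("apply_spatial_cue called without a side; no-op")
        return mix
    a = 0 if side == "left" else 1  # attended ear index
    b = 1 - a
    up = 10.0 ** (SPATIAL_GAIN_DB / 20.0)
    dn = 10.0 ** (-SPATIAL_GAIN_DB / 20.0)
    tt = mix.target_track.copy()
    mt = mix.masker_track.copy()
    tt[:, a] *= up
    tt[:, b] *= dn
    mt[:, a] *= dn
    mt[:, b] *= up
    meta = dict(mix.metadata)
    g = {"target": [0.0, 0.0], "masker": [0.0, 0.0]}
    g["target"][a], g["target"][b] = SPATIAL_GAIN_DB, -SPATIAL_GAIN_DB
    g["masker"][a], g["masker"][b] = -SPATIAL_GAIN_DB, SPATIAL_GAIN_DB
    meta["ear_gains_db"] = g
    meta["side"] = side
    return StereoMix(
        target_track=tt,
        masker_track=mt,
        sample_rate=mix.sample_rate,
        snr_db=mix.snr_db,
        embed_offset=mix.embed_offset,
        target_support=mix.target_support,
        metadata=meta,
    )


def measured_target_ild(mix: StereoMix) -> float:
    """Between-ear level difference of the target component, in dB (>= 0)."""
    l = mix.target_channel(0).rms(mix.target_support)
    r = mix.target_channel(1).rms(mix.target_support)
    return abs(20.0 * float(np.log10(l / r)))


# ---------------------------------------------------------------------------
# cues and trials


@dataclass(frozen=True)
class PianoRollCue:
    """Scrolling-tone cue: one (start, end, vertical position) per note.

    Vertical position is linear in MIDI pitch within the melody's own
    range (0 = lowest note, 1 = highest); the cue spans only the in-noise
    portion of the trial.
    """

    events: tuple[tuple[float, float, float], ...]
    span: tuple[float, float]


def make_visual_cue(m: Melody, embed_offset: float = EMBED_OFFSET_S) -> PianoRollCue:
    beat_s = 60.0 / m.tempo_bpm
    pitches = m.pitches
    lo, hi = min(pitches), max(pitches)
    events = []
    for note in m.notes:
        start = embed_offset + note.onset_beats * beat_s
        end = start + note.duration_beats * beat_s
        vpos = 0.5 if hi == lo else (note.pitch - lo) / (hi - lo)
        events.append((start, end, float(vpos)))
    return PianoRollCue(
        events=tuple(events), span=(embed_offset, embed_offset + m.duration_seconds)
    )


@dataclass(frozen=True)
class Trial:
    trial_id: str
    condition: str
    snr_db: float | None
    is_match: bool
    interval_order: tuple[str, str]  # e.g. ("noise", "silence")
    isi_s: float
    target: Melody
    foil: Melody | None
    item_index: int = 0
    spatial_side: str | None = None
    visual_cue: PianoRollCue | None = None
    excerpt_offset: float | None = None
    familiarization: bool = False
    feedback: bool = False
    seed: int = 0

    @property
    def comparison(self) -> Melody:
        """The melody presented in silence: target on match, foil otherwise."""
        return self.target if self.is_match else self.foil


def _interval_order(condition: str) -> tuple[str, str]:
    if condition == "prediction":
        return ("silence", "noise")
    if condition == CONTROL:
        return ("silence", "silence")
    return ("noise", "silence")


def assemble_trial(
    condition: str,
    pair: MelodyPair,
    snr_db: float | None,
    is_match: bool,
    seed: int = 0,
    *,
    trial_id: str = "",
    item_index: int = 0,
    spatial_side: str | None = None,
    excerpt_offset: float | None = None,
    embed_offset: float = EMBED_OFFSET_S,
    isi_s: float = ISI_S,
    familiarization: bool = False,
) -> Trial:
    """Build the metadata record for one trial (audio is rendered lazily).

    The in-noise interval always embeds the target; on mismatch trials the
    in-silence interval carries the foil.  The Prediction condition puts
    the silent interval first; the control condition has no masker at all.
    """
    if condition not in ALL_CONDITIONS:
        raise InputError(f"unknown condition: {condition}")
    if not is_match and pair.foil is None:
        raise InputError("mismatch trial requires a foil")
    if condition == "spatial" and spatial_side is None:
        spatial_side = ["left", "right"][int(np.random.default_rng(seed).integers(0, 2))]
    cue = make_visual_cue(pair.target, embed_offset) if condition == "visual" else None
    if condition == CONTROL:
        snr_db = None
        excerpt_offset = None
    return Trial(
        trial_id=trial_id or f"{condition}-{item_index:02d}",
        condition=condition,
        snr_db=snr_db,
        is_match=is_match,
        interval_order=_interval_order(condition),
        isi_s=isi_s,
        target=pair.target,
        foil=pair.foil,
        item_index=item_index,
        spatial_side=spatial_side if condition == "spatial" else None,
        visual_cue=cue,
        excerpt_offset=excerpt_offset,
        familiarization=familiarization,
        feedback=familiarization,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# sessions


@dataclass
class SessionVersion:
    version_id: int
    blocks: dict[str, list[Trial]]
    block_order: list[str]
    familiarization: dict[str, list[Trial]]
    seeds: dict
    config: SessionConfig

    def main_trials(self):
        for cond in self.block_order:
            yield from self.blocks[cond]

    def all_trials(self):
        for cond in self.block_order:
            yield from self.familiarization[cond]
            yield from self.blocks[cond]

    def trial_map(self) -> dict[str, Trial]:
        return {t.trial_id: t for t in self.all_trials()}


def _sub_seed(*tags: int) -> int:
    """Stable 31-bit seed derived from a tuple of integer tags."""
    return int(np.random.SeedSequence(list(tags)).generate_state(1)[0] % (2**31))


def build_session(
    version_id: int,
    master_seed: int,
    config: SessionConfig | None = None,
) -> SessionVersion:
    """Assemble one of the four task versions as a full trial manifest.

    The stimulus pools (melodies, foils, and the masker-bed seed) depend
    only on ``master_seed``, so the four versions share materials; the
    SNR-stimulus pairing, match/mismatch assignment, spatial sides, trial
    order, and block order are re-randomized per version.  Per block:
    10 match + 10 mismatch, each SNR exactly 5 times (match counts 3/2
    counterbalanced across SNR levels so both marginals stay exact).
    """
    if not 1 <= version_id <= 4:
        raise InputError("version_id must be 1-4")
    cfg = config or SessionConfig()
    n_trials = cfg.trials_per_block
    n_snr = len(cfg.snr_levels)
    per_snr = n_trials // n_snr
    bed_seed = _sub_seed(master_seed, 9)

    blocks: dict[str, list[Trial]] = {}
    fam: dict[str, list[Trial]] = {}
    for ci, cond in enumerate(ALL_CONDITIONS):
        # --- stimulus pool (shared across versions) -----------------------
        pairs = []
        for item in range(n_trials):
            pseed = _sub_seed(master_seed, 0, ci, item)
            rhythm_pitch = None
            if cond == "rhythm":
                rhythm_pitch = int(
                    np.random.default_rng(pseed).integers(
                        cfg.melody.pitch_low + 6, cfg.melody.pitch_high - 5
                    )
                )
            pairs.append(make_pair(cfg.melody, pseed, rhythm_pitch=rhythm_pitch))

        # --- per-version randomization ------------------------------------
        rng = np.random.default_rng(_sub_seed(master_seed, 2, version_id, ci))
        if cond == CONTROL:
            snr_of_item = [None] * n_trials
        else:
            snrs = np.repeat(cfg.snr_levels, per_snr)
            snr_of_item = list(snrs[rng.permutation(n_trials)])
        # match counts per SNR: half the levels get ceil, half floor
        match_of_item = [False] * n_trials
        if cond == CONTROL:
            flags = rng.permutation(n_trials) < n_trials // 2
            match_of_item = list(map(bool, flags))
        else:
            hi_count = (per_snr + 1) // 2  # 3 when per_snr == 5
            lo_count = per_snr - hi_count
            counts = [hi_count] * (n_snr // 2) + [lo_count] * (n_snr - n_snr // 2)
            if sum(counts) * 2 != n_trials:  # odd split needs balancing
                counts = rng.permutation(counts).tolist()
            counts = list(np.array(counts)[rng.permutation(n_snr)])
            for level, cnt in zip(cfg.snr_levels, counts):
                items = [i for i in range(n_trials) if snr_of_item[i] == level]
                chosen = rng.permutation(items)[:cnt]
                for i in chosen:
                    match_of_item[int(i)] = True
        sides = None
        if cond == "spatial":
            sides_arr = np.array(["left"] * (n_trials // 2) + ["right"] * (n_trials - n_trials // 2))
            sides = list(sides_arr[rng.permutation(n_trials)])

        order = rng.permutation(n_trials)
        trials = []
        for pos, item in enumerate(order):
            item = int(item)
            tseed = _sub_seed(master_seed, 5, version_id, ci, item)
            offset = None
            if cond != CONTROL:
                dur = pairs[item].target.duration_seconds
                feasible = cfg.masker.bed_seconds - (dur + cfg.excerpt_margin_s)
                offset = float(np.random.default_rng(tseed).uniform(0.0, feasible))
            trials.append(
                assemble_trial(
                    cond,
                    pairs[item],
                    snr_of_item[item],
                    match_of_item[item],
                    seed=tseed,
                    trial_id=f"v{version_id}-{cond}-{pos:02d}",
                    item_index=item,
                    spatial_side=sides[item] if sides else None,
                    excerpt_offset=offset,
                    embed_offset=cfg.embed_offset_s,
                    isi_s=cfg.isi_s,
                )
            )
        blocks[cond] = trials

        # --- familiarization at the easiest SNR ---------------------------
        fam_trials = []
        easiest = max(cfg.snr_levels) if cond != CONTROL else None
        for j in range(cfg.familiarization_trials):
            fseed = _sub_seed(master_seed, 1, ci, j)
            rhythm_pitch = None
            if cond == "rhythm":
                rhythm_pitch = int(
                    np.random.default_rng(fseed).integers(
                        cfg.melody.pitch_low + 6, cfg.melody.pitch_high - 5
                    )
                )
            fpair = make_pair(cfg.melody, fseed, rhythm_pitch=rhythm_pitch)
            offset = None
            if cond != CONTROL:
                dur = fpair.target.duration_seconds
                feasible = cfg.masker.bed_seconds - (dur + cfg.excerpt_margin_s)
                offset = float(np.random.default_rng(fseed).uniform(0.0, feasible))
            fam_trials.append(
                assemble_trial(
                    cond,
                    fpair,
                    easiest,
                    is_match=(j % 2 == 0),
                    seed=fseed,
                    trial_id=f"v{version_id}-{cond}-fam{j}",
                    item_index=j,
                    spatial_side=("left", "right")[j % 2] if cond == "spatial" else None,
                    excerpt_offset=offset,
                    embed_offset=cfg.embed_offset_s,
                    isi_s=cfg.isi_s,
                    familiarization=True,
                )
            )
        fam[cond] = fam_trials

    order_rng = np.random.default_rng(_sub_seed(master_seed, 4, version_id))
    block_order = [ALL_CONDITIONS[i] for i in order_rng.permutation(len(ALL_CONDITIONS))]
    return SessionVersion(
        version_id=version_id,
        blocks=blocks,
        block_order=block_order,
        familiarization=fam,
        seeds={"master_seed": master_seed, "bed_seed": bed_seed},
        config=cfg,
    )


# ---------------------------------------------------------------------------
# rendering


@dataclass
class TrialAudio:
    """Rendered audio for one trial: two stereo intervals plus components."""

    interval_1: Waveform
    interval_2: Waveform
    mix: StereoMix | None  # components of the in-noise interval, if any
    isi_s: float


def _silent_interval(m: Melody, synth: SynthParams | None, sr: int) -> Waveform:
    w = render_melody(m, synth, sr)
    scaled = w.samples * (SILENT_INTERVAL_RMS / w.rms())
    return Waveform(np.column_stack([scaled, scaled]), sr)


def render_trial(
    trial: Trial,
    bed: MaskerBed | None,
    synth: SynthParams | None = None,
    config: SessionConfig | None = None,
) -> TrialAudio:
    """Render a trial's two intervals from its manifest record.

    Deterministic given the bed and synth: the excerpt offset and all gains
    are stored on the trial, so re-rendering reproduces identical audio.
    """
    cfg = config or SessionConfig()
    sr = bed.waveform.sample_rate if bed is not None else cfg.sample_rate
    silent = _silent_interval(trial.comparison, synth, sr)
    if trial.condition == CONTROL:
        first = _silent_interval(trial.target, synth, sr)
        return TrialAudio(first, silent, None, trial.isi_s)
    if bed is None:
        raise InputError("noise-condition trial needs a masker bed")
    target_wave = render_melody(trial.target, synth, sr)
    excerpt = extract_excerpt(
        bed,
        trial.target.duration_seconds,
        margin_s=cfg.excerpt_margin_s,
        offset=trial.excerpt_offset,
    )
    mix = mix_target_in_noise(target_wave, excerpt, trial.snr_db, cfg.embed_offset_s)
    if trial.condition == "spatial":
        mix = apply_spatial_cue(mix, trial.spatial_side)
    noise_int = mix.waveform
    if trial.interval_order == ("silence", "noise"):
        return TrialAudio(silent, noise_int, mix, trial.isi_s)
    return TrialAudio(noise_int, silent, mix, trial.isi_s)


# ---------------------------------------------------------------------------
# manifests

def _cue_to_dict(cue: PianoRollCue | None):
    if cue is None:
        return None
    return {"events": [list(e) for e in cue.events], "span": list(cue.span)}


def _cue_from_dict(d) -> PianoRollCue | None:
    if d is None:
        return None
    return PianoRollCue(
        events=tuple(tuple(e) for e in d["events"]), span=tuple(d["span"])
    )


def trial_to_dict(t: Trial) -> dict:
    return {
        "trial_id": t.trial_id,
        "condition": t.condition,
        "snr_db": t.snr_db,
        "is_match": t.is_match,
        "interval_order": list(t.interval_order),
        "isi_s": t.isi_s,
        "item_index": t.item_index,
        "spatial_side": t.spatial_side,
        "excerpt_offset": t.excerpt_offset,
        "familiarization": t.familiarization,
        "feedback": t.feedback,
        "seed": t.seed,
        "target": melody_to_dict(t.target),
        "foil": melody_to_dict(t.foil) if t.foil else None,
        "visual_cue": _cue_to_dict(t.visual_cue),
    }


def trial_from_dict(d: dict) -> Trial:
    return Trial(
        trial_id=d["trial_id"],
        condition=d["condition"],
        snr_db=d["snr_db"],
        is_match=d["is_match"],
        interval_order=tuple(d["interval_order"]),
        isi_s=d["isi_s"],
        target=melody_from_dict(d["target"]),
        foil=melody_from_dict(d["foil"]) if d["foil"] else None,
        item_index=d["item_index"],
        spatial_side=d["spatial_side"],
        visual_cue=_cue_from_dict(d["visual_cue"]),
        excerpt_offset=d["excerpt_offset"],
        familiarization=d["familiarization"],
        feedback=d["feedback"],
        seed=d["seed"],
    )


def _config_to_dict(cfg: SessionConfig) -> dict:
    d = asdict(cfg)
    return d


def session_to_json(session: SessionVersion, files: dict | None = None) -> str:
    doc = {
        "version_id": session.version_id,
        "seeds": session.seeds,
        "config": _config_to_dict(session.config),
        "block_order": session.block_order,
        "familiarization": {
            c: [trial_to_dict(t) for t in ts]
            for c, ts in session.familiarization.items()
        },
        "blocks": {
            c: [trial_to_dict(t) for t in ts] for c, ts in session.blocks.items()
        },
        "files": files or {},
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def session_from_json(text: str) -> SessionVersion:
    doc = json.loads(text)
    cfg_d = doc["config"]
    mel = cfg_d.pop("melody")
    msk = cfg_d.pop("masker")
    for key in ("snr_levels",):
        cfg_d[key] = tuple(cfg_d[key])
    mel = {
        k: tuple(v) if isinstance(v, list) else v for k, v in mel.items()
    }
    msk = {k: tuple(v) if isinstance(v, list) else v for k, v in msk.items()}
    cfg = SessionConfig(melody=MelodyParams(**mel), masker=MaskerConfig(**msk), **cfg_d)
    return SessionVersion(
        version_id=doc["version_id"],
        blocks={
            c: [trial_from_dict(t) for t in ts] for c, ts in doc["blocks"].items()
        },
        block_order=doc["block_order"],
        familiarization={
            c: [trial_from_dict(t) for t in ts]
            for c, ts in doc["familiarization"].items()
        },
        seeds=doc["seeds"],
        config=cfg,
    )


def session_to_frame(session: SessionVersion) -> pd.DataFrame:
    """Flat one-row-per-trial view of a session (familiarization included)."""
    rows = []
    for t in session.all_trials():
        rows.append(
            {
                "trial_id": t.trial_id,
                "condition": t.condition,
                "snr_db": t.snr_db,
                "is_match": t.is_match,
                "interval_1": t.interval_order[0],
                "interval_2": t.interval_order[1],
                "isi_s": t.isi_s,
                "item_index": t.item_index,
                "spatial_side": t.spatial_side,
                "excerpt_offset": t.excerpt_offset,
                "familiarization": t.familiarization,
                "target_id": t.target.id,
                "n_notes": len(t.target),
                "seed": t.seed,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def render_session(
    session: SessionVersion,
    out_dir,
    synth: SynthParams | None = None,
    write_components: bool = True,
    subtype: str = "float32",
    bed: MaskerBed | None = None,
) -> dict:
    """Render every trial to WAV under ``out_dir`` and write the manifests.

    Per trial: ``<id>_int1.wav`` and ``<id>_int2.wav`` (stereo intervals);
    noise trials additionally get ``<id>_target.wav`` / ``<id>_masker.wav``
    component tracks so SNR and ILD contracts can be re-verified from disk.
    If the summed mixture exceeds full scale, mixture and components are
    scaled jointly (recorded in the manifest), which preserves all ratios.
    Returns the file table {trial_id: {role: {path, sha256}}}.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    if bed is None:
        bed = make_masker_bed(
            session.seeds["bed_seed"], session.config.masker, session.config.sample_rate
        )
    files: dict[str, dict] = {}
    for trial in session.all_trials():
        audio = render_trial(trial, bed, synth, session.config)
        entry: dict[str, dict] = {}
        scale = 1.0
        if audio.mix is not None:
            peak = max(
                float(np.max(np.abs(audio.mix.mixture))),
                float(np.max(np.abs(audio.mix.target_track))),
                float(np.max(np.abs(audio.mix.masker_track))),
            )
            if peak > 0.99:
                scale = 0.99 / peak
        for role, wave in (("int1", audio.interval_1), ("int2", audio.interval_2)):
            w = wave
            if scale != 1.0 and role == ("int1" if trial.interval_order[0] == "noise" else "int2"):
                w = Waveform(wave.samples * scale, wave.sample_rate)
            path = os.path.join(out_dir, f"{trial.trial_id}_{role}.wav")
            write_wav(path, w, subtype)
            entry[role] = {"path": os.path.basename(path), "sha256": _sha256(path)}
        if write_components and audio.mix is not None:
            for role, track in (
                ("target", audio.mix.target_track),
                ("masker", audio.mix.masker_track),
            ):
                path = os.path.join(out_dir, f"{trial.trial_id}_{role}.wav")
                write_wav(path, Waveform(track * scale, audio.mix.sample_rate), subtype)
                entry[role] = {"path": os.path.basename(path), "sha256": _sha256(path)}
        entry["scale"] = scale
        entry["target_support"] = (
            list(audio.mix.target_support) if audio.mix is not None else None
        )
        files[trial.trial_id] = entry
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        fh.write(session_to_json(session, files))
    session_to_frame(session).to_csv(os.path.join(out_dir, "trials.csv"), index=False)
    return files


def load_session_dir(directory) -> tuple[SessionVersion, dict]:
    import os

    with open(os.path.join(directory, "manifest.json")) as fh:
        doc = json.load(fh)
    session = session_from_json(json.dumps(doc))
    return session, doc.get("files", {})


def validate_session(
    directory,
    snr_tolerance_db: float = 0.1,
    max_audio_checks: int = 20,
) -> dict:
    """Re-check a rendered session directory against its manifest.

    Verifies file presence and hashes for every referenced WAV, the block
    combinatorics, and — for up to ``max_audio_checks`` noise trials —
    re-measures SNR from the stored component tracks (and target ILD for
    spatial trials).  Returns a report dict with any violations listed.
    """
    import os

    from .audio import read_wav

    session, files = load_session_dir(directory)
    report = {"n_trials": 0, "violations": [], "snr_checked": 0, "ild_checked": 0}
    cfg = session.config
    for cond in ALL_CONDITIONS:
        block = session.blocks[cond]
        if len(block) != cfg.trials_per_block:
            report["violations"].append(f"{cond}: {len(block)} trials")
        n_match = sum(t.is_match for t in block)
        if n_match * 2 != cfg.trials_per_block:
            report["violations"].append(f"{cond}: {n_match} match trials")
        if cond != CONTROL:
            for level in cfg.snr_levels:
                k = sum(t.snr_db == level for t in block)
                if k != cfg.trials_per_block // len(cfg.snr_levels):
                    report["violations"].append(f"{cond}: SNR {level} x{k}")
    checked = 0
    for trial in session.all_trials():
        report["n_trials"] += 1
        entry = files.get(trial.trial_id, {})
        for role, info in entry.items():
            if not isinstance(info, dict):
                continue
            path = os.path.join(directory, info["path"])
            if not os.path.exists(path):
                report["violations"].append(f"{trial.trial_id}: missing {role}")
            elif _sha256(path) != info["sha256"]:
                report["violations"].append(f"{trial.trial_id}: hash mismatch {role}")
        if (
            checked < max_audio_checks
            and trial.condition != CONTROL
            and "target" in entry
        ):
            tw = read_wav(os.path.join(directory, entry["target"]["path"]))
            mw = read_wav(os.path.join(directory, entry["masker"]["path"]))
            support = tuple(entry["target_support"])
            snr = measure_snr(tw, mw, support)
            if abs(snr - trial.snr_db) > snr_tolerance_db:
                report["violations"].append(
                    f"{trial.trial_id}: SNR {snr:.2f} vs {trial.snr_db}"
                )
            report["snr_checked"] += 1
            if trial.condition == "spatial":
                ild = abs(
                    20 * np.log10(tw.channel(0).rms(support) / tw.channel(1).rms(support))
                )
                if abs(ild - 2 * SPATIAL_GAIN_DB) > 0.05:
                    report["violations"].append(
                        f"{trial.trial_id}: target ILD {ild:.2f} dB"
                    )
                report["ild_checked"] += 1
            checked += 1
    report["ok"] = not report["violations"]
    return report
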