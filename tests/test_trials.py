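"""SNR mixing, condition cues, trial and session assembly."""

import numpy as np
import pytest

from mint.audio import render_melody
from mint.errors import GeometryError, InputError
from mint.masker import extract_excerpt
from mint.melody import generate_melody, make_pair
from mint.trials import (
    ALL_CONDITIONS,
    CONTROL,
    NOISE_CONDITIONS,
    SNR_LEVELS,
    apply_spatial_cue,
    assemble_trial,
    build_session,
    make_visual_cue,
    measured_target_ild,
    mix_target_in_noise,
    render_session,
    render_trial,
    session_to_frame,
    session_to_json,
    validate_session,
)


@pytest.fixture(scope="module")
def mix(bed):
    m = generate_melody(seed=21)
    ex = extract_excerpt(bed, m.duration_seconds, seed=4)
    return mix_target_in_noise(render_melody(m), ex, snr_db=-6.0)


class TestMixing:
    @pytest.mark.parametrize("snr", SNR_LEVELS)
    def test_measured_snr_matches_configured(self, bed, snr):
        m = generate_melody(seed=int(5 + abs(snr)))
        ex = extract_excerpt(bed, m.duration_seconds, seed=8)
        mx = mix_target_in_noise(render_melody(m), ex, snr_db=snr)
        assert mx.measured_snr() == pytest.approx(snr, abs=0.1)

    def test_target_embedded_half_second_after_noise_onset(self, mix):
        assert mix.target_support[0] == pytest.approx(0.5, abs=1e-4)
        i0 = int(round(0.5 * mix.sample_rate))
        assert np.all(mix.target_track[:i0] == 0.0)

    def test_masker_unscaled_and_identical_across_snrs(self, bed):
        m = generate_melody(seed=33)
        ex = extract_excerpt(bed, m.duration_seconds, seed=5)
        w = render_melody(m)
        a = mix_target_in_noise(w, ex, 0.0)
        b = mix_target_in_noise(w, ex, -9.0)
        assert np.array_equal(a.masker_track, b.masker_track)
        assert np.array_equal(a.masker_track[:, 0], ex.waveform.samples)

    def test_mixture_is_exact_sum_of_components(self, mix):
        assert np.array_equal(
            mix.mixture, mix.target_track + mix.masker_track
        )

    def test_target_longer_than_excerpt_raises(self, bed):
        m = generate_melody(seed=21)
        ex = extract_excerpt(bed, m.duration_seconds, seed=4)
        long_target = render_melody(generate_melody(seed=2))
        padded = np.concatenate([long_target.samples, np.zeros(2 * 44100)])
        from mint.audio import Waveform

        with pytest.raises(GeometryError):
            mix_target_in_noise(Waveform(padded, 44100), ex, 0.0)


class TestSpatialCue:
    def test_target_ild_is_6_db(self, mix):
        sp = apply_spatial_cue(mix, "left")
        assert measured_target_ild(sp) == pytest.approx(6.0, abs=1e-9)

    def test_per_ear_snr_shifts_by_6_db_opposite_signs(self, mix):
        sp = apply_spatial_cue(mix, "left")
        assert sp.measured_snr(0) == pytest.approx(mix.snr_db + 6.0, abs=0.1)
        assert sp.measured_snr(1) == pytest.approx(mix.snr_db - 6.0, abs=0.1)

    def test_left_mirrored_equals_right(self, mix):
        left = apply_spatial_cue(mix, "left")
        right = apply_spatial_cue(mix, "right")
        assert np.allclose(left.target_track[:, ::-1], right.target_track)
        assert np.allclose(left.masker_track[:, ::-1], right.masker_track)

    def test_no_side_is_noop_with_warning(self, mix):
        with pytest.warns(UserWarning):
            out = apply_spatial_cue(mix, None)
        assert out is mix


class TestVisualCue:
    def test_one_event_per_note_with_pitch_order(self, melody):
        cue = make_visual_cue(melody)
        assert len(cue.events) == len(melody)
        vpos = {p: v for (_, _, v), p in zip(cue.events, melody.pitches)}
        ordered = sorted(set(melody.pitches))
        assert [vpos[p] for p in ordered] == sorted(vpos[p] for p in ordered)
        top = max(melody.pitches)
        assert vpos[top] == max(v for _, _, v in cue.events)

    def test_events_offset_by_embed_delay(self, melody):
        cue = make_visual_cue(melody, embed_offset=0.5)
        starts = [e[0] for e in cue.events]
        expected = [0.5 + n.onset_beats * 60 / melody.tempo_bpm for n in melody.notes]
        assert starts == pytest.approx(expected)
        assert cue.span[0] == 0.5
        assert cue.span[1] == pytest.approx(0.5 + melody.duration_seconds)


class TestTrialAssembly:
    def test_interval_order_per_condition(self):
        pair = make_pair(seed=1)
        assert assemble_trial("prediction", pair, -3.0, True).interval_order == (
            "silence",
            "noise",
        )
        assert assemble_trial("baseline", pair, -3.0, True).interval_order == (
            "noise",
            "silence",
        )
        assert assemble_trial(CONTROL, pair, None, True).interval_order == (
            "silence",
            "silence",
        )

    def test_mismatch_uses_foil_in_silence(self):
        pair = make_pair(seed=2)
        t = assemble_trial("baseline", pair, 0.0, is_match=False)
        assert t.comparison is pair.foil
        t = assemble_trial("baseline", pair, 0.0, is_match=True)
        assert t.comparison is pair.target

    def test_visual_cue_present_iff_visual(self):
        pair = make_pair(seed=3)
        assert assemble_trial("visual", pair, 0.0, True).visual_cue is not None
        for cond in ("baseline", "rhythm", "prediction", "spatial", CONTROL):
            assert assemble_trial(cond, pair, 0.0, True, seed=1).visual_cue is None

    def test_unknown_condition_raises(self):
        with pytest.raises(InputError):
            assemble_trial("sing-along", make_pair(seed=4), 0.0, True)

    def test_control_trial_has_no_masker_energy(self, mini_session):
        trial = mini_session.blocks[CONTROL][0]
        audio = render_trial(trial, None, config=mini_session.config)
        assert audio.mix is None
        assert audio.interval_1.n_channels == 2


class TestSession:
    def test_block_combinatorics(self, session):
        assert set(session.blocks) == set(ALL_CONDITIONS)
        for cond in ALL_CONDITIONS:
            block = session.blocks[cond]
            assert len(block) == 20
            assert sum(t.is_match for t in block) == 10
            if cond != CONTROL:
                for level in SNR_LEVELS:
                    assert sum(t.snr_db == level for t in block) == 5

    def test_familiarization_four_easiest_trials_with_feedback(self, session):
        for cond in ALL_CONDITIONS:
            fam = session.familiarization[cond]
            assert len(fam) == 4
            assert all(t.feedback for t in fam)
            if cond != CONTROL:
                assert all(t.snr_db == max(SNR_LEVELS) for t in fam)

    def test_spatial_sides_balanced(self, session):
        sides = [t.spatial_side for t in session.blocks["spatial"]]
        assert sides.count("left") == sides.count("right") == 10

    def test_versions_share_stimuli_but_differ_in_snr_pairing(self, session):
        other = build_session(2, session.seeds["master_seed"], session.config)

        def by_item(s, cond):
            return {t.item_index: t for t in s.blocks[cond]}

        for cond in NOISE_CONDITIONS:
            a, b = by_item(session, cond), by_item(other, cond)
            assert all(a[i].target.notes == b[i].target.notes for i in a)
            assert [a[i].snr_db for i in sorted(a)] != [
                b[i].snr_db for i in sorted(b)
            ]

    def test_rebuild_reproduces_manifest_exactly(self, session):
        again = build_session(1, session.seeds["master_seed"], session.config)
        assert session_to_json(again) == session_to_json(session)

    def test_frame_has_one_row_per_trial(self, session):
        df = session_to_frame(session)
        assert len(df) == 6 * 20 + 6 * 4
        assert df.trial_id.is_unique


class TestRenderAndValidate:
    def test_rendered_session_passes_validation(self, mini_session, tmp_path):
        out = tmp_path / "v1"
        render_session(mini_session, out)
        report = validate_session(out, max_audio_checks=30)
        assert report["ok"], report["violations"]
        assert report["snr_checked"] > 0
        assert report["ild_checked"] > 0

    def test_hash_mismatch_detected(self, mini_session, tmp_path):
        out = tmp_path / "v2"
        files = render_session(mini_session, out, write_components=False)
        some_wav = next(iter(files.values()))["int1"]["path"]
        with open(out / some_wav, "r+b") as fh:
            fh.seek(100)
            fh.write(b"\x00\x01\x02\x03")
        report = validate_session(out, max_audio_checks=0)
        assert not report["ok"]
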