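"""Ground-truth spindle generation, rendering, and filtering."""

import numpy as np
import pytest
from scipy import signal

from spindlesync import (
    CorePatch,
    GeneratorConfig,
    SpindleEvent,
    empty_room_recording,
    filter_recording,
    render_recording,
    sample_durations,
    sample_spindle_events,
    synthesize_background,
    synthesize_core_activity,
    synthesize_matrix_activity,
)
from spindlesync.simulate import attach_array, patch_members
from spindlesync import assemble_gain


@pytest.fixture(scope="module")
def gen():
    return GeneratorConfig(n_subjects=1, spindles_per_subject=6, seed=0)


class TestDurations:
    def test_moments_match_printed_values(self, rng):
        d = sample_durations(10_000, rng) * 1e3  # ms
        assert d.mean() == pytest.approx(721, abs=5)
        assert d.std() == pytest.approx(235, abs=5)

    def test_truncation(self, rng):
        d = sample_durations(10_000, rng) * 1e3
        assert d.min() >= 483 and d.max() <= 1123


class TestEvents:
    def test_events_valid_and_disjoint(self, gen, small_source_space):
        events = sample_spindle_events(gen, small_source_space, seed=4)
        assert len(events) == gen.spindles_per_subject
        events = sorted(events, key=lambda e: e.onset)
        for a, b in zip(events, events[1:]):
            assert a.offset < b.onset
        for ev in events:
            assert 10 <= ev.matrix_frequency <= 15
            for p in ev.core_patches:
                assert 10 <= p.frequency <= 15
                assert p.radius > 0

    def test_unfittable_count_raises(self, small_source_space):
        gen = GeneratorConfig(spindles_per_subject=300, record_duration=30.0)
        with pytest.raises(ValueError, match="cannot fit"):
            sample_spindle_events(gen, small_source_space, seed=0)

    def test_core_centers_are_tangential(self, gen, small_source_space):
        events = sample_spindle_events(gen, small_source_space, seed=4)
        ss = small_source_space
        u = ss.positions / np.linalg.norm(ss.positions, axis=1, keepdims=True)
        radiality = np.abs(np.sum(ss.orientations * u, axis=1))
        pool_max = np.sort(radiality)[max(20, ss.n_sources // 10) - 1]
        for ev in events:
            for p in ev.core_patches:
                assert radiality[p.center_source_index] <= pool_max + 1e-12


def _event(duration=0.8, f=12.0, patches=()):
    return SpindleEvent(
        onset=1.0, duration=duration, matrix_frequency=f, matrix_phase=0.3,
        core_patches=patches,
    )


class TestMatrixActivity:
    def test_perfect_synchrony(self, gen, small_source_space):
        act = synthesize_matrix_activity(_event(), small_source_space, gen)
        v = act.values
        r = np.corrcoef(v[3], v[77])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_envelope_endpoints_zero(self, gen, small_source_space):
        v = synthesize_matrix_activity(_event(), small_source_space, gen).values
        assert np.all(v[:, 0] == 0) and np.all(v[:, -1] == 0)

    def test_spectral_peak_at_event_frequency(self, gen, small_source_space):
        act = synthesize_matrix_activity(_event(f=12.0), small_source_space, gen)
        f, p = signal.periodogram(act.values[5], fs=gen.sampling_rate)
        assert abs(f[np.argmax(p)] - 12.0) <= 0.5


class TestCoreActivity:
    def test_patch_structure(self, gen, small_source_space):
        ss = small_source_space
        p1 = CorePatch(3, 0.012, 10.5, 0.1, 0.0, 0.0, 1e-8)
        p2 = CorePatch(90, 0.012, 14.5, 1.2, 0.0, 0.0, 1e-8)
        act = synthesize_core_activity(_event(patches=(p1, p2)), ss, gen)
        m1, m2 = patch_members(ss, p1), patch_members(ss, p2)
        assert set(m1).isdisjoint(m2)
        # same patch: identical waveform
        assert np.corrcoef(act.values[m1[0]], act.values[m1[-1]])[0, 1] == pytest.approx(1.0, abs=1e-12)
        # distinct frequencies decorrelate over >= 0.7 s
        r = np.corrcoef(act.values[m1[0]], act.values[m2[0]])[0, 1]
        assert abs(r) < 0.2
        # untouched sources are silent
        outside = np.setdiff1d(np.arange(ss.n_sources), np.concatenate([m1, m2]))
        assert np.all(act.values[outside] == 0)

    def test_requires_patches(self, gen, small_source_space):
        with pytest.raises(ValueError, match="no core patches"):
            synthesize_core_activity(_event(), small_source_space, gen)

    def test_oversized_patch_raises(self, gen, small_source_space):
        huge = CorePatch(0, 1.0, 12.0, 0.0, 0.0, 0.0, 1e-8)
        with pytest.raises(ValueError, match="radius"):
            synthesize_core_activity(_event(patches=(huge,)), small_source_space, gen)


class TestBackground:
    def test_zero_amplitude(self, gen, small_source_space):
        cfg = GeneratorConfig(background_amplitude=0.0)
        act = synthesize_background(1000, small_source_space, cfg, seed=0)
        assert np.all(act.values == 0)

    def test_one_over_f_slope(self, small_source_space):
        cfg = GeneratorConfig(background_amplitude=1e-9)
        act = synthesize_background(2**15, small_source_space, cfg, seed=1)
        f, p = signal.welch(act.values[0], fs=cfg.sampling_rate, nperseg=4096)
        band = (f >= 1) & (f <= 40)
        slope = np.polyfit(np.log(f[band]), np.log(p[band]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.3)

    def test_sources_independent(self, small_source_space):
        """Distinct sources' backgrounds are independent draws: their
        correlation is zero within the Bartlett null scale for colored
        series (3 * sqrt(sum rho^2 / T), the analog of 3/sqrt(T) for
        white noise)."""
        T = 5000
        cfg = GeneratorConfig(background_amplitude=1e-9)
        act = synthesize_background(T, small_source_space, cfg, seed=1)
        x, y = act.values[0], act.values[64]
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        r = float(x @ y) / T
        acf_x = np.correlate(x, x, "full")[T - 1 : T + 200] / T
        acf_y = np.correlate(y, y, "full")[T - 1 : T + 200] / T
        var_r = (acf_x[0] * acf_y[0] + 2 * np.sum(acf_x[1:] * acf_y[1:])) / T
        assert abs(r) < 3 * np.sqrt(var_r)
        # and the null scale itself is modest at this record length
        assert np.sqrt(var_r) < 0.1


@pytest.fixture(scope="module")
def small_gain(small_source_space, eeg_array, head):
    gain = assemble_gain(small_source_space, eeg_array, head)
    return attach_array(gain, eeg_array)


class TestRendering:
    def test_zero_activity_zero_noise(self, small_gain, small_source_space):
        cfg = GeneratorConfig(
            record_duration=70.0, quiet_epochs_per_subject=30,
            sensor_noise_sd={"EEG": 0.0, "MAG": 0.0, "GRAD1": 0.0, "GRAD2": 0.0},
        )
        rec = render_recording([], small_gain, small_source_space, cfg, seed=0)
        assert np.all(rec.values == 0)

    def test_linearity_in_amplitude(self, small_gain, small_source_space, gen):
        cfg = GeneratorConfig(
            record_duration=70.0, quiet_epochs_per_subject=30,
            sensor_noise_sd={"EEG": 0.0, "MAG": 0.0, "GRAD1": 0.0, "GRAD2": 0.0},
        )
        act = synthesize_matrix_activity(_event(), small_source_space, cfg)
        rec1 = render_recording([act], small_gain, small_source_space, cfg, seed=0)
        act2 = synthesize_matrix_activity(_event(), small_source_space, cfg)
        act2.values *= 2.0
        rec2 = render_recording([act2], small_gain, small_source_space, cfg, seed=0)
        assert np.allclose(rec2.values, 2.0 * rec1.values, rtol=1e-12)

    def test_matrix_topography_stable_across_spindles(
        self, small_gain, small_source_space
    ):
        """The diffuse system projects a fixed spatial pattern: the first
        principal component of the sensor covariance is the same for any
        two spindles."""
        cfg = GeneratorConfig(
            record_duration=70.0, quiet_epochs_per_subject=30,
            sensor_noise_sd={"EEG": 0.0, "MAG": 0.0, "GRAD1": 0.0, "GRAD2": 0.0},
        )
        ev1 = _event(f=11.0)
        ev2 = SpindleEvent(onset=3.0, duration=0.9, matrix_frequency=14.0, matrix_phase=2.0)
        patterns = []
        for ev in (ev1, ev2):
            act = synthesize_matrix_activity(ev, small_source_space, cfg)
            rec = render_recording([act], small_gain, small_source_space, cfg, seed=0)
            x = rec.values[:, rec.sample_slice(rec.annotations[0])]
            _, _, vt = np.linalg.svd(x.T - x.T.mean(0), full_matrices=False)
            patterns.append(vt[0])
        r = abs(np.corrcoef(patterns[0], patterns[1])[0, 1])
        assert r > 0.9

    def test_annotations_cover_events_and_quiet(self, small_gain, small_source_space):
        cfg = GeneratorConfig(record_duration=70.0, quiet_epochs_per_subject=30)
        act = synthesize_matrix_activity(_event(), small_source_space, cfg)
        rec = render_recording([act], small_gain, small_source_space, cfg, seed=0)
        spindles = [a for a in rec.annotations if a.label == "spindle"]
        quiet = [a for a in rec.annotations if a.label == "quiet_epoch"]
        assert len(spindles) == 1 and len(quiet) == 30
        for q in quiet:
            assert q.offset <= spindles[0].onset or q.onset >= spindles[0].offset


class TestEmptyRoom:
    def test_noise_statistics(self, meg_array):
        cfg = GeneratorConfig()
        rec = empty_room_recording(meg_array, cfg, 20_000, seed=3)
        assert rec.provenance == "empty_room"
        var = rec.values.var(axis=1)
        expected = np.array(
            [cfg.sensor_noise_sd[ch.kind.value] ** 2 for ch in meg_array.channels]
        )
        assert np.all(np.abs(var / expected - 1) < 0.1)
        r = np.corrcoef(rec.values[0], rec.values[150])[0, 1]
        assert abs(r) < 3 / np.sqrt(20_000)

    def test_eeg_refused(self, eeg_array):
        with pytest.raises(ValueError, match="empty-room"):
            empty_room_recording(eeg_array, GeneratorConfig(), 1000, seed=0)


class TestFiltering:
    def _tone_recording(self, eeg_array, freq, n=5000, fs=500.0, dc=0.0):
        from spindlesync.simulate import Recording

        t = np.arange(n) / fs
        vals = np.tile(np.sin(2 * np.pi * freq * t) + dc, (60, 1))
        return Recording(values=vals, sampling_rate=fs, array=eeg_array)

    def test_passband_tone_preserved(self, eeg_array):
        rec = self._tone_recording(eeg_array, 12.0)
        out = filter_recording(rec, "band10_15")
        x, y = rec.values[0, 1000:-1000], out.values[0, 1000:-1000]
        gain = np.sqrt((y**2).mean() / (x**2).mean())
        assert gain > 0.95
        # zero-phase: in-phase with the input tone
        phase = np.arccos((x @ y) / np.linalg.norm(x) / np.linalg.norm(y))
        assert np.degrees(phase) < 1.0

    def test_stopband_tone_rejected(self, eeg_array):
        rec = self._tone_recording(eeg_array, 25.0)
        out = filter_recording(rec, "band10_15")
        atten = 1 - out.values[0, 1000:-1000].std() / rec.values[0, 1000:-1000].std()
        assert atten > 0.95

    def test_dc_removed(self, eeg_array):
        rec = self._tone_recording(eeg_array, 12.0, dc=5.0)
        out = filter_recording(rec, "band10_15")
        assert abs(out.values[0, 500:-500].mean()) < 1e-3

    def test_short_record_raises(self, eeg_array):
        rec = self._tone_recording(eeg_array, 12.0, n=100)
        with pytest.raises(ValueError, match="too short"):
            filter_recording(rec, "band10_15")

    def test_annotations_preserved(self, small_source_space, eeg_array, head):
        gain = attach_array(assemble_gain(small_source_space, eeg_array, head), eeg_array)
        cfg = GeneratorConfig(record_duration=70.0, quiet_epochs_per_subject=30)
        act = synthesize_matrix_activity(_event(), small_source_space, cfg)
        rec = render_recording([act], gain, small_source_space, cfg, seed=0)
        out = filter_recording(rec, "lowpass40")
        assert out.annotations == rec.annotations


class TestReproducibility:
    def test_identical_seeds_bit_identical(self, small_source_space, eeg_array, head):
        gain = attach_array(assemble_gain(small_source_space, eeg_array, head), eeg_array)
        cfg = GeneratorConfig(record_duration=70.0, quiet_epochs_per_subject=30)
        ev = sample_spindle_events(cfg, small_source_space, seed=9)[0]
        out = []
        for _ in range(2):
            act = synthesize_matrix_activity(ev, small_source_space, cfg)
            bg = synthesize_background(
                int(70 * cfg.sampling_rate), small_source_space, cfg, seed=9
            )
            rec = render_recording([act], gain, small_source_space, cfg, seed=9)
            out.append((act.values.copy(), bg.values.copy(), rec.values.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])
        assert np.array_equal(out[0][2], out[1][2])
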