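import numpy as np
import pytest

from nightcough.features import (VOICED_H_BAND, VOICED_H_WIN_S, _voiced_track)
from nightcough.synth import (DEFAULT_TRANSITIONS, STAGES, Hypnogram,
                              SynthConfig, cough_wave, generate_event,
                              generate_hypnogram, generate_night, noise_wave,
                              pink_noise, read_annotations_csv, snore_wave,
                              stage_dependent_cough_times,
                              write_annotations_csv, write_hypnogram_tsv,
                              write_wav)

SR = 16_000


class TestGenerateEvent:
    def test_voiced_cough_passes_voiced_oracle(self, rng, synth_config):
        # the post-0.079 s tail must exceed the 0.45 voicing criterion
        for _ in range(10):
            w = generate_event("cough", True, synth_config, rng)
            tail = w[int(0.079 * SR):]
            track = _voiced_track(tail, SR, VOICED_H_BAND, VOICED_H_WIN_S)
            assert track.max() > 0.45

    def test_unvoiced_cough_duration(self, rng, synth_config):
        for _ in range(20):
            w = generate_event("cough", False, synth_config, rng)
            assert 0.15 <= len(w) / SR <= 1.1

    def test_zero_amplitude_gives_silence(self, rng, synth_config):
        for kind in ("cough", "snore", "noise"):
            w = generate_event(kind, False, synth_config, rng, amplitude=0.0)
            assert np.all(w == 0)

    def test_unknown_kind_errors(self, rng, synth_config):
        with pytest.raises(ValueError, match="unknown event kind"):
            generate_event("sneeze", False, synth_config, rng)

    def test_peak_amplitude_bounded(self, rng, synth_config):
        for kind in ("cough", "snore", "noise"):
            w = generate_event(kind, kind == "cough", synth_config, rng)
            assert np.abs(w).max() <= 1.0

    def test_snore_autocorr_lag_matches_f0(self, rng):
        # oracle: direct autocorrelation peak lag == round(sr / f0) +- 1
        for f0 in (20.0, 35.0, 60.0, 90.0):
            x = snore_wave(f0, 0.8, SR, rng, amplitude=0.8)
            x = x - x.mean()
            ac = np.correlate(x, x, "full")[len(x) - 1:]
            lo, hi = SR // 100, SR // 10   # 10-100 Hz band
            lag = lo + int(np.argmax(ac[lo:hi]))
            assert abs(lag - round(SR / f0)) <= 1


class TestHypnogram:
    def test_epoch_count(self, rng):
        hyp = generate_hypnogram(90.0, rng)
        assert len(hyp) == 3

    def test_identity_matrix_absorbing(self, rng):
        hyp = generate_hypnogram(3600.0, rng, transition_matrix=np.eye(5),
                                 start_stage="W")
        assert all(s == "W" for s in hyp.stages)

    def test_n2_occupancy_dominant(self):
        # Monte-Carlo check of the default chain's stationary distribution:
        # 1000 replicates of an 8 h night, N2 occupancy the largest
        n_rep, n_epochs = 1000, 960
        rng = np.random.default_rng(0)
        cum = np.cumsum(DEFAULT_TRANSITIONS, axis=1)
        states = np.zeros(n_rep, dtype=int)   # start Wake
        occupancy = np.zeros(5)
        for _ in range(n_epochs):
            u = rng.random(n_rep)
            states = (cum[states] < u[:, None]).sum(axis=1)
            np.add.at(occupancy, states, 1)
        assert int(np.argmax(occupancy)) == STAGES.index("N2")

    def test_too_short_errors(self, rng):
        with pytest.raises(ValueError):
            generate_hypnogram(29.0, rng)

    def test_invalid_matrix_errors(self, rng):
        with pytest.raises(ValueError):
            generate_hypnogram(300.0, rng, transition_matrix=np.ones((5, 5)))

    def test_stage_at_convention(self):
        hyp = Hypnogram(stages=["W", "N1", "N2"])
        assert hyp.stage_at(0.0) == "W"
        assert hyp.stage_at(30.0) == "N1"   # boundary belongs to next epoch
        with pytest.raises(ValueError):
            hyp.stage_at(90.0)


class TestGenerateNight:
    def test_zero_rates_background_only(self):
        cfg = SynthConfig(night_duration=60.0,
                          events_per_hour={"cough": 0, "snore": 0, "noise": 0})
        night = generate_night(cfg)
        assert night.annotations == []
        bg_rms = 10 ** (-cfg.event_to_background_snr / 20)
        assert np.abs(night.samples).max() < 8 * bg_rms

    def test_poisson_event_counts(self):
        # count draws follow Poisson(rate * hours): mean ~= var ~= 20
        from nightcough.synth import _poisson_counts
        cfg = SynthConfig(night_duration=3600.0,
                          events_per_hour={"cough": 20.0, "snore": 0, "noise": 0})
        counts = [_poisson_counts(cfg, np.random.default_rng(s))["cough"]
                  for s in range(2000)]
        assert np.mean(counts) == pytest.approx(20.0, abs=0.5)
        assert np.var(counts) == pytest.approx(20.0, rel=0.15)

    def test_voiced_fraction(self):
        # voiced:unvoiced defaults to 2:3 -> fraction 0.4
        voiced = total = 0
        for seed in range(6):
            cfg = SynthConfig(night_duration=300.0, rng_seed=seed,
                              voiced_cough_fraction=0.4,
                              events_per_hour={"cough": 1200.0, "snore": 0,
                                               "noise": 0})
            night = generate_night(cfg)
            coughs = [a for a in night.annotations if a.label == "cough"]
            voiced += sum(a.voiced for a in coughs)
            total += len(coughs)
        assert total > 400
        assert voiced / total == pytest.approx(0.4, abs=0.07)

    def test_annotations_sorted_nonoverlapping(self):
        cfg = SynthConfig(night_duration=300.0, rng_seed=4,
                          events_per_hour={"cough": 60, "snore": 200, "noise": 200})
        night = generate_night(cfg)
        anns = night.annotations
        assert all(a.offset_s > a.onset_s for a in anns)
        for a, b in zip(anns, anns[1:]):
            assert a.offset_s <= b.onset_s
        assert all(0 <= a.onset_s and a.offset_s <= 300.0 for a in anns)

    def test_cough_durations_in_detector_band(self):
        cfg = SynthConfig(night_duration=300.0, rng_seed=5,
                          events_per_hour={"cough": 200, "snore": 0, "noise": 0})
        night = generate_night(cfg)
        for a in night.annotations:
            assert 0.15 <= a.duration <= 1.1

    def test_bit_reproducible(self):
        cfg = SynthConfig(night_duration=60.0, rng_seed=77)
        a = generate_night(cfg)
        b = generate_night(cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.annotations == b.annotations
        assert a.hypnogram.stages == b.hypnogram.stages

    def test_overcrowded_night_errors(self):
        cfg = SynthConfig(night_duration=40.0,
                          events_per_hour={"cough": 0, "snore": 0,
                                           "noise": 20000.0})
        with pytest.raises(RuntimeError, match="overlap"):
            generate_night(cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SynthConfig(voiced_cough_fraction=1.5)
        with pytest.raises(ValueError):
            SynthConfig(snore_f0_range=(5.0, 80.0))
        with pytest.raises(ValueError):
            SynthConfig(events_per_hour={"cough": -1, "snore": 0, "noise": 0})


class TestStageDependentCoughs:
    def test_rates_modulate_counts(self, rng):
        hyp = Hypnogram(stages=["W"] * 60 + ["N3"] * 60)
        times = stage_dependent_cough_times(hyp, {"W": 40.0, "N3": 1.0}, rng)
        w_count = sum(1 for t in times if t < 1800)
        n3_count = len(times) - w_count
        assert w_count > 5 * max(n3_count, 1)

    def test_times_within_span(self, rng):
        hyp = Hypnogram(stages=["N2"] * 10)
        times = stage_dependent_cough_times(hyp, {"N2": 120.0}, rng)
        assert all(0 <= t < 300 for t in times)


class TestWriters:
    def test_roundtrip_files(self, tmp_path, rng):
        cfg = SynthConfig(night_duration=60.0, rng_seed=1,
                          events_per_hour={"cough": 60, "snore": 60, "noise": 60})
        night = generate_night(cfg)
        write_wav(night, tmp_path / "n.wav")
        write_annotations_csv(night.annotations, tmp_path / "a.csv")
        write_hypnogram_tsv(night.hypnogram, tmp_path / "h.tsv")

        from scipy.io import wavfile
        rate, data = wavfile.read(tmp_path / "n.wav")
        assert rate == SR and data.dtype == np.int16
        anns = read_annotations_csv(tmp_path / "a.csv")
        assert len(anns) == len(night.annotations)
        assert anns[0].label == night.annotations[0].label

        from nightcough.sleep import read_hypnogram_tsv
        hyp = read_hypnogram_tsv(tmp_path / "h.tsv")
        assert hyp.stages == night.hypnogram.stages

    def test_pink_noise_unit_rms(self, rng):
        x = pink_noise(1 << 16, rng)
        assert np.std(x) == pytest.approx(1.0, rel=1e-6)
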