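"""Filtering, epoching, artifact rejection, referencing and EOG control."""

import numpy as np
import pytest

from eegspan import (average_reference, bandpass, eog_variability,
                     epoch_and_baseline, reject_by_variance)
from eegspan.preprocess import interpolate_channels, preprocess_pipeline

from conftest import make_recording


def tone(freq, secs=60.0, fs=250.0):
    t = np.arange(int(secs * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_passband_preserved(self):
        rec = make_recording(tone(10.0)[None, :])
        out = bandpass(rec, 0.5, 45.0)
        mid = slice(5000, 10000)  # away from edge transients
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio > 0.99

    def test_stopband_attenuated(self):
        rec = make_recording(tone(60.0)[None, :])
        out = bandpass(rec, 0.5, 45.0)
        mid = slice(5000, 10000)
        assert out.data[0, mid].std() / rec.data[0, mid].std() < 0.05

    def test_band_limiting_reduces_noise_variance(self, rng):
        rec = make_recording(rng.standard_normal((3, 15000)))
        out = bandpass(rec, 0.5, 45.0)
        assert np.all(out.data.var(axis=1) < rec.data.var(axis=1))

    def test_invalid_band_rejected(self, rng):
        rec = make_recording(rng.standard_normal((1, 5000)))
        with pytest.raises(ValueError):
            bandpass(rec, 50.0, 45.0)


class TestEpoching:
    def test_constant_offset_removed(self):
        rec = make_recording(np.full((2, 150000), 7.3))
        out = epoch_and_baseline(rec, 10.0, 60)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_ten_minutes_sixty_epochs(self, rng):
        rec = make_recording(rng.standard_normal((3, 160000)))
        out = epoch_and_baseline(rec, 10.0, 60)
        assert out.data.shape == (3, 60, 2500)
        assert out.epoch_length == 10.0

    def test_per_epoch_means_zero(self, rng):
        rec = make_recording(rng.standard_normal((4, 150000)) + 5.0)
        out = epoch_and_baseline(rec, 10.0, 60)
        assert np.max(np.abs(out.data.mean(axis=2))) < 1e-10

    def test_insufficient_duration(self, rng):
        rec = make_recording(rng.standard_normal((2, 1000)))
        with pytest.raises(ValueError, match="required"):
            epoch_and_baseline(rec, 10.0, 60)


class TestVarianceRejection:
    def test_noisy_channel_rejected(self, rng):
        data = rng.standard_normal((8, 20, 500))
        data[3] *= 10.0  # 100× variance
        rec = make_recording(data)
        out, report = reject_by_variance(rec, z_channel=2.0, z_epoch=5.0)
        # brute-force z-score of log variance
        logv = np.log(data.var(axis=2)).mean(axis=1)
        z = (logv - logv.mean()) / logv.std()
        assert z[3] > 2.0
        assert report.rejected_channels == ["E4"]
        assert out.n_channels == 7

    def test_homogeneous_data_untouched(self, rng):
        rec = make_recording(rng.standard_normal((8, 20, 500)))
        out, report = reject_by_variance(rec, z_channel=5.0, z_epoch=5.0)
        assert report.n_rejected == 0
        assert out.data.shape == rec.data.shape

    def test_mass_rejection_aborts(self, rng):
        data = rng.standard_normal((8, 20, 500))
        data[:5] *= 40.0
        rec = make_recording(data)
        with pytest.raises(RuntimeError, match="50%"):
            reject_by_variance(rec, z_channel=0.1, z_epoch=5.0)


class TestAverageReference:
    def test_identical_channels_become_zero(self):
        row = np.sin(np.linspace(0, 20, 5000))
        rec = make_recording(np.stack([row, row]))
        out = average_reference(rec)
        assert np.allclose(out.data, 0.0, atol=1e-12)

    def test_channel_mean_zero_everywhere(self, rng):
        rec = make_recording(rng.standard_normal((7, 10, 400)))
        out = average_reference(rec)
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-10

    def test_idempotent(self, rng):
        rec = make_recording(rng.standard_normal((5, 3000)))
        once = average_reference(rec)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_commutes_with_baseline(self, rng):
        rec = make_recording(rng.standard_normal((5, 150000)))
        a = average_reference(epoch_and_baseline(rec, 10.0, 60))
        b = epoch_and_baseline(average_reference(rec), 10.0, 60)
        assert np.max(np.abs(a.data - b.data)) < 1e-9


class TestInterpolation:
    def test_rejected_channel_refilled_from_neighbours(self, rng, montage_small):
        data = rng.standard_normal((12, 4, 500))
        rec = make_recording(data, labels=montage_small.labels)
        reduced = rec.copy_with(np.delete(data, 5, axis=0),
                                labels=tuple(l for i, l in
                                             enumerate(montage_small.labels)
                                             if i != 5))
        out = interpolate_channels(reduced, montage_small,
                                   [montage_small.labels[5]])
        assert out.labels == montage_small.labels
        # refilled channel is a convex combination of neighbours: bounded
        assert np.all(np.abs(out.data[5]) <= np.abs(data).max())


class TestEog:
    def _raw(self, data, fs=250.0):
        labels = ("25", "127", "8", "126")
        return make_recording(data, fs, labels=labels)

    def test_stationary_noise_halves_balanced(self, rng):
        raw = self._raw(rng.standard_normal((4, 60000)))
        tc = eog_variability(raw)
        assert abs(tc.halves_means[0] - tc.halves_means[1]) < 0.1
        assert tc.values.mean() == pytest.approx(1.0)

    def test_bursts_in_first_half_detected(self, rng):
        data = 0.01 * rng.standard_normal((4, 60000))
        t = np.arange(30000) / 250.0
        data[0, :30000] += 5.0 * np.sin(2 * np.pi * 2.0 * t)  # 2 Hz bursts
        tc = eog_variability(self._raw(data))
        assert tc.halves_means[0] > tc.halves_means[1]

    def test_all_zero_flagged_degenerate(self):
        tc = eog_variability(self._raw(np.zeros((4, 30000))))
        assert tc.degenerate
        assert np.all(tc.values == 0)

    def test_missing_channels_named(self, rng):
        raw = make_recording(rng.standard_normal((2, 30000)),
                             labels=("25", "127"))
        with pytest.raises(ValueError, match="126"):
            eog_variability(raw)


class TestPipeline:
    def test_order_and_provenance(self, rng, montage_small):
        rec = make_recording(rng.standard_normal((12, 40000)),
                             labels=montage_small.labels)
        out, report = preprocess_pipeline(rec, montage_small,
                                          epoch_length=2.0, n_epochs=10)
        steps = [p.split(":")[0] for p in out.provenance]
        assert steps == ["bandpass", "epoch", "reject", "average_reference"]
        assert np.isfinite(out.data).all()
        assert np.max(np.abs(out.data.mean(axis=0))) < 1e-9
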