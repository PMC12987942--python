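import numpy as np
import pytest

import microspike as ms
from microspike.waveforms import DriftResult, drift_test, template_distances


def _pulse_recording(centers, amp=8.0, rate=10_000.0, duration=2.0):
    """Recording with ideal biphasic pulses at the given times."""
    n = int(duration * rate)
    samples = np.zeros(n)
    t = np.arange(-20, 21) / 10.0  # ms grid at 10 kHz
    kernel = np.exp(-(t**2) / (2 * 0.35**2)) - 0.8 * np.exp(-((t - 0.6) ** 2) / (2 * 0.35**2))
    kernel /= kernel.max()
    for c in centers:
        i = int(round(c * rate))
        samples[i - 20 : i + 21] += amp * kernel
    return ms.Recording(samples=samples, rate=rate)


class TestAlignment:
    def test_center_is_steepest_falling_edge(self):
        rec = _pulse_recording([1.0])
        w = ms.extract_and_align(rec, 1.0, search_halfwidth_ms=1.0)
        # oracle: explicit argmin over the first differences in the search span
        i = rec.sample_index(1.0)
        diffs = np.diff(rec.samples[i - 10 : i + 12])
        expected = i - 10 + int(np.argmin(diffs))
        assert rec.sample_index(w.source_time) == expected
        assert w.center_index == 15

    def test_realignment_is_idempotent(self):
        rec = _pulse_recording([1.0])
        w1 = ms.extract_and_align(rec, 1.0)
        w2 = ms.extract_and_align(rec, w1.source_time)
        assert w1.source_time == w2.source_time
        np.testing.assert_array_equal(w1.values, w2.values)

    def test_translation_invariance(self):
        rec = _pulse_recording([0.5, 1.3])
        w1 = ms.extract_and_align(rec, 0.5)
        w2 = ms.extract_and_align(rec, 1.3)
        np.testing.assert_allclose(w1.values, w2.values, atol=1e-12)

    def test_edge_clipping_raises(self):
        rec = _pulse_recording([1.0])
        with pytest.raises(ms.BoundaryError):
            ms.extract_and_align(rec, 0.0005)

    def test_flat_signal_raises(self):
        rec = ms.Recording(samples=np.zeros(10_000))
        with pytest.raises(ms.DegenerateSignalError):
            ms.extract_and_align(rec, 0.5)


class TestTemplate:
    def _wave(self, values):
        return ms.SpikeWaveform(values=np.asarray(values, float), center_index=15, source_time=0.0)

    def test_single_waveform_is_its_own_template(self):
        v = np.sin(np.arange(30) / 3.0)
        tpl = ms.compute_template([self._wave(v)])
        np.testing.assert_array_equal(tpl.values, v)
        assert tpl.n_spikes == 1
        assert tpl.amplitude == pytest.approx(np.max(np.abs(v)))

    def test_opposite_waveforms_cancel(self):
        v = np.sin(np.arange(30) / 3.0)
        tpl = ms.compute_template([self._wave(v), self._wave(-v)])
        np.testing.assert_allclose(tpl.values, 0.0, atol=1e-15)
        assert tpl.amplitude == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_template_converges_at_clt_rate(self, seed):
        """100 noisy copies (sd σ) deviate from truth by < 5σ/√100."""
        rng = np.random.default_rng(seed)
        shape = 6.0 * np.exp(-((np.arange(30) - 15.0) ** 2) / 12.0)
        sigma = 1.0
        waves = [self._wave(shape + rng.normal(0, sigma, 30)) for _ in range(100)]
        tpl = ms.compute_template(waves)
        assert np.max(np.abs(tpl.values - shape)) < 5 * sigma / 10.0

    def test_empty_input_raises(self):
        with pytest.raises(ms.EmptyInputError):
            ms.compute_template([])


class TestSnr:
    def _template(self, amplitude):
        v = np.zeros(30)
        v[15] = amplitude
        return ms.Template(values=v, n_spikes=10)

    def _unit_noise(self, seed=0, n=400):
        """Noise segment rescaled so MAD / 0.6745 is exactly 1 µV."""
        x = np.random.default_rng(seed).normal(size=n)
        mad = np.median(np.abs(x - np.median(x)))
        return x * 0.6745 / mad

    def test_unit_noise_snr_equals_amplitude(self):
        res = ms.compute_snr(self._template(6.0), self._unit_noise())
        assert res.snr == pytest.approx(6.0)
        assert res.noise_sd == pytest.approx(1.0)

    def test_doubling_noise_halves_snr(self):
        noise = self._unit_noise()
        r1 = ms.compute_snr(self._template(6.0), noise)
        r2 = ms.compute_snr(self._template(6.0), 2 * noise)
        assert r2.snr == pytest.approx(r1.snr / 2)

    def test_common_rescaling_invariance(self):
        noise = self._unit_noise(3)
        r1 = ms.compute_snr(self._template(6.0), noise)
        r2 = ms.compute_snr(self._template(6.0 * 7.5), 7.5 * noise)
        assert r2.snr == pytest.approx(r1.snr)

    def test_constant_noise_segment_rejected(self):
        with pytest.raises(ms.DegenerateSignalError):
            ms.compute_snr(self._template(6.0), np.ones(400))


class TestDrift:
    def _waves(self, amps, base=None):
        base = base if base is not None else np.exp(-((np.arange(30) - 15.0) ** 2) / 10.0)
        return [
            ms.SpikeWaveform(values=a * base, center_index=15, source_time=float(i))
            for i, a in enumerate(amps)
        ]

    def test_identical_waveforms_have_zero_drift(self):
        res = drift_test(self._waves([8.0] * 9))
        assert res.drift_rmse == 0.0

    def test_remainder_goes_to_earliest_subset(self):
        res = drift_test(self._waves([8.0] * 7))
        assert res.subset_sizes == (3, 2, 2)

    def test_linear_amplitude_drift_recovered(self):
        """Begin/end template amplitudes track the injected linear drift."""
        n = 30
        amps = 8.0 + np.linspace(0.0, 1.0, n)
        res = drift_test(self._waves(amps))
        parts = np.array_split(np.arange(n), 3)
        expected = amps[parts[2]].mean() - amps[parts[0]].mean()
        measured = res.templates[2].amplitude - res.templates[0].amplitude
        assert measured == pytest.approx(expected, rel=1e-9)
        assert res.drift_rmse > 0

    def test_too_few_waveforms(self):
        with pytest.raises(ms.InsufficientDataError):
            drift_test(self._waves([8.0, 8.0]))


class TestTemplateDistances:
    def _tpl(self, values, track):
        return ms.Template(values=np.asarray(values, float), n_spikes=5, track=track)

    def test_identical_templates_have_zero_distance(self):
        t = self._tpl(np.arange(30.0), "A")
        res = template_distances([t, self._tpl(np.arange(30.0), "B")])
        assert res.min_distance == {"mse": 0.0, "rmse": 0.0, "mae": 0.0}

    def test_hand_computed_three_sample_oracle(self):
        # a=[0,1,2], b=[1,1,1]: mse = (1+0+1)/3, mae = 2/3, rmse = sqrt(mse)
        a = np.zeros(30)
        b = np.zeros(30)
        a[:3], b[:3] = [0, 1, 2], [1, 1, 1]
        d = a - b
        res = template_distances([self._tpl(a, "A"), self._tpl(b, "B")])
        assert res.mse[0, 1] == pytest.approx(np.mean(d**2))
        assert res.mae[0, 1] == pytest.approx(np.mean(np.abs(d)))
        assert res.rmse[0, 1] == pytest.approx(np.sqrt(np.mean(d**2)))
        # restricted to the 3 informative samples the classic values hold
        assert np.mean(d[:3] ** 2) == pytest.approx(2 / 3)
        assert np.mean(np.abs(d[:3])) == pytest.approx(2 / 3)

    def test_rmse_is_sqrt_of_mse_elementwise(self):
        rng = np.random.default_rng(1)
        tpls = [self._tpl(rng.normal(size=30), f"T{i}") for i in range(4)]
        res = template_distances(tpls)
        np.testing.assert_allclose(res.rmse, np.sqrt(res.mse))

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        tpls = [self._tpl(rng.normal(size=30), f"T{i}") for i in range(3)]
        res = template_distances(tpls)
        for m in (res.rmse, res.mae):
            np.testing.assert_allclose(m, m.T)
            assert np.all(np.diag(m) == 0)
            for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
                assert m[i, j] <= m[i, k] + m[k, j] + 1e-12

    def test_single_template_rejected(self):
        with pytest.raises(ms.InsufficientDataError):
            template_distances([self._tpl(np.zeros(30), "A")])


class TestTrackSelection:
    def _tpl(self, amp, track):
        v = np.zeros(30)
        v[15] = amp
        return ms.Template(values=v, n_spikes=3, track=track)

    def test_highest_amplitude_wins(self):
        assert ms.select_track_of_interest(
            [self._tpl(9.5, "Track1"), self._tpl(4.0, "Track3")]
        ) == "Track1"

    def test_single_template(self):
        assert ms.select_track_of_interest([self._tpl(5.0, "only")]) == "only"

    def test_tie_breaks_lexicographically_with_warning(self):
        with pytest.warns(UserWarning, match="tie"):
            winner = ms.select_track_of_interest([self._tpl(5.0, "B"), self._tpl(5.0, "A")])
        assert winner == "A"
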