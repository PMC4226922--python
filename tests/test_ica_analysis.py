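import numpy as np
import pytest

from perfmoco import _dwt
from perfmoco.ica_analysis import (
    ComponentLabels,
    ICADecomposition,
    classify_wavelet,
    decompose,
    fallback_motion_label,
    mean_frequency,
    segment_rv_lv,
    synthetic_references,
)
from perfmoco.series_model import Frame, PerfusionSeries
from perfmoco.phantom import generate_series
from perfmoco.series_model import strip_proton_density

from conftest import small_config


def series_from_stack(stack, dt=0.8):
    frames = [Frame(stack[t], t * dt) for t in range(stack.shape[0])]
    return PerfusionSeries(frames, (1.4, 1.4), pd_stripped=True)


def three_source_mixture(rng, n_t=40, shape=(24, 32), noise=0.01):
    t = np.arange(n_t) * 0.8
    curves = np.stack(
        [
            np.sin(2 * np.pi * t / 4.8),
            np.exp(-0.5 * ((t - 10.0) / 3.0) ** 2),
            np.exp(-0.5 * ((t - 20.0) / 5.0) ** 2),
        ]
    )
    patterns = np.zeros((3, *shape))
    patterns[0, 4:10, 4:12] = 1.0
    patterns[1, 12:20, 6:14] = 1.0
    patterns[2, 6:16, 18:28] = 1.0
    stack = np.tensordot(curves.T, patterns.reshape(3, -1), axes=1).reshape(n_t, *shape)
    stack += rng.normal(scale=noise, size=stack.shape)
    return series_from_stack(stack), curves


class TestDwt:
    def test_perfect_reconstruction(self, rng):
        for n in (32, 58, 64, 100):
            x = rng.normal(size=n)
            coeffs = _dwt.wavedec(x, level=3)
            np.testing.assert_allclose(_dwt.waverec(coeffs)[:n], x, atol=1e-9)

    def test_orthogonality_preserves_energy(self, rng):
        x = rng.normal(size=64)
        coeffs = _dwt.wavedec(x, level=3)
        assert _dwt.band_energies(coeffs).sum() == pytest.approx(np.sum(x * x), rel=1e-10)

    def test_fine_energy_separates_oscillation_from_bolus(self):
        t = np.arange(58)
        for signal, expect_fine in ((np.sin(2 * np.pi * t / 6), True),
                                    (np.exp(-0.5 * ((t - 20) / 6.0) ** 2), False)):
            coeffs = _dwt.wavedec(signal, level=3)
            e = _dwt.band_energies(coeffs)
            fine_frac = e[-2:].sum() / e.sum()
            assert (fine_frac > 0.5) == expect_fine


class TestDecompose:
    def test_three_source_recovery(self):
        series, curves = three_source_mixture(np.random.default_rng(0))
        dec = decompose(series, n_components=3, seed=0)
        used = set()
        for k in range(3):
            rs = [
                abs(np.corrcoef(dec.mixing[:, i], curves[k])[0, 1])
                for i in range(3)
            ]
            best = int(np.argmax(rs))
            assert rs[best] > 0.95
            used.add(best)
        assert used == {0, 1, 2}          # permutation, not duplication

    def test_reconstruction_completeness(self):
        # noise-free input of rank n_frames - 1: the decomposition spans it
        gen = np.random.default_rng(11)
        n_t = 10
        curves = gen.normal(size=(n_t, n_t - 1))
        patterns = gen.normal(size=(n_t - 1, 24 * 32))
        stack = (curves @ patterns).reshape(n_t, 24, 32) + 100.0
        series = series_from_stack(stack)
        dec = decompose(series, n_components=n_t - 1, seed=0)
        err = np.linalg.norm(dec.reconstruct() - stack) / np.linalg.norm(stack)
        assert err < 1e-6

    def test_seed_reproducibility(self, rng):
        series, _ = three_source_mixture(rng)
        a = decompose(series, 3, seed=42)
        b = decompose(series, 3, seed=42)
        np.testing.assert_array_equal(a.mixing, b.mixing)
        np.testing.assert_array_equal(a.components, b.components)

    def test_too_many_components_errors(self, rng):
        series, _ = three_source_mixture(rng, n_t=10)
        with pytest.raises(ValueError, match="components"):
            decompose(series, n_components=10)

    def test_too_few_components_errors(self, rng):
        series, _ = three_source_mixture(rng)
        with pytest.raises(ValueError, match="at least 3"):
            decompose(series, n_components=2)


def synthetic_decomposition(mixing, shape=(8, 8), times=None):
    k = mixing.shape[1]
    components = np.zeros((k, *shape))
    for i in range(k):
        components[i, i % shape[0], :] = 1.0
    if times is None:
        times = np.arange(mixing.shape[0]) * 0.8
    return ICADecomposition(
        components=components,
        mixing=mixing,
        mean_image=np.zeros(shape),
        times=np.asarray(times, dtype=float),
    )


class TestClassifyWavelet:
    def test_phantom_motion_found_by_wavelet(self, free_breathing_phantom):
        series = strip_proton_density(free_breathing_phantom.series)
        dec = decompose(series, 5, seed=0)
        labels = classify_wavelet(dec)
        assert labels.motion_index is not None
        assert labels.method_used == "wavelet"
        freq = mean_frequency(dec.mixing[:, labels.motion_index], dec.times)
        rate = free_breathing_phantom.config.breathing_rate
        assert 0.5 * rate < freq < 2.0 * rate

    def test_smooth_ramps_unresolved(self):
        t = np.arange(40, dtype=float)
        mixing = np.column_stack([t, t**2 / 40.0, np.sqrt(t + 1.0)])
        labels = classify_wavelet(synthetic_decomposition(mixing))
        assert labels.motion_index is None
        assert labels.method_used is None

    def test_rv_peak_precedes_lv_peak_on_phantom(self, free_breathing_phantom):
        series = strip_proton_density(free_breathing_phantom.series)
        dec = decompose(series, 5, seed=0)
        labels = classify_wavelet(dec)
        if labels.rv_index is None or labels.lv_index is None:
            pytest.skip("rv/lv unresolved for this decomposition")
        rv = dec.signed_curve(labels.rv_index)
        lv = dec.signed_curve(labels.lv_index)
        assert np.argmax(_dwt.coarse_reconstruction(rv, 2)) < np.argmax(
            _dwt.coarse_reconstruction(lv, 2)
        )

    def test_label_permutation_invariance(self, free_breathing_phantom):
        series = strip_proton_density(free_breathing_phantom.series)
        dec = decompose(series, 5, seed=0)
        labels = classify_wavelet(dec)
        perm = np.array([4, 2, 0, 1, 3])
        permuted = ICADecomposition(
            components=dec.components[perm],
            mixing=dec.mixing[:, perm],
            mean_image=dec.mean_image,
            times=dec.times,
        )
        plabels = classify_wavelet(permuted)
        inverse = np.argsort(perm)
        for name in ("motion_index", "rv_index", "lv_index"):
            a = getattr(labels, name)
            b = getattr(plabels, name)
            if a is None:
                assert b is None
            else:
                assert b == inverse[a]

    def test_distinct_labels_enforced(self):
        with pytest.raises(ValueError, match="distinct"):
            ComponentLabels(motion_index=1, rv_index=1)


class TestMeanFrequency:
    def test_quarter_hertz_sinusoid(self):
        times = np.arange(61.0)          # 61 samples, 60 s duration
        curve = np.sin(2 * np.pi * 0.25 * times + 0.3)
        assert mean_frequency(curve, times) == pytest.approx(15.0)

    def test_constant_curve_zero(self):
        assert mean_frequency(np.full(10, 3.3), np.arange(10.0)) == 0.0

    def test_nyquist_alternation(self):
        times = np.arange(60.0)
        curve = np.where(np.arange(60) % 2 == 0, 1.0, -1.0)
        assert mean_frequency(curve, times) == pytest.approx(30.0, rel=0.02)

    def test_short_curve_errors(self):
        with pytest.raises(ValueError, match="4 samples"):
            mean_frequency(np.ones(3), np.arange(3.0))


class TestFallback:
    def _mixing_at_frequencies(self, freqs_per_min, times):
        cols = [
            np.sin(2 * np.pi * (f / 60.0) * times + 0.37) for f in freqs_per_min
        ]
        return np.column_stack(cols)

    def test_highest_frequency_above_threshold_labeled(self):
        times = np.arange(60.0)
        mixing = self._mixing_at_frequencies([15.0, 8.0, 5.0], times)
        dec = synthetic_decomposition(mixing, times=times)
        labels = fallback_motion_label(dec)
        assert labels.motion_index == 0
        assert labels.method_used == "frequency_fallback"

    def test_exactly_14_not_above_threshold(self):
        times = np.arange(0.0, 120.0)
        mixing = self._mixing_at_frequencies([14.0, 8.0, 3.0], times)
        dec = synthetic_decomposition(mixing, times=times)
        freqs = [mean_frequency(mixing[:, i], times) for i in range(3)]
        assert max(freqs) <= 14.0
        labels = fallback_motion_label(dec)
        assert labels.motion_index is None

    def test_oscillation_among_ramps(self):
        times = np.arange(60.0)
        osc = np.sin(2 * np.pi * (20.0 / 60.0) * times + 0.1)
        mixing = np.column_stack([times / 60.0, osc, (times / 60.0) ** 2])
        labels = fallback_motion_label(synthetic_decomposition(mixing, times=times))
        assert labels.motion_index == 1

    def test_tie_reported_unresolved(self):
        times = np.arange(60.0)
        osc = np.sin(2 * np.pi * 0.3 * times + 0.1)
        mixing = np.column_stack([osc, osc, times])
        labels = fallback_motion_label(synthetic_decomposition(mixing, times=times))
        assert labels.motion_index is None


def blob_decomposition(distance_px, shape=(96, 128), r=6):
    """Two-component decomposition whose IC images are disc blobs."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    c0 = (shape[0] // 2, shape[1] // 2 - distance_px // 2)
    c1 = (shape[0] // 2, shape[1] // 2 + (distance_px - distance_px // 2))
    components = np.zeros((3, *shape))
    components[0] = np.exp(-(((rr - c0[0]) ** 2 + (cc - c0[1]) ** 2) / (2 * r**2)))
    components[1] = np.exp(-(((rr - c1[0]) ** 2 + (cc - c1[1]) ** 2) / (2 * r**2)))
    t = np.arange(20) * 0.8
    mixing = np.column_stack(
        [np.exp(-0.5 * ((t - 5) / 2) ** 2), np.exp(-0.5 * ((t - 9) / 2) ** 2), t * 0]
    )
    return ICADecomposition(components, mixing, np.zeros(shape), t)


class TestSegmentRvLv:
    def labels(self):
        return ComponentLabels(rv_index=0, lv_index=1)

    def test_centers_25mm_apart_rejected(self):
        dec = blob_decomposition(distance_px=25)     # 1 mm spacing below
        roi = segment_rv_lv(dec, self.labels(), (1.0, 1.0))
        assert roi.rejected
        assert roi.roi_box is None
        assert roi.center_distance_mm == pytest.approx(25.0, abs=1.0)

    def test_centers_35mm_apart_accepted(self):
        dec = blob_decomposition(distance_px=35)
        roi = segment_rv_lv(dec, self.labels(), (1.0, 1.0))
        assert not roi.rejected
        r0, r1, c0, c1 = roi.roi_box
        for mask in (roi.rv_mask, roi.lv_mask):
            rows, cols = np.nonzero(mask)
            assert rows.min() >= r0 and rows.max() < r1
            assert cols.min() >= c0 and cols.max() < c1

    def test_identical_images_rejected(self):
        dec = blob_decomposition(distance_px=35)
        dec.components[1] = dec.components[0]
        roi = segment_rv_lv(dec, self.labels(), (1.0, 1.0))
        assert roi.rejected
        assert roi.center_distance_mm == pytest.approx(0.0, abs=1e-9)

    def test_unresolved_labels_error(self):
        dec = blob_decomposition(distance_px=35)
        with pytest.raises(ValueError, match="resolved"):
            segment_rv_lv(dec, ComponentLabels(), (1.0, 1.0))

    def test_distance_measured_in_mm(self):
        dec = blob_decomposition(distance_px=20)
        # 20 px at 2 mm spacing = 40 mm -> accepted
        roi = segment_rv_lv(dec, self.labels(), (2.0, 2.0))
        assert not roi.rejected
        assert roi.center_distance_mm == pytest.approx(40.0, abs=2.0)


class TestSyntheticReferences:
    def test_drop_none_equals_reconstruction(self):
        series, _ = three_source_mixture(np.random.default_rng(2), noise=0.0)
        dec = decompose(series, n_components=3, seed=0)
        full = dec.reconstruct()
        np.testing.assert_allclose(dec.reconstruct(drop=set()), full)

    def test_references_have_less_temporal_high_frequency(self, free_breathing_phantom):
        series = strip_proton_density(free_breathing_phantom.series)
        dec = decompose(series, 5, seed=0)
        labels = classify_wavelet(dec)
        assert labels.motion_index is not None
        refs = synthetic_references(dec, labels)
        stack = series.pixel_array()
        energy = lambda s: float(np.sum(np.diff(s, axis=0) ** 2))
        assert energy(refs) < energy(stack)

    def test_unresolved_motion_errors(self, rng):
        series, _ = three_source_mixture(rng)
        dec = decompose(series, 3, seed=0)
        with pytest.raises(ValueError, match="fallback"):
            synthetic_references(dec, ComponentLabels())

    def test_motion_free_references_close_to_input(self, motion_free_phantom):
        series = strip_proton_density(motion_free_phantom.series)
        dec = decompose(series, 5, seed=0)
        labels = classify_wavelet(dec)
        if labels.motion_index is None:
            labels = fallback_motion_label(dec, base_labels=labels)
        if labels.motion_index is None:
            pytest.skip("no motion candidate on this decomposition")
        refs = synthetic_references(dec, labels)
        stack = series.pixel_array()
        rel = np.linalg.norm(refs - stack) / np.linalg.norm(stack - stack.mean())
        assert rel < 0.2      # only noise-level energy may be removed


class TestMotionIdentificationRate:
    def test_motion_found_in_at_least_9_of_10_seeds(self):
        hits = 0
        for seed in range(10):
            res = generate_series(small_config(seed=seed))
            series = strip_proton_density(res.series)
            dec = decompose(series, 5, seed=101)
            labels = classify_wavelet(dec)
            if labels.motion_index is None:
                labels = fallback_motion_label(dec, base_labels=labels)
            if labels.motion_index is None:
                continue
            freq = mean_frequency(dec.mixing[:, labels.motion_index], dec.times)
            rate = res.config.breathing_rate
            if 0.5 * rate <= freq <= 2.0 * rate:
                hits += 1
        assert hits >= 9
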