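"""Detection, PCA clustering, ISI validation and waveform metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import silhouette_score

from mspipe import spikesort as sp
from mspipe.simulate import biphasic_template


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs = 30_000
        t = np.arange(fs) / fs
        x = np.sin(2 * np.pi * 1000 * t)
        y = sp.bandpass_spike(x, fs)
        assert np.max(np.abs(y[fs // 4 : -fs // 4])) == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        fs = 30_000
        t = np.arange(fs) / fs
        x = np.sin(2 * np.pi * 10 * t)
        y = sp.bandpass_spike(x, fs)
        atten_db = 20 * np.log10(np.max(np.abs(y[fs // 4 : -fs // 4])))
        assert atten_db < -20

    def test_dc_removed(self):
        y = sp.bandpass_spike(np.full(30_000, 3.7), 30_000)
        assert np.max(np.abs(y)) < 1e-6

    def test_nyquist_violation(self):
        with pytest.raises(ValueError):
            sp.bandpass_spike(np.zeros(100), 1000, 300, 6000)


class TestDetect:
    def test_all_zero_trace(self):
        out = sp.detect_spikes(np.zeros(30_000), 30_000)
        assert len(out) == 0

    def test_short_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = sp.detect_spikes(np.zeros(5), 30_000)
        assert len(out) == 0

    def test_threshold_scales_with_noise_sd(self):
        """MAD-based threshold is linear in the injected noise SD: scaling
        the trace by c scales the count-at-threshold behaviour identically."""
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1.0, 30_000 * 5)
        f = sp.bandpass_spike(x, 30_000)
        n1 = len(sp.detect_spikes(f, 30_000, 3.0))
        n2 = len(sp.detect_spikes(5.0 * f, 30_000, 3.0))
        assert n1 == n2
        assert sp.robust_noise_sd(5.0 * f) == pytest.approx(5.0 * sp.robust_noise_sd(f))

    def test_recall_and_precision_on_synthetic_session(self, two_unit_session):
        """At template SNR >= 3 (inclusion threshold) with QC gating, sorted
        MSN spikes recover ground truth at recall and precision >= 0.95."""
        ses = two_unit_session
        units = sp.sort_session(ses.wideband, ses.fs_wideband, seed=0)
        kept = [u for u in units if u.accepted and u.msn_flag]
        est = np.sort(np.concatenate([u.spike_times for u in kept]))
        true = np.sort(
            np.concatenate([g["spike_times"] for g in ses.ground_truth.values()])
        )
        tp = sp.match_spike_times(est, true)
        assert tp / true.size >= 0.95
        assert tp / est.size >= 0.95

    def test_noise_false_positives_after_qc(self):
        """On pure noise the 3-sigma crossings all land in rejected clusters:
        accepted-MSN false positives stay below 1 per second."""
        rng = np.random.default_rng(1)
        trace = rng.normal(0, 1.0, 30_000 * 10)
        units = sp.sort_session(trace, 30_000, seed=0)
        fp = sum(u.n_spikes for u in units if u.accepted and u.msn_flag)
        assert fp / 10.0 < 1.0


class TestPCsAndClustering:
    def _snippets(self, rng, tpl, n, noise=0.1):
        return tpl[None, :] + rng.normal(0, noise, (n, tpl.size))

    def test_two_templates_separate_in_pc_space(self, rng):
        t1 = biphasic_template(trough_to_peak_us=400.0, amplitude=6.0)
        t2 = biphasic_template(trough_to_peak_us=600.0, amplitude=5.0, post_peak_frac=0.7)
        X = np.vstack([self._snippets(rng, t1, 100, 0.3), self._snippets(rng, t2, 100, 0.3)])
        scores = sp.extract_pcs(X, 3)
        labels = np.r_[np.zeros(100), np.ones(100)]
        assert silhouette_score(scores, labels) > 0.5

    def test_single_waveform_pc1_dominates(self, rng):
        tpl = biphasic_template(amplitude=6.0)
        X = self._snippets(rng, tpl, 50, noise=1e-4)
        X[0] += 0.01  # break exact degeneracy
        scores = sp.extract_pcs(X, 3)
        var = scores.var(axis=0)
        assert var[0] / var.sum() > 0.99

    def test_identical_snippets_raise(self):
        X = np.tile(biphasic_template(), (10, 1))
        with pytest.raises(sp.RankDeficientError):
            sp.extract_pcs(X, 3)

    def test_too_few_snippets_raise(self):
        with pytest.raises(ValueError):
            sp.extract_pcs(np.zeros((3, 49)), 3)

    def test_cluster_count_one_template(self, rng):
        X = rng.normal(0, 1.0, (200, 3))
        labels = sp.cluster_units(X, seed=0)
        assert len(np.unique(labels)) == 1

    def test_cluster_count_three_templates(self, rng):
        """Three well-separated blobs are resolved as three clusters in
        >= 90% of seeds."""
        hits = 0
        for s in range(20):
            r = np.random.default_rng(s)
            X = np.vstack(
                [r.normal(c, 0.5, (80, 3)) for c in ((0, 0, 0), (8, 0, 0), (0, 8, 0))]
            )
            labels = sp.cluster_units(X, seed=s)
            hits += len(np.unique(labels)) == 3
        assert hits / 20 >= 0.9

    def test_two_template_session_label_agreement(self, two_unit_session):
        """Adjusted Rand agreement with ground-truth identity >= 0.9 on the
        matched spikes of a two-template session."""
        from sklearn.metrics import adjusted_rand_score

        ses = two_unit_session
        units = sp.sort_session(ses.wideband, ses.fs_wideband, seed=0)
        kept = [u for u in units if u.accepted and u.msn_flag]
        est_times = np.concatenate([u.spike_times for u in kept])
        est_labels = np.concatenate([np.full(u.n_spikes, u.unit_id) for u in kept])
        order = np.argsort(est_times)
        est_times, est_labels = est_times[order], est_labels[order]
        true_pairs = []
        for name, g in ses.ground_truth.items():
            for t in g["spike_times"]:
                true_pairs.append((t, name))
        true_pairs.sort()
        true_times = np.array([t for t, _ in true_pairs])
        true_labels = np.array([l for _, l in true_pairs])
        # pair each estimated spike with the nearest unused true spike
        idx = np.searchsorted(true_times, est_times)
        matched_est, matched_true = [], []
        used = np.zeros(true_times.size, bool)
        for k, t in enumerate(est_times):
            for j in (idx[k] - 1, idx[k]):
                if 0 <= j < true_times.size and not used[j] and abs(true_times[j] - t) <= 0.002:
                    used[j] = True
                    matched_est.append(est_labels[k])
                    matched_true.append(true_labels[j])
                    break
        assert adjusted_rand_score(matched_true, matched_est) >= 0.9


class TestISI:
    def test_type_one_error_calibrated(self):
        """Pass rate on true Poisson-with-refractory trains ~ 1 - alpha
        (within 5 percentage points)."""
        rng = np.random.default_rng(0)
        n_rep = 500
        passes = 0
        for s in range(n_rep):
            t = np.cumsum(rng.exponential(1 / 5.0, 1000) + 0.002)
            passes += sp.validate_isi(t, refractory_ms=2.0, seed=s).passed
        assert abs(passes / n_rep - 0.95) <= 0.05

    def test_periodic_train_fails(self):
        res = sp.validate_isi(np.arange(0, 100, 0.1), refractory_ms=2.0)
        assert res.passed is False

    def test_too_few_spikes_indeterminate(self):
        res = sp.validate_isi(np.linspace(0, 1, 10), refractory_ms=2.0)
        assert res.passed is None

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError):
            sp.validate_isi(np.array([0.5, 0.1] * 30), refractory_ms=2.0)


class TestWaveformMetrics:
    def test_analytic_template_peak_trough(self):
        fs = 30_000
        tpl = biphasic_template(fs=fs, trough_to_peak_us=400.0)
        m = sp.waveform_metrics(tpl, fs)
        assert abs(m.peak_trough_us - 400.0) <= 1e6 / fs

    def test_symmetric_waveform_zero_index(self):
        tpl = biphasic_template(
            trough_to_peak_us=400.0, pre_peak_us=400.0, post_peak_frac=0.5, pre_peak_frac=0.5
        )
        m = sp.waveform_metrics(tpl, 30_000)
        assert m.symmetry_index == pytest.approx(0.0, abs=1e-9)
        assert m.peak_peak_us == pytest.approx(800.0, abs=2 * 1e6 / 30_000)

    def test_inverted_waveform_rejected(self):
        with pytest.raises(sp.WaveformShapeError):
            sp.waveform_metrics(-biphasic_template(), 30_000)

    @given(scale=st.floats(0.1, 100.0))
    def test_invariant_to_amplitude_scaling(self, scale):
        tpl = biphasic_template(trough_to_peak_us=500.0)
        m1 = sp.waveform_metrics(tpl, 30_000)
        m2 = sp.waveform_metrics(scale * tpl, 30_000)
        assert m1.peak_trough_us == m2.peak_trough_us
        assert m1.symmetry_index == pytest.approx(m2.symmetry_index)


class TestClassifyAndRate:
    @pytest.mark.parametrize(
        "rate,width,isi_pass,expected",
        [
            (2.0, 500.0, True, True),  # MSN-like
            (25.0, 150.0, True, False),  # fast, narrow interneuron-like
            (2.0, 500.0, False, False),  # ISI veto
            (2.0, 500.0, None, True),  # indeterminate ISI does not veto
        ],
    )
    def test_msn_rule(self, rate, width, isi_pass, expected):
        assert sp.classify_msn(rate, width, isi_pass) is expected

    def test_firing_rate_definition(self):
        assert sp.firing_rate(np.linspace(0, 4.5, 10), (0.0, 5.0)) == 2.0
        assert sp.firing_rate(np.array([]), (0.0, 5.0)) == 0.0
        with pytest.raises(ValueError):
            sp.firing_rate(np.array([1.0]), (2.0, 2.0))
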