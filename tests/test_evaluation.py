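"""Metrics arithmetic, ERF averaging, SNR and recording cleaning."""

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from opmclean import (
    Recording,
    SimConfig,
    clean_recording,
    compute_metrics,
    detect_trigger_onsets,
    erf_average,
    f1_score_from_pr,
    macro_from_per_class,
    simulate_session,
    snr_db,
)
from opmclean.evaluation import ERFWaveform
from opmclean.recording import ROLE_MCG, ROLE_MEG, ROLE_MOG, ROLE_TRIGGER


class TestMetrics:
    def test_f1_harmonic_mean(self):
        assert f1_score_from_pr(98.87, 96.88) == pytest.approx(97.86, abs=0.005)
        assert f1_score_from_pr(0.0, 0.0) == 0.0

    def test_macro_aggregation(self):
        out = macro_from_per_class([98.87, 98.25, 97.96], [96.88, 97.92, 99.09])
        np.testing.assert_allclose(
            np.round(out["per_class_f1"], 2), [97.86, 98.08, 98.52]
        )
        assert out["macro_precision"] == pytest.approx(98.36, abs=0.005)
        assert out["macro_recall"] == pytest.approx(97.96, abs=0.005)
        assert np.mean([97.86, 98.08, 98.52]) == pytest.approx(98.15, abs=0.005)

    def test_perfect_predictions(self):
        y = np.array([0, 1, 2] * 10)
        rep = compute_metrics(y, y)
        assert rep.accuracy == 100.0
        assert rep.macro_f1 == 100.0
        assert (rep.per_class.values == 100.0).all()

    def test_against_sklearn(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 3, 200)
        y_pred = np.where(rng.random(200) < 0.25, rng.integers(0, 3, 200), y_true)
        rep = compute_metrics(y_true, y_pred)
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=[0, 1, 2], zero_division=0
        )
        np.testing.assert_allclose(rep.per_class["precision"], 100 * p, atol=1e-9)
        np.testing.assert_allclose(rep.per_class["recall"], 100 * r, atol=1e-9)
        np.testing.assert_allclose(rep.per_class["f1"], 100 * f1, atol=1e-9)
        assert rep.accuracy == pytest.approx(100 * (y_true == y_pred).mean())
        assert rep.macro_f1 == pytest.approx(100 * f1.mean())

    def test_confusion_matrix_totals(self):
        y_true = [0, 0, 1, 1, 2, 2]
        y_pred = [0, 1, 1, 1, 2, 0]
        rep = compute_metrics(y_true, y_pred)
        assert rep.confusion.sum() == 6
        assert rep.confusion[0, 0] == 1 and rep.confusion[2, 0] == 1

    def test_macro_is_unweighted_mean(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 3, 100)
        y_pred = rng.integers(0, 3, 100)
        rep = compute_metrics(y_true, y_pred)
        assert rep.macro_f1 == pytest.approx(rep.per_class["f1"].mean())
        assert rep.macro_precision == pytest.approx(rep.per_class["precision"].mean())

    def test_zero_denominator_warns_and_reports_zero(self):
        with pytest.warns(UserWarning, match="zero denominator"):
            rep = compute_metrics([0, 0, 1, 2], [0, 0, 0, 0])
        assert rep.per_class.loc["blink", "precision"] == 0.0

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([], [])


def _erf_recording(n_trials=200, noise=1.0, seed=0, fs=1000.0):
    """Trial-locked bump + Gaussian noise on 4 MEG channels."""
    rng = np.random.default_rng(seed)
    onsets = 500 + np.arange(n_trials) * 1000
    n = int(onsets[-1] + 800)
    t = np.arange(n) / fs
    bump = np.exp(-0.5 * ((np.arange(700) / fs - 0.1) / 0.03) ** 2)
    signal = np.zeros(n)
    for o in onsets:
        signal[o : o + 700] += bump
    data = np.vstack(
        [signal + noise * rng.standard_normal(n) for _ in range(4)]
        + [np.zeros(n), np.zeros(n), np.zeros(n)]
    )
    trig = data[6]
    for o in onsets:
        trig[o : o + 200] = 1.0
    roles = [ROLE_MEG] * 4 + [ROLE_MOG, ROLE_MCG, ROLE_TRIGGER]
    return Recording(data, fs, roles), onsets, bump


class TestERF:
    def test_identical_trials_recover_the_trial(self):
        rec, onsets, bump = _erf_recording(n_trials=20, noise=0.0)
        erf = erf_average(rec, window=(-0.2, 0.5))
        # baseline-corrected copy of the bump
        expected = bump[:500] - bump[:500].mean() * 0  # bump is 0 pre-onset
        got = erf.data[0][erf.times >= 0]
        np.testing.assert_allclose(got, expected[: got.shape[0]], atol=1e-9)

    def test_noise_shrinks_as_sqrt_trials(self):
        rec, onsets, bump = _erf_recording(n_trials=200, noise=1.0, seed=1)
        erf = erf_average(rec, window=(-0.2, 0.5))
        pre = erf.data[:, erf.times < 0]
        # residual pre-stimulus noise ~ sigma/sqrt(200)
        expected = 1.0 / np.sqrt(200)
        assert np.std(pre) == pytest.approx(expected, rel=0.2)

    def test_baseline_zero_mean(self):
        rec, *_ = _erf_recording(n_trials=30, noise=0.5, seed=2)
        erf = erf_average(rec)
        np.testing.assert_allclose(
            erf.data[:, erf.times < 0].mean(axis=1), 0.0, atol=1e-12
        )

    def test_clipped_trials_dropped(self):
        rec, onsets, _ = _erf_recording(n_trials=10, noise=0.0)
        erf = erf_average(rec, window=(-0.6, 0.5))  # first onset at 0.5 s is clipped
        assert erf.n_trials == 9

    def test_onset_detection(self):
        rec, onsets, _ = _erf_recording(n_trials=10, noise=0.0)
        np.testing.assert_array_equal(detect_trigger_onsets(rec.trigger), onsets)

    def test_no_usable_trials_rejected(self):
        rec, *_ = _erf_recording(n_trials=3, noise=0.0)
        rec.data[rec.trigger_index] = 0.0
        with pytest.raises(ValueError, match="no trial"):
            erf_average(rec)


class TestSNR:
    def _erf(self, pre, post, fs=1000.0):
        times = np.arange(-200, 500) / fs
        data = np.where(times < 0, pre, post)[None, :].repeat(3, axis=0)
        return ERFWaveform(data, times, (-0.2, 0.5), 10, fs)

    def test_equal_windows_zero_db(self):
        assert snr_db(self._erf(1.0, 1.0)) == pytest.approx(0.0)

    def test_tenfold_is_twenty_db(self):
        assert snr_db(self._erf(1.0, 10.0)) == pytest.approx(20.0)

    def test_scale_invariance(self):
        erf = self._erf(0.5, 2.0)
        scaled = ERFWaveform(7.3 * erf.data, erf.times, erf.window, 10, 1000.0)
        assert snr_db(scaled) == pytest.approx(snr_db(erf))

    def test_zero_prestim_rejected(self):
        with pytest.raises(ValueError, match="pre-stimulus"):
            snr_db(self._erf(0.0, 1.0))

    def test_window_must_cover_both_sides(self):
        erf = self._erf(1.0, 2.0)
        short = ERFWaveform(erf.data[:, 150:], erf.times[150:], (-0.05, 0.5), 10, 1000.0)
        with pytest.raises(ValueError, match="cover"):
            snr_db(short)


class _NeverFlag:
    """Stub classifier predicting non-artifact for every component."""

    class config:
        input_length = 10000

    def predict(self, x):
        return np.full(x.shape[0], 2)


class _OracleFlag:
    """Stub flagging every component correlated with a ground-truth source.

    Unlike the dataset labeler (one component per reference), a classifier
    may flag several components of one artifact; the threshold mimics that.
    Sources must be band-matched to the filtered pipeline.
    """

    class config:
        input_length = 10000

    def __init__(self, sources_by_epoch, threshold=0.25):
        self.sources_by_epoch = sources_by_epoch
        self.threshold = threshold
        self.calls = 0

    def predict(self, x):
        truth = self.sources_by_epoch[self.calls]
        self.calls += 1
        labels = np.full(x.shape[0], 2)
        for lab, src in truth.items():
            cors = np.abs(np.corrcoef(np.vstack([x, src]))[:-1, -1])
            labels[cors > self.threshold] = lab
        return labels


@pytest.fixture(scope="module")
def session():
    return simulate_session(SimConfig(duration=20.0, blink_mode="rapid", seed=6))


class TestCleanRecording:

    def test_never_flagging_model_is_identity(self, session):
        rec, _ = session
        from opmclean.preprocessing import bandpass_filter

        cleaned = clean_recording(rec, _NeverFlag(), seed=0)
        filtered = bandpass_filter(rec)
        meg = rec.meg_indices
        rel = np.linalg.norm(
            cleaned.data[meg] - filtered.data[meg][:, : cleaned.n_samples]
        ) / np.linalg.norm(filtered.data[meg])
        assert rel < 1e-6

    def test_references_and_trigger_untouched(self, session):
        rec, _ = session
        cleaned = clean_recording(rec, _NeverFlag(), seed=0)
        for idx in (rec.mog_index, rec.mcg_index, rec.trigger_index):
            np.testing.assert_array_equal(
                cleaned.data[idx], rec.data[idx][: cleaned.n_samples]
            )

    def test_oracle_cleaning_strips_artifact_correlation(self, short_session):
        # the pipeline operates on 1.5-40 Hz data, so ground-truth sources
        # are band-matched before flagging and measuring
        from opmclean.preprocessing import bandpass_array, bandpass_filter

        rec, truth = short_session
        fs = rec.sampling_rate
        fb = bandpass_array(truth.blink_source, fs, 1.5, 40.0)
        fc = bandpass_array(truth.cardiac_source, fs, 1.5, 40.0)
        epochs = [
            {1: fb[e * 10000 : (e + 1) * 10000], 0: fc[e * 10000 : (e + 1) * 10000]}
            for e in range(2)
        ]
        cleaned = clean_recording(rec, _OracleFlag(epochs), seed=0)
        n = cleaned.n_samples

        def mean_abs_corr(data):
            return np.mean(
                np.abs([np.corrcoef(row, fb[:n])[0, 1] for row in data])
            )

        before = mean_abs_corr(bandpass_filter(rec).data[rec.meg_indices][:, :n])
        after = mean_abs_corr(cleaned.data[cleaned.meg_indices])
        assert after < 0.2 * before
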