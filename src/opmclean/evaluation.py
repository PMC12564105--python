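"""Classification metrics, artifact-removal orchestration, ERF and SNR.

Metrics follow the one-vs-rest convention for the three component classes
(0 cardiac, 1 blink, 2 non-artifact): per class, precision TP/(TP+FP),
recall TP/(TP+FN), F1 = 2PR/(P+R) and accuracy (TP+TN)/total; the macro
figures are unweighted class means, all reported as percentages.

Cleaning efficacy is judged on the event-related field (ERF): per-channel
trial averages around stimulus onset, baseline-corrected on the
pre-stimulus interval, summarized as SNR = 20*log10(RMS post / RMS pre)
over the +/-0.2 s windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .caseqnet import CASeqNet, TrainedModel, predict_components
from .preprocessing import bandpass_filter, ica_decompose, ica_reconstruct, segment_epochs
from .recording import Recording

CLASS_NAMES = {0: "cardiac", 1: "blink", 2: "none"}


@dataclass
class MetricsReport:
    """Per-class and macro classification metrics (percentages)."""

    confusion: np.ndarray  # 3x3, rows = true, cols = predicted
    per_class: pd.DataFrame  # index: class name; columns: precision/recall/f1/accuracy
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        total = self.per_class.copy()
        total.loc["total"] = {
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f1": self.macro_f1,
            "accuracy": self.accuracy,
        }
        return total


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def f1_score_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (same units as the inputs)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def macro_from_per_class(precisions, recalls) -> dict:
    """Macro precision/recall/F1 from per-class precision/recall values.

    Inputs and outputs are on the percent scale; per-class F1s are the
    harmonic means and every macro figure is an unweighted class mean.
    """
    precisions = np.asarray(precisions, dtype=np.float64)
    recalls = np.asarray(recalls, dtype=np.float64)
    f1s = np.array([f1_score_from_pr(p, r) for p, r in zip(precisions, recalls)])
    return {
        "per_class_f1": f1s,
        "macro_precision": float(precisions.mean()),
        "macro_recall": float(recalls.mean()),
        "macro_f1": float(f1s.mean()),
    }


def compute_metrics(true_labels, predicted_labels) -> MetricsReport:
    """One-vs-rest metrics for the 3-class artifact problem, in percent."""
    y_true = np.asarray(true_labels, dtype=np.int64)
    y_pred = np.asarray(predicted_labels, dtype=np.int64)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1, 2])
    total = cm.sum()
    rows = {}
    for c in (0, 1, 2):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        tn = total - tp - fp - fn
        name = CLASS_NAMES[c]
        p = 100.0 * _safe_div(tp, tp + fp, f"precision[{name}]")
        r = 100.0 * _safe_div(tp, tp + fn, f"recall[{name}]")
        rows[name] = {
            "precision": p,
            "recall": r,
            "f1": f1_score_from_pr(p, r),
            "accuracy": 100.0 * _safe_div(tp + tn, total, f"accuracy[{name}]"),
        }
    per_class = pd.DataFrame(rows).T
    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        macro_precision=float(per_class["precision"].mean()),
        macro_recall=float(per_class["recall"].mean()),
        macro_f1=float(per_class["f1"].mean()),
        accuracy=float(100.0 * np.trace(cm) / total),
    )


def clean_recording(
    recording: Recording,
    model: TrainedModel | CASeqNet,
    low: float = 1.5,
    high: float = 40.0,
    epoch_seconds: float = 10.0,
    n_components: int | None = None,
    seed: int = 0,
) -> Recording:
    """Remove classifier-flagged components from every epoch.

    Pipeline per epoch: FastICA on the MEG channels, classification of
    every component, reconstruction with flagged (cardiac/blink)
    components zeroed.  Epochs are re-concatenated; reference and trigger
    rows are passed through untouched (truncated to whole epochs).
    """
    filtered = bandpass_filter(recording, low, high)
    epochs = segment_epochs(filtered, epoch_seconds)
    meg_rows = recording.meg_indices
    L = epochs.epoch_length
    T = len(epochs) * L

    out = recording.copy()
    out.data = out.data[:, :T]
    for e in range(len(epochs)):
        dec = ica_decompose(
            epochs.epochs[e][meg_rows], n_components, seed=seed + 1000 * e
        )
        _, flagged = predict_components(model, dec)
        cleaned = ica_reconstruct(dec, set(flagged))
        out.data[meg_rows, e * L : (e + 1) * L] = cleaned
    return out


@dataclass
class ERFWaveform:
    """Trial-averaged, baseline-corrected evoked response of MEG channels."""

    data: np.ndarray  # (n_meg_channels, n_window_samples)
    times: np.ndarray  # seconds relative to onset
    window: tuple[float, float]
    n_trials: int
    sampling_rate: float


def detect_trigger_onsets(trigger: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Sample indices of rising edges of a rectangular trigger pulse train."""
    high = trigger > threshold * np.max(trigger) if np.max(trigger) > 0 else np.zeros_like(trigger, bool)
    edges = np.flatnonzero(np.diff(high.astype(np.int8)) == 1) + 1
    if high[0]:
        edges = np.concatenate([[0], edges])
    return edges


def erf_average(
    recording: Recording,
    window: tuple[float, float] = (-0.2, 0.5),
    onsets: np.ndarray | None = None,
) -> ERFWaveform:
    """Average MEG channels across trials time-locked to stimulus onset.

    Trials whose window is clipped by the recording edges are dropped; the
    pre-stimulus mean is subtracted per channel (baseline correction).
    """
    if not window[0] <= 0 <= window[1]:
        raise ValueError("the window must contain onset (time 0)")
    fs = recording.sampling_rate
    if onsets is None:
        onsets = detect_trigger_onsets(recording.trigger)
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    meg = recording.meg
    segments = []
    for onset in np.asarray(onsets, dtype=int):
        lo, hi = onset + i0, onset + i1
        if lo < 0 or hi > meg.shape[1]:
            continue
        segments.append(meg[:, lo:hi])
    if not segments:
        raise ValueError("no trial window fits inside the recording")
    erf = np.mean(segments, axis=0)
    times = (np.arange(i0, i1)) / fs
    baseline = erf[:, times < 0].mean(axis=1, keepdims=True)
    erf = erf - baseline
    return ERFWaveform(erf, times, window, len(segments), fs)


def snr_db(erf: ERFWaveform, sub_window: float = 0.2) -> float:
    """ERF signal-to-noise ratio in dB.

    ``20*log10(RMS(post) / RMS(pre))`` with post-stimulus samples in
    [0, +sub_window] and pre-stimulus samples in [-sub_window, 0); RMS is
    aggregated over all MEG channels and samples jointly.
    """
    if erf.window[0] > -sub_window or erf.window[1] < sub_window:
        raise ValueError(f"ERF window must cover [-{sub_window}, {sub_window}] s")
    pre = erf.data[:, (erf.times >= -sub_window) & (erf.times < 0)]
    post = erf.data[:, (erf.times >= 0) & (erf.times <= sub_window)]
    rms_pre = np.sqrt(np.mean(pre**2))
    rms_post = np.sqrt(np.mean(post**2))
    if rms_pre == 0:
        raise ValueError("zero pre-stimulus RMS; SNR undefined")
    return float(20.0 * np.log10(rms_post / rms_pre))


def plot_erf_comparison(erf_before: ERFWaveform, erf_after: ERFWaveform, path) -> None:
    """Butterfly plot of the ERF before and after artifact removal."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, erf, title in zip(axes, (erf_before, erf_after), ("raw", "cleaned")):
        ax.plot(erf.times, erf.data.T, lw=0.5)
        ax.axvline(0, color="k", ls="--", lw=0.8)
        ax.set_title(f"ERF ({title}, {erf.n_trials} trials)")
        ax.set_xlabel("time relative to onset (s)")
    axes[0].set_ylabel("field (a.u.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
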