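"""Ground-truthed synthetic OPM-MEG sessions.

Emulates an auditory evoked-response session recorded with a wearable
magnetometer array: 1 kHz tone pips every 2 s, neural background activity
(band-limited noise plus an alpha rhythm), non-periodic eye-blink artifact
trains, quasi-periodic QRS-like cardiac trains, and two near-source
magnetic reference sensors (MOG for blinks, MCG for heartbeats) that carry
almost-clean copies of the artifact sources.  Every stochastic choice flows
from one master seed, so a session is bit-reproducible.

No biophysical forward model is attempted: artifact and evoked sources are
mixed into the sensor array through fixed random topography vectors, which
is all the downstream blind-source-separation pipeline assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import bandpass_array
from .recording import ROLE_MCG, ROLE_MEG, ROLE_MOG, ROLE_TRIGGER, Recording

#: blink-rate bands (events/s) per blinking mode
BLINK_RATE_BANDS = {"normal": (0.2, 0.5), "rapid": (1.0, 3.0)}
DEFAULT_BLINK_RATES = {"normal": 0.3, "rapid": 2.0}

# Base peak amplitudes relative to a unit-RMS neural background.  Blink and
# cardiac fields picked up at the scalp dwarf cortical activity; the evoked
# response is far below the single-trial background and only emerges after
# trial averaging.
BASE_AMPLITUDE = {"blink": 25.0, "cardiac": 15.0, "evoked": 4.0}


@dataclass
class SimConfig:
    """Parameters of one synthetic session.

    Amplitude scales are dimensionless multipliers on built-in base
    amplitudes expressed relative to a unit-RMS neural background.
    """

    n_meg_channels: int = 32
    sampling_rate: float = 1000.0
    duration: float = 60.0
    blink_mode: str = "normal"
    blink_rate: float | None = None  # events/s; None -> mode default
    cardiac_period_range: tuple[float, float] = (900.0, 1000.0)  # ms
    n_trials: int | None = None  # None -> as many as fit
    tone_duration_range: tuple[float, float] = (200.0, 300.0)  # ms
    isi: float = 2.0  # inter-stimulus interval, s
    artifact_amplitude_scales: dict = field(
        default_factory=lambda: {"blink": 1.0, "cardiac": 1.0, "evoked": 1.0}
    )
    noise_scale: float = 1.0
    ref_noise_frac: float = 0.05  # reference-sensor noise, fraction of source RMS
    blink_rise_ms: float = 100.0
    blink_decay_ms: float = 200.0
    qrs_width_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.blink_mode not in BLINK_RATE_BANDS:
            raise ValueError(f"unknown blink_mode {self.blink_mode!r}")
        if self.blink_rate is None:
            self.blink_rate = DEFAULT_BLINK_RATES[self.blink_mode]
        lo, hi = BLINK_RATE_BANDS[self.blink_mode]
        if not lo <= self.blink_rate <= hi:
            raise ValueError(
                f"blink_rate {self.blink_rate} outside the {self.blink_mode} "
                f"band [{lo}, {hi}] events/s"
            )
        pmin, pmax = self.cardiac_period_range
        if not (600.0 <= pmin <= pmax <= 1200.0):
            raise ValueError(
                "cardiac_period_range must satisfy 600 <= min <= max <= 1200 ms"
            )
        if self.duration < 10.0:
            raise ValueError("duration must be at least 10 s (one epoch)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class GroundTruth:
    """The latent sources and mixing used to build a synthetic session."""

    blink_source: np.ndarray
    cardiac_source: np.ndarray
    erf_source: np.ndarray
    mixing_topographies: dict  # source name -> (n_meg_channels,) gains
    trigger_onsets: np.ndarray  # sample indices


# ---------------------------------------------------------------------------
# artifact waveform templates
# ---------------------------------------------------------------------------


def blink_template(
    fs: float, rise_ms: float = 100.0, decay_ms: float = 200.0
) -> np.ndarray:
    """Asymmetric biphasic blink bump, peak normalized to 1.

    Fast rise, slower decay, followed by a small negative rebound — the
    stereotyped ocular deflection seen on frontal magnetometers.
    """
    sig_r = rise_ms / 2.5 / 1000.0
    sig_d = decay_ms / 2.5 / 1000.0
    t = np.arange(-3 * sig_r, 4 * sig_d + 0.35, 1.0 / fs)
    w = np.where(
        t < 0,
        np.exp(-0.5 * (t / sig_r) ** 2),
        np.exp(-0.5 * (t / sig_d) ** 2),
    )
    rebound_center = 3 * sig_d + 0.1
    w = w - 0.15 * np.exp(-0.5 * ((t - rebound_center) / 0.06) ** 2)
    return w / np.max(np.abs(w))


def qrs_template(fs: float, width_ms: float = 100.0) -> np.ndarray:
    """Three-lobe piecewise-Gaussian Q-R-S complex, R peak normalized to 1."""
    half = width_ms / 2.0 / 1000.0
    t = np.arange(-half, half + 1.0 / fs, 1.0 / fs)
    scale = width_ms / 100.0
    q = -0.15 * np.exp(-0.5 * ((t + 0.025 * scale) / (0.008 * scale)) ** 2)
    r = 1.0 * np.exp(-0.5 * (t / (0.010 * scale)) ** 2)
    s = -0.25 * np.exp(-0.5 * ((t - 0.025 * scale) / (0.008 * scale)) ** 2)
    w = q + r + s
    return w / np.max(np.abs(w))


def _add_events(series: np.ndarray, template: np.ndarray, peaks: np.ndarray) -> None:
    """Add ``template`` (peak-aligned) at each sample index in ``peaks``."""
    peak_off = int(np.argmax(np.abs(template)))
    n = series.shape[0]
    for p in peaks:
        start = p - peak_off
        lo, hi = max(start, 0), min(start + template.shape[0], n)
        if hi <= lo:
            continue
        series[lo:hi] += template[lo - start : hi - start]


def make_blink_train(
    mode: str,
    duration: float,
    rate: float,
    seed: int,
    fs: float = 1000.0,
    rise_ms: float = 100.0,
    decay_ms: float = 200.0,
) -> np.ndarray:
    """Non-periodic blink artifact train (zero baseline, unit peak events).

    Event times follow a homogeneous Poisson process of the given rate
    (exponential inter-event intervals), so the train is jittered and
    non-periodic; the expected event count is ``rate * duration``.
    """
    if mode not in BLINK_RATE_BANDS:
        raise ValueError(f"unknown blink mode {mode!r}")
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    series = np.zeros(n)
    times = []
    t = rng.exponential(1.0 / rate)
    while t < duration:
        times.append(t)
        t += rng.exponential(1.0 / rate)
    peaks = (np.array(times) * fs).astype(int)
    _add_events(series, blink_template(fs, rise_ms, decay_ms), peaks)
    return series


def make_cardiac_train(
    duration: float,
    period_range: tuple[float, float] = (900.0, 1000.0),
    seed: int = 0,
    fs: float = 1000.0,
    width_ms: float = 100.0,
) -> np.ndarray:
    """Quasi-periodic QRS-like cardiac train with unit R peaks.

    Successive R-R intervals are drawn uniformly from ``period_range`` (ms);
    the first R peak falls one such interval after recording start.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    pmin, pmax = period_range
    if pmin > pmax:
        raise ValueError("period_range min must not exceed max")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    series = np.zeros(n)
    peaks = []
    t_ms = rng.uniform(pmin, pmax)
    while t_ms / 1000.0 < duration:
        peaks.append(int(round(t_ms / 1000.0 * fs)))
        t_ms += rng.uniform(pmin, pmax)
    _add_events(series, qrs_template(fs, width_ms), np.array(peaks, dtype=int))
    return series


def count_peaks(series: np.ndarray, height: float = 0.5) -> int:
    """Count well-separated suprathreshold peaks (used by tests and examples)."""
    from scipy.signal import find_peaks

    pk, _ = find_peaks(series, height=height, distance=100)
    return int(pk.shape[0])


# ---------------------------------------------------------------------------
# full session
# ---------------------------------------------------------------------------


def _neural_background(
    n_channels: int, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-RMS 1.5-40 Hz noise plus an alpha-band rhythm per channel.

    The alpha rhythm is 8-13 Hz band-filtered noise (RMS 0.5), not a pure
    sinusoid: real alpha waxes, wanes and drifts in phase, so it must
    decorrelate from the stimulus grid and average out across trials.  A
    fixed-phase sinusoid at 10 Hz would be exactly periodic in the 2-s
    inter-stimulus interval and masquerade as a trial-locked response.
    """
    noise = rng.standard_normal((n_channels, n))
    noise = bandpass_array(noise, fs, 1.5, 40.0)
    noise /= np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
    alpha = rng.standard_normal((n_channels, n))
    alpha = bandpass_array(alpha, fs, 8.0, 13.0)
    alpha *= 0.5 / np.sqrt(np.mean(alpha**2, axis=1, keepdims=True))
    return noise + alpha


def _evoked_template(fs: float) -> np.ndarray:
    """M100-like bump peaking 100 ms post-onset, confined to [0, 0.5] s."""
    t = np.arange(0, 0.5, 1.0 / fs)
    w = np.exp(-0.5 * ((t - 0.1) / 0.03) ** 2)
    # small later deflection of opposite sign (M200-ish) for realism
    w = w - 0.4 * np.exp(-0.5 * ((t - 0.2) / 0.04) ** 2)
    return w


def simulate_session(config: SimConfig) -> tuple[Recording, GroundTruth]:
    """Build one synthetic session.

    Channel layout: ``n_meg_channels`` MEG rows, then MOG_REF, MCG_REF and
    TRIGGER.  MEG rows are neural background plus topography-weighted blink,
    cardiac and trial-locked evoked sources; each reference row is its
    source plus a small independent noise; the trigger row holds a
    rectangular pulse per tone.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    master = np.random.SeedSequence(config.seed)
    keys = master.spawn(6)
    rng_bg, rng_topo, rng_trial, rng_refs = (
        np.random.default_rng(keys[0]),
        np.random.default_rng(keys[1]),
        np.random.default_rng(keys[2]),
        np.random.default_rng(keys[3]),
    )
    blink_seed = int(keys[4].generate_state(1)[0] % (2**31))
    cardiac_seed = int(keys[5].generate_state(1)[0] % (2**31))

    # ---- sources
    blink = make_blink_train(
        config.blink_mode,
        config.duration,
        config.blink_rate,
        blink_seed,
        fs,
        config.blink_rise_ms,
        config.blink_decay_ms,
    )
    cardiac = make_cardiac_train(
        config.duration,
        config.cardiac_period_range,
        cardiac_seed,
        fs,
        config.qrs_width_ms,
    )

    # ---- trials / trigger
    first_onset = 0.5
    max_trials = int(np.floor((config.duration - first_onset - 0.5) / config.isi)) + 1
    if max_trials < 1:
        raise ValueError("duration too short for a single trial")
    n_trials = config.n_trials if config.n_trials is not None else max_trials
    if n_trials > max_trials:
        raise ValueError(
            f"{n_trials} trials at isi={config.isi}s do not fit in "
            f"{config.duration}s (max {max_trials})"
        )
    onsets = (first_onset + config.isi * np.arange(n_trials)) * fs
    onsets = onsets.astype(int)

    trigger = np.zeros(n)
    tone_durations = rng_trial.uniform(
        config.tone_duration_range[0] / 1000.0,
        config.tone_duration_range[1] / 1000.0,
        size=n_trials,
    )
    evoked = np.zeros(n)
    ev = _evoked_template(fs)
    for onset, dur in zip(onsets, tone_durations):
        trigger[onset : onset + int(dur * fs)] = 1.0
        stop = min(onset + ev.shape[0], n)
        evoked[onset:stop] += ev[: stop - onset]

    # ---- mixing
    def unit_topography(rng) -> np.ndarray:
        v = rng.standard_normal(config.n_meg_channels)
        while np.linalg.norm(v) == 0:  # pragma: no cover
            v = rng.standard_normal(config.n_meg_channels)
        return v / np.linalg.norm(v)

    topo = {
        "blink": unit_topography(rng_topo),
        "cardiac": unit_topography(rng_topo),
        "evoked": unit_topography(rng_topo),
    }
    scales = config.artifact_amplitude_scales
    amp = {
        name: BASE_AMPLITUDE[name] * scales.get(name, 1.0) for name in BASE_AMPLITUDE
    }

    meg = _neural_background(config.n_meg_channels, n, fs, rng_bg) * config.noise_scale
    meg += amp["blink"] * np.outer(topo["blink"], blink)
    meg += amp["cardiac"] * np.outer(topo["cardiac"], cardiac)
    meg += amp["evoked"] * np.outer(topo["evoked"], evoked)

    def reference(source: np.ndarray) -> np.ndarray:
        rms = np.sqrt(np.mean(source**2))
        rms = rms if rms > 0 else 1.0
        return source + config.ref_noise_frac * rms * rng_refs.standard_normal(n)

    data = np.vstack([meg, reference(blink), reference(cardiac), trigger])
    roles = [ROLE_MEG] * config.n_meg_channels + [ROLE_MOG, ROLE_MCG, ROLE_TRIGGER]
    recording = Recording(data, fs, roles)
    truth = GroundTruth(
        blink_source=blink,
        cardiac_source=cardiac,
        erf_source=evoked,
        mixing_topographies=topo,
        trigger_onsets=onsets,
    )
    return recording, truth
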