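"""Synthetic FMG / load-cell data following the isometric exertion protocol.

The emulated protocol: a subject holds an instrumented sphere and, in each
trial, exerts isometric force along X, Y, Z (about 20 N peak), then torque
about the same axes (about 2 Nm peak), 40 s per axis at 10 Hz, tracing an
approximately sinusoidal profile; a final "free" session mixes all six axes
at once.  Five trials give 5 x 7 x 400 = 14,000 samples per subject.

Ground-truth labels are generated first; FMG channels are then synthesized
as nonnegative, softplus-compressed mixtures of the six axes with baseline,
slow drift, additive noise, and a per-trial multiplicative gain (emulating
band re-seating between trials).  Band informativeness is encoded in a
4 x 6 gain matrix: the forearm muscle-belly band (position 3) is the most
informative for every axis, while the upper-arm band (position 4) carries
essentially no torque information — the structure the placement analysis is
expected to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import firwin, lfilter

from .dataset import AXES, FREE_SESSION, SESSIONS, BandLayout, SubjectDataset
from .errors import ConfigError, DataError

#: Default band-position x axis gain scale (rows: wrist, midway, muscle
#: belly, upper arm; columns: Fx..Tz).  Row 3 dominates every axis; row 4 is
#: ~0 on the torque axes (<= 0.05 x the muscle-belly torque gains).
DEFAULT_BAND_GAIN_SCALE = np.array(
    [
        [0.40, 0.40, 0.40, 0.50, 0.50, 0.50],  # 1: wrist
        [0.60, 0.60, 0.60, 0.60, 0.60, 0.60],  # 2: forearm midway
        [1.00, 1.00, 1.00, 1.00, 1.00, 1.00],  # 3: forearm muscle belly
        [0.60, 0.60, 0.60, 0.02, 0.02, 0.02],  # 4: upper arm
    ]
)


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and amplitude parameters of the exertion protocol.

    Defaults reproduce the study protocol: 5 trials of 7 sessions (Fx, Fy,
    Fz, Tx, Ty, Tz, free), 40 s per session at 10 Hz.  Sinusoid frequency
    is drawn per session from ``sine_freq_range_hz`` (0.05–0.125 Hz gives
    2–5 cycles per session); cross-axis leakage coefficients are drawn from
    ``leakage_range``.  ``focused_noise_frac`` bounds the smooth off-axis
    noise relative to the focused amplitude.
    """

    n_trials: int = 5
    session_order: tuple[str, ...] = SESSIONS
    session_duration_s: float = 40.0
    sample_rate_hz: float = 10.0
    force_amp_n: float = 20.0
    torque_amp_nm: float = 2.0
    sine_freq_range_hz: tuple[float, float] = (0.05, 0.125)
    leakage_range: tuple[float, float] = (0.05, 0.30)
    focused_noise_frac: float = 0.1
    free_amp_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ConfigError("n_trials must be >= 2 for cross-trial evaluation")
        n = self.session_duration_s * self.sample_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ConfigError("session_duration_s x sample_rate_hz must be an integer")
        lo, hi = self.sine_freq_range_hz
        if not (0 < lo <= hi < self.sample_rate_hz / 2):
            raise ConfigError("sine_freq_range_hz must lie within (0, Nyquist)")
        lo, hi = self.leakage_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("leakage_range must lie within [0, 1)")
        unknown = set(self.session_order) - set(SESSIONS)
        if unknown:
            raise ConfigError(f"unknown session labels {sorted(unknown)}")

    @property
    def samples_per_session(self) -> int:
        return int(round(self.session_duration_s * self.sample_rate_hz))

    def amplitude(self, axis: str) -> float:
        """Nominal peak amplitude for one axis (N for forces, Nm for torques)."""
        if axis not in AXES:
            raise ConfigError(f"unknown axis {axis!r}")
        return self.force_amp_n if axis.startswith("F") else self.torque_amp_nm

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session_order"] = list(self.session_order)
        d["sine_freq_range_hz"] = list(self.sine_freq_range_hz)
        d["leakage_range"] = list(self.leakage_range)
        return d


@dataclass
class CouplingModel:
    """Per-subject mixing structure from 6-DoF loads to FMG channel drive.

    Channel j responds as::

        fmg_j(t) = baseline_j + g_trial * softplus(w_j . y(t))
                   + drift_j * t + noise

    where ``w_j`` is the channel's 6-vector of weights scaled by the gain
    row of its band, ``g_trial ~ N(1, trial_gain_sd^2)`` once per trial,
    and the output is clamped at 0 (an FSR cannot report negative force).
    """

    band_gain_scale: np.ndarray
    channel_weights: np.ndarray
    baseline: np.ndarray
    drift_rate: np.ndarray
    noise_sd: float = 0.05
    trial_gain_sd: float = 0.05
    nonlinearity: str = "softplus"

    def __post_init__(self) -> None:
        self.band_gain_scale = np.asarray(self.band_gain_scale, dtype=float)
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.drift_rate = np.asarray(self.drift_rate, dtype=float)
        if self.band_gain_scale.shape[1] != len(AXES):
            raise ConfigError("band_gain_scale must have one column per axis")
        if np.any(self.band_gain_scale < 0):
            raise ConfigError("band gains must be nonnegative")
        if self.noise_sd < 0 or self.trial_gain_sd < 0:
            raise ConfigError("noise_sd and trial_gain_sd must be nonnegative")
        if self.nonlinearity not in ("softplus", "identity"):
            raise ConfigError(f"unknown nonlinearity {self.nonlinearity!r}")

    def apply_nonlinearity(self, drive: np.ndarray) -> np.ndarray:
        if self.nonlinearity == "softplus":
            return np.logaddexp(0.0, drive)
        return drive

    @classmethod
    def default(
        cls,
        layout: BandLayout,
        seed: int = 0,
        preset: str = "default",
        cfg: ProtocolConfig | None = None,
    ) -> "CouplingModel":
        """Build a random per-subject coupling under a named preset.

        Presets: ``default`` / ``band3-dominant`` (the study conditions:
        muscle-belly band dominant, upper-arm band torque-blind),
        ``uniform`` (all band gains equal — no placement structure), and
        ``noiseless`` (default gains with noise, drift and trial-gain
        variation all zero, for parameter-recovery studies).
        """
        cfg = cfg or ProtocolConfig()
        rng = np.random.default_rng(seed)
        n_ch = layout.n_channels
        if preset in ("default", "band3-dominant", "noiseless"):
            gains = DEFAULT_BAND_GAIN_SCALE.copy()
        elif preset == "uniform":
            gains = np.ones((layout.n_bands, len(AXES)))
        else:
            raise ConfigError(f"unknown coupling preset {preset!r}")
        # weights expressed per unit of each axis' nominal amplitude so the
        # softplus drive is O(1) for every axis
        scale = np.array([cfg.amplitude(a) for a in AXES])
        weights = rng.normal(0.0, 1.0, size=(n_ch, len(AXES))) / scale
        baseline = rng.uniform(0.2, 0.6, size=n_ch)
        drift = rng.uniform(-2e-5, 2e-5, size=n_ch)
        noise_sd, trial_gain_sd = 0.05, 0.05
        if preset == "noiseless":
            noise_sd, trial_gain_sd = 0.0, 0.0
            drift = np.zeros(n_ch)
        return cls(
            band_gain_scale=gains,
            channel_weights=weights,
            baseline=baseline,
            drift_rate=drift,
            noise_sd=noise_sd,
            trial_gain_sd=trial_gain_sd,
        )


def _smooth_noise(n: int, cutoff_hz: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean band-limited Gaussian noise (spectral content <= cutoff)."""
    pad = 100
    white = rng.standard_normal(n + pad)
    taps = firwin(51, cutoff_hz, window="hamming", fs=fs)
    y = lfilter(taps, [1.0], white)[pad:]
    return y - y.mean()


def _scaled_to_peak(x: np.ndarray, peak: float) -> np.ndarray:
    m = np.max(np.abs(x))
    if m == 0 or peak == 0:
        return np.zeros_like(x)
    return x * (peak / m)


def generate_focused_session(
    cfg: ProtocolConfig, axis: str, rng: np.random.Generator
) -> np.ndarray:
    """Labels for one focused session: a sinusoid on one axis plus leakage.

    The focused axis follows ``A sin(2 pi f t + phi)`` with ``f`` drawn from
    ``sine_freq_range_hz`` and ``A`` the axis amplitude jittered by +-10%.
    Every other axis receives a leakage copy (coefficient drawn from
    ``leakage_range``) of the focused signal plus independent smooth noise
    bounded by ``focused_noise_frac`` x the focused amplitude — subjects
    cannot isolate a single axis perfectly.
    """
    if axis not in AXES:
        raise DataError(f"unknown axis label {axis!r}")
    n = cfg.samples_per_session
    t = np.arange(n) / cfg.sample_rate_hz
    amp_nominal = cfg.amplitude(axis)
    f = rng.uniform(*cfg.sine_freq_range_hz)
    phase = rng.uniform(0, 2 * np.pi)
    amp = amp_nominal * (1.0 + rng.uniform(-0.1, 0.1))
    focused = amp * np.sin(2 * np.pi * f * t + phase)
    out = np.zeros((n, len(AXES)))
    for j, ax in enumerate(AXES):
        if ax == axis:
            out[:, j] = focused
        else:
            c = rng.uniform(*cfg.leakage_range)
            noise_peak = rng.uniform(0.2, 1.0) * cfg.focused_noise_frac * amp_nominal
            noise = _scaled_to_peak(
                _smooth_noise(n, 0.4, cfg.sample_rate_hz, rng), noise_peak
            )
            out[:, j] = c * focused + noise
    return out


def generate_free_session(cfg: ProtocolConfig, rng: np.random.Generator) -> np.ndarray:
    """Labels for a free-exertion session: independent smooth load on each axis.

    Each axis is zero-mean band-limited (<= 0.4 Hz) Gaussian noise scaled to
    a peak of ``free_amp_frac`` x the axis amplitude; the subject wanders
    through the 6-DoF load space without favoring any axis.
    """
    n = cfg.samples_per_session
    out = np.zeros((n, len(AXES)))
    for j, ax in enumerate(AXES):
        peak = cfg.free_amp_frac * cfg.amplitude(ax)
        out[:, j] = _scaled_to_peak(_smooth_noise(n, 0.4, cfg.sample_rate_hz, rng), peak)
    return out


def synthesize_fmg(
    labels: np.ndarray,
    coupling: CouplingModel,
    layout: BandLayout,
    trial_id: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """FMG channel matrix for one trial's label matrix.

    Applies the coupling model channel-wise: band-scaled weighted drive,
    monotone nonlinearity, per-trial gain, baseline, linear drift, additive
    Gaussian noise, and a clamp at zero (the FSR floor).
    """
    labels = np.asarray(labels, dtype=float)
    if not np.all(np.isfinite(labels)):
        raise DataError("labels must be finite")
    if labels.ndim != 2 or labels.shape[1] != len(AXES):
        raise DataError(f"labels must be samples x {len(AXES)}, got {labels.shape}")
    bands = np.asarray(layout.channel_bands)
    if coupling.channel_weights.shape[0] != layout.n_channels:
        raise DataError("coupling channel count does not match layout")
    if coupling.band_gain_scale.shape[0] < layout.n_bands:
        raise DataError("coupling band_gain_scale does not cover all bands")
    w_eff = coupling.channel_weights * coupling.band_gain_scale[bands - 1]
    g_trial = 1.0 + coupling.trial_gain_sd * rng.standard_normal()
    n = labels.shape[0]
    drive = labels @ w_eff.T
    resp = (
        coupling.baseline[None, :]
        + g_trial * coupling.apply_nonlinearity(drive)
        + coupling.drift_rate[None, :] * np.arange(n)[:, None]
    )
    if coupling.noise_sd > 0:
        resp = resp + coupling.noise_sd * rng.standard_normal(resp.shape)
    return np.clip(resp, 0.0, None)


def generate_subject(
    cfg: ProtocolConfig,
    coupling: CouplingModel,
    layout: BandLayout,
    seed: int,
) -> SubjectDataset:
    """Generate a full subject: ``n_trials`` trials of the 7-session protocol.

    Deterministic given (cfg, coupling, layout, seed); the seed and the
    protocol configuration are recorded in the dataset metadata.
    """
    if cfg.n_trials < 2:
        raise ConfigError("n_trials must be >= 2")
    rng = np.random.default_rng(seed)
    fmg_parts, label_parts, trial_parts, session_parts = [], [], [], []
    for trial in range(cfg.n_trials):
        trial_labels = []
        trial_sessions = []
        for session in cfg.session_order:
            if session == FREE_SESSION:
                y = generate_free_session(cfg, rng)
            else:
                y = generate_focused_session(cfg, session, rng)
            trial_labels.append(y)
            trial_sessions.extend([session] * y.shape[0])
        y_trial = np.vstack(trial_labels)
        x_trial = synthesize_fmg(y_trial, coupling, layout, trial, rng)
        fmg_parts.append(x_trial)
        label_parts.append(y_trial)
        trial_parts.append(np.full(y_trial.shape[0], trial, dtype=int))
        session_parts.extend(trial_sessions)
    return SubjectDataset(
        fmg=np.vstack(fmg_parts),
        labels=np.vstack(label_parts),
        trial_id=np.concatenate(trial_parts),
        session_id=np.array(session_parts, dtype=object),
        layout=layout,
        channel_names=layout.channel_names,
        channel_bands=layout.channel_bands,
        meta={"seed": int(seed), "protocol": cfg.to_dict()},
    )
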