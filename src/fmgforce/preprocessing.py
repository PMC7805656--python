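"""Signal conditioning: detrending high-pass, smoothing low-pass, min-max
normalization referenced to the training split.

The chain is fixed: drop inactive sensors, high-pass the FMG channels with
a causal 1st-order Butterworth at 0.5 Hz (removes baseline and slow drift),
low-pass both FMG and the six load-cell channels with a causal 5th-order
(6-tap) Hamming-windowed FIR at 4 Hz, split into training / testing trials,
then rescale each FMG channel by the min and max observed on the *training*
data only.  Filters are applied per trial so no state crosses a trial
boundary.  Test values outside the training range are deliberately not
clipped — the affine map is applied as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, firwin, lfilter

from .errors import ConfigError, DataError


@dataclass(frozen=True)
class FilterSpec:
    """Filter parameters; defaults follow the acquisition pipeline."""

    hp_order: int = 1
    hp_cutoff_hz: float = 0.5
    lp_numtaps: int = 6  # FIR order 5 -> 6 coefficients
    lp_cutoff_hz: float = 4.0
    window: str = "hamming"
    sample_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        nyq = self.sample_rate_hz / 2.0
        if not (0 < self.hp_cutoff_hz < nyq):
            raise ConfigError(f"hp_cutoff_hz must lie in (0, {nyq})")
        if not (0 < self.lp_cutoff_hz < nyq):
            raise ConfigError(f"lp_cutoff_hz must lie in (0, {nyq})")
        if self.lp_numtaps < 2:
            raise ConfigError("lp_numtaps must be >= 2")

    def lowpass_taps(self) -> np.ndarray:
        """Hamming-windowed sinc taps, normalized to unit DC gain."""
        return firwin(
            self.lp_numtaps, self.lp_cutoff_hz, window=self.window, fs=self.sample_rate_hz
        )


def _check_signal(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 10:
        raise DataError("need at least 10 samples per channel to filter")
    if not np.all(np.isfinite(x)):
        raise DataError("signal contains non-finite values")
    return x


def highpass(signal: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Causal 1st-order Butterworth high-pass per channel (DC gain 0)."""
    x = _check_signal(signal)
    b, a = butter(spec.hp_order, spec.hp_cutoff_hz, btype="highpass", fs=spec.sample_rate_hz)
    y = lfilter(b, a, x, axis=0)
    return y if np.asarray(signal).ndim > 1 else y[:, 0]


def lowpass(signal: np.ndarray, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Causal Hamming-window FIR low-pass per channel (unit DC gain)."""
    x = _check_signal(signal)
    taps = spec.lowpass_taps()
    y = lfilter(taps, [1.0], x, axis=0)
    return y if np.asarray(signal).ndim > 1 else y[:, 0]


def filter_by_trial(
    x: np.ndarray,
    trial_id: np.ndarray,
    spec: FilterSpec = FilterSpec(),
    high: bool = False,
) -> np.ndarray:
    """Apply lowpass (and optionally highpass first) independently per trial."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x, dtype=float)
    for t in np.unique(trial_id):
        m = trial_id == t
        seg = x[m]
        if high:
            seg = highpass(seg, spec)
        out[m] = lowpass(seg, spec)
    return out


@dataclass(frozen=True)
class NormalizationRef:
    """Per-channel min/max learned from training FMG data."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def constant_channels(self) -> np.ndarray:
        return np.flatnonzero(self.maxs <= self.mins)


def fit_normalizer(train_fmg: np.ndarray) -> NormalizationRef:
    """Learn per-channel min and max from the training FMG matrix."""
    x = np.asarray(train_fmg, dtype=float)
    if x.size == 0:
        raise DataError("cannot fit a normalizer on an empty matrix")
    if x.ndim == 1:
        x = x[:, None]
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    if np.any(maxs <= mins):
        warnings.warn(
            f"{int(np.sum(maxs <= mins))} constant training channel(s); mapped to 0",
            stacklevel=2,
        )
    return NormalizationRef(mins=mins, maxs=maxs)


def apply_normalizer(ref: NormalizationRef, fmg: np.ndarray) -> np.ndarray:
    """Affine map to [0, 1] on the training range; no clipping outside it."""
    x = np.asarray(fmg, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    if x.shape[1] != len(ref.mins):
        raise DataError(
            f"channel count {x.shape[1]} does not match normalizer ({len(ref.mins)})"
        )
    span = ref.maxs - ref.mins
    safe = np.where(span > 0, span, 1.0)
    y = (x - ref.mins) / safe
    y[:, ref.constant_channels] = 0.0
    return y[:, 0] if squeeze else y
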