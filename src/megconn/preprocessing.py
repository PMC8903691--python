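"""Sensor-level preprocessing: DC removal, band-pass/notch filtering, epoching.

The analysis operates in the five canonical electrophysiological frequency
bands (delta 1-4 Hz, theta 4-8 Hz, alpha 8-12 Hz, beta 13-30 Hz, gamma
30-90 Hz).  Filtering is zero-phase (forward-backward 4th-order Butterworth)
so that band-limited evoked components are not delayed relative to the
stimulus trigger.  Continuous data are filtered before epoching: the analysis
window (default 90-180 ms post-trigger) is far too short to filter at the
low band edges, and filtering first avoids edge transients inside the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "EpochWindow",
    "CANONICAL_BANDS",
    "get_band",
    "remove_dc",
    "bandpass",
    "notch",
    "epoch_and_average",
    "extract_epochs",
    "exclude_by_movement",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with low and high edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo={self.lo} must be < hi={self.hi}")

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


#: The canonical five-band decomposition used throughout the pipeline.
CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 90.0),
}


def get_band(name: str) -> BandDefinition:
    """Look up one of the five canonical bands by name."""
    try:
        return CANONICAL_BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; canonical bands are {sorted(CANONICAL_BANDS)}"
        ) from None


@dataclass(frozen=True)
class EpochWindow:
    """Analysis window in milliseconds relative to the stimulus trigger."""

    start_ms: float = 90.0
    end_ms: float = 180.0

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("start_ms must be < end_ms")

    def to_samples(self, sfreq: float) -> tuple[int, int]:
        """Window as (start, stop) sample offsets relative to the trigger."""
        start = int(round(self.start_ms * sfreq / 1000.0))
        stop = int(round(self.end_ms * sfreq / 1000.0))
        return start, stop


def _check_finite(data: np.ndarray) -> None:
    if not np.all(np.isfinite(data)):
        bad = np.unique(np.nonzero(~np.isfinite(data))[0])
        raise ValueError(f"non-finite values in channels {bad.tolist()}")


def remove_dc(data: np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean (direct-current offset).

    ``data`` is channels x samples (trailing trial axes are allowed; the mean
    is taken over the sample axis independently per channel and trial).
    """
    data = np.asarray(data, dtype=float)
    _check_finite(data)
    return data - data.mean(axis=1, keepdims=True)


def _butter_sos(lo: float, hi: float, sfreq: float, order: int = 4) -> np.ndarray:
    nyq = sfreq / 2.0
    if hi >= nyq:
        raise ValueError(
            f"band edge {hi} Hz violates Nyquist ({nyq} Hz at sfreq={sfreq})"
        )
    return signal.butter(order, [lo, hi], btype="bandpass", fs=sfreq, output="sos")


def bandpass(data: np.ndarray, sfreq: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass along the sample axis."""
    data = np.asarray(data, dtype=float)
    _check_finite(data)
    sos = _butter_sos(band.lo, band.hi, sfreq)
    return signal.sosfiltfilt(sos, data, axis=1)


def notch(data: np.ndarray, sfreq: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (default 50 Hz power-line)."""
    data = np.asarray(data, dtype=float)
    _check_finite(data)
    if freq >= sfreq / 2.0:
        raise ValueError(f"notch frequency {freq} violates Nyquist at sfreq={sfreq}")
    b, a = signal.iirnotch(freq, q, fs=sfreq)
    return signal.filtfilt(b, a, data, axis=1)


def default_reject_threshold(data: np.ndarray, k: float = 5.0) -> float:
    """Peak-amplitude artifact threshold: ``k`` x the median per-channel robust SD.

    The robust SD is 1.4826 x the median absolute deviation, so the default is
    calibrated for roughly Gaussian background activity.
    """
    flat = data.reshape(data.shape[0], -1)
    mad = np.median(np.abs(flat - np.median(flat, axis=1, keepdims=True)), axis=1)
    return float(k * np.median(1.4826 * mad))


def extract_epochs(
    data: np.ndarray,
    sfreq: float,
    trigger_samples: np.ndarray,
    window: EpochWindow,
) -> np.ndarray:
    """Slice window epochs around each trigger; returns trials x channels x samples."""
    data = np.asarray(data, dtype=float)
    trigger_samples = np.asarray(trigger_samples, dtype=int)
    start, stop = window.to_samples(sfreq)
    n_samples = data.shape[1]
    epochs = []
    for trig in trigger_samples:
        a, b = trig + start, trig + stop
        if a < 0 or b > n_samples:
            raise ValueError(
                f"window [{a}, {b}) around trigger {trig} falls outside the recording"
            )
        epochs.append(data[:, a:b])
    return np.stack(epochs)


def epoch_and_average(
    data: np.ndarray,
    sfreq: float,
    trigger_samples: np.ndarray,
    window: EpochWindow,
    reject: float | None = None,
) -> tuple[np.ndarray, int]:
    """Epoch, artifact-reject, and average.

    Trials whose peak absolute amplitude exceeds ``reject`` are dropped before
    averaging.  ``reject=None`` uses :func:`default_reject_threshold`;
    ``reject=inf`` disables rejection.  Returns the channels x window-samples
    average over kept trials and the kept-trial count.  Raises if every trial
    is rejected rather than returning an empty average.
    """
    _check_finite(np.asarray(data, dtype=float))
    epochs = extract_epochs(data, sfreq, trigger_samples, window)
    if reject is None:
        reject = default_reject_threshold(epochs)
    peaks = np.abs(epochs).max(axis=(1, 2))
    keep = peaks <= reject
    n_kept = int(keep.sum())
    if n_kept == 0:
        raise ValueError(
            f"all {len(epochs)} trials exceeded the rejection threshold {reject:g}"
        )
    return epochs[keep].mean(axis=0), n_kept


def exclude_by_movement(movement_mm: float, limit_mm: float = 5.0) -> bool:
    """Keep/drop decision from head movement; returns True when the subject is kept.

    Movement strictly beyond the limit drops the recording; movement exactly at
    the limit is kept.
    """
    if movement_mm < 0:
        raise ValueError("movement must be non-negative")
    keep = movement_mm <= limit_mm
    if not keep:
        warnings.warn(
            f"recording dropped: head movement {movement_mm:.2f} mm exceeds "
            f"{limit_mm:.2f} mm",
            stacklevel=2,
        )
    return keep
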