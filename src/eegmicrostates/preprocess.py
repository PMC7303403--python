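"""Filtering, resampling, referencing and epoching of raw recordings.

The filter chain mirrors common clinical-EEG practice: a zero-phase Kaiser-
window FIR bandpass (1-70 Hz) followed by a 45-55 Hz band-stop, resampling to
200 Hz, one-second epochs and average re-referencing.  Band-specific analyses
use delta (lowpass < 4 Hz), theta (4-8), alpha (8-13) and beta (13-30) in
addition to the 40 Hz-lowpassed broadband signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import EpochedRecording, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec", "BANDS", "BROADBAND",
    "fir_filter", "downsample", "average_reference", "epoch", "band_filter",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band; ``low_hz=None`` means a pure lowpass band."""

    name: str
    low_hz: float | None
    high_hz: float

    def __post_init__(self):
        low = 0.0 if self.low_hz is None else self.low_hz
        if not 0 <= low < self.high_hz:
            raise ValueError(f"invalid band edges for {self.name!r}")


#: broadband analysis band: 40 Hz lowpass applied after the 1-70 Hz bandpass
BROADBAND = BandSpec("broadband", None, 40.0)

#: delta is realized as a pure lowpass below 4 Hz despite its 1-4 Hz name
BANDS: tuple[BandSpec, ...] = (
    BROADBAND,
    BandSpec("delta", None, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)


def _kaiser_taps(kind: str, edges: tuple[float, ...], fs: float,
                 max_ripple: float) -> np.ndarray:
    """Design a linear-phase Kaiser FIR; transition width = 25% of the lower edge."""
    nyq = fs / 2.0
    if any(not 0 < e < nyq for e in edges):
        raise ValueError(f"filter edges {edges} must lie strictly inside (0, {nyq})")
    atten_db = -20.0 * math.log10(max_ripple)
    lower_edge = min(edges)
    width_hz = 0.25 * lower_edge
    numtaps, beta = sps.kaiserord(atten_db, width_hz / nyq)
    numtaps |= 1  # odd length -> integer group delay, exactly zero-phase
    if kind == "lowpass":
        (cutoff,) = edges
        taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta),
                          pass_zero="lowpass", fs=fs)
    elif kind == "highpass":
        (cutoff,) = edges
        taps = sps.firwin(numtaps, cutoff, window=("kaiser", beta),
                          pass_zero="highpass", fs=fs)
    elif kind == "bandpass":
        taps = sps.firwin(numtaps, list(edges), window=("kaiser", beta),
                          pass_zero="bandpass", fs=fs)
    elif kind == "bandstop":
        taps = sps.firwin(numtaps, list(edges), window=("kaiser", beta),
                          pass_zero="bandstop", fs=fs)
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    logger.info("designed %s FIR: edges=%s Hz, order=%d, beta=%.2f",
                kind, edges, numtaps - 1, beta)
    return taps


def fir_filter(rec: Recording, kind: str, edges, max_ripple: float = 0.001) -> Recording:
    """Zero-phase Kaiser-window FIR filter (forward filtering, delay compensated).

    ``kind`` is one of ``lowpass``, ``highpass``, ``bandpass``, ``bandstop``;
    ``edges`` the corresponding corner frequencies in Hz.  The Kaiser beta and
    order follow from ``max_ripple`` (maximum passband ripple as a fraction)
    with a transition width of 25% of the lower edge.
    """
    edges = tuple(np.atleast_1d(np.asarray(edges, dtype=float)))
    taps = _kaiser_taps(kind, edges, rec.fs, max_ripple)
    if rec.n_samples <= len(taps):
        raise ValueError(
            f"signal ({rec.n_samples} samples) shorter than filter length "
            f"({len(taps)} taps)")
    # odd symmetric taps + 'same' convolution == forward filter with the
    # group delay compensated, i.e. zero-phase
    padded = np.pad(rec.data, ((0, 0), (len(taps) // 2, len(taps) // 2)), mode="reflect")
    filtered = sps.oaconvolve(padded, taps[None, :], mode="valid", axes=1)
    return Recording(data=filtered, fs=rec.fs, montage=rec.montage,
                     reference=rec.reference, subject_id=rec.subject_id)


def downsample(rec: Recording, target_fs: float) -> Recording:
    """Polyphase resampling (anti-alias filtered) to ``target_fs``."""
    if target_fs > rec.fs:
        raise ValueError("target_fs must not exceed the current sampling rate")
    if target_fs == rec.fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    data = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data=data, fs=target_fs, montage=rec.montage,
                     reference=rec.reference, subject_id=rec.subject_id)


def average_reference(rec: Recording) -> Recording:
    """Re-express every channel relative to the instantaneous channel mean."""
    if rec.n_channels < 2:
        raise ValueError("average referencing needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data=data, fs=rec.fs, montage=rec.montage,
                     reference="average", subject_id=rec.subject_id)


def epoch(rec: Recording, epoch_length_s: float = 1.0) -> EpochedRecording:
    """Cut into consecutive fixed-length epochs; a trailing partial is dropped."""
    samples_per_epoch = round(rec.fs * epoch_length_s)
    if samples_per_epoch < 1 or rec.n_samples < samples_per_epoch:
        raise ValueError("recording shorter than one epoch")
    n_epochs = rec.n_samples // samples_per_epoch
    used = rec.data[:, :n_epochs * samples_per_epoch]
    epochs = used.reshape(rec.n_channels, n_epochs, samples_per_epoch)
    epochs = np.moveaxis(epochs, 1, 0)
    return EpochedRecording(epochs=epochs.copy(), fs=rec.fs, montage=rec.montage,
                            epoch_length_s=epoch_length_s, subject_id=rec.subject_id)


def band_filter(rec: Recording, band: BandSpec, max_ripple: float = 0.001) -> Recording:
    """Apply one analysis band: lowpass if ``low_hz`` is absent, else bandpass."""
    if band.low_hz is None:
        return fir_filter(rec, "lowpass", (band.high_hz,), max_ripple)
    return fir_filter(rec, "bandpass", (band.low_hz, band.high_hz), max_ripple)
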