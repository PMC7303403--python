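"""Core in-memory containers shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import validate_montage


@dataclass
class Recording:
    """One subject's multichannel EEG: channels x samples, arbitrary units."""

    data: np.ndarray
    fs: float
    montage: tuple[str, ...]
    reference: str = "other"
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        self.montage = validate_montage(self.montage)
        if len(self.montage) != self.data.shape[0]:
            raise ValueError("montage length must equal channel count")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochedRecording:
    """Fixed-length epochs treated as temporally discontinuous blocks."""

    epochs: np.ndarray  # n_epochs x channels x samples_per_epoch
    fs: float
    montage: tuple[str, ...]
    epoch_length_s: float
    subject_id: str = ""

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be n_epochs x channels x samples")
        self.montage = validate_montage(self.montage)
        expected = round(self.fs * self.epoch_length_s)
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"samples per epoch {self.epochs.shape[2]} != "
                f"round(fs * epoch_length) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def concatenate(self) -> np.ndarray:
        """channels x (n_epochs * samples_per_epoch) view of all epochs."""
        return np.concatenate(list(self.epochs), axis=1)


@dataclass
class TemplateMaps:
    """K reference scalp topographies (zero-mean, unit-norm rows)."""

    montage: tuple[str, ...]
    maps: np.ndarray  # K x channels
    labels: tuple[str, ...]

    def __post_init__(self):
        self.montage = validate_montage(self.montage)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.shape != (len(self.labels), len(self.montage)):
            raise ValueError("maps must be K x n_channels with K labels")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class MicrostateMaps:
    """Cluster maps from modified K-means; polarity is always ambiguous."""

    maps: np.ndarray  # K x channels
    montage: tuple[str, ...]
    labels: tuple[str, ...]
    polarity_ambiguous: bool = True
    residual_variance: float | None = None
    template_correlations: tuple[float, ...] | None = None

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=float)
        self.montage = validate_montage(self.montage)
        if len(self.labels) != self.maps.shape[0]:
            raise ValueError("one label per map required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("map labels must be unique")

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]


@dataclass
class GfpPeaks:
    """GFP-peak topographies retained for clustering, one subject."""

    subject_id: str
    peak_times: np.ndarray          # global sample indices, strictly increasing
    topographies: np.ndarray        # n_peaks x channels
    gfp_values: np.ndarray

    def __post_init__(self):
        self.peak_times = np.asarray(self.peak_times, dtype=int)
        self.topographies = np.atleast_2d(np.asarray(self.topographies, dtype=float))
        self.gfp_values = np.asarray(self.gfp_values, dtype=float)

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


@dataclass
class Segmentation:
    """Per-sample microstate labels for one epoched recording."""

    labels: np.ndarray   # n_epochs x samples_per_epoch, int map indices
    fit: np.ndarray      # squared spatial correlation with the assigned map
    gfp: np.ndarray      # per-sample global field power
    fs: float
    maps: MicrostateMaps
    subject_id: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.fit = np.asarray(self.fit, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        if not (self.labels.shape == self.fit.shape == self.gfp.shape):
            raise ValueError("labels, fit and gfp must share one shape")
        if self.labels.ndim != 2:
            raise ValueError("labels must be n_epochs x samples_per_epoch")

    @property
    def n_maps(self) -> int:
        return self.maps.n_maps


@dataclass
class MicrostateStats:
    """Per-subject summary: duration (ms), occurrence (1/s), coverage (%), GEV."""

    map_labels: tuple[str, ...]
    duration_ms: np.ndarray    # NaN for a map that never occurs
    occurrence_per_s: np.ndarray
    coverage_pct: np.ndarray
    gev_total: float
    subject_id: str = ""

    def __post_init__(self):
        self.duration_ms = np.asarray(self.duration_ms, dtype=float)
        self.occurrence_per_s = np.asarray(self.occurrence_per_s, dtype=float)
        self.coverage_pct = np.asarray(self.coverage_pct, dtype=float)

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        out: dict[str, float] = {}
        for i, label in enumerate(self.map_labels):
            out[f"{prefix}duration_{label}_ms"] = float(self.duration_ms[i])
            out[f"{prefix}occurrence_{label}_per_s"] = float(self.occurrence_per_s[i])
            out[f"{prefix}coverage_{label}_pct"] = float(self.coverage_pct[i])
        out[f"{prefix}gev_total"] = float(self.gev_total)
        return out


@dataclass
class TransitionProfile:
    """Observed vs occurrence-expected transition percentages (12 ordered pairs)."""

    pair_labels: tuple[str, ...]    # e.g. ("A->B", "A->C", ...)
    observed_pct: np.ndarray
    expected_pct: np.ndarray
    chi2_distance: float = field(default=float("nan"))

    def __post_init__(self):
        self.observed_pct = np.asarray(self.observed_pct, dtype=float)
        self.expected_pct = np.asarray(self.expected_pct, dtype=float)
        if self.observed_pct.shape != self.expected_pct.shape:
            raise ValueError("observed and expected must have one length")
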