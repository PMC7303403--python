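"""Synthetic resting-state EEG with planted microstate structure.

The generator emits 19-channel, average-referenced EEG whose topography
alternates among K template maps according to a semi-Markov chain (explicit
gamma-distributed dwell times, next state drawn from a transition-weight
matrix).  The active map is modulated by a rectified sinusoid so the global
field power shows discrete peaks at twice the carrier frequency, as in
alpha-dominant resting EEG; white sensor noise is added at a configurable
signal-to-noise ratio.  Cohorts add group-specific dwell-time offsets and a
demographic covariate table so the covariate-adjusted group statistics and
the classifiers can be exercised by parameter recovery.

Dwell times and transitions are planted independently, so per-map duration
and occurrence effects can be controlled separately.  Covariates are drawn
independently of the EEG except through group membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Recording, TemplateMaps
from .montage import MONTAGE_10_20, channel_positions, validate_montage

__all__ = [
    "make_canonical_maps",
    "SubjectSimConfig",
    "GroupSpec",
    "GroupCovariates",
    "CohortSimConfig",
    "SyntheticCohort",
    "simulate_subject",
    "simulate_cohort",
    "default_covariate_model",
    "default_cohort_config",
]


def _zero_mean_unit_norm(maps: np.ndarray) -> np.ndarray:
    maps = maps - maps.mean(axis=1, keepdims=True)
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


def make_canonical_maps(montage=MONTAGE_10_20) -> TemplateMaps:
    """Build four archetypal template topographies on the 10-20 montage.

    The four maps follow the canonical resting-state archetypes: A and B are
    mirror-image diagonal gradients (left-posterior to right-anterior and its
    left-right reflection), C is an antero-posterior gradient, and D a
    fronto-central focal pattern.  Rows are average-referenced and unit-norm;
    no published numeric values exist for such maps, so these are synthetic
    stand-ins with the right symmetry and mutual-correlation structure.
    """
    montage = validate_montage(montage)
    xy = channel_positions(montage)
    x, y = xy[:, 0], xy[:, 1]
    s = np.sqrt(0.5)
    map_a = s * x + s * y          # right-anterior vs left-posterior diagonal
    map_b = -s * x + s * y         # mirror image of A
    map_c = y                      # anterior vs posterior
    map_d = np.exp(-((x / 0.55) ** 2 + ((y - 0.25) / 0.55) ** 2))  # fronto-central focus
    maps = _zero_mean_unit_norm(np.vstack([map_a, map_b, map_c, map_d]))
    return TemplateMaps(montage=montage, maps=maps, labels=("A", "B", "C", "D"))


@dataclass
class SubjectSimConfig:
    """Parameters of the single-subject semi-Markov EEG generator."""

    templates: TemplateMaps
    dwell_mean_ms: tuple[float, ...] = (75.0, 80.0, 85.0, 100.0)
    dwell_shape: float = 2.0
    transition_weights: np.ndarray | None = None  # K x K, zero diagonal
    carrier_freq_hz: float = 10.0
    snr: float = 8.0
    duration_s: float = 60.0
    fs: float = 200.0

    def __post_init__(self):
        k = self.templates.n_maps
        if len(self.dwell_mean_ms) != k:
            raise ValueError("one dwell mean per template map required")
        if any(m <= 0 for m in self.dwell_mean_ms):
            raise ValueError("dwell means must be positive")
        if self.dwell_shape <= 0:
            raise ValueError("gamma dwell shape must be positive")
        if self.transition_weights is None:
            self.transition_weights = np.ones((k, k)) - np.eye(k)
        self.transition_weights = np.asarray(self.transition_weights, dtype=float)
        if self.transition_weights.shape != (k, k):
            raise ValueError("transition_weights must be K x K")
        if np.any(np.diag(self.transition_weights) != 0):
            raise ValueError("transition_weights diagonal must be zero")
        if np.any(self.transition_weights < 0):
            raise ValueError("transition_weights must be nonnegative")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if not self.fs > 2 * self.carrier_freq_hz:
            raise ValueError("fs must exceed twice the carrier frequency")

    def with_dwell_offset(self, offset_ms) -> "SubjectSimConfig":
        dwell = tuple(m + o for m, o in zip(self.dwell_mean_ms, offset_ms))
        return SubjectSimConfig(
            templates=self.templates,
            dwell_mean_ms=dwell,
            dwell_shape=self.dwell_shape,
            transition_weights=self.transition_weights.copy(),
            carrier_freq_hz=self.carrier_freq_hz,
            snr=self.snr,
            duration_s=self.duration_s,
            fs=self.fs,
        )


def _draw_state_sequence(cfg: SubjectSimConfig, n_samples: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Semi-Markov label sequence: gamma dwells rounded to >= 1 sample."""
    k = cfg.templates.n_maps
    weights = cfg.transition_weights
    labels = np.empty(n_samples, dtype=int)
    state = int(rng.integers(k))
    t = 0
    scale_samples = cfg.fs / 1000.0
    while t < n_samples:
        mean_ms = cfg.dwell_mean_ms[state]
        dwell_ms = rng.gamma(cfg.dwell_shape, mean_ms / cfg.dwell_shape)
        dwell = max(1, int(round(dwell_ms * scale_samples)))
        labels[t:t + dwell] = state
        t += dwell
        row = weights[state]
        total = row.sum()
        if total <= 0:  # absorbing row: stay (degenerate config)
            labels[t:] = state
            break
        state = int(rng.choice(k, p=row / total))
    return labels


def simulate_subject(cfg: SubjectSimConfig, seed: int,
                     subject_id: str = "sim") -> tuple[Recording, np.ndarray]:
    """Simulate one subject; returns the recording and the true label sequence.

    The emitted frame at sample t is ``map[state_t] * |sin(2*pi*f*t/fs)|`` plus
    white noise scaled so that the ratio of clean-signal RMS to noise RMS
    equals ``cfg.snr``; the sum is then average-referenced.  ``snr=np.inf``
    gives a noise-free recording.
    """
    rng = np.random.default_rng(seed)
    n_samples = int(round(cfg.duration_s * cfg.fs))
    if n_samples < 1:
        raise ValueError("recording must contain at least one sample")
    labels = _draw_state_sequence(cfg, n_samples, rng)
    t = np.arange(n_samples) / cfg.fs
    envelope = np.abs(np.sin(2 * np.pi * cfg.carrier_freq_hz * t))
    clean = cfg.templates.maps[labels].T * envelope  # channels x samples
    signal_rms = np.sqrt(np.mean(clean ** 2))
    if np.isfinite(cfg.snr):
        noise = rng.normal(0.0, signal_rms / cfg.snr, size=clean.shape)
    else:
        noise = 0.0
    data = clean + noise
    data = data - data.mean(axis=0, keepdims=True)
    rec = Recording(data=data, fs=cfg.fs, montage=cfg.templates.montage,
                    reference="average", subject_id=subject_id)
    return rec, labels


@dataclass
class GroupSpec:
    name: str
    n_subjects: int
    dwell_offset_ms: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("each group needs at least 2 subjects")


@dataclass
class GroupCovariates:
    """Marginal covariate distributions for one diagnostic group."""

    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    female_prop: float
    med_probs: dict[str, float]
    mmse_mean: float
    mmse_sd: float
    cerad_learning_mean: float
    cerad_learning_sd: float
    cerad_recall_mean: float
    cerad_recall_sd: float

    def __post_init__(self):
        for sd in (self.age_sd, self.education_sd, self.mmse_sd,
                   self.cerad_learning_sd, self.cerad_recall_sd):
            if sd < 0:
                raise ValueError("standard deviations must be nonnegative")
        probs = [self.female_prop, *self.med_probs.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


MED_FLAGS = ("med_antipsychotic", "med_antidepressant", "med_hypnotic",
             "med_antidementia", "med_painkiller")


def default_covariate_model() -> dict[str, GroupCovariates]:
    """Marginals emulating the published three-group memory-clinic cohort."""
    return {
        "HC": GroupCovariates(66.44, 7.64, 13.89, 3.61, 0.607,
                              dict(zip(MED_FLAGS, (0.0, 0.0, 3 / 135, 0.0, 4 / 135))),
                              28.91, 1.34, 20.49, 3.99, 7.39, 1.69),
        "MCI": GroupCovariates(70.15, 8.13, 11.57, 3.92, 0.530,
                               dict(zip(MED_FLAGS, (1 / 117, 25 / 117, 12 / 117,
                                                    2 / 117, 6 / 117))),
                               27.11, 2.16, 15.25, 4.29, 3.66, 2.34),
        "AD": GroupCovariates(75.49, 7.65, 10.07, 3.39, 0.607,
                              dict(zip(MED_FLAGS, (4 / 117, 18 / 117, 6 / 117,
                                                   18 / 117, 4 / 117))),
                              23.52, 3.79, 11.06, 3.83, 1.52, 1.64),
    }


@dataclass
class CohortSimConfig:
    groups: list[GroupSpec]
    covariate_model: dict[str, GroupCovariates]
    subject: SubjectSimConfig
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("at least one group is required")
        for g in self.groups:
            if g.name not in self.covariate_model:
                raise ValueError(f"no covariate model for group {g.name!r}")
            if len(g.dwell_offset_ms) != self.subject.templates.n_maps:
                raise ValueError("dwell offset length must equal map count")


def default_cohort_config(n_per_group: int = 30, *, seed: int = 0,
                          duration_s: float = 60.0, snr: float = 8.0,
                          map_a_effect_ms: float = 15.0) -> CohortSimConfig:
    """Three-group cohort with the planted patient effect on map A.

    The planted direction mirrors the published finding: longer microstate-A
    dwell times in the MCI and AD groups than in healthy controls, with a
    default shift of +15 ms.
    """
    templates = make_canonical_maps()
    subject = SubjectSimConfig(templates=templates, duration_s=duration_s, snr=snr)
    effect = (map_a_effect_ms, 0.0, 0.0, 0.0)
    groups = [
        GroupSpec("HC", n_per_group),
        GroupSpec("MCI", n_per_group, effect),
        GroupSpec("AD", n_per_group, effect),
    ]
    return CohortSimConfig(groups=groups, covariate_model=default_covariate_model(),
                           subject=subject, seed=seed)


@dataclass
class SyntheticCohort:
    recordings: list[Recording]
    true_labels: list[np.ndarray]
    covariates: pd.DataFrame     # subject_id, group, age, sex, ... scores
    true_dwell_mean_ms: pd.DataFrame  # one row per subject, one column per map
    config: CohortSimConfig = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    def ground_truth(self) -> dict:
        """JSON-serializable record of the planted parameters."""
        cfg = self.config
        return {
            "seed": cfg.seed,
            "groups": [
                {"name": g.name, "n_subjects": g.n_subjects,
                 "dwell_offset_ms": list(g.dwell_offset_ms)}
                for g in cfg.groups
            ],
            "base_dwell_mean_ms": list(cfg.subject.dwell_mean_ms),
            "dwell_shape": cfg.subject.dwell_shape,
            "transition_weights": cfg.subject.transition_weights.tolist(),
            "carrier_freq_hz": cfg.subject.carrier_freq_hz,
            "snr": cfg.subject.snr,
            "duration_s": cfg.subject.duration_s,
            "fs": cfg.subject.fs,
            "template_labels": list(cfg.subject.templates.labels),
            "template_maps": cfg.subject.templates.maps.tolist(),
            "per_subject_dwell_mean_ms": {
                row["subject_id"]: [row[lbl] for lbl in cfg.subject.templates.labels]
                for _, row in self.true_dwell_mean_ms.iterrows()
            },
        }


def _draw_covariates(model: GroupCovariates, rng: np.random.Generator) -> dict:
    row = {
        "age": float(rng.normal(model.age_mean, model.age_sd)),
        "sex": int(rng.random() < model.female_prop),  # 1 = female
        "education_years": float(rng.normal(model.education_mean, model.education_sd)),
        "mmse": float(np.clip(rng.normal(model.mmse_mean, model.mmse_sd), 0, 30)),
        "cerad_learning": float(np.clip(
            rng.normal(model.cerad_learning_mean, model.cerad_learning_sd), 0, 30)),
        "cerad_recall": float(np.clip(
            rng.normal(model.cerad_recall_mean, model.cerad_recall_sd), 0, 10)),
    }
    for flag in MED_FLAGS:
        row[flag] = int(rng.random() < model.med_probs.get(flag, 0.0))
    return row


def simulate_cohort(cfg: CohortSimConfig) -> SyntheticCohort:
    """Simulate every subject of every group; bit-identical for equal seeds."""
    root = np.random.SeedSequence(cfg.seed)
    map_labels = cfg.subject.templates.labels
    recordings, true_labels, cov_rows, dwell_rows = [], [], [], []
    idx = 0
    for group in cfg.groups:
        model = cfg.covariate_model[group.name]
        for _ in range(group.n_subjects):
            subject_seed, covariate_seed = root.spawn(1)[0].generate_state(2) % (2 ** 31)
            subject_id = f"sub-{idx:03d}"
            sub_cfg = cfg.subject.with_dwell_offset(group.dwell_offset_ms)
            rec, labels = simulate_subject(sub_cfg, int(subject_seed), subject_id)
            recordings.append(rec)
            true_labels.append(labels)
            row = {"subject_id": subject_id, "group": group.name}
            row.update(_draw_covariates(model, np.random.default_rng(int(covariate_seed))))
            cov_rows.append(row)
            dwell_rows.append({"subject_id": subject_id,
                               **dict(zip(map_labels, sub_cfg.dwell_mean_ms))})
            idx += 1
    covariates = pd.DataFrame(cov_rows)
    dwell = pd.DataFrame(dwell_rows)
    return SyntheticCohort(recordings, true_labels, covariates, dwell, cfg)
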