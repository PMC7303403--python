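"""End-to-end orchestration: simulate/load -> preprocess -> microstates per
band -> syntax -> group statistics -> classification, from one config with a
single master seed.

Every stochastic stage derives a child seed from ``master_seed`` in a fixed
order, so a run is reproducible end to end.  Artifacts are written to a run
directory with one subfolder per stage and a JSON manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import Recording, TemplateMaps
from .classify import build_feature_matrix, feature_columns, loo_cv
from .group_stats import DEFAULT_COVARIATES, run_battery
from .io import read_cohort_recordings, write_maps
from .microstates import (aggregate_and_cluster, backfit,
                          canonicalize_to_templates, compute_stats,
                          extract_gfp_peaks, smooth_segmentation)
from .preprocess import (BANDS, average_reference, band_filter, downsample,
                         epoch, fir_filter)
from .synthetic import default_cohort_config, make_canonical_maps, simulate_cohort
from .syntax import syntax_permutation_test, transition_profile

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyze_band",
           "preprocess_recording", "band_features_row"]

_BAND_BY_NAME = {b.name: b for b in BANDS}


@dataclass
class PipelineConfig:
    """Everything one analysis run needs; loadable from YAML."""

    input_dir: str | None = None          # cohort directory; None -> simulate
    n_per_group: int = 20                 # simulation size when input_dir is None
    duration_s: float = 60.0
    snr: float = 8.0
    map_a_effect_ms: float = 15.0
    bands: tuple[str, ...] = ("broadband", "delta", "theta", "alpha", "beta")
    k: int = 4                            # 3, 5 and 6 supported for reruns
    peaks_per_subject: int = 1000
    min_peak_distance_ms: float = 10.0
    sd_threshold: float = 2.0
    gfp_exclude_rule: str = "mean+2sd"
    smoothing_ms: float = 30.0
    n_restarts: int = 50
    kmeans_max_iter: int = 1000
    n_permutations: int = 5000
    classifiers: tuple[str, ...] = ("multinomial", "logistic")
    epoch_length_s: float = 1.0
    target_fs: float = 200.0
    apply_line_filters: bool = True       # 1-70 Hz bandpass + 45-55 Hz stop
    master_seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")
        for name in self.bands:
            if name not in _BAND_BY_NAME:
                raise ValueError(f"unknown band {name!r}")
        for count in (self.peaks_per_subject, self.n_restarts,
                      self.kmeans_max_iter, self.n_permutations):
            if count < 1:
                raise ValueError("all counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    @property
    def battery_size(self) -> int:
        return 3 * self.k + self.k * (self.k - 1)


def preprocess_recording(rec: Recording, cfg: PipelineConfig) -> Recording:
    """Standard chain: optional 1-70 Hz bandpass + 45-55 Hz stop, resample,
    average re-reference."""
    if cfg.apply_line_filters:
        rec = fir_filter(rec, "bandpass", (1.0, min(70.0, 0.95 * rec.fs / 2)))
        if 55.0 < rec.fs / 2:
            rec = fir_filter(rec, "bandstop", (45.0, 55.0))
    if rec.fs > cfg.target_fs:
        rec = downsample(rec, cfg.target_fs)
    return average_reference(rec)


def band_features_row(stats, profile, band: str) -> dict[str, float]:
    """One subject's tidy feature row for one band."""
    row: dict[str, float] = {}
    for i, m in enumerate(stats.map_labels):
        row[f"{band}_duration_{m}"] = float(stats.duration_ms[i])
        row[f"{band}_occurrence_{m}"] = float(stats.occurrence_per_s[i])
        row[f"{band}_coverage_{m}"] = float(stats.coverage_pct[i])
    for lab, value in zip(profile.pair_labels, profile.observed_pct):
        a, b = lab.split("->")
        row[f"{band}_trans_{a}_to_{b}_pct"] = float(value)
    row[f"{band}_gev"] = float(stats.gev_total)
    return row


def analyze_band(recordings: list[Recording], band_name: str,
                 cfg: PipelineConfig, templates: TemplateMaps | None,
                 seed: int):
    """Segment one frequency band for a whole cohort.

    Returns (maps, map_info, features DataFrame, per-subject transition
    profiles).  Recordings must already be at the target rate and
    average-referenced.
    """
    band = _BAND_BY_NAME[band_name]
    epoched, peaks = [], []
    for rec in recordings:
        filtered = band_filter(rec, band)
        ep = epoch(filtered, cfg.epoch_length_s)
        epoched.append(ep)
        peaks.append(extract_gfp_peaks(
            ep, cfg.min_peak_distance_ms, cfg.peaks_per_subject,
            cfg.sd_threshold, cfg.gfp_exclude_rule))
    maps = aggregate_and_cluster(peaks, cfg.k, cfg.peaks_per_subject,
                                 restarts=cfg.n_restarts,
                                 max_iter=cfg.kmeans_max_iter, seed=seed,
                                 montage=recordings[0].montage)
    info: dict = {}
    if templates is not None and cfg.k == templates.n_maps:
        maps, info = canonicalize_to_templates(maps, templates)
    rows, profiles = [], []
    for ep in epoched:
        seg = smooth_segmentation(backfit(ep, maps), cfg.smoothing_ms)
        stats = compute_stats(seg)
        profile = transition_profile(seg)
        profiles.append(profile)
        rows.append({"subject_id": ep.subject_id,
                     **band_features_row(stats, profile, band.name)})
    return maps, info, pd.DataFrame(rows), profiles


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig, outdir) -> Path:
    """Run the full analysis and write stage artifacts plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(cfg.master_seed)
    seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
             for name, s in zip(
                 ["simulate", *[f"cluster_{b}" for b in cfg.bands],
                  "syntax", "classify"],
                 root.spawn(len(cfg.bands) + 3))}

    # --- input ---------------------------------------------------------
    if cfg.input_dir is None:
        sim = default_cohort_config(cfg.n_per_group, seed=seeds["simulate"],
                                    duration_s=cfg.duration_s, snr=cfg.snr,
                                    map_a_effect_ms=cfg.map_a_effect_ms)
        cohort = simulate_cohort(sim)
        recordings, covariates = cohort.recordings, cohort.covariates
        (outdir / "ground_truth.json").write_text(
            json.dumps(_jsonable(cohort.ground_truth()), indent=1))
    else:
        recordings, covariates = read_cohort_recordings(cfg.input_dir)
    templates = make_canonical_maps(recordings[0].montage)

    # --- preprocess ----------------------------------------------------
    recordings = [preprocess_recording(r, cfg) for r in recordings]

    # --- microstates per band -----------------------------------------
    features = covariates.copy()
    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    syntax_results = {}
    for band in cfg.bands:
        maps, info, band_feats, profiles = analyze_band(
            recordings, band, cfg, templates, seeds[f"cluster_{band}"])
        write_maps(maps, maps_dir / band, metadata=_jsonable(info))
        features = features.merge(band_feats, on="subject_id")
        p, stat, _ = syntax_permutation_test(profiles, cfg.n_permutations,
                                             seed=seeds["syntax"])
        syntax_results[band] = {"p": p, "chi2_distance": stat,
                                "n_permutations": cfg.n_permutations}
    features.to_csv(outdir / "features.csv", index=False)
    (outdir / "syntax.json").write_text(json.dumps(_jsonable(syntax_results),
                                                   indent=1))

    # --- group statistics ---------------------------------------------
    stats_frames = []
    map_labels = (templates.labels if cfg.k == templates.n_maps
                  else tuple(str(i) for i in range(cfg.k)))
    if features["group"].nunique() >= 2:
        for band in cfg.bands:
            cols = feature_columns(band, map_labels)
            table = run_battery(features, cols,
                                covariate_cols=DEFAULT_COVARIATES,
                                battery_size=cfg.battery_size)
            table.insert(0, "band", band)
            stats_frames.append(table)
        pd.concat(stats_frames).to_csv(outdir / "group_stats.csv", index=False)

    # --- classification ------------------------------------------------
    clf_results = {}
    band_sets = {"broadband": "broadband"}
    if set(cfg.bands) >= {"broadband", "delta", "theta", "alpha", "beta"}:
        band_sets["all_bands"] = "all"
    for model in cfg.classifiers:
        for set_name, bands in band_sets.items():
            fm = build_feature_matrix(features, bands, map_labels)
            y = features["group"].to_numpy()
            if model == "logistic" and len(np.unique(y)) > 2:
                mask = np.isin(y, ["HC", "AD"])
                res = loo_cv(fm.X[mask], y[mask], model,
                             seed=seeds["classify"])
                key = f"{model}_HC_vs_AD_{set_name}"
            else:
                res = loo_cv(fm.X, y, model, seed=seeds["classify"])
                key = f"{model}_{set_name}"
            clf_results[key] = {
                "accuracy_pct": res.accuracy_pct,
                "sensitivity_pct": res.sensitivity_pct,
                "specificity_pct": res.specificity_pct,
                "classes": list(res.classes),
                "confusion": res.confusion.tolist(),
            }
    (outdir / "classification.json").write_text(
        json.dumps(_jsonable(clf_results), indent=1))

    # --- manifest ------------------------------------------------------
    features_hash = hashlib.sha256(
        (outdir / "features.csv").read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": _jsonable(asdict(cfg)),
        "child_seeds": seeds,
        "n_subjects": len(recordings),
        "features_sha256": features_hash,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    logger.info("pipeline finished: %s", outdir)
    return outdir
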