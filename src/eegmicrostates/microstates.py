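"""Microstate segmentation: GFP peaks, modified K-means, back-fitting, statistics.

The modified K-means is polarity-invariant: a topography and its sign-flip
belong to the same class.  Assignment maximizes the squared spatial
projection onto unit-norm maps (equivalent to squared spatial correlation for
average-referenced frames) and the map update is the dominant eigenvector of
the scatter of the assigned topographies, so each "centroid" is the best
polarity-invariant one-dimensional subspace for its cluster.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import signal as sps
from scipy.optimize import linear_sum_assignment

from .containers import (EpochedRecording, GfpPeaks, MicrostateMaps,
                         MicrostateStats, Segmentation, TemplateMaps)

logger = logging.getLogger(__name__)

__all__ = [
    "gfp", "extract_gfp_peaks", "modified_kmeans", "aggregate_and_cluster",
    "assign_canonical_labels", "canonicalize_to_templates", "backfit",
    "smooth_segmentation", "compute_stats",
    "spatial_correlation", "runs_from_labels",
]


def gfp(frames: np.ndarray) -> np.ndarray | float:
    """Global field power: spatial SD across channels of each frame.

    Accepts one frame (channel vector) or a channels x samples matrix.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 1:
        if frames.size < 2:
            raise ValueError("GFP needs at least 2 channels")
        return float(frames.std(ddof=0))
    if frames.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return frames.std(axis=0, ddof=0)


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two topographies across channels."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def extract_gfp_peaks(rec: EpochedRecording, min_distance_ms: float = 10.0,
                      max_peaks: int = 1000, sd_threshold: float = 2.0,
                      exclude_rule: str = "mean+2sd") -> GfpPeaks:
    """Extract topographies at GFP local maxima, epoch by epoch.

    Peaks are local maxima of the within-epoch GFP trace with a minimum
    spacing of ``min_distance_ms`` (the higher peak wins a conflict); peaks
    never span epoch boundaries.  Unusually large peaks are excluded:
    ``exclude_rule="mean+2sd"`` drops peaks whose GFP exceeds the mean plus
    ``sd_threshold`` SDs of all detected peak GFPs, ``"2sd"`` drops peaks
    above ``sd_threshold`` times the SD.  The first ``max_peaks`` surviving
    peaks in temporal order are retained.
    """
    distance = max(1, int(round(min_distance_ms * rec.fs / 1000.0)))
    times, topos, values = [], [], []
    spe = rec.epochs.shape[2]
    for e, block in enumerate(rec.epochs):
        trace = gfp(block)
        peaks, _ = sps.find_peaks(trace, distance=distance)
        for p in peaks:
            times.append(e * spe + p)
            topos.append(block[:, p])
            values.append(trace[p])
    if not times:
        logger.warning("no GFP peaks found in %s", rec.subject_id or "recording")
        return GfpPeaks(rec.subject_id, np.empty(0, int),
                        np.empty((0, len(rec.montage))), np.empty(0))
    times = np.asarray(times)
    topos = np.asarray(topos)
    values = np.asarray(values)
    sd = values.std(ddof=0)
    if sd > 0:
        if exclude_rule == "mean+2sd":
            keep = values <= values.mean() + sd_threshold * sd
        elif exclude_rule == "2sd":
            keep = values <= sd_threshold * sd
        else:
            raise ValueError(f"unknown exclude_rule {exclude_rule!r}")
        times, topos, values = times[keep], topos[keep], values[keep]
    return GfpPeaks(rec.subject_id, times[:max_peaks], topos[:max_peaks],
                    values[:max_peaks])


def _assign(topos: np.ndarray, maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-invariant assignment; returns labels and signed projections."""
    proj = topos @ maps.T                      # n x K
    labels = np.argmax(proj ** 2, axis=1)      # ties -> lowest map index
    return labels, proj[np.arange(len(topos)), labels]


def _dominant_eigvec(cluster: np.ndarray) -> np.ndarray:
    scatter = cluster.T @ cluster
    eigvals, eigvecs = np.linalg.eigh(scatter)
    v = eigvecs[:, -1]
    # deterministic sign: first nonzero coefficient positive
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return v


def _kmeans_once(topos: np.ndarray, k: int, init_idx: np.ndarray,
                 max_iter: int, tol: float) -> tuple[np.ndarray, float]:
    total_ss = float(np.sum(topos ** 2))
    maps = topos[init_idx].copy()
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    prev_resid = np.inf
    for _ in range(max_iter):
        labels, proj = _assign(topos, maps)
        # re-seed any empty cluster from the worst-fit topography
        norms_sq = np.sum(topos ** 2, axis=1)
        fit = np.divide(proj ** 2, norms_sq, out=np.zeros_like(norms_sq),
                        where=norms_sq > 0)
        for j in range(k):
            if not np.any(labels == j):
                worst = int(np.argmin(fit))
                maps[j] = topos[worst] / np.linalg.norm(topos[worst])
                labels[worst] = j
        for j in range(k):
            members = topos[labels == j]
            if len(members):
                maps[j] = _dominant_eigvec(members)
        labels, proj = _assign(topos, maps)
        resid = 1.0 - float(np.sum(proj ** 2)) / total_ss
        if prev_resid - resid < tol * max(prev_resid, 1e-300):
            break
        prev_resid = resid
    return maps, resid


def modified_kmeans(topographies: np.ndarray, k: int, restarts: int = 50,
                    max_iter: int = 1000, tol: float = 1e-6,
                    seed: int | None = None,
                    montage=None) -> MicrostateMaps:
    """Polarity-invariant modified K-means over topographies.

    Runs ``restarts`` seeded restarts (initial maps drawn uniformly without
    replacement from the topographies) of up to ``max_iter`` assignment /
    eigenvector-update iterations each and returns the solution with the
    lowest residual variance (fraction of total squared amplitude left
    unexplained by the assigned maps).
    """
    topos = np.asarray(topographies, dtype=float)
    if topos.ndim != 2:
        raise ValueError("topographies must be n x channels")
    n = len(topos)
    if k > n:
        raise ValueError(f"cannot fit {k} maps to {n} topographies")
    rng = np.random.default_rng(seed)
    best_maps, best_resid = None, np.inf
    for _ in range(restarts):
        init = rng.choice(n, size=k, replace=False)
        maps, resid = _kmeans_once(topos, k, init, max_iter, tol)
        if resid < best_resid:
            best_maps, best_resid = maps, resid
    if montage is None:
        from .montage import MONTAGE_10_20
        montage = MONTAGE_10_20[:topos.shape[1]]
    labels = tuple(str(i) for i in range(k))
    return MicrostateMaps(maps=best_maps, montage=montage, labels=labels,
                          residual_variance=best_resid)


def aggregate_and_cluster(cohort_peaks: list[GfpPeaks], k: int = 4,
                          peaks_per_subject: int = 1000,
                          **kmeans_kwargs) -> MicrostateMaps:
    """Pool up to ``peaks_per_subject`` topographies per subject and cluster.

    Truncating every subject to the same number of peaks equalizes the
    contribution of long and short recordings to the global maps.
    """
    if not cohort_peaks:
        raise ValueError("at least one subject's peaks required")
    blocks = [p.topographies[:peaks_per_subject] for p in cohort_peaks
              if p.n_peaks > 0]
    if not blocks:
        raise ValueError("no peaks available for clustering")
    pooled = np.concatenate(blocks, axis=0)
    return modified_kmeans(pooled, k, **kmeans_kwargs)


def assign_canonical_labels(maps: MicrostateMaps, templates: TemplateMaps,
                            hybrid_margin: float = 0.05) -> MicrostateMaps:
    """Label cluster maps by optimal one-to-one matching to template maps.

    The assignment maximizes total absolute spatial correlation (Hungarian
    algorithm; polarity ignored).  A map whose two best template correlations
    differ by less than ``hybrid_margin`` receives a hybrid label such as
    ``"A/B"``.
    """
    if maps.n_maps != templates.n_maps:
        logger.warning("map count %d != template count %d; keeping index labels",
                       maps.n_maps, templates.n_maps)
        return maps
    corr = np.array([[abs(spatial_correlation(m, t)) for t in templates.maps]
                     for m in maps.maps])
    rows, cols = linear_sum_assignment(-corr)
    labels, assigned_corr = [], []
    for i, j in zip(rows, cols):
        order = np.argsort(-corr[i])
        best, second = order[0], order[1]
        if corr[i, best] - corr[i, second] < hybrid_margin:
            pair = sorted([templates.labels[best], templates.labels[second]])
            label = f"{pair[0]}/{pair[1]}"
        else:
            label = templates.labels[j]
        labels.append(label)
        assigned_corr.append(float(corr[i, j]))
    # enforce uniqueness if two maps straddle the same template pair
    seen: dict[str, int] = {}
    unique = []
    for lab in labels:
        if lab in seen:
            seen[lab] += 1
            unique.append(f"{lab}({seen[lab]})")
        else:
            seen[lab] = 0
            unique.append(lab)
    return replace(maps, labels=tuple(unique),
                   template_correlations=tuple(assigned_corr))


def canonicalize_to_templates(maps: MicrostateMaps, templates: TemplateMaps,
                              hybrid_margin: float = 0.05
                              ) -> tuple[MicrostateMaps, dict]:
    """Reorder cluster maps into template order for stable feature keys.

    Rows are permuted so map i corresponds to template i (Hungarian matching
    on absolute spatial correlation) and relabeled with the template letters;
    hybrid names ("A/B") for maps sitting between two templates are kept as
    display metadata rather than as keys, since downstream feature columns
    must be stable across cohorts.
    """
    if maps.n_maps != templates.n_maps:
        raise ValueError("map count must equal template count to canonicalize")
    labeled = assign_canonical_labels(maps, templates, hybrid_margin)
    corr = np.array([[abs(spatial_correlation(m, t)) for t in templates.maps]
                     for m in maps.maps])
    rows, cols = linear_sum_assignment(-corr)
    order = np.argsort(cols)           # row order that yields template order
    reordered = MicrostateMaps(
        maps=maps.maps[rows[order]], montage=maps.montage,
        labels=tuple(templates.labels),
        residual_variance=maps.residual_variance,
        template_correlations=tuple(corr[rows[order], cols[order]]))
    info = {
        "display_labels": tuple(np.asarray(labeled.labels)[rows[order]]),
        "correlations": tuple(float(c) for c in corr[rows[order], cols[order]]),
    }
    return reordered, info


def backfit(rec: EpochedRecording, maps: MicrostateMaps) -> Segmentation:
    """Label every sample with its best-matching map (polarity ignored).

    The per-sample fit is the squared spatial correlation with the winning
    map; the full per-map fit matrix is kept for smoothing.
    """
    if tuple(rec.montage) != tuple(maps.montage):
        raise ValueError("recording montage does not match the maps' montage")
    n_epochs, n_ch, spe = rec.epochs.shape
    k = maps.n_maps
    labels = np.empty((n_epochs, spe), dtype=int)
    fit = np.empty((n_epochs, spe))
    gfp_trace = np.empty((n_epochs, spe))
    fit_all = np.empty((n_epochs, k, spe))
    for e, block in enumerate(rec.epochs):
        centered = block - block.mean(axis=0, keepdims=True)
        norms_sq = np.sum(centered ** 2, axis=0)
        proj = maps.maps @ centered                       # K x S
        corr2 = np.divide(proj ** 2, norms_sq,
                          out=np.zeros_like(proj), where=norms_sq > 0)
        labels[e] = np.argmax(corr2, axis=0)
        fit[e] = corr2[labels[e], np.arange(spe)]
        gfp_trace[e] = np.sqrt(norms_sq / n_ch)
        fit_all[e] = corr2
    seg = Segmentation(labels=labels, fit=fit, gfp=gfp_trace, fs=rec.fs,
                       maps=maps, subject_id=rec.subject_id)
    seg.fit_all = fit_all
    return seg


def runs_from_labels(labels_1d: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal constant runs of a label vector as (start, length, label)."""
    labels_1d = np.asarray(labels_1d)
    if labels_1d.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels_1d)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels_1d.size]))
    return [(int(s), int(e - s), int(labels_1d[s])) for s, e in zip(starts, ends)]


def _smooth_epoch(labels: np.ndarray, corr2: np.ndarray, min_samples: int,
                  max_iter: int) -> np.ndarray:
    """Reassign sub-threshold runs to the better-fitting flanking map."""
    labels = labels.copy()
    for _ in range(max_iter):
        runs = runs_from_labels(labels)
        short = [r for r in runs if r[1] < min_samples]
        if not short or len(runs) == 1:
            break
        # shortest run first; leftmost on ties
        start, length, _ = min(short, key=lambda r: (r[1], r[0]))
        idx = next(i for i, r in enumerate(runs) if r[0] == start)
        candidates = []
        if idx > 0:
            candidates.append(runs[idx - 1][2])
        if idx < len(runs) - 1:
            candidates.append(runs[idx + 1][2])
        sl = slice(start, start + length)
        sub = corr2[candidates, sl]                       # n_cand x length
        labels[sl] = np.asarray(candidates)[np.argmax(sub, axis=0)]
    return labels


def smooth_segmentation(seg: Segmentation, min_duration_ms: float = 30.0,
                        max_iter: int = 1000) -> Segmentation:
    """Reject microstate segments shorter than ``min_duration_ms``.

    Each sub-threshold run's samples are reassigned, sample by sample, to
    whichever flanking run's map fits them better, iterating until no run is
    shorter than the threshold (or the iteration cap).  Runs never merge
    across epoch boundaries.
    """
    min_samples = int(round(min_duration_ms * seg.fs / 1000.0))
    if min_samples <= 1:
        return seg
    fit_all = getattr(seg, "fit_all", None)
    if fit_all is None:
        raise ValueError("segmentation lacks the per-map fit matrix "
                         "(produce it with backfit)")
    new_labels = np.empty_like(seg.labels)
    new_fit = np.empty_like(seg.fit)
    for e in range(seg.labels.shape[0]):
        new_labels[e] = _smooth_epoch(seg.labels[e], fit_all[e], min_samples,
                                      max_iter)
        new_fit[e] = fit_all[e][new_labels[e], np.arange(seg.labels.shape[1])]
    out = Segmentation(labels=new_labels, fit=new_fit, gfp=seg.gfp, fs=seg.fs,
                       maps=seg.maps, subject_id=seg.subject_id)
    out.fit_all = fit_all
    return out


def compute_stats(seg: Segmentation,
                  include_edge_runs: bool = True) -> MicrostateStats:
    """Per-map duration, occurrence, coverage plus total GEV.

    Duration is the mean run length (ms) over within-epoch runs; occurrence
    the number of run onsets per second of labeled data; coverage the percent
    of samples.  GEV is the GFP^2-weighted mean squared correlation between
    each frame and its assigned map, over all samples.  A map that never
    occurs gets duration NaN, occurrence 0 and coverage 0.
    """
    k = seg.n_maps
    ms_per_sample = 1000.0 / seg.fs
    run_lengths: list[list[int]] = [[] for _ in range(k)]
    onsets = np.zeros(k)
    for e in range(seg.labels.shape[0]):
        runs = runs_from_labels(seg.labels[e])
        for i, (start, length, label) in enumerate(runs):
            edge = i == 0 or i == len(runs) - 1
            if include_edge_runs or not edge:
                run_lengths[label].append(length)
            onsets[label] += 1
    n_total = seg.labels.size
    total_s = n_total / seg.fs
    duration = np.array([np.mean(r) * ms_per_sample if r else np.nan
                         for r in run_lengths])
    occurrence = onsets / total_s
    counts = np.bincount(seg.labels.ravel(), minlength=k)
    coverage = 100.0 * counts / n_total
    duration = np.where(counts == 0, np.nan, duration)
    occurrence = np.where(counts == 0, 0.0, occurrence)
    gfp_sq = seg.gfp ** 2
    denom = float(gfp_sq.sum())
    gev = float((gfp_sq * seg.fit).sum() / denom) if denom > 0 else 0.0
    return MicrostateStats(map_labels=seg.maps.labels, duration_ms=duration,
                           occurrence_per_s=occurrence, coverage_pct=coverage,
                           gev_total=gev, subject_id=seg.subject_id)
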