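"""Reading and writing recordings, cohorts and result tables.

Recordings are read from EDF (via MNE, channel labels matched
case-insensitively against the 10-20 montage) or from the simulator's
headerless float32 binary + JSON sidecar format.  Cohorts are written as one
binary/sidecar pair per subject plus a covariate CSV and a ground-truth JSON
of the planted parameters.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MicrostateMaps, Recording
from .montage import validate_montage
from .synthetic import SyntheticCohort

__all__ = ["read_edf", "read_binary", "write_binary", "write_cohort",
           "read_cohort_recordings", "write_maps"]


def read_edf(path, montage=None) -> Recording:
    """Load an EDF recording, optionally restricted/reordered to ``montage``."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = validate_montage(raw.ch_names if montage is None else montage)
    lower = {ch.lower(): ch for ch in raw.ch_names}
    try:
        picks = [lower[ch.lower()] for ch in labels]
    except KeyError as err:
        raise ValueError(f"EDF lacks montage channel {err}") from None
    data = raw.get_data(picks=picks)
    return Recording(data=data, fs=float(raw.info["sfreq"]), montage=labels,
                     subject_id=Path(path).stem)


def write_binary(rec: Recording, stem: Path) -> None:
    """Write ``<stem>.bin`` (float32, channel-major) and ``<stem>.json``."""
    stem = Path(stem)
    rec.data.astype(np.float32).tofile(stem.with_suffix(".bin"))
    sidecar = {
        "fs": rec.fs,
        "montage": list(rec.montage),
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "order": "channels_x_samples",
        "reference": rec.reference,
        "subject_id": rec.subject_id,
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_binary(stem: Path) -> Recording:
    """Read a recording written by :func:`write_binary`."""
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype=np.dtype(meta["dtype"]))
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return Recording(data=data, fs=meta["fs"], montage=meta["montage"],
                     reference=meta.get("reference", "other"),
                     subject_id=meta.get("subject_id", stem.stem))


def write_cohort(cohort: SyntheticCohort, outdir) -> Path:
    """Write one binary+sidecar per subject, covariates.csv, ground_truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_binary(rec, outdir / rec.subject_id)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    (outdir / "ground_truth.json").write_text(
        json.dumps(cohort.ground_truth(), indent=1))
    return outdir


def read_cohort_recordings(indir) -> tuple[list[Recording], pd.DataFrame]:
    """Load every binary recording in a cohort directory plus its covariates."""
    indir = Path(indir)
    covariates = pd.read_csv(indir / "covariates.csv")
    recs = [read_binary(indir / sid) for sid in covariates["subject_id"]]
    return recs, covariates


def write_maps(maps: MicrostateMaps, stem: Path, metadata: dict | None = None) -> None:
    """Maps as a channels x K CSV plus a JSON with labels and fit metadata."""
    stem = Path(stem)
    frame = pd.DataFrame(maps.maps.T, index=list(maps.montage),
                         columns=list(maps.labels))
    frame.to_csv(stem.with_suffix(".csv"), index_label="channel")
    meta = {
        "labels": list(maps.labels),
        "polarity_ambiguous": maps.polarity_ambiguous,
        "residual_variance": maps.residual_variance,
        "template_correlations": (list(maps.template_correlations)
                                  if maps.template_correlations else None),
    }
    if metadata:
        meta.update(metadata)
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
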