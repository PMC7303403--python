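"""The 19-channel international 10-20 montage used throughout the package.

Channel order is fixed; all matrices index channels in this order. Approximate
2-D scalp coordinates (x: left->right, y: posterior->anterior, unit disc) are
used only to construct synthetic template topographies.
"""

from __future__ import annotations

import numpy as np

MONTAGE_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T3", "T5", "T4",
    "T6", "C3", "Cz", "C4", "P3", "Pz", "P4", "O1", "O2",
)

#: left <-> right homologue pairs; midline channels map to themselves
_MIRROR_PAIRS = {
    "Fp1": "Fp2", "F7": "F8", "F3": "F4", "T3": "T4", "T5": "T6",
    "C3": "C4", "P3": "P4", "O1": "O2",
    "Fz": "Fz", "Cz": "Cz", "Pz": "Pz",
}
_MIRROR = {**_MIRROR_PAIRS, **{v: k for k, v in _MIRROR_PAIRS.items()}}

# (x, y) positions on the unit disc, left-right symmetric by construction
_COORDS = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.52), "Fz": (0.0, 0.50),
    "F4": (0.40, 0.52), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.00, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.40, -0.52), "Pz": (0.0, -0.50),
    "P4": (0.40, -0.52), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}


def validate_montage(montage) -> tuple[str, ...]:
    """Normalize channel labels (case-insensitive) against the 10-20 set."""
    canon = {ch.lower(): ch for ch in MONTAGE_10_20}
    out = []
    for label in montage:
        key = str(label).strip().lower()
        if key not in canon:
            raise ValueError(f"unknown 10-20 channel label: {label!r}")
        out.append(canon[key])
    if len(set(out)) != len(out):
        raise ValueError("duplicate channel labels in montage")
    return tuple(out)


def mirror_permutation(montage) -> np.ndarray:
    """Index permutation swapping each channel with its left-right homologue."""
    montage = validate_montage(montage)
    index = {ch: i for i, ch in enumerate(montage)}
    try:
        return np.array([index[_MIRROR[ch]] for ch in montage])
    except KeyError as err:  # homologue absent from a partial montage
        raise ValueError(f"montage lacks the mirror of channel {err}") from None


def channel_positions(montage) -> np.ndarray:
    """(n_channels, 2) array of approximate scalp-disc coordinates."""
    montage = validate_montage(montage)
    return np.array([_COORDS[ch] for ch in montage], dtype=float)
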