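"""Microstate syntax: observed vs occurrence-expected transition structure.

If microstates followed one another at random, the rate of each ordered
transition i->j would be proportional to the product of the two classes'
relative occurrences (self-transitions excluded).  The deviation of the
observed transition percentages from this product-rule expectation is
summarized by a chi-square distance and tested with a label-permutation test
that randomly swaps each subject's "observed" and "expected" 12-vectors.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import Segmentation, TransitionProfile
from .microstates import runs_from_labels

logger = logging.getLogger(__name__)

__all__ = [
    "transition_pair_labels", "observed_transitions", "expected_transitions",
    "chi_square_distance", "transition_profile", "syntax_permutation_test",
]


def transition_pair_labels(map_labels) -> tuple[str, ...]:
    """Ordered distinct pairs i->j in row-major order (12 pairs for K=4)."""
    return tuple(f"{a}->{b}" for a in map_labels for b in map_labels if a != b)


def _pair_index(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


def observed_transitions(seg: Segmentation) -> np.ndarray:
    """Percent of all run-to-run transitions for each ordered pair i->j.

    Transitions are counted within epochs only; epochs are discontinuous.
    """
    k = seg.n_maps
    counts = np.zeros((k, k))
    for e in range(seg.labels.shape[0]):
        runs = runs_from_labels(seg.labels[e])
        for (_, _, a), (_, _, b) in zip(runs, runs[1:]):
            counts[a, b] += 1
    total = counts.sum()
    if total < 1:
        raise ValueError("fewer than 2 runs: no transitions to count")
    return np.array([100.0 * counts[i, j] / total for i, j in _pair_index(k)])


def expected_transitions(occurrence: np.ndarray) -> np.ndarray:
    """Product-rule expected transition percentages from relative occurrences.

    ``expected(i->j) = 100 * p_i * p_j / sum_{k != m} p_k * p_m``.  A map with
    zero occurrence contributes zero to every pair involving it.
    """
    p = np.asarray(occurrence, dtype=float)
    if np.any(p < 0):
        raise ValueError("occurrence frequencies must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("occurrence frequencies must not all be zero")
    p = p / total
    k = len(p)
    products = np.array([p[i] * p[j] for i, j in _pair_index(k)])
    denom = products.sum()
    if denom <= 0:
        raise ValueError("all pairwise occurrence products are zero")
    return 100.0 * products / denom


def chi_square_distance(observed: np.ndarray, expected: np.ndarray) -> float:
    """``sum (obs - exp)^2 / exp``; zero-expected entries are skipped."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have one length")
    mask = expected > 0
    if not mask.any():
        raise ValueError("expected vector is all zero")
    diff = observed[mask] - expected[mask]
    return float(np.sum(diff ** 2 / expected[mask]))


def transition_profile(seg: Segmentation) -> TransitionProfile:
    """Observed and product-rule-expected transition percentages for one subject."""
    observed = observed_transitions(seg)
    k = seg.n_maps
    # relative occurrence = share of microstate segments (run onsets) per map
    counts = np.zeros(k)
    for e in range(seg.labels.shape[0]):
        for _, _, label in runs_from_labels(seg.labels[e]):
            counts[label] += 1
    expected = expected_transitions(counts / counts.sum())
    return TransitionProfile(
        pair_labels=transition_pair_labels(seg.maps.labels),
        observed_pct=observed, expected_pct=expected,
        chi2_distance=chi_square_distance(observed, expected))


def syntax_permutation_test(profiles: list[TransitionProfile],
                            n_perm: int = 5000, seed: int | None = None
                            ) -> tuple[float, float, np.ndarray]:
    """Permutation test of observed vs expected mean transition profiles.

    The statistic is the chi-square distance between the across-subject mean
    observed and mean expected 12-vectors.  Under the null each subject's
    (observed, expected) pair is swapped independently with probability 1/2;
    the add-one convention ``p = (1 + #{null >= stat}) / (1 + n_perm)``
    avoids zero p-values.  Returns (p, statistic, null distribution).
    """
    if len(profiles) < 2:
        raise ValueError("permutation test needs at least 2 subjects")
    if n_perm < 100:
        logger.warning("n_perm=%d is very low; p-value resolution is poor", n_perm)
    obs = np.vstack([p.observed_pct for p in profiles])
    exp = np.vstack([p.expected_pct for p in profiles])
    n = len(profiles)
    stat = chi_square_distance(obs.mean(axis=0), exp.mean(axis=0))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        flip = rng.random(n) < 0.5
        o = np.where(flip[:, None], exp, obs).mean(axis=0)
        e = np.where(flip[:, None], obs, exp).mean(axis=0)
        null[b] = chi_square_distance(o, e)
    p = (1.0 + np.sum(null >= stat)) / (1.0 + n_perm)
    return float(p), float(stat), null
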