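import numpy as np
import pytest

from eegmicrostates.montage import MONTAGE_10_20
from eegmicrostates.preprocess import average_reference, epoch
from eegmicrostates.synthetic import (SubjectSimConfig, make_canonical_maps,
                                      simulate_subject)


@pytest.fixture(scope="session")
def templates():
    return make_canonical_maps(MONTAGE_10_20)


@pytest.fixture(scope="session")
def subject_cfg(templates):
    return SubjectSimConfig(templates=templates, duration_s=60.0, snr=8.0)


@pytest.fixture(scope="session")
def sim_subject(subject_cfg):
    """One 60 s simulated subject plus its ground-truth label sequence."""
    return simulate_subject(subject_cfg, seed=12345)


@pytest.fixture(scope="session")
def sim_epoched(sim_subject):
    rec, _ = sim_subject
    return epoch(average_reference(rec), 1.0)


def brute_force_kmeans(topographies: np.ndarray, k: int) -> float:
    """Exhaustive polarity-invariant clustering: minimum residual variance.

    Enumerates all k^n assignments; for each cluster the optimal map is the
    dominant eigenvector of its scatter, so the explained sum of squares is
    the sum of leading eigenvalues.  Independent of the iterative algorithm.
    """
    from itertools import product

    topos = np.asarray(topographies, dtype=float)
    n = len(topos)
    total = float(np.sum(topos ** 2))
    best = np.inf
    for assignment in product(range(k), repeat=n):
        assignment = np.asarray(assignment)
        explained = 0.0
        for j in range(k):
            members = topos[assignment == j]
            if len(members):
                scatter = members.T @ members
                explained += float(np.linalg.eigvalsh(scatter)[-1])
        best = min(best, 1.0 - explained / total)
    return best
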