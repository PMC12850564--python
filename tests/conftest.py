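"""Shared fixtures: standard synthetic studies reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import overlapkernel as ok


@pytest.fixture(scope="session")
def study64():
    """Standard 2-shot mosaic study: 64^2, 4 coils, overlap 15, poly-2
    phases of 1.5 rad peak, noiseless, seed 1."""
    bundle, phantom, coils, phases = ok.simulate_study(seed=1)
    return bundle, phantom, coils, phases


@pytest.fixture(scope="session")
def study64_eigen(study64):
    """Eigen extraction (w=7, keep 0.5) of the standard study's pair (0,1)."""
    bundle, *_ = study64
    return ok.eigen_pair_result(bundle, (0, 1))


@pytest.fixture(scope="session")
def identical_shot_bundle():
    """2-shot mosaic with zero phase fluctuation (shots agree exactly)."""
    bundle, phantom, coils, phases = ok.simulate_study(seed=2, amplitude_rad=0.0)
    return bundle, phantom


def weighted_truth_pair(phases: ok.ShotPhaseSet, rel_est: np.ndarray) -> tuple:
    """Wrap a single-pair relative-phase estimate and the matching truth."""
    zeros = np.zeros_like(rel_est)
    est = ok.ShotPhaseSet(2, np.stack([zeros, rel_est]))
    tru = ok.ShotPhaseSet(2, phases.phase_maps[:2])
    return est, tru
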