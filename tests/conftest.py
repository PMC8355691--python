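"""Shared fixtures: phantom geometries and the planted evaluation cohort.

Heavy artefacts (the 37-case cohort, its feature matrix, the repeated
selection run) are session-scoped so the acceptance tests can share them.
"""

import numpy as np
import pytest

from fusimorph import (
    fit_centreline,
    frenet,
    make_centreline,
    make_cohort,
    VesselSpec,
)
from fusimorph.pipeline import extract_cohort

#: master seed for the planted evaluation cohort and selection runs
EVAL_SEED = 1


@pytest.fixture(scope="session")
def helix_spec():
    return VesselSpec(centreline_kind="helix", helix_radius=2.0, helix_pitch=1.0)


@pytest.fixture(scope="session")
def helix_centreline(helix_spec):
    points, _, _ = make_centreline(helix_spec)
    return frenet(fit_centreline(points))


@pytest.fixture(scope="session")
def planted_cohort():
    """The default study-scale cohort: 37 cases, 12 ruptured."""
    return make_cohort(seed=EVAL_SEED)


@pytest.fixture(scope="session")
def planted_extraction(planted_cohort):
    matrix, segmentations, failures = extract_cohort(planted_cohort)
    assert not failures, f"extraction failures in evaluation cohort: {failures}"
    return matrix, segmentations


@pytest.fixture(scope="session")
def planted_matrix(planted_extraction):
    return planted_extraction[0]


@pytest.fixture(scope="session")
def feature_table(planted_matrix):
    """Feature columns only (no identifier/label)."""
    return planted_matrix.drop(columns=["identifier", "label"])


@pytest.fixture(scope="session")
def labels(planted_matrix):
    return planted_matrix["label"].to_numpy()


@pytest.fixture(scope="session")
def frequency_table(feature_table, labels):
    """The full 30-repetition consensus selection run at the 1.0x threshold.

    Shared by the planted-recovery and threshold-sensitivity checks.
    """
    from fusimorph.selection import SelectionConfig, repeated_selection

    return repeated_selection(
        feature_table, labels, SelectionConfig(seed=EVAL_SEED + 100)
    )


def brute_force_s(areas: np.ndarray, a: int, b: int, threshold: float) -> int:
    """Independent exhaustive-scan oracle for the per-segment point count.

    Enumerates every candidate segment length and takes the largest one with
    no baseline exceedance strictly closer to the aneurysm, bounded by the
    fallback length; mirrors the first-exceedance definition without
    sharing code with the implementation.
    """
    n = len(areas)
    default_s = min((a - 1) // 2, (n - b) // 2)
    ps, pe = areas[a - 1], areas[b - 1]
    prox = [a - i for i in range(a - 1, 0, -1) if abs(areas[i - 1] - ps) > threshold]
    dist = [i - b for i in range(b + 1, n + 1) if abs(areas[i - 1] - pe) > threshold]
    s_prox = min(prox) if prox else default_s
    s_dist = min(dist) if dist else default_s
    return min(s_prox, s_dist, default_s)
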