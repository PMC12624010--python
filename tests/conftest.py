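"""Shared fixtures: small synthetic fields and matching helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree

from smfish3d import PipelineConfig, SimulationConfig, simulate_field


def small_sim_config(**overrides) -> SimulationConfig:
    """A one-cell field sized for fast unit tests (~1 s to render)."""
    defaults = dict(
        field_shape_voxels=(31, 192, 192),
        n_cells=1,
        granule_density=0.0,
        fraction_dividing=0.0,
        fraction_edge=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def pipeline_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_field():
    """One simulated single-cell field with ground truth."""
    return simulate_field(small_sim_config())


@pytest.fixture(scope="session")
def default_field():
    """One field at the full default configuration."""
    return simulate_field(SimulationConfig(seed=1))


def match_to_truth(detected_zyx: np.ndarray, truth_zyx: np.ndarray,
                   max_dist_vox: float = 2.0):
    """Greedy nearest matching of detections to truth positions.

    Returns (matched_truth_indices, matched_det_indices) with each truth
    and each detection used at most once.
    """
    if len(detected_zyx) == 0 or len(truth_zyx) == 0:
        return np.array([], int), np.array([], int)
    dists, idx = cKDTree(detected_zyx).query(truth_zyx)
    order = np.argsort(dists)
    used_det, mt, md = set(), [], []
    tree = cKDTree(detected_zyx)
    for t in order:
        if dists[t] > max_dist_vox:
            break
        # allow fallback to the next-nearest free detection
        for d in tree.query(truth_zyx[t], k=min(3, len(detected_zyx)))[1].ravel():
            d = int(d)
            if d in used_det:
                continue
            if np.linalg.norm(detected_zyx[d] - truth_zyx[t]) <= max_dist_vox:
                used_det.add(d)
                mt.append(t)
                md.append(d)
            break
    return np.array(mt, int), np.array(md, int)
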