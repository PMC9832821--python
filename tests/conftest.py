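"""Shared fixtures: phantoms, cohorts, and their analyses.

Expensive synthetic-cohort analyses are session-scoped so the unit suite and
the acceptance tests reuse one computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from q3d import (CohortSpec, EffectRegionSpec, GroupComparison, PhantomSpec,
                 SAVMap, SmoothingKernel, aggregate_to_voxels, binarize_sav,
                 generate_cohort, generate_phantom, make_toy_atlas,
                 smooth_spherical, voxelwise_ttest)

# cohort study grid: a 64-voxel-cube atlas window (25 um spacing) covered by
# an acquisition volume of 492 x 492 x 400 voxels at 3.26 x 3.26 x 3.0 um
COHORT_GRID = (65, 65, 48)
COHORT_PHANTOM = dict(shape=(492, 492, 400), n_plaques=5000)
EFFECT_CENTER = (32, 32, 24)
EFFECT_RADIUS = 20.0


@pytest.fixture(scope="session")
def sharp_phantom():
    """Noiseless, sharp-edged, well-separated 100-plaque phantom.

    With no noise and no edge blur the rendered plaque support is exactly
    the lattice support recorded in the ground truth, so segmentation can be
    held to exact recovery.
    """
    spec = PhantomSpec(
        shape=(160, 160, 120),
        n_plaques=100,
        radius_log_mean=np.log(9.0),   # keep every plaque above the 200 um^3 noise floor
        radius_log_sigma=0.2,
        noise_sigma=(0.0, 0.0),
        edge_sigma=0.0,
        min_separation_factor=3.0,
        seed=42,
    )
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def toy_atlas():
    return make_toy_atlas(shape=(48, 48, 36))


@dataclass
class CohortAnalysis:
    comparison: GroupComparison
    sav05: SAVMap
    sav10: SAVMap
    inside: np.ndarray      # planted effect sphere on the atlas grid
    far: np.ndarray         # beyond the effect sphere dilated by the kernel radius
    brains: list


def _analyse_cohort(effects, seed) -> CohortAnalysis:
    phantom = PhantomSpec(seed=0, **COHORT_PHANTOM)
    spec = CohortSpec(n_control=5, n_treated=5, phantom=phantom, effects=effects,
                      inter_brain_cv=0.05, seed=seed)
    brains = generate_cohort(spec, render=False)
    kernel = SmoothingKernel(15)
    groups = {"control": [], "treated": []}
    for b in brains:
        hm = aggregate_to_voxels(b.truth, COHORT_GRID, b.brain_id)
        groups[b.group].append(smooth_spherical(hm["count"], kernel))
    comparison = voxelwise_ttest(groups["treated"], groups["control"])
    idx = np.indices(COHORT_GRID)
    d2 = sum((idx[a] - EFFECT_CENTER[a]) ** 2 for a in range(3))
    inside = d2 <= EFFECT_RADIUS ** 2
    far = d2 > (EFFECT_RADIUS + kernel.diameter_voxels / 2.0) ** 2
    return CohortAnalysis(
        comparison=comparison,
        sav05=binarize_sav(comparison, 0.05),
        sav10=binarize_sav(comparison, 0.10),
        inside=inside,
        far=far,
        brains=brains,
    )


@pytest.fixture(scope="session")
def planted_cohort_analysis():
    """5 vs 5 cohort with an 80% plaque-count reduction planted in a
    radius-20-voxel sphere; smoothed-count voxel statistics."""
    effect = EffectRegionSpec(center_vox=EFFECT_CENTER, radius_vox=EFFECT_RADIUS,
                              affected_metric="count", effect_size=0.2)
    return _analyse_cohort([effect], seed=3)


@pytest.fixture(scope="session")
def null_cohort_analysis():
    """Same study design with no planted effect (both groups identical)."""
    return _analyse_cohort([], seed=11)
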