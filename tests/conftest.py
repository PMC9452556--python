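import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from astrocircuit.prq import (
    GridImage,
    build_reference,
    normalize_grid,
    normalize_pair,
    partition_grid,
)
from astrocircuit.simulate import SceneSimConfig, simulate_scene_pair


def make_grid(values, nucleus=None, subregions=None, **kw) -> GridImage:
    """Small helper: wrap a 2-D array as a GridImage with a full nucleus."""
    values = np.asarray(values, dtype=float)
    if nucleus is None:
        nucleus = np.ones(values.shape, dtype=bool)
    return GridImage(
        values=values.copy(),
        nucleus_mask=np.asarray(nucleus, dtype=bool),
        subregion_masks=dict(subregions or {}),
        **kw,
    )


def analyze_scene(scene):
    """Run a scene through the full grid-normalization chain."""
    subs = {"core": scene.core_mask, "shell": scene.shell_mask}

    def grid_of(img, condition):
        return partition_grid(
            img,
            scene.grid_um,
            scene.source_um_per_px,
            scene.nucleus_mask,
            subs,
            condition=condition,
        )

    reference = build_reference([grid_of(c, "control") for c in scene.controls])
    basal = normalize_grid(grid_of(scene.basal, "basal"), reference, scene.background_roi_grid)
    stim = normalize_grid(grid_of(scene.stim, "stim"), reference, scene.background_roi_grid)
    afferent = normalize_grid(
        grid_of(scene.afferent, "afferent"), reference, scene.background_roi_grid
    )
    basal, stim = normalize_pair(basal, stim)
    return basal, stim, afferent


@pytest.fixture(scope="session")
def default_scene():
    scene, gt = simulate_scene_pair(SceneSimConfig(seed=11))
    return scene, gt


@pytest.fixture(scope="session")
def analyzed_scene(default_scene):
    scene, gt = default_scene
    basal, stim, afferent = analyze_scene(scene)
    return scene, gt, basal, stim, afferent
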