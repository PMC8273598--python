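"""Shared fixtures: one small phantom specimen reused across the suite."""

import numpy as np
import pytest

from osteogrid import phantoms as ph
from osteogrid.compartments import (
    cast_cortex_rays,
    clean_components,
    estimate_closing_radius,
    label_compartments,
    segment_bone,
    total_volume_mask,
)
from osteogrid.morphometry import compute_thickness_maps, grid_sample
from osteogrid.volume_io import VoxelVolume


@pytest.fixture(scope="session")
def small_spec():
    # quick specimen: ~70x62x79 lattice, resolved rods, graded shell
    return ph.PhantomSpec(
        outer_shape=(2.6, 2.3, 3.0),
        shell_thickness_proximal=0.35,
        shell_thickness_distal=0.5,
        shell_porosity=0.05,
        pore_radius=0.08,
        rod_radius=0.14,
        rod_spacing=0.55,
        kappa=20.0,
        spacing=0.08,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return ph.make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_stages(small_phantom):
    """Every intermediate of the compartment chain, for conservation checks."""
    grey, truth, gt = small_phantom
    bone, thr = segment_bone(grey)
    bone = clean_components(bone)
    r = estimate_closing_radius(bone)
    tv = total_volume_mask(bone, closing_radius_mm=r)
    cand = cast_cortex_rays(bone, tv)
    labels = label_compartments(bone, tv, cand, r)
    return {"bone": bone, "tv": tv, "candidate": cand,
            "labels": labels, "closing_radius": r, "threshold": thr}


@pytest.fixture(scope="session")
def small_labels(small_stages):
    return small_stages["labels"]


@pytest.fixture(scope="session")
def small_maps(small_labels):
    return compute_thickness_maps(small_labels.volume, max_levels=24)


@pytest.fixture(scope="session")
def small_grid(small_labels, small_maps):
    return grid_sample(
        small_labels.volume,
        grid_spacing=0.9,
        sphere_diameter=1.8,
        n_directions=48,
        line_spacing_mm=0.16,
        step_mm=0.08,
        thickness_maps=small_maps,
    )


def digital_ball(radius_vox: int, spacing: float = 1.0) -> VoxelVolume:
    n = 2 * radius_vox + 5
    c = (n - 1) / 2
    g = np.arange(n)
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    mask = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius_vox**2
    return VoxelVolume(mask.astype(np.uint8), spacing)
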