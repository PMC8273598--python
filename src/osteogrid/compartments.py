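"""Cortical / trabecular / internal compartmentalisation of a segmented bone.

A short bone has no medullary canal: a thin, often porous cortical shell
encloses a trabecular lattice.  Compartmentalisation proceeds in stages:

1. two-class intensity clustering separates bone from background;
2. the enclosed volume (TV) is the complement of the outside background
   after a morphological closing seals surface pores;
3. rays marched inward from outside the bone along the lattice axes mark
   the first continuous bone run they meet — the periosteal wall;
4. a closing with radius tied to the average trabecular thickness fills
   the pores of that wall, and the result is restricted to the true shell
   (every interior patch the closing did not absorb stays endosteal);
5. voxels are labelled background / cortical bone / cortical pore /
   trabecular bone / internal (marrow); pores are kept inside the cortex
   compartment so porosity remains measurable.

Specimens whose cortex is too porous for a confident boundary are flagged
by :func:`qc_cortex` and excluded from comparative statistics rather than
silently producing empty trabecular values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    BorderContactError,
    DegenerateClusteringError,
    DegenerateSpecimenError,
    UndefinedMeasureError,
    ValidationError,
)
from .morphometry import local_thickness, mean_thickness
from .volume_io import (
    LABEL_BACKGROUND,
    LABEL_CORTICAL_BONE,
    LABEL_CORTICAL_PORE,
    LABEL_INTERNAL,
    LABEL_TRABECULAR_BONE,
    VoxelVolume,
)

logger = logging.getLogger(__name__)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class CompartmentLabels:
    """Voxel-wise compartment codes plus the parameters that produced them."""

    volume: VoxelVolume  # label payload
    provenance: dict = field(default_factory=dict)

    @property
    def data(self) -> np.ndarray:
        return np.asarray(self.volume.data)

    @property
    def spacing(self) -> float:
        return self.volume.spacing


@dataclass
class CortexQCReport:
    cortical_porosity: float
    boundary_confidence: float
    flagged: bool


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_bone(
    grey: VoxelVolume,
    method: str = "kmeans",
    threshold: float | None = None,
    max_iter: int = 100,
) -> tuple[VoxelVolume, float]:
    """Binarise a greyscale volume into bone / background.

    ``kmeans`` runs two-class Lloyd iteration on intensity (centres
    initialised at the 10th/90th percentiles; the decision threshold is the
    midpoint of the converged centres); ``threshold`` applies a fixed
    value.  Returns (binary volume, decision threshold).
    """
    data = np.asarray(grey.data, np.float64)
    if method == "threshold":
        if threshold is None:
            raise ValidationError("method='threshold' requires a threshold")
        t = float(threshold)
    elif method == "kmeans":
        lo, hi = np.percentile(data, [10, 90])
        if data.max() == data.min():
            raise DegenerateClusteringError(
                "constant-intensity volume cannot be clustered"
            )
        c0, c1 = float(lo), float(hi)
        if c0 == c1:
            c0, c1 = float(data.min()), float(data.max())
        t = (c0 + c1) / 2.0
        for _ in range(max_iter):
            low = data < t
            if low.all() or not low.any():
                raise DegenerateClusteringError(
                    "two-class clustering collapsed to a single class"
                )
            c0, c1 = float(data[low].mean()), float(data[~low].mean())
            t_new = (c0 + c1) / 2.0
            if t_new == t:
                break
            t = t_new
    else:
        raise ValidationError(f"unknown segmentation method {method!r}")
    bone = (data >= t).astype(np.uint8)
    return grey.with_data(bone), t


def clean_components(
    bone: VoxelVolume, min_size_mm3: float = math.inf
) -> VoxelVolume:
    """Keep the largest 26-connected component; drop others below a size cut.

    Size ties are broken toward the component containing the lowest flat
    lattice index (logged).  An empty mask warns and returns empty.
    """
    bone.validate_binary()
    mask = np.asarray(bone.data, bool)
    if not mask.any():
        warnings.warn("clean_components: empty bone mask", stacklevel=2)
        return bone.with_data(np.zeros_like(mask, np.uint8))
    lab, n = ndimage.label(mask, structure=_STRUCT26)
    sizes = np.bincount(lab.ravel())[1:]
    biggest = sizes.max()
    tied = np.flatnonzero(sizes == biggest) + 1
    if len(tied) > 1:
        first_idx = [np.flatnonzero(lab.ravel() == t)[0] for t in tied]
        keep_id = tied[int(np.argmin(first_idx))]
        logger.info(
            "clean_components: %d equal-size components, keeping the one "
            "with the lowest lattice index", len(tied),
        )
    else:
        keep_id = tied[0]
    min_vox = min_size_mm3 / bone.spacing**3
    keep = np.zeros(n + 1, bool)
    keep[keep_id] = True
    keep[1:] |= sizes >= min_vox
    return bone.with_data(keep[lab].astype(np.uint8))


# ---------------------------------------------------------------------------
# morphology helpers (exact Euclidean, via distance transforms)
# ---------------------------------------------------------------------------

def _ball_close(mask: np.ndarray, radius_vox: float) -> np.ndarray:
    """Morphological closing with a Euclidean ball (two distance transforms)."""
    if radius_vox <= 0:
        return mask.copy()
    pad = int(math.ceil(radius_vox)) + 2
    m = np.pad(mask, pad)
    dil = ndimage.distance_transform_edt(~m) <= radius_vox
    closed = ndimage.distance_transform_edt(dil) > radius_vox
    sl = tuple(slice(pad, pad + s) for s in mask.shape)
    return closed[sl] | mask


def estimate_closing_radius(
    bone: VoxelVolume, k: float = 2.0, downsample: int = 2
) -> float:
    """Closing radius = k × mean local bone thickness, in mm.

    The thickness proxy for "average trabecular thickness" is the mean
    maximal-sphere thickness of the whole bone phase on a coarse
    (``downsample``-strided) copy — cheap, and adequate because the radius
    only needs the right order of magnitude to seal cortical pores.
    Clamped to at least 2 voxels of the original spacing.
    """
    bone.validate_binary()
    s = downsample
    coarse = np.asarray(bone.data, bool)[::s, ::s, ::s]
    floor_mm = 2.0 * bone.spacing
    if not coarse.any():
        return floor_mm
    vol = VoxelVolume(coarse.astype(np.uint8), bone.spacing * s)
    tmap = local_thickness(vol, max_levels=32)
    # one coarse voxel compensates the surface-offset underestimate of the
    # thickness map on structures a few voxels wide
    mean_th = mean_thickness(tmap, coarse) + vol.spacing
    return max(k * mean_th, floor_mm)


# ---------------------------------------------------------------------------
# enclosed volume and periosteal wall
# ---------------------------------------------------------------------------

def total_volume_mask(
    bone: VoxelVolume, closing_radius_mm: float | None = None
) -> VoxelVolume:
    """Enclosed (total) volume: everything not in the outside background.

    The bone is closed with ``closing_radius_mm`` (estimated if omitted) to
    seal surface pores; the background is the 6-connected component of the
    complement that touches the lattice border; TV is its complement,
    always a superset of the bone.
    """
    bone.validate_binary()
    mask = np.asarray(bone.data, bool)
    faces = [mask[0], mask[-1], mask[:, 0], mask[:, -1], mask[..., 0], mask[..., -1]]
    if any(f.any() for f in faces):
        raise BorderContactError("bone touches the lattice border; TV undefined")
    if closing_radius_mm is None:
        closing_radius_mm = estimate_closing_radius(bone)
    closed = _ball_close(mask, closing_radius_mm / bone.spacing)
    lab, _ = ndimage.label(~closed, structure=_STRUCT6)
    border_ids = np.unique(
        np.concatenate(
            [lab[0].ravel(), lab[-1].ravel(), lab[:, 0].ravel(),
             lab[:, -1].ravel(), lab[..., 0].ravel(), lab[..., -1].ravel()]
        )
    )
    border_ids = border_ids[border_ids > 0]
    outside = np.isin(lab, border_ids)
    tv = ~outside | mask
    return bone.with_data(tv.astype(np.uint8))


def _first_runs_along_axis(bone: np.ndarray, axis: int, reverse: bool) -> np.ndarray:
    """Voxels of the first contiguous bone run met marching along one axis."""
    b = np.flip(bone, axis) if reverse else bone
    seen_bone = np.maximum.accumulate(b, axis=axis)
    after_gap = np.maximum.accumulate((~b) & seen_bone, axis=axis)
    run = b & ~after_gap
    return np.flip(run, axis) if reverse else run


def cast_cortex_rays(bone: VoxelVolume, tv: VoxelVolume) -> VoxelVolume:
    """Union over the 6 axis directions of the first bone run per lattice line.

    Each lattice line is marched from outside the bone inward; from the
    first bone voxel, consecutive bone voxels are marked until the first
    non-bone voxel — the candidate periosteal wall.
    """
    bone.validate_binary()
    tv.validate_binary()
    B = np.asarray(bone.data, bool)
    T = np.asarray(tv.data, bool)
    if (B & ~T).any():
        raise ValidationError("tv must be a superset of bone")
    cand = np.zeros_like(B)
    for axis in range(3):
        for reverse in (False, True):
            cand |= _first_runs_along_axis(B, axis, reverse)
    return bone.with_data(cand.astype(np.uint8))


def label_compartments(
    bone: VoxelVolume,
    tv: VoxelVolume,
    candidate: VoxelVolume,
    closing_radius_mm: float,
) -> CompartmentLabels:
    """Partition TV into cortical bone / cortical pore / trabecular / internal.

    The ray-cast wall candidate is closed with a ball of the given radius
    (sealing cortical pores), then restricted to the shell: connected
    patches of TV outside the closed wall that do not reach the periosteal
    surface form the endosteal region; everything else in TV is the cortex
    region.  Cortex ∩ bone → cortical bone, cortex ∩ ¬bone → cortical pore,
    endosteal ∩ bone → trabecular bone, endosteal ∩ ¬bone → internal.
    """
    bone.validate_binary()
    B = np.asarray(bone.data, bool)
    T = np.asarray(tv.data, bool)
    C = np.asarray(candidate.data, bool)
    sp = bone.spacing
    closed = _ball_close(C, closing_radius_mm / sp) & T

    rest = T & ~closed
    lab, _ = ndimage.label(rest, structure=_STRUCT6)
    exterior_adjacent = ndimage.binary_dilation(~T, structure=_STRUCT6)
    surface_ids = np.unique(lab[rest & exterior_adjacent])
    surface_ids = surface_ids[surface_ids > 0]
    endo = rest & ~np.isin(lab, surface_ids)
    if not endo.any():
        raise DegenerateSpecimenError(
            "no endosteal region: cortex boundary cannot be defined"
        )

    # restrict the cortex to the shell: non-bone pockets of the closed wall
    # that the closing bridged over (rather than enclosed) open broadly
    # into the marrow — release them back to the endosteal region.  The
    # test is an erosion gate: a pocket drains only if its connection to
    # the marrow survives eroding the non-bone space by ~2 voxels; genuine
    # cortical pores communicate through channels narrower than that (or
    # not at all) and stay in the cortex.
    pockets = closed & ~B
    pocket_lab, _ = ndimage.label(pockets, structure=_STRUCT6)
    if pocket_lab.max() > 0:
        nonbone = endo | pockets
        core = nonbone & (ndimage.distance_transform_edt(nonbone) > 2.0)
        core_lab, _ = ndimage.label(core, structure=_STRUCT6)
        endo_core_ids = np.unique(core_lab[core & endo])
        endo_core_ids = endo_core_ids[endo_core_ids > 0]
        linked = core & np.isin(core_lab, endo_core_ids)
        drain_ids = np.unique(pocket_lab[linked & pockets])
        drain_ids = drain_ids[drain_ids > 0]
        if drain_ids.size:
            endo |= np.isin(pocket_lab, drain_ids)

    # trabecular fingers bridged onto the wall are far thinner than the
    # wall itself: an opening of the cortex region with a ball of a
    # quarter closing radius releases them without touching the shell
    # (pores ride along — they are interior to the region)
    cortex0 = T & ~endo
    rho = max(2.0, closing_radius_mm / sp / 4.0)
    ero = ndimage.distance_transform_edt(cortex0) > rho
    opened = cortex0 & (ndimage.distance_transform_edt(~ero) <= rho)
    trimmed = cortex0 & ~opened
    # trimmed patches on the periosteal surface are outer-surface bumps and
    # belong to the cortex; interior trimmed patches are released fingers
    if trimmed.any():
        tl, _ = ndimage.label(trimmed, structure=_STRUCT6)
        ext_adj = ndimage.binary_dilation(~T, structure=_STRUCT6)
        surf = np.unique(tl[trimmed & ext_adj])
        surf = surf[surf > 0]
        endo |= trimmed & ~np.isin(tl, surf)
    if not endo.any():
        raise DegenerateSpecimenError(
            "no endosteal region survives shell restriction"
        )
    cortex = T & ~endo

    out = np.full(B.shape, LABEL_BACKGROUND, np.uint8)
    out[cortex & B] = LABEL_CORTICAL_BONE
    out[cortex & ~B] = LABEL_CORTICAL_PORE
    out[endo & B] = LABEL_TRABECULAR_BONE
    out[endo & ~B] = LABEL_INTERNAL
    vol = VoxelVolume(out, sp, axis_roles=dict(bone.axis_roles))
    return CompartmentLabels(
        volume=vol,
        provenance={
            "closing_radius_mm": float(closing_radius_mm),
            "ray_directions": 6,
        },
    )


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_cortex(
    labels: CompartmentLabels,
    porosity_flag_threshold: float = 0.30,
    confidence_threshold: float = 0.80,
    min_run_voxels: int = 3,
) -> CortexQCReport:
    """Flag specimens whose cortical boundary is not trustworthy.

    ``cortical_porosity`` is pores / (pores + cortical bone).
    ``boundary_confidence`` is judged on the axis rays that traverse the
    endosteal region: a ray is well-formed when its first bone run is at
    least ``min_run_voxels`` long (a rubble wall yields only fragmentary
    runs) and terminates at a non-bone voxel inside TV (it found an inner
    boundary instead of exiting the bone).  Specimens with no endosteal
    region at all (e.g. a solid ball) get confidence 0.
    """
    lab = labels.data
    n_cb = int((lab == LABEL_CORTICAL_BONE).sum())
    n_cp = int((lab == LABEL_CORTICAL_PORE).sum())
    porosity = n_cp / (n_cb + n_cp) if (n_cb + n_cp) else 0.0

    B = (lab == LABEL_CORTICAL_BONE) | (lab == LABEL_TRABECULAR_BONE)
    T = lab > 0
    E = (lab == LABEL_INTERNAL) | (lab == LABEL_TRABECULAR_BONE)
    hits = bounded = 0
    for axis in range(3):
        for reverse in (False, True):
            b = np.flip(B, axis) if reverse else B
            t = np.flip(T, axis) if reverse else T
            e = np.flip(E, axis) if reverse else E
            relevant = b.any(axis=axis) & e.any(axis=axis)
            hits += int(relevant.sum())
            # first bone index, and first non-bone index after it
            seen = np.maximum.accumulate(b, axis=axis)
            after_gap = (~b) & seen
            first_bone = np.argmax(b, axis=axis)
            term_idx = np.argmax(after_gap, axis=axis)
            term = np.expand_dims(term_idx, axis)
            term_in_tv = np.take_along_axis(t, term, axis=axis).squeeze(axis)
            has_term = after_gap.any(axis=axis)
            long_run = (term_idx - first_bone) >= min_run_voxels
            bounded += int((relevant & has_term & term_in_tv & long_run).sum())
    confidence = bounded / hits if hits else 0.0
    flagged = porosity > porosity_flag_threshold or confidence < confidence_threshold
    return CortexQCReport(
        cortical_porosity=float(porosity),
        boundary_confidence=float(confidence),
        flagged=bool(flagged),
    )


def compartmentalize(
    grey: VoxelVolume,
    method: str = "kmeans",
    threshold: float | None = None,
    closing_k: float = 2.0,
    min_component_mm3: float = math.inf,
) -> tuple[CompartmentLabels, float]:
    """Convenience chain: segment → clean → TV → rays → labels.

    If the estimated closing radius is so large relative to the specimen
    that it obliterates the endosteal region (dense trabecular phantoms),
    the chain retries with a halved radius (twice) before giving up — a
    deterministic fallback, noted in the provenance.

    Returns the labels and the closing radius used (mm).
    """
    bone, t = segment_bone(grey, method=method, threshold=threshold)
    bone = clean_components(bone, min_size_mm3=min_component_mm3)
    r0 = estimate_closing_radius(bone, k=closing_k)
    last: DegenerateSpecimenError | None = None
    for attempt in range(3):
        r = r0 / 2**attempt
        tv = total_volume_mask(bone, closing_radius_mm=r)
        cand = cast_cortex_rays(bone, tv)
        try:
            labels = label_compartments(bone, tv, cand, r)
        except DegenerateSpecimenError as e:
            last = e
            continue
        labels.provenance.update(
            {"segmentation_threshold": t, "closing_k": closing_k,
             "closing_halvings": attempt}
        )
        return labels, r
    raise last  # type: ignore[misc]
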