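"""Proximal / distal volumes of interest and distal:proximal ratio variables.

The proximal segment of a capitate (the "head", articulating at the
midcarpal joint) and the distal segment (carrying the metacarpal facets
and ligament attachments) experience different loading; each specimen is
split at a stated cut plane orthogonal to the proximodistal axis (an
anatomical landmark in real bones, a configured index in phantoms), and a
distal/proximal ratio is built per parameter, plus two cortical-
contribution ratios (total BV/TV over trabecular BV/TV within each
segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compartments import CompartmentLabels
from .errors import ValidationError
from .morphometry import MorphometrySummary

__all__ = ["split_proximal_distal", "build_ratios", "RatioRecord", "RATIO_PARAMETERS"]

RATIO_PARAMETERS = (
    "trab_bvtv", "total_bvtv", "da", "tbth_mm", "tbn_per_mm", "tbsp_mm", "ctth_mm",
)


@dataclass
class RatioRecord:
    """Distal:proximal ratios for one specimen (NaN where undefined)."""

    specimen_id: str
    trab_bvtv: float
    total_bvtv: float
    da: float
    tbth_mm: float
    tbn_per_mm: float
    tbsp_mm: float
    ctth_mm: float
    cortical_contribution_distal: float
    cortical_contribution_proximal: float


def split_proximal_distal(
    labels: CompartmentLabels, cut_plane_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split TV at a plane orthogonal to the proximodistal axis.

    The plane's voxel layer belongs to the distal mask, so the two masks
    partition TV exactly.  Low indices are proximal.
    """
    lab = labels.data
    axis = labels.volume.proximodistal_axis
    n = lab.shape[axis]
    if not (0 < cut_plane_index < n):
        raise ValidationError(
            f"cut plane {cut_plane_index} not strictly inside (0, {n})"
        )
    tv = lab > 0
    idx = np.arange(n)
    shape = [1, 1, 1]
    shape[axis] = n
    proximal = tv & (idx.reshape(shape) < cut_plane_index)
    distal = tv & ~proximal
    if not proximal.any() or not distal.any():
        raise ValidationError("cut plane leaves one side without enclosed volume")
    return proximal, distal


def _ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or den <= 0:
        return float("nan")
    return float(num / den)


def build_ratios(
    distal: MorphometrySummary,
    proximal: MorphometrySummary,
    specimen_id: str = "",
) -> RatioRecord:
    """Elementwise distal/proximal ratios; invalid components propagate as NaN."""
    vals = {p: _ratio(getattr(distal, p), getattr(proximal, p)) for p in RATIO_PARAMETERS}
    return RatioRecord(
        specimen_id=specimen_id,
        cortical_contribution_distal=_ratio(distal.total_bvtv, distal.trab_bvtv),
        cortical_contribution_proximal=_ratio(proximal.total_bvtv, proximal.trab_bvtv),
        **vals,
    )
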