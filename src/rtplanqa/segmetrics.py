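"""Contour-similarity metrics between two segmentations of one structure.

Three metrics quantify how far an automatic contour is from the clinical
one: the volumetric Dice coefficient (VDSC, voxel overlap), the surface
Dice at a distance tolerance (SDSC, fraction of the two boundaries lying
within tau mm of each other; tau = 3 mm by default), and the 95th-percentile
Hausdorff distance (HD95, a robust worst-case boundary separation).

Surface convention: a member voxel is a surface voxel iff at least one of
its six face neighbours is non-member or lies outside the array (so voxels
on the array edge count as surface — masks are expected padded).  Surfaces
are represented by voxel centres; distances are Euclidean in mm, respecting
anisotropic spacing.  The HD95 is the max of the two directed 95th
percentiles, with linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .grids import StructMask, require_aligned

__all__ = [
    "SegComparison",
    "surface_points",
    "vdsc",
    "sdsc",
    "hd95",
    "compare_masks",
]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class SegComparison:
    structure: str
    vdsc: float
    sdsc_3mm: float
    hd95: float  # mm

    def __post_init__(self):
        if not (0.0 <= self.vdsc <= 1.0 and 0.0 <= self.sdsc_3mm <= 1.0):
            raise ValueError("Dice coefficients must lie in [0, 1]")
        if self.hd95 < 0:
            raise ValueError("HD95 must be >= 0")


def surface_points(m: StructMask) -> np.ndarray:
    """(n, 3) mm coordinates of the centres of the surface voxels of ``m``."""
    if m.is_empty:
        raise ValueError(f"mask '{m.name}' is empty; no surface")
    interior = ndimage.binary_erosion(m.values, structure=_FACE_STRUCTURE, border_value=0)
    surf = m.values & ~interior
    idx = np.argwhere(surf)
    return idx * np.asarray(m.spacing) + np.asarray(m.origin)


def vdsc(a: StructMask, b: StructMask) -> float:
    """Volumetric Dice 2|A&B| / (|A|+|B|); two empty masks give 1."""
    require_aligned(a, b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        warnings.warn("both masks empty; VDSC defined as 1", stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def _directed_distances(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Distance from every point of p to its nearest point of q (mm)."""
    tree = cKDTree(q)
    d, _ = tree.query(p, k=1)
    return d


def sdsc(a: StructMask, b: StructMask, tau: float = 3.0) -> float:
    """Surface Dice at tolerance ``tau`` mm.

    The fraction of surface points (pooled over both surfaces) whose
    distance to the other surface is at most tau.
    """
    require_aligned(a, b)
    if tau < 0:
        raise ValueError("tau must be >= 0")
    sa, sb = surface_points(a), surface_points(b)
    dab = _directed_distances(sa, sb)
    dba = _directed_distances(sb, sa)
    hits = np.count_nonzero(dab <= tau) + np.count_nonzero(dba <= tau)
    return hits / (len(sa) + len(sb))


def hd95(a: StructMask, b: StructMask) -> float:
    """95th-percentile Hausdorff distance in mm (max of directed percentiles)."""
    require_aligned(a, b)
    sa, sb = surface_points(a), surface_points(b)
    dab = _directed_distances(sa, sb)
    dba = _directed_distances(sb, sa)
    return float(max(np.percentile(dab, 95), np.percentile(dba, 95)))


def compare_masks(ref: StructMask, test: StructMask, tau: float = 3.0) -> SegComparison:
    """All three metrics for one reference/test contour pair."""
    return SegComparison(
        structure=ref.name,
        vdsc=vdsc(ref, test),
        sdsc_3mm=sdsc(ref, test, tau),
        hd95=hd95(ref, test),
    )
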