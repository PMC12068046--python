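"""3D collagen invasion quantification.

Cells seeded at the bottom of a collagen gel are imaged as a z-stack of
planes (default spacing 30 um, depth 0 = plate bottom).  Nuclei are
detected per plane as blobs and counted only when both their nuclear and
GFP intensities clear configurable thresholds, which suppresses debris and
out-of-focus decoys.  The invasion index is the fraction of detected cells
above the bottom plane:

    I = sum(counts at depth > 0) / sum(counts at all planes)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import blob_log

__all__ = ["InvasionStack", "count_cells_per_plane", "invasion_index"]

PLANE_SPACING_UM = 30.0


@dataclass
class InvasionStack:
    """Filtered per-plane cell counts for one well."""

    depths_um: np.ndarray  # ascending, depths_um[0] == 0 (bottom)
    counts: np.ndarray
    well_id: str = ""
    nuclear_threshold: float | None = None
    gfp_threshold: float | None = None
    centroids: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.depths_um = np.asarray(self.depths_um, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.depths_um.size != self.counts.size:
            raise ValueError("depths and counts differ in length")
        if np.any(np.diff(self.depths_um) <= 0):
            raise ValueError("plane depths must be strictly ascending")
        if self.depths_um[0] != 0.0:
            raise ValueError("bottom plane (depth 0) must be present first")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")


def _blob_mean(img: np.ndarray, centre: np.ndarray, radius: float) -> float:
    r0, c0 = centre
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    if not mask.any():
        return 0.0
    return float(img[mask].mean())


def count_cells_per_plane(
    nuclear_stack,
    gfp_stack,
    nuclear_threshold: float,
    gfp_threshold: float,
    depths_um=None,
    min_sigma: float = 2.0,
    max_sigma: float = 8.0,
    detect_threshold: float = 0.02,
    well_id: str = "",
) -> InvasionStack:
    """Detect and dual-filter nuclei per plane of an invasion z-stack.

    Parameters
    ----------
    nuclear_stack, gfp_stack
        Arrays of shape (planes, H, W); plane 0 is the plate bottom.
    nuclear_threshold, gfp_threshold
        Minimum mean blob intensity in each channel for a detection to be
        counted as a cell (both must pass).
    depths_um
        Plane depths; defaults to 30-um spacing from 0.
    """
    nuc = np.asarray(nuclear_stack, dtype=float)
    gfp = np.asarray(gfp_stack, dtype=float)
    if nuc.shape != gfp.shape or nuc.ndim != 3:
        raise ValueError("stacks must share a (planes, H, W) shape")
    if nuc.shape[0] < 2:
        raise ValueError("invasion index needs at least 2 planes")
    if nuclear_threshold < 0 or gfp_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    if depths_um is None:
        depths_um = PLANE_SPACING_UM * np.arange(nuc.shape[0])

    counts = np.zeros(nuc.shape[0], dtype=int)
    centroids = []
    for z in range(nuc.shape[0]):
        plane = nuc[z]
        span = plane.max() - plane.min()
        if span <= 0:
            centroids.append(np.empty((0, 2)))
            continue
        norm = (plane - plane.min()) / span
        blobs = blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma, threshold=detect_threshold)
        kept = []
        for r, c, sigma in blobs:
            radius = np.sqrt(2.0) * sigma
            if (
                _blob_mean(plane, (r, c), radius) >= nuclear_threshold
                and _blob_mean(gfp[z], (r, c), radius) >= gfp_threshold
            ):
                kept.append((r, c))
        counts[z] = len(kept)
        centroids.append(np.asarray(kept).reshape(-1, 2))
    return InvasionStack(
        depths_um=depths_um,
        counts=counts,
        well_id=well_id,
        nuclear_threshold=nuclear_threshold,
        gfp_threshold=gfp_threshold,
        centroids=centroids,
    )


def invasion_index(stack: InvasionStack) -> float:
    """Fraction of detected cells above the bottom plane (NaN when empty)."""
    total = int(stack.counts.sum())
    if total == 0:
        import warnings

        warnings.warn("no cells detected in any plane; invasion index undefined", stacklevel=2)
        return float("nan")
    middle = int(stack.counts[stack.depths_um > 0].sum())
    return middle / total
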