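"""Morphology and texture feature extraction for segmented cells.

The feature registry is shared by the shape classifier and the normal
(penetrance) filter.  It combines:

* morphology — area (um^2), perimeter, roundness 4*pi*A/P^2, length,
  width, axial ratio, solidity, eccentricity, extent, equivalent diameter,
  protrusion count (convexity defects deeper than a configurable depth),
  nucleus area/roundness and nucleus:cell area ratio;
* intensity — background-free mean intensity of each channel over the
  cell and the nucleus;
* SER texture — spot / edge / ridge / valley / saddle / hole / bright /
  dark responses from a Gaussian-derivative (Hessian) decomposition of
  each channel at a fixed scale, averaged over the cell mask and
  normalized by the mean intensity (so they are invariant to global
  intensity scaling).

The registry is ordered and fixed per run; vectors from different cells
always align.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops
from skimage.morphology import convex_hull_image

__all__ = ["feature_registry", "extract_features", "SER_TYPES"]

SER_TYPES = ("spot", "edge", "ridge", "valley", "saddle", "hole", "bright", "dark")

_MORPH = (
    "area_um2",
    "perimeter_um",
    "roundness",
    "length_um",
    "width_um",
    "axial_ratio",
    "solidity",
    "eccentricity",
    "extent",
    "equivalent_diameter_um",
    "protrusion_count",
    "nucleus_area_um2",
    "nucleus_roundness",
    "nucleus_cell_area_ratio",
)


def feature_registry(channels=("dna", "tubulin", "actin")) -> list[str]:
    """Ordered feature names for the given texture/intensity channels."""
    names = list(_MORPH)
    for ch in channels:
        names.append(f"mean_{ch}_cell")
        names.append(f"mean_{ch}_nucleus")
    for ch in channels:
        for s in SER_TYPES:
            names.append(f"ser_{s}_{ch}")
    return names


def _roundness(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 0.0
    return float(4.0 * np.pi * area / perimeter**2)


def protrusion_count(mask: np.ndarray, min_depth: float = 3.0, min_area: int = 20) -> int:
    """Count convexity defects of the outline deeper than ``min_depth`` px.

    A protrusion-rich outline (e.g. a three-pointed cell) carves deep
    concave bays out of its convex hull; each sufficiently deep bay counts
    once.  Convex outlines return 0.
    """
    if mask.sum() < 4:
        return 0
    hull = convex_hull_image(mask)
    defects = hull & ~mask
    lab, n = ndi.label(defects)
    if n == 0:
        return 0
    # depth of a bay = its maximum distance from the cell outline
    dist = ndi.distance_transform_edt(~mask)
    count = 0
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() >= min_area and dist[comp].max() >= min_depth:
            count += 1
    return count


def _hessian_fields(img: np.ndarray, sigma: float):
    gx = ndi.gaussian_filter(img, sigma, order=(0, 1))
    gy = ndi.gaussian_filter(img, sigma, order=(1, 0))
    hxx = ndi.gaussian_filter(img, sigma, order=(0, 2))
    hyy = ndi.gaussian_filter(img, sigma, order=(2, 0))
    hxy = ndi.gaussian_filter(img, sigma, order=(1, 1))
    return gx, gy, hxx, hyy, hxy


def ser_responses(img: np.ndarray, mask: np.ndarray, sigma: float = 1.0) -> dict[str, float]:
    """Mean SER texture responses over ``mask``, intensity-normalized.

    Eigenvalues l1 <= l2 of the scale-space Hessian classify local
    structure: bright blobs (both negative) feed *spot*, dark blobs (both
    positive) *hole*, bright lines *ridge*, dark lines *valley*, mixed
    curvature *saddle*; *edge* is the gradient magnitude and bright/dark
    are the positive/negative deviations from the in-mask mean.  A
    structure-free (uniform) region scores 0 on every response.
    """
    img = np.asarray(img, dtype=float)
    m = mask.astype(bool)
    if not m.any():
        return {s: 0.0 for s in SER_TYPES}
    mean_int = img[m].mean()
    norm = mean_int if mean_int > 0 else 1.0

    gx, gy, hxx, hyy, hxy = _hessian_fields(img, sigma)
    tr = hxx + hyy
    det_term = np.sqrt(np.clip(((hxx - hyy) * 0.5) ** 2 + hxy**2, 0, None))
    l2 = 0.5 * tr + det_term
    l1 = 0.5 * tr - det_term

    both_neg = (l1 < 0) & (l2 < 0)
    both_pos = (l1 > 0) & (l2 > 0)
    mixed = (l1 < 0) & (l2 > 0)
    out = {
        "spot": np.where(both_neg, np.sqrt(np.clip(l1 * l2, 0, None)), 0.0),
        "hole": np.where(both_pos, np.sqrt(np.clip(l1 * l2, 0, None)), 0.0),
        "ridge": np.where(l1 < 0, np.clip(-l1 - np.abs(l2), 0, None), 0.0),
        "valley": np.where(l2 > 0, np.clip(l2 - np.abs(l1), 0, None), 0.0),
        "saddle": np.where(mixed, np.sqrt(np.clip(-l1 * l2, 0, None)), 0.0),
        "edge": np.sqrt(gx**2 + gy**2),
        "bright": np.clip(img - mean_int, 0, None) / max(norm, 1e-12),
        "dark": np.clip(mean_int - img, 0, None) / max(norm, 1e-12),
    }
    return {s: float(v[m].mean() / (norm if s not in ("bright", "dark") else 1.0)) for s, v in out.items()}


def extract_features(
    cell,
    channel_images: dict[str, np.ndarray],
    pixel_size: float = 1.0,
    ser_sigma: float = 1.0,
    backgrounds: dict[str, float] | None = None,
) -> dict[str, float]:
    """Compute the full registry for one cell; returns name -> value.

    ``pixel_size`` converts pixel measures to um; ``backgrounds`` holds
    optional per-channel background levels subtracted from intensity
    means.  Degenerate masks yield defined limits rather than errors.
    """
    backgrounds = backgrounds or {}
    px, px2 = pixel_size, pixel_size**2
    # crop to the cell bounding box (with a margin for the derivative
    # filters) — full-frame filtering per cell is needless work
    margin = int(np.ceil(4 * ser_sigma)) + 4
    ys, xs = np.nonzero(cell.cell_mask)
    y0, y1 = max(0, ys.min() - margin), min(cell.cell_mask.shape[0], ys.max() + margin + 1)
    x0, x1 = max(0, xs.min() - margin), min(cell.cell_mask.shape[1], xs.max() + margin + 1)
    win = (slice(y0, y1), slice(x0, x1))
    cmask = cell.cell_mask[win]
    nmask = cell.nucleus_mask[win]
    channel_images = {ch: np.asarray(img, dtype=float)[win] for ch, img in channel_images.items()}

    props = regionprops(cmask.astype(np.uint8))[0]
    nprops = regionprops(nmask.astype(np.uint8))[0] if nmask.any() else props
    length = props.axis_major_length * px
    width = props.axis_minor_length * px
    feats = {
        "area_um2": props.area * px2,
        "perimeter_um": props.perimeter * px,
        "roundness": _roundness(props.area, props.perimeter),
        "length_um": length,
        "width_um": width,
        "axial_ratio": length / width if width > 0 else 1.0,
        "solidity": props.solidity,
        "eccentricity": props.eccentricity,
        "extent": props.extent,
        "equivalent_diameter_um": props.equivalent_diameter_area * px,
        "protrusion_count": float(protrusion_count(cmask)),
        "nucleus_area_um2": nprops.area * px2,
        "nucleus_roundness": _roundness(nprops.area, nprops.perimeter),
        "nucleus_cell_area_ratio": nprops.area / props.area,
    }
    for ch, img in channel_images.items():
        img = np.asarray(img, dtype=float)
        bg = backgrounds.get(ch, 0.0)
        feats[f"mean_{ch}_cell"] = float(img[cmask].mean() - bg)
        feats[f"mean_{ch}_nucleus"] = float(img[nmask].mean() - bg)
    for ch, img in channel_images.items():
        ser = ser_responses(img, cmask, ser_sigma)
        for s in SER_TYPES:
            feats[f"ser_{s}_{ch}"] = ser[s]
    return feats
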