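"""Synthetic high-content screening plates.

Each well contains a mixture of five cell-shape archetypes:

* ``spindly``      — elongated body with two tip protrusions (pinched waist)
* ``large_round``  — large, nearly circular spread cell
* ``triangular``   — three protrusions at 120 degrees
* ``fan``          — asymmetric half-spread body with an offset nucleus
* ``small_round``  — small, round, compact cell

Cells are drawn as radial polygons with per-cell size/rotation jitter,
blurred, and corrupted with Poisson shot noise plus Gaussian read noise.
A marker channel (YAP/TAZ-like) is painted so that the log10 ratio of the
mean nuclear intensity to the mean perinuclear-ring intensity equals
``class baseline + well ratio_shift + per-cell noise``; ground truth
records the programmed class and ratio of every rendered cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon

SHAPE_CLASSES = ("spindly", "large_round", "triangular", "fan", "small_round")

# log10 nuclear:ring marker baseline per class (mock conditions)
DEFAULT_RATIO_BASELINES = {
    "spindly": 0.20,
    "large_round": 0.10,
    "triangular": 0.30,
    "fan": 0.15,
    "small_round": 0.40,
}

DEFAULT_CHANNELS = ("dna", "tubulin", "actin", "marker")

# rendering intensity levels (photons); read noise sd and camera offset
_NUCLEUS_DNA = 600.0
_CELL_BODY = 300.0
_MARKER_CYTO = 120.0
_READ_NOISE_SD = 3.0
_OFFSET = 10.0
_BLUR_SIGMA = 1.0


@dataclass
class WellSpec:
    well_id: str
    condition: str
    shape_mixture: tuple[float, float, float, float, float]
    ratio_shift: float = 0.0  # log10 units added to every cell's ratio
    cells_per_field: int = 50
    fields_per_well: int = 1
    plate: str = "P1"
    column: int = 3
    is_mock: bool = False
    # fraction of cells pre-labelled "normal" (used by the table-level
    # simulator to exercise the penetrance readout; rendered plates leave
    # normal-calling to the classifier)
    normal_fraction: float = 0.0
    # extra per-well offset on the ratio (log10), emulating well-to-well
    # variability beyond cell sampling noise
    well_noise_sd: float = 0.0


@dataclass
class PlateSpec:
    wells: list[WellSpec]
    pixel_size: float = 0.6  # um/px
    image_size: int = 1024
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0
    cell_scale_px: float = 18.0  # base radial scale of the archetypes
    ratio_noise_sd: float = 0.10  # per-cell log10 ratio noise
    ratio_baselines: dict = field(default_factory=lambda: dict(DEFAULT_RATIO_BASELINES))

    def validate(self) -> None:
        seen = set()
        for w in self.wells:
            if w.well_id in seen:
                raise ValueError(f"duplicate well_id {w.well_id!r}")
            seen.add(w.well_id)
            mix = np.asarray(w.shape_mixture, dtype=float)
            if mix.size != 5 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-9):
                raise ValueError(
                    f"well {w.well_id!r}: shape mixture must be 5 non-negative fractions summing to 1"
                )
        max_r = 1.8 * self.cell_scale_px
        for w in self.wells:
            grid = int(np.ceil(np.sqrt(w.cells_per_field)))
            if grid and self.image_size / grid < 2 * max_r + 6:
                raise ValueError(
                    f"image_size {self.image_size} too small for {w.cells_per_field} cells per field"
                )


def _radial_profile(shape_class: str, theta: np.ndarray, r0: float) -> np.ndarray:
    """Radius as a function of polar angle for each archetype."""
    if shape_class == "spindly":
        # two-lobed: pinched waist gives two tip protrusions, tip-to-tip
        # extent ~4x the waist width
        return r0 * 1.45 * (0.18 + 0.82 * np.abs(np.cos(theta)) ** 1.5)
    if shape_class == "large_round":
        return np.full_like(theta, 1.55 * r0)
    if shape_class == "triangular":
        return 0.85 * r0 * (1.0 + 0.45 * np.cos(3.0 * theta))
    if shape_class == "fan":
        # spread toward +x, compact behind; asymmetric outline
        return r0 * (0.55 + 0.65 * np.clip(np.cos(theta), 0.0, None))
    if shape_class == "small_round":
        return np.full_like(theta, 0.60 * r0)
    raise ValueError(f"unknown shape class {shape_class!r}")


def render_archetype_cell(
    shape_class: str,
    centre: tuple[float, float],
    rotation: float,
    r0: float,
    image_shape: tuple[int, int],
    size_jitter: float = 1.0,
):
    """Rasterize one archetype cell; returns (cell_mask, nucleus_mask).

    The nucleus is a disk of radius 0.32*r0 placed at the cell centroid,
    except for the fan archetype where it is offset backwards by 0.45*r0
    (nucleus to one side).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, 96, endpoint=False)
    r = _radial_profile(shape_class, theta, r0) * size_jitter
    rows = centre[0] + r * np.sin(theta + rotation)
    cols = centre[1] + r * np.cos(theta + rotation)
    cell = np.zeros(image_shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=image_shape)
    cell[rr, cc] = True

    if shape_class == "fan":
        off = 0.45 * r0 * size_jitter
        nuc_centre = (centre[0] - off * np.sin(rotation), centre[1] - off * np.cos(rotation))
    else:
        nuc_centre = centre
    rn = 0.32 * r0 * size_jitter
    yy, xx = np.ogrid[: image_shape[0], : image_shape[1]]
    nucleus = (yy - nuc_centre[0]) ** 2 + (xx - nuc_centre[1]) ** 2 <= rn**2
    nucleus &= cell
    return cell, nucleus


def _place_centres(n: int, image_size: int, rng: np.random.Generator, max_r: float):
    """Jittered grid placement keeping cells from overlapping."""
    grid = int(np.ceil(np.sqrt(n)))
    pitch = image_size / grid
    jitter = max(0.0, (pitch - 2.0 * max_r) / 2.0 - 2.0)
    centres = []
    for k in range(grid * grid):
        i, j = divmod(k, grid)
        cy = (i + 0.5) * pitch + rng.uniform(-jitter, jitter)
        cx = (j + 0.5) * pitch + rng.uniform(-jitter, jitter)
        centres.append((cy, cx))
    order = rng.permutation(grid * grid)[:n]
    return [centres[k] for k in order]


def _camera(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Blur + Poisson shot noise + Gaussian read noise + offset, as uint16."""
    blurred = ndi.gaussian_filter(img, _BLUR_SIGMA)
    shot = rng.poisson(np.clip(blurred, 0, None)).astype(float)
    out = shot + rng.normal(0.0, _READ_NOISE_SD, img.shape) + _OFFSET
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def generate_plate(spec: PlateSpec):
    """Render every field of every well of a plate.

    Returns
    -------
    images : dict
        ``images[well_id][field][channel]`` -> uint16 image.
    truth : pandas.DataFrame
        One row per rendered cell: well_id, field, cell_index,
        centroid_row, centroid_col, shape_class, true_ratio.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    images: dict[str, list[dict[str, np.ndarray]]] = {}
    records = []
    shape = (spec.image_size, spec.image_size)
    for well in spec.wells:
        mix = np.asarray(well.shape_mixture, dtype=float)
        images[well.well_id] = []
        for f in range(well.fields_per_well):
            n = well.cells_per_field
            classes = rng.choice(5, size=n, p=mix)
            chan = {c: np.zeros(shape, dtype=float) for c in spec.channels}
            centres = _place_centres(n, spec.image_size, rng, 1.8 * spec.cell_scale_px)
            for ci in range(n):
                cls = SHAPE_CLASSES[classes[ci]]
                rot = rng.uniform(0.0, 2.0 * np.pi)
                jit = rng.uniform(0.92, 1.08)
                cell, nucleus = render_archetype_cell(
                    cls, centres[ci], rot, spec.cell_scale_px, shape, jit
                )
                if not nucleus.any():
                    continue
                cyto = cell & ~nucleus
                true_ratio = (
                    spec.ratio_baselines[cls]
                    + well.ratio_shift
                    + rng.normal(0.0, spec.ratio_noise_sd)
                )
                if "dna" in chan:
                    chan["dna"][nucleus] += _NUCLEUS_DNA
                if "tubulin" in chan:
                    chan["tubulin"][cell] += _CELL_BODY
                if "actin" in chan:
                    chan["actin"][cell] += _CELL_BODY
                if "marker" in chan:
                    chan["marker"][cyto] += _MARKER_CYTO
                    chan["marker"][nucleus] += _MARKER_CYTO * 10.0**true_ratio
                com = np.argwhere(nucleus).mean(axis=0)
                records.append(
                    {
                        "well_id": well.well_id,
                        "field": f,
                        "cell_index": ci,
                        "centroid_row": float(com[0]),
                        "centroid_col": float(com[1]),
                        "shape_class": cls,
                        "true_ratio": float(true_ratio),
                    }
                )
            images[well.well_id].append({c: _camera(img, rng) for c, img in chan.items()})
    truth = pd.DataFrame(records)
    return images, truth


def simulate_cell_table(
    wells: list[WellSpec],
    n_cells_per_well: int | None = None,
    ratio_noise_sd: float = 0.10,
    ratio_baselines: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a per-cell classification/ratio table without rendering images.

    Statistically equivalent to segmenting and measuring a rendered plate
    with a perfect classifier: classes are multinomial draws from each
    well's mixture, ratios are class baseline + well ratio_shift +
    Gaussian noise.  Used for large screen-level simulations where image
    rendering adds nothing.
    """
    baselines = ratio_baselines or DEFAULT_RATIO_BASELINES
    rng = np.random.default_rng(seed)
    rows = []
    for well in wells:
        mix = np.asarray(well.shape_mixture, dtype=float)
        if mix.size != 5 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0, atol=1e-9):
            raise ValueError(f"well {well.well_id!r}: invalid shape mixture")
        n = n_cells_per_well or well.cells_per_field * well.fields_per_well
        classes = rng.choice(5, size=n, p=mix)
        noise = rng.normal(0.0, ratio_noise_sd, size=n)
        well_offset = rng.normal(0.0, well.well_noise_sd) if well.well_noise_sd > 0 else 0.0
        is_normal = rng.random(n) < well.normal_fraction if well.normal_fraction > 0 else np.zeros(n, bool)
        for i in range(n):
            cls = "normal" if is_normal[i] else SHAPE_CLASSES[classes[i]]
            base = baselines[SHAPE_CLASSES[classes[i]]]
            rows.append(
                {
                    "well_id": well.well_id,
                    "shape_class": cls,
                    "ratio": base + well.ratio_shift + well_offset + noise[i],
                }
            )
    return pd.DataFrame(rows)
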