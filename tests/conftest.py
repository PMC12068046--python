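import warnings

import numpy as np
import pandas as pd
import pytest

from morphoscreen.synthetic.plate import PlateSpec, WellSpec, generate_plate

# scikit-image deprecation chatter is irrelevant to the science under test
warnings.filterwarnings("ignore", category=FutureWarning, module="skimage")


@pytest.fixture(scope="session")
def rendered_field():
    """One rendered mixed-archetype field plus its ground truth."""
    spec = PlateSpec(
        wells=[WellSpec("w1", "mix", (0.2, 0.2, 0.2, 0.2, 0.2), cells_per_field=25)],
        image_size=640,
        seed=101,
    )
    images, truth = generate_plate(spec)
    return images["w1"][0], truth


@pytest.fixture(scope="session")
def labelled_archetype_features():
    """Measured features with ground-truth class labels from 4 rendered fields."""
    from morphoscreen import features, imaging

    wells = [
        WellSpec(f"w{i}", "mix", (0.2, 0.2, 0.2, 0.2, 0.2), cells_per_field=30)
        for i in range(6)
    ]
    spec = PlateSpec(wells=wells, image_size=704, seed=202)
    images, truth = generate_plate(spec)
    rows = []
    for wid, fields_ in images.items():
        chan = fields_[0]
        cells = imaging.segment_cells(chan["dna"], chan["tubulin"])
        bg = {
            ch: imaging.estimate_background(img, [c.cell_mask for c in cells])
            for ch, img in chan.items()
        }
        tw = truth[truth.well_id == wid]
        for c in cells:
            if c.is_border:
                continue
            com = c.centroid
            d = np.hypot(tw.centroid_row - com[0], tw.centroid_col - com[1])
            j = d.idxmin()
            if d[j] > 5:
                continue
            f = features.extract_features(
                c, {k: chan[k] for k in ("dna", "tubulin", "actin")},
                pixel_size=0.6, backgrounds=bg,
            )
            f["true_class"] = tw.loc[j, "shape_class"]
            f["well_id"] = wid
            rows.append(f)
    return pd.DataFrame(rows)
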