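"""Self-contained simulation studies exercising the whole pipeline.

Each function generates its own synthetic inputs with known ground truth,
runs the corresponding analysis stage(s), and returns headline numbers
(accuracies, error rates, coverages).  They are used by the acceptance
test-suite and the reproduction script; problem sizes are chosen so the
full set runs in minutes on one CPU.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import adhesions as fa
from . import features, imaging, invasion, scoring, shapes
from .config import RunConfig
from .effectsize import hedges_g_bootstrap
from .pipeline import default_synthetic_screen, run_pipeline
from .synthetic.adhesion_movies import generate_fa_movie
from .synthetic.invasion_stacks import generate_invasion_stack
from .synthetic.plate import SHAPE_CLASSES, PlateSpec, WellSpec, generate_plate


def _measure_plate(images, truth, pixel_size=0.6, max_dist=5.0):
    """Segment + measure every field; label cells by ground-truth match."""
    rows = []
    for wid, fields_ in images.items():
        for f, chan in enumerate(fields_):
            cells = imaging.segment_cells(chan["dna"], chan["tubulin"])
            bg = {
                ch: imaging.estimate_background(img, [c.cell_mask for c in cells])
                for ch, img in chan.items()
            }
            tw = truth[(truth.well_id == wid) & (truth.field == f)]
            for c in cells:
                if c.is_border:
                    continue
                d = np.hypot(tw.centroid_row - c.centroid[0], tw.centroid_col - c.centroid[1])
                if len(d) == 0 or d.min() > max_dist:
                    continue
                feats = features.extract_features(
                    c, {k: chan[k] for k in ("dna", "tubulin", "actin")},
                    pixel_size=pixel_size, backgrounds=bg,
                )
                feats["well_id"] = wid
                feats["true_class"] = tw.loc[d.idxmin(), "shape_class"]
                rows.append(feats)
    return pd.DataFrame(rows)


# twenty well mixtures: five pure archetype wells (classifier exemplars),
# five uniform, ten assorted heterogeneous profiles
def _recovery_mixtures():
    mixtures = [tuple(1.0 if i == k else 0.0 for i in range(5)) for k in range(5)]
    mixtures += [(0.2,) * 5] * 5
    assorted = [
        (0.10, 0.05, 0.55, 0.05, 0.25),
        (0.25, 0.05, 0.10, 0.55, 0.05),
        (0.55, 0.25, 0.05, 0.05, 0.10),
        (0.05, 0.55, 0.10, 0.25, 0.05),
        (0.05, 0.10, 0.25, 0.05, 0.55),
        (0.40, 0.10, 0.30, 0.10, 0.10),
        (0.10, 0.30, 0.10, 0.40, 0.10),
        (0.30, 0.30, 0.20, 0.10, 0.10),
        (0.15, 0.15, 0.40, 0.15, 0.15),
        (0.10, 0.10, 0.10, 0.10, 0.60),
    ]
    return mixtures + assorted


def shape_mixture_recovery(
    seed: int,
    n_wells: int = 20,
    cells_per_field: int = 50,
    fields_per_well: int = 10,
    image_size: int = 512,
    cell_scale_px: float = 14.0,
) -> dict:
    """Render a 20-well plate (500 cells/well), classify, compare fractions.

    The classifier trains on cells from the five pure archetype wells
    (ground-truth labels by centroid matching); fractions of every well
    are then predicted and compared with the realized ground truth.
    """
    mixtures = _recovery_mixtures()[:n_wells]
    wells = [
        WellSpec(
            f"w{i:02d}", f"cond{i:02d}", mixtures[i],
            cells_per_field=cells_per_field, fields_per_well=fields_per_well,
        )
        for i in range(n_wells)
    ]
    spec = PlateSpec(
        wells=wells, image_size=image_size, cell_scale_px=cell_scale_px, seed=seed
    )
    images, truth = generate_plate(spec)
    df = _measure_plate(images, truth)
    reg = features.feature_registry()

    pure_wells = {f"w{k:02d}" for k in range(5)}
    train = df[df.well_id.isin(pure_wells)]
    model = shapes.train_shape_classifier(train[reg], train["true_class"], seed=seed)
    df = df.assign(predicted=shapes.classify_cells(model, df[reg]))

    errors = []
    for wid, grp in df.groupby("well_id"):
        tw = truth[truth.well_id == wid]
        for cls in SHAPE_CLASSES:
            true_frac = np.mean(tw["shape_class"] == cls)
            got_frac = np.mean(grp["predicted"] == cls)
            errors.append(abs(got_frac - true_frac))
    return {
        "holdout_accuracy": float(model.holdout_accuracy),
        "max_fraction_error_pp": float(100.0 * max(errors)),
        "n_cells_measured": int(len(df)),
        "n_wells": n_wells,
    }


def z_standardization(seed: int, n_mock: int = 40, n_cells: int = 200) -> dict:
    """Mock-only screen: worst-case Z mean/sd over all metrics."""
    from .synthetic.screen import build_mock_screen

    cells, layout = build_mock_screen(n_mock=n_mock, n_cells=n_cells, seed=seed)
    z = scoring.zscore_vs_mock(scoring.summarize_wells(cells, layout))
    metrics = [f"frac_{s}" for s in SHAPE_CLASSES] + ["median_ratio", "normal_fraction"]
    means = [z.loc[z.is_mock, m].mean() for m in metrics]
    sds = [z.loc[z.is_mock, m].std() for m in metrics]
    return {
        "max_abs_mock_z_mean": float(max(abs(m) for m in means)),
        "worst_mock_z_sd": float(max(sds, key=lambda s: abs(s - 1.0))),
        "n_mock_wells": n_mock,
    }


def hit_calling(seed: int) -> dict:
    """500-well screen: yap_low sensitivity on shifted wells, FPR on nulls."""
    from .synthetic.screen import build_hit_screen

    cells, layout, truth = build_hit_screen(seed=seed)
    hits = scoring.call_hits(
        scoring.zscore_vs_mock(scoring.summarize_wells(cells, layout))
    ).join(truth)
    test = hits[~hits.is_mock]
    return {
        "yap_low_sensitivity": float(test.loc[test.true_hit, "yap_low"].mean()),
        "yap_low_fpr": float(test.loc[~test.true_hit, "yap_low"].mean()),
        "n_test_wells": int(len(test)),
    }


def dock5_worked_example() -> dict:
    """Published per-well Z-scores of the siGENOME DOCK5 pool at -1.5."""
    z = pd.DataFrame(
        {
            "condition": ["siDOCK5"] * 4,
            "median_ratio": [-1.73, -2.33, -2.77, -0.79],
            "excluded": [False] * 4,
        },
        index=[f"rep{i+1}" for i in range(4)],
    )
    flags = scoring.call_hits(z)["yap_low"].tolist()
    return {"flags": flags, "n_flagged": int(sum(flags))}


def invasion_recovery(seed: int, n_stacks: int = 5) -> dict:
    """Rendered z-stacks with decoys: recovered index vs ground truth."""
    rng = np.random.default_rng(seed)
    errors = []
    for k in range(n_stacks):
        counts = rng.integers(20, 90, size=3)
        counts[0] = max(counts[0], 40)  # seeded assay: most cells at bottom
        nuc, gfp, _ = generate_invasion_stack(
            counts, seed=int(rng.integers(2**31)), decoy_fraction=0.5, decoy_intensity=0.1
        )
        stack = invasion.count_cells_per_plane(nuc, gfp, nuclear_threshold=30, gfp_threshold=20)
        true_idx = counts[1:].sum() / counts.sum()
        errors.append(abs(invasion.invasion_index(stack) - true_idx))
    return {"max_index_error": float(max(errors)), "n_stacks": n_stacks}


def fa_rate_recovery(seed: int, n_tracks: int = 200, k_a: float = 0.1, k_d: float = 0.05) -> dict:
    """Noiseless exactness and SNR-10 rate errors over 200 tracks."""
    movie, _ = generate_fa_movie(
        25, k_a=k_a, k_d=k_d, frame_interval_min=3.0, noise_sd=0.0, seed=seed,
        image_size=320, read_noise_sd=0.0,
    )
    clean = fa.filter_tracks(fa.segment_track_adhesions(movie, 3.0))
    noiseless_err = []
    for t in clean:
        fa.fit_phase_rates(t)
        if t.k_a is not None:
            noiseless_err.append(abs(t.k_a - k_a))
        if t.k_d is not None:
            noiseless_err.append(abs(t.k_d - k_d))

    movie, _ = generate_fa_movie(
        n_tracks, k_a=k_a, k_d=k_d, frame_interval_min=3.0, noise_sd=0.1,
        seed=seed + 1, image_size=1024,
    )
    tracks = fa.filter_tracks(fa.segment_track_adhesions(movie, 3.0))
    rel = []
    for t in tracks:
        fa.fit_phase_rates(t)
        if t.k_a is not None:
            rel.append(abs(t.k_a - k_a) / k_a)
        if t.k_d is not None:
            rel.append(abs(t.k_d - k_d) / k_d)
    return {
        "noiseless_max_abs_error": float(max(noiseless_err)),
        "snr10_median_rel_error": float(np.median(rel)),
        "n_tracks_snr10": int(len(tracks)),
    }


def bca_coverage(
    seed: int, n_rep: int = 500, n_per_group: int = 30, true_delta: float = 0.5,
    n_boot: int = 2000,
) -> dict:
    """Coverage of the 95% BCa interval for the true standardized difference."""
    rng = np.random.default_rng(seed)
    hits = 0
    for r in range(n_rep):
        a = rng.normal(0.0, 1.0, n_per_group)
        b = rng.normal(true_delta, 1.0, n_per_group)
        res = hedges_g_bootstrap(a, b, n_boot=n_boot, seed=int(rng.integers(2**31)))
        if res.ci_low <= true_delta <= res.ci_high:
            hits += 1
    return {"coverage": hits / n_rep, "n_replicates": n_rep, "n_per_group": n_per_group}


def fdr_type1_and_power(seed: int, n_seeds: int = 20) -> dict:
    """Null flag rate averaged over seeds; spike sensitivity at delta=1."""
    from .proteomics import permutation_fdr_ttest
    from .synthetic.abundance import generate_abundance_table

    rng = np.random.default_rng(seed)
    null_rates = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        table, meta, _ = generate_abundance_table(500, 0, 0.0, n_reps=3, noise_sd=0.2, seed=s)
        r = permutation_fdr_ttest(table, meta, seed=s)
        null_rates.append(r.table["significant"].mean())
    table, meta, truth = generate_abundance_table(1000, 50, 1.0, n_reps=3, noise_sd=0.2, seed=seed)
    r = permutation_fdr_ttest(table, meta, seed=seed)
    return {
        "null_mean_flag_rate": float(np.mean(null_rates)),
        "spike_sensitivity": float(r.table.loc[truth["spiked"], "significant"].mean()),
        "n_null_seeds": n_seeds,
    }


def pipeline_determinism(seed: int, base_dir) -> dict:
    """Run the small synthetic screen twice; compare output file bytes."""
    base = Path(base_dir)
    spec_args = dict(n_mock=8, cells_per_field=30, image_size=640)
    digests = []
    for run in ("run1", "run2"):
        out = base / run
        cfg = RunConfig(seed=seed, output_dir=str(out))
        run_pipeline(cfg, plate_spec=default_synthetic_screen(seed, **spec_args))
        d = {}
        for p in sorted(out.rglob("*")):
            if p.is_file():
                d[p.relative_to(out).as_posix()] = hashlib.sha256(p.read_bytes()).hexdigest()
        digests.append(d)
    identical = digests[0] == digests[1]
    return {"identical": bool(identical), "n_files": len(digests[0])}
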