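"""End-to-end orchestration of the synthetic screen analysis.

``run_pipeline`` executes the stages in dependency order::

    simulate -> segment -> classify -> score -> cluster

writing per-stage CSV/TIFF outputs plus a machine-readable JSON run
report (parameters, seeds, per-stage record counts).  Runs are
deterministic given a fixed config seed; a failed run still leaves a
report with its failure marker.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, features, imaging, io, scoring, shapes
from .config import RunConfig, module_seed
from .synthetic.plate import PlateSpec, WellSpec, SHAPE_CLASSES, generate_plate

STAGES = ("simulate", "segment", "classify", "score", "cluster")

# heterogeneous mock mixture (dominant triangular, as in basal-like lines)
MOCK_MIXTURE = (0.10, 0.05, 0.55, 0.05, 0.25)


def default_synthetic_screen(
    seed: int,
    n_mock: int = 8,
    cells_per_field: int = 36,
    image_size: int = 768,
) -> PlateSpec:
    """A compact synthetic screen: mock wells, five shape-enriched wells
    (training exemplars for the classifier and the normal filter), and
    perturbed wells with programmed ratio shifts."""
    wells: list[WellSpec] = []
    col = 3
    for i in range(n_mock):
        wells.append(
            WellSpec(
                well_id=f"mock{i:02d}", condition="mock", shape_mixture=MOCK_MIXTURE,
                cells_per_field=cells_per_field, fields_per_well=2,
                column=col + i % 8, is_mock=True,
            )
        )
    for k, cls in enumerate(SHAPE_CLASSES):
        mix = [0.0] * 5
        mix[k] = 1.0
        wells.append(
            WellSpec(
                well_id=f"enr_{cls}", condition=f"enrich_{cls}", shape_mixture=tuple(mix),
                cells_per_field=cells_per_field, fields_per_well=2, column=3 + k,
            )
        )
    for name, shift in (("siRatioDown", -0.45), ("siRatioUp", 0.45), ("siNull", 0.0)):
        for rep in range(2):
            wells.append(
                WellSpec(
                    well_id=f"{name}_r{rep}", condition=name, shape_mixture=MOCK_MIXTURE,
                    ratio_shift=shift, cells_per_field=cells_per_field,
                    fields_per_well=2, column=10 + rep,
                )
            )
    return PlateSpec(wells=wells, image_size=image_size, seed=seed)


def _layout_from_spec(spec: PlateSpec) -> scoring.ScreenLayout:
    rows = [
        {
            "well_id": w.well_id,
            "condition": w.condition,
            "plate": w.plate,
            "column": w.column,
            "is_mock": w.is_mock,
        }
        for w in spec.wells
    ]
    return scoring.ScreenLayout(wells=pd.DataFrame(rows).set_index("well_id"))


def _segment_screen(images, cfg: RunConfig, pixel_size: float) -> pd.DataFrame:
    """Segment every field and measure features + translocation ratio."""
    params = imaging.SegmentationParams(
        smoothing_sigma=cfg.segmentation.smoothing_sigma,
        min_nucleus_area=cfg.segmentation.min_nucleus_area,
        min_cell_area=cfg.segmentation.min_cell_area,
    )
    rows = []
    for well_id, fields_ in images.items():
        for f, chan in enumerate(fields_):
            cells = imaging.segment_cells(chan["dna"], chan["tubulin"], params)
            bg = {
                ch: imaging.estimate_background(img, [c.cell_mask for c in cells])
                for ch, img in chan.items()
            }
            texture = {ch: chan[ch] for ch in ("dna", "tubulin", "actin") if ch in chan}
            for c in cells:
                if c.is_border:
                    continue
                imaging.define_regions(
                    c, cfg.segmentation.ring_width_px, cfg.segmentation.band_width_px
                )
                ratio = (
                    imaging.measure_nc_ratio(chan["marker"], c, bg.get("marker", 0.0))
                    if "marker" in chan
                    else np.nan
                )
                feats = features.extract_features(c, texture, pixel_size=pixel_size, backgrounds=bg)
                row = {
                    "well_id": well_id,
                    "field": f,
                    "cell_id": c.cell_id,
                    "centroid_row": c.centroid[0],
                    "centroid_col": c.centroid[1],
                    "ratio": ratio,
                }
                row.update(feats)
                rows.append(row)
    return pd.DataFrame(rows)


def _match_truth(cell_table: pd.DataFrame, truth: pd.DataFrame, max_dist: float = 5.0) -> pd.Series:
    """True class per measured cell by nearest ground-truth centroid."""
    out = pd.Series(index=cell_table.index, dtype=object)
    for (well, fld), grp in cell_table.groupby(["well_id", "field"]):
        t = truth[(truth["well_id"] == well) & (truth["field"] == fld)]
        if t.empty:
            continue
        tc = t[["centroid_row", "centroid_col"]].to_numpy()
        for idx, row in grp.iterrows():
            d = np.hypot(tc[:, 0] - row["centroid_row"], tc[:, 1] - row["centroid_col"])
            j = int(np.argmin(d))
            if d[j] <= max_dist:
                out.loc[idx] = t.iloc[j]["shape_class"]
    return out


def run_pipeline(
    config: RunConfig,
    stages=STAGES,
    plate_spec: PlateSpec | None = None,
    write_images: bool = False,
) -> dict:
    """Run the requested stages on a synthetic screen; returns the report."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # the report sits inside output_dir; keeping the path out of the body
    # makes runs with identical seeds byte-identical wherever they land
    params = config.to_dict()
    params.pop("output_dir", None)
    report: dict = {
        "seed": config.seed,
        "parameters": params,
        "stages": {},
        "status": "running",
    }
    report_path = out_dir / "run_report.json"

    def _save_report():
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))

    try:
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        state: dict = {}

        if "simulate" in stages:
            spec = plate_spec or default_synthetic_screen(module_seed(config.seed, "simulate"))
            images, truth = generate_plate(spec)
            layout = _layout_from_spec(spec)
            io.write_table(truth, out_dir / "ground_truth.csv", index=False)
            io.write_layout_yaml(layout, out_dir / "layout.yaml")
            if write_images:
                for well_id, fields_ in images.items():
                    for f, chan in enumerate(fields_):
                        for ch, img in chan.items():
                            io.write_tiff(out_dir / "images" / f"{well_id}_f{f}_{ch}.tif", img)
            state.update(images=images, truth=truth, layout=layout, spec=spec)
            report["stages"]["simulate"] = {
                "wells": len(spec.wells),
                "cells_rendered": int(len(truth)),
            }

        if "segment" in stages:
            if "images" not in state:
                raise ValueError("stage 'segment' requires stage 'simulate' outputs")
            cell_table = _segment_screen(state["images"], config, state["spec"].pixel_size)
            io.write_table(cell_table, out_dir / "cell_table.csv", index=False)
            state["cell_table"] = cell_table
            report["stages"]["segment"] = {"cells_measured": int(len(cell_table))}

        if "classify" in stages:
            if "cell_table" not in state:
                raise ValueError("stage 'classify' requires stage 'segment' outputs")
            cell_table = state["cell_table"]
            truth = state["truth"]
            feat_cols = features.feature_registry()
            true_class = _match_truth(cell_table, truth)
            labelled = cell_table[true_class.notna()].copy()
            labelled["true_class"] = true_class[true_class.notna()]
            model = shapes.train_shape_classifier(
                labelled[feat_cols],
                labelled["true_class"],
                seed=module_seed(config.seed, "classifier"),
                min_exemplars=config.classifier.min_exemplars,
                C=config.classifier.l2_C,
                holdout_fraction=config.classifier.holdout_fraction,
            )
            (out_dir / "shape_model.json").write_text(model.to_json())
            predicted = shapes.classify_cells(model, cell_table[feat_cols])

            layout = state["layout"]
            mock_wells = set(layout.mock_wells)
            is_mock_cell = cell_table["well_id"].isin(mock_wells)
            enriched_mask = cell_table["well_id"].str.startswith("enr_")
            if is_mock_cell.any() and enriched_mask.any():
                normal_model = shapes.derive_normal_classifier(
                    cell_table.loc[is_mock_cell, feat_cols].reset_index(drop=True),
                    cell_table.loc[enriched_mask, feat_cols].reset_index(drop=True),
                    seed=module_seed(config.seed, "normal"),
                    box_population=config.classifier.normal_box_population,
                )
                (out_dir / "normal_model.json").write_text(normal_model.to_json())
                is_normal = normal_model.predict_normal(cell_table[feat_cols])
            else:
                is_normal = np.zeros(len(cell_table), dtype=bool)
            cell_table = cell_table.copy()
            cell_table["shape_class"] = np.where(is_normal, "normal", predicted)
            io.write_table(cell_table, out_dir / "classified_cells.csv", index=False)
            state["cell_table"] = cell_table
            report["stages"]["classify"] = {
                "holdout_accuracy": model.holdout_accuracy,
                "n_normal": int(is_normal.sum()),
            }

        if "score" in stages:
            if "cell_table" not in state or "shape_class" not in state["cell_table"]:
                raise ValueError("stage 'score' requires stage 'classify' outputs")
            wells = scoring.summarize_wells(
                state["cell_table"], state["layout"], min_cells=config.scoring.min_cells_per_well
            )
            z = scoring.zscore_vs_mock(
                wells,
                plate_normalize=config.scoring.plate_normalize,
                min_mock_wells=config.scoring.min_mock_wells,
            )
            hits = scoring.call_hits(
                z,
                yap_threshold=config.scoring.yap_z_threshold,
                normal_threshold=config.scoring.normal_z_threshold,
            )
            qms = scoring.assemble_qms(z)
            io.write_table(wells, out_dir / "well_summary.csv")
            io.write_table(hits, out_dir / "well_hits.csv")
            io.write_table(qms, out_dir / "qms.csv")
            state.update(wells=wells, zscores=z, qms=qms, hits=hits)
            report["stages"]["score"] = {
                "wells": int(len(wells)),
                "conditions": int(qms.shape[0]),
                "yap_low_wells": int(hits["yap_low"].sum()),
                "yap_high_wells": int(hits["yap_high"].sum()),
            }

        if "cluster" in stages:
            if "qms" not in state:
                qms_path = out_dir / "qms.csv"
                if not qms_path.exists():
                    raise ValueError("stage 'cluster' requires a QMS table (run 'score' first)")
                state["qms"] = io.read_table(qms_path)
            metrics = [c for c in state["qms"].columns if c.startswith("frac_")]
            dend = clustering.hierarchical_cluster(
                state["qms"][metrics], linkage_method=config.clustering.linkage
            )
            clusters = clustering.cut_phenoclusters(dend, config.clustering.pcc_threshold)
            io.write_table(clustering.assignments_frame(clusters), out_dir / "phenoclusters.csv", index=False)
            (out_dir / "dendrogram.nwk").write_text(clustering.to_newick(dend))
            report["stages"]["cluster"] = {
                "n_clusters": len(clusters),
                "n_multigene": sum(1 for c in clusters if len(c.members) > 1),
            }

        report["status"] = "ok"
    except Exception as e:
        report["status"] = "failed"
        report["error"] = f"{type(e).__name__}: {e}"
        _save_report()
        raise
    _save_report()
    return report
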