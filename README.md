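# morphoscreen

Analysis pipeline for multiplexed high-content RNAi screens that link
perturbations of Rho-family regulators (RhoGEFs/RhoGAPs, Rho GTPases) to
single-cell shape changes and YAP/TAZ nuclear translocation in breast
cancer cell lines — together with the downstream assays such screens are
paired with: 3D collagen invasion, wound-healing polarity, focal-adhesion
(FA) dynamics with estimation statistics, and permutation-FDR differential
proteomics.

It is written for image-analysis and screening groups who want the full
statistical chain — segmentation → features → shape classification →
well-level Z-scores → hit calling → phenotype clustering — as tested,
scriptable Python rather than vendor software. A synthetic-data module
generates every input (plates, movies, z-stacks, abundance tables) with
known ground truth, so the whole pipeline is verifiable without any
external download.

## The statistics at the core

* **YAP/TAZ translocation ratio** per cell:
  `log10(mean nuclear intensity / mean perinuclear-ring intensity)`,
  background-subtracted; ring = 4-px dilation of the nucleus clipped to
  the cell.
* **QMS (quantitative morphological signature)** per condition: the
  vector of mock-referenced Z-scores of per-well shape-class percentages,
  `Z = (value − mean_mock) / sd_mock`, computed per screen after
  per-plate normalization. Cells are assigned to five reference shapes
  (spindly, large round, triangular, fan, small round) by a regularized
  linear classifier over ≥30 morphology/texture features; a PCA-derived
  "normal" filter (1-SD box in PC1/PC2) measures penetrance.
* **Hit calling**: |Z| ≥ 1.5 on the translocation ratio (sign gives
  direction); normal-fraction Z ≤ −1 marks a shape hit.
* **Phenoclusters**: average-linkage agglomeration on distance
  `1 − uncentered Pearson correlation`; clusters are maximal subtrees
  whose root merge similarity exceeds 0.73.
* **Invasion index**: cells detected above the bottom plane divided by
  cells in all planes of a z-stack (planes 30 µm apart), with dual
  nuclear+GFP intensity filtering of detections.
* **FA dynamics**: adhesions tracked by mask overlap; assembly and
  disassembly rates are least-squares slopes of ln(intensity) over the
  birth→peak and peak→death phases (1/min); tracks kept when present ≥5
  frames with mean axial ratio <3. Group comparisons use unpaired
  Hedges' *g* = `(mean_b − mean_a)/s_pooled × (1 − 3/(4N−9))` with a BCa
  bootstrap 95% CI and two-sided Mann–Whitney tests; |g| bins:
  0.2–0.5 small, 0.5–0.8 medium, 0.8–1.2 large, 1.2–2.0 very large.
* **Differential proteomics**: within-cell-line scaling, per-protein
  log2 ratios, SAM-style moderated t with label-permutation FDR;
  significant = |log2| > 0.5 and permutation FDR < 0.05.

## Worked example

```python
import pandas as pd
from morphoscreen import scoring

# per-well Z-scores of the YAP/TAZ ratio for one siRNA's four replicate
# wells (the DOCK5 siGENOME pool of the original screen)
z = pd.DataFrame(
    {"condition": ["siDOCK5"] * 4,
     "median_ratio": [-1.73, -2.33, -2.77, -0.79],
     "excluded": [False] * 4},
    index=["rep1", "rep2", "rep3", "rep4"],
)
print(scoring.call_hits(z)[["median_ratio", "yap_low", "yap_high"]])
```

prints

```
      median_ratio  yap_low  yap_high
rep1         -1.73     True     False
rep2         -2.33     True     False
rep3         -2.77     True     False
rep4         -0.79    False     False
```

i.e. three of four replicate wells cross the −1.5 activator threshold —
the well pattern of a reproducible low-YAP/TAZ-ratio hit.

An end-to-end synthetic screen (render → segment → classify → score →
cluster) runs with:

```bash
morphoscreen run-all --seed 7 --out screen_out
```

and reports per-stage counts (cells rendered/measured, classifier
hold-out accuracy, hit wells, phenocluster count) as JSON.

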