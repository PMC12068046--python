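"""Differential protein abundance with permutation-based FDR control.

The pipeline starts from a proteins x samples abundance table (arbitrary
positive units) with sample metadata assigning each column a cell line and
a condition (mock vs perturbed):

1. within-cell-line scaling: per-sample median normalization on the log2
   scale, then per-protein centring within the cell line;
2. per-protein log2 ratio = mean log2(perturbed) - mean log2(mock);
3. a two-sample Welch t statistic moderated by an additive fuzz ``s0``
   (SAM-style), with the null built from label permutations; the q-value
   of a protein is the median permuted exceedance count divided by the
   observed exceedance count at its |t|, monotonized;
4. significance = |log2 ratio| > 0.5 (strict) AND q < 0.05.

Benjamini-Hochberg on permutation p-values is available as an alternative
FDR method.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "scale_within_cellline",
    "log2_ratio",
    "permutation_fdr_ttest",
    "select_significant",
    "DifferentialResult",
]

LOG2_CUT = 0.5
ALPHA_DEFAULT = 0.05


@dataclass
class DifferentialResult:
    """Per-protein differential statistics (one table per comparison)."""

    table: pd.DataFrame  # index = protein; log2_ratio, t, q_value, significant, direction
    n_perm_used: int
    method: str


def _check_meta(meta: pd.DataFrame) -> None:
    required = {"cell_line", "condition"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata needs columns {sorted(required)}")
    bad = set(meta["condition"]) - {"mock", "perturbed"}
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected mock/perturbed")


def scale_within_cellline(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Scale abundances within each cell line; returns log2-scale values.

    Per cell line: each sample is shifted so its median log2 abundance is
    zero (median normalization), then each protein is centred on its
    within-cell-line mean.  Requires >= 2 samples per cell line.
    """
    _check_meta(meta)
    if (table.values <= 0).any():
        raise ValueError("abundances must be strictly positive before log transform")
    log2 = np.log2(table.astype(float))
    out = log2.copy()
    for line, cols in meta.groupby("cell_line").groups.items():
        cols = list(cols)
        if len(cols) < 2:
            raise ValueError(f"cell line {line!r} has a single sample; cannot scale")
        block = log2[cols]
        block = block - block.median(axis=0)
        block = block.sub(block.mean(axis=1), axis=0)
        out[cols] = block
    return out


def log2_ratio(table: pd.DataFrame, meta: pd.DataFrame, already_log2: bool = False) -> pd.Series:
    """Per-protein mean log2(perturbed) - mean log2(mock), pooled over cell lines."""
    _check_meta(meta)
    vals = table.astype(float) if already_log2 else np.log2(table.astype(float))
    mock_cols = meta.index[meta["condition"] == "mock"]
    pert_cols = meta.index[meta["condition"] == "perturbed"]
    if len(mock_cols) == 0 or len(pert_cols) == 0:
        raise ValueError("both mock and perturbed samples are required")
    return vals[pert_cols].mean(axis=1) - vals[mock_cols].mean(axis=1)


def _welch_t(x: np.ndarray, labels: np.ndarray, s0: float) -> np.ndarray:
    """Moderated Welch t per row; labels is a boolean perturbed mask."""
    a = x[:, ~labels]
    b = x[:, labels]
    na, nb = a.shape[1], b.shape[1]
    se = np.sqrt(a.var(axis=1, ddof=1) / na + b.var(axis=1, ddof=1) / nb)
    return (b.mean(axis=1) - a.mean(axis=1)) / (se + s0)


def _distinct_label_permutations(labels: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Permuted perturbed-masks: exhaustive when few, else random draws."""
    n = labels.size
    k = int(labels.sum())
    from math import comb

    total = comb(n, k)
    if total <= n_perm:
        perms = []
        for idx in combinations(range(n), k):
            m = np.zeros(n, dtype=bool)
            m[list(idx)] = True
            perms.append(m)
        return perms, total
    perms = []
    for _ in range(n_perm):
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=k, replace=False)] = True
        perms.append(m)
    return perms, total


def permutation_fdr_ttest(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    n_perm: int = 1000,
    s0: float = 0.1,
    seed: int = 0,
    alpha: float = ALPHA_DEFAULT,
    log2_cut: float = LOG2_CUT,
    already_log2: bool = False,
    method: str = "sam",
) -> DifferentialResult:
    """Permutation-FDR differential test (perturbed vs mock).

    Parameters
    ----------
    method
        ``"sam"`` (default): q = median permuted exceedance / observed
        exceedance at each protein's |t|, monotonized.  ``"bh"``:
        Benjamini-Hochberg on p-values from the permutation null pooled
        across proteins.
    """
    _check_meta(meta)
    x = (table.astype(float) if already_log2 else np.log2(table.astype(float))).to_numpy()
    labels = (meta["condition"] == "perturbed").to_numpy()
    na, nb = int((~labels).sum()), int(labels.sum())
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(seed)
    perms, total = _distinct_label_permutations(labels, n_perm, rng)
    if total < 10:
        raise ValueError(f"only {total} distinct label permutations; need >= 10")

    t_obs = _welch_t(x, labels, s0)
    abs_obs = np.abs(t_obs)
    t_perm = np.abs(np.stack([_welch_t(x, m, s0) for m in perms]))  # (P, proteins)

    order = np.argsort(-abs_obs, kind="stable")
    thresholds = abs_obs[order]
    # observed exceedance at each protein's threshold is its rank (ties share
    # the count of values >= threshold)
    obs_count = np.searchsorted(-np.sort(-abs_obs), -thresholds, side="right")

    if method == "sam":
        sorted_perm = np.sort(t_perm.reshape(t_perm.shape[0], -1), axis=1)
        # per-permutation count of |t_perm| >= threshold, then median over perms
        exceed = t_perm.shape[1] * np.ones((len(perms), len(thresholds)))
        for p in range(len(perms)):
            exceed[p] = t_perm.shape[1] - np.searchsorted(sorted_perm[p], thresholds, side="left")
        med = np.median(exceed, axis=0)
        q_sorted = med / np.maximum(obs_count, 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]  # monotone in |t|
        q_sorted = np.clip(q_sorted, 0.0, 1.0)
        q = np.empty_like(q_sorted)
        q[order] = q_sorted
    elif method == "bh":
        from statsmodels.stats.multitest import multipletests

        # permutation null pooled across proteins for fine-grained p-values
        null = np.sort(t_perm.ravel())
        pvals = (1.0 + (null.size - np.searchsorted(null, abs_obs, side="left"))) / (
            1.0 + null.size
        )
        q = multipletests(pvals, method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown FDR method {method!r}")

    ratios = log2_ratio(table, meta, already_log2=already_log2)
    sig = (np.abs(ratios.to_numpy()) > log2_cut) & (q < alpha)
    direction = np.where(ratios.to_numpy() > 0, "up", "down")
    res = pd.DataFrame(
        {
            "log2_ratio": ratios.to_numpy(),
            "t": t_obs,
            "q_value": q,
            "significant": sig,
            "direction": np.where(sig, direction, "ns"),
        },
        index=table.index,
    )
    return DifferentialResult(table=res, n_perm_used=len(perms), method=method)


def select_significant(result: DifferentialResult, log2_cut: float = LOG2_CUT, alpha: float = ALPHA_DEFAULT):
    """Split a differential result into up- and down-regulated protein sets.

    Both cuts are strict on the ratio (log2 == 0.5 is not selected) and
    strict on the q-value (< alpha).
    """
    t = result.table
    up = t.index[(t["log2_ratio"] > log2_cut) & (t["q_value"] < alpha)].tolist()
    down = t.index[(t["log2_ratio"] < -log2_cut) & (t["q_value"] < alpha)].tolist()
    return up, down
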