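"""Regulon definition by joint expression / binding criteria, plus
length-bias-corrected functional-category enrichment.

A gene belongs to the regulon iff all four hold:

* fold change  > threshold (strict; default 2-fold, i.e. log2FC > 1),
* adjusted p-value < alpha (default 0.05),
* ChIP occupancy >= threshold in the control condition (inclusive; default 2),
* ChIP occupancy >= threshold in the shock condition,

mirroring the finding that binding is copper-independent: occupancy must
clear the bar under both conditions.

Category enrichment corrects for gene-length selection bias by weighted
resampling: genes are drawn without replacement with probability
proportional to a binned length-based selection propensity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._utils import sub_rng
from .dge import bh_adjust

__all__ = ["select_regulon", "category_enrichment"]


def select_regulon(
    dge: pd.DataFrame,
    occupancy: pd.DataFrame,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    occ_threshold: float = 2.0,
    occ_columns: tuple[str, str] = ("occ_control", "occ_copper_shock"),
) -> pd.DataFrame:
    """Apply the conjunction of expression and binding criteria per gene.

    ``dge`` must carry log2FoldChange and padj (indexed by gene_id);
    ``occupancy`` the two per-condition occupancy columns. Genes missing
    occupancy values are never selected and flagged. Returns one row per
    gene in the dge table with a boolean ``selected`` and the list of
    failed criteria in ``reasons``.
    """
    if len(dge) == 0:
        raise ValueError("empty gene universe")
    missing = [c for c in occ_columns if c not in occupancy.columns]
    if missing:
        raise ValueError(f"occupancy table lacks columns {missing}")
    occ = occupancy[list(occ_columns)].reindex(dge.index)
    log2_thr = np.log2(fc_threshold)
    rows = []
    for gid in dge.index:
        lfc = float(dge.at[gid, "log2FoldChange"])
        padj = float(dge.at[gid, "padj"])
        occ_c = occ.at[gid, occ_columns[0]]
        occ_s = occ.at[gid, occ_columns[1]]
        reasons = []
        if not lfc > log2_thr:  # strict: FC exactly at threshold fails
            reasons.append("fold-change")
        if not padj < alpha:
            reasons.append("padj")
        if pd.isna(occ_c) or pd.isna(occ_s):
            reasons.append("missing-occupancy")
        else:
            if not occ_c >= occ_threshold:  # inclusive: occupancy at threshold passes
                reasons.append("occupancy-control")
            if not occ_s >= occ_threshold:
                reasons.append("occupancy-shock")
        rows.append(
            {
                "gene_id": gid,
                "log2FoldChange": lfc,
                "padj": padj,
                "occ_control": occ_c,
                "occ_shock": occ_s,
                "selected": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def _weighted_sample_without_replacement(
    rng: np.random.Generator, weights: np.ndarray, k: int, n_draws: int
) -> np.ndarray:
    """(n_draws, k) index matrix of weighted draws without replacement.

    Uses the Gumbel top-k trick, equivalent to sequential sampling with
    probability proportional to the remaining weights.
    """
    logw = np.log(weights)
    keys = logw[None, :] + rng.gumbel(size=(n_draws, weights.size))
    return np.argpartition(-keys, k - 1, axis=1)[:, :k]


def category_enrichment(
    selected: set[str],
    table: pd.DataFrame,
    n_resample: int = 10_000,
    seed: int = 0,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Per-category enrichment p-values with gene-length bias correction.

    ``table`` has one row per gene in the universe with columns ``category``
    and ``length``. The null draws |selected| genes without replacement with
    probability proportional to a length-based selection propensity: genes
    are split into ``n_bins`` equal-occupancy length bins and each bin's
    propensity is its observed selected fraction (floored at 1/(2N)).
    p = (1 + #{resamples >= observed}) / (1 + n_resample), one-sided for
    enrichment, BH-adjusted across categories.
    """
    if n_resample < 1000:
        raise ValueError("n_resample must be >= 1000")
    table = table.copy()
    if not {"category", "length"} <= set(table.columns):
        raise ValueError("table needs 'category' and 'length' columns")
    table["category"] = table["category"].fillna("unassigned")
    unknown = set(selected) - set(table.index)
    if unknown:
        warnings.warn(f"{len(unknown)} selected genes absent from the category table; ignored")
        selected = set(selected) & set(table.index)
    N = len(table)
    k = len(selected)
    if k == 0:
        raise ValueError("no selected genes in the universe")
    is_sel = table.index.isin(selected)
    # equal-occupancy bins on the length values; tied lengths share a bin so
    # the no-bias limit (all lengths equal) collapses to uniform propensity
    bins = pd.qcut(table["length"], q=min(n_bins, N), labels=False, duplicates="drop")
    bins = bins.fillna(0).to_numpy()
    prop = pd.Series(is_sel, index=table.index).groupby(bins).mean()
    weights = np.maximum(prop.reindex(bins).to_numpy(), 1.0 / (2 * N))

    categories = pd.unique(table["category"])
    cat_codes = pd.Categorical(table["category"], categories=categories).codes
    observed = np.bincount(cat_codes[is_sel], minlength=len(categories))

    rng = sub_rng(seed, "category-enrichment")
    null_counts = np.zeros((n_resample, len(categories)), dtype=np.int32)
    chunk = 1000
    for start in range(0, n_resample, chunk):
        m = min(chunk, n_resample - start)
        idx = _weighted_sample_without_replacement(rng, weights, k, m)
        drawn = cat_codes[idx]  # (m, k)
        for c in range(len(categories)):
            null_counts[start:start + m, c] = (drawn == c).sum(axis=1)

    geq = (null_counts >= observed[None, :]).sum(axis=0)
    pvals = (1.0 + geq) / (1.0 + n_resample)
    expected = null_counts.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expected > 0, observed / expected, np.inf)
    out = pd.DataFrame(
        {
            "category": categories,
            "observed": observed,
            "expected": expected,
            "enrichment_ratio": ratio,
            "pvalue": pvals,
        }
    ).set_index("category")
    out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out
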