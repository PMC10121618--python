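"""Multi-omics integration: LFQ normalisation, fold-change filters, Venn sets.

Implements the downstream integration of RBP target lists with knockout
transcriptome and proteome profiling: total-intensity normalisation of raw
label-free protein intensities, per-gene log2 fold changes with a one-sided
rank test, differential-expression filters with inclusive fold-change and
strict FDR boundaries, Venn region counting over 2-3 gene sets, and the
edit-count vs expression rank correlation.
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_protein_matrix",
    "protein_log2fc_test",
    "filter_de",
    "venn_counts",
    "edits_vs_expression_correlation",
]


def normalize_protein_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so all column totals equal the mean input total.

    Within-sample proportions are unchanged; the operation is homogeneous
    (scaling all inputs by c scales all outputs by c).
    """
    m = matrix.astype(float)
    if (m.to_numpy() < 0).any():
        raise ValueError("intensities must be non-negative")
    totals = m.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    target = totals.mean()
    return m * (target / totals)


def protein_log2fc_test(
    matrix: pd.DataFrame,
    groups: dict[str, str],
    treat: str = "KO",
    control: str = "WT",
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-gene log2 fold change and one-sided rank test on a normalised matrix.

    log2fc = log2((mean treat + eps) / (mean control + eps)) with eps
    defaulting to half the smallest nonzero intensity in the matrix. The
    one-sided Wilcoxon rank-sum p-value is taken in the direction of the
    observed fold change (exact for small groups, no ties assumed);
    BH FDR across genes. Genes with all-zero intensities in both groups are
    dropped (counted in a log message).
    """
    t_cols = [s for s, g in groups.items() if g == treat]
    c_cols = [s for s, g in groups.items() if g == control]
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError("both groups need at least 2 samples")
    X = matrix[t_cols].to_numpy(dtype=float)
    Y = matrix[c_cols].to_numpy(dtype=float)
    all_zero = (X.sum(axis=1) == 0) & (Y.sum(axis=1) == 0)
    n_dropped = int(all_zero.sum())
    if n_dropped:
        logger.info("dropped %d genes with all-zero intensities", n_dropped)
    X, Y = X[~all_zero], Y[~all_zero]
    genes = matrix.index[~all_zero]
    nz = matrix.to_numpy(dtype=float)
    nz = nz[nz > 0]
    eps = pseudocount if pseudocount is not None else (nz.min() / 2 if nz.size else 1.0)
    log2fc = np.log2((X.mean(axis=1) + eps) / (Y.mean(axis=1) + eps))
    p = np.empty(len(genes))
    for i in range(len(genes)):
        alternative = "greater" if log2fc[i] >= 0 else "less"
        if np.all(X[i] == X[i][0]) and np.all(Y[i] == Y[i][0]) and X[i][0] == Y[i][0]:
            p[i] = 1.0
            continue
        p[i] = stats.mannwhitneyu(
            X[i], Y[i], alternative=alternative, method="exact"
        ).pvalue
    out = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "p_value": p, "layer": "protein"}
    )
    out["fdr"] = benjamini_hochberg(p)
    return out.reset_index(drop=True)


def filter_de(
    table: pd.DataFrame, fdr_max: float, fc_min: float, direction: str
) -> set[str]:
    """Genes passing the differential-expression filter.

    ``down``: log2fc <= -log2(fc_min); ``up``: log2fc >= log2(fc_min); both
    require fdr < fdr_max. Fold-change boundaries are inclusive, the FDR
    boundary strict.
    """
    if fdr_max <= 0 or fc_min <= 0:
        raise ValueError("thresholds must be positive")
    lfc = np.log2(fc_min)
    if direction == "down":
        mask = table["log2fc"] <= -lfc
    elif direction == "up":
        mask = table["log2fc"] >= lfc
    else:
        raise ValueError(f"unknown direction {direction!r}; use 'up' or 'down'")
    mask &= table["fdr"] < fdr_max
    return set(table.loc[mask, "gene"].astype(str))


def venn_counts(sets: dict[str, set]) -> tuple[pd.DataFrame, dict[str, set]]:
    """Venn region counts and member lists for 2 or 3 named gene sets.

    Regions are keyed by membership pattern, e.g. "A&B" (in A and B, not in
    any other set). The regions containing a set partition it exactly.
    """
    names = list(sets.keys())
    if len(names) not in (2, 3):
        raise ValueError("venn_counts takes 2 or 3 sets")
    clean = {n: {str(g) for g in s} for n, s in sets.items()}
    universe = set().union(*clean.values())
    regions: dict[str, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(clean[n] for n in combo))
            outside = set().union(*(clean[n] for n in names if n not in combo), set())
            regions["&".join(combo)] = inside - outside
    table = pd.DataFrame(
        {"region": list(regions.keys()), "count": [len(v) for v in regions.values()]}
    )
    assert sum(len(v) for v in regions.values()) == len(universe)
    return table, regions


def edits_vs_expression_correlation(
    gene_site_counts: pd.DataFrame, expression: pd.DataFrame, value_col: str = "log2fc"
) -> dict:
    """Spearman correlation of per-gene edit-site counts vs expression.

    Returns rho, p and n; an all-constant vector yields rho = NaN with an
    explanatory note rather than an error.
    """
    merged = gene_site_counts[["gene", "n_edit_sites"]].merge(
        expression[["gene", value_col]], on="gene", how="inner"
    )
    n = len(merged)
    if n < 10:
        raise ValueError(f"need >= 10 genes in common; got {n}")
    x = merged["n_edit_sites"].to_numpy(dtype=float)
    y = merged[value_col].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p_value": float("nan"), "n": n,
                "note": "constant input vector; correlation undefined"}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p), "n": n}
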