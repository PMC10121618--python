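"""Paired-daughter-cell division classification and polarity scoring.

Classification rules (all ratio-based, hence invariant to intensity
rescaling):

* NUMB pairs: at least a 2-fold intensity difference between daughters
  (ratio >= 2, boundary inclusive) -> asymmetric; otherwise symmetric, split
  into commitment (high mean intensity) vs renewal (low mean intensity) by a
  per-replicate high/low threshold.
* LAMP1 / TMI pairs: |log2(i1/i2)| >= 0.6 (inclusive) -> asymmetric; the
  symmetric remainder splits into symmetric-high vs symmetric-low by mean
  intensity.
* Tubulin polarity on split cells: |log2(h1/h2)| > 0.6 (strict) -> polar.

The high/low threshold is set per experimental replicate; when not supplied
it defaults to the replicate's median pair-mean intensity.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .stats import fisher_exact_two_sided

__all__ = [
    "classify_numb_pairs",
    "classify_log2fc_pairs",
    "score_polarity_cells",
    "cosegregation_table",
    "summarize_divisions",
]

NUMB_CLASSES = ("sym_renewal", "sym_commitment", "asymmetric")
LOG2FC_CLASSES = ("sym_low", "sym_high", "asymmetric")

# relative tolerance for threshold comparisons: a computed ratio within one
# part in 1e12 of the boundary is treated as exactly at the boundary, so the
# inclusive (pairs) vs strict (polarity) semantics survive float round-off
_REL_EPS = 1e-12


def _ge(x, thr):
    return np.asarray(x) >= thr * (1 - _REL_EPS)


def _gt(x, thr):
    return np.asarray(x) > thr * (1 + _REL_EPS)


def _check_positive(df: pd.DataFrame, cols) -> None:
    for c in cols:
        if (df[c] <= 0).any():
            raise ValueError(f"non-positive intensity in column {c!r}")


def _resolve_thresholds(df: pd.DataFrame, high_threshold) -> pd.Series:
    """Per-row high/low threshold: a number, or per-replicate median of pair means."""
    if high_threshold is not None and not isinstance(high_threshold, str):
        return pd.Series(float(high_threshold), index=df.index)
    means = (df["i1"] + df["i2"]) / 2
    if "replicate" in df.columns:
        return means.groupby(df["replicate"]).transform("median")
    return pd.Series(means.median(), index=df.index)


def classify_numb_pairs(pairs: pd.DataFrame, high_threshold=None) -> pd.DataFrame:
    """Score NUMB daughter pairs.

    Ratio max/min >= 2 (inclusive) -> ``asymmetric``; otherwise
    ``sym_commitment`` when the pair's mean intensity reaches the high
    threshold, else ``sym_renewal``.
    """
    _check_positive(pairs, ["i1", "i2"])
    out = pairs.copy()
    thr = _resolve_thresholds(out, high_threshold)
    ratio = np.maximum(out["i1"], out["i2"]) / np.minimum(out["i1"], out["i2"])
    mean = (out["i1"] + out["i2"]) / 2
    out["ratio"] = ratio
    out["class"] = np.where(
        _ge(ratio, 2.0),
        "asymmetric",
        np.where(mean >= thr, "sym_commitment", "sym_renewal"),
    )
    return out


def classify_log2fc_pairs(
    pairs: pd.DataFrame,
    log2fc_threshold: float = 0.6,
    high_threshold=None,
    intensity_cols: tuple[str, str] = ("i1", "i2"),
    out_col: str = "class",
) -> pd.DataFrame:
    """Score LAMP1/TMI-style daughter pairs by absolute log2 ratio.

    |log2(i1/i2)| >= ``log2fc_threshold`` (inclusive) -> ``asymmetric``;
    symmetric pairs split into ``sym_high``/``sym_low`` by mean intensity vs
    the high threshold.
    """
    a, b = intensity_cols
    _check_positive(pairs, [a, b])
    out = pairs.copy()
    if high_threshold is None or isinstance(high_threshold, str):
        tmp = out.rename(columns={a: "i1", b: "i2"}) if (a, b) != ("i1", "i2") else out
        thr = _resolve_thresholds(tmp, None)
    else:
        thr = pd.Series(float(high_threshold), index=out.index)
    lfc = np.abs(np.log2(out[a] / out[b]))
    mean = (out[a] + out[b]) / 2
    out[out_col] = np.where(
        _ge(lfc, log2fc_threshold),
        "asymmetric",
        np.where(mean >= thr, "sym_high", "sym_low"),
    )
    return out


def score_polarity_cells(cells: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Score split cells as polar when |log2(h1/h2)| > ``threshold`` (strict)."""
    _check_positive(cells, ["h1", "h2"])
    out = cells.copy()
    lfc = np.abs(np.log2(out["h1"] / out["h2"]))
    out["log2fc"] = lfc
    out["polar"] = _gt(lfc, threshold)
    return out


def cosegregation_table(
    pairs: pd.DataFrame,
    class1_col: str = "class_m1",
    class2_col: str = "class_m2",
) -> dict:
    """Co-segregation analysis of two markers classified on the same pairs.

    Returns the full class-by-class contingency table, the high-side
    concordance among doubly-asymmetric pairs (fraction where the same
    daughter is high for both markers; NaN when no such pair exists), and a
    Fisher exact p-value for the asymmetric/asymmetric association on the
    2x2 collapse.
    """
    table = pd.crosstab(pairs[class1_col], pairs[class2_col])
    a1 = pairs[class1_col] == "asymmetric"
    a2 = pairs[class2_col] == "asymmetric"
    both = pairs[a1 & a2]
    if len(both):
        concordance = float(
            np.mean((both["i1"] > both["i2"]) == (both["j1"] > both["j2"]))
        )
    else:
        concordance = float("nan")
    p = fisher_exact_two_sided(
        int((a1 & a2).sum()), int((a1 & ~a2).sum()),
        int((~a1 & a2).sum()), int((~a1 & ~a2).sum()),
    )
    return {
        "contingency": table,
        "n_doubly_asymmetric": int(len(both)),
        "concordance": concordance,
        "fisher_p": p,
    }


def summarize_divisions(
    classified: pd.DataFrame,
    class_col: str = "class",
    categories=None,
) -> dict:
    """Per-genotype category fractions with replicate-level statistics.

    Fractions are computed per replicate and averaged (mean +/- sem) per
    genotype; with exactly two genotypes and >= 2 replicates each, each
    category's replicate-level fractions are compared by a two-tailed
    two-sample t-test. With a single replicate the tests are skipped and a
    notice recorded.
    """
    df = classified.copy()
    if "replicate" not in df.columns:
        df["replicate"] = 1
    if categories is None:
        categories = sorted(df[class_col].unique())
    frac = (
        df.groupby(["genotype", "replicate"])[class_col]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=categories, fill_value=0.0)
    )
    per_genotype = frac.groupby("genotype").agg(["mean", "sem", "count"])
    n_pairs = df.groupby("genotype").size().rename("n_pairs")
    genotypes = sorted(df["genotype"].unique())
    tests = None
    notice = None
    reps_per_gt = frac.reset_index().groupby("genotype").size()
    if len(genotypes) == 2 and (reps_per_gt >= 2).all():
        rows = []
        for cat in categories:
            x = frac.loc[genotypes[0]][cat]
            y = frac.loc[genotypes[1]][cat]
            t, p = stats.ttest_ind(x, y)
            rows.append((cat, float(t), float(p)))
        tests = pd.DataFrame(rows, columns=["category", "t_stat", "p_value"])
    else:
        notice = "tests skipped: need exactly 2 genotypes with >= 2 replicates each"
    return {
        "fractions_by_replicate": frac,
        "summary": per_genotype,
        "n_pairs": n_pairs,
        "tests": tests,
        "notice": notice,
    }
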