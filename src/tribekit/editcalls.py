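"""Differential RNA-editing calling from per-site read counts.

An ADAR-fusion (HyperTRIBE) experiment marks transcripts bound by the fused
RBP with A-to-I edits, read out as A->G mismatches. Given per-site reference/
alternate read counts for fusion ("S_ADAR") and empty-vector ("EV")
replicates, this module:

1. computes per-sample editing frequencies alt/(ref+alt) and unweighted
   per-condition means;
2. tests each sufficiently covered site for differential editing, by default
   with a two-sided Fisher exact test on replicate-pooled counts
   (``fisher_pooled``), optionally with a beta-binomial likelihood-ratio
   test that keeps replicates separate (``betabinom_lrt``);
3. applies Benjamini-Hochberg FDR across all tested sites of a dataset and
   calls sites with q < alpha and differential frequency delta_f > min_delta
   (defaults 0.05 and 0.1);
4. annotates calls with their genic region (5'UTR/CDS/3'UTR) and collapses
   them to gene-level target summaries.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .stats import benjamini_hochberg, fisher_exact_many

logger = logging.getLogger(__name__)

__all__ = [
    "sample_names",
    "split_conditions",
    "compute_site_frequencies",
    "test_site",
    "call_edits",
    "apply_call_thresholds",
    "annotate_sites",
    "summarize_targets",
    "compare_target_sets",
]

DEFAULT_CONDITIONS = ("S_ADAR", "EV")
_REGION_PRIORITY = {"3UTR": 0, "CDS": 1, "5UTR": 2}


def sample_names(counts: pd.DataFrame) -> list[str]:
    """Sample names derived from paired ref_/alt_ column headers."""
    refs = [c[4:] for c in counts.columns if c.startswith("ref_")]
    alts = {c[4:] for c in counts.columns if c.startswith("alt_")}
    missing = [s for s in refs if s not in alts]
    if missing or not refs:
        raise ValueError(f"counts table must carry paired ref_/alt_ columns; bad: {missing}")
    return refs


def split_conditions(
    samples: list[str], conditions: tuple[str, str] = DEFAULT_CONDITIONS
) -> dict[str, list[str]]:
    """Group sample names by condition prefix (``<condition>_<replicate>``)."""
    out: dict[str, list[str]] = {c: [] for c in conditions}
    for s in samples:
        for c in conditions:
            if s == c or s.startswith(c + "_"):
                out[c].append(s)
                break
        else:
            raise ValueError(f"sample {s!r} matches no condition in {conditions}")
    for c, ss in out.items():
        if not ss:
            raise ValueError(f"no samples for condition {c!r}")
    return out


def compute_site_frequencies(
    counts: pd.DataFrame, conditions: tuple[str, str] = DEFAULT_CONDITIONS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample editing frequencies and per-condition unweighted means.

    Returns ``(freqs, summary)``. Samples with zero depth at a site do not
    contribute to that site's condition mean; a site with zero depth across
    an entire condition is flagged ``testable == False``. The condition mean
    is the unweighted mean of per-sample frequencies (each replicate counts
    equally regardless of depth).
    """
    samples = sample_names(counts)
    by_cond = split_conditions(samples, conditions)
    ref = counts[[f"ref_{s}" for s in samples]].to_numpy()
    alt = counts[[f"alt_{s}" for s in samples]].to_numpy()
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("read counts must be non-negative")
    depth = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    freqs = pd.DataFrame(
        freq, columns=[f"freq_{s}" for s in samples], index=counts.index
    )
    freqs.insert(0, "site_id", counts["site_id"].to_numpy())

    treat, ctrl = conditions
    cols = {s: i for i, s in enumerate(samples)}

    def cond_stats(cond: str):
        idx = [cols[s] for s in by_cond[cond]]
        f = freq[:, idx]
        n_informative = np.sum(~np.isnan(f), axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean = np.nanmean(f, axis=1)
        mean = np.where(n_informative > 0, mean, np.nan)
        pooled_alt = alt[:, idx].sum(axis=1)
        pooled_ref = ref[:, idx].sum(axis=1)
        return mean, n_informative, pooled_alt, pooled_ref

    f_adar, n_adar, alt_adar, ref_adar = cond_stats(treat)
    f_ev, n_ev, alt_ev, ref_ev = cond_stats(ctrl)
    summary = pd.DataFrame(
        {
            "site_id": counts["site_id"].to_numpy(),
            "f_adar": f_adar,
            "f_ev": f_ev,
            "delta_f": f_adar - f_ev,
            "n_samples_adar": n_adar,
            "n_samples_ev": n_ev,
            "alt_adar": alt_adar,
            "ref_adar": ref_adar,
            "alt_ev": alt_ev,
            "ref_ev": ref_ev,
            "testable": (n_adar > 0) & (n_ev > 0),
        },
        index=counts.index,
    )
    return freqs, summary


# ---------------------------------------------------------------------------
# per-site tests


def _betabinom_loglik(alt, n, p, rho):
    rho = min(max(rho, 1e-9), 1 - 1e-9)
    p = min(max(p, 1e-9), 1 - 1e-9)
    a = p * (1 - rho) / rho
    b = (1 - p) * (1 - rho) / rho
    return float(np.sum(stats.betabinom.logpmf(alt, n, a, b)))


def _betabinom_lrt(alt1, n1, alt2, n2) -> float:
    """Likelihood-ratio test: shared vs per-condition editing mean, shared
    beta-binomial dispersion; p from chi-square with 1 df."""
    alt_all = np.concatenate([alt1, alt2])
    n_all = np.concatenate([n1, n2])

    def neg_null(theta):
        p = special.expit(theta[0])
        rho = special.expit(theta[1])
        return -_betabinom_loglik(alt_all, n_all, p, rho)

    def neg_alt(theta):
        p1, p2 = special.expit(theta[0]), special.expit(theta[1])
        rho = special.expit(theta[2])
        return -(
            _betabinom_loglik(alt1, n1, p1, rho) + _betabinom_loglik(alt2, n2, p2, rho)
        )

    p0 = (alt_all.sum() + 0.5) / (n_all.sum() + 1.0)
    pa = (alt1.sum() + 0.5) / (n1.sum() + 1.0)
    pb = (alt2.sum() + 0.5) / (n2.sum() + 1.0)
    r0 = special.logit(0.05)
    res0 = optimize.minimize(
        neg_null, x0=[special.logit(p0), r0], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400},
    )
    res1 = optimize.minimize(
        neg_alt, x0=[special.logit(pa), special.logit(pb), r0], method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 600},
    )
    lr = max(0.0, 2.0 * (res0.fun - res1.fun))
    return float(stats.chi2.sf(lr, df=1))


def test_site(
    alt_adar, ref_adar, alt_ev, ref_ev, method: str = "fisher_pooled"
) -> float:
    """p-value for differential editing at one site.

    ``fisher_pooled`` pools replicate counts per condition and runs a
    two-sided Fisher exact test on the 2x2 (alt, ref) x condition table.
    ``betabinom_lrt`` keeps replicates separate (pass per-replicate arrays).
    """
    alt_adar = np.atleast_1d(np.asarray(alt_adar, dtype=np.int64))
    ref_adar = np.atleast_1d(np.asarray(ref_adar, dtype=np.int64))
    alt_ev = np.atleast_1d(np.asarray(alt_ev, dtype=np.int64))
    ref_ev = np.atleast_1d(np.asarray(ref_ev, dtype=np.int64))
    n_adar = alt_adar + ref_adar
    n_ev = alt_ev + ref_ev
    if n_adar.sum() == 0 or n_ev.sum() == 0:
        raise ValueError("both conditions need at least one covered sample")
    if method == "fisher_pooled":
        return float(
            fisher_exact_many(
                [alt_adar.sum()], [ref_adar.sum()], [alt_ev.sum()], [ref_ev.sum()]
            )[0]
        )
    if method == "betabinom_lrt":
        return _betabinom_lrt(alt_adar, n_adar, alt_ev, n_ev)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# calling


def apply_call_thresholds(
    tested: pd.DataFrame, alpha: float = 0.05, min_delta: float = 0.1
) -> pd.DataFrame:
    """Select calls with q < alpha (strict) and delta_f > min_delta (strict)."""
    called = tested[(tested["q_value"] < alpha) & (tested["delta_f"] > min_delta)]
    return called.sort_values(
        ["q_value", "delta_f", "site_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def call_edits(
    counts: pd.DataFrame,
    alpha: float = 0.05,
    min_delta: float = 0.1,
    min_depth: int = 10,
    method: str = "fisher_pooled",
    conditions: tuple[str, str] = DEFAULT_CONDITIONS,
    return_all: bool = False,
) -> pd.DataFrame:
    """Call significant editing events from a per-site count table.

    A site is tested only when each condition carries at least ``min_depth``
    summed reads. BH FDR is applied once across all tested sites of the
    table (one dataset = one cell type). Called sites satisfy
    q < ``alpha`` and delta_f > ``min_delta``; output is sorted by q, then by
    decreasing delta_f, then site_id. With ``return_all`` the full tested
    table (plus a ``called`` flag) is returned instead.
    """
    if not (0 < alpha <= 1) or not (0 < min_delta <= 1):
        raise ValueError("alpha and min_delta must lie in (0, 1]")
    base_cols = ["site_id", "gene", "chrom", "pos", "strand"]
    if counts.empty:
        empty = pd.DataFrame(
            columns=base_cols
            + ["f_adar", "f_ev", "delta_f", "p_value", "q_value"]
        )
        if return_all:
            empty["called"] = pd.Series(dtype=bool)
        return empty
    _, summary = compute_site_frequencies(counts, conditions)
    n_skipped = int((~summary["testable"]).sum())
    if n_skipped:
        logger.warning("%d sites had zero depth in one condition and were skipped", n_skipped)
    depth_ok = (
        summary["testable"]
        & (summary["alt_adar"] + summary["ref_adar"] >= min_depth)
        & (summary["alt_ev"] + summary["ref_ev"] >= min_depth)
    )
    tested = pd.concat(
        [counts.loc[depth_ok, [c for c in base_cols if c in counts.columns]],
         summary.loc[depth_ok, ["f_adar", "f_ev", "delta_f"]]],
        axis=1,
    ).reset_index(drop=True)
    sub = summary.loc[depth_ok].reset_index(drop=True)
    if method == "fisher_pooled":
        p = fisher_exact_many(
            sub["alt_adar"], sub["ref_adar"], sub["alt_ev"], sub["ref_ev"]
        )
    elif method == "betabinom_lrt":
        samples = sample_names(counts)
        by_cond = split_conditions(samples, conditions)
        treat, ctrl = conditions
        alt_t = counts.loc[depth_ok, [f"alt_{s}" for s in by_cond[treat]]].to_numpy()
        ref_t = counts.loc[depth_ok, [f"ref_{s}" for s in by_cond[treat]]].to_numpy()
        alt_c = counts.loc[depth_ok, [f"alt_{s}" for s in by_cond[ctrl]]].to_numpy()
        ref_c = counts.loc[depth_ok, [f"ref_{s}" for s in by_cond[ctrl]]].to_numpy()
        p = np.array(
            [
                _betabinom_lrt(alt_t[i], alt_t[i] + ref_t[i], alt_c[i], alt_c[i] + ref_c[i])
                for i in range(len(sub))
            ]
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    tested["p_value"] = p
    tested["q_value"] = benjamini_hochberg(p)
    if return_all:
        tested["called"] = (tested["q_value"] < alpha) & (tested["delta_f"] > min_delta)
        return tested
    return apply_call_thresholds(tested, alpha, min_delta)


def annotate_sites(calls: pd.DataFrame, transcripts: pd.DataFrame) -> pd.DataFrame:
    """Assign genic region (and gene) to each call by interval overlap.

    Multi-isoform conflicts resolve by fixed priority 3UTR > CDS > 5UTR;
    sites overlapping no transcript get region "other" and keep their input
    gene.
    """
    calls = calls.copy()
    calls["region"] = "other"
    if calls.empty or transcripts.empty:
        return calls
    merged = calls[["site_id", "chrom", "pos"]].merge(
        transcripts[["chrom", "gene", "region", "start", "end"]], on="chrom", how="inner"
    )
    hit = merged[(merged["pos"] >= merged["start"]) & (merged["pos"] < merged["end"])].copy()
    if not hit.empty:
        hit["prio"] = hit["region"].map(_REGION_PRIORITY).fillna(3)
        best = (
            hit.sort_values(["site_id", "prio"]).groupby("site_id", as_index=True).first()
        )
        idx = calls["site_id"].map(best["region"])
        mask = idx.notna()
        calls.loc[mask, "region"] = idx[mask]
        gene_map = calls["site_id"].map(best["gene"])
        calls.loc[gene_map.notna(), "gene"] = gene_map[gene_map.notna()]
    return calls


def summarize_targets(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse calls to gene level.

    Returns ``(gene_table, histogram)`` where the gene table has one row per
    gene (n_edit_sites, best q, max delta_f) and the histogram counts genes
    by their number of edit sites.
    """
    if calls.empty:
        return (
            pd.DataFrame(columns=["gene", "n_edit_sites", "best_q", "max_delta_f"]),
            pd.Series(dtype=int, name="n_genes"),
        )
    gene_table = (
        calls.groupby("gene")
        .agg(
            n_edit_sites=("site_id", "size"),
            best_q=("q_value", "min"),
            max_delta_f=("delta_f", "max"),
        )
        .reset_index()
        .sort_values(["n_edit_sites", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    hist = gene_table["n_edit_sites"].value_counts().sort_index().rename("n_genes")
    return gene_table, hist


def compare_target_sets(genes_a, genes_b) -> dict[str, int]:
    """Shared/unique gene counts across two cell-type target sets."""
    a, b = set(genes_a), set(genes_b)
    return {
        "n_a": len(a),
        "n_b": len(b),
        "shared": len(a & b),
        "a_only": len(a - b),
        "b_only": len(b - a),
    }
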