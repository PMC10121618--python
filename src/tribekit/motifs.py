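"""K-mer motif enrichment around edit sites and nearest-motif distances.

The RBP footprint is inferred from sequence context: windows (default
+/-250 nt) around called edit sites form the foreground, windows around
random positions of non-target transcripts the background, and every k-mer
(k 4-7, RNA alphabet) is scored by presence/absence enrichment with a
one-sided binomial test against the background presence rate, BH-corrected.
Per-sequence presence counting (rather than total occurrences) avoids
length bias. Signed distances from edit sites to the nearest motif
occurrence are summarised as a Gaussian-kernel density.
"""
from __future__ import annotations

import itertools
import logging
import re

import numpy as np
import pandas as pd
from scipy import stats

from .stats import benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "extract_context_sequences",
    "sample_background_windows",
    "rank_kmers",
    "motif_regex",
    "find_motif_occurrences",
    "nearest_motif_distances",
    "DistanceProfile",
]

_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


def reverse_complement_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def extract_context_sequences(
    calls: pd.DataFrame,
    transcripts: pd.DataFrame,
    sequences: dict[str, str],
    window: int = 250,
) -> pd.DataFrame:
    """Sense-strand RNA windows of +/-``window`` nt around each call.

    Windows are clipped at the contig ends; minus-strand sites are
    reverse-complemented so the edited base reads A. Returns one row per
    retained site with the window sequence and the site's offset inside it;
    sites whose contig has no sequence record are skipped with a warning.
    """
    strand_by_chrom = (
        transcripts.drop_duplicates("chrom").set_index("chrom")["strand"]
        if not transcripts.empty
        else pd.Series(dtype=object)
    )
    rows = []
    n_missing = 0
    for _, call in calls.iterrows():
        chrom = call["chrom"]
        seq = sequences.get(chrom)
        if seq is None:
            n_missing += 1
            continue
        pos = int(call["pos"])
        lo = max(0, pos - window)
        hi = min(len(seq), pos + window + 1)
        sub = seq[lo:hi]
        offset = pos - lo
        strand = call.get("strand", strand_by_chrom.get(chrom, "+"))
        if strand == "-":
            sub = reverse_complement_rna(sub)
            offset = len(sub) - 1 - offset
        rows.append(
            (call["site_id"], call.get("gene"), call.get("region", "other"), sub, offset)
        )
    if n_missing:
        logger.warning("%d sites skipped: no sequence record", n_missing)
    return pd.DataFrame(rows, columns=["site_id", "gene", "region", "seq", "site_offset"])


def sample_background_windows(
    sequences: dict[str, str],
    transcripts: pd.DataFrame,
    exclude_genes,
    n_windows: int,
    window: int = 250,
    seed: int = 0,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Windows around random positions of non-target transcripts.

    ``regions`` optionally lists region labels to draw positions from
    (sampled uniformly over the listed labels), matching the foreground's
    region composition.
    """
    rng = np.random.default_rng(seed)
    exclude = set(exclude_genes)
    pool = transcripts[~transcripts["gene"].isin(exclude)]
    pool = pool[pool["chrom"].isin(sequences)]
    if pool.empty:
        raise ValueError("no non-target transcripts available for the background")
    if regions:
        pool = pool[pool["region"].isin(regions)]
        if pool.empty:
            raise ValueError(f"no background intervals for regions {regions}")
    pool = pool.reset_index(drop=True)
    picks = rng.integers(0, len(pool), size=n_windows)
    rows = []
    for i, row_idx in enumerate(picks):
        row = pool.iloc[row_idx]
        pos = int(rng.integers(row["start"], row["end"]))
        seq = sequences[row["chrom"]]
        lo = max(0, pos - window)
        hi = min(len(seq), pos + window + 1)
        sub = seq[lo:hi]
        if row["strand"] == "-":
            sub = reverse_complement_rna(sub)
        rows.append((f"bg{i + 1:06d}", row["gene"], row["region"], sub, pos - lo))
    return pd.DataFrame(rows, columns=["site_id", "gene", "region", "seq", "site_offset"])


def _present_kmers(seq: str, kmin: int, kmax: int) -> set[str]:
    out: set[str] = set()
    n = len(seq)
    for k in range(kmin, kmax + 1):
        for i in range(n - k + 1):
            out.add(seq[i : i + k])
    return out


def rank_kmers(
    fg_seqs,
    bg_seqs,
    k_range: tuple[int, int] = (4, 7),
) -> pd.DataFrame:
    """Presence/absence k-mer enrichment of foreground vs background windows.

    Each k-mer seen in the foreground is scored by the one-sided binomial
    tail P(X >= fg_count | n = fg_total, p = background presence rate); BH
    correction runs across all scored k-mers. Output is ranked by q-value,
    then decreasing enrichment, then k-mer.
    """
    fg = [str(s) for s in fg_seqs]
    bg = [str(s) for s in bg_seqs]
    if len(fg) == 0:
        raise ValueError("foreground is empty")
    if len(fg) < 10 or len(bg) < 10:
        raise ValueError("need at least 10 foreground and 10 background sequences")
    kmin, kmax = k_range
    fg_sets = [_present_kmers(s, kmin, kmax) for s in fg]
    bg_sets = [_present_kmers(s, kmin, kmax) for s in bg]
    fg_counts: dict[str, int] = {}
    for s in fg_sets:
        for kmer in s:
            fg_counts[kmer] = fg_counts.get(kmer, 0) + 1
    bg_counts: dict[str, int] = {}
    for s in bg_sets:
        for kmer in s:
            bg_counts[kmer] = bg_counts.get(kmer, 0) + 1
    n_fg, n_bg = len(fg), len(bg)
    kmers = sorted(fg_counts)
    fg_c = np.array([fg_counts[k] for k in kmers])
    bg_c = np.array([bg_counts.get(k, 0) for k in kmers])
    # background presence rate with a half-count floor so unseen k-mers do
    # not produce zero-probability nulls
    bg_rate = np.maximum(bg_c, 0.5) / n_bg
    p = stats.binom.sf(fg_c - 1, n_fg, bg_rate)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = (fg_c / n_fg) / (bg_c / n_bg)
    enr = np.where(bg_c > 0, enr, np.inf)
    out = pd.DataFrame(
        {
            "kmer": kmers,
            "k": [len(k) for k in kmers],
            "fg_count": fg_c,
            "fg_total": n_fg,
            "bg_count": bg_c,
            "bg_total": n_bg,
            "enrichment": enr,
            "p_value": p,
        }
    )
    out["q_value"] = benjamini_hochberg(out["p_value"])
    return out.sort_values(
        ["q_value", "enrichment", "kmer"], ascending=[True, False, True]
    ).reset_index(drop=True)


def motif_regex(motif: str) -> re.Pattern:
    """Compile a motif string to an overlap-aware regex.

    Supports IUPAC degenerate letters and a leading "X/Y" alternation as in
    G/AGUAAG (either G or A at the first position).
    """
    m = motif.upper().replace("T", "U")
    alt = re.match(r"^([ACGU])/([ACGU])(.*)$", m)
    if alt:
        first = f"[{alt.group(1)}{alt.group(2)}]"
        rest = alt.group(3)
    else:
        first = _IUPAC.get(m[0])
        rest = m[1:]
        if first is None:
            raise ValueError(f"bad motif character {m[0]!r}")
    bad = [ch for ch in rest if ch not in _IUPAC]
    if bad:
        raise ValueError(f"bad motif character(s) {bad!r} in {motif!r}")
    body = first + "".join(_IUPAC[ch] for ch in rest)
    return re.compile(f"(?=({body}))")


def find_motif_occurrences(seq: str, motif: str) -> list[int]:
    """Start offsets of all (possibly overlapping) motif matches in ``seq``."""
    return [m.start() for m in motif_regex(motif).finditer(seq)]


class DistanceProfile:
    """Signed edit-site-to-nearest-motif distances and their kernel density."""

    def __init__(self, motif: str, region: str, distances: np.ndarray,
                 n_sites: int, n_without_motif: int, window: int):
        self.motif = motif
        self.region = region
        self.distances = np.asarray(distances, dtype=float)
        self.n_sites = n_sites
        self.n_without_motif = n_without_motif
        self.window = window
        self.grid = np.linspace(-window, window, 501)
        if self.distances.size >= 2 and np.ptp(self.distances) > 0:
            kde = stats.gaussian_kde(self.distances, bw_method="silverman")
            self.density = kde(self.grid)
        else:
            self.density = np.full_like(self.grid, np.nan)

    @property
    def empty(self) -> bool:
        return self.distances.size == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.grid, "density": self.density})


def nearest_motif_distances(
    windows: pd.DataFrame,
    motifs,
    window: int = 250,
    by_region: bool = True,
) -> dict[tuple[str, str], DistanceProfile]:
    """Nearest-motif distance profile per motif (and per genic region).

    Distance = motif start offset - edit-site offset, signed; the nearest
    occurrence by absolute value wins, with exact ties resolved to the
    negative (upstream) side. Sites with no occurrence within +/-``window``
    are excluded and counted in the profile.
    """
    profiles: dict[tuple[str, str], DistanceProfile] = {}
    groups = windows.groupby("region") if by_region else [("all", windows)]
    for motif in motifs:
        pat = motif_regex(motif)
        any_occurrence = False
        for region, grp in groups:
            dists = []
            n_without = 0
            for _, row in grp.iterrows():
                occ = [m.start() for m in pat.finditer(row["seq"])]
                if occ:
                    any_occurrence = True
                d_best = None
                for start in occ:
                    d = start - int(row["site_offset"])
                    if abs(d) > window:
                        continue
                    if (
                        d_best is None
                        or abs(d) < abs(d_best)
                        or (abs(d) == abs(d_best) and d < d_best)
                    ):
                        d_best = d
                if d_best is None:
                    n_without += 1
                else:
                    dists.append(d_best)
            profiles[(motif, region)] = DistanceProfile(
                motif, region, np.array(dists), len(grp), n_without, window
            )
        if not any_occurrence:
            logger.warning("motif %s has no occurrence in any window", motif)
    return profiles
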