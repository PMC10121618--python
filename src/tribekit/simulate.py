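"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (edit calling, motif analysis,
multi-omics integration, division scoring) can be exercised on output of this
module without any external download. The generators emulate:

* per-site A->G read counts with beta-binomially overdispersed editing,
  elevated at true target sites in RBP-ADAR samples relative to empty-vector
  controls;
* single-isoform transcript architectures with a k-mer motif planted near
  each true edit site;
* gene-level mRNA/protein differential-expression tables with a designated
  direct-target subset and planted set intersections, plus a raw label-free
  protein intensity matrix (2 groups x 3 samples);
* paired-daughter-cell and split-cell fluorescence intensities as mixtures
  of symmetric/asymmetric divisions with multiplicative noise.

All randomness flows from one master seed through named child streams, so a
fixed configuration is byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EditSimConfig",
    "SimulatedEditDataset",
    "simulate_edit_dataset",
    "simulate_expression_tables",
    "simulate_daughter_pairs",
    "simulate_costained_pairs",
    "simulate_polarity_cells",
]

RNA_BASES = np.array(["A", "C", "G", "U"])
REGIONS = ("5UTR", "CDS", "3UTR")


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-stage generator derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(abs(hash_stable(stream)),))
    )


def hash_stable(s: str) -> int:
    """Platform-stable small hash of a stream name (FNV-1a, 31-bit)."""
    h = 2166136261
    for ch in s.encode():
        h = ((h ^ ch) * 16777619) & 0x7FFFFFFF
    return h


@dataclass
class EditSimConfig:
    """Configuration of the editing-count simulator.

    Defaults reflect the study design being emulated: 3 RBP-ADAR ("S_ADAR")
    vs 3 empty-vector ("EV") replicates, ~1.5 candidate sites per transcript,
    ~100x coverage, a low background editing rate, and most true sites in the
    3'UTR with the ACUUAG motif planted nearby.
    """

    n_genes: int = 500
    sites_per_gene_mean: float = 1.5
    n_replicates_per_condition: int = 3
    coverage_mean: float = 100.0
    coverage_shape: float = 10.0  # negative-binomial size parameter
    baseline_edit_rate: float = 0.005
    true_site_fraction: float = 0.3
    effect_delta: float = 0.3
    overdispersion_rho: float = 0.02
    motif: str = "ACUUAG"
    motif_offset_sd: float = 50.0
    utr5_len: int = 200
    cds_len: int = 900
    utr3_len: int = 600
    region_weights: tuple[float, float, float] = (0.05, 0.30, 0.65)
    conditions: tuple[str, str] = ("S_ADAR", "EV")
    seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_edit_rate", "true_site_fraction", "overdispersion_rho"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1); got {v}")
        if not 0.0 <= self.effect_delta <= 1.0:
            raise ValueError(f"effect_delta must lie in [0, 1]; got {self.effect_delta}")
        if self.baseline_edit_rate + self.effect_delta > 1.0:
            raise ValueError(
                "baseline_edit_rate + effect_delta must not exceed 1; got "
                f"{self.baseline_edit_rate + self.effect_delta}"
            )
        if self.coverage_mean <= 0:
            raise ValueError(f"coverage_mean must be positive; got {self.coverage_mean}")
        if self.n_genes <= 0:
            raise ValueError(f"n_genes must be positive; got {self.n_genes}")
        if self.n_replicates_per_condition < 1:
            raise ValueError("n_replicates_per_condition must be >= 1")
        if set(self.motif) - set("ACGU"):
            raise ValueError(f"motif must be over the RNA alphabet; got {self.motif!r}")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")

    @property
    def transcript_len(self) -> int:
        return self.utr5_len + self.cds_len + self.utr3_len


@dataclass
class SimulatedEditDataset:
    """Bundle returned by :func:`simulate_edit_dataset`."""

    counts: pd.DataFrame
    transcripts: pd.DataFrame
    sequences: dict[str, str]  # chrom -> RNA-alphabet sequence
    truth: pd.DataFrame
    config: EditSimConfig = field(repr=False)

    @property
    def sample_names(self) -> list[str]:
        return [c[4:] for c in self.counts.columns if c.startswith("ref_")]


def _region_bounds(cfg: EditSimConfig) -> dict[str, tuple[int, int]]:
    a, b = cfg.utr5_len, cfg.utr5_len + cfg.cds_len
    return {"5UTR": (0, a), "CDS": (a, b), "3UTR": (b, cfg.transcript_len)}


def simulate_edit_dataset(config: EditSimConfig) -> SimulatedEditDataset:
    """Simulate per-site editing counts, transcript models, sequences, truth.

    Each gene occupies its own contig (chrom == gene id) with a single
    plus-strand isoform laid out as 5'UTR | CDS | 3'UTR. Candidate sites are
    A positions; alternate-read counts are drawn beta-binomially with mean
    ``baseline_edit_rate`` everywhere except true sites in RBP-ADAR samples,
    where the mean is ``baseline_edit_rate + effect_delta``. The configured
    motif is planted within ~``motif_offset_sd`` bases (never farther than
    250) of every true site.
    """
    config.validate()
    cfg = config
    bounds = _region_bounds(cfg)
    rng_sites = _child_rng(cfg.seed, "sites")
    rng_seq = _child_rng(cfg.seed, "sequences")
    rng_counts = _child_rng(cfg.seed, "counts")

    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{str(i + 1).zfill(width)}" for i in range(cfg.n_genes)]

    # transcript models: one BED-like row per region interval
    tx_rows = []
    for g in genes:
        for region in REGIONS:
            s, e = bounds[region]
            tx_rows.append((g, f"{g}.t1", g, "+", region, s, e))
    transcripts = pd.DataFrame(
        tx_rows, columns=["gene", "transcript_id", "chrom", "strand", "region", "start", "end"]
    )

    # candidate sites
    n_sites_per_gene = rng_sites.poisson(cfg.sites_per_gene_mean, size=cfg.n_genes)
    site_rows = []
    for g, n_sites in zip(genes, n_sites_per_gene):
        if n_sites == 0:
            continue
        regions = rng_sites.choice(REGIONS, size=n_sites, p=cfg.region_weights)
        used: set[int] = set()
        for region in regions:
            lo, hi = bounds[region]
            pos = int(rng_sites.integers(lo, hi))
            while pos in used:
                pos = int(rng_sites.integers(lo, hi))
            used.add(pos)
            site_rows.append((g, pos, region))
    site_rows.sort()
    n_total = len(site_rows)
    is_true = rng_sites.random(n_total) < cfg.true_site_fraction
    if cfg.effect_delta == 0.0:
        is_true[:] = False

    # sequences with planted motifs; site positions forced to A
    k = len(cfg.motif)
    motif_arr = np.array(list(cfg.motif))
    sequences: dict[str, np.ndarray] = {
        g: RNA_BASES[rng_seq.integers(0, 4, size=cfg.transcript_len)] for g in genes
    }
    for g, pos, _region in site_rows:
        sequences[g][pos] = "A"
    sites_by_gene: dict[str, list[int]] = {}
    for g, pos, _region in site_rows:
        sites_by_gene.setdefault(g, []).append(pos)

    def plant(seq: np.ndarray, pos: int, gene: str) -> int:
        """Plant the motif near ``pos``; returns the planted start offset."""
        max_off = 250 - k
        for _attempt in range(64):
            off = int(round(rng_seq.normal(0.0, cfg.motif_offset_sd)))
            off = int(np.clip(off, -max_off, max_off))
            start = int(np.clip(pos + off, 0, cfg.transcript_len - k))
            # never overwrite a candidate site's A with a non-A motif base
            clash = any(
                start <= p < start + k and cfg.motif[p - start] != "A"
                for p in sites_by_gene[gene]
            )
            if not clash:
                seq[start : start + k] = motif_arr
                return start
        # deterministic fallback: scan outwards for a clash-free start
        for delta in range(0, max_off + 1):
            for start in (pos - delta - k, pos + delta + 1):
                if start < 0 or start + k > cfg.transcript_len:
                    continue
                if abs(start - pos) > max_off:
                    continue
                clash = any(
                    start <= p < start + k and cfg.motif[p - start] != "A"
                    for p in sites_by_gene[gene]
                )
                if not clash:
                    seq[start : start + k] = motif_arr
                    return start
        raise RuntimeError("could not plant motif without clobbering a site")

    motif_starts = np.full(n_total, -1, dtype=int)
    for i, (g, pos, _region) in enumerate(site_rows):
        if is_true[i]:
            motif_starts[i] = plant(sequences[g], pos, g)

    # read counts
    samples = [
        f"{cond}_{r + 1}"
        for cond in cfg.conditions
        for r in range(cfg.n_replicates_per_condition)
    ]
    treat = cfg.conditions[0]
    nb_p = cfg.coverage_shape / (cfg.coverage_shape + cfg.coverage_mean)
    p_true = cfg.baseline_edit_rate + cfg.effect_delta
    count_cols: dict[str, np.ndarray] = {}
    for s in samples:
        depth = rng_counts.negative_binomial(cfg.coverage_shape, nb_p, size=n_total)
        depth = np.maximum(depth, 1)
        p = np.full(n_total, cfg.baseline_edit_rate)
        if s.startswith(treat):
            p[is_true] = p_true
        if cfg.overdispersion_rho > 0:
            rho = cfg.overdispersion_rho
            a = p * (1 - rho) / rho
            b = (1 - p) * (1 - rho) / rho
            p_draw = rng_counts.beta(a, b)
        else:
            p_draw = p
        alt = rng_counts.binomial(depth, p_draw)
        count_cols[f"ref_{s}"] = depth - alt
        count_cols[f"alt_{s}"] = alt

    site_ids = [f"{g}:{pos}" for g, pos, _region in site_rows]
    counts = pd.DataFrame(
        {
            "site_id": site_ids,
            "gene": [g for g, _p, _r in site_rows],
            "chrom": [g for g, _p, _r in site_rows],
            "pos": [p for _g, p, _r in site_rows],
            "strand": "+",
            **count_cols,
        }
    )
    truth = pd.DataFrame(
        {
            "site_id": site_ids,
            "gene": [g for g, _p, _r in site_rows],
            "pos": [p for _g, p, _r in site_rows],
            "region": [r for _g, _p, r in site_rows],
            "is_true_target": is_true,
            "true_delta": np.where(is_true, cfg.effect_delta, 0.0),
            "motif_start": motif_starts,
        }
    )
    seq_strings = {g: "".join(arr) for g, arr in sequences.items()}
    return SimulatedEditDataset(counts, transcripts, seq_strings, truth, cfg)


# ---------------------------------------------------------------------------
# expression / proteome tables


def simulate_expression_tables(
    n_genes: int,
    target_genes: Sequence[str],
    frac_targets_down_rna: float,
    frac_targets_down_protein: float,
    noise_sd: float = 0.25,
    seed: int = 0,
    *,
    rna_fdr_max: float = 0.05,
    prot_fdr_max: float = 0.1,
    n_rna_down_total: int | None = None,
    n_prot_down_total: int | None = None,
    n_protein_samples_per_group: int = 3,
):
    """Simulate mRNA/protein differential-expression tables with planted truth.

    Down-regulated genes receive log2FC <= -1 (i.e. FC <= -2, boundary
    inclusive) and an FDR below the respective cutoff; all other genes are
    kept clear of both filters. The RNA-down target subset is nested inside
    the protein-down target subset (or vice versa when larger), so the
    planted Venn regions are controlled exactly:

    * triple region (targets ∩ RNA-down ∩ protein-down) =
      round(frac_targets_down_rna * n_targets) when that is the smaller set;
    * targets ∩ protein-down only = the protein excess over the triple.

    ``n_rna_down_total`` / ``n_prot_down_total`` optionally top the down sets
    up with non-target genes to a fixed total size. Also returns a raw
    label-free intensity matrix (2 groups x ``n_protein_samples_per_group``)
    consistent with the planted protein fold changes.

    Returns ``(rna_table, protein_table, intensity_matrix, groups, truth)``.
    """
    if n_genes <= 0:
        raise ValueError("gene universe must be non-empty")
    for name, v in (
        ("frac_targets_down_rna", frac_targets_down_rna),
        ("frac_targets_down_protein", frac_targets_down_protein),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]; got {v}")
    target_genes = list(dict.fromkeys(target_genes))
    width = max(4, len(str(n_genes)))
    universe = list(target_genes)
    i = 1
    while len(universe) < n_genes:
        g = f"x{str(i).zfill(width)}"
        if g not in target_genes:
            universe.append(g)
        i += 1
    if len(universe) > n_genes:
        raise ValueError("target_genes must fit inside the gene universe")

    rng = _child_rng(seed, "expression")
    shuffled_targets = list(target_genes)
    rng.shuffle(shuffled_targets)
    n_t = len(shuffled_targets)
    n_rna_t = int(round(frac_targets_down_rna * n_t))
    n_prot_t = int(round(frac_targets_down_protein * n_t))
    # nested subsets -> exact planted intersections
    rna_down = set(shuffled_targets[:n_rna_t])
    prot_down = set(shuffled_targets[:n_prot_t])

    non_targets = [g for g in universe if g not in set(target_genes)]
    rng.shuffle(non_targets)
    if n_rna_down_total is not None:
        extra = n_rna_down_total - len(rna_down)
        if extra < 0 or extra > len(non_targets):
            raise ValueError("n_rna_down_total incompatible with planted target subset")
        rna_down |= set(non_targets[:extra])
    if n_prot_down_total is not None:
        extra = n_prot_down_total - len(prot_down)
        pool = non_targets[::-1]  # fill from the other end to decouple the sets
        if extra < 0 or extra > len(pool):
            raise ValueError("n_prot_down_total incompatible with planted target subset")
        prot_down |= set(pool[:extra])

    def _table(down: set[str], fdr_max: float, layer: str) -> pd.DataFrame:
        log2fc = rng.normal(0.0, noise_sd, size=len(universe))
        log2fc = np.clip(log2fc, -0.9, 0.9)  # non-planted genes stay inside |FC|<2
        fdr = rng.uniform(0.5, 1.0, size=len(universe))
        down_mask = np.array([g in down for g in universe])
        log2fc[down_mask] = -1.0 - np.abs(rng.normal(0.0, noise_sd, size=down_mask.sum()))
        fdr[down_mask] = rng.uniform(0.0, 0.8 * fdr_max, size=down_mask.sum())
        return pd.DataFrame(
            {"gene": universe, "log2fc": log2fc, "fdr": fdr, "layer": layer}
        )

    rna = _table(rna_down, rna_fdr_max, "mRNA")
    protein = _table(prot_down, prot_fdr_max, "protein")

    # raw intensity matrix consistent with the planted protein fold changes
    n_s = n_protein_samples_per_group
    groups = {f"WT_{j+1}": "WT" for j in range(n_s)} | {
        f"KO_{j+1}": "KO" for j in range(n_s)
    }
    base = rng.lognormal(mean=np.log(1e6), sigma=1.0, size=len(universe))
    fc = 2.0 ** protein["log2fc"].to_numpy()
    cols = {}
    for j in range(n_s):
        cols[f"WT_{j+1}"] = base * rng.lognormal(0.0, 0.05, size=len(universe))
    for j in range(n_s):
        cols[f"KO_{j+1}"] = base * fc * rng.lognormal(0.0, 0.05, size=len(universe))
    matrix = pd.DataFrame(cols, index=pd.Index(universe, name="gene"))

    truth = {
        "targets": set(target_genes),
        "rna_down": set(rna_down),
        "protein_down": set(prot_down),
        "targets_and_protein_down": set(target_genes) & prot_down,
        "triple": set(target_genes) & rna_down & prot_down,
    }
    return rna, protein, matrix, groups, truth


# ---------------------------------------------------------------------------
# paired-daughter and polarity generators

DIVISION_CLASSES = ("sym_renewal", "sym_commitment", "asymmetric")


def simulate_daughter_pairs(
    n_pairs: int,
    mix: Sequence[float] = (0.4, 0.3, 0.3),
    intensity_scales: tuple[float, float] = (100.0, 400.0),
    noise_cv: float = 0.1,
    seed: int = 0,
    *,
    marker: str = "NUMB",
    genotype: str = "WT",
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Simulate paired-daughter marker intensities from a class mixture.

    ``mix`` gives fractions over (sym_renewal, sym_commitment, asymmetric).
    Asymmetric pairs get a between-daughter ratio in [4, 8] (well past the
    2-fold rule); symmetric pairs a ratio below 1.5, around the low or high
    intensity scale respectively. Multiplicative log-normal noise with
    coefficient of variation ``noise_cv`` is applied per daughter.
    """
    mix = np.asarray(mix, dtype=float)
    if mix.shape != (3,):
        raise ValueError("mix must have three components")
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError(f"mix must sum to 1; got {mix.sum()!r}")
    rng = _child_rng(seed, f"pairs:{marker}:{genotype}")
    labels = rng.choice(DIVISION_CLASSES, size=n_pairs, p=mix)
    low, high = intensity_scales
    i1 = np.empty(n_pairs)
    i2 = np.empty(n_pairs)
    for idx, lab in enumerate(labels):
        if lab == "asymmetric":
            a = low
            b = a * rng.uniform(4.0, 8.0)
        else:
            base = low if lab == "sym_renewal" else high
            a = base
            b = base * rng.uniform(1.0, 1.4)
        if rng.random() < 0.5:
            a, b = b, a
        i1[idx], i2[idx] = a, b
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        i1 = i1 * rng.lognormal(0.0, sigma, size=n_pairs)
        i2 = i2 * rng.lognormal(0.0, sigma, size=n_pairs)
    return pd.DataFrame(
        {
            "pair_id": [f"p{idx+1:05d}" for idx in range(n_pairs)],
            "genotype": genotype,
            "replicate": (np.arange(n_pairs) % n_replicates) + 1,
            "marker": marker,
            "i1": i1,
            "i2": i2,
            "true_class": labels,
        }
    )


def simulate_costained_pairs(
    n_pairs: int,
    frac_asymmetric: float = 0.5,
    coseg_prob: float = 0.8,
    intensity_scales: tuple[float, float] = (100.0, 400.0),
    noise_cv: float = 0.05,
    seed: int = 0,
    *,
    markers: tuple[str, str] = ("LAMP1", "TMI"),
    genotype: str = "WT",
) -> pd.DataFrame:
    """Simulate pairs co-stained for two markers with controlled co-segregation.

    With probability ``frac_asymmetric`` a pair is asymmetric for both
    markers; the high daughter then coincides between markers with
    probability ``coseg_prob``. Remaining pairs are symmetric for both.
    Columns i1/i2 hold the first marker, j1/j2 the second.
    """
    if not 0.0 <= coseg_prob <= 1.0:
        raise ValueError("coseg_prob must lie in [0, 1]")
    rng = _child_rng(seed, f"costain:{genotype}")
    low, high = intensity_scales
    rows = []
    for idx in range(n_pairs):
        asym = rng.random() < frac_asymmetric
        if asym:
            ratio1 = rng.uniform(4.0, 8.0)
            ratio2 = rng.uniform(4.0, 8.0)
            high_side1 = int(rng.random() < 0.5)
            same = rng.random() < coseg_prob
            high_side2 = high_side1 if same else 1 - high_side1
            i = [low, low]
            i[high_side1] *= ratio1
            j = [low, low]
            j[high_side2] *= ratio2
            truth = "asym_both"
        else:
            base = low if rng.random() < 0.5 else high
            i = [base, base * rng.uniform(1.0, 1.3)]
            j = [base, base * rng.uniform(1.0, 1.3)]
            truth = "sym_both"
        if noise_cv > 0:
            sigma = np.sqrt(np.log1p(noise_cv**2))
            i = [v * rng.lognormal(0.0, sigma) for v in i]
            j = [v * rng.lognormal(0.0, sigma) for v in j]
        rows.append((f"p{idx+1:05d}", genotype, markers[0], markers[1], *i, *j, truth))
    return pd.DataFrame(
        rows,
        columns=["pair_id", "genotype", "marker1", "marker2", "i1", "i2", "j1", "j2", "true_class"],
    )


def simulate_polarity_cells(
    n_cells: int,
    frac_polar: float = 0.3,
    polar_log2fc_mean: float = 1.0,
    seed: int = 0,
    *,
    noise_sd: float = 0.1,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Simulate split-cell tubulin half-intensities.

    Polar cells draw a half-to-half |log2 ratio| strictly above 0.6 (centred
    on ``polar_log2fc_mean``); non-polar cells draw below 0.5.
    """
    if not 0.0 <= frac_polar <= 1.0:
        raise ValueError("frac_polar must lie in [0, 1]")
    rng = _child_rng(seed, f"polarity:{genotype}")
    is_polar = rng.random(n_cells) < frac_polar
    lfc = np.where(
        is_polar,
        0.601 + np.abs(rng.normal(polar_log2fc_mean - 0.6, noise_sd, size=n_cells)),
        rng.uniform(0.0, 0.5, size=n_cells),
    )
    sign = np.where(rng.random(n_cells) < 0.5, 1.0, -1.0)
    h1 = np.full(n_cells, 1000.0)
    h2 = h1 * 2.0 ** (sign * lfc)
    return pd.DataFrame(
        {
            "cell_id": [f"c{idx+1:05d}" for idx in range(n_cells)],
            "genotype": genotype,
            "h1": h1,
            "h2": h2,
            "true_polar": is_polar,
        }
    )
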