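"""End-to-end orchestration: simulate -> call edits -> motifs -> integrate
-> score divisions, with config loading, logging and a run report.

Default thresholds are the study's printed ones: edit-call FDR < 0.05 and
differential editing frequency > 0.1; mRNA filter FDR < 0.05 at 2-fold;
protein filter FDR < 0.1 at 2-fold; pair asymmetry |log2FC| >= 0.6; polarity
|log2FC| > 0.6; NUMB asymmetry ratio >= 2.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import division as div
from . import editcalls as ec
from . import integrate as integ
from . import io as tio
from . import motifs as mo
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Pipeline-wide configuration; defaults equal the printed thresholds."""

    seed: int = 0
    # simulate
    simulate: bool = True
    n_genes: int = 500
    sites_per_gene_mean: float = 1.5
    coverage_mean: float = 100.0
    baseline_edit_rate: float = 0.005
    true_site_fraction: float = 0.3
    effect_delta: float = 0.3
    overdispersion_rho: float = 0.02
    motif: str = "ACUUAG"
    motif_offset_sd: float = 50.0
    # external inputs (used when simulate is false)
    counts_path: str | None = None
    transcripts_path: str | None = None
    fasta_path: str | None = None
    # edit calling
    alpha: float = 0.05
    min_delta: float = 0.1
    min_depth: int = 10
    method: str = "fisher_pooled"
    # motif analysis
    window: int = 250
    kmin: int = 4
    kmax: int = 6
    # integration
    rna_fdr: float = 0.05
    rna_fc: float = 2.0
    prot_fdr: float = 0.1
    prot_fc: float = 2.0
    frac_targets_down_rna: float = 0.1
    frac_targets_down_protein: float = 0.2
    # division scoring
    numb_ratio: float = 2.0
    pair_log2fc: float = 0.6
    polarity_log2fc: float = 0.6
    n_pairs: int = 1000
    division_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)
    n_polarity_cells: int = 500
    frac_polar: float = 0.3

    def non_default_fields(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            default = f.default if f.default is not dataclasses.MISSING else None
            v = getattr(self, f.name)
            if v != default:
                out[f.name] = v
        return out


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config file; unknown keys are rejected.

    An empty file yields all defaults (the study's printed thresholds).
    """
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig) if not f.name.startswith("_")}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "division_mix" in data:
        data["division_mix"] = tuple(data["division_mix"])
    return PipelineConfig(**data)


def _count_lines(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for line in fh if not line.startswith("#")) - 1  # minus header


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages in dependency order and write every artefact.

    Returns the run report (also written to ``report.json``), which records
    per-stage record counts, filter survival counts, the config echo, any
    non-default settings, the seed and wall-clock per stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "non_default": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in config.non_default_fields().items()
        },
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def finish(**counts):
            report["stages"][name] = {
                "wall_clock_s": round(time.perf_counter() - t0, 3),
                **counts,
            }

        return finish

    # --- simulate / load -------------------------------------------------
    done = stage("simulate")
    if config.simulate:
        ecfg = sim.EditSimConfig(
            n_genes=config.n_genes,
            sites_per_gene_mean=config.sites_per_gene_mean,
            coverage_mean=config.coverage_mean,
            baseline_edit_rate=config.baseline_edit_rate,
            true_site_fraction=config.true_site_fraction,
            effect_delta=config.effect_delta,
            overdispersion_rho=config.overdispersion_rho,
            motif=config.motif,
            motif_offset_sd=config.motif_offset_sd,
            seed=config.seed,
        )
        ds = sim.simulate_edit_dataset(ecfg)
        tio.write_edit_dataset(ds, out / "sim")
        counts, transcripts, sequences = ds.counts, ds.transcripts, ds.sequences
        truth = ds.truth
        done(n_sites=len(counts), n_genes=config.n_genes,
             n_true_sites=int(truth["is_true_target"].sum()))
    else:
        if not config.counts_path or not Path(config.counts_path).exists():
            raise FileNotFoundError(
                "simulate is disabled and counts_path is missing or does not exist"
            )
        counts = tio.read_counts_tsv(config.counts_path)
        transcripts = (
            tio.read_transcripts_tsv(config.transcripts_path)
            if config.transcripts_path
            else pd.DataFrame(columns=["gene", "transcript_id", "chrom", "strand", "region", "start", "end"])
        )
        sequences = tio.read_fasta(config.fasta_path) if config.fasta_path else {}
        truth = None
        done(n_sites=len(counts))

    # --- edit calling -----------------------------------------------------
    done = stage("edit_calling")
    calls = ec.call_edits(
        counts, alpha=config.alpha, min_delta=config.min_delta,
        min_depth=config.min_depth, method=config.method,
    )
    calls = ec.annotate_sites(calls, transcripts)
    gene_table, hist = ec.summarize_targets(calls)
    tio.write_calls_tsv(calls, out / "calls.tsv")
    tio.write_calls_vcf(calls, out / "calls.vcf")
    gene_table.to_csv(out / "gene_targets.tsv", sep="\t", index=False)
    done(n_calls=len(calls), n_target_genes=len(gene_table),
         region_counts=calls["region"].value_counts().to_dict() if len(calls) else {})

    # --- motif analysis ---------------------------------------------------
    done = stage("motif")
    target_genes = list(gene_table["gene"])
    motif_summary = {}
    if len(calls) >= 10 and sequences:
        fg = mo.extract_context_sequences(calls, transcripts, sequences, config.window)
        bg = mo.sample_background_windows(
            sequences, transcripts, target_genes,
            n_windows=max(2 * len(fg), 50), window=config.window,
            seed=config.seed + 1, regions=sorted(fg["region"].unique()),
        )
        kmers = mo.rank_kmers(fg["seq"], bg["seq"], (config.kmin, config.kmax))
        kmers.to_csv(out / "motifs.tsv", sep="\t", index=False)
        top = kmers.iloc[0]["kmer"]
        profiles = mo.nearest_motif_distances(fg, [top], window=config.window, by_region=False)
        prof = profiles[(top, "all")]
        prof.to_frame().to_csv(out / "motif_distance_density.tsv", sep="\t", index=False)
        pd.DataFrame({"distance": prof.distances}).to_csv(
            out / "motif_distances.tsv", sep="\t", index=False
        )
        motif_summary = {
            "top_kmer": str(top),
            "n_fg_windows": len(fg),
            "n_distances": int(prof.distances.size),
            "n_without_motif": prof.n_without_motif,
        }
    done(**(motif_summary or {"skipped": "fewer than 10 calls or no sequences"}))

    # --- multi-omics integration -----------------------------------------
    done = stage("integration")
    rna, protein, matrix, groups, omics_truth = sim.simulate_expression_tables(
        n_genes=max(config.n_genes, len(target_genes)),
        target_genes=target_genes,
        frac_targets_down_rna=config.frac_targets_down_rna,
        frac_targets_down_protein=config.frac_targets_down_protein,
        seed=config.seed + 2,
        rna_fdr_max=config.rna_fdr,
        prot_fdr_max=config.prot_fdr,
    )
    norm = integ.normalize_protein_matrix(matrix)
    prot_records = integ.protein_log2fc_test(norm, groups)
    rna_down = integ.filter_de(rna, config.rna_fdr, config.rna_fc, "down")
    prot_down = integ.filter_de(protein, config.prot_fdr, config.prot_fc, "down")
    venn_table, venn_regions = integ.venn_counts(
        {"targets": set(target_genes), "rna_down": rna_down, "protein_down": prot_down}
    )
    venn_table.to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    (out / "venn_regions.json").write_text(
        json.dumps({k: sorted(v) for k, v in venn_regions.items()}, indent=2) + "\n"
    )
    rna.to_csv(out / "rna_de.tsv", sep="\t", index=False)
    protein.to_csv(out / "protein_de.tsv", sep="\t", index=False)
    prot_records.to_csv(out / "protein_de_recomputed.tsv", sep="\t", index=False)
    corr = (
        integ.edits_vs_expression_correlation(gene_table, rna)
        if len(gene_table) >= 10
        else {"rho": float("nan"), "p_value": float("nan"), "n": len(gene_table)}
    )
    done(
        n_rna_down=len(rna_down), n_protein_down=len(prot_down),
        venn={row["region"]: int(row["count"]) for _, row in venn_table.iterrows()},
        planted_triple=len(omics_truth["triple"]),
        edit_expression_rho=None if np.isnan(corr["rho"]) else round(corr["rho"], 4),
    )

    # --- division scoring -------------------------------------------------
    done = stage("division")
    pairs = sim.simulate_daughter_pairs(
        config.n_pairs, mix=config.division_mix, seed=config.seed + 3, n_replicates=3
    )
    classified = div.classify_numb_pairs(pairs, high_threshold=200.0)
    classified.to_csv(out / "numb_pairs_classified.tsv", sep="\t", index=False)
    summary = div.summarize_divisions(classified)
    summary["fractions_by_replicate"].to_csv(out / "division_fractions.tsv", sep="\t")
    cells = sim.simulate_polarity_cells(
        config.n_polarity_cells, frac_polar=config.frac_polar, seed=config.seed + 4
    )
    scored = div.score_polarity_cells(cells, threshold=config.polarity_log2fc)
    scored.to_csv(out / "polarity_cells_scored.tsv", sep="\t", index=False)
    done(
        n_pairs=len(pairs),
        class_counts=classified["class"].value_counts().to_dict(),
        n_cells=len(cells),
        frac_polar_scored=round(float(scored["polar"].mean()), 4),
    )

    # --- report -----------------------------------------------------------
    report["survival_check"] = {
        "calls_tsv_rows": _count_lines(out / "calls.tsv"),
        "n_calls": report["stages"]["edit_calling"]["n_calls"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report
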