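"""Readers and writers for the pipeline's on-disk formats.

Tabular data travel as TSV with a header row; transcript models as BED-like
TSV (0-based, half-open); sequences as FASTA (DNA alphabet on disk, RNA
alphabet in memory); calls additionally as a VCF-like text file (1-based
positions on write).
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimulatedEditDataset

_DNA2RNA = str.maketrans("Tt", "Uu")
_RNA2DNA = str.maketrans("Uu", "Tt")


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"site_id", "gene", "chrom", "pos", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def write_transcripts_tsv(transcripts: pd.DataFrame, path) -> None:
    bed = transcripts[["chrom", "start", "end", "gene", "transcript_id", "strand", "region"]]
    bed.to_csv(path, sep="\t", index=False)


def read_transcripts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df[["gene", "transcript_id", "chrom", "strand", "region", "start", "end"]]


def write_fasta(sequences: dict[str, str], path) -> None:
    """Write RNA-alphabet sequences as DNA-alphabet FASTA."""
    records = [
        SeqRecord(Seq(seq.translate(_RNA2DNA)), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA, returning uppercase RNA-alphabet sequences."""
    return {
        rec.id: str(rec.seq).upper().translate(_DNA2RNA)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_edit_dataset(ds: SimulatedEditDataset, outdir) -> dict[str, Path]:
    """Write all artefacts of a simulated dataset; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "transcripts": outdir / "transcripts.tsv",
        "sequences": outdir / "sequences.fasta",
        "truth": outdir / "truth.tsv",
        "config": outdir / "sim_config.json",
    }
    write_counts_tsv(ds.counts, paths["counts"])
    write_transcripts_tsv(ds.transcripts, paths["transcripts"])
    write_fasta(ds.sequences, paths["sequences"])
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    from dataclasses import asdict

    cfg = asdict(ds.config)
    cfg["conditions"] = list(cfg["conditions"])
    cfg["region_weights"] = list(cfg["region_weights"])
    paths["config"].write_text(json.dumps(cfg, indent=2) + "\n")
    return paths


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_calls_vcf(calls: pd.DataFrame, path) -> None:
    """Write calls as a minimal VCF-like text file (positions 1-based)."""
    lines = ["##fileformat=VCFv4.2", "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    for _, row in calls.iterrows():
        ref, alt = ("A", "G") if row.get("strand", "+") == "+" else ("T", "C")
        info = (
            f"F_ADAR={row['f_adar']:.6g};F_EV={row['f_ev']:.6g};"
            f"DELTA_F={row['delta_f']:.6g};Q={row['q_value']:.6g};"
            f"REGION={row.get('region', 'other')};GENE={row['gene']}"
        )
        lines.append(
            f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['site_id']}\t{ref}\t{alt}\t.\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
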