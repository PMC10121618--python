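# tribekit

Analysis pipeline for ADAR-fusion (HyperTRIBE) RNA-editing experiments that
identify the direct mRNA targets of an RNA-binding protein (RBP), and for
the analyses that surround such a target list in a stem-cell study:

* **Edit calling** — from per-site reference/alternate read counts in
  RBP-ADAR ("S_ADAR") vs empty-vector ("EV") replicates, call A→G editing
  events with a two-sided Fisher exact test on pooled counts (or a
  replicate-aware beta-binomial likelihood-ratio test), Benjamini–Hochberg
  FDR < 0.05 and differential editing frequency
  Δf = f̄_S-ADAR − f̄_EV > 0.1; annotate sites with their genic region
  (5'UTR/CDS/3'UTR) and collapse to gene-level targets.
* **Motif analysis** — presence/absence k-mer enrichment (k 4–7, one-sided
  binomial vs a matched background, BH-corrected) in ±250 nt windows around
  edit sites, and signed nearest-motif distance densities.
* **Multi-omics integration** — total-intensity normalisation of label-free
  proteomics, per-gene log2 fold changes with one-sided Wilcoxon rank
  tests, differential-expression filters (inclusive |FC| ≥ 2, strict FDR),
  Venn intersections of target/transcriptome/proteome gene sets, and the
  edit-count vs expression rank correlation.
* **Division scoring** — classification of paired daughter cells
  (NUMB: ratio ≥ 2 asymmetric; LAMP1/TMI: |log2FC| ≥ 0.6 asymmetric;
  tubulin polarity: |log2FC| > 0.6 strict), marker co-segregation, and
  per-genotype summaries with replicate-level t-tests.
* **Synthetic data** — generators for every input (beta-binomial editing
  counts with planted true sites and motifs, expression tables with planted
  set intersections, division/polarity mixtures) with recorded ground
  truth, so the whole pipeline is testable end to end.

## Worked example

```python
import tribekit as tk
from tribekit.motifs import extract_context_sequences, sample_background_windows, rank_kmers

cfg = tk.EditSimConfig(n_genes=500, effect_delta=0.3, seed=42)
ds = tk.simulate_edit_dataset(cfg)

calls = tk.annotate_sites(tk.call_edits(ds.counts), ds.transcripts)
genes, hist = tk.summarize_targets(calls)
print(f"{len(ds.counts)} candidate sites -> {len(calls)} called edit events on {len(genes)} genes")
print(calls.head(3)[["site_id", "region", "f_adar", "f_ev", "delta_f", "q_value"]].to_string(index=False))

fg = extract_context_sequences(calls, ds.transcripts, ds.sequences)
bg = sample_background_windows(ds.sequences, ds.transcripts, calls["gene"].unique(),
                               2 * len(fg), seed=43, regions=sorted(fg["region"].unique()))
print(rank_kmers(fg["seq"], bg["seq"], (6, 6)).head(3).to_string(index=False))
```

prints

```
726 candidate sites -> 232 called edit events on 186 genes
   site_id region   f_adar  f_ev  delta_f      q_value
g0488:1601   3UTR 0.319632   0.0 0.319632 5.428996e-49
g0116:1133   3UTR 0.373236   0.0 0.373236 7.422421e-47
  g0022:88   5UTR 0.338199   0.0 0.338199 5.932491e-45
  kmer  fg_count  fg_total  bg_count  bg_total  enrichment       q_value
ACUUAG       232       232        47       464    9.872340 8.070334e-228
AACUUA        97       232        50       464    3.880000  1.145344e-30
CUUAGC        74       232        31       464    4.774194  2.143151e-27
```

Each called site reports its mean editing frequency per condition, their
difference Δf, and the BH-adjusted q-value; most calls land in the 3'UTR,
where the generator plants most true sites. The k-mer table recovers the
planted ACUUAG motif as the top-ranked 6-mer: present in all 232 foreground
windows against a ~10% background presence rate.

The same stages are available from the shell:

```bash
tribekit simulate --n-genes 500 --seed 42 --out-dir out/sim
tribekit call-edits --counts out/sim/counts.tsv --transcripts out/sim/transcripts.tsv \
    --alpha 0.05 --min-delta 0.1 --min-depth 10 --out out/calls.tsv
tribekit motif --calls out/calls.tsv --fasta out/sim/sequences.fasta \
    --transcripts out/sim/transcripts.tsv --out out/motifs.tsv
tribekit run-all --seed 42 --out-dir out/full   # all stages + report.json
```

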