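# miromics

Integrative miRNome / transcriptome / proteome analysis of retinoic-acid
(RA)-induced differentiation of unrestricted somatic stem cells (USSC),
built as a tested, reusable pipeline. It is aimed at computational
biologists who want to reproduce — or stress-test on data with known
ground truth — the analysis chain behind the conclusion that miRNAs act
as fine-tuners rather than primary switches of the differentiating
proteome: transcription explains most protein regulation, and ectopic
perturbation of individual miRNAs moves only a small, predicted-target-
enriched set of proteins.

The pipeline starts at count and abundance matrices (read alignment and
spectral processing are out of scope) and covers:

- **Expression quantification** — CPM normalisation (`CPM = count · 10⁶ /
  library size`), expression and protein-coding filters, per-timepoint
  fold changes `log2FC = log2(mean CPM_t / mean CPM_native)` (means over
  cell lines), per-feature pooled-variance t-tests on log2(CPM + 0.5)
  with Benjamini–Hochberg correction, and the shared significance gate
  *p* < 0.01 ∧ *q* < 0.05 ∧ FC > 1.5. miRNAs significant at 3d, 7d and
  14d with one direction form the consistently regulated set.
- **Proteome statistics** — per-protein one-way ANOVA across timepoints
  (BH across proteins) with Tukey HSD post-hoc (Tukey–Kramer for
  unbalanced groups), replicate-correlation QC, PCA scores and volcano
  tables.
- **Integration** — gene↔protein joining via an explicit identifier map,
  coverage, quadrant classification of parallel/inverse regulation,
  Pearson correlation of fold changes (overall and on significant
  subsets), Venn region counts, and CV-filtered Pearson-distance
  clustering for heatmap ordering.
- **miRNA-target networks** — 12-algorithm prediction tables with
  per-pair support counts, bipartite inverse-regulation networks
  (support ≥ 5 by default) exported as GraphML/SIF/TSV, and the
  transfection crossmatch that intersects mimic/inhibitor-responsive
  proteins with predicted targets and with inversely regulated proteins
  of the untreated time course.
- **Synthetic data** — a generator for the complete study design
  (negative-binomial counts for 3 lines × 4 timepoints, coupled protein
  abundances for 6 lines × 3 timepoints, prediction tables with
  controlled sensitivity/false-positive rate, transfection proteomes
  with planted target effects) with stored ground truth, so every stage
  runs and calibrates without any external download.

A transcription of the reference time-course table of regulated miRNAs
(mean CPM at four timepoints, per-timepoint log2FC and significance
flags) ships with the package (`miromics.datasets.load_mirna_timecourse`).

## Worked example

```python
import numpy as np
from miromics import SynthConfig, PipelineConfig
from miromics import datasets, expression, integrate, proteome
from miromics.simulate import simulate_counts, simulate_proteome

# recompute a printed fold change from the packaged reference table
table = datasets.load_mirna_timecourse().set_index("mirna")
row = table.loc["hsa-miR-221-5p"]
fc = np.log2(row["cpm_d3"] / row["cpm_native"])
print(f"miR-221-5p 3d: recomputed log2FC = {fc:.3f} -> rounds to {expression.round_half_away(fc, 1)}")

# simulate the study design and measure mRNA-protein concordance
cfg = SynthConfig(seed=1)
mrna, rna_truth = simulate_counts(cfg, "mrna_counts")
prot, prot_truth, gmap = simulate_proteome(cfg, rna_truth)
de = expression.run_de(mrna, PipelineConfig())
da = proteome.differential_abundance(prot)
res = integrate.join_omics(de["d3"], da["d3"], gmap)
print(f"proteome covered by transcriptome: {100 * res.coverage:.0f}%")
print(f"fold-change correlation, all pairs:        r = {integrate.fc_correlation(res.table, 'all'):.2f}")
print(f"fold-change correlation, significant mRNA: r = {integrate.fc_correlation(res.table, 'significant_mrna'):.2f}")
```

prints

```
miR-221-5p 3d: recomputed log2FC = -2.845 -> rounds to -2.8
proteome covered by transcriptome: 96%
fold-change correlation, all pairs:        r = 0.58
fold-change correlation, significant mRNA: r = 0.85
```

The first line shows that the downregulation of miR-221-5p printed in the
reference table (−2.8 at 3d) is exactly the rounded log2 ratio of its
mean CPM columns. The synthetic study then reproduces the integration
story: 96% of quantified proteins have a transcript counterpart, mRNA and
protein fold changes correlate moderately overall (the true coupling is
ρ = 0.65; count noise attenuates the estimate), and the correlation
rises sharply when only significantly regulated transcripts are kept —
transcription, not post-transcriptional regulation, dominates protein
abundance changes.

The same stages are available as a CLI:

```bash
miromics simulate --seed 1 --out data/
miromics de --in data/ --out out/
miromics proteome --in data/ --out out/
miromics integrate --in data/ --de-dir out/ --out out/
miromics network --in data/ --de-dir out/ --out out/
miromics crossmatch --in data/ --de-dir out/ --out out/ \
    --mirna hsa-miR-S00000 --mode mimic
miromics table1-check
```

Every run logs the full threshold set, so each reported count is
reproducible from the log alone.

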