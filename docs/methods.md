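# Methods

`miromics` re-implements, as a tested pipeline, an integrative analysis of
miRNome, transcriptome and proteome during retinoic-acid (RA)-induced
differentiation of unrestricted somatic stem cells (USSC): native cells and
cells incubated in RA-containing differentiation medium for 3, 7 and (for
RNA only) 14 days. This note records the statistical procedures, the
synthetic-data model that stands in for the deposited raw data, and the
design choices made where the design was genuinely open.

## Expression quantification (mRNA / miRNA counts)

Counts are intra-sample normalised to counts per million (CPM): each
sample's counts are scaled by 10^6 / library size. No between-sample
scaling factor (such as trimmed-mean-of-M normalisation) is applied; depth
normalisation alone matches the convention the downstream fold-change
arithmetic assumes.

Filters, in order:

1. **Expression floor** — a feature is kept if its mean CPM across cell
   lines exceeds `cpm_floor` (default 1) at one or more timepoints. The
   filter is evaluated at timepoint granularity, not per sample, because
   that is the granularity at which "expressed at a timepoint" is
   meaningful for three donor lines.
2. **Protein-coding filter** (mRNA only, optional) — an order-preserving
   intersection with an externally supplied protein-coding identifier
   list. The identifier namespace is deliberately an explicit input (a
   list and a gene-protein mapping table), never an inferred join.

**Fold change.** The reported log2FC of a timepoint vs native is
`log2(mean CPM_t / mean CPM_native)` with means over cell lines and
pseudocount 0; an undefined ratio (zero denominator) is reported as
missing, never as a silent infinity. This ratio-of-means convention with
no pseudocount is what reproduces the reference miRNA table's printed
values to one decimal. For display, values are rounded half away from
zero. The differential test carries a second, pseudocounted effect column
(`log2fc_eff`, pseudocount 0.5) so that the significance gate never
depends on a missing value.

**Differential test.** Per feature, a two-sided pooled-variance t-test on
`log2(CPM + 0.5)` between the timepoint's lines and the native lines,
with Benjamini-Hochberg (BH) step-up correction within each contrast.
The pooled (equal-variance) form was chosen over Welch's test after
measuring both: the noise model is homoscedastic on the log scale (one
dispersion shared across groups), and at three replicates per group
Welch's estimated degrees of freedom make it markedly conservative — true
size ≈0.005 at nominal 0.01 even on Gaussian data, ≈0.004 on simulated
counts, versus ≈0.008 for the pooled test. This per-feature test is
deliberately simpler than a moderated count model; it borrows no strength
across features, so with n = 3 lines it is substantially less powerful
than empirical-Bayes machinery, and dataset-level discovery counts are
expected to undershoot what a moderated analysis of the same design
reports. Its calibration (type-I error, FDR, power on planted effects) is
what the test suite verifies.

**Significance gate.** Everywhere in the package one triple gate defines
"significant": p < 0.01, BH q < 0.05, and fold change > 1.5
(|log2FC| > log2 1.5 ≈ 0.585). BH is applied per contrast. The gate's
thresholds live in `PipelineConfig` and every CLI run logs the full set,
so any reported count is reproducible from the log alone.

**Consistently regulated miRNAs.** A miRNA is selected when it passes the
gate at 3d, 7d and 14d with the same direction. The headline summary
splits regulated miRNAs into those downregulated *from* a mean CPM > 100
in native cells and those upregulated *to* a mean CPM > 100 at any
treated timepoint.

## Proteome statistics

Label-free protein abundances (6 lines × native/3d/7d; quantification
requires ≥ 2 unique peptides, applied at ingest) are log2-transformed by
default — label-free intensities are approximately log-normal and log
scale makes fold changes additive; the transform is exposed as a flag.

Per protein: one-way fixed-effects ANOVA across timepoints, BH across
proteins, then a Tukey HSD post-hoc (studentized-range distribution;
Tukey–Kramer adjustment for unbalanced groups) restricted to
ANOVA-significant proteins. A protein is differentially abundant at
timepoint t iff ANOVA q < 0.05 AND Tukey p(t vs native) < 0.01 AND
|log2FC| > log2 1.5. The gate order matters only for logging. The Tukey
p-values are computed vectorised over features and are identical to
`scipy.stats.tukey_hsd` (asserted in the tests). Features with zero
within-group variance everywhere get a missing p and a `degenerate` flag;
proteins with missing values in a contrast would be excluded
complete-case (the generator produces complete matrices).

The observation that no protein flips direction between 3d and 7d is
implemented as a *check* (`direction_flip_report`), not an assumption;
the time-course inverse set treats a flip as a validation error by
default and offers an explicit drop-with-warning policy for data where
mild inconsistency is planted by design.

QC and visualisation numbers: pairwise Pearson correlation of samples on
log2 abundance (diagonal 1, constant samples → missing), centered-SVD PCA
scores with the component sign fixed by a non-negative first loading
(reproducibility convention), and volcano tables (log2FC, −log10 p,
gate flag).

## Integration (mRNA ↔ protein)

Differential tables join via the explicit gene-protein map;
many-to-many relations are expanded to all pairs with a logged warning
rather than silently picking one. Coverage is the fraction of quantified
proteins represented by a transcript. Concordance is quantified by:

- **Quadrant counts** — parallel / inverse / one-sided regulation under
  either the full significance gate (`both_significant`) or a pure
  fold-change gate (`fc_only`, |log2FC| > log2 1.5 on both sides with
  significance ignored). Both gates are implemented because the inverse-
  regulation counts quoted for non-significant pairs use the FC-only
  convention; the mode is an explicit argument.
- **Fold-change correlation** — Pearson r over (mRNA log2FC, protein
  log2FC) pairs, either all pairs or those whose mRNA passes the full
  gate. Restricting to regulated transcripts raises the correlation
  because planted effects dominate the measurement noise.
- **Venn region counts** for 2–3 named sets (exclusive regions, labels =
  '&'-joined sorted names), checked against brute-force enumeration.

Heatmap support: features pass a coefficient-of-variation filter
(sd/mean on the analysis scale; threshold default 0.1, unspecified
upstream and therefore configurable and logged), are ordered by
agglomerative clustering with distance 1 − Pearson r and average linkage
(the default of the common heatmap tooling; exposed as a parameter), and
rows are z-scored for display. Plotting itself is out of scope; the
package computes orders and scaled matrices.

## miRNA target predictions and networks

Predictions are ingested as long-format (miRNA, gene, algorithm) triples
over a fixed panel of 12 algorithms (miRWalk, miRDB, PITA, MicroT4,
miRMap, RNA22, miRanda, miRNAMap, RNAhybrid, miRBridge, PicTar2,
Targetscan). Names are normalised (case-insensitive, optional `hsa-`
prefix restored) and isoform-level duplicates collapse before support
counting — support is the number of *distinct* algorithms per pair, never
the number of binding sites. Running any prediction algorithm is out of
scope; tables are inputs.

The inverse-regulation networks connect miRNAs regulated consistently
across all three timepoints to proteins significantly regulated in the
opposite direction at 3d and/or 7d whose (miRNA, gene) pair is supported
by ≥ `min_support` algorithms (default 5 of 12). Two bipartite graphs are
built (down-miRNAs × up-proteins, up-miRNAs × down-proteins); protein
nodes carry their predicting-miRNA count. With independent algorithms at
false-positive rate 0.02, P(false pair reaches support ≥ 5) is the
binomial tail ≈ 2.3 × 10⁻⁶, so network edges are overwhelmingly planted
targets — the rationale for the support filter, asserted statistically in
the tests.

The transfection crossmatch takes the support rule as an explicit
argument because the two workflows differ deliberately: networks use
≥ 5 algorithms, the crossmatch uses any-algorithm predictions. Its
counts, in order: quantified proteins; predicted targets among them;
regulated up/down; regulated in the expected direction (down for a mimic,
up for an inhibitor) ∩ predicted; and the overlap of that set with
predicted targets inversely regulated in the untreated time course
(up in the time course for a mimic of a downregulated miRNA, down for an
inhibitor). The report validates its own invariants (overlap ≤ both
parents, every count ≤ quantified).

## Synthetic data generator

The generator emulates the full study design with known ground truth; its
defaults are the study conditions used by every calibration test.

- **Counts** (mRNA: 13,000 features, miRNA: 600; 3 lines × 4 timepoints):
  negative binomial with dispersion 0.1 shared across features (a
  standard RNA-seq noise model at donor-line replication), mean =
  baseline × 2^(line effect + timepoint effect). Baseline relative
  abundances are gamma-distributed (long-tailed); library sizes are
  1.5 × 10⁷ (mRNA) / 5 × 10⁶ (miRNA) reads × Uniform[0.7, 1.3];
  per-feature-per-line effects are N(0, 0.2²) log2 and persist across
  timepoints, so they cancel in fold changes vs native.
- **Planted regulation**: per feature, probability 0.18 up / 0.12 down;
  magnitudes Uniform[log2 1.5, 3] drawn per timepoint; the native
  timepoint carries no effect. A configurable 90% of regulated features
  keep one sign across timepoints (sign consistency is a knob precisely
  because the consistent-direction miRNA filter only matters when some
  features are inconsistent). The regulated fraction (30%) is above the
  ~17% detected under the stringent gate at n = 3, reflecting that true
  regulation exceeds what that design can call significant.
- **Proteome** (1,800 proteins, 6 lines × native/3d/7d): 96% of proteins
  map to mRNA genes, sampled with probability proportional to transcript
  abundance (label-free MS detects predominantly abundant products).
  Protein true log2FC = ρ·(mRNA log2FC) + √(1−ρ²)·σ·ε with ρ = 0.65 and σ
  the mRNA effect spread, so the population correlation of true fold
  changes is ρ; ε is drawn once per protein and shared across timepoints
  (protein-level regulation rarely reverses between 3d and 7d), and a 1%
  minority is sign-flipped (inverse regulation). Observed abundance =
  2^(baseline + true FC + line effect + N(0, 0.4)) with baseline log2
  intensities N(20, 2). Count noise attenuates the *estimated* FC
  correlation from 0.65 to ≈ 0.58–0.60 at these settings — the same
  attenuation any real count-based estimate carries.
- **Predictions**: each of the 12 algorithms independently reports each
  planted pair (200 targets per miRNA) with sensitivity 0.6 and each
  false pair with false-positive rate 0.02. Real prediction algorithms
  are correlated; independence is the simplest controllable null and is
  used as such.
- **Transfections**: paired transfected / scrambled-control groups of
  3 replicate wells of one line at 3d. Both groups share the 3d
  time-course shift; quantified true targets additionally get −1.0 log2
  (mimic) or +0.7 (inhibitor; inhibition is the weaker perturbation), and
  5% of off-target proteins get indirect shifts ~N(0, 0.5) — ectopic
  transfection produces widespread secondary effects. Replicate noise is
  0.1 log2 (≈7% CV): these are technical replicate wells of a single
  clonal line, far more precise than cross-donor biological replicates.
  With ~30 quantified targets among ~1,800 proteins, the BH step-up
  effectively requires p ≲ 10⁻³; the indirect-effect burden and
  technical-replicate precision are what make ≥80% target recovery
  attainable at n = 3 under the triple gate — at cross-donor noise levels
  the same design would recover almost nothing.

Determinism: every stage draws from `default_rng([seed, stream...])`
substreams, so identical configs give bit-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated prediction algorithms, missing
protein values, isoform structure, count composition biases beyond
library size, batch effects, and any sequence-level biology. Calibration
results transfer to real data only to the extent the noise model does.

## Numerical conventions

- BH step-up implemented once (`bh_fdr`) and shared by all branches;
  ties are handled by a stable sort and are safe by construction;
  q capped at 1. Checked against a brute-force tail-minimum oracle.
- Zero-variance degenerate rows in t-tests: p = 1 when the group means
  agree, 0 when a noiseless difference is planted.
- Rounding for table display: half away from zero, one decimal.
- Matrix text IO parses floats via correctly-rounded `float()`, so
  write-then-read round trips are bit-exact.
- PCA sign fix: first feature's loading forced non-negative.
- Correlation of a constant sample: reported missing, never 0.

## Known limitations

- The per-feature t-test underpowers small-n designs relative to
  moderated count models; at the default study conditions the
  three-timepoint consistent-miRNA gate is rarely cleared in simulation
  (the selection logic is validated on the packaged reference table
  instead), and the networks built from a default synthetic run are
  typically empty.
- ANOVA assumes homoscedastic log-scale noise across timepoints.
- The crossmatch treats gene identity as exact; no orthology or isoform
  resolution.
- Problem sizes in the test suite are scaled down (e.g. 2,000-feature
  null panels, 20-seed power runs) — chosen as the smallest sizes at
  which the Monte-Carlo error is well below the asserted margins.
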