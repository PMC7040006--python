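"""Synthetic study generator with known ground truth.

Emulates the full experimental design — mRNA and miRNA counts for 3 cell
lines at native/3d/7d/14d, log-scale protein abundances for 6 lines at
native/3d/7d, an mRNA-coupled protein fold-change structure, a
12-algorithm target-prediction table, and mimic/inhibitor transfection
proteomes — so every pipeline stage runs with no external download and
every call can be checked against stored truth.

Counts follow a negative binomial with a dispersion shared across
features; per-feature per-line effects model donor variation; treated
timepoints add planted log2 effects to a configurable fraction of
features. Protein true fold changes are a correlated mixture of the mRNA
truth (population correlation = ``rho_mrna_protein``) with a small
inversely regulated minority. Prediction algorithms report true pairs
with a per-algorithm sensitivity and false pairs with a small
false-positive rate, independently of each other.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GeneProteinMap, OmicsMatrix, SampleMeta

RNA_LINES = ("4/101", "4/146", "5/03")
PROTEIN_LINES = ("4/101", "4/146", "5/03", "5/73", "7/18", "8/77")
TRANSFECTION_LINE = "5/03"
RNA_TIMEPOINTS = ("native", "d3", "d7", "d14")
PROTEIN_TIMEPOINTS = ("native", "d3", "d7")


@dataclass
class SynthConfig:
    """Generator parameters; defaults define the study conditions.

    Effects are on the log2 scale throughout. ``frac_up``/``frac_down``
    are the per-feature probabilities of a planted up/down regulation
    program (sign shared across timepoints for a ``frac_consistent``
    majority). Transfection runs model replicate wells of a single line,
    hence the tighter ``transfection_noise_sd``; ``frac_indirect`` of
    quantified proteins receive secondary (indirect) shifts.
    """

    seed: int = 0
    n_lines_rna: int = 3
    n_lines_protein: int = 6
    n_mrna: int = 13000
    n_mirna: int = 600
    n_protein: int = 1800
    protein_mrna_coverage: float = 0.96
    lib_size_mrna: float = 1.5e7
    lib_size_mirna: float = 5e6
    nb_dispersion: float = 0.1
    line_effect_sd: float = 0.2
    frac_up: float = 0.18
    frac_down: float = 0.12
    frac_consistent: float = 0.9
    effect_low: float = math.log2(1.5)
    effect_high: float = 3.0
    rho_mrna_protein: float = 0.65
    frac_inverse: float = 0.01
    protein_noise_sd: float = 0.4
    pred_sensitivity: float = 0.6
    pred_fp_rate: float = 0.02
    n_algorithms: int = 12
    true_targets_per_mirna: int = 200
    mimic_effect: float = -1.0
    inhibitor_effect: float = 0.7
    transfection_noise_sd: float = 0.1
    n_transfection_reps: int = 3
    frac_indirect: float = 0.05
    indirect_effect_sd: float = 0.5

    def __post_init__(self) -> None:
        for name in ("frac_up", "frac_down", "frac_consistent", "frac_inverse",
                     "pred_sensitivity", "pred_fp_rate", "protein_mrna_coverage",
                     "frac_indirect"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        if not (-1.0 < self.rho_mrna_protein < 1.0):
            raise ValueError("rho_mrna_protein must be in (-1, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def rng(self, *stream: int) -> np.random.Generator:
        """Independent, reproducible substream keyed by (seed, stream...)."""
        return np.random.default_rng([self.seed, *stream])


@dataclass
class GroundTruth:
    """Planted truth for one modality (plus study-level annex fields)."""

    true_log2fc: pd.DataFrame  # features x treated timepoints
    baseline_log2: pd.Series  # per-feature baseline (log2 CPM or abundance)
    regulated: pd.DataFrame = None  # bool, features x treated timepoints
    target_sets: dict[str, set[str]] = field(default_factory=dict)
    responsive: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.regulated is None:
            self.regulated = self.true_log2fc.abs() > math.log2(1.5)

    def direction(self, timepoint: str) -> pd.Series:
        fc = self.true_log2fc[timepoint]
        return pd.Series(
            np.where(~self.regulated[timepoint], "none", np.where(fc > 0, "up", "down")),
            index=fc.index,
        )


# ---------------------------------------------------------------------------
# counts (mRNA / miRNA)
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def _planted_effects(
    cfg: SynthConfig, rng: np.random.Generator, n: int, timepoints: tuple[str, ...]
) -> pd.DataFrame:
    """Per-feature true log2FC per treated timepoint with consistent signs
    for a ``frac_consistent`` majority of regulated features."""
    treated = [t for t in timepoints if t != "native"]
    u = rng.random(n)
    sign = np.zeros(n)
    sign[u < cfg.frac_up] = 1.0
    sign[(u >= cfg.frac_up) & (u < cfg.frac_up + cfg.frac_down)] = -1.0
    fc = pd.DataFrame(0.0, index=range(n), columns=treated)
    de = sign != 0
    for t in treated:
        mag = rng.uniform(cfg.effect_low, cfg.effect_high, size=n)
        fc.loc[de, t] = sign[de] * mag[de]
    if treated and cfg.frac_consistent < 1.0:
        flip = de & (rng.random(n) >= cfg.frac_consistent)
        which = rng.integers(0, len(treated), size=n)
        for j, t in enumerate(treated):
            rows = flip & (which == j)
            fc.loc[rows, t] *= -1.0
    return fc


def simulate_counts(cfg: SynthConfig, modality: str = "mrna_counts") -> tuple[OmicsMatrix, GroundTruth]:
    """NB counts for ``n_lines_rna`` lines at native/3d/7d/14d.

    Counts are drawn with mean = baseline x 2^(line effect + timepoint
    effect); the native timepoint carries no timepoint effect; library
    sizes vary uniformly over x[0.7, 1.3] of the nominal depth.
    """
    if modality not in ("mrna_counts", "mirna_counts"):
        raise ValueError(f"unknown counts modality {modality!r}")
    stream = 1 if modality == "mrna_counts" else 2
    rng = cfg.rng(stream)
    n = cfg.n_mrna if modality == "mrna_counts" else cfg.n_mirna
    prefix = "G" if modality == "mrna_counts" else "hsa-miR-S"
    features = [f"{prefix}{i:05d}" for i in range(n)]
    lib_nominal = cfg.lib_size_mrna if modality == "mrna_counts" else cfg.lib_size_mirna

    # long-tailed relative abundance; log2 CPM spread matches bulk profiles
    rel = rng.gamma(0.6, size=n)
    rel /= rel.sum()
    fc = _planted_effects(cfg, rng, n, RNA_TIMEPOINTS)
    fc.index = features
    lines = RNA_LINES[: cfg.n_lines_rna]
    line_eff = rng.normal(0.0, cfg.line_effect_sd, size=(n, len(lines)))

    columns, samples = {}, []
    for j, line in enumerate(lines):
        for t in RNA_TIMEPOINTS:
            lib = lib_nominal * rng.uniform(0.7, 1.3)
            shift = fc[t].to_numpy() if t != "native" else 0.0
            mean = rel * lib * 2.0 ** (line_eff[:, j] + shift)
            sid = f"{modality.split('_')[0]}_{line.replace('/', '-')}_{t}"
            columns[sid] = _nb_draw(rng, mean, cfg.nb_dispersion)
            samples.append(SampleMeta(sid, line, t, "untreated", modality))

    values = pd.DataFrame(columns, index=pd.Index(features, name="feature_id"))
    truth = GroundTruth(
        true_log2fc=fc,
        baseline_log2=pd.Series(np.log2(rel * 1e6), index=features, name="baseline_log2cpm"),
    )
    return OmicsMatrix(values, samples), truth


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def simulate_proteome(
    cfg: SynthConfig, rna_truth: GroundTruth
) -> tuple[OmicsMatrix, GroundTruth, GeneProteinMap]:
    """Protein abundances for 6 lines at native/3d/7d, coupled to mRNA truth.

    Protein true log2FC = rho * mRNA log2FC + sqrt(1 - rho^2) * sigma * eps
    with sigma the mRNA fold-change spread, so the population correlation
    of true fold changes equals ``rho_mrna_protein``; a ``frac_inverse``
    minority gets sign-flipped effects. Mapped genes are sampled with a
    bias toward higher baseline expression (detectability by MS). Observed
    abundance = baseline x 2^(true FC + line effect + N(0, noise_sd)).
    """
    rng = cfg.rng(3)
    genes = rna_truth.true_log2fc.index
    n_mapped = int(round(cfg.n_protein * cfg.protein_mrna_coverage))
    if n_mapped > len(genes):
        raise ValueError("protein set is not a subset of the mapped gene universe")
    # detectability bias: label-free MS quantifies predominantly abundant
    # gene products, so sampling weight is proportional to transcript abundance
    w = 2.0 ** rna_truth.baseline_log2.to_numpy()
    w /= w.sum()
    mapped_genes = rng.choice(np.asarray(genes), size=n_mapped, replace=False, p=w)
    n_unmapped = cfg.n_protein - n_mapped

    protein_ids = [f"P{i:05d}" for i in range(cfg.n_protein)]
    pairs = pd.DataFrame(
        {"protein_id": protein_ids[:n_mapped], "gene_id": mapped_genes}
    )
    gmap = GeneProteinMap(pairs)

    treated = [t for t in PROTEIN_TIMEPOINTS if t != "native"]
    rho = cfg.rho_mrna_protein
    mfc = rna_truth.true_log2fc.loc[mapped_genes, treated].to_numpy()
    sigma = rna_truth.true_log2fc[treated].to_numpy().std()
    # protein-specific deviation is persistent across timepoints (protein-level
    # regulation such as translation/stability rarely reverses between 3d and 7d)
    eps = np.repeat(rng.normal(0.0, 1.0, size=(n_mapped, 1)), len(treated), axis=1)
    pfc_mapped = rho * mfc + math.sqrt(1.0 - rho**2) * sigma * eps
    flip = rng.random(n_mapped) < cfg.frac_inverse
    pfc_mapped[flip] *= -1.0
    pfc_unmapped = sigma * np.repeat(
        rng.normal(0.0, 1.0, size=(n_unmapped, 1)), len(treated), axis=1
    )
    pfc = pd.DataFrame(
        np.vstack([pfc_mapped, pfc_unmapped]), index=protein_ids, columns=treated
    )

    base = pd.Series(rng.normal(20.0, 2.0, size=cfg.n_protein), index=protein_ids)
    lines = PROTEIN_LINES[: cfg.n_lines_protein]
    line_eff = rng.normal(0.0, cfg.line_effect_sd, size=(cfg.n_protein, len(lines)))

    columns, samples = {}, []
    for j, line in enumerate(lines):
        for t in PROTEIN_TIMEPOINTS:
            shift = pfc[t].to_numpy() if t != "native" else 0.0
            noise = rng.normal(0.0, cfg.protein_noise_sd, size=cfg.n_protein)
            sid = f"prot_{line.replace('/', '-')}_{t}"
            columns[sid] = 2.0 ** (base.to_numpy() + shift + line_eff[:, j] + noise)
            samples.append(SampleMeta(sid, line, t, "untreated", "protein_abundance"))

    values = pd.DataFrame(columns, index=pd.Index(protein_ids, name="feature_id"))
    truth = GroundTruth(true_log2fc=pfc, baseline_log2=base.rename("baseline_log2"))
    return OmicsMatrix(values, samples), truth, gmap


# ---------------------------------------------------------------------------
# target predictions
# ---------------------------------------------------------------------------

def assign_targets(cfg: SynthConfig, truth: GroundTruth, mirnas) -> None:
    """Plant ``true_targets_per_mirna`` target genes for each listed miRNA."""
    rng = cfg.rng(4)
    genes = np.asarray(truth.true_log2fc.index)
    for m in mirnas:
        chosen = rng.choice(genes, size=cfg.true_targets_per_mirna, replace=False)
        truth.target_sets[str(m)] = set(chosen)


def simulate_predictions(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Long-format (mirna, gene, algorithm) table over the planted targets.

    Each of the 12 algorithms independently reports each true pair with
    probability ``pred_sensitivity`` and each false pair with probability
    ``pred_fp_rate``.
    """
    from .networks import ALGORITHMS

    if not truth.target_sets:
        raise ValueError("no target sets planted; call assign_targets first")
    rng = cfg.rng(5)
    genes = np.asarray(truth.true_log2fc.index)
    algorithms = ALGORITHMS[: cfg.n_algorithms]
    frames = []
    for mirna, targets in truth.target_sets.items():
        is_true = np.isin(genes, list(targets))
        prob = np.where(is_true, cfg.pred_sensitivity, cfg.pred_fp_rate)
        hits = rng.random((len(genes), len(algorithms))) < prob[:, None]
        gi, ai = np.nonzero(hits)
        frames.append(
            pd.DataFrame(
                {
                    "mirna": mirna,
                    "gene_id": genes[gi],
                    "algorithm": np.asarray(algorithms)[ai],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# transfections
# ---------------------------------------------------------------------------

def simulate_transfection(
    cfg: SynthConfig,
    base_proteome: OmicsMatrix,
    truth: GroundTruth,
    proteome_truth: GroundTruth,
    gmap: GeneProteinMap,
    mirna: str,
    mode: str = "mimic",
) -> OmicsMatrix:
    """Paired transfected / control replicate groups at 3d.

    Quantified true targets of the miRNA receive the transfection effect
    on the log2 scale (mimic: ``mimic_effect`` < 0; inhibitor:
    ``inhibitor_effect`` > 0); a random ``frac_indirect`` subset of
    off-target proteins receives indirect shifts ~N(0, indirect sd). Both
    groups share the 3d time-course fold change of the untreated study.
    The planted responsive-protein set is recorded in
    ``proteome_truth.responsive[f"{mirna}|{mode}"]``.
    """
    if mode not in ("mimic", "inhibitor"):
        raise ValueError(f"unknown mode {mode!r}")
    if str(mirna) not in truth.target_sets:
        raise ValueError(f"unknown miRNA {mirna!r}: no planted targets")
    rng = cfg.rng(6, 0 if mode == "mimic" else 1, _name_stream(mirna))
    effect = cfg.mimic_effect if mode == "mimic" else cfg.inhibitor_effect

    prot_ids = base_proteome.features
    gene_of = dict(zip(gmap.pairs["protein_id"], gmap.pairs["gene_id"]))
    targets = truth.target_sets[str(mirna)]
    is_target = np.array([gene_of.get(p, p) in targets for p in prot_ids])

    indirect = (~is_target) & (rng.random(len(prot_ids)) < cfg.frac_indirect)
    indirect_shift = np.where(indirect, rng.normal(0.0, cfg.indirect_effect_sd, len(prot_ids)), 0.0)

    base = proteome_truth.baseline_log2.loc[prot_ids].to_numpy()
    tc_shift = proteome_truth.true_log2fc.loc[prot_ids, "d3"].to_numpy()

    columns, samples = {}, []
    label = f"{mode}:{mirna}"
    for cond, shift in ((label, effect * is_target + indirect_shift), ("control_sirna", 0.0)):
        for r in range(cfg.n_transfection_reps):
            noise = rng.normal(0.0, cfg.transfection_noise_sd, size=len(prot_ids))
            sid = f"{'trans' if cond != 'control_sirna' else 'ctrl'}_{_name_stream(mirna)}_{mode}_r{r + 1}"
            columns[sid] = 2.0 ** (base + tc_shift + shift + noise)
            samples.append(SampleMeta(sid, TRANSFECTION_LINE, "d3", cond, "protein_abundance"))

    proteome_truth.responsive[f"{mirna}|{mode}"] = {
        gene_of.get(p, p) for p, hit in zip(prot_ids, is_target) if hit
    }
    values = pd.DataFrame(columns, index=pd.Index(prot_ids, name="feature_id"))
    return OmicsMatrix(values, samples)


def _name_stream(mirna: str) -> int:
    # stable (non-salted) integer stream id for a miRNA name
    return int(np.frombuffer(str(mirna).encode(), dtype=np.uint8).sum())


def split_transfection(m: OmicsMatrix) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Split a paired transfection matrix into (transfected, control)."""
    ctrl_ids = m.sample_ids(condition="control_sirna")
    trans_ids = [s.sample_id for s in m.samples if s.condition != "control_sirna"]
    if not ctrl_ids or not trans_ids:
        raise ValueError("matrix does not contain both transfected and control groups")
    return m.subset_samples(trans_ids), m.subset_samples(ctrl_ids)


# ---------------------------------------------------------------------------
# study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """Everything one run of the full design produces, truth included."""

    cfg: SynthConfig
    mrna: OmicsMatrix
    mrna_truth: GroundTruth
    mirna: OmicsMatrix
    mirna_truth: GroundTruth
    proteome: OmicsMatrix
    proteome_truth: GroundTruth
    gene_map: GeneProteinMap
    predictions: pd.DataFrame
    transfections: dict[str, OmicsMatrix]


#: default transfection panel: two mimics of downregulated miRNAs and one
#: inhibitor of an upregulated miRNA, mirroring the study design
DEFAULT_TRANSFECTIONS = (("hsa-miR-S00000", "mimic"), ("hsa-miR-S00001", "mimic"),
                         ("hsa-miR-S00002", "inhibitor"))


def simulate_study(cfg: SynthConfig, n_target_mirnas: int = 8) -> SyntheticStudy:
    """Generate the complete synthetic study with a consistent design."""
    mrna, mrna_truth = simulate_counts(cfg, "mrna_counts")
    mirna, mirna_truth = simulate_counts(cfg, "mirna_counts")
    proteome, prot_truth, gmap = simulate_proteome(cfg, mrna_truth)
    mirnas = [f"hsa-miR-S{i:05d}" for i in range(n_target_mirnas)]
    assign_targets(cfg, mrna_truth, mirnas)
    predictions = simulate_predictions(cfg, mrna_truth)
    transfections = {}
    for name, mode in DEFAULT_TRANSFECTIONS:
        transfections[f"{name}|{mode}"] = simulate_transfection(
            cfg, proteome, mrna_truth, prot_truth, gmap, name, mode
        )
    return SyntheticStudy(
        cfg, mrna, mrna_truth, mirna, mirna_truth, proteome, prot_truth,
        gmap, predictions, transfections,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the full dataset bundle as TSVs (matrices + metadata + truth)."""
    from .io import write_gene_protein_map, write_matrix, write_prediction_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(study.mrna, out / "mrna_counts.tsv", out / "mrna_counts.meta.tsv")
    write_matrix(study.mirna, out / "mirna_counts.tsv", out / "mirna_counts.meta.tsv")
    write_matrix(study.proteome, out / "proteome.tsv", out / "proteome.meta.tsv")
    write_gene_protein_map(study.gene_map, out / "gene_protein_map.tsv")
    write_prediction_table(study.predictions, out / "predictions.tsv")
    for key, m in study.transfections.items():
        tag = key.replace("|", "_").replace(":", "_").replace("/", "-")
        write_matrix(m, out / f"transfection_{tag}.tsv", out / f"transfection_{tag}.meta.tsv")
    study.mrna_truth.true_log2fc.to_csv(out / "truth_mrna_log2fc.tsv", sep="\t", index_label="feature_id")
    study.proteome_truth.true_log2fc.to_csv(out / "truth_protein_log2fc.tsv", sep="\t", index_label="feature_id")
    targets = pd.DataFrame(
        [(m, g) for m, gs in study.mrna_truth.target_sets.items() for g in sorted(gs)],
        columns=["mirna", "gene_id"],
    )
    targets.to_csv(out / "truth_targets.tsv", sep="\t", index=False)
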