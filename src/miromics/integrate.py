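"""Joining transcript and protein differential results.

Quantifies mRNA-protein concordance: coverage of the proteome by the
transcriptome, quadrant classification of parallel vs inverse regulation,
Pearson correlation of fold changes (overall and on significant subsets),
Venn region counts for up to three feature sets, and the coefficient-of-
variation filter plus Pearson-distance clustering that orders heatmaps.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .config import PipelineConfig
from .io import GeneProteinMap, OmicsMatrix

log = logging.getLogger("miromics")


@dataclass
class JoinResult:
    """Inner join of an mRNA and a protein DiffTable via the identifier map."""

    table: pd.DataFrame  # gene_id, protein_id + mrna_*/protein_* columns
    coverage: float  # matched proteins / all quantified proteins


def join_omics(
    mrna: pd.DataFrame, prot: pd.DataFrame, gmap: GeneProteinMap
) -> JoinResult:
    """Join per-gene and per-protein differential results.

    Coverage is the fraction of quantified proteins represented by a
    transcript. Many-to-many maps are expanded to all pairs with a logged
    warning; the joined table has one record per (gene, protein) pair.
    """
    if gmap.pairs.empty:
        raise ValueError("empty gene/protein map")
    contrasts_m = set(mrna["contrast"].unique())
    contrasts_p = set(prot["contrast"].unique())
    if contrasts_m != contrasts_p:
        raise ValueError(f"contrasts do not align: {contrasts_m} vs {contrasts_p}")

    n_multi = (
        (gmap.pairs["protein_id"].duplicated(keep=False)
         & gmap.pairs["gene_id"].duplicated(keep=False)).sum()
    )
    if n_multi:
        log.warning("gene/protein map: %d row(s) in many-to-many relations; expanding all pairs", n_multi)

    cols = ["feature_id", "log2fc", "log2fc_eff", "p", "q", "significant", "direction"]
    mr = mrna[cols + ["contrast"]].rename(
        columns={c: f"mrna_{c}" for c in cols + ["contrast"] if c != "feature_id"}
    ).rename(columns={"feature_id": "gene_id"})
    pr = prot[cols].rename(
        columns={c: f"protein_{c}" for c in cols if c != "feature_id"}
    ).rename(columns={"feature_id": "protein_id"})

    matched = pr.merge(gmap.pairs, on="protein_id")
    joined = matched.merge(mr, on="gene_id")
    coverage = joined["protein_id"].nunique() / prot["feature_id"].nunique()
    return JoinResult(joined.reset_index(drop=True), float(coverage))


@dataclass
class QuadrantCounts:
    """Counts of parallel / inverse / one-sided regulation for one contrast."""

    contrast: str
    n_both_up: int = 0
    n_both_down: int = 0
    n_mrna_up_protein_down: int = 0
    n_mrna_down_protein_up: int = 0
    n_mrna_only_up: int = 0
    n_mrna_only_down: int = 0
    n_protein_only_up: int = 0
    n_protein_only_down: int = 0

    def as_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "contrast"}


QUADRANT_MODES = ("both_significant", "fc_only")


def quadrant_classify(
    joined: pd.DataFrame,
    mode: str = "both_significant",
    cfg: PipelineConfig | None = None,
) -> QuadrantCounts:
    """Classify joined pairs into regulation quadrants.

    ``both_significant`` gates each side on its full significance call;
    ``fc_only`` gates each side on |log2FC| > log2(fc_cut) alone
    (significance ignored), the convention behind the inverse-regulation
    counts quoted for non-significant pairs. "Inverse" always means the
    two sides pass their gate with opposite signs.
    """
    if mode not in QUADRANT_MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {QUADRANT_MODES}")
    cfg = cfg or PipelineConfig()
    contrast = joined["mrna_contrast"].iloc[0] if len(joined) else "NA"

    if mode == "both_significant":
        m_pass = joined["mrna_significant"].to_numpy(dtype=bool)
        p_pass = joined["protein_significant"].to_numpy(dtype=bool)
    else:
        m_pass = (joined["mrna_log2fc_eff"].abs() > cfg.log2_fc_cut).to_numpy()
        p_pass = (joined["protein_log2fc_eff"].abs() > cfg.log2_fc_cut).to_numpy()
    m_up = (joined["mrna_log2fc_eff"] > 0).to_numpy()
    p_up = (joined["protein_log2fc_eff"] > 0).to_numpy()

    both = m_pass & p_pass
    return QuadrantCounts(
        contrast=contrast,
        n_both_up=int((both & m_up & p_up).sum()),
        n_both_down=int((both & ~m_up & ~p_up).sum()),
        n_mrna_up_protein_down=int((both & m_up & ~p_up).sum()),
        n_mrna_down_protein_up=int((both & ~m_up & p_up).sum()),
        n_mrna_only_up=int((m_pass & ~p_pass & m_up).sum()),
        n_mrna_only_down=int((m_pass & ~p_pass & ~m_up).sum()),
        n_protein_only_up=int((p_pass & ~m_pass & p_up).sum()),
        n_protein_only_down=int((p_pass & ~m_pass & ~p_up).sum()),
    )


def fc_correlation(joined: pd.DataFrame, subset: str = "all") -> float:
    """Pearson r between mRNA and protein log2 fold changes.

    ``subset='significant_mrna'`` keeps pairs whose mRNA passes the full
    significance gate (the convention that raises the correlation from the
    overall ~0.6 to ~0.9 on regulated transcripts).
    """
    if subset not in ("all", "significant_mrna"):
        raise ValueError(f"unknown subset {subset!r}")
    df = joined
    if subset == "significant_mrna":
        df = df[df["mrna_significant"].astype(bool)]
    df = df[["mrna_log2fc", "protein_log2fc"]].dropna()
    if len(df) < 3:
        raise ValueError(f"need >= 3 pairs after subsetting, got {len(df)}")
    r, _ = stats.pearsonr(df["mrna_log2fc"], df["protein_log2fc"])
    return float(r)


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts for 2-3 named sets.

    Region labels are '&'-joined sorted set names; every element of the
    union lands in exactly one region.
    """
    names = sorted(sets)
    if not (2 <= len(names) <= 3):
        raise ValueError(f"venn_counts needs 2 or 3 sets, got {len(names)}")
    out: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            region = set.intersection(*(sets[n] for n in inside))
            for n in names:
                if n not in inside:
                    region = region - sets[n]
            out["&".join(inside)] = len(region)
    return out


def heatmap_order(
    m: OmicsMatrix,
    cv_threshold: float = 0.1,
    linkage_method: str = "average",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Feature/sample ordering and row scaling for expression heatmaps.

    Features pass when their coefficient of variation (sd/mean on the
    analysis scale) exceeds the threshold; both axes are ordered by
    agglomerative clustering with distance 1 - Pearson r (average linkage
    by default); rows are z-scored for display.
    """
    if cv_threshold < 0:
        raise ValueError("cv_threshold must be >= 0")
    vals = m.values.astype(float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, sd / mean, 0.0)
    keep = cv > cv_threshold
    if not keep.any():
        raise ValueError(f"no feature passes CV threshold {cv_threshold}")
    sub = vals.loc[keep]
    log.info("CV>%g heatmap filter: %d of %d features kept", cv_threshold, keep.sum(), len(vals))

    def _cluster_order(x: np.ndarray, labels: list[str]) -> list[str]:
        if len(labels) < 3:
            return labels
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(x)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(dist, 0.0)
        z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
        return [labels[i] for i in hierarchy.leaves_list(z)]

    feat_order = _cluster_order(sub.to_numpy(), list(sub.index))
    sample_order = _cluster_order(sub.to_numpy().T, list(sub.columns))
    scaled = sub.sub(sub.mean(axis=1), axis=0)
    row_sd = sub.std(axis=1, ddof=0).replace(0, 1.0)
    scaled = scaled.div(row_sd, axis=0)
    return feat_order, sample_order, scaled.loc[feat_order, sample_order]
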