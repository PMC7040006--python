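"""Counts -> CPM -> filters -> per-timepoint fold changes -> significance.

The transcript/miRNA branch of the pipeline. Counts are intra-sample
normalised to counts per million (no between-sample scaling factor), low
expression is filtered on per-timepoint mean CPM, fold changes are log2
ratios of across-line mean CPMs against the native reference, and the
differential test is a per-feature two-sided pooled-variance t-test on
log2(CPM + 0.5) with Benjamini-Hochberg correction within each contrast.
The pooled (equal-variance) form matches the homoscedastic log-scale noise
model (one dispersion shared across groups); at three replicates per group
Welch's estimated degrees of freedom would make the test markedly
conservative (true size ~0.005 at nominal 0.01). A feature is called
significant only when it clears the full gate
p < p_cut AND q < q_cut AND |log2FC| > log2(fc_cut).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import COUNT_MODALITIES, OmicsMatrix

log = logging.getLogger("miromics")

#: canonical DiffTable columns
DIFF_COLUMNS = [
    "feature_id", "contrast", "mean_ref", "mean_alt",
    "log2fc", "log2fc_eff", "p", "q", "significant", "direction",
]


def compute_cpm(m: OmicsMatrix) -> OmicsMatrix:
    """Scale each sample's counts to counts per million of its library size."""
    if m.modality not in COUNT_MODALITIES:
        raise ValueError(f"CPM requires a counts modality, got {m.modality!r}")
    if m.normalized:
        raise ValueError("matrix is already normalized")
    libsize = m.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    cpm = m.values.astype(float) * 1e6 / libsize
    return OmicsMatrix(cpm, list(m.samples), normalized=True)


def timepoint_means(cpm: OmicsMatrix, condition: str | None = "untreated") -> pd.DataFrame:
    """Per-feature mean CPM per timepoint (mean over the cell lines)."""
    cols = {}
    for t in cpm.timepoints():
        ids = cpm.sample_ids(timepoint=t, condition=condition)
        if ids:
            cols[t] = cpm.values[ids].mean(axis=1)
    return pd.DataFrame(cols)


def filter_low_expression(cpm: OmicsMatrix, floor: float = 1.0) -> pd.Index:
    """Keep features whose mean CPM exceeds ``floor`` at >= 1 timepoint.

    The filter is evaluated at timepoint granularity (mean over lines),
    not per sample.
    """
    means = timepoint_means(cpm)
    keep = (means > floor).any(axis=1)
    return cpm.features[keep]


def filter_protein_coding(features: Sequence[str], coding_ids: Iterable[str]) -> list[str]:
    """Order-preserving intersection with a protein-coding identifier list."""
    coding = set(coding_ids)
    if not coding:
        warnings.warn("empty protein-coding list: all features filtered out", stacklevel=2)
        return []
    return [f for f in features if f in coding]


def log2fc_vs_native(cpm: OmicsMatrix, t: str, pseudocount: float = 0.0) -> pd.Series:
    """log2((mean CPM at t + pc) / (mean CPM native + pc)), means over lines.

    With pseudocount 0 a zero denominator yields a missing value (NaN),
    never a silent +/-inf; a zero numerator over a positive denominator
    yields -inf, which is reported as missing as well.
    """
    if t == "native":
        raise ValueError("contrast timepoint must differ from the native reference")
    ids_t = cpm.sample_ids(timepoint=t, condition="untreated")
    ids_ref = cpm.sample_ids(timepoint="native", condition="untreated")
    if not ids_ref:
        raise ValueError("no native samples present")
    if not ids_t:
        raise ValueError(f"no samples at timepoint {t!r}")
    alt = cpm.values[ids_t].mean(axis=1) + pseudocount
    ref = cpm.values[ids_ref].mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(alt / ref)
    return pd.Series(np.where(np.isfinite(fc), fc, np.nan), index=cpm.features, name=f"log2fc_{t}")


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min_{j >= i} (p(j) * m / j) after an ascending (stable) sort,
    capped at 1. Ties are safe by construction.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if np.isnan(p).any():
        raise ValueError("p-values contain missing values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    m = len(p)
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _ttest_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided pooled-variance t-test p-values with
    degenerate-row handling."""
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=True)
    p = np.asarray(p)
    degenerate = ~np.isfinite(p)  # zero variance in both groups
    if degenerate.any():
        equal = np.isclose(x[degenerate].mean(axis=1), y[degenerate].mean(axis=1))
        p[degenerate] = np.where(equal, 1.0, 0.0)
    return p


def test_differential(
    m: OmicsMatrix,
    contrast: str,
    cfg: PipelineConfig | None = None,
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Differential expression of ``contrast`` timepoint vs native.

    Pooled-variance t on log2(CPM + pseudocount) per feature, BH within the
    contrast, and the full significance gate. The ``log2fc`` column is the
    table-style ratio of mean CPMs (pseudocount 0, may be missing for
    all-zero features); ``log2fc_eff`` is the pseudocounted effect column
    used for gating so the gate never depends on a missing value.
    """
    cfg = cfg or PipelineConfig()
    cpm = compute_cpm(m)
    if features is not None:
        cpm = cpm.subset_features(features)
    ids_ref = cpm.sample_ids(timepoint="native", condition="untreated")
    ids_alt = cpm.sample_ids(timepoint=contrast, condition="untreated")
    for name, ids in (("native", ids_ref), (contrast, ids_alt)):
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has {len(ids)} replicate(s); need >= 2")

    logc = np.log2(cpm.values.to_numpy() + cfg.pseudocount)
    col = {c: i for i, c in enumerate(cpm.values.columns)}
    p = _ttest_rows(logc[:, [col[i] for i in ids_alt]], logc[:, [col[i] for i in ids_ref]])
    q = bh_fdr(p)

    fc = log2fc_vs_native(cpm, contrast, pseudocount=0.0)
    fc_eff = log2fc_vs_native(cpm, contrast, pseudocount=cfg.pseudocount)
    mean_ref = cpm.values[ids_ref].mean(axis=1)
    mean_alt = cpm.values[ids_alt].mean(axis=1)

    sig = (p < cfg.p_cut) & (q < cfg.q_cut) & (np.abs(fc_eff) > cfg.log2_fc_cut)
    direction = np.where(~sig, "none", np.where(fc_eff > 0, "up", "down"))

    return pd.DataFrame(
        {
            "feature_id": cpm.features,
            "contrast": f"{contrast}_vs_native",
            "mean_ref": mean_ref.to_numpy(),
            "mean_alt": mean_alt.to_numpy(),
            "log2fc": fc.to_numpy(),
            "log2fc_eff": fc_eff.to_numpy(),
            "p": p,
            "q": q,
            "significant": sig.to_numpy(),
            "direction": direction,
        }
    ).reset_index(drop=True)


def run_de(
    m: OmicsMatrix,
    cfg: PipelineConfig | None = None,
    coding_ids: Iterable[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Full DE branch: CPM filter (and optional coding filter) then one
    DiffTable per non-native timepoint."""
    cfg = cfg or PipelineConfig()
    cpm = compute_cpm(m)
    kept = filter_low_expression(cpm, cfg.cpm_floor)
    log.info("CPM>%g filter: %d of %d features kept", cfg.cpm_floor, len(kept), len(m.features))
    features: Sequence[str] = list(kept)
    if coding_ids is not None:
        features = filter_protein_coding(features, coding_ids)
        log.info("protein-coding filter: %d features kept", len(features))
    return {
        t: test_differential(m, t, cfg, features=features)
        for t in m.timepoints()
        if t != "native"
    }


def select_consistent_mirnas(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """miRNAs significant at d3, d7 AND d14 with the same direction.

    Returns a DataFrame (mirna, direction) sorted by miRNA name.
    """
    missing = {"d3", "d7", "d14"} - set(tables)
    if missing:
        raise ValueError(f"missing contrast(s): {sorted(missing)}")
    per_t = []
    for t in ("d3", "d7", "d14"):
        df = tables[t]
        sig = df[df["significant"]][["feature_id", "direction"]]
        per_t.append(sig.rename(columns={"direction": f"dir_{t}"}))
    joined = per_t[0].merge(per_t[1], on="feature_id").merge(per_t[2], on="feature_id")
    same = joined[(joined["dir_d3"] == joined["dir_d7"]) & (joined["dir_d7"] == joined["dir_d14"])]
    out = (
        same[["feature_id", "dir_d3"]]
        .rename(columns={"feature_id": "mirna", "dir_d3": "direction"})
        .sort_values("mirna", kind="stable")
        .reset_index(drop=True)
    )
    return out


def classify_cpm100(table1_rows: pd.DataFrame, cpm_high: float = 100.0) -> tuple[list[str], list[str]]:
    """Split a regulated-miRNA summary table into the two headline sets.

    down-set: direction down AND native mean CPM > cpm_high (downregulated
    *from* a high level); up-set: direction up AND mean CPM > cpm_high at
    >= 1 treated timepoint (upregulated *to* a high level).
    """
    down = table1_rows[
        (table1_rows["direction"] == "down") & (table1_rows["cpm_native"] > cpm_high)
    ]
    treated = table1_rows[["cpm_d3", "cpm_d7", "cpm_d14"]].max(axis=1)
    up = table1_rows[(table1_rows["direction"] == "up") & (treated > cpm_high)]
    return list(down["mirna"]), list(up["mirna"])


def round_half_away(x: float | np.ndarray, decimals: int = 1) -> np.ndarray:
    """Round half away from zero (the convention of the printed fold changes)."""
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    return np.copysign(np.floor(np.abs(x) * factor + 0.5) / factor, x)
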