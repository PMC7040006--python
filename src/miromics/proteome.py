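"""Differential protein abundance across timepoints and proteome QC.

Statistics mirror a label-free LC-MS/MS workflow: per-protein one-way
ANOVA on log2 abundance across timepoints with BH correction across
proteins, followed by a Tukey HSD post-hoc (Tukey-Kramer for unbalanced
groups) against the native reference. A protein is differentially
abundant at timepoint t iff ANOVA q < q_cut AND Tukey p(t vs native)
< p_cut AND |log2FC| > log2(fc_cut). Replicate-correlation matrices,
PCA scores and volcano tables supply the QC/visualisation numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .expression import bh_fdr
from .io import OmicsMatrix

log = logging.getLogger("miromics")


def _log2_values(m: OmicsMatrix, log_transform: bool) -> pd.DataFrame:
    if not log_transform:
        return m.values.astype(float)
    vals = m.values.astype(float)
    if (vals.to_numpy() <= 0).any():
        raise ValueError("non-positive abundance cannot be log-transformed")
    return np.log2(vals)


def anova_by_feature(
    m: OmicsMatrix,
    log_transform: bool = True,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA per feature across timepoints.

    Returns a DataFrame with per-feature F, p, BH q (across features) and
    one ``log2fc_<t>`` column per non-native timepoint (mean difference of
    log2 abundances vs native). Features with zero within-group variance
    everywhere get a missing p and are flagged ``degenerate``.
    """
    cfg = cfg or PipelineConfig()
    groups = m.timepoints()
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 timepoint groups")
    vals = _log2_values(m, log_transform)
    arrays = []
    for t in groups:
        ids = m.sample_ids(timepoint=t)
        if len(ids) < 2:
            raise ValueError(f"timepoint {t!r} has {len(ids)} replicate(s); need >= 2")
        arrays.append(vals[ids].to_numpy())

    k = len(arrays)
    ns = np.array([a.shape[1] for a in arrays])
    n_tot = ns.sum()
    means = np.column_stack([a.mean(axis=1) for a in arrays])
    grand = np.concatenate(arrays, axis=1).mean(axis=1)
    ss_between = (ns * (means - grand[:, None]) ** 2).sum(axis=1)
    ss_within = sum(
        ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays
    )
    df_b, df_w = k - 1, n_tot - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    degenerate = ss_within == 0
    p = np.full(len(f), np.nan)
    ok = ~degenerate
    p[ok] = stats.f.sf(f[ok], df_b, df_w)
    # a planted difference with zero noise is still a real difference
    exact = degenerate & (ss_between > 0)
    p[exact] = 0.0
    f = np.where(degenerate & ~exact, 0.0, f)

    out = pd.DataFrame({"feature_id": m.features, "F": f, "p": p})
    out["degenerate"] = degenerate & ~exact
    valid = ~out["p"].isna()
    q = np.full(len(out), np.nan)
    q[valid] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["q"] = q
    ids_native = m.sample_ids(timepoint="native")
    ref = vals[ids_native].mean(axis=1)
    for t in groups:
        if t == "native":
            continue
        out[f"log2fc_{t}"] = (vals[m.sample_ids(timepoint=t)].mean(axis=1) - ref).to_numpy()
    return out


def tukey_posthoc(m: OmicsMatrix, feature_ids, log_transform: bool = True) -> pd.DataFrame:
    """All pairwise timepoint comparisons per feature (studentized range).

    Run on the ANOVA-significant features only. The studentized-range
    statistic is q = |mean_a - mean_b| / sqrt(MSW/2 * (1/n_a + 1/n_b)),
    the Tukey-Kramer form that reduces to classic Tukey HSD for balanced
    groups; p-values come from the studentized-range distribution with
    k groups and N - k error degrees of freedom. Computed vectorised over
    features (equivalent to scipy.stats.tukey_hsd per feature).
    """
    vals = _log2_values(m, log_transform)
    groups = m.timepoints()
    feature_ids = list(feature_ids)
    if not feature_ids:
        return pd.DataFrame(columns=["feature_id", "timepoint_a", "timepoint_b", "mean_diff", "p"])
    sub = vals.loc[feature_ids]
    arrays = [sub[m.sample_ids(timepoint=t)].to_numpy() for t in groups]
    ns = np.array([a.shape[1] for a in arrays])
    k, n_tot = len(groups), ns.sum()
    df_w = n_tot - k
    means = np.column_stack([a.mean(axis=1) for a in arrays])
    ssw = sum(((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for a in arrays)
    msw = ssw / df_w

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[:, i] - means[:, j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            with np.errstate(divide="ignore", invalid="ignore"):
                q = np.abs(diff) / se
            p = np.where(
                se > 0,
                stats.studentized_range.sf(np.where(se > 0, q, 0.0), k, df_w),
                np.where(diff == 0, 1.0, 0.0),
            )
            rows.append(
                pd.DataFrame(
                    {
                        "feature_id": feature_ids,
                        "timepoint_a": groups[i],
                        "timepoint_b": groups[j],
                        "mean_diff": diff,
                        "p": np.clip(p, 0.0, 1.0),
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["feature_id", "timepoint_a", "timepoint_b"], kind="stable", ignore_index=True)


def differential_abundance(
    m: OmicsMatrix,
    log_transform: bool = True,
    cfg: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Dual-gate differential abundance: one DiffTable per treated timepoint.

    Gate order follows the workflow: ANOVA q < q_cut first, then the Tukey
    native-vs-t p < p_cut and the fold-change cut (the order only matters
    for logging; the final set is gate-order invariant).
    """
    cfg = cfg or PipelineConfig()
    anova = anova_by_feature(m, log_transform=log_transform, cfg=cfg)
    anova_sig = anova[(anova["q"] < cfg.q_cut) & ~anova["q"].isna()]
    log.info("ANOVA: %d of %d proteins at q<%g", len(anova_sig), len(anova), cfg.q_cut)
    tukey = tukey_posthoc(m, anova_sig["feature_id"], log_transform=log_transform)

    vals = _log2_values(m, log_transform)
    ids_native = m.sample_ids(timepoint="native")
    ref_mean = vals[ids_native].mean(axis=1)
    out: dict[str, pd.DataFrame] = {}
    for t in m.timepoints():
        if t == "native":
            continue
        fc = anova[f"log2fc_{t}"]
        pair = tukey[
            ((tukey["timepoint_a"] == "native") & (tukey["timepoint_b"] == t))
            | ((tukey["timepoint_a"] == t) & (tukey["timepoint_b"] == "native"))
        ].set_index("feature_id")["p"]
        tukey_p = anova["feature_id"].map(pair)
        sig = (
            (anova["q"] < cfg.q_cut)
            & (tukey_p < cfg.p_cut)
            & (fc.abs() > cfg.log2_fc_cut)
        ).fillna(False)
        direction = np.where(~sig, "none", np.where(fc > 0, "up", "down"))
        alt_mean = vals[m.sample_ids(timepoint=t)].mean(axis=1)
        out[t] = pd.DataFrame(
            {
                "feature_id": anova["feature_id"],
                "contrast": f"{t}_vs_native",
                "mean_ref": ref_mean.to_numpy(),
                "mean_alt": alt_mean.to_numpy(),
                "log2fc": fc.to_numpy(),
                "log2fc_eff": fc.to_numpy(),
                "p": tukey_p.to_numpy(),
                "q": anova["q"].to_numpy(),
                "significant": sig.to_numpy(),
                "direction": direction,
            }
        )
    return out


def direction_flip_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Check, not assumption: proteins significant at both d3 and d7 whose
    directions disagree. Returns the offending rows (empty when none)."""
    if not {"d3", "d7"} <= set(tables):
        raise ValueError("needs both d3 and d7 tables")
    a = tables["d3"][tables["d3"]["significant"]][["feature_id", "direction"]]
    b = tables["d7"][tables["d7"]["significant"]][["feature_id", "direction"]]
    j = a.merge(b, on="feature_id", suffixes=("_d3", "_d7"))
    return j[j["direction_d3"] != j["direction_d7"]].reset_index(drop=True)


def replicate_correlation(m: OmicsMatrix, log_transform: bool = True) -> pd.DataFrame:
    """Pairwise Pearson correlation of samples on log2 abundance.

    Diagonal is 1; a constant sample yields missing correlations.
    """
    if len(m.samples) < 2:
        raise ValueError("need >= 2 samples")
    vals = _log2_values(m, log_transform).to_numpy()
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(vals, rowvar=False)
    sd = vals.std(axis=0)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    ids = [s.sample_id for s in m.samples]
    return pd.DataFrame(r, index=ids, columns=ids)


def pca_scores(m: OmicsMatrix, n_components: int = 2, log_transform: bool = True) -> pd.DataFrame:
    """Per-sample principal-component scores via centered SVD.

    Component sign is fixed by forcing the first feature's loading to be
    non-negative, so scores are reproducible across runs. Also attaches
    the eigenvalue (explained variance) of each component as metadata in
    ``DataFrame.attrs['explained_variance']``.
    """
    n_samples = len(m.samples)
    if n_samples < n_components:
        raise ValueError(f"{n_samples} samples < {n_components} components")
    vals = _log2_values(m, log_transform)
    vals = vals.dropna(axis=0)  # complete-case features only
    x = vals.to_numpy().T  # samples x features
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    signs = np.where(vt[:, 0] < 0, -1.0, 1.0)
    u, s, vt = u * signs, s, vt * signs[:, None]
    scores = u[:, :n_components] * s[:n_components]
    out = pd.DataFrame(
        scores,
        index=[smp.sample_id for smp in m.samples],
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    out.attrs["explained_variance"] = (s[:n_components] ** 2) / max(n_samples - 1, 1)
    return out


def volcano_table(diff: pd.DataFrame, tiny: float = 1e-300) -> pd.DataFrame:
    """(log2fc, -log10 p, significance flag) per feature for volcano plots."""
    p = diff["p"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "feature_id": diff["feature_id"],
            "log2fc": diff["log2fc"],
            "neg_log10_p": -np.log10(np.clip(p, tiny, None)),
            "significant": diff["significant"],
        }
    )
    return out.reset_index(drop=True)
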