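"""miRNA target-prediction integration, inverse-regulation networks and
the transfection crossmatch.

Predictions arrive as long-format (miRNA, gene, algorithm) triples from a
panel of 12 algorithms; the support count of a pair is the number of
distinct algorithms reporting it (isoform-level duplicates collapse to
gene level). Networks connect consistently regulated miRNAs to
significantly inversely regulated proteins whose pair passes a minimum
support (default 5 of 12). The crossmatch reproduces, per transfection,
the set algebra: quantified proteins -> predicted targets -> regulated in
the expected direction -> overlap with inversely regulated predicted
targets of the untreated time course.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .config import PipelineConfig
from .expression import bh_fdr
from .io import OmicsMatrix
from scipy import stats

log = logging.getLogger("miromics")

#: the 12-algorithm prediction panel
ALGORITHMS = (
    "miRWalk", "miRDB", "PITA", "MicroT4", "miRMap", "RNA22",
    "miRanda", "miRNAMap", "RNAhybrid", "miRBridge", "PicTar2", "Targetscan",
)


def normalize_mirna(name: str) -> str:
    """Canonical miRNA name: case-insensitive, 'hsa-' prefix optional on
    input, stored canonically with the prefix (hsa-miR-xxx / hsa-let-xxx)."""
    s = str(name).strip()
    low = s.lower()
    if low.startswith("hsa-"):
        low = low[4:]
    if low.startswith("mir-"):
        low = "miR-" + low[4:]
    return "hsa-" + low


def validate_predictions(pred: pd.DataFrame) -> pd.DataFrame:
    """Normalise miRNA names, check algorithm names, drop duplicate triples."""
    known = {a.lower(): a for a in ALGORITHMS}
    algo = pred["algorithm"].astype(str)
    bad = sorted(set(algo[~algo.str.lower().isin(known)]))
    if bad:
        raise ValueError(f"unknown prediction algorithm(s): {bad}")
    out = pd.DataFrame(
        {
            "mirna": pred["mirna"].map(normalize_mirna),
            "gene_id": pred["gene_id"].astype(str),
            "algorithm": algo.str.lower().map(known),
        }
    )
    return out.drop_duplicates(ignore_index=True)


def support_counts(pred: pd.DataFrame) -> pd.DataFrame:
    """Distinct-algorithm support per (mirna, gene) pair."""
    pred = validate_predictions(pred)
    return (
        pred.groupby(["mirna", "gene_id"], sort=False)["algorithm"]
        .nunique()
        .rename("support")
        .reset_index()
    )


def support_filter(
    pred: pd.DataFrame, mirnas, min_support: int = 5
) -> set[tuple[str, str]]:
    """(mirna, gene) pairs of the listed miRNAs with support >= min_support."""
    if not (1 <= min_support <= len(ALGORITHMS)):
        raise ValueError(f"min_support must be in [1, {len(ALGORITHMS)}]")
    wanted = {normalize_mirna(m) for m in mirnas}
    sup = support_counts(pred)
    hit = sup[sup["mirna"].isin(wanted) & (sup["support"] >= min_support)]
    return set(zip(hit["mirna"], hit["gene_id"]))


def predicted_genes(pred: pd.DataFrame, mirna: str, min_support: int = 1) -> set[str]:
    """Genes predicted as targets of one miRNA by >= min_support algorithms."""
    pairs = support_filter(pred, [mirna], min_support)
    return {g for _, g in pairs}


def build_inverse_network(
    mirnas: pd.DataFrame,
    proteins: pd.DataFrame,
    pred: pd.DataFrame,
    min_support: int = 5,
    gene_of: Mapping[str, str] | None = None,
) -> dict[str, nx.Graph]:
    """Bipartite networks of regulated miRNAs and inversely regulated proteins.

    ``mirnas`` carries (mirna, direction) for the consistently regulated
    miRNAs; ``proteins`` is a DiffTable restricted to significant proteins
    with direction (d3 and/or d7 union). Two networks are returned:
    ``down_up`` (down-miRNAs x up-proteins) and ``up_down``. Protein nodes
    are annotated with the number of predicting miRNAs (their degree);
    edges carry the support count and algorithm names.
    """
    pred = validate_predictions(pred)
    gene_of = gene_of or {}
    sig = proteins[proteins["significant"].astype(bool)]
    algset = (
        pred.groupby(["mirna", "gene_id"], sort=False)["algorithm"]
        .agg(lambda s: ",".join(sorted(set(s))))
        .to_dict()
    )

    nets: dict[str, nx.Graph] = {}
    for key, mdir, pdir in (("down_up", "down", "up"), ("up_down", "up", "down")):
        g = nx.Graph(direction_pairing=key, min_support=min_support)
        mlist = [normalize_mirna(m) for m in mirnas[mirnas["direction"] == mdir]["mirna"]]
        plist = sig[sig["direction"] == pdir]["feature_id"].unique()
        for m in mlist:
            g.add_node(m, node_type="mirna", direction=mdir)
        pairs = support_filter(pred, mlist, min_support)
        for prot in plist:
            gene = gene_of.get(prot, prot)
            for m in mlist:
                if (m, gene) in pairs:
                    algs = algset[(m, gene)]
                    if prot not in g:
                        g.add_node(prot, node_type="protein", direction=pdir)
                    g.add_edge(m, prot, support=len(algs.split(",")), algorithms=algs)
        for n, d in g.nodes(data=True):
            if d["node_type"] == "protein":
                g.nodes[n]["n_predicting_mirnas"] = g.degree(n)
        nets[key] = g
    return nets


def transfection_diff(
    trans: OmicsMatrix,
    control: OmicsMatrix,
    cfg: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Transfected vs control differential protein abundance at 3d.

    Per-protein two-sided pooled-variance t on log2 abundance, BH q
    within the contrast, and the shared significance gate (same test as
    the expression branch; replicate-count mismatches are handled by the
    pooled two-sample form).
    """
    cfg = cfg or PipelineConfig()
    for name, m in (("transfected", trans), ("control", control)):
        if len(m.samples) < 2:
            raise ValueError(f"group {name!r} has {len(m.samples)} replicate(s); need >= 2")
    common = trans.features.intersection(control.features, sort=False)
    a = np.log2(trans.values.loc[common].astype(float).to_numpy())
    b = np.log2(control.values.loc[common].astype(float).to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(p)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(a[degenerate].mean(axis=1), b[degenerate].mean(axis=1))
        p[degenerate] = np.where(equal, 1.0, 0.0)
    q = bh_fdr(p)
    fc = a.mean(axis=1) - b.mean(axis=1)
    sig = (p < cfg.p_cut) & (q < cfg.q_cut) & (np.abs(fc) > cfg.log2_fc_cut)
    direction = np.where(~sig, "none", np.where(fc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "feature_id": common,
            "contrast": "transfected_vs_control",
            "mean_ref": b.mean(axis=1),
            "mean_alt": a.mean(axis=1),
            "log2fc": fc,
            "log2fc_eff": fc,
            "p": p,
            "q": q,
            "significant": sig,
            "direction": direction,
        }
    ).reset_index(drop=True)


@dataclass
class CrossmatchReport:
    """Machine-readable per-transfection summary of the crossmatch workflow."""

    mirna: str
    mode: str
    n_quantified: int
    n_predicted_of_quantified: int
    n_regulated_up: int
    n_regulated_down: int
    n_regulated_expected_direction_and_predicted: int
    n_inverse_regulated_predicted_in_timecourse: int
    n_overlap: int

    def __post_init__(self) -> None:
        counts = [
            self.n_predicted_of_quantified,
            self.n_regulated_up,
            self.n_regulated_down,
            self.n_regulated_expected_direction_and_predicted,
        ]
        if any(c > self.n_quantified for c in counts):
            raise ValueError("crossmatch count exceeds the quantified universe")
        if self.n_overlap > min(
            self.n_regulated_expected_direction_and_predicted,
            self.n_inverse_regulated_predicted_in_timecourse,
        ):
            raise ValueError("overlap exceeds a parent set")

    def as_dict(self) -> dict:
        return asdict(self)


def crossmatch(
    diff: pd.DataFrame,
    pred: pd.DataFrame,
    mirna: str,
    mode: str,
    timecourse_inverse: Mapping[str, str],
    support_rule: str | int = "any",
    gene_of: Mapping[str, str] | None = None,
) -> CrossmatchReport:
    """Cross-analyse one transfection against predictions and the time course.

    The expected direction of direct targets is down for a mimic and up
    for an inhibitor. ``timecourse_inverse`` maps gene -> direction for
    proteins significantly regulated at 3d and/or 7d of the untreated time
    course; the overlap is taken against those regulated *inversely* to
    the transfected miRNA's expected target effect (up in the time course
    for a mimic of a downregulated miRNA, down for an inhibitor).
    ``support_rule`` is 'any' (>= 1 algorithm) or an integer minimum.
    """
    if mode not in ("mimic", "inhibitor"):
        raise ValueError(f"unknown mode {mode!r}")
    mirna = normalize_mirna(mirna)
    pred_v = validate_predictions(pred)
    if mirna not in set(pred_v["mirna"]):
        raise ValueError(f"{mirna} absent from the prediction table")
    min_support = 1 if support_rule == "any" else int(support_rule)
    gene_of = gene_of or {}

    predicted = predicted_genes(pred_v, mirna, min_support)
    genes = diff["feature_id"].map(lambda prot: gene_of.get(prot, prot))
    quantified = set(genes)
    predicted_quant = quantified & predicted

    sig = diff[diff["significant"].astype(bool)]
    sig_genes = sig["feature_id"].map(lambda prot: gene_of.get(prot, prot))
    up = set(sig_genes[sig["direction"] == "up"])
    down = set(sig_genes[sig["direction"] == "down"])

    expected_dir = "down" if mode == "mimic" else "up"
    inverse_dir = "up" if mode == "mimic" else "down"
    regulated_expected = (down if expected_dir == "down" else up) & predicted_quant

    tc_inverse_pred = {
        g for g, d in timecourse_inverse.items() if d == inverse_dir and g in predicted
    }
    overlap = regulated_expected & tc_inverse_pred

    return CrossmatchReport(
        mirna=mirna,
        mode=mode,
        n_quantified=len(quantified),
        n_predicted_of_quantified=len(predicted_quant),
        n_regulated_up=len(up),
        n_regulated_down=len(down),
        n_regulated_expected_direction_and_predicted=len(regulated_expected),
        n_inverse_regulated_predicted_in_timecourse=len(tc_inverse_pred),
        n_overlap=len(overlap),
    )


def timecourse_inverse_set(
    tables: Mapping[str, pd.DataFrame],
    gene_of: Mapping[str, str] | None = None,
    on_conflict: str = "error",
) -> dict[str, str]:
    """Union of significantly regulated proteins at d3 and/or d7 with their
    direction, keyed by gene.

    A direction conflict between the two timepoints is a validation error
    by default (no flip is expected biologically, and the flip count is
    reported separately); ``on_conflict='drop'`` removes conflicted genes
    with a logged count instead, for data where mild inconsistency is
    expected.
    """
    if on_conflict not in ("error", "drop"):
        raise ValueError(f"unknown on_conflict policy {on_conflict!r}")
    gene_of = gene_of or {}
    out: dict[str, str] = {}
    conflicts: set[str] = set()
    for t in ("d3", "d7"):
        if t not in tables:
            continue
        df = tables[t]
        for prot, d in zip(df.loc[df["significant"].astype(bool), "feature_id"],
                           df.loc[df["significant"].astype(bool), "direction"]):
            gene = gene_of.get(prot, prot)
            if gene in out and out[gene] != d:
                if on_conflict == "error":
                    raise ValueError(f"direction conflict for {gene!r} between d3 and d7")
                conflicts.add(gene)
            out[gene] = d
    if conflicts:
        log.warning("dropped %d gene(s) with d3/d7 direction conflicts", len(conflicts))
        for g in conflicts:
            del out[g]
    return out


def predicted_coverage_check(quantified: set[str], pred: pd.DataFrame, mirna: str) -> float:
    """Fraction of quantified proteins predicted (>= 1 algorithm) as targets."""
    if not quantified:
        raise ValueError("empty quantified set")
    predicted = predicted_genes(pred, mirna, min_support=1)
    return len(quantified & predicted) / len(quantified)
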