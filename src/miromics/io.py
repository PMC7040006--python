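"""Readers/writers for the pipeline's tabular inputs and graph outputs.

All tables are TAB-separated UTF-8 text with '.' decimals. A count or
abundance matrix is a feature-by-sample grid whose first column holds
feature IDs; sample metadata lives in a sidecar TSV keyed by sample ID
(columns: sample_id, line, timepoint, condition, modality), never encoded
in sample names. Write-then-read of any matrix or network reproduces the
values exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger("miromics")

TIMEPOINTS = ("native", "d3", "d7", "d14")
MODALITIES = ("mrna_counts", "mirna_counts", "protein_abundance")
COUNT_MODALITIES = ("mrna_counts", "mirna_counts")

#: conditions are either plain labels or "<kind>:<miRNA>" for transfections
_PLAIN_CONDITIONS = ("untreated", "control_sirna")


def _valid_condition(cond: str) -> bool:
    if cond in _PLAIN_CONDITIONS:
        return True
    kind, _, name = cond.partition(":")
    return kind in ("mimic", "inhibitor") and bool(name)


@dataclass(frozen=True)
class SampleMeta:
    """Experimental-design annotation of one sample (cell line x timepoint)."""

    sample_id: str
    line: str
    timepoint: str
    condition: str = "untreated"
    modality: str = "mrna_counts"

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown timepoint {self.timepoint!r}"
            )
        if self.modality not in MODALITIES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown modality {self.modality!r}"
            )
        if not _valid_condition(self.condition):
            raise ValueError(
                f"sample {self.sample_id!r}: unknown condition {self.condition!r}"
            )
        if self.modality == "protein_abundance" and self.timepoint == "d14":
            # no proteome exists at 14d in this design (apoptotic cell loss)
            raise ValueError(
                f"sample {self.sample_id!r}: protein abundance has no d14 timepoint"
            )


@dataclass
class OmicsMatrix:
    """Feature-by-sample non-negative matrix with per-sample metadata.

    ``values`` is a DataFrame whose index holds the feature IDs and whose
    columns are sample IDs, ordered as in ``samples``. Count modalities
    must contain integers; all values must be non-negative.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    unique_peptides: pd.Series | None = None
    #: True once counts have been scaled (e.g. to CPM); lifts the integer check
    normalized: bool = False

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(self.values.columns) != ids:
            raise ValueError("matrix columns do not match sample metadata order")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate feature IDs: {list(dup[:5])}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("matrix contains non-numeric values")
        if np.isnan(arr).any():
            raise ValueError("matrix contains missing values")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at feature {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        modalities = {s.modality for s in self.samples}
        if len(modalities) != 1:
            raise ValueError(f"mixed modalities in one matrix: {sorted(modalities)}")
        if (
            self.modality in COUNT_MODALITIES
            and not self.normalized
            and not np.allclose(arr, np.round(arr))
        ):
            raise ValueError("count matrix contains non-integer values")

    # -- convenience accessors -------------------------------------------------

    @property
    def modality(self) -> str:
        return self.samples[0].modality

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def sample_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.line, s.timepoint, s.condition, s.modality) for s in self.samples],
            columns=["sample_id", "line", "timepoint", "condition", "modality"],
        )

    def sample_ids(self, timepoint: str | None = None, condition: str | None = None) -> list[str]:
        return [
            s.sample_id
            for s in self.samples
            if (timepoint is None or s.timepoint == timepoint)
            and (condition is None or s.condition == condition)
        ]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        keep = [s for s in self.samples if s.sample_id in set(sample_ids)]
        return OmicsMatrix(
            self.values[[s.sample_id for s in keep]].copy(),
            keep,
            None if self.unique_peptides is None else self.unique_peptides.copy(),
            self.normalized,
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "OmicsMatrix":
        idx = self.values.index.intersection(pd.Index(feature_ids), sort=False)
        return OmicsMatrix(
            self.values.loc[idx].copy(),
            list(self.samples),
            None if self.unique_peptides is None else self.unique_peptides.loc[idx].copy(),
            self.normalized,
        )

    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.timepoint not in seen:
                seen.append(s.timepoint)
        return seen


@dataclass
class GeneProteinMap:
    """Protein-to-gene identifier pairs; many-to-one allowed either way."""

    pairs: pd.DataFrame  # columns: protein_id, gene_id

    def __post_init__(self) -> None:
        missing = {"protein_id", "gene_id"} - set(self.pairs.columns)
        if missing:
            raise ValueError(f"gene/protein map missing columns: {sorted(missing)}")
        self.pairs = self.pairs[["protein_id", "gene_id"]].astype(str)
        if self.pairs.duplicated().any():
            raise ValueError("gene/protein map contains exactly duplicated pairs")

    def genes_of(self) -> pd.DataFrame:
        return self.pairs


# ---------------------------------------------------------------------------
# matrix IO
# ---------------------------------------------------------------------------

MIN_UNIQUE_PEPTIDES = 2  # quantification requires >= 2 unique peptides/protein


def read_matrix(path: str | Path, meta_path: str | Path) -> OmicsMatrix:
    """Read a feature-by-sample TSV plus its sample-metadata sidecar.

    Protein matrices may carry a ``unique_peptides`` column; features with
    fewer than two unique peptides are dropped at ingest (and the dropped
    count logged) so that every downstream count refers to the filtered
    matrix.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)

    unique_peptides = None
    if "unique_peptides" in raw.columns:
        unique_peptides = pd.to_numeric(raw.pop("unique_peptides"), errors="raise").astype(int)

    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            # astype(float) parses via correctly-rounded float(), so a
            # write-then-read round trip reproduces values bit-exactly
            converted = raw[col].astype(float)
        except (TypeError, ValueError):
            probe = pd.to_numeric(raw[col], errors="coerce")
            bad = probe.isna() & raw[col].notna()
            feat = raw.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"{path}: non-numeric value {raw.loc[feat, col]!r} "
                f"at feature {feat!r}, sample {col!r}"
            ) from None
        if converted.isna().any():
            feat = raw.index[converted.isna().to_numpy().nonzero()[0][0]]
            raise ValueError(f"{path}: missing value at feature {feat!r}, sample {col!r}")
        values[col] = converted

    by_id = {row.sample_id: row for row in meta.itertuples(index=False)}
    samples = []
    for col in values.columns:
        if col not in by_id:
            raise ValueError(f"sample {col!r} present in {path} but absent from {meta_path}")
        row = by_id[col]
        samples.append(
            SampleMeta(row.sample_id, row.line, row.timepoint, row.condition, row.modality)
        )

    if samples and samples[0].modality in COUNT_MODALITIES:
        arr = values.to_numpy()
        if np.allclose(arr, np.round(arr)):
            values = values.round().astype(np.int64)

    m = OmicsMatrix(values, samples, unique_peptides)
    if m.modality == "protein_abundance" and unique_peptides is not None:
        keep = unique_peptides >= MIN_UNIQUE_PEPTIDES
        dropped = int((~keep).sum())
        if dropped:
            log.info("dropped %d protein(s) with <%d unique peptides", dropped, MIN_UNIQUE_PEPTIDES)
        m = OmicsMatrix(m.values.loc[keep], m.samples, unique_peptides.loc[keep])
    return m


def write_matrix(m: OmicsMatrix, path: str | Path, meta_path: str | Path) -> None:
    values = m.values.copy()
    if m.unique_peptides is not None:
        values.insert(0, "unique_peptides", m.unique_peptides)
    values.to_csv(path, sep="\t", index_label="feature_id")
    m.sample_table().to_csv(meta_path, sep="\t", index=False)


def read_gene_protein_map(path: str | Path) -> GeneProteinMap:
    return GeneProteinMap(pd.read_csv(path, sep="\t", dtype=str))


def write_gene_protein_map(gmap: GeneProteinMap, path: str | Path) -> None:
    gmap.pairs.to_csv(path, sep="\t", index=False)


def read_prediction_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format (mirna, gene_id, algorithm) prediction table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"mirna", "gene_id", "algorithm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: prediction table missing columns {sorted(missing)}")
    return df


def write_prediction_table(pred: pd.DataFrame, path: str | Path) -> None:
    pred[["mirna", "gene_id", "algorithm"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network IO (GraphML / SIF / edge TSV, ready for graph-viewer import)
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "sif", "edge_tsv")


def write_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a bipartite miRNA-protein network.

    GraphML keeps all node attributes (node_type, direction, predicting-miRNA
    count) and edge attributes (support, algorithms). SIF uses the
    interaction label "targets". The edge TSV lists miRNA, protein, the
    number of supporting algorithms and their names.
    """
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; choose from {NETWORK_FORMATS}")
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    mirnas = sorted(n for n, d in net.nodes(data=True) if d.get("node_type") == "mirna")
    with open(path, "w", encoding="utf-8") as fh:
        if format == "sif":
            for m in mirnas:
                targets = sorted(net.neighbors(m))
                if targets:
                    fh.write(f"{m}\ttargets\t" + "\t".join(targets) + "\n")
        else:  # edge_tsv
            fh.write("mirna\tprotein\tn_algorithms\talgorithms\n")
            for m in mirnas:
                for prot in sorted(net.neighbors(m)):
                    e = net.edges[m, prot]
                    fh.write(f"{m}\t{prot}\t{e['support']}\t{e['algorithms']}\n")


def read_network(path: str | Path) -> nx.Graph:
    """Re-read a GraphML network (round-trip counterpart of write_network)."""
    g = nx.read_graphml(path)
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
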