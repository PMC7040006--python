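"""Pipeline configuration: the shared threshold set and run parameters.

Every significance call in the pipeline flows through one triple gate
(p < p_cut, BH q < q_cut, fold change > fc_cut), and every count reported
anywhere is reproducible from the thresholds logged with it.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

log = logging.getLogger("miromics")


@dataclass
class PipelineConfig:
    """Thresholds and conventions used across all pipeline stages.

    Parameters
    ----------
    p_cut, q_cut : float
        Raw and BH-adjusted p-value cutoffs of the significance gate.
    fc_cut : float
        Linear fold-change cutoff; the gate uses ``|log2fc| > log2(fc_cut)``.
    cpm_floor : float
        Expression filter: a feature is kept if its mean CPM exceeds this
        floor at one or more timepoints.
    cpm_high : float
        "Highly expressed" CPM threshold used for the regulated-miRNA
        summary table (down *from* > cpm_high, up *to* > cpm_high).
    min_support : int
        Minimum number of prediction algorithms that must support a
        miRNA-target pair for it to enter an inverse-regulation network.
    n_algorithms : int
        Size of the prediction-algorithm panel.
    pseudocount : float
        Added to mean CPMs on the effect-size scale of the differential
        test; the reported (table-style) log2FC always uses pseudocount 0.
    seed : int
        Random seed for any stochastic step launched from this config.
    """

    p_cut: float = 0.01
    q_cut: float = 0.05
    fc_cut: float = 1.5
    cpm_floor: float = 1.0
    cpm_high: float = 100.0
    min_support: int = 5
    n_algorithms: int = 12
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_cut <= 1.0):
            raise ValueError(f"p_cut must be in (0, 1], got {self.p_cut}")
        if not (0.0 < self.q_cut <= 1.0):
            raise ValueError(f"q_cut must be in (0, 1], got {self.q_cut}")
        if not self.fc_cut > 1.0:
            raise ValueError(f"fc_cut must exceed 1, got {self.fc_cut}")
        if not (1 <= self.min_support <= self.n_algorithms):
            raise ValueError(
                f"min_support must be in [1, {self.n_algorithms}], got {self.min_support}"
            )

    @property
    def log2_fc_cut(self) -> float:
        return math.log2(self.fc_cut)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def log_thresholds(self) -> None:
        """Log the full threshold set so downstream counts are reproducible."""
        log.info(
            "thresholds: p<%g q<%g FC>%g (|log2FC|>%.4f) cpm_floor=%g "
            "cpm_high=%g min_support=%d/%d pseudocount=%g seed=%d",
            self.p_cut, self.q_cut, self.fc_cut, self.log2_fc_cut,
            self.cpm_floor, self.cpm_high, self.min_support,
            self.n_algorithms, self.pseudocount, self.seed,
        )
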