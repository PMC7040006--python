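"""Shared fixtures: small synthetic studies and toy matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from miromics import OmicsMatrix, PipelineConfig, SampleMeta, SynthConfig
from miromics.simulate import simulate_study


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """Down-scaled study conditions for fast structural tests."""
    return SynthConfig(seed=11, n_mrna=2000, n_mirna=200, n_protein=400)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    return simulate_study(small_cfg)


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


def make_counts_matrix(values: np.ndarray, lines, timepoints, modality="mrna_counts",
                       features=None) -> OmicsMatrix:
    """Counts matrix with one sample per (line, timepoint) pair, in the
    order given by zip-ordering of the two lists."""
    samples = [
        SampleMeta(f"s_{ln.replace('/', '-')}_{t}", ln, t, "untreated", modality)
        for ln, t in zip(lines, timepoints)
    ]
    if features is None:
        features = [f"F{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                      columns=[s.sample_id for s in samples])
    return OmicsMatrix(df, samples)


def make_protein_matrix(values: np.ndarray, lines, timepoints, features=None,
                        conditions=None) -> OmicsMatrix:
    conditions = conditions or ["untreated"] * len(lines)
    samples = [
        SampleMeta(f"p{i}_{ln.replace('/', '-')}_{t}", ln, t, c, "protein_abundance")
        for i, (ln, t, c) in enumerate(zip(lines, timepoints, conditions))
    ]
    if features is None:
        features = [f"P{i}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                      columns=[s.sample_id for s in samples])
    return OmicsMatrix(df, samples)


@pytest.fixture
def toy_counts() -> OmicsMatrix:
    """3 features x 2 samples with library sizes 1e6 and 5e5."""
    vals = np.array([[50, 50], [999_900, 499_925], [50, 25]])
    return make_counts_matrix(vals, ["4/101", "4/101"], ["native", "d3"])
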