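"""Packaged reference tables.

Currently one fixture: the published summary table of regulated miRNAs
(mean CPM at native/3d/7d/14d, per-timepoint log2 fold change,
per-timepoint significance flag, transfection-candidate marker) for the
13 miRNAs downregulated from a mean CPM > 100 and the 15 upregulated to
a mean CPM > 100.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_mirna_timecourse() -> pd.DataFrame:
    """The regulated-miRNA summary table as a DataFrame (28 rows)."""
    ref = resources.files("miromics").joinpath("data/table1_mirnas.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    for c in ("sig_d3", "sig_d7", "sig_d14", "transfection_candidate"):
        df[c] = df[c].astype(bool)
    return df


def mirna_timecourse_difftables(df: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Re-express the summary table as one DiffTable per timepoint.

    Significance flags are the printed ones; directions follow the sign of
    the printed log2FC. Suitable for the consistent-direction selection.
    """
    if df is None:
        df = load_mirna_timecourse()
    out = {}
    for t in ("d3", "d7", "d14"):
        sig = df[f"sig_{t}"].to_numpy()
        fc = df[f"log2fc_{t}"].to_numpy()
        out[t] = pd.DataFrame(
            {
                "feature_id": df["mirna"],
                "contrast": f"{t}_vs_native",
                "mean_ref": df["cpm_native"],
                "mean_alt": df[f"cpm_{t}"],
                "log2fc": fc,
                "log2fc_eff": fc,
                "p": float("nan"),
                "q": float("nan"),
                "significant": sig,
                "direction": [
                    "none" if not s else ("up" if f > 0 else "down")
                    for s, f in zip(sig, fc)
                ],
            }
        )
    return out
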