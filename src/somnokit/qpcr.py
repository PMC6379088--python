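"""RT-qPCR expression ratios: efficiency-corrected normalized relative
quantities (NRQ) against multiple reference genes, and the extended/common
3'UTR isoform ratio used to assay alternative polyadenylation.

The isoform ratio for a primer pair with amplification efficiency E is

    ratio_ext/com = E^(-Ct_ext) / E^(-Ct_comm) = E^(Ct_comm - Ct_ext)

and a gene's relative quantity in a sample is RQ = E^(mean Ct - Ct),
normalized by the geometric mean of the reference-gene RQs of the same
sample, then rescaled so each gene's grand-mean NRQ is 1.0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: measurements with mean Ct beyond this are conventionally unreliable
CT_RELIABLE_MAX = 30.0


def ext_com_ratio(E, Ct_ext, Ct_comm):
    """Extended-to-common isoform abundance ratio E^(Ct_comm - Ct_ext)."""
    E = np.asarray(E, float)
    if np.any(E <= 1):
        raise ValueError("amplification efficiency must exceed 1")
    out = E ** (np.asarray(Ct_comm, float) - np.asarray(Ct_ext, float))
    return float(out) if out.ndim == 0 else out


def flag_unreliable(table: pd.DataFrame, ct_max: float = CT_RELIABLE_MAX) -> pd.Series:
    """Per-gene flag: mean Ct above the reliability cut-off."""
    return table.groupby("gene")["Ct"].mean() > ct_max


def normalized_relative_quantity(
    table: pd.DataFrame,
    drop_unreliable: bool = False,
    ct_max: float = CT_RELIABLE_MAX,
) -> pd.DataFrame:
    """NRQ per gene x sample from a long-format Ct table.

    ``table`` columns: gene, sample, Ct, E, is_reference (>= 2 reference
    genes, each measured in every sample).  Steps: per gene,
    RQ = E^(Ct_mean - Ct); per sample, divide by the geometric mean of the
    reference-gene RQs; finally rescale each gene so its grand-mean NRQ is
    1.0.  Output columns: gene, sample, NRQ, log2_NRQ, unreliable.
    """
    required = {"gene", "sample", "Ct", "E", "is_reference"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    refs = table.loc[table["is_reference"], "gene"].unique()
    if len(refs) < 2:
        raise ValueError("need at least two reference genes")
    samples = table["sample"].unique()
    for g in refs:
        have = set(table.loc[table["gene"] == g, "sample"])
        missing = set(samples) - have
        if missing:
            raise ValueError(
                f"reference gene {g!r} missing in samples {sorted(missing)}"
            )

    df = table.copy()
    ct_mean = df.groupby("gene")["Ct"].transform("mean")
    df["RQ"] = df["E"] ** (ct_mean - df["Ct"])

    ref_rq = (
        df[df["gene"].isin(refs)]
        .groupby("sample")["RQ"]
        .apply(lambda v: float(np.exp(np.mean(np.log(v)))))
    )
    df["NRQ"] = df["RQ"] / df["sample"].map(ref_rq)
    df["NRQ"] = df["NRQ"] / df.groupby("gene")["NRQ"].transform("mean")

    unreliable = flag_unreliable(table, ct_max)
    df["unreliable"] = df["gene"].map(unreliable)
    if drop_unreliable:
        df = df[~df["unreliable"]]
    df["log2_NRQ"] = np.log2(df["NRQ"])
    return df[["gene", "sample", "NRQ", "log2_NRQ", "unreliable"]].reset_index(
        drop=True
    )
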