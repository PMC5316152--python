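"""Translational-efficiency changes.

The TE change of a gene is the ratio of its footprint fold change to its
mRNA fold change: transcription moves both assays together, so a TE ratio
away from 1 isolates translational regulation.  The TE z-score divides
log2(TE ratio) by the sample standard deviation of log2(TE ratio) over
all analysed genes; because both fold changes are median-centered the
log2 TE ratios already sit near zero, and no additional mean-centering is
applied by default.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexpr import local_sigma_all
from .errors import ParameterError

SD_EPSILON = 1e-12


def te_change(fc_fp: float, fc_mrna: float) -> float:
    """TE ratio = footprint fold change / mRNA fold change."""
    if fc_fp <= 0 or fc_mrna <= 0:
        raise ParameterError(f"fold changes must be > 0, got fp={fc_fp}, mrna={fc_mrna}")
    return fc_fp / fc_mrna


def te_zscores(log2_te: np.ndarray, center: bool = False) -> np.ndarray:
    """log2 TE ratios divided by their global sample SD (n-1).

    Degenerate convention: if the SD is numerically zero every z is 0.
    """
    x = np.asarray(log2_te, dtype=float)
    if x.size < 2:
        raise ParameterError(f"need >= 2 genes for a TE z-score, have {x.size}")
    shifted = x - x.mean() if center else x
    sd = float(np.std(x, ddof=1))
    if sd < SD_EPSILON:
        return np.zeros_like(x)
    return shifted / sd


def te_table(
    fc_mrna: pd.DataFrame,
    fc_fp: pd.DataFrame,
    center: bool = False,
    local_k: int | None = None,
    sigma_floor: float = 0.05,
) -> pd.DataFrame:
    """Join the two per-assay fold-change tables and compute TE statistics.

    Only genes present in both tables — i.e. passing the read filter in
    both assays independently — are scored.  ``local_k`` switches the
    denominator from the global SD to a read-depth-local SD computed over
    the ``local_k`` genes with the most similar combined reads (averaged
    over the two assays).
    """
    merged = pd.merge(
        fc_mrna[["gene_id", "combined_reads", "F"]].rename(
            columns={"F": "fc_mrna", "combined_reads": "reads_mrna"}
        ),
        fc_fp[["gene_id", "combined_reads", "F"]].rename(
            columns={"F": "fc_fp", "combined_reads": "reads_fp"}
        ),
        on="gene_id",
        how="inner",
    ).sort_values("gene_id", ignore_index=True)
    if len(merged) < 2:
        raise ParameterError(f"need >= 2 genes passing both filters, have {len(merged)}")
    te_ratio = merged["fc_fp"].to_numpy() / merged["fc_mrna"].to_numpy()
    log2_te = np.log2(te_ratio)
    if local_k is None:
        te_z = te_zscores(log2_te, center=center)
    else:
        reads = ((merged["reads_mrna"] + merged["reads_fp"]) // 2).to_numpy()
        sigma = local_sigma_all(log2_te, reads, k=local_k, sigma_floor=sigma_floor)
        te_z = (log2_te - log2_te.mean() if center else log2_te) / sigma
    return pd.DataFrame(
        {
            "gene_id": merged["gene_id"],
            "fc_mrna": merged["fc_mrna"],
            "fc_fp": merged["fc_fp"],
            "te_ratio": te_ratio,
            "log2_te": log2_te,
            "te_z": te_z,
        }
    )
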