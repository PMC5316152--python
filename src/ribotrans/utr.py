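"""5'UTR ribosome-loading analysis.

For each gene the footprint occupancy of the 5'UTR is summarized as the
ratio of 5'UTR footprints to CDS footprints per condition, and as the
between-condition fold change of each region (library-normalized with the
same per-file totals as the gene-level fold changes).  Genes whose
translational efficiency increased (te_z above the cutoff) are then sorted
into three loading classes by where the extra ribosomes went:

* class1 — footprints increase much more in the CDS than in the 5'UTR
  (more initiation at the canonical start, the GCN4-like pattern);
* class2 — footprints increase much more in the 5'UTR (loading at
  non-canonical upstream sites);
* class3 — both regions change together (uniform loading).

The boundary is a band of half-width ``delta`` log2 units around the
diagonal of the (5'UTR fold change, CDS fold change) plane.

The 5'UTR counts used here carry no TSS-exclusion window: the window is a
bias correction for gene-abundance counting, while 5'UTR occupancy itself
is the signal of interest.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .models import GeneModel
from .quantify import CountTable

DEFAULT_DELTA = 1.0          # log2 units; half-width of the class-3 diagonal band
DEFAULT_TE_Z_CUTOFF = 2.0
DEFAULT_MIN_EVIDENCE = 16    # footprints (utr5 + cds) needed per condition to classify


def utr_cds_ratio(utr5_count: int, cds_count: int) -> float:
    """5'UTR / CDS footprint ratio; NaN (undefined) when the CDS count is 0."""
    if utr5_count < 0 or cds_count < 0:
        raise ParameterError("counts must be >= 0")
    if cds_count == 0:
        return float("nan")
    return utr5_count / cds_count


def classify_loading(fc_utr5: float, fc_cds: float, delta: float = DEFAULT_DELTA) -> str:
    """Loading class from the two region fold changes.

    d = log2(fc_cds) - log2(fc_utr5); d > delta -> class1, d < -delta ->
    class2, otherwise class3.
    """
    if fc_utr5 <= 0 or fc_cds <= 0:
        raise ParameterError("region fold changes must be > 0")
    if delta <= 0:
        raise ParameterError(f"delta must be > 0, got {delta}")
    d = math.log2(fc_cds) - math.log2(fc_utr5)
    if d > delta:
        return "class1"
    if d < -delta:
        return "class2"
    return "class3"


def build_utr_table(
    counts: CountTable,
    te: pd.DataFrame,
    models: Sequence[GeneModel],
    delta: float = DEFAULT_DELTA,
    te_z_cutoff: float = DEFAULT_TE_Z_CUTOFF,
    min_evidence: int = DEFAULT_MIN_EVIDENCE,
    pseudocount: float = 0.5,
    classify_all: bool = False,
) -> pd.DataFrame:
    """Per-gene 5'UTR occupancy record.

    Uses footprint counts only.  ``te`` is the output of
    :func:`ribotrans.efficiency.te_table`; genes absent from it (failed a
    read filter) fall in te_group "other".  Classes are assigned only to
    te_group "up" genes with at least ``min_evidence`` footprints
    (utr5 + cds) in each condition, unless ``classify_all`` is set (then
    every gene with enough evidence is classified, which is useful when
    the classifier itself is being evaluated).
    """
    utr5 = counts.region_counts("footprint", "utr5")
    utr3 = counts.region_counts("footprint", "utr3")
    cds = counts.region_counts("footprint", "cds")
    n_sd = counts.library_totals[("SD", "footprint")]
    n_metr = counts.library_totals[("MetR", "footprint")]
    utr5_len = pd.Series({m.gene_id: m.utr5_len for m in models}, name="utr5_length")
    te_z = te.set_index("gene_id")["te_z"] if len(te) else pd.Series(dtype=float)

    gene_ids = utr5.index
    frame = pd.DataFrame(index=gene_ids)
    frame["ratio_sd"] = [utr_cds_ratio(u, c) for u, c in zip(utr5["SD"], cds["SD"])]
    frame["ratio_metr"] = [utr_cds_ratio(u, c) for u, c in zip(utr5["MetR"], cds["MetR"])]
    # 3'UTR occupancy ratios are reported as-is; no class logic uses them
    frame["ratio3_sd"] = [utr_cds_ratio(u, c) for u, c in zip(utr3["SD"], cds["SD"])]
    frame["ratio3_metr"] = [utr_cds_ratio(u, c) for u, c in zip(utr3["MetR"], cds["MetR"])]
    frame["fc_utr5"] = ((utr5["MetR"] + pseudocount) / n_metr) / ((utr5["SD"] + pseudocount) / n_sd)
    frame["fc_cds"] = ((cds["MetR"] + pseudocount) / n_metr) / ((cds["SD"] + pseudocount) / n_sd)
    frame["utr5_length"] = utr5_len.reindex(gene_ids)

    z = te_z.reindex(gene_ids)
    frame["te_group"] = np.select(
        [z > te_z_cutoff, z < -te_z_cutoff], ["up", "down"], default="other"
    )
    evidence = ((utr5["SD"] + cds["SD"]) >= min_evidence) & (
        (utr5["MetR"] + cds["MetR"]) >= min_evidence
    )
    eligible = evidence if classify_all else (evidence & (frame["te_group"] == "up"))
    frame["loading_class"] = [
        classify_loading(fu, fc, delta) if ok else "unassigned"
        for fu, fc, ok in zip(frame["fc_utr5"], frame["fc_cds"], eligible)
    ]
    return frame.reset_index().rename(columns={"index": "gene_id"})


def group_ratio_summary(
    records: pd.DataFrame,
    counts: CountTable,
    exclude_ids: Iterable[str] = (),
) -> pd.DataFrame:
    """Pooled and median 5'UTR/CDS ratios per TE group and condition.

    The pooled ratio is sum(utr5) / sum(cds) over the group's genes; the
    median is over per-gene ratios where defined.  ``exclude_ids`` drops
    designated outliers (e.g. a gene with an extreme, mechanistically
    distinct 5'UTR signal) from the summaries.
    """
    exclude = set(exclude_ids)
    utr5 = counts.region_counts("footprint", "utr5")
    cds = counts.region_counts("footprint", "cds")
    rows = []
    kept = records[~records["gene_id"].isin(exclude)]
    for group, sub in kept.groupby("te_group"):
        ids = sub["gene_id"].tolist()
        for condition, ratio_col in (("SD", "ratio_sd"), ("MetR", "ratio_metr")):
            total_cds = int(cds.loc[ids, condition].sum())
            pooled = (
                float(utr5.loc[ids, condition].sum()) / total_cds if total_cds > 0 else float("nan")
            )
            per_gene = sub[ratio_col].dropna()
            rows.append(
                {
                    "te_group": group,
                    "condition": condition,
                    "n_genes": len(ids),
                    "pooled_ratio": pooled,
                    "median_ratio": float(per_gene.median()) if len(per_gene) else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["te_group", "condition", "n_genes", "pooled_ratio", "median_ratio"])
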