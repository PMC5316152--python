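"""Fold changes with an empirical, read-depth-local noise estimate.

For each assay the per-gene fold change between the two conditions is a
library-size-normalized count ratio, rescaled so that the median fold
change over the analysed genes is exactly 1.  Because count noise depends
strongly on expression level, the significance of a fold change is judged
against genes of similar coverage: for gene *i* the ``k`` other genes with
the most similar combined read count are collected and the sample standard
deviation ``sigma_i`` of their log2 fold changes (including gene *i*, so
k + 1 values) estimates the local null spread.  The statistic is

    z_i = log2(F_i) / sigma_i,

with a two-sided normal p-value.  ``z`` is invariant to the logarithm base
as long as numerator and sigma share it.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .quantify import CountTable

DEFAULT_MIN_TOTAL = 128
DEFAULT_K = 100
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SIGMA_FLOOR = 0.05  # log2 units; prevents infinite z in flat neighborhoods


def filter_low_counts(table: CountTable, assay: str, min_total: int = DEFAULT_MIN_TOTAL) -> list[str]:
    """Genes whose raw CDS reads summed over both conditions reach ``min_total``.

    Genes below the threshold are too noisy for a reliable two-condition
    comparison and are excluded from all downstream statistics.
    """
    combined = table.combined_cds(assay)
    return sorted(combined.index[combined >= min_total])


def normalized_fold_changes(
    table: CountTable,
    assay: str,
    genes: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """MetR/SD fold change per gene, median-rescaled to 1 over ``genes``.

    A symmetric pseudocount keeps ratios finite for genes with a zero
    count in one condition that still pass the read filter.
    """
    totals = table.library_totals
    n_sd = totals[("SD", assay)]
    n_metr = totals[("MetR", assay)]
    if n_sd <= 0 or n_metr <= 0:
        raise DegenerateInputError(f"{assay}: empty library (totals SD={n_sd}, MetR={n_metr})")
    if len(genes) == 0:
        return pd.Series(dtype=float, name="F")
    mat = table.region_counts(assay, "cds").loc[list(genes)]
    ratio = ((mat["MetR"] + pseudocount) / n_metr) / ((mat["SD"] + pseudocount) / n_sd)
    fold = ratio / np.median(ratio.to_numpy())
    fold.name = "F"
    return fold


def local_sigma_all(
    log2_fold: np.ndarray,
    combined_reads: np.ndarray,
    k: int = DEFAULT_K,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    center: str = "mean",
) -> np.ndarray:
    """Neighborhood sigma for every gene at once.

    Arrays must be ordered by gene_id; ties in read-count distance are
    broken by that order, so the result is deterministic.  ``center`` is
    "mean" (sample SD about the neighborhood mean, n-1 denominator) or
    "zero" (RMS about zero, same denominator).
    """
    x = np.asarray(log2_fold, dtype=float)
    reads = np.asarray(combined_reads, dtype=np.int64)
    n = x.size
    if n < k + 1:
        raise ParameterError(
            f"need at least k+1={k + 1} genes for a size-{k} neighborhood, have {n}; "
            "use a smaller k"
        )
    if center not in ("mean", "zero"):
        raise ParameterError(f"center must be 'mean' or 'zero', got {center!r}")
    sigma = np.empty(n)
    order_key = np.arange(n, dtype=np.int64)
    block = max(1, int(2**24 // max(n, 1)))  # bound scratch memory
    for lo in range(0, n, block):
        hi = min(lo + block, n)
        dist = np.abs(reads[lo:hi, None] - reads[None, :])
        key = dist * np.int64(n) + order_key[None, :]
        neighborhood = np.argpartition(key, k, axis=1)[:, : k + 1]
        vals = x[neighborhood]
        if center == "mean":
            s = vals.std(axis=1, ddof=1)
        else:
            s = np.sqrt((vals**2).sum(axis=1) / (vals.shape[1] - 1))
        sigma[lo:hi] = np.maximum(s, sigma_floor)
    return sigma


def local_sigma(
    gene_id: str,
    fold_changes: Mapping[str, float],
    combined_reads: Mapping[str, int],
    k: int = DEFAULT_K,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    center: str = "mean",
) -> float:
    """Neighborhood sigma for a single gene (mapping-based convenience form)."""
    genes = sorted(fold_changes)
    if gene_id not in fold_changes:
        raise ParameterError(f"gene {gene_id!r} has no fold change")
    log2_fold = np.array([np.log2(fold_changes[g]) for g in genes])
    reads = np.array([combined_reads[g] for g in genes], dtype=np.int64)
    sigma = local_sigma_all(log2_fold, reads, k=k, sigma_floor=sigma_floor, center=center)
    return float(sigma[genes.index(gene_id)])


def fold_change_z(fold: float, sigma: float) -> tuple[float, float]:
    """(z, two-sided p) for one normalized fold change and its local sigma."""
    if fold <= 0:
        raise ParameterError(f"fold change must be > 0, got {fold}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    z = float(np.log2(fold) / sigma)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return z, p


def fold_change_table(
    table: CountTable,
    assay: str,
    min_total: int = DEFAULT_MIN_TOTAL,
    k: int = DEFAULT_K,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    sigma_floor: float = DEFAULT_SIGMA_FLOOR,
    center: str = "mean",
) -> pd.DataFrame:
    """Full per-gene fold-change statistics for one assay.

    Columns: gene_id, assay, combined_reads, F, log2F, sigma, z, p and a
    Benjamini-Hochberg ``q_bh`` column provided as an optional extra (the
    core statistic is the uncorrected z/p pair).
    """
    genes = filter_low_counts(table, assay, min_total)
    fold = normalized_fold_changes(table, assay, genes, pseudocount)
    combined = table.combined_cds(assay).loc[genes]
    log2_fold = np.log2(fold.to_numpy())
    sigma = local_sigma_all(log2_fold, combined.to_numpy(), k, sigma_floor, center)
    z = log2_fold / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    frame = pd.DataFrame(
        {
            "gene_id": genes,
            "assay": assay,
            "combined_reads": combined.to_numpy(),
            "F": fold.to_numpy(),
            "log2F": log2_fold,
            "sigma": sigma,
            "z": z,
            "p": p,
            "q_bh": stats.false_discovery_control(p) if len(p) else p,
        }
    )
    return frame
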