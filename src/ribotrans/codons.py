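"""Codon-usage statistics and their correlation with TE changes.

Lysine (AAA/AAG), glutamine (CAA/CAG) and glutamate (GAA/GAG) codons are
decoded by tRNAs whose wobble-uridine thiolation depends on sulfur
availability; under methionine/sulfur limitation, genes rich in these
"KQE" codons are expected to lose translational efficiency.  This module
computes per-gene K/Q/E (and methionine, as a control) codon frequencies
from CDS sequences and correlates them with log2 TE changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError, SequenceError
from .genesets import module_zscore

K_CODONS = frozenset({"AAA", "AAG"})
Q_CODONS = frozenset({"CAA", "CAG"})
E_CODONS = frozenset({"GAA", "GAG"})
M_CODONS = frozenset({"ATG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = set("ACGTN")


@dataclass(frozen=True)
class CodonStats:
    gene_id: str
    n_codons: int
    freq_K: float
    freq_Q: float
    freq_E: float
    freq_KQE: float
    freq_M: float


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class GenesetCodonContrast:
    """Member-vs-background contrast of KQE usage and TE change."""

    freq_kqe_z: float       # rank-sum z, members' freq_KQE vs others
    log2_te_z: float        # rank-sum z, members' log2 TE vs others
    r_members: float        # Pearson r within the member set
    r_complement: float     # Pearson r after excluding the member set
    n_members: int


def codon_frequencies(
    cds_sequence: str, gene_id: str = "", include_stop: bool = False
) -> CodonStats:
    """Per-gene codon frequencies, read in frame.

    The terminal stop codon is excluded from numerator and denominator by
    default; codons containing an ambiguous base (N) are dropped from
    both.  Internal stops or a length not divisible by 3 raise
    :class:`SequenceError` naming the gene.
    """
    seq = cds_sequence.upper().replace("U", "T")
    if len(seq) == 0 or len(seq) % 3 != 0:
        raise SequenceError(f"{gene_id or 'sequence'}: length {len(seq)} not a positive multiple of 3")
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise SequenceError(f"{gene_id or 'sequence'}: invalid nucleotides {bad}")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != "ATG":
        raise SequenceError(f"{gene_id or 'sequence'}: CDS must start with ATG, got {codons[0]}")
    if codons[-1] in STOP_CODONS and not include_stop:
        codons = codons[:-1]
    counts = {"K": 0, "Q": 0, "E": 0, "M": 0}
    n_codons = 0
    for i, codon in enumerate(codons):
        if "N" in codon:
            continue
        if codon in STOP_CODONS and i < len(codons) - 1:
            raise SequenceError(f"{gene_id or 'sequence'}: internal stop codon at codon {i}")
        n_codons += 1
        if codon in K_CODONS:
            counts["K"] += 1
        elif codon in Q_CODONS:
            counts["Q"] += 1
        elif codon in E_CODONS:
            counts["E"] += 1
        elif codon in M_CODONS:
            counts["M"] += 1
    if n_codons < 1:
        raise SequenceError(f"{gene_id or 'sequence'}: no unambiguous codons")
    return CodonStats(
        gene_id=gene_id,
        n_codons=n_codons,
        freq_K=counts["K"] / n_codons,
        freq_Q=counts["Q"] / n_codons,
        freq_E=counts["E"] / n_codons,
        freq_KQE=(counts["K"] + counts["Q"] + counts["E"]) / n_codons,
        freq_M=counts["M"] / n_codons,
    )


def codon_table(sequences: Mapping[str, str], include_stop: bool = False) -> pd.DataFrame:
    """Codon statistics for a whole CDS collection, one row per gene."""
    rows = [codon_frequencies(seq, gene_id, include_stop) for gene_id, seq in sequences.items()]
    return pd.DataFrame([r.__dict__ for r in rows]).sort_values("gene_id", ignore_index=True)


def _frequency_column(variable: str) -> str:
    mapping = {"K": "freq_K", "Q": "freq_Q", "E": "freq_E", "KQE": "freq_KQE", "M": "freq_M"}
    if variable not in mapping:
        raise ParameterError(f"variable must be one of {sorted(mapping)}, got {variable!r}")
    return mapping[variable]


def correlate_frequency_te(
    stats_frame: pd.DataFrame,
    te: pd.DataFrame,
    variable: str = "KQE",
    log_scale: bool = True,
) -> CorrelationResult:
    """Pearson correlation of a codon frequency with the TE change.

    Computed over the genes present in both tables; p from the
    t-distribution with n-2 degrees of freedom, two-sided.  ``log_scale``
    correlates against log2(TE ratio) (default) rather than the raw ratio.
    """
    col = _frequency_column(variable)
    merged = pd.merge(
        stats_frame[["gene_id", col]], te[["gene_id", "log2_te", "te_ratio"]], on="gene_id"
    )
    if len(merged) < 3:
        raise ParameterError(f"need >= 3 genes in the intersection, have {len(merged)}")
    freq = merged[col].to_numpy(dtype=float)
    if np.ptp(freq) == 0:
        raise DegenerateInputError(f"{variable} frequency is constant; correlation undefined")
    response = merged["log2_te"].to_numpy() if log_scale else merged["te_ratio"].to_numpy()
    r, p = stats.pearsonr(freq, response)
    return CorrelationResult(variable=variable, r=float(r), p=float(p), n=len(merged))


def geneset_codon_contrast(
    stats_frame: pd.DataFrame,
    te: pd.DataFrame,
    members: Iterable[str],
) -> GenesetCodonContrast:
    """Contrast one gene set (e.g. ribosome biogenesis) against the rest.

    Rank-sum z-scores test whether the set's KQE frequency and TE change
    deviate from the background; the complement-only Pearson r shows how
    much of a global frequency-TE correlation is carried by the set.
    """
    member_set = set(members)
    merged = pd.merge(
        stats_frame[["gene_id", "freq_KQE"]], te[["gene_id", "log2_te", "te_ratio"]], on="gene_id"
    )
    freq = merged.set_index("gene_id")["freq_KQE"]
    log2_te = merged.set_index("gene_id")["log2_te"]
    freq_z = module_zscore(freq, member_set)
    te_z = module_zscore(log2_te, member_set)

    def _pearson(sub: pd.DataFrame) -> float:
        if len(sub) < 3 or np.ptp(sub["freq_KQE"].to_numpy()) == 0:
            return float("nan")
        return float(stats.pearsonr(sub["freq_KQE"], sub["log2_te"])[0])

    in_set = merged["gene_id"].isin(member_set)
    return GenesetCodonContrast(
        freq_kqe_z=freq_z,
        log2_te_z=te_z,
        r_members=_pearson(merged[in_set]),
        r_complement=_pearson(merged[~in_set]),
        n_members=int(in_set.sum()),
    )
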