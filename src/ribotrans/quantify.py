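"""Region-aware counting of aligned read positions.

Each read is reduced to a single genomic coordinate: ribosome footprints
are shifted ``offset`` nucleotides (default 15) from their 5' end towards
the 3' end of the transcript to approximate the ribosomal P-site, while
mRNA reads keep their biological 5' end.  A read then contributes its
weight to a gene's CDS count when the assigned position lies inside the
CDS *and* at least ``tss_exclusion`` nucleotides (default 50) downstream
of the TSS in transcript coordinates — the window near the TSS is dropped
because read density there is systematically biased.  5'UTR and 3'UTR
counts use plain interval membership with no exclusion window.

Positions that fall inside two overlapping gene loci on the same strand
are assigned to neither gene and tallied as ``ambiguous``; positions in no
annotated region are tallied as ``unassigned``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .errors import InputError, ParameterError
from .models import ASSAYS, CONDITIONS, GeneModel

COUNT_COLUMNS = ["gene_id", "condition", "assay", "cds_count", "utr5_count", "utr3_count"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One aligned read (or a stack of identical reads) as a genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str
    weight: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(f"alignment requires 0 <= start < end, got [{self.start}, {self.end})")
        if self.weight < 1:
            raise ParameterError(f"alignment weight must be >= 1, got {self.weight}")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class CountTable:
    """Per-gene, per-region read counts for every condition x assay library.

    ``counts`` holds one row per (gene_id, condition, assay);
    ``library_totals`` the summed read weights of each input library;
    ``diagnostics`` per-library tallies of reads that were not counted
    (ambiguous, unassigned, TSS-window-excluded, wrong strand over a locus).
    """

    counts: pd.DataFrame
    library_totals: dict[tuple[str, str], int]
    diagnostics: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    def combined_cds(self, assay: str) -> pd.Series:
        """Raw CDS reads per gene summed over both conditions for one assay."""
        sub = self.counts[self.counts["assay"] == assay]
        return sub.groupby("gene_id")["cds_count"].sum().sort_index()

    def region_counts(self, assay: str, region: str) -> pd.DataFrame:
        """Genes x conditions matrix of raw counts for one region."""
        sub = self.counts[self.counts["assay"] == assay]
        mat = sub.pivot(index="gene_id", columns="condition", values=f"{region}_count")
        return mat.sort_index()

    def is_degenerate(self) -> bool:
        return any(total <= 0 for total in self.library_totals.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            for (condition, assay) in sorted(self.library_totals):
                total = self.library_totals[(condition, assay)]
                handle.write(f"# library_total\t{condition}\t{assay}\t{total}\n")
            for (condition, assay) in sorted(self.diagnostics):
                for key in sorted(self.diagnostics[(condition, assay)]):
                    val = self.diagnostics[(condition, assay)][key]
                    handle.write(f"# diagnostic\t{condition}\t{assay}\t{key}\t{val}\n")
        self.counts.to_csv(path, sep="\t", index=False, mode="a")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        totals: dict[tuple[str, str], int] = {}
        diagnostics: dict[tuple[str, str], dict[str, int]] = {}
        header_lines = 0
        try:
            with open(path) as handle:
                for line in handle:
                    if not line.startswith("#"):
                        break
                    header_lines += 1
                    fields = line.rstrip("\n").split("\t")
                    if fields[0] == "# library_total":
                        totals[(fields[1], fields[2])] = int(fields[3])
                    elif fields[0] == "# diagnostic":
                        diagnostics.setdefault((fields[1], fields[2]), {})[fields[3]] = int(fields[4])
        except OSError as exc:
            raise InputError(f"cannot read count table {path}: {exc}") from exc
        counts = pd.read_csv(path, sep="\t", skiprows=header_lines)
        missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
        if missing:
            raise InputError(f"count table {path} is missing columns: {missing}")
        return cls(counts=counts, library_totals=totals, diagnostics=diagnostics)


def assign_position(read: AlignmentRecord, assay: str, offset: int = 15) -> int:
    """Genomic coordinate a read is counted at.

    Footprints: 5' end shifted ``offset`` nt towards the 3' end of the
    transcript (P-site approximation).  mRNA: the unshifted 5' end.
    """
    if offset < 0:
        raise ParameterError(f"offset must be >= 0, got {offset}")
    if assay not in ASSAYS:
        raise ParameterError(f"unknown assay {assay!r}")
    if assay == "footprint" and offset >= read.end - read.start:
        raise ParameterError(
            f"offset {offset} >= read length {read.end - read.start}; shifted position "
            "would leave the read"
        )
    five_prime = read.start if read.strand == "+" else read.end - 1
    if assay == "mRNA":
        return five_prime
    return five_prime + offset if read.strand == "+" else five_prime - offset


def assign_positions_vec(
    start: np.ndarray, end: np.ndarray, strand_plus: np.ndarray, assay: str, offset: int = 15
) -> np.ndarray:
    """Vectorized :func:`assign_position` over BED columns."""
    if offset < 0:
        raise ParameterError(f"offset must be >= 0, got {offset}")
    five_prime = np.where(strand_plus, start, end - 1)
    if assay == "mRNA":
        return five_prime
    if np.any(offset >= end - start):
        raise ParameterError(f"offset {offset} >= length of at least one read")
    return np.where(strand_plus, five_prime + offset, five_prime - offset)


def _excluded_cds_interval(model: GeneModel, tss_exclusion: int) -> tuple[int, int]:
    """CDS genomic interval after removing positions < tss_exclusion nt from the TSS."""
    lo, hi = model.region_intervals()["cds"]
    if model.strand == "+":
        lo = max(lo, model.tss + tss_exclusion)
    else:
        hi = min(hi, model.tss - tss_exclusion)
    if lo >= hi:
        return lo, lo
    return lo, hi


def count_gene(
    reads: Iterable[AlignmentRecord],
    model: GeneModel,
    assay: str,
    offset: int = 15,
    tss_exclusion: int = 50,
) -> tuple[int, int, int]:
    """Count one gene's (cds, utr5, utr3) read weights by direct membership.

    Reads on the wrong strand or chromosome are ignored.  Used for single
    genes and as a readable reference for the vectorized table builder.
    """
    cds = utr5 = utr3 = 0
    regions = model.region_intervals()
    cds_lo, cds_hi = _excluded_cds_interval(model, tss_exclusion)
    for read in reads:
        if read.chrom != model.chrom or read.strand != model.strand:
            continue
        pos = assign_position(read, assay, offset)
        if cds_lo <= pos < cds_hi:
            cds += read.weight
        lo, hi = regions["utr5"]
        if lo <= pos < hi:
            utr5 += read.weight
        lo, hi = regions["utr3"]
        if lo <= pos < hi:
            utr3 += read.weight
    return cds, utr5, utr3


def _ambiguous_intervals(spans: np.ndarray) -> np.ndarray:
    """Merged intervals covered by >= 2 gene spans; spans is an (n, 2) array."""
    if len(spans) < 2:
        return np.empty((0, 2), dtype=np.int64)
    events = np.concatenate(
        [np.stack([spans[:, 0], np.ones(len(spans), dtype=np.int64)], axis=1),
         np.stack([spans[:, 1], -np.ones(len(spans), dtype=np.int64)], axis=1)]
    )
    order = np.lexsort((events[:, 1], events[:, 0]))
    events = events[order]
    coverage = np.cumsum(events[:, 1])
    out = []
    open_at = None
    for i in range(len(events)):
        if coverage[i] >= 2 and open_at is None:
            open_at = events[i, 0]
        elif coverage[i] < 2 and open_at is not None:
            if events[i, 0] > open_at:
                out.append((open_at, events[i, 0]))
            open_at = None
    return np.array(out, dtype=np.int64).reshape(-1, 2)


class _PositionIndex:
    """Sorted assigned positions with cumulative weights per (chrom, strand)."""

    def __init__(self, positions: np.ndarray, weights: np.ndarray):
        order = np.argsort(positions, kind="stable")
        self.pos = positions[order]
        self.cumw = np.concatenate([[0], np.cumsum(weights[order])])

    def weight_in(self, lo: int, hi: int) -> int:
        if hi <= lo:
            return 0
        i = np.searchsorted(self.pos, lo, side="left")
        j = np.searchsorted(self.pos, hi, side="left")
        return int(self.cumw[j] - self.cumw[i])

    def mask_out(self, intervals: np.ndarray) -> int:
        """Drop positions inside the given merged intervals; return dropped weight."""
        if len(intervals) == 0 or len(self.pos) == 0:
            return 0
        bounds = intervals.reshape(-1)
        inside = (np.searchsorted(bounds, self.pos, side="right") % 2) == 1
        dropped = int(np.sum(np.diff(self.cumw)[inside]))
        keep = ~inside
        weights = np.diff(self.cumw)[keep]
        self.pos = self.pos[keep]
        self.cumw = np.concatenate([[0], np.cumsum(weights)])
        return dropped


def count_library(
    bed: pd.DataFrame,
    models: Sequence[GeneModel],
    assay: str,
    offset: int = 15,
    tss_exclusion: int = 50,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene region counts for one library (one BED frame).

    Returns a frame indexed by gene_id with cds/utr5/utr3 columns plus a
    diagnostics dict (ambiguous, unassigned, tss_excluded, wrong_strand).
    """
    gene_ids = [m.gene_id for m in models]
    out = pd.DataFrame(
        0, index=pd.Index(gene_ids, name="gene_id"),
        columns=["cds_count", "utr5_count", "utr3_count"], dtype="int64",
    )
    diagnostics = {"ambiguous": 0, "unassigned": 0, "tss_excluded": 0, "wrong_strand": 0}
    total = int(bed["score"].sum()) if len(bed) else 0
    diagnostics["library_total"] = total
    if len(bed) == 0:
        return out, diagnostics

    strand_plus = (bed["strand"] == "+").to_numpy()
    positions = assign_positions_vec(
        bed["start"].to_numpy(), bed["end"].to_numpy(), strand_plus, assay, offset
    )
    weights = bed["score"].to_numpy()
    chroms = bed["chrom"].to_numpy()

    indexes: dict[tuple[str, str], _PositionIndex] = {}
    for chrom in np.unique(chroms):
        on_chrom = chroms == chrom
        for strand, smask in (("+", strand_plus), ("-", ~strand_plus)):
            sel = on_chrom & smask
            if sel.any():
                indexes[(chrom, strand)] = _PositionIndex(positions[sel], weights[sel])

    by_group: dict[tuple[str, str], list[GeneModel]] = {}
    for model in models:
        by_group.setdefault((model.chrom, model.strand), []).append(model)

    assigned = 0
    for (chrom, strand), group in by_group.items():
        spans = np.array([m.span for m in group], dtype=np.int64)
        index = indexes.get((chrom, strand))
        ambiguous = _ambiguous_intervals(spans)
        if index is not None:
            diagnostics["ambiguous"] += index.mask_out(ambiguous)
        opposite = indexes.get((chrom, "-" if strand == "+" else "+"))
        for model, span in zip(group, spans):
            if opposite is not None:
                diagnostics["wrong_strand"] += opposite.weight_in(int(span[0]), int(span[1]))
            if index is None:
                continue
            regions = model.region_intervals()
            cds_lo, cds_hi = _excluded_cds_interval(model, tss_exclusion)
            cds = index.weight_in(cds_lo, cds_hi)
            cds_full = index.weight_in(*regions["cds"])
            utr5 = index.weight_in(*regions["utr5"])
            utr3 = index.weight_in(*regions["utr3"])
            out.loc[model.gene_id] = [cds, utr5, utr3]
            diagnostics["tss_excluded"] += cds_full - cds
            assigned += cds_full + utr5 + utr3
    diagnostics["unassigned"] = total - diagnostics["ambiguous"] - assigned
    return out, diagnostics


def build_count_table(
    beds: Mapping[tuple[str, str], "pd.DataFrame | str"],
    models: Sequence[GeneModel],
    offset: int = 15,
    tss_exclusion: int = 50,
) -> CountTable:
    """Aggregate four (condition, assay) libraries into one :class:`CountTable`.

    ``beds`` maps (condition, assay) to an already-parsed BED frame or a
    file path.  Deterministic given inputs; BED line order is immaterial.
    """
    expected = {(c, a) for c in CONDITIONS for a in ASSAYS}
    if set(beds) != expected:
        raise ParameterError(
            f"need exactly the libraries {sorted(expected)}, got {sorted(beds)}"
        )
    frames = []
    totals: dict[tuple[str, str], int] = {}
    diagnostics: dict[tuple[str, str], dict[str, int]] = {}
    for condition in CONDITIONS:
        for assay in ASSAYS:
            bed = beds[(condition, assay)]
            if not isinstance(bed, pd.DataFrame):
                bed = _io.read_bed6(bed)
            counts, diag = count_library(bed, models, assay, offset, tss_exclusion)
            totals[(condition, assay)] = diag.pop("library_total")
            diagnostics[(condition, assay)] = diag
            block = counts.reset_index()
            block.insert(1, "condition", condition)
            block.insert(2, "assay", assay)
            frames.append(block)
    table = CountTable(
        counts=pd.concat(frames, ignore_index=True),
        library_totals=totals,
        diagnostics=diagnostics,
    )
    return table
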