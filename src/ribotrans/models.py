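"""Gene models on a reference sequence.

All coordinates are 0-based, half-open (BED convention).  A gene model
stores four transcript landmarks in genomic coordinates: the transcription
start site (``tss``), the CDS boundaries (``cds_start``/``cds_end``, start
codon to stop codon) and the 3'UTR end (``utr3_end``).  On the plus strand
these are increasing, ``tss <= cds_start < cds_end <= utr3_end``; on the
minus strand the ordering is mirrored (``tss >= cds_start > cds_end >=
utr3_end``) so that each field keeps its transcript meaning: ``tss`` is
always the 5' end of the transcript and ``utr3_end`` the 3' end.

Genomic region intervals (half-open) follow from the landmarks:

========  ==========================  ==========================
region    plus strand                 minus strand
========  ==========================  ==========================
5'UTR     ``[tss, cds_start)``        ``[cds_start, tss)``
CDS       ``[cds_start, cds_end)``    ``[cds_end, cds_start)``
3'UTR     ``[cds_end, utr3_end)``     ``[utr3_end, cds_end)``
========  ==========================  ==========================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import InputError, ModelError

CONDITIONS = ("SD", "MetR")
ASSAYS = ("mRNA", "footprint")
REGIONS = ("cds", "utr5", "utr3")

MODEL_COLUMNS = ["gene_id", "chrom", "strand", "tss", "cds_start", "cds_end", "utr3_end"]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    cds_start: int
    cds_end: int
    utr3_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+":
            ordered = 0 <= self.tss <= self.cds_start < self.cds_end <= self.utr3_end
        else:
            ordered = self.tss >= self.cds_start > self.cds_end >= self.utr3_end >= 0
        if not ordered:
            raise ModelError(
                f"{self.gene_id}: landmarks out of order for strand {self.strand}: "
                f"tss={self.tss} cds_start={self.cds_start} cds_end={self.cds_end} "
                f"utr3_end={self.utr3_end}"
            )
        if self.cds_len % 3 != 0:
            raise ModelError(f"{self.gene_id}: CDS length {self.cds_len} not divisible by 3")

    @property
    def cds_len(self) -> int:
        return abs(self.cds_end - self.cds_start)

    @property
    def utr5_len(self) -> int:
        return abs(self.cds_start - self.tss)

    @property
    def utr3_len(self) -> int:
        return abs(self.utr3_end - self.cds_end)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent of the transcript as a half-open interval."""
        lo, hi = sorted((self.tss, self.utr3_end))
        return lo, hi

    def region_intervals(self) -> dict[str, tuple[int, int]]:
        """Genomic half-open interval of each region, keyed by region name."""
        if self.strand == "+":
            return {
                "utr5": (self.tss, self.cds_start),
                "cds": (self.cds_start, self.cds_end),
                "utr3": (self.cds_end, self.utr3_end),
            }
        return {
            "utr5": (self.cds_start, self.tss),
            "cds": (self.cds_end, self.cds_start),
            "utr3": (self.utr3_end, self.cds_end),
        }

    def transcript_pos(self, position: int) -> int:
        """Distance of a genomic position from the TSS along the transcript."""
        if self.strand == "+":
            return position - self.tss
        return (self.tss - 1) - position

    def region_of(self, position: int) -> str | None:
        """Name of the region containing a genomic position, or None."""
        for region, (lo, hi) in self.region_intervals().items():
            if lo <= position < hi:
                return region
        return None


def models_to_frame(models: Iterable[GeneModel]) -> pd.DataFrame:
    rows = [
        (m.gene_id, m.chrom, m.strand, m.tss, m.cds_start, m.cds_end, m.utr3_end)
        for m in models
    ]
    return pd.DataFrame(rows, columns=MODEL_COLUMNS)


def models_from_frame(frame: pd.DataFrame) -> list[GeneModel]:
    missing = [c for c in MODEL_COLUMNS if c not in frame.columns]
    if missing:
        raise InputError(f"gene-model table is missing columns: {missing}")
    return [
        GeneModel(
            gene_id=str(r.gene_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            tss=int(r.tss),
            cds_start=int(r.cds_start),
            cds_end=int(r.cds_end),
            utr3_end=int(r.utr3_end),
        )
        for r in frame.itertuples(index=False)
    ]


def write_gene_models(models: Iterable[GeneModel], path) -> None:
    models_to_frame(models).to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read gene-model table {path}: {exc}") from exc
    return models_from_frame(frame)
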