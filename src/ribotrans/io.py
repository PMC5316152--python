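"""Readers and writers for the plain-text interchange formats.

BED6 for aligned read positions (0-based half-open, the ``score`` column
carries the collapsed read multiplicity), FASTA for CDS sequences, GMT for
gene-set memberships and TSV for everything tabular.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed6(path) -> pd.DataFrame:
    """Read a BED6 file into a data frame, validating every line.

    The score column is interpreted as the read multiplicity at that
    position (>= 1).  Malformed lines raise :class:`InputError` naming the
    file and 1-based line number.
    """
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=BED_COLUMNS,
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except (OSError, pd.errors.ParserError, ValueError) as exc:
        raise InputError(f"cannot parse BED file {path}: {exc}") from exc
    if frame.empty:
        return pd.DataFrame(columns=BED_COLUMNS).astype(
            {"start": "int64", "end": "int64", "score": "int64"}
        )
    for col in ("start", "end", "score"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise InputError(f"{path}: line {line}: non-integer {col!r} field")
        frame[col] = numeric.astype("int64")
    bad = (frame["start"] < 0) | (frame["start"] >= frame["end"])
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise InputError(f"{path}: line {line}: requires 0 <= start < end")
    bad = frame["score"] < 1
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise InputError(f"{path}: line {line}: score (read weight) must be >= 1")
    bad = ~frame["strand"].isin(["+", "-"])
    if bad.any():
        line = int(bad.idxmax()) + 1
        raise InputError(f"{path}: line {line}: strand must be '+' or '-'")
    return frame


def write_bed6(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False, columns=BED_COLUMNS)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping."""
    try:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read FASTA {path}: {exc}") from exc


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="") for gene_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file (set name, description, member ids, tab-separated)."""
    sets: dict[str, set[str]] = {}
    try:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise InputError(
                        f"{path}: line {lineno}: GMT needs name, description and >= 1 member"
                    )
                sets[fields[0]] = {g for g in fields[2:] if g}
    except OSError as exc:
        raise InputError(f"cannot read GMT {path}: {exc}") from exc
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as handle:
        for name in sets:
            members = sorted(sets[name])
            desc = descriptions.get(name, "na")
            handle.write("\t".join([name, desc, *members]) + "\n")


def write_tsv(frame: pd.DataFrame, path) -> None:
    """Write a tabular output with a fixed float format for reproducibility."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read table {path}: {exc}") from exc
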