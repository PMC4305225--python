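"""Reading and writing the flat-file formats of the binning workflow.

Covers multi-FASTA input of assembled contigs or long reads (with the
minimum-length filter applied at read time), the per-sequence annotation
file (comma-separated, positional), 2-D embedding tables, and FASTA export
of selected bins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "AnnotationRecord",
    "FilteredFasta",
    "read_fasta",
    "read_annotations",
    "write_fasta",
    "write_bin_fasta",
    "write_embedding",
    "read_embedding",
]

# Unambiguous + ambiguous IUPAC nucleotide one-letter codes (incl. U).
IUPAC_NUCLEOTIDES = frozenset("ACGTUNRYSWKMBDHV")

FASTA_WRAP = 70


@dataclass
class SequenceRecord:
    """One FASTA entry: id (header token up to first whitespace), sequence.

    Sequences are uppercased on read; the remainder of the header line is
    kept as ``description`` and re-emitted on export.
    """

    id: str
    sequence: str
    description: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationRecord:
    """Optional per-sequence metadata from the annotation file.

    All fields are optional, but at least one must be present. ``length``
    is informational (the FASTA is authoritative); ``coverage`` is mean
    read depth; ``gc`` is %GC in [0, 100]; ``label`` is a free-form tag
    such as a taxonomic or bin id; ``is_marker`` flags sequences carrying
    a marker gene of interest.
    """

    length: int | None = None
    coverage: float | None = None
    gc: float | None = None
    label: str | None = None
    is_marker: bool | None = None

    def __post_init__(self) -> None:
        if all(
            v is None
            for v in (self.length, self.coverage, self.gc, self.label, self.is_marker)
        ):
            raise ValueError("annotation record has no fields set")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if self.gc is not None and not (0.0 <= self.gc <= 100.0):
            raise ValueError(f"gc must be in [0, 100], got {self.gc}")


@dataclass
class FilteredFasta:
    """Result of reading a FASTA with a length filter applied.

    ``records`` are the retained entries in file order; ``kept_indices``
    are their 0-based positions in the unfiltered file, which is what
    positional annotation alignment needs.
    """

    records: list[SequenceRecord]
    kept_indices: list[int]
    n_input: int

    @property
    def n_dropped(self) -> int:
        return self.n_input - len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _validate_sequence(rec_id: str, seq: str) -> None:
    bad = set(seq) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(
            f"record {rec_id!r} contains non-IUPAC nucleotide characters: "
            f"{sorted(bad)}"
        )


def read_fasta(path: str | Path, min_length: int = 1000) -> FilteredFasta:
    """Read a multi-FASTA, keeping records of at least ``min_length`` nt.

    The threshold is inclusive. Duplicate ids and non-IUPAC characters
    are errors; lowercase bases are uppercased.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    path = Path(path)
    records: list[SequenceRecord] = []
    kept: list[int] = []
    seen: set[str] = set()
    n_input = 0
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        seq = str(bio_rec.seq).upper()
        rec_id = bio_rec.id
        if rec_id in seen:
            raise ValueError(f"duplicate sequence id {rec_id!r} in {path}")
        seen.add(rec_id)
        _validate_sequence(rec_id, seq)
        desc = bio_rec.description
        if desc.startswith(rec_id):
            desc = desc[len(rec_id):].strip()
        if len(seq) >= min_length:
            records.append(SequenceRecord(rec_id, seq, desc))
            kept.append(n_input)
        n_input += 1
    if n_input == 0:
        raise ValueError(f"no FASTA records found in {path}")
    return FilteredFasta(records=records, kept_indices=kept, n_input=n_input)


_ANNOTATION_FIELDS = {"length", "coverage", "gc", "label", "isMarker"}
_TRUE = {"1", "true"}
_FALSE = {"0", "false"}


def _parse_marker(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"isMarker value {value!r} not in {{0, 1, true, false}}")


def read_annotations(path: str | Path, fasta: FilteredFasta) -> list[AnnotationRecord]:
    """Parse the comma-separated annotation file and align it to ``fasta``.

    The file has a header naming a subset of ``{length, coverage, gc,
    label, isMarker}`` and one row per record of the *unfiltered* FASTA,
    in FASTA file order; rows are then subset to the retained records so
    annotation i belongs to retained record i. Alignment is purely
    positional — the format carries no id column.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    unknown = set(df.columns) - _ANNOTATION_FIELDS
    if unknown:
        raise ValueError(
            f"unknown annotation fields {sorted(unknown)}; "
            f"expected a subset of {sorted(_ANNOTATION_FIELDS)}"
        )
    if not len(df.columns):
        raise ValueError("annotation file has no columns")
    if len(df) != fasta.n_input:
        raise ValueError(
            f"annotation file has {len(df)} rows but the FASTA has "
            f"{fasta.n_input} records"
        )

    def _num(col: str, row: int, cast):
        raw = df[col].iloc[row]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            return None
        try:
            return cast(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric {col} value {raw!r} at row {row + 1}") from exc

    def _cell(col: str, row: int):
        raw = df[col].iloc[row]
        return None if pd.isna(raw) else raw

    annotations: list[AnnotationRecord] = []
    for idx in fasta.kept_indices:
        marker_raw = _cell("isMarker", idx) if "isMarker" in df else None
        annotations.append(
            AnnotationRecord(
                length=_num("length", idx, lambda v: int(float(v))) if "length" in df else None,
                coverage=_num("coverage", idx, float) if "coverage" in df else None,
                gc=_num("gc", idx, float) if "gc" in df else None,
                label=(str(_cell("label", idx)) if "label" in df and _cell("label", idx) is not None else None),
                is_marker=(_parse_marker(marker_raw) if marker_raw is not None else None),
            )
        )
    return annotations


def _format_record(rec: SequenceRecord) -> str:
    header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
    body = "\n".join(
        rec.sequence[i : i + FASTA_WRAP] for i in range(0, len(rec.sequence), FASTA_WRAP)
    )
    return f"{header}\n{body}\n" if body else f"{header}\n"


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> int:
    """Write records to FASTA (70-column wrap). Returns the count written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(_format_record(rec))
            n += 1
    return n


def write_bin_fasta(
    records: Sequence[SequenceRecord], ids: Iterable[str], path: str | Path
) -> int:
    """Export the records whose ids are in ``ids``, preserving input order.

    Every requested id must occur among ``records``; unknown ids are an
    error. Returns the number of records written.
    """
    wanted = set(ids)
    known = {r.id for r in records}
    missing = wanted - known
    if missing:
        raise KeyError(f"ids not present among records: {sorted(missing)}")
    selected = [r for r in records if r.id in wanted]
    return write_fasta(selected, path)


def write_embedding(path: str | Path, ids: Sequence[str], coords: np.ndarray) -> None:
    """Write a (id, x, y) comma-separated embedding table.

    Coordinates are written with repr precision so the file loads back to
    the exact same doubles, allowing re-selection without recomputation.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (len(ids), 2):
        raise ValueError(f"coords shape {coords.shape} does not match {len(ids)} ids")
    with open(path, "w") as fh:
        fh.write("id,x,y\n")
        for rec_id, (x, y) in zip(ids, coords):
            fh.write(f"{rec_id},{float(x)!r},{float(y)!r}\n")


def read_embedding(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read an embedding table written by :func:`write_embedding`."""
    df = pd.read_csv(
        path, dtype={"id": str, "x": float, "y": float}, float_precision="round_trip"
    )
    expected = ["id", "x", "y"]
    if list(df.columns) != expected:
        raise ValueError(f"embedding file columns {list(df.columns)} != {expected}")
    return df["id"].tolist(), df[["x", "y"]].to_numpy()
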