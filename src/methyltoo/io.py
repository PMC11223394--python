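"""Readers and writers for every on-disk artifact.

Formats: FASTA genomes (via pyfaidx), BED region sets, and
tab-separated tables for methylation calls, region-value matrices and
sample labels.  Coordinates are 0-based half-open everywhere; missing
matrix cells serialize as the literal ``NA``.  Parsing never silently
coerces — every rejected token is reported with its location.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from methyltoo.constants import ALL_CLASSES, NA_TOKEN, UNKNOWN_LABEL
from methyltoo.regions import GenomicRegion, RegionValueMatrix


class FormatError(ValueError):
    """A file does not conform to its declared tabular format."""


@dataclass(frozen=True)
class MethylCallRecord:
    """One per-read CpG observation event.

    ``cpg_position`` is the 0-based forward-strand coordinate of the
    CpG's C; reverse-strand observations are assumed already projected
    to this convention upstream.
    """

    read_id: str
    chrom: str
    cpg_position: int
    methylated: bool

    def __post_init__(self) -> None:
        if self.cpg_position < 0:
            raise ValueError(f"negative CpG position {self.cpg_position}")


@dataclass(frozen=True)
class SampleRecord:
    """A sample's identity, class label and location of its calls."""

    sample_id: str
    class_label: str
    path: str


_CALL_COLUMNS = ("read_id", "chrom", "pos", "meth")


def read_methyl_calls(path: str | Path) -> Iterator[MethylCallRecord]:
    """Stream methylation-call records from a TSV file.

    Requires header columns ``read_id``, ``chrom``, ``pos``, ``meth``
    with ``meth`` in {0, 1}.  Malformed lines raise with their line
    number; records are yielded in file order.
    """
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected header") from None
        col = {name: i for i, name in enumerate(header)}
        for required in _CALL_COLUMNS:
            if required not in col:
                raise FormatError(f"{path}: missing required column '{required}'")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            try:
                pos = int(row[col["pos"]])
            except (ValueError, IndexError):
                raise FormatError(f"{path}: line {lineno}: unparsable pos") from None
            meth_tok = row[col["meth"]] if len(row) > col["meth"] else ""
            if meth_tok not in ("0", "1"):
                raise ValueError(
                    f"{path}: line {lineno}: meth must be 0 or 1, got {meth_tok!r}"
                )
            yield MethylCallRecord(
                read_id=row[col["read_id"]],
                chrom=row[col["chrom"]],
                cpg_position=pos,
                methylated=meth_tok == "1",
            )


def write_methyl_calls(records, path: str | Path) -> None:
    """Write call records (or a read_id/chrom/pos/meth DataFrame) as TSV."""
    if isinstance(records, pd.DataFrame):
        records[list(_CALL_COLUMNS)].to_csv(path, sep="\t", index=False)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_CALL_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.read_id, rec.chrom, rec.cpg_position, int(rec.methylated)]
            )


def calls_to_frame(records) -> pd.DataFrame:
    """Materialize a record stream as a DataFrame for vectorized work."""
    rows = [(r.read_id, r.chrom, r.cpg_position, int(r.methylated)) for r in records]
    return pd.DataFrame(rows, columns=list(_CALL_COLUMNS))


def frame_to_calls(frame: pd.DataFrame) -> Iterator[MethylCallRecord]:
    for row in frame.itertuples(index=False):
        yield MethylCallRecord(str(row.read_id), str(row.chrom), int(row.pos), bool(row.meth))


def write_regions_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED (0-based half-open).

    Columns: chrom, start, end, region id, CpG count, then the CpG
    coordinates comma-joined (so a round trip preserves all fields).
    Input must already be sorted by (chrom, start).
    """
    keys = [(r.chrom, r.start) for r in regions]
    if keys != sorted(keys):
        raise ValueError("regions must be sorted by (chrom, start) before writing")
    with open(path, "w") as fh:
        for r in regions:
            cpgs = ",".join(str(p) for p in r.cpg_positions)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{len(r.cpg_positions)}\t{cpgs}\n")


def read_regions_bed(path: str | Path) -> list[GenomicRegion]:
    """Read regions written by :func:`write_regions_bed`."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 BED columns")
            chrom, start, end, rid, count, cpgs = fields[:6]
            positions = tuple(int(p) for p in cpgs.split(","))
            if len(positions) != int(count):
                raise FormatError(
                    f"{path}: line {lineno}: CpG count {count} != {len(positions)} listed"
                )
            regions.append(GenomicRegion(chrom, int(start), int(end), positions, rid))
    return regions


def write_matrix_tsv(matrix: RegionValueMatrix, path: str | Path) -> None:
    """Serialize a region-value matrix: sample rows, region columns, NA for missing."""
    frame = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.region_ids)
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="sample_id", float_format="%.10g")


def read_matrix_tsv(path: str | Path) -> RegionValueMatrix:
    """Read a region-value matrix TSV; out-of-range cells raise with their address."""
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[NA_TOKEN], keep_default_na=False
    )
    values = frame.to_numpy(dtype=float)
    bad = np.argwhere(np.isfinite(values) & ((values < 0.0) | (values > 1.0)))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: value {values[i, j]} outside [0, 1] at "
            f"(sample {frame.index[i]!r}, region {frame.columns[j]!r})"
        )
    return RegionValueMatrix(
        sample_ids=[str(s) for s in frame.index],
        region_ids=[str(c) for c in frame.columns],
        values=values,
    )


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read a sample table TSV with columns sample_id, class_label, path."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for required in ("sample_id", "class_label", "path"):
        if required not in frame.columns:
            raise FormatError(f"{path}: missing required column '{required}'")
    if frame["sample_id"].duplicated().any():
        dup = frame["sample_id"][frame["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    allowed = set(ALL_CLASSES) | {UNKNOWN_LABEL}
    records = []
    for row in frame.itertuples(index=False):
        if row.class_label not in allowed:
            raise FormatError(
                f"{path}: unknown class_label {row.class_label!r} for sample "
                f"{row.sample_id!r}; expected one of {sorted(allowed)}"
            )
        records.append(SampleRecord(row.sample_id, row.class_label, row.path))
    return records


def write_sample_table(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.class_label, r.path) for r in records],
        columns=["sample_id", "class_label", "path"],
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id / class_label TSV into a dict."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for required in ("sample_id", "class_label"):
        if required not in frame.columns:
            raise FormatError(f"{path}: missing required column '{required}'")
    return dict(zip(frame["sample_id"], frame["class_label"]))
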