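"""CpG-dense region discovery and per-sample region methylation values.

A *CpG region* is a 100 bp genomic interval containing at least five CpG
dinucleotides.  For one sample, the *region value* beta of region j is
M_j / N_j where N_j counts (read, in-region CpG) observation events and
M_j counts the methylated ones.  Regions with no coverage are missing —
no imputation is ever applied.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

REGION_LENGTH = 100
MIN_CPG_COUNT = 5


@dataclass(frozen=True)
class GenomicRegion:
    """A 100 bp CpG-dense interval, 0-based half-open coordinates.

    ``cpg_positions`` holds the forward-strand coordinates of the C of
    every CpG dinucleotide inside ``[start, end)``, sorted ascending.
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]
    region_id: str

    def __post_init__(self) -> None:
        if self.end - self.start != REGION_LENGTH:
            raise ValueError(
                f"region {self.region_id}: length {self.end - self.start} != {REGION_LENGTH}"
            )
        if len(self.cpg_positions) < MIN_CPG_COUNT:
            raise ValueError(
                f"region {self.region_id}: only {len(self.cpg_positions)} CpGs (< {MIN_CPG_COUNT})"
            )
        if any(p < self.start or p >= self.end for p in self.cpg_positions):
            raise ValueError(f"region {self.region_id}: CpG position outside interval")
        if list(self.cpg_positions) != sorted(self.cpg_positions):
            raise ValueError(f"region {self.region_id}: CpG positions not sorted")


@dataclass
class RegionValueMatrix:
    """Samples x regions methylation levels with explicit missingness.

    ``values[i, j]`` is beta for sample i at region j, NaN when region j
    had zero coverage in sample i.  ``depth_n`` optionally carries the
    event counts N_j for diagnostics; ``missing <=> depth_n == 0``.
    """

    sample_ids: list[str]
    region_ids: list[str]
    values: np.ndarray
    depth_n: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.region_ids)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.sample_ids)}, {len(self.region_ids)})"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("region values must lie in [0, 1]")
        if self.depth_n is not None:
            self.depth_n = np.asarray(self.depth_n)
            if self.depth_n.shape != self.values.shape:
                raise ValueError("depth_n shape mismatch")

    @property
    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]


def find_cpg_positions(sequence: str) -> list[int]:
    """Forward-strand CpG sites: positions of the C of every ``CG``.

    Ambiguous bases never count; matching is case-insensitive.
    """
    seq = sequence.upper()
    out: list[int] = []
    i = seq.find("CG")
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1)
    return out


def discover_cpg_regions(
    genome: Mapping[str, str],
    region_length: int = REGION_LENGTH,
    min_cpgs: int = MIN_CPG_COUNT,
) -> list[GenomicRegion]:
    """Greedy scan for non-overlapping CpG-dense regions.

    Chromosomes are processed in lexicographic name order.  Along each
    one, at every CpG position ``p`` not yet covered the window
    ``[p, p + region_length)`` is tested; if it holds at least
    ``min_cpgs`` CpGs it is emitted and the scan jumps past its end.
    The result is deterministic, non-overlapping, CpG-anchored and
    sorted by (chrom, start).

    ``genome`` maps sequence names to sequences; a ``pyfaidx.Fasta``
    works directly (records coerce to ``str``).  Sequences shorter than
    ``region_length`` simply yield no regions.
    """
    regions: list[GenomicRegion] = []
    for chrom in sorted(genome.keys()):
        seq = str(genome[chrom])
        cpgs = find_cpg_positions(seq)
        n = len(seq)
        i = 0
        while i < len(cpgs):
            p = cpgs[i]
            end = p + region_length
            if end > n:
                break
            j = bisect_left(cpgs, end, lo=i)
            if j - i >= min_cpgs:
                rid = f"r{len(regions):06d}"
                regions.append(
                    GenomicRegion(chrom, p, end, tuple(cpgs[i:j]), rid)
                )
                i = j  # jump past the emitted window
            else:
                i += 1
    return regions


def compute_region_value(calls: Iterable, region: GenomicRegion) -> float:
    """Region value beta = M/N for one sample at one region.

    ``calls`` yields objects with ``chrom``, ``cpg_position`` and
    ``methylated`` attributes.  Only events whose CpG lies in
    ``region.cpg_positions`` contribute; CpG observations outside the
    region are discarded.  Returns NaN when no event overlaps (missing,
    never imputed).
    """
    in_region = set(region.cpg_positions)
    n = m = 0
    for rec in calls:
        if rec.chrom == region.chrom and rec.cpg_position in in_region:
            n += 1
            m += int(rec.methylated)
    return m / n if n else float("nan")


@dataclass
class _RegionIndex:
    """Maps (chrom, cpg position) to region index for fast aggregation."""

    lookup: dict[tuple[str, int], int] = field(default_factory=dict)

    @classmethod
    def build(cls, regions: Sequence[GenomicRegion]) -> "_RegionIndex":
        idx = cls()
        for k, region in enumerate(regions):
            for p in region.cpg_positions:
                idx.lookup[(region.chrom, p)] = k
        return idx


def tally_calls(
    calls: Iterable, regions: Sequence[GenomicRegion], index: _RegionIndex | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Count (M, N) event totals per region for one sample's calls."""
    if index is None:
        index = _RegionIndex.build(regions)
    n = np.zeros(len(regions), dtype=np.int64)
    m = np.zeros(len(regions), dtype=np.int64)
    for rec in calls:
        k = index.lookup.get((rec.chrom, rec.cpg_position))
        if k is not None:
            n[k] += 1
            m[k] += int(rec.methylated)
    return m, n


def tally_call_frame(
    frame, regions: Sequence[GenomicRegion], index: _RegionIndex | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (M, N) tally for a calls DataFrame (read_id/chrom/pos/meth)."""
    if index is None:
        index = _RegionIndex.build(regions)
    n = np.zeros(len(regions), dtype=np.int64)
    m = np.zeros(len(regions), dtype=np.int64)
    for chrom, sub in frame.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy()
        keys = [index.lookup.get((chrom, int(p)), -1) for p in pos]
        keys = np.asarray(keys)
        ok = keys >= 0
        np.add.at(n, keys[ok], 1)
        np.add.at(m, keys[ok], meth[ok].astype(np.int64))
    return m, n


def betas_from_counts(m: np.ndarray, n: np.ndarray) -> np.ndarray:
    """M/N with NaN where N = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 0, m / np.maximum(n, 1), np.nan)


def build_region_matrix(
    samples: Sequence, regions: Sequence[GenomicRegion]
) -> RegionValueMatrix:
    """Aggregate every sample's methylation calls into a RegionValueMatrix.

    ``samples`` is a sequence of records with ``sample_id`` and ``path``
    attributes (see :func:`methyltoo.io.read_sample_table`).  Each call
    file is streamed once; a per-sample coverage summary is logged.
    """
    from methyltoo.io import read_methyl_calls  # avoid import cycle

    index = _RegionIndex.build(regions)
    values = np.full((len(samples), len(regions)), np.nan)
    depth = np.zeros((len(samples), len(regions)), dtype=np.int64)
    for i, sample in enumerate(samples):
        try:
            calls = read_methyl_calls(sample.path)
            m, n = tally_calls(calls, regions, index)
        except OSError as exc:
            raise OSError(f"sample {sample.sample_id}: cannot read calls: {exc}") from exc
        values[i] = betas_from_counts(m, n)
        depth[i] = n
        covered = int((n > 0).sum())
        logger.info(
            "sample %s: %d/%d regions covered, median depth %.0f",
            sample.sample_id, covered, len(regions),
            float(np.median(n[n > 0])) if covered else 0.0,
        )
    return RegionValueMatrix(
        sample_ids=[s.sample_id for s in samples],
        region_ids=[r.region_id for r in regions],
        values=values,
        depth_n=depth,
    )
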