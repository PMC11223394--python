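"""Per-sample feature blocks for the tissue-of-origin classifier.

Two feature families are computed here: genome-wide methylation density
(GWMD, the mean methylation over non-overlapping 1 Mb genomic bins) and
atlas-region values derived from microarray per-CpG beta tables.
``assemble_features`` concatenates named blocks (deconvolution weights,
GWMD, arbitrary precomputed extras) into flat vectors, z-scored with
statistics fitted on training samples only — the kNN graph downstream
is scale-sensitive, and test-set leakage into scaling would break the
transductive hygiene contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from methyltoo.regions import GenomicRegion

DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class GwmdVector:
    """Per-bin methylation density over a non-overlapping genome tiling."""

    bin_ids: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.bin_ids),):
            raise ValueError("GWMD values length != number of bins")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValueError("GWMD densities must lie in [0, 1]")


@dataclass
class FeatureMatrix:
    """Stacked per-sample feature vectors with recorded block boundaries."""

    sample_ids: list[str]
    block_slices: dict[str, slice]
    values: np.ndarray


def gwmd_bins(genome_lengths: Mapping[str, int], bin_size: int = DEFAULT_BIN_SIZE) -> list[tuple[str, int]]:
    """Non-overlapping bin tiling; the final partial bin is kept."""
    bins: list[tuple[str, int]] = []
    for chrom in sorted(genome_lengths.keys()):
        length = genome_lengths[chrom]
        n_bins = (length + bin_size - 1) // bin_size
        bins.extend((chrom, k) for k in range(n_bins))
    return bins


def compute_gwmd(
    calls: Iterable,
    genome_lengths: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> GwmdVector:
    """Genome-wide methylation density per bin.

    Density = methylated events / total events over all CpG calls in the
    bin; bins with zero events are missing (NaN).
    """
    bins = gwmd_bins(genome_lengths, bin_size)
    index = {b: i for i, b in enumerate(bins)}
    n = np.zeros(len(bins), dtype=np.int64)
    m = np.zeros(len(bins), dtype=np.int64)
    for rec in calls:
        key = (rec.chrom, rec.cpg_position // bin_size)
        i = index.get(key)
        if i is not None:
            n[i] += 1
            m[i] += int(rec.methylated)
    with np.errstate(invalid="ignore"):
        values = np.where(n > 0, m / np.maximum(n, 1), np.nan)
    return GwmdVector(bin_ids=bins, values=values)


def microarray_to_region_values(
    beta_table, regions: Sequence[GenomicRegion]
) -> np.ndarray:
    """Project per-CpG microarray betas onto atlas regions.

    ``beta_table`` is a DataFrame with columns chrom, pos, beta; probe
    coordinates are forward-strand CpG C positions.  Probes falling in a
    region's CpG set are averaged; probes outside every region are
    discarded, and regions with zero probes are missing (NaN).
    """
    betas = beta_table["beta"].to_numpy(dtype=float)
    bad = np.flatnonzero((betas < 0.0) | (betas > 1.0) | ~np.isfinite(betas))
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"beta {betas[i]} outside [0, 1] at row {i} "
            f"({beta_table['chrom'].iloc[i]}:{beta_table['pos'].iloc[i]})"
        )
    lookup: dict[tuple[str, int], int] = {}
    for k, region in enumerate(regions):
        for p in region.cpg_positions:
            lookup[(region.chrom, p)] = k
    total = np.zeros(len(regions))
    count = np.zeros(len(regions), dtype=np.int64)
    for chrom, pos, beta in zip(beta_table["chrom"], beta_table["pos"], betas):
        k = lookup.get((str(chrom), int(pos)))
        if k is not None:
            total[k] += beta
            count[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / np.maximum(count, 1), np.nan)


def assemble_features(
    blocks: Mapping[str, np.ndarray],
    sample_ids: Sequence[str],
    train_indices: Sequence[int],
) -> tuple[FeatureMatrix, tuple[np.ndarray, np.ndarray]]:
    """Concatenate named blocks into z-scored per-sample feature vectors.

    Every block is a (n_samples, block_dim) array in ``blocks`` order.
    NaNs (e.g. uncovered GWMD bins) are imputed with the training-set
    per-column mean, then columns are standardized with train-fitted
    mean and standard deviation; constant training columns scale to 0
    (unit-variance guard).  Returns the feature matrix and the fitted
    (mean, std) so the transform is auditable.  Note the transform is
    deliberately not idempotent: re-applying train statistics to
    already-scaled data shifts it again.
    """
    n = len(sample_ids)
    slices: dict[str, slice] = {}
    parts = []
    offset = 0
    for name, block in blocks.items():
        block = np.asarray(block, dtype=float)
        if block.ndim == 1:
            block = block[:, None]
        if block.shape[0] != n:
            raise ValueError(
                f"block {name!r} has {block.shape[0]} rows, expected {n} samples"
            )
        slices[name] = slice(offset, offset + block.shape[1])
        offset += block.shape[1]
        parts.append(block)
    x = np.concatenate(parts, axis=1)
    train = np.asarray(train_indices, dtype=int)
    if train.size == 0:
        raise ValueError("no training samples to fit scaling statistics")
    col_mean = np.nanmean(x[train], axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    x = np.where(np.isfinite(x), x, col_mean[None, :])
    mean = x[train].mean(axis=0)
    std = x[train].std(axis=0)
    safe_std = np.where(std > 0.0, std, 1.0)
    scaled = (x - mean) / safe_std
    scaled[:, std == 0.0] = 0.0
    return FeatureMatrix(list(sample_ids), slices, scaled), (mean, std)
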