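"""Synthetic cohorts, cfDNA backgrounds and ctDNA spike-in mixtures.

The generator emulates the structure of the study designs this package
targets: a multi-class tumor/WBC cohort in which each class carries its
own set of hypomethylated marker regions; WBC-dominant (~90%) cfDNA
backgrounds; and spike-in mixtures in which a known fraction of tumor
events is mixed into a background at ratios spanning 0.01%-25%.
Mixture composition is exact by construction (event counts, not
probabilities).  Everything is driven by a single integer seed through
a fixed seed-derivation scheme, so outputs are reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from methyltoo.constants import ALL_CLASSES, TUMOR_CLASSES
from methyltoo.regions import GenomicRegion, RegionValueMatrix

#: In-silico spike-in ratios: 0.01%, 0.05%, 0.1%, 1%, 10%, 25%.
INSILICO_RATIOS = (0.0001, 0.0005, 0.001, 0.01, 0.10, 0.25)
#: Wet-lab spike-in ratios: 0.1%, 1%, 10%, 25%.
WETLAB_RATIOS = (0.001, 0.01, 0.10, 0.25)


def derive_seed(base_seed: int, *parts) -> int:
    """Stable sub-seed from a base seed and arbitrary hashable parts."""
    token = repr((base_seed,) + parts).encode()
    return (zlib.crc32(token) ^ base_seed) % (2**31)


@dataclass(frozen=True)
class SpikeInDesign:
    """One planned spike-in mixture."""

    background_id: str
    cancer_type: str
    ratio: float
    repeat_index: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError(f"ratio {self.ratio} outside (0, 1)")


@dataclass
class CohortSpec:
    """Parameters of a synthetic tumor/WBC cohort.

    Each class's planted marker regions are hypomethylated by ``delta``
    relative to ``beta_background``; per-(sample, region) methylation
    probabilities get truncated Gaussian noise of sd ``noise_sd``, and
    per-region event counts are Poisson with mean ``read_depth``.
    """

    class_counts: dict[str, int] = field(
        default_factory=lambda: {c: 10 for c in ALL_CLASSES}
    )
    n_regions: int = 2000
    n_planted_per_class: int = 50
    beta_background: float = 0.8
    delta: float = 0.4
    noise_sd: float = 0.05
    read_depth: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_counts:
            raise ValueError("class_counts is empty")
        if any(n <= 0 for n in self.class_counts.values()):
            raise ValueError("every class needs a positive sample count")
        if self.beta_background - self.delta < 0.0:
            raise ValueError("beta_background - delta must be >= 0")
        if not 0.0 <= self.beta_background <= 1.0:
            raise ValueError("beta_background outside [0, 1]")
        if self.noise_sd < 0.0 or self.read_depth <= 0.0:
            raise ValueError("noise_sd must be >= 0 and read_depth > 0")
        if self.n_planted_per_class * len(self.class_counts) > self.n_regions:
            raise ValueError("not enough regions for disjoint planted marker sets")

    @property
    def classes(self) -> list[str]:
        return list(self.class_counts.keys())

    def planted_markers(self) -> dict[str, np.ndarray]:
        """Disjoint per-class marker region indices (deterministic in seed)."""
        rng = np.random.default_rng(derive_seed(self.seed, "planted"))
        perm = rng.permutation(self.n_regions)
        out = {}
        for i, cls in enumerate(self.classes):
            lo = i * self.n_planted_per_class
            out[cls] = np.sort(perm[lo : lo + self.n_planted_per_class])
        return out

    def class_betas(self) -> pd.DataFrame:
        """True per-class, per-region methylation levels (no noise)."""
        betas = np.full((len(self.classes), self.n_regions), self.beta_background)
        for i, cls in enumerate(self.classes):
            betas[i, self.planted_markers()[cls]] -= self.delta
        return pd.DataFrame(
            betas, index=self.classes, columns=[f"r{j:06d}" for j in range(self.n_regions)]
        )


def synthetic_regions(n_regions: int, chrom: str = "sim") -> list[GenomicRegion]:
    """Non-overlapping 100 bp regions tiled every 200 bp, 5 CpGs each."""
    regions = []
    for j in range(n_regions):
        start = j * 200
        cpgs = tuple(start + off for off in (10, 30, 50, 70, 90))
        regions.append(GenomicRegion(chrom, start, start + 100, cpgs, f"r{j:06d}"))
    return regions


def _noisy_probs(base: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    return np.clip(base + rng.normal(0.0, noise_sd, size=base.shape), 0.0, 1.0)


def sample_calls(
    betas: np.ndarray,
    regions: Sequence[GenomicRegion],
    rng: np.random.Generator,
    read_prefix: str,
    n_events: int | None = None,
    read_depth: float | None = None,
    cpgs_per_read: int = 1,
) -> pd.DataFrame:
    """Draw event-level methylation calls from per-region probabilities.

    Either ``n_events`` total events are spread uniformly over regions,
    or per-region counts are Poisson(``read_depth``).  By default each
    event is its own single-CpG read; ``cpgs_per_read > 1`` groups that
    many same-region CpG observations under one read id for region-value
    realism.
    """
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (len(regions),):
        raise ValueError("betas length != number of regions")
    if (n_events is None) == (read_depth is None):
        raise ValueError("give exactly one of n_events or read_depth")
    if n_events is not None:
        region_idx = rng.integers(0, len(regions), size=n_events)
    else:
        counts = rng.poisson(read_depth, size=len(regions))
        region_idx = np.repeat(np.arange(len(regions)), counts)
    if cpgs_per_read > 1:
        region_idx = np.repeat(region_idx, cpgs_per_read)
    total = region_idx.size
    n_cpgs = np.array([len(r.cpg_positions) for r in regions])
    choice = rng.integers(0, n_cpgs[region_idx])
    pos = np.fromiter(
        (regions[i].cpg_positions[c] for i, c in zip(region_idx, choice)),
        dtype=np.int64,
        count=total,
    )
    meth = (rng.random(total) < betas[region_idx]).astype(np.int8)
    read_no = (
        np.arange(total) // cpgs_per_read if cpgs_per_read > 1 else np.arange(total)
    )
    chroms = np.array([r.chrom for r in regions], dtype=object)[region_idx]
    return pd.DataFrame(
        {
            "read_id": [f"{read_prefix}_{k}" for k in read_no],
            "chrom": chroms,
            "pos": pos,
            "meth": meth,
        }
    )


@dataclass
class CohortResult:
    """Event-level synthetic cohort plus its ground truth."""

    regions: list[GenomicRegion]
    calls: dict[str, pd.DataFrame]
    labels: dict[str, str]
    class_betas: pd.DataFrame
    sample_betas: pd.DataFrame
    planted: dict[str, np.ndarray]


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Generate event-level methylation calls for a full cohort.

    Deterministic in ``spec.seed`` (same spec -> byte-identical output).
    Truth tables record the planted markers, the noiseless class betas,
    and each sample's realized per-region methylation probabilities.
    """
    regions = synthetic_regions(spec.n_regions)
    class_betas = spec.class_betas()
    calls: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    sample_rows = {}
    for cls in spec.classes:
        base = class_betas.loc[cls].to_numpy()
        for k in range(spec.class_counts[cls]):
            sid = f"{cls}_{k:02d}"
            rng = np.random.default_rng(derive_seed(spec.seed, "sample", cls, k))
            probs = _noisy_probs(base, spec.noise_sd, rng)
            calls[sid] = sample_calls(
                probs, regions, rng, read_prefix=sid, read_depth=spec.read_depth
            )
            labels[sid] = cls
            sample_rows[sid] = probs
    sample_betas = pd.DataFrame.from_dict(
        sample_rows, orient="index", columns=class_betas.columns
    )
    return CohortResult(regions, calls, labels, class_betas, sample_betas, spec.planted_markers())


def simulate_cohort_matrix(spec: CohortSpec) -> tuple[RegionValueMatrix, dict[str, str], CohortSpec]:
    """Region-value matrix of a cohort, drawn directly at the count level.

    Distributionally identical to aggregating :func:`simulate_cohort`
    output (per region: N ~ Poisson(depth), M ~ Binomial(N, p)), but
    vectorized so large cohorts are cheap.  Missing cells arise where
    Poisson draws give zero coverage.
    """
    class_betas = spec.class_betas().to_numpy()
    sample_ids, labels = [], {}
    rows_v, rows_n = [], []
    for i, cls in enumerate(spec.classes):
        for k in range(spec.class_counts[cls]):
            sid = f"{cls}_{k:02d}"
            rng = np.random.default_rng(derive_seed(spec.seed, "sample", cls, k))
            probs = _noisy_probs(class_betas[i], spec.noise_sd, rng)
            n = rng.poisson(spec.read_depth, size=spec.n_regions)
            m = rng.binomial(n, probs)
            with np.errstate(invalid="ignore"):
                beta = np.where(n > 0, m / np.maximum(n, 1), np.nan)
            sample_ids.append(sid)
            labels[sid] = cls
            rows_v.append(beta)
            rows_n.append(n)
    matrix = RegionValueMatrix(
        sample_ids=sample_ids,
        region_ids=[f"r{j:06d}" for j in range(spec.n_regions)],
        values=np.vstack(rows_v),
        depth_n=np.vstack(rows_n),
    )
    return matrix, labels, spec


def simulate_cfdna_background(
    class_betas: pd.DataFrame,
    regions: Sequence[GenomicRegion],
    n_events: int,
    rng: np.random.Generator,
    wbc_fraction: float = 0.9,
    read_prefix: str = "bg",
) -> pd.DataFrame:
    """WBC-dominant cfDNA background: ~90% WBC events, rest mixed tissue."""
    if "WBC" not in class_betas.index:
        raise ValueError("class_betas must include a WBC row")
    n_wbc = int(round(wbc_fraction * n_events))
    tumors = [c for c in class_betas.index if c != "WBC"]
    parts = [
        sample_calls(
            class_betas.loc["WBC"].to_numpy(), regions, rng,
            read_prefix=f"{read_prefix}_wbc", n_events=n_wbc,
        )
    ]
    remaining = n_events - n_wbc
    for i, cls in enumerate(tumors):
        share = remaining // len(tumors) + (1 if i < remaining % len(tumors) else 0)
        if share > 0:
            parts.append(
                sample_calls(
                    class_betas.loc[cls].to_numpy(), regions, rng,
                    read_prefix=f"{read_prefix}_{cls}", n_events=share,
                )
            )
    frame = pd.concat(parts, ignore_index=True)
    return frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)


def simulate_spike_in(
    background_calls: pd.DataFrame,
    tumor_calls: pd.DataFrame,
    ratio: float,
    total_events: int,
    seed: int,
) -> pd.DataFrame:
    """Mix tumor events into a background at an exact ratio.

    round(ratio * total_events) tumor events and the remainder of
    background events are drawn uniformly without replacement from the
    two pools and shuffled together.  Pools too small to supply their
    share raise.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"ratio {ratio} outside [0, 1]")
    rng = np.random.default_rng(seed)
    n_tumor = int(round(ratio * total_events))
    n_background = total_events - n_tumor
    if n_tumor > len(tumor_calls):
        raise ValueError(
            f"tumor pool exhausted: need {n_tumor}, have {len(tumor_calls)}"
        )
    if n_background > len(background_calls):
        raise ValueError(
            f"background pool exhausted: need {n_background}, have {len(background_calls)}"
        )
    t_idx = rng.choice(len(tumor_calls), size=n_tumor, replace=False)
    b_idx = rng.choice(len(background_calls), size=n_background, replace=False)
    mixed = pd.concat(
        [tumor_calls.iloc[t_idx], background_calls.iloc[b_idx]], ignore_index=True
    )
    return mixed.iloc[rng.permutation(len(mixed))].reset_index(drop=True)


def enumerate_insilico_design(
    n_backgrounds: int = 3,
    cancer_types: Sequence[str] = TUMOR_CLASSES,
    ratios: Sequence[float] = INSILICO_RATIOS,
    repeats: int = 3,
    base_seed: int = 0,
) -> list[SpikeInDesign]:
    """Full factorial in-silico spike-in plan.

    Defaults reproduce the 3 backgrounds x 5 cancer types x 6 ratios
    design, repeated 3 times: 270 mixtures (90 per repeat).
    """
    if n_backgrounds <= 0 or repeats <= 0:
        raise ValueError("n_backgrounds and repeats must be positive")
    designs = []
    for rep in range(repeats):
        for bg in range(n_backgrounds):
            for cls in cancer_types:
                for ratio in ratios:
                    designs.append(
                        SpikeInDesign(
                            background_id=f"bg{bg}",
                            cancer_type=cls,
                            ratio=ratio,
                            repeat_index=rep,
                            seed=derive_seed(base_seed, f"bg{bg}", cls, ratio, rep),
                        )
                    )
    return designs


def enumerate_wetlab_design(
    donors_per_type: int = 2,
    cancer_types: Sequence[str] = TUMOR_CLASSES,
    ratios: Sequence[float] = WETLAB_RATIOS,
    base_seed: int = 0,
) -> list[SpikeInDesign]:
    """Wet-lab-style spike-in plan: pooled healthy background, per-type
    tumor donors.  Defaults give 2 donors x 5 types x 4 ratios = 40."""
    if donors_per_type <= 0:
        raise ValueError("donors_per_type must be positive")
    designs = []
    for cls in cancer_types:
        for donor in range(donors_per_type):
            for ratio in ratios:
                designs.append(
                    SpikeInDesign(
                        background_id="pooled_healthy",
                        cancer_type=cls,
                        ratio=ratio,
                        repeat_index=donor,
                        seed=derive_seed(base_seed, "wetlab", cls, donor, ratio),
                    )
                )
    return designs
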