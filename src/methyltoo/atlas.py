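"""Tumor-specific methylation atlas (TSMA) construction.

For each class a one-vs-rest Welch t-test is run at every region,
p-values are Bonferroni-corrected per class, and the top regions with
significantly *negative* log2 fold change (hypomethylated in the class,
reflecting that cell-type-specific differentially methylated regions
are predominantly unmethylated) are retained, ranked by |log2FC|.  The
atlas is the classes x regions matrix of per-class mean region values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from methyltoo.regions import RegionValueMatrix

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 500
DEFAULT_ALPHA = 0.05
LOG2FC_PSEUDOCOUNT = 1e-3
MIN_GROUP_SIZE = 3


@dataclass(frozen=True)
class DifferentialRegionResult:
    """One region's one-vs-rest test outcome for one class."""

    region_id: str
    class_label: str
    t_statistic: float
    p_value: float
    p_adjusted: float
    log2fc: float


@dataclass
class AtlasMatrix:
    """Classes x regions reference matrix of mean methylation values."""

    class_labels: list[str]
    region_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.class_labels), len(self.region_ids)):
            raise ValueError("atlas shape inconsistent with labels/regions")
        if not np.isfinite(self.values).all():
            raise ValueError("atlas must have no missing entries")
        if self.values.min() < 0.0 or self.values.max() > 1.0:
            raise ValueError("atlas values must lie in [0, 1]")

    def row(self, class_label: str) -> np.ndarray:
        return self.values[self.class_labels.index(class_label)]


def _group_indices(
    matrix: RegionValueMatrix, labels: Mapping[str, str], class_label: str
) -> tuple[np.ndarray, np.ndarray]:
    lab = np.array([labels.get(s) for s in matrix.sample_ids], dtype=object)
    in_class = lab == class_label
    if not in_class.any():
        raise ValueError(f"class {class_label!r} absent from labels")
    return np.flatnonzero(in_class), np.flatnonzero(~in_class)


def test_one_vs_rest(
    matrix: RegionValueMatrix,
    labels: Mapping[str, str],
    class_label: str,
    min_group_size: int = MIN_GROUP_SIZE,
    epsilon: float = LOG2FC_PSEUDOCOUNT,
) -> list[DifferentialRegionResult]:
    """Welch two-sided t-test of ``class_label`` vs all other samples, per region.

    A region is testable only when both groups have at least
    ``min_group_size`` non-missing values; untestable regions are
    skipped.  Bonferroni adjustment is applied across the regions
    actually tested for this class.  log2fc uses a pseudocount to stay
    finite at fully unmethylated means.
    """
    idx_class, idx_rest = _group_indices(matrix, labels, class_label)
    vals = matrix.values
    results: list[DifferentialRegionResult] = []
    raw: list[tuple[str, float, float, float]] = []
    for j, region_id in enumerate(matrix.region_ids):
        a = vals[idx_class, j]
        b = vals[idx_rest, j]
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if a.size < min_group_size or b.size < min_group_size:
            continue
        if np.ptp(a) == 0.0 and np.ptp(b) == 0.0:
            # both groups constant: the t statistic is 0/0 or ±inf/0
            if abs(a.mean() - b.mean()) < 1e-12:
                t, p = 0.0, 1.0
            else:
                t = math.copysign(math.inf, a.mean() - b.mean())
                p = 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            if not math.isfinite(p):
                t, p = 0.0, 1.0
        log2fc = math.log2((a.mean() + epsilon) / (b.mean() + epsilon))
        raw.append((region_id, float(t), float(p), log2fc))
    n_tested = len(raw)
    for region_id, t, p, log2fc in raw:
        results.append(
            DifferentialRegionResult(
                region_id=region_id,
                class_label=class_label,
                t_statistic=t,
                p_value=p,
                p_adjusted=min(1.0, p * n_tested),
                log2fc=log2fc,
            )
        )
    return results


# not a test, despite the field-standard name
test_one_vs_rest.__test__ = False  # type: ignore[attr-defined]


def select_top_regions(
    results: Sequence[DifferentialRegionResult],
    top_k: int = DEFAULT_TOP_K,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Keep significant negative-log2FC regions, ranked by |log2FC|.

    Filters to ``p_adjusted < alpha`` and ``log2fc < 0``, sorts by
    |log2fc| descending with a deterministic region-id tie-break, and
    cuts at ``top_k``.  Fewer survivors than ``top_k`` returns them all
    with a logged warning.
    """
    survivors = [r for r in results if r.p_adjusted < alpha and r.log2fc < 0.0]
    survivors.sort(key=lambda r: (-abs(r.log2fc), r.region_id))
    if len(survivors) < top_k:
        logger.warning(
            "class %s: only %d significant hypomethylated regions (< top_k=%d)",
            results[0].class_label if results else "?", len(survivors), top_k,
        )
    return [r.region_id for r in survivors[:top_k]]


def build_atlas(
    matrix: RegionValueMatrix,
    labels: Mapping[str, str],
    selections: Mapping[str, Sequence[str]],
) -> AtlasMatrix:
    """Aggregate per-class mean region values over the selected regions.

    The atlas region set is the deduplicated union of the per-class
    selections: classes are visited in ``selections`` order and a region
    appearing in several classes' lists is claimed by the first.  Each
    cell is the mean of non-missing values over that class's samples;
    missing values are removed before aggregating, and a class with zero
    non-missing samples at a selected region is a build error.
    """
    class_labels = list(selections.keys())
    region_ids: list[str] = []
    seen: set[str] = set()
    for cls in class_labels:
        for rid in selections[cls]:
            if rid not in seen:
                seen.add(rid)
                region_ids.append(rid)
    if not region_ids:
        raise ValueError("union of selections is empty")
    col = {rid: j for j, rid in enumerate(matrix.region_ids)}
    missing_regions = [rid for rid in region_ids if rid not in col]
    if missing_regions:
        raise ValueError(f"selected regions absent from matrix: {missing_regions[:5]}")
    values = np.empty((len(class_labels), len(region_ids)))
    for i, cls in enumerate(class_labels):
        idx_class, _ = _group_indices(matrix, labels, cls)
        sub = matrix.values[np.ix_(idx_class, [col[r] for r in region_ids])]
        counts = np.isfinite(sub).sum(axis=0)
        if (counts == 0).any():
            j = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(
                f"class {cls!r} has no non-missing values at region {region_ids[j]!r}"
            )
        values[i] = np.nanmean(sub, axis=0)
    return AtlasMatrix(class_labels=class_labels, region_ids=region_ids, values=values)


def write_atlas_tsv(atlas: AtlasMatrix, path) -> None:
    """Atlas as TSV: class rows, region columns."""
    import pandas as pd

    pd.DataFrame(atlas.values, index=atlas.class_labels, columns=atlas.region_ids).to_csv(
        path, sep="\t", index_label="class_label", float_format="%.10g"
    )


def read_atlas_tsv(path) -> AtlasMatrix:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return AtlasMatrix(
        class_labels=[str(i) for i in frame.index],
        region_ids=[str(c) for c in frame.columns],
        values=frame.to_numpy(dtype=float),
    )
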