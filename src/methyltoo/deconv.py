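"""Non-negative least-squares deconvolution against the atlas.

A sample's region-value vector alpha is regressed on the atlas rows:
minimize ||alpha - W^T X||_2 subject to W >= 0, restricted to the
regions where the sample is observed; W is then normalized to unit sum
and read as class fractions.  Tissue of origin is the class with the
largest weight, conventionally after removing the WBC component, which
dominates cfDNA (~90%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from methyltoo.atlas import AtlasMatrix
from methyltoo.constants import ALL_CLASSES

#: Sentinel returned instead of a class label when no call can be made.
ABSTAIN = "abstain"


@dataclass(frozen=True)
class DeconvolutionResult:
    """Unit-sum non-negative class weights plus the NNLS residual.

    ``degenerate`` is set when the constrained solution is identically
    zero, in which case weights stay zero and downstream assignment
    abstains rather than inventing a tissue of origin.
    """

    class_labels: tuple[str, ...]
    weights: np.ndarray
    residual: float
    n_regions_used: int
    degenerate: bool = False

    def weight(self, class_label: str) -> float:
        return float(self.weights[self.class_labels.index(class_label)])


@dataclass(frozen=True)
class TooAssignment:
    """Tissue-of-origin call: a class label or the abstain sentinel."""

    label: str
    tied: bool = False

    @property
    def abstained(self) -> bool:
        return self.label == ABSTAIN


def nnls_deconvolve(atlas: AtlasMatrix, sample: np.ndarray) -> DeconvolutionResult:
    """Solve the constrained least-squares problem for one sample.

    ``sample`` is a region-value vector aligned with ``atlas.region_ids``
    and may contain NaN for missing regions; the fit is restricted to
    the observed columns (imputation is never applied).  Uses the
    Lawson-Hanson active-set solver, a true constrained routine.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (len(atlas.region_ids),):
        raise ValueError(
            f"sample length {sample.shape} != atlas regions {len(atlas.region_ids)}"
        )
    observed = np.isfinite(sample)
    n_used = int(observed.sum())
    if n_used == 0:
        raise ValueError("no non-missing region shared between sample and atlas")
    design = atlas.values[:, observed].T  # (n_obs, n_classes)
    target = sample[observed]
    raw, residual = nnls(design, target)
    total = raw.sum()
    if total <= 0.0:
        return DeconvolutionResult(
            class_labels=tuple(atlas.class_labels),
            weights=np.zeros_like(raw),
            residual=float(residual),
            n_regions_used=n_used,
            degenerate=True,
        )
    return DeconvolutionResult(
        class_labels=tuple(atlas.class_labels),
        weights=raw / total,
        residual=float(residual),
        n_regions_used=n_used,
    )


def assign_too(result: DeconvolutionResult, drop_wbc: bool = True) -> TooAssignment:
    """Call tissue of origin as the argmax weight class.

    With ``drop_wbc`` the WBC component is removed first and the argmax
    taken over the remaining tumor classes.  Ties break alphabetically
    and are flagged; a degenerate result (or all-zero tumor weights
    after dropping WBC) abstains rather than returning a silent label.
    """
    if result.degenerate:
        return TooAssignment(ABSTAIN)
    candidates = [
        (label, result.weights[i])
        for i, label in enumerate(result.class_labels)
        if not (drop_wbc and label == "WBC")
    ]
    best = max(w for _, w in candidates)
    if best <= 0.0:
        return TooAssignment(ABSTAIN)
    winners = sorted(label for label, w in candidates if w == best)
    return TooAssignment(winners[0], tied=len(winners) > 1)


def deconvolve_matrix(atlas: AtlasMatrix, matrix, drop_wbc: bool = True):
    """Deconvolve every row of a RegionValueMatrix; returns a DataFrame.

    Columns: one weight per atlas class, plus residual, n_regions_used,
    and the assigned label (``abstain`` where no call is possible).
    Matrix regions are aligned to the atlas by region id; atlas regions
    absent from the matrix count as missing for every sample.
    """
    import pandas as pd

    col = {rid: j for j, rid in enumerate(matrix.region_ids)}
    aligned = np.full((len(matrix.sample_ids), len(atlas.region_ids)), np.nan)
    for j, rid in enumerate(atlas.region_ids):
        if rid in col:
            aligned[:, j] = matrix.values[:, col[rid]]
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        res = nnls_deconvolve(atlas, aligned[i])
        call = assign_too(res, drop_wbc=drop_wbc)
        rows.append(
            list(res.weights) + [res.residual, res.n_regions_used, call.label]
        )
    return pd.DataFrame(
        rows,
        index=pd.Index(matrix.sample_ids, name="sample_id"),
        columns=list(atlas.class_labels) + ["residual", "n_regions_used", "label"],
    )
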