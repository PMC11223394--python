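"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they verify: brute-force window
scanning for region discovery, textbook Welch/Bonferroni formulas for
the differential test, and a simplex grid search for NNLS.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy import stats


def brute_force_windows(sequence: str, length: int = 100, min_cpgs: int = 5) -> set[int]:
    """Start positions of every window with >= min_cpgs CpGs (exhaustive)."""
    seq = sequence.upper()
    valid = set()
    for start in range(0, len(seq) - length + 1):
        count = sum(
            1 for q in range(start, start + length) if seq[q : q + 2] == "CG"
        )
        if count >= min_cpgs:
            valid.add(start)
    return valid


def window_cpg_count(sequence: str, start: int, length: int = 100) -> int:
    seq = sequence.upper()
    return sum(1 for q in range(start, start + length) if seq[q : q + 2] == "CG")


def welch_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test from the textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    dof = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), dof)
    return t, p


def _compositions(total: int, parts: int):
    """All tuples of `parts` non-negative ints summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for head in range(total + 1):
        for tail in _compositions(total - head, parts - 1):
            yield (head,) + tail


def simplex_grid_residual(design: np.ndarray, target: np.ndarray, coarse_steps: int = 10) -> float:
    """Best 2-norm residual over the unit simplex: coarse grid (step
    1/coarse_steps) followed by local pairwise-transfer refinement at
    steps 0.05, 0.01 and 0.002."""
    n = design.shape[1]

    def residual(w):
        return float(np.linalg.norm(target - design @ w))

    best_w, best_r = None, np.inf
    for comp in _compositions(coarse_steps, n):
        w = np.array(comp, float) / coarse_steps
        r = residual(w)
        if r < best_r:
            best_w, best_r = w, r
    for step in (0.05, 0.01, 0.002):
        improved = True
        while improved:
            improved = False
            for i, j in product(range(n), range(n)):
                if i == j or best_w[i] < step - 1e-12:
                    continue
                w = best_w.copy()
                w[i] -= step
                w[j] += step
                r = residual(w)
                if r < best_r - 1e-15:
                    best_w, best_r = w, r
                    improved = True
    return best_r


def make_cluster_sequence(
    n_clusters: int, rng: np.random.Generator, spacer_min: int = 200
) -> tuple[str, list[int]]:
    """Sequence with CpG clusters (5 CGs in < 100 bp) separated by CpG-free
    spacers; returns the sequence and each cluster's start offset."""
    parts, starts = [], []
    pos = 0
    for _ in range(n_clusters):
        spacer_len = spacer_min + int(rng.integers(0, 100))
        spacer = "".join(rng.choice(list("AT"), size=spacer_len))
        parts.append(spacer)
        pos += spacer_len
        starts.append(pos)
        cluster = "CGA" * 5  # five CGs in 15 bp
        parts.append(cluster)
        pos += len(cluster)
    tail = "".join(rng.choice(list("AT"), size=spacer_min))
    parts.append(tail)
    return "".join(parts), starts
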