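"""End-to-end compositions of the library modules.

These are the workflows a user would script by hand: build an atlas
from a synthetic cohort, generate WBC-dominant backgrounds, mix in
tumor events at known ratios, deconvolve the mixtures and call tissue
of origin.  They exist so that tests and reproduction scripts exercise
one shared, seeded path through the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from methyltoo import atlas as atlas_mod
from methyltoo import deconv as deconv_mod
from methyltoo import simulate as simulate_mod
from methyltoo.atlas import AtlasMatrix
from methyltoo.constants import ALL_CLASSES, TUMOR_CLASSES
from methyltoo.regions import betas_from_counts, tally_call_frame, _RegionIndex


def atlas_from_cohort(
    spec: simulate_mod.CohortSpec, top_k: int
) -> tuple[AtlasMatrix, dict[str, list[str]]]:
    """Simulate a cohort matrix, select per-class regions, build the atlas."""
    matrix, labels, _ = simulate_mod.simulate_cohort_matrix(spec)
    selections = {}
    for cls in spec.classes:
        results = atlas_mod.test_one_vs_rest(matrix, labels, cls)
        selections[cls] = atlas_mod.select_top_regions(results, top_k=top_k)
    return atlas_mod.build_atlas(matrix, labels, selections), selections


@dataclass
class SpikeInOutcome:
    """Deconvolution outcome of one synthetic spike-in mixture."""

    cancer_type: str
    ratio: float
    repeat_index: int
    spiked_weight: float
    called_label: str
    wbc_weight: float


def run_spikein_experiment(
    base_seed: int,
    ratios=(0.001, 0.01, 0.10, 0.25),
    cancer_types=TUMOR_CLASSES,
    replicates: int = 4,
    n_regions: int = 300,
    n_planted_per_class: int = 30,
    samples_per_class: int = 8,
    top_k: int = 30,
    total_events: int = 30_000,
    wbc_fraction: float = 0.9,
    background_pool_events: int = 120_000,
    tumor_pool_events: int = 60_000,
) -> pd.DataFrame:
    """Cohort -> atlas -> spike-in mixtures -> deconvolution, seeded.

    Backgrounds emulate cfDNA (~90% WBC-profile events, the rest an even
    tumor-tissue mix); tumor pools are drawn from the spiked class's
    methylation profile; mixtures have exact event-count composition.
    Returns one row per mixture with the spiked class's deconvolution
    weight and the argmax tissue-of-origin call (WBC dropped).
    """
    spec = simulate_mod.CohortSpec(
        class_counts={c: samples_per_class for c in ALL_CLASSES},
        n_regions=n_regions,
        n_planted_per_class=n_planted_per_class,
        seed=simulate_mod.derive_seed(base_seed, "cohort"),
    )
    built, _ = atlas_from_cohort(spec, top_k=top_k)
    regions = simulate_mod.synthetic_regions(spec.n_regions)
    class_betas = spec.class_betas()
    index = _RegionIndex.build(regions)
    region_pos = {rid: j for j, rid in enumerate(f"r{j:06d}" for j in range(spec.n_regions))}
    atlas_cols = [region_pos[rid] for rid in built.region_ids]

    rows = []
    for rep in range(replicates):
        bg_rng = np.random.default_rng(simulate_mod.derive_seed(base_seed, "bg", rep))
        background = simulate_mod.simulate_cfdna_background(
            class_betas, regions, background_pool_events, bg_rng,
            wbc_fraction=wbc_fraction, read_prefix=f"bg{rep}",
        )
        for cls in cancer_types:
            t_rng = np.random.default_rng(simulate_mod.derive_seed(base_seed, "tumor", cls, rep))
            tumor_pool = simulate_mod.sample_calls(
                class_betas.loc[cls].to_numpy(), regions, t_rng,
                read_prefix=f"t_{cls}{rep}", n_events=tumor_pool_events,
            )
            for ratio in ratios:
                mixed = simulate_mod.simulate_spike_in(
                    background, tumor_pool, ratio, total_events,
                    seed=simulate_mod.derive_seed(base_seed, "mix", cls, ratio, rep),
                )
                m, n = tally_call_frame(mixed, regions, index)
                sample = betas_from_counts(m, n)[atlas_cols]
                result = deconv_mod.nnls_deconvolve(built, sample)
                call = deconv_mod.assign_too(result, drop_wbc=True)
                rows.append(
                    SpikeInOutcome(
                        cancer_type=cls,
                        ratio=ratio,
                        repeat_index=rep,
                        spiked_weight=result.weight(cls),
                        called_label=call.label,
                        wbc_weight=result.weight("WBC"),
                    )
                )
    return pd.DataFrame([vars(r) for r in rows])
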