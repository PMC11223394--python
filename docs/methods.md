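# Methods

## Region model

A CpG region is a 100 bp interval with at least five CpG dinucleotides,
built on the observation that nearby CpGs tend to share methylation
state, so one short sequencing read can report several informative
sites at once. Discovery is a greedy left-to-right scan per chromosome:
at each CpG position `p` not covered by an already-emitted region the
window `[p, p+100)` is tested; if it holds ≥ 5 CpGs it is emitted and
the scan jumps past its end. The scan is deterministic, CpG-anchored
and yields non-overlapping regions; the test suite verifies every
emitted region against an exhaustive all-start-positions window scan.
CpGs are forward-strand `CG` dinucleotides indexed by the C coordinate
(0-based, half-open intervals throughout); callers are expected to
project reverse-strand calls onto this convention, the standard
bisulfite practice.

The region value is β = M/N over (read, in-region CpG) events. CpG
observations a read carries *outside* the region are discarded. A
region with zero coverage is missing; no imputation is applied at any
point of the pipeline, and deconvolution instead restricts itself to
observed regions.

## Atlas construction

Per class, a two-sided Welch t-test compares that class's samples
against all others at every region with at least `min_group_size = 3`
non-missing values per group. Welch rather than the pooled-variance
variant because group sizes are deliberately unequal (the WBC group is
typically twice the size of a tumor group). P-values are
Bonferroni-adjusted per class across the regions actually tested.
Selection keeps regions with adjusted p < 0.05 *and* negative log2 fold
change (hypomethylated in the class — cell-type-specific differential
methylation is predominantly loss of methylation), ranks by |log2FC|
with a region-id tie-break, and cuts at 500 per class. log2FC uses a
pseudocount ε = 1e-3 so fully unmethylated means stay finite. The atlas
region set is the deduplicated union of per-class selections (first
class in label order claims a duplicated region), and each atlas cell
is the mean of non-missing class samples; a class with no data at a
selected region is a hard build error rather than a silent gap.

Bonferroni is applied per class, not globally across the six tests;
with ~equal numbers of tested regions per class the two differ by a
constant factor of 6 on the adjusted p, which the 0.05 threshold
absorbs for the strongly separated markers this method targets.

## Deconvolution

The sample vector α is regressed on the atlas rows:
min‖αᵒ − WᵀXᵒ‖₂ subject to W ≥ 0, over the columns where the sample is
observed. The solver is the Lawson–Hanson active-set NNLS
(`scipy.optimize.nnls`) — an exact constrained routine, not a projected
unconstrained fit. W is then normalized to unit sum and read as class
fractions. An identically-zero solution is flagged degenerate and
downstream assignment abstains; the package never invents a tissue of
origin. TOO is the argmax weight, conventionally after removing WBC
(which dominates cfDNA at ~90%), with alphabetical, flagged
tie-breaking.

The independent optimality check is a grid search over the unit
6-simplex (coarse step 0.1, then local pairwise-transfer refinement
down to step 0.002). Because the simplex is a subset of the solver's
feasible cone, the solver's residual can never exceed the grid
optimum; the acceptance script measures the worst-case excess over 100
random problems.

## Synthetic data

The generator emulates the structure of the validation designs, not
their biology:

- **Cohort**: 6 classes (5 tumor + WBC) × 10 samples by default, 2,000
  regions, background methylation 0.8, 50 planted markers per class
  hypomethylated by Δβ = 0.4, per-(sample, region) truncated Gaussian
  noise σ = 0.05, per-region event counts Poisson(200). The planted
  effect size matches a strong tissue-specific differentially
  methylated region; the noise level is of the order of between-sample
  β variability at moderate depth.
- **Backgrounds**: 90% WBC-profile events plus an even mix of the five
  tumor profiles, emulating the observed WBC dominance of cfDNA.
- **Spike-ins**: exact event-count mixtures — round(ratio × total)
  tumor events sampled without replacement from a pooled tumor event
  set, merged with background events and shuffled. The factorial
  designs enumerate 3 backgrounds × 5 types × 6 ratios × 3 repeats =
  270 (in-silico) and 2 donors × 5 types × 4 ratios = 40
  (wet-lab-style).
- A "read" is by default a single-CpG event; a grouped
  `cpgs_per_read > 1` mode exists for region-value realism. Event-level
  mixing is exact by construction, which is the property the spike-in
  analyses rely on.

Not emulated: bisulfite conversion failure, sequencing error, fragment
length and end-motif structure, copy-number variation, and real
inter-individual methylation heterogeneity. Passing synthetic tests
therefore demonstrates the *mechanics* — marker selection, solver
optimality, ratio response, classifier behavior — not clinical
performance on patient cfDNA.

All randomness flows from one base seed through a CRC-based
derivation scheme (`derive_seed(base, *parts)`, kept below 2³¹), so
every cohort, pool and mixture is reproducible and independent
sub-streams never alias.

## End-to-end spike-in experiment

`workflows.run_spikein_experiment` chains cohort → atlas (top-30 of 300
regions, 30 planted markers per class, 8 samples per class) → 4
backgrounds × 5 tumor types × ratios {0.1%, 1%, 10%, 25%} → 30,000-event
mixtures → NNLS → TOO. These problem sizes keep the full experiment
around ten seconds while leaving ~170 events per region, comfortably
above the depth where β estimates stabilize. Expected behavior,
verified by the acceptance suite: the spiked class's weight is
monotone in ratio in replicate means, TOO accuracy is ≥ 90% at ratios
≥ 10%, and degrades toward chance at ≤ 1% — the same ratio dependence
that motivates adding a classifier on top of raw deconvolution.

## Graph-transformer classifier

Feature vectors (deconvolution weights ⊕ genome-wide methylation
density over 1 Mb bins ⊕ optional precomputed blocks) are z-scored with
training-set statistics only; missing density bins are imputed with
the training-set per-bin mean so dimensions stay fixed. Scaling
matters because the kNN graph is Euclidean-distance based.

The graph has an edge from each node to its k = 5 nearest neighbors,
union-symmetrized, with self-loops; distance ties break by node index
for determinism. Each of the L = 2 layers (hidden width 64, preceded by
a linear input embedding) computes dot-product attention
a_uv = softmax_v((W_Q z_u)ᵀ(W_K z_v)) with the softmax restricted to
the kNN neighborhood plus self-loop — the reading that actually uses
the adjacency; a dense all-nodes softmax is available behind
`dense_softmax=True`. The update is residual,
z_u' = Σ_v a_uv (W_V z_v) + z_u, with a rectifier between the two
layers and inside the single-hidden-layer MLP head.

Training is transductive: all node features participate in the graph,
but the loss and validation accuracy only ever read labels of
train-pool nodes (a property the tests enforce bit-exactly by
scrambling test labels). The loss is focal,
−w_y (1 − p_y)^γ log p_y with γ = 2 and inverse-class-frequency
weights (the standard choice when the focus is class imbalance),
optimized with Adam at lr 1e-3 for up to 300 epochs with early stopping
(patience 30) on validation accuracy. Stratified 10-fold splitting of
the labeled pool selects the fold parameters with the best validation
accuracy. Forward, backward and Adam are hand-written NumPy; gradients
are verified against central finite differences in the test suite, and
training is bit-reproducible from the config seed.

Numerical details: attention rows subtract their max before
exponentiation; softmax probabilities are floored at 1e-12 inside the
loss; constant features scale to zero rather than dividing by zero; a
non-finite loss aborts with the epoch index rather than continuing.

## Benchmarks and problem sizes

The classifier benchmark uses 5 Gaussian classes × 100 nodes in 8
dimensions with class means separated by 3× the within-class deviation
magnitude (σ√d for unit per-dimension noise) and a 20% test mask —
separable by construction, so ≥ 95% test accuracy indicates a correct
implementation rather than a strong model; the label-permuted control
should land near the 20% chance level. The acceptance script's other
problem sizes (100 NNLS problems of shape 6 × 20, 20 noisy mixtures,
one 60-sample × 2,000-region cohort, 80 spike-in mixtures) were chosen
to give stable statistics in about a minute on a single CPU.

## Known limitations

- The atlas quality degrades gracefully but silently when classes have
  few samples: Bonferroni at n = 3 per class is very conservative, and
  selection then returns fewer than top-k regions (with a warning).
- The deconvolution reads weights as fractions, but they are fractions
  of *atlas-explained* signal; tissues absent from the atlas fold into
  whichever rows fit best.
- The classifier predicts only within its transductive graph; scoring
  a new cohort means rebuilding the graph and retraining.
- Region discovery is greedy and CpG-anchored; it does not attempt an
  optimal (maximum-count) tiling, and a different anchoring convention
  would yield a slightly different but equally valid region set.
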