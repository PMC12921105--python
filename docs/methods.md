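# Methods

## The model

`mountpat` implements an explainable feature-engineering pipeline for
multichannel EEG epoch classification. An epoch is an `L × nc` matrix `X`
(rows = time samples, columns = channels). The pipeline has four phases.

### Phase 1 — deterministic rank-transition features

A window of `n` consecutive time samples (default `n = 5`, stride `s = 1`)
slides over the epoch, producing `B = ⌊(L − n)/s⌋ + 1` blocks of `n`
channel-vectors `v_1 … v_n`. A fixed, non-trainable linear operator
`T ∈ {−1, 0, 1}^{(n + C(n,2)) × n}` maps each block to `R = n + C(n,2)`
vectors: the `n` identities `p_k = v_k` followed by every pairwise
difference `v_i − v_j` (`i < j`, lexicographic). The operator's graph is a
"mountain": `n` base nodes and all `C(n,2)` difference edges, edges at
increasing temporal lag capturing increasingly long-range local dynamics.
For `n = 5` this yields 15 maps per block.

For every map the `nc` channels are ranked by descending amplitude
(`argsort(−p)`, 1-based); concatenating the per-block permutations gives
one rank sequence of length `nc·B` per map. Each sequence's
consecutive-symbol transitions are counted in an `nc × nc` table
(transitions across block boundaries included — the sequence is one flat
symbol stream), each table is flattened row-major (source channel outer,
destination inner) and the `R` tables are concatenated: a feature vector
of length `R·nc²` (e.g. `15·14² = 2940` for a 14-channel montage).

Properties that the tests pin down: the matrix form equals the explicit
pairwise enumeration; every `nc`-slice of a rank sequence is a permutation
of `1..nc`; every table sums to `nc·B − 1` (constant for fixed `L, nc, n,
s`, which is why raw counts need no normalisation); adding a constant to
the whole epoch leaves the features unchanged (ranking is
shift-invariant, and differences cancel common offsets). No filtering,
artifact removal or amplitude normalisation is applied anywhere.

One documented inconsistency in the method's published description
concerns the rank-sequence length (`nc·L` vs the `L − n + 1` blocks
actually available); we use `nc·B` blocks, the only self-consistent
choice. Likewise the printed concatenation offset cannot produce an
`R·nc²` vector and is treated as a typo: plain concatenation at offset
`(u − 1)·nc²`. Tie-ranking is stable (lower channel index first) — the
published description is silent and any fixed deterministic rule works;
this one matches common argsort semantics.

### Phase 2 — CWINCA feature selection

Neighbourhood component analysis with a *diagonal* metric: distance
`d(i,j) = Σ_f w_f² |x_if − x_jf|`, neighbour probabilities
`p_ij ∝ exp(−d_ij/σ)`, objective = expected leave-one-out accuracy
`Σ_i Σ_{j∈class(i)} p_ij − λ Σ_f w_f²`. Batch gradient ascent from
`w = 1` with an adaptive step (grow ×1.05 on improvement, halve on a
worse step), at most 100 iterations, early stop on relative objective
change < 1e−6. Defaults: `σ = 1`, `λ = 1/N`. Features are z-scored
(training statistics) for the optimisation only — selection returns
indices and downstream consumers see raw values, consistent with the
no-normalisation policy. The optimiser is batch and therefore
deterministic; the `seed` parameter exists for API symmetry.

The sorted weights are normalised to sum 1; the smallest prefix reaching
cumulative mass `tr1 = 0.85` gives the candidate-size loop start, the
smallest reaching `tr2 = 0.9999` the stop. Every size `k` in
`[start, stop]` is scored by stratified 10-fold 1-NN accuracy (Euclidean,
raw features) on the training partition; the best `k` wins, ties to the
smallest `k` (parsimony). The sweep is computed incrementally — the
top-(k+1) distance matrix is the top-k matrix plus one feature's
contribution — so its cost is `O(stop · N²)` rather than quadratic in the
candidate count.

### Phase 3 — tkNN classification

A kNN grid of `k ∈ {1..5}` crossed with three Euclidean vote weightings
(equal, `1/d`, `1/d²`) gives 15 configurations. The published parameter
table lists `k = 1..5` with Euclidean distance only, but a voting range
of 3–20 requires more than five outcomes; the three weighting schemes
(from the original self-organising kNN formulation) fill the grid and are
configurable. Each configuration is scored by inner stratified fivefold
CV on the training data (pooled out-of-fold predictions). Iterative
majority voting then adds one outcome per ensemble size `j ∈ {3..20}`:
the elementwise majority of the `j` most accurate prediction vectors,
per-position ties resolved by the single most accurate configuration. The
best outcome overall — parameter-based or voted — is refit on the full
training data and applied to the test fold. kNN vote ties break to the
lowest class label; a zero-distance neighbour dominates the
distance-weighted votes.

### Phase 4 — symbolic explanation (Directed Lobish)

Feature index `z` (1-based) decodes exactly to `(u, a, b)` — transform
map, source channel, destination channel — by inverting the flatten +
concatenate layout. Selected features, visited in descending-weight
order, emit their source then destination channel's lobe symbol (16-symbol
alphabet: F/T/C/P/O/A × L/R/z), giving a "sentence" of length `2k`; a
hemispheric sentence maps each symbol to L/R/M. For each sentence we
report the histogram, the transition table, Shannon entropy
`H = −Σ p log₂ p` over the empirical symbol frequencies, and the
complexity ratio `100·H / log₂ S` with `S` the montage's active alphabet
size (defined as 0 for `S = 1`). Duplicate symbols from repeated channel
pairs are kept — the statistics describe the full sentence. Channel →
symbol maps are configuration (JSON), with shipped defaults for a common
14-channel consumer montage (8 active lobe symbols, 2 hemispheres) and a
standard 32-channel 10–20 layout (14 symbols, 3 hemispheres); no mapping
is hard-coded because electrode naming varies by vendor. These statistics
locate discriminative features; they are not functional-connectivity or
neurophysiological activation measures.

## Validation harness

Sample-wise stratified tenfold CV (default) or leave-one-subject-out when
subject ids exist. Selection and classifier tuning are embedded per fold:
both see only the training partition, and every fold's log records the
train / selection / test index sets so the no-leakage property is
auditable (`audit_no_leakage`). Feature extraction is deterministic and
label-free, so it is computed once per epoch before the fold loop without
leakage. Metrics come from the pooled confusion matrix: accuracy, macro
recall/precision/F1 (zero-support classes excluded with a warning),
geometric mean of per-class recalls, balanced accuracy (= macro recall),
multiclass Matthews correlation, Cohen's kappa. The geometric mean is
defined over per-class recalls — the convention that makes it an
imbalance-robust accuracy summary.

## The synthetic generator

The features are functions of per-timepoint channel rankings, so the
generator plants class structure exactly there: channel `c` of a
class-`k` epoch is `A_kc·sin(2π f_k t/L + θ_kc) + ε`, with per-channel
phases `θ ~ U[0, 2π)` and amplitudes `A ~ U[0.5, 1.5]` drawn once per
class from the seeded generator, distinct integer frequencies per class
(3, 4, … cycles/epoch), and `ε ~ N(0, σ²)`. Optional subjects multiply
channels by a per-subject gain `U[0.8, 1.2]`, emulating cross-subject
shift for LOSO tests. Default conditions: 2 classes, 14 channels,
`L = 512`, 50 epochs/class, `σ = 0.05`.

What this emulates: labelled fixed-length epochs whose classes differ in
channel-ordering dynamics, with controllable noise. What it does not:
1/f spectra, artifacts, nonstationarity, volume conduction — so passing
recovery tests demonstrates the pipeline recovers rank-encoded class
structure, not that it matches any real dataset's accuracy. A class
difference that is rank-invariant (e.g. a pure common gain) is correctly
invisible to these features, and test expectations respect that.

## Numerical choices and degenerate inputs

- Ranking ties: stable, lower channel first (constant epochs rank
  `1, 2, …, nc` everywhere).
- Cumulative thresholds compared with a 1e−12 slack so exact boundary
  sums are not lost to floating-point rounding; if `tr2` is never reached
  the stop clamps to the feature count.
- NCA pairwise |difference| tensor is stored float32 (memory ~`N²F`
  bytes ×4; 95 MB at `N = 90`, `F = 2940`) — counts are exact well within
  float32 range; the weight vector and objective stay float64.
- All-constant feature matrices give equal weights (gradient is pure
  regularisation) — the selector still returns a valid prefix.
- Inner CV fold counts clamp to the smallest class size (≥ 2).
- Segments must be finite, ≥ 2 channels, `L ≥ n`; violations raise
  descriptive errors rather than propagating NaNs.

## Problem sizes used by the test-suite and acceptance script

The recovery battery runs the full pipeline (tenfold CV, fold-embedded
selection) on the default synthetic conditions at noise σ ∈
{0.05, 0.5, 2.0} — five generator seeds per level in the test suite,
three per level in `scripts/acceptance.py` — plus one label-shuffle
control; expected behaviour is ≥ 95 % mean accuracy at σ = 0.05,
chance-level accuracy (±3 s.e.) under shuffled labels, and accuracy
non-increasing in σ. These sizes exercise every code path at the default
operating point while keeping a single battery run to a few minutes on
one CPU.

## Known limitations

- The NCA optimiser materialises the `N² × F` difference tensor; for
  `N ≳ 500` with the full 2940-feature space a chunked or stochastic
  variant would be needed.
- The inner selection classifier is fixed to 1-NN (the published
  description says only that "a kNN" scores candidate subsets).
- LOSO folds are not stratified (they cannot be); single-class training
  partitions raise rather than silently degrade.
- Symbol sentences depend on the montage configuration; shipped montages
  are sensible defaults, not vendor-exact electrode maps.
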