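# Methods

## Statistic

For alignment columns *i*, *j* with plug-in (observed-frequency)
distributions `p_i(x)`, `p_j(y)`, `p_ij(x,y)` over the extended 22-symbol
alphabet, mutual information is computed in the entropy-difference form
`MI_ij = H_i + H_j − H_ij`. This is algebraically identical to the direct
Kullback–Leibler form `Σ p_ij log p_ij/(p_i p_j)`; the test suite asserts
agreement to 1e-12 on random small alignments, which pins down the handling
of empty cells and the 0·log 0 convention.

Gap (`-` or `.`) and non-standard residues participate as ordinary symbols:
the alphabet is extended rather than the data filtered, so a conserved gap
stretch is a low-entropy column like any other. Entropies default to bits
(base 2); any other base is a pure rescaling that cancels in Z-scores. The
plug-in MI is mathematically non-negative but floating-point cancellation
can leave residues of order 1e-16 below zero; public MI output clamps these
to 0 while the null-model path consumes the raw values so that observed and
null statistics are on exactly the same footing.

No analytic small-sample bias correction (Miller–Madow or similar) is
applied: the finite-size bias is handled empirically by the shuffle null.

## Null model and Z-scores

Per replicate, **every** column is independently permuted across sequences
and the full MI matrix recomputed. Shuffling conserves each column's symbol
multiset, hence each single-column entropy bit-for-bit; what it destroys is
inter-column correlation. Per-pair sample mean and standard deviation over
replicates (unbiased n−1 denominator, accumulated with Welford's algorithm
so constant samples give an exact zero variance) standardize the observed
value: `Z_ij = (MI_ij − mean_ij)/std_ij`.

Cells with `std == 0` — the diagonal (self-MI is the shuffle-invariant
column entropy) and any pair involving a constant column — are masked as
undefined rather than propagated as infinities; they are omitted from
exports, fail any Z-bounded filter, and carry zero saturation weight.

Randomness uses one master seed expanded through numpy `SeedSequence`
spawning, one stream per replicate and per column, so results are
bit-reproducible and independent of iteration order. The default replicate
count is 100, always overridable; the Monte-Carlo error of the null mean
shrinks as 1/√replicates and the package makes no normality claim about the
null MI distribution (it is visibly skewed), which is why Z thresholds are
exploration aids, not calibrated p-values.

## Matrix seriation

The sorting algorithm is a greedy nearest-neighbour chain: the *seed row*
(maximal value-sum) goes first, then repeatedly the remaining row with the
smallest l1 distance to the last placed row. The same pass then runs on the
columns of the row-reordered matrix; the two passes are sequential and
independent, so a symmetric matrix can receive different row and column
permutations. Ties — in seed selection and in nearest-row selection — break
to the lowest original index, making the ordering fully deterministic and
testable against a brute-force trace. Masked cells contribute 0 to row sums
and masked positions contribute 0 to distances, keeping the algorithm total
on filtered matrices. Complexity is O(L²) distance evaluations. This is a
heuristic seriation, not an optimal ordering; hierarchical or spectral leaf
ordering is out of scope.

## Filtering, weighting, rendering

Filters are inclusive `[min, max]` windows on MI and on Z, evaluated
cellwise into a boolean mask; values are never mutated, and widening a
bound can only grow the mask. The Z matrix can be combined with the data by
elementwise multiplication, or mapped through a linear ramp
`clamp((Z − lo)/(hi − lo), 0, 1)` to per-cell color-saturation weights
(linear is the minimal documented transfer function; undefined Z ⇒ 0).

Rendering normalizes values to [0,1] (global min–max by default, a constant
matrix maps to 0.5; a fixed-range mode supports comparable scales across
images), looks colors up in a named continuous scale (matplotlib's Blues by
default, RdBu for diverging Z displays, plus viridis and greys), paints
masked cells in a neutral background grey, and blends saturation-weighted
cells linearly in RGB toward that background. Each cell becomes a
`cell_px × cell_px` block, so `cell_px=1` gives one pixel per pair. PNG
output is lossless 8-bit RGB and byte-deterministic for identical inputs
and options. Histograms over a symmetric matrix count unique `i ≤ j` cells
so each pair is counted once.

The default render pipeline order is sort → filter → combine → normalize →
colorize; the filter mask and the subset export are computed in original
coordinates so exported `row column value` triples keep 1-based alignment
positions regardless of sorting, and a label sidecar maps displayed
rows/columns back to original positions.

## File formats

Matrices travel as plain-ASCII triple-per-line files, `row column value`
with 1-based indices, written space-separated with 17 significant digits
(lossless for doubles); the reader also accepts comma separators, ignores
blank and `#` lines, and treats absent cells as missing without symmetric
completion. The compute command exports unique pairs `i ≤ j` with the
diagonal carrying the column entropy. Because masked cells are omitted, a
sparse file can under-report the matrix extent; the render command pads a
smaller weight matrix with missing cells up to the data extent and rejects
a larger one.

## Synthetic data generator

Test alignments draw each column iid from a background distribution
(default: uniform over the reduced 4-symbol set {A,C,D,E} — high per-column
entropy of 2 bits and fast convergence of plug-in estimates; full 22-symbol
backgrounds are supported). A planted coevolving pair (i, j) with coupling
c sets the symbol at j to a fixed bijective image (cyclic shift over the
background support) of the symbol at i with probability c, else to an
independent background draw. The mechanism is chosen for its closed-form
joint table — `expected_mi` evaluates the population MI exactly, giving the
estimator-consistency tests an oracle — and claims no biological realism:
no phylogenetic correlation between sequences (rows are iid), no
substitution-model structure, no gap patterns, no conservation gradient
along the protein. Passing tests therefore demonstrate statistical
correctness of the estimator, null and pipeline on exchangeable data, not
robustness to phylogenetic redundancy in real alignments (sequence
weighting and tree-aware nulls are explicitly out of scope).

Study-condition defaults used by the end-to-end checks: 200 sequences
(the order of magnitude of a typical curated family), 30 columns, one pair
at coupling 0.9, 100 shuffle replicates; estimator consistency is checked
at n ∈ {100, 1000, 10000} against a 3/√n bits band; the no-signal
false-positive check uses the same 200×30 geometry. Problem sizes in the
acceptance script match these.

## Numerical and design choices

- Logarithm base: bits by default, configurable; Z is base-invariant
  (asserted to 1e-9).
- Null statistics: unbiased (n−1) sample standard deviation; at least 2
  replicates required.
- Filter bounds inclusive on both ends so exact threshold hits survive.
- Matrix container: numpy arrays with NaN as the missing/masked marker;
  producing functions enforce symmetry, bounds and masking invariants.
- Known limitations: no average-product correction or DCA-style couplings;
  no p-values or multiple-testing control beyond the Z-score; the greedy
  seriation is order-heuristic; the interactive viewer of the original
  workflow is replaced by static rendering with sub-range drill-down
  (`--rows A:B --cols C:D`).
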