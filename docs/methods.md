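# Methods

## Preprocessing model

Inputs are per-study probe × sample matrices assumed to be on the log2
scale (a `log2_input` flag applies `log2(max(x, ε))`, ε = 1e-6, for
raw-scale data). The chain is:

1. *Optional normalisation.* `quantile_normalize` forces all sample
   columns onto the common distribution of averaged order statistics
   (ties keep their within-column order, so identical columns are
   fixed points). `lowess_normalize_two_color(M, A)` subtracts a
   locally weighted regression of log-ratio M on mean log-intensity A;
   the local fit uses span 0.4 with 3 robustifying iterations (the
   method is classically cited without parameters; 0.4 is a
   conventional middle value, and both knobs are exposed). At least 10
   finite points are required for the fit to be meaningful.
2. *Median collapse*, three times: technical replicates (samples
   sharing condition and replicate id), probes per gene symbol (after
   expanding multi-symbol probes to one row per symbol), and
   biological replicates (to one column per condition). The median is
   robust to outlying replicates; even-sized groups take the midpoint
   of the central pair. Gene symbols are canonicalised by
   whitespace-stripping and upper-casing.
3. *Control centring.* Sample metadata assigns every condition to a
   `control_group`; each treated condition has the median of its
   group's control columns subtracted and control columns are then
   removed. Explicit control-group keys were chosen over positional
   inference: "matched control" is a statement about design, and the
   metadata is where design lives.
4. *Merge.* Studies are merged on the intersection of their canonical
   gene symbols; genes with any missing value after collapse are
   dropped first, so the merged matrix is complete. Columns are
   labelled `study:condition`.

The full chain is equivariant to permutations of a study's sample
columns, and centring maps every control condition to the zero vector
before removal (both property-tested).

## Bimax and the repeated wrapper

A bicluster of the binary matrix B is a pair (R, C) with B[r, c] = 1
for all r ∈ R, c ∈ C, inclusion-maximal: no row or column can be added
without introducing a 0. `bimax_enumerate` finds all of them by divide
and conquer: choose a template row whose support is a proper subset of
the current columns, split the columns into the template's support C₁
and the rest C₂, and recurse on (all rows, C₁) and (rows with a 1 in
C₂, unchanged columns). Any maximal bicluster survives intact down one
branch and surfaces as an all-ones leaf; leaves failing a closure
check against the full matrix (row set ≠ all rows supporting C, or a
column addable) are discarded and duplicates removed. Rows are
bitmask-encoded so subset tests are single integer operations, and
branches are pruned when the surviving rows or columns fall below the
size minima. Correctness is tested by exact equivalence with a
brute-force oracle (enumeration over column subsets) on hundreds of
random matrices.

`repeated_bimax` iterates: enumerate, accept the largest-area
candidate, zero out its cells, repeat until no candidate meets the
minima (defaults: ≥15 genes, 5–15 conditions, two-fold cutoff). Design
choices where the procedure is genuinely underdetermined:

- *Tie-breaking* on equal area: more rows first, then the
  lexicographically smallest condition-label set — determinism is a
  hard requirement (identical inputs give identical runs, list order
  included).
- *Column maximum.* Bimax has no native column maximum, so a wider
  maximal bicluster is truncated to the `max_cols` columns with the
  most 1s outside the bicluster's rows (ties lexicographic), then
  re-extended to all supporting rows. The maximum is thus a constraint
  on reported biclusters, not on the search.
- *Masking* zeroes cells, not rows/columns, so overlapping biclusters
  that share genes or conditions (but not cells) remain discoverable.
  Each acceptance removes ≥ min_rows × min_cols ones, so termination
  is guaranteed.

Binarization is inclusive at the boundary (|log2 FC| = log2 cutoff →
1), and the up/down matrices from one input are disjoint. Lowering the
cutoff (2 → 1.75 → 1.5) can only add 1s, and on a corpus with blocks
planted at graded effects the bicluster count grows as the cutoff
drops (tested).

For display, `order_for_heatmap` orders genes and conditions by
average-linkage (UPGMA) hierarchical clustering on distance
1 − Spearman ρ (midrank ties); zero-variance vectors make ρ undefined
and raise an error naming the offending labels. Only the leaf ordering
is produced; rendering is out of scope.

## Gene-set enrichment

For a study with k ≥ 2 dose groups of ≥ 2 samples each, each gene
receives F = MS_between / MS_within with dose as a categorical factor
(the overall dose-effect statistic; no monotone-trend assumption).
Genes with MS_within = 0 or F = 0 are flagged and excluded from the
log2 transform rather than silently dropped. A set is scored by
Welch's t on log2 F, set versus background, with the
Welch–Satterthwaite df and a two-sided p-value by default.

- *Background = all genes* (set included) is the default, matching the
  mean-of-all-genes formulation; with sets of ~20 genes in a
  ~2000-gene universe the induced overlap is negligible and, if
  anything, conservative. `background="complement"` is available and
  recorded in the output.
- *Two-sided* p-values are the default since enrichment is reported as
  −log10(p) without a sign convention; `alternative="greater"` (set
  above background) is exposed.
- No multiplicity adjustment by default; Benjamini–Hochberg across
  sets within a study is optional (`adjust="BH"`).

The F and Welch statistics are computed from explicit formulas and
verified against scipy's `f_oneway` and `ttest_ind(equal_var=False)`
to 1e-10 relative error; calibration is checked empirically (null
type-I error within the 95% binomial band around 0.05 over 1000
replicates) along with power against planted responder sets. Adding a
constant to all expression values changes no F, t or p.

## Synthetic data

`generate_corpus` emulates the structure of a multi-platform
lung-disease compendium: 11 studies totalling 50 conditions (2–6 per
study), a 3000-symbol universe with 10% per-study symbol dropout
(platform differences), study baselines N(7, 1) per gene, replicate
noise N(0, 0.3) per measurement, 3 biological replicates per condition
(typical of the emulated studies), one shared control group per study,
and ~10% of genes carrying a duplicate probe so the collapse steps do
real work. Each study has a fold-change compression factor drawn from
[0.6, 1.0], applied multiplicatively to planted effects — the simplest
mechanism consistent with cross-platform fold-change attenuation.

*Planted signal model.* Planted blocks (≥15 genes × 5–15 conditions,
spanning ≥2 studies, disjoint from each other) specify a log2 effect
that is a **guaranteed minimum fold change**: after drawing replicate
noise, any planted gene × condition whose realized median-collapsed
fold change falls short of `compression × effect` is shifted up to
that floor (symmetrically for down-blocks). Background cells keep
symmetric noise. This makes survival of a planted cell under a fold
cutoff the deterministic predicate `compression × effect ≥
log2(cutoff)`, which the ground-truth registry records per condition —
without the floor, 120-cell all-ones blocks would be destroyed by
single sub-threshold cells at any realistic noise level, and recovery
would measure noise rather than the algorithm. Planted genes are
exempt from symbol dropout (they must survive the intersection merge
for the planted block to exist in the merged matrix). Spec validation
warns when the worst-case compressed effect falls below the cutoff and
when the expected background 1-density exceeds 0.05 (Bimax output
grows explosively on dense matrices).

What the generator does **not** model: probe-level hybridisation
physics, annotation errors, correlated (batch) noise, dye bias beyond
the LOWESS test fixtures, and platform-specific probe sets beyond
i.i.d. symbol dropout. Passing recovery tests therefore demonstrates
correctness of the pipeline's algorithms under the stated noise model,
not performance on raw public microarray data.

`generate_exposure_study` builds dose-response studies: control + 3
dose levels × 3 replicates (defaults), gene baselines N(7, 1),
residuals N(0, 0.5), and planted sets whose group means rise linearly
by `slope` log2 units per dose index. All randomness in both
generators flows from the single spec seed through
`numpy.random.SeedSequence`; identical specs give byte-identical
output.

## Problem sizes and numerical notes

The shipped tests and the acceptance script run the corpus at its
default size (11 studies / 50 conditions / 3000 symbols — about one
second end to end), Bimax-vs-bruteforce equivalence on 200 random
matrices up to 8×8 at densities 0.2–0.8, type-I calibration on 1000
independent null studies of 2000 genes, and power on 100 seeds; these
sizes give stable estimates while keeping the whole suite fast. The
recovery corpus draws compression from [0.7, 1.0] so that every
planted 1.5-effect block deterministically survives the two-fold
cutoff (at 0.6, compressed effects of 0.9 log2 units fall below
log2 2 = 1 and the affected conditions are — by design — recorded as
non-surviving in the registry).

Ties in quantile normalization follow stable sort order; Spearman
correlations use midranks; hierarchical ordering uses scipy's average
linkage on the condensed distance matrix; Welch edge cases (both
variances zero) return t = 0 or ±inf rather than NaN. Matrices with
non-finite fold changes are rejected at binarization — completeness is
the preprocessing stage's contract.

## Known limitations

- The intersection merge discards genes absent from any one study; with
  many studies and high dropout the merged universe shrinks
  multiplicatively (0.9¹¹ ≈ 0.31 of the universe at defaults). This
  mirrors the real cost of symbol-intersection meta-analysis.
- Bimax enumeration is exponential in the worst case; the repeated
  wrapper is intended for the sparse binary matrices produced by
  stringent fold cutoffs (density ≲ 0.05, warned about at generation).
- The enrichment test treats genes as exchangeable and independent;
  correlated expression within a set inflates the effective variance
  and is not corrected for.
- Studies within one accession that used several platforms are treated
  as separate studies; no cross-platform reconciliation beyond the
  fold-change scale is attempted.
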