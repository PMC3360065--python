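# Methods

## Data model and conventions

A record is a 19-nt antisense (guide) strand over {A, C, G, U}, written
5′→3′, with a **product level** in [0, 1]: the mRNA/protein fraction
remaining after silencing. Lower product level = more potent siRNA;
"potent" means product level < 0.3 throughout. Every correlation in the
validation module is computed against the product level, so a *negative*
coefficient means the feature *increases* potency. Tables deposited with
sense-strand sequences are converted by RNA reverse complement; `T` on
input is silently read as `U` (DNA-encoded deposits are common), any other
character is a hard per-record error naming the offending position.
Efficacy normalisation defaults to clipping into [0, 1]; min–max rescaling
is opt-in per dataset, because cross-platform rescaling is exactly what the
joint model is designed to avoid.

The built-in `DEFAULT_MANIFEST` records the ten-platform meta-collection
the method targets (sizes 2431, 601, 702, 239, 42, 108, 10, 76, 50, 223;
total 4,482 siRNAs; platforms 3 and 10 deposited sense strands). The
datasets themselves are external and are not bundled or downloaded.

## The 497-feature space

The schema is a versioned, machine-readable manifest (JSON) of 497
descriptors; the block layout is documented in `sirnarank.features`. Two
properties fix the ordering: the positional block runs nucleotide-major in
the order A, G, U, C over positions PS1..PS19 (so 'A @ PS1' is feature 2,
'U @ PS1' is 40, 'C @ PS19' is 77), and the k-mer blocks use the same
A, G, U, C alphabet in base-4 order (so 'CU' is 92, 'UCU' is 140, 'GGG' is
115). The dinucleotide-stability block ('GG in PS[i,i+1]', features
414–431) holds nearest-neighbor stack free energies, not G/G flags.

The published feature list this space reconstructs is not available in
machine-readable form, so several choices are explicitly marked
`reconstruction_uncertain` in the manifest: the identity of feature 1
(here: a constant column that doubles as the unpenalised intercept), the
exact thresholds of the GC block (here: a 0.05 grid, lower bounds
'>0.05'…'>0.45' at 477–485 and upper bounds '<0.95'…'<0.55' at 486–494),
and whether the structure features are scalars or flags (here: paired
fraction, a ≥5 stem-length flag, a hairpin flag). Amending the manifest
does not require code changes.

**Thermodynamics.** Stack free energies are the Watson–Crick ΔG°37 values
of Xia et al. (1998), *Biochemistry* 37:14719–14735, embedded as a 16-entry
constant table; the 10 published unique stacks are expanded to all 16
dinucleotides via reverse-complement symmetry. Window features sum
consecutive stacks (duplex free energy up to end effects).

**Secondary structure.** Intramolecular folding uses maximum base-pair
matching (Nussinov dynamic programming) over Watson–Crick plus G·U wobble
pairs with a minimum hairpin loop of 3 — not minimum free energy. This
keeps the package dependency-free and exactly testable against brute-force
enumeration of nested pairings (tested for lengths ≤ 12). The traceback is
deterministic (leftmost partner first). The hairpin flag requires a stem of
at least 2 stacked pairs, so a single isolated pair does not count as
structure. Note that with wobble pairs admitted, paired fraction is *not*
invariant under reverse complement (a G·U pair maps to A·C); the invariance
holds in Watson–Crick-only mode.

**Immune/palindrome block.** Immune-stimulatory motifs default to UGUGU
and GUCCUUCAA presence flags. A palindrome flag fires when a contiguous
substring of length ≥ 6 (or ≥ 8) equals its own RNA reverse complement.

## Joint multi-task regression

Objective: `Σ_j 1/(2 n_j) ‖X_j w_j − y_j‖² + λ Ω(W)` with Ω one of ℓ2,1,
ℓ1,∞ or trace norm. The per-task 1/n_j scaling stops the 2,431-record
platform from dominating the 10-record one; unnormalised ("global")
scaling is a config switch. A per-task intercept (feature row 0) is always
fitted and never penalised.

**Solver.** Monotone FISTA: accelerated proximal gradient with step 1/L (L
by power iteration), where an iteration that would increase the objective
is replaced by a plain proximal step from the best iterate and the momentum
restarts. Proximal maps: row-wise group soft-thresholding (ℓ2,1), row-wise
Moreau decomposition through a sort-based ℓ1-ball projection (ℓ1,∞), and
singular-value soft-thresholding (trace). Convergence: relative objective
change < 1e-6 (default), max 10,000 iterations; non-convergence returns
the best iterate with a warning.

**Standardization.** The solve runs on per-task-centred columns scaled by
their pooled (all-task) standard deviation, with the intercept recovered in
closed form afterwards. This matters twice: raw feature scales differ by
two orders of magnitude (summed ΔG windows vs binary flags), which would
(a) let large-scale columns evade the penalty and (b) inflate the Lipschitz
constant and stall the solver. Weights are mapped back to the original
scale, so `X @ W` predicts directly. λ_max (the smallest λ at which every
penalised row of the optimum is zero — dual norm of the loss gradient at
the intercept-only solution) is computed in the same geometry.

**Cross-validation.** Folds are stratified within task; fold f trains on
the complement across all tasks jointly and scores per-task RMSE on the
held-out rows. A task smaller than the fold count distributes its records
one per fold (leave-one-out within task); a task of size 1 is always
trained on, never tested, with a warning.

**λ selection.** A 20-point logarithmic grid from λ_max down to λ_max/10³,
scored by 10-fold CV with warm-started continuation (grid fits use a looser
1e-4 tolerance; the final model is refitted at full tolerance). Two rules
are exposed: `"min"` (the literal RMSE minimiser — used when the question
is predictive accuracy) and `"1se"` (the largest λ within one standard
error of the minimum — the default for *selection*, because the RMSE curve
is flat and noisy at the bottom and its minimiser drifts into dense,
unstable fits).

## Feature ranking and selection

Cross-task weight: `w_i = Σ_j |W_ij|` (row ℓ1; the row ℓ2 norm is a config
switch). It is zero exactly on all-zero rows, matching the "common
feature" criterion, and its magnitude ranks importance. Stability: only
features with `w_i` above the zero threshold (1e-8) in **every** CV fold
are kept, ranked by mean weight (fold weights are sorted before averaging
so the result is bit-identical under fold reordering). Ties break by
ascending feature index.

**Gap cut.** At a prediction-chosen λ, group-sparse fits retain a residue
of features correlated with the true ones (a positional flag leaks into
the stack energies and GC flags at the same position) at distinctly
smaller weight. The pipeline therefore truncates each stable list at the
largest consecutive weight ratio, searched only within the head of the
list (weights ≥ 5% of the maximum — ratios between near-threshold tail
weights are meaningless). On the default benchmark this separates the
planted support almost perfectly (mean F1 0.96–0.99 over seeds); when the
weight decay is smooth the cut simply keeps the head cluster.

The per-norm *stable* lists (not the gap-cut lists) are intersected to the
shared universe and aggregated, mirroring the published fold-then-norm
procedure; the gap-cut set is what "selected features" means downstream.

## Rank aggregation

The consensus ordering minimises `Σ_i w_i · d_K(δ, L_i)` with raw
(integer) Kendall distances and uniform list weights by default. The
Cross-Entropy Monte Carlo search keeps an item × position probability
matrix, samples `10·k²` permutations per iteration by sequential position
filling, refits the matrix to the top 10% and smooths with ν = 0.7,
stopping after 10 stagnant iterations. Elite ties break in first-sampled
order under the fixed seed. A k! brute-force oracle (k ≤ 8) certifies
optimality in tests; on random k = 5 instances the CE result matches it in
≥ 95% of cases (20/20 in the shipped run). A weighted mean-rank list is
available as a diagnostic only.

## Validation statistics

* **Welch t-test** — one-tailed, two-sample, unequal variance, with
  Welch–Satterthwaite degrees of freedom; significance convention 0.05.
  Two zero-variance groups yield p ∈ {0, 0.5, 1} by sign with a warning.
* **Association table** — per feature: Pearson R against product level and
  a Welch p comparing feature-present vs feature-absent records (binary
  features split at 0.5, continuous at their median; the one-tailed
  direction follows the sign of R). Constant columns are reported with
  missing R/p rather than raising. No multiple-testing correction is
  applied; raw p-values are reported with the 0.05 convention.
* **GC window scan** — fraction of potent records inside [ℓ, 0.55] for ℓ
  on a 0.05 grid from 0.45 down to 0.05 (arbitrary windows supported). An
  empty window reports a missing fraction, not zero.
* **Motif profiles** — per start position: occurrences among all records,
  among potent records, their ratio, and each position's share of all
  potent-record occurrences (both normalisations).
* **Ridge comparison** — repeated (default 1,000 rounds) random 2-fold CV
  of closed-form ridge with unpenalised intercept on standardized columns,
  the same α (default 1.0) for both feature sets; per-round RMSE averages
  both directions, and a paired one-tailed t-test compares sets across
  rounds or datasets. α = 0 falls back to minimum-norm least squares on a
  singular system.

## Synthetic benchmark

The generator emulates the heterogeneous-platform structure: default task
sizes (500, 200, 200, 100, 40, 40, 10, 40, 40, 100) mirroring the real
collection's spread; i.i.d. uniform-composition 19-mers; product levels
`y = clamp(offset_j + Σ_{i∈S} β_{j,i} x_i + N(0, σ_j²), 0, 1)`. The planted
support S is ten positional one-hot flags at distinct positions (nearly
uncorrelated columns under i.i.d. sequences); per-feature magnitudes are
uniform on [0.15, 0.30] with a fixed half-negative sign pattern, scaled per
task by a multiplier on [0.7, 1.3] (shared support and signs, near-rank-1
true W); σ_j is spread evenly over [0.05, 0.20] and offsets over
[0.30, 0.60], both ascending with task index. Ground truth (S, β, σ,
offsets) is always emitted as JSON.

What the generator does **not** emulate: real position-dependent
composition bias, duplicated sequences across platforms, categorical or
saturated efficacy readouts, target-mRNA context, and measurement error
structure beyond additive Gaussian noise. Passing recovery tests therefore
demonstrate correctness of the machinery under the stated linear model,
not performance on real screens.

**Clamping.** Responses are clamped to [0, 1] rather than resampled. This
is deliberate simplicity, but it is not a mild detail: with the default
offsets, 14–21% of the dominant task's responses sit on the boundary, so
the best *linear* predictor is strictly worse than σ — the planted linear
model itself scores a pooled held-out RMSE 1.15–1.24× the pooled σ. As a
consequence, regularized fits hover near 1.2× (ℓ2,1) to 1.4× (trace) of
the σ floor on this benchmark: the gap is structural (clamping plus
shrinkage bias), not a solver deficiency — an OLS refit restricted to the
true support reaches 0.98× σ. This bounds what "RMSE near the noise
floor" can mean here and is the reason the package reports the trace-norm
RMSE/floor ratio openly rather than tuning the generator to hide it.

## Numerical and design choices

* Zero threshold for a "non-zero row": ℓ2 row norm > 1e-8 after fitting.
* Power iteration for L: 50 iterations, fixed internal seed; deterministic.
* Fold assignment, CE sampling and the ridge splits all derive from
  explicit integer seeds; the full pipeline is bit-reproducible for a
  fixed seed (tested by hashing artefacts of two complete CLI runs).
* `brute_force_aggregate` refuses k > 8 (40,320 permutations is the
  practical ceiling for an oracle).
* The CLI is a thin veneer: every subcommand is I/O plumbing around one
  library call; the importable API is the primary surface.

## Known limitations

* The 497-feature composition is a reconstruction pinned to the published
  anchor indices; blocks without anchors (window thermodynamics, structure
  flags, GC grid) are plausible but not certified.
* Secondary structure is maximum matching, not MFE; an external folding
  engine can be substituted by editing the schema manifest and supplying a
  custom encoder.
* The trace-norm penalty does not zero rows, so its "stable list" is
  nearly the full feature set and its contribution to the consensus enters
  through ordering only.
* Rank aggregation weights w_i default to uniform; there is no
  data-driven estimate of per-list reliability.
* p-values are reported without multiple-testing correction, matching the
  0.05-per-feature convention of the validation tables they mirror.
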