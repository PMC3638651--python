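# Methods

## The scoring model

`rerankfs` ranks markers in a two-group study by a centered
rank-over-variable statistic.  For subject *i* and marker *j*, let
`x*ᵢⱼ = xᵢⱼ − μⱼ` where `μⱼ` is the marker's overall mean with cases and
controls pooled.  Within each subject the centered values are ranked across
markers in decreasing order (rank 1 = largest; tied values receive
midranks), and

    Sⱼ = | mean over cases of R(i,j) − mean over controls of R(i,j) | ∈ [0, p−1].

The centering is essential: without it a marker whose mean differs between
groups but whose *position* among the other markers is the same in both
groups would be invisible to a within-subject ranking.  The implicit null
hypothesis is that the ordering of the centered markers within a subject has
the same distribution in both groups; a mean shift in a relevant marker
breaks it in opposite directions for cases and controls.

Because the rank is taken across *p* markers rather than across *n*
subjects, the statistic has fine resolution even when *n* is tiny — the
regime where the two-sample t becomes unstable (variance estimated from a
handful of observations) and the Mann–Whitney AUC collapses onto at most
`n₀n₁` distinct values.

## Ensemble sharpening

**Random subset** (`random_subset_scores`): draw `B` marker subsets of size
`max(2, ⌈p/2⌉)` uniformly without replacement, recompute `S` within each
subset (the centering means are subset-independent; the within-subject ranks
are not and are recomputed), and set `S*ⱼ` to the mean of `Sⱼ⁽ᵇ⁾` over the
subsets containing *j*.  With fewer irrelevant markers in a subset, a
relevant marker's rank signal is less diluted.  Every marker is guaranteed
at least one inclusion: in the (astronomically unlikely, for practical `B`)
event a marker is never drawn, dedicated draws containing it are appended,
keeping the estimator total.

**Rerank** (`rerank`): starting from the full active set `I₀`, iteration *t*
computes `S*⁽ᵗ⁾` on `I_t` and keeps the top `⌈q/100 · p_t⌉` markers (capped
at `p_t − 1`, which forces strict shrinkage for any `q` and guarantees
termination).  Scores from different set sizes are made comparable by the
normalization `S*ⱼ⁽ᵗ⁾/p_t`, and iterations are weighted by their mean
normalized score `w_t` — an iteration whose active set separates the groups
well counts for more.  The final score is

    S**ⱼ = Σ_{t : j ∈ I_t} w_t · S*ⱼ⁽ᵗ⁾ / p_t .

The iteration stops when the next active set would fall below `stop_floor`
(default 10).  The natural floor is the number of markers one intends to
take forward; when that number is unknown it is itself estimated by the
partial-permutation rule below, which only needs the ranking, not the floor,
to be right near the top of the list.

**Prescreen** (`prescreen`): an optional two-sample-t filter keeps the top
`M0` markers (default 5000) before the ensemble machinery runs; with
`p ≤ M0` it is a no-op.  A conservative `M0` (several times the plausible
signal size) barely affects the final list and caps the cost at GWAS scale.

**Final list**: screened markers ordered by `S**` (ties by |t|, then column
index), followed by prescreen-rejected markers ordered by |t|, so every run
yields a total order over all *p* markers.

Subset draws and retention operate on the active set listed in marker-id
order, which makes results invariant to the column order of the input file.
All randomness flows from one root seed through named `SeedSequence` spawn
keys; reruns are bit-identical.

## Selecting the number of relevant markers

Given the ranked list `ℓ(1), …, ℓ(p)` by `S**⁽⁰⁾`, for each cutoff *m* the
group assignment is permuted *only on the markers ranked below m* — one
shared row permutation per replicate, so correlation among the permuted
markers is preserved (an independent-per-column mode would destroy it) —
and `S**` is recomputed on the partially permuted data.  With

    ν_m = (1/B_perm) Σ_b  1( mean S**⁽ᵇ⁾ ≥ mean S**⁽⁰⁾ ),

the selected count is `M₁ = min{m : ν_m ≥ 0.5}`.  Rationale: if the top *m*
markers contain all the real signal, permuting the rest is close to a no-op
and the permuted mean score is as likely as not to reach the observed one;
if a truly relevant marker is permuted, the mean collapses and `ν_m` sits
near 0.

Each permutation replicate recomputes `S**` with its own fresh subset-draw
stream, so `ν_m` integrates over the ensemble's Monte-Carlo variability as
well as the permutation.  An empty permutation set (`m = p`) is recognized
as the no-op it is and reuses the baseline evaluation, so `ν_p = 1`
identically.

A property worth knowing when reading per-dataset curves: below the true
signal count `ν_m` collapses decisively (a permuted relevant marker drags
the mean score far down), so the rule essentially never undershoots; *at*
the true count, `ν_{m*}` compares the observed dataset against its own
permutation orbit, and for independent null markers the dataset's
"alignment luck" has the same scale as the orbit spread — `ν_{m*}` is
therefore roughly uniform across datasets rather than pinned at 0.5, and
the selected `M₁` carries a right tail (crossings a few steps above `m*` on
unlucky datasets).  Averaged over datasets the curve crosses 0.5 at `m*`,
which is how the curve is best read; medians over a handful of datasets
land at or slightly above `m*`.

The mean in `ν_m` runs over the same active set the rerank was computed on
(after the prescreen, if any).  With `m_max="auto"` the sweep stops a
confirmation window (default 5 cutoffs) after the first crossing; the full
sweep remains available.  `B_perm` controls the binomial resolution of each
`ν_m` (SE ≤ 0.5/√B_perm).

## Baselines

* `t_scores` — pooled-variance two-sample |t| (Welch optional).  Pooled is
  the classic default and matches the SAM denominator family.  Zero-variance
  markers: score 0 if the means agree, +∞ (sorted first) if not.
* `auc_scores` — midrank Mann–Whitney AUC, reported as |AUC − 0.5|.
* `sam_scores` — |mean difference| / (pooled SE + s₀) for a user-supplied
  fudge factor `s₀ ≥ 0`; `s₀ = 0` recovers |t|, `s₀ → ∞` the fold-change
  ordering.  Automatic `s₀` estimation is deliberately out of scope — the
  method's sensitivity to `s₀` is one of the problems the rank approach
  avoids.

## Synthetic data

`gaussian_two_group`: irrelevant markers N(0,1) in both groups; the
`m_star` relevant markers N(delta,1) in cases.  Default study conditions:
`p = 2000`, `m_star = 10`, `delta = 2`, `n1 = n0 = 100`.

`genotype_pools` + `add_pooling_noise`: per marker a base minor-allele
frequency `f ~ U(0.05, 0.5)`; individual allele counts Binomial(2, f); case
frequency at relevant markers `f₁ = OR·f / (1 − f + OR·f)` with a shared
odds ratio (default 1.8) or per-marker odds ratios drawn from a range;
pools of `s` individuals report their mean allele frequency; measurement
error perturbs each cell on the logit scale, `X = expit(logit(X̃) + ε)`,
`ε ~ N(0, σ²)`, with an outlier fraction using an inflated σ.  Named noise
scenarios: A (σ = 0), B (σ = 0.05), C (σ = 0.05 with 1% outliers at σ = 5).
True frequencies are clamped to `[1/(4s), 1 − 1/(4s)]` before the logit —
the transform is undefined at 0 and 1, and the clamp sits below the
smallest nonzero pool-frequency step `1/(2s)`.  Cells whose noise draw is
exactly zero pass through unchanged (the expit/logit round-trip is not
bit-exact).

What the generators do *not* emulate: linkage disequilibrium (markers are
independent), realistic MAF spectra, array-specific probe error, or
population structure.  Tests passing on these generators therefore
demonstrate correctness of the algorithms and their comparative behavior
under idealized noise, not performance on real pooled arrays.

## Method comparison at desk scale

`rerankfs.compare.compare_methods` benchmarks rerank against t, AUC and a
SAM `s₀` grid on the pooling generator with 8 + 8 pools of 200, sparse
signal (10 relevant among 10000 markers, 0.1% — matching the sparsity
regime of genome-wide screens), per-marker odds ratios U(1.2, 2.0) (top
association hits carry a spread of effects, not one), and σ = 0.05 pooling
error.  The comparison metric is the mean truth-recovery curve: the
fraction of relevant markers inside the top `M₁`, as a function of `M₁`.

Observed structure (recomputed by `scripts/compare_methods.py`): the rerank
curve dominates the AUC curve throughout the selection range `M₁ ≤ m*` —
the range a researcher actually selects for follow-up, and the range the
`M₁` rule targets — with the largest margins at small `M₁` where AUC's tie
blocks randomize the order.  Deeper in the list the curves converge and
cross within Monte-Carlo noise: a relevant marker that the backward
elimination drops early keeps only its early-iteration contributions and is
ranked behind longer-surviving null markers, a structural property of the
weighted sum `S**`.  The test suite asserts the dominance over AUC on
`M₁ = 1..m*`.

## Numerical and performance notes

* Per-subset ranks are read off a single descending argsort of each row:
  walking the sorted order and counting subset members yields within-subset
  ranks, so each iteration costs `O(B·n·p_t)` rather than
  `O(B·n·k log k)` sorts.  When the active set shrinks, the sort order is
  filtered, never re-sorted.
* On tie-free rows (the generic case for continuous data) ordinal ranks
  equal midranks and the per-group rank sums are accumulated in int32 by a
  numba kernel that processes all subsets in one contiguous pass per row; a
  midrank-aware kernel covers tied data, and a `scipy.stats.rankdata`
  reference engine (`engine="reference"`) defines the semantics both
  compiled kernels are tested against.
* Tie detection uses exact equality of centered values.  Centering is exact
  only when the arithmetic is (e.g., integer data with power-of-two group
  sizes); on noisy data users who care about reproducible tie handling
  should pre-round.
* Problem sizes in the test suite and the acceptance script: the Gaussian
  recovery experiment averages 10 datasets and the `M₁` selection
  experiment 5 datasets with `B_perm = 50` and cutoffs up to 20 with early
  stopping — enough for binomial noise on each `ν_m` of about 0.07 and a
  stable median, while keeping a full run in the tens of minutes on one
  CPU.

## Known limitations

* The `S**` ordering buries markers eliminated in early iterations (see
  above); if deep-list behavior matters, consult the per-marker
  `dropped_at` column of the ranking report.
* `ν_m` is reported raw — no isotonic smoothing, no change-point detection;
  only the first-crossing rule is implemented.
* The correlation-change detection ability sometimes attributed to
  rank-over-variable statistics is not exposed as a test statistic here;
  the score targets mean shifts.
* PLINK/VCF genotype input is out of scope; the tool consumes continuous
  feature matrices as TSV/CSV.
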