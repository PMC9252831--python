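# Methods

`mirten` ranks post-transcriptional regulators (miRNAs, miRNA families,
RBPs) by the enrichment of their predicted targets in a transcriptional
signature. This note describes the statistical models, the conventions that
tie them together, the synthetic-data generator used to validate them, and
the numerical choices that a maintainer would otherwise have to reverse-
engineer from the code.

## Inputs and conventions

**Collections.** A target collection stores one record per
(regulator, feature) pair: a site count (≥ 1; non-targets are absent, not
zero rows), an optional repression score and an optional best site type
(8mer > 7mer-m8 > 7mer-A1 > other). Scores are canonicalised at read time to
"more negative = stronger predicted repression" (the TargetScan context++
orientation); sources that report positive strengths are flipped with
`score_sign=-1`. Duplicate rows merge by summing sites, keeping the most
negative score and the strongest site type. Family-level aggregation takes,
per (family, feature), the strongest member prediction — max sites, min
score — rather than summing, because family members share a seed and their
predictions are not independent evidence. Transcript-level analysis is
supported simply by using transcript ids as features; no gene↔transcript
mapping is attempted.

**Signal.** Continuous tests consume a per-feature statistic
`s_i = sign(logFC_i) · (−log10 FDR_i)`, which tracks logFC for
well-measured genes and damps noisy fold changes. `FDR = 0` is floored to
half the smallest positive FDR in the table (keeps rank order, avoids
infinities). Two exceptions:

* the rank tests (ks, mw) are fed the raw logFC vector by the dispatcher.
  BH-adjusted FDRs tie in large plateaus, and tied signals make the KS
  statistic conservative (measured null rejection 0.022 at the 0.05 level
  versus 0.048 on logFCs); the Mann-Whitney test is tie-corrected and does
  not care.
* `n_selected_targets` (the dot size of enrichment plots) always means
  "targets with FDR < 0.05 and logFC < 0", whatever signal the test used.

**Selected sets.** Binary tests compare a selected gene set against a
universe. From a DEA the default selection is FDR < 0.05 and downregulated
(the gain-of-function convention: extra miRNA represses its targets).
`derive_sets(..., use="pvalue")` selects on the unadjusted p-value instead;
the synthetic benchmark uses this mode because at realistic per-gene effect
sizes (repression scores of −0.1 to −1, per-gene noise SD 0.3) nothing
survives multiple-testing correction yet the target signal is plainly there
— the selection then reads "nominally downregulated genes". An empty
selection is an error, never an empty result.

**Direction.** All p-values are two-sided; the statistic's sign carries the
direction, so loss-of-function designs (targets go up) are read from the
sign rather than re-running tests.

## The twelve tests

Binary (set vs universe):

* **overlap** — gene-level hypergeometric upper tail
  `P(X ≥ a), X ~ Hypergeom(N, K, n)` with N universe genes, K targets, n
  selected, a selected targets. Statistic: Haldane-corrected (+0.5) log2
  odds ratio.
* **siteoverlap** — the same construction on binding-site units: population
  = all sites of all regulators on universe features (S), successes = the
  regulator's sites (S_m), draws = sites on selected features (S_sel),
  observed = the regulator's sites on selected features. A regulator that
  hits targets through multiple sites gets proportionally more weight.
* **woverlap** — site-level ORA correcting for 3'UTR length: under the
  null a site lands in the selected set with probability
  π = (selected UTR length)/(universe UTR length), and
  `p = P(Bin(S_m, π) ≥ a)`. With equal lengths π = n/N and the correction
  vanishes. A Wallenius noncentral hypergeometric formulation would model
  the finite-population draw more faithfully; the binomial was chosen for
  its exact reduction to the uncorrected test and closed form.

Continuous (signal-based):

* **ks / mw** — two-sample tests of target vs non-target values; KS D is
  signed by the median difference, MW reports the rank-biserial
  correlation. Exact small-sample p-values where SciPy's exact
  distributions apply.
* **modsites / modscore** — per-regulator OLS of the signal on the site
  count (resp. score) over all universe features, non-targets at 0;
  statistic = slope t with n−2 df. Using the whole universe (not just
  targets) is what makes the slope identifiable.
* **ebayes** — modscore with empirical-Bayes variance moderation: a scaled
  inverse-chi-square prior (d0, s0²) is moment-matched to the per-regulator
  residual variances on the log scale (digamma/trigamma matching, Newton
  trigamma inverse), the posterior variance is
  (d0 s0² + d s²_m)/(d0 + d) and the moderated t has d0 + d df. When the
  observed spread of variances is no larger than sampling noise the prior
  df is infinite and the common variance is used (with normal tails); with
  fewer than 10 testable regulators moderation is skipped entirely.
* **lmadd** — forward additive joint regression: candidates are walked in
  ebayes-p order; each is added to the joint OLS only if its coefficient is
  repression-consistent (positive on score) with conditional p below
  `alpha_add` (default 0.05), up to `max_terms` (default 10). Selected
  regulators report their p from the final joint model — entry-order
  conditional p-values are not exchangeable across regulators — the rest
  report the conditional p observed when tested. Candidates collinear with
  the accepted set (design condition number > 1e8) are skipped with p = 1:
  no separable additional effect. This is what disentangles same-seed
  twins: the second twin has nothing left to explain.
* **areamir** — analytic rank enrichment: signal ranks are mapped to
  normal quantiles `q_i = Φ⁻¹(rank_i/(n+1))` (average ranks on ties) and
  each regulator scores the weighted sum of its targets' quantiles,
  weights w = max(0, −score). The sum is standardised by its *exact*
  permutation moments — centred q, variance
  Σ(w−w̄)² · Σ(q−q̄)²/(n−1) — rather than the naive √Σw², so z is
  unit-variance under the null even with heavily tied signals and sparse
  weights (the naive denominator deflates z to sd ≈ 0.8 on BH-tied
  signals, which measurably over-conserves the test).
* **regmir** — lasso on the feature × regulator matrix of repression
  magnitudes (columns standardised so the penalty is scale-free), penalty
  chosen by k-fold CV (seeded folds, default 10) with the 1-SE rule;
  the surviving support is re-fit by joint OLS and tested. Empty support at
  the 1-SE penalty falls back to the CV-minimum penalty; still-empty
  support reports p = 1 throughout.
* **gsea** — the classic weighted running sum (weight exponent 1 on |s|)
  over features ranked by descending signal; ES ∈ [−1, 1] is the maximum
  deviation from zero. p-values come from seeded gene-label permutations
  with the (b+1)/(nperm+1) estimator (two-sided on |ES|), so p > 0 always.
  Gene-label permutation is the only option here — no sample-level data
  exists at this stage. Set sizes outside [5, universe/2] are untestable.

**Multiple testing.** Benjamini-Hochberg step-up over testable regulators;
untestable regulators keep their row with p = NA and are excluded from the
correction, so result tables have a stable regulator index.

## Synthetic data

The generator emulates the structure the tests assume about annotation
sources and mimic-transfection experiments, with defaults at the package's
working scale (5000 genes, 50 regulators; the validation suite uses 2000
genes to keep runs short):

* UTR lengths L_i ~ LogNormal(log 1000, 0.6) nucleotides — median ~1 kb,
  right-skewed like real 3'UTRs.
* site counts ~ Poisson(λ_m · L_i / mean L) with λ_m ~ Uniform(0.05, 0.25)
  per regulator: site counts scale with UTR length (the bias woverlap
  corrects), and target-set sizes vary across regulators.
* best site types drawn 8mer 20% / 7mer-m8 50% / 7mer-A1 30%; scores
  −(0.05 + 0.12 · sites · τ + Exp(0.05)) with τ = 1.5/1.0/0.6 by site
  type, i.e. stronger site types and more sites predict stronger
  repression.
* a perturbation shifts expected logFC by Σ_active β_m · score_mi; observed
  logFC adds N(0, noise_sd) with noise_sd = 0.3 by default, p-values are
  the exact z-test with the known SD and FDR is BH. Null p-values are
  uniform *by construction*, which is precisely what the type-I-error
  checks need.
* twin pairs copy a source regulator's records and re-draw a (1−overlap)
  fraction of its targets onto fresh features — same-seed miRNA family
  members for exercising lmadd.

Each operation draws from its own seeded RNG sub-stream
(`default_rng([seed, k])`); the DEA generator must not replay the bit
stream that decided targethood, or its noise correlates with the target
mask.

What the generator does **not** emulate: count-level mean-variance
structure (negative binomial noise, replicate estimation of dispersions),
correlated co-expression modules, indirect/downstream regulation,
annotation error (false target predictions), or miRNA-expression
measurement. Passing tests therefore demonstrate the statistics behave as
designed under their own assumptions — calibrated nulls, graceful
degradation, twin disentanglement — not that any test is well-calibrated
on real RNA-seq data, where DE p-values are themselves approximate and
targets co-vary.

## Benchmark protocol

Scrambling swaps the *entire* DE statistic row (logFC, p, FDR, mean
expression) of a random fraction of the true regulator's targets with as
many random non-targets — feature ids stay in place, so every marginal
distribution is preserved exactly and only the target/statistic linkage is
destroyed. Each run records the rank of the true regulator (p ascending;
ties broken by |enrichment|, then |statistic|, then id), whether it passed
FDR < 0.05, and the number of other regulators that did. Empirical FDR is
averaged per run as FP/(FP+TP) with 0/0 → 0 (a pooled variant is
available); a family map makes any same-family member count as a true
positive, since family-level annotations cannot distinguish members.

## Numerical choices

* p-values are floored at 1e−300 (perfect fits would otherwise underflow
  to 0) and never exceed 1.
* Haldane's +0.5 in every odds ratio keeps log-odds finite at empty cells.
* background restriction to the top-N expressed genes breaks boundary ties
  by feature id, so runs are reproducible across pandas versions.
* duplicate DEA rows keep the smallest FDR (the most informative
  measurement); duplicate collection rows merge as above.
* the GSEA running-sum extrema are evaluated only at target positions
  (maxima at hits, minima just before hits or at the end), making
  permutation scoring O(K log K) per permutation instead of O(N).
* lmadd's forward pass stops *accepting* after `max_terms` but still
  reports conditional p-values for the remaining candidates.
* every stochastic component (GSEA permutations, regmir CV folds,
  simulation, scrambling) is driven by an explicit seed; reruns are
  byte-identical.

## Validation problem sizes

The test suite validates calibration with 2000 pooled null replicates
(2000 genes × 50 regulators; 20 independent collections), rank recovery
and twin disentanglement over 100 seeds, and scrambling monotonicity over
20 seeds × 5 fractions × all 12 tests. `scripts/acceptance.py` recomputes
the same quantities at reduced sizes (400 null replicates, 50 seeds, 10
benchmark seeds) chosen to finish in a few minutes on one CPU.

## Known limitations

* The binomial form of woverlap ignores the finite-population correction;
  for selected sets approaching the whole universe it is slightly
  conservative.
* siteoverlap treats site units as exchangeable across genes; when sites
  cluster heavily on few genes its null is mildly over-dispersed relative
  to the hypergeometric (measured type-I error stays within [0.03, 0.07]
  under the generator's site distributions).
* GSEA p-values are bounded below by 1/(nperm+1); ranking among
  floor-tied regulators falls back to |ES|.
* regmir's selection (hence its p-values) is post-selection inference
  without correction; its p-values are best read as ranking scores, as in
  the original regularised-regression approaches.
* With very small universes (tens of genes) the normal-quantile transform
  of areamir is coarse; the test is restricted to n ≥ 10.
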