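# Methods

## The statistic

For a group of `N` biallelic SNVs, CAPS compares the observed number of
singletons `S` (allele count 1) with the number expected under neutrality,
`E = Σ_c n_c p_ref(c)`, where the sum runs over the group's trinucleotide
context classes and `p_ref(c)` is the singleton proportion of class `c` in a
near-neutral reference set:

```
CAPS = (S − E) / N
```

Positive values mean a singleton excess, i.e. stronger negative selection
and hence higher average deleteriousness. The estimator is linear in the
per-variant terms `(1[singleton] − p_ref(c))`, which gives two exact
algebraic properties the tests rely on: the statistic of the reference set
against its own model is 0, and any partition of a table recomposes exactly
(`Σ_k (N_k/N)·CAPS_k = CAPS`).

**Uncertainty.** `S ~ Binomial(N, p)` with `p̂ = S/N`; `SE = sqrt(p̂(1−p̂)/N)`
and the 95% interval is `CAPS ± z·SE`. The reference expectation `E` is
treated as fixed: the model assumes a reference set orders of magnitude
larger than any query group, so reference sampling noise is ignored. This is
the convention of the proportion-of-singletons literature; its adequacy at
our problem sizes is checked empirically (null CI coverage, criterion
below). For small groups or `p̂` near 0/1 the normal interval degenerates
(`SE = 0` at `p̂ ∈ {0,1}`, logged with a warning) and a Wilson interval is
available via `ci_method="wilson"`; it is computed on the `p` scale and
shifted by `−E/N`.

**Context classes.** Substitutions are strand-collapsed so the middle base
is a pyrimidine: 32 trinucleotides × 3 alternates = 96 classes. The four CpG
C>T classes are split by ordinal methylation level 0/1/2 (CpG transition
rates are strongly methylation-dependent), replacing 4 classes with 12 — 8
additional classes, 104 total. Only CpG C>T carries a methylation level;
levels supplied for other classes are ignored. Contexts containing
ambiguous bases are unassignable: callers choose between a hard error and
dropping with a logged count. Contexts absent from the reference model are a
hard error when queried — silently dropping them would bias the statistic.

**Simplified MAPS.** For comparison, `compute_maps` replaces the per-context
expectation with fitted values from a least-squares regression of reference
`p_ref(c)` on `log10 μ_c` (mutability), weighted by reference counts, with
fitted proportions clipped to [0, 1]. The log-linear form is the
conventional choice; the full mutation-rate machinery behind
population-database constraint models is out of scope — the mutability table
is an input. When the regression is saturated (as many distinct mutability
values as parameters) it interpolates the per-context proportions and MAPS
reduces to CAPS exactly; the tests exercise this and the degenerate
(constant-mutability) error.

## QC and annotation conventions

* Site QC keeps variants with no filter flags, callable fraction ≥ 0.8 and
  coverage ≥ 30. Both rules are strict on the removal side (29.5 removed,
  30.0 kept; 0.79 removed, 0.80 kept). `callable_fraction` is consumed as a
  precomputed per-variant fraction (calls ÷ potential carriers, with the
  chrY male-carrier denominator handled upstream), keeping QC a pure row
  filter. QC is idempotent and monotone in its thresholds.
* Score annotation takes, per variant and tool, the most deleterious value
  over all transcript rows — the orientation-aware extreme (min for
  lower-is-deleterious tools such as SIFT, max otherwise). Scores outside a
  tool's registered valid range become missing rather than being clamped,
  to avoid manufacturing evidence; out-of-range counts are logged.
* ClinVar review-status phrases map deterministically onto 0–3 stars:
  expert-panel review (and practice guidelines) → 3; multiple concordant
  submitters with criteria → 2; a single submitter with criteria → 1;
  everything else, including conflicting interpretations and unknown
  phrases, → 0 (conservative default, logged when unknown).
* Coordinates are 1-based fully closed; the TSV dialect is the primary
  format, with a minimal biallelic-SNV VCF dialect (INFO keys AC, CONTEXT,
  COV, CALLF, optional MET/CSQ) read through pysam.

## Benchmarking analyses

* **Threshold filters.** A filter is `tool comparator threshold`; the
  comparator must point to the tool's deleterious side, and variants with a
  missing score fail the filter (threshold filters are evidence gates).
  *Chaining* applies filters sequentially, reporting CAPS after each step;
  counts are non-increasing and an emptying step truncates the chain.
* **Top-fraction curves.** Variants are ranked orientation-aware; the top
  group at fraction `f` holds exactly `⌈f·N/100⌉` variants, ties broken by
  stable input order. The default grid halves from 100% down to ~1.6%,
  bracketing the few-percent regime where well-calibrated predictors keep
  differentiating. For multi-tool comparison the table is first reduced to
  complete cases (no missing score for any compared tool), because some
  tools score only variants they deem deleterious and per-tool missingness
  would otherwise change the variant set between curves.
* **Pairwise grids and the key annotation.** All 1- and 2-filter
  conjunctions are evaluated (pairs are unordered; empty cells are marked,
  not errors). The *key annotation* is the filter with the highest
  single-filter CAPS provided every pair containing it has a confidence
  interval overlapping its own — adding any other filter neither raises nor
  dilutes the signal. CI overlap is plain interval intersection with no
  multiple-testing adjustment.
* **ClinVar stratification and label calibration.** CAPS is computed per
  (significance class × star tier) cell, optionally folding "likely" classes
  into their parents; the cells partition the labelled set, so the weighted
  cell values recompose the overall labelled-set CAPS exactly. Label
  calibration computes CAPS of the set passing each tool's own labelled
  threshold ("Damaging", "Disease causing", …) so the report can contrast
  the words with the measured average deleteriousness.

## The synthetic cohort generator

The generator emulates a QC-annotated exome cohort with known ground truth;
it exists so that every pipeline stage has an oracle, not to be
demographically realistic.

* **Selection model.** Each variant draws a context `c` and a mixture
  component with selection strength `s ∈ [0,1]`; its singleton probability
  is `p = p_neutral(c) + s·(1 − p_neutral(c))`. Selection acting
  multiplicatively on the non-singleton mass makes the designed CAPS of any
  (component, context)-marginal group available in closed form:
  `Σ_c f'_c Σ_k w'_k s_k (1 − p_neutral(c))` (`expected_caps`). Predicates
  on realized noise have no closed form and are rejected; the emitted truth
  table supports Monte-Carlo checks instead. The default mixture is 50%
  neutral, 30% moderate (`s = 0.3`), 20% extreme (`s = 0.8`).
* **Context space.** All 104 classes, with frequencies from a Dirichlet(5)
  draw at a fixed internal seed — abundances vary severalfold, as exome
  context counts do, while every class stays well-populated in any cohort
  large enough to build a reference model from. Neutral singleton
  proportions are uniform in [0.30, 0.60], with methylated CpG C>T classes
  shifted downward (more methylation → more recurrent mutation → fewer
  singletons). A two-context `toy_params` preset supports hand-checkable
  tests.
* **Scores.** `score = clamp01(s + Normal(0, σ))`, inverted for
  lower-is-deleterious tools and mapped affinely onto each tool's range.
  The default tool set spans the fidelity range seen in practice (REVEL-
  and CADD-like tools least noisy) and includes a MutPred-like tool that
  returns no score below a latent floor, inducing the complete-case
  reduction a real multi-tool comparison faces. Because the maps are
  affine, the conventional published thresholds (SIFT < 0.05 / < 0.49,
  PolyPhen > 0.8 / > 0.022, CADD > 20 / > 10.37) land directly on the
  synthetic score scales.
* **ClinVar labels.** A labelled fraction of study variants gets a true
  class from thresholds on `s`, a star tier from a categorical draw, and
  star-tier-dependent misclassification (worst at 0 stars). An optional
  switch makes half of the 3-star uncertain-grade variants carry a "benign"
  label, the scenario in which expert-panel benign calls are
  indistinguishable from VUSs.
* **QC fields and allele counts.** Flags, low coverage and low callable
  fraction are independent Bernoulli events (defaults 3%/5%/3%), so QC does
  not perturb designed CAPS values. Non-singleton allele counts are
  `1 + Geometric(0.3)`; only the singleton indicator matters to the
  statistic, the tail is cosmetic. The reference table is the same model
  with `s = 0` throughout and synonymous consequence — the conventional
  near-neutral reference class.
* **Determinism.** One integer seed fixes the full output bit-exactly;
  reference and study use independently spawned RNG streams, so study
  replicates can be drawn without regenerating the reference.
* **Mutability.** `generate_mutability_table` inverts
  `p_neutral = 0.8 − 0.1·log10 μ` (optionally with Gaussian scatter on the
  log rate), so a reference whose proportions sit exactly on that line
  makes the MAPS regression exact; a sampled reference adds noise, and the
  MAPS/CAPS agreement is then checked statistically (3·SE on null groups).

### What the synthetic data does not emulate

No demographic structure, growth, or depth-dependent site-frequency
spectra; no sequence-level simulation of genomic trinucleotide runs; score
distributions are unimodal noise around a one-dimensional latent rather
than the multimodal, feature-driven distributions of real predictors; and
ClinVar label noise is independent across variants. Passing tests therefore
demonstrate the estimator's and the analyses' correctness and calibration
under a controlled selection model — not predictor performance on real
cohort data.

## Problem sizes and numerical choices

Test and acceptance simulations use reference cohorts of 10⁵–2×10⁵ variants
and study cohorts of 2–5×10⁴, with 40–100 seeded replicates for the
stochastic claims; at these sizes per-context reference proportions are
tight enough that treating `E` as fixed is harmless (shared bias ≲ 0.002
versus group SEs ≥ 0.003). Exact claims (self-reference zero, partition
additivity, saturated MAPS = CAPS, oracle equivalence) are asserted at
1e-12. Ranking ties in top-fraction selection are broken by stable input
order, making every selection deterministic; an include-all-ties variant
was considered and rejected to keep counts exactly `⌈f·N/100⌉`.

## Known limitations

* CAPS measures average negative selection; weakly selected pathogenic
  variation (late-onset or complex disease) is poorly captured by design.
* The CI treats the reference expectation as fixed; with small reference
  sets the intervals are anticonservative (use a larger reference or the
  Wilson option as partial mitigation).
* The simplified MAPS regression is a two-parameter log-linear fit, not the
  full mutation-rate model used by population databases.
* The grid analysis covers 1- and 2-filter combinations only; higher-order
  exhaustive grids are out of scope.
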