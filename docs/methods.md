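# Methods

## Data model

A cohort is a subjects × markers table: case/control status (1/0), a
population label, an optional matched-pair id, and unphased genotypes at
biallelic SNPs stored as unordered allele pairs (`AC` ≡ `CA`; the
canonical form is alphabetical). Each marker declares its two alleles and
an a-priori **risk allele**; nothing in the pipeline estimates which
allele is deleterious. Missing genotypes are allowed and excluded
per-marker (tabulation) or per-pool (burden counting) with a logged
count, although the reference fixture has a 100% call rate.

Two study designs are supported per population: `unconditional`
(unmatched controls) and `matched_pairs` (1:1 case-control pairs sharing
a `pair_id`). Matching covariates themselves (sex, age, family history)
are deliberately not modelled — the pair id is the only trace of the
matching, which is how the matched analysis consumes it.

## Inheritance-model coding and selection

Only the dominant and recessive codings are implemented: with a fixed
risk allele they reduce the three genotype classes to a binary exposure
(carrier / homozygous-risk carrier). Codominant, additive and
overdominant models are out of scope by design; restricting to two models
keeps the multiple-testing burden at m = 2 per marker.

Both fits are run per marker and population and one is selected:

- `lowest_p` (default): the model with the smaller nominal P, ties broken
  by the larger OR;
- `max_or`: the model whose estimated OR for the risk allele is larger.

Both criteria appear in the applied literature for this workflow and they
can disagree on null-ish markers (a protective-direction recessive fit
can have the lower P while the dominant fit has the larger risk
estimate), so the criterion is a configuration switch rather than a
constant. Markers whose fits are degenerate under both models are
excluded from downstream pools and logged.

## Regression and inference

**Unconditional samples.** Maximum-likelihood logistic regression of
status on the (binary or integer) covariate, delegated to
`statsmodels.Logit` (Newton, gradient tolerance 1e-10, ≤ 50 iterations).
For a single binary covariate the MLE equals the 2×2 cross-product ratio,
which the test suite asserts to ≤ 1e-6 relative error.

**Matched pairs.** The conditional likelihood of a 1:1 pair depends only
on the within-pair covariate difference dᵢ: ℓ(β) = Σᵢ log σ(β·dᵢ).
Concordant pairs (dᵢ = 0) drop out. The in-package implementation runs a
one-dimensional Newton iteration (gradient ∞-norm ≤ 1e-10, ≤ 50 steps) on
the informative pairs, with SE from the observed information; this
supports integer covariates (the cumulative test) as well as binary ones,
where it reduces to β̂ = log(n₁₀/n₀₁), SE = √(1/n₁₀ + 1/n₀₁). The suite
cross-checks it against `statsmodels` `ConditionalLogit` on random integer
data.

**Inference convention.** Wald throughout: 95% CI exp(β̂ ± z₀.₉₇₅·SE)
with the exact normal quantile, two-sided Wald P. This matches the
OR-(95% CI) reporting convention of the reference study; the one nominal
P recomputable from its printed counts agrees with the Wald value.

**Degenerate data.** An empty 2×2 cell (separation) triggers the
Haldane-Anscombe 0.5 continuity correction for the reported OR/CI/P and a
`separation` flag; no discordant pairs yields an undefined (NaN), flagged
result; a constant covariate is flagged `constant_covariate` /
`constant_burden`. Flags propagate to the run log — degenerate statistics
are visible, never silent.

**Multiple testing.** Bonferroni, min(1, m·p). Defaults: m = 2 per marker
(two inheritance models, applied per population without pooling) and
m = 2 for the cumulative trend test. The pool-curve family uses
m = number of pools tested (panel size − 1). All three factors are
configurable; the reference study's printed corrections are internally
inconsistent for one population, so no single factor is asserted as
canonical.

## Quality control

**Exact HWE.** The two-sided exact test conditions on the observed allele
counts and enumerates every heterozygote count of matching parity; the P
value sums the conditional probabilities of tables no more probable than
the observed one (ties included with a 1+1e-12 relative guard).
Probabilities are normalized from log weights (lgamma), so study-sized
strata (hundreds of subjects) are safe. The asymptotic χ² test is *not*
offered: at these sample sizes it visibly disagrees with the exact value
(e.g. ≈ 0.034 vs 0.045 on the fixture's one deviating stratum), and the
exact test is the field standard for SNP QC.

**Between-population heterogeneity.** Pearson χ² on genotype-class ×
population tables via `scipy.stats.chi2_contingency` (no continuity
correction). With all markers stacked, each subject contributes one count
per marker — six markers × three classes over four populations gives
df = (18−1)(4−1) = 51. All-zero rows/columns are dropped with a warning
and df adjusts automatically.

## Cumulative burden and pool curves

Per subject, k = Σ over the pool of the selected-model risk-genotype
indicators; k is undefined (subject excluded, logged) if any pool
genotype is missing. The **trend test** regresses status on integer k
with the design-appropriate likelihood.

Markers are ordered by ascending nominal P of the selected model (ties:
descending OR, then marker id — the ordering is deterministic). For each
prefix pool of size 2…panel size, the **pool curve** gives, per burden
class k, the OR against an expected 1:1 case:control split of the same
class total: the constructed 2×2 table is [a, b; n/2, n/2] with
n = a + b, so OR = a/b and the Woolf log-OR variance is
1/a + 1/b + 2/n + 2/n. Odd totals keep n/2 as a real number — the
reference row is a mathematical construct, not an observed count. When
a = 0 or b = 0 the OR is reported as undefined (NaN), not infinite; the
reference study itself hit this case (no case noncarriers in one sample).
This 1:1 reference sacrifices power for cross-population comparability
and is conservative; the CI formula is isolated in `or_vs_expected` so an
alternative (e.g. noncarrier-referenced) could be swapped in.

Curves default to exact-k classes (`exact_k`); `at_least_k` aggregates
running tail sums, matching the "k or more risk markers" convention some
reports use. The tail-sum identity is property-tested.

## Synthetic cohorts

**Model-based.** Controls' source population is at Hardy-Weinberg
proportions (p², 2pq, q²) per marker, markers in linkage equilibrium;
status follows logit P(case) = α + Σⱼ βⱼ·gⱼ with gⱼ the true-model risk
indicator. Case-control ascertainment is retrospective: the population is
oversampled in seeded batches and thinned by status until the requested
counts are reached (hard error after a bounded number of batches if the
disease model is degenerate). Defaults: α = 0 — the OR is invariant to
case-control ascertainment, so the baseline is a nuisance, and a balanced
prevalence makes sampling efficient. Matched pairs are generated by
pairing the i-th case with the i-th control of the same population
(pairing is exchangeable because matching covariates are not modelled).
Everything is bit-reproducible for a fixed seed.

What the generator does **not** emulate: linkage disequilibrium between
markers (two fixture SNPs share a chromosome arm, but no LD information
is published), population admixture, genotyping error, and real matching
covariates. Passing calibration tests therefore shows the statistics are
correct under the stated model, not that real cohorts satisfy that model.

**Margin-exact.** Given a genotype count table, each (population, status,
marker) stratum gets exactly the printed class counts; the joint
distribution across markers is an independent seeded permutation per
marker, because count margins constrain nothing else. Consequently
single-marker statistics recomputed from a reconstruction are exact
functions of the margins (seed-invariant), while burden-level statistics
(trend test, pool curves) vary with the seed and are *not* comparable to
the study's own individual-level results — the published peak pool-curve
ORs and cumulative P values are unrecoverable from margins and are
nowhere asserted.

## Calibration results the suite computes

With the default generator settings the acceptance tests verify, at the
stated sizes: empirical type-I error of the cumulative trend test within
[0.03, 0.07] at α = 0.05 (1000 replicates of six null study-like markers,
250+250 subjects); 95% Wald CI coverage within [0.93, 0.97] and mean OR
within [1.9, 2.1] for a dominant OR = 2 marker at 250+250 (500
replicates; the small upward mean bias is the usual Jensen effect on
exp(β̂)); and recessive-model recovery in ≥ 90% of replicates for a
simulated recessive OR = 2.5 at 1000+1000 (100 replicates). Replicate
counts follow the property being measured; they keep the default test run
well inside a normal CI budget.

## Known limitations

- No covariate adjustment beyond the matching structure; no additive or
  codominant models; no trend test on allele dosage.
- Pool search is restricted to P-ordered prefixes — no subset search, no
  interaction terms.
- The Wald CI undercovers for very sparse cells; the continuity-corrected
  fallback is flagged so downstream users can filter.
- Population labels are free strings; the packaged design map only covers
  the reference fixture's four populations.
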