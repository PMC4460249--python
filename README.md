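# snpburden

Case-control SNP association and cumulative risk-genotype burden analysis
for multi-population panels of low-penetrance markers.

## The problem

Individually, low-penetrance cancer-risk SNPs found by GWAS carry odds
ratios too small (OR ≈ 1.1–2) to be clinically useful. A natural question
is whether *compound carriers* — subjects accumulating risk genotypes at
several such markers — form an identifiable high-risk group. `snpburden`
implements the complete analysis for that question on unmatched or 1:1
matched case-control samples from one or more populations:

- **Per-marker inheritance-model selection.** Each biallelic marker has an
  a-priori risk allele; the genotype is coded as a binary risk-genotype
  indicator under a *dominant* (≥ 1 risk allele) or *recessive*
  (homozygous risk) model, and the better-suiting model is selected per
  marker and population (lowest nominal P by default, maximal estimated
  risk as an alternative).
- **Single-marker association.** Unconditional logistic regression for
  unmatched samples; the conditional likelihood for 1:1 matched pairs
  (which, for a binary exposure, reduces to the discordant-pair ratio
  OR = n₁₀/n₀₁). Wald 95% CIs and two-sided P values, Bonferroni-corrected
  for the two inheritance models tested.
- **Quality control.** Two-sided *exact* Hardy-Weinberg tests per stratum
  (conditional enumeration over heterozygote counts, log-space), and
  Pearson χ² heterogeneity of genotype distributions between populations
  (all markers stacked — e.g. 18 genotype classes × 4 populations,
  df = 51 — or per marker).
- **Cumulative burden test.** Logistic regression of case status on the
  integer count k of carried risk genotypes (the "linear cumulative
  model"), unconditional or matched-pair conditional.
- **Compound-carrier OR curves.** Markers are sorted by ascending P; for
  every prefix pool the OR of each burden class k is computed against an
  expected 1:1 case:control split of the same class total — so OR(k) =
  n_cases(k)/n_controls(k), with Woolf-type CIs — keeping curves
  comparable across populations and pool sizes.
- **Synthetic cohorts.** A seeded generator producing (a) model-based
  cohorts with known truth — genotypes at Hardy-Weinberg proportions,
  status from logit P(case) = α + Σ βⱼ gⱼ, retrospective case-control
  sampling — and (b) margin-exact reconstructions of a published genotype
  count table, for fixture-driven tests.

The package ships the published genotype counts of a four-population
colorectal-cancer study (Estonia 166/166, Latvia 81/81, Lithuania 123/123,
Poland 795/795 cases/controls; six GWAS risk SNPs) as its reference
fixture.

## Worked example

```python
import snpburden as sb

counts = sb.load_fixture()                      # published genotype counts
cohort = sb.margin_exact_cohort(counts, rng_seed=7, design=sb.STUDY_DESIGN)

res = sb.fit_marker(cohort, "Lithuania", "rs3802842", sb.InheritanceModel.DOMINANT)
hwe = sb.hwe_exact_test(counts.counts("Lithuania", 1, "rs4464148"))
chi2, df, p = sb.heterogeneity_chisq(counts, status=0)

sel = sb.analyze_population(cohort, "Lithuania")
order = sb.order_markers(sel)
models = {m: r.model for m, r in sel.items()}
prof = sb.count_risk_genotypes(cohort.subset("Lithuania"), models, order)
trend = sb.cumulative_trend_test(prof, "unconditional", "Lithuania")
```

prints (via the obvious f-strings):

```
rs3802842 (Lithuania, dominant): OR=1.93 95% CI (1.16-3.20) P=0.011, corrected P=0.022
exact HWE, Lithuanian cases, rs4464148: P=0.045
between-country heterogeneity (controls): chi2=31.7, df=51, P=0.98
Lithuanian markers by ascending P: rs4939827, rs3802842, rs4779584, rs4464148, rs6983267, rs10795668
cumulative trend (Lithuania): OR per risk genotype=1.60, P=0.00031
```

That is: Lithuanian carriers of the rs3802842 C allele have 1.93× the
odds of being a case (significant after correcting for the two models
tested); Lithuanian cases deviate from Hardy-Weinberg at rs4464148
(P = 0.045) — not unexpected in an ascertained case group; genotype
distributions are homogeneous across the four countries (df = 51,
P = 0.98); and each additional risk genotype multiplies the estimated
disease odds by 1.60 in the Lithuanian sample. Note the cumulative trend
and marker ordering are computed from a *reconstructed* individual-level
cohort whose joint genotype distribution is a seeded permutation
consistent with the published margins — single-marker statistics are
exact functions of the margins, burden-level statistics are not (see
`docs/methods.md`).

## Command line

```sh
snpburden run --input fixture --seed 7 --out report/        # full pipeline
snpburden run --input cohort.tsv --panel panel.tsv \
              --design "Estonia=matched_pairs,Latvia=unconditional" --out report/
snpburden simulate --spec spec.yaml --seed 1 --out cohort.tsv
snpburden calibrate --spec spec.yaml --replicates 1000 --seed 1 --out calib.csv
snpburden fixture --out counts.csv                          # dump packaged counts
```

`run` writes `genotype_counts.csv`, `hwe.csv`, `heterogeneity.csv`,
`single_marker.csv`, `cumulative.csv`, `pool_curves.csv` and
`run_log.txt`, deterministically for a given input and seed.

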