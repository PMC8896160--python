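# Methods

## The factorial decomposition

The experiment crosses two factors: condition (reference vs stress) and
genotype (wild type vs sRNA deletion). With reference levels fixed at
(reference condition, deletion genotype), the log2-scale linear predictor
of the count model is

```
log2 mu = beta0 + beta1*[stress] + beta2*[wildtype] + beta3*[stress]*[wildtype]
```

Four group contrasts follow by linear algebra, never by refitting:

| contrast | meaning | value |
|---|---|---|
| wt stress response | stress vs reference, wild type | `beta1 + beta3` |
| deletion stress response | stress vs reference, deletion | `beta1` |
| genotype at stress | wt vs deletion, stress | `beta2 + beta3` |
| genotype at reference | wt vs deletion, reference | `beta2` |

`beta3` is the interaction: the part of the stress response present only
when the sRNA is present. It captures both direct regulation of a target
and indirect effects routed through the sRNA's interactions with other
regulators — the model cannot separate those two. The contribution
fraction is computed on the log2 scale, `beta3 / log2FC_wt`; a linear-scale
ratio would not decompose additively. Fractions are reported only when
`|log2FC_wt| >= epsilon` (default 0.1 log2 units) and are deliberately not
clamped to [0, 1]: when `beta1` and `beta3` act in opposite directions the
fraction exceeds 1 and the gene is categorised `opposing`, which is a
biologically meaningful configuration (the sRNA overriding other
regulators), not an artifact.

## Count model and estimation

Counts are negative binomial, `Var = mu + alpha*mu^2`, fitted per gene by
IRLS on the natural-log scale with `log(s_j)` offsets; reported
coefficients are divided by `ln 2`. Size factors are median-of-ratios over
the genes with all-positive counts, with linear-scale ratios and
midpoint-interpolated medians for determinism. Convergence is declared at
a relative coefficient change below 1e-8 (at most 100 iterations); the
covariance is the inverse Fisher information at the optimum. When a
factor combination has no counts at all the corresponding coefficient
separates; it is clamped at ±30 log2 units (a 2^30-fold change) and
flagged rather than allowed to diverge, so downstream arithmetic stays
finite.

Dispersion handling is a deliberately compact empirical-Bayes scheme:

1. per-gene profile maximum likelihood over `log alpha` in
   `[log 1e-8, log 10]` (bounded scalar search, tolerance 1e-6; the
   coefficients are re-fit at every candidate);
2. a nonnegative least-squares fit of the trend `alpha ~ a1/mu + a0`
   across genes with mean normalized count above 5, iterated twice with
   exclusion of genes more than two decades off the trend; with fewer than
   50 usable genes the trend degenerates to the constant
   `median(alpha)`;
3. the prior variance of `log alpha` around the trend is the residual
   variance minus 0.5 (a proxy for estimation noise), floored at 0.25;
4. a maximum a posteriori re-estimate per gene under a normal prior on
   `log alpha` centred at the trend.

The MAP dispersion is used for the final coefficient fit and for both
tests. Estimates within half a log-unit of a search bound are flagged as
boundary values but retained.

Wald z-tests cover the two condition contrasts; the interaction is tested
by a likelihood ratio test against the model without the interaction
column, both fits sharing the full model's MAP dispersion (this keeps the
statistic nonnegative and is the common convention for reduced-model
tests), with a chi-square(1) reference. Benjamini–Hochberg correction is
applied separately within each test family across all tested genes; genes
that are all-zero, below 1 mean normalized count (`low_count`), or
non-converged are excluded from the families and carry NaN adjusted
p-values. There is no independent filtering, no outlier replacement and
no fold-change shrinkage: these are refinements of other pipelines that
this package omits for transparency, so estimates are plain MLEs given the
moderated dispersion.

## Enrichment

Operon propagation marks every gene that shares an `operon_id` with a
direct target as `operon_with_target` (direct targets keep their own
label; the labels are disjoint). Four planned one-sided hypergeometric
tests are reported with raw p-values: targets and operon partners among
the condition-significant genes (population: all tested genes), and
targets and operon partners among the interaction-significant genes, where
the population is the condition-significant set — the interaction can only
be resolved for genes whose level changed at all, so the genome-wide
population would overstate the enrichment base. Tail probabilities are
accumulated in log space, so p-values of order 1e-300 are still exact.

## Synthetic data

The generator emulates the structure of a 13-library bacterial stress
experiment. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| genes / targets / operon partners | 4377 / 195 / 56 | study-scale structure; targets + partners = 251 operon-covered genes |
| replicates | 4/3/3/3 | 13 libraries over 4 groups |
| baseline `q` | lognormal, ln-scale N(5, 1.5) | median ≈ 150 counts, realistic bulk RNA-seq spread |
| `beta1` | N(0, 1.5) for an 8% responsive fraction | a minority of genes respond to the condition, with occasional large effects |
| `beta2` | N(0, 0.5) for a 2% fraction | deleting a single sRNA rarely changes baseline expression |
| target `beta3` | magnitude N(1.5, 0.5); 80% repression | matches the observed predominance of repression and the magnitude range of significant interaction effects |
| dispersion | `(0.01 + 2/q) * lognormal(sd 0.3)` | standard trended overdispersion with gene-level scatter |
| size factors | lognormal, log-sd 0.2 | moderate depth variation |

Operon partners inherit their co-transcribed target's `beta3` exactly,
mirroring how polycistronic degradation propagates an sRNA's effect. The
deleted sRNA itself is simulated as a designated gene (`srna`): strongly
induced by stress in the wild type, exactly zero in every deletion
library. It is excluded from fitting by default (`FitConfig.exclude_genes`)
since a gene absent in half the libraries carries no information about the
factorial coefficients.

What the generator does **not** emulate: correlated counts within operons
beyond the shared effect size, compositional distortion when a large
fraction of the transcriptome shifts, batch effects, gene-length bias, and
any mechanistic transcription-factor dynamics. Passing recovery tests
therefore show that the estimator is correct *under its own model
assumptions*, not that those assumptions hold for any particular real
dataset.

## Numerical and design choices

* All fitting is deterministic given the input; the only randomness in the
  package is the generator's seeded stream.
* `mu` is clipped to `[1e-10, 1e14]` inside IRLS to keep weights finite
  during early iterations.
* Problem sizes in the test suite — a 400-gene panel for unit tests, 2000
  genes × 40 libraries for the calibration checks, the full 4377 × 13
  scenario once for the end-to-end run — were chosen so the estimator's
  bias, type-I error and false-rejection properties are measured with
  usefully small Monte Carlo error while the suite stays quick to run.
* The condition-responsive fraction, effect and dispersion defaults above
  are the generator's definition of a realistic experiment; they are not
  adjusted per test.

## Limitations

* Only 2×2 designs with 0/1 encodings are supported; no continuous
  covariates, batch terms or >2 factor levels.
* The chi-square reference for the LRT is asymptotic; at 3–4 replicates
  per group it is mildly anticonservative, which is why the calibration
  checks run at 10 replicates per group and the study-scale check only
  bounds the null rejection rate rather than asserting exact nominal size.
* Wald intervals at small replication undercover slightly (≈0.87–0.90
  observed at 13 libraries for 95% intervals), a known small-sample
  property of GLM standard errors combined with dispersion shrinkage.
* The contribution fraction is undefined for genes whose total change is
  below `epsilon`, by construction: a share of nothing is meaningless.
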