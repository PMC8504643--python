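# Methods

## Model

Counts for gene *i* in cell *c* of subject *j*, within one cell type, follow
a three-stage hierarchy:

1. **Subject stage.** θᵢⱼ ~ Gamma(shape αᵢ⁻¹, scale qᵢⱼ αᵢ), so E θᵢⱼ = qᵢⱼ
   and CV²(θᵢⱼ) = αᵢ. The regression log qᵢⱼ = Σᵣ xⱼᵣ βᵢᵣ carries the
   systematic (group) effects; αᵢ — the *subject-level variance* — is the
   residual between-subject dispersion of gene *i*'s relative expression.
2. **Cell stage.** λᵢⱼ꜀ | θᵢⱼ ~ Gamma(shape σᵢⱼ⁻², scale θᵢⱼ σᵢⱼ²):
   cell-to-cell variation around the subject's level, with squared CV σᵢⱼ²
   (the *cell-level variance*), free to differ between genes and subjects.
3. **Sampling stage.** Kᵢⱼ꜀ | λᵢⱼ꜀ ~ Poisson(sⱼ꜀ λᵢⱼ꜀), where the size
   factor sⱼ꜀ is the cell's total UMI count.

αᵢ = 0 or σᵢⱼ² = 0 are implemented as point masses at the stage mean (the
shape → ∞ limit), so the Poisson and plain negative-binomial models are
exact special cases rather than numerical edge cases.

For the aggregated counts Kᵢⱼ = Σ꜀ Kᵢⱼ꜀ and sⱼ = Σ꜀ sⱼ꜀, iterating the laws
of total mean and variance gives E Kᵢⱼ = μᵢⱼ = sⱼ qᵢⱼ and

    Var Kᵢⱼ = sⱼ² qᵢⱼ² αᵢ + σᵢⱼ² (1+αᵢ) qᵢⱼ² Σ꜀ sⱼ꜀² + sⱼ qᵢⱼ.

Since Σ꜀ sⱼ꜀² / sⱼ² → 0 as cells per subject grow, the middle (cell-level)
term is asymptotically negligible and Kᵢⱼ is approximately negative binomial
with variance μᵢⱼ + αᵢ μᵢⱼ². This is the justification for the *subject*
method: analyze pseudobulk counts with a bulk-style NB GLM, subjects as
units. `simulate.theoretical_moments` exposes the exact finite-cell formula
and is used as the oracle for every simulator test.

## The subject method

Per gene: NB GLM with log link and offset log sⱼ, fitted by IRLS (deviance
tolerance 10⁻⁸, ≤ 100 iterations, deterministic start at the intercept-only
closed form; linear predictors capped at ±50, genes hitting the cap are
flagged non-converged and excluded from testing). Standard errors come from
the expected Fisher information X'WX with W = μ/(1+αμ). The Wald statistic
β̂ᵢ₂/SE is referred to the standard normal, two-sided; P-values are BH
step-up adjusted over the tested genes (genes with zero counts in all
subjects are removed first; no other independent filtering). Log fold
changes are reported in base 2.

**Dispersion.** Gene-wise estimation alone is the weak point with typical
subject counts (here 4 + 3): maximum likelihood in αᵢ, even with means held
at the fitted values, has large downward noise and bias at 5 residual
degrees of freedom, and the genes whose αᵢ is underestimated dominate the
discovery list — measured on this package's own generator at the default
study conditions, the empirical FDR at BH 0.05 was ≈ 0.22 with plain ML and
≈ 0.15 with the Cox–Reid adjustment alone. The estimator therefore follows
the standard small-sample treatment for NB GLMs: (i) method-of-moments
initialization from Poisson-fit residuals; (ii) per-gene maximization of the
Cox–Reid-adjusted likelihood (penalty −½ log det X'WX), refreshing fitted
means twice; (iii) empirical-Bayes moderation — a trend α(μ) = a₀ + a₁/μ is
fitted across genes by trimmed least squares (median fallback), the prior
width is the MAD of log residuals in excess of the estimator's sampling
variance (trigamma((n−p)/2), floored at 0.25), and each gene's final value
maximizes the penalized likelihood; genes more than 2 MADs *above* the trend
keep their gene-wise estimate so genuinely hypervariable genes are not
shrunk into significance. With moderation the same measurement gives
FDR ≈ 0.08. Dispersions are floored at 10⁻⁸; the floor is the exact Poisson
limit of the fitting code.

Subject size factors are sⱼ = Σ꜀ sⱼ꜀ (conservation with the model's offset);
a median-of-ratios alternative was considered and not adopted — the offsets
enter only through the intercept for the balanced designs used here, and the
summed size factor is the quantity the aggregated-count moments are stated
in.

## The wilcox baseline

The conventional cell-level recipe: entries log(1 + 10⁴·Kᵢⱼ꜀/sⱼ꜀) (natural
log; the 10⁴ scale and log1p follow the dominant single-cell toolkit
default), then a two-sided Wilcoxon rank-sum test per gene between the two
groups' pooled cells — exact enumeration when both groups have ≤ 50 cells
and no ties, otherwise the tie-corrected normal approximation with
continuity correction. No min-count or min-fraction prefilters are applied
by default so that FDR comparisons against the subject method are clean.
Its reported fold change is the difference of group means of normalized
expression (base 2).

## Permutation calibration

For n subjects split n₁/n₂, all C(n, n₁) group-label assignments are
enumerated (guarded at 20 subjects). The permutation statistic is the
method's unadjusted P-value; the permutation P-value of a gene is the
fraction of assignments (observed labeling included, so values live in
[1/C, 1] and the test is valid) whose statistic is ≤ the observed one.
Comparing empirical CDFs of method vs permutation P-values on [0, 0.2]
quantifies anti-conservativeness; the reported summary is the maximum
absolute CDF gap on that range. Mirrored assignments under equal group
sizes are kept as distinct labelings; the two-sided statistics used here are
symmetric under the swap, so this convention does not change any P-value.

## Evaluation

Detection is padj < cutoff (strict). PR and ROC curves are built on the grid
of distinct adjusted P-values ∪ {0, 1}, with a closing detect-all point so
curves always end at the full-detection corner; precision over an empty
detection set is 1 on the curve but reported as not-computable (NaN) in the
single-cutoff confusion table. AUPR uses step-wise interpolation (precision
carried from the next attained recall), avoiding the optimism of linear PR
interpolation; AUROC uses the trapezoid rule and equals the tie-corrected
Mann–Whitney concordance. Replicates are averaged vertically: precision
interpolated onto the recall grid {0, 0.01, …, 1} and averaged pointwise,
AUPR averaged as the mean of per-replicate areas. Genes filtered before
testing count as never detected but stay in the denominators.

## Synthetic data: what it emulates, what it does not

The generator's study conditions mirror the design the method was evaluated
under: two groups of 4 and 3 subjects, effect proportion pDE ∈
{0.01, 0.3, 0.6}, effect spread τ ∈ {0.5, 1.0, 1.5} (βᵢ₂ ~ N(0, τ²) on the
natural-log scale for DE genes, exactly 0 otherwise), 100 replicates at full
scale and 21 731 genes by default.

Where the original evaluation matched baseline parameters to an unpublished
tissue dataset (per-subject cell counts, per-cell UMI totals, moment-matched
αᵢ, σᵢⱼ², βᵢ₁ vectors), this package draws them once from documented
distributions chosen to be realistic for 10x-style UMI data:

- 200 cells per subject; sⱼ꜀ log-normal with mean 5000 UMIs (σ = 0.3);
- relative expression exp(βᵢ₁) ∝ LogNormal(0, 2), normalized to sum to 1
  (a long-tailed composition, like real transcriptomes);
- αᵢ ~ LogNormal(log 0.1, 1): typical between-subject squared CVs of a few
  percent to tens of percent;
- σᵢⱼ² ~ LogNormal(0, 0.5): cell-level squared CV around 1.

Consequently desk-scale results reproduce the *qualitative* orderings (FDR
control of the subject method, inflation of the cell-level baseline, AUPR /
PPV ranking, calibration agreement) but not the exact magnitudes of any
empirical-data figures. The generator also omits features of real data:
multimodal or zero-inflated expression beyond gamma–Poisson, cell-level
covariates (the stage-2 regression extension is out of scope), doublets,
ambient RNA and batch effects. Passing tests therefore demonstrate internal
consistency of the model, estimator and test — not robustness to these
violations.

Moment matching to data follows the normalized-expression recipe: with
Eᵢⱼ꜀ = Kᵢⱼ꜀/Σᵢ'Kᵢ'ⱼ꜀ and Eᵢⱼ = Σ꜀Kᵢⱼ꜀/Σᵢ'Σ꜀Kᵢ'ⱼ꜀, set α̃ᵢ = vᵢ/mᵢ² and
σ̃ᵢⱼ² = vᵢⱼ/mᵢⱼ² from ddof-1 sample moments, and exp(β̃ᵢ₁) = gene total /
grand total. Negative or undefined ratios (all-zero or constant genes) are
floored at 0 and flagged. Recovery accuracy is limited by the number of
subjects — the sample variance over n subjects has relative noise
≈ √(2/(n−1)) — hence the 40-subject setting used in the recovery check.

## Determinism and problem sizes

All randomness flows from one root seed; replicate r uses the independent
stream SeedSequence((seed, r)), so any replicate is reproducible in
isolation. The reproduction script (`scripts/acceptance.py`) and the
acceptance-style tests run the study at desk scale — 2000 genes, 200 cells
per subject, 20 replicates per grid setting, the grid restricted to
pDE ∈ {0.3, 0.6} × τ ∈ {1.0, 1.5}, 500-gene null data for calibration —
sizes chosen so the full suite completes in minutes on one CPU while keeping
binomial error on the reported rates a few percent.

## Known limitations

- Exact P-value parity with any particular bulk engine is not a goal; the
  dispersion-moderation details (trend form, prior floor, outlier rule)
  follow the standard approach but are not bit-compatible with DESeq2/edgeR.
- With very few cells for some subject, the NB approximation for that
  subject's aggregated count weakens (the σᵢⱼ² term is only asymptotically
  negligible); subjects with no cells in the selected type are dropped with
  a warning, not zero-filled.
- The Wald/normal reference is asymptotic in the number of subjects; with
  4 + 3 subjects the moderated test is near-nominal on model data (measured
  null rejection ≈ 6% at p < 0.05) but no finite-sample guarantee is made.
- Exhaustive permutation is limited to ≤ 20 subjects by design; beyond that
  a seeded Monte-Carlo subsample of assignments is the intended route.
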