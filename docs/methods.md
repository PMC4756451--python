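# Methods

This note records the statistical models implemented in `ewaskit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions made where the design
was genuinely open.

## Scales and transforms

Methylation is carried as β (proportion methylated, in [0, 1]) for
reporting and as M = log₂(β/(1−β)) for modeling, since M is closer to
homoscedastic and unbounded. β is clipped to [0.001, 0.999] before the
logit so boundary values map to finite M; the inverse is
β = 2^M/(2^M+1). Missing measurements are NaN throughout and are stripped
from every mean, variance and model fit rather than imputed (the single
exception is PCA/k-means diagnostics, where missing cells are mean-imputed
for the decomposition only).

## Quality control

**Sample identity** uses the pairwise Pearson correlation of β restricted
to the SNP genotyping (`rs`) probes, whose β is trimodal (≈0, 0.5, 1 — the
two homozygous and the heterozygous genotype). Samples sharing an
individual must be mutual nearest neighbors; anything else is flagged.
**Sex** is predicted by 2-means clustering on chrX/chrY probe β; the
cluster with higher mean chrY β is labeled male, since real Y-chromosome
signal exists only in males. **Per-sample quality** summarizes the number
of detection failures (p > 0.01), the number of low-bead measurements
(< 3 beads), and the mean detection p (a signal-confidence summary — raw
intensity does not exist at the β level, so this stands in for average
sample intensity). A sample is an outlier when any metric leaves
median ± 3·MAD across samples (scaled MAD, constant 1.4826); the rule is a
documented choice — robust, and consistent with the MAD convention used
elsewhere in the package — not a universal standard.

**Probe filtering** removes, in a fixed order so category counts are
disjoint: systemically poor probes (failure in more than 20% of samples by
detection p or bead count), sex-chromosome probes, polymorphic probes and
probes cross-hybridizing to the sex chromosomes. Remaining individually
failed cells are masked to NaN. Of each technical replicate pair the first
sample in sheet order is kept (deterministic); pair correlations are
recorded at every pipeline stage where the handler is invoked.

## Batch adjustment

The model is the parametric empirical-Bayes location/scale formulation:
per probe g and batch i, standardized residuals get a batch location γ_gi
(normal prior across probes) and scale δ_gi (inverse-gamma prior, moment
matched), estimated per batch, shrunk toward the priors by the standard
iterative posterior equations, and removed. Protected covariates —
status, sex and gestational age by default — enter the standardization
design so biology confounded with batch is not scrubbed; this default is a
deliberate choice (the design matrix used in the original studies of this
kind is rarely reported) and is switchable. Missing cells are excluded
from every estimate; a probe with fewer than two observed values in any
batch level must be removed first (`drop_underrepresented`), mirroring
standard practice. Successive rounds run over plate, then chip row, then
chip id — coarsest technical layer first; the operation is not
commutative and the order is recorded. With a single batch level the
input is returned unchanged. The implementation is cross-checked in the
test suite against the Bioconductor reference implementation on a complete
toy (agreement ≈ 1e-5, limited by the iteration tolerance).

## Differential methylation

Per probe, OLS of M on status (control as reference), sex (F = 0, M = 1)
and gestational age in weeks. Residual variances are optionally (default
on) shrunk by empirical Bayes: a scaled inverse chi-square prior (d₀,
s₀²) is fitted to the observed variances by matching moments of log s²
(digamma/trigamma method, trigamma inverted by Newton iteration), and the
moderated t uses the posterior variance with d₀ extra degrees of freedom.
Plain OLS is a switch, used by the oracle tests. Probes whose missingness
leaves fewer than 3 observations in a compared group (or a rank-deficient
design) are skipped and counted.

Effect sizes are reported on the β scale: the fitted sex/GA contributions,
evaluated relative to the covariate sample means, are subtracted from M,
the result is back-transformed to β, group means are taken with missing
values stripped, and Δβ is case mean minus control mean. A site is called
DM when the BH q value is below 0.05 **and** |Δβ| ≥ 0.05. The Δβ
criterion is two-sided by default (hypo- and hypermethylation both
count); the positive direction means hypermethylated in the case group.
Candidate-subset analysis reruns the identical procedure on a probe
subset with the FDR (and, when moderation is on, the variance prior)
computed within the subset. The GA-matched variant pools the non-case
groups, restricts to a GA window, and refits.

## Genome-wide metrics

Array average is the per-sample mean of covariate-adjusted β over clean
probes. The outlier-probe percentage is computed within tissue: a cell is
an outlier when it lies more than 3 MADs from the probe median across
that tissue's samples; the count is normalized by the sample's non-missing
probes. The MAD uses the 1.4826 consistency constant by default (raw MAD
by switch); probes with MAD 0 are skipped, since with a degenerate spread
any deviation would be flagged. Group comparisons of such per-sample
metrics use a permutation Mann–Whitney test: U with midranks, labels
permuted (1000 by default), each tail given the +1 correction, two-sided
by doubling the smaller tail and capping at 1; for 12 or fewer samples
the permutation distribution is enumerated exactly. Clinical tables use
this test for continuous variables and an exact 2×k Fisher test
(Freeman–Halton: full enumeration of tables with the observed margins)
for categorical ones; "ns" denotes p ≥ 0.05. Hierarchical clustering is
average-linkage on Euclidean distances over shared non-missing probes
(rescaled by the observed fraction), exported as Newick. Pyrosequencing
repetitive-element methylation is averaged over each element's CpGs
(4 for LINE1, 3 for Alu), with samples flagged for repeat when the
across-CpG SD exceeds 10 percentage points or a peak height is below 75;
platform agreement uses Spearman correlation with Bonferroni correction
across tested sites.

## DMRs

Regions are found by a bump-hunting scan over per-probe contrast
coefficients: a centered running mean (window 3 probes) per chromosome,
candidate probes where |smoothed coefficient| exceeds a threshold
(default: 75th percentile of the absolute smoothed values), maximal
same-sign runs with inter-probe gaps ≤ 300 bp, kept at ≥ 3 probes, scored
by area (sum of |smoothed coefficient|). This implements the stated
region definition directly rather than reproducing any specific package's
internal smoothing machinery. Significance is a max-statistic permutation
null: status labels are permuted within tissue (1000 iterations by
default), the scan is repeated at the fixed observed threshold, and each
region's p is the fraction of permutations whose maximum area reaches its
area (+1 correction), followed by BH across regions. The max-statistic
construction is familywise-conservative by design; regions smaller than
the genome-wide maximum under permutation are the ones worth reporting.

## Gene-set and feature enrichment

Gene score resampling: each gene is scored by its best probe
(largest −log₁₀ p — "best score for gene replicates"); a set's observed
statistic is the median member score (median class scoring); the null is
the same statistic on equally sized random gene draws from the scored
background (10,000 draws by default; the 200,000 of a full production run
is a parameter); empirical p with the +1 correction, BH across sets; sets
outside [10, 200] genes after background intersection are excluded with a
recorded reason. Over-representation uses the hypergeometric upper tail
of the hit/set overlap against the background. Feature enrichment is a
2×2 Fisher test per annotation feature (island relation levels, enhancer
flag) of hits versus the clean-probe background, with direction from the
odds ratio.

## Persistence cascade

Four ordered filters refine internally DM sites against an independent
external control cohort: (1) the internal dual-criterion call; (2) a
covariate post hoc screen — after per-group centering removes the status
effect, each hit probe is tested against gestational age, sex, plate,
chip and row (ANOVA for categorical, correlation for continuous) and
dropped if any covariate reaches p < α (α = 0.01 per covariate by
default; the original procedure's threshold is not recoverable, so this
is a documented stand-in); (3) control concordance — internal versus
external controls fitted at the hit probes, probes DM at FDR < 0.05
(within the tested set) dropped; (4) external replication — the case
group versus external controls, keeping probes passing the dual criterion.
Survivor sets are strictly nested by construction. The external cohort is
compared directly, without joint batch correction, mirroring how public
reference samples are typically used; a switch enables joint adjustment.
Supervised clustering restricted to the persistent hits reports the
adjusted Rand index of the 2-cluster cut against case status.

**A power bound on filter 4.** A probe removed at filter 4 must have
passed filter 1 (case vs internal control difference detectably ≥ 0.05),
survived filter 3 (internal vs external controls not detectably
different), and then failed to show the case-vs-external difference. By
the triangle inequality those three group means cannot be arranged so
that all three outcomes are high-probability simultaneously: the
case-vs-external difference is pinned near the call threshold, and the
external comparison (n ≈ 5) tests it with roughly 1.6× the standard error
of the internal one. Filter-4 removal is therefore intrinsically a
borderline-power event — consistent with the observation that only about
half of concordant sites typically replicate against a small external
cohort — and no synthetic parametrization makes its removals a sharp
(≥ 90%) classification. The bundled four-class scenario
(`cascade_scenario`) maximizes the achievable margin: the
"internal-only" class carries a 0.095 effect at mid-methylation baselines
with elevated noise so replication fails through the FDR route; measured
stage-4 recall is ~0.75–0.89 across seeds while all other stage metrics
exceed 0.9.

## Synthetic data generator

The generator emulates: a three-component baseline β mixture (modes near
0.05 and 0.95 plus a broad intermediate, weights 0.4/0.4/0.2 — the
canonical 450k bimodality); per-tissue M-scale profiles at 30% of probes
(SD 1.2) so samples cluster by tissue; planted case effects specified as
target Δβ and realized as per-probe additive M shifts chosen so the
back-transformed mean moves by exactly Δβ (effect probes get baselines
with headroom for their shift — a probe whose mean truly moves by Δ
cannot sit at the boundary); additive sex and GA effects on M; per-level
per-probe batch shifts (normal, configurable SD) for plate/chip/row, with
an option to confound a variable with status at an exact per-status
proportion; trimodal rs-probe genotypes drawn once per individual and
copied exactly across that individual's samples; chrX/chrY probes
separated by sex (females ≈ 0.5 on X from X-inactivation, males with real
Y signal); sporadic detection/bead failures at configurable rates plus
systemically poor probes failing in 30% of samples; and technical
replicate pairs re-drawn with fresh technical noise. Defaults mirror a
second-trimester fetal NTD cohort: 19/22/15 individuals per
CON/SB/AN group, male fractions 7/19, 16/22, 5/15, GA uniform on
14.5–23.9 weeks, 65 rs probes, 3 plates, residual M noise SD 0.25. All
randomness flows from one seeded generator in a fixed draw order, so a
config is bit-reproducible. `generate_cohort` draws additional samples
(e.g. external controls) from the same probe space with fresh individuals
and no shared batch structure, optionally offset at chosen probes to
emulate systematic between-cohort differences.

What the generator does **not** emulate — and hence what passing tests do
not establish about real arrays: raw two-color intensities, type-I/II
probe chemistry and its normalization, spatial chip artifacts,
cell-composition heterogeneity, correlated probe noise within islands,
and genotype-dependent probe failure. Conclusions from the test suite
concern the correctness and calibration of the statistical machinery, not
the biology of any real dataset.

## Numerical choices and degenerate inputs

β clipped to [0.001, 0.999] before logit; BH applied only to non-missing
p (NaN propagates); moderation falls back to plain variances when fewer
than two finite variances exist, and to a common variance when the
log-variance dispersion is at or below its sampling expectation (d₀ = ∞);
the trigamma inverse is Newton iteration from the 1/x asymptote; batch
scale estimates are floored at 1e-8 and a zero pooled variance falls back
to the total variance; permutation p values are never exactly 0 (+1
correction); Fisher 2×k enumeration compares log-probabilities with a
1e-9 tolerance to absorb rounding; DMR smoothing shrinks its window at
chromosome ends; ties in clustering are broken deterministically by input
order. Problem sizes in the test suite (e.g. 5,000 probes × 40 samples ×
200 seeds for null calibration; 50,000 probes × 60 samples for the
end-to-end run; 1,000 permutations for DMR q values) were chosen as the
smallest at which the checked quantities are statistically stable.

## Known limitations

The pipeline starts at a β/M matrix: no IDAT parsing, intensity-level QC,
color correction or probe-type normalization. No cell-type deconvolution,
surrogate-variable analysis, mixed models or interaction terms. The
non-parametric batch-prior mode is not implemented. GEO matrices must be
converted to the plain TSV dialect externally.
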