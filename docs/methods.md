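# Methods

## Scope and model overview

`reposyn` couples three classical quantitative tools into one pipeline:
empirical-Bayes moderated differential expression for consensus-signature
construction, the weighted Kolmogorov–Smirnov connectivity statistic for
signature-reversal drug repurposing, and Chou–Talalay median-effect
analysis for pairwise synergy quantification. All stages run on synthetic
data with planted ground truth; the generators are first-class, tested
code, and their defaults define the benchmark conditions used throughout
the test suite.

## Moderated differential expression

For a two-group design with n₁ condition and n₂ control samples, each
gene g has log fold change `logFC_g = mean(cond) − mean(ctrl)`, pooled
variance s²_g on d = n₁ + n₂ − 2 degrees of freedom, and design leverage
c = 1/n₁ + 1/n₂ (so var(logFC) = c·σ²).

The variance prior assumes s² ~ s₀²·F(d, d₀) and is fitted by the method
of moments on log s²: with e = log s² − ψ(d/2) + log(d/2) (ψ the digamma
function), mean(e) estimates log s₀² up to a digamma correction and
var(e) − ψ′(d/2) estimates ψ′(d₀/2), inverted by Newton iteration. When
the excess variance is non-positive, d₀ = ∞ (complete shrinkage). Genes
with s² = 0 are excluded from estimation; if *all* variances are zero the
fit raises an error naming the cause — the hierarchy is unidentifiable on
constant data.

Posterior variances are s²_post = (d₀s₀² + d·s²)/(d₀ + d), the moderated
t is logFC/√(s²_post·c) on d + d₀ total degrees of freedom (capped at the
pooled df across genes so the d₀ = ∞ limit keeps a proper reference
distribution). The B statistic is the log posterior odds of differential
expression under a two-component normal mixture: prior probability
`pi_de = 0.01` of a true effect, whose variance is `v0_ratio` times the
sampling variance. `v0_ratio` is estimated by matching the top
⌈pi_de/2·n⌉ |t| statistics to their expected mixture quantiles, clipped to
[0.1, 1e4]; the floor keeps B finite on null data. These choices follow
the standard conventions of the moderated linear-model literature; one
test cross-checks d₀, s₀², t and p against the reference R implementation
(limma) to ~1e−6 and requires rank agreement of B.

Two limits are asserted numerically: d₀ → 0 reproduces the ordinary
two-sample t exactly, and d₀ → ∞ equalizes all posterior variances at s₀².

## Consensus signature rule

Per study, a gene is called **up** when B > 0 and its fold change exceeds
1.5, **down** when B > 0 and the fold change is below 0.75; all cutoffs
are strict. The thresholds are interpreted on the *linear* fold-change
scale (logFC > log₂1.5 ≈ 0.585, logFC < log₂0.75 ≈ −0.415): a bound of
0.75 denotes depletion only as a ratio, not as a log2 quantity. The
consensus keeps genes called in the same direction in ≥ 2 studies over the
shared gene universe (index intersection); a gene reaching both quotas —
possible only across discordant studies — is excluded and reported as
ambiguous rather than silently assigned.

The same machinery exposes a generic ratio/p filter for proteomics-style
tables: up ⇔ ratio > 1.2 and p < 0.05, down ⇔ ratio < 0.8 and p < 0.05,
boundaries excluded.

## Connectivity scoring and aggregation

Condition profiles are ranked by descending z-score, ties broken by
ascending gene id so the ordering is deterministic. The enrichment score
is the signed maximum deviation of a running sum in which a hit at rank i
adds |z_i|^w normalized by the gene set's total weight and a miss
subtracts 1/(N − N_hit); w = 1 by default (the convention of the
large-scale connectivity compendia), w = 0 for the classic KS statistic.
ES ∈ [−1, 1]; at w = 0 reversing the ranked list negates ES exactly and
the null mean over random sets is 0. The weighted form is *not* symmetric
on a null profile: hit weight concentrates at both extremes of the ranking
and the long low-weight middle drift dominates the signed maximum, giving
a negative null mode (≈ −0.23 for 50-gene sets on 1000 standard-normal
genes). This is a property of the statistic, not of the implementation,
and is why the analytic symmetry checks use w = 0.

The two tail scores combine as WTCS = (ES_up − ES_down)/2 when they have
opposite signs and 0 otherwise; a down-only query negates its single ES so
that negative always means reversal. Per perturbagen, the repurposing
score RS is the unweighted mean over cell lines of the within-cell-line
mean WTCS — invariant, by construction, to duplicating conditions inside a
cell line, so heavily assayed cell lines carry no extra weight. Candidate
reversers must have strictly more than 10 scored conditions and RS
strictly below −0.3.

An optional permutation null (random same-size gene sets) supplies an
empirical two-sided p-value with the add-one estimator
(1 + #{|ES*| ≥ |ES|})/(n_perm + 1).

## Median-effect fitting and combination index

Viability percentages convert to fraction affected fa = 1 − v/100,
clamped to (ε, 1−ε) with ε = 1e−6 because the linearization diverges at
0 and 1; replicates are averaged on the viability scale before conversion
(fitting all replicates individually is available by flag). Clamped
boundary points are excluded from fits and counted. The fit is OLS of
log₁₀(fa/fu) on log₁₀ D; validity requires ≥ 3 distinct usable doses,
m > 0, Dm > 0 and Pearson r ≥ 0.90 (the customary acceptability floor for
median-effect plots). Invalid fits void the pair rather than producing a
CI.

CI uses the mutually exclusive (Loewe) form without the product term,
evaluated at each combination point's *observed* fa with its actual
(d₁, d₂) — valid for constant- and non-constant-ratio designs. The
pair-level call is the arithmetic mean CI over valid points, strictly
below 0.8 for synergy; per-point flags are retained. IC50 is Dm by
definition under the model. Rescaling all doses of a pair by a common
factor (a unit change) leaves every CI unchanged.

## Synthetic-data generators

All generators draw from streams derived from the master seed by stable
text labels (seed, CRC32(label)), so adding or reordering generators never
perturbs another's draws, and identical configuration + seed gives
bit-identical outputs.

**Expression systems.** Three systems of 5 + 5 samples over 1000 genes,
baseline expression N(7, 1) per gene on the log2 scale, with a planted
core of 50 up and 50 down genes at |log2FC| = 2, per-observation noise SD
0.5, and 20% per-system core dropout. The effect size and noise are typical
of a strong oncogenic transcriptional program on arrays; the dropout
models genes missing from individual platforms or species. Ground truth
(core membership and per-system activity) is returned and written as a
JSON sidecar.

**Perturbagen compendium.** 200 perturbagens × 12 conditions cycling over
3 cell lines, 3 doses and 2 time points; null scores are unit normal;
planted reversers shift the core genes by ∓2 (strength 2 against unit
noise — a clear but not caricatural reversal; the resulting RS ≈ −0.83
versus a null spread of |RS| ≲ 0.12). One non-reverser is always generated
with ≤ 10 conditions so the robustness filter has something to remove.

**Dose–response.** Single agents follow fa(D) = 1/(1 + (Dm/D)^m); for a
combination at total dose D split (w₁D, w₂D), the noise-free fa solves
d₁/Dx₁(fa) + d₂/Dx₂(fa) = ψ — the left side is strictly decreasing in fa,
so Brent bisection on (ε, 1−ε) finds the unique root to |residual| <
1e−10; doses admitting no root are clamped at the boundary, flagged and
logged. ψ is exactly the CI a perfect analysis recovers: ψ = 1 is
Loewe-additive, ψ < 1 synergistic, ψ > 1 antagonistic. Noise is Gaussian
on logit(fa) (SD 0.1 by default, 6 doses from Dm/4 to 4·Dm, 3 replicates),
which keeps fa in (0,1) and matches the scale on which the fit is linear.

**shRNA screen.** Six shRNAs per gene, log-normal reference abundances,
treated mean abundance = (1 − planted depletion) × reference with
multiplicative (log2-Gaussian) noise; gene-level depletion is
1 − mean(treated)/mean(reference), binned as strong (> 30%), moderate
(20–30%], weak (10–20%], below otherwise.

What the generators do **not** emulate: gene–gene correlation structure of
real tumors, platform/batch effects, landmark-gene inference of L1000-class
compendia, plate-position effects in viability screens, and heavy-tailed
measurement error. Passing tests therefore demonstrate correctness of the
decision rules and estimators under the stated generative models, not
robustness to every artefact of real data.

## Numerical and design choices

- ε = 1e−6 clamp on fa; the logit transform and the median-effect
  linearization are undefined at 0/1.
- Ranking ties broken by ascending gene id (stable argsort after
  pre-sorting the gene index), making every score reproducible.
- WTCS with equal-signed tails is exactly 0; sign convention throughout is
  negative = reversal of the query.
- The >10-condition filter counts condition profiles, not distinct cell
  lines.
- Consensus-signature exactness is verified at noise SD 1e−3 rather than
  exactly 0: with literally constant replicates every gene has s² = 0 and
  the variance hierarchy is unidentifiable (by design an error), while at
  1e−3 the calls are deterministic and match the planted truth exactly.
- Benchmark sizes (10–100 seeds per stochastic check, 200-perturbagen
  compendia, 6-dose screens) were chosen so the complete suite exercises
  every recovery claim at desk scale.

## Known limitations

- Two-group designs only; no covariates, batch terms or multi-factor
  contrasts.
- No cross-species orthology mapping: studies must share gene identifiers.
- Raw-data preprocessing (array normalization, RNA-seq quantification,
  proteomics quantitation) is upstream of this package.
- The repurposing score is reported on the raw WTCS scale; no
  percentile/tau normalization against a touchstone reference.
- Only Loewe/Chou–Talalay synergy; no Bliss, HSA or ZIP scores, and no
  dose-reduction indices.
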