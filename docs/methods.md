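# Methods

This note documents the statistical model behind `transqtl`, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Association model

Within each cohort, for variant $v$ with dosage $g \in [0,2]$ and gene $k$
with inverse-normal-transformed expression $y_k$, the scan fits

$$y_k = \alpha + \beta\, g + X\gamma + \varepsilon$$

where $X$ holds sex, six expression principal components, and six genotype
principal components. The reported statistic is $(\hat\beta, \text{se}, p)$
with $p$ two-sided from the $t$ distribution on $n - (c + 2)$ degrees of
freedom ($c$ = number of covariates). The $t$ reference (rather than the
large-sample normal) is exact at the small synthetic cohort sizes and
converges to the score-test normal at biobank scale.

The implementation residualizes $y$ and $g$ on $[1, X]$ once per cohort
and then runs simple regressions with a degrees-of-freedom correction.
This is the Frisch–Waugh–Lovell identity, not an approximation; the test
suite enforces equality with per-pair full regressions (statsmodels) to
1e-8. Missing dosages are mean-imputed per variant at scan time only
(QC sees the true missingness); samples missing a gene's expression are
dropped pairwise for that gene via a slower per-gene path.

Rank-INT uses $\Phi^{-1}((r - 0.5)/n)$ with average ranks for ties. The
offset is a convention (others use the Blom constant 3/8); it is fixed
here and symmetric, so the output mean is 0.

## Meta-analysis

Fixed effects: $\hat\beta = \sum w_i b_i / \sum w_i$, $w_i = se_i^{-2}$,
$se = (\sum w_i)^{-1/2}$, $p = 2\Phi(-|z|)$. The normal reference for the
pooled $z$ against the per-cohort $t$ is the standard large-sample
mismatch; at the cohort sizes used here the discrepancy is far below the
Monte-Carlo noise of any downstream decision, and the null-calibration
test verifies uniform meta p-values empirically.

Heterogeneity: $Q = \sum w_i (b_i - \hat\beta)^2$,
$I^2 = \max(0, (Q - df)/Q)$ with $I^2 = 0$ at $Q = 0$, and the
DerSimonian–Laird moment estimator
$\hat\tau^2 = \max(0,\ (Q - df) / (\sum w - \sum w^2/\sum w))$ with
random-effects re-weighting $w^*_i = 1/(se_i^2 + \hat\tau^2)$. REML and
Paule–Mandel estimators are out of scope. Pairs observed in a single
cohort pass through with $k = 1$ and undefined heterogeneity — array and
RNA-seq cohorts measure different gene panels, so singletons are a normal
condition, not an error.

## Locus definition

* **Cis/trans**: distance from the variant to the gene *body* (minimum
  over start/end, 0 inside), boundary inclusive at 5 Mb. Measuring to the
  TSS instead shifts assignments by at most a gene length and is not
  exposed as an option.
* **Clumping**: greedy per gene — take the smallest-p variant at or below
  the suggestive threshold 1e-11, delete everything within ±1.5 Mb on its
  chromosome, repeat. Distance clumping (not LD clumping) matches the
  pipeline's summary-statistics-only design; the default synthetic panel
  has no LD, so the radius is the binding constraint.
* **Locus merging**: per-gene leads within ±1.5 Mb on one chromosome merge
  into one locus led by the smallest-p variant; members are the
  contributing genes plus every trans gene with $p < 5\times10^{-8}$ at
  the locus lead. The merge radius deliberately reuses the clump radius
  rather than introducing a second tunable.
* **Crossmap filter**: a target fails if its symmetrized crossmap score
  with *any* protein-coding gene within ±1.5 Mb of the lead is ≥ 1.
  Symmetrization (max of both stored directions) is the conservative
  reading of an undirected "high cross-mappability between" relation, and
  ≥ 1 (rather than > 1) is the stricter of the two stated boundaries.
* **Candidacy**: lead $p \le 10^{-11}$ and ≥ 5 crossmap-clean targets at
  $p < 5\times10^{-8}$. This is intentionally conservative: a true trans
  signal with one or two targets is invisible to this design.
* **Per-locus FDR**: Benjamini–Hochberg at 5% over all genes tested at the
  lead minus the lead's cis window. The universe is per locus; a global
  FDR across loci would couple unrelated regions.

## Replication

Criterion 1 (primary): replication $p < 0.05$ with concordant sign for the
lead pair. Criterion 2: Storey $\pi_1 > 0.5$ over the replication
p-values of the discovery FDR-5% targets. Both flags are always reported;
the verdict defers to criterion 2 only when the lead pair is absent from
the replication data. Allele harmonization flips the sign for swapped
ref/alt; strand-ambiguous (A/T, C/G) variants are excluded rather than
guessed.

$\pi_0$ estimation: $\hat\pi_0(\lambda) = \#\{p > \lambda\}/(m(1-\lambda))$
on $\lambda = 0.05, \dots, 0.95$, smoothed by a heavily-smoothed cubic
spline (effectively the least-squares cubic trend, ~3 effective df) and
evaluated at $\lambda = 0.95$, clipped to $[0,1]$. The smoother weights
each grid estimate by its inverse sampling standard deviation
($\mathrm{var} \approx \lambda/(m(1-\lambda))$), which damps the noisy
right edge of the grid; without the weighting the uniform-input estimate
of $\pi_1$ carries a positive bias of ~0.05. Below $m = 100$ p-values the
grid is too noisy and a fixed $\lambda = 0.5$ is used.

## Colocalisation

Standard single-causal-variant enumeration over Wakefield log-ABFs with
priors $p_1 = p_2 = 10^{-4}$, $p_{12} = 10^{-5}$ and prior effect
variances $W = 0.2^2$ (quantitative, standardized scale) and $0.15^2$
(case-control, log-odds). All sums are log-sum-exp; H3 uses
$\log(\exp(a) - \exp(b))$ on the pair-sum minus the diagonal, so a
single-variant region yields PP3 = 0 exactly and posteriors sum to 1
within 1e-10.

Lead-only GWAS input is expanded with $z_j = r_{j,\text{lead}}\, z_\text{lead}$
from an LD panel, $se_j = 1/\sqrt{2 n\, \text{maf}_j (1-\text{maf}_j)}$
under a standardized-trait model and $\beta_j = z_j\, se_j$. The standard
error imputation is an approximation (it ignores the trait's residual
variance reduction at the causal variant); it is therefore validated
functionally — full-stats and imputed colocalisation must agree on the
argmax hypothesis in ≥ 80% of strong single-causal simulations — not for
numeric identity.

## Synthetic data: what it emulates

The generator produces $C$ cohorts of unequal size on a shared panel of
biallelic variants laid out in contiguous blocks over `n_chromosomes`
chromosomes at fixed spacing, with gene $j$ placed 50 kb from its paired
"local" variant. Defaults (the packaged study): 3 cohorts × 200 samples,
480 variants, 400 genes on 4 chromosomes, MAF ~ U(0.05, 0.5), imputation
R² ~ Beta(8, 1), hard-call Binomial(2, MAF) dosages (hence exact HWE).
An optional haplotype Markov-copying scheme (`ld_rho`) adds block LD for
colocalisation and proxy tests; the discovery procedures themselves never
require realistic LD beyond a lead-proxy pair.

Expression for gene $k$ in cohort $c$:

$$y_k = b_{kc} + s_c e_k \mathbb{1}[k \in S]
      + \ell_k^\top F + \text{genetic}_k + \varepsilon_k$$

with per-cohort batch offsets $b_{kc} \sim N(0, 0.3^2)$ (between-cohort
only, so they vanish in per-cohort analysis), a balanced binary sex
covariate with additive effect 0.5 on a random 10% gene subset, and six
latent technical factors whose per-gene loadings are normalized to a total
latent variance of 0.3. Genetic structure: explicit cis effects
(β per allele), mediated trans networks (regulator
$y_R = \beta_{cis} g + \dots$; target $y_k \mathrel{+}= \gamma_k y_R$,
marginal slope $\beta_{cis}\gamma_k$), and post-hoc contamination
$y_t \mathrel{+}= \lambda\, y_s$ applied on the normalized scale, which
reproduces the additive leakage signature the crossmap filter targets
without modelling reads.

Each gene's residual noise is scaled so its within-cohort variance is 1.
Planted marginal slopes are therefore in phenotype-SD units per allele and
survive the rank-INT essentially unchanged, which is what makes "estimated
beta within 3 SE of planted slope" a meaningful recovery check.
Contamination-source genes (and network regulators) are exempted from the
latent/sex components: they emulate genes whose variance is dominated by a
strong cis effect, and the exemption keeps the unit-variance budget
feasible at $\beta_{cis} = 1.4$.

Two calibrations deserve a note because they are consequences of doing
PCA-based covariate correction on data with a planted network:

* **Transcriptome size.** With 400 genes and $n = 200$, the planted
  network factor (population eigenvalue ≈ 2.8) sits below the
  Marchenko–Pastur bulk edge ≈ 5.8, while each latent factor (≈ 20) sits
  far above it. The six expression PCs therefore capture the technical
  factors and not the network. On a small transcriptome (e.g., 120 genes)
  the network factor crosses the detection edge and the PCs absorb a
  large part of the trans signal — which is exactly what happens in real
  analyses when the target set is a large fraction of the measured genes.
* **Mediation strength.** The default $\beta_{cis} = 1.1$ at MAF 0.5
  keeps the regulator-to-target loadings $\gamma_k = s_k/\beta_{cis}$
  small, which further shrinks the network eigenvalue and the residual
  PC leakage into the estimated slopes (measured bias ≈ −0.3 SE at the
  packaged study size; it would be ≈ −1 SE at $\beta_{cis} = 0.8$).

The default network: 20 targets on chr3/chr4 with marginal slopes evenly
spaced over 0.25–0.40 SD per allele at a common (MAF 0.5) variant,
combined $n = 600$. At these conditions roughly the top three-quarters of
targets clear $5\times10^{-8}$ after meta-analysis, the lead clears
$10^{-11}$ comfortably, and the locus is the study's single candidate.
The contamination locus: source cis $\beta = 1.4$ (MAF 0.4), leakage
$\lambda = 0.3$ into six genes, giving apparent slopes ≈ 0.4 — strong
enough to be a candidate when the crossmap filter is off, and fully
removed when it is on.

**What the generator does not emulate**, hence what passing tests do not
show about real data: read-level artifacts other than additive leakage,
LD beyond first-order Markov copying, population structure and admixture,
related individuals (no mixed models — the cohorts are unrelated by
construction), cell-type composition effects, non-Gaussian expression
noise, and GC-content-dependent normalization error.

## Numerical conventions

* Coordinates are 1-based inclusive (VCF convention); all window
  boundaries are inclusive.
* The Hardy–Weinberg test is the exact conditional enumeration over
  heterozygote counts (no mid-p), computed in log space and verified
  against integer-arithmetic enumeration up to $n = 100$.
* Summary tables are written at 12 significant digits (`%.12g`) and
  round-trip losslessly at that precision; determinism is byte-level for
  fixed config and seed.
* One global seed fans out to per-stage generators through
  `SeedSequence(entropy=seed, spawn_key=(stage, cohort))`, so any stage
  can be re-run independently and reproducibly.
* Low-expression boundary: a gene is removed when the fraction of samples
  below 1 TPM is ≥ 0.95 (inclusive reading).
* BH q-values come from `statsmodels.stats.multitest`; hypergeometric and
  Fisher tests from scipy, cross-checked against exact-rational
  enumeration in the test suite.

## Command-line interface

The CLI exposes `simulate`, `discover`, `replicate`, `coloc` and `enrich`.
QC, scan, meta-analysis and locus reporting are folded into `discover` as
one stage with per-stage artifacts (exclusion reports, meta summary, locus
tables, manifest) because the stages share aligned in-memory cohorts and
splitting them at the shell boundary would force re-reading multi-matrix
state; the library functions (`prepare_cohort`, `scan_cohort`,
`meta_analyse`, …) expose each stage separately for programmatic use.

## Known limitations

* No mixed-model association (ridge/LMM step for related samples);
  cohorts with relatedness need external pre-processing.
* Distance-based clumping cannot split two independent causal signals
  closer than 1.5 Mb, and conditional/stepwise analysis of secondary
  signals within a locus is not implemented.
* The enrichment module requires the caller to state the background
  universe; there is no default gene-set database.
* The pi1 smoother's uniform-input bias is small (≈ 0.03–0.05) but
  positive; with fewer than ~200 p-values, criterion 2 decisions near the
  0.5 boundary should not be over-read.
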