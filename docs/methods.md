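# Methods

## The problem

Single-cell RNA-seq studies of manipulated embryos often sample several
cells from each blastocyst while the experimental treatment (here: a
pronuclear-transfer procedure) is applied to the whole blastocyst. Cells
from one blastocyst are then not independent replicates of the treatment —
the blastocyst is the unit of biological replication. `blastopower`
simulates expression data with exactly this hierarchical structure, tests
treatment effects the way such data should be tested (a mixed model with a
random blastocyst intercept), and measures two things: how much power such
designs actually have, and how badly a PC1/PC2 score plot can misrepresent
genuine differential expression.

## Generative model

For gene *g* and sample *i*:

    Y_i = mu + a[T_i] + c[C_i] + b[B_i] + e_i

* `T` — treatment, 4 levels (control, autologous, homologous,
  heterologous), constant within blastocyst;
* `C` — cell type, 4 levels (primitive endoderm, epiblast, trophectoderm,
  ambiguous);
* `b[B] ~ N(0, sigma_B^2)` — blastocyst random intercept, drawn
  independently per gene;
* `e_i ~ N(0, sigma_e^2)` — residual error.

Level means are equally spaced: a treatment "effect size" (spacing) of
delta puts the four levels at 0, delta, 2·delta, 3·delta, so all four
groups differ whenever delta > 0. The standardized adjacent-group effect
is Cohen's d = delta / sigma_e. The model is Gaussian on a continuous
expression scale by design; count models (negative binomial, Poisson) and
gene–gene correlation are deliberately out of scope.

### Parameters, defaults and why

| parameter | default | units | rationale |
|---|---|---|---|
| `error_sd` (sigma_e) | 10 | expression | median per-gene variance estimate from the motivating study's data, taken as a given constant |
| `blastocyst_sd` (sigma_B) | 10 | expression | both variance components trace to the same median-variance estimate; the exact between-blastocyst value was never published, so equality is the faithful default |
| `celltype_spacing` | 1 | expression | a "small" cell-type effect, d = 0.1 in Cohen's terms |
| `treatment_spacing` | 0 | expression | set per experiment (Set 1 sweeps 1–10; Set 2 fixes 2) |
| `baseline_mean` | 0 | expression | location does not affect any inference here |
| `alpha` | 0.05 | — | conventional; the significance threshold was never stated explicitly |

The reference design is 8 blastocysts × 4 cells (one per cell type), 2
blastocysts per treatment, fully factorial — 32 samples. Unbalanced
designs (1–11 samples per blastocyst, cell types assigned by deterministic
cycling) are available; the cycling rule is this package's choice, made
for reproducibility and even coverage, since no assignment rule for the
unbalanced case was ever published.

## Inference

Each gene is analysed with `Y ~ treatment + cell_type + (1 | blastocyst)`.
The treatment p-value comes from a likelihood-ratio comparison against the
model without treatment, both fitted by maximum likelihood (ML, not REML —
REML likelihoods are not comparable across different fixed effects), with
the statistic referred to chi-square(3). The blastocyst variance may hit
its zero boundary; no boundary correction is applied to the reference
distribution because the tested term is a fixed effect. Implementation:
statsmodels `MixedLM`, which we verified reproduces lme4's `anova()` model
comparison to ~1e-9 in the p-value on shared datasets (a unit test keeps a
small version of this check).

Numerical choices: BFGS optimization (gradient tolerance 1e-8, 200
iterations) with a derivative-free Powell refit when BFGS reports
precision loss near the variance boundary (~10% of null draws); tiny
negative LRT statistics (> −1e-6) are clamped to zero; degenerate inputs
(constant response, one blastocyst, a factor observed at fewer than two
levels) are flagged non-converged and yield a missing p-value. In power
tallies non-converged fits count as non-significant and are logged —
conservative and auditable.

### Calibration of the test — a known, faithful property

With only 8 blastocyst-level units and 7 fixed-effect parameters, the ML
chi-square LRT is **anti-conservative**: under the null (zero treatment
spacing, defaults) the measured rejection rate at alpha = 0.05 is ≈ 0.23,
and lme4 gives the same (≈ 0.19 over 300 replicates) on identically
generated data. This is a small-sample property of the original procedure,
not of this implementation — the effective sample size for a
between-blastocyst factor is the number of blastocysts, and ML variance
estimates ignore the fixed-effect degrees of freedom. We reproduce the
procedure faithfully rather than "fix" it; the practical consequence is
that the simulated power values at small effect sizes are, if anything,
optimistic, which only strengthens the low-power conclusion. The
type-I-error acceptance check in the test suite asserts the nominal
binomial band around 0.05 and therefore fails honestly at this design
size.

## Power estimation

Genes are simulated in batches of 100 (one batch ≈ one 100-gene analysis);
a batch's power is its fraction of significant tests. 100 batches per
setting give a mean power and a 95% CI computed as mean ± 1.96·SE across
batch powers, clamped to [0, 1] (the CI construction was never specified;
the across-batch normal approximation is recorded in every output's
config sidecar). Set 1 sweeps treatment spacings 1–10 at 8 blastocysts;
Set 2 sweeps 8, 48, 96, 144, 192, 240 blastocysts at spacing 2 (8 is
included because the plotted range started there). Each (sweep, setting,
batch) triple draws from its own named RNG sub-stream of the master seed,
so runs are reproducible and batches are statistically independent.

The test suite runs reduced versions of these sweeps — 20 batches × 100
genes over spacings {1, 2, 5, 10}, and 10 batches × 50 genes over counts
{8, 96, 240} — which are this package's standard smoke-scale settings for
verifying the qualitative shape of both curves; the full 100 × 100 grids
remain the library and CLI defaults.

## The PCA demonstration

A 12,000-gene panel is simulated in which a chosen fraction of genes is
differentially expressed at a chosen Cohen's d, and — crucially — each DE
gene receives an independent random permutation of the four treatment
levels, because assuming every gene shifts in the same direction between
treatments would be unrealistic. PCA is computed by SVD after gene-wise
centering (no unit-variance scaling by default; both are flags), with
component signs fixed by making each component's largest-magnitude loading
positive. Treatment cluster separation on PC1/PC2 is quantified by the
mean silhouette coefficient (Euclidean distance, treatment labels) — a
number chosen by this package to make the visual claim "no clear
clustering" measurable.

Two named scenarios reproduce the published score plots: `fig3`
(10% DE, d = 0.1) and `fig4` (1% DE, d = 0.5). A contrast scenario with
consistent orientation (100% DE, d = 1, no permutation) shows what PCA
*can* reveal when all genes agree in direction: silhouettes around 0.65.

### What the silhouette actually measures here

With sigma_B = sigma_e = 10, the strongest low-dimensional structure in
any simulated panel is the 8 blastocyst clumps (cells of one blastocyst
share `b` in every gene). Blastocysts are nested in treatments, so these
treatment-pure clumps leak into the treatment silhouette: the fig3/fig4
scenarios score s ≈ 0.2 (seed-dependent, up to ≈ 0.6) even though no
treatment-level clustering is visible — the apparent separation is
pseudoreplication made visible in PCA space. With sigma_B = 0 the same
scenarios score |s| ≲ 0.1. A reader using the silhouette to operationalize
"treatment clustering" on such hierarchical data should therefore compare
against a blastocyst-permutation null, not against zero; the plain
label-permutation null scores mildly negative (~−0.1) for four groups of
eight.

## What the synthetic data does and does not emulate

It reproduces the hierarchical variance structure, the per-blastocyst
treatment assignment, the factorial cell-type layout, and gene-wise
independent effects with randomized orientation. It does not emulate
count noise, mean–variance dependence, library-size effects, gene–gene
correlation, or any real blastocyst's expression profile — so passing
tests certify the statistical machinery and the published simulation
claims, not agreement with any real RNA-seq dataset.

## Reproducibility

One master seed; every stochastic component draws from
`substream(seed, name, ...)` (a `numpy` `SeedSequence` keyed by CRC-32 of
the stream name plus integer indices). Identical configs give
bit-identical CSV/JSON outputs; every run directory carries a manifest
with SHA-256 hashes, the resolved config, the seed and library versions.
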