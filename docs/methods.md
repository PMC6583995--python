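# Methods

This note documents the statistical models, the defaults and the design
choices behind `mctomics`, and what the synthetic-data experiments do and do
not establish.

## Composite malignancy scoring

A tumour's malignancy score is the sum of four integer sub-scores:

| axis | bands | score |
|---|---|---|
| two-tier histological grade | low / high | 1 / 2 |
| survival after surgery | > 365 d; 180–365 d; < 180 d | 1; 2; 3 |
| death due to the tumour | alive or censored; tumour death | 0; 3 |
| Ki67 index | < 3 %; 3–7 %; > 7 % | 1; 2; 3 |

Totals range over [3, 11]; ≥ 6 defines high-risk. The middle bands are read
as closed intervals ([180, 365] days, [3, 7] %), which makes the three bands
a partition and is consistent with every worked example in the bundled
cohort (day 364 scores 2; Ki67 7.95 % scores 3). The three-tier Patnaik
grade is carried as metadata and never scored; optional fields (age, sex,
location) never block scoring. The cohort summary reports the n−1-denominator
SD for Ki67.

## Expression units and filtering

CPM = count / library size × 10⁶; FPKM = count × 10⁹ / (library size ×
gene length in bp). The heatmap scale is log₁₀(FPKM + 1); when no gene
lengths are supplied the pipeline substitutes log₁₀(CPM + 1) with a logged
warning (lengths cannot be recovered from a count matrix). The expression
filter keeps genes with CPM ≥ 1 in ≥ 4 samples, both comparisons inclusive.
Sample clustering for the heatmap view uses Euclidean distance and average
linkage on the log-scale matrix; neither choice is forced by the method, so
both are recorded in the clustering API and overridable.

## Differential expression

The count model is NB(mean μ, variance μ + φμ²) with one common dispersion
φ shared across genes.

* **Normalisation.** Trimmed-mean-of-M-values factors (log-ratio trim 0.30,
  abundance trim 0.05, inverse-asymptotic-variance weights, reference column
  by upper-quartile-closest-to-mean), rescaled to geometric mean 1. The
  implementation agrees with edgeR's `calcNormFactors` to ≤ 1e-6 on random
  matrices (cross-checked in the test suite via Rscript when available).
* **Library equalisation.** Expected counts are scaled deterministically to
  the geometric-mean effective library size and rounded; no resampling, so
  the whole chain is reproducible bit-for-bit.
* **Dispersion.** φ maximises the summed per-gene conditional
  (group-sum-conditioned) NB log-likelihood over both groups (qCML), solved
  by bounded scalar minimisation on log φ over [1e-4, 4]; a boundary
  solution at the lower bound is reported as effectively Poisson. On
  simulated data the estimator recovers φ = 0.2 within ±0.05 at 2000 genes
  and returns ≤ 0.01 for Poisson data.
* **Exact test.** Conditional on a gene's two-group total after library
  equalisation, the group-A sum follows a negative hypergeometric law
  (binomial with p = n_A/(n_A + n_B) in the Poisson limit). The two-sided
  p-value sums the probabilities of all outcomes no more probable than the
  observed one; under the null the p distribution is uniform (KS < 0.05 at
  2000 genes in the suite).
* **Effect size.** log₂FC from equalised group means with a prior count
  (default 0.125) to keep fold changes finite; positive log FC means higher
  expression in the comparison (high-risk) group.
* **Calling.** BH-adjusted p ≤ 0.05 and |log₂FC| ≥ 2, both inclusive. BH is
  statsmodels' step-up; hand-computed step-up vectors serve as the test
  oracle.

Tagwise/trended dispersion and GLM/quasi-likelihood testing are deliberately
out of scope: the classic single-dispersion exact path is the simplest
published variant consistent with the two-group design, and the choice is
surfaced in `DEConfig`.

## Co-expression network

Unsigned adjacency a_ij = |cor_ij|^β with β = 11 (fixed; scale-free fit
selection is out of scope). Connectivity is the soft sum Σ_{j≠i} |cor_ij|^β,
consistent with the β-power network; a raw Σ|cor| mode is available because
the phrase "sum of correlations" admits both readings. The 6000
most-connected genes (ties broken by stable input order) enter the network.

Topological overlap: TOM_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with
l_ij = Σ_{u≠i,j} a_iu a_uj; entries lie in [0, 1] and the implementation is
checked against a brute-force triple loop to 1e-10. Note that TOM ≥ a does
**not** hold for arbitrary dense adjacencies; only the [0, 1] range is an
invariant.

Modules come from average-linkage clustering of 1 − TOM, cutting at a fixed
fraction (default 0.99) of the maximum merge height and keeping clusters of
≥ 30 genes — the simple fixed-height tree cut, not the hybrid PAM-assisted
refinement, since no cut parameters are prescribed for the latter; adequacy
is established by planted-module recovery (ARI ≥ 0.9) instead of algorithmic
mimicry. Module labels are deterministic and size-ranked (M1, M2, …) with
conventional colour names attached only as cosmetic aliases.

The module eigengene is the first right-singular vector of the
gene-standardised module submatrix (unit norm in sample space), sign-oriented
so its mean correlation with member genes is ≥ 0; variance explained is the
first squared singular value's share. Eigengene–score association uses
Pearson correlation with the two-sided t-test (t = r√(n−2)/√(1−r²), n−2 df);
at n = 15 this reproduces the reference (r, p) pairs 0.51 → 0.05 and
0.45 → 0.09 at two decimals. Significance is strict: p < 0.1. Zero-variance
genes are screened out with a logged list before any correlation.

## Enrichment

Two-set over-representation: for background N, term size K, target n,
overlap k, p = P(X ≥ k) under Hypergeometric(N, K, n) (scipy's survival
function; verified against full pmf enumeration at N ≤ 30 to 1e-12). BH is
applied over all tested terms by default, or within namespaces when a
term → namespace map is provided; terms need ≥ 1 background gene and no size
cap by default (both configurable). Orthologue conversion is a pure table
lookup with unmapped genes removed from target and background and reported —
no orthology is computed, and no GO release is bundled; both are inputs.
The ranked-list (minimum-hypergeometric) mode of web GO tools is out of
scope: the analysis here has a defined target list and a defined background.

## Validation statistics

Ki67 index = mean over fields of 100·positive/(positive+negative) — fields
weigh equally, matching the "average percentage over five fields" protocol
rather than pooling cells. Sections totalling < 200 cells are flagged, not
dropped (the 200-cell rule is a counting practice, not an exclusion rule).
CAF score = summed positive-fibroblast counts over the five hot-spot fields.

Mann-Whitney U: midranks throughout; for n₁ + n₂ ≤ 12 the two-sided p is
exact by full enumeration of all C(N, n₁) group assignments, with extremity
measured by |U − n₁n₂/2| (enumeration remains exact under ties and yields
p = 1 for identical groups); larger samples use the normal approximation
with tie-corrected variance and a 0.5 continuity correction. Both paths are
cross-checked against scipy's implementations.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets: 15 samples
split 4 high-risk / 11 low-risk, ~14,000 expressed genes (default
`n_genes=14000`; tests use smaller universes for speed and state their
sizes), NB counts with φ = 0.1, library-size factors log-uniform in
[0.5, 2], ~70 planted DE genes of which 3 are down-regulated
(|log₂FC| = 3), and four planted modules of sizes 85/53/54/43 of which two
are score-coupled.

* **Cohort.** Each record's sub-score combination is drawn uniformly from
  the combinations compatible with its intended risk class, then realised
  as concrete follow-up days / status / Ki67 values inside the matching
  bands, so rescoring always reproduces the intended labels (tested across
  seeds).
* **Counts.** Gene baselines are log2-uniform in [2, 9]; DE effects add
  log₂FC to the high-risk group's log-mean, so the group mean ratio is
  exactly 2^log₂FC; module structure is one latent per-sample factor per
  module added on the log₂-mean scale with loading 0.8.
* **Trait coupling.** A trait-linked module's factor is built to have the
  requested *empirical* correlation (default 0.7) with the cohort's
  malignancy scores: standardised scores mixed with noise orthogonalised
  against them. Coupling is therefore exact in every dataset rather than
  only in expectation, which makes recovery properties meaningful at n = 15.
* **Annotation.** Per-gene Bernoulli memberships; the designated enriched
  term uses separate inclusion rates for target and non-target genes, so
  setting the two rates equal yields a calibrated null (p uniform over
  seeds up to hypergeometric discreteness).
* **Field counts.** Ki67 positives are binomial at the record's true index
  over 5 × 40 cells; CAF counts are Poisson with a higher mean in high-risk
  samples.

All randomness flows from explicit seeds through named
`numpy.random.Generator` objects; `simulate_dataset` derives stage sub-seeds
from one master seed via `SeedSequence`. Identical seeds give byte-identical
fixture files.

**What the synthetic experiments do not show.** The generator has no batch
effects, no gene-length or GC bias, no outlier samples, no correlated
annotation structure (real GO terms are nested), and modules are driven by a
single factor each. Passing the planted-recovery suites therefore
demonstrates correctness of the algorithms under the stated model, not
robustness to the full messiness of real RNA-seq. CPM normalisation does
produce realistic composition artefacts (strongly up-regulated genes depress
the CPM of everything else in high-risk samples), and spurious
score-correlated background modules arising from this effect are visible in
simulated runs — a useful reminder that module–trait screens at p < 0.1 are
exploratory.

## Numerical choices and degenerate inputs

Exact-test outcome ranking uses a 1e-10 log-probability slack so
numerically tied outcomes count as equally extreme. Dispersion estimation
rounds equalised counts to integers (the conditional likelihood needs
integer support) and drops all-zero genes. Connectivity ties are broken by
stable input order; module label ties by first gene occurrence. Empty
matrices, single-gene modules, constant traits, all-zero samples and
sub-minimum gene sets raise informative errors or warnings as documented in
the API. Problem sizes in the test suite (up to 2000 genes for calibration
checks, 20-seed recovery loops) were chosen so the full suite runs in well
under a minute on one core.

## Known limitations

* The exact-test flavour is the classic common-dispersion variant;
  per-gene (tagwise) shrinkage would change borderline calls on real data.
* The fixed-height tree cut is cruder than adaptive branch cutting; very
  unequal module densities can merge or shatter modules that the hybrid
  algorithm would resolve.
* The composite score mixes prognostic axes with an outcome axis (death),
  so the score is a label construction device, not a prognostic model;
  no survival modelling is attempted here by design.
* Orthologue mapping is one-to-one; genuine one-to-many paralogy must be
  resolved upstream in the mapping table.
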