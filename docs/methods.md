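# Methods

## Model

A population trait x (body weight in grams, fat mass, or BMI) is modelled
as a two-component Gaussian mixture

    f(x) = (1 − π) N(x; μ₁, σ₁²) + π N(x; μ₂, σ₂²),   μ₁ < μ₂,

interpreted as a lean sub-population plus a heavy ("on") sub-population
entered with probability π.  π is the quantity of interest — the
penetrance, or on-rate, of the heavy state — together with the percent
effect size 100·(μ₂ − μ₁)/μ₁.  The model assumes individuals are
exchangeable draws (litter or survey-design structure is handled by
normalization or weights, not by the mixture), components are Gaussian on
the analysed scale, and k ≤ 2.  No skew, lognormal or k > 2 alternatives
are fitted; distinct heavy states beyond one would be absorbed into σ₂.

## Fitting

**Binned nonlinear least squares (primary).**  Traits are histogrammed
into half-open bins of fixed width and the curve
A₁·exp(−(x−μ₁)²/2σ₁²) + A₂·exp(−(x−μ₂)²/2σ₂²) is least-squares fitted to
the bin counts at bin midpoints (scipy `curve_fit`, trust-region with
bounds).  Amplitudes convert to mixing fractions through component areas
Aᵢσᵢ√(2π), normalized to the total.  Goodness of fit is the plain
coefficient of determination over bins, R² = 1 − SS_res/SS_tot with
SS_tot about the mean bin count; it is invariant to uniform count
rescaling (so counts vs relative frequencies do not matter).  This is the
primary method because it reproduces the semantics of published
histogram-fit R² values for this kind of analysis.

Initialization follows a dominant-lean prior: component means at the 25th
and 90th percentiles of the binned mass, σ at half the pooled SD,
fractions 0.8/0.2, plus uniform-random restarts (default 8, seeded); the
best of the restarts by residual sum of squares wins.  Numerical guards: a
σ floor of bin_width/2 against point-mass collapse, amplitudes bounded by
10× the maximal bin count, means bounded by the data range.  A converged
double fit whose means lie within one bin width of each other is flagged
*effectively unimodal*; model comparison then must prefer k = 1, so near-
duplicate components are never reported as bimodality.

**Maximum-likelihood EM (cross-check).**  A hand-written univariate EM on
the raw samples supplies log-likelihood, AIC and BIC (parameter counts 2
and 5 for k = 1, 2) and posterior responsibilities.  k = 1 is the closed
form (weighted mean, ML SD).  Case weights are supported; σ is floored at
10⁻³ of the data range; the per-iteration log-likelihood trace is retained
and is non-decreasing (tested).  On ≤ 12-bin toys the binned fit is checked
against an exhaustive grid search, and EM against scikit-learn's
`GaussianMixture`, as independent oracles; well-separated scenarios must
agree between the two routes within 0.03 in the fraction.

**Model preference.**  k = 2 is preferred iff the double fit is not
effectively unimodal, the sample-level AIC favours two components, and
either the binned R² improves by ≥ 0.03 over the single Gaussian or the
sample-level BIC also favours two components.  The R² margin captures
histogram-visible bimodality.  The BIC route exists because the margin
alone fails genuine low-penetrance mixtures: with a ~12% heavy fraction
and a wide heavy component, the single Gaussian already reaches R² ≈ 0.99
on the binned data, so the gain is ~0.008 at n = 4000 even though the
sample-level evidence for two components is decisive; BIC's ln(n)
per-parameter penalty keeps its false-positive rate on unimodal data
near zero (0/120 in seeded checks at n = 1000–4000), so the disjunction
does not loosen the unimodal control.  `bin_sensitivity` deliberately uses
only the histogram-level rule (margin + AIC): its purpose is to audit what
each bin width can resolve, which the width-independent BIC would defeat.

**Classification.**  When k = 2 is preferred, individuals are assigned by
the posterior responsibility of the heavy component at their trait value,
threshold 0.5, ties to lean.

**Uncertainty.**  Nonparametric bootstrap (percentile intervals, default
B = 200) re-fits each resample under a fixed restart policy; label
switching is resolved by mean-ordering before aggregation.  More than 20%
non-converged replicates is recorded as a warning, more than 50% is a
failure.  Coverage is checked by simulation on a well-separated
calibration scenario.

**Tail outliers.**  Per-bin prediction intervals are built from count
sampling variation around the fitted curve (normal approximation
c ± z·√c with a one-count floor, the Poisson-like dispersion of bin
counts).  The upper tail is scanned for a run of ≥ 2 consecutive bins
above the interval; the run's left edge is reported as the systematic
threshold, and the exceeding mass beyond it as the fraction of the
population the mixture fails to describe.  This is one reasonable
operationalization of "bins outside confidence intervals"; interval
construction from model-parameter uncertainty instead would be tighter in
the bulk and looser in the tail.

## Normalizations

* **Wild-type normalization** divides each trait by the mean wild-type
  trait of its scope (per litter or global), putting mutants on a
  fold-of-control scale where the heavy mode of a +40% scenario sits at
  1.4.
* **Age/sex normalization** divides by a group statistic — median, mode
  (midpoint of the maximal-count bin at a configurable width, groups of
  ≥ 5 required), or winsorized mean.  Group-wise location statistics align
  the lean modes of populations whose heavy fractions differ; a plain mean
  would be dragged by the heavy tail, which is exactly why mean-normalized
  era comparisons mislead.
* On-rate and percent effect size are invariant under any global
  multiplicative rescaling, so both normalizations commute with the
  downstream estimates (tested).

## Era comparison

`era_shift` contrasts two fitted reports on (a) the *lean-component*
means — not cohort means, since a growing heavy fraction moves the cohort
mean without the lean mode moving — and (b) the heavy fractions, as a
ratio.  Both reports must prefer k = 2.

## Synthetic data

`simulate_cohort` draws each mutant from the heavy component with
probability π, wild-type individuals from the lean component only, with
optional shared per-litter normal effects and uniform or two-stratum
survey weights.  Scenario presets encode the published generative values:

| preset | n | π | μ_lean | heavy shift | σ_lean | σ_heavy |
|---|---|---|---|---|---|---|
| `nnat` | 200 | 0.26 | 30 g | ×1.40 | 2.4 | 3.36 |
| `peg3` | 80 | 0.20 | 10 g | ×2.0 | 0.8 | 1.6 |
| `nhanes_child_1963` | 4000 | 0.12 | 15.81 BMI | +4.5 | 1.3 | 3.0 |
| `nhanes_child_1999` | 4000 | 0.38 | 15.87 BMI | +4.5 | 1.3 | 3.0 |

Component SDs are not published; mouse scenarios use a CV of 8% of the
component mean and the BMI scenarios σ_lean = 1.3, σ_heavy = 3.0, chosen
once to match the qualitative profiles of the published histograms (a
sharp lean mode, a broad heavy shoulder).  The mouse lean mean (30 g,
typical for a 14–18-week male) and the fat-mass scale of the `peg3`
scenario (10 g lean) are likewise unpublished choices.  Litter effects
default off; facility-to-facility on-rate differences are represented as
π differences only.

`simulate_expression` generates log2-normal expression with a marker gene
lower by 2 log2 units in a latent marker-low class, a 9-gene imprinted
panel suppressed (default 1 log2 unit) only in marker-low *and* obese
samples, housekeeping genes with no class effects, and a 30% slice of
background genes carrying marker-class-linked offsets so that the marker
class dominates sample-space variance, with a much weaker adiposity
signature — the structure in which transcriptome clustering follows the
marker rather than the obese/lean label.  Ct values are 34 − log2
abundance, clipped to (1, 44).  Marker class and adiposity are drawn
independently; real cohorts couple them (marker-low individuals are more
often obese), which only strengthens the stratification signal, so the
independent case is the conservative test bed.

What passing tests on these generators shows — and what it does not: the
pipeline recovers the parameters of data that match its own model
(Gaussian components, exchangeable individuals, class-conditional panel
suppression).  Real BMI surveys add skew within components, age structure,
design weights and measurement error; real expression data add library-
size, batch and GC effects none of which are simulated.  Recovery here
validates the estimators, not the model's adequacy for any particular
real dataset.

## Expression quantification

ΔCt = Ct_gene − mean Ct of the housekeeping genes per sample (the
arithmetic mean of Cts, i.e. the geometric mean of the linear abundances —
the combination rule is a package choice; the sources name the genes
only); ΔΔCt references the mean ΔCt of a designated reference group;
fold = 2^−ΔΔCt.  Every gene's geometric-mean fold over the reference group
is exactly 1.  The marker split is at the across-sample median, ties to
the Low stratum (spilling to High only to keep sizes within one).  Panel
contrasts are obese vs lean within each stratum on log2 folds,
Mann–Whitney by default (strata are small), Welch's t on request,
Benjamini–Hochberg adjusted across the panel within each stratum; cells
with < 2 samples are reported not-evaluable rather than dropped silently.
Transcriptome structure: genes above a mean-abundance floor (default 1.0
in linear units) ranked by log2 variance, top n (default 6000) kept; PCA
on gene-standardized log2 values with deterministic component signs;
sample–sample Pearson correlation; average-linkage clustering on
correlation distance cut at k = 2.  Internal computations run on sorted
gene/sample views so results are invariant to input ordering.

## Problem sizes and determinism

Recovery suites use 50 replicates at n = 5000 (mouse body weight), 200
replicates at the published N = 80 (fat mass), and 20–50 replicates at
n = 4000 (BMI eras) — sizes at which the mean estimates are stable to
well under the tolerances while the full suite runs in a few minutes on
one CPU.  All randomness flows through explicit integer seeds
(numpy `default_rng` / `SeedSequence`); identical scenario + seed gives
bitwise-identical cohorts and byte-identical pipeline reports.

## Known limitations

* k is capped at 2; no formal bimodality test (dip test etc.) beyond the
  model comparison, and no skewed or heavy-tailed components.
* The binned least-squares fraction estimator is noticeably noisier than
  ML when components overlap (observed ~1.7× the EM sd on the BMI-era
  scenarios); per-replicate functionals of the fractions, such as the
  era fraction ratio, inherit that variance.  EM is the better choice
  when the fraction itself is the endpoint and the histogram semantics
  are not required.
* Bootstrap intervals are percentile-based; no BCa correction.
* The tail-outlier intervals ignore parameter-estimation uncertainty.
* GSEA-style enrichment, differential expression beyond the panel
  contrasts, and any methylation analysis are out of scope.
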