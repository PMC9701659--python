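# Methods

## The community abstraction

A feature table from an untargeted LC-MS run is read as an ecological
community: each m/z_rt ion feature is a species, each biological
replicate a sampling unit, and the ion area its abundance.  Zero is the
instrument's absence code, so presence is defined by a strict inequality
against a detection threshold (default 0).  Replicates pooled by
treatment × time (logical OR of presence) form the condition-level
sampling units used for richness comparisons.  All matrices are samples
in rows, features in columns, the convention community-ecology methods
assume.

## Diversity layer

Shannon H′ uses natural logarithms; with communities of hundreds to
thousands of species this puts H′ in the 3–6 nat range typical of these
data.  "Simpson diversity" is the inverse form 1/Σp² (effective species
count): reported values of 3–4.5 for species-rich communities are only
consistent with the inverse index, not with the complement 1 − Σp².
Pielou J′ = H′/ln S is undefined at S < 2 and raises rather than
returning a silent 0.

The species accumulation curve uses the "random" method: cumulative
richness averaged over `n_perm` (default 100) seeded random permutations
of unit order, with a normal-approximation 95 % band.  The analytic
expectation (Mao's τ), E[S_k] = S − Σ_j C(n−n_j, k)/C(n, k), is
implemented with log-gamma arithmetic and agrees with exhaustive subset
enumeration (tested at n ≤ 8) and with the permutation mean as
n_perm → ∞.

Richness estimators are incidence-based, driven by Q1/Q2 (species in
exactly one/two units) over n units:

- Chao: S + ((n−1)/n)·Q1²/(2Q2), bias-corrected
  S + ((n−1)/n)·Q1(Q1−1)/2 when Q2 = 0 — applied to presence/absence
  data this is the incidence (Chao2) form; an abundance-based Chao1 is
  available separately (`chao1_abundance`).
- Jackknife-1: S + Q1(n−1)/n.
- Jackknife-2: S + Q1(2n−3)/n − Q2(n−2)²/(n(n−1)).  Note jack2 can fall
  below S when duplicates outnumber uniques; it is reported as defined,
  not clamped (matching vegan's behaviour).

Bootstrap CIs are percentile intervals over unit resamples with
replacement, B = 100 by default (the floor is 50), seeded.

## Rank-abundance models

Five models are fitted to the descending-sorted abundance vector by
maximum Poisson likelihood (ion counts are count data) and ranked by
AIC = −2 logLik + 2k, ties broken by fewer parameters:

| model            | expected abundance at rank r              | free parameters |
|------------------|-------------------------------------------|-----------------|
| broken stick     | (N/S) Σ_{x=r..S} 1/x                       | 0 |
| preemption       | N α(1−α)^{r−1} / (1−(1−α)^S)               | α |
| lognormal        | exp(μ + σ Φ⁻¹((S−r+0.5)/S))               | μ, σ |
| Zipf             | N p₁ r^γ                                   | p₁, γ |
| Zipf–Mandelbrot  | N c (r+β)^γ                                | c, β, γ |

Free parameters are optimized unconstrained through transforms (logit α,
log σ, γ = −e^t, …) with L-BFGS-B from a heuristic initial guess plus 4
seeded random restarts, because the Zipf–Mandelbrot surface is
multimodal.  Non-convergence is flagged on the fit object, never raised,
so the selection table always has five rows.  Zipf is nested in
Zipf–Mandelbrot at β = 0, and the nesting inequality
deviance(ZM) ≤ deviance(Zipf) is property-tested.  AIC is the sole
selection criterion; the residual SD is reported per fit for
information only.

## Inferential layer

Lilliefors normality: D = sup|ECDF − Φ((x−x̄)/s)|; the p-value defaults
to a seeded Monte-Carlo null (10⁴ standard-normal samples of the same n,
add-one corrected), since printed tables are approximation-dependent; a
statsmodels table approximation is available for speed.  ANOVA is the
classical one-way decomposition (scipy), Tukey HSD uses the studentized
range (scipy) with a compact letter display computed as the maximal
cliques of the non-significance graph.  Pearson r is reported with
R² = 100 r² (%) and the least-squares line.  Diversity ANOVAs use one
observation per sample (replicate-level H′), grouped by concentration or
by time; both groupings are exposed.

## Chemometrics

Normalization = optional cube-root transform, then per-feature scaling:
autoscale (x−mean)/sd, range (x−mean)/(max−min), Pareto (x−mean)/√sd.
The two mode presets mirror common practice for the two ionization
polarities (positive: no transform + autoscale; negative: cube root +
range).  Constant features are dropped with a warning.  PCA is a
centered SVD — scaling is the explicit upstream step, never repeated
inside PCA — with a deterministic sign convention (largest-magnitude
loading positive) and an elbow rule: keep the largest component whose
eigenvalue drop to the next exceeds the mean drop; `n_components` can be
pinned (e.g. 5) instead.  Heatmap inputs default to correlation distance
with average linkage; a reusable threshold filter keeps features whose
normalized abundance reaches ≥ 2 anywhere.

## Differential screening

Fold change is the ratio of raw group means (control in the
denominator); scaled data are never used here because scaling destroys
ratio meaning.  A zero group mean is replaced by a pseudo-count, by
default half the smallest positive abundance in the table; features
undetected in both groups are excluded and logged.  The volcano p-value
is a Welch t-test on log abundance with undetected values imputed at
half the feature's smallest positive abundance (per-variable half-min,
the standard missing-value treatment in metabolomics software): a
global floor would turn a dropout in a high-abundance feature into a
huge log outlier and destroy the test's power.  A feature passes at
FC ≥ 2 or ≤ ½ and p ≤ 0.05 (the p threshold is a documented default;
with < 2 replicates per group the screen runs FC-only and logs it).
Consolidation counts how often each feature recurs across comparisons
and keeps those seen ≥ 2 times (`frequency_filter`); plain deduplication
(`dedup_all`) is also exported because both bookkeeping conventions are
in circulation.  No multiple-testing correction is applied by default,
matching the workflow this mirrors.

## Annotation and enrichment

Neutral monoisotopic masses come from embedded IUPAC atomic masses
(C, H, N, O, S, P, Na, Cl); adducts are fixed electron-corrected shifts
for singly charged ions ([M+H]⁺ +1.007276, [M+Na]⁺ +22.989218,
[M−H]⁻ −1.007276, [M+Cl]⁻ +34.969402, [M+FA−H]⁻ +44.998201, water-loss
variants −18.010565).  Matching reports every (feature, compound,
adduct) candidate within ±5 ppm, sorted by |ppm|; retention time is
carried through but not used for matching (level-3 identification is
mass-only), with an optional rt-window filter off by default.  The
compound reference (TSV) and pathway sets (GMT) ship as local flat
files; no online queries.

Enrichment reports two p-values per pathway: the exact hypergeometric
upper tail over the annotated-compound universe, and a permutation p in
which random feature lists of the significant-list size are drawn from
all detected features, re-annotated through the same matcher, and scored
for ≥ k pathway hits (add-one corrected, seeded).  The permutation null
absorbs the m/z-annotatability bias that the plain hypergeometric
ignores; the two converge on fixtures where every feature annotates
uniquely and uniformly.

## Synthetic data

The generator emulates a 3-concentration × 5-time × 3-replicate
stress-course design at the scale of real positive/negative-mode
exports: a feature pool of 269 (positive preset) or 2807 (negative
preset) unique m/z_rt labels with lognormal template abundances
(μ = 8, σ = 1 on the log scale, i.e. ion counts around 3 × 10³);
per-condition baseline richness 195/1818; stress-dependent richness
decline at late times (28.2 %/37.3 % positive, 18.8 %/29 % negative, for
intermediate/severe stress); condition-exclusive "rare" features drawn
from the low-abundance tail of the pool (12/40 per declining condition);
multiplicative replicate noise (lognormal, σ = 0.2); independent
Bernoulli detection dropout (p = 0.1 per replicate × feature); and
spiked marker features (10 common features boosted 4-fold in stressed
conditions).  `spike_pathway` additionally injects features at the exact
theoretical adduct m/z of chosen reference compounds for end-to-end
enrichment tests.  A fixed seed gives bit-identical output, and the
returned truth object carries per-condition species sets, richness,
marker identities and spiked pathway compounds.

What the generator does *not* emulate: isotope envelopes, in-source
fragments and adduct multiplicity of one analyte, correlated
(co-eluting) features, retention-time drift, heteroscedastic
intensity-dependent noise, and batch effects.  Recovery results on this
generator therefore demonstrate the correctness of the bookkeeping and
the statistical machinery under the stated noise model, not performance
on real spectra.

## Problem sizes and numerical choices

Simulation-backed tests and the acceptance script run down-scaled
designs (pools of 60–80 features, 20 seeds, 100–200 permutations),
chosen so the full recovery studies complete in well under a minute
while keeping Monte-Carlo noise far from the decision boundaries; the
full-scale presets are exercised once per run.  Tolerances: estimator
identities are exact; Monte-Carlo comparisons use 3-standard-error
bands; the ZM/Zipf nesting check allows 1e-3 deviance slack for
optimizer jitter.  Degenerate inputs (all-zero vectors, single species,
single unit, constant samples) raise informative errors rather than
returning NaN, except inside model selection, where failed fits are
flagged rows.

## Known limitations

- The workflow reproduces published positive/negative-mode analyses
  only when given the corresponding export; the bundled compound and
  pathway references are small snapshots for annotation tests, not a
  full KEGG mirror, so pathway sizes are not comparable to a live KEGG
  query.
- The permutation enrichment draws features uniformly; a
  retention-time- or intensity-stratified null is not implemented.
- The Zipf–Mandelbrot fit can sit on a likelihood ridge for small S;
  restarts make selection stable but parameter values should not be
  over-interpreted there.
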