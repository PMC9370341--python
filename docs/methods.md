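# Methods

This note records the models, conventions and design choices behind
`sufucore`, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Odor activity and quantification

The odor activity value is implemented as **OAV = C / (100·T)** with C
in µg/100 g and T in µg/g. Published presentations of this quantity are
often unit-sloppy ("C·T·100" style); C/(100·T) is the only reading that
is dimensionally consistent with those units, and under it every
compound of the bundled flavor table clears its own screen (max OAV ≥ 1
at some timepoint) — which is what the table, by construction, is
supposed to show. The boundary is inclusive (OAV ≥ 1), and a compound's
characteristic status uses the **maximum** OAV across the series: a
compound that is flavor-active at any stage of the fermentation counts.

"Not detected" cells ("−" or blank) are stored as missing — they are
distinguishable from a measured zero — and enter OAV and correlation
computations as concentration 0, controlled by an explicit
`missing_as_zero` flag.

Internal-standard quantification C = A_x·C₀·V/(A₀·m) exposes a
`unit_factor` (default 0.1, mapping mg/L · µL / g onto µg/100 g) rather
than hard-coding a unit chain; GC-MS unit bookkeeping varies between
instruments and the factor makes the choice auditable. The Kovats
retention index is affine-invariant in the three retention times, which
the property suite checks.

The exploratory flavor PCA defaults to unit-variance scaling
(autoscaling, the usual chemometrics convention); mean-centering
without scaling is available. Constant compounds are dropped before
autoscaling. The published per-component percentages for this kind of
plot depend on the full (unpublished) compound list and the vendor
software's preprocessing, so they are reference values, not tests.

## Stages, dominance, alpha diversity

The default stage rule places day 0 in a separate "start" category and
screens only early (days 10–30) and late (days 60–130) stages: the
inoculation-day community reflects the dressing mixture rather than the
fermentation, and the screening stages follow the diversity-trajectory
break. The rule is a plain configuration object.

Dominance (">1%") is evaluated on the **stage-mean** relative abundance
with a **strict** inequality. Mean-over-stage (rather than
any-sample-over-stage) matches how per-stage dominant lists are
ordinarily compiled; the strict reading follows the wording ">1%".

Alpha-diversity conventions, chosen once and used everywhere:

* Chao1 in the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) — finite
  when no doubletons exist;
* ACE with rare cutoff 10 and the standard rare-class coefficient of
  variation; with no rare class it degenerates to S_obs, and when the
  rare class is all singletons (sample coverage 0) the bias-corrected
  Chao1 value is returned — both degenerate branches are documented in
  the docstring and exercised in tests;
* Shannon in natural log; Simpson reported as Gini–Simpson 1 − Σp²
  (the raw concentration Σp² is also exposed, since "Simpson" plots in
  the wild use either);
* Good's coverage 1 − F1/N.

Implementations are direct transcriptions of these formulas; the test
suite cross-checks them against scikit-bio on random count vectors.

## Spearman machinery

ρ is the Pearson correlation of mid-ranks (average ranks on ties),
vectorized as a rank-then-matrix-product for the all-pairs screens. The
default p-value is the two-sided t approximation
t = ρ√((n−2)/(1−ρ²)) on n−2 df, with |ρ| = 1 mapped to p = 0 by
convention; an exact permutation p (all n! permutations of the observed
values, ties as observed) is available for n ≤ 8 and the two agree
within 0.03 at n = 7 in the acceptance suite. Raw p-values are the
default — the screening rule is stated on raw p < 0.05 — with optional
Benjamini–Hochberg adjustment for users who want it. Constant columns
yield undefined correlations: an error in the scalar API, NaN-with-p=1
(never an edge) in the matrix path.

The count thresholds "more than 12" / "more than 7" default to strict
inequalities, faithful to the wording; an inclusive `at_least` mode
exists because published outcomes rarely disambiguate the boundary. The
degree rule "> 4" is handled identically.

Correlations use replicate-level samples within a stage (n = 9 under
the default design). When flavor data exist only as timepoint means —
as in the bundled table — the means are replicated across within-day
replicates with a loud warning: the correlations then effectively use
n = number of timepoints, and replicate-level flavor variation is
simply unavailable. This is a documented limitation, not a statistical
claim.

Compositional-correlation corrections (SparCC-style) are deliberately
out of scope: the screening chain being implemented uses plain Spearman
on relative abundances, and changing that would change the method.

## The core screen and the sign rule

Core = dominant ∩ strongly-flavor-associated ∩ degree > 4, per stage,
with deterministic output ordering (descending degree, then name) and a
full per-genus evidence table.

`ScreeningCriteria.flavor_sign` selects whether the qualifying-compound
count uses |ρ| (default, `both`) or positive correlations only
(`positive_only`). The distinction matters: fermentations contain
*antagonists* — abundant, network-central genera that suppress flavor
producers and correlate negatively with the flavor compounds. Under the
unsigned rule they satisfy all three criteria and are reported
alongside the promoters; under the promoter-only rule the core reduces
to the flavor formers. Both readings are defensible; the package
defaults to the unsigned rule and reports correlation signs so either
can be applied downstream. The synthetic-data recovery experiments use
`positive_only`, because their planted "core" is defined as the flavor
promoters (see below).

## Constrained ordination

RDA column-centers the species matrix (no transform by default; apply
Hellinger upstream if desired), standardizes the factors, projects by
least squares and eigen-decomposes the fitted covariance; the
constrained fraction is trace(fitted)/trace(total). CCA forms the
correspondence-analysis standardized residuals
Q = (P − rcᵀ)/√(rcᵀ), standardizes factors under row-mass weights and
projects Q onto the weighted factor space; total inertia equals the
table's chi-square statistic over its grand total. Constant and
collinear factors are dropped with a warning (greedy, in input order);
the sample count must exceed the supplied factor count.

The early-RDA / late-CCA pairing is kept as a default only; both
methods accept either stage. The usual rationale for such a switch is
gradient length — unimodal (CCA) responses fit long successional
gradients better than linear (RDA) ones — but with four factors and
nine samples per stage neither choice is sharply testable, so the
pairing is a convention, not a claim.

Both implementations are verified to 1e-10 against independent
hat-matrix / chi-square oracles on random matrices, and satisfy the
structural identities (fraction 1 under a spanning factor basis,
0 under orthogonal factors, inertia invariance under rescaling).

## The synthetic-data generator

The generator emulates the target study design — 7 days (0, 10, 20,
30, 60, 90, 130) × 3 replicates — with planted structure:

* **Stage progression.** Each screening stage gets a fixed latent
  gradient u: equally spaced normal quantiles over the stage's nine
  samples, ordered by (day, replicate). This encodes the monotone
  succession a ripening fermentation imposes; it also concentrates
  sample correlations around their population targets relative to an
  i.i.d. latent, which is what a designed time series does.
* **Gaussian copula.** Core genera load on u with a²= 0.95
  (pairwise genus–genus Spearman ≈ 0.94); each stage's planted
  compounds load so that the genus–compound **population Spearman is
  0.9** (latent Pearson 2·sin(π·0.9/6) ≈ 0.908). Monotone (lognormal)
  links map latents to abundances and concentrations, so the planted
  rank correlations survive the marginal transforms; with `noise_sd=0`
  every planted pair's sample Spearman is exactly ±1.
* **Defaults as study conditions.** 30 genera, 45 compounds; 5 early /
  3 late core genera; 18 planted compounds per early core genus and 12
  per late one (the screens require >12 / >7); 2 early and 4 late
  antagonists so that every core genus has six potential same-stage
  edges (degree > 4 requires five).
* **Antagonists, not "failing partners".** A subtle point dictated the
  design: with every threshold at |ρ| > 0.7, a positively coupled
  partner strong enough to donate a co-occurrence edge to a core genus
  is forced — by positive-semidefiniteness of the latent correlation
  matrix — to correlate above 0.7 with that genus's planted compounds
  as well, and (being dominant, as network nodes must be) would then
  satisfy all three core criteria itself. The only way to plant extra
  degree without planting extra core is antagonists: genera loading
  negatively on u, mirroring the Bacillus/Lysinibacillus-type
  inhibitors of real fermentations. They donate (negative) edges,
  correlate negatively with the compounds, and are excluded exactly
  when the promoter-only sign rule is applied — which is why the
  recovery experiments pair the default generator with
  `flavor_sign="positive_only"`. Under the unsigned default the
  antagonists are *also* reported, which is not an error but the other
  reading of the criteria.
* **Closure.** Abundances are closed to 1 by plain division; a large
  bulk genus with small independent noise (≈ 3/4 of total mass,
  emulating the single overwhelming genus typical of such ferments)
  keeps the denominator jitter far below the planted log-scale signal,
  so closure leaves planted ranks essentially intact (exactly intact in
  the zero-noise limit, as the tests check). Planted genera are a
  minority of total mass, keeping compositional spurious correlation
  small. A counts mode draws multinomial reads at configurable depth.
* **Environment.** Salt and total acidity couple to the early gradient,
  ethanol to the late one (Spearman target 0.9), on smooth trajectories
  qualitatively matching a ripening curd; moisture is near-stable.
  Exact published values are not emulated.

What the generator does **not** emulate: sequencing noise beyond
multinomial sampling, temporal autocorrelation beyond the monotone
trend, taxon-specific overdispersion, and compositional artifacts at
high planted mass. Passing recovery tests therefore demonstrate that
the chain's logic and thresholds behave as specified under the planted
model — they do not certify performance on real sequencing data.

## Problem sizes and determinism

All stochastic tests are seeded. The recovery experiment uses 20 seeds
of the default configuration (mean precision and recall of the planted
cores ≥ 0.9) and 500 replicates of the no-signal configuration (both
cores empty in ≥ 95%); a 3-point noise grid (noise multipliers 1, 2.5,
5; 20 seeds each) checks that recovery degrades monotonically on
average. These sizes give the Monte-Carlo assertions comfortable
margins while keeping the whole suite in the tens of seconds.
Identical configuration and seed reproduce byte-identical pipeline
reports; the config hash is recorded in each run log.

## Known limitations

* Flavor-table correlations from timepoint means (the bundled table)
  use effectively n = 7; significance at p < 0.05 then demands
  |ρ| ≳ 0.75, and results should be read as descriptive.
* The ANOVA grouping letters of the bundled table are not modeled.
* Network inference is plain Spearman thresholding — no compositional
  correction, no multiple-testing correction by default, no modularity
  analysis — because that is the method being implemented.
* RDA/CCA significance testing (permutation ANOVA) and variance
  partitioning are out of scope.
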