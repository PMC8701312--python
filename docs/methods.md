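# Methods

This note documents the statistical models implemented in `longicort`, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical and design decisions a maintainer
should know about.  No empirical claim here goes beyond what the test
suite and `scripts/acceptance.py` themselves compute.

## Symmetrized percent change

Thickness change between two scans is annualized and normalized by the
two-timepoint average:

    rate    = (CT_T2 − CT_T1) / ISI        [mm/year]
    average = (CT_T1 + CT_T2) / 2          [mm]
    CT_spc  = 100 · rate / average         [%/year]

This is the standard two-stage longitudinal reduction: each subject's pair
of registered maps collapses to one change map before any group model is
fitted.  CT_spc is exactly antisymmetric under exchanging the timepoints,
which the suite verifies bit-for-bit.  Vertices with `average ≤ 1e−6 mm`
are masked invalid rather than divided; the guard exists for degenerate
synthetic or pathological inputs and the mask propagates through the unit
system (`VertexMap` carries a mandatory unit tag; mixing mm with %/year is
an error by construction).

## Surface smoothing

Smoothing is explicit heat diffusion on the mesh graph:
`x ← x + τ·A⁻¹(W − D)x` with unit edge weights, vertex-area matrix `A`,
and a step `τ` fixed at one tenth of the stability bound
`min_v(area_v/degree_v)`.  The operator is linear, conserves the
area-weighted integral exactly (the graph Laplacian annihilates
constants), and never increases the area-weighted variance.

The iteration count for a requested FWHM is calibrated once per
(mesh, FWHM) by an impulse-response experiment: the response is regressed
as a Gaussian in geodesic distance (ln x against d²) and the iteration
count whose fitted FWHM best matches the request is cached, together with
the achieved FWHM, in the provenance sidecar.  On the 2562-vertex,
100-mm-radius sphere the default 10-mm kernel calibrates to 3 iterations
with a fitted FWHM of 9.96 mm.  Smoothing is applied to CT_spc after its
computation, not to the raw thickness maps.

## Vertex-wise GLM

One design matrix is shared across vertices; OLS is fitted per vertex in a
single vectorized solve, with a contrast t-map
`t = cᵀβ / √(σ̂²·cᵀ(XᵀX)⁻¹c)`.  Group is coded TD=0/ASD=1 and sex
male=0/female=1; continuous covariates are mean centered over a declared
centering population (all subjects, or ASD-only for the subgroup
analysis), and the quadratic age term is built from centered age and then
centered itself, keeping the design well conditioned over an adolescent
age range.  With this coding the group coefficient is the adjusted ASD−TD
difference in CT_spc, which is also the quantity the parameter-recovery
check compares against the generative slopes.

**Step-up model selection.**  Candidate models must be strictly nested.
The default aggregation pools the per-vertex residual sums of squares over
the cortex and performs one extra-sum-of-squares F test with degrees of
freedom scaled by the vertex count.  This is exact when vertices are
independent, and the type-I calibration test therefore uses spatially
independent (unsmoothed) null maps; under spatial smoothing the pooled
degrees of freedom are optimistic, which is documented here as a known
approximation (a conservative whole-cortex mean-p summary is available via
`summary="mean-p"`).  The per-step F maps are returned for inspection.

## Cluster inference

Clusters form as connected components (shared-edge adjacency, no geodesic
bridging) of `|t| > u`, `u = t_{1−p/2}(dof)` for a two-tailed forming
p (default 0.05, following the study design this pipeline reproduces; see
the caveat below).

**Nonstationary smoothness.**  Residuals are normalized to unit sum of
squares per vertex; squared differences along the three edges of each
triangle estimate the local variogram `dᵀΛd`, a 3×3 linear system per
triangle whose geometry factor is precomputed per mesh.  The local resel
density is `area·√(det Λ)/(4 ln 2)` and local FWHM `√(4 ln 2)/det(Λ)^¼`;
per-vertex resel densities (one third of incident triangle resels) make a
cluster's extent the sum of its members' resels — extent in units of the
local correlation area, the standard warped-space treatment of
nonisotropy.  On noise smoothed to a known 10-mm FWHM by the calibrated
smoother, the estimator recovers the kernel width within the tolerance the
suite asserts (20%).

**Corrected p.**  With `R2` total resels, dof `v`, and Euler
characteristic 2 for the closed search surface (no boundary term):

    ρ2(u)  = (4 ln 2)/(2π)^{3/2} · (1 + u²/v)^{(1−v)/2} · u
             · Γ((v+1)/2) / (√(v/2)·Γ(v/2))
    E[m]   = 2·P(T>u) + R2·ρ2(u)           expected cluster count, one tail
    E[N]   = R2·P(T>u)                      expected supra-threshold resels
    P(n≥k) = exp(−k·E[m]/E[N])              exponential extent tail
    p      = 1 − exp(−E[m*]·P(n≥k))         family-wise corrected

Two-tailed inference doubles the expected cluster count inside the
Poisson-clumping formula (`E[m*] = 2·E[m]`) rather than doubling and
capping the one-tailed p.  The two forms agree to first order in the
significant range; the chosen form is strictly monotone in cluster extent
everywhere, whereas the capped form collapses the great majority of null
clusters into an exact tie at p = 1, which would make the p-value useless
for ranking and for comparison against the permutation oracle.

**Caveat — liberal forming thresholds.**  A cluster-forming p of 0.05 is
unusually liberal, and the exponential extent approximation degrades
there.  On the synthetic study conditions (n = 70, 2562-vertex sphere of
radius 100 mm, 10-mm smoothing ≈ 1.3 mean edge lengths) the acceptance
suite measures the RFT route's family-wise error on seeded null cohorts
and finds it conservative — the observed cluster-extent tail decays faster
than the exponential model on this lattice, so corrected p-values are too
large by a factor of several at the decision threshold and the measured
FWER falls below the nominal 0.05 rather than above it.  The permutation
oracle under identical conditions is calibrated, and the two routes agree
closely in rank over the clusters the oracle can order.  Consequence for
users: RFT p-values from this module do not inflate false positives at
this resolution, but at liberal thresholds and coarse meshes the
permutation test is the authoritative inference, exactly as implemented in
`permutation_cluster_test` (Freedman–Lane residual permutation under the
reduced model, max-cluster-resel-extent null, seeded).

## Cohort statistics

Welch's unequal-variance t is the default two-sample test: it reproduces
the published group-comparison statistics from printed means/SDs/sizes
where the pooled form does not (the pooled form is retained as an option).
The 2×2 χ² defaults to the Yates continuity correction for the same
reason.  RBS-R items are scored as a total plus four factor sums
(persistent, stereotyped, self-injurious, compulsive); the item→factor
assignment is user-supplied configuration, since no canonical mapping
ships with the package.  Missing items (at most 3 of 43 per person per
timepoint; numeric sentinels are rejected at ingestion) are imputed by
single-imputation predictive mean matching: an OLS prediction from the
columns observed in that row, fitted on complete rows, a donor pool of the
k = 5 nearest predictions, and a seeded uniform draw from the donors'
observed values — so imputations always lie in the item's observed support
and complete rows pass through untouched.

## Brain–behavior correlation

Cluster features are unweighted means of CT_spc over member vertices (an
area-weighted option is recorded in provenance when used).  Pearson
correlations with two-sided p are adjusted by Benjamini–Hochberg over the
full cluster × measure family computed in one call — the widest, most
conservative family definition, recorded in the output.

## Decoding and enrichment

Decoding correlates each gene's expression profile across spatial samples
with the t-map at the sample vertices (parcel means when parcel-assigned).
Candidates require r > 0 and nominal p < α (default 0.05): the selection
targets spatially *similar* expression, and is a candidate-selection step,
not a hypothesis test; a signed mode also returning the dissimilar list is
available but off by default.  Enrichment of a candidate list against a
gene set over a declared universe N uses the hypergeometric upper tail
P(X ≥ a) (exact to 1e−12 against exhaustive pmf summation in the suite)
with the odds ratio from the 2×2 table; a zero cell gets the
Haldane–Anscombe 0.5 correction for the reported OR only (an empty overlap
reports OR = 0), never for p.  The default universe is the number of genes
in the supplied matrix — the tested population — with the study-scale
universe (20,787 protein-coding genes) available as configuration.  BH
adjustment spans all sets tested in one run.

## Synthetic cohort generator

The generator produces the study-shaped conditions the acceptance suite
runs under; its defaults are fixed, not tuning knobs:

| parameter | default | unit | rationale |
|---|---|---|---|
| n_asd / n_td | 33 / 37 | subjects | study sample sizes |
| mesh | icosphere s=4, r=100 | — | 2562 vertices; 100 mm is the spherical-template convention |
| baseline_ct | 2.7 | mm | adolescent mean cortical thickness |
| thinning_rate_td | −0.035 | mm/yr | mean two-year thickness change ≈ −0.07 mm over ISI ≈ 2.07 yr |
| group_rate_delta | 0 (plants: +0.02) | mm/yr | slowed ASD thinning inside planted patches |
| subject_sd | 0.12 | mm | between-subject spread of mean thickness |
| noise_sd | 0.05 | mm | per-timepoint measurement noise |
| age range / slope | 11–18 / −0.02 | yr, mm/yr | study age window; cross-sectional age effect |
| isi_mean / sd | 2.07 / 0.24 | yr | interscan interval distribution |

Thickness: `CT_T1 = baseline + subject_offset + age_slope·(age − mean age)
+ ε₁`; `CT_T2 = signal_T1 + ISI·(thinning_rate + delta·1[ASD]·1[patch]) +
ε₂` with independent per-timepoint noise.  Planted patches are geodesic
balls by Dijkstra over edge lengths, so they are connected in the same
adjacency the cluster finder uses.  RBS-R items are Poisson counts with a
gamma-distributed subject severity multiplier (hence marginally negative
binomial), truncated at the item maximum of 3, with group-specific
per-item means calibrated to the observed subscale totals (ASD total ≈ 25,
TD ≈ 2 — the zero-heavy TD distribution); published per-item distributions
do not exist, so the item-level parameters are under-determined by design
and documented as such.  Missingness is completely at random, capped at 3
items per person.  Expression matrices place samples at random vertices;
planted genes are the effect map at those vertices plus noise scaled to a
target expected correlation, remaining genes are iid noise.

One master seed feeds a named sub-stream per component (mesh, thickness,
behavior, expression, demographics), so changing one component's draw
leaves the others bit-identical.  Ground truth (planted labels, true
delta, planted gene ids) lives on a separate `truth` channel that analysis
stages never receive; the pipeline writes it to a separate `truth/`
directory.

**What the generator does not emulate** — and hence what green tests do
not show about real data: cortical folding geometry and registration
error (the template is a sphere, born in template space), spatially
structured scanner artifacts, site or motion effects correlated with
diagnosis, non-Gaussian heavy-tailed thickness noise, donor structure and
probe-level noise of real expression atlases, and spatial autocorrelation
of gene expression (decoding uses a parametric correlation p; a
spatial-permutation null would be the extension for real atlas data).

## Problem sizes in the validation suite

The acceptance tests run the full pipeline at the study's own scale
(n = 70 on the 2562-vertex sphere): 200 null replicates for the FWER
measurement, 12 planted-effect cohorts × 199 permutations for the
rank-agreement measurement, 50 replicates each for cluster detection and
decoding recovery, and all 2×2 tables with universe ≤ 200 for the
enrichment oracle.  These sizes give binomial/Monte-Carlo resolution well
inside the asserted tolerances while keeping the whole suite at a few
minutes on one CPU; `scripts/acceptance.py` reports each measured quantity
alongside the problem size used.

## Known limitations

- RFT cluster p-values are conservative at liberal forming thresholds on
  coarse lattices (measured, quantified above); use the permutation route
  for calibrated inference there.
- The pooled-F model-selection summary ignores spatial correlation.
- PMM is single imputation; between-imputation variance is not propagated.
- Parcel-assigned expression sampling is O(samples × parcel size) and
  meant for small sample sets.
- Anatomical labeling of clusters (atlas regions, stereotaxic
  coordinates) is out of scope; clusters are reported by vertex sets.
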