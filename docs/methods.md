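# Methods

## Data model and baseline adjustment

A plate experiment is a set of OD600 time series on a shared, strictly
uniform grid (default 0.5-h steps over 0–22 h, 45 points). Curves with
missing timepoints are rejected rather than interpolated; plate geometry is
not modelled because no analysis step uses well position. Every plate must
carry a media blank and a phage-free bacterial control.

Baseline adjustment defaults to *timewise blank subtraction*: the blank
well's OD at each timepoint is subtracted from every other well, and
negatives are clipped to zero (optical density cannot be negative). The
blank is read on the same plate at the same times, so reader drift and
condensation cancel. A per-well t=0 subtraction is available as an option
for plates without a usable blank. Double adjustment raises, and every
downstream analysis refuses unadjusted curves.

## Virulence scores

Areas under curves use the composite trapezoid rule on the native grid.
For each treatment well and its same-plate phage-free control:

* PhageScore = 100·(AUC_ctrl − AUC_trt)/AUC_ctrl over the full 22 h;
* local virulence score = the same ratio truncated at the index *before*
  the control's maximum OD (the control's entry into stationary phase).

Conventions worth making explicit:

* Ties on a plateaued control are broken by the *first* occurrence of the
  maximum — otherwise reader noise on the plateau would push the cutoff
  arbitrarily late. The minimum cutoff index is 1.
* Scores are computed per replicate against the matching control;
  mean ± SE aggregation across replicates is a separate reporting step.
* Negative scores (treatment outgrowing its control) are retained, not
  clipped: the ratio definition permits them and they are informative.
* Endpoint infectivity uses the closed interval [0.2, 0.5] for "somewhat
  successful"; both boundary values fall in the middle category.

## Fixed-effects factor model

Scores are regressed on phage, bacterium and MOI (all categorical — MOI has
exactly three levels by design) plus all two-way interactions, by OLS on a
treatment-coded design. Sums of squares are sequential (Type I) in the
order main effects → interactions; for the balanced or near-balanced
designs this package targets, the term order is immaterial (verified
empirically in the tests). F tests use the residual mean square of the full
model; p-values come from the F distribution with no multiplicity
correction. Rank deficiency after coding (e.g. confounded factors) is
detected from the QR diagonal and reported with the aliased term names.
The implementation keeps the orthogonalised design cached so that
simulation studies can refit hundreds of null responses cheaply; it is
cross-checked against `statsmodels.anova_lm(typ=1)` in the test suite.

## Ordination

Curve dissimilarity is the plain Euclidean distance between full adjusted
OD vectors. NMDS minimises Kruskal stress-1,
`sqrt(Σ(d_ij − d̂_ij)² / Σ d_ij²)`, where the disparities d̂ are the
isotonic (pool-adjacent-violators) regression of the configuration
distances on the rank order of the observed dissimilarities. Ties receive
the primary treatment (tied observed dissimilarities may get unequal
disparities, ordered by the current configuration distances).

Optimisation is by iterative majorization: isotonic disparity fit, then a
Guttman transform of the configuration. Stress-1 is scale-invariant under
this scheme and is checked to be non-increasing every iteration (a rise
beyond 1e-8 aborts). The first start is the classical-scaling
configuration; the remaining starts (default 20 total) are seeded random
Gaussians; convergence is a stress change below 1e-7 within 300
iterations. These defaults make the final stress reproducible across runs
at a fixed seed. Stress labels: < 0.01 good, 0.01–0.02 acceptable,
otherwise poor.

Factor effects on an ordination are quantified envfit-style. Categorical:
r² = 1 − SS_within/SS_total of the coordinates about level centroids, with
a label-permutation p-value `(1 + #{r²_perm ≥ r²_obs})/(1 + n_perm)`
(default 999 permutations). Continuous (used for log10 MOI): the arrow is
the normalised least-squares regression of the variable on the
coordinates, r² its coefficient of determination, same permutation scheme.
PCA of the curve matrix (covariance eigen-decomposition via SVD) serves as
a linear sanity check on how much variance a 2-D view can capture.

## Clustering and pattern labels

Hierarchical agglomeration uses the ward.D convention: the Ward
Lance–Williams update applied directly to the unsquared Euclidean
dissimilarities, with deterministic lowest-pair-index tie-breaking. (This
is deliberately not the ward.D2/squared-distance variant implemented by
`scipy.cluster.hierarchy.linkage`; the tests therefore validate the merge
order and heights against an exhaustive re-agglomeration oracle.)

The cluster count is chosen by the gap statistic: B = 100 reference sets
drawn uniformly over the bounding box of a classical-scaling embedding
(up to 10 informative axes), W_k from the squared dissimilarities, and the
standard first-SE rule. k can always be fixed from config instead.

Clusters get semantic labels from curve features, not by eye:

* final OD (mean of last three points), peak OD, lag (last time before OD
  exceeds 0.1), time-to-stationary (first time OD ≥ 95% of final OD), and
  a regrowth flag;
* Group 2 = lowest median peak OD (killing); Group 1 = highest median
  final OD among non-regrowing clusters (resistant growth — phage-free
  controls always land here); everything else = Group 3;
* Group 3 is re-clustered on its own subset; regrowing subclusters become
  3.1–3.3 (3.1 = longest lag, then 3.2 < 3.3 by final OD), non-regrowing
  become 3.4 < 3.5 by final OD. The subgroup count defaults to 5 but is
  configurable (3.2/3.3 and 3.4/3.5 are similar enough that merging them
  is a defensible alternative).

The regrowth flag is true when a curve either rises above 0.1, falls back
below 0.1 and rises again, or starts suppressed — below 0.1 with no net
growth (OD at 2 h ≤ 1.1× its initial value) for at least 2 h — and only
later grows out. The no-net-growth clause is essential: without it, slow
but steady impaired growers that merely cross the threshold late would be
misread as killed-then-recovered. Feature thresholds default to 0.1
absorbance, midway between the adjusted baseline and the 0.2 successful-
infection endpoint bound.

The repeatability audit groups assignments by (phage, bacterium, MOI) and
flags any combination whose replicates disagree in group or subgroup.

## Coculture simulator

State variables (per mL): susceptible cells S, phage-resistant cells R,
latently infected cells I, free phage P, cumulative lysed cells D.

    dS/dt = r·S·(1 − N/K) − δ·S·P
    dR/dt = c_r·r·R·(1 − N/K) + μ·r·S·(1 − N/K)
    dI/dt = δ·S·P − I/τ
    dP/dt = (β/τ)·I − δ·S·P
    dD/dt = I/τ,                N = S + R + I

with OD(t) = α_od·(S + R + I + debris_frac·D), clipped at a saturation
ceiling of 1.2. Defaults: S0 = 1e8 CFU/mL (overnight culture diluted to
working density), r = 0.85 h⁻¹, K = 2e9 cells/mL, τ = 0.5 h, β = 100,
α_od = 3.5e-10 absorbance·mL/cell (so a full-density culture reads
OD ≈ 0.7), debris_frac = 0.1 (lysed cells keep a tenth of their optical
contribution — turbidity does not distinguish live from dead biomass).

Assumptions and approximations:

* The latent period is an exponentially distributed stage of mean τ
  (Markovian), not a fixed delay; this avoids delay equations at the cost
  of a smeared burst. At the 30-min output resolution the difference is
  not visible.
* μ is an *effective* resistance-supply parameter: it absorbs both de novo
  mutation and any standing partially-resistant subpopulation present at
  inoculation. Calibrated values for the regrowth presets (0.06–0.2) are
  far above per-division mutation rates and should be read as "fraction of
  growth flux feeding the resistant lineage", not as a mutation rate.
* Free phage have no decay term, so any preset with δ > 0 and β > 1
  eventually burns through the susceptible population. The
  impaired-growth archetypes are therefore modelled host-side (reduced r
  and K, phage inert) — the observable shapes pin the phenotype, not the
  mechanism, and partially-resistant hosts growing slowly to a lower
  plateau are a parsimonious reading.
* Integration uses LSODA with rtol 1e-8, atol 1e-6·S0; states are floored
  at zero, and a negative excursion beyond 1e-3·S0 is an error. An
  independent fixed-step RK4 oracle at dt = 1e-3 h agrees to < 1e-4 OD in
  the tests.

### Archetype presets

Seven packaged presets reproduce the canonical pattern features
(noise-free): unimpeded logistic growth (final OD 0.70, stationary at
7 h); full killing (endpoint < 0.2, no recovery); slow regrowth after a
~9-h suppressed phase to final OD 0.45; sharp regrowth from ~7 h to 0.5;
the same shape with the highest plateau 0.75; impaired growth to 0.26 by
9.5 h; impaired growth to 0.45 by 12 h. Free parameters per preset
(carrying capacity → final OD; resistance supply μ → lag/onset; host rate
r → time-to-stationary) were calibrated once by grid refinement
(`scripts/calibrate_presets.py`) and ship as constants.

### Study generator

A synthetic study lays out one plate per (bacterium, replicate): every
phage × MOI treatment for that strain plus a phage-free bacterial control
(logistic), a bacteria-free phage control and a media blank (flat
background, 0.04 absorbance). Raw wells are background + signal with
measurement noise — multiplicative lognormal (sd 0.02) then additive
Gaussian (sd 0.005), clipped at zero — small relative to the 0.2/0.5
endpoint thresholds, as appropriate for a modern plate reader. The default
pattern map mirrors the qualitative structure of a realistic screen: nine
of eighteen phages never infect, one phage kills every host, two hosts are
broadly resistant, and the remaining combinations cycle through the
in-between patterns deterministically. The well's actual MOI overrides the
preset MOI, so higher MOI kills earlier and scores respond to MOI. The
generator returns a truth table (combination → generating pattern) for
parameter-recovery tests; identical seeds give identical studies.

What the generator does **not** emulate: biological between-replicate
variability (replicates differ only by measurement noise), stochastic
timing of resistant-mutant emergence, plate edge/position effects,
pathlength or temperature artefacts, phage cocktails, and co-evolution
beyond a single resistant lineage. Consequently, passing recovery tests
shows the analysis machinery is correct and well-calibrated, not that real
data will cluster this cleanly: real replicates of borderline combinations
straddle group boundaries, which is precisely what the repeatability audit
is for.

One consequence of the clean generator deserves a note: on synthetic
studies the seven archetypes form genuinely separated tight clusters, so
the gap statistic keeps improving past k = 3 and settles at its k_max
rather than the three coarse groups. The semantic feature-based labelling
is deliberately robust to this: however finely the tree is cut, clusters
collapse onto groups 1/2/3 (and 3.1–3.5), and truth-table agreement on
default-noise studies is 100% at every seed we tried. On real data, where
within-group spread is large, the gap choice and the semantic grouping are
expected to coincide at small k.

## Problem sizes and determinism

The test suite and the reproduction script use a reduced study — 6 phages
× 4 bacteria × 3 MOIs × 3 replicates (216 treatment wells + controls on 12
plates) — which exercises all seven patterns and keeps a full pipeline run
around a minute on one core. All randomness flows from a single top-level
seed expanded into per-stage seeds (numpy SeedSequence); NMDS, the gap
statistic, subclustering and permutation tests are bitwise reproducible at
fixed seed, and pipeline outputs carry the config hash and seed.

## Known limitations

* The ODE model is deterministic; it cannot produce the one-in-a-few-wells
  stochastic regrowth events seen in real screens.
* Ward heights are checked for monotonicity but non-fatal violations are
  only logged (the ward.D criterion on arbitrary dissimilarities is not
  guaranteed ultrametric).
* The sequential-SS ANOVA assumes a (near-)balanced design; heavily
  unbalanced score tables make the Type I decomposition order-dependent.
* Endpoint categories use replicate-level final ODs inside `score_plate`;
  combination-level averaging happens in the aggregation step, so a
  borderline combination can be "somewhat successful" on average while
  individual replicates split.
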