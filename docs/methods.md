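# Methods

This note documents the models implemented in `lewontin`, the defaults and
why, what the synthetic-data generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Census sizes from macroecology

Census size is approximated as N_c = D·R: population density D (individuals
per km²) times range area R (km²). Density is rarely measured, so it is
predicted from body mass through a log-linear abundance–body-size
(Damuth-type) allometry, log₁₀D = a + b·log₁₀m; when only body length is
available, mass is first predicted from length through a second log-linear
allometry with near-cubic scaling. Both regressions are ordinary least
squares on the log₁₀ scale. The default density coefficients
(a = 4.23, b = −0.78, log₁₀ individuals/km² versus log₁₀ g) are a
documented stand-in trained on a packaged *synthetic* density–mass table of
696 rows (`census_allometry.synthetic_density_table`, masses log-uniform
over 10⁻³–10⁷ g with lognormal scatter of SD 0.5 dex); supplying a real
training table to `fit_loglog_allometry` overrides them. Point predictions
use the plug-in two-stage fit; Monte-Carlo draws from the coefficient
covariance plus the residual scale propagate uncertainty when asked. A
joint hierarchical fit of both allometries would give more honest
intervals; the point predictions coincide, so the two-stage fit is the
default.

Taxa with an observed mass skip the length→mass stage and are flagged
(`mass_predicted = False`).

## Range estimation

A species range is the α-shape of its occurrence coordinates: the union of
Delaunay triangles (planar, in lon/lat degrees) whose circumradius is at
most α. Large α recovers the convex hull; small α allows concavities and
holes. Defaults: α = 6° for terrestrial taxa, 20° for marine taxa (marine
occurrence data are sparser, so the marine shape is more permissive); both
are per-call overridable. A taxon is terrestrial when at least half of its
occurrences fall on the supplied landmass polygons (the exact-tie goes to
terrestrial), and ranges are clipped — terrestrial ranges intersected with
land, marine ranges minus land. Point sets that cannot support an α-shape
(fewer than three distinct points, or collinear) fall back to the union of
100 km buffers around the points, so degenerate taxa get an automated,
reproducible range rather than a manual fix.

Areas are geodesic on a sphere of radius 6371 km, computed by the
spherical-excess line integral with edges treated as linear in lon/lat and
densified to ≤ 0.25°; the result is exact for latitude–longitude cells
(1°×1° at the equator = 12,364 km²), additive over disjoint parts, and
invariant to longitude rotation. Geometries straddling the antimeridian are
detected by a >180° longitude jump and re-expressed in [0°, 360°) when that
representation is strictly tighter; `split_at_antimeridian` produces
canonical GeoJSON output. Limitations: ranges ignore habitat suitability
and anthropogenic fragmentation, so N_c is overestimated for patchy or
depleted species and underestimated for dense commensals.

## The phylogenetic mixed-effects model

For traits y and x on the log₁₀ scale across n species with a
time-calibrated, ultrametric phylogeny:

y = α + βx + u + ε, u ~ MVN(0, σ_p²·C), ε ~ N(0, σ_r²·I)

where C is the Brownian-motion covariance of the tree scaled to unit height
(C_ij = shared root-to-MRCA path length; diagonal exactly 1 — scaling makes
σ_p² identifiable). The phylogenetic signal λ = σ_p²/(σ_p² + σ_r²) is
computed draw-wise from the posterior, so λ ∈ [0, 1] holds exactly.

Inference marginalizes u: y ~ MVN(Xθ, σ_p²C + σ_r²I). With the
eigendecomposition C = QΛQᵀ computed once, rotating the data by Qᵀ makes
the covariance diagonal and each likelihood evaluation O(n). Sampling uses
a differential-evolution ensemble sampler (emcee; 80% `DEMove`, 20%
`DESnookerMove`) with 32 walkers, 1500 burn-in and 2000 retained sweeps by
default; walkers are treated as chains for split-Rhat and effective sample
size (arviz). A fit is `converged` only when every parameter has
Rhat < 1.01 and ESS > 1000; non-convergence is flagged, never silently
accepted. Stretch moves were rejected during development because they
missed this bar at comparable cost. Priors are weakly informative on
centered/scaled data — normal(0, 10) for α and β, half-normal(0, 1) for σ_p
and σ_r; coefficients are reported back on the original scale, variance
components on the standardized scale (λ is scale-free). Fixed seed and
settings give bit-identical posterior summaries.

Phylum-level subsets (≥ 10 complete taxa) prune and re-scale the subtree;
if the full model misses the convergence bar the fit is repeated without
the phylogenetic term and flagged `reduced`. Degenerate situations are
flagged rather than fatal: C numerically the identity
(`unidentifiable-lambda`), constant predictor (`degenerate-design`),
vanishing residual variance (`degenerate-residual`).

The recombination map-length model reuses this machinery on
log₁₀L = a_L + b_L·log₁₀N_c + u + ε, a lognormal model linear in log₁₀N_c
(the curvature of the real relationship is left out deliberately —
documented choice, since the appropriate functional form is not settled).
Social taxa are excluded before fitting (social insects have adaptively
longer maps) and listed in the returned metadata; natural-scale predictions
apply the lognormal half-variance correction exp(σ²ln²10/2).

## Contrasts, node-height tests, ancestral states

Standardized phylogenetic independent contrasts follow Felsenstein's
pruning recursion; under constant-rate BM with rate σ² they are iid
N(0, σ²). The same recursion evaluates the exact BM likelihood (contrast
terms plus a root term), which the tests verify against the dense
multivariate-normal likelihood to 10⁻⁸.

The node-height test regresses |standardized contrast| on node age (Myr
before present, tips at 0) by Huber M-estimation (tuning constant 1.345,
MAD scale); a negative slope means the rate of trait evolution increases
toward the present. The default p-value is the robust-SE Wald test. The
permutation alternative permutes node *ages* across contrasts (conditioning
on contrast magnitudes): permuting trait values across tips would destroy
the BM covariance itself and has essentially no power, which was measured
directly. No automatic outlier trimming is done.

Ancestral states are maximum-likelihood BM estimates in GLS closed form:
the root is the GLS mean (1ᵀC⁻¹y)/(1ᵀC⁻¹1) and each internal node is its
conditional expectation given the tips.

Non-ultrametric input trees are repaired by extending tip branches when the
worst deviation is ≤ 10⁻³ of tree height (rounding slop in published
chronograms), otherwise rejected.

## Linked-selection predictions

π_BGS+HH = θ / (1/B + 2NS) with θ = 4Nμ, B = exp(−U/L), S = γJ/L. The
sweep coalescence rate is implemented as γ·J/L — dimensionally, sweeps per
generation times the trapping probability, diluted by map length; this is
the only reading consistent with (i) S ≈ 10⁻⁸–10⁻⁷ for L ∈ [10, 100] at the
Drosophila parameters, (ii) stronger reductions for short-map species, and
(iii) the ~85% D. melanogaster reduction. The alternative product form γLJ
is available behind `sweep_form="product"` for sensitivity analysis.
Predicted θ_eff = 4NμR is passed through the four-alleles map *after* the
reduction; a flag disables the transform for raw-θ work.

Drosophila parameter bundle: U = 1.6 per diploid genome per generation;
γ = α·m/2T = 2.26×10⁻³ per generation from α = 0.42 of substitutions
beneficial, m = 4.52×10⁵ substitutions on the D. melanogaster–D. simulans
divergence path (back-solved for consistency with γ, flagged as such) and
T = 4.2×10⁷ generations (4.2 Myr at ten generations per year);
J = 4.5×10⁻⁴; G = 9.66×10⁷ bp (consistent with ν = γ/G = 2.34×10⁻¹¹ and
the euchromatic autosome length); map length 1.05 M for the within-species
85% computation (provisional — chosen as the value reproducing that printed
reduction). μ spans 10⁻⁹–10⁻⁸ per bp per generation. By default N is the
census size (`Ne_mode="use_Nc"`, the stress-test assumption); `fixed_Ne`
reproduces within-species computations.

The across-taxa band is the raw pointwise min/max envelope of per-taxon
prediction curves over a log₁₀N_c grid at the two μ bounds; smoothing is
left to plotting so the envelope is deterministic and testable. Taxa
missing map length are skipped and listed. Out of scope: genome
heterogeneity in recombination and functional density, soft/partial sweeps,
selective interference (omitting it makes the predicted reductions
conservative upper bounds).

## Biomass validation

For each phylum, the sample's implied carbon biomass is
b = 0.15·Σᵢ mᵢNᵢ·10⁻¹⁵ Gt C (0.15 = (1 − 0.7)·0.5: 70% water, carbon half
of dry mass). Derived consistency columns against the global per-phylum
carbon biomass B and described species counts T: biomass proportions of
each total, the over-representation factor (prop b / prop B), the sampled
fraction f = n/T, and the ratio b/(f·B) — observed sample biomass relative
to a random n-of-T sample. Masses are grams internally, Gt (10¹⁵ g) at the
reporting boundary. The packaged reference table carries the printed
per-phylum inputs.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, not
any particular clade: a pure-birth chronogram (exactly ultrametric by
construction); log₁₀ body length and log₁₀ range area evolving by BM on the
unit-height tree (range clamped to Earth-plausible [10², 1.5×10⁸] km²);
mass and density through the log-linear allometries with lognormal noise;
log₁₀π = a + b·log₁₀N_c + u + e with the BM effect u and iid noise e
empirically rescaled so Var(u)/(Var(u)+Var(e)) equals the target λ
*exactly*, making λ a true recovery target; π clamped below 3/4 (the
four-alleles ceiling); map length log-linear in log₁₀N_c with optional
social taxa given threefold longer maps. Occurrence points are uniform over
a polygon's spherical area (latitude drawn uniform in sin φ, rejected
against the polygon). Every generator is a pure function of its seed; each
stage draws from its own sub-seeded generator so stages are independently
reproducible.

Defaults are the study conditions the package tests itself against: 166
taxa, diversity slope 0.0531 per decade (a 13% increase per order of
magnitude), λ = 0.67, total diversity scatter 0.31 dex, density slope
−0.78, μ ∈ [10⁻⁹, 10⁻⁸]. Under these defaults N_c spans ≥ 8 orders of
magnitude (typically 11–12).

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: spatial sampling bias in occurrence
records, technical noise heterogeneity across collated diversity estimates,
non-equilibrium demography, mutation-rate variation across clades, and any
dependence of diversity on life history beyond the modeled N_c effect. The
generative model for π dispersion is an idealization and is labelled as
such in outputs.

For the rate-shift power scenario, "a rate multiplier on branches in the
recent epoch" is defined at the branch level: branches lying entirely
within the epoch get multiplier × σ²; branches crossing the boundary keep
the base rate. The time-dependent alternative (only the in-epoch *portion*
of each branch inflated) is available behind `whole_branch=False`; it
smears the shift into nearly every contrast — because almost all branches
terminate at the present — and roughly halves the node-height test's power,
which is why branch-level membership is the scenario definition used in the
calibration tests.

## Problem sizes and numerical choices

Calibration studies run at sizes chosen to make Monte-Carlo error small
relative to the acceptance bands while keeping the suite quick: 50
replicate 166-tip datasets for credible-interval coverage (90% intervals,
band 80–97%), 200 null and 100 shifted replicates at 100 tips for
node-height calibration and power, 50 taxa × 500 occurrence points for
census recovery. Ultrametry is enforced to 10⁻⁶ relative (10⁻⁹ for
generated trees); eigenvalues of C are clipped at zero; ties in realm
classification go to terrestrial; the α-shape of exactly collinear points
is an error by design (buffer fallback). Species absent from the tree are
dropped with a logged manifest before any phylogenetic fit.

## Known limitations

Single-CPU MCMC only; no Ornstein–Uhlenbeck or multi-rate comparison; no
Pagel's-λ branch-length transformation (the variance-ratio λ is the
implemented quantity); planar-in-lon/lat α-shapes distort at high latitude
(areas, however, are geodesic); the default allometry coefficients are
synthetic stand-ins until a real training table is supplied.
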