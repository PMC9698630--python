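# Methods

`rapaflux` implements an integrated analysis for locating metabolic drivers of
rapamycin overproduction under chemical-elicitor treatments (DMSO, LaCl3,
sodium butyrate) in *Streptomyces hygroscopicus*: multivariate biomarker
scoring, weighted co-response network modules, pathway impact analysis, and
constraint-based screening of gene targets.  Because the raw metabolomics and
the organism's genome-scale model are not publicly distributed, the package
ships a synthetic-data generator that reproduces the study design and a
compact surrogate metabolic network; every statistical and numerical claim the
test suite makes is checked against these.

## Synthetic data generator (`synthgen`)

**Design.** 4 conditions (control + 3 elicitors) x 3 sampling times (12, 24,
48 h after elicitor feeding at 72 h) x 4 biological replicates = 48 samples;
93 metabolites (83 GC-MS, 10 LC-MS sugar phosphates).  The panel uses the
named compounds of the study's module tables plus indexed real-metabolite
padding.

**Model.** Intensities are log-normal.  For a planted module with members
*j*, samples *i*:

    log10 x_ij = b_j + c_i + g_i + e_ij,
    c_i = effect_size * T(t_i) * 1[condition_i = responsive],
    g_i ~ N(0, tau^2),  e_ij ~ N(0, noise_sd^2),

with time response `T = {12h: 0.6, 24h: 1.0, 48h: 0.7}` peaking at 24 h
(where treatments separate most clearly).  The module-shared variance `tau^2`
is solved from `within_module_cor = (Var(c) + tau^2) / (Var(c) + tau^2 +
noise_sd^2)` so the expected pairwise member correlation over the whole
design equals the requested value; if the planted shift alone already exceeds
the target the shared factor is clipped to zero with a warning.  Non-members
are independent log-normal noise.

**Defaults** (chosen once, during the recovery calibration of the module
stage): `noise_sd = 0.3` (log10 units), `within_module_cor = 0.84`,
per-module effect sizes 1.4 (DMSO module), 1.25 (each sodium-butyrate
module), 1.5 (LaCl3 module).  The graded effect pattern mirrors the observed
association strengths, where the two SB modules are the weakest — and it is
also what keeps those two modules statistically separable, since they share
the same responsive condition.

**Yield trait.**  `yield_i = m(condition_i) + sum_j w_j z_ij + N(0, (0.05
m)^2)` with condition means 112.59 / 161.16 / 157.03 / 151.80 (arbitrary
titer units, control / DMSO / LaCl3 / SB) and standardized-driver weights
`{PEP: 25, pyruvate: 20}`, so phosphoenolpyruvate and pyruvate are planted as
the strongest yield correlates.  The driver term adds within-condition
variance beyond the 5% CV of the error term; this is intentional, otherwise
no metabolite could correlate with yield beyond the condition contrast.

**What it does not emulate:** chromatographic drift, batch effects, missing
values, heteroscedastic detector noise, metabolite-metabolite correlations
outside the planted blocks, and any real biochemical covariance between the
padding metabolites.  Passing tests therefore certify the algorithms against
a known ground truth, not performance on real GC-MS data.

## Normalization (`preprocess`)

Default log10 transform then autoscaling (zero mean, unit *sample* variance,
n-1 denominator, consistent with the correlation tests downstream).  Pareto
scaling (`(x - mean)/sqrt(sd)`) is available.  Zeros count as missing: a
column with more than `missing_threshold` zeros is dropped under the drop
policy, otherwise zeros are imputed with half the column's minimum positive
value before the log.  Constant columns cannot be autoscaled and are set to 0
with a warning.

## Multivariate stage (`multivariate`)

PCA is a plain SVD of the normalized matrix (`scores = X @ loadings`), with
each loading's largest-|entry| made positive for sign determinism.

PLS is NIPALS with deflation of both blocks.  Two responses are fitted: a
one-hot treatment matrix (PLS-DA, for biomarker VIP) and the centered
rapamycin yield (for yield association).  Convergence: weight change below
1e-12 or 500 iterations; if the cap is reached with residual motion below
1e-6 (near-degenerate response eigenvalues, where any direction in the
degenerate subspace is equally valid) the component is accepted with a
warning, otherwise an error names the component.

VIP for metabolite *j*:

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ),
    SSY_a = ||q_a||^2 t_a' t_a,

which satisfies `sum_j VIP_j^2 = p` exactly.  Biomarkers are metabolites with
VIP strictly greater than 1.0 (tier-2 flag above 1.5).  Yield association is
reported both as the per-metabolite Pearson r (sorted by |r|, sign kept) and
through the single-response PLS fit; the two emphasize the same planted
drivers.

## Co-response network modules (`modnet`)

Unsigned weighted correlation network on the 24 h samples only (n = 16: 4
conditions x 4 replicates) — the time point where the treatments separate —
with adjacency `a_ij = |cor|^beta`, topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage clustering of `1 - TOM`, and a static height cut.  Defaults:

* `power = 9`.  The standard unsigned-network recommendation for fewer than
  20 samples; chance correlations at n = 16 are large and need a high power
  to be suppressed.  `pick_soft_threshold` implements the scale-free fit
  criterion (sign-adjusted R^2 of log p(k) vs log k over >= 8 connectivity
  bins, smallest power reaching the target, best-fit fallback) for data-driven
  choice.
* `cut_height = 0.9`, `min_module_size = 3`.  With beta = 9 and realistic
  within-module correlation (~0.85 at 24 h) the within-module TOM
  dissimilarity sits near 0.6–0.8 while background pairs sit above 0.97, so
  the cut lies in the gap.  (A cut at the eigenprofile-merging scale of 0.25,
  sometimes quoted for module *merging*, would label everything grey under a
  static cut on 1 - TOM; this package's default is therefore 0.9.)
* Modules are labelled M1, M2, ... by decreasing size (ties by first member
  name); clusters below the minimum size are grey.

Each module is summarized by its eigenprofile — the first principal component
of the standardized member profiles, unit sample variance, oriented positively
with the module's average profile.  Module–treatment association uses binary
per-treatment indicator traits, Pearson r, and the two-sided Student-t
p-value on n-2 df.  A module is selected for a treatment when `r > 0.65` and
`p < 0.01`, both strict.  No multiple-testing correction is applied (the
screening rule is used as reported).  At n = 16 this rule needs r above
~0.62 just for the p criterion, so moderately associated modules can fall on
either side of the cut on a given simulation — the same regime the reported
module correlations (0.66–0.81) live in.

## Pathway enrichment (`enrich`)

Over-representation is the exact hypergeometric upper tail `P(X >= k)` for
`k` hits out of a size-`M` pathway, a size-`n` mapped query, and a background
of `N` compounds.  The default background is the pathway library's compound
universe (`background_size = 1600` for the bundled database), matching the
convention of web pathway-analysis tools when no custom reference metabolome
is supplied; a measured-metabolome background is configurable but makes small
amino-acid queries (k ~ 4, M ~ 20, N ~ 50) insignificant and fails to
reproduce the reported treatment-wise pathway lists.  Pathway impact is the
summed normalized betweenness centrality of hit compounds divided by the sum
over all pathway compounds (endpoint pairs excluded); an edge-free pathway
(e.g. aminoacyl-tRNA biosynthesis) has impact 0 by construction.

Screening rule: `p < 0.05` and `k >= 3`, no correction.  Modules selected for
the same treatment are pooled into one query per treatment by default.  The
bundled database holds 12 hand-curated pathways (pentose phosphate;
phenylalanine/tyrosine/tryptophan biosynthesis; aminoacyl-tRNA; nicotinate and
nicotinamide; glycine/serine/threonine; valine/leucine/isoleucine
biosynthesis; plus glycolysis, TCA, fatty-acid biosynthesis, starch/sucrose,
pyruvate and glyoxylate metabolism as negative controls) with compound sets
and graphs reduced to the measured chemical space.  It is a surrogate for a
full KEGG-derived library: compound coverage and graph topology are
simplified, and absolute p-values depend on the curated set sizes.

## Constraint-based screening (`gsmm`)

**Model container.** Stoichiometric model with bounded, optionally reversible
reactions; fluxes in mmol/(gDCW.h), biomass flux in 1/h.  JSON round trip
with schema validation naming the offending reaction.

**FBA.** `max c'v  s.t.  S v = 0, lb <= v <= ub` via HiGHS.  Among alternate
optima the reported vector additionally minimizes `||v||_2` (a quadratic
program with the optimal objective pinned), giving MOMA a deterministic
wild-type reference.

**MOMA.** `min ||v - v_wt||^2` over the mutant polytope.  Both QPs are solved
by eliminating the equality rows with an SVD nullspace basis and running an
exact primal active-set projection in the reduced coordinates (KKT solves
with multiplier-sign add/drop steps, initialized from a feasibility LP
point).  The returned flux vector satisfies `||S v||_inf` at nullspace
accuracy (~1e-12, asserted < 1e-8 in tests) and matches an independent SQP
solver to 1e-6 on random networks.

**Perturbations.** Knockout: both bounds to 0.  Overexpression: the
reaction's bound in its wild-type flux direction is pushed to `factor x
|v_wt|` (default factor 2; a wild-type-silent reaction is forced to `factor x
1e-3` mmol/(gDCW.h) forward; bounds are clipped to the reaction's capacity
with a warning).  This "force the flux" encoding is the standard in-silico
overexpression convention; the factor is configurable.

**Scoring.**  `f_PH = w * (mu_mut/mu_wt) + (1-w) * (q_mut/q_wt)` with
`w = 0.5` — a weighted arithmetic mean of the dimensionless growth and
rapamycin-secretion ratios; a geometric-mean variant is selectable, and the
two order the tested perturbations identically.  A no-op perturbation scores
exactly 1; promising targets score above 1.  `screen_targets` evaluates a
candidate list of (reaction, strategy) pairs against the constrained
wild type and returns the top-k by f_PH (ties by reaction ID).

**Surrogate network** (`synthgen.build_toy_model`).  49 reactions / 46
metabolites: glycolysis, two-lump TCA, oxidative phosphorylation (P/O = 2),
oxidative + non-oxidative pentose phosphate pathway, carbonic anhydrase,
GDH and GS/GOGAT nitrogen assimilation, the aspartate -> lysine ->
pipecolate route with a lysine-degradation branch through glutaryl-CoA, the
shikimate branch from DAHP to chorismate splitting into phenylalanine and
the DHCHC starter unit, lumped methylmalonyl-CoA supply, and a lumped
rapamycin synthase consuming 1 DHCHC + 7 methylmalonyl-CoA + 1 pipecolate +
4 NADPH.  Ten curated target reactions (r532, r279, r47, r51, r381, r274,
r18, r23, r293, r421) appear with their full curated stoichiometries.  Lumped
steps conserve the model's own P/N/redox bookkeeping but are not atom-exact.

Two calibration choices shape its behavior under the measured constraints
(glucose <= 1.08, ammonium <= 0.132, phosphate <= 0.0074 mmol/(gDCW.h);
rapamycin exchange lower bound 2.1e-5 mmol/(gDCW.h), converted from 0.021
umol):

* biomass P stoichiometry (0.131 P per unit biomass) makes phosphate the
  growth-limiting nutrient, putting the wild-type growth rate at 0.0565 1/h —
  the physiological magnitude of the fermentation it imitates — while glucose
  stays in excess, leaving slack for flux redistribution toward the product;
* the oxygen exchange is capped at 0.36 mmol/(gDCW.h), ~0.15% above the
  wild-type respiratory requirement.  This keeps ATP supply tight enough that
  the NADPH-linked glutamate dehydrogenase (not the ATP/NADH-costly GS/GOGAT
  cycle) carries nitrogen assimilation at the minimum-norm optimum, as it
  does in N-replete cells; without the cap the quadratic tie-break prefers
  the bypass and the GDH knockout would be a no-op.

With this fixture the four leading strategies (DAHP synthase, transketolase
and G6P-dehydrogenase overexpression; GDH knockout) all raise the rapamycin
secretion ratio above 1 through the same two levers as claimed for the
organism — NADPH availability and DHCHC starter-unit supply.  The f_PH
magnitudes are surrogate-specific (the forced product rate is tiny, so
ratios are large) and only their direction and ranking are meaningful.

## Pipeline and reproducibility

`pipeline.run_pipeline` executes preprocess -> multivariate -> modules ->
enrich -> screen, writing per-stage TSVs before the next stage starts and a
sorted-key JSON report; identical config + seed reproduce every output byte
for byte (graph construction and all reductions use sorted iteration).  The
`rapaflux` CLI exposes `run-all` plus per-stage subcommands.

## Numerical choices

* sample standard deviation (n-1) throughout; Pearson correlations via the
  population form (consistent numerator/denominator);
* component/loading signs: largest-|entry| positive;
* deterministic tie-breaks: metabolite name (VIP, correlations), first member
  name and size (module labels), reaction ID (target ranking);
* p-value underflow guard: the smallest positive double;
* LP/QP tolerances: HiGHS defaults (~1e-9 feasibility); active-set
  projection uses 1e-9 feasibility and 1e-10 multiplier tolerances;
* degenerate inputs: constant metabolites get zero correlation (logged),
  constant traits are excluded, all-zero columns are dropped.

## Known limitations

* The synthetic generator plants block covariance only; module recovery
  rates (ARI >= 0.9 in >= 95% of seeds at defaults) do not transfer to real
  data with correlated backgrounds.
* The bundled pathway database is a reduced surrogate; absolute enrichment
  p-values are not comparable to a full KEGG analysis.
* The surrogate metabolic network reproduces directions and rankings, not
  absolute fluxes; the reported growth-rate prediction belongs to the
  study's own (undistributed) genome-scale model, and only its magnitude is
  mirrored here.
* PLS-DA is fitted without cross-validation or permutation validation, as in
  the workflow it reproduces.
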