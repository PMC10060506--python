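# Methods

This note records the modeling choices behind `gmfa`: the assumptions of the
generalized flux framework, the numerical decisions in the twin fit, the
defaults and what they mean, what the synthetic-data generator does and does
not emulate, and the limitations a user should keep in mind.

## Generalized stoichiometry

The framework's core move is to treat non-metabolic clinical read-outs
(pulse wave velocity, carotid intima-media thickness, reactive hyperemia
index, systolic blood pressure, BMI, urine pH) as nodes of the same
stoichiometric system as the metabolites, under the assumption that — like
the metabolite concentrations — they change quasi-linearly along the
disease-progression extent.  "Stoichiometric coefficients" on edges touching
physiological nodes are couplings, not mass balances; they default to 1 and
are overridable per edge.  The matrix S uses the standard flux-analysis sign
convention (substrates negative, products positive) and is validated for
dangling references, duplicate ids, inverted bounds and all-zero columns.

Because heterogeneous units (mmol/L, m/s, mm, %) enter one objective, all
state arithmetic happens on a per-node z-score scale: node i's raw value r
maps to (r − mean_i)/sd_i using reference statistics stored on the node.
Source/sink nodes are unobserved boundary pools; they carry no reference
statistics and are assigned the identity scale (0, 1) internally.

### The packaged example map

The example type 2 diabetes map has 24 nodes and 24 fluxes covering the
glucose arm (Food→Glucose→{ROM, Triglycerides}, glycation fluxes
Glucose/ROM/Haemoglobin→HbA1c), the lipoprotein arm (Food→{HDL, VLDL},
HDL+VLDL→LDL→ox-LDL), the iron/oxidation arm (Inflammation→Ferritin→ox-LDL,
Inflammation→hs-CRP), heme catabolism (Haemoglobin→Bilirubin→Bile), protein
turnover (Food→Protein→{Urine-pH, Creatinine}) and the vascular arm
(ox-LDL→PWV→Systolic-BP, RHI→CIMT left/right, BMI→Systolic-BP).  Reference
means/SDs are cohort summary statistics typical of a type 2 diabetes
population where published (e.g. fasting glucose 8.89 (3.18) mmol/L, HbA1c
8.60 (1.84) %, PWV 8.35 (1.74) m/s, CIMT 0.65 (0.13) mm).  Two read-outs are
usually summarized as median (IQR); their SDs were derived with the normal
approximation SD ≈ IQR/1.349 (hs-CRP 1.45 (2.3) mg/L, ROM 271 (53)).  Nodes
without published summaries carry standard clinical reference values (serum
protein 70 (5) g/L, urine pH 6.0 (0.7), VLDL 0.84 (0.4) mmol/L, bilirubin
10 (5) µmol/L, haemoglobin 14 (1.5) g/dL).  The edge set is an example
reconstruction — a plausible, fully connected wiring of the named nodes —
and is labeled as such; every pipeline stage is model-agnostic.

## Digital twin fit

With a single cross-sectional time point there is no basis for discretizing
the extent integral finer than one step, so the state equation is
linearized as x = x_A + S v over one extent unit, and both x and v are
decision variables (x eliminated by substitution).  The program is

    min_v  Σ_i w_i (x_i − y_i)² + λ‖v‖²,   lb ≤ v ≤ ub,
           band_i: fitted raw value within ±w of reading i (observed nodes)

* **window_fraction w = 0.20.**  The soft-constraint band is applied on the
  raw measurement scale ("within ±20%" reads as relative to the measured
  value) and then mapped per node into z-units.  For readings with |y| <
  1e-9 the relative band degenerates and is replaced by an absolute band of
  0.2 reference SD.
* **ridge λ = 1e-6.**  S is column-rank-deficient for most interesting maps
  (parallel routes, unobserved boundary pools), so the pure least-squares
  twin is not unique.  The ridge makes the program strictly convex — twins
  are unique and bit-reproducible — while being ~6 orders of magnitude below
  typical data terms, so it does not visibly bias the fit.
* **weights.**  Observed nodes weigh 1 (overridable per node), unobserved
  nodes 0 and carry no band.  Population-mean-imputed readings participate
  like observations: the imputation is recorded per patient, and the
  association screen excludes imputed entries from its tests.
* **solver.**  Bounded ridge least squares (BVLS) first; if a band binds,
  the full QP via `trust-constr` with exact gradient/Hessian followed by an
  active-set KKT polish (the interior-point iterate is snapped onto its
  active constraints; the polished point is accepted only if feasible and
  not worse).  This yields band-edge solutions exact to machine precision.
* **infeasibility.**  When the bands and flux bounds are jointly infeasible
  (outlier patients), the bands are relaxed with a squared-hinge penalty
  (weight 1e3) and the twin is flagged `relaxed_optimal`; cohort pipelines
  skip only `failed` twins and log both counts.  This keeps batch runs from
  halting on single patients.
* **equivariances.**  Changing a node's unit (readings and reference stats
  together) leaves the normalized solution unchanged; repeated solves agree
  to 1e-8.  Both are enforced by tests.

Flux bounds default to [−10, 10] z-units per extent unit when a spec omits
them: wide enough to be non-binding for plausible cohorts, finite for solver
stability.

## Extent, reference states, distances

The extent of a state x is its scalar projection onto the A→B segment:
ξ(x) = (x − x_A)·(x_B − x_A)/‖x_B − x_A‖².  It is affine and deliberately
unclipped — states outside the segment report ξ < 0 or ξ > 1 — preserving
linearity.  State A defaults to the all-reference-means state (0 in
z-units).  For state B two constructions are provided:

* `disease_state_from_cohort`: the cohort's mean displacement from A defines
  the disease direction; B sits at the 97.5th percentile of the cohort's
  projections onto it — just past the sickest patients observed.  This is
  the default when a fitted cohort exists.
* `unit_flux_trajectory`: x_B = x_A + S·1 (unit flux on every edge, clipped
  to bounds).  This cohort-free construction is the synthetic generator's
  default, because the generator must define a trajectory before any cohort
  exists; it also guarantees S v_AB = x_B − x_A exactly, which makes
  parameter recovery well-posed.

Both endpoints are overridable by explicit state files (CSV of node_id,
value in raw units).  The flux template v_AB between two arbitrary states
is the bounded least-squares solution of S v = x_B − x_A.

Two metrics compare flux states.  The Euclidean distance is the plain ℓ2
norm.  The **health state distance** is implemented as a k-nearest-neighbour
graph geodesic (Isomap-style): a symmetric k-NN graph (k = 10 by default,
Euclidean edge weights) over the cohort's flux vectors, query states wired
to their k nearest cohort points, shortest path by Dijkstra.  This is the
standard construction of a manifold-respecting metric; the exact weighting
of the original formulation is not recoverable, so the choice is documented
here prominently and k is configurable.  Zero-length edges are stored with
weight 1e-300 because sparse-graph routines treat explicit zeros as absent.
If the query states fall in disconnected components the metric falls back
to Euclidean with a warning.  k = 10 balances locality against
connectivity for cohorts of a few hundred; with k → n−1 the geodesic
reduces to the Euclidean distance on convex clouds (tested).

The complication-free reference state is the component-wise **median** flux
vector over patients without the diagnosis — medians, not means, so single
outlier twins cannot drag the reference.

## Association screening

Each reading variable and each flux is tested against the phenotype with
the two-sided Wilcoxon–Mann–Whitney test.  For smaller-group sizes ≤ 8 the
null distribution of U is enumerated exactly over all label assignments
(ties handled exactly; two-sided P = 2·min(P(U ≤ u), P(U ≥ u)) capped at
1); above that, the normal approximation with tie and continuity
correction.  The switch point keeps full enumeration below ~13k
assignments.  Multiplicity is controlled by Benjamini–Yekutieli (valid
under arbitrary dependence — fluxes sharing nodes are strongly correlated),
readings and fluxes adjusted as **separate families** to mirror the
two-table reporting structure; family sizes are logged.  Associations with
FDR ≤ 15% are reported, sorted by P.  Constant variables are skipped with a
warning; imputed entries are excluded from the readings family.

Kendall's τ (tau-b, tie-corrected) with asymptotic two-sided P quantifies
the correlation between the distance metric and the logistic output; for
n ≤ 6 the P is computed by exact permutation enumeration.  Note the normal
approximation is coarse at such n (deviations up to ~0.2 in the far tail),
which is why the exact branch exists.

## Risk models

The resampling design balances unequal case counts: per iteration, half of
the positives and an equally sized random draw of negatives (without
replacement) train the logistic model; the held-out remainder is scored and
its AUC recorded.  Fifty iterations give the median AUC and its IQR;
coefficients are averaged over the first ten refits and parametrize the
final scoring function (features z-scored on the full sample for scoring,
on the training fold during fitting; coefficients are reported on the
standardized scale because flux magnitudes are heterogeneous).  Separation
in small folds is detected as |standardized coefficient| > 50 and handled
by a ridge-penalized refit (penalty 1e-4).  AUC is computed as the
Mann–Whitney concordance probability with ties counting 0.5, which makes
AUC(s) + AUC(−s) = 1 exactly and equals the trapezoidal area under the
tie-aware ROC step curve.

Twilight-zone exclusion removes samples whose score lies strictly inside a
central percentile band of the score distribution before evaluating
discrimination; the five standard bands (45–55 … 25–75) and the degenerate
no-exclusion band (50, 50) are presets.  The exclusion defines the
analyzable sub-population, so it applies to training and testing alike (a
`test_only` evaluation can be assembled from the retained index set).

Risk quadrants: high risk = upper quartile jointly in logistic score and in
distance to the complication-free state; low risk = lower quartile in both;
the rest intermediate.  Quartiles use linear interpolation between order
statistics (the convention of the common statistical environments, making
thresholds reproducible).  Fisher's exact test (two-sided, sum of
hypergeometric probabilities ≤ the observed table's) measures risk-group ×
diagnosis coincidence over the low+high patients.  Group flux profiles are
reported as (group median − population median)/population IQR per flux,
sign preserved; zero-IQR fluxes report 0 with a warning.

## Synthetic cohorts

The generator emulates the generative structure the twin fit assumes:
latent extent ξ_i ~ Uniform(0,1) (or Beta), true fluxes v_i = ξ_i v_AB +
N(0, σ_v²), diagnosis y_i ~ Bernoulli(sigmoid(β0 + β_ξ ξ_i + β_v v_i[j*])),
group-specific flux shifts added to diagnosed patients, readings = raw
scale of (x_A + S v_i) plus N(0, σ_x²) in z-units, MCAR missingness.
Labels derive from extent plus one named flux — never from the readings —
so flux-based risk models have a recoverable planted signal and the
simulation's causal diagram is explicit.

Defaults, fixed once as the package's reference study conditions: n = 300
patients, σ_x = σ_v = 0.05, missing rate 0.05, label model β0 = −2.5,
β_ξ = 2, β_v = 2 on the glucose-glycation flux (≈40% prevalence, matching
ophthalmic-complication rates in type 2 diabetes cohorts), and a +2
flux-unit shift on the lipoprotein-remodeling flux in the diagnosed group
for planted-effect experiments.  Everything is reproducible bit-for-bit
from (config, seed).

What the generator does **not** emulate: informative missingness (MCAR
only, by design), assay detection limits and floor/ceiling effects,
heavy-tailed or skewed biomarker distributions (ferritin and triglycerides
are notoriously log-normal), medication effects, longitudinal correlation,
or model misspecification (readings are generated from the same S used for
fitting).  Passing recovery tests therefore demonstrates the pipeline's
internal consistency and statistical calibration, not clinical validity on
real data.

## Problem sizes and numerical checks

The test suite and the acceptance script run at sizes chosen to exercise
every code path while staying desk-scale: twin-QP verification on 100
random 3-node/3-flux instances against a dense 0.01-step grid search over
the feasible flux box; exact-WMW verification on 200 instances with group
sizes ≤ 8 against direct enumeration; BY against its closed form on random
p-vectors; distance axioms on 1000 random triples; recovery and resampling
on the 300-patient reference cohort; null calibration via 20 label
shufflings of that cohort and 1000 WMW null repetitions at n = 12 per
group.  Degenerate inputs are handled explicitly: empty cohorts and groups
raise, all-missing nodes are dropped with a warning, constant variables are
skipped, zero IQRs are flagged, disconnected graph components fall back to
Euclidean, twilight band (50, 50) retains everyone.

## Known limitations

* The example map's edge set and coupling coefficients are a documented
  reconstruction, not a validated physiological model; absolute flux values
  on it are meaningful only relative to the map.
* The one-step extent linearization cannot capture curved trajectories; the
  extent projection is only as meaningful as the A/B endpoints chosen.
* The manifold metric depends on k and on cohort density; for small cohorts
  (< ~5k) the k-NN graph may shortcut across the manifold.
* Twin uniqueness comes from the ridge term; fluxes in the null space of S
  restricted to observed nodes are determined by the regularizer, not the
  data, and should be interpreted with care (the per-flux recovery report
  makes this visible).
* WMW exact enumeration is O(C(n, n1)) and intentionally capped at
  smaller-group size 8.
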