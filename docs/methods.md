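# Methods

This note documents the models, conventions and design choices behind
`sepclust`, in the order data flows through the pipeline.

## Synthetic cohorts

The generator emulates a two-cohort ICU study (development + external
validation) with a planted cluster structure and ASE-relevant event
patterns. It exists because real patient-level ICU data cannot be shared;
it is first-class, tested code, not a fixture.

**Latent mixture.** Each patient draws a cluster from mixing proportions
`mix`; cluster means for the `n_cont` continuous features are sampled
N(0, δ²) per coordinate (δ = `separation`, default 5 — planted clusters are
recoverable by K-means at ARI > 0.9, which is the regime the downstream
recovery tests require), patients are N(μ_c, I), and an ε fraction of
outliers comes from an inflated-variance component N(μ_c, 25·I) so that
robust trimming has something detectable without shifting cluster means.
Binary features are per-cluster Bernoulli with rates drawn U(0.1, 0.6).
A `structure_seed` separates the population parameters (means, Bernoulli
rates, diagnosis mixtures) from patient-level sampling: two cohorts with
the same `structure_seed` and different `seed`s are independent samples
from one population — the development/validation design. With a single
`seed` the tables are byte-reproducible.

**Events.** All events carry 1-based integer hospital days (the ASE
criteria operate at day granularity; no clock times). Labs (lactate,
creatinine, eGFR, bilirubin, platelets) follow piecewise-constant baselines
drawn from normal reference ranges with 3% measurement noise, observed
daily for up to 8 days. Septic-cluster patients receive a blood-culture
day and either a *severe* profile (probability `p_sev`: ≥5 consecutive
antimicrobial days and organ-dysfunction excursions crossing the default
ASE thresholds — lactate always, renal/liver/hematologic/ventilation/
vasopressor with fixed sub-probabilities) or a *near-miss* profile
(probability `p_mild`: exactly 3 antimicrobial days and lab excursions
landing between the liberalized and default thresholds). Consequently,
with `p_sev = 1` every septic-cluster patient is default-ASE positive, and
with `p_sev = 0, p_mild = 1` none is, while all pass the fully liberalized
combined variant.

**Background rates.** Non-septic patients receive blood cultures (20%),
antimicrobial runs of 1–3 days (48%), ventilation (33%) and vasopressors
(11%), plus *sterile* organ derangements at typical ICU rates
(hyperlactatemia 30%, acute kidney injury 30%, thrombocytopenia 20%,
cholestasis 10%). These choices serve two purposes: the cohort marginals
land near a mixed ICU population (culture ≈ 37%, antimicrobials ≈ 59%,
ventilation ≈ 39%, vasopressors ≈ 19%, mortality ≈ 11% once septic
patients are included), and organ-derangement variance is spread across
all clusters rather than concentrated in the septic one — without this,
lab-summary features would carve the septic cluster into organ-combination
subgroups and the elbow would overcount k. Background patients never reach
four antimicrobial days, so they are never default-ASE positive; default
prevalence therefore equals the septic share times `p_sev` (≈21.5% under
the study-condition mix).

**Missingness** deletes lab rows (the observation was never recorded)
independently per lab name at configurable rates, e.g. 0.403 for the
lactate analog.

**What the generator does not emulate:** real pharmacology, ICD coding,
time-of-day structure, correlated missingness, inter-lab correlation
beyond the excursion patterns, or admission casemix drift between cohorts.
Passing tests therefore demonstrate algorithmic correctness and
recoverability under the planted model, not clinical validity on real EHR
data.

## Preprocessing

Fixed order: time-series summaries → static encoding → prevalence filter →
collinearity filter → mean imputation → standardization; deterministic and
rerun-stable.

* Lab summaries use the sample SD (n−1); single observations get SD = 0 so
  the dispersion feature is defined for every observed patient.
* Binary indicators use full dummy encoding; the <1% prevalence filter
  (strict `<`) removes rare and empty levels afterwards.
* Collinearity is pairwise-greedy in column order with |r| > 0.9 on
  pairwise-complete rows; the later column of a violating pair is dropped
  (deterministic, order-stable). Constant columns count as r = 0.
* Continuous columns are z-scored with the population (n) denominator;
  binaries stay 0/1 — z-scoring indicators would distort prevalence
  interpretation. Constant continuous columns become zeros with a warning.
* Outcome variables (death, discharge day) and ids never enter the
  matrix; derived lengths of stay do.

## KMO + PCA reduction

Per-variable sampling adequacy MSA_j compares squared correlations with
squared partial correlations from the (pseudo-)inverse of R. The filter is
iterative by default: drop the single worst variable and recompute until
all MSA ≥ 0.6, the standard MSA practice (a `single_pass` mode is
config-exposed). An exactly diagonal correlation matrix makes the
statistic 0/0; the convention here is 0 with a warning.

PCA runs on the already-standardized matrix (correlation-scale). The
number of components is the smallest m with cumulative explained variance
≥ the target (0.95; equality qualifies). Eigenvector signs are fixed by
making each component's largest-magnitude loading positive, so results
reproduce across linear-algebra backends.

## Clustering bench

All algorithms satisfy one contract: exactly k non-empty 1-based clusters
when feasible (empty clusters are re-seeded with the farthest point) and
determinism given the seed. K-means variants and the Gaussian mixture
delegate to scikit-learn; CLARA (PAM build+swap on ≤5 subsamples of size
40 + 2k, best medoid set by total dissimilarity on the full data) and the
SOM (smallest square grid ≥ 4k units, online training with exponentially
decaying learning rate and neighborhood, codebooks grouped into k clusters
by K-means) are implemented here. A deep-clustering auto-encoder is *not*
in the default registry — it needs a training stack this package does not
depend on — but `register_algorithm` accepts any
`(X, k, params, seed) → ClusteringResult` plug-in.

**RSKC conventions.**

* Initialization is k-means++ on weighted distances, made *trim-aware*:
  the ⌈αn⌉ currently-farthest points are excluded from seed sampling.
  Without this, gross outliers (the points trimming exists to discard)
  are near-certain seed choices and every restart starts pathological.
* Restarts are compared by the **trimmed weighted within-cluster sum of
  squares** (cases outside O_W ∪ O_E). A between-cluster criterion would
  prefer restarts whose centers sit on a few far-away kept cases; the
  within-criterion is the robust choice. The weighted between-cluster
  objective is still computed and reported.
* When the L1 bound is at its maximum (s ≥ √p) the sparsity device is
  inactive by convention: weights stay uniform at 1/√p and the procedure
  reduces exactly to (trimmed) Lloyd K-means. This makes the
  α = 0, s = √p case a strict K-means equivalence, which the test suite
  verifies from shared initializations.
* Δ in the weight update is found by 80 bisection steps on [0, max b];
  Δ = 0 is used when the unthresholded weights already satisfy the bound.
  The final labels assign *every* case — including trimmed ones — to the
  nearest weighted center.

**Elbow.** WCSS is computed per k (one seed stream per (algorithm, k):
`seed + k`); both axes are min-max normalized and the selected k maximizes
perpendicular distance to the chord joining the curve's endpoints. Ties
and exactly linear curves resolve to the smallest k with a warning. The
detector is pluggable; k is never a constant of the pipeline.

## Evaluation

Silhouette, Davies–Bouldin and Calinski–Harabasz delegate to scikit-learn
(singleton silhouette = 0; DB errors on identical centroids; CH returns an
infinity sentinel when W = 0). Shannon diversity uses natural logs; the
Gini index is the mean-absolute-difference form Σ|n_i−n_j| / (2k²n̄).
Ranks are direction-aware with average ranks on ties; the final ordering
follows the rank sum strictly, breaking ties alphabetically and flagging
them — note the published eight-algorithm comparison's final-rank column
is not consistent with its own rank sums for the middle of the field, so
only the top-two identification is treated as reproducible.

Stability: B subsamples of 80% without replacement; R runs with distinct
seeds per subsample; per-subsample agreement is the mean pairwise ARI (and
NMI, geometric-mean normalization, switchable to arithmetic) over at most
`pair_budget` (default 200) random run pairs — pairwise comparison keeps
the full 200 × 100 protocol feasible while desk-scale defaults are
B = 50, R = 20 (tests and the acceptance script use B = 20, R = 10, sizes
chosen to exercise the protocol at desk scale). The stability score is the
coefficient of variation across subsamples.

## Membership model and attribution

The external-assignment model consumes the post-KMO *variables*, not the
PCA scores (the scores stay clustering-only). Hyperparameters (learning
rate, depth, subsample ratio, boosting rounds) are tuned by sequential
model-based optimization — a Matérn-5/2 Gaussian process over the
normalized box, expected-improvement acquisition over 256 random
candidates, 8 random initial points — maximizing mean stratified k-fold CV
accuracy (log-loss available; folds default to 5, capped by the smallest
class). A pure random-search mode is config-selectable; budget = 1 fits a
single random configuration. Assignment takes the maximum predicted
probability with ties to the smallest cluster id (logged).

Attributions are exact tree-SHAP values from the boosted ensemble itself,
satisfying additivity per class (baseline + Σ contributions = margin,
tolerance 1e-4). For binary models the single positive-class margin is
mirrored with a sign flip so both classes report attributions.

## ASE engine

Day windows are inclusive integer-day intervals. QAD is the longest run of
consecutive antimicrobial calendar days whose first day lies within
±window of the culture day; gaps break runs. The discharged-alive rule
(variant i) lets a shorter run qualify when it extends to the
discharged-alive day. Baselines follow the encounter-extremum convention:
minimum creatinine and bilirubin, maximum eGFR and platelets over the full
encounter (the CDC toolkit's look-back windows are simplified to the
encounter). eGFR is a supplied lab series; no creatinine-based equation is
computed.

Comparison conventions: strict `>` for the lactate threshold (matching the
"> 1.5 instead of > 2.0" phrasing of the liberalized table), `≥` for the
ratio and absolute criteria stated with ≥. The hematologic rule requires
an adequate baseline; that floor is a separate field fixed at 100·10⁹/L
across variants — tying it to the (liberalizable) platelet threshold would
make relaxing the threshold *tighten* the rule and break the monotonicity
guarantee that liberalized variants only add positives. Variant j combines
a–d with the 3-day window (f), the 3-day antimicrobial minimum (h) and the
discharged-alive rule (i); g (4-day window) is deliberately not part of j.

Percentages in composition and reclassification reports round to one
decimal; medians/IQRs use linear-interpolation quantiles. Standardized
differences use d = (p₂−p₁)/√((p₁(1−p₁)+p₂(1−p₂))/2) for proportions and
the pooled-SD form for continuous variables, classed at |d| = 0.2/0.4/0.8.
(Published two-cohort tables are not consistent in sign direction across
rows; magnitudes are the comparable quantity.)

## Numerical conventions and degenerate inputs

* Empty cohorts yield empty tables with headers; n < k is a config error.
* Fully-missing feature columns fail imputation loudly with the column
  name; near-singular correlation matrices fall back to the pseudo-inverse
  with clipped diagonals.
* All stochastic stages take explicit seeds; the pipeline derives stage
  seeds from one master seed and records them in `manifest.json` together
  with a configuration hash (output path excluded) and package version.

## Known limitations

* The generator's event model is minimal: one excursion window per
  patient, no competing events, no correlated multi-organ trajectories.
* CLARA and SOM are compact reference implementations adequate for
  desk-scale cohorts, not high-performance ones.
* The bench excludes hierarchical clustering, HDBSCAN and latent-class
  models by design; ASE status is never used as a clustering label or an
  external validity index — it is a comparator analyzed after the fact.
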