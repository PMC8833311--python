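# Methods

## Analysis model

The pipeline treats a subject's ICA component time courses as a
multivariate series whose second-order structure switches between a small
number of recurrent covariance regimes ("brain states"). Connectivity is
Pearson correlation; windowed estimates use rectangular windows of 30 TR
sliding by 1 TR, so a series of length T yields T − 30 windows under the
default counting convention (225 for T = 255). The alternative
T − W + 1 convention is available via `WindowSpec(count_convention=
"n_minus_w_plus_1")`. An optional Gaussian taper (σ in TR) can weight the
samples inside each window; the default is untapered.

Windowed correlation vectors are Fisher-transformed before clustering and
testing: atanh is variance-stabilizing for correlations, making squared
Euclidean distance in pair space comparable across the correlation range.
Values with |r| ≥ 1 − 1e−7 (degenerate windows) are clamped before atanh
and logged.

Two orders of Fisher transform vs. nuisance residualization exist in the
literature and both are kept explicit rather than unified: the **dynamic
path** transforms windowed correlations first and residualizes subject
covariates (age, sex, mean FD) across subjects at the test stage; the
**static path** residualizes subject-level correlation vectors and then
transforms. The choice is a config concern, not hidden behaviour.

## State clustering

K-means uses squared Euclidean distance with k-means++ initialization and
`n_replicates` restarts (default 100 in the pipeline; the validation
studies use 10, which the recovery results show is sufficient at their
separation levels); the restart with the lowest within-cluster sum of
squares wins. State ids are assigned by descending total occupancy, so
"State 1" is always the dominant state.

The number of states is chosen from the validity curve
v(k) = within-cluster dispersion / between-cluster dispersion. The elbow
is defined as the k maximizing the ratio of successive drops,
(v(k−1) − v(k)) / (v(k) − v(k+1)). A raw second difference was
considered and rejected: on a convex decreasing curve the largest second
difference almost always sits at the smallest k, whereas the quantity of
interest is where the curve turns from steep to flat. On cohorts with four
separated generator states the drop collapses by nearly an order of
magnitude after k = 4, and the ratio criterion selects 4; the raw second
difference selects 3 on the same curves. A curve whose successive relative
drops all stay below `flat_tol` (default 5%) is declared elbow-free; the
smallest k is returned with a warning.

Cross-run or run-vs-ground-truth state correspondence uses Hungarian
assignment maximizing summed Pearson correlation between centroid
pair-vectors (`match_states`). All recovery scores are computed after this
matching, so they are invariant to the arbitrary k-means numbering.

## Group statistics

The pairwise group test permutes group labels of the subject-level vectors
and compares the observed Welch t against the permuted distribution,
p = (1 + #{|t*| ≥ |t|}) / (n_perm + 1), with a shared permutation set
across pairs and Benjamini–Hochberg correction across the C(C−1)/2 pairs.
Note an interaction between the permutation count and FDR: with m pairs
and a single true effect, BH at q requires p ≤ q/m, so n_perm must exceed
m/q for a lone discovery to be possible at all (10,000 permutations for
741 pairs at q = 0.05). This is why the default permutation count is not
lowered in reduced-scale runs of the pair tests.

Dynamics metrics use two-way (group × state) ANOVA with type-II sums of
squares — cell sizes are unbalanced by construction because state-wise
comparisons include only subjects who visited the state. Post hoc
comparisons are Kruskal–Wallis, Tukey HSD, rank-sum, or the permutation
t-test, reported uncorrected. Occurrence rates use the pooled
two-proportion z-test; a pooled proportion of exactly 0 or 1 returns
p = 1 (no information). Severity associations are plain Pearson
correlations, uncorrected. A constant-response ANOVA returns F = 0, p = 1
for all effects rather than 0/0.

## Classification

Per state, the feature matrix holds each visitor's mean windowed Fisher-z
vector restricted to pairs with both endpoints in {VIS, FPN, DMN}. The
LOOCV protocol is leakage-safe by construction: for each held-out subject,
feature z-scoring statistics, the regularization strength λ (chosen by
inner stratified 5-fold CV over a linearly spaced grid from near-dense to
the analytic all-zero λ_max = max |X^T (y − ȳ)|), and the final L1 fit all
use training rows only. Ties in the inner CV go to the larger penalty
(sparser model). Selection frequency is the fraction of outer folds in
which a feature's weight is non-zero; maps threshold at 10%. The leakage
guard in the validation module re-runs the whole protocol on permuted
labels 20 times and checks the mean accuracy stays within 0.5 ± 0.12.

## Synthetic cohort generator

The generator emulates a two-group resting-state cohort at the study's
dimensions (defaults 61 control-like / 57 patient-like subjects, C = 39,
T = 255, TR = 2.25 s, 4 states).

**State templates.** Each state is a unit-diagonal correlation matrix
built from network-block levels (within-network, between-network) set by
the state's character, plus per-state per-network variation (SD 0.12 —
states differ in *which* networks engage) and a per-pair jitter (SD 0.15)
that makes states mutually distinguishable. The four characters:
State 1 low connectivity / intermediate modularity (the dominant,
static-FC-like state), State 2 high within-network connectivity / high
modularity, State 3 dense unstructured connectivity / low modularity,
State 4 low connectivity / high modularity with mild between-network
anticorrelation. Matrices are repaired to positive definite by eigenvalue
clipping with a floor of 0.1 — deliberately generous so that pair-level
group offsets up to ~0.3 cannot make a template indefinite — and the
construction is retried over derived seeds until the overall-connectivity
and modularity orderings implied by the characters hold (states 2–3
strongest overall connectivity; modularity 2, 4 > 1 > 3).

**State process.** A first-order Markov chain at TR resolution. Mean dwell
times are long relative to the 30-TR window (controls: ~130 TR in the
dominant state, ~100 TR elsewhere); a window can only reflect a state
that persists through it, and pilot analysis with 10-TR dwells showed the
windowed representation cannot recover such fast switching (that is a
property of the method, not a bug). The patient-like group leaves State 1
about twice as fast (~65 TR), dwells longer in State 2 (~170 TR), and is
more volatile overall, with the extra transitions biased toward the
1↔2 and 3↔4 pairs. Scans start in State 1 with probability 0.4
(dominant-state preference).

**Group effects.** Connectivity offsets are injected per (state, pair,
delta) into the patient-like group's templates, with a positive-definite
check that errors naming the offending pair. The baseline value of an
effect pair is pinned to its profile-tag block level in *all* states, so
the realized ground-truth contrast is exactly interpretable rather than
convolved with the random template structure. Severity (ordinal 0–4,
binomial) modulates each patient-like subject's transition matrix between
the control-like and an exaggerated patient-like matrix, giving severity a
genuine monotone link to transition volatility for correlation analyses.

**Metadata.** Age ~ N(26, 8) clipped to [18, 65]; sex Bernoulli(0.88
female); framewise displacement lognormal (median 0.12 mm, σ = 0.5 log
units) with 2% spike probability adding 0.5–1.5 mm, so despiking has real
work; 12 motion-parameter stand-ins are drifting noise.

**Ground-truth window labels.** A window straddling a state transition has
no single true state. The ground truth labels a window with a state only
when that state occupies ≥ 2/3 of its frames and marks it ambiguous
otherwise; recovery ARI is computed over labelled windows. (At the default
dwell lengths, ~75–80% of windows are labelled.)

**What the generator does not emulate** — and hence what passing recovery
tests do not demonstrate about real data: hemodynamic response convolution
and temporal autocorrelation (samples are conditionally independent given
the state; an optional smoothing flag exists but is off by default),
between-subject variation in the state templates themselves, non-Markov
(e.g. heavy-tailed) dwell distributions, spatially structured artefacts,
and any coupling between motion and signal. Recovery results bound what
the pipeline can do under favourable, known-truth conditions; they are not
sensitivity estimates for clinical data.

## Validation study sizes

The recovery study uses 20 replicate cohorts of 50 + 50 subjects, C = 20,
T = 255, one −0.3 offset on the between-network pair (4, 19) in State 1,
k-means with 10 restarts, elbow over k = 2..8 with 5 restarts, and 10,000
permutations for the state-wise tests. Calibration studies use 1,000 null
replicates (permutation t-test, 20 + 20), 500 replicates (ANOVA group
effect), and 20 null cohorts of 40 + 40 subjects at C = 39 (741 pairs) for
FDR false-discovery counting. Classifier checks use 60 subjects with 3
features shifted by 2 SD (separable case) and 20 label-permutation runs.
These sizes make the studies cheap enough to re-run routinely while
keeping every acceptance margin comfortably measurable.

## Numerical conventions

* Constant columns in a correlation produce r = 0 with a warning, never NaN.
* Modularity is Newman Q on the positive-weight graph (negative entries
  dropped), best of 20 seeded Louvain runs; an all-nonpositive matrix
  returns Q = 0 with a single community and a warning.
* A low-pass cutoff at or above Nyquist (1/(2·TR)) passes data through
  with a warning — the conventional dFC cutoff at these TRs is 0.15 Hz.
* Despiking refuses subjects with > 50% flagged frames; boundary spikes
  are spline-extrapolated from the nearest clean frames.
* All stage seeds derive deterministically from one master seed; rerunning
  a pipeline config reproduces byte-identical artifacts (hash manifest).
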