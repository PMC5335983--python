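# Methods

`beatset` classifies ECG beats by ranking per-class *corpus sets* against a
*query set* of same-class beats, in three stages: wavelet sub-band feature
encoding, Mahalanobis metric learning by ranking-loss structural
optimization (metric learning to rank, MLR), and a minority-based
set-to-set dissimilarity (MBD). This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Beat segmentation and features

A beat is a 235-sample window around an annotated R peak: 90 samples
before, the peak, 144 after (at 360 Hz ≈ 0.25 s before / 0.4 s after).
Annotations whose window would cross a signal boundary are dropped.
Windows are decomposed by a discrete wavelet transform to 8 levels
(default wavelet Bior 6.8), giving 9 sub-bands; the default encoding keeps
(max, min, mean, variance) per sub-band → 36 features. The full-coefficient
encoding concatenates all sub-band coefficients instead.

Frozen conventions the upstream description leaves open:

- **Variance** is the population variance (divide by *n*), so length-1
  sub-bands are well defined and deterministic.
- **Boundary extension** is half-point symmetric (`symmetric` in
  PyWavelets), the usual default for biorthogonal families; it is exposed
  in `WaveletConfig` for users who prefer another rule.
- **Sub-band order** inside the feature vector is approximation first,
  then details coarse→fine. Any fixed order works; this one is frozen so
  feature files are reproducible.
- Supported families: `bior6.8`, `db14`, `sym8`, `coif5`, `rbio6.8`. The
  Fejér–Korovkin family is not available in the installed PyWavelets
  build, so `fk22` is recognised but reported as unavailable.

Detail sub-bands of a constant signal vanish, so a constant baseline
offset moves only approximation-derived features — the encoding absorbs
slow baseline wander without explicit detrending.

## Metric learning to rank

For a query `q` and corpus item `x`, the similarity score is
`g_w(q,x) = <w, phi(q,x)>` with `phi = -(q-x)(q-x)'`; sorting scores
descending sorts by ascending Mahalanobis distance under the symmetric PSD
matrix `w`. A ranking is summarised by the partial-order feature `psi`, the
normalised signed sum of `phi` differences over (same-class,
different-class) pairs. Training solves the structural program

    min_w  R(w) + (C/|Q|) Σ_q ξ_q
    s.t.   <w, psi(q, y*)> ≥ <w, psi(q, y)> + Δ(y*, y) − ξ_q   ∀q, y,
           w ⪰ 0,

with the truncated reciprocal-rank loss Δ = 1 − 1/r for first-relevant
position r ≤ k (else Δ = 1), k = 3 by default. Queries are the
leave-one-out instantiation: every training sample serves once as `q`
against all remaining training samples.

**Cutting planes with an exact dual inner solver.** The exponential
constraint set is generated by a separation oracle that returns each
query's loss-augmented most-violated ranking *exactly*: with relevant and
irrelevant items each sorted by descending score, the pair term decomposes
over irrelevant items given how many relevant items precede each, and the
loss depends only on how many irrelevant items precede all relevant ones;
the joint maximiser follows in closed form (verified against exhaustive
enumeration in the tests). The working-set subproblem with
`R(w) = a·tr(w) + (b/2)·‖w‖²` is solved in its dual by FISTA with
per-query box/simplex projections; the primal minimiser over the PSD cone
is the closed form `w(α) = Π_PSD((A(α) − aI)/b)`, so the PSD constraint
lives *inside* the subproblem and every returned metric is PSD. The solve
stops at a primal–dual gap below `1e-9·(1+|objective|)`, which makes the
recorded working-set objective monotone across outer iterations and lets
the outer loop genuinely reach its violation tolerance (default `1e-4`,
`max_iter` 200; hitting `max_iter` returns the best model with a warning
flag rather than raising).

**Regularizers.** `frobenius` (`‖w‖²/2`, the default) needs no
perturbation and its subproblem is solved exactly. `trace` (`tr(w)`) with
the PSD cone is a semidefinite program; it is implemented as
`tr(w) + (ε/2)‖w‖²` with a small quadratic damping `ε`
(`trace_smoothing`, default 0.05) so the same exact dual applies. The two
regularizers produce near-identical Rank-1 rates on the synthetic
clusters (tested to within 2 points), so the damping is immaterial in
practice; users who need the undamped trace path can lower `ε` at the
cost of slower inner convergence.

**Defaults.** `C = 1`, `k = 3`, zero initialisation (feasible with slack
equal to the maximal loss), stable tie-breaking by original index in all
score sorts. `seed` fixes only the query sweep order. One regime note:
because the trace penalty charges linearly at `w = 0` while the Frobenius
penalty's gradient vanishes there, trace regularization on unit-scale
features needs a larger `C` (≈100 on the synthetic clusters) before any
metric is worth learning; in that regime the two regularizers give
near-identical Rank-1 rates.

**A structural caveat discovered while building the package.** The
ground-truth ranking demands *every* same-class sample above every
different-class sample. If the training corpus's same-class sets contain
gross outliers, the loss-augmented adversary gains linearly in `‖w‖` by
demoting them, and the exact optimum of the program collapses to `w = 0`
(verified with the exact dual: the working-set optimum reaches the
all-slack bound with a duality gap of ~1e-10). Ranking-based metric
learning therefore presumes coherent same-class training data; the
synthetic study below trains the metric on the curated training half and
injects contamination at the measurement stage. On real beats the same
consideration argues for annotation-verified training segments.

**Factorization.** `w = l'l` by eigendecomposition, keeping eigenvalues
above `rank_tol` (absolute, default 1e-8; training uses 1e-12). Distances
under `w` equal Euclidean distances after projecting with `l`, which is
how the metric enters the set measures. Matrices with an eigenvalue below
−1e-6 times the largest are rejected as non-PSD.

## Set-based dissimilarity

With point-to-set distance `d(a,B) = min_b ‖a−b‖` (Euclidean, optionally
in the `l`-projected space):

- **MBD** averages `d(·,B)` over the α members of A nearest to B and
  symmetrically for B, combining the two directional terms with sum
  (default; max and min are options). Both minorities share one size
  `α = max(1, floor(β·min(|A|,|B|)))`, β = 1/10 by default.
- **MPD** is the global minimum pairwise distance, **MAD** the sum of the
  two mean point-to-set distances, **APD** the mean over all pairwise
  distances.

MBD degenerates to MPD at α = 1 with the min combination (any set sizes),
and to MAD at β = 1 with the sum combination *for equal-cardinality sets*
— the equal-quantity minority rule cannot reach both full sets when the
cardinalities differ, which is also why a full-minority MBD differs from
MAD in the original experiments. Both identities are exercised bitwise in
the tests (MAD sums its distances in ascending order so the two code
paths agree exactly).

Ties in minority selection and in class ranking break stably by
(distance, original index) and by ascending class symbol respectively.

## Evaluation protocol

Ten repeated stratified 50/50 splits (the repeated-halving reading of the
protocol; an odd sample goes to training). Classes exceeding 500 training
samples are randomly capped at 500. One corpus set per class holds all
capped training samples of that class. Each class's test samples are
shuffled and partitioned into query sets of the configured size (default
50, with the small-class overrides J/Q/e → 5 and S → singleton); a final
partial chunk is kept as a smaller set by default (discarding it would
silently drop rare-class data; both behaviours are configurable). A query
set counts as one decision; Rank-1 is the fraction of query sets whose
true class tops the dissimilarity ranking, Rank-5 the fraction with the
true class in the top five. Splits are deterministic per (seed, trial),
so every compared method consumes identical splits under one seed. The
single-sample baseline treats each test sample as a singleton query
ranked by distance to each class's nearest training sample
(singleton-query MPD), in raw space (Euclidean baseline) or the projected
space (single-sample metric classifier).

## Synthetic data

**Beats** are sums of Gaussian humps (P/QRS/T-like) with relative
amplitude jitter (8%), timing jitter (2 samples), additive white noise
(0.04), and a random-phase baseline sinusoid (amplitude 0.15, period 350
samples); four default classes mimic a narrow-QRS beat, a wide
bundle-branch-block-like beat, a PVC-like complex and a paced beat. With
all stochastic terms zero a beat equals its class template bitwise. The
generator accepts per-class counts spanning orders of magnitude, matching
the extreme imbalance of real beat-type inventories.

**Feature clusters** place class means at scaled simplex vertices (all
pairwise separations equal — one interpretable knob), draw spherical
Gaussians around them, and apply a linear distortion to every sample. The
study conditions (frozen defaults of `contaminated_cluster_study`): 4
classes in 6 dimensions, separation 6, within-class SD 1, distortion
`diag(0.3, 0.3, 0.3, 0.3, 3, 3)` — compressing the class-mean subspace
and inflating the nuisance axes so raw Euclidean distances are dominated
by uninformative directions; 120 samples per class; 10 trials; query-set
size 20; 10% of corpus and test samples displaced by magnitude 30 in a
uniformly random direction *at measure time* (after metric training, see
the caveat above); `C = 1`, frobenius regularizer. Problem sizes are
chosen so the full 10-trial study, including ten metric fits, runs in a
few minutes on one core.

**What this does and does not show.** The study reproduces the method's
qualitative findings — the learned metric improves both single-sample and
set-based classification on distorted clusters, and the minority/minimum
measures (MBD, MPD) are far more robust to contaminated sets than the
averaging measures (MAD, APD) — under conditions where the ground truth
is known exactly. It does not emulate real ECG variability
(inter-patient morphology drift, non-stationary noise, label noise), so
passing it demonstrates correctness of the machinery, not clinical
performance. Reproducing the published MIT-BIH rates requires the real
recordings via the WFDB path.

## Known limitations

- The WFDB reader covers single-segment records in formats 212 and 16
  with MIT-format beat annotations — sufficient for the MIT-BIH
  arrhythmia records and the package's fixtures, not a general WFDB
  implementation.
- The flutter-wave symbol W has no defined AAMI group and errors in AAMI
  mode rather than being guessed.
- Training cost grows with the square of the training-set size (leave-one-
  out queries × corpus); the per-class cap is the practical control.
- MBD assumes both sets carry at least one "regular" member near the true
  class; sets consisting mostly of outliers defeat every measure offered.
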