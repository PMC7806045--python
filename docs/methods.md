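# Methods

## Problem setting

A screen-free brain–computer interface selects one of several physical
candidate objects by highlighting each of them with a robot-mounted laser
pointer while recording the user's EEG. Every individual highlighting `k`
elicits an event-related potential (ERP); windows time-locked to target
highlightings (the object the user attends) carry a P300-like positivity
that non-target windows lack. Decoding reduces to binary classification of
single 1 s windows, followed by per-trial selection of the object whose
windows received the highest mean target score.

Because the laser looks different on different surfaces, the ERP
distribution differs across objects. Objects (or sequence positions) are
treated as *subclasses* of the binary problem, and the package implements
three pipelines that differ only in how they use this subclass structure:

* **TS+LDA** — ignore subclasses: one Riemannian tangent space at the
  Fréchet mean of all training covariances, one LDA.
* **sep. TS+LDA** — one tangent space and one LDA per subclass, fitted
  only on that subclass's windows.
* **cTS+reg-LDA** — center each subclass by parallel transport of its
  covariances to the identity, so all subclasses share one tangent space;
  train one LDA per subclass whose class means are *multi-target-shrunk*
  convex combinations of all subclasses' class means, with a pooled
  within-class scatter.

## Signal representation

Continuous EEG (μV) is band-passed 0.5–16 Hz with a 4th-order Butterworth
applied forward–backward (zero-phase, so ERP latencies are unaffected;
transition behavior is a design choice since only the band edges are part
of the protocol), then resampled to 100 Hz with a polyphase anti-aliasing
FIR. Windows span `[onset, onset + 1 s]` inclusive of both endpoints — 101
samples at 100 Hz — with the mean of the preceding 200 ms subtracted per
channel; baselines are half-open `[-0.2 s, 0)`. Windows whose peak-to-peak
amplitude strictly exceeds 100 μV on any channel are rejected (the boundary
case is retained; the rule is stated as an exceedance).

Each window `X_k` is augmented with class-prototype responses

    X̃_k = [W_t X̄_t ; W_nt X̄_nt ; W_t X_k ; W_nt X_k]  ∈ ℝ^{8×101}

where `X̄_i` are the Euclidean class means of the training windows and
`W_i ∈ ℝ^{2×N_c}` are the two leading xDAWN spatial filters per class. The
8×8 covariance of `X̃_k` then contains the signal covariance plus
signal–prototype cross-covariance blocks that encode the phase of the
window relative to the class templates. Covariances are estimated with
analytic Ledoit–Wolf shrinkage toward scaled identity, which guarantees
positive definiteness. A batched implementation of the same estimator is
used for stacks of windows; a unit test pins it to
`sklearn.covariance.ledoit_wolf` to machine precision.

The xDAWN filters solve, per class, the generalized eigenproblem of
(covariance of the least-squares-estimated evoked response) against (total
signal covariance). The least-squares step uses a Toeplitz 0/1
stimulus-onset design over the concatenated training windows, so that
overlapping responses (guaranteed at 250 ms SOA, where each 1 s window
contains up to four stimuli) are estimated jointly rather than smeared
into the class means. Fitting uses only training-fold, non-rejected
windows; events from outside the training set are invisible to the design,
which leaves a negligible model misspecification at fold boundaries.
A near-singular total covariance raises an error instead of being
regularized silently — upstream shrinkage and real noise make it
full-rank, so degeneracy indicates a broken input.

## Geometry

Covariances live in the SPD cone with the affine-invariant Riemannian
metric `d(C1, C2) = ||logm(C1^{-1/2} C2 C1^{-1/2})||_F`. Matrix functions
are computed by eigendecomposition; eigenvalues below `1e-12 × λ_max`
raise a validation error rather than being clipped, for the same reason as
above. The Fréchet mean is found by fixed-point tangent averaging (step
size 1, tolerance 1e-8 on the Frobenius norm of the mean tangent, at most
50 iterations, warning on non-convergence) initialized at the arithmetic
mean. Tangent matrices are vectorized diagonal-first, then upper triangle
row-major with √2 weighting, making the Euclidean inner product of vectors
equal the Frobenius inner product of matrices (so LDA in vector form is
congruent to matrix-form computation); vectors for 8×8 covariances have
length 36 = n(n+1)/2.

Parallel transport of a subclass to the identity is the congruence
`C ↦ C_j^{m,-1/2} C C_j^{m,-1/2}` by its Fréchet mean — an isometry, so
within-subclass structure is untouched while subclass location is
removed. Tangent projection of a transported covariance at the identity
coincides with tangent projection of the original at the subclass mean;
the centered pipeline exploits this identity.

## Multi-target shrinkage of class means

For the classifier of subclass `j`, the class-`i` mean is replaced by

    μ_MTS = (1 − Σ α_{j'}) μ̂_{i,j} + Σ α_{j'} μ̂_{i,j'}

with weights minimizing an estimate of E‖μ_MTS − μ_{i,j}‖²:

    (1 − Σα)² V̂_j + Σ α_{j'}² V̂_{j'} + αᵀ B α,

where `V̂` is the summed per-dimension sample variance divided by the cell
size (the variance of the mean estimator) and `B` estimates the Gram
matrix of the bias vectors `μ_{j'} − μ_j`: diagonal entries
`‖μ̂_{j'} − μ̂_j‖² − V̂_j − V̂_{j'}`, off-diagonal entries debiased by
`V̂_j` only (the `μ̂_j` estimate is shared). `B` is floored to the positive
semidefinite cone by eigenvalue clipping so the program stays convex; on
the diagonal this reduces to the usual max(·, 0) floor. The QP is solved
with SLSQP over `α ≥ 0, Σα ≤ 1` (dimension ≤ N_sub − 1, so the solver cost
is negligible); a failed solve falls back to α = 0 with a warning. A test
pins the achieved objective against exhaustive grid search on the
constrained simplex.

Shrinkage is applied independently per class (target and non-target), and
only to the means. The within-class scatter of the centered pipeline is
pooled over all centered subclasses (residuals taken against the
subclass-and-class cell means, Ledoit–Wolf shrunk): the centering removes
the between-subclass location differences that would otherwise inflate a
pooled scatter, and pooling uses all data — the same data-efficiency
rationale as the mean shrinkage. A per-subclass scatter remains available
(`pooled_scatter=False`), and with `use_mts=False` the centered pipeline
reduces exactly to sep. TS+LDA; a test asserts score equality of this
reduction. Subclass cells with fewer than two windows of a class fall back
to the pooled class mean with a warning.

LDA solves `C_lda w = μ_t − μ_nt` with the offset placing the decision
value's zero at the midpoint of the class means. Scores are raw decision
values — object selection by argmax of per-object mean scores is invariant
to calibration, and means (rather than sums) keep trials with rejected
windows comparable. Ties break toward the lowest object id.

## Evaluation protocol

Cross-validation is chronological: trials sorted by onset are split into
k = 5 contiguous blocks, and all windows of a trial share its fold, so no
trial straddles train/test. Prototypes, xDAWN filters, references,
shrinkage weights and classifiers are all refitted per fold. The
reduced-data condition keeps only repetition 1 of each trial (33 % of
windows) before folding. AUC is computed per fold on retained test windows
and averaged (pooled-scores AUC was the design alternative; fold-averaging
matches per-fold reporting). Paired pipeline comparisons use the two-sided
Wilcoxon signed-rank test — exact null for n ≤ 25 without zeros or ties,
normal approximation with Pratt zero-handling otherwise — with
Holm–Bonferroni adjustment across the comparison family.

## Session simulator

The simulator emulates the paradigm's schedule and response structure so
every pipeline is testable without recorded EEG. Defaults: 24 trials with targets balanced over 4 candidate objects, 3
repetitions per trial, 3 s sequences of 100 ms stimuli at 250 ms SOA
(12 per sequence), 31 channels at 1 kHz, 1 s inter-sequence gap (a proxy
for robot repositioning; no protocol value exists).

Responses are linear superpositions of three components with fixed spatial
patterns on a fictitious concentric-ring montage: an N1-like negativity
(−3 μV, 120 ms, posterior), a P2-like positivity (+4 μV, 200 ms, central)
for every highlighting, and a parietal P300-like bump for targets only
(default 6 μV, centered 300 ms, σ = 40 ms). These amplitudes sit in the
physiological range for visual ERPs and P300. Per-object heterogeneity
enters as gain multipliers and latency shifts; the first stimulus of each
sequence is boosted ×1.5, echoing the larger initial-position responses.
Background noise is pink (1/f amplitude) with exponential spatial
correlation over the montage, 10 μV RMS per channel; blink artifacts
(150 μV frontal deflections) arrive at 2/min via a Poisson process and are
caught by the 100 μV rejection rule. The `heterogeneous` preset uses gains
(1.5, 1.2, 0.7, 0.5) and latency shifts (0, 0, 10, 25) ms — two salient
and two low-salience objects; `homogeneous` uses unit gains and no shifts.

What the simulator does *not* model: realistic head-volume conduction,
alpha rhythms and other structured oscillations, habituation and attention
drift over a session, eye movements correlated with the task, and
waveform-level (rather than gain/latency) differences between objects.
Passing the simulation-level tests therefore shows that the pipelines
behave correctly under controlled subclass heterogeneity — not that the
specific AUC levels transfer to recorded EEG, where they are generally
lower.

## Problem sizes in the test suite

Simulation-backed tests run sessions with the default trial counts
(24 trials; 12 for the amplitude ladder) but simulate at 250 Hz rather
than 1 kHz — the decoding pipeline operates at 100 Hz regardless, and
250 Hz comfortably oversamples the 16 Hz band edge — and aggregate over
10 seeds. These sizes are the package's choice for a fast, deterministic
suite; the simulator's own defaults keep the full acquisition conditions.

Observed behavior at these sizes (each recomputed by the suite): on the
heterogeneous preset at the 33 % fraction, cTS+reg-LDA attains the highest
mean AUC of the three pipelines; on the homogeneous preset at the full
fraction all three agree within 0.05 mean AUC, with sep. TS+LDA lowest
(its per-subclass training sets are smallest); with the target component
removed the decoders are at chance; and AUC increases monotonically with
target amplitude.

## Numerical choices and degenerate inputs

* Validation errors (not clipping) for non-symmetric / non-PD matrices;
  smallest eigenvalue named in the message.
* Onsets snapped to the nearest sample at the pipeline rate; events too
  close to the recording edge are dropped with a warning.
* Artifact rejection strictly exceeds the threshold; the exact-boundary
  window is kept.
* Unseen subclasses at prediction time fall back to the pooled TS+LDA
  model (always fitted alongside the subclass variants) with a warning.
* All randomness flows through seeded NumPy generators; schedules and
  recordings are bit-reproducible from a session seed. The analysis itself
  is deterministic — chronological CV involves no shuffling.

## Known limitations

* The Fréchet mean solver assumes moderate conditioning (fine for shrunk
  8×8 covariances); no Riemannian line search is attempted.
* Prototypes and xDAWN filters are fitted once per training fold, pooled
  across subclasses; per-subclass refits would multiply estimation
  variance for little expected gain, but were not evaluated.
* MTS shrinkage is independent per class; a joint program over both class
  means is a possible variant.
* No probability calibration of scores, no dynamic stopping, no online
  (incremental) fitting.
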