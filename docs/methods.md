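# Methods

This note records the model this package implements, the numerical choices
made where the design was genuinely open, what the synthetic generators do
and do not emulate, and the known limitations.

## Data model and preprocessing

Each of K subjects contributes either a continuous recording (channels ×
samples, microvolts, with cue-onset markers and class labels 1 = right
hand, 2 = right foot) or an epoched trial tensor. Trials are half-open
windows `[pos, pos + window_s·fs)` starting **at the cue onset**; the
source material does not state a latency offset, so none is applied.
Trials whose window overruns the recording are dropped with a warning, not
zero-padded: padding would bias the autocovariances that both whitening and
the AR features rest on. The 100 Hz competition MAT dialect stores the
signal as integers at 0.1 µV per count; the loader applies that scaling and
drops markers whose class is undefined (the competition's withheld test
trials), logging the count. Only the published 37-channel fronto-central
subset ships as a named constant; other subsets are user-definable because
their channel lists were never published.

Whitening is the exact eigendecomposition form `V = Λ^{-1/2}Eᵀ` of the
biased sample covariance after mean removal, retaining all M dimensions.
A rank-deficient covariance (relative eigenvalue below 1e-10) is an error
that tells the user to reduce the channel set — silently switching to a
dimension-reducing PCA would change the model order underneath the demixing
stage. In the pipeline, whitening is fitted per subject *and per class* on
the concatenated class-specific training trials, then frozen.

## IVA-G core

The cost is `Σ_m ½ log det Σ_m − Σ_k log|det W[k]|`, dropping the additive
entropy constants and `(2πe)` terms: they shift the value, not the
minimiser. `Σ_m` is the biased (1/N), mean-removed sample covariance of SCV
m under the current demixing matrices, with a conditional ridge
`ε = 1e-10·trace/K` applied only when the smallest eigenvalue falls below
ε. Because `Σ_m` is defined from the data, the expectation term
`E{[Σ_m⁻¹ y_m]_k z[k]}` is the *exact* derivative of `½ log det Σ_m`, and
the decoupling term `h/(hᵀw)` is the exact row derivative of
`−log|det W|`; the analytic gradient therefore matches central finite
differences of the cost to ~1e-9 on random instances (asserted at 1e-5 in
the tests). The printed form of the determinant term is implemented as a
division `h/(hᵀw)`; the finite-difference agreement is what arbitrates
this reading.

Decoupling vectors come from the SVD null space of the (M−1)×M submatrix,
sign-fixed so `hᵀw > 0`. Within a sweep, SCV covariances are held fixed
(re-estimated once per full sweep) while the component values and Gaussian
scores are updated after every accepted row via a rank-1 update of
`Σ_m⁻¹Y_m` — an exactness/cost trade-off validated by the
finite-difference and recovery tests.

**Step-size policy.** The update is a gradient step of size µ followed by
row renormalisation, with µ = 1 initially. A genuinely fixed µ = 1 was
measured to limit-cycle on typical whitened instances (cost oscillating
~2 units above the optimum, joint ISI stuck near 0.14), so a sweep that
fails to decrease the cost is rejected — the matrices are restored — and µ
shrinks by 0.9 before retrying. The accepted cost sequence is therefore
non-increasing, and the returned cost never exceeds the initialisation's.
This mirrors the annealing used in the standard second-order IVA
implementations. Convergence is declared when an accepted sweep changes the
cost by less than `tol` (default 1e-6, default cap 512 sweeps); step-size
underflow below 1e-8 ends the run flagged as non-converged.

Identifiability: IVA-G can only separate sources whose SCV covariance
profiles differ. The JBSS generator therefore *requires* planted
correlations that are pairwise distinct by ≥ 0.05; with identical profiles
(e.g. all sources independent across datasets) no recovery guarantee exists
and none is asserted.

The joint ISI pools the combined systems `G[k] = W[k]V[k]A[k]` as
`Ḡ = Σ_k |G[k]|` and applies the normalised Amari index, so it is zero only
when *one common* permutation aligns all datasets — the relevant notion of
success for joint separation.

## AR features

Yule–Walker with biased (1/T) autocovariances of the mean-removed signal —
the biased estimator keeps the Toeplitz matrix positive semidefinite. The
order is q = 4 by default (the value the accompanying study fixed).
Estimation is per trial and per stacked component channel; per-trial
estimation is what makes trial-wise classification possible at all. The
innovation variance is computed and retained for diagnostics but excluded
from the feature vector, which is the flattened (channels × q) coefficient
block. Coefficients are exactly scale- and sign-invariant, which is the
reason AR features pair well with blind-source outputs: the separation's
per-component scale and sign are arbitrary, and nothing of that
arbitrariness survives into the classifier.

## Pipeline

Per fold of a stratified k-fold split (default kf = 10): a stratified 10%
hold-out is carved from the training trials (at least one trial per class);
for each of `n_init` candidate initialisations — a single standard-normal
M×M matrix shared across subjects and across both class-wise IVA runs —
class-wise IVA is fitted on the whitened concatenation of each class's
training trials, every trial is pushed through *both* class transforms and
stacked to 2M component channels, AR features are extracted, and a
per-subject classifier (linear SVM with C = 1, or k-NN with k = 5; both
preceded by z-scoring on training statistics) is trained on the training
trials and scored on the hold-out. The candidate with the highest mean
validation accuracy across subjects wins (ties to the lowest index;
per-subject selection is available behind a flag). Test trials only ever
meet frozen transforms and classifiers. The search is repeated per fold —
the source material is silent on this, and per-fold search is the variant
that keeps every test fold untouched during selection.

Subjects may have different label sequences; class-wise concatenations are
then truncated to the shortest subject so the joint time axis stays
aligned. Classifier hyperparameters and the feature z-scoring are not
specified in the source material; the defaults above are logged and
configurable. All randomness (splits, hold-outs, initialisations) derives
from one seed, making reports exactly reproducible.

SCV correlation analysis uses Pearson correlation of component time series
(the analysed quantities are bounded by 1, which is what printed
"covariance" tables with unit diagonals imply), computed on the
matching-class test trials under the selected class transform and averaged
over folds before ranking. Ranking is per subject by absolute value, ties
to the lower component then partner index. The accuracy KDE uses a Gaussian
kernel with Silverman's rule and boundary reflection at 0 and 1, so the
density integrates to 1 on its support.

## Synthetic generators

`generate_jbss` realises the JBSS model directly: SCV m is i.i.d. over time
from a K-variate Gaussian with unit variances and compound-symmetric
correlation ρ_m (chosen for analytic transparency; arbitrary SCV
covariances can be passed through the expert path of building sources
directly), mixed by random orthogonal-times-diagonal matrices with
condition number ≤ 9.

`generate_two_class_dataset` emulates the *structure* of a cue-based
motor-imagery study: 2 balanced classes, 4 s trials at 100 Hz, K subjects
with per-subject mixing, sensor noise at a stated per-channel SNR (default
10 dB), and latent AR(2) sources whose spectral peak depends on the class —
by default 10 Hz (mu) for right hand vs 20 Hz (beta) for right foot, with
small per-source detuning — driven by innovations correlated across
subjects (correlation decreasing 0.9 → 0.1 over sources), which plants the
cross-subject SCV structure the method exploits. It does **not** emulate
volume conduction geometry, 1/f background spectra, artifacts (EOG/EMG),
non-stationarity within or across trials, or realistic inter-subject
variability in source topography. Passing tests on these data therefore
demonstrate the correctness of the machinery (recovery of planted
parameters, absence of leakage, calibration of the null), not expected
accuracy on real EEG.

## Problem sizes used in the automated checks

The test suite and the acceptance script run the pipeline at K = 5
subjects, M = 8 channels, 60 trials/class, T = 400 samples, with the search
reduced to n_init = 10 over kf = 5 folds and the per-fit sweep cap at 32 —
sizes chosen so the full parameter-recovery suite completes in minutes on
one CPU while every stage still operates in its intended regime. The
separation benchmark uses K = 5, M = 8, N = 5000 with planted correlations
0.85 … 0.15 and 5 random initialisations.

## Known limitations

- IVA-G uses second-order statistics only; sources distinguishable solely
  by higher-order structure are invisible to it.
- Gradient descent with annealing finds local minima; the initialisation
  search mitigates but does not eliminate this.
- The 1.0-second question of cue latency is resolved as "window starts at
  the cue"; datasets with a known reaction latency should pre-shift their
  markers.
- Deep-network classification heads are out of scope; the stacked component
  export exists so external models can consume the transforms.
- With very small trial counts the stratified hold-out floors at one trial
  per class, making validation accuracy coarse; prefer n_trials/class ≥ 20.
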