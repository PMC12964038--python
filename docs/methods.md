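# Methods

This note documents the models, parameter choices, and numerical
decisions behind `canheart`, and what the validation experiments do and
do not establish.

## Neuronal model and the self-connection convention

Hidden neuronal states follow `dx/dt = A x + v`.  All matrices use the
target-row / source-column convention: `A[i, j]` is the influence of
region `j` on region `i`, in Hz.  Off-diagonal couplings are free
parameters; diagonals are `-0.5 * exp(theta_self)` with `theta_self`
unitless, so self-connections are always inhibitory and `theta_self = 0`
is the reference rate of −0.5 Hz.  More positive `theta_self` means
stronger self-inhibition (a less responsive node); the display matrices
flag the diagonal as being on this log scale.

## Hemodynamics

The Balloon model per region: vasodilatory signal `s`, inflow `f`,
venous volume `v`, deoxyhemoglobin `q`, with

    ds/dt = x − κ s − γ(f − 1);  df/dt = s;
    dv/dt = (f − v^{1/α})/τ;     dq/dt = (f·E(f)/E0 − v^{1/α} q/v)/τ

and BOLD `y = V0 (k1(1−q) + k2(1−q/v) + k3(1−v))`, `k1 = 7E0`, `k2 = 2`,
`k3 = 2E0 − 0.2`.  Fixed constants: γ = 0.32 s⁻¹, α = 0.32, E0 = 0.4,
V0 = 0.04.  Baselines κ0 = 0.64 s⁻¹ (signal decay) and τ0 = 2.0 s
(transit time) carry per-region free log-scalings with N(0, 1/256)
priors.  The generative cross-spectrum uses the exact Jacobian
linearization of these equations around their fixed point; the
linearization reproduces the nonlinear simulator within ~2% for the
small neural amplitudes used here (checked in the test suite).

## Generative cross-spectrum and noise model

    G_y(f) = K(f) T(f) G_v(f) T(f)* K(f)* + G_e(f),  T(f) = (i2πf I − A)^{-1}

`G_v` and `G_e` are power-law spectra `exp(a) (f / 0.03 Hz)^{-b}`,
pooled over regions, with N(0, 1/64) priors on the log-amplitudes.  The
exponents are mapped from an unbounded latent through `2·sigmoid(2θ)`
into [0, 2] with unit slope at the pink-noise center (θ = 0 ⇒ b = 1),
priors N(0, 1/64) on the latent.  Off-diagonal couplings have N(0, 1/64)
priors (standard shrinkage).  The analysis grid is 32 linear frequencies
from 1/128 Hz to 0.25 Hz — the resting-state band below the TR = 0.961 s
Nyquist rate; grid, order and priors are configurable.

## Spectral estimation

The subject-level data feature is the MAR(8)-implied cross-spectral
density of the de-meaned, detrended region series,
`S(f) = Δ·H(f) Σ H(f)*`.  The MAR fit is least squares with a small
default ridge (3% of mean regressor power): at fMRI run lengths the pure
least-squares spectra are noticeably rough, and the ridge stabilizes
them while leaving long-data estimates essentially unchanged (an AR(1)
coefficient of 0.5 fits as 0.485 at T = 10⁴).  A Welch
averaged-periodogram estimator with the same two-sided per-Hz
convention serves as an independent cross-check; the two agree within
~10% (relative Frobenius norm, in-band) on long simulations.

## Variational inversion

Features are the non-redundant real and imaginary CSD entries (upper
triangle), stacked over frequencies.  Because the sampling variance of a
cross-spectral estimate scales with `S_ii(f)·S_jj(f)`, squared residuals
are weighted by the inverse of that product (a Whittle-likelihood
scaling) — without it, the fit is dominated by the high-power
low-frequency diagonal entries and coupling recovery degrades badly.
One residual log-precision per region-pair block is then profiled at its
conditional optimum at every candidate step, capped at 10³ on the
weighted scale (a tight hyperprior: weighted residuals are never trusted
beyond ~3% of the local spectral scale).  The cap is what prevents the
search from chasing estimation noise in the observed spectra with
runaway confidence; it was the single most important robustness choice
in the package.

The ascent is Gauss–Newton with Levenberg–Marquardt regularization on
the profiled objective: steps that destabilize `A` (max real eigenvalue
> −10⁻⁶) or fail to increase the objective are rejected and the damping
increased, so the recorded free-energy trace is non-decreasing by
construction.  Convergence: improvement < 10⁻² for 4 consecutive
accepted steps, or 128 iterations.  `Cp` is the inverse Gauss–Newton
curvature (plus prior precision) at the optimum, eigenvalue-floored to
stay PSD.  The reported `free_energy` adds the Gaussian-volume (Occam)
terms at the optimum.  Data are rescaled once by a scalar so the mean
diagonal power matches the model at the prior mean; a scalar rescaling
leaves `A` unchanged and is recorded in the posterior.

Explained variance is `1 − SSE/SST` over the fitted spectral features,
floored at 0; a companion time-domain figure applies the same score to
lagged covariances obtained by inverse-transforming both spectra,
since the two can differ and the inclusion rule's natural domain is
ambiguous.  The inclusion screen uses the spectral figure with an
inclusive threshold: EV ≥ 0.10 passes.

## Group level (PEB)

Subject posteriors over the connectivity block (30 off-diagonals + 6
selfs for the full network) enter
`theta_i = (x_i ⊗ I) β + ε_i, ε ~ N(0, exp(−γ) Q)` with a single
isotropic component `Q = diag(prior variance)/16` — the conventional
expectation that between-subject variability is an order of magnitude
tighter than the first-level priors.  Given γ, each subject contributes
with precision `(Cp_i + exp(−γ)Q)^{-1}`, so uncertain first-level
estimates move the group posterior less.  γ (prior N(0, 1/16)) is
optimized by bounded scalar search on the exact Gaussian marginal
likelihood — for this linear model the marginal evidence is available in
closed form given γ, so no free-energy approximation is needed there.
Second-level priors on β are zero-mean with the first-level prior
variance of the matching parameter.

Design matrices: constant first column; group coded +1 patients / −1
controls then mean-centered; HR mean-centered; the interaction is the
product of the two centered columns, re-centered (tested invariant to
which group is labelled +1).  In the per-group HR analyses the HR slope
is invariant to centering on the group versus the grand mean because
the constant column absorbs the offset, so only the within-group
centered design is built.

Per-effect posterior probabilities use Bayesian model reduction: the
log-evidence change when that effect's prior is collapsed to a point
mass at zero (precision 10⁸), mapped through `PP = 1/(1 + exp(−ΔF))`;
the formula is verified in the tests against direct evidence
computation on a scalar model.  Display matrices blank entries with
PP ≤ 0.99 (strict) and show Ep with the posterior SD in parentheses.

## QC and physiology

Framewise displacement is the sum of absolute backward differences of
the six rigid-body parameters, rotations converted to arc length on a
50 mm sphere (the standard convention; configurable).  Exclusion rules
are strict inequalities: mean FD > 0.30 mm, or > 20% of FDs above
0.30 mm.  PPG is band-passed 0.05–3 Hz (zero-phase Butterworth);
systolic peaks are local maxima above an adaptive threshold (40% of the
upper-tail amplitude) separated by at least max(0.25 s, 60% of the
dominant autocorrelation period) — the adaptive separation is what
rejects dicrotic bumps even at half the systolic amplitude.  Mean HR is
60 / mean inter-beat interval; the beat-count-per-duration figure is
reported alongside because the two differ under missed beats.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure the analysis
assumes: a stable fully connected coupling matrix (rejection-resampled,
max 100 draws), two groups of 26 and 40 with connection-specific ±
offsets, per-subject HR ~ N(65.06, 10²) and N(74.1, 10²) bpm linearly
coupled to designated connections through the mean-centered HR,
subject-level coupling noise (SD 0.03 Hz), Balloon BOLD at TR 0.961 s
for 750 volumes with the first 4 discarded, and pink (1/f) observation
noise scaled to SNR 1 in the 0.01–0.1 Hz band — a deliberately
conservative noise level recorded in the cohort config.  Endogenous
fluctuations are white by default (the case with a closed-form
stationary covariance, used as the simulation oracle); an AR(1)-shaped
option adds realism.  The neural integration step is ~0.05 s, kept
commensurate with the TR (0.961/19 s).

Synthetic PPG is a log-normal-shaped systolic template with a 35%
dicrotic bump, beat-interval jitter, drift and broadband noise — enough
morphology to exercise the detector, not a cardiovascular model.
Motion traces are smooth random walks with optional persistent step
displacements.  None of this emulates scanner artifacts, respiration,
cardiorespiratory coupling into BOLD, or nonlinear neuronal effects;
passing the validation suite therefore shows the estimator chain is
correct and well calibrated under its own assumptions, not that those
assumptions hold in any particular empirical dataset.

## Validation experiment sizes

The acceptance computations use sizes chosen to exercise the study
conditions while staying desk-scale: 3-node networks with ±0.3 Hz
couplings for subject-level recovery (10 seeds, 746 volumes each);
26+40-subject cohorts for group-level power (three planted 0.2 Hz
effects) and specificity (10 null cohorts), with inversions capped at
32 iterations at the group level (posterior means are stable well
before full convergence of the uncertainty terms); 6+6 cohorts for the
end-to-end determinism check.  Determinism is guaranteed for a fixed
BLAS configuration; the test harness pins linear algebra to one thread
because some multi-threaded BLAS reductions are not bitwise
reproducible.

## VOI stage scope

Sphere extraction operates at the stated MNI coordinates (inclusive
membership in world space, mean or sign-aligned first eigenvariate).
The subject-specific peak search used upstream of sphere placement in
empirical studies requires per-subject statistical maps and is out of
scope; a per-subject center table can be supplied instead.  The printed
coordinates' en-dash typography is interpreted as minus signs, e.g.
vmPFC (0, 44, −14).

## Known limitations

- The inversion assumes the six-region linear model; model-space search
  and bilinear/two-state extensions are out of scope.
- Recovery correlation ~0.87 at single-scan length means individual
  couplings still carry substantial posterior uncertainty; group
  inferences lean on the PEB precision weighting, and the FPR/power
  figures quantify that trade-off only under the generator's conditions.
- The explained-variance screen is reported in both spectral and
  time-domain forms; empirical thresholds calibrated on one form do not
  transfer exactly to the other.
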