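# Methods

This note documents the models, algorithms and design choices behind
`bgdcm`, in the package's own terms: what is computed, under which
assumptions, with which defaults, and what the synthetic-data experiments
do and do not demonstrate.

## 1. Generative model of resting-state node signals

Neuronal dynamics in the four modelled regions (M1, putamen, STN,
thalamus) follow a linear stochastic differential equation

    dx/dt = A x + v,

where `A[target, source]` holds the directed couplings in Hz and the
diagonal carries inhibitory self-connections parameterized as
`a_ii = −0.5·exp(θ_i)`, negative for every finite `θ_i`.  The node order
(M1, PUT, STN, THAL) and the `[target, source]` orientation are fixed
package-wide and asserted in tests.  Endogenous fluctuations `v` are
independent across nodes with a shared power-law spectral density
`g_v(f) = exp(α)·(f/f₀)^(−exp(β))`, i.e. pink noise at the prior mean
(`β = 0`).  The reference frequency `f₀ = 0.03` Hz is roughly the
geometric centre of the analysed band; it only fixes the units of `α`.

The observed signal is the neuronal state convolved with a canonical
double-gamma hemodynamic kernel (gamma shapes 6 and 16, unit scale,
undershoot ratio 1/6 — response peak near 6 s, undershoot near 16 s),
whose Fourier transform is closed-form:
`h(f) = (1+i2πfd)⁻⁶ − (1/6)(1+i2πfd)⁻¹⁶`, with one free per-node delay
log-scaler `d = exp(θ)`.  A linear kernel (rather than a nonlinear balloon
model) keeps the cross-spectral density closed-form and the whole model
differentiable and cheap; this is a deliberate simplification and the main
structural difference from reference implementations of cross-spectral
DCM.  Observation noise is per-node power-law with fixed exponent 1 and a
structural scale of 1/16 relative to the neuronal density at `f₀`; the
scale puts synthetic fits in the ~80% variance-explained regime reported
for good empirical resting-state fits, and was found to influence neither
fit quality nor recovery error strongly over a factor-of-two range.

The model's cross-spectral density (CSD) is

    G_y(f) = H(f) G_v(f) H(f)^* + G_e(f),
    H(f)   = diag(h(f)) (i2πf I − A)^{-1},

Hermitian positive semidefinite at every frequency by construction.  All
spectra in the package are two-sided densities in units²/Hz, so the model
prediction, the autoregressive estimate and a Welch periodogram of a long
simulation are directly comparable (verified to a few percent per
frequency band in the tests).

**Parameter vector (20 entries).** 6 couplings (Hz), 4 self log-scalers,
4 hemodynamic delay log-scalers, 2 neuronal noise parameters
(log-amplitude, log-exponent), 4 observation log-amplitudes.  Priors are
zero-mean diagonal Gaussians: variance 1/16 for couplings, 1/64 for all
log-scaling parameters — shrinkage scales comparable to reference
cross-spectral DCM implementations, declared once in `network.py`.  The
prior mean is itself a meaningful model: −0.5 Hz self-inhibition, unit
hemodynamics, pink noise of unit amplitude.  Hemodynamic delays can be
frozen (`freeze_hemo`) for users who prefer fixed regional hemodynamics;
the default leaves them free.

## 2. Spectral estimation

Empirical CSDs come from a multivariate autoregressive (MVAR) fit of
order 8 by ordinary least squares, evaluated as
`S(f) = Δt·A(f)^{-1} Σ A(f)^{-H}` on the analysis grid — 32 linearly
spaced frequencies in [1/128, 0.1] Hz, matching the resting-state band
used throughout (the upper Nyquist limit at TR 3 s is 1/6 Hz).  AR
spectra are smooth at the short series lengths involved (161 volumes),
which is why the estimator is AR rather than Welch; Welch remains the
independent oracle in tests.  Degenerate inputs (constant channels,
rank-deficient lag matrices) raise typed errors rather than produce
garbage spectra.

## 3. Variational Laplace inversion

The stacked real/imaginary CSD entries (diagonal + upper triangle, 16 real
numbers per frequency, 512 in total) enter a Gaussian likelihood with a
single estimated log-precision `λ` (Gaussian prior N(0, 9)) and the
diagonal parameter prior above.  Gauss–Newton steps with Levenberg
damping maximize the Laplace free energy; `λ` is updated by Newton steps
inside each iteration; a step is accepted only if the joint free energy
does not decrease, so accepted free energies are monotone (asserted in
tests).  Proposals whose `A` is unstable are rejected and the damping
increased — eigenvalues are never projected.  Convergence: ΔF < 0.01 for
4 consecutive iterations, or 64 iterations (non-convergence is flagged on
the result, never silent).  Initialization is deterministic (prior mean;
moment-matched `λ`), so inversion is a pure function of the data.

**Whitening.**  The sampling error of a spectral estimate `S_ij` scales
with `sqrt(S_ii S_jj)`, so fitting raw entries with an isotropic
likelihood lets the large low-frequency terms dominate.  Each frequency's
entries are therefore scaled by the observed mean diagonal density at that
frequency (a fixed, data-derived weight).  In recovery simulations this
halves the per-subject coupling error (~0.13 → ~0.06 Hz RMSE) with
negligible bias; a full per-entry (coherence-style) weighting performed
similarly and is available via `InversionSettings.whiten`.  Variance
explained is always reported on the raw (unwhitened) scale.

## 4. Hierarchical group model (PEB)

Subject-level posteriors over the *field* parameters (couplings +
self-connections by default) enter a second level

    θ_i = (x_i' ⊗ I_p) β + ε_i,   ε_i ~ N(0, Σ_b),

with design rows `x_i` = intercept plus mean-centred covariates (sex and
scanner become 0/1 dummies before centring; the motor design is
(mean, TMS, age, sex, scanner), the apathy design additionally carries
depression and motor score).  Because replacing a subject's first-level
prior with the implied second-level prior `N((x_i'⊗I)β, Σ_b)` changes the
subject's log evidence in closed form (the model-reduction identity), the
likelihood of `β` is exactly Gaussian given `Σ_b`, and the conditional
posterior over `β` is available in one linear solve.

**Between-subject covariance.**  `Σ_b^{-1} = e^{-8}·I + Σ_j exp(γ_j) Q_j`
with `Q_j` the subject-prior precision of parameter group `j` and
`γ_j ~ N(0, 4)`.  By default every field parameter has its own component
("per-param").  The pooled alternative (one component for couplings, one
for self-connections) is available, but it lets a parameter with large
*unmodelled* between-subject spread — e.g. an edge driven by a covariate
absent from the design, exactly the situation of the motor design when
apathy also varies — inflate the apparent variability of every other
coupling, which in simulations widened the motor-effect standard errors by
~1.6×.  The per-parameter default removes that coupling of nuisance
variance across edges.  The 2- or p-dimensional `γ` maximization uses
Nelder–Mead / L-BFGS-B with a Laplace correction at the optimum.

**Effect priors.**  The group-mean column inherits the first-level prior
variances.  Covariate-effect blocks are additionally divided by the
covariate's sample variance — the prior a z-scored covariate would get,
while effects remain reported per raw unit.  Without this, a per-unit
effect of a 0–124 scale would carry a prior SD of 0.25 Hz *per point*
(absurdly wide), and the resulting Occam penalty in model comparison
suppresses genuinely present effects.

## 5. Model search and averaging

Candidate effects are all (covariate, parameter) elements of `β` for the
searched covariate columns (all non-intercept columns by default).
Switching an effect off means reducing its prior variance to 1e−8 (not
exactly zero, keeping the reduced precision positive definite).  While
more than 8 candidates remain undecided, the single switch-off with the
largest free-energy gain is committed greedily; if no removal helps, the
most clearly needed effects are fixed on.  The final ≤ 2⁸ = 256 models
are scored exhaustively and averaged with softmax free-energy weights;
an effect's posterior probability (pp) is the summed weight of models
retaining it (pruned effects report pp ≈ 0, fixed-on effects pp = 1).
With ≤ 8 candidates the search *is* exhaustive enumeration; tests verify
the weights against evidences computed directly from generating
linear-Gaussian models.  Reported effects use the pp > 0.99 convention
("very strong evidence") but the full table is always written.

## 6. Leave-one-out covariate prediction

For each subject the group model is refit from scratch on the remaining
subjects (including re-centring the design), so the test case contributes
nothing to training.  The held-out covariate is then treated as unknown:
the subject's first-level posterior induces a Gaussian pseudo-likelihood
over their implied group-level parameters; marginalizing the effect
posterior makes the likelihood's variance grow quadratically in the
candidate covariate value, and the covariate's posterior is integrated on
a grid spanning ±4 training SDs under the training cohort's empirical
Gaussian prior.  The posterior mean is the prediction; Pearson r and its
one-tailed p summarize predictive validity.  In the full workflow,
prediction follows model search: LOO runs on the connections the search
identified for the covariate (pp > 0.99), since without identified weights
there is nothing to predict from; a null cohort therefore normally yields
no prediction step at all rather than a noise correlation.  Note that an
*unconditional* null LOO correlation is not tightly bounded: even an
ideal uninformative predictor produces |r| up to the intrinsic Pearson
sampling width 1/sqrt(n−3), and leave-one-out predictions additionally
carry a small negative finite-sample correlation bias.  The variance-marginalized
grid form matters: a plug-in estimate divides by the squared effect norm
and produces heavy-tailed predictions when effects are near zero, which
inflates |r| under the null.  Constant predictions flag the result rather
than raising.

## 7. Synthetic cohorts

`canonical_scenario()` plants the published group means (thalamo-cortical
−0.39 Hz, direct +0.43 Hz, subthalamo-thalamic −0.10 Hz,
striato-subthalamic −0.17 Hz, null hyperdirect) plus a +0.2 Hz cortical
input (a mid-range magnitude; the input strength is not printed anywhere),
and the published per-unit covariate effects — motor score on both
indirect components (+0.013, +0.011), cortical input (−0.009),
thalamo-cortical output (−0.019) and STN self-connection (+0.010); apathy
on the direct edge (+0.022) and STN self-connection (−0.013).  Subject
couplings add effect terms (sample-centred covariates, so group means are
exact) and N(0, 0.05 Hz) between-subject noise; log-scaling parameters
get N(0, 0.02) jitter.  Unstable draws are resampled.  The 0.05 Hz
between-subject SD is a calibration constant — large enough that the
hierarchical level matters, small enough that n = 30 recovers group means;
it is not an estimate of any real cohort's heterogeneity.

Clinical tables match the target demographics: age 45.5 ± 8.9, motor
score 10.5 ± 8.5 on [0, 124], apathy 10.9 ± 6.0 on [0, 42], depression
6.6 ± 6.8 ≥ 0, CAG 43.1 ± 2.3 ≥ 40, 50% female, scanner split 52:42.
Truncation shifts a naive truncated normal's mean upward (by ~1.8 points
for the motor score), so the generator solves for the pre-truncation
location that makes the *truncated* mean equal the printed mean; the
realized SD sits slightly below the printed value.  Covariates are
sampled independently by default.

BOLD simulation integrates the Euler recursion
`x_{k+1} = (I + ΔtA)x_k + Δt v_k` at Δt = 0.1 s via a complex Schur
decomposition (exact for the recursion, and — unlike an
eigendecomposition — valid for defective `A`, e.g. a single coupling
between otherwise identical nodes), convolves with the delay-scaled
kernel, decimates to TR = 3 s, and adds observation noise synthesized
directly at the output rate.  Pink innovations are synthesized in the
frequency domain with the model's exact spectral density.

Toy 4-D volumes embed the node signals in four disjoint spherical masks
(24³ grid, 3 mm isotropic) with shared broadband nuisance signals,
voxelwise noise, and motion regressors dominated by frame-to-frame jitter
with occasional small steps and a weak drift (mean framewise displacement
~0.17 mm, the low-movement regime of well-behaved cohorts).  Motion and
nuisance series are deliberately broadband: regressors concentrated at
the lowest in-band frequencies would absorb genuine band-limited signal by
chance correlation — with only ~45 in-band Fourier components, a handful
of smooth regressors can steal 20–50% of a pink signal's variance, which
is a property of confound regression itself, not of the extraction code.

**What the synthetic data do not emulate:** spatial structure beyond
block-constant ROI signals (no smoothing, no partial-volume gradients),
real motion artefacts (the volumes are not actually displaced), scanner
drift and physiological aliasing, non-Gaussian clinical score
distributions, covariate correlations (e.g. motor–apathy), and any
nonlinearity of neurovascular coupling.  Passing recovery tests therefore
demonstrates the estimator chain is consistent and calibrated under its
own assumptions at realistic noise levels — not that those assumptions
hold in empirical data.

## 8. Extraction stage

The DCT basis uses orthonormal type-II cosines with frequencies
`j/(2·N·TR)`; for 161 volumes at TR 3 s over 0.0078–0.1 Hz this yields 89
components (the count follows from the formula and is surfaced, never
hardcoded).  M1 uses a 6 mm-radius sphere at the peak of the partial-F
map of the DCT block (confounds controlled); putamen and thalamus use
4 mm-radius spheres centred on the masked voxel whose confound-residualized
series correlates best with the M1 eigenvariate; the STN uses its whole
mask.  Sphere membership is evaluated in world space through the affine
(anisotropic voxels handled); radii are interpreted as radii, not
diameters.  Eigenvariates are the first singular vector of the
confound-residualized voxel matrix, unit-variance, signed to correlate
positively with the mean voxel series; the in-band DCT components are not
among the removed confounds (they model the signal of interest).
Framewise displacement uses the standard 50 mm rotation-to-displacement
radius; ties in peak searches break to the lowest linear index with a
logged warning.

## 9. Problem sizes and numerical conventions

Recovery experiments use n = 30 subjects, 161 volumes at TR 3 s; the
null-calibration suite uses 20 cohorts of n = 15, chosen so the whole
test suite and the acceptance script each run in minutes on one CPU.
Model reduction uses switch-off variance 1e−8; incompatible reductions
(non-PD reduced precision) raise.  All cohort generation, simulation and
inversion is deterministic given the configured seed; the pipeline stamps
every artifact with the config hash, seed and package version.

## 10. Known limitations

* The linear hemodynamic kernel ignores nonlinear balloon dynamics; real
  data with strong vascular nonlinearity will bias noise parameters.
* A single noise log-precision over all whitened CSD entries ignores
  residual error correlation across neighbouring frequencies; posterior
  variances at the first level are approximate, though the hierarchical
  level re-estimates between-subject variance on top of them.
* The per-parameter between-subject precision default trades a small loss
  of pooling efficiency for robustness to unmodelled covariate structure.
* Greedy pruning above 8 undecided effects is not guaranteed to find the
  global best 256-model set (the exhaustive tail mitigates but cannot
  remove this).
* Group-level recovery at n = 30 leaves ~±0.03 Hz uncertainty on group
  means; effects smaller than ~0.005 Hz per covariate unit are below the
  design's detection floor at these noise levels.
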