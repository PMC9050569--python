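"""Synthetic cohorts with planted ground truth.

Everything the analysis pipeline consumes can be generated here: per-subject
coupling parameters drawn around planted group means with covariate effects
on specific pathway edges, clinical covariate tables calibrated to the
demographics of a peri-manifest Huntington's disease cohort, BOLD-like node
time series simulated from the generative model itself, and small 4-D toy
volumes with the node signals embedded for testing the extraction stage.

The canonical scenario plants the published group-mean couplings of the
motor cortico-striato-thalamic loop (excitatory direct pathway, inhibitory
indirect components, net suppression of motor cortex) together with the
published motor-score and apathy associations, so that recovery of those
numbers by the full pipeline is a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from .invert import PosteriorDensity
from .network import (DCMParams, NetworkSpec, ParamLayout, PriorDensity,
                      build_bg_network, default_priors)
from .spectra import (F_REF_HZ, OBS_NOISE_EXPONENT, OBS_NOISE_SCALE,
                      SubjectTimeSeries)

CLINICAL_COLUMNS = ["subject_id", "TMS", "BAS", "BDI", "age", "sex", "scanner", "CAG"]


@dataclass
class TruthScenario:
    """Planted ground truth for a synthetic cohort.

    ``group_mean`` maps edge names ("SRC->TGT") to couplings in Hz;
    ``effects`` maps covariate name -> {parameter name: Hz per
    covariate-unit}, where parameter names follow the model layout (e.g.
    "PUT->STN" or "self_STN"); covariates are centred (cohort sample mean)
    before effects are applied, so group means are preserved exactly.
    """

    group_mean: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    between_subject_sd: float = 0.05  # Hz, on couplings
    aux_sd: float = 0.02  # between-subject jitter on log-scaling parameters
    n_volumes: int = 161
    tr: float = 3.0
    sim_dt: float = 0.1  # Euler step (s)
    spec: NetworkSpec = field(default_factory=build_bg_network)

    # clinical covariate calibration (mean, sd, truncation bounds)
    tms_moments: tuple = (10.5, 8.5, 0.0, 124.0)
    bas_moments: tuple = (10.9, 6.0, 0.0, 42.0)
    bdi_moments: tuple = (6.6, 6.8, 0.0, np.inf)
    age_moments: tuple = (45.5, 8.9, 18.0, 65.0)
    cag_moments: tuple = (43.1, 2.3, 40.0, np.inf)
    p_female: float = 0.5
    p_scanner_a: float = 52.0 / 94.0  # Siemens : Philips split

    def mean_vector(self) -> np.ndarray:
        """Ground-truth group mean as a flat parameter vector."""
        layout = ParamLayout(self.spec)
        names = layout.names()
        theta = np.zeros(layout.dim)
        for key, val in self.group_mean.items():
            theta[names.index(key)] = val
        return theta

    def effect_matrix(self, covariate: str) -> np.ndarray:
        """Planted effect of one covariate as a flat vector (Hz per unit)."""
        layout = ParamLayout(self.spec)
        names = layout.names()
        out = np.zeros(layout.dim)
        for key, val in self.effects.get(covariate, {}).items():
            if key not in names:
                raise ValueError(f"effect on unknown parameter {key!r}")
            out[names.index(key)] = val
        return out


def canonical_scenario() -> TruthScenario:
    """The default ground-truth scenario.

    Group means plant the published between-node estimates: thalamo-cortical
    output -0.39 Hz, direct (striato-thalamic) +0.43 Hz, the indirect
    components striato-subthalamic -0.17 Hz and subthalamo-thalamic
    -0.10 Hz, a null hyperdirect connection and a positive cortico-striatal
    input (+0.2 Hz, a mid-range magnitude; the input strength itself is not
    printed).  Motor-score effects are planted on both indirect components,
    the cortico-striatal input, the thalamo-cortical output and the STN
    self-connection; the apathy effect on the direct edge and the STN
    self-connection, each at its published per-unit slope.
    """
    return TruthScenario(
        group_mean={
            "THAL->M1": -0.39,
            "PUT->THAL": 0.43,
            "STN->THAL": -0.10,
            "PUT->STN": -0.17,
            "M1->STN": 0.0,
            "M1->PUT": 0.20,
        },
        effects={
            "TMS": {
                "PUT->STN": 0.013,
                "STN->THAL": 0.011,
                "M1->PUT": -0.009,
                "THAL->M1": -0.019,
                "self_STN": 0.010,
            },
            "BAS": {
                "PUT->THAL": 0.022,
                "self_STN": -0.013,
            },
        },
    )


def null_scenario() -> TruthScenario:
    """Canonical group means but all covariate effects removed (for
    false-positive calibration of the full chain)."""
    return replace(canonical_scenario(), effects={})


# ---------------------------------------------------------------------------
# Clinical covariates
# ---------------------------------------------------------------------------

def _truncnorm_match_mean(target_mean: float, sd: float, lo: float, hi: float):
    """Location mu such that a N(mu, sd) truncated to [lo, hi] has the
    target mean; returns a frozen truncnorm."""

    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    lo_b = target_mean - 4 * sd
    hi_b = target_mean + 4 * sd
    mu = optimize.brentq(trunc_mean, lo_b, hi_b, xtol=1e-8)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def sample_clinical(scenario: TruthScenario, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariate table with moments calibrated to the cohort
    demographics (means matched after truncation)."""
    cols = {}
    for name, (m, s, lo, hi), integer in [
        ("TMS", scenario.tms_moments, True),
        ("BAS", scenario.bas_moments, True),
        ("BDI", scenario.bdi_moments, True),
        ("age", scenario.age_moments, False),
        ("CAG", scenario.cag_moments, True),
    ]:
        dist = _truncnorm_match_mean(m, s, lo, hi)
        x = dist.rvs(size=n, random_state=rng)
        if integer:
            x = np.clip(np.round(x), lo, hi if np.isfinite(hi) else None)
        cols[name] = x.astype(int) if integer else x
    sex = np.where(rng.random(n) < scenario.p_female, "F", "M")
    scanner = np.where(rng.random(n) < scenario.p_scanner_a, "siemens", "philips")
    df = pd.DataFrame({
        "subject_id": [f"sub-{i + 1:03d}" for i in range(n)],
        "TMS": cols["TMS"], "BAS": cols["BAS"], "BDI": cols["BDI"],
        "age": cols["age"], "sex": sex, "scanner": scanner, "CAG": cols["CAG"],
    })
    return df


# ---------------------------------------------------------------------------
# Cohort parameters
# ---------------------------------------------------------------------------

def sample_cohort(scenario: TruthScenario, n: int, seed: int
                  ) -> tuple[list[DCMParams], pd.DataFrame]:
    """Draw per-subject model parameters and a clinical table.

    Subject couplings = group mean + sum over covariates of planted effect
    times the (sample-mean-centred) covariate + N(0, between_subject_sd);
    log-scaling parameters get small independent jitter.  Subjects whose
    coupling matrix is unstable are redrawn (the planted means themselves
    are well inside the stable regime).  Deterministic given the seed.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    clinical = sample_clinical(scenario, n, rng)
    layout = ParamLayout(scenario.spec)
    base = scenario.mean_vector()

    # covariate-driven shifts (centred covariates preserve the group mean)
    shift = np.zeros((n, layout.dim))
    for cov in scenario.effects:
        x = clinical[cov].to_numpy(dtype=float)
        shift += np.outer(x - x.mean(), scenario.effect_matrix(cov))

    sd = np.full(layout.dim, scenario.aux_sd)
    sd[layout.sl_coupling] = scenario.between_subject_sd

    params = []
    for i in range(n):
        for _attempt in range(100):
            theta = base + shift[i] + rng.normal(0.0, sd)
            p = DCMParams.from_vector(theta, layout)
            ev = np.linalg.eigvals(p.a_matrix())
            if ev.real.max() < -1e-3:
                break
        else:
            raise RuntimeError("could not draw a stable subject in 100 attempts")
        params.append(p)
    return params, clinical


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def _synth_noise(psd, n: int, dt: float, rng: np.random.Generator,
                 n_channels: int = 1) -> np.ndarray:
    """Real Gaussian series with a prescribed two-sided PSD (units^2/Hz).

    Frequency-domain synthesis: each positive-frequency rFFT bin is complex
    normal with E|X_k|^2 = S(f_k) * n / dt; DC is zero.
    """
    freqs = np.fft.rfftfreq(n, d=dt)
    amp = np.zeros_like(freqs)
    amp[1:] = np.sqrt(np.asarray(psd(freqs[1:])) * n / (2.0 * dt))
    X = amp[None, :] * (rng.standard_normal((n_channels, freqs.size))
                        + 1j * rng.standard_normal((n_channels, freqs.size)))
    X[:, 0] = 0.0
    if n % 2 == 0:
        X[:, -1] = X[:, -1].real * np.sqrt(2.0)
    return np.fft.irfft(X, n=n, axis=1)


def _hrf_kernel(dt: float, delay_scale: float, t_max: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic kernel sampled at dt (unit area
    weighting handled by the caller via the dt factor in the convolution)."""
    t = np.arange(0.0, t_max * max(delay_scale, 1.0), dt) / delay_scale
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    return h / delay_scale


def simulate_bold(params: DCMParams, scenario: TruthScenario, seed: int,
                  n_volumes: int | None = None) -> SubjectTimeSeries:
    """Simulate one subject's node time series from the generative model.

    Euler integration of dx/dt = A x + v at the scenario's step size with
    power-law ("pink") neuronal innovations, convolution with the per-node
    delay-scaled hemodynamic kernel, decimation to the repetition time, and
    additive per-node power-law observation noise.  The long-run Welch
    cross-spectra of the output match the model-predicted CSD.
    """
    rng = np.random.default_rng(seed)
    n_vol = n_volumes or scenario.n_volumes
    dt, tr = scenario.sim_dt, scenario.tr
    stride = int(round(tr / dt))
    burn = int(round(120.0 / dt))  # settle dynamics + hemodynamic kernel
    n_steps = n_vol * stride + burn + 1

    A = params.a_matrix()
    ev = np.linalg.eigvals(A)
    if ev.real.max() >= 0:
        raise ValueError("unstable coupling matrix; resample the subject")
    n_nodes = A.shape[0]

    amp_v = np.exp(params.noise_neuronal[0])
    expo_v = np.exp(params.noise_neuronal[1])
    v = _synth_noise(lambda f: amp_v * (f / F_REF_HZ) ** (-expo_v),
                     n_steps, dt, rng, n_channels=n_nodes)

    # Euler recursion x_{k+1} = (I + dt A) x_k + dt v_k, solved exactly via
    # a complex Schur form: the triangular system is integrated channel by
    # channel with scalar IIR filters.  (An eigendecomposition would fail
    # silently for defective A, e.g. a single coupling on otherwise
    # identical nodes.)
    from scipy.linalg import schur

    M = np.eye(n_nodes) + dt * A
    T, Q = schur(M.astype(complex), output="complex")  # M = Q T Q^H
    w = Q.conj().T @ v
    z = np.zeros((n_nodes, n_steps), dtype=complex)
    for i in range(n_nodes - 1, -1, -1):
        drive = dt * w[i]
        for j in range(i + 1, n_nodes):
            drive = drive + T[i, j] * z[j]
        # z_i[k] = T_ii z_i[k-1] + drive[k-1]
        z[i] = signal.lfilter([0.0, 1.0], [1.0, -T[i, i]], drive)
    x = (Q @ z).real

    # hemodynamic convolution (continuous convolution ~ discrete * dt)
    y = np.empty((n_nodes, n_vol))
    delays = np.exp(params.hemo_delay_log)
    for i in range(n_nodes):
        h = _hrf_kernel(dt, delays[i])
        bi = signal.fftconvolve(x[i], h)[:n_steps] * dt
        y[i] = bi[burn:burn + n_vol * stride:stride]

    # observation noise, synthesized directly at the output sampling rate
    amp_e = OBS_NOISE_SCALE * np.exp(params.noise_observation)
    for i in range(n_nodes):
        e = _synth_noise(lambda f: amp_e[i] * (f / F_REF_HZ) ** (-OBS_NOISE_EXPONENT),
                         n_vol, tr, rng)
        y[i] += e[0]

    return SubjectTimeSeries(node_series=y, tr=tr,
                             node_labels=scenario.spec.node_labels)


# ---------------------------------------------------------------------------
# Posterior cohorts (for second-level unit testing without full inversion)
# ---------------------------------------------------------------------------

def sample_posterior_cohort(scenario: TruthScenario, n: int, seed: int,
                            est_sd: float = 0.06
                            ) -> tuple[list[PosteriorDensity], pd.DataFrame]:
    """Synthesize first-level posteriors directly around the planted truth.

    Emulates the output of per-subject inversion — posterior mean = true
    parameters + estimation noise, posterior covariance diag(est_sd^2) —
    without running the spectral fits.  Intended for unit tests of the
    hierarchical level, where the first level is not the component under
    test.  Labelled synthetic by construction.
    """
    params, clinical = sample_cohort(scenario, n, seed)
    rng = np.random.default_rng(seed + 7_000_000)
    layout = ParamLayout(scenario.spec)
    posteriors = []
    for i, p in enumerate(params):
        theta = p.to_vector()
        mean = theta + rng.normal(0.0, est_sd, size=theta.size)
        cov = np.eye(theta.size) * est_sd ** 2
        posteriors.append(PosteriorDensity(
            mean=mean, covariance=cov, free_energy=0.0,
            variance_explained=float("nan"),
            subject_id=clinical["subject_id"].iloc[i],
            param_names=layout.names(),
        ))
    return posteriors, clinical


# ---------------------------------------------------------------------------
# Toy volumes for the extraction stage
# ---------------------------------------------------------------------------

def _sphere_mask(shape, centre, radius_vox) -> np.ndarray:
    grid = np.indices(shape)
    dist2 = sum((g - c) ** 2 for g, c in zip(grid, centre))
    return dist2 <= radius_vox ** 2


def make_toy_volumes(subject_ts: SubjectTimeSeries, seed: int,
                     shape=(24, 24, 24), voxel_mm: float = 3.0,
                     snr_amplitude: float = 1.0, noise_sd: float = 0.35):
    """Embed a subject's node signals into a small 4-D volume.

    Returns (VolumeSeries, dict of 4 RoiMasks, MotionParams, nuisance
    matrix).  Four disjoint spherical masks carry the four node signals plus
    shared confound signals and voxelwise noise; background voxels carry
    confounds and noise only.  Motion parameters are a slow random walk with
    occasional small steps (mean framewise displacement well under 0.5 mm)
    and are regressors only — the toy volume is not actually moved.
    """
    from .extract import MotionParams, RoiMask, VolumeSeries

    rng = np.random.default_rng(seed)
    t = subject_ts.n_time
    sig = subject_ts.node_series.copy()
    sig = (sig - sig.mean(axis=1, keepdims=True)) / sig.std(axis=1, keepdims=True)

    centres = {"M1": (12, 12, 19), "PUT": (7, 12, 12),
               "STN": (17, 12, 9), "THAL": (12, 7, 12)}
    radii = {"M1": 2.6, "PUT": 1.8, "STN": 1.2, "THAL": 1.8}
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.array(shape) - 1) / 2.0

    # shared confound (nuisance) signals: broadband physiological noise
    # (AR(1)) plus a respiratory-like oscillation.  Kept broadband on
    # purpose: regressors concentrated at the lowest in-band frequencies
    # would absorb genuine resting-state signal by chance correlation.
    nuis = np.column_stack([
        signal.lfilter([1.0], [1.0, -0.3], rng.standard_normal(t)),
        signal.lfilter([1.0], [1.0, -0.3], rng.standard_normal(t)),
    ])
    nuis = (nuis - nuis.mean(0)) / nuis.std(0)

    data = noise_sd * rng.standard_normal(shape + (t,))
    data += 0.3 * nuis[:, 0] + 0.2 * nuis[:, 1]
    masks = {}
    for k, name in enumerate(subject_ts.node_labels):
        m = _sphere_mask(shape, centres[name], radii[name])
        masks[name] = RoiMask(name=name, data=m)
        data[m] += snr_amplitude * sig[k]

    vol = VolumeSeries(data=data, voxel_size_mm=np.full(3, voxel_mm),
                       affine=affine, tr=subject_ts.tr)

    # motion: frame-to-frame jitter (realignment noise) + a slow drift of
    # much smaller norm + occasional small steps; dominated by the
    # broadband jitter so the regressors do not alias resting-state signal
    walk = np.cumsum(rng.normal(0.0, 0.0005, size=(t, 3)), axis=0)
    steps = np.cumsum((rng.random((t, 3)) < 0.01)
                      * rng.normal(0.0, 0.006, size=(t, 3)), axis=0)
    trans = 0.03 * rng.standard_normal((t, 3)) + walk + steps
    rot = (4e-4 * rng.standard_normal((t, 3))
           + np.cumsum(rng.normal(0.0, 8e-6, size=(t, 3)), axis=0)
           + np.cumsum((rng.random((t, 3)) < 0.01)
                       * rng.normal(0.0, 8e-5, size=(t, 3)), axis=0))
    motion = MotionParams(values=np.hstack([trans, rot]).T)
    return vol, masks, motion, nuis


# ---------------------------------------------------------------------------
# Cohort writer
# ---------------------------------------------------------------------------

def write_cohort(scenario: TruthScenario, n: int, seed: int, out_dir: str | Path,
                 volumes: bool = False) -> dict:
    """Simulate a cohort and write TSV time series, clinical table, truth
    JSON (and optionally NIfTI toy volumes) under ``out_dir``."""
    import json

    from .extract import save_motion, save_nifti_mask, save_nifti_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params, clinical = sample_cohort(scenario, n, seed)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    layout = ParamLayout(scenario.spec)
    truth = {
        "seed": seed,
        "group_mean": scenario.group_mean,
        "effects": scenario.effects,
        "subjects": {},
    }
    for i, p in enumerate(params):
        sid = clinical["subject_id"].iloc[i]
        ts = simulate_bold(p, scenario, seed=seed * 100_003 + i)
        ts.subject_id = sid
        ts.to_tsv(out / f"{sid}_timeseries.tsv")
        truth["subjects"][sid] = dict(zip(layout.names(), p.to_vector().tolist()))
        if volumes:
            vol, masks, motion, nuis = make_toy_volumes(ts, seed=seed * 7 + i)
            vdir = out / sid
            vdir.mkdir(exist_ok=True)
            save_nifti_volume(vol, vdir / "func.nii")
            for name, m in masks.items():
                save_nifti_mask(m, vol, vdir / f"mask_{name}.nii")
            save_motion(motion, vdir / "motion.txt")
            np.savetxt(vdir / "nuisance.txt", nuis)
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
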