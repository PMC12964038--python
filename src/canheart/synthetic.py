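"""Synthetic cohort generator: known-truth test bed for the full pipeline.

Emulates the statistical structure the analysis assumes: linear
stochastic neural dynamics with a stable coupling matrix, Balloon
hemodynamic convolution sampled at the scanner TR, power-law observation
noise, two groups with connection-specific offsets, heart-rate covariates
linearly coupled to designated connections, plus synthetic PPG and
rigid-body motion traces for the physiological QC stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import TrueConnectivity, make_connectivity
from .hemodynamics import HemodynamicParams, simulate_bold_nonlinear

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "simulate_neural",
    "powerlaw_noise",
    "simulate_bold",
    "simulate_cohort",
    "simulate_ppg",
    "simulate_motion",
    "write_cohort",
]

# Study-condition defaults: 26 patients / 40 controls, TR 0.961 s,
# 750 volumes with the first 4 discarded, group mean HR 65.06 / 74.1 bpm
# with SD ~10 bpm.
DEFAULT_TR = 0.961
DEFAULT_N_VOLUMES = 750
DEFAULT_N_DUMMY = 4


@dataclass
class CohortSpec:
    """Population-level description of a synthetic two-group cohort.

    ``effect_map_group`` entries (target, source, delta_hz) are added with
    sign +1 for the first group and -1 for the second;
    ``effect_map_hr`` entries (target, source, hz_per_bpm) couple the
    mean-centered heart rate to the named connection.
    """

    n_regions: int = 6
    n_per_group: tuple[int, int] = (26, 40)
    group_labels: tuple[str, str] = ("AN", "HC")
    coupling_sd: float = 0.15
    effect_map_group: tuple[tuple[int, int, float], ...] = ()
    effect_map_hr: tuple[tuple[int, int, float], ...] = ()
    hr_mean_per_group: tuple[float, float] = (65.06, 74.1)
    hr_sd: float = 10.0
    subject_noise_sd: float = 0.03
    tr_seconds: float = DEFAULT_TR
    n_volumes: int = DEFAULT_N_VOLUMES
    n_dummy: int = DEFAULT_N_DUMMY
    neural_fluct_sd: float = 0.05
    neural_ar1: float = 0.0      # 0 = white endogenous fluctuations
    obs_noise_exponent: float = 1.0
    obs_snr_band: tuple[float, float] = (0.01, 0.1)
    obs_snr: float = 1.0
    dt: float | None = None   # None: nearest divisor of TR to 0.05 s
    with_ppg: bool = False
    with_motion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("group sizes must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_dummy >= self.n_volumes:
            raise ValueError("n_dummy must be smaller than n_volumes")
        if self.dt is None:
            # integration step ~0.05 s, kept commensurate with the TR
            self.dt = self.tr_seconds / max(1, round(self.tr_seconds / 0.05))

    @property
    def grand_mean_hr(self) -> float:
        n1, n2 = self.n_per_group
        m1, m2 = self.hr_mean_per_group
        return (n1 * m1 + n2 * m2) / (n1 + n2)


@dataclass
class SyntheticSubject:
    id: str
    group: str
    group_code: int              # +1 first group (patients), -1 second
    hr_bpm: float
    true_connectivity: TrueConnectivity
    bold: np.ndarray             # (n_volumes - n_dummy) x N
    ppg: np.ndarray | None = None       # (time, amplitude) columns at ppg_fs
    ppg_fs: float = 500.0
    motion: np.ndarray | None = None    # frames x 6 (mm, mm, mm, rad, rad, rad)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("non-finite BOLD values")


def simulate_neural(
    conn: TrueConnectivity,
    duration: float,
    dt: float = 0.05,
    fluct_sd: float = 1.0,
    seed: int | None = None,
    ar1: float = 0.0,
) -> np.ndarray:
    """Euler-Maruyama integration of dx/dt = A x + v from x(0) = 0.

    ``fluct_sd`` is the white-noise spectral amplitude: the stationary
    covariance P solves A P + P A' + fluct_sd^2 I = 0 (for ar1 = 0).
    Setting ``ar1`` in (0, 1) low-pass shapes the endogenous fluctuations
    with a discrete AR(1) of that coefficient (variance-normalized).
    """
    a = conn.matrix
    if not conn.is_stable():
        raise ValueError("coupling matrix must be stable")
    n = conn.n_regions
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    out = np.empty((n_steps, n))
    scale = fluct_sd * np.sqrt(dt)
    eps = rng.normal(0.0, 1.0, size=(n_steps, n))
    if ar1 > 0.0:
        shaped = np.empty_like(eps)
        state = np.zeros(n)
        norm = np.sqrt(1.0 - ar1**2)
        for t in range(n_steps):
            state = ar1 * state + norm * eps[t]
            shaped[t] = state
        eps = shaped
    bound = 1e6 * max(fluct_sd, 1.0)
    bad = _neural_core(out, a, eps, dt, scale, bound)
    if bad >= 0:
        raise RuntimeError(f"neural state diverged at step {bad}; reduce dt")
    return out


def _neural_core(out, a, eps, dt, scale, bound):
    n_steps, n = out.shape
    x = np.zeros(n)
    for t in range(n_steps):
        out[t] = x
        x = x + dt * (a @ x) + scale * eps[t]
        if np.max(np.abs(x)) > bound:
            return t
    return -1


try:
    from numba import njit

    _neural_core = njit(cache=False)(_neural_core)
except ImportError:  # pragma: no cover
    pass


def powerlaw_noise(
    n: int, dt: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with spectral density proportional to f^-exponent."""
    white = rng.normal(0.0, 1.0, size=n)
    if exponent == 0.0:
        return sd * white
    f = np.fft.rfftfreq(n, d=dt)
    shaping = np.ones_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    spec = np.fft.rfft(white) * shaping
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return sd * x / s if s > 0 else x


def band_power(x: np.ndarray, dt: float, band: tuple[float, float]) -> float:
    """Mean periodogram power of each column inside a frequency band."""
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    f = np.fft.rfftfreq(x.shape[0], d=dt)
    sel = (f >= band[0]) & (f <= band[1])
    p = np.abs(np.fft.rfft(x - x.mean(axis=0), axis=0)) ** 2
    return float(p[sel].mean())


def simulate_bold(
    latent: np.ndarray,
    dt: float,
    tr: float,
    hemo: HemodynamicParams | None = None,
    obs_noise_sd: float = 0.0,
    obs_noise_exponent: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Hemodynamic convolution of neural activity, sampled at the TR.

    Integrates the nonlinear Balloon equations at ``dt``, reads out BOLD,
    downsamples to one frame per ``tr`` and adds power-law observation
    noise of the given standard deviation.
    """
    latent = np.asarray(latent, float)
    step = tr / dt
    if abs(step - round(step)) > 1e-6:
        raise ValueError("tr must be an integer multiple of dt")
    if hemo is None:
        hemo = HemodynamicParams(n_regions=latent.shape[1])
    y = simulate_bold_nonlinear(latent, dt, hemo)
    bold = y[:: int(round(step))]
    if obs_noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        noise = np.column_stack(
            [
                powerlaw_noise(bold.shape[0], tr, obs_noise_exponent, obs_noise_sd, rng)
                for _ in range(bold.shape[1])
            ]
        )
        bold = bold + noise
    return bold


def _stable_subject_matrix(
    rng: np.random.Generator,
    base: TrueConnectivity,
    offset: np.ndarray,
    noise_sd: float,
    max_resamples: int = 100,
) -> tuple[TrueConnectivity, np.ndarray]:
    """Subject matrix = base + fixed offsets + random noise, kept stable."""
    n = base.n_regions
    mask = ~np.eye(n, dtype=bool)
    for _ in range(max_resamples):
        noise = rng.normal(0.0, noise_sd, size=(n, n)) * mask
        offdiag = base.theta_offdiag + offset + noise
        conn = TrueConnectivity(offdiag, base.theta_self.copy(), base.labels)
        if conn.is_stable():
            return conn, noise
    raise RuntimeError("could not find a stable subject-level matrix in 100 draws")


def _effect_matrix(n: int, entries) -> np.ndarray:
    m = np.zeros((n, n))
    for tgt, src, val in entries:
        if tgt == src:
            raise ValueError("effect maps address off-diagonal connections only")
        m[tgt, src] = val
    return m


def simulate_cohort(
    spec: CohortSpec, base: TrueConnectivity | None = None
) -> tuple[list[SyntheticSubject], dict]:
    """Generate a two-group cohort plus a ground-truth record.

    Each subject's off-diagonal couplings are
    ``base + group_code*group_effect + (hr - grand_mean_hr)*hr_effect +
    subject_noise`` (resampled until stable); BOLD is simulated through
    the hemodynamic model with power-law observation noise scaled so the
    in-band SNR matches ``spec.obs_snr``.  The truth record is sufficient
    to recompute every subject matrix exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_regions
    if base is None:
        base = make_connectivity(n, spec.coupling_sd, seed=int(rng.integers(2**31)))
    g_eff = _effect_matrix(n, spec.effect_map_group)
    hr_eff = _effect_matrix(n, spec.effect_map_hr)
    duration = spec.n_volumes * spec.tr_seconds
    n_keep = spec.n_volumes - spec.n_dummy
    hemo = HemodynamicParams(n_regions=n)
    subjects: list[SyntheticSubject] = []
    truth_subjects = []
    idx = 0
    for g, (n_g, label, hr_mean) in enumerate(
        zip(spec.n_per_group, spec.group_labels, spec.hr_mean_per_group)
    ):
        code = 1 if g == 0 else -1
        for _ in range(n_g):
            idx += 1
            sid = f"sub-{idx:03d}"
            hr = float(rng.normal(hr_mean, spec.hr_sd))
            offset = code * g_eff + (hr - spec.grand_mean_hr) * hr_eff
            conn, noise = _stable_subject_matrix(rng, base, offset, spec.subject_noise_sd)
            latent = simulate_neural(
                conn,
                duration,
                dt=spec.dt,
                fluct_sd=spec.neural_fluct_sd,
                seed=int(rng.integers(2**31)),
                ar1=spec.neural_ar1,
            )
            clean = simulate_bold(latent, spec.dt, spec.tr_seconds, hemo)
            sig_power = band_power(clean[spec.n_dummy :], spec.tr_seconds, spec.obs_snr_band)
            noise_rng = np.random.default_rng(int(rng.integers(2**31)))
            unit = np.column_stack(
                [
                    powerlaw_noise(n_keep, spec.tr_seconds, spec.obs_noise_exponent, 1.0, noise_rng)
                    for _ in range(n)
                ]
            )
            unit_power = band_power(unit, spec.tr_seconds, spec.obs_snr_band)
            scale = np.sqrt(sig_power / (spec.obs_snr * unit_power)) if unit_power > 0 else 0.0
            bold = clean[spec.n_dummy :] + scale * unit
            ppg = ppg_fs = None
            if spec.with_ppg:
                ppg = simulate_ppg(
                    hr_bpm=hr, fs=500.0, duration=600.0, seed=int(rng.integers(2**31))
                )
                ppg_fs = 500.0
            motion = None
            if spec.with_motion:
                motion = simulate_motion(
                    n_frames=n_keep, baseline_sd=0.005, seed=int(rng.integers(2**31))
                )
            subjects.append(
                SyntheticSubject(
                    id=sid, group=label, group_code=code, hr_bpm=hr,
                    true_connectivity=conn, bold=bold,
                    ppg=ppg, ppg_fs=ppg_fs or 500.0, motion=motion,
                )
            )
            truth_subjects.append(
                {
                    "id": sid,
                    "group": label,
                    "group_code": code,
                    "hr_bpm": hr,
                    "subject_noise": noise.tolist(),
                    "theta_offdiag": conn.theta_offdiag.tolist(),
                    "theta_self": conn.theta_self.tolist(),
                    "obs_noise_sd": float(scale),
                }
            )
    truth = {
        "seed": spec.seed,
        "labels": list(base.labels),
        "base_theta_offdiag": base.theta_offdiag.tolist(),
        "base_theta_self": base.theta_self.tolist(),
        "effect_map_group": [list(e) for e in spec.effect_map_group],
        "effect_map_hr": [list(e) for e in spec.effect_map_hr],
        "grand_mean_hr": spec.grand_mean_hr,
        "tr_seconds": spec.tr_seconds,
        "subjects": truth_subjects,
    }
    return subjects, truth


def _pulse_template(t: np.ndarray) -> np.ndarray:
    """Asymmetric unimodal pulse: log-normal systolic peak plus a dicrotic
    bump at 35% amplitude (morphology for the detector, not physiology)."""
    t = np.maximum(t, 1e-9)
    systolic = np.exp(-((np.log(t / 0.17)) ** 2) / (2 * 0.35**2))
    dicrotic = 0.35 * np.exp(-((np.log(t / 0.45)) ** 2) / (2 * 0.18**2))
    return systolic + dicrotic


def simulate_ppg(
    hr_bpm: float,
    hr_jitter_sd: float = 0.02,
    fs: float = 500.0,
    duration: float = 600.0,
    seed: int | None = None,
    drift_amp: float = 0.1,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Synthetic photoplethysmogram: (time, amplitude) columns.

    Beats are placed at inter-beat intervals 60/hr_bpm plus Gaussian
    jitter; each beat contributes the asymmetric pulse template.  Slow
    baseline drift and broadband noise are superimposed.
    """
    if not 30.0 <= hr_bpm <= 200.0:
        raise ValueError("hr_bpm must be in [30, 200]")
    if fs < 100.0:
        raise ValueError("fs must be >= 100 Hz")
    rng = np.random.default_rng(seed)
    ibi = 60.0 / hr_bpm
    beats = []
    t = 0.2
    while t < duration:
        beats.append(t)
        t += ibi + (rng.normal(0.0, hr_jitter_sd) if hr_jitter_sd > 0 else 0.0)
    n = int(round(duration * fs))
    time = np.arange(n) / fs
    x = np.zeros(n)
    span = int(round(min(1.2, ibi) * fs))
    tmpl = _pulse_template(np.arange(span) / fs)
    for b in beats:
        i0 = int(round(b * fs))
        i1 = min(n, i0 + span)
        if i0 < n:
            x[i0:i1] += tmpl[: i1 - i0]
    drift = drift_amp * np.sin(2 * np.pi * 0.03 * time + rng.uniform(0, 2 * np.pi))
    drift += drift_amp * 0.5 * np.sin(2 * np.pi * 0.01 * time + rng.uniform(0, 2 * np.pi))
    x = x + drift + rng.normal(0.0, noise_sd, size=n)
    return np.column_stack([time, x])


def simulate_motion(
    n_frames: int,
    baseline_sd: float = 0.01,
    spike_frames: tuple[int, ...] = (),
    spike_size: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Rigid-body motion traces: smooth random walk plus step displacements.

    Columns are 3 translations (mm) and 3 rotations (rad).  Spikes are
    persistent steps of ``spike_size`` mm added to the x-translation at
    the listed frames, so the framewise displacement shows one large value
    per spike frame.
    """
    if any(i >= n_frames or i < 0 for i in spike_frames):
        raise ValueError("spike frame indices must lie within the run")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, baseline_sd, size=(n_frames, 6))
    steps[:, 3:] /= 50.0  # rotations drift ~50x smaller in rad
    steps[0] = 0.0
    traj = np.cumsum(steps, axis=0)
    for i in spike_frames:
        traj[i:, 0] += spike_size
    return traj


def write_cohort(subjects: list[SyntheticSubject], truth: dict, outdir) -> None:
    """Write a cohort directory: per-subject BOLD/PPG/motion TSVs,
    participants.csv and truth.json."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    labels = truth["labels"]
    for s in subjects:
        pd.DataFrame(s.bold, columns=labels).to_csv(
            outdir / f"{s.id}_bold.tsv", sep="\t", index=False, float_format="%.17g"
        )
        if s.ppg is not None:
            pd.DataFrame(s.ppg, columns=["time", "amplitude"]).to_csv(
                outdir / f"{s.id}_ppg.tsv", sep="\t", index=False, float_format="%.17g"
            )
        if s.motion is not None:
            pd.DataFrame(
                s.motion, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
            ).to_csv(outdir / f"{s.id}_motion.tsv", sep="\t", index=False, float_format="%.17g")
        rows.append({"subject": s.id, "group": s.group, "hr_bpm": s.hr_bpm})
    pd.DataFrame(rows).to_csv(outdir / "participants.csv", index=False, float_format="%.17g")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
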