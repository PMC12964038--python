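"""Generative cross-spectral model and its variational-Laplace inversion.

The generative model predicts the complex cross-spectral density of the
observed BOLD signals from (i) a linear neuronal state-space
dx/dt = A x + v with inhibitory self-connections A[i,i] = -0.5*exp(theta_self[i]),
(ii) per-region linearized hemodynamic transfer functions K(f), and
(iii) power-law spectra for the endogenous fluctuations v and the
observation noise e:

    G_y(f) = K(f) T(f) G_v(f) T(f)^H K(f)^H + G_e(f),
    T(f) = (i 2 pi f I - A)^-1.

Inversion maximizes a variational free energy (Gaussian likelihood over
the stacked real and imaginary spectral features with block-wise residual
precisions, minus the KL complexity to shrinkage priors) by Gauss-Newton
ascent with adaptive Levenberg-Marquardt regularization; residual
precisions (one log-precision per region-pair block) are profiled out at
every candidate step, so accepted steps can only increase the objective.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .connectivity import effective_matrix
from .hemodynamics import HemodynamicParams, hemodynamic_kernel
from .spectra import CrossSpectrum, default_freq_grid

__all__ = [
    "NoiseParams",
    "DCMPriors",
    "ParamLayout",
    "SubjectPosterior",
    "default_priors",
    "generative_csd",
    "invert",
    "explained_variance",
    "explained_variance_time",
    "screen_subjects",
]

#: Reference frequency (Hz) at which power-law spectra equal their
#: amplitude; mid resting-state band.
F_REF = 0.03

#: Explained-variance inclusion threshold (inclusive).
EV_THRESHOLD = 0.10


@dataclass
class NoiseParams:
    """Power-law spectra G(f) = exp(log_amp) * (f/F_REF)^-exponent for the
    endogenous neuronal fluctuations and the observation noise (pooled
    across regions)."""

    log_amp_neural: float = 0.0
    exponent_neural: float = 1.0
    log_amp_obs: float = 0.0
    exponent_obs: float = 1.0


def _exponent_transform(raw: np.ndarray | float) -> np.ndarray | float:
    """Map an unbounded latent exponent parameter into [0, 2], with 0 -> 1
    and unit local slope (so the latent prior variance is preserved)."""
    return 2.0 / (1.0 + np.exp(-2.0 * np.asarray(raw, float)))


class ParamLayout:
    """Index bookkeeping for the flat latent-parameter vector.

    Order: off-diagonal couplings (row-major, skipping the diagonal),
    self log-scalings, hemodynamic decay log-scalings, hemodynamic
    transit log-scalings, then 4 pooled noise parameters
    (neural log-amp, neural exponent raw, obs log-amp, obs exponent raw).
    """

    def __init__(self, n_regions: int):
        self.n = n_regions
        self.offdiag_idx = [
            (i, j) for i in range(n_regions) for j in range(n_regions) if i != j
        ]
        m = len(self.offdiag_idx)
        self.sl_offdiag = slice(0, m)
        self.sl_self = slice(m, m + n_regions)
        self.sl_decay = slice(m + n_regions, m + 2 * n_regions)
        self.sl_transit = slice(m + 2 * n_regions, m + 3 * n_regions)
        self.sl_noise = slice(m + 3 * n_regions, m + 3 * n_regions + 4)
        self.n_params = m + 3 * n_regions + 4
        # connectivity block (off-diagonals then selfs) used by the group level
        self.sl_conn = slice(0, m + n_regions)

    def split(self, theta: np.ndarray):
        n = self.n
        offdiag = np.zeros((n, n))
        for k, (i, j) in enumerate(self.offdiag_idx):
            offdiag[i, j] = theta[self.sl_offdiag][k]
        theta_self = theta[self.sl_self]
        hemo = HemodynamicParams(
            n_regions=n,
            theta_decay=theta[self.sl_decay].copy(),
            theta_transit=theta[self.sl_transit].copy(),
        )
        nz = theta[self.sl_noise]
        noise = NoiseParams(
            log_amp_neural=float(nz[0]),
            exponent_neural=float(_exponent_transform(nz[1])),
            log_amp_obs=float(nz[2]),
            exponent_obs=float(_exponent_transform(nz[3])),
        )
        return offdiag, theta_self, hemo, noise

    def effective_matrix(self, theta: np.ndarray) -> np.ndarray:
        offdiag, theta_self, _, _ = self.split(theta)
        return effective_matrix(offdiag, theta_self)

    def conn_names(self, labels) -> list[str]:
        names = [f"{labels[j]}->{labels[i]}" for i, j in self.offdiag_idx]
        names += [f"{lab}->{lab}" for lab in labels]
        return names


@dataclass
class DCMPriors:
    """Gaussian shrinkage priors over the flat latent-parameter vector."""

    mean: np.ndarray
    variance: np.ndarray
    layout: ParamLayout

    def __post_init__(self) -> None:
        if np.any(self.variance < 0):
            raise ValueError("prior variances must be non-negative")


def default_priors(n_regions: int) -> DCMPriors:
    """Shrinkage priors: couplings N(0, 1/64); self and hemodynamic
    log-scalings N(0, 1/256); noise log-amplitudes N(0, 1/64); latent
    spectral exponents N(0, 1/64) (centered on pink noise after the
    [0, 2] transform)."""
    layout = ParamLayout(n_regions)
    mean = np.zeros(layout.n_params)
    var = np.empty(layout.n_params)
    var[layout.sl_offdiag] = 1.0 / 64.0
    var[layout.sl_self] = 1.0 / 256.0
    var[layout.sl_decay] = 1.0 / 256.0
    var[layout.sl_transit] = 1.0 / 256.0
    var[layout.sl_noise] = 1.0 / 64.0
    return DCMPriors(mean, var, layout)


def generative_csd(
    theta_offdiag: np.ndarray,
    theta_self: np.ndarray,
    freqs: np.ndarray,
    hemo: HemodynamicParams | None = None,
    noise: NoiseParams | None = None,
    labels=None,
) -> CrossSpectrum:
    """Predicted BOLD cross-spectral density for one parameter set.

    ``hemo=None`` uses identity hemodynamic kernels (the neuronal spectrum
    itself), which is the analytically tractable Ornstein-Uhlenbeck case;
    ``noise=None`` uses flat unit fluctuation spectra and no observation
    noise.
    """
    freqs = np.asarray(freqs, dtype=float)
    a = effective_matrix(theta_offdiag, theta_self)
    if np.max(np.linalg.eigvals(a).real) >= 0:
        raise ValueError("effective matrix must be stable")
    n = a.shape[0]
    eye = np.eye(n)
    mats = 1j * 2.0 * np.pi * freqs[:, None, None] * eye - a
    t = np.linalg.inv(mats)
    if noise is None:
        g_v = np.ones(freqs.size)
        g_e = np.zeros(freqs.size)
    else:
        rel = freqs / F_REF
        g_v = np.exp(noise.log_amp_neural) * rel ** (-noise.exponent_neural)
        g_e = np.exp(noise.log_amp_obs) * rel ** (-noise.exponent_obs)
    if hemo is not None:
        k = hemodynamic_kernel(hemo, freqs)  # (n_f, N)
        m = k[:, :, None] * t
    else:
        m = t
    values = np.einsum("fij,f,flj->fil", m, g_v, m.conj())
    values += g_e[:, None, None] * eye
    values = 0.5 * (values + values.conj().transpose(0, 2, 1))
    return CrossSpectrum(freqs, values, labels)


# ---------------------------------------------------------------------------
# feature packing


class _FeatureMap:
    """Stacks the non-redundant real/imaginary CSD entries into a vector
    with one residual-precision block per region pair."""

    def __init__(self, n_regions: int, n_freq: int):
        self.n = n_regions
        self.n_freq = n_freq
        self.pairs = [(i, j) for i in range(n_regions) for j in range(i, n_regions)]
        self.block_sizes = [
            n_freq if i == j else 2 * n_freq for (i, j) in self.pairs
        ]
        self.n_feat = sum(self.block_sizes)

    def pack(self, csd_values: np.ndarray) -> np.ndarray:
        parts = []
        for i, j in self.pairs:
            if i == j:
                parts.append(csd_values[:, i, i].real)
            else:
                parts.append(csd_values[:, i, j].real)
                parts.append(csd_values[:, i, j].imag)
        return np.concatenate(parts)

    def block_slices(self):
        out = []
        start = 0
        for size in self.block_sizes:
            out.append(slice(start, start + size))
            start += size
        return out


@dataclass
class SubjectPosterior:
    """Posterior bundle from one subject's inversion."""

    Ep: np.ndarray                 # flat latent-parameter expectation
    Cp: np.ndarray                 # posterior covariance (n_params x n_params)
    free_energy: float
    explained_variance: float      # on the fitted cross-spectral features
    explained_variance_time: float  # companion time-domain figure
    converged: bool
    n_iter: int
    layout: ParamLayout
    labels: tuple[str, ...] | None = None
    f_trace: list = field(default_factory=list)
    data_scale: float = 1.0

    @property
    def connectivity_matrix(self) -> np.ndarray:
        """Posterior expectation of A (Hz; diagonal on the -0.5*exp scale)."""
        return self.layout.effective_matrix(self.Ep)

    def to_dict(self) -> dict:
        labels = list(self.labels) if self.labels else [f"R{i}" for i in range(self.layout.n)]
        names = self.layout.conn_names(labels)
        conn = self.Ep[self.layout.sl_conn]
        return {
            "n_regions": self.layout.n,
            "labels": labels,
            "Ep": {name: float(v) for name, v in zip(names, conn)},
            "Ep_full": self.Ep.tolist(),
            "Cp": self.Cp.tolist(),
            "free_energy": float(self.free_energy),
            "explained_variance": float(self.explained_variance),
            "explained_variance_time": float(self.explained_variance_time),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "data_scale": float(self.data_scale),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectPosterior":
        layout = ParamLayout(d["n_regions"])
        return cls(
            Ep=np.asarray(d["Ep_full"], float),
            Cp=np.asarray(d["Cp"], float),
            free_energy=d["free_energy"],
            explained_variance=d["explained_variance"],
            explained_variance_time=d["explained_variance_time"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            layout=layout,
            labels=tuple(d["labels"]),
            data_scale=d.get("data_scale", 1.0),
        )

    @classmethod
    def load(cls, path) -> "SubjectPosterior":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class InversionOptions:
    max_iter: int = 128
    f_tol: float = 1e-2       # convergence: |dF| below this ...
    patience: int = 4         # ... for this many consecutive accepted steps
    fd_step: float = 1e-3     # forward-difference step for the Jacobian
    lm_init: float = 0.01     # initial Levenberg-Marquardt factor
    lm_max: float = 1e8
    stability_margin: float = 1e-6
    lambda_cap: float = 1e3   # ceiling on profiled block precisions (see below)


def _whittle_weights(scaled_values: np.ndarray, fmap: "_FeatureMap") -> np.ndarray:
    """Fixed per-feature weights 1/(S_ii(f) S_jj(f)) from the observed CSD.

    The sampling variance of a cross-spectral estimate S_ij(f) is
    proportional to S_ii(f) S_jj(f), so weighting squared residuals by the
    inverse product puts every region pair and frequency on a comparable
    (Whittle-likelihood) scale.
    """
    parts = []
    for i, j in fmap.pairs:
        wij = 1.0 / np.maximum(
            scaled_values[:, i, i].real * scaled_values[:, j, j].real, 1e-300
        )
        parts.append(wij)
        if i != j:
            parts.append(wij)
    return np.concatenate(parts)


def _profile_free_energy(e: np.ndarray, blocks, wfix: np.ndarray,
                         dtheta: np.ndarray, prior_prec: np.ndarray, cap: float):
    """Free energy with one residual log-precision per region-pair block,
    profiled at its conditional optimum over the Whittle-weighted
    residuals.  ``cap`` bounds each block precision (a tight hyperprior:
    weighted residuals are never trusted beyond 1/sqrt(cap) of the local
    spectral scale), which prevents the search from fitting estimation
    noise in the observed spectra with runaway confidence.

    Returns (F, per-feature precision weights).
    """
    weights = np.empty_like(e)
    f_data = 0.0
    for sl in blocks:
        eb = e[sl]
        n_b = eb.size
        s_b = float(np.sum(wfix[sl] * eb * eb))
        lam = n_b / (s_b + n_b / cap)
        weights[sl] = lam * wfix[sl]
        f_data += -0.5 * lam * s_b + 0.5 * n_b * np.log(lam)
    f_prior = -0.5 * float(dtheta @ (prior_prec * dtheta))
    return f_data + f_prior, weights


def invert(
    observed: CrossSpectrum,
    priors: DCMPriors | None = None,
    options: InversionOptions | None = None,
) -> SubjectPosterior:
    """Fit the generative cross-spectral model to an observed CSD.

    Gauss-Newton ascent on the variational free energy with profiled
    residual precisions; candidate steps whose effective matrix is
    unstable, or which do not increase the free energy, are rejected and
    the regularization increased, so the recorded free-energy trace is
    non-decreasing by construction.  The posterior covariance is the
    inverse Gauss-Newton curvature (plus prior precision) at the optimum.
    """
    if not observed.is_hermitian(tol=1e-6):
        raise ValueError("observed CSD violates the Hermitian/diagonal invariants")
    opts = options or InversionOptions()
    n = observed.n_regions
    priors = priors or default_priors(n)
    layout = priors.layout
    freqs = observed.freqs
    fmap = _FeatureMap(n, freqs.size)
    blocks = fmap.block_slices()

    prior_prec = np.where(priors.variance > 0, 1.0 / np.maximum(priors.variance, 1e-12), 1e12)
    free = priors.variance > 0

    # scale data to the natural amplitude of the model at the prior mean
    g0 = _predict(priors.mean, layout, freqs)
    obs_power = float(np.mean(np.diagonal(observed.values, axis1=1, axis2=2).real))
    mod_power = float(np.mean(np.diagonal(g0, axis1=1, axis2=2).real))
    scale = mod_power / obs_power if obs_power > 0 else 1.0
    scaled_values = observed.values * scale
    y = fmap.pack(scaled_values)
    wfix = _whittle_weights(scaled_values, fmap)

    theta = priors.mean.copy()

    def objective(th):
        a = layout.effective_matrix(th)
        if np.max(np.linalg.eigvals(a).real) >= -opts.stability_margin:
            return -np.inf, None, None
        g = _predict(th, layout, freqs)
        e = y - fmap.pack(g)
        f, w = _profile_free_energy(e, blocks, wfix, th - priors.mean, prior_prec, opts.lambda_cap)
        return f, e, w

    f_cur, e_cur, w_cur = objective(theta)
    if not np.isfinite(f_cur):
        raise ValueError("prior-mean parameters are unstable; check priors")
    f_trace = [f_cur]
    lm = opts.lm_init
    n_small = 0
    converged = False
    it = 0
    jac = None
    for it in range(1, opts.max_iter + 1):
        jac = _jacobian(theta, layout, freqs, fmap, free, opts.fd_step)
        jw = jac * w_cur[:, None]
        hess = jac.T @ jw
        hess[np.diag_indices_from(hess)] += prior_prec
        grad = jw.T @ e_cur - prior_prec * (theta - priors.mean)
        accepted = False
        while lm <= opts.lm_max:
            reg = hess + lm * np.diag(np.maximum(np.diag(hess), 1e-12))
            try:
                step = np.linalg.solve(reg, grad)
            except np.linalg.LinAlgError:
                lm *= 4.0
                continue
            step[~free] = 0.0
            cand = theta + step
            f_new, e_new, w_new = objective(cand)
            if f_new > f_cur:
                d_f = f_new - f_cur
                theta, f_cur, e_cur, w_cur = cand, f_new, e_new, w_new
                f_trace.append(f_cur)
                lm = max(lm / 2.0, 1e-8)
                accepted = True
                n_small = n_small + 1 if d_f < opts.f_tol else 0
                break
            lm *= 4.0
        if not accepted:
            break
        if n_small >= opts.patience:
            converged = True
            break
    else:
        it = opts.max_iter

    if not converged and n_small > 0:
        # ran out of iterations while still improving slowly
        converged = bool(len(f_trace) > 1 and (f_trace[-1] - f_trace[-2]) < opts.f_tol)

    # posterior covariance from the curvature at the optimum
    jac = _jacobian(theta, layout, freqs, fmap, free, opts.fd_step)
    hess = jac.T @ (jac * w_cur[:, None])
    hess[np.diag_indices_from(hess)] += prior_prec
    cp = np.linalg.inv(hess)
    cp = 0.5 * (cp + cp.T)
    evals, evecs = np.linalg.eigh(cp)
    if evals.min() < -1e-6 * max(evals.max(), 1e-30):
        raise np.linalg.LinAlgError("posterior covariance not PSD after conditioning")
    cp = (evecs * np.clip(evals, 1e-15, None)) @ evecs.T

    predicted = _predict(theta, layout, freqs)
    pred_cs = CrossSpectrum(freqs, predicted)
    obs_scaled = CrossSpectrum(freqs, observed.values * scale)
    ev = explained_variance(obs_scaled, pred_cs)
    ev_t = explained_variance_time(obs_scaled, pred_cs)
    # full free energy: ascent objective plus the Gaussian-volume terms
    sign, logdet_h = np.linalg.slogdet(hess)
    log_prior_prec = float(np.sum(np.log(prior_prec[free])))
    f_full = f_cur + 0.5 * (log_prior_prec - logdet_h)

    return SubjectPosterior(
        Ep=theta,
        Cp=cp,
        free_energy=float(f_full),
        explained_variance=ev,
        explained_variance_time=ev_t,
        converged=converged,
        n_iter=it,
        layout=layout,
        labels=observed.labels,
        f_trace=f_trace,
        data_scale=scale,
    )


def _predict(theta: np.ndarray, layout: ParamLayout, freqs: np.ndarray) -> np.ndarray:
    offdiag, theta_self, hemo, noise = layout.split(theta)
    return generative_csd(offdiag, theta_self, freqs, hemo=hemo, noise=noise).values


def _jacobian(theta, layout, freqs, fmap, free, step):
    g0 = fmap.pack(_predict(theta, layout, freqs))
    jac = np.zeros((g0.size, theta.size))
    for k in np.flatnonzero(free):
        th = theta.copy()
        th[k] += step
        try:
            gk = fmap.pack(_predict(th, layout, freqs))
        except ValueError:
            th[k] = theta[k] - step
            gk = 2 * g0 - fmap.pack(_predict(th, layout, freqs))
        jac[:, k] = (gk - g0) / step
    return jac


def explained_variance(observed: CrossSpectrum, predicted: CrossSpectrum) -> float:
    """1 - SSE/SST over the stacked real and imaginary CSD features,
    floored at 0."""
    if observed.values.shape != predicted.values.shape or not np.allclose(
        observed.freqs, predicted.freqs
    ):
        raise ValueError("observed and predicted spectra must share the grid")
    o = np.concatenate([observed.values.real.ravel(), observed.values.imag.ravel()])
    p = np.concatenate([predicted.values.real.ravel(), predicted.values.imag.ravel()])
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        return 1.0 if np.allclose(o, p) else 0.0
    sse = float(np.sum((o - p) ** 2))
    return max(0.0, 1.0 - sse / sst)


def _csd_to_autocov(csd: CrossSpectrum, n_lags: int, lag_step: float) -> np.ndarray:
    """Approximate lagged covariance functions by inverting the spectral
    density on its (Hermitian-extended) grid."""
    lags = np.arange(n_lags + 1) * lag_step
    f = csd.freqs
    phase = np.exp(2j * np.pi * lags[:, None] * f[None, :])
    # two-sided integral: S(-f) = S(f)^T for real processes
    acov = np.trapezoid(
        phase[:, :, None, None] * csd.values[None] +
        np.conj(phase)[:, :, None, None] * csd.values.transpose(0, 2, 1)[None],
        f, axis=1,
    )
    return acov.real


def explained_variance_time(
    observed: CrossSpectrum, predicted: CrossSpectrum, n_lags: int = 8,
    lag_step: float | None = None,
) -> float:
    """Companion time-domain explained variance: the spectra are
    inverse-transformed to lagged covariance sequences and compared with
    the same 1 - SSE/SST score."""
    if lag_step is None:
        lag_step = 0.5 / observed.freqs[-1]
    o = _csd_to_autocov(observed, n_lags, lag_step).ravel()
    p = _csd_to_autocov(predicted, n_lags, lag_step).ravel()
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        return 1.0 if np.allclose(o, p) else 0.0
    return max(0.0, 1.0 - float(np.sum((o - p) ** 2)) / sst)


@dataclass
class InclusionReport:
    """Model-fit screen: subjects with spectral explained variance below
    the threshold (exclusive) or failed convergence are flagged."""

    explained_variance: list
    converged: list
    included: list
    threshold: float
    n_included: int
    n_excluded: int


def screen_subjects(
    posteriors: list, threshold: float = EV_THRESHOLD
) -> InclusionReport:
    """Apply the explained-variance inclusion rule (>= threshold passes)."""
    evs = [float(p.explained_variance) for p in posteriors]
    conv = [bool(p.converged) for p in posteriors]
    included = [ev >= threshold and c for ev, c in zip(evs, conv)]
    return InclusionReport(
        explained_variance=evs,
        converged=conv,
        included=included,
        threshold=threshold,
        n_included=int(sum(included)),
        n_excluded=int(len(included) - sum(included)),
    )
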