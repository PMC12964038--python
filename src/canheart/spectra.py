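"""Cross-spectral density estimation for multivariate BOLD series.

The data feature fitted by the spectral DCM is the complex cross-spectral
density (CSD) of the region time series.  The parametric route fits a
multivariate autoregressive (MAR) model by least squares and converts it
to a CSD; an averaged-periodogram (Welch) estimator is provided as a
nonparametric cross-check.

Conventions: frequencies in Hz; spectra are two-sided densities, so for
white noise of variance sigma^2 sampled every ``delta`` seconds the
density is ``sigma^2 * delta`` and the integral of each diagonal over
(-Nyquist, Nyquist) recovers the process variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "MARModel",
    "CrossSpectrum",
    "default_freq_grid",
    "fit_mar",
    "mar_to_csd",
    "welch_csd",
]


def default_freq_grid(n_freq: int = 32, f_min: float = 1.0 / 128.0, f_max: float = 0.25):
    """Default analysis grid: 32 linear points in the resting-state band."""
    return np.linspace(f_min, f_max, n_freq)


@dataclass
class MARModel:
    """Least-squares multivariate autoregression x_t = sum_k A_k x_{t-k} + e_t."""

    order: int
    coeffs: np.ndarray          # (order, N, N), target-row/source-column
    innovation_cov: np.ndarray  # (N, N)
    sample_interval: float      # s
    stationary: bool = True

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[1]

    def companion_spectral_radius(self) -> float:
        p, n, _ = self.coeffs.shape
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class CrossSpectrum:
    """Complex cross-spectral density on a frequency grid.

    ``values[k]`` is the Hermitian N x N density matrix at ``freqs[k]``;
    diagonals are real and non-negative (up to numerical tolerance).
    """

    freqs: np.ndarray            # (n_freq,), Hz, strictly increasing
    values: np.ndarray           # (n_freq, N, N) complex
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.values.shape[0] != self.freqs.size or (
            self.values.shape[1] != self.values.shape[2]
        ):
            raise ValueError("values must be (n_freq, N, N)")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def is_hermitian(self, tol: float = 1e-8) -> bool:
        scale = max(1.0, float(np.max(np.abs(self.values))))
        herm = np.max(np.abs(self.values - self.values.conj().transpose(0, 2, 1)))
        diags = np.diagonal(self.values, axis1=1, axis2=2)
        return bool(herm <= tol * scale and np.min(diags.real) >= -tol * scale
                    and np.max(np.abs(diags.imag)) <= tol * scale)

    def save(self, path) -> None:
        np.savez(
            path,
            freqs=self.freqs,
            real=self.values.real,
            imag=self.values.imag,
            labels=np.asarray(self.labels if self.labels else [], dtype=object),
        )

    @classmethod
    def load(cls, path) -> "CrossSpectrum":
        with np.load(path, allow_pickle=True) as z:
            labels = tuple(z["labels"].tolist()) or None
            return cls(z["freqs"], z["real"] + 1j * z["imag"], labels)


def _preprocess(bold: np.ndarray) -> np.ndarray:
    """De-mean and linearly detrend each column (MAR assumes zero mean)."""
    return sps.detrend(np.asarray(bold, dtype=float), axis=0, type="linear")


def fit_mar(
    bold: np.ndarray,
    order: int = 8,
    sample_interval: float = 1.0,
    shrinkage: float = 0.03,
) -> MARModel:
    """Fit a MAR(p) model by (lightly regularized) least squares.

    ``bold`` is time x N; columns are de-meaned and detrended internally.
    ``shrinkage`` adds a ridge penalty of that fraction of the mean
    regressor power, which stabilizes the implied spectra at fMRI-length
    runs while leaving long-data estimates essentially untouched; 0 gives
    ordinary least squares.  Returns coefficient matrices (lag-major) and
    the innovation covariance from the dof-corrected residuals.  A
    non-stationary fit (companion spectral radius >= 1) sets
    ``stationary=False`` with a warning.
    """
    x = _preprocess(bold)
    t, n = x.shape
    if t <= order * n + n:
        raise ValueError(f"need more than order*N+N={order * n + n} samples, got {t}")
    # lagged design: [x_{t-1}, ..., x_{t-p}]
    z = np.concatenate([x[order - k - 1 : t - k - 1] for k in range(order)], axis=1)
    y = x[order:]
    gram = z.T @ z
    rank = np.linalg.matrix_rank(gram)
    if rank < z.shape[1]:
        bad = [i for i in range(z.shape[1]) if gram[i, i] <= 1e-12 * np.trace(gram) / z.shape[1]]
        raise ValueError(f"rank-deficient MAR regression (rank {rank} < {z.shape[1]}; "
                         f"degenerate lagged columns {bad})")
    ridge = shrinkage * np.trace(gram) / gram.shape[0]
    beta = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), z.T @ y)
    coeffs = np.stack([beta[k * n : (k + 1) * n].T for k in range(order)])
    resid = y - z @ beta
    dof = max(1, y.shape[0] - z.shape[1])
    cov = resid.T @ resid / dof
    cov = 0.5 * (cov + cov.T)
    model = MARModel(order, coeffs, cov, sample_interval)
    if model.companion_spectral_radius() >= 1.0:
        model.stationary = False
        warnings.warn("MAR fit is non-stationary (companion spectral radius >= 1)")
    return model


def mar_to_csd(mar: MARModel, freqs: np.ndarray) -> CrossSpectrum:
    """Parametric CSD of a MAR model: S(f) = delta * H(f) Sigma H(f)^H.

    ``H(f) = (I - sum_k A_k exp(-i 2 pi f k delta))^-1``; the ``delta``
    factor makes S a two-sided density in per-Hz units.
    """
    freqs = np.asarray(freqs, dtype=float)
    delta = mar.sample_interval
    nyq = 0.5 / delta
    if np.any(freqs >= nyq):
        raise ValueError(f"frequencies must lie below Nyquist = {nyq:.4g} Hz")
    n = mar.n_channels
    ks = np.arange(1, mar.order + 1)
    phase = np.exp(-2j * np.pi * freqs[:, None] * ks[None, :] * delta)  # (n_f, p)
    acc = np.tensordot(phase, mar.coeffs, axes=(1, 0))  # (n_f, N, N)
    mats = np.eye(n)[None] - acc
    try:
        h = np.linalg.inv(mats)
    except np.linalg.LinAlgError as err:
        dets = np.abs(np.linalg.det(mats))
        f_bad = freqs[int(np.argmin(dets))]
        raise np.linalg.LinAlgError(f"singular MAR transfer function at {f_bad:.4g} Hz") from err
    s = delta * np.einsum("fij,jk,flk->fil", h, mar.innovation_cov, h.conj())
    s = 0.5 * (s + s.conj().transpose(0, 2, 1))
    return CrossSpectrum(freqs, s)


def welch_csd(
    bold: np.ndarray,
    sample_interval: float,
    window_s: float = 256.0,
    overlap: float = 0.5,
) -> CrossSpectrum:
    """Averaged-periodogram cross-spectral estimate (nonparametric oracle).

    Returns two-sided densities on scipy's positive-frequency grid
    (one-sided output halved away from DC/Nyquist to match the two-sided
    convention used throughout).
    """
    x = _preprocess(bold)
    t, n = x.shape
    fs = 1.0 / sample_interval
    nperseg = int(round(window_s * fs))
    if nperseg > t:
        raise ValueError("window longer than the series")
    noverlap = int(round(overlap * nperseg))
    if (t - noverlap) // (nperseg - noverlap) < 2:
        raise ValueError("need at least 2 Welch windows; shorten the window")
    freqs = None
    values = None
    for i in range(n):
        for j in range(n):
            f, pij = sps.csd(
                x[:, i], x[:, j], fs=fs, nperseg=nperseg, noverlap=noverlap,
                scaling="density", return_onesided=True,
            )
            if values is None:
                freqs = f
                values = np.zeros((f.size, n, n), dtype=complex)
            # scipy conjugates the first argument; our convention is
            # S_ij(f) = F{E[x_i(t+tau) x_j(t)]}, the conjugate of that
            values[:, i, j] = np.conj(pij)
    # one-sided -> two-sided density (interior bins carry a factor 2)
    interior = slice(1, -1) if freqs[-1] == 0.5 * fs else slice(1, None)
    values[interior] *= 0.5
    keep = freqs > 0
    values = values[keep]
    freqs = freqs[keep]
    values = 0.5 * (values + values.conj().transpose(0, 2, 1))
    return CrossSpectrum(freqs, values)
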