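"""Balloon hemodynamic forward model.

Neural activity drives a vasodilatory signal which in turn drives blood
flow, venous volume and deoxyhemoglobin content; BOLD is a static
nonlinear readout of volume and deoxyhemoglobin.  Per region the states
are (s, f, v, q) with fixed point (0, 1, 1, 1) at zero input:

    ds/dt = x - kappa*s - gamma*(f - 1)
    df/dt = s
    dv/dt = (f - v**(1/alpha)) / tau
    dq/dt = (f*E(f)/E0 - v**(1/alpha) * q / v) / tau,   E(f) = 1-(1-E0)**(1/f)

    y = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

``kappa`` (signal decay, 1/s) and ``tau`` (transit time, s) carry free
per-region log-scalings; ``gamma``, ``alpha`` (Grubb exponent), ``E0``
(resting O2 extraction) and ``V0`` (resting venous volume fraction) are
fixed constants.  Observation coefficients use the classic values
k1 = 7*E0, k2 = 2, k3 = 2*E0 - 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HemodynamicParams", "hemodynamic_kernel", "simulate_bold_nonlinear"]


@dataclass
class HemodynamicParams:
    """Balloon-model constants plus per-region free log-scalings.

    ``theta_decay`` and ``theta_transit`` scale the baseline decay rate
    and transit time as ``kappa = kappa0*exp(theta_decay)`` and
    ``tau = tau0*exp(theta_transit)``; 0 means the baseline value.
    """

    n_regions: int = 6
    kappa0: float = 0.64  # 1/s, baseline signal decay
    tau0: float = 2.0     # s, baseline mean transit time
    gamma: float = 0.32   # 1/s, flow feedback rate
    alpha: float = 0.32   # Grubb vessel-stiffness exponent
    E0: float = 0.4       # resting oxygen extraction fraction
    V0: float = 0.04      # resting venous volume fraction
    theta_decay: np.ndarray = field(default=None)
    theta_transit: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.theta_decay is None:
            self.theta_decay = np.zeros(self.n_regions)
        if self.theta_transit is None:
            self.theta_transit = np.zeros(self.n_regions)
        self.theta_decay = np.atleast_1d(np.asarray(self.theta_decay, float))
        self.theta_transit = np.atleast_1d(np.asarray(self.theta_transit, float))
        if self.theta_decay.shape != (self.n_regions,) or self.theta_transit.shape != (
            self.n_regions,
        ):
            raise ValueError("log-scaling vectors must have length n_regions")

    @property
    def kappa(self) -> np.ndarray:
        return self.kappa0 * np.exp(self.theta_decay)

    @property
    def tau(self) -> np.ndarray:
        return self.tau0 * np.exp(self.theta_transit)

    @property
    def k_coeffs(self) -> tuple[float, float, float]:
        return 7.0 * self.E0, 2.0, 2.0 * self.E0 - 0.2


def _linearized_system(hemo: HemodynamicParams, region: int):
    """Jacobian, input and output vectors of the Balloon model at rest."""
    kappa = hemo.kappa[region]
    tau = hemo.tau[region]
    gamma, alpha, e0, v0 = hemo.gamma, hemo.alpha, hemo.E0, hemo.V0
    k1, k2, k3 = hemo.k_coeffs
    # d(f*E(f)/E0)/df at f=1
    dqin_df = (e0 + (1.0 - e0) * np.log(1.0 - e0)) / e0
    jac = np.array(
        [
            [-kappa, -gamma, 0.0, 0.0],
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0 / tau, -1.0 / (alpha * tau), 0.0],
            [0.0, dqin_df / tau, -(1.0 / alpha - 1.0) / tau, -1.0 / tau],
        ]
    )
    b = np.array([1.0, 0.0, 0.0, 0.0])
    c = np.array([0.0, 0.0, v0 * (k2 - k3), -v0 * (k1 + k2)])
    if not np.all(np.isfinite(jac)):
        raise ValueError("non-finite hemodynamic Jacobian")
    return jac, b, c


def hemodynamic_kernel(hemo: HemodynamicParams, freqs: np.ndarray) -> np.ndarray:
    """First-order neural->BOLD transfer function per region.

    Returns a complex array of shape (n_freq, n_regions):
    ``K_r(f) = c (i*2*pi*f*I - J_r)^-1 b`` from Jacobian linearization of
    the hemodynamic states around their resting fixed point.  The kernel
    is low-pass: BOLD attenuates fast neural fluctuations.
    """
    freqs = np.asarray(freqs, dtype=float)
    out = np.empty((freqs.size, hemo.n_regions), dtype=complex)
    eye = np.eye(4)
    for r in range(hemo.n_regions):
        jac, b, c = _linearized_system(hemo, r)
        # batched solve over frequencies
        mats = 1j * 2.0 * np.pi * freqs[:, None, None] * eye - jac
        sol = np.linalg.solve(mats, np.broadcast_to(b, (freqs.size, 4))[..., None])
        out[:, r] = sol[:, :, 0] @ c
    return out


def _balloon_core(latent, dt, kappa, tau, gamma, alpha, e0, v0, k1, k2, k3):
    n_t, n = latent.shape
    s = np.zeros(n)
    f = np.ones(n)
    v = np.ones(n)
    q = np.ones(n)
    y = np.empty((n_t, n))
    inv_alpha = 1.0 / alpha
    for t in range(n_t):
        for r in range(n):
            y[t, r] = v0 * (
                k1 * (1.0 - q[r]) + k2 * (1.0 - q[r] / v[r]) + k3 * (1.0 - v[r])
            )
            fv = v[r] ** inv_alpha  # outflow
            ef = 1.0 - (1.0 - e0) ** (1.0 / f[r])
            ds = latent[t, r] - kappa[r] * s[r] - gamma * (f[r] - 1.0)
            df = s[r]
            dv = (f[r] - fv) / tau[r]
            dq = (f[r] * ef / e0 - fv * q[r] / v[r]) / tau[r]
            s[r] = s[r] + dt * ds
            f[r] = f[r] + dt * df
            v[r] = v[r] + dt * dv
            q[r] = q[r] + dt * dq
            if v[r] <= 0.0 or f[r] <= 0.0 or q[r] <= 0.0:
                return y, t
    return y, -1


try:  # JIT the integration loop when numba is present
    from numba import njit

    _balloon_core = njit(cache=False)(_balloon_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    pass


def simulate_bold_nonlinear(
    latent: np.ndarray, dt: float, hemo: HemodynamicParams
) -> np.ndarray:
    """Integrate the nonlinear Balloon equations driven by neural activity.

    ``latent`` is a time x N matrix sampled at ``dt`` seconds; the output
    is the BOLD signal on the same grid (baseline 0).  Raises if the
    hemodynamic states leave their physical domain (volume <= 0).
    """
    latent = np.ascontiguousarray(latent, dtype=float)
    n_t, n = latent.shape
    if n != hemo.n_regions:
        raise ValueError("latent column count must equal n_regions")
    k1, k2, k3 = hemo.k_coeffs
    y, bad = _balloon_core(
        latent, dt, hemo.kappa, hemo.tau, hemo.gamma, hemo.alpha, hemo.E0,
        hemo.V0, k1, k2, k3,
    )
    if bad >= 0:
        raise RuntimeError(
            f"non-physical hemodynamic state at step {bad} "
            "(input too large for the integration step)"
        )
    return y
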