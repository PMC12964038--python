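"""Effective-connectivity containers and the self-connection convention.

The coupling matrix ``A`` (units: Hz) follows the target-row / source-column
convention: entry ``A[i, j]`` is the influence of region ``j`` on region
``i``.  Off-diagonal entries are free parameters; diagonal entries are
re-parameterised as ``A[i, i] = -0.5 * exp(theta_self[i])`` so that
self-connections are inhibitory by construction — ``theta_self`` is a
unitless log-scaling, with 0 mapping to the default -0.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrueConnectivity",
    "effective_matrix",
    "self_connection",
    "is_stable",
    "make_connectivity",
    "DEFAULT_LABELS",
]

#: The six left-lateralised central-autonomic-network nodes.
DEFAULT_LABELS = ("vmPFC", "ACC", "INS", "AMY", "HYPO", "BS")

#: Baseline self-inhibition rate in Hz (the value at theta_self = 0).
SELF_BASE_HZ = 0.5


def self_connection(theta_self: np.ndarray) -> np.ndarray:
    """Map unitless log-scalings to diagonal (self) coupling values in Hz."""
    return -SELF_BASE_HZ * np.exp(np.asarray(theta_self, dtype=float))


def effective_matrix(theta_offdiag: np.ndarray, theta_self: np.ndarray) -> np.ndarray:
    """Assemble the effective coupling matrix A (Hz) from its parameters."""
    theta_offdiag = np.asarray(theta_offdiag, dtype=float)
    n = theta_offdiag.shape[0]
    if theta_offdiag.shape != (n, n):
        raise ValueError("theta_offdiag must be square")
    a = theta_offdiag.copy()
    np.fill_diagonal(a, self_connection(theta_self))
    return a


def is_stable(a: np.ndarray, margin: float = 0.0) -> bool:
    """True when every eigenvalue of ``a`` has real part < -margin."""
    return bool(np.max(np.linalg.eigvals(a).real) < -margin)


@dataclass
class TrueConnectivity:
    """Ground-truth coupling parameters for a synthetic network.

    Attributes
    ----------
    theta_offdiag
        N x N matrix of between-region couplings in Hz; the diagonal is
        ignored (self-coupling lives in ``theta_self``).
    theta_self
        Length-N vector of unitless self-inhibition log-scalings.
    labels
        Region names, one per node.
    """

    theta_offdiag: np.ndarray
    theta_self: np.ndarray
    labels: tuple[str, ...] = field(default=DEFAULT_LABELS)

    def __post_init__(self) -> None:
        self.theta_offdiag = np.asarray(self.theta_offdiag, dtype=float)
        self.theta_self = np.asarray(self.theta_self, dtype=float)
        n = self.n_regions
        if self.theta_offdiag.shape != (n, n):
            raise ValueError("theta_offdiag must be square N x N")
        if self.theta_self.shape != (n,):
            raise ValueError("theta_self length must match theta_offdiag")
        if len(self.labels) != n:
            self.labels = tuple(f"R{i}" for i in range(n))

    @property
    def n_regions(self) -> int:
        return self.theta_offdiag.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Effective matrix A with the inhibitory diagonal filled in."""
        return effective_matrix(self.theta_offdiag, self.theta_self)

    def is_stable(self, margin: float = 0.0) -> bool:
        return is_stable(self.matrix, margin=margin)


def make_connectivity(
    n_regions: int,
    coupling_sd: float,
    seed: int | None = None,
    labels: tuple[str, ...] | None = None,
    max_resamples: int = 100,
) -> TrueConnectivity:
    """Draw a random, fully connected, stable coupling matrix.

    Off-diagonal couplings are i.i.d. N(0, coupling_sd^2) in Hz;
    ``theta_self`` is zero (diagonal -0.5 Hz).  Draws are rejected and
    resampled until the effective matrix is stable; failure after
    ``max_resamples`` attempts signals that ``coupling_sd`` is too large
    for a stable fully connected system of this size.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if coupling_sd < 0:
        raise ValueError("coupling_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = DEFAULT_LABELS if n_regions == len(DEFAULT_LABELS) else tuple(
            f"R{i}" for i in range(n_regions)
        )
    theta_self = np.zeros(n_regions)
    for _ in range(max_resamples):
        offdiag = rng.normal(0.0, coupling_sd, size=(n_regions, n_regions))
        np.fill_diagonal(offdiag, 0.0)
        conn = TrueConnectivity(offdiag, theta_self, labels)
        if conn.is_stable():
            return conn
    raise RuntimeError(
        f"no stable coupling matrix in {max_resamples} draws "
        f"(coupling_sd={coupling_sd} too large for n={n_regions})"
    )
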