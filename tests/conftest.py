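import os

# single-threaded BLAS before numpy loads: bitwise-reproducible linear
# algebra, which the end-to-end determinism contract relies on
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from canheart.connectivity import TrueConnectivity
from canheart.hemodynamics import HemodynamicParams
from canheart.inversion import InversionOptions, default_priors, invert
from canheart.spectra import default_freq_grid, fit_mar, mar_to_csd
from canheart.synthetic import band_power, powerlaw_noise, simulate_bold, simulate_neural

TR = 0.961
DT = TR / 10.0


def make_pattern(n: int, seed: int, strength: float = 0.3) -> TrueConnectivity:
    """Random stable +-strength coupling pattern (the recovery test bed)."""
    rng = np.random.default_rng(seed)
    mask = ~np.eye(n, dtype=bool)
    while True:
        off = rng.choice([-strength, strength], size=(n, n)) * mask
        conn = TrueConnectivity(off, np.zeros(n), tuple(f"R{i}" for i in range(n)))
        if conn.is_stable():
            return conn


def synth_bold(
    conn: TrueConnectivity,
    seed: int,
    n_volumes: int = 750,
    n_dummy: int = 4,
    snr: float | None = 1.0,
    fluct_sd: float = 0.05,
) -> np.ndarray:
    """One subject's BOLD through the nonlinear hemodynamics, with pink
    observation noise at the stated in-band SNR (None = noiseless)."""
    rng = np.random.default_rng(seed)
    n = conn.n_regions
    latent = simulate_neural(
        conn, n_volumes * TR, dt=DT, fluct_sd=fluct_sd, seed=int(rng.integers(2**31))
    )
    clean = simulate_bold(latent, DT, TR, HemodynamicParams(n_regions=n))
    sig = clean[n_dummy:]
    if snr is None:
        return sig
    unit = np.column_stack(
        [powerlaw_noise(sig.shape[0], TR, 1.0, 1.0, rng) for _ in range(n)]
    )
    scale = np.sqrt(
        band_power(sig, TR, (0.01, 0.1)) / (snr * band_power(unit, TR, (0.01, 0.1)))
    )
    return sig + scale * unit


def invert_bold(bold: np.ndarray, max_iter: int = 64):
    csd = mar_to_csd(fit_mar(bold, 8, TR), default_freq_grid())
    return invert(csd, default_priors(bold.shape[1]), InversionOptions(max_iter=max_iter))


@pytest.fixture(scope="session")
def recovered_subject():
    """A single 3-node subject inverted end to end (shared across tests)."""
    conn = make_pattern(3, seed=100)
    bold = synth_bold(conn, seed=0)
    post = invert_bold(bold)
    return conn, bold, post
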