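"""Validation experiments: the package's own evidence that each stage
does what it claims, on synthetic data with known truth.

Every routine here builds its inputs through the public API, runs the
method under test, and measures the outcome; nothing is looked up.
These back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import TrueConnectivity, make_connectivity
from .hemodynamics import HemodynamicParams
from .inversion import InversionOptions, default_priors, generative_csd, invert
from .peb import build_design, peb_fit
from .qc import heart_rate_from_ppg
from .spectra import default_freq_grid, fit_mar, mar_to_csd, welch_csd
from .synthetic import (
    CohortSpec,
    band_power,
    powerlaw_noise,
    simulate_bold,
    simulate_cohort,
    simulate_neural,
    simulate_ppg,
    write_cohort,
)

TR = 0.961
DT = TR / 10.0


# ---------------------------------------------------------------------------
# spectral oracles


def ou_oracle_error(seeds=(1, 2, 3), sizes=(2, 3, 4), coupling_sd=0.2) -> float:
    """Max |generative CSD - closed-form OU cross-spectrum| with identity
    hemodynamics, over random stable systems."""
    freqs = default_freq_grid()
    worst = 0.0
    for n, seed in zip(sizes, seeds):
        conn = make_connectivity(n, coupling_sd, seed=seed)
        cs = generative_csd(conn.theta_offdiag, conn.theta_self, freqs)
        a = conn.matrix
        for k, f in enumerate(freqs):
            t = np.linalg.inv(2j * np.pi * f * np.eye(n) - a)
            worst = max(worst, float(np.max(np.abs(cs.values[k] - t @ t.conj().T))))
    return worst


def mar_welch_agreement(seed=7, n_samples=8192, n_regions=2) -> float:
    """Relative Frobenius discrepancy between the MAR-derived and Welch
    CSDs of one long simulated series, inside 0.01-0.25 Hz."""
    conn = make_connectivity(n_regions, 0.25, seed=5)
    x = simulate_neural(conn, n_samples * TR, dt=DT, fluct_sd=1.0, seed=seed)
    bold = x[::10]
    grid = default_freq_grid()
    c_mar = mar_to_csd(fit_mar(bold, 8, TR), grid)
    c_wel = welch_csd(bold, TR, window_s=128.0)
    w = np.stack(
        [
            np.interp(grid, c_wel.freqs, c_wel.values[:, i, j].real)
            + 1j * np.interp(grid, c_wel.freqs, c_wel.values[:, i, j].imag)
            for i in range(n_regions)
            for j in range(n_regions)
        ],
        axis=1,
    ).reshape(grid.size, n_regions, n_regions)
    return float(np.linalg.norm(w - c_mar.values) / np.linalg.norm(c_mar.values))


# ---------------------------------------------------------------------------
# subject-level recovery


def random_sign_pattern(n: int, seed: int, strength: float = 0.3) -> TrueConnectivity:
    rng = np.random.default_rng(seed)
    mask = ~np.eye(n, dtype=bool)
    while True:
        off = rng.choice([-strength, strength], size=(n, n)) * mask
        conn = TrueConnectivity(off, np.zeros(n), tuple(f"R{i}" for i in range(n)))
        if conn.is_stable():
            return conn


def synth_subject_bold(
    conn: TrueConnectivity,
    seed: int,
    n_volumes: int = 750,
    n_dummy: int = 4,
    snr: float = 1.0,
    fluct_sd: float = 0.05,
) -> np.ndarray:
    """One subject's BOLD: nonlinear hemodynamics plus pink observation
    noise at the stated in-band SNR."""
    rng = np.random.default_rng(seed)
    n = conn.n_regions
    latent = simulate_neural(
        conn, n_volumes * TR, dt=DT, fluct_sd=fluct_sd, seed=int(rng.integers(2**31))
    )
    clean = simulate_bold(latent, DT, TR, HemodynamicParams(n_regions=n))
    sig = clean[n_dummy:]
    unit = np.column_stack(
        [powerlaw_noise(sig.shape[0], TR, 1.0, 1.0, rng) for _ in range(n)]
    )
    scale = np.sqrt(
        band_power(sig, TR, (0.01, 0.1)) / (snr * band_power(unit, TR, (0.01, 0.1)))
    )
    return sig + scale * unit


def recovery_experiment(
    n_seeds: int = 10, n_regions: int = 3, base_seed: int = 0, max_iter: int = 64
) -> dict:
    """Invert synthetic subjects with known +-0.3 Hz couplings (746
    retained volumes at TR 0.961 s) and score the posterior couplings."""
    corrs, biases, monotone = [], [], []
    freqs = default_freq_grid()
    mask = ~np.eye(n_regions, dtype=bool)
    for s in range(n_seeds):
        conn = random_sign_pattern(n_regions, seed=100 + base_seed + s)
        bold = synth_subject_bold(conn, seed=base_seed + s)
        csd = mar_to_csd(fit_mar(bold, 8, TR), freqs)
        post = invert(csd, default_priors(n_regions), InversionOptions(max_iter=max_iter))
        tv = conn.matrix[mask]
        ev = post.connectivity_matrix[mask]
        corrs.append(float(np.corrcoef(tv, ev)[0, 1]))
        biases.append(float(np.mean(ev - tv)))
        monotone.append(bool(np.all(np.diff(post.f_trace) >= 0)))
    return {
        "corr_mean": float(np.mean(corrs)),
        "corr_per_seed": corrs,
        "bias_mean": float(np.mean(biases)),
        "free_energy_monotone_all": all(monotone),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# group-level power and specificity


def _invert_cohort(spec: CohortSpec, max_iter: int = 32):
    subjects, truth = simulate_cohort(spec)
    freqs = default_freq_grid()
    opts = InversionOptions(max_iter=max_iter)
    priors = default_priors(spec.n_regions)
    posts = [
        invert(mar_to_csd(fit_mar(s.bold, 8, TR), freqs), priors, opts)
        for s in subjects
    ]
    cov = pd.DataFrame(
        {
            "subject": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "hr_bpm": [s.hr_bpm for s in subjects],
        }
    )
    return posts, cov


def peb_group_effect_experiment(
    n_seeds: int = 10,
    effect_hz: float = 0.2,
    n_regions: int = 3,
    base_seed: int = 0,
    max_iter: int = 32,
) -> dict:
    """Planted 0.2 Hz group effects on 3 connections in 26+40 cohorts:
    fraction of planted connections reaching PP > 0.99, per seed."""
    planted = ((0, 1, effect_hz), (1, 2, effect_hz), (2, 0, effect_hz))
    detected = []
    for s in range(n_seeds):
        spec = CohortSpec(
            n_regions=n_regions, n_per_group=(26, 40), seed=1000 + base_seed + s,
            effect_map_group=planted,
        )
        posts, cov = _invert_cohort(spec, max_iter=max_iter)
        res = peb_fit(posts, build_design(cov, ("group",), "AN"))
        pp = res.PP[res.regressor_names.index("group")]
        layout = posts[0].layout
        idx = [layout.offdiag_idx.index((t, s_)) for t, s_, _ in planted]
        detected.append([bool(pp[k] > 0.99) for k in idx])
    det = np.asarray(detected)
    return {
        "detection_rate": float(det.mean()),
        "seeds_all_detected": int(np.sum(det.all(axis=1))),
        "n_seeds": n_seeds,
    }


def peb_null_experiment(
    n_seeds: int = 10, n_regions: int = 3, base_seed: int = 0, max_iter: int = 32
) -> dict:
    """Null cohorts (no group effects): per-connection rate of spurious
    PP > 0.99 group differences."""
    hits, total = 0, 0
    for s in range(n_seeds):
        spec = CohortSpec(
            n_regions=n_regions, n_per_group=(26, 40), seed=5000 + base_seed + s
        )
        posts, cov = _invert_cohort(spec, max_iter=max_iter)
        res = peb_fit(posts, build_design(cov, ("group",), "AN"))
        pp = res.PP[res.regressor_names.index("group")]
        m = n_regions * (n_regions - 1)
        hits += int(np.sum(pp[:m] > 0.99))
        total += m
    return {"false_positive_rate": hits / total, "n_tests": total, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# physiology and determinism


def hr_recovery_experiment(
    rates=(50.0, 65.06, 75.0, 95.0), seed: int = 123
) -> dict:
    """Synthetic 10-minute 500 Hz PPG at each rate through the full HR
    pipeline; absolute recovery errors in bpm."""
    out = {}
    for hr in rates:
        ppg = simulate_ppg(hr, fs=500.0, duration=600.0, seed=seed)
        res = heart_rate_from_ppg(ppg[:, 1], 500.0)
        out[hr] = {"estimate": float(res.mean_hr), "abs_error": abs(res.mean_hr - hr)}
    return out


def _tree_hash(path: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(path.rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes().replace(str(path).encode(), b"@OUT@"))
    return h.hexdigest()


def determinism_experiment(workdir, seed: int = 21, max_iter: int = 24) -> dict:
    """Full pipeline twice on the same small cohort with one seed: the
    output trees (posteriors, matrices, report) must hash identically."""
    from .pipeline import RunConfig, run_all
    from .synthetic import simulate_motion

    workdir = Path(workdir)
    spec = CohortSpec(
        n_regions=3, n_per_group=(6, 6), seed=seed, with_motion=True,
        effect_map_group=((0, 1, 0.25),),
    )
    subjects, truth = simulate_cohort(spec)
    write_cohort(subjects, truth, workdir / "cohort")
    hashes = []
    for tag in ("first", "second"):
        out = workdir / f"out_{tag}"
        cfg = RunConfig(
            data_dir=str(workdir / "cohort"), out_dir=str(out),
            max_iter=max_iter, log_level="WARNING", seed=seed,
        )
        run_all(cfg)
        hashes.append(_tree_hash(out))
    return {"identical": hashes[0] == hashes[1], "hash": hashes[0][:16]}
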