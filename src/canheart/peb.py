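"""Hierarchical (parametric-empirical-Bayes) group analysis.

Subject-level posteriors (Ep_i, Cp_i) over the connectivity parameters
are treated as data for a second-level general linear model

    theta_i = (x_i kron I) beta + eps_i,     eps_i ~ N(0, Sigma_between),

where x_i is the subject's row of the design matrix and Sigma_between is
a single isotropic random-effects component whose log-precision gamma is
estimated by maximizing the (exact, Gaussian) second-level model
evidence.  Subjects contribute with precision (Cp_i + Sigma_between)^-1,
so uncertain first-level estimates move the group posterior less.

Per-effect posterior probabilities come from Bayesian model reduction:
the free-energy difference between the full model and a reduced model in
which that effect's prior is collapsed to a point mass at zero, mapped
through PP = 1/(1 + exp(-dF)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .inversion import SubjectPosterior, default_priors

__all__ = [
    "DesignMatrix",
    "PEBResult",
    "build_design",
    "peb_fit",
    "bmr_log_evidence_change",
    "posterior_probability_matrix",
    "threshold_matrix",
    "run_analysis_suite",
]

PP_CUTOFF = 0.99


@dataclass
class DesignMatrix:
    """Subjects x regressors matrix: constant first column, every later
    column mean-centered; raw (uncentered) codings kept in metadata."""

    X: np.ndarray
    names: list[str]
    subjects: list[str]
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the constant 1")
        if self.X.shape[1] > 1:
            col_means = self.X[:, 1:].mean(axis=0)
            if np.max(np.abs(col_means)) > 1e-10:
                raise ValueError("regressors after the constant must be mean-centered")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


def build_design(
    covariates: pd.DataFrame,
    regressors: tuple[str, ...] = ("group",),
    patient_label: str | None = None,
) -> DesignMatrix:
    """Build the second-level design from a covariate table.

    ``covariates`` needs columns ``subject`` and, as requested, ``group``
    (two labels; patients coded +1, controls -1) and/or ``hr_bpm``.
    Regressor names: ``"group"``, ``"hr"``, ``"group_x_hr"``.  The group
    and HR columns are mean-centered; the interaction is the elementwise
    product of the two centered columns, itself re-centered.  Subjects
    with missing requested covariates raise an error naming them.
    """
    cov = covariates.reset_index(drop=True)
    subjects = [str(s) for s in cov["subject"]]
    cols = [np.ones(len(cov))]
    names = ["mean"]
    raw: dict = {}

    needed = set()
    for r in regressors:
        if r == "group":
            needed.add("group")
        elif r == "hr":
            needed.add("hr_bpm")
        elif r == "group_x_hr":
            needed.update(("group", "hr_bpm"))
        else:
            raise ValueError(f"unknown regressor '{r}'")
    for c in needed:
        missing = cov.loc[cov[c].isna(), "subject"].tolist() if c in cov else subjects
        if missing:
            raise ValueError(f"missing covariate '{c}' for subjects: {missing}")

    centered: dict[str, np.ndarray] = {}
    if "group" in needed:
        labels = sorted(cov["group"].unique())
        if len(labels) != 2:
            raise ValueError(f"need exactly two group labels, got {labels}")
        if patient_label is None:
            patient_label = labels[0]
        code = np.where(cov["group"] == patient_label, 1.0, -1.0)
        raw["group_coding"] = {patient_label: 1, [l for l in labels if l != patient_label][0]: -1}
        raw["group_raw"] = code.copy()
        centered["group"] = code - code.mean()
    if "hr_bpm" in needed:
        hr = cov["hr_bpm"].to_numpy(dtype=float)
        raw["hr_raw"] = hr.copy()
        centered["hr"] = hr - hr.mean()

    for r in regressors:
        if r == "group_x_hr":
            inter = centered["group"] * centered["hr"]
            cols.append(inter - inter.mean())
        else:
            cols.append(centered[r])
        names.append(r)
    return DesignMatrix(np.column_stack(cols), names, subjects, raw)


@dataclass
class PEBResult:
    """Group-level posterior over the second-level GLM parameters."""

    Ep: np.ndarray            # (n_regressors, n_params)
    Sd: np.ndarray            # posterior standard deviations, same shape
    Cp: np.ndarray            # full (n_regressors*n_params)^2 covariance
    PP: np.ndarray            # per-effect posterior probabilities
    free_energy: float
    gamma: float              # log-precision of the random-effects component
    regressor_names: list[str]
    param_names: list[str]
    n_regions: int
    prior_variance: np.ndarray  # second-level prior variance per beta


def _collate(posteriors: list[SubjectPosterior]):
    layout = posteriors[0].layout
    sl = layout.sl_conn
    eps = np.stack([p.Ep[sl] for p in posteriors])
    cps = np.stack([p.Cp[sl, sl] for p in posteriors])
    return layout, eps, cps


def peb_fit(
    posteriors: list[SubjectPosterior],
    design: DesignMatrix,
    prior_variance: np.ndarray | None = None,
    gamma_bounds: tuple[float, float] = (-6.0, 10.0),
) -> PEBResult:
    """Empirical-Bayes fit of the second-level GLM over connectivity.

    The between-subject covariance is ``exp(-gamma) * Q`` with
    ``Q = diag(prior_variance) / 16`` (the conventional expectation that
    random effects are an order of magnitude tighter than the first-level
    priors); ``gamma`` carries a N(0, 1/16) prior and is optimized on the
    exact marginal evidence.  Second-level priors on beta are zero-mean
    with the first-level prior variance of the matching parameter.
    """
    if len(posteriors) == 0:
        raise ValueError("no posteriors supplied")
    layout, eps, cps = _collate(posteriors)
    n_sub, n_p = eps.shape
    if design.X.shape[0] != n_sub:
        raise ValueError("design rows must align with posteriors")
    x = design.X
    n_r = x.shape[1]
    if prior_variance is None:
        prior_variance = default_priors(layout.n).variance[layout.sl_conn]
    q = np.asarray(prior_variance, float) / 16.0

    beta_prior_var = np.tile(prior_variance, n_r)
    prior_prec_beta = np.diag(1.0 / beta_prior_var)

    def moments(gamma: float):
        sigma_b = np.exp(-gamma) * q
        h = np.zeros((n_r * n_p, n_r * n_p))
        rhs = np.zeros(n_r * n_p)
        quad = 0.0
        logdet_s = 0.0
        for i in range(n_sub):
            s_i = cps[i] + np.diag(sigma_b)
            sign, ld = np.linalg.slogdet(s_i)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    "singular second-level covariance; first-level posteriors may "
                    "be degenerate (conditioning of Cp required)"
                )
            logdet_s += ld
            pi_i = np.linalg.inv(s_i)
            h += np.kron(np.outer(x[i], x[i]), pi_i)
            rhs += np.kron(x[i], pi_i @ eps[i])
            quad += float(eps[i] @ pi_i @ eps[i])
        p_beta = h + prior_prec_beta
        m_beta = np.linalg.solve(p_beta, rhs)
        return p_beta, m_beta, rhs, quad, logdet_s

    def neg_evidence(gamma: float) -> float:
        p_beta, m_beta, rhs, quad, logdet_s = moments(gamma)
        sign, ld_p = np.linalg.slogdet(p_beta)
        f = (
            -0.5 * logdet_s
            - 0.5 * np.sum(np.log(beta_prior_var))
            - 0.5 * ld_p
            - 0.5 * (quad - rhs @ m_beta)
            - 8.0 * gamma**2  # N(0, 1/16) prior on gamma
        )
        return -f

    res = minimize_scalar(neg_evidence, bounds=gamma_bounds, method="bounded",
                          options={"xatol": 1e-3})
    gamma = float(res.x)
    p_beta, m_beta, rhs, quad, logdet_s = moments(gamma)
    cp_beta = np.linalg.inv(p_beta)
    cp_beta = 0.5 * (cp_beta + cp_beta.T)

    pp = _bmr_pp(p_beta, m_beta, 1.0 / beta_prior_var).reshape(n_r, n_p)
    labels = posteriors[0].labels or tuple(f"R{i}" for i in range(layout.n))
    return PEBResult(
        Ep=m_beta.reshape(n_r, n_p),
        Sd=np.sqrt(np.clip(np.diag(cp_beta), 0, None)).reshape(n_r, n_p),
        Cp=cp_beta,
        PP=pp,
        free_energy=float(-res.fun),
        gamma=gamma,
        regressor_names=list(design.names),
        param_names=layout.conn_names(list(labels)),
        n_regions=layout.n,
        prior_variance=np.asarray(prior_variance, float),
    )


def bmr_log_evidence_change(
    post_prec: np.ndarray,
    post_mean: np.ndarray,
    prior_prec_diag: np.ndarray,
    reduced_prec_diag: np.ndarray,
) -> float:
    """Log-evidence change F_reduced - F_full by Gaussian model reduction.

    Valid for linear-Gaussian models with zero prior means: the data
    Hessian ``post_prec - diag(prior_prec)`` and information vector are
    invariant to the prior, so the evidence under any reduced diagonal
    prior follows analytically.
    """
    h = post_prec - np.diag(prior_prec_diag)
    rhs = post_prec @ post_mean
    p_r = h + np.diag(reduced_prec_diag)
    sign_r, ld_r = np.linalg.slogdet(p_r)
    sign_f, ld_f = np.linalg.slogdet(post_prec)
    if sign_r <= 0 or sign_f <= 0:
        raise np.linalg.LinAlgError("non-PSD precision in model reduction")
    m_r = np.linalg.solve(p_r, rhs)
    return float(
        0.5 * (np.sum(np.log(reduced_prec_diag)) - np.sum(np.log(prior_prec_diag)))
        - 0.5 * (ld_r - ld_f)
        + 0.5 * (m_r @ p_r @ m_r - post_mean @ post_prec @ post_mean)
    )


def _bmr_pp(p_beta: np.ndarray, m_beta: np.ndarray, prior_prec_diag: np.ndarray,
            collapse_prec: float = 1e8) -> np.ndarray:
    """PP that each effect is nonzero: collapse one prior at a time."""
    n = m_beta.size
    pp = np.empty(n)
    for k in range(n):
        reduced = prior_prec_diag.copy()
        reduced[k] = collapse_prec
        df_red = bmr_log_evidence_change(p_beta, m_beta, prior_prec_diag, reduced)
        # F_full - F_reduced
        pp[k] = 1.0 / (1.0 + np.exp(np.clip(df_red, -700, 700)))
    return pp


def posterior_probability_matrix(result: PEBResult, regressor: str) -> np.ndarray:
    """PP of each connectivity parameter for one regressor, as an N x N
    matrix (row = target, column = source; diagonal = self-connections)."""
    r = result.regressor_names.index(regressor)
    return _row_to_matrix(result.PP[r], result.n_regions)


def _row_to_matrix(row: np.ndarray, n: int) -> np.ndarray:
    m = np.empty((n, n))
    k = 0
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = row[k]
                k += 1
    for i in range(n):
        m[i, i] = row[k]
        k += 1
    return m


def threshold_matrix(
    result: PEBResult, regressor: str, cutoff: float = PP_CUTOFF
) -> dict:
    """Displayable N x N matrices with sub-threshold entries blanked (NaN).

    Survivors (PP > cutoff, strict) carry the posterior expectation and
    standard deviation; the diagonal is on the unitless self-connection
    log-scale, flagged in the output schema.
    """
    r = result.regressor_names.index(regressor)
    n = result.n_regions
    ep = _row_to_matrix(result.Ep[r], n)
    sd = _row_to_matrix(result.Sd[r], n)
    pp = _row_to_matrix(result.PP[r], n)
    mask = pp > cutoff
    return {
        "regressor": regressor,
        "cutoff": cutoff,
        "Ep": np.where(mask, ep, np.nan),
        "Sd": np.where(mask, sd, np.nan),
        "PP": pp,
        "diagonal_scale": "self-connection log-scaling (unitless)",
    }


def run_analysis_suite(
    posteriors: list[SubjectPosterior],
    covariates: pd.DataFrame,
    patient_label: str | None = None,
    cutoff: float = PP_CUTOFF,
    hr_centering: str = "within",
) -> dict:
    """The four-group-level analyses over one cohort's posteriors.

    1. per-group mean connectivity (commonalities);
    2. pooled group-difference analysis (+1 patients / -1 controls);
    3. per-group heart-rate association (HR centered within group by
       default, ``hr_centering="grand"`` centers across the pooled sample);
    4. pooled group + HR + group-x-HR interaction analysis.
    Returns the fitted PEBResult plus thresholded display matrices per
    analysis.
    """
    cov = covariates.reset_index(drop=True)
    if len(cov) != len(posteriors):
        raise ValueError("covariate rows must align with posteriors")
    labels = sorted(cov["group"].unique())
    if patient_label is None:
        patient_label = labels[0]
    out: dict = {}

    # (1) commonalities per group
    for lab in labels:
        idx = cov.index[cov["group"] == lab].tolist()
        sub = [posteriors[i] for i in idx]
        design = DesignMatrix(
            np.ones((len(sub), 1)), ["mean"], [str(cov.loc[i, "subject"]) for i in idx]
        )
        res = peb_fit(sub, design)
        out[f"commonalities_{lab}"] = {
            "result": res,
            "matrices": {"mean": threshold_matrix(res, "mean", cutoff)},
        }

    # (2) group difference
    design = build_design(cov, ("group",), patient_label)
    res = peb_fit(posteriors, design)
    out["group_difference"] = {
        "result": res,
        "matrices": {n: threshold_matrix(res, n, cutoff) for n in ("mean", "group")},
    }

    # (3) HR association per group.  Note: because the constant column is
    # free, the HR slope in a per-group GLM is invariant to whether HR is
    # centered on the group mean or the grand mean (the offset folds into
    # the constant), so only the within-group-centered design is built.
    for lab in labels:
        idx = cov.index[cov["group"] == lab].tolist()
        sub = [posteriors[i] for i in idx]
        cov_g = cov.loc[idx].copy()
        design_g = build_design(cov_g, ("hr",))
        res_g = peb_fit(sub, design_g)
        out[f"hr_{lab}"] = {
            "result": res_g,
            "matrices": {"hr": threshold_matrix(res_g, "hr", cutoff)},
        }

    # (4) interaction
    design4 = build_design(cov, ("group", "hr", "group_x_hr"), patient_label)
    res4 = peb_fit(posteriors, design4)
    out["interaction"] = {
        "result": res4,
        "matrices": {
            n: threshold_matrix(res4, n, cutoff)
            for n in ("mean", "group", "hr", "group_x_hr")
        },
    }
    return out
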