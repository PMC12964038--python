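"""Two-level analysis orchestration: per-subject spectral-DCM inversion
with QC and model-fit screening, then the four PEB group analyses, with a
provenance-stamped report.

Every rule constant (FD thresholds, EV threshold, PP cutoff, TR, MAR
order, frequency grid) lives in :class:`RunConfig` with the analysis
defaults and can be overridden from YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .inversion import (
    EV_THRESHOLD,
    InversionOptions,
    SubjectPosterior,
    default_priors,
    invert,
    screen_subjects,
)
from .peb import PP_CUTOFF, run_analysis_suite
from .qc import FD_LARGE_THRESH, FD_MEAN_THRESH, FD_PROP_THRESH, framewise_displacement, qc_exclude
from .spectra import default_freq_grid, fit_mar, mar_to_csd

log = logging.getLogger("canheart")

__all__ = ["RunConfig", "run_first_level", "run_second_level", "run_all", "make_figures"]


@dataclass
class RunConfig:
    data_dir: str = "."
    out_dir: str = "derived"
    tr_seconds: float = 0.961
    mar_order: int = 8
    n_freq: int = 32
    f_min: float = 1.0 / 128.0
    f_max: float = 0.25
    ev_threshold: float = EV_THRESHOLD
    pp_cutoff: float = PP_CUTOFF
    fd_mean_thresh: float = FD_MEAN_THRESH
    fd_prop_thresh: float = FD_PROP_THRESH
    fd_large_thresh: float = FD_LARGE_THRESH
    patient_label: str | None = None
    max_iter: int = 128
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("ev_threshold", "pp_cutoff", "fd_prop_thresh"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be within [0, 1], got {v}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        return cfg

    def freq_grid(self) -> np.ndarray:
        return default_freq_grid(self.n_freq, self.f_min, self.f_max)

    def config_hash(self) -> str:
        """Identity of the analysis settings; input/output locations are
        excluded so reruns of the same analysis elsewhere hash alike."""
        d = {k: v for k, v in asdict(self).items() if k not in ("data_dir", "out_dir")}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _subject_ids(data_dir: Path) -> list[str]:
    return sorted(p.name.replace("_bold.tsv", "") for p in data_dir.glob("*_bold.tsv"))


def run_first_level(config: RunConfig) -> dict:
    """Per subject: (motion QC ->) MAR -> CSD -> inversion -> EV screen.

    Posterior JSONs land in ``<out_dir>/posteriors``; the returned ledger
    records every subject with its stage outcomes, and every drop carries
    exactly one primary reason (qc_motion, missing_hr, inversion_error,
    low_ev, not_converged).
    """
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    post_dir = out_dir / "posteriors"
    post_dir.mkdir(parents=True, exist_ok=True)
    participants = cio.read_participants(data_dir / "participants.csv")
    participants = participants.set_index("subject", drop=False)
    freqs = config.freq_grid()
    opts = InversionOptions(max_iter=config.max_iter)
    ledger: dict = {"subjects": {}, "n_input": 0, "n_analyzed": 0, "n_excluded": 0}

    for sid in _subject_ids(data_dir):
        ledger["n_input"] += 1
        entry: dict = {"stages": {}}
        ledger["subjects"][sid] = entry
        try:
            motion_path = data_dir / f"{sid}_motion.tsv"
            if motion_path.exists():
                fd = framewise_displacement(cio.read_motion_tsv(motion_path))
                rep = qc_exclude(
                    fd, config.fd_mean_thresh, config.fd_prop_thresh, config.fd_large_thresh
                )
                entry["stages"]["qc_motion"] = {
                    "mean_fd": rep.mean_fd, "prop_large": rep.prop_large,
                    "excluded": rep.excluded, "reason": rep.reason,
                }
                if rep.excluded:
                    entry["excluded"] = True
                    entry["reason"] = "qc_motion"
                    log.info("%s dropped at motion QC (%s)", sid, rep.reason)
                    continue
            if sid in participants.index and participants.loc[sid].get("missing_hr", False):
                entry["excluded"] = True
                entry["reason"] = "missing_hr"
                log.info("%s dropped: no HR covariate", sid)
                continue
            roi = cio.read_bold_tsv(data_dir / f"{sid}_bold.tsv", config.tr_seconds)
            mar = fit_mar(roi.data, config.mar_order, config.tr_seconds)
            csd = mar_to_csd(mar, freqs)
            csd.labels = roi.labels
            post = invert(csd, default_priors(len(roi.labels)), opts)
            entry["stages"]["inversion"] = {
                "explained_variance": post.explained_variance,
                "free_energy": post.free_energy,
                "converged": post.converged,
                "n_iter": post.n_iter,
            }
            screen = screen_subjects([post], config.ev_threshold)
            if not screen.included[0]:
                entry["excluded"] = True
                entry["reason"] = "low_ev" if post.converged else "not_converged"
                log.info("%s dropped at EV screen (EV=%.3f)", sid, post.explained_variance)
                continue
            post.save(post_dir / f"{sid}_post.json")
            entry["excluded"] = False
            ledger["n_analyzed"] += 1
        except Exception as err:  # isolate per-subject failures
            entry["excluded"] = True
            entry["reason"] = "inversion_error"
            entry["error"] = str(err)
            log.warning("%s failed: %s", sid, err)
    ledger["n_excluded"] = ledger["n_input"] - ledger["n_analyzed"]
    with open(out_dir / "first_level_ledger.json", "w") as fh:
        json.dump(ledger, fh, indent=1)
    return ledger


def _matrix_payload(mat_dict: dict, labels) -> dict:
    def clean(a):
        return [[None if not np.isfinite(v) else float(v) for v in row] for row in a]

    return {
        "regressor": mat_dict["regressor"],
        "cutoff": mat_dict["cutoff"],
        "labels": list(labels),
        "Ep": clean(mat_dict["Ep"]),
        "Sd": clean(mat_dict["Sd"]),
        "PP": [[float(v) for v in row] for row in mat_dict["PP"]],
        "diagonal_scale": mat_dict["diagonal_scale"],
    }


def run_second_level(config: RunConfig) -> dict:
    """Run the four PEB analyses over the stored posteriors and write the
    analysis report (thresholded Ep (SD) matrices, inclusion ledger,
    provenance)."""
    out_dir = Path(config.out_dir)
    post_dir = out_dir / "posteriors"
    participants = cio.read_participants(Path(config.data_dir) / "participants.csv")
    posts, rows = [], []
    for _, row in participants.iterrows():
        p = post_dir / f"{row['subject']}_post.json"
        if p.exists():
            posts.append(SubjectPosterior.load(p))
            rows.append(row)
    cov = pd.DataFrame(rows).reset_index(drop=True)
    for lab in cov["group"].unique():
        if (cov["group"] == lab).sum() < 2:
            raise ValueError(f"fewer than 2 analyzable subjects in group '{lab}'")
    suite = run_analysis_suite(
        posts, cov, patient_label=config.patient_label, cutoff=config.pp_cutoff
    )
    labels = posts[0].labels or tuple(f"R{i}" for i in range(posts[0].layout.n))
    report: dict = {
        "provenance": {
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "n_subjects": len(posts),
            "pp_cutoff": config.pp_cutoff,
            "ev_threshold": config.ev_threshold,
        },
        "analyses": {},
    }
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)
    for name, bundle in suite.items():
        res = bundle["result"]
        report["analyses"][name] = {
            "free_energy": res.free_energy,
            "gamma": res.gamma,
            "regressors": res.regressor_names,
            "matrices": {
                rn: _matrix_payload(md, labels) for rn, md in bundle["matrices"].items()
            },
        }
        for rn, md in bundle["matrices"].items():
            n = len(labels)
            disp = np.empty((n, n), dtype=object)
            for i in range(n):
                for j in range(n):
                    ep, sd = md["Ep"][i, j], md["Sd"][i, j]
                    disp[i, j] = "" if not np.isfinite(ep) else f"{ep:.3g} ({sd:.2g})"
            pd.DataFrame(disp, index=list(labels), columns=list(labels)).to_csv(
                mat_dir / f"{name}_{rn}.tsv", sep="\t"
            )
    with open(out_dir / "analysis_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def run_all(config: RunConfig) -> dict:
    """First level then second level; returns the analysis report."""
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    ledger = run_first_level(config)
    report = run_second_level(config)
    report["first_level_ledger"] = ledger
    with open(Path(config.out_dir) / "analysis_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def make_figures(report: dict, out_dir) -> list[str]:
    """Heatmaps plus directed-graph renderings of each thresholded matrix.

    Solid arrows are between-region connections, dashed loops are
    self-connections, matching the display convention of the analysis
    matrices.  Deterministic layout (circular).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, analysis in report["analyses"].items():
        for rn, md in analysis["matrices"].items():
            labels = md["labels"]
            n = len(labels)
            ep = np.array(
                [[np.nan if v is None else v for v in row] for row in md["Ep"]], float
            )
            fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4.5))
            vmax = np.nanmax(np.abs(ep)) if np.any(np.isfinite(ep)) else 1.0
            im = ax1.imshow(ep, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax1.set_xticks(range(n), labels, rotation=45)
            ax1.set_yticks(range(n), labels)
            ax1.set_xlabel("source")
            ax1.set_ylabel("target")
            ax1.set_title(f"{name}: {rn} (blank = PP <= {md['cutoff']})")
            fig.colorbar(im, ax=ax1, shrink=0.8)
            # directed graph on a circle
            angle = 2 * np.pi * np.arange(n) / n
            pos = np.column_stack([np.cos(angle), np.sin(angle)])
            ax2.set_aspect("equal")
            ax2.axis("off")
            for i, lab in enumerate(labels):
                ax2.add_patch(plt.Circle(pos[i], 0.09, fill=True, color="#dddddd", zorder=2))
                ax2.text(*pos[i], lab, ha="center", va="center", zorder=3, fontsize=8)
            for i in range(n):
                for j in range(n):
                    if not np.isfinite(ep[i, j]):
                        continue
                    color = "#b2182b" if ep[i, j] > 0 else "#2166ac"
                    if i == j:
                        loop = pos[i] * 1.22
                        ax2.add_patch(
                            plt.Circle(loop, 0.08, fill=False, ls="--", color=color, zorder=1)
                        )
                    else:
                        src, tgt = pos[j], pos[i]
                        vec = tgt - src
                        vec = vec / np.linalg.norm(vec)
                        ax2.annotate(
                            "", xy=tgt - 0.12 * vec, xytext=src + 0.12 * vec,
                            arrowprops={"arrowstyle": "-|>", "color": color},
                        )
            ax2.set_xlim(-1.45, 1.45)
            ax2.set_ylim(-1.45, 1.45)
            ax2.set_title("solid = directed, dashed = self")
            path = out_dir / f"{name}_{rn}.png"
            fig.savefig(path, dpi=110, bbox_inches="tight")
            plt.close(fig)
            written.append(str(path))
    return written
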