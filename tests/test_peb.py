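import numpy as np
import pandas as pd
import pytest

from canheart.inversion import ParamLayout, SubjectPosterior, default_priors
from canheart.peb import (
    DesignMatrix,
    bmr_log_evidence_change,
    build_design,
    peb_fit,
    posterior_probability_matrix,
    run_analysis_suite,
    threshold_matrix,
)


def fabricate_posteriors(
    n_regions=3,
    n_per_group=(26, 40),
    group_effects=(),
    hr_effects=(),
    noise_sd=0.03,
    cp_scale=1e-3,
    seed=0,
    base=None,
):
    """Subject posteriors drawn from the second-level model itself: the
    independent test bed for the group stage (no inversions involved)."""
    rng = np.random.default_rng(seed)
    layout = ParamLayout(n_regions)
    n_conn = layout.sl_conn.stop
    if base is None:
        base = rng.normal(0, 0.08, n_conn)
    posts, rows = [], []
    hrs = np.concatenate(
        [rng.normal(65.06, 10, n_per_group[0]), rng.normal(74.1, 10, n_per_group[1])]
    )
    hr_c = hrs - hrs.mean()
    codes = np.array([1] * n_per_group[0] + [-1] * n_per_group[1])
    for i, (code, hr) in enumerate(zip(codes, hrs)):
        theta = base.copy()
        for k, delta in group_effects:
            theta[k] += code * delta
        for k, slope in hr_effects:
            theta[k] += hr_c[i] * slope
        theta += rng.normal(0, noise_sd, n_conn)
        ep = np.zeros(layout.n_params)
        ep[:n_conn] = theta
        posts.append(
            SubjectPosterior(
                Ep=ep, Cp=np.eye(layout.n_params) * cp_scale, free_energy=0.0,
                explained_variance=0.9, explained_variance_time=0.9, converged=True,
                n_iter=5, layout=layout, labels=tuple(f"R{r}" for r in range(n_regions)),
            )
        )
        rows.append(
            {"subject": f"s{i:03d}", "group": "AN" if code == 1 else "HC", "hr_bpm": hr}
        )
    return posts, pd.DataFrame(rows), base


class TestBuildDesign:
    def test_balanced_groups_centered_coding_is_plus_minus_one(self):
        cov = pd.DataFrame(
            {"subject": ["a", "b"], "group": ["AN", "HC"], "hr_bpm": [60.0, 70.0]}
        )
        d = build_design(cov, ("group",), patient_label="AN")
        assert np.allclose(d.X[:, 1], [1.0, -1.0])

    def test_hr_centering_arithmetic(self):
        cov = pd.DataFrame(
            {"subject": ["a", "b"], "group": ["AN", "HC"], "hr_bpm": [65.06, 74.10]}
        )
        d = build_design(cov, ("hr",))
        assert np.allclose(d.X[:, 1], [-4.52, 4.52])

    def test_unbalanced_group_column_mean_zero_raw_kept(self):
        cov = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(66)],
                "group": ["AN"] * 26 + ["HC"] * 40,
                "hr_bpm": np.linspace(50, 90, 66),
            }
        )
        d = build_design(cov, ("group", "hr", "group_x_hr"), patient_label="AN")
        assert np.allclose(d.X[:, 1:].mean(axis=0), 0.0, atol=1e-10)
        assert set(np.unique(d.raw["group_raw"])) == {1.0, -1.0}
        assert d.raw["group_coding"] == {"AN": 1, "HC": -1}

    def test_missing_hr_error_names_subjects(self):
        cov = pd.DataFrame(
            {
                "subject": ["a", "b", "c"],
                "group": ["AN", "HC", "HC"],
                "hr_bpm": [60.0, np.nan, 70.0],
            }
        )
        with pytest.raises(ValueError, match="b"):
            build_design(cov, ("hr",))

    def test_constant_first_column_enforced(self):
        with pytest.raises(ValueError, match="constant"):
            DesignMatrix(np.array([[2.0], [2.0]]), ["mean"], ["a", "b"])

    def test_rank_deficiency_detected(self):
        x = np.column_stack([np.ones(4), [1, -1, 1, -1], [1, -1, 1, -1]])
        with pytest.raises(ValueError, match="rank"):
            DesignMatrix(x, ["mean", "g", "g2"], list("abcd"))


class TestPebFit:
    def test_single_subject_mean_shrinks_toward_prior(self):
        posts, cov, base = fabricate_posteriors(n_per_group=(1, 0), noise_sd=0.0)
        d = DesignMatrix(np.ones((1, 1)), ["mean"], ["s000"])
        res = peb_fit(posts, d)
        ep = res.Ep[0]
        subj = posts[0].Ep[posts[0].layout.sl_conn]
        # between subject's value and the zero prior mean, close to subject
        assert np.all(np.abs(ep) <= np.abs(subj) + 1e-9)
        assert np.corrcoef(ep, subj)[0, 1] > 0.99

    def test_planted_group_effects_rank_top(self):
        planted = [(0, 0.2), (3, 0.2), (4, 0.2)]
        posts, cov, _ = fabricate_posteriors(group_effects=planted, seed=1)
        res = peb_fit(posts, build_design(cov, ("group",), "AN"))
        row = np.abs(res.Ep[res.regressor_names.index("group")])
        top5 = set(np.argsort(row)[-5:])
        assert {0, 3, 4} <= top5

    def test_null_regressor_effects_near_zero(self):
        maxima = []
        for seed in range(10):
            posts, cov, _ = fabricate_posteriors(n_per_group=(13, 20), seed=seed)
            rng = np.random.default_rng(1000 + seed)
            cov = cov.copy()
            cov["hr_bpm"] = rng.normal(70, 10, len(cov))  # pure noise covariate
            res = peb_fit(posts, build_design(cov, ("hr",)))
            maxima.append(np.max(np.abs(res.Ep[res.regressor_names.index("hr")])))
        assert np.max(maxima) < 0.05

    def test_pp_half_for_uninformative_effect(self):
        # posterior equals prior for one parameter -> BMR is indifferent
        prior_prec = np.ones(3)
        post_prec = np.diag([5.0, 5.0, 1.0])  # third untouched by data
        post_mean = np.array([0.1, -0.2, 0.0])
        reduced = prior_prec.copy()
        reduced[2] = 1e8
        df = bmr_log_evidence_change(post_prec, post_mean, prior_prec, reduced)
        pp = 1.0 / (1.0 + np.exp(df))
        assert pp == pytest.approx(0.5, abs=0.01)

    def test_bmr_matches_direct_evidence_computation(self):
        """1-D oracle: evidence of y = theta + noise under full/reduced
        priors computed directly from Gaussian marginals."""
        y, s2 = 0.7, 0.5          # one observation, noise var
        v0, v0r = 1.0, 1e-8       # full and reduced prior variances
        # posterior under full prior
        prec_post = 1 / s2 + 1 / v0
        m_post = (y / s2) / prec_post
        # direct log evidence: y ~ N(0, s2 + v)
        def log_ev(v):
            return -0.5 * np.log(2 * np.pi * (s2 + v)) - 0.5 * y**2 / (s2 + v)
        expected = log_ev(v0r) - log_ev(v0)
        got = bmr_log_evidence_change(
            np.array([[prec_post]]), np.array([m_post]),
            np.array([1 / v0]), np.array([1 / v0r]),
        )
        assert got == pytest.approx(expected, abs=1e-6)

    def test_pp_invariant_to_group_relabeling(self):
        posts, cov, _ = fabricate_posteriors(group_effects=[(1, 0.15)], seed=3)
        res_a = peb_fit(posts, build_design(cov, ("group",), patient_label="AN"))
        res_b = peb_fit(posts, build_design(cov, ("group",), patient_label="HC"))
        ga, gb = (r.regressor_names.index("group") for r in (res_a, res_b))
        assert np.allclose(res_a.Ep[ga], -res_b.Ep[gb], atol=1e-4)
        assert np.allclose(res_a.PP[ga], res_b.PP[gb], atol=1e-3)

    def test_uncertain_subjects_move_group_mean_less(self):
        layout = ParamLayout(2)
        n_conn = layout.sl_conn.stop

        def post_with(ep_val, cp_scale):
            ep = np.zeros(layout.n_params)
            ep[0] = ep_val
            return SubjectPosterior(
                Ep=ep, Cp=np.eye(layout.n_params) * cp_scale, free_energy=0.0,
                explained_variance=0.9, explained_variance_time=0.9, converged=True,
                n_iter=1, layout=layout,
            )

        d = DesignMatrix(np.ones((2, 1)), ["mean"], ["a", "b"])
        # second subject disagrees; confident version pulls the mean more
        confident = peb_fit([post_with(0.2, 1e-4), post_with(-0.2, 1e-4)], d)
        uncertain = peb_fit([post_with(0.2, 1e-4), post_with(-0.2, 1.0)], d)
        assert uncertain.Ep[0][0] > confident.Ep[0][0]

    def test_misaligned_design_raises(self):
        posts, cov, _ = fabricate_posteriors(n_per_group=(2, 2))
        d = DesignMatrix(np.ones((3, 1)), ["mean"], ["a", "b", "c"])
        with pytest.raises(ValueError, match="align"):
            peb_fit(posts, d)


class TestThreshold:
    def test_cutoff_is_strict(self):
        posts, cov, _ = fabricate_posteriors(group_effects=[(0, 0.25)], seed=4)
        res = peb_fit(posts, build_design(cov, ("group",), "AN"))
        md = threshold_matrix(res, "group", cutoff=0.99)
        pp = md["PP"]
        ep = md["Ep"]
        assert np.all(np.isnan(ep[(pp <= 0.99)]))
        assert np.all(np.isfinite(ep[(pp > 0.99)]))
        # the planted connection (target 0, source 1) survives
        assert np.isfinite(ep[0, 1])

    def test_pp_matrix_orientation(self):
        posts, cov, _ = fabricate_posteriors(group_effects=[(0, 0.3)], seed=5)
        res = peb_fit(posts, build_design(cov, ("group",), "AN"))
        pp = posterior_probability_matrix(res, "group")
        # first off-diagonal parameter is (target 0, source 1)
        assert pp[0, 1] > 0.99


class TestSuite:
    def test_four_analyses_present_and_sensitive(self):
        posts, cov, base = fabricate_posteriors(
            group_effects=[(0, 0.2)], hr_effects=[(3, 0.01)], seed=6
        )
        out = run_analysis_suite(posts, cov, patient_label="AN")
        assert set(out) == {
            "commonalities_AN", "commonalities_HC", "group_difference",
            "hr_AN", "hr_HC", "interaction",
        }
        gd = out["group_difference"]["result"]
        assert gd.PP[gd.regressor_names.index("group")][0] > 0.99
        # commonalities recover that group's mean couplings (base - effect)
        cm = out["commonalities_HC"]["result"]
        ep = cm.Ep[0][: len(base)]
        expected = base.copy()
        expected[0] -= 0.2
        assert np.max(np.abs(ep - expected)) < 0.05

    def test_hr_association_detected_within_group(self):
        posts, cov, _ = fabricate_posteriors(hr_effects=[(2, 0.01)], seed=7)
        out = run_analysis_suite(posts, cov, patient_label="AN")
        for lab in ("AN", "HC"):
            res = out[f"hr_{lab}"]["result"]
            assert res.PP[res.regressor_names.index("hr")][2] > 0.99
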