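import numpy as np
import pytest
from scipy import linalg

from canheart.connectivity import TrueConnectivity, make_connectivity
from canheart.hemodynamics import HemodynamicParams
from canheart.synthetic import (
    CohortSpec,
    powerlaw_noise,
    simulate_bold,
    simulate_cohort,
    simulate_motion,
    simulate_neural,
    simulate_ppg,
    write_cohort,
)
from canheart.qc import framewise_displacement


def two_node(a12=0.2, a21=-0.1):
    off = np.array([[0.0, a12], [a21, 0.0]])
    return TrueConnectivity(off, np.zeros(2), ("x", "y"))


class TestNeural:
    def test_no_input_stays_at_zero(self):
        x = simulate_neural(two_node(), duration=50, dt=0.05, fluct_sd=0.0, seed=0)
        assert np.all(x == 0.0)

    def test_ou_stationary_variance_matches_lyapunov(self):
        # single node, a=-0.5, unit fluctuations: var = 1/(2*0.5) = 1
        conn = TrueConnectivity(np.zeros((2, 2)), np.zeros(2), ("x", "y"))
        x = simulate_neural(conn, duration=20000, dt=0.05, fluct_sd=1.0, seed=3)
        assert np.allclose(x.var(axis=0), 1.0, rtol=0.1)

    def test_stationary_covariance_matches_lyapunov_equation(self):
        # independent oracle: solve A P + P A' = -sigma^2 I
        conn = make_connectivity(3, 0.2, seed=9)
        sd = 0.7
        p_ref = linalg.solve_lyapunov(conn.matrix, -sd**2 * np.eye(3))
        x = simulate_neural(conn, duration=40000, dt=0.05, fluct_sd=sd, seed=4)
        p_emp = np.cov(x.T)
        assert np.max(np.abs(p_emp - p_ref)) < 0.12 * np.max(np.abs(p_ref))

    def test_deterministic_given_seed(self):
        a = simulate_neural(two_node(), 30, 0.05, 1.0, seed=7)
        b = simulate_neural(two_node(), 30, 0.05, 1.0, seed=7)
        assert np.array_equal(a, b)

    def test_unstable_matrix_rejected(self):
        off = np.array([[0.0, 5.0], [5.0, 0.0]])
        conn = TrueConnectivity(off, np.zeros(2), ("x", "y"))
        with pytest.raises(ValueError, match="stable"):
            simulate_neural(conn, 10, 0.05, 1.0, seed=0)


class TestBold:
    def test_zero_input_zero_noise_stays_at_baseline(self):
        latent = np.zeros((2000, 2))
        y = simulate_bold(latent, 0.0961, 0.961)
        assert np.allclose(y, 0.0, atol=1e-12)

    def test_impulse_response_peaks_3_to_7_seconds(self):
        dt = 0.05
        latent = np.zeros((int(30 / dt), 1))
        latent[: int(0.5 / dt), 0] = 1.0  # brief unit impulse
        y = simulate_bold(latent, dt, dt, HemodynamicParams(n_regions=1))
        t_peak = np.argmax(y[:, 0]) * dt
        assert 3.0 <= t_peak <= 7.0

    def test_volume_count_after_dummy_discard(self):
        spec = CohortSpec(n_regions=2, n_per_group=(1, 1), seed=0)
        subjects, _ = simulate_cohort(spec)
        assert spec.n_volumes == 750 and spec.n_dummy == 4
        assert all(s.bold.shape[0] == 746 for s in subjects)

    def test_incommensurate_tr_raises(self):
        with pytest.raises(ValueError, match="multiple"):
            simulate_bold(np.zeros((100, 1)), dt=0.07, tr=0.961)


class TestPowerlawNoise:
    def test_spectrum_slope_and_sd(self):
        rng = np.random.default_rng(0)
        x = powerlaw_noise(2**14, 1.0, exponent=1.0, sd=2.0, rng=rng)
        assert np.isclose(x.std(), 2.0, rtol=1e-6)
        f = np.fft.rfftfreq(x.size, 1.0)[1:]
        p = np.abs(np.fft.rfft(x))[1:] ** 2
        lo = p[(f > 0.001) & (f < 0.01)].mean()
        hi = p[(f > 0.1) & (f < 0.5)].mean()
        assert lo > 5 * hi  # strongly red spectrum


class TestCohort:
    def test_group_sizes_and_codes_match_study_design(self):
        spec = CohortSpec(n_regions=2, n_per_group=(26, 40), seed=1)
        subjects, truth = simulate_cohort(spec)
        assert sum(s.group_code == 1 for s in subjects) == 26
        assert sum(s.group_code == -1 for s in subjects) == 40
        assert subjects[0].group == "AN" and subjects[-1].group == "HC"

    def test_hr_group_means_near_targets(self):
        spec = CohortSpec(n_regions=2, n_per_group=(26, 40), seed=5)
        subjects, _ = simulate_cohort(spec)
        an = [s.hr_bpm for s in subjects if s.group_code == 1]
        hc = [s.hr_bpm for s in subjects if s.group_code == -1]
        assert abs(np.mean(an) - 65.06) < 2 * 10.0 / np.sqrt(26)
        assert abs(np.mean(hc) - 74.1) < 2 * 10.0 / np.sqrt(40)

    def test_truth_record_reconstructs_every_subject_matrix(self):
        spec = CohortSpec(
            n_regions=3,
            n_per_group=(3, 3),
            seed=2,
            effect_map_group=((0, 1, 0.2),),
            effect_map_hr=((1, 2, 0.01),),
        )
        subjects, truth = simulate_cohort(spec)
        base = np.asarray(truth["base_theta_offdiag"])
        g_eff = np.zeros((3, 3))
        g_eff[0, 1] = 0.2
        h_eff = np.zeros((3, 3))
        h_eff[1, 2] = 0.01
        for s, rec in zip(subjects, truth["subjects"]):
            expected = (
                base
                + s.group_code * g_eff
                + (s.hr_bpm - truth["grand_mean_hr"]) * h_eff
                + np.asarray(rec["subject_noise"])
            )
            assert np.allclose(expected, s.true_connectivity.theta_offdiag)

    def test_null_cohort_groups_exchangeable(self):
        # no group effects: the coupling truth must not separate the groups
        spec = CohortSpec(n_regions=2, n_per_group=(10, 10), seed=8)
        subjects, _ = simulate_cohort(spec)
        vals = np.array([s.true_connectivity.theta_offdiag[0, 1] for s in subjects])
        codes = np.array([s.group_code for s in subjects])
        obs = abs(vals[codes == 1].mean() - vals[codes == -1].mean())
        rng = np.random.default_rng(0)
        null = []
        for _ in range(500):
            perm = rng.permutation(codes)
            null.append(abs(vals[perm == 1].mean() - vals[perm == -1].mean()))
        p = np.mean(np.asarray(null) >= obs)
        assert 0.01 < p  # observed difference not extreme under permutation

    def test_fixed_seed_reproduces_cohort_exactly(self):
        spec = CohortSpec(n_regions=2, n_per_group=(2, 2), seed=3)
        a, _ = simulate_cohort(spec)
        b, _ = simulate_cohort(spec)
        for s, t in zip(a, b):
            assert np.array_equal(s.bold, t.bold) and s.hr_bpm == t.hr_bpm

    def test_all_subject_matrices_stable(self):
        spec = CohortSpec(n_regions=3, n_per_group=(5, 5), seed=4, subject_noise_sd=0.05)
        subjects, _ = simulate_cohort(spec)
        assert all(s.true_connectivity.is_stable() for s in subjects)


class TestPPG:
    def test_60bpm_no_jitter_gives_600_beats(self):
        ppg = simulate_ppg(60.0, hr_jitter_sd=0.0, fs=500, duration=600, seed=0)
        from canheart.qc import heart_rate_from_ppg

        res = heart_rate_from_ppg(ppg[:, 1], 500)
        assert abs(res.n_beats - 600) <= 1

    def test_deterministic_trace(self):
        a = simulate_ppg(70, fs=250, duration=60, seed=9)
        b = simulate_ppg(70, fs=250, duration=60, seed=9)
        assert np.array_equal(a, b)

    def test_rejects_out_of_range_hr(self):
        with pytest.raises(ValueError):
            simulate_ppg(20.0, fs=500, duration=60, seed=0)
        with pytest.raises(ValueError):
            simulate_ppg(60.0, fs=50, duration=60, seed=0)


class TestMotion:
    def test_zero_baseline_no_spikes_is_all_zero(self):
        m = simulate_motion(100, baseline_sd=0.0, seed=0)
        assert np.all(m == 0.0)
        assert np.all(framewise_displacement(m) == 0.0)

    def test_single_step_appears_as_single_fd_spike(self):
        m = simulate_motion(746, baseline_sd=0.0, spike_frames=(100,), spike_size=0.4, seed=0)
        fd = framewise_displacement(m)
        assert fd[100] == pytest.approx(0.4)
        assert np.sum(fd > 0) == 1

    def test_spike_indices_validated(self):
        with pytest.raises(ValueError):
            simulate_motion(10, spike_frames=(20,), spike_size=0.1)


def test_write_cohort_layout(tmp_path):
    spec = CohortSpec(
        n_regions=2, n_per_group=(1, 1), seed=0, with_ppg=True, with_motion=True,
        n_volumes=40, n_dummy=4,
    )
    subjects, truth = simulate_cohort(spec)
    write_cohort(subjects, truth, tmp_path)
    assert (tmp_path / "participants.csv").exists()
    assert (tmp_path / "truth.json").exists()
    for s in subjects:
        assert (tmp_path / f"{s.id}_bold.tsv").exists()
        assert (tmp_path / f"{s.id}_ppg.tsv").exists()
        assert (tmp_path / f"{s.id}_motion.tsv").exists()
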