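import numpy as np
import pytest

from canheart.connectivity import make_connectivity
from canheart.hemodynamics import HemodynamicParams
from canheart.inversion import (
    InversionOptions,
    NoiseParams,
    ParamLayout,
    SubjectPosterior,
    default_priors,
    explained_variance,
    explained_variance_time,
    generative_csd,
    invert,
    screen_subjects,
)
from canheart.spectra import CrossSpectrum, default_freq_grid

from conftest import invert_bold, make_pattern, synth_bold


class TestGenerativeCsd:
    def test_self_scaling_zero_gives_minus_half_diagonal(self):
        layout = ParamLayout(4)
        a = layout.effective_matrix(np.zeros(layout.n_params))
        assert np.allclose(np.diag(a), -0.5)

    def test_matches_ou_closed_form_with_identity_kernels(self):
        freqs = default_freq_grid()
        for n, seed in [(2, 1), (3, 2), (4, 3)]:
            conn = make_connectivity(n, 0.2, seed=seed)
            cs = generative_csd(conn.theta_offdiag, conn.theta_self, freqs)
            a = conn.matrix
            for k, f in enumerate(freqs):
                t = np.linalg.inv(2j * np.pi * f * np.eye(n) - a)
                assert np.max(np.abs(cs.values[k] - t @ t.conj().T)) < 1e-8

    def test_single_node_closed_form(self):
        # zero coupling, identity kernels, flat unit fluctuations + floor
        freqs = default_freq_grid()
        noise = NoiseParams(0.0, 0.0, np.log(0.2), 0.0)
        cs = generative_csd(np.zeros((1, 1)), np.zeros(1), freqs, noise=noise)
        expected = 1.0 / ((2 * np.pi * freqs) ** 2 + 0.25) + 0.2
        assert np.max(np.abs(cs.values[:, 0, 0].real - expected)) < 1e-10

    def test_hermitian_nonneg_diagonal_for_random_stable_params(self):
        freqs = default_freq_grid()
        rng = np.random.default_rng(0)
        for seed in range(5):
            conn = make_connectivity(3, 0.25, seed=seed)
            hemo = HemodynamicParams(
                n_regions=3,
                theta_decay=rng.normal(0, 0.1, 3),
                theta_transit=rng.normal(0, 0.1, 3),
            )
            cs = generative_csd(
                conn.theta_offdiag, conn.theta_self, freqs, hemo=hemo, noise=NoiseParams()
            )
            assert cs.is_hermitian()

    def test_unstable_matrix_rejected(self):
        off = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="stable"):
            generative_csd(off, np.zeros(2), default_freq_grid())


class TestInvert:
    def test_self_consistency_at_prior_mean(self):
        n = 3
        pri = default_priors(n)
        obs = generative_csd(
            np.zeros((n, n)), np.zeros(n), default_freq_grid(),
            hemo=HemodynamicParams(n_regions=n), noise=NoiseParams(),
        )
        post = invert(obs)
        assert np.max(np.abs(post.Ep - pri.mean)) < 0.05
        assert post.explained_variance > 0.99

    def test_recovers_known_couplings(self, recovered_subject):
        conn, _, post = recovered_subject
        mask = ~np.eye(3, dtype=bool)
        r = np.corrcoef(conn.matrix[mask], post.connectivity_matrix[mask])[0, 1]
        assert r > 0.7

    def test_free_energy_trace_monotone(self, recovered_subject):
        _, _, post = recovered_subject
        assert len(post.f_trace) > 1
        assert np.all(np.diff(post.f_trace) >= 0)

    def test_posterior_shrinks_with_more_data(self):
        conn = make_pattern(2, seed=5, strength=0.25)
        short = invert_bold(synth_bold(conn, seed=1, n_volumes=204, snr=None))
        long = invert_bold(synth_bold(conn, seed=1, n_volumes=2004, snr=None))
        sl = short.layout.sl_conn
        assert np.trace(long.Cp[sl, sl]) < np.trace(short.Cp[sl, sl])

    def test_invalid_observed_rejected(self):
        freqs = default_freq_grid()
        vals = np.ones((freqs.size, 2, 2), complex)
        vals[:, 0, 1] = 5j  # breaks Hermitian symmetry
        with pytest.raises(ValueError, match="Hermitian"):
            invert(CrossSpectrum(freqs, vals))

    def test_posterior_roundtrip_json(self, recovered_subject, tmp_path):
        _, _, post = recovered_subject
        path = tmp_path / "post.json"
        post.save(path)
        back = SubjectPosterior.load(path)
        assert np.allclose(back.Ep, post.Ep)
        assert np.allclose(back.Cp, post.Cp)
        assert back.converged == post.converged


class TestExplainedVariance:
    def _pair(self):
        freqs = default_freq_grid()
        conn = make_connectivity(2, 0.2, seed=0)
        cs = generative_csd(conn.theta_offdiag, conn.theta_self, freqs)
        return cs, freqs

    def test_perfect_fit_is_one(self):
        cs, _ = self._pair()
        assert explained_variance(cs, cs) == 1.0
        assert explained_variance_time(cs, cs) == 1.0

    def test_null_prediction_floors_at_zero(self):
        cs, freqs = self._pair()
        null = CrossSpectrum(freqs, np.zeros_like(cs.values))
        assert explained_variance(cs, null) == 0.0

    def test_grid_mismatch_raises(self):
        cs, freqs = self._pair()
        other = CrossSpectrum(freqs + 0.001, cs.values)
        with pytest.raises(ValueError, match="grid"):
            explained_variance(cs, other)


class TestScreen:
    def _post(self, ev, converged=True):
        layout = ParamLayout(2)
        return SubjectPosterior(
            Ep=np.zeros(layout.n_params), Cp=np.eye(layout.n_params),
            free_energy=0.0, explained_variance=ev, explained_variance_time=ev,
            converged=converged, n_iter=1, layout=layout,
        )

    def test_threshold_is_inclusive_at_exactly_10_percent(self):
        rep = screen_subjects([self._post(0.10), self._post(0.09), self._post(0.85)])
        assert rep.included == [True, False, True]
        assert rep.n_included == 2 and rep.n_excluded == 1

    def test_high_ev_subjects_all_included(self):
        rep = screen_subjects([self._post(0.85), self._post(0.92)])
        assert all(rep.included)

    def test_nonconverged_flagged(self):
        rep = screen_subjects([self._post(0.9, converged=False)])
        assert rep.included == [False]


def test_self_inhibition_monotone_in_theta_self():
    layout = ParamLayout(2)
    diags = []
    for ts in np.linspace(-0.5, 0.5, 9):
        theta = np.zeros(layout.n_params)
        theta[layout.sl_self] = ts
        diags.append(layout.effective_matrix(theta)[0, 0])
    assert np.all(np.diff(diags) < 0)  # increasingly inhibitory
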