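import numpy as np
import pytest
from scipy import stats as sps

from psyfi.angles import deg_to_rad, signed_diff_deg
from psyfi.circular import sliding_profile
from psyfi.fisher import extract_sqrt_fi
from psyfi.model import mixture_density
from psyfi.observer import (CohortSpec, DecoderSpec, add_late_noise,
                            encoder_from_params, internal_kappa_for_lambda,
                            lambda_for_internal_kappa, observer_parameters,
                            simulate_cohort, simulate_trial, simulate_trials)

from conftest import simulate_observer_dataset


class TestEncoder:
    def test_uniform_prior_gives_linear_map(self):
        enc = encoder_from_params(10.0, 0.0)
        theta = np.linspace(0, np.pi, 11)
        np.testing.assert_allclose(enc.cum_map(theta), theta / np.pi, atol=1e-12)

    def test_pure_cardinal_prior_flat_at_oblique(self):
        enc = encoder_from_params(10.0, 1.0)
        assert enc.prior_density(np.pi / 4) == pytest.approx(0.0, abs=1e-12)
        eps = 1e-3
        flat = enc.cum_map(np.pi / 4 + eps) - enc.cum_map(np.pi / 4 - eps)
        assert flat < 1e-5

    def test_natural_scene_prior_peaks_at_cardinals(self):
        enc = encoder_from_params(10.0, 0.5)
        dens = enc.prior_density(deg_to_rad(np.array([0.0, 45.0, 90.0, 135.0])))
        assert dens[0] == pytest.approx(dens[2], rel=1e-12)
        assert dens[1] == pytest.approx(dens[3], rel=1e-9)
        assert dens[0] > dens[1]

    def test_cum_map_inverts_to_high_precision(self):
        for omega in (0.0, 0.3, 0.7):
            enc = encoder_from_params(12.0, omega)
            u = np.linspace(0.001, 0.999, 997)
            theta = enc.ppf(u)
            np.testing.assert_allclose(enc.cum_map(theta), u, atol=1e-9)

    def test_analytic_sqrt_fi_is_scaled_mixture(self):
        enc = encoder_from_params(13.0, 0.4)
        theta = np.linspace(0, np.pi, 181)[:-1]
        expected = 13.0 * mixture_density(theta, 0.4)
        np.testing.assert_allclose(enc.analytic_sqrt_fi(theta), expected,
                                   rtol=1e-12)

    def test_internal_kappa_lambda_roundtrip(self):
        assert lambda_for_internal_kappa(internal_kappa_for_lambda(14.7)) == \
            pytest.approx(14.7)

    def test_omega_domain_error(self):
        with pytest.raises(ValueError):
            encoder_from_params(10.0, 1.2)


class TestSimulateTrials:
    def test_noiseless_inverse_map_is_identity(self):
        enc = encoder_from_params(10.0, 0.5, internal_kappa=1e9)
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, np.pi, 500)
        resp = simulate_trials(enc, DecoderSpec(), theta, rng)
        np.testing.assert_allclose(resp, theta, atol=5e-4)

    def test_identity_remap_matches_inverse_map(self):
        enc = encoder_from_params(12.0, 0.5)
        theta = np.random.default_rng(1).uniform(0, np.pi, 10000)
        r1 = simulate_trials(enc, DecoderSpec(kind="inverse_map"), theta,
                             np.random.default_rng(42))
        r2 = simulate_trials(enc, DecoderSpec(kind="remapped",
                                              remap_amplitude=0.0), theta,
                             np.random.default_rng(42))
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_late_noise_sets_response_spread(self):
        enc = encoder_from_params(10.0, 0.0, internal_kappa=1e9)
        dec = DecoderSpec(late_noise_sd_deg=5.0)
        rng = np.random.default_rng(3)
        theta = np.full(20000, np.pi / 3)
        resp = simulate_trials(enc, dec, theta, rng)
        err = signed_diff_deg(np.degrees(resp), np.degrees(theta))
        assert np.std(err) == pytest.approx(5.0, rel=0.05)

    def test_single_trial_wrapper(self):
        enc = encoder_from_params(10.0, 0.5)
        resp = simulate_trial(enc, DecoderSpec(), 0.7, np.random.default_rng(5))
        assert 0.0 <= resp < np.pi

    def test_invalid_decoder_specs(self):
        with pytest.raises(ValueError):
            DecoderSpec(kind="oracle")
        with pytest.raises(ValueError):
            DecoderSpec(kind="remapped", remap_amplitude=1.5)
        with pytest.raises(ValueError):
            DecoderSpec(late_noise_sd_deg=-1.0)


class TestCohort:
    def test_reproducible_from_seed(self):
        spec = CohortSpec(trials_per_block=20, rng_seed=5)
        d1 = simulate_cohort(spec)
        d2 = simulate_cohort(spec)
        assert d1.frame.equals(d2.frame)

    def test_study_shape(self):
        spec = CohortSpec(trials_per_block=10, rng_seed=2)
        ds = simulate_cohort(spec)
        assert len(ds) == 10 * 3 * (25 + 17)
        assert set(ds.frame["group"]) == {"NT", "ASD"}
        assert set(ds.frame["block"]) == {"woFB", "wFB1", "wFB2"}
        assert len(ds.participants()) == 42

    def test_targets_uniform(self):
        spec = CohortSpec(trials_per_block=200, rng_seed=9)
        ds = simulate_cohort(spec)
        stat = sps.kstest(ds.target_deg / 180.0, "uniform")
        assert stat.pvalue > 0.01

    def test_flexibility_coupling_links_capacity_to_learning(self):
        spec = CohortSpec(rng_seed=3, flexibility_coupling=2.0)
        params = observer_parameters(spec)
        nt = params.query("group == 'NT'")
        lam0 = nt.query("block == 'woFB'").set_index("participant_id")["lam"]
        om2 = nt.query("block == 'wFB2'").set_index("participant_id")["omega"]
        r = np.corrcoef(lam0, om2.loc[lam0.index])[0, 1]
        assert r < -0.5  # higher initial capacity -> flatter final allocation

    def test_add_late_noise_edge_cases(self):
        ds = simulate_observer_dataset(12.0, 0.3, 200, seed=8)
        rng = np.random.default_rng(0)
        same = add_late_noise(ds, 0.0, rng)
        assert same.frame.equals(ds.frame)
        noisy = add_late_noise(ds, 4.0, rng)
        np.testing.assert_array_equal(noisy.target_deg, ds.target_deg)
        assert not np.allclose(noisy.response_deg, ds.response_deg)
        with pytest.raises(ValueError):
            add_late_noise(ds, -1.0, rng)


class TestBoundAttainment:
    def test_extraction_matches_analytic_profile_at_large_n(self):
        # bound attainment: (1 + b')/sigma from data tracks the encoder's
        # analytic sqrt FI profile (moderate tolerance: window smoothing and
        # the 1/kappa convention distort a few percent at study noise)
        lam, omega = 14.7, 0.5
        ds = simulate_observer_dataset(lam, omega, 60000, seed=21)
        prof = sliding_profile(ds, 18.0)
        fp = extract_sqrt_fi(prof)
        enc = encoder_from_params(lam, omega)
        analytic = enc.analytic_sqrt_fi(deg_to_rad(prof.grid_deg))
        rel = np.sqrt(np.mean((fp.sqrt_fi - analytic) ** 2)) / \
            np.sqrt(np.mean(analytic ** 2))
        assert rel < 0.25
        assert np.corrcoef(fp.sqrt_fi, analytic)[0, 1] > 0.9
        # total is deflated ~9% at the 18-deg window because the fitted
        # variance includes the window's uniform target spread
        assert fp.total == pytest.approx(lam, rel=0.15)
        assert fp.total < lam
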