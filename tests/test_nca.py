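"""Noncompartmental analysis: moments, terminal fit, derived parameters."""

import math

import numpy as np
import pytest

from pknet.nca import (
    ConcentrationTimeProfile,
    batch_nca,
    fit_lambda_z,
    nca_parameters,
    trapezoid_moments,
    PARAM_COLUMNS,
)
from pknet.synthetic import SCHEDULE_H, PKSimConfig, simulate_profiles


def profile(times, concs, dose=5000.0, subject="s1", group="g", bloq=None):
    return ConcentrationTimeProfile(
        subject_id=subject, group=group, dose=dose,
        times=np.asarray(times, float), concentrations=np.asarray(concs, float),
        bloq=bloq,
    )


def mono_profile(c0=1000.0, lam=0.1, t_end=48.0, step=0.05, dose=5000.0):
    t = np.arange(0.0, t_end + step / 2, step)
    return profile(t, c0 * np.exp(-lam * t), dose=dose)


class TestProfileInvariants:
    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at time 0"):
            profile([1, 2, 3], [3, 2, 1])

    def test_times_strictly_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            profile([0, 1, 1], [3, 2, 1])

    def test_minimum_quantifiable_points(self):
        with pytest.raises(ValueError, match="quantifiable"):
            profile([0, 1, 2], [3, 2, 1], bloq=[False, True, True])


class TestTrapezoidMoments:
    def test_hand_computed_triangle(self):
        auc, aumc, m2 = trapezoid_moments(profile([0, 1, 2], [10, 5, 0]))
        assert auc == pytest.approx(10.0)
        assert aumc == pytest.approx(5.0)
        assert m2 == pytest.approx(5.0)

    def test_constant_concentration(self):
        auc, _, _ = trapezoid_moments(profile([0, 2, 4, 6], [7, 7, 7, 7]))
        assert auc == pytest.approx(42.0)

    def test_dense_exponential_close_to_closed_form(self):
        p = mono_profile(c0=1000.0, lam=0.1)
        auc, _, _ = trapezoid_moments(p)
        analytic = 1000.0 * (1 - math.exp(-4.8)) / 0.1
        assert auc == pytest.approx(analytic, rel=5e-3)

    def test_halving_step_reduces_error_monotonically(self):
        errors = []
        analytic = 1000.0 * (1 - math.exp(-4.8)) / 0.1
        for step in (1.0, 0.5, 0.25, 0.125):
            auc, _, _ = trapezoid_moments(mono_profile(step=step))
            errors.append(abs(auc - analytic))
        assert errors == sorted(errors, reverse=True)


class TestFitLambdaZ:
    def test_noise_free_terminal_phase_recovered_exactly(self):
        t = np.array([0.0, 10.0, 24.0, 32.0, 48.0])
        c = 100.0 * np.exp(-0.05 * t)
        fit = fit_lambda_z(profile(t, c))
        assert fit.lambda_z == pytest.approx(0.05, rel=1e-12)
        assert fit.r2_adjusted == pytest.approx(1.0, abs=1e-12)
        assert fit.c_last_pred == pytest.approx(100.0 * math.exp(-0.05 * 48), rel=1e-10)

    def test_rising_profile_rejected(self):
        with pytest.raises(ValueError, match="terminal decline"):
            fit_lambda_z(profile([0, 1, 2, 3, 4], [1, 2, 3, 4, 5]))

    def test_cmax_excluded_from_candidates(self):
        # C_max at t=1; only the four later points can enter the fit
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0, 12.0])
        c = np.array([5.0, 50.0, 30.0, 18.0, 6.0, 2.0])
        fit = fit_lambda_z(profile(t, c))
        assert fit.t_first >= 2.0

    def test_last_n_selection(self):
        t = np.array([0.0, 10.0, 24.0, 32.0, 48.0])
        c = 100.0 * np.exp(-0.05 * t)
        fit = fit_lambda_z(profile(t, c), selection=3)
        assert fit.n_points == 3 and fit.t_first == 24.0

    def test_bloq_points_excluded(self):
        t = np.array([0.0, 10.0, 24.0, 32.0, 48.0])
        c = 100.0 * np.exp(-0.05 * t)
        c[-1] = 99.0  # nonsense value, but flagged below LOQ
        fit = fit_lambda_z(profile(t, c, bloq=[0, 0, 0, 0, 1]))
        assert fit.t_last == 32.0
        assert fit.lambda_z == pytest.approx(0.05, rel=1e-12)

    def test_recovery_from_noisy_biexponential(self):
        """auto selection lands near the true terminal slope at 10% CV;
        the sparse terminal design (a handful of points over 6-48 h)
        supports recovery to roughly 15%."""
        cfg = PKSimConfig(seed=42, n_per_group=25, groups=("g",))
        errors = [
            abs(fit_lambda_z(p).lambda_z - cfg.beta) / cfg.beta
            for p in simulate_profiles(cfg)
        ]
        assert np.median(errors) < 0.15


class TestNCAParameters:
    def test_mono_exponential_closed_forms(self):
        c0, lam, dose = 1000.0, 0.1, 5000.0
        res = nca_parameters(mono_profile(c0=c0, lam=lam, t_end=120.0, dose=dose))
        assert res.auc_0_inf == pytest.approx(c0 / lam, rel=0.01)
        assert res.mrt_0_inf == pytest.approx(1 / lam, rel=0.01)
        assert res.vrt_0_inf == pytest.approx(1 / lam**2, rel=0.01)
        assert res.cl == pytest.approx(dose * lam / c0, rel=0.01)
        assert res.v == pytest.approx(dose / c0, rel=0.01)
        assert res.t_half == pytest.approx(math.log(2) / lam, rel=0.01)

    def test_definitional_identities_exact(self):
        res = nca_parameters(mono_profile())
        assert res.t_half * res.lambda_z == pytest.approx(math.log(2), rel=1e-15)
        assert res.cl * res.auc_0_inf == pytest.approx(5000.0, rel=1e-15)
        assert res.v == pytest.approx(res.cl / res.lambda_z, rel=1e-15)
        assert res.auc_0_inf >= res.auc_0_t

    def test_c_max_is_max_observed(self):
        t = np.array([0.0, 0.5, 1.0, 2.0, 4.0, 8.0])
        c = np.array([10.0, 40.0, 25.0, 12.0, 5.0, 1.5])
        res = nca_parameters(profile(t, c))
        assert res.c_max == 40.0

    def test_scale_equivariance(self):
        t = np.asarray(SCHEDULE_H)
        c = 1470 * np.exp(-3.0 * t) + 25 * np.exp(-0.022 * t)
        r1 = nca_parameters(profile(t, c))
        r2 = nca_parameters(profile(t, 10 * c))
        for name in ("auc_0_t", "auc_0_inf", "aumc_0_t", "c_max"):
            assert getattr(r2, name) == pytest.approx(10 * getattr(r1, name), rel=1e-10)
        for name in ("lambda_z", "t_half", "mrt_0_inf", "vrt_0_inf"):
            assert getattr(r2, name) == pytest.approx(getattr(r1, name), rel=1e-10)


class TestBatchNCA:
    def test_identical_profiles_have_zero_sd(self):
        t = np.asarray(SCHEDULE_H)
        c = 1470 * np.exp(-3.0 * t) + 25 * np.exp(-0.022 * t)
        profiles = [
            profile(t, c, subject=f"s{i}", group="g") for i in range(6)
        ]
        batch = batch_nca(profiles)
        assert len(batch.table) == 6
        assert set(PARAM_COLUMNS) <= set(batch.table.columns)
        assert (batch.table[PARAM_COLUMNS].nunique() == 1).all()

    def test_failed_subject_flagged_not_fatal(self):
        t = np.asarray(SCHEDULE_H)
        c = 1470 * np.exp(-3.0 * t) + 25 * np.exp(-0.022 * t)
        rising = profile(t, np.linspace(1, 100, t.size), subject="bad", group="g")
        batch = batch_nca([profile(t, c, subject="ok", group="g"), rising])
        assert len(batch.table) == 1
        assert batch.failures["subject"].to_list() == ["bad"]

    def test_generator_defaults_produce_no_failures(self):
        batch = batch_nca(simulate_profiles(PKSimConfig(seed=11)))
        assert batch.failures.empty
        assert len(batch.table) == 14
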