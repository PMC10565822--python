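import numpy as np
import pytest

from gkvisc import (
    RheoDataset,
    RossMintonFit,
    ValidationError,
    concentration_uncertainty_band,
    cone_plate_viscosity,
    invert_concentration,
    invert_concentration_closed_form,
    load_mab_dataset,
    load_rheo_dataset,
    ross_minton_eval,
    ross_minton_fit,
)
from gkvisc.rheometry import write_rheo_dataset


class TestConePlate:
    def test_zero_torque_gives_zero_viscosity(self):
        assert cone_plate_viscosity(0.0, 10.0, 0.0175, 0.0175) == 0.0

    def test_proportionality(self):
        base = cone_plate_viscosity(1e-5, 10.0, 0.0175, 0.0175)
        assert cone_plate_viscosity(2e-5, 10.0, 0.0175, 0.0175) == pytest.approx(
            2 * base, rel=1e-12
        )
        assert cone_plate_viscosity(1e-5, 20.0, 0.0175, 0.0175) == pytest.approx(
            base / 2, rel=1e-12
        )

    def test_stress_over_shear_rate_oracle(self):
        # 35 mm diameter cone, 1 degree angle; torque chosen so the shear
        # stress 3M/(2 pi R^3) is 10 Pa at shear rate omega/alpha ~ 3283 1/s
        R, alpha, omega = 0.0175, np.deg2rad(1.0), 57.3
        M = 10.0 * 2 * np.pi * R**3 / 3.0
        eta = cone_plate_viscosity(M, omega, alpha, R)
        assert eta == pytest.approx(10.0 / (omega / alpha) * 1e3, rel=1e-12)
        assert eta == pytest.approx(3.05, abs=0.01)

    @pytest.mark.parametrize(
        "kwargs", [dict(angular_velocity=0.0), dict(cone_radius=-1.0),
                   dict(cone_angle=0.5)]
    )
    def test_invalid_geometry_rejected(self, kwargs):
        base = dict(torque=1e-5, angular_velocity=10.0, cone_angle=0.0175,
                    cone_radius=0.0175)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            cone_plate_viscosity(**base)


def synthetic_fit(eta0=1.1, iv=0.008, ratio=0.3):
    return RossMintonFit(eta0=eta0, intrinsic_viscosity=iv, crowding_ratio=ratio,
                         eta0_mode="fixed", residual_norm=0.0)


def synthetic_dataset(fit, rhos):
    return RheoDataset(
        points=[(r, float(ross_minton_eval(fit, r)), True) for r in rhos]
    )


class TestRossMintonEval:
    def test_zero_concentration_gives_buffer_viscosity(self):
        fit = synthetic_fit()
        assert ross_minton_eval(fit, 0.0) == pytest.approx(fit.eta0, rel=1e-14)

    def test_zero_crowding_is_pure_exponential(self):
        fit = synthetic_fit(ratio=0.0)
        rho = 150.0
        assert ross_minton_eval(fit, rho) == pytest.approx(
            fit.eta0 * np.exp(fit.intrinsic_viscosity * rho), rel=1e-14
        )
        assert fit.rho_max == np.inf

    def test_strictly_increasing_and_log_convex(self):
        fit = synthetic_fit()
        rho = np.linspace(0, 0.9 * fit.rho_max, 200)
        log_eta = np.log(ross_minton_eval(fit, rho))
        assert np.all(np.diff(log_eta) > 0)
        assert np.all(np.diff(log_eta, 2) > -1e-12)

    def test_singularity_rejected(self):
        fit = synthetic_fit()
        with pytest.raises(ValidationError, match="singularity"):
            ross_minton_eval(fit, fit.rho_max * 1.01)


class TestRossMintonFitting:
    def test_noiseless_round_trip_recovers_parameters(self):
        truth = synthetic_fit(eta0=1.1, iv=0.008, ratio=0.3)
        data = synthetic_dataset(truth, [40, 80, 120, 160, 200, 240])
        fit = ross_minton_fit(data)
        assert fit.eta0 == pytest.approx(truth.eta0, rel=1e-3)
        assert fit.intrinsic_viscosity == pytest.approx(truth.intrinsic_viscosity,
                                                        rel=1e-3)
        assert fit.crowding_ratio == pytest.approx(truth.crowding_ratio, rel=1e-2)
        # fitted curve reproduces the generating curve at the fit points
        np.testing.assert_allclose(
            ross_minton_eval(fit, data.rho), data.eta, rtol=1e-4
        )

    def test_fixed_eta0_mode(self):
        truth = synthetic_fit(eta0=1.0)
        data = synthetic_dataset(truth, [50, 100, 150, 200])
        fit = ross_minton_fit(data, eta0_mode="fixed", eta0_value=1.0)
        assert fit.eta0 == 1.0
        assert fit.intrinsic_viscosity == pytest.approx(0.008, rel=1e-4)

    def test_duplicate_concentrations_are_kept(self):
        data = load_mab_dataset()
        assert len(data.points) == 9
        assert sorted(r for r, _, _ in data.points).count(216) == 2
        fit = ross_minton_fit(data)  # must accept both 216 rows
        assert fit.residual_norm > 0  # scatter between duplicates is real

    def test_fewer_than_four_points_rejected(self):
        data = RheoDataset(points=[(50, 2.0, True), (100, 5.0, True),
                                   (150, 12.0, True)])
        with pytest.raises(ValidationError, match=">= 4"):
            ross_minton_fit(data)

    def test_fitted_curve_within_factor_two_of_measurements(self):
        data = load_mab_dataset()
        fit = ross_minton_fit(data)
        pred = ross_minton_eval(fit, data.rho)
        ratio = pred / data.eta
        assert np.all(ratio < 2.0) and np.all(ratio > 0.5)

    def test_invalid_modes_rejected(self):
        data = load_mab_dataset()
        with pytest.raises(ValidationError):
            ross_minton_fit(data, eta0_mode="frozen")
        with pytest.raises(ValidationError):
            ross_minton_fit(data, eta0_mode="fixed")


class TestInversion:
    def test_round_trip_identity(self):
        fit = synthetic_fit()
        for rho0 in (10.0, 100.0, 250.0):
            eta = ross_minton_eval(fit, rho0)
            assert invert_concentration(fit, eta) == pytest.approx(rho0, rel=1e-10)
            assert invert_concentration_closed_form(fit, eta) == pytest.approx(
                rho0, rel=1e-10
            )

    def test_bracketing_agrees_with_closed_form(self):
        data = load_mab_dataset()
        fit = ross_minton_fit(data)
        for eta in (5.0, 9.2, 25.0):
            assert invert_concentration(fit, eta) == pytest.approx(
                invert_concentration_closed_form(fit, eta), rel=1e-9
            )

    def test_zero_crowding_inversion_expands_bracket(self):
        fit = synthetic_fit(ratio=0.0)
        eta = ross_minton_eval(fit, 300.0)
        assert invert_concentration(fit, eta) == pytest.approx(300.0, rel=1e-9)

    def test_viscosity_below_buffer_rejected(self):
        fit = synthetic_fit()
        with pytest.raises(ValidationError, match="exceed"):
            invert_concentration(fit, fit.eta0 * 0.5)


class TestUncertaintyBand:
    def test_zero_uncertainty_collapses_onto_central_fit(self):
        data = load_mab_dataset()
        central = ross_minton_fit(data)
        lo, hi = concentration_uncertainty_band(data, 0.0)
        rho = np.linspace(10, 200, 20)
        np.testing.assert_allclose(
            ross_minton_eval(lo, rho), ross_minton_eval(central, rho), rtol=1e-6
        )
        np.testing.assert_allclose(
            ross_minton_eval(hi, rho), ross_minton_eval(central, rho), rtol=1e-6
        )

    def test_central_curve_lies_inside_band(self):
        data = load_mab_dataset()
        central = ross_minton_fit(data)
        lo, hi = concentration_uncertainty_band(data, 0.10)
        for rho in (50.0, 100.0, 150.0, 200.0):
            values = sorted(
                [float(ross_minton_eval(f, rho)) for f in (lo, hi)]
            )
            assert values[0] <= float(ross_minton_eval(central, rho)) <= values[1]

    def test_invalid_uncertainty_rejected(self):
        with pytest.raises(ValidationError):
            concentration_uncertainty_band(load_mab_dataset(), 0.6)


class TestDatasetIo:
    def test_round_trip(self, tmp_path):
        data = load_mab_dataset()
        p = tmp_path / "rheo.tsv"
        write_rheo_dataset(data, p)
        back = load_rheo_dataset(p)
        assert back.points == data.points

    def test_validation(self):
        with pytest.raises(ValidationError):
            RheoDataset(points=[(-1.0, 2.0, True)])
        with pytest.raises(ValidationError):
            RheoDataset(points=[(10.0, 0.0, True)])
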