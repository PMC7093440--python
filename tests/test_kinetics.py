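"""Input-function handling, Patlak estimation and the 2TC simulator.

The compartment simulator is cross-checked against an independent
scipy.integrate.solve_ivp oracle; Patlak recovery is checked against the
closed-form influx rate K1*k3/(k2+k3).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from atlasquant.core import DynamicImage4D, ImageGrid
from atlasquant.kinetics import (
    PlasmaInput,
    TimeActivityCurve,
    correct_to_plasma,
    dense_plasma_input,
    extract_idif,
    feng_input,
    frame_average,
    m_value,
    patlak_fit,
    simulate_tissue_curve,
    steady_state_gir,
    voxelwise_ki,
)
from atlasquant.phantom import default_frame_schedule


def constant_plasma(value=1.0, t_end=60.0, n=121):
    times = np.linspace(0.0, t_end, n)
    return PlasmaInput(TimeActivityCurve(times, np.full(n, value)))


class TestIdif:
    def _pet(self, rng, n_frames=4):
        grid = ImageGrid((4, 4, 4), (2, 2, 2))
        mids = np.arange(1.0, n_frames + 1)
        vals = rng.random((4, 4, 4, n_frames))
        return DynamicImage4D(grid, mids, np.ones(n_frames), vals)

    def test_uniform_activity_recovered_exactly(self, rng):
        pet = self._pet(rng)
        mask = np.zeros(pet.grid.shape, dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        a_t = np.array([1.0, 5.0, 3.0, 2.0])
        pet.values[mask] = a_t
        assert np.allclose(extract_idif(pet, mask).values, a_t)

    def test_single_voxel_voi(self, rng):
        pet = self._pet(rng)
        mask = np.zeros(pet.grid.shape, dtype=bool)
        mask[0, 0, 0] = True
        assert np.allclose(extract_idif(pet, mask).values, pet.values[0, 0, 0])

    def test_empty_voi_rejected(self, rng):
        pet = self._pet(rng)
        with pytest.raises(ValueError, match="empty"):
            extract_idif(pet, np.zeros(pet.grid.shape, dtype=bool))


class TestPlasmaCorrection:
    def test_unit_partition_is_identity(self):
        wb = TimeActivityCurve([1.0, 2.0], [3.0, 4.0])
        assert np.allclose(correct_to_plasma(wb, 0.45, 1.0).tac.values, wb.values)

    def test_zero_hematocrit_is_identity(self):
        wb = TimeActivityCurve([1.0, 2.0], [3.0, 4.0])
        assert np.allclose(correct_to_plasma(wb, 0.0, 0.0).tac.values, wb.values)

    def test_textbook_value(self):
        wb = TimeActivityCurve([1.0], [1.0])
        out = correct_to_plasma(wb, hematocrit=0.45, rbc_partition=0.0)
        assert out.tac.values[0] == pytest.approx(1.0 / 0.55)
        assert out.provenance == "idif_corrected"

    def test_degenerate_denominator_rejected(self):
        wb = TimeActivityCurve([1.0], [1.0])
        with pytest.raises(ValueError):
            correct_to_plasma(wb, hematocrit=0.999999, rbc_partition=-1.0)


class TestPatlakFit:
    def test_analytic_line_recovered_to_machine_precision(self):
        plasma = constant_plasma()
        t = plasma.tac.times
        tissue = TimeActivityCurve(t, 0.01 * t + 0.5)
        res = patlak_fit(tissue, plasma, t_star=5.0)
        assert res.ki == pytest.approx(0.01, abs=1e-12)
        assert res.v0 == pytest.approx(0.5, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_zero_tissue_gives_zero(self):
        plasma = constant_plasma()
        tissue = TimeActivityCurve(plasma.tac.times, np.zeros_like(plasma.tac.times))
        res = patlak_fit(tissue, plasma, t_star=5.0)
        assert res.ki == 0.0 and res.v0 == 0.0

    def test_too_few_frames_rejected(self):
        plasma = constant_plasma()
        tissue = TimeActivityCurve(plasma.tac.times, plasma.tac.times)
        with pytest.raises(ValueError, match="fewer than 2"):
            patlak_fit(tissue, plasma, t_star=59.9)

    @settings(deadline=None, max_examples=20)
    @given(c=st.floats(min_value=1e-3, max_value=1e3))
    def test_slope_invariant_to_joint_scaling(self, c):
        """Patlak Ki is a ratio of concentrations: joint scaling cancels."""
        frames = default_frame_schedule()
        plasma = dense_plasma_input(frames.ends[-1], dt=0.1)
        curve = simulate_tissue_curve(0.1, 0.15, 0.05, 0.05, plasma)
        tac = TimeActivityCurve(frames.mids, frame_average(curve, np.asarray(frames.starts), frames.ends))
        base = patlak_fit(tac, plasma, 40.0).ki
        scaled = patlak_fit(
            tac.scaled(c), PlasmaInput(plasma.tac.scaled(c)), 40.0
        ).ki
        assert scaled == pytest.approx(base, rel=1e-9)


class Test2TCSimulator:
    @pytest.mark.parametrize(
        "K1,k2,k3,Vb",
        [(0.1, 0.15, 0.05, 0.0), (0.045, 0.12, 0.036, 0.03), (0.012, 0.25, 0.065, 0.1)],
    )
    def test_matches_solve_ivp_oracle(self, K1, k2, k3, Vb):
        plasma = dense_plasma_input(30.0, dt=0.02)
        ours = simulate_tissue_curve(K1, k2, k3, Vb, plasma)

        t, cp = plasma.tac.times, plasma.tac.values

        def rhs(tt, y):
            cp_t = np.interp(tt, t, cp)
            return [K1 * cp_t - (k2 + k3) * y[0], k3 * y[0]]

        sol = solve_ivp(rhs, (0, t[-1]), [0.0, 0.0], t_eval=t, rtol=1e-9, atol=1e-12)
        oracle = sol.y[0] + sol.y[1] + Vb * cp
        scale = oracle.max()
        assert np.allclose(ours.values, oracle, atol=2e-4 * scale)

    def test_zero_delivery_gives_zero_activity(self):
        plasma = dense_plasma_input(20.0)
        curve = simulate_tissue_curve(0.0, 0.2, 0.05, 0.0, plasma)
        assert np.allclose(curve.values, 0.0)

    def test_reversible_limit_reaches_equilibrium_ratio(self):
        """With k3 = 0 the tissue/plasma ratio approaches K1/k2 + Vb."""
        K1, k2, Vb = 0.1, 0.2, 0.05
        times = np.arange(0.0, 400.0, 0.05)
        cp = np.exp(-0.002 * times) * (1 - np.exp(-2 * times))  # slow decay
        plasma = PlasmaInput(TimeActivityCurve(times, cp))
        curve = simulate_tissue_curve(K1, k2, 0.0, Vb, plasma)
        ratio = curve.values[-1] / cp[-1]
        assert ratio == pytest.approx(K1 / k2 + Vb, rel=0.02)

    def test_negative_parameters_rejected(self):
        plasma = dense_plasma_input(10.0)
        with pytest.raises(ValueError):
            simulate_tissue_curve(-0.1, 0.2, 0.05, 0.0, plasma)


class TestPatlakRecovery:
    def test_noiseless_2tc_recovers_influx_rate(self):
        """Ki = K1*k3/(k2+k3) = 0.025 recovered within 2% past the transient."""
        frames = default_frame_schedule()
        plasma = dense_plasma_input(frames.ends[-1])
        curve = simulate_tissue_curve(0.1, 0.15, 0.05, 0.05, plasma)
        tac = TimeActivityCurve(
            frames.mids, frame_average(curve, np.asarray(frames.starts), frames.ends)
        )
        res = patlak_fit(tac, plasma, t_star=40.0)
        assert res.ki == pytest.approx(0.025, rel=0.02)

    def test_bias_shrinks_with_later_t_star(self):
        """The Patlak transient decays: later windows are less biased."""
        frames = default_frame_schedule()
        plasma = dense_plasma_input(frames.ends[-1])
        true_ki = 0.03 * 0.025 / (0.18 + 0.025)
        curve = simulate_tissue_curve(0.03, 0.18, 0.025, 0.0, plasma)
        tac = TimeActivityCurve(
            frames.mids, frame_average(curve, np.asarray(frames.starts), frames.ends)
        )
        errs = [abs(patlak_fit(tac, plasma, ts).ki - true_ki) for ts in (16.0, 28.0, 40.0)]
        assert errs[0] >= errs[1] >= errs[2]

    def test_reversible_tracer_has_vanishing_slope(self):
        """k3 = 0: no irreversible trapping, fitted Ki -> 0 at late times."""
        times = np.arange(0.0, 300.0, 0.05)
        cp = np.exp(-0.002 * times) * (1 - np.exp(-2 * times))
        plasma = PlasmaInput(TimeActivityCurve(times, cp))
        curve = simulate_tissue_curve(0.1, 0.2, 0.0, 0.0, plasma)
        mids = np.arange(200.0, 300.0, 10.0)
        tac = TimeActivityCurve(mids, np.interp(mids, curve.times, curve.values))
        res = patlak_fit(tac, plasma, t_star=200.0)
        assert abs(res.ki) < 5e-5  # slope two orders below a typical Ki


class TestVoxelwiseKi:
    def test_constant_linear_tac_gives_constant_image(self):
        grid = ImageGrid((3, 3, 3), (2, 2, 2))
        plasma = constant_plasma(t_end=30.0, n=61)
        mids = np.array([10.0, 15.0, 20.0, 25.0, 30.0])
        series = 0.02 * mids + 0.3
        values = np.broadcast_to(series, (3, 3, 3, 5)).copy()
        pet = DynamicImage4D(grid, mids, np.ones(5), values)
        ki, ok = voxelwise_ki(pet, plasma, t_star=10.0)
        assert ok.all()
        assert np.allclose(ki.values, 0.02, atol=1e-12)

    def test_voi_mean_of_ki_equals_ki_of_mean_tac(self, rng):
        """OLS on shared regressors is linear: readout order cannot matter."""
        grid = ImageGrid((4, 4, 4), (2, 2, 2))
        frames = default_frame_schedule()
        plasma = dense_plasma_input(frames.ends[-1], dt=0.1)
        base = simulate_tissue_curve(0.08, 0.2, 0.04, 0.03, plasma)
        avg = frame_average(base, np.asarray(frames.starts), frames.ends)
        scales = 1.0 + 0.2 * rng.random(grid.shape)
        values = scales[..., None] * avg
        pet = DynamicImage4D(grid, frames.mids, np.asarray(frames.durations), values)
        ki, _ = voxelwise_ki(pet, plasma, t_star=16.0)
        mask = np.ones(grid.shape, dtype=bool)
        mean_tac = TimeActivityCurve(frames.mids, values.mean(axis=(0, 1, 2)))
        direct = patlak_fit(mean_tac, plasma, t_star=16.0).ki
        assert ki.values[mask].mean() == pytest.approx(direct, rel=1e-9)


class TestMValue:
    def test_textbook_value(self):
        assert m_value(560.0, 56.0) == pytest.approx(10.0)

    def test_zero_infusion(self):
        assert m_value(0.0, 70.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            m_value(100.0, 0.0)
        with pytest.raises(ValueError):
            m_value(-1.0, 70.0)

    def test_steady_state_window_ignores_early_samples(self):
        times = np.arange(0.0, 125.0, 5.0)
        rates = np.where(times < 60.0, 100.0, 300.0)
        gir = steady_state_gir(times, rates)
        assert gir == pytest.approx(300.0)
        assert gir != pytest.approx(rates.mean())

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            steady_state_gir(np.array([0.0, 10.0]), np.array([1.0, 1.0]))


def test_feng_input_starts_at_zero_and_peaks_early():
    t = np.linspace(0, 60, 6001)
    cp = feng_input(t)
    assert cp[0] == 0.0
    assert t[np.argmax(cp)] < 2.0  # bolus peak within the first pass
    assert cp[-1] > 0  # slow tail persists
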