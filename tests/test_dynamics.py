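"""Dynamics: brute-force excitation oracle, closed-form decay, fixed points."""

import numpy as np
import pytest

from directorfield import (
    DirectorField,
    KernelParams,
    ModelParams,
    build_kernel_bank,
    excitatory_input,
    global_activity,
    kernel_weight,
    run,
    steady_state_estimate,
    step,
    threshold_nonlinearity,
)
from directorfield.kernel import orientation_bin

from tests.conftest import random_field


def brute_force_excitation(f, kp, quantize_bins=None):
    """Independent oracle: per-pair double loop over source-target pairs.

    Evaluates the analytic kernel for every (source, target) pair within the
    kernel half-extent, with periodic wrapping identical to the lattice sum
    (every offset in the square support contributes once).
    """
    L = f.L
    M = kp.M
    E = np.zeros((L, L), dtype=complex)
    mag = f.magnitude
    theta_map = np.angle(f.values) / 2.0
    for r0 in range(L):
        for c0 in range(L):
            m = mag[r0, c0]
            if m == 0:
                continue
            th = theta_map[r0, c0]
            if quantize_bins is not None:
                th = orientation_bin(th, quantize_bins) * np.pi / quantize_bins
            for dr in range(-M, M + 1):
                for dc in range(-M, M + 1):
                    if dr == 0 and dc == 0:
                        continue
                    z = complex(dc, dr) * np.exp(-1j * th)
                    w = np.exp(2j * th) * kernel_weight(z, kp.sigma, kp.R_min)
                    E[(r0 + dr) % L, (c0 + dc) % L] += m * w
    return E


@pytest.fixture(scope="module")
def kp():
    return KernelParams(sigma=2.0, R_min=1.5, n_angle_bins=16)


@pytest.fixture(scope="module")
def bank(kp):
    return build_kernel_bank(kp)


class TestExcitatoryInput:
    def test_zero_field_gives_zero_excitation(self, kp, bank):
        f = DirectorField.zeros(16)
        assert not excitatory_input(f, bank).any()

    def test_single_source_reproduces_base_kernel(self, kp, bank):
        L, M = 16, kp.M
        f = DirectorField.zeros(L)
        f.values[8, 8] = 1.0  # orientation 0, magnitude 1
        E = excitatory_input(f, bank)
        base = bank.base
        for dr in range(-M, M + 1):
            for dc in range(-M, M + 1):
                assert E[8 + dr, 8 + dc] == pytest.approx(
                    base[M + dr, M + dc], abs=1e-12
                )

    def test_exact_mode_matches_brute_force(self, kp, rng):
        f = random_field(rng, L=16)
        E = excitatory_input(f, params=kp, mode="exact")
        oracle = brute_force_excitation(f, kp)
        np.testing.assert_allclose(E, oracle, rtol=1e-6, atol=1e-9)

    def test_bank_mode_matches_brute_force_at_bin_resolution(self, kp, bank, rng):
        f = random_field(rng, L=16)
        E = excitatory_input(f, bank)
        oracle = brute_force_excitation(f, kp, quantize_bins=kp.n_angle_bins)
        np.testing.assert_allclose(E, oracle, rtol=1e-6, atol=1e-9)

    def test_numpy_engine_matches_numba(self, kp, bank, rng):
        f = random_field(rng, L=16)
        a = excitatory_input(f, bank, engine="numpy")
        b = excitatory_input(f, bank, engine="numba")
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_linearity_in_source_magnitude(self, kp, bank, rng):
        f = random_field(rng, L=16)
        doubled = DirectorField(2 * f.values)
        np.testing.assert_allclose(
            excitatory_input(doubled, bank), 2 * excitatory_input(f, bank), atol=1e-12
        )


def test_threshold_nonlinearity_contract():
    zeta, eth = 0.3, 1.0
    E = np.array([[0.5, 2.0 * np.exp(1j * 0.7), 0.0]], dtype=complex)
    out = threshold_nonlinearity(E, zeta, eth)
    assert out[0, 0] == 0  # below threshold
    assert out[0, 1] == pytest.approx(0.3 * np.exp(1j * 0.7))  # saturated at zeta
    assert out[0, 2] == 0  # degenerate input, no division blowup
    mags = np.abs(out)
    assert set(np.round(mags.ravel(), 12)) <= {0.0, 0.3}


def test_global_activity_hand_sum():
    f = DirectorField.zeros(8)
    f.values[1, 1] = 0.2 * np.exp(1j * 0.3)
    f.values[5, 2] = 0.3
    assert global_activity(f) == pytest.approx(0.5)
    # phase rotation leaves activity unchanged
    g = DirectorField(f.values * np.exp(1j * 1.1))
    assert global_activity(g) == pytest.approx(0.5)


def test_disc_inhibition_scope_sums_neighbourhood():
    f = DirectorField.zeros(16)
    f.values[4, 4] = 1.0
    f.values[4, 8] = 1.0
    A = global_activity(f, radius=3.0)
    assert A[4, 4] == pytest.approx(1.0)  # only itself within 3 sites
    assert A[4, 6] == pytest.approx(2.0)  # both sources within 3


class TestStep:
    def params(self, kp, **kw):
        defaults = dict(kernel=kp, zeta=0.3, E_th=1.0, g1=0.1, g2=0.01, dt=1.0)
        defaults.update(kw)
        return ModelParams(**defaults)

    def test_zero_field_is_fixed_point(self, kp, bank):
        f = DirectorField.zeros(16)
        g = step(f, self.params(kp), bank)
        assert not g.values.any()

    def test_isolated_subthreshold_site_decays_exponentially(self, kp, bank):
        params = self.params(kp, E_th=100.0, g2=0.0)
        f = DirectorField.zeros(16)
        f.values[5, 5] = 0.8 * np.exp(2j * 0.4)
        g = step(f, params, bank)
        assert g.values[5, 5] == pytest.approx(
            f.values[5, 5] * np.exp(-params.g1 * params.dt), rel=1e-12
        )

    def test_magnitude_growth_bound(self, kp, bank, rng):
        """No site can gain more than dt*zeta before decay."""
        params = self.params(kp)
        f = random_field(rng, L=16)
        g = step(f, params, bank)
        bound = (f.magnitude + params.dt * params.zeta) * np.exp(
            -params.dt * params.g1
        )
        assert (g.magnitude <= bound + 1e-12).all()

    def test_rotation_equivariance_quarter_turn(self, kp, rng):
        """Rotating the stimulus by 90 degrees rotates the whole trajectory."""
        params = self.params(kp)
        f = random_field(rng, L=16)
        # rotate the lattice: (r, c) -> (c, L-1-r) and orientations + pi/2
        rot_values = np.rot90(f.values, k=-1) * np.exp(1j * np.pi)
        # director phase adds 2 * (pi/2) = pi under a quarter turn
        f_rot = DirectorField(rot_values)
        t1 = run(f, params, 3, mode="exact")
        t2 = run(f_rot, params, 3, mode="exact")
        for (s1, a), (s2, b) in zip(t1, t2):
            expected = np.rot90(a.values, k=-1) * np.exp(1j * np.pi)
            np.testing.assert_allclose(b.values, expected, atol=1e-9)


class TestRun:
    def test_zero_steps_returns_initial_only(self, kp, bank, rng):
        f = random_field(rng, L=16)
        traj = run(f, ModelParams(kp, 0.3, 1.0, 0.1, 0.01), 0, bank=bank)
        assert traj.steps == [0]
        np.testing.assert_array_equal(traj.fields[0].values, f.values)

    def test_recording_grid_and_final_step(self, kp, bank):
        f = DirectorField.zeros(8)
        traj = run(f, ModelParams(kp, 0.3, 1.0, 0.1, 0.01), 25, 10, bank=bank)
        assert traj.steps == [0, 10, 20, 25]

    def test_determinism(self, kp, bank, rng):
        f = random_field(rng, L=16)
        params = ModelParams(kp, 0.3, 1.0, 0.1, 0.01)
        t1 = run(f, params, 5, bank=bank)
        t2 = run(f, params, 5, bank=bank)
        for (_, a), (_, b) in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)


class TestSteadyState:
    def test_closed_form_with_no_global_inhibition(self):
        kp = KernelParams(sigma=2.0, R_min=1.0)
        params = ModelParams(kp, zeta=1.0, E_th=1.0, g1=1.0, g2=0.0, dt=1.0)
        expected = np.exp(-1) / (1 - np.exp(-1))
        assert steady_state_estimate(params, 10) == pytest.approx(expected, rel=1e-9)

    def test_continuum_limit_is_zeta_over_g1(self):
        kp = KernelParams(sigma=2.0, R_min=1.0)
        params = ModelParams(kp, zeta=0.5, E_th=1.0, g1=0.25, g2=0.0, dt=1e-4)
        assert steady_state_estimate(params, 10) == pytest.approx(2.0, rel=1e-3)

    def test_fixed_point_matches_single_site_iteration(self):
        """Oracle: iterate the one-site map m <- (m + dt z) e^{-dt(g1+g2 n m)}."""
        kp = KernelParams(sigma=2.0, R_min=1.0)
        params = ModelParams(kp, zeta=0.3, E_th=1.0, g1=0.05, g2=0.002, dt=1.0)
        n = 50
        m = 1.0
        for _ in range(5000):
            m = (m + params.dt * params.zeta) * np.exp(
                -params.dt * (params.g1 + params.g2 * n * m)
            )
        assert steady_state_estimate(params, n) == pytest.approx(m, rel=1e-6)

    def test_driven_site_converges_to_estimate(self):
        """A lattice site held above threshold approaches m* within 1%."""
        kp = KernelParams(sigma=2.0, R_min=1.0, half_width=2)
        params = ModelParams(kp, zeta=0.3, E_th=1e-9, g1=0.1, g2=0.0, dt=1.0)
        # E_th ~ 0: a pair of adjacent collinear sites keeps exciting itself
        f = DirectorField.zeros(8)
        f.values[4, 4] = 1.0
        f.values[4, 5] = 1.0
        traj = run(f, params, 300, 300)
        mstar = steady_state_estimate(params, 1)
        assert traj.final.magnitude[4, 4] == pytest.approx(mstar, rel=0.01)

    def test_unsustainable_parameters_flagged(self):
        kp = KernelParams(sigma=2.0, R_min=1.0)
        params = ModelParams(kp, zeta=0.3, E_th=1.0, g1=0.0, g2=0.0)
        with pytest.raises(ValueError):
            steady_state_estimate(params, 10)


def test_bimodal_asymptotic_magnitudes():
    """Long runs push magnitudes toward 0 or the sustained level."""
    kp = KernelParams(sigma=3.0, R_min=1.0, n_angle_bins=16)
    bank = build_kernel_bank(kp)
    # a long straight line sustains itself; two isolated dots decay
    f = DirectorField.zeros(32)
    f.values[16, 4:28] = 1.0
    f.values[4, 4] = 1.0
    f.values[26, 30] = 1.0
    params = ModelParams(kp, zeta=0.2, E_th=2.0, g1=0.05, g2=0.05 / 24)
    traj = run(f, params, 120, 120, bank=bank)
    mag = traj.final.magnitude
    line = mag[16, 8:24]
    assert line.min() > 0.5, "line interior should sustain high magnitude"
    assert mag[4, 4] < 0.01 and mag[26, 30] < 0.01, "isolated dots should decay"
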