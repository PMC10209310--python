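"""Photon transport: samplers, kinematics, scoring, conservation, statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minikv import (
    DoseGrid,
    PointSource,
    TransportConfig,
    applicator_scene,
    bare_probe_scene,
    compton_energy,
    compton_scatter,
    estimate_uncertainty,
    run,
    sample_free_path,
    sample_interaction,
    water_scene,
)
from minikv.physics import PhysicsData, default_physics
from minikv.transport import ShellTally, rotate_direction

PHYS = default_physics()


class _FixedRng:
    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestFreePath:
    def test_closed_form_at_u_e_minus_one(self):
        # U = e^-1  ->  s = -ln(U)/mu = 1/mu exactly
        assert sample_free_path(2.5, _FixedRng(math.exp(-1))) == pytest.approx(
            1 / 2.5, rel=1e-12
        )

    def test_sample_mean_is_inverse_mu(self, rng):
        mu = 0.8
        n = 200_000
        s = np.array([sample_free_path(mu, rng) for _ in range(n)])
        se = (1 / mu) / math.sqrt(n)  # exponential: sd = mean
        assert abs(s.mean() - 1 / mu) < 3 * se

    def test_nonpositive_mu_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_free_path(0.0, rng)
        with pytest.raises(ValueError):
            sample_free_path(-1.0, rng)


class TestInteractionSampling:
    def test_branch_fractions_match_coefficients(self, rng):
        e = 30.0
        pe, inc, _ = PHYS.mu_components("water", e)
        n = 100_000
        draws = [sample_interaction("water", e, PHYS, rng, ("pe", "incoh"))
                 for _ in range(n)]
        frac_pe = draws.count("pe") / n
        p = pe / (pe + inc)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(frac_pe - p) < 3 * se

    def test_disabled_branch_never_drawn(self, rng):
        draws = {sample_interaction("water", 30.0, PHYS, rng, ("pe", "incoh"))
                 for _ in range(2000)}
        assert "coh" not in draws

    def test_degenerate_single_branch(self, rng):
        draws = {sample_interaction("Au", 40.0, PHYS, rng, ("pe",))
                 for _ in range(100)}
        assert draws == {"pe"}


class TestComptonKinematics:
    def test_forward_scatter_deposits_nothing(self):
        assert compton_energy(50.0, 0.0) == pytest.approx(50.0, rel=1e-12)

    def test_backscatter_formula_by_hand(self):
        # E' = 50 / (1 + 2*50/511) = 41.8167 keV
        assert compton_energy(50.0, math.pi) == pytest.approx(41.8167, abs=1e-3)

    def test_kinematic_bounds_over_samples(self, rng):
        for e in (5.0, 30.0, 150.0):
            for _ in range(300):
                e_out, theta, e_dep = compton_scatter(e, rng)
                assert 0.0 < e_out <= e
                assert e_dep == pytest.approx(e - e_out, rel=1e-12)
                assert 0.0 <= theta <= math.pi

    def test_rotation_preserves_unit_norm(self, rng):
        u = np.array([0.3, -0.5, math.sqrt(1 - 0.09 - 0.25)])
        for _ in range(200):
            mu = rng.uniform(-1, 1)
            phi = rng.uniform(0, 2 * math.pi)
            v = rotate_direction(*u, mu, phi)
            assert np.hypot(np.hypot(v[0], v[1]), v[2]) == pytest.approx(1.0, abs=1e-9)
            assert np.dot(u, v) == pytest.approx(mu, abs=1e-9)


class TestEnergyConservation:
    def test_entered_equals_deposited_plus_escaped(self, small_probe_sim):
        phsp, _ = small_probe_sim
        grid = DoseGrid.from_extents((-1, 1), (-1, 1), (0.2, 2.2))
        cfg = TransportConfig(scoring="collision", n_batches=2)
        res = run(phsp.records[:4000], applicator_scene(2.5), cfg, seed=3,
                  grid=grid)
        b = res.balance
        assert b.entered > 0
        assert abs(b.entered - b.deposited - b.escaped) < 1e-6 * b.entered

    def test_conservation_holds_in_tracklength_mode(self, small_probe_sim):
        phsp, _ = small_probe_sim
        cfg = TransportConfig(scoring="tracklength", n_batches=2)
        grid = DoseGrid.from_extents((-1, 1), (-1, 1), (0.2, 2.2))
        res = run(phsp.records[:3000], bare_probe_scene(), cfg, seed=4, grid=grid)
        b = res.balance
        assert abs(b.entered - b.deposited - b.escaped) < 1e-6 * b.entered

    def test_vacuum_limit_all_photons_escape(self, small_probe_sim):
        phsp, _ = small_probe_sim
        ghost = PhysicsData(mu_scale=0.0)
        grid = DoseGrid.from_extents((-1, 1), (-1, 1), (0.2, 2.2))
        cfg = TransportConfig(scoring="collision", n_batches=2)
        res = run(phsp.records[:2000], water_scene(), cfg, seed=5, grid=grid,
                  physics=ghost)
        assert res.balance.deposited == 0.0
        assert res.balance.escaped == pytest.approx(res.balance.entered, rel=1e-12)
        assert np.all(res.grid.dose == 0.0)


class TestPrimaryKermaClosedForm:
    def test_pe_only_point_source_matches_exp_mu_r_over_r2(self):
        """Photoelectric-only transport of an isotropic point source must
        reproduce the exp(-mu_pe r)/r^2 primary-kerma form (chi^2 within
        batch uncertainty)."""
        e0 = 30.0
        mu_pe = PHYS.mu_linear("water", e0, "pe")
        cfg = TransportConfig(interactions=("pe",), scoring="collision",
                              n_batches=10)
        grid = DoseGrid.from_extents((-0.2, 0.2), (-0.2, 0.2), (0.4, 2.4),
                                     voxel_cm=(0.4, 0.4, 0.2))
        src = PointSource((0.0, 0.0, 0.0), e0, n_histories=150_000)
        res = run(src, water_scene(), cfg, seed=8, grid=grid)
        z = grid.centers(2)
        d = grid.dose[0, 0, :]
        sig = res.grid.rel_unc[0, 0, :] * d
        flat = d * z**2 * np.exp(mu_pe * z)
        sig_flat = sig * z**2 * np.exp(mu_pe * z)
        w = 1.0 / sig_flat**2
        mean = np.sum(w * flat) / np.sum(w)
        chi2 = float(np.sum(((flat - mean) / sig_flat) ** 2))
        dof = len(flat) - 1
        assert chi2 < dof + 4 * math.sqrt(2 * dof)


class TestUncertainty:
    def test_hand_arithmetic_three_batches(self):
        batches = np.array([1.0, 2.0, 3.0]).reshape(3, 1)
        rel = estimate_uncertainty(batches, k=1.0)
        assert rel[0] == pytest.approx((1 / math.sqrt(3)) / 2.0, rel=1e-12)

    def test_coverage_scaling_and_zero_variance(self):
        batches = np.array([[2.0, 1.0], [2.0, 3.0], [2.0, 2.0]])
        r1 = estimate_uncertainty(batches, k=1.0)
        r3 = estimate_uncertainty(batches, k=3.0)
        assert r1[0] == 0.0
        assert r3[1] == pytest.approx(3 * r1[1], rel=1e-12)

    def test_zero_dose_voxels_flagged_not_divided(self):
        batches = np.zeros((4, 2))
        batches[:, 1] = [1, 2, 1, 2]
        rel = estimate_uncertainty(batches)
        assert np.isnan(rel[0]) and np.isfinite(rel[1])

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            estimate_uncertainty(np.ones((1, 3)))

    def test_uncertainty_scales_inverse_sqrt_histories(self):
        cfg = TransportConfig(scoring="collision", n_batches=10)
        grid_a = DoseGrid.from_extents((-1, 1), (-1, 1), (0.3, 2.3),
                                       voxel_cm=(0.4, 0.4, 0.2))
        grid_b = DoseGrid.from_extents((-1, 1), (-1, 1), (0.3, 2.3),
                                       voxel_cm=(0.4, 0.4, 0.2))
        src_a = PointSource((0, 0, 0), 30.0, n_histories=30_000)
        src_b = PointSource((0, 0, 0), 30.0, n_histories=60_000)
        ra = run(src_a, water_scene(), cfg, seed=21, grid=grid_a)
        rb = run(src_b, water_scene(), cfg, seed=22, grid=grid_b)
        med_a = np.nanmedian(ra.grid.rel_unc)
        med_b = np.nanmedian(rb.grid.rel_unc)
        assert med_b / med_a == pytest.approx(1 / math.sqrt(2), rel=0.25)


class TestDoseGridIO:
    def test_3ddose_round_trip(self, tmp_path):
        grid = DoseGrid.from_extents((-0.5, 0.5), (-0.3, 0.3), (0.0, 1.0))
        rng = np.random.default_rng(2)
        grid.dose = rng.random(grid.shape)
        grid.rel_unc = 0.1 * rng.random(grid.shape)
        path = tmp_path / "run.3ddose"
        grid.write_3ddose(path)
        back = DoseGrid.read_3ddose(path)
        assert back.shape == grid.shape
        assert np.allclose(back.dose, grid.dose, rtol=1e-7)
        assert np.allclose(back.rel_unc, grid.rel_unc, atol=1e-5)
        assert np.allclose(back.edges(2), grid.edges(2), atol=1e-6)

    def test_track_scoring_matches_brute_force(self, rng):
        grid = DoseGrid((0, 0, 0), (0.1, 0.1, 0.1), (10, 10, 10))
        arr = np.zeros(grid.shape)
        p0, p1 = (0.05, 0.08, 0.02), (0.93, 0.71, 0.88)
        grid.score_track(arr, p0, p1, 1.0)
        # brute force: fine sub-sampling of the segment
        ref = np.zeros(grid.shape)
        n = 200_000
        t = (np.arange(n) + 0.5) / n
        pts = np.outer(1 - t, p0) + np.outer(t, p1)
        ds = math.dist(p0, p1) / n
        for x, y, z in pts[:: n // 20000]:
            idx = grid.voxel_index(x, y, z)
            ref[idx] += ds * (n // 20000)
        assert arr.sum() == pytest.approx(math.dist(p0, p1), rel=1e-6)
        assert np.allclose(arr, ref, atol=2e-3)


class TestShellTally:
    def test_uniform_track_through_cone(self):
        tally = ShellTally(np.arange(0.5, 2.5, 0.5), cone_half_angle_deg=90.0)
        arr = tally.new_array()
        # a radial track along +z crosses every shell with ds = width
        tally.score(arr, (0, 0, 0.5), (0, 0, 2.0), 1.0)
        assert np.allclose(arr, 0.5, atol=0.02)

    def test_outside_cone_not_scored(self):
        tally = ShellTally(np.arange(0.5, 2.5, 0.5), cone_half_angle_deg=20.0)
        arr = tally.new_array()
        tally.score(arr, (0.5, 0, 0.0), (2.0, 0, 0.0), 1.0)  # equatorial ray
        assert arr.sum() == 0.0


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            TransportConfig(cutoff_kev=0.5)
        with pytest.raises(ValueError):
            TransportConfig(n_batches=1)
        with pytest.raises(ValueError):
            TransportConfig(scoring="magic")
        with pytest.raises(ValueError):
            TransportConfig(interactions=("pe", "banana"))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(e=st.floats(min_value=1.0, max_value=200.0),
       theta=st.floats(min_value=0.0, max_value=math.pi))
def test_compton_energy_bounds(e, theta):
    e_out = compton_energy(e, theta)
    assert 0 < e_out <= e
    assert e_out >= e / (1 + 2 * e / 511.0) - 1e-12
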