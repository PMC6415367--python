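"""Synthetic trajectory generator: kinetics, geometry and determinism."""

import numpy as np
import pytest
from scipy import stats

import gagnet as g
from gagnet.dynamics import track_bonds
from gagnet.synthetic_data import (
    BondSiteSpec,
    KineticsSpec,
    SyntheticTrajectory,
    generate_trajectory,
    simulate_two_state,
    write_trajectory,
)

from conftest import narrow_sites


def _dwell_lengths(states):
    """ON-run lengths (frames) per column, completed runs only."""
    out = []
    for col in states.T:
        x = np.concatenate(([0], col.astype(int), [0]))
        starts = np.flatnonzero(np.diff(x) == 1)
        ends = np.flatnonzero(np.diff(x) == -1)
        # drop censored runs touching either boundary
        for s, e in zip(starts, ends):
            if s > 0 and e < len(col):
                out.append(e - s)
    return np.asarray(out)


class TestKinetics:
    def test_arrhenius_off_rate_increases_with_temperature(self):
        kin = KineticsSpec(k_off_ref=1.0, t_ref=310.0, activation_energy=50.0)
        assert kin.k_off(300.0) < kin.k_off(310.0) < kin.k_off(320.0)
        assert kin.k_off(310.0) == pytest.approx(1.0)

    def test_zero_activation_energy_means_no_temperature_dependence(self):
        kin = KineticsSpec(activation_energy=0.0)
        assert kin.k_off(300.0) == pytest.approx(kin.k_off(320.0))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            KineticsSpec(k_on=0.0)
        with pytest.raises(ValueError):
            KineticsSpec(temperatures=(200.0,))
        with pytest.raises(ValueError):
            BondSiteSpec("O2H", "O8", "intra-HA", bounds=(0.5, 2.5))
        with pytest.raises(ValueError):
            BondSiteSpec("O2H", "O8", "nowhere")

    def test_dwell_times_are_exponential(self):
        """ON dwell times follow Exponential(1/k_off): KS test at alpha=0.01."""
        k_off, dt_ns = 0.5, 0.01
        p_off = 1.0 - np.exp(-k_off * dt_ns)
        p_on = 1.0 - np.exp(-2.0 * dt_ns)
        rng = np.random.default_rng(1234)
        states = simulate_two_state(30000, np.full(30, p_on), np.full(30, p_off), rng)
        dwells = _dwell_lengths(states) * dt_ns
        assert len(dwells) >= 2000
        res = stats.kstest(dwells, "expon", args=(0, 1.0 / k_off))
        assert res.pvalue > 0.01

    def test_mean_dwell_matches_closed_form_and_orders_with_temperature(self):
        """Hotter runs break bonds faster; each mean matches 1/k_off(T)
        within three standard errors."""
        kin = KineticsSpec(k_on=2.0, k_off_ref=2.0, activation_energy=50.0)
        dt_ns = 0.01
        means = {}
        for temperature in (300.0, 320.0):
            k_off = kin.k_off(temperature)
            p_off = 1.0 - np.exp(-k_off * dt_ns)
            p_on = 1.0 - np.exp(-kin.k_on * dt_ns)
            rng = np.random.default_rng(77)
            states = simulate_two_state(5000, np.full(10, p_on), np.full(10, p_off), rng)
            dwells = _dwell_lengths(states) * dt_ns
            expected = 1.0 / k_off
            se = dwells.std(ddof=1) / np.sqrt(len(dwells))
            assert abs(dwells.mean() - expected) < 3 * se + dt_ns
            means[temperature] = dwells.mean()
        assert means[320.0] < means[300.0]


class TestGeneration:
    def test_identical_seeds_reproduce_bit_for_bit(self, small_system):
        sites = narrow_sites([("O2H", "O8", "intra-HA")])
        a = generate_trajectory(small_system, sites, KineticsSpec(), 310.0,
                                n_frames=30, seed=9)
        b = generate_trajectory(small_system, sites, KineticsSpec(), 310.0,
                                n_frames=30, seed=9)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.ground_truth, b.ground_truth)
        c = generate_trajectory(small_system, sites, KineticsSpec(), 310.0,
                                n_frames=30, seed=10)
        assert not np.array_equal(a.coords, c.coords)

    def test_vanishing_off_rate_keeps_the_bond_on_for_good(self, small_system):
        sites = narrow_sites([("O2H", "O8", "intra-HA")])
        kin = KineticsSpec(k_on=100.0, k_off_ref=1e-12)
        traj = generate_trajectory(small_system, sites, kin, 310.0,
                                   n_frames=100, seed=2)
        assert traj.ground_truth.all()
        obs = g.detect_trajectory(traj.coords, small_system)
        events = track_bonds(obs, traj.frame_spacing, n_frames=100)
        assert len(events) == 1
        assert events.loc[0, "n_frames"] == 100
        assert events.loc[0, "duration_ns"] == pytest.approx(1.0)  # 100 × 10 ps

    def test_vanishing_on_rate_yields_no_bonds(self, small_system):
        sites = narrow_sites([("O2H", "O8", "intra-HA")])
        kin = KineticsSpec(k_on=1e-12, k_off_ref=10.0)
        traj = generate_trajectory(small_system, sites, kin, 310.0,
                                   n_frames=100, seed=3)
        assert not traj.ground_truth.any()
        obs = g.detect_trajectory(traj.coords, small_system)
        assert len(obs) == 0

    def test_planted_on_lengths_respect_hard_truncation(self, small_system):
        sites = [BondSiteSpec("O2H", "O8", "intra-HA")]  # default law on [1.5, 2.5]
        traj = generate_trajectory(small_system, sites, KineticsSpec(), 310.0,
                                   n_frames=400, seed=8)
        d, h, a = traj.site_atoms[0]
        on = np.flatnonzero(traj.ground_truth[:, 0])
        assert len(on) > 50
        dists = np.linalg.norm(traj.coords[on, h] - traj.coords[on, a], axis=1)
        assert dists.min() >= 1.5
        assert dists.max() <= 2.5
        off = np.flatnonzero(~traj.ground_truth[:, 0])
        far = np.linalg.norm(traj.coords[off, h] - traj.coords[off, a], axis=1)
        assert far.min() > 3.5

    def test_zero_sites_is_a_valid_trivial_trajectory(self, small_system):
        traj = generate_trajectory(small_system, [], KineticsSpec(), 310.0,
                                   n_frames=5, seed=1)
        assert traj.ground_truth.shape == (5, 0)
        assert len(g.detect_trajectory(traj.coords, small_system)) == 0

    def test_unlisted_temperature_warns_but_proceeds(self, small_system):
        with pytest.warns(UserWarning, match="temperature"):
            generate_trajectory(small_system, [], KineticsSpec(), 305.0,
                                n_frames=3, seed=1)

    def test_too_few_frames_rejected(self, small_system):
        with pytest.raises(ValueError):
            generate_trajectory(small_system, [], KineticsSpec(), 310.0,
                                n_frames=1, seed=1)

    def test_empty_trajectory_cannot_be_written(self, small_system, tmp_path):
        traj = SyntheticTrajectory(
            system=small_system,
            coords=np.empty((0, small_system.n_atoms, 3)),
            frame_spacing=10.0, temperature=310.0, sites=[], site_atoms=[],
            ground_truth=np.zeros((0, 0), dtype=bool), seed=0,
        )
        with pytest.raises(ValueError, match="empty"):
            write_trajectory(traj, tmp_path / "x.pdb")
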