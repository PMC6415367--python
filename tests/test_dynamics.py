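"""Bond tracking, duration/length distributions, energy time series."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

import gagnet as g
from gagnet.dynamics import (
    duration_distribution,
    energy_timeseries,
    length_distribution,
    track_bonds,
)

from conftest import make_observations


class TestTrackBonds:
    def test_uninterrupted_presence_is_one_event(self):
        obs = make_observations([(t, 1, 2) for t in range(100)])
        events = track_bonds(obs, frame_spacing=10.0, n_frames=100)
        assert len(events) == 1
        assert events.loc[0, "duration_ns"] == pytest.approx(1.0)

    def test_gap_splits_event_without_tolerance(self):
        obs = make_observations([(t, 1, 2) for t in (0, 1, 2, 5, 6)])
        events = track_bonds(obs, 10.0, gap_tolerance=0, n_frames=10)
        assert list(events["n_frames"]) == [3, 2]

    def test_gap_tolerance_merges_across_short_absences(self):
        obs = make_observations([(t, 1, 2) for t in (0, 1, 2, 5, 6)])
        events = track_bonds(obs, 10.0, gap_tolerance=2, n_frames=10)
        assert len(events) == 1
        assert (events.loc[0, "start_frame"], events.loc[0, "end_frame"]) == (0, 6)
        assert events.loc[0, "n_frames"] == 7

    def test_identity_is_donor_acceptor_pair(self):
        rows = [(0, 1, 2), (1, 1, 2), (0, 1, 3)]
        events = track_bonds(make_observations(rows), 10.0, n_frames=5)
        assert len(events) == 2
        assert set(zip(events.donor, events.acceptor)) == {(1, 2), (1, 3)}

    def test_unsorted_frames_rejected(self):
        obs = make_observations([(5, 1, 2), (0, 1, 2)])
        obs = obs.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            track_bonds(obs, 10.0)

    def test_durations_conserve_presence_frames(self):
        """With zero gap tolerance the event durations of an identity sum to
        exactly its number of present frames."""
        rng = np.random.default_rng(31)
        present = np.flatnonzero(rng.random(400) < 0.4)
        obs = make_observations([(int(t), 1, 2) for t in present])
        events = track_bonds(obs, 10.0, n_frames=400)
        assert events["n_frames"].sum() == len(present)
        assert events["duration_ns"].sum() == pytest.approx(len(present) * 0.01)

    def test_rechunked_input_gives_identical_events(self):
        rng = np.random.default_rng(7)
        rows = [(int(t), 1, 2) for t in np.flatnonzero(rng.random(100) < 0.5)]
        rows += [(int(t), 3, 4) for t in np.flatnonzero(rng.random(100) < 0.3)]
        obs = make_observations(rows)
        chunks = [obs[obs.frame == t] for t in range(100)]
        rechunked = pd.concat(chunks, ignore_index=True)
        pd.testing.assert_frame_equal(
            track_bonds(obs, 10.0, n_frames=100),
            track_bonds(rechunked, 10.0, n_frames=100),
        )

    def test_censoring_flags_touching_events(self):
        obs = make_observations([(t, 1, 2) for t in (0, 1)] +
                                [(t, 3, 4) for t in (4, 5)] +
                                [(t, 5, 6) for t in (8, 9)])
        events = track_bonds(obs, 10.0, n_frames=10)
        flags = dict(zip(zip(events.donor, events.acceptor), events.censored))
        assert flags[(1, 2)] and flags[(5, 6)]
        assert not flags[(3, 4)]


class TestDurationDistribution:
    def test_single_event_cdf(self):
        events = track_bonds(make_observations([(t, 1, 2) for t in range(100)]),
                             10.0, n_frames=200)
        dist = duration_distribution(events)
        assert dist.cdf(2.0) == 1.0
        assert dist.cdf(0.5) == 0.0

    def test_exponential_durations_recover_closed_form_cdf(self):
        """Events planted from Exponential(mean 1 ns): the empirical CDF at
        2 ns sits within 3 standard errors of 1 − e⁻²."""
        rng = np.random.default_rng(99)
        n = 4000
        durations = rng.exponential(1.0, size=n)
        events = pd.DataFrame({
            "donor": np.arange(n), "acceptor": np.arange(n) + n,
            "category": "intra-HA", "donor_class": "O2H", "acceptor_class": "O8",
            "start_frame": 0, "end_frame": 1, "n_frames": 1,
            "duration_ns": durations, "mean_energy": 10.0, "mean_length": 1.8,
            "censored": False,
        })
        p = 1.0 - np.exp(-2.0)
        se = np.sqrt(p * (1 - p) / n)
        assert duration_distribution(events).cdf(2.0) == pytest.approx(p, abs=3 * se)

    def test_category_filter_and_empty_warning(self):
        events = track_bonds(make_observations([(0, 1, 2)]), 10.0, n_frames=5)
        with pytest.warns(UserWarning, match="no events"):
            dist = duration_distribution(events, category="inter")
        assert dist.n == 0


class TestLengthDistribution:
    def test_recovers_planted_truncated_normal(self):
        """10⁴ lengths from truncnorm(1.77, 0.28) on [1.5, 2.5]: the Gaussian
        fit to the histogram recovers the mean within 0.02 Å with R² ≥ 0.9."""
        mean, sd, lo, hi = 1.77, 0.28, 1.5, 2.5
        rng = np.random.default_rng(2024)
        samples = truncnorm.rvs((lo - mean) / sd, (hi - mean) / sd, loc=mean,
                                scale=sd, size=10_000, random_state=rng)
        obs = pd.DataFrame({"dist_ha": samples, "category": "intra-HA"})
        dist = length_distribution(obs)
        assert dist.fit is not None
        assert dist.fit.mean == pytest.approx(mean, abs=0.02)
        assert dist.fit.r_squared >= 0.9

    def test_degenerate_sample_skips_fit(self):
        obs = pd.DataFrame({"dist_ha": np.full(100, 1.8), "category": "intra-HA"})
        with pytest.warns(UserWarning, match="degenerate|too few"):
            dist = length_distribution(obs)
        assert dist.fit is None
        assert np.count_nonzero(dist.counts) == 1

    def test_small_sample_skips_fit(self):
        obs = pd.DataFrame({"dist_ha": np.linspace(1.6, 2.0, 10),
                            "category": "intra-HA"})
        with pytest.warns(UserWarning):
            assert length_distribution(obs).fit is None

    def test_empty_filter_warns(self):
        obs = pd.DataFrame({"dist_ha": [1.8], "category": ["intra-HA"]})
        with pytest.warns(UserWarning, match="no observations"):
            dist = length_distribution(obs, category="inter")
        assert dist.n == 0


class TestEnergyTimeseries:
    def test_single_bond_frame(self):
        obs = make_observations([(0, 1, 2, 10.0)])
        ts = energy_timeseries(obs, n_frames=2)
        assert ts.loc[0, "total"] == pytest.approx(10.0)
        assert ts.loc[0, "intra_HA"] == pytest.approx(10.0)
        assert ts.loc[0, "intra_CS"] == 0.0 and ts.loc[0, "inter"] == 0.0
        assert ts.loc[1, "total"] == 0.0

    def test_total_is_exact_category_sum(self, small_obs):
        n_frames = int(small_obs["frame"].max()) + 1
        ts = energy_timeseries(small_obs, n_frames)
        assert np.array_equal(
            ts["total"].to_numpy(),
            (ts["intra_HA"] + ts["intra_CS"] + ts["inter"]).to_numpy(),
        )

    def test_rate_switch_shows_in_running_mean(self, small_system):
        """A kinetics change mid-run moves the running mean of the total
        energy — the analysis resolves non-equilibrium segments."""
        from conftest import narrow_sites
        from gagnet.synthetic_data import KineticsSpec, generate_trajectory

        sites = narrow_sites([("O2H", "O8", "intra-HA"),
                              ("O3H", "OAC", "intra-HA"),
                              ("O4H", "O5", "intra-HA")])
        fast_off = KineticsSpec(k_on=0.5, k_off_ref=50.0)
        slow_off = KineticsSpec(k_on=50.0, k_off_ref=0.5)
        a = generate_trajectory(small_system, sites, fast_off, 310.0,
                                n_frames=200, seed=4)
        b = generate_trajectory(small_system, sites, slow_off, 310.0,
                                n_frames=200, seed=4)
        coords = np.concatenate([a.coords, b.coords])
        ts = energy_timeseries(g.detect_trajectory(coords, small_system), 400)
        early = ts["total"][:200].mean()
        late = ts["total"][200:].mean()
        assert late > 2 * early
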