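"""Detect hydrogen bonds in a synthetic trajectory and track lifetimes.

Builds a small HA + CS system, plants three bond sites with two-state
(on/off) kinetics, detects bonds frame by frame and merges them into
lifetime events.  The mean event duration estimates 1/k_off of the
planted kinetics; the duration CDF answers questions like "what fraction
of bonds lasted at most 2 ns".
"""

import gagnet as g
from gagnet.dynamics import duration_distribution, track_bonds
from gagnet.synthetic_data import BondSiteSpec, KineticsSpec, generate_trajectory

system = g.build_system(n_ha_repeats=4, n_cs_chains=1, n_cs_repeats=3)
sites = [
    BondSiteSpec("O2H", "O8", "intra-HA", mean_length=1.75, sd_length=0.08,
                 bounds=(1.55, 1.95)),
    BondSiteSpec("NH", "O5", "intra-CS", mean_length=1.75, sd_length=0.08,
                 bounds=(1.55, 1.95)),
    BondSiteSpec("O3H", "SO4", "inter", mean_length=1.75, sd_length=0.08,
                 bounds=(1.55, 1.95)),
]
kinetics = KineticsSpec(k_on=2.0, k_off_ref=1.0)  # rates per ns, T_ref 310 K

traj = generate_trajectory(system, sites, kinetics, temperature=310.0,
                           n_frames=5000, frame_spacing=10.0, seed=42)
obs = g.detect_trajectory(traj.coords, system)
events = track_bonds(obs, frame_spacing=10.0, n_frames=traj.n_frames)

print(f"{traj.n_frames} frames ({traj.n_frames * 10 / 1000:.0f} ns), "
      f"{len(obs)} bond observations, {len(events)} events")
print("observations by category:",
      obs["category"].value_counts().to_dict())

completed = events[~events["censored"]]
dist = duration_distribution(events, include_censored=False)
print(f"mean duration over {len(completed)} completed events: "
      f"{completed['duration_ns'].mean():.3f} ns "
      f"(planted 1/k_off = {1 / kinetics.k_off(310.0):.3f} ns; "
      f"relative sampling error ~{1 / len(completed) ** 0.5:.0%})")
print(f"fraction of bonds lasting at most 2 ns: {dist.cdf(2.0):.2f}")
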