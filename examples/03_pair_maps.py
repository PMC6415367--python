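"""Site-class pair maps: which functional groups bond with which.

Aggregates bond observations over the 11 donor/acceptor classes per
molecule.  The intramolecular pair space has 66 unordered class pairs,
the HA–CS one 121 ordered pairs; cells never touched by a bond are
counted as absent — the sparser the map, the more selective the bonding.
"""

import gagnet as g
from gagnet.sitemap import absent_pair_count, build_pair_map
from gagnet.synthetic_data import KineticsSpec, default_planted_sites, generate_trajectory

system = g.build_system(n_ha_repeats=6, n_cs_chains=2, n_cs_repeats=4)
traj = generate_trajectory(system, default_planted_sites(6, 4, 6),
                           KineticsSpec(), 310.0, n_frames=500, seed=7)
obs = g.detect_trajectory(traj.coords, system)

ha = system.class_labels("HA")
cs = system.class_labels("CS")
spaces = {
    "intra-HA": g.enumerate_pair_space(ha, mode="intra"),
    "intra-CS": g.enumerate_pair_space(cs, mode="intra"),
    "inter": g.enumerate_pair_space(ha, cs, mode="inter"),
}
for mode, space in spaces.items():
    pm = build_pair_map(obs, mode, space)
    print(f"{mode}: {len(pm.occupied)} occupied, "
          f"{absent_pair_count(pm)} absent of {len(space)} pairs")
    for pair in pm.occupied[:3]:
        print(f"   {pair[0]:>4}-{pair[1]:<4} n={pm.count[pair]:4d} "
              f"log10(total E)={pm.log10_total_energy(pair):5.2f}")
print("(each occupied cell lists bond count and log10 of summed energy)")
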