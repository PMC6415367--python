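import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import gagnet as g
from gagnet.hbond import OBSERVATION_COLUMNS, HBondCriteria, hbond_energy, scale_factor
from gagnet.synthetic_data import BondSiteSpec, KineticsSpec, generate_trajectory

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_system():
    """4-repeat HA chain plus one 3-repeat CS chain."""
    return g.build_system(n_ha_repeats=4, n_cs_chains=1, n_cs_repeats=3)


@pytest.fixture(scope="session")
def criteria():
    return HBondCriteria()


def narrow_sites(specs):
    """Site specs whose planted lengths stay inside the detectable envelope,
    so every planted ON frame passes all three criteria."""
    return [
        BondSiteSpec(d, a, cat, mean_length=1.75, sd_length=0.08, bounds=(1.55, 1.95))
        for d, a, cat in specs
    ]


@pytest.fixture(scope="session")
def small_traj(small_system):
    """A reusable 300-frame trajectory with one lossless site per category."""
    sites = narrow_sites(
        [
            ("O2H", "O8", "intra-HA"),
            ("O3H", "OAC", "intra-HA"),
            ("NH", "O5", "intra-CS"),
            ("O4H", "SO4", "inter"),
        ]
    )
    return generate_trajectory(
        small_system, sites, KineticsSpec(), 310.0,
        n_frames=300, frame_spacing=10.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_obs(small_traj, small_system):
    return g.detect_trajectory(small_traj.coords, small_system)


def brute_force_detect(coords, system, criteria=None):
    """Independent all-pairs detection oracle: tests every (D, H, A) triple
    directly against the criteria, no neighbour lists, same dedup rule."""
    criteria = criteria or HBondCriteria()
    rows = []
    for d, h in system.donors:
        for a in system.acceptors:
            if a == d or (min(d, a), max(d, a)) in system.covalent_pairs:
                continue
            dist_ha = float(np.linalg.norm(coords[h] - coords[a]))
            dist_da = float(np.linalg.norm(coords[d] - coords[a]))
            if dist_ha >= criteria.max_h_acceptor or dist_da >= criteria.max_donor_acceptor:
                continue

            def ang(p, q, r):
                v1, v2 = p - q, r - q
                c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                return float(np.degrees(np.arccos(np.clip(c, -1, 1))))

            a_dha = ang(coords[d], coords[h], coords[a])
            s1 = scale_factor(a_dha, *criteria.dha_ramp)
            xs = system.heavy_neighbors.get(a, [])
            if not xs:
                s2, a_hax = 1.0, 180.0
            else:
                cands = [(scale_factor(ang(coords[h], coords[a], coords[x]),
                                       *criteria.hax_ramp),
                          ang(coords[h], coords[a], coords[x])) for x in xs]
                s2, a_hax = max(cands)
            e = hbond_energy(dist_ha, s1, s2, criteria)
            if e > criteria.min_energy:
                rows.append((0, d, h, a, dist_ha, dist_da, a_dha, a_hax, e,
                             g.categorize(system.species[d], system.species[a]),
                             system.class_label[d], system.class_label[a],
                             system.species[d]))
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    for c in OBSERVATION_COLUMNS:
        if c in ("frame", "donor", "hydrogen", "acceptor"):
            df[c] = df[c].astype("int64")
        elif c in ("category", "donor_class", "acceptor_class", "donor_species"):
            df[c] = df[c].astype("object")
        else:
            df[c] = df[c].astype("float64")
    if len(df) and criteria.dedup == "best":
        df = df.sort_values("energy", ascending=False).drop_duplicates(
            subset=["frame", "hydrogen"], keep="first"
        )
    return df.sort_values(["donor", "acceptor"]).reset_index(drop=True)


def make_observations(rows, default_energy=10.0):
    """Build an observation table from compact tuples.

    Each row: (frame, donor, acceptor[, energy[, dist_ha[, category,
    donor_class, acceptor_class, donor_species]]]).
    """
    out = []
    for r in rows:
        frame, donor, acceptor = r[0], r[1], r[2]
        energy = r[3] if len(r) > 3 else default_energy
        dist = r[4] if len(r) > 4 else 1.8
        cat = r[5] if len(r) > 5 else "intra-HA"
        dc = r[6] if len(r) > 6 else "O2H"
        ac = r[7] if len(r) > 7 else "O8"
        dsp = r[8] if len(r) > 8 else ("HA" if cat != "intra-CS" else "CS")
        out.append((frame, donor, donor + 1000, acceptor, dist, dist + 0.9,
                    170.0, 150.0, energy, cat, dc, ac, dsp))
    return (
        pd.DataFrame(out, columns=OBSERVATION_COLUMNS)
        .sort_values("frame", kind="mergesort")
        .reset_index(drop=True)
    )
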