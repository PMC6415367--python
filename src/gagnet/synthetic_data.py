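"""Seeded synthetic HA/CS trajectories with planted hydrogen bonds.

The generator stands in for an all-atom MD run at the statistical level
the downstream analysis consumes.  Each *planted site* is a chosen
(donor, hydrogen, acceptor) triple whose on/off dynamics follow a
two-state continuous-time Markov chain, discretised at the frame
spacing:

    OFF -> ON  with rate k_on            (temperature independent)
    ON  -> OFF with rate k_off(T) = k_off_ref · exp[(E_a/R)(1/T_ref − 1/T)]

so that higher temperatures break bonds faster (Arrhenius activation),
which is the mechanism behind temperature-dependent bond stability.

While a site is ON, the hydrogen–acceptor distance is drawn from the
site's truncated normal law (default mean 1.77 Å, sd 0.28 Å, hard bounds
[1.5, 2.5] Å — the range real hydrogen bonds span) and the acceptor's
functional group is placed rigidly so that the donor–H–acceptor geometry
is as close to linear as the donor–acceptor distance criterion allows.
While OFF, the acceptor is parked > 3.5 Å from the hydrogen.  All other
atoms get small Gaussian jitter around the template.  Identical seeds
reproduce identical trajectories bit for bit.

The per-frame on/off ground truth is stored alongside the coordinates so
detection and tracking can be scored; analysis modules never see it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from .hbond import CATEGORY_INTER, CATEGORY_INTRA_CS, CATEGORY_INTRA_HA
from .topology import SystemTopology

__all__ = [
    "GAS_CONSTANT_KJ",
    "KineticsSpec",
    "BondSiteSpec",
    "SyntheticTrajectory",
    "generate_trajectory",
    "simulate_two_state",
    "default_planted_sites",
    "write_trajectory",
    "write_ground_truth",
]

#: molar gas constant, kJ/(mol K)
GAS_CONSTANT_KJ = 8.31446261815324e-3

#: nominal donor–H–acceptor angle of a planted bond (degrees)
_PLANT_DHA = 172.0
#: nominal hydrogen–acceptor–X angle of a planted bond (degrees)
_PLANT_HAX = 150.0
#: donor–acceptor distance the planted geometry is bent to respect (Å)
_PLANT_DA = 2.78
#: hydrogen–acceptor distance of a parked (OFF) acceptor (Å)
_PLANT_OFF_DIST = 4.5


@dataclass(frozen=True)
class KineticsSpec:
    """Two-state bond kinetics with an Arrhenius off-rate.

    Rates are per ns.  ``activation_energy`` is in kJ/mol; ~50 kJ/mol is
    a plausible barrier for breaking a strong hydrogen bond and gives
    roughly a factor 1.9 in off-rate per 10 K around physiological
    temperature.
    """

    k_on: float = 2.0
    k_off_ref: float = 1.0
    t_ref: float = 310.0
    activation_energy: float = 50.0
    temperatures: tuple[float, ...] = (300.0, 310.0, 320.0)

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off_ref <= 0:
            raise ValueError("rates must be > 0")
        if self.activation_energy < 0:
            raise ValueError("activation_energy must be >= 0")
        for t in (self.t_ref, *self.temperatures):
            if not (273.0 <= t <= 373.0):
                raise ValueError(f"temperature {t} K outside [273, 373]")

    def k_off(self, temperature: float) -> float:
        """Off-rate (per ns) at ``temperature`` K."""
        ea_over_r = self.activation_energy / GAS_CONSTANT_KJ
        return self.k_off_ref * float(
            np.exp(ea_over_r * (1.0 / self.t_ref - 1.0 / temperature))
        )


@dataclass(frozen=True)
class BondSiteSpec:
    """One planted donor-class → acceptor-class bond site."""

    donor_class: str
    acceptor_class: str
    category: str  # intra-HA | intra-CS | inter
    mean_length: float = 1.77
    sd_length: float = 0.28
    bounds: tuple[float, float] = (1.5, 2.5)

    def __post_init__(self) -> None:
        if self.category not in (CATEGORY_INTRA_HA, CATEGORY_INTRA_CS, CATEGORY_INTER):
            raise ValueError(f"unknown category {self.category!r}")
        lo, hi = self.bounds
        if not (1.0 <= lo < hi <= 2.6):
            raise ValueError(f"bounds {self.bounds} outside [1.0, 2.6]")
        if not (lo <= self.mean_length <= hi):
            raise ValueError("mean_length outside bounds")
        if self.sd_length <= 0:
            raise ValueError("sd_length must be > 0")


@dataclass
class SyntheticTrajectory:
    """A generated multi-frame coordinate set with planted-bond ground truth."""

    system: SystemTopology
    coords: np.ndarray  # (n_frames, n_atoms, 3) Å
    frame_spacing: float  # ps
    temperature: float  # K
    sites: list[BondSiteSpec]
    site_atoms: list[tuple[int, int, int]]  # (donor, hydrogen, acceptor) per site
    ground_truth: np.ndarray  # (n_frames, n_sites) bool
    seed: int

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps in ps."""
        return np.arange(self.n_frames, dtype=float) * self.frame_spacing


def simulate_two_state(
    n_frames: int,
    p_on: np.ndarray,
    p_off: np.ndarray,
    rng: np.random.Generator,
    initial_on_prob: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate two-state Markov chains, one column per site.

    ``p_on``/``p_off`` are per-frame transition probabilities (OFF→ON and
    ON→OFF).  The initial state is drawn from the stationary distribution
    unless ``initial_on_prob`` is given.  Returns (n_frames, n_sites) bool.
    """
    p_on = np.atleast_1d(np.asarray(p_on, dtype=float))
    p_off = np.atleast_1d(np.asarray(p_off, dtype=float))
    n_sites = len(p_on)
    if initial_on_prob is None:
        denom = p_on + p_off
        initial_on_prob = np.where(denom > 0, p_on / np.where(denom > 0, denom, 1.0), 0.0)
    states = np.empty((n_frames, n_sites), dtype=bool)
    states[0] = rng.random(n_sites) < np.atleast_1d(initial_on_prob)
    u = rng.random((n_frames - 1, n_sites))
    for t in range(1, n_frames):
        prev = states[t - 1]
        states[t] = np.where(prev, u[t - 1] >= p_off, u[t - 1] < p_on)
    return states


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation of ``v`` about the unit ``axis``."""
    th = np.radians(angle_deg)
    return (
        v * np.cos(th)
        + np.cross(axis, v) * np.sin(th)
        + axis * np.dot(axis, v) * (1.0 - np.cos(th))
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 matrix rotating unit vector ``a`` onto unit vector ``b``."""
    c = float(np.dot(a, b))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # pick any perpendicular axis for the half-turn
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis = _unit(axis)
        return _axis_angle_matrix(axis, 180.0)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    axis = axis / s
    angle = np.degrees(np.arctan2(s, c))
    return _axis_angle_matrix(axis, angle)


def _axis_angle_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    th = np.radians(angle_deg)
    k = np.asarray(axis, dtype=float)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * kx + (1 - np.cos(th)) * (kx @ kx)


def _perp_axis(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to ``v`` (deterministic choice)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(_unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(v, ref))


class _PlantedSite:
    """Precomputed placement machinery for one planted site."""

    def __init__(self, system: SystemTopology, spec: BondSiteSpec,
                 donor: int, hydrogen: int, acceptor: int):
        self.spec = spec
        self.donor = donor
        self.hydrogen = hydrogen
        self.acceptor = acceptor
        group = system.group_index[acceptor]
        self.group_atoms = np.flatnonzero(system.group_index == group)
        tmpl = system.template_coords
        self.rel = tmpl[self.group_atoms] - tmpl[acceptor]
        neighbors = system.heavy_neighbors.get(acceptor, [])
        if neighbors:
            self.x_atom = neighbors[0]
            self.rel_x_dir = _unit(tmpl[self.x_atom] - tmpl[acceptor])
        else:  # degenerate template; keep the group unrotated
            self.x_atom = None
            self.rel_x_dir = np.array([0.0, 0.0, 1.0])
        self.roll = self._best_roll(system)

    def _placement(self, d_pos, h_pos, dist, roll):
        """Positions of the acceptor group for one frame; acceptor lands
        exactly ``dist`` Å from the hydrogen."""
        v = _unit(h_pos - d_pos)  # donor -> hydrogen
        dh = float(np.linalg.norm(h_pos - d_pos))
        # bend the D–H–A angle just enough to keep D–A inside its criterion
        rhs = (dist**2 + dh**2 - _PLANT_DA**2) / (2.0 * dist * dh)
        theta = _PLANT_DHA
        if rhs > -1.0:
            theta = min(theta, float(np.degrees(np.arccos(np.clip(rhs, -1.0, 1.0)))))
        axis = _perp_axis(v)
        w = _rotate(v, axis, 180.0 - theta)  # hydrogen -> acceptor direction
        a_pos = h_pos + dist * w
        # acceptor -> X direction making the H–A–X angle
        m = -w
        n = _rotate(m, axis, _PLANT_HAX)
        rot = _axis_angle_matrix(n, roll) @ _rotation_between(self.rel_x_dir, n)
        return a_pos + self.rel @ rot.T

    def _best_roll(self, system: SystemTopology) -> float:
        """Roll angle about the A→X axis keeping the rest of the acceptor
        group as far as possible from the donor pair (avoids spurious
        contacts from e.g. a hydroxyl acceptor's own hydrogen)."""
        tmpl = system.template_coords
        d_pos, h_pos = tmpl[self.donor], tmpl[self.hydrogen]
        others = self.group_atoms != self.acceptor
        if not np.any(others):
            return 0.0
        best_roll, best_score = 0.0, -np.inf
        for roll in range(0, 360, 30):
            placed = self._placement(d_pos, h_pos, self.spec.mean_length, float(roll))
            dmin = min(
                float(np.linalg.norm(placed[others] - d_pos, axis=1).min()),
                float(np.linalg.norm(placed[others] - h_pos, axis=1).min()),
            )
            if dmin > best_score:
                best_roll, best_score = float(roll), dmin
        return best_roll

    def place(self, coords: np.ndarray, dist: float, on: bool) -> None:
        """Write the acceptor-group coordinates for one frame in place."""
        d_pos = coords[self.donor]
        h_pos = coords[self.hydrogen]
        dist = dist if on else _PLANT_OFF_DIST
        coords[self.group_atoms] = self._placement(d_pos, h_pos, dist, self.roll)


# ---------------------------------------------------------------------------
# Site planning
# ---------------------------------------------------------------------------

def default_planted_sites(
    n_intra_ha: int = 6,
    n_intra_cs: int = 4,
    n_inter: int = 6,
) -> list[BondSiteSpec]:
    """A default bond-site panel spanning the three categories.

    Donor classes rotate over the hydroxyls and the amide; acceptor
    classes favour single-oxygen acceptors (ring/glycosidic oxygens and
    the carbonyl) plus the carboxylate and, on CS, the sulfate.
    """
    ha_donors = ["O2H", "O3H", "O4H", "O6H", "NH"]
    cs_donors = ["O2H", "O3H", "O6H", "NH"]
    ha_acceptors = ["O5", "O8", "O10", "OAC", "COO"]
    cs_acceptors = ["O5", "O8", "O10", "OAC", "SO4", "COO"]
    sites = []
    for k in range(n_intra_ha):
        sites.append(BondSiteSpec(ha_donors[k % len(ha_donors)],
                                  ha_acceptors[k % len(ha_acceptors)],
                                  CATEGORY_INTRA_HA))
    for k in range(n_intra_cs):
        sites.append(BondSiteSpec(cs_donors[k % len(cs_donors)],
                                  cs_acceptors[k % len(cs_acceptors)],
                                  CATEGORY_INTRA_CS))
    for k in range(n_inter):
        sites.append(BondSiteSpec(ha_donors[(k + 1) % len(ha_donors)],
                                  cs_acceptors[k % len(cs_acceptors)],
                                  CATEGORY_INTER))
    return sites


def _assign_site_atoms(
    system: SystemTopology, sites: list[BondSiteSpec]
) -> list[tuple[int, int, int]]:
    """Deterministically bind each site spec to concrete atoms.

    Donor and acceptor functional groups are never shared between sites,
    so planted geometries cannot interfere with each other.
    """
    h_of = {parent: h for h, parent in system.h_parent.items()}
    used_groups: set[int] = set()
    out = []
    for spec in sites:
        if spec.category == CATEGORY_INTRA_HA:
            d_species = a_species = "HA"
        elif spec.category == CATEGORY_INTRA_CS:
            d_species = a_species = "CS"
        else:
            d_species, a_species = "HA", "CS"
            if spec.donor_class not in system.class_labels("HA"):
                d_species, a_species = "CS", "HA"

        donors = [
            i for i in system.class_members(d_species, spec.donor_class)
            if i in h_of and system.group_index[i] not in used_groups
        ]
        if not donors:
            raise ValueError(
                f"no free donor atom for site {spec.donor_class}->{spec.acceptor_class} "
                f"({spec.category})"
            )
        donor = donors[0]
        used_groups.add(int(system.group_index[donor]))

        same_mol = spec.category in (CATEGORY_INTRA_HA, CATEGORY_INTRA_CS)
        acceptors = [
            i for i in system.class_members(a_species, spec.acceptor_class)
            if system.group_index[i] not in used_groups
            and (not same_mol or system.mol_index[i] == system.mol_index[donor])
        ]
        if not acceptors:
            raise ValueError(
                f"no free acceptor atom for site {spec.donor_class}->{spec.acceptor_class} "
                f"({spec.category})"
            )
        acceptor = acceptors[0]
        used_groups.add(int(system.group_index[acceptor]))
        out.append((donor, h_of[donor], acceptor))
    return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_trajectory(
    system: SystemTopology,
    planted_sites: list[BondSiteSpec],
    kinetics: KineticsSpec,
    temperature: float,
    n_frames: int = 1000,
    frame_spacing: float = 10.0,
    seed: int = 0,
    jitter: float = 0.05,
) -> SyntheticTrajectory:
    """Generate a seeded trajectory with planted two-state bond kinetics.

    ``frame_spacing`` is in ps; the default 1000 frames × 10 ps emulate a
    10 ns production run sampled at analysis resolution.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if seed is None:
        raise ValueError("an explicit seed is required")
    if temperature not in kinetics.temperatures:
        warnings.warn(
            f"temperature {temperature} K not in kinetics.temperatures "
            f"{kinetics.temperatures}; proceeding",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    site_atoms = _assign_site_atoms(system, planted_sites)
    planted = [
        _PlantedSite(system, spec, d, h, a)
        for spec, (d, h, a) in zip(planted_sites, site_atoms)
    ]

    coords = system.template_coords[None, :, :] + rng.normal(
        0.0, jitter, size=(n_frames, system.n_atoms, 3)
    )

    n_sites = len(planted)
    if n_sites:
        dt_ns = frame_spacing / 1000.0
        k_off = kinetics.k_off(temperature)
        p_on = np.full(n_sites, 1.0 - np.exp(-kinetics.k_on * dt_ns))
        p_off = np.full(n_sites, 1.0 - np.exp(-k_off * dt_ns))
        states = simulate_two_state(n_frames, p_on, p_off, rng)
        for s, site in enumerate(planted):
            spec = site.spec
            lo, hi = spec.bounds
            a_, b_ = (lo - spec.mean_length) / spec.sd_length, (hi - spec.mean_length) / spec.sd_length
            on_frames = np.flatnonzero(states[:, s])
            dists = np.full(n_frames, spec.mean_length)
            if len(on_frames):
                dists[on_frames] = truncnorm.rvs(
                    a_, b_, loc=spec.mean_length, scale=spec.sd_length,
                    size=len(on_frames), random_state=rng,
                )
            for t in range(n_frames):
                site.place(coords[t], float(dists[t]), bool(states[t, s]))
    else:
        states = np.zeros((n_frames, 0), dtype=bool)

    return SyntheticTrajectory(
        system=system,
        coords=coords,
        frame_spacing=frame_spacing,
        temperature=temperature,
        sites=list(planted_sites),
        site_atoms=site_atoms,
        ground_truth=states,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_trajectory(traj: SyntheticTrajectory, path, fmt: str = "pdb") -> None:
    """Write a trajectory to disk as multi-model PDB or a plain-text frame stream."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    from . import trajio

    if fmt == "pdb":
        trajio.write_multimodel_pdb(traj.system, traj.coords, path)
    elif fmt == "frames":
        trajio.write_frame_stream(traj.system, traj.coords, traj.frame_spacing, path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r} (use 'pdb' or 'frames')")


def write_ground_truth(traj: SyntheticTrajectory, path) -> None:
    """Write the planted on/off ground truth as a TSV sidecar (frame, site, state)."""
    with open(path, "w") as fh:
        fh.write("frame\tsite\tdonor\tacceptor\tstate\n")
        for s, (d, _h, a) in enumerate(traj.site_atoms):
            for t in range(traj.n_frames):
                fh.write(f"{t}\t{s}\t{d}\t{a}\t{int(traj.ground_truth[t, s])}\n")
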