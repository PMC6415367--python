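"""Hydrogen-bond identification and energy.

A candidate (donor D carrying a covalent hydrogen H, acceptor A) counts
as a hydrogen bond in a frame iff

  (i)   dist(H, A) < 2.6 Å,
  (ii)  dist(D, A) < 2.8 Å, and
  (iii) the bond energy exceeds 6.25 kJ/mol (25% of the 25 kJ/mol
        optimum),

with the energy

    E = 25 kJ/mol · (2.6 − max(d_HA, 2.1)) / 0.5 · s_DHA · s_HAX

where the two unitless scale factors, both in [0, 1], depend on the
donor–hydrogen–acceptor angle and on the hydrogen–acceptor–X angle (X is
an atom covalently bound to the acceptor).  The energy plateaus at the
25 kJ/mol optimum for d_HA ≤ 2.1 Å and falls linearly to zero at 2.6 Å.
The scale factors are piecewise-linear ramps: 0 below ``ramp_start``, 1
above ``ramp_end`` (their published description fixes only the 0–1 range
and the two angles; the ramp bounds are configurable).

The 6.25 kJ/mol criterion is applied to the fully scaled energy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .topology import SystemTopology

logger = logging.getLogger(__name__)

__all__ = [
    "KCAL_TO_KJ",
    "HBondCriteria",
    "CATEGORY_INTRA_HA",
    "CATEGORY_INTRA_CS",
    "CATEGORY_INTER",
    "scale_factor",
    "hbond_energy",
    "categorize",
    "detect_frame",
    "detect_trajectory",
    "OBSERVATION_COLUMNS",
]

#: thermochemical calorie; the 6.25 kJ/mol threshold is 1.5 kcal/mol missing a hair
KCAL_TO_KJ = 4.184

CATEGORY_INTRA_HA = "intra-HA"
CATEGORY_INTRA_CS = "intra-CS"
CATEGORY_INTER = "inter"


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric and energetic hydrogen-bond criteria (distances in Å, energies kJ/mol)."""

    max_h_acceptor: float = 2.6
    max_donor_acceptor: float = 2.8
    min_energy: float = 6.25
    optimum_energy: float = 25.0
    saturation_distance: float = 2.1
    zero_distance: float = 2.6
    normalization: float = 0.5
    #: donor–hydrogen–acceptor scale ramp (degrees)
    dha_ramp: tuple[float, float] = (100.0, 165.0)
    #: hydrogen–acceptor–X scale ramp (degrees)
    hax_ramp: tuple[float, float] = (85.0, 165.0)
    #: X selection when the acceptor has several heavy neighbours: "max" scale or "first"
    x_policy: str = "max"
    #: per-hydrogen deduplication: "best" keeps the highest-energy acceptor, "all" keeps all
    dedup: str = "best"

    def __post_init__(self) -> None:
        if not (self.saturation_distance < self.zero_distance):
            raise ValueError("saturation_distance must be < zero_distance")
        for name in ("max_h_acceptor", "max_donor_acceptor", "saturation_distance",
                     "zero_distance", "normalization"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for ramp in (self.dha_ramp, self.hax_ramp):
            if not (ramp[0] < ramp[1] <= 180.0):
                raise ValueError(f"invalid scale ramp {ramp}")
        if self.x_policy not in ("max", "first"):
            raise ValueError("x_policy must be 'max' or 'first'")
        if self.dedup not in ("best", "all"):
            raise ValueError("dedup must be 'best' or 'all'")

    def with_overrides(self, **kwargs) -> "HBondCriteria":
        return replace(self, **kwargs)


def scale_factor(angle, ramp_start: float, ramp_end: float):
    """Piecewise-linear angular scale factor in [0, 1].

    0 for ``angle <= ramp_start``, 1 for ``angle >= ramp_end``, linear in
    between; monotone non-decreasing.  Angles outside [0, 180] are clamped
    with a logged warning.
    """
    if not (ramp_start < ramp_end <= 180.0):
        raise ValueError(f"invalid ramp ({ramp_start}, {ramp_end})")
    angle = np.asarray(angle, dtype=float)
    if np.any(angle < 0.0) or np.any(angle > 180.0):
        logger.warning("angle outside [0, 180] clamped in scale_factor")
        angle = np.clip(angle, 0.0, 180.0)
    out = (angle - ramp_start) / (ramp_end - ramp_start)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def hbond_energy(dist_ha, scale_dha, scale_hax, criteria: HBondCriteria | None = None):
    """Hydrogen-bond energy (kJ/mol) at hydrogen–acceptor distance ``dist_ha`` (Å).

    E = optimum · (zero − max(d, saturation)) / normalization · s₁ · s₂,
    clamped at 0 for d ≥ zero.  With the defaults this gives 25 kJ/mol on
    the plateau d ≤ 2.1 Å and 0 at d ≥ 2.6 Å.
    """
    if criteria is None:
        criteria = HBondCriteria()
    d = np.asarray(dist_ha, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative hydrogen-acceptor distance")
    eff = np.maximum(d, criteria.saturation_distance)
    base = (
        criteria.optimum_energy
        * (criteria.zero_distance - eff)
        / criteria.normalization
    )
    base = np.maximum(base, 0.0)
    out = base * np.asarray(scale_dha, dtype=float) * np.asarray(scale_hax, dtype=float)
    return float(out) if out.ndim == 0 else out


def categorize(donor_species: str, acceptor_species: str) -> str:
    """Bond category from the species of the donor and acceptor chains."""
    valid = ("HA", "CS")
    if donor_species not in valid or acceptor_species not in valid:
        raise ValueError(
            f"unknown species pair ({donor_species!r}, {acceptor_species!r})"
        )
    if donor_species == acceptor_species:
        return CATEGORY_INTRA_HA if donor_species == "HA" else CATEGORY_INTRA_CS
    return CATEGORY_INTER


OBSERVATION_COLUMNS = [
    "frame", "donor", "hydrogen", "acceptor", "dist_ha", "dist_da",
    "angle_dha", "angle_hax", "energy", "category", "donor_class",
    "acceptor_class", "donor_species",
]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of the triple a-b-c, degrees."""
    v1 = a - b
    v2 = c - b
    cosv = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def _empty_observations() -> pd.DataFrame:
    return pd.DataFrame(
        {
            c: pd.Series(dtype=("int64" if c in ("frame", "donor", "hydrogen", "acceptor")
                                 else "object" if c in ("category", "donor_class",
                                                        "acceptor_class", "donor_species")
                                 else "float64"))
            for c in OBSERVATION_COLUMNS
        }
    )


def detect_frame(
    coords: np.ndarray,
    system: SystemTopology,
    criteria: HBondCriteria | None = None,
    frame_index: int = 0,
    _tree: cKDTree | None = None,
) -> pd.DataFrame:
    """Detect hydrogen bonds in one frame.

    ``coords`` is an (n_atoms, 3) array in Å covering every topology atom.
    Candidates are all (donor, hydrogen, acceptor) triples where the donor
    is an O/N with a statically assigned covalent hydrogen and the
    acceptor is an O/N member of an acceptor-capable class; self pairs and
    covalently bonded donor–acceptor pairs are excluded.  Output is sorted
    by (donor, acceptor); by default one hydrogen reports at most its
    highest-energy acceptor.

    A neighbour-list (k-d tree) restricts the candidate set; the result is
    identical to exhaustive all-pairs search.
    """
    if criteria is None:
        criteria = HBondCriteria()
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (system.n_atoms, 3):
        raise ValueError(
            f"coordinates shape {coords.shape} does not cover the "
            f"{system.n_atoms} topology atoms"
        )
    if not np.all(np.isfinite(coords)):
        bad = int(np.argwhere(~np.isfinite(coords))[0, 0])
        raise ValueError(f"atom {system.atom_label(bad)} has non-finite coordinates")

    acceptors = system.acceptors
    if not system.donors or not acceptors:
        return _empty_observations()
    acc_idx = np.asarray(acceptors, dtype=int)
    tree = _tree if _tree is not None else cKDTree(coords[acc_idx])

    h_idx = np.asarray([h for _, h in system.donors], dtype=int)
    d_idx = np.asarray([d for d, _ in system.donors], dtype=int)
    neighbor_lists = tree.query_ball_point(coords[h_idx], r=criteria.max_h_acceptor)

    rows = []
    for k in range(len(h_idx)):
        h = int(h_idx[k])
        d = int(d_idx[k])
        for local_a in neighbor_lists[k]:
            a = int(acc_idx[local_a])
            if a == d:
                continue
            if (min(d, a), max(d, a)) in system.covalent_pairs:
                continue
            dist_ha = float(np.linalg.norm(coords[h] - coords[a]))
            if dist_ha >= criteria.max_h_acceptor:
                continue
            dist_da = float(np.linalg.norm(coords[d] - coords[a]))
            if dist_da >= criteria.max_donor_acceptor:
                continue
            angle_dha = _angle_deg(coords[d], coords[h], coords[a])
            s1 = scale_factor(angle_dha, *criteria.dha_ramp)
            # X = covalent heavy neighbour of the acceptor
            neighbors = system.heavy_neighbors.get(a, [])
            if not neighbors:
                angle_hax, s2 = 180.0, 1.0
            elif criteria.x_policy == "first":
                angle_hax = _angle_deg(coords[h], coords[a], coords[neighbors[0]])
                s2 = scale_factor(angle_hax, *criteria.hax_ramp)
            else:
                angle_hax, s2 = 0.0, -1.0
                for x in neighbors:
                    ang = _angle_deg(coords[h], coords[a], coords[x])
                    s = scale_factor(ang, *criteria.hax_ramp)
                    if s > s2:
                        angle_hax, s2 = ang, s
            energy = hbond_energy(dist_ha, s1, s2, criteria)
            if energy <= criteria.min_energy:
                continue
            rows.append(
                (
                    frame_index, d, h, a, dist_ha, dist_da, angle_dha, angle_hax,
                    energy,
                    categorize(system.species[d], system.species[a]),
                    system.class_label[d], system.class_label[a],
                    system.species[d],
                )
            )

    if not rows:
        return _empty_observations()
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    if criteria.dedup == "best":
        df = df.sort_values("energy", ascending=False).drop_duplicates(
            subset=["frame", "hydrogen"], keep="first"
        )
    return df.sort_values(["donor", "acceptor"]).reset_index(drop=True)


def detect_trajectory(
    coords_stack: np.ndarray,
    system: SystemTopology,
    criteria: HBondCriteria | None = None,
) -> pd.DataFrame:
    """Detect hydrogen bonds in every frame of an (n_frames, n_atoms, 3) stack.

    Returns one table with a ``frame`` column, frames in ascending order.
    """
    coords_stack = np.asarray(coords_stack, dtype=float)
    if coords_stack.ndim != 3:
        raise ValueError("expected an (n_frames, n_atoms, 3) coordinate stack")
    frames = [
        detect_frame(coords_stack[t], system, criteria, frame_index=t)
        for t in range(coords_stack.shape[0])
    ]
    non_empty = [f for f in frames if len(f)]
    if not non_empty:
        return _empty_observations()
    return pd.concat(non_empty, ignore_index=True)
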