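"""Pseudo-atom topologies for glycosaminoglycan chains.

Hyaluronan (HA) and chondroitin sulfate (CS) are polymers of repeating
disaccharide units.  For hydrogen-bond analysis only a small set of
functional groups matters: hydroxyls, the carboxylate, the N-acetyl amide,
the acetyl carbonyl, ring/glycosidic oxygens and (for CS) the sulfate
oxygens.  Each such group is a *site class*: a labelled set of equivalent
donor/acceptor atoms, one instance per repeat unit.  The default
configuration defines 11 classes per species, so a molecule's
intramolecular pair space has 11·12/2 = 66 unordered class pairs and the
HA–CS intermolecular space has 11·11 = 121 ordered (HA class, CS class)
pairs.

Repeat units are templated pseudo-atom layouts: groups are spread far
apart along the chain axis so that no hydrogen bond exists at rest, with
chemically sensible covalent geometry (O–H ≈ 0.96 Å, N–H ≈ 1.0 Å,
C–O ≈ 1.43 Å) so that distance and angle criteria behave as they would on
real coordinates.  No claim of sugar stereochemistry is made; the
analysis consumes only names, elements and coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Species",
    "SiteClass",
    "AtomRecord",
    "MoleculeTopology",
    "SystemTopology",
    "TopologyConfigError",
    "default_site_classes",
    "build_polymer",
    "build_system",
    "enumerate_pair_space",
]

#: spacing between functional-group anchors along the chain axis (Å);
#: large enough that un-planted groups never satisfy any H-bond criterion
GROUP_SPACING = 4.5

#: vertical offset between chains in a system (Å)
CHAIN_SPACING = 14.0

SUPPORTED_ELEMENTS = frozenset({"C", "N", "O", "S", "H"})


class Species(str, Enum):
    """Polymer species tag."""

    HA = "HA"
    CS = "CS"


class TopologyConfigError(ValueError):
    """A site-class configuration cannot be resolved against the template."""


@dataclass(frozen=True)
class SiteClass:
    """A labelled donor/acceptor functional-group class.

    ``selectors`` are atom names identifying the heavy member atoms of the
    class inside one repeat unit.  ``role`` states whether members can
    donate (carry a covalent hydrogen), accept, or both.
    """

    label: str
    role: str  # "donor" | "acceptor" | "both"
    selectors: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor", "both"):
            raise TopologyConfigError(
                f"class {self.label!r}: role must be donor/acceptor/both, got {self.role!r}"
            )
        if not self.selectors:
            raise TopologyConfigError(f"class {self.label!r}: empty selector list")


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a molecule topology."""

    atom_id: int
    name: str
    element: str
    chain_id: str
    residue_index: int  # repeat-unit ordinal, 1-based
    species: Species


# ---------------------------------------------------------------------------
# Repeat-unit group templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Group:
    """A functional group inside the repeat-unit template."""

    atoms: tuple[tuple[str, str, tuple[float, float, float]], ...]  # (name, element, offset)
    members: tuple[str, ...]  # heavy atoms selectable by a site class


def _hydroxyl(idx: str) -> _Group:
    # O–H 0.96 Å, pointing off the chain plane so planted bonds extend in +z
    return _Group(
        atoms=(
            (f"C{idx}", "C", (0.0, 0.0, 0.0)),
            (f"O{idx}", "O", (0.0, 1.43, 0.0)),
            (f"HO{idx}", "H", (0.0, 1.67, 0.93)),
        ),
        members=(f"O{idx}",),
    )


def _ether(idx: str) -> _Group:
    return _Group(
        atoms=(
            (f"C{idx}", "C", (0.0, 0.0, 0.0)),
            (f"O{idx}", "O", (0.0, 1.43, 0.0)),
        ),
        members=(f"O{idx}",),
    )


def _carboxylate() -> _Group:
    return _Group(
        atoms=(
            ("CCO", "C", (0.0, 0.0, 0.0)),
            ("OC1", "O", (-0.63, 1.08, 0.0)),
            ("OC2", "O", (0.63, 1.08, 0.0)),
        ),
        members=("OC1", "OC2"),
    )


def _amide() -> _Group:
    return _Group(
        atoms=(
            ("CN", "C", (0.0, 0.0, 0.0)),
            ("N", "N", (0.0, 1.35, 0.0)),
            ("HN", "H", (0.0, 1.71, 0.94)),
        ),
        members=("N",),
    )


def _carbonyl() -> _Group:
    return _Group(
        atoms=(
            ("CAC", "C", (0.0, 0.0, 0.0)),
            ("OAC", "O", (0.0, 1.23, 0.0)),
        ),
        members=("OAC",),
    )


def _sulfate() -> _Group:
    return _Group(
        atoms=(
            ("S", "S", (0.0, 0.0, 0.0)),
            ("OS1", "O", (-0.85, 1.20, 0.0)),
            ("OS2", "O", (0.85, 1.20, 0.0)),
            ("OS3", "O", (0.0, -1.45, 0.0)),
        ),
        members=("OS1", "OS2", "OS3"),
    )


# group builders keyed by class label
_GROUP_BUILDERS = {
    "O2H": lambda: _hydroxyl("2"),
    "O3H": lambda: _hydroxyl("3"),
    "O4H": lambda: _hydroxyl("4"),
    "O6H": lambda: _hydroxyl("6"),
    "NH": _amide,
    "COO": _carboxylate,
    "OAC": _carbonyl,
    "SO4": _sulfate,
    "O5": lambda: _ether("5"),
    "O7": lambda: _ether("7"),
    "O8": lambda: _ether("8"),
    "O10": lambda: _ether("10"),
}


def default_site_classes(species: Species | str) -> tuple[SiteClass, ...]:
    """The default 11 hydrogen-bonding site classes of a species.

    Labels cover the groups named for these polymers — the carboxylate
    (COO), the N-acetyl amide (NH), the acetyl carbonyl (OAC),
    ring/glycosidic oxygens (O5, O7, O8, O10), hydroxyls, and for CS the
    sulfate oxygens (SO4).  The full set is user-overridable via
    configuration.
    """
    species = Species(species)
    if species is Species.HA:
        labels = [
            ("O2H", "both"), ("O3H", "both"), ("O4H", "both"), ("O6H", "both"),
            ("NH", "donor"), ("COO", "acceptor"), ("OAC", "acceptor"),
            ("O5", "acceptor"), ("O7", "acceptor"), ("O8", "acceptor"),
            ("O10", "acceptor"),
        ]
    else:
        labels = [
            ("O2H", "both"), ("O3H", "both"), ("O6H", "both"),
            ("NH", "donor"), ("COO", "acceptor"), ("SO4", "acceptor"),
            ("OAC", "acceptor"), ("O5", "acceptor"), ("O7", "acceptor"),
            ("O8", "acceptor"), ("O10", "acceptor"),
        ]
    out = []
    for label, role in labels:
        group = _GROUP_BUILDERS[label]()
        out.append(SiteClass(label=label, role=role, selectors=group.members))
    return tuple(out)


# ---------------------------------------------------------------------------
# Molecule topology
# ---------------------------------------------------------------------------

@dataclass
class MoleculeTopology:
    """One polymer chain: atoms, coordinates template and class assignment."""

    species: Species
    n_repeats: int
    chain_id: str
    atoms: list[AtomRecord]
    template_coords: np.ndarray  # (n_atoms, 3) Å
    class_assignment: dict[int, str]  # atom_id -> class label (heavy member atoms)
    site_classes: tuple[SiteClass, ...]
    group_index: np.ndarray = field(default=None)  # functional-group id per atom

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def class_members(self, label: str) -> list[int]:
        return [i for i, lab in self.class_assignment.items() if lab == label]


def build_polymer(
    species: Species | str,
    n_repeats: int,
    site_classes: Sequence[SiteClass] | None = None,
    chain_id: str = "A",
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> MoleculeTopology:
    """Build a chain of ``n_repeats`` templated repeat units.

    Each repeat unit instantiates one functional group per site class,
    spread ``GROUP_SPACING`` Å apart along x.  Deterministic: identical
    inputs give identical atom ordering and class assignment.

    Raises
    ------
    TopologyConfigError
        If a class selector matches no atom of the generated repeat unit.
    """
    species = Species(species)
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if site_classes is None:
        site_classes = default_site_classes(species)
    site_classes = tuple(site_classes)
    labels = [c.label for c in site_classes]
    if len(set(labels)) != len(labels):
        raise TopologyConfigError(f"duplicate class labels in configuration: {labels}")

    # instantiate the repeat-unit template from the class list
    groups: list[tuple[SiteClass, _Group]] = []
    for cls in site_classes:
        builder = _GROUP_BUILDERS.get(cls.label)
        group = builder() if builder is not None else None
        if group is not None and not set(cls.selectors) <= set(group.members):
            group = None
        if group is None:
            raise TopologyConfigError(
                f"class {cls.label!r}: selector {cls.selectors!r} matches no atom "
                f"of the repeat-unit template"
            )
        groups.append((cls, group))

    atoms: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    assignment: dict[int, str] = {}
    group_ids: list[int] = []
    origin = np.asarray(origin, dtype=float)
    n_groups = len(groups)
    atom_id = 0
    gid = 0
    for unit in range(n_repeats):
        for g, (cls, group) in enumerate(groups):
            base = origin + np.array([(unit * n_groups + g) * GROUP_SPACING, 0.0, 0.0])
            for name, element, offset in group.atoms:
                atoms.append(
                    AtomRecord(
                        atom_id=atom_id,
                        name=name,
                        element=element,
                        chain_id=chain_id,
                        residue_index=unit + 1,
                        species=species,
                    )
                )
                coords.append(tuple(base + np.asarray(offset)))
                if name in cls.selectors:
                    assignment[atom_id] = cls.label
                group_ids.append(gid)
                atom_id += 1
            gid += 1

    return MoleculeTopology(
        species=species,
        n_repeats=n_repeats,
        chain_id=chain_id,
        atoms=atoms,
        template_coords=np.asarray(coords, dtype=float),
        class_assignment=assignment,
        site_classes=site_classes,
        group_index=np.asarray(group_ids, dtype=int),
    )


# ---------------------------------------------------------------------------
# System topology (1 HA chain + m CS chains)
# ---------------------------------------------------------------------------

#: covalent-bond inference cutoffs on the template (Å)
COVALENT_H_CUTOFF = 1.2
COVALENT_HEAVY_CUTOFF = 1.8


class SystemTopology:
    """The analysis system: one HA chain plus several CS chains.

    Concatenates per-molecule topologies into global atom arrays and
    precomputes everything hydrogen-bond detection needs: the covalent
    adjacency (inferred from template distances), the donor list (heavy
    O/N atoms carrying a covalent hydrogen — the hydrogen is assigned
    statically to the nearest O/N within 1.2 Å of the template), the
    acceptor list (O/N member atoms of acceptor-capable classes) and the
    class label of every member atom.
    """

    def __init__(self, molecules: Sequence[MoleculeTopology]):
        if not molecules:
            raise ValueError("system needs at least one molecule")
        chain_ids = [m.chain_id for m in molecules]
        if len(set(chain_ids)) != len(chain_ids):
            raise ValueError(f"duplicate chain ids: {chain_ids}")
        self.molecules = list(molecules)

        names, elements, chains, res_ids, species, mol_idx = [], [], [], [], [], []
        coords = []
        class_label: list[str | None] = []
        group_index = []
        group_offset = 0
        for mi, mol in enumerate(self.molecules):
            for atom in mol.atoms:
                names.append(atom.name)
                elements.append(atom.element)
                chains.append(atom.chain_id)
                res_ids.append(atom.residue_index)
                species.append(atom.species.value)
                mol_idx.append(mi)
                class_label.append(mol.class_assignment.get(atom.atom_id))
            coords.append(mol.template_coords)
            group_index.append(mol.group_index + group_offset)
            group_offset += int(mol.group_index.max()) + 1

        self.names = np.asarray(names, dtype=object)
        self.elements = np.asarray(elements, dtype=object)
        self.chain_ids = np.asarray(chains, dtype=object)
        self.res_ids = np.asarray(res_ids, dtype=int)
        self.species = np.asarray(species, dtype=object)
        self.mol_index = np.asarray(mol_idx, dtype=int)
        self.class_label = np.asarray(class_label, dtype=object)
        self.template_coords = np.vstack(coords)
        self.group_index = np.concatenate(group_index)
        self.n_atoms = len(self.names)

        self._infer_covalent()
        self._index_sites()

    # -- construction helpers ------------------------------------------------

    def _infer_covalent(self) -> None:
        from scipy.spatial import cKDTree

        tree = cKDTree(self.template_coords)
        pairs = tree.query_pairs(r=COVALENT_HEAVY_CUTOFF, output_type="ndarray")
        adj: dict[int, list[int]] = {i: [] for i in range(self.n_atoms)}
        bonded: set[tuple[int, int]] = set()
        for i, j in pairs:
            ei, ej = self.elements[i], self.elements[j]
            d = float(np.linalg.norm(self.template_coords[i] - self.template_coords[j]))
            if "H" in (ei, ej):
                if d > COVALENT_H_CUTOFF:
                    continue
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
            bonded.add((min(i, j), max(i, j)))
        self.covalent_adjacency = {k: sorted(v) for k, v in adj.items()}
        self.covalent_pairs = bonded

    def _index_sites(self) -> None:
        # hydrogen -> parent heavy atom (nearest O/N within the cutoff)
        self.h_parent: dict[int, int] = {}
        for i in range(self.n_atoms):
            if self.elements[i] != "H":
                continue
            best, best_d = None, COVALENT_H_CUTOFF
            for j in self.covalent_adjacency[i]:
                if self.elements[j] in ("O", "N"):
                    d = float(
                        np.linalg.norm(self.template_coords[i] - self.template_coords[j])
                    )
                    if d <= best_d:
                        best, best_d = j, d
            if best is not None:
                self.h_parent[i] = best

        role_of: dict[tuple[str, str], str] = {}
        for mol in self.molecules:
            for cls in mol.site_classes:
                role_of[(mol.species.value, cls.label)] = cls.role

        donors = []  # (heavy donor, hydrogen)
        for h, parent in sorted(self.h_parent.items()):
            label = self.class_label[parent]
            if label is None:
                continue
            role = role_of.get((self.species[parent], label))
            if role in ("donor", "both"):
                donors.append((parent, h))
        self.donors = donors

        acceptors = []
        for i in range(self.n_atoms):
            label = self.class_label[i]
            if label is None or self.elements[i] not in ("O", "N"):
                continue
            role = role_of.get((self.species[i], label))
            if role in ("acceptor", "both"):
                acceptors.append(i)
        self.acceptors = acceptors

        # heavy covalent neighbours of each acceptor (candidate X atoms)
        self.heavy_neighbors = {
            a: [j for j in self.covalent_adjacency[a] if self.elements[j] != "H"]
            for a in self.acceptors
        }

    # -- queries -------------------------------------------------------------

    def site_classes(self, species: Species | str) -> tuple[SiteClass, ...]:
        species = Species(species).value
        for mol in self.molecules:
            if mol.species.value == species:
                return mol.site_classes
        raise KeyError(f"no molecule of species {species}")

    def class_labels(self, species: Species | str) -> list[str]:
        return [c.label for c in self.site_classes(species)]

    def class_members(self, species: Species | str, label: str) -> list[int]:
        """Global atom ids of a class's member atoms, over all chains of a species."""
        species = Species(species).value
        return [
            i
            for i in range(self.n_atoms)
            if self.species[i] == species and self.class_label[i] == label
        ]

    def atom_label(self, i: int) -> str:
        return f"{self.chain_ids[i]}/{self.res_ids[i]}/{self.names[i]}"


def build_system(
    n_ha_repeats: int = 10,
    n_cs_chains: int = 3,
    n_cs_repeats: int = 4,
    ha_classes: Sequence[SiteClass] | None = None,
    cs_classes: Sequence[SiteClass] | None = None,
) -> SystemTopology:
    """Build the default system: one long HA chain and several short CS chains.

    The defaults mirror a dense-network region — a single long HA chain
    (chain A) with a few shorter CS chains stacked above it (chains B, C,
    ...), standing in for the ~2.5:1 HA:CS concentration ratio of the
    modelled solution on a per-system basis.
    """
    mols = [build_polymer(Species.HA, n_ha_repeats, ha_classes, chain_id="A")]
    for c in range(n_cs_chains):
        mols.append(
            build_polymer(
                Species.CS,
                n_cs_repeats,
                cs_classes,
                chain_id=chr(ord("B") + c),
                origin=(0.0, 0.0, CHAIN_SPACING * (c + 1)),
            )
        )
    return SystemTopology(mols)


# ---------------------------------------------------------------------------
# Pair spaces
# ---------------------------------------------------------------------------

def enumerate_pair_space(
    classes_a: Iterable[SiteClass | str],
    classes_b: Iterable[SiteClass | str] | None = None,
    mode: str = "intra",
) -> list[tuple[str, str]]:
    """Enumerate the class-pair space of a bond map.

    ``intra``: all unordered pairs including self-pairs of one class set —
    n(n+1)/2 pairs.  ``inter``: the full ordered Cartesian product
    (class of A, class of B) — n_a · n_b pairs.  Deterministic,
    lexicographically sorted.
    """
    def _labels(cs):
        return [c.label if isinstance(c, SiteClass) else str(c) for c in cs]

    a = _labels(classes_a)
    if not a:
        raise ValueError("empty class set")
    if mode == "intra":
        if classes_b is not None and _labels(classes_b) != a:
            raise ValueError("intra mode requires identical class sets")
        pairs = {tuple(sorted((x, y))) for x in a for y in a}
        return sorted(pairs)
    if mode == "inter":
        if classes_b is None:
            raise ValueError("inter mode requires a second class set")
        b = _labels(classes_b)
        if not b:
            raise ValueError("empty class set")
        return sorted((x, y) for x in a for y in b)
    raise ValueError(f"unknown mode {mode!r}")
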