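"""Trajectory and results I/O.

Coordinates travel as multi-model PDB (``MODEL``/``ENDMDL`` blocks,
parsed and written through biotite) or as a minimal plain-text frame
stream.  Result tables are TSV with a header row plus JSON summaries;
writers are deterministic, so re-running a seeded pipeline produces
byte-identical files.  Coordinates are Å throughout; energies kJ/mol.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .topology import SystemTopology

__all__ = [
    "TrajectoryParseError",
    "write_multimodel_pdb",
    "read_multimodel_pdb",
    "write_frame_stream",
    "read_frame_stream",
    "write_tsv",
    "write_json",
    "write_tables",
]


class TrajectoryParseError(ValueError):
    """A coordinate file could not be parsed or matched to the topology."""


# ---------------------------------------------------------------------------
# Multi-model PDB
# ---------------------------------------------------------------------------

def _atom_array_stack(system: SystemTopology, coords: np.ndarray):
    import biotite.structure as struc

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    if n_atoms != system.n_atoms:
        raise ValueError("coordinate count does not match the topology")
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = coords.astype(np.float32)
    stack.chain_id = np.asarray(system.chain_ids, dtype="U4")
    stack.res_id = np.asarray(system.res_ids, dtype=int)
    stack.res_name = np.asarray(
        ["HYA" if s == "HA" else "CSD" for s in system.species], dtype="U5"
    )
    stack.atom_name = np.asarray(system.names, dtype="U6")
    stack.element = np.asarray(system.elements, dtype="U2")
    stack.hetero = np.ones(n_atoms, dtype=bool)
    return stack


def write_multimodel_pdb(system: SystemTopology, coords: np.ndarray, path) -> None:
    """Write an (n_frames, n_atoms, 3) stack as a multi-model PDB file."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_atom_array_stack(system, coords))
    pdb.write(str(path))


def _validate_atom_lines(path) -> None:
    """Cheap structural pre-scan so parse errors can name the line."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line.rstrip("\n")) < 54:
                raise TrajectoryParseError(
                    f"{path}: malformed ATOM record on line {ln} (truncated)"
                )


def read_multimodel_pdb(path, system: SystemTopology) -> np.ndarray:
    """Read a (multi-)model PDB into an (n_frames, n_atoms, 3) stack.

    Atoms are matched to the topology by (chain id, residue number, atom
    name), so the file's atom order is irrelevant.  Missing or surplus
    atoms raise with the offending identifier.
    """
    from biotite.structure.io.pdb import PDBFile

    _validate_atom_lines(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except TrajectoryParseError:
        raise
    except Exception as exc:  # biotite's own parse failures
        raise TrajectoryParseError(f"{path}: cannot parse PDB ({exc})") from exc

    import biotite.structure as struc

    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    n_atoms_file = stack.array_length()
    if n_atoms_file != system.n_atoms:
        raise TrajectoryParseError(
            f"{path}: file has {n_atoms_file} atoms, topology expects {system.n_atoms}"
        )
    key_to_file = {
        (stack.chain_id[i], int(stack.res_id[i]), stack.atom_name[i]): i
        for i in range(n_atoms_file)
    }
    order = np.empty(system.n_atoms, dtype=int)
    for i in range(system.n_atoms):
        key = (system.chain_ids[i], int(system.res_ids[i]), system.names[i])
        if key not in key_to_file:
            raise TrajectoryParseError(
                f"{path}: atom {system.atom_label(i)} missing from file"
            )
        order[i] = key_to_file[key]
    return np.asarray(stack.coord, dtype=float)[:, order, :]


# ---------------------------------------------------------------------------
# Plain-text frame stream
# ---------------------------------------------------------------------------

_FRAME_MAGIC = "#gagnet-frames 1"


def write_frame_stream(system: SystemTopology, coords: np.ndarray,
                       frame_spacing: float, path) -> None:
    """Write coordinates as a documented fixed-width text stream.

    Header: magic line, then ``n_frames n_atoms frame_spacing_ps``.  Each
    frame is one ``FRAME i`` line followed by ``n_atoms`` lines of three
    fixed-width ``%12.4f`` coordinates in topology atom order.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms, _ = coords.shape
    if n_atoms != system.n_atoms:
        raise ValueError("coordinate count does not match the topology")
    with open(path, "w") as fh:
        fh.write(_FRAME_MAGIC + "\n")
        fh.write(f"{n_frames} {n_atoms} {frame_spacing:.6g}\n")
        for t in range(n_frames):
            fh.write(f"FRAME {t}\n")
            for row in coords[t]:
                fh.write("".join(f"{x:12.4f}" for x in row) + "\n")


def read_frame_stream(path, system: SystemTopology) -> tuple[np.ndarray, float]:
    """Read a frame stream; returns (coords stack, frame spacing in ps)."""
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _FRAME_MAGIC:
            raise TrajectoryParseError(f"{path}: not a gagnet frame stream")
        n_frames, n_atoms, spacing = fh.readline().split()
        n_frames, n_atoms, spacing = int(n_frames), int(n_atoms), float(spacing)
        if n_atoms != system.n_atoms:
            raise TrajectoryParseError(
                f"{path}: stream has {n_atoms} atoms, topology expects {system.n_atoms}"
            )
        coords = np.empty((n_frames, n_atoms, 3), dtype=float)
        for t in range(n_frames):
            header = fh.readline()
            if not header.startswith("FRAME"):
                raise TrajectoryParseError(f"{path}: missing FRAME header for frame {t}")
            for i in range(n_atoms):
                line = fh.readline()
                coords[t, i] = [float(line[j * 12:(j + 1) * 12]) for j in range(3)]
    return coords, spacing


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

#: fixed float format so reruns are byte-identical and cells parse back exactly
_FLOAT_FORMAT = "%.8g"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT, lineterminator="\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def write_tables(results: dict, out_dir) -> list[str]:
    """Write a results bundle to ``out_dir`` with deterministic names.

    ``results`` maps a base file name (without extension) to either a
    DataFrame (written as ``<name>.tsv``) or a JSON-serialisable object
    (written as ``<name>.json``).  Returns the written file names.
    """
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.tsv"
            write_tsv(obj, out_dir / fname)
        else:
            fname = f"{name}.json"
            write_json(obj, out_dir / fname)
        written.append(fname)
    return written
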