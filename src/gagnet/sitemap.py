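"""Site-class pair maps.

Bond observations are aggregated over donor/acceptor functional-group
classes into a per-pair map: observation count, total and mean energy,
and log10 of the total energy for occupied cells (the customary display
scale for such maps).  Intramolecular maps fold donor/acceptor
orientation into unordered class pairs (66 cells for 11 classes);
the intermolecular map keeps the (HA class, CS class) orientation
(121 cells).  Cells with no observation are *absent*; occupied + absent
always equals the pair-space size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hbond import CATEGORY_INTER, CATEGORY_INTRA_CS, CATEGORY_INTRA_HA

__all__ = ["PairMap", "build_pair_map", "absent_pair_count"]

_MODES = (CATEGORY_INTRA_HA, CATEGORY_INTRA_CS, CATEGORY_INTER)


@dataclass
class PairMap:
    """Aggregated bond statistics over a class-pair space."""

    mode: str
    pair_space: list[tuple[str, str]]
    count: dict[tuple[str, str], int]
    total_energy: dict[tuple[str, str], float]

    @property
    def occupied(self) -> list[tuple[str, str]]:
        return [p for p in self.pair_space if self.count.get(p, 0) > 0]

    @property
    def absent(self) -> list[tuple[str, str]]:
        return [p for p in self.pair_space if self.count.get(p, 0) == 0]

    def mean_energy(self, pair: tuple[str, str]) -> float:
        n = self.count.get(pair, 0)
        if n == 0:
            raise KeyError(f"pair {pair} has no observations")
        return self.total_energy[pair] / n

    def log10_total_energy(self, pair: tuple[str, str]) -> float:
        """Display value log10(summed energy); defined only for occupied cells."""
        if self.count.get(pair, 0) == 0:
            raise KeyError(f"pair {pair} has no observations")
        return float(np.log10(self.total_energy[pair]))

    # -- exports ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """One row per cell: a, b, n, total, mean, log10_total (NaN if absent)."""
        rows = []
        for a, b in self.pair_space:
            n = self.count.get((a, b), 0)
            total = self.total_energy.get((a, b), 0.0)
            rows.append(
                (a, b, n, total,
                 total / n if n else np.nan,
                 float(np.log10(total)) if n else np.nan)
            )
        return pd.DataFrame(
            rows, columns=["class_a", "class_b", "n", "total_energy",
                           "mean_energy", "log10_total_energy"]
        )

    def to_matrix(self) -> pd.DataFrame:
        """Square (intra) or rectangular (inter) log10-total-energy matrix;
        absent cells are NaN (written as the sentinel NA in TSV)."""
        rows = sorted({p[0] for p in self.pair_space})
        cols = sorted({p[1] for p in self.pair_space})
        if self.mode != CATEGORY_INTER:
            rows = cols = sorted(set(rows) | set(cols))
        mat = pd.DataFrame(np.nan, index=rows, columns=cols)
        for a, b in self.occupied:
            v = self.log10_total_energy((a, b))
            mat.loc[a, b] = v
            if self.mode != CATEGORY_INTER:
                mat.loc[b, a] = v
        mat.index.name = "class"
        return mat

    def to_json_dict(self) -> dict:
        return {
            "mode": self.mode,
            "occupied": len(self.occupied),
            "absent": len(self.absent),
            "cells": [
                {
                    "a": a, "b": b,
                    "n": self.count.get((a, b), 0),
                    "total": self.total_energy.get((a, b), 0.0),
                    "mean": (self.total_energy[(a, b)] / self.count[(a, b)])
                    if self.count.get((a, b), 0) else None,
                }
                for a, b in self.pair_space
            ],
        }


def _fold(mode: str, donor_class: str, acceptor_class: str,
          donor_species: str) -> tuple[str, str]:
    if mode == CATEGORY_INTER:
        # orient as (HA class, CS class)
        if donor_species == "HA":
            return (donor_class, acceptor_class)
        return (acceptor_class, donor_class)
    return tuple(sorted((donor_class, acceptor_class)))


def build_pair_map(
    observations: pd.DataFrame,
    mode: str,
    pair_space: list[tuple[str, str]],
) -> PairMap:
    """Aggregate categorized, class-labelled observations into a pair map.

    Only observations of the matching category are counted.  For the
    intermolecular map, cells are oriented (HA class, CS class) using the
    observation's donor species.  Intra maps fold donor/acceptor order
    into unordered cells.

    Raises
    ------
    KeyError
        If an observation's class pair falls outside ``pair_space``.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    space = set(map(tuple, pair_space))
    count: dict[tuple[str, str], int] = {}
    total: dict[tuple[str, str], float] = {}
    sel = observations[observations["category"] == mode]
    for row in sel.itertuples(index=False):
        dsp = getattr(row, "donor_species", "HA")
        cell = _fold(mode, row.donor_class, row.acceptor_class, dsp)
        if cell not in space:
            raise KeyError(
                f"class pair {cell} outside the {mode} pair space "
                f"(labels {row.donor_class!r}, {row.acceptor_class!r})"
            )
        count[cell] = count.get(cell, 0) + 1
        total[cell] = total.get(cell, 0.0) + float(row.energy)
    return PairMap(mode=mode, pair_space=sorted(map(tuple, pair_space)),
                   count=count, total_energy=total)


def absent_pair_count(pair_map: PairMap) -> int:
    """Number of pair-space cells with zero observations."""
    return len(pair_map.absent)
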