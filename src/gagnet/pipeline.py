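"""End-to-end workflow: generate → detect → track → map → network.

One :class:`RunConfig` drives the whole analysis over a list of
temperatures; each temperature gets its own seeded trajectory (or a user
trajectory is analysed as-is), per-frame bond tables, bond events,
distributions, the three pair maps and the class graphs with their
characteristic path lengths.  All outputs are deterministic for a fixed
config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, sitemap, swnet, trajio
from .hbond import (
    CATEGORY_INTER,
    CATEGORY_INTRA_CS,
    CATEGORY_INTRA_HA,
    HBondCriteria,
    detect_trajectory,
)
from .synthetic_data import (
    BondSiteSpec,
    KineticsSpec,
    SyntheticTrajectory,
    default_planted_sites,
    generate_trajectory,
    write_ground_truth,
    write_trajectory,
)
from .topology import SystemTopology, build_system, enumerate_pair_space

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_trajectory", "PipelineError"]

_CATEGORIES = (CATEGORY_INTRA_HA, CATEGORY_INTRA_CS, CATEGORY_INTER)
_SCOPES = ("HA", "CS", "HA-CS")


class PipelineError(RuntimeError):
    """At least one per-temperature run failed."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int
    temperatures: tuple[float, ...] = (300.0, 310.0, 320.0)
    n_frames: int = 1000
    frame_spacing: float = 10.0  # ps
    ha_repeats: int = 10
    cs_chains: int = 3
    cs_repeats: int = 4
    gap_tolerance: int = 0
    criteria: HBondCriteria = field(default_factory=HBondCriteria)
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    sites: list[BondSiteSpec] | None = None
    weight_types: tuple[str, ...] = ("length", "energy", "number")
    length_frame_stride: int = 5
    trajectory_path: str | None = None  # analyse this PDB instead of generating
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.temperatures:
            raise ValueError("temperatures must be nonempty")
        for w in self.weight_types:
            if w not in ("length", "energy", "number"):
                raise ValueError(f"unknown weight type {w!r}")


def _log_provenance(config: RunConfig) -> None:
    c = config.criteria
    logger.info(
        "criteria: H-A < %.4g A, D-A < %.4g A, E > %.4g kJ/mol "
        "(optimum %.4g, saturation %.4g A, zero %.4g A, norm %.4g A); seed %d",
        c.max_h_acceptor, c.max_donor_acceptor, c.min_energy,
        c.optimum_energy, c.saturation_distance, c.zero_distance,
        c.normalization, config.seed,
    )


def analyze_trajectory(
    system: SystemTopology,
    coords: np.ndarray,
    frame_spacing: float,
    criteria: HBondCriteria | None = None,
    gap_tolerance: int = 0,
    weight_types: tuple[str, ...] = ("length", "energy", "number"),
    length_frame_stride: int = 1,
) -> tuple[dict, dict]:
    """Run the full analysis on one coordinate stack.

    Returns ``(report_block, results)`` where ``results`` maps output
    base names to DataFrames/JSON objects ready for
    :func:`gagnet.trajio.write_tables`.
    """
    criteria = criteria or HBondCriteria()
    n_frames = int(np.asarray(coords).shape[0])
    observations = detect_trajectory(coords, system, criteria)
    events = dynamics.track_bonds(
        observations, frame_spacing, gap_tolerance=gap_tolerance, n_frames=n_frames
    )
    timeseries = dynamics.energy_timeseries(observations, n_frames)

    results: dict = {"observations": observations, "events": events,
                     "energy_timeseries": timeseries}
    report: dict = {
        "n_frames": n_frames,
        "frame_spacing_ps": frame_spacing,
        "n_observations": int(len(observations)),
        "n_events": int(len(events)),
    }

    distributions = {}
    import warnings as _warnings

    for cat in (None, *_CATEGORIES):
        key = cat or "all"
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            dur = dynamics.duration_distribution(events, category=cat)
            length = dynamics.length_distribution(observations, category=cat)
        distributions[key] = {
            "duration": dur.summary() | (
                {"cdf_2ns": dur.cdf(2.0)} if dur.n else {}
            ),
            "length": length.summary(),
        }
    results["distributions"] = distributions
    report["distributions"] = distributions

    ha_classes = system.class_labels("HA")
    cs_classes = system.class_labels("CS")
    spaces = {
        CATEGORY_INTRA_HA: enumerate_pair_space(ha_classes, mode="intra"),
        CATEGORY_INTRA_CS: enumerate_pair_space(cs_classes, mode="intra"),
        CATEGORY_INTER: enumerate_pair_space(ha_classes, cs_classes, mode="inter"),
    }
    report["pair_maps"] = {}
    for mode, space in spaces.items():
        pm = sitemap.build_pair_map(observations, mode, space)
        tag = mode.replace("intra-", "intra_").replace("-", "_")
        results[f"pair_map_{tag}"] = pm.to_frame()
        results[f"pair_map_{tag}_summary"] = pm.to_json_dict()
        report["pair_maps"][mode] = {
            "pairs": len(space),
            "occupied": len(pm.occupied),
            "absent": sitemap.absent_pair_count(pm),
        }

    report["cpl"] = {}
    graph_summaries = {}
    for scope in _SCOPES:
        report["cpl"][scope] = {}
        for wt in weight_types:
            graph = swnet.build_class_graph(
                system, wt, scope,
                coords_stack=coords if wt == "length" else None,
                observations=observations if wt != "length" else None,
                n_frames=n_frames,
                **({"frame_stride": length_frame_stride} if wt == "length" else {}),
            )
            cpl = swnet.characteristic_path_length(graph)
            tag = f"{scope.replace('-', '_')}_{wt}"
            results[f"graph_{tag}_edges"] = graph.to_edge_frame()
            results[f"graph_{tag}_paths"] = cpl.to_frame()
            graph_summaries[tag] = {
                "scope": scope,
                "weight_type": wt,
                "cpl": cpl.value,
                "n_pairs": cpl.n_pairs,
                "excluded": len(cpl.excluded),
            }
            report["cpl"][scope][wt] = cpl.value
    results["graph_summary"] = graph_summaries
    return report, results


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured workflow; returns the top-level report.

    With an ``out_dir``, every temperature writes its tables under
    ``<out_dir>/T<temperature>/`` plus a top-level ``report.json``.  A
    failure in one temperature run does not stop the others; if any run
    failed a :class:`PipelineError` is raised after the rest complete
    (the report is attached as its ``report`` attribute).
    """
    _log_provenance(config)
    system = build_system(config.ha_repeats, config.cs_chains, config.cs_repeats)
    report: dict = {"seed": config.seed, "runs": {}}
    failures = []

    if config.trajectory_path is not None:
        coords = trajio.read_multimodel_pdb(config.trajectory_path, system)
        block, results = analyze_trajectory(
            system, coords, config.frame_spacing, config.criteria,
            config.gap_tolerance, config.weight_types, config.length_frame_stride,
        )
        block["source"] = str(config.trajectory_path)
        report["runs"]["user"] = {"status": "ok", **block}
        if config.out_dir is not None:
            files = trajio.write_tables(results, f"{config.out_dir}/user")
            report["runs"]["user"]["files"] = files
    else:
        sites = config.sites if config.sites is not None else default_planted_sites()
        for i, temperature in enumerate(config.temperatures):
            label = f"T{temperature:g}"
            sub_seed = int(config.seed) + 7919 * i
            try:
                traj = generate_trajectory(
                    system, sites, config.kinetics, temperature,
                    n_frames=config.n_frames, frame_spacing=config.frame_spacing,
                    seed=sub_seed,
                )
                block, results = analyze_trajectory(
                    system, traj.coords, config.frame_spacing, config.criteria,
                    config.gap_tolerance, config.weight_types,
                    config.length_frame_stride,
                )
                block["temperature_K"] = temperature
                block["generator_seed"] = sub_seed
                report["runs"][label] = {"status": "ok", **block}
                if config.out_dir is not None:
                    out = f"{config.out_dir}/{label}"
                    files = trajio.write_tables(results, out)
                    write_trajectory(traj, f"{out}/trajectory.pdb", fmt="pdb")
                    write_ground_truth(traj, f"{out}/ground_truth.tsv")
                    report["runs"][label]["files"] = sorted(
                        files + ["trajectory.pdb", "ground_truth.tsv"]
                    )
            except Exception as exc:  # noqa: BLE001 - per-run isolation
                logger.exception("run %s failed", label)
                report["runs"][label] = {"status": "error", "error": str(exc)}
                failures.append(label)

    summary_rows = []
    for label, block in report["runs"].items():
        if block.get("status") != "ok":
            continue
        for scope, by_wt in block["cpl"].items():
            for wt, value in by_wt.items():
                summary_rows.append((label, scope, wt, value))
    report["cpl_table"] = summary_rows

    if config.out_dir is not None:
        import os

        os.makedirs(config.out_dir, exist_ok=True)
        trajio.write_json(report, f"{config.out_dir}/report.json")
        if summary_rows:
            trajio.write_tsv(
                pd.DataFrame(summary_rows, columns=["run", "scope", "weight_type", "cpl"]),
                f"{config.out_dir}/cpl_summary.tsv",
            )

    if failures:
        err = PipelineError(f"failed runs: {', '.join(failures)}")
        err.report = report
        raise err
    return report
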