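"""End-to-end pipeline: trajectory -> tables, SDF cubes and manifests.

``run_pipeline`` orchestrates the stages (H-bond detection, shell
classification, SDFs and plane partition, optional electronic post-
processing) with one declarative :class:`RunConfig` and writes every
output plus the resolved configuration into an output directory, so a
run is reproducible from its own manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .hbond import (
    R_CUT_DEFAULT,
    THETA_CUT_DEFAULT,
    detect_hbonds_trajectory,
    site_stats,
    water_coordination,
    water_roles,
    write_bond_table,
)
from .io_formats import (
    Frame,
    SugarTemplate,
    Topology,
    perceive_topology,
    read_wannier_trajectory,
    read_xyz_trajectory,
)
from .electronic import assign_wannier, dipole_by_class, molecular_dipoles
from .sdf import accumulate_sdf, export_sdf_cube, plane_partition
from .shells import R_PHOBE_DEFAULT, shell_counts
from .stats import bootstrap_mean

log = logging.getLogger("sugarshell")

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Cutoff defaults are the analysis thresholds used throughout:
    r(O...H) < 2.5 Å with the H-O...O angle < 30 deg for hydrogen bonds,
    and r(C...O_water) < 4.5 Å for the hydrophobic shell.
    """

    trajectory: str = ""
    box_edge: float = 15.2640
    template: str = "beta-glucose"
    wannier: Optional[str] = None
    output_dir: str = "sugarshell_out"
    r_cut: float = R_CUT_DEFAULT
    theta_cut: float = THETA_CUT_DEFAULT
    r_phobe: float = R_PHOBE_DEFAULT
    sdf_voxel: float = 0.2
    sdf_extent: float = 6.5
    bootstrap_n: int = 1000
    bootstrap_block: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    site_stats: pd.DataFrame
    shell_means: pd.DataFrame
    plane: pd.DataFrame
    dipole_classes: Optional[pd.DataFrame]
    output_dir: Path


def _load_inputs(config: RunConfig) -> tuple[list[Frame], Topology, SugarTemplate]:
    from .synthetic import sugar_template

    template = sugar_template(config.template)
    traj = read_xyz_trajectory(config.trajectory, box_edge=config.box_edge)
    if not traj:
        raise ValueError(f"{config.trajectory}: empty trajectory")
    topo = perceive_topology(traj[0], template)
    return traj, topo, template


def run_pipeline(
    config: RunConfig,
    traj: Optional[list[Frame]] = None,
    topo: Optional[Topology] = None,
) -> PipelineResult:
    """Run every stage and write the result bundle to the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if traj is None or topo is None:
        log.info("reading trajectory %s", config.trajectory)
        traj, topo, _template = _load_inputs(config)

    log.info("stage hbond: %d frames", len(traj))
    bonds_per_frame = detect_hbonds_trajectory(
        traj, topo, r_cut=config.r_cut, theta_cut=config.theta_cut
    )
    all_bonds = [b for frame_bonds in bonds_per_frame for b in frame_bonds]
    write_bond_table(all_bonds, out / "hbonds.tsv")
    stats = site_stats(all_bonds, topo, n_frames=len(traj))
    stats_df = stats.to_dataframe()
    stats_df.to_csv(out / "site_stats.csv", index=False)

    log.info("stage shells")
    series = shell_counts(
        traj, topo, r_phobe=config.r_phobe, bonds_per_frame=bonds_per_frame
    )
    pd.DataFrame(
        {
            "frame": np.arange(len(traj)),
            "nphile": series.nphile_series,
            "nphobe": series.nphobe_series,
        }
    ).to_csv(out / "shell_series.csv", index=False)
    rows = []
    for name, s in (("NHPHILE", series.nphile_series), ("NHPHOBE", series.nphobe_series)):
        if len(s) >= 2:
            bs = bootstrap_mean(
                s,
                n_resamples=config.bootstrap_n,
                block_length=config.bootstrap_block,
                seed=config.seed,
                observable=name,
            )
            rows.append({"observable": name, "mean": bs.mean, "stderr": bs.stderr})
        else:
            rows.append({"observable": name, "mean": float(np.mean(s)), "stderr": np.nan})
    shell_means = pd.DataFrame(rows)
    shell_means.to_csv(out / "shell_means.csv", index=False)

    log.info("stage sdf")
    for cls in ("all", "hydrophilic", "hydrophobic"):
        grid = accumulate_sdf(
            traj,
            topo,
            shell_class=cls,
            shells=series.assignments,
            voxel_edge=config.sdf_voxel,
            extent=config.sdf_extent,
        )
        export_sdf_cube(grid, topo, traj[0], out / f"sdf_{cls}.cube")
    plane = plane_partition(traj, topo, series.assignments)
    plane_rows = []
    for cls in ("hydrophilic", "hydrophobic"):
        above_s, below_s = plane.above_series[cls], plane.below_series[cls]
        stderr_a = (
            bootstrap_mean(above_s, config.bootstrap_n, config.bootstrap_block,
                           config.seed, f"{cls}_above").stderr
            if len(above_s) >= 2 else np.nan
        )
        stderr_b = (
            bootstrap_mean(below_s, config.bootstrap_n, config.bootstrap_block,
                           config.seed, f"{cls}_below").stderr
            if len(below_s) >= 2 else np.nan
        )
        plane_rows.append(
            {
                "class": cls,
                "above": plane.above[cls],
                "above_stderr": stderr_a,
                "below": plane.below[cls],
                "below_stderr": stderr_b,
            }
        )
    plane_df = pd.DataFrame(plane_rows)
    plane_df.to_csv(out / "plane_partition.csv", index=False)

    dipole_classes = None
    if config.wannier:
        log.info("stage electronic: %s", config.wannier)
        wframes = read_wannier_trajectory(config.wannier)
        if len(wframes) != len(traj):
            raise ValueError(
                f"{len(wframes)} Wannier frames for {len(traj)} trajectory frames"
            )
        dip_rows = []
        grouped = []
        for fr, wf, frame_bonds in zip(traj, wframes, bonds_per_frame):
            assignment = assign_wannier(fr, topo, wf)
            dipoles = molecular_dipoles(fr, topo, assignment)
            coord = water_coordination(fr, topo, frame_bonds)
            roles = water_roles(topo, frame_bonds)
            grouped.append(dipole_by_class(dipoles, coord, roles))
            for d in dipoles:
                dip_rows.append(
                    {
                        "frame": wf.frame_index,
                        "molecule": d.molecule_id,
                        "dipole_D": d.magnitude,
                    }
                )
        pd.DataFrame(dip_rows).to_csv(out / "dipoles.csv", index=False)
        allg = pd.concat(grouped, ignore_index=True)
        dipole_classes = (
            allg.groupby(["coordination", "role"], as_index=False)
            .apply(
                lambda g: pd.Series(
                    {
                        "mean_dipole_D": np.average(g.mean_dipole_D, weights=g["count"]),
                        "count": g["count"].sum(),
                    }
                ),
                include_groups=False,
            )
            .reset_index(drop=True)
        )
        dipole_classes.to_csv(out / "dipole_classes.csv", index=False)
    else:
        log.info("no Wannier input; electronic stage skipped")

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "n_frames": len(traj),
        "n_waters": topo.n_waters,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return PipelineResult(stats_df, shell_means, plane_df, dipole_classes, out)
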