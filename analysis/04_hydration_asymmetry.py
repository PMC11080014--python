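#!/usr/bin/env python
"""Spatial distribution functions and above/below-plane shell asymmetry.

Accumulates the water-oxygen SDF in the molecule-fixed frame (origin at
the sugar center of mass, XY plane through C5-CM-C1, +x along the
C5-CM-C1 bisector) for the hydrophilic and hydrophobic shells, exports
viewer-ready cube files, and counts shell waters above and below the
molecular plane — the quantity in which the β anomer's O1/O6 geometry
shows up as shell symmetry.
"""

from pathlib import Path

import pandas as pd

from sugarshell.io_formats import perceive_topology, read_xyz_trajectory
from sugarshell.sdf import accumulate_sdf, export_sdf_cube, plane_partition
from sugarshell.shells import shell_counts
from sugarshell.stats import bootstrap_mean
from sugarshell.synthetic import sugar_template

ROOT = Path(__file__).resolve().parents[1]
SYN = ROOT / "scratch" / "synthetic"
OUT = ROOT / "results" / "tables"
CUBES = ROOT / "scratch" / "sdf_cubes"  # multi-MB volumetric output
BOXES = {"beta": ("beta-glucose", 15.2640), "alpha": ("alpha-glucose", 15.2577)}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    CUBES.mkdir(parents=True, exist_ok=True)
    rows = []
    for tag, (anomer, box) in BOXES.items():
        traj = read_xyz_trajectory(SYN / tag / "trajectory.xyz", box_edge=box)
        topo = perceive_topology(traj[0], sugar_template(anomer))
        series = shell_counts(traj, topo)
        for cls in ("hydrophilic", "hydrophobic"):
            grid = accumulate_sdf(
                traj, topo, cls, series.assignments, voxel_edge=0.25, extent=7.0
            )
            export_sdf_cube(grid, topo, traj[0], CUBES / f"sdf_{tag}_{cls}.cube")
        pp = plane_partition(traj, topo, series.assignments)
        for cls in ("hydrophilic", "hydrophobic"):
            above = bootstrap_mean(pp.above_series[cls], seed=0)
            below = bootstrap_mean(pp.below_series[cls], seed=0)
            rows.append(
                {
                    "system": anomer,
                    "shell": cls,
                    "above": above.mean,
                    "above_stderr": above.stderr,
                    "below": below.mean,
                    "below_stderr": below.stderr,
                }
            )
            print(
                f"{anomer} {cls}: {above.mean:.1f} above / {below.mean:.1f} below "
                f"the XY plane"
            )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "plane_partition.csv", index=False)
    print(f"cube files for visualization in {CUBES}")


if __name__ == "__main__":
    main()
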