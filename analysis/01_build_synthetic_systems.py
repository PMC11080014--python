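#!/usr/bin/env python
"""Build the planted α- and β-glucose hydration systems used downstream.

Each system is one 24-atom hexopyranose plus 99 rigid waters (321 atoms)
in its cubic box, with 11 hydrogen-bonded (hydrophilic) waters, 9
exclusive hydrophobic contacts and 79 bulk waters planted with safety
margins to every classification threshold. Trajectories, Wannier-center
files and the machine-readable truth records land in results/synthetic/.
"""

import json
from pathlib import Path

import numpy as np

from sugarshell.io_formats import write_wannier_trajectory, write_xyz_trajectory
from sugarshell.synthetic import PlantSpec, build_system, make_wannier, sugar_template

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic"  # regenerable intermediates

BOXES = {"beta-glucose": 15.2640, "alpha-glucose": 15.2577}
N_FRAMES = 10
JITTER = 0.03  # Å, well inside the planted margins
SEED = 2024


def main() -> None:
    for anomer, box in BOXES.items():
        out = OUT / anomer.split("-")[0]
        out.mkdir(parents=True, exist_ok=True)
        template = sugar_template(anomer)
        spec = PlantSpec(box_edge=box, n_frames=N_FRAMES, jitter_sigma=JITTER, seed=SEED)
        traj, truth = build_system(spec, template)
        write_xyz_trajectory(traj, out / "trajectory.xyz")
        wframes, _ = make_wannier(traj, truth.topology, template)
        write_wannier_trajectory(wframes, out / "wannier.xyz")
        record = {
            "anomer": anomer,
            "box_edge_A": box,
            "n_frames": N_FRAMES,
            "jitter_A": JITTER,
            "seed": SEED,
            "n_atoms": traj[0].n_atoms,
            "hydrophilic": sorted(truth.hydrophilic),
            "hydrophobic": sorted(truth.hydrophobic),
            "sugar_bonds": truth.sugar_bonds,
            "water_water_bonds": [list(b) for b in truth.water_water_bonds],
            "coordination": np.asarray(truth.coordination).tolist(),
            "above_below": {k: list(v) for k, v in truth.above_below.items()},
        }
        (out / "truth.json").write_text(json.dumps(record, indent=2) + "\n")
        print(
            f"{anomer}: {traj[0].n_atoms} atoms/frame, "
            f"{len(truth.hydrophilic)} hydrophilic + {len(truth.hydrophobic)} "
            f"hydrophobic planted, {len(truth.water_water_bonds)} incidental "
            f"water-water bonds -> {out}"
        )


if __name__ == "__main__":
    main()
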