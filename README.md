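# sugarshell

Hydration-shell analysis of hexopyranose sugars (glucose, galactose,
mannose anomers) in water, for people post-processing ab initio or
classical MD trajectories of one solute in a periodic water box: how many
waters are hydrogen-bonded to each hydroxyl, how many sit in hydrophobic
contact with the ring carbons, how the shell is arranged in space around
the molecule, and what the electronic structure (molecular dipoles,
atomic partial charges) of solute and shell looks like.

## What it computes

**Hydrogen bonds** use the geometric criterion

> donor-O–H···O_acceptor is a bond iff r(H···O) < 2.5 Å **and** the
> H–O···O angle at the donor oxygen < 30°,

with strict inequalities, minimum-image distances and an exact periodic
KD-tree search. Per-site statistics (mean donor/acceptor counts and bond
lengths for O1–O6), water coordination numbers, and 2D (r, θ) maps follow.

**Shells.** The first hydration sphere is split exclusively:

- *hydrophilic* (N<sub>HPHILE</sub>): waters in ≥ 1 sugar–water H-bond;
- *hydrophobic* (N<sub>HPHOBE</sub>): waters with min<sub>i</sub>
  r(C<sub>i</sub>···O<sub>water</sub>) < 4.5 Å that are not H-bonded.

**Spatial distribution functions** are accumulated in the molecule-fixed
frame (origin = solute center of mass; XY plane through C5, CM, C1; +x
along the C5–CM–C1 bisector), normalized to number density or relative
to bulk water (0.0334 molecules/Å³), and exported as Gaussian cube
files. Shell waters are also counted above/below the XY plane.

**Electronic post-processing.** Molecular dipoles from Wannier centers
(μ = Σ q<sub>core</sub> r + Σ (−2e) r<sub>center</sub>, cores O +6 / H +1 /
C +4, in Debye), classified by water coordination number and
donor/acceptor role; and grid-based Bader partitioning (on-grid steepest
ascent) giving per-atom charges, atomic dipoles and basin volumes,
aggregated onto the O1–O6/OH sites.

**Uncertainties** for all time averages come from a seeded block
bootstrap over frames.

Because no trajectory data ship with the package, `sugarshell.synthetic`
builds complete test systems — one 24-atom chair hexopyranose + 99 rigid
waters in a ~15.26 Å cubic box (321 atoms) — with *planted* ground truth
for every quantity above, protected by explicit safety margins so jitter
cannot flip a classification.

## Worked example

```python
from sugarshell import (PlantSpec, build_system, sugar_template,
                        perceive_topology, detect_hbonds, classify_shells)

template = sugar_template("beta-glucose")
traj, truth = build_system(PlantSpec(n_frames=3, jitter_sigma=0.0, seed=3), template)
topo = perceive_topology(traj[0], template)
bonds = detect_hbonds(traj[0], topo)          # r_cut=2.5 Å, theta_cut=30°
shell = classify_shells(traj[0], topo, bonds)  # r_phobe=4.5 Å
print(len(bonds), len(shell.hydrophilic), len(shell.hydrophobic))
```

prints `38 11 9`: 38 hydrogen bonds in the frame (11 sugar–water plus 27
incidental water–water bonds), 11 hydrophilic shell waters and 9
hydrophobic ones — exactly the planted populations. The same system run
through the CLI,

```
sugarshell shells --trajectory traj.xyz --output-dir out
```

writes the shell series and prints the bootstrap summary

```
observable  mean  stderr
   NHPHILE  11.0     0.0
   NHPHOBE   9.0     0.0
```

(zero stderr because zero-jitter frames are identical). The numbered
scripts under `analysis/` run the full narrative on planted α- and
β-glucose systems: `01` builds the systems (intermediates under
`scratch/`), `02` reproduces the per-site donor/acceptor statistics and
the donor-shorter-than-acceptor bond-length ordering (mean 1.81 Å vs
2.00 Å on the planted geometry), `03` the shell populations with
bootstrap errors, `04` the SDF cubes and the above/below-plane
asymmetry, and `05` the Wannier-dipole classes and Bader site charges;
tables land in `results/tables/`.

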