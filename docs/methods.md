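# Methods

This note documents the models, conventions and numerical choices behind
`sugarshell`, and what the synthetic-data tests do and do not establish
about real trajectories.

## System and units

The package analyses trajectories of one hexopyranose solute (24 atoms:
ring C1–C5 + O5, hydroxyl oxygens O1–O4 on C1–C4, the exocyclic
C6–O6 hydroxymethyl on C5, five hydroxyl hydrogens and seven C–H
hydrogens) plus N three-site waters in a cubic periodic box. All internal
lengths are Å; GRO input (nm) and Gaussian-cube input (Bohr) are
converted at the I/O boundary, and cube *values* are rescaled
Bohr⁻³ → Å⁻³ so grid integrals (electron counts) are unit-invariant.
Non-cubic cells are rejected rather than silently mishandled. Minimum
imaging uses `round`, so it is valid for unwrapped coordinates.

## Topology perception

Bonds are pairs within 1.2× the covalent-radius sum, with two chemical
guards: H–H pairs never bond, and a hydrogen keeps only its nearest
heavy-atom bond (without these, hydrogens of adjacent waters at
liquid-like packing can fuse two molecules into one component). Connected
components are classified: the unique component matching the solute
template's element multiset is the solute (0 or ≥ 2 matches is an
error); every other component must be H₂O with both H within 1.2 Å of
the O — 1.2 Å cleanly separates covalent O–H (~1.0 Å) from hydrogen
bonds (> 1.5 Å). Solute sites are labeled by graph isomorphism against
the template's own bond graph (this is also how ring C–H hydrogens are
distinguished from hydroxyl hydrogens: by what they are bonded to);
graph-equivalent hydrogens such as the two C6 hydrogens are canonicalized
by sorted index so the site map is invariant under atom reordering.

## Hydrogen-bond criterion

A donor-H···acceptor triple is a bond iff r(H···O_acc) < 2.5 Å and the
angle at the **donor oxygen** between O→H and O→O_acc is < 30°
(θ = 0 is linear). This angle-at-oxygen convention matters: the
alternative angle-at-H convention gives different sets. Both
inequalities are strict; boundary geometries are excluded (measure-zero
for statistics, but deterministic). Donors are hydroxyl and water
oxygens; acceptors all oxygens including the ring O5; intramolecular
sugar–sugar pairs are excluded. Bifurcated donors are kept as two bonds.
Candidate pairs come from a periodic `scipy.spatial.cKDTree` query at
r_cut, which is exact under minimum image (the query is inclusive at the
boundary, so the strict `<` is re-applied); an O(N²) brute-force
enumeration, coded independently in the test suite and acceptance
script, must agree bond-for-bond.

Bond-length statistics average over contributing bonds only; a site with
no bonds of a kind reports NaN rather than entering zero-count frames
into the average.

## Shell classification

Hydrophilic = waters in ≥ 1 sugar–water bond (counted as distinct
molecules, not bonds — one water donating and accepting counts once).
Hydrophobic = waters with min over all six carbons C1–C6 of
r(C···O_w) < 4.5 Å, minus the hydrophilic set. The sets are exclusive by
construction so their sum is a total first-shell population without
double counting. Partial RDFs use the standard 4πr²dr ideal-gas
normalization at the partner number density with the instantaneous (NVT)
box volume; `first_minimum` smooths g(r) with a 3-bin moving average and
returns the first interior local minimum after the first local maximum —
for double-well shapes this is deliberately the *earlier* minimum, and a
monotone curve raises instead of guessing.

## Molecule-fixed frame and SDFs

Origin = mass-weighted solute center of mass (standard atomic masses);
the solute is first made whole by imaging each atom relative to the
first solute atom (valid because the molecule is compact relative to the
half-box). x̂ bisects the unit vectors CM→C5 and CM→C1,
ẑ = (CM→C5)×(CM→C1) normalized, ŷ = ẑ×x̂; C1 and C5 then lie exactly in
the XY plane. Waters are imaged relative to the CM before transforming.
SDFs default to 0.2 Å voxels over ±6.5 Å (±10 Å would exceed the
half-box of the 15.26 Å systems); densities divide by voxel volume ×
frame count, and relative densities by the bulk-water reference
0.0334 molecules/Å³ (computed from 1.00 g/cm³ and M = 18.015 g/mol).
Plane counts assign z = 0 to "above" (measure-zero, deterministic). The
SDF integral × voxel volume equals the mean shell population whenever
the extent covers the shell — this conservation identity is tested.

## Wannier dipoles

Each center carries −2e; cores are valence charges O +6, H +1, C +4
(matching norm-conserving pseudopotential bookkeeping). Dipoles are
summed about the molecular center of mass after making the molecule
whole; for neutral molecules the result is reference-independent (tested
with randomized reference shifts), and a non-neutral grouping without an
explicit reference is an error rather than a silently gauge-dependent
number. Centers are assigned to the molecule of their minimum-image
nearest atom; waters with ≠ 4 centers are flagged and skipped in dipole
reporting, and a center > 1.5 Å from every atom aborts. 1 e·Å = 4.8032 D.

## Bader partitioning

On-grid steepest ascent: every voxel points to the 26-neighbor with the
largest (ρ_nb − ρ)/|Δr|; pointer-jumping resolves each voxel to its
terminal local maximum, maxima map to the nearest atom (an orphan
maximum > 1.0 Å from every atom is an error), and near-vacuum voxels
(< 10⁻⁹ of the peak) go directly to the nearest atom so that
Σ basin electrons ≡ grid integral holds to machine precision. This is
the plain on-grid method without trajectory correction: it carries a
small lattice bias at basin boundaries (sub-percent on the Gaussian
fixtures used here; the bias shrinks from 64³ to 128³ grids but does not
vanish smoothly between all grid pairs). Charges are Z − ∫ρ with Z
either full atomic numbers or caller-supplied (valence or planted)
charges; atomic dipoles are −∫ρ(r − r_atom) about each nucleus, the
standard Bader atomic-moment convention.

## Bootstrap

Moving-block bootstrap: ⌈N/b⌉ contiguous blocks drawn with replacement,
concatenated, truncated to N; stderr = SD of resample means; one seeded
`numpy` generator per call, seed recorded in the result. Default block
length 1 is correct for independent frames only — MD frames are
correlated, and the AR(1) property test shows block ≥ 20 roughly doubles
the stderr at φ = 0.9; callers analysing real trajectories should set
the block length beyond the correlation time.

## Synthetic systems and what they establish

`build_system` plants, by default, the conditions of the β-glucose-like
system: 99 waters in a 15.2640 Å box (15.2577 Å for α-glucose), of which
11 are hydrogen-bonded (each hydroxyl donates one bond and accepts one,
O6 accepts a second), 9 are exclusive hydrophobic contacts at 3.5–4.2 Å
from a carbon, and 79 are bulk, for 321 atoms per frame. Planted
sugar-donor bonds are shorter (1.80 ± 0.06 Å) than sugar-acceptor bonds
(1.95 ± 0.06 Å), reproducing the donor-stronger-than-acceptor ordering.
Waters are rigid (0.9572 Å / 104.52°). Frames are the base configuration
plus i.i.d. Gaussian jitter (default σ = 0.03 Å) at 0.5 fs nominal
cadence.

Every planted classification keeps an explicit margin to its threshold:
bonds at r ≤ 2.2 Å and θ ≤ 15°, non-bonds at r ≥ 2.8 Å or θ ≥ 45°,
hydrophobic contacts ≤ 4.2 Å, bulk ≥ 4.8 Å from carbons, and shell
waters ≥ 0.6 Å from the XY plane (the plane margin also absorbs the
small frame tilt jitter induces through C1/C5/CM). At liquid-like
packing, incidental water–water bonds are unavoidable; orientations are
rejection-sampled so every water–water pair is *unambiguous* under the
margins, and the resulting bonds are recorded in the ground-truth record
— "planted truth" means the full recorded bond set, not only the
sugar–water bonds. A final sweep re-derives every classification from
the built geometry and aborts if any pair is ambiguous or any
sugar–water bond disagrees with the plant.

Hydrophobic-contact distances are sampled up to 4.2 Å (not up to the
4.5 Å threshold itself) precisely so the 0.3 Å margin covers 3σ of the
σ = 0.05 Å jitter used in the robustness tests.

These fixtures establish that the *pipeline* is correct: exact recovery
of planted truth at zero jitter, no classification flips at σ = 0.05 Å,
oracle-exact bond detection, conservation identities. They do **not**
emulate real liquid structure — there is no energetics, no realistic
O–O RDF, no orientational correlations, no shell-water exchange — so
passing tests says nothing about force fields or sampling, only that the
measurement code measures correctly.

Wannier fixtures place two bond centers at half the O–H vectors and two
lone pairs 0.34 Å from O at ±45° off the negative bisector (water
dipole ≈ 4.6 D); the solute gets one center per covalent bond plus two
lone pairs per oxygen (36 centers, completing 864 valence electrons for
the 321-atom system). Density fixtures are sums of isotropic normalized
Gaussians with analytic integrals; widths must exceed 2 voxel edges.

## Problem sizes

Default test and acceptance runs use 3–6 frame trajectories of the full
321-atom system, 200 random 99-water frames for the detector oracle,
128³ grids for the Bader recovery target (64³/40³ for quicker unit
checks), and 50 × N=1000 series for bootstrap calibration — sizes chosen
so the planted statistics are exact and the stochastic calibrations have
comfortable margins.

## Known limitations

- On-grid Bader bias (above); weight-method refinements are out of scope.
- `perceive_topology` is template matching, not general perception; it
  requires exactly one solute and intact waters.
- Non-orthorhombic cells, velocities/forces, D/H isotopes and
  energetic/charge-transfer H-bond definitions are out of scope.
- The first-shell analysis is static: no residence times or exchange
  kinetics.
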