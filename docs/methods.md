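# Methods

`chitosim` analyzes chitosan assembly on *synthetic* all-atom
configurations. This note records the models, the geometry of the
generator, the numerical choices, and what the synthetic setting does and
does not establish about real systems. Units throughout: Å, degrees,
kcal/mol.

## Sequence model

A chain is an ordered list of GlcN / GlcNAc monomers, index 1 at the
non-reducing end. DP is the chain length, DA the GlcNAc fraction, PA the
arrangement. The deterministic patterns require DA×DP to be an integer:
`block` places the GlcNAc run at the reducing end (DP 10, DA 50 % →
`GGGGGAAAAA`; DA 20 % → GlcNAc at positions 9–10), `alternating` spreads
the GlcNAc units as evenly as possible (strict alternation at DA 0.5,
starting with GlcN), `random` draws positions uniformly without replacement
from a seed. Where the acetylated block sits along a real chain is not
observable from composition alone; the placement here is a convention, and
`from_pattern_string` accepts any explicit arrangement.

## Residue templates and chain geometry

Chains are rigid stacks of idealized residue templates (JSON data files in
`chitosim/data/`, swappable by path). Each template is a chair-like pyranose
ring (C1–C5, O5; carbons puckered ±0.25 Å out of the mean plane) carrying
the standard substituents: the amine/acetyl arm on C2 and the O3 hydroxyl on
one lateral side, the C6–O6 hydroxymethyl arm on the other, and the
glycosidic O4 bridging each residue's C4 to the previous residue's C1. GlcN
has 22 atoms, GlcNAc 27 (acetyl C7=O7 plus methyl C8); three cap atoms per
chain (HO4 at the non-reducing end, O1/HO1 at the anomeric end) close the
free valences, so a DP-10 DA-50 % chain has 5·22 + 5·27 + 3 = 248 atoms.
Successive residues are rotated 180° about the chain axis (two-fold screw)
with a rise of 5.2 Å per monomer, the textbook value for β-1,4 glycans. Bond
lengths are standard (C–C ≈ 1.5, C–O ≈ 1.4, O–H 0.96, C–H 1.09, N–H 1.01 Å);
angles are approximate — the templates are geometric stand-ins, not
energy-minimized structures. Two constraints are enforced exactly by the
template generator (`scripts/make_residue_templates.py`): every hydrogen has
exactly one heavy atom within 1.2 Å (the bond-inference rule used by the
h-bond detector), and no non-bonded heavy pair within a chain falls below
1.8 Å (so distance-based bond counting, used by LCPO typing, reproduces the
intended topology).

## Fibril, solution and trajectory generators

`build_fibril` stacks chains on a rectangular lattice: spacing 9.0 Å between
chain axes within a sheet, 5.0 Å between sheets. In the antiparallel
arrangement chain direction alternates in a checkerboard over (sheet,
position), so every adjacent pair — lateral and stacking — is antiparallel.
Every second chain within a sheet is shifted axially by the register offset,
default 1.9 Å for antiparallel and 0 for parallel packing. These defaults
were chosen by scanning spacing and register over the template geometry for
configurations that (a) keep all interchain atom distances above ~1.6 Å and
(b) realize interchain hydrogen bonds between facing hydroxyls — with the
default criteria the sheets form O3–H···O6 bonds, ≈ 0.8 per monomer in a
3×8 fibril. They are properties of these templates, not measured lattice
constants; real chitosan packs more tightly (intra-sheet spacings near
4.5–4.7 Å) because real side groups rotate out of the way, which rigid
templates cannot. Configurations that would put two chains' atoms closer
than 1.0 Å are rejected as steric failures. Positional disorder is modeled
as isotropic per-atom Gaussian noise applied after rigid placement.

`random_solution_frame` places rigid chains with uniformly random rotations
and positions in an orthorhombic box, rejecting placements whose minimum
heavy-atom distance to previously placed chains (minimum image) is below the
separation floor; 24 DP-10 chains in an 85 Å box place reliably up to a
floor of ~6 Å. `solvate_lattice` adds rigid 3-site waters (O–H 0.9572 Å,
H–O–H 104.52°) on a cubic lattice, deleting sites near solute heavy atoms —
it provides water positions for h-bond bookkeeping, not water structure; all
lattice waters share one orientation, so orientation-sensitive water
statistics on it are meaningful only with relaxed angle criteria.

`make_assembly_trajectory` interpolates each chain rigidly between its pose
in a dispersed frame (mixing coefficient λ = 0) and in a fibril centered in
the box (λ = 1): rotations by spherical interpolation of the relative
rotation (Kabsch fit, exact for rigid chains), translations linearly. A
monotone λ schedule emulates progressive ordering. Because chains sweep
straight paths, transient close approaches can form and break a few
hydrogen bonds mid-path; the assembly "signature" (h-bonds per monomer
rising, solvent exposure falling) is therefore assessed by rank correlation
against the schedule plus endpoint ordering, not strict frame-to-frame
monotonicity.

## Hydrogen bonds

An event requires donor→acceptor heavy-atom distance ≤ 3.0 Å and D–H···A
angle ≥ 135° (both configurable; minimum image under a box). Donors are N/O
atoms with at least one hydrogen within 1.2 Å. Acceptors are all oxygens,
plus nitrogens only when they carry two or more hydrogens: a free amine can
accept, an amide nitrogen's lone pair is delocalized into the carbonyl and
cannot — this is what makes GlcN hydrate differently from GlcNAc. Donor and
acceptor in the same residue are never paired; intrachain bonds between
different residues are kept and labeled by scope. Type labels derive purely
from the donor-heavy and acceptor atom names (`O6H-O7`, `NH-O6`, `water-N`);
pair classes from the two residue kinds (NAc–NAc, NAc–N, N–N,
water–solute). Occupancy is the per-frame event count divided by the solute
monomer count (240 for 24 DP-10 chains), averaged over the analyzed frames;
pair-class percentages are per type label. Water-mediated sheet–sheet
contacts are operationalized as bridging waters: a water donating to or
accepting from atoms of ≥ 2 distinct chains in one frame.

Neighbor search uses a KD-tree; the test suite checks exact agreement with a
dense all-pairs evaluation on hundreds of random frames (periodic and
open), and monotonicity of event sets under criteria tightening.

## Order metrics

The chain vector points from the ring-atom centroid of residue 2 to that of
residue 9 (equal weights over C1,C2,C3,C4,C5,O5; equal weighting is declared
for determinism — mass weighting over ring atoms differs negligibly). The
director is the principal eigenvector of the second-moment matrix
(1/N)Σ v vᵀ, which depends only on unsigned orientations; sign and
eigenvalue ties are fixed deterministically. The primary order parameter is
the mean squared projection p2 = (1/N)Σ (v·d)²: exactly 1 for perfectly
aligned (parallel or antiparallel) chains, → 1/3 for isotropic chains. The
conventional nematic order parameter is (3·p2 − 1)/2 and is exposed
alongside. For finite N the fitted director inflates p2 above 1/3 by an
O(N^−1/2) selection bias (~+0.005 at N = 10⁴); tests therefore check the
unbiased fixed-axis projection within 3 standard errors and give the fitted
value twice that band. Adjacent chains (minimum heavy-atom distance ≤ 4.5 Å)
get pair angles arccos(v_i·v_j) ∈ [0°, 180°]; pairs above 90° count as
antiparallel. End-to-end distance uses mass-weighted residue centers of
residues 2 and 9, matching the chain-vector span. Assemblies are connected
components of the chain-contact graph; singleton components are chains in
solution.

## SASA and percent exposure

Shrake–Rupley: each atom's sphere of radius r_vdw + 1.4 Å carries a
deterministic golden-spiral point set (default 960 points); points inside
any neighbor's expanded sphere are occluded. The estimate is exact for an
isolated sphere and converges as the point count grows (two overlapping
spheres agree with the analytic spherical-cap area to < 0.1 % at 5000
points; 120–240 points suffice for percent-exposure trends and are used in
the batched per-frame workflows). LCPO: per-atom area as the published
linear combination of the isolated-sphere area, pairwise neighbor overlaps,
neighbor–neighbor overlaps and the mixed term, with weights keyed by
(element, bonded heavy atoms, carbonyl flag) from the bundled table;
hydrogens carry zero area. On heavy-atom fixtures from these templates LCPO
totals agree with Shrake–Rupley within a few percent (documented accuracy
class ~15 %). Radii: C 1.70, N 1.65, O 1.60, H 1.20 Å.

Percent exposure of a chain = 100 × SASA(chain atoms within the whole
solute) / SASA(the same chain extracted alone, same conformation). The
denominator uses the instantaneous conformation (for rigid chains this
equals any other conformational convention). Waters are excluded from both
contexts by default, and SASA ignores periodic images (an assembly is
treated as a cluster in open solvent). An isolated chain scores exactly
100 %; a core chain of the default 3×8 fibril ≈ 7 %.

## Free-energy surfaces

Samples are (Rg, interchain h-bonds per monomer) per frame, with Rg over
the chains of the largest assembly (all chains when fully dispersed — the
declared fallback) and the h-bond count normalized by all solute monomers.
F(bin) = −kT·ln(count/max count) with kT = 0.596 kcal/mol (300 K); empty
bins are NaN, never zero. Default bins: 0.5 Å in Rg, 0.05 in h-bonds per
monomer. No reweighting is applied; counts are taken as unbiased. Basin
free-energy differences equal −kT ln(n₂/n₁) exactly by construction, and a
two-Gaussian mixture test recovers −kT ln(w₂/w₁) within Monte-Carlo error at
10⁵ samples. The 20-frame synthetic trajectories populate the surface
sparsely; depths comparable to the multi-microsecond sampling regime (a few
kcal/mol between dispersed and assembled basins) require correspondingly
many samples.

## Torsion fitting

The dihedral energy is Σ K_n (1 + cos(nφ − δ_n)), K_n ≥ 0, multiplicities
unique, phases {0°, 180°} by default. Fitting minimizes the RMSE between
model-plus-constant-offset and a tabulated scan: with the conventional phase
set the signed cosine coefficient is solved by ordinary least squares and
its sign mapped to the phase (exact, no iteration); general phase sets
enumerate one phase per multiplicity and solve each assignment by bounded
least squares. The offset absorbs the scan's arbitrary zero, so fits are
invariant to constant shifts, and the fit is exact (machine-precision RMSE)
whenever the target lies in the model span. Adding a multiplicity can never
raise the RMSE (nested models). Scan comparison shifts both scans to minimum
zero before the RMS difference and refuses mismatched angle grids. This
replaces interactive parameter tuning with a deterministic least-squares
procedure whose quality is the reported RMSE.

## What the synthetic setting shows — and what it does not

Passing tests establish that the analyses are correct on configurations
with known answers: exact order-parameter limits, oracle-identical h-bond
detection, analytic SASA agreement, closed-form free energies, exact fit
recovery. The generator spans dispersed through fibrillar states with
controllable order, register, arrangement and noise, and reproduces the
qualitative assembly signature (interchain h-bonds rise as solvent exposure
falls, antiparallel packing dominates ordered sheets at the default
geometry). It does not provide thermodynamics or kinetics: chains are rigid,
water is a lattice or absent, there are no energies, and the particular
h-bond types realized by the idealized sheets (O3–H···O6 at the default
spacing) depend on template geometry rather than on a force field.
Quantitative statements about real chitosan — occupancy percentages, basin
depths, exposure distributions — require trajectories from molecular
dynamics, which this package analyzes but does not produce.

## Problem sizes

The default study setting mirrors a 24-chain, DP-10 system in an
85×85×85 Å box (≈ 6 000 solute atoms). Test and acceptance runs use
20-frame trajectories, 10⁴ orientation vectors, 10⁵ free-energy samples,
200 random frames for the h-bond oracle, and 120–960-point SASA
quadratures; a full acceptance pass takes a few minutes on one CPU.
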