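# Methods

This note documents what each stage of `ncs-hetero` computes, the
conventions and parameters it commits to, what the synthetic generator
does and does not emulate, and the numerical choices a careful user
should know about.

## Structure model and parsing

Coordinate files (PDB v3.3, optionally mmCIF) are parsed with gemmi and
mapped onto a small validated model: chains of residues of atom records,
waters kept separately but retaining their author chain id (water counts
are reported per chain), and the crystal frame (cell + space-group
operators, resolved from the Hermann–Mauguin symbol through gemmi's full
table — an unrecognized symbol is an error, never a guessed lattice).

Altloc semantics follow deposition convention: atoms with a blank altloc
in a residue that also has lettered atoms are shared by every conformer;
a residue *has alternate conformations* iff ≥2 distinct lettered altlocs
appear on its atoms. Lettered-conformer occupancies may sum to at most
1 + 0.01 (rounding in deposited files). Hydrogens are ignored in all
metrics; the target models are X-ray structures without them.

The writer emits fixed-column PDB and round-trips through the parser at
column precision (10⁻³ Å coordinates, 10⁻² occupancy/B). Anisotropic
B records and structure factors are out of scope.

## Superposition and displacement profiles

Superposition is the closed-form Kabsch solution (SVD of the
cross-covariance; a reflection is corrected by flipping the smallest
singular direction) over **all** common Cα atoms with unit weights and
no outlier-rejection cycles. Interactive alignment tools typically
iterate with outlier trimming; that changes absolute Å values slightly
but not which regions move most. We prefer the deterministic contract
and state the difference here rather than emulate a particular tool.

Residues are paired by author numbering (res_seq + insertion code), not
sequence alignment — the intended comparisons are chains of the same
construct. Cα coordinates are taken from the lowest-lettered conformer.
Near-collinear point sets trigger a warning (the rotation about the
point axis is unconstrained); fewer than three pairs is an error.

## B-factor disorder metrics

Because the compared chains come from one crystal and one refinement, no
B-factor normalization is applied anywhere — a deliberate property of
the single-crystal design, asserted by the tests. Chain and per-residue
means are plain unweighted means over atom records (an altloc pair
contributes two records), matching a spreadsheet mean over the deposited
lines; occupancy weighting exists as an option but is off by default.
Waters and non-polymer heteroatoms are excluded from chain averages.

The per-residue relative difference uses the symmetric denominator
100·(B_A−B_B)/mean(B_A,B_B); a plot against a different denominator
(e.g. one chain's value) will differ in the tails, so the convention is
stated in the output schema. Summary tables round B to one decimal and
percent differences to integers; raw CSVs keep full precision. A 0-vs-0
metric reports a 0% difference.

## Rotamers

χ atom quadruples follow the standard per-residue definitions (χ₁ =
N–CA–CB–XG, etc., up to χ₄ for LYS/ARG). Dihedrals use the IUPAC sign
convention on the half-open interval [−180°, 180°), with +180 reported
as −180. Binning is by nearest mode within a half-width: sp³–sp³ wells
p ≈ +60°, t ≈ 180°, m ≈ −60° with half-width 55° (the eclipsed gaps are
OUTLIER); terminal χ with two-fold symmetric ends (PHE/TYR χ₂, ASP χ₂,
GLU χ₃) are folded to [0°, 180°) and binned against modes 0°/90° with
half-width 45°, so 180°-equivalent orientations can never produce a
spurious rotamer difference. This compact modal library is built in; its
labels are deterministic but not guaranteed to coincide with any
external validation tool's tiers, which is why inter-chain difference
fractions should be compared to published numbers with a few percentage
points of tolerance.

A conformer missing any χ-defining atom is INCOMPLETE and dropped from
statistics (no imputation). Zero-χ residues (GLY/ALA) carry a constant
label: they are trivially comparable, always match, and therefore sit in
the denominator of the difference fraction.

Inter-chain comparison enumerates all (conformer_A, conformer_B) label
pairs per position; the position is SAME if any pair matches. Ensemble
tables count one vote per conformer (no occupancy weighting) per
position over all supplied chains; rarity flags an observed label whose
ensemble frequency falls below the threshold (default 0.20). The
structure-level rare count treats a residue as rare if any of its
conformers carries a rare label.

## Crystal lattice, contacts, buried area

Symmetry mates are generated per chain by applying every space-group
operator and integer lattice translations in ±2 cells per axis
(sufficient for a compact molecule in cells ≥ 30 Å) to fractionalized
first-conformer coordinates, keeping mates with ≥1 atom within the
search cutoff of the asymmetric unit. The identity-with-zero-translation
copy of a chain onto itself is excluded; the identity copy of the
*other* chain in the ASU is a legitimate partner, so the in-ASU
interface counts as one contact interface.

A contact interface is a (chain, mate) pair with ≥1 heavy-atom pair
within the contact cutoff (default 4.0 Å); contacting residues are those
with any such atom. Buried area is SASA(chain alone) −
SASA(chain + contacting mates), clipped at zero, using an internal
Shrake–Rupley engine: deterministic golden-spiral test points (default
960/atom), probe 1.4 Å, and a fixed radius table (C 1.70, N 1.55,
O 1.52, S 1.80, P 1.80, SE 1.90 Å). Contact counts and areas are
self-consistent under these published definitions; they are *not*
comparable number-for-number with interface servers (different
algorithms, different criteria), and the package never claims such
agreement.

Altconf-contact attribution counts alternate-conformation residues with
≥1 atom (any conformer) within a shell (default = contact cutoff) of any
mate atom — the residues whose splitting a lattice contact could
plausibly explain.

## Site openness and pocket volume

Openness is the Cα–Cα distance between two marker residues flanking a
site mouth; the default pair (235, 239) corresponds to the L16
allosteric site in PTP1B numbering. It is trivially invariant under
rigid motion and is meant for *ranking* chains/structures along an
open–closed axis.

Pocket volume is a grid approximation: a voxel grid (spacing 0.5 Å,
valid range (0.2, 1.0] Å) anchored to a local frame built
deterministically from the site atoms (centroid + Gram–Schmidt over the
first well-conditioned atom vectors, so the estimate co-moves with the
structure), over a bounding sphere (default 12 Å) around the site
residues. A voxel is pocket if it lies outside every vdW+probe sphere
and at least k of 14 cast rays (6 axial + 8 body-diagonal) hit protein
before leaving the bounding region (default k = 9). The default site
for L16 is all atoms of residues 35–42, 235–245 and 282–298 within the
bounding sphere of their centroid — a reproducible stand-in for sites
that interactive tools delineate visually. Against an analytic spherical
cavity the estimate lands within ~1% at 0.5 Å spacing; 10% is the
documented accuracy bound. This is a deliberate approximation of
alpha-shape pocket computation, not a reimplementation, and no numeric
agreement with such tools is claimed.

## Synthetic generator

The generator builds chains from ideal internal coordinates (N–CA
1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard valence angles, ω = 180°,
chosen φ/ψ — default extended, −140°/+135°) via NeRF construction, with
side chains of 17 residue types placed at requested χ torsions.
B factors are per-residue (baseline + Gaussian bumps); waters are
rejection-sampled 3.0–8.0 Å from the protein; everything is
deterministic under the seed (same seed ⇒ byte-identical PDB).

The two-chain builder emulates a crystal with two non-identical copies
in the asymmetric unit. Chain B is a rigid copy of chain A carrying
designed perturbations, and the builder emits the ground truth each
stage should recover. The loop-shift displacement field is projected
orthogonal to the six rigid-body modes of the Cα set before application
(then rescaled so the apex residue moves by exactly the designed
amount): this makes the cross-covariance of the two Cα sets symmetric,
so the subsequent least-squares fit recovers the rigid placement exactly
and absorbs none of the designed signal — the profile apex reproduces
the design to numerical precision rather than "design minus fit
absorption".

Default study conditions (chosen once, used by tests and the acceptance
script): a 100-residue chain numbered 180–279 (spanning the 235/239
openness markers), chain B with a 1.4 Å Cα loop shift at residue 239
(half-window 3), B factors scaled by 0.75 (a −25% Cα-B differential
after rounding), 149 vs 100 ordered waters (+49%), ten χ₁ rotamer flips
(a 0.10 difference fraction over 100 comparable positions), and 6 vs 5
alternate-conformation residues. A separate 60-residue single-chain
fixture is built in a P1 cell whose a axis is chosen by a clearance scan
so the ±a lattice images touch the chain termini (≥2.6 Å clearance,
terminal residues within the 4 Å contact cutoff — the builder verifies
its own construction): its five altconf residues split 2 at the
engineered interfaces / 3 interior, giving exact contact-attribution
truth. Loop templates (closed / open / extra-open) translate the chain
tail along the marker-pair axis by 0 / 1.4 / 2.8 Å so openness
differences are exact by construction; a hollow golden-spiral carbon
cage provides the analytic pocket reference.

What the generator does **not** emulate: real tertiary structure and
packing density (chains are extended), electron density and refinement
noise, correlated backbone–side-chain motions, realistic solvation, or
occupancy refinement error. Passing the recovery tests therefore shows
the *measurement machinery* is correct and unbiased on known signals; it
does not validate scientific conclusions about any particular real
structure.

## Problem sizes and determinism

Test and acceptance problem sizes (100-residue chains, 200–500-chain
label ensembles, 960 SASA points, 0.5 Å pocket grids) were chosen as the
smallest sizes at which every designed or analytic signal is recovered
with comfortable margins — e.g. ensemble frequencies are checked within
3 binomial standard errors, which at n = 200 distinguishes the designed
0.30 from alternatives. All randomness flows from explicit seeds;
reruns with identical configuration are byte-identical (fixed point
sets, deterministic orderings everywhere).

## Known limitations

- Residue pairing by author numbering only; constructs with different
  numbering need renumbering first.
- The rotamer library is modal and backbone-independent; labels near
  bin boundaries can differ from validation-tool assignments.
- The SASA engine is O(atoms × points × neighbors) pure numpy —
  adequate for chains of a few thousand atoms, not for large complexes.
- Contact counts depend on the cutoff convention; only trends and
  attributions, not absolute interface counts, transfer across
  conventions.
- The generator supports 17 side-chain types (no HIS/TRP/PRO); synthetic
  sequences are drawn from that set.
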