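# Methods

This note records the models, parameter choices and numerical
conventions behind `fibrilscan`, and what the synthetic fixtures do and
do not establish about real fibril data.

## Assembly model and stack extension

A protofilament is an ordered stack of layers (chains), each one folded
monomer, sharing one sequence and author residue numbering.  Author
numbering is never rewritten, so results on tau constructs map directly
onto motif coordinates such as 306–311 (VQIVYK).  Layer order along the
fibril axis is defined by projecting chain centroids onto the first
principal axis of the centroids; "top" is the smaller projection.  The
convention is arbitrary but consistent, and every downstream quantity is
symmetric under reversal.

Stack extension duplicates the assembly, superposes the duplicate's top
two chains onto the current bottom two chains using backbone atoms
(N, CA, C, O), discards the overlapping pair and appends the rest,
repeating until the target layer count is reached, then trims to the
central window (to avoid edge-chain bias) and reletters chains A…
top-to-bottom.  For helically regular input this preserves the
inter-layer transform to machine precision; an overlap RMSD above 0.5 Å
aborts with an error, since stitching incompatible geometry would
fabricate a fibril.  The inter-layer transform is estimated as the
chordal mean of per-pair Kabsch solutions; rise is the projection of the
mean translation on the rotation axis, sign-normalised to be
non-negative (the twist sign follows the same axis choice).

Paired-protofilament inputs are handled by selection only: the retained
chains must form one connected, singly-stacked column, and the partner
filament is discarded.  Alternate locations keep altloc A; waters,
heteroatoms and hydrogens are dropped.

## Geometry

Superposition is closed-form Kabsch with the determinant correction
(mirror solutions are never returned).  Dihedrals follow the IUPAC
convention, degrees on (−180, 180]; terminal and chain-break torsions
(C–N > 2.5 Å) are flagged undefined rather than zero-filled.  The
torsion-driven peptide builder (NeRF internal coordinates, ideal bond
lengths/angles) and the torsion reader are mutual inverses on ideal
geometry, which the tests exploit for exact round trips.

Torsion permissibility is judged against shipped 5°×5° φ/ψ probability
grids for alanine-like residues and glycine, using a highest-density
region: a conformation is allowed at quantile *q* (default 0.995) if its
bin lies inside the smallest region holding *q* of the probability mass.
The shipped grids are **synthetic** Gaussian-mixture stand-ins over the
canonical Ramachandran basins (β, PPII, α_R; plus α_L and the mirror
regions for glycine) — built by `scripts/make_rama_grids.py`, labelled
`*_synthetic.tsv`, and swappable for any grid in the same plain-text
format, e.g. one derived from high-resolution experimental structures.

## SASA and folding burial

SASA uses Shrake–Rupley sphere points on a deterministic golden-section
spiral (default 960 points; 92 is the accepted floor), with a 1.4 Å
probe and per-element van der Waals radii from a shipped table
(C 1.70, N 1.55, O 1.52, S 1.80 Å).  Hydrogens are never considered.
Accuracy anchors: an isolated sphere is analytic (4π(r+probe)²), two
intersecting spheres follow the spherical-cap formula, and a
10,000-point lattice serves as the numerical oracle in tests.

Folding burial compares three states of the central layer: a fully
extended chain rebuilt from sequence at φ = −120°, ψ = +120° (a
conventional β-extended reference), the folded layer alone, and the
folded layer inside the central trimer.  `ΔSASA_single = extended −
monomer`, `ΔSASA_fibril = extended − in-fibril`; extra layers only bury,
so the fibril burial dominates the single-layer burial residue by
residue.  `buried_nonpolar_area` restricts the same difference to carbon
and sulfur atoms.

## The energy surrogate

The published protocol relies on an external molecular-mechanics engine
(full-atom energy function plus a backbone sampler).  `fibrilscan` does
not reimplement it.  The backend is a contract; the built-in
`CrossBetaPotential` is a documented surrogate designed to preserve the
*term structure* and *orderings* the analysis depends on — which
residues are strongly coupled, which mutations are most destabilising —
not absolute energies:

- **attractive**: Lennard-Jones 6 well, ε from per-element well depths
  (geometric-mean mixing), floored at −ε inside the minimum and switched
  smoothly to zero between 5 and 6 Å;
- **repulsive**: the LJ-12 excess inside the minimum, capped at 20
  energy units per pair so clashes saturate instead of exploding;
- **solvation**: per-atom σ·(A − A_max) with A the exposed area, A_max
  the fully exposed area and σ a per-element atomic solvation parameter
  (positive for C/S, negative for N/O).  The reference shift makes a
  free atom contribute zero, so deleting an exposed side chain is
  solvation-neutral while deleting a buried nonpolar one forfeits its
  burial bonus — the behaviour a mutation analysis needs once no
  explicit unfolded-state reference energy exists;
- **electrostatic**: screened Coulomb between single charged-group atoms
  (Lys NZ, Arg CZ, Asp OD1, Glu OE1), cut at 8 Å.

Pairs within a residue or between sequence-adjacent residues of a chain
are excluded as bonded neighbourhood.  Per-residue attribution splits
every pair term half/half between the partners and assigns solvation to
the owning atom, which makes `edge + internal = assembly` an exact
identity for the layer decomposition (edge = the two terminal layers).

## Scan protocol

Defaults follow the published conditions: 35 replicates per position,
an 8 Å neighbourhood around the mutation site, pairwise harmonic
restraints to the input coordinates for atom pairs within 9 Å at unit
weight, convergence when a sweep improves the objective by less than
one energy unit, glycines excluded, and the alanine mutation applied in
every layer.  The backbone-sampling step of the original protocol is
replaced by seeded side-chain χ jitter (Gaussian, default 8°) around
the site: the replicate ensemble plays the same statistical role
(per-position mean ± spread) at desk scale.  Sampler parameters of the
external engine (backrub temperature 1.2 kT, 35,000 steps) are recorded
in `ScanConfig.sampler_note` for provenance but unused by the built-in
backend.

Each replicate relaxes a perturbed copy (greedy coordinate descent on
backend energy plus restraints; trial moves are bounded χ steps of
±10° and ±10/3°, so descent ends near — not bit-identically at — the
input, which is where the ensemble spread comes from), then branches
into a mutant arm (mutate → repack → relax) and a wild-type arm
(repack → relax).  Branch arms run without fresh perturbation and from
identical random streams, so an alanine-to-alanine scan gives exactly
zero at every replicate.  The backbone is fixed throughout: restrained
minimisation keeps fibril backbones near-native anyway, and a fixed
backbone makes the surrogate deterministic and fast.
Bound states are scored directly; the unbound state rigidly translates
the central trimer 512 Å along x (any separation beyond all cutoffs is
equivalent) without re-optimisation.  Replicate seeds derive from
(seed, position, replicate), so scans are reproducible and
parallelisable by position.  The mean over replicates (not the median)
is reported.

External score tables (TSV: structure_id, residue, replicate,
bound_mut, bound_wt) can be ingested in place of the surrogate, giving
the same downstream objects for engine-produced data.

## Profiles and statistics

Mean ΔREU profiles are min–max normalized to 0–100 per structure; a
degenerate (constant) profile maps to all zeros.  Excluded positions
stay NA and are skipped by the 5-residue window (divisor = values
actually present, truncated at termini) rather than propagated, keeping
motif-level maps contiguous.  Hotspots are residues above 40, neutral
below 10; the band between is deliberately unassigned.  The
Kyte–Doolittle scale ships as data.  The Mann–Whitney U test is exact
(no ties, C(n1+n2, n1) ≤ 2·10⁶) with a midrank tie-corrected normal
approximation otherwise; the result records which path was used.

## Classification

Replicate profiles are normalized with one scale per structure (min/max
of the replicate-mean profile) — a per-replicate scale was tried and
rejected because it injects row-scale noise — then restricted to
residues scanned in every structure.  Structure-level relationships use
Euclidean distances between replicate-mean profiles and Ward linkage
(scipy).  For classification, residues are agglomerated to 20 composite
clusters (Ward/Euclidean feature agglomeration, cluster value = member
mean), and a 100-tree random forest is trained per restart on a
per-structure split of replicates (9 train / 26 test of 35; the
published protocol's numbers, exposed as options), keeping the
best-held-out-accuracy restart with ties to the earlier restart.  The
default restart count is 50; the published value (2500) is available by
flag.  Structure labels map to parent classes via a shipped editable
table plus a suffix-stripping rule (`_T1`, `-PHF`, `-SF`, …).

Predictions are decomposed by walking each tree's decision path and
attributing the change in class-probability at every split to the
splitting feature; bias is the mean root probability.  The identity
`bias + Σ contributions = predict_proba` holds to floating-point
round-off for every sample, tree count and depth.

## Synthetic fixtures — what they show and what they don't

The fibril generator threads a sequence onto a 2-D fold path (straight
strand, hairpin, two-sided serpentine presets) with a zig-zag backbone
reproducing 3.8 Å CA spacing, side chains pointing alternately to the
two sheet faces, and rigid (rise, twist) stacking (defaults 4.75 Å,
−1.0°, inside the canonical cross-β spacing).  Side chains use a
simplified pseudo-atom representation: shells of heavy atoms along a
35°-kinked side-chain axis with per-residue atom counts and elements
from a template.  This preserves the size, nonpolarity and charge
orderings that drive SASA and the surrogate potential; it does not
reproduce rotamer-level packing.  Serpentine strand spacing (≈11.7 Å
with 4-residue turns) puts facing pseudo side chains near their contact
minimum, a steric-zipper-like regime.

Planted-signal fixtures define the recovery conditions: three buried
hydrophobics (I/L/F) on the core strand of a nine-layer two-sided fold
against a serine background with glycine turns; and, for
classification, seven classes × two structures × 35 replicates with
three class-distinctive residues elevated by Δ = 3σ above a base ramp
(ramp ends left unplanted so the normalization anchors are
class-independent; noise σ = 3 on the raw scale).

Passing these tests shows the pipeline recovers planted energetic
structure through the full chain — geometry → energetics → profiles →
classification — under controlled conditions.  It does not show that
the surrogate reproduces engine energetics on deposited structures;
for that, ingest external score tables.

## Numerical choices and limitations

- Scan problem sizes in tests and the acceptance script: 20-residue
  layers, nine (energetics) or five (burial-coupling) layers, 1–3
  replicates, chosen as the sizes the method's properties are invariant
  to; protocol constants stay at their published defaults.
- The SASA kernel is numba-compiled with an exact neighbour-candidate
  construction (supersets with a displacement margin during descent), so
  local energy deltas equal full-score deltas to round-off.
- Interface ΔΔG requires ≥5 layers (a central trimer and a nonempty
  remainder); layer decomposition requires ≥3.
- The generator's rigid backbone cannot reproduce edge-strand
  relaxation; consequently the observed edge/internal behaviour is
  "edge contributes much less per layer than internal", not the
  edge-stabilising sign flip reported for engine-relaxed fibrils.
- Charged termini are not modelled; electrostatics acts only between
  side-chain charge groups.
- Whether per-residue SASA should include hydrogens is moot here:
  inputs are heavy-atom models and hydrogens are always excluded.
- The extended-monomer reference uses the package's own side-chain
  representation; for engine-derived structures the extended state is
  therefore consistent in representation with synthetic fibrils but not
  with full-atom models.
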