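# fibrilscan

Energetic profiling and classification of amyloid fibril polymorphs.

Amyloid fibrils — including the tau fibrils of Alzheimer's disease, CBD,
PSP and other tauopathies — are stacks of identically folded monomer
layers in a cross-β architecture (≈4.75 Å rise per layer, slight helical
twist).  One protein sequence can adopt many distinct folds
(*polymorphs*), and which residues stabilise each fold is not obvious
from structure alone.  `fibrilscan` estimates that per-residue
contribution computationally and uses the resulting energetic profiles
to tell polymorphs apart.

The core quantities, for a mutation of residue *i* to alanine applied in
every layer of the assembly:

```
ΔREU_assembly(i)  = bound_mut − bound_wt
ΔΔG_interface(i)  = [bound − unbound]_mut − [bound − unbound]_wt
```

where *bound* is the energy of the relaxed stack, *unbound* rigidly
separates the central trimer from the remaining layers without
re-optimisation, and each value is averaged over an ensemble of
replicates (35 by default) generated by seeded side-chain perturbation
plus restrained relaxation.  Glycines are excluded (no side chain to
truncate).  Mean ΔREU profiles are min–max normalized to 0–100 per
structure; residues above 40 are *hotspots*, below 10 *neutral*.
Downstream, profiles from many structures are intersected on common
residues, clustered (Ward/Euclidean), agglomerated to 20 composite
residue clusters, and classified with a best-of-restarts random forest
whose every prediction is decomposed exactly into a bias plus
per-cluster contributions.

The package is organised as a library:

| module | what it does |
| --- | --- |
| `fibrilscan.model` | layered assembly data model, PDB/mmCIF IO, protofilament selection, stack extension by superposition |
| `fibrilscan.geometry` | Kabsch superposition, backbone RMSD, φ/ψ/ω torsions, torsion-permissibility grids |
| `fibrilscan.sasa` | Shrake–Rupley SASA, extended-monomer reference state, two-state ΔSASA folding burial |
| `fibrilscan.energetics` | the alanine-scan engine with a pluggable backend (built-in `CrossBetaPotential` surrogate), edge/internal layer decomposition, external score ingestion |
| `fibrilscan.profiles` | normalization, 5-residue windowing, hotspot calling, Kyte–Doolittle hydropathy, exact Mann–Whitney |
| `fibrilscan.classify` | profile matrices, Ward clustering, feature agglomeration, random-forest protocol, decision-path contribution decomposition |
| `fibrilscan.synthetic` | synthetic cross-β fibrils (fold presets, planted hotspots) and replicate-structured profile generators |
| `fibrilscan.cli` | thin `fibrilscan` command (`synth`, `stack`, `sasa`, `scan`, `profile`, `classify`) |

Real use targets deposited fibril structures (PDB/mmCIF) and,
optionally, per-replicate score tables produced by an external energy
engine (`ingest_external_scores`).  The built-in potential is a
documented surrogate that preserves term structure and orderings, not
absolute energies — see `docs/methods.md`.

## Worked example

`examples/02_alanine_scan.py` builds a nine-layer synthetic fibril with
three buried hydrophobics (Ile9, Leu10, Phe11) planted on the core
strand of a two-sided serpentine fold against a serine background, scans
every position, and prints:

```
sequence SSSSSGGSILFSSGGSSSSS  planted hotspots at [9, 10, 11]
excluded (glycine turns): [6, 7, 14, 15]
top 5 by mean ΔREU (positive = mutation destabilises the fibril):
  F11:    72.51
  I9:     57.15
  L10:    54.54
  S13:    -4.13
  S4:     -4.24
I9 decomposition: edge 11.53 + internal 45.62 = assembly 57.15
```

The three planted residues top the ranking by a wide margin — truncating
a buried hydrophobic costs the assembly its packing and burial energy —
while background serines are near zero.  The edge/internal split shows
the destabilisation concentrated in the interior layers, and sums to the
assembly value exactly.  The other example scripts cover stack building
(`01`), ΔSASA burial (`03`), profile/hotspot statistics (`04`) and
polymorph classification with per-cluster attribution (`05`); each
prints a short, annotated result in under a minute.

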