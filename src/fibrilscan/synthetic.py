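"""Synthetic cross-β fibrils and replicate-structured energetic profiles.

The fibril generator threads a sequence onto a 2-D fold path (the monomer
fold in the layer plane), builds an idealised β-layer with side chains
pointing alternately to the two sheet faces, and stacks ``n_layers``
copies with a constant helical (rise, twist) transform — emulating the
cross-β architecture (≈4.75 Å rise, small left-handed twist).  The profile
generator emits replicate-structured per-residue energy tables with
planted class means plus Gaussian noise, in the external-score ingest
schema, so the classification stage is testable without any scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._aa import CANONICAL
from .construct import sidechain_atoms
from .model import Atom, FibrilAssembly, Layer, Residue, StructureError

CA_SPACING = 3.8  # Å between consecutive fold-path points
DEFAULT_RISE = 4.75  # Å, inside the canonical 4.7-4.8 cross-β spacing
DEFAULT_TWIST = -1.0  # degrees per layer

# backbone zigzag offsets reproducing CA-CA 3.8 Å with ideal bond lengths
_C_PAR, _N_PAR, _PERP = 1.267, 1.194, 0.83


@dataclass
class FibrilSpec:
    """Recipe for an idealised protofilament stack."""

    sequence: str
    fold_path: np.ndarray  # (m, 2) CA positions in the layer plane, Å
    rise: float = DEFAULT_RISE
    twist: float = DEFAULT_TWIST
    n_layers: int = 5
    jitter_sigma: float = 0.0
    rng_seed: int = 0
    author_start: int = 1

    def __post_init__(self) -> None:
        self.fold_path = np.asarray(self.fold_path, dtype=float)
        if self.fold_path.shape != (len(self.sequence), 2):
            raise StructureError("fold_path must provide one 2-D point per residue")
        bad = set(self.sequence.upper()) - CANONICAL
        if bad:
            raise StructureError(f"non-canonical residues: {sorted(bad)}")
        steps = np.linalg.norm(np.diff(self.fold_path, axis=0), axis=1)
        if len(steps) and (steps.min() < 3.5 or steps.max() > 4.1):
            raise StructureError(
                f"fold-path spacing must be ≈{CA_SPACING} Å (got "
                f"{steps.min():.2f}–{steps.max():.2f})"
            )


# ---------------------------------------------------------------------------
# fold paths
# ---------------------------------------------------------------------------

def straight_path(n: int) -> np.ndarray:
    return np.column_stack([CA_SPACING * np.arange(n), np.zeros(n)])


def _walk(headings_deg: np.ndarray) -> np.ndarray:
    pts = [np.zeros(2)]
    for h in np.radians(headings_deg):
        pts.append(pts[-1] + CA_SPACING * np.array([np.cos(h), np.sin(h)]))
    return np.array(pts)


def meander_path(n_strands: int, n_strand: int, n_turn: int = 4) -> np.ndarray:
    """Serpentine path: parallel strands joined by ~180° turns.

    With the default 4-residue turns the inter-strand spacing is ≈11.7 Å,
    which puts facing pseudo side chains near their contact minimum (a
    steric-zipper-like packing) rather than in clash.
    """
    headings = []
    direction = 0.0
    for s in range(n_strands):
        headings.extend([direction] * (n_strand - 1))
        if s < n_strands - 1:
            sweep = 180.0 if s % 2 == 0 else -180.0
            step = sweep / (n_turn + 1)
            for k in range(1, n_turn + 2):
                headings.append(direction + step * k)
            direction += sweep
    return _walk(np.array(headings))


def hairpin_path(n_strand: int, n_turn: int = 4) -> np.ndarray:
    return meander_path(2, n_strand, n_turn)


def inward_positions(spec: FibrilSpec) -> list[int]:
    """Author numbers whose side chains face the fold interior."""
    path = spec.fold_path
    centroid = path.mean(axis=0)
    out = []
    for i in range(len(path)):
        s = _side_direction(path, i)
        if s @ (centroid - path[i]) > 0:
            out.append(spec.author_start + i)
    return out


# ---------------------------------------------------------------------------
# layer / stack construction
# ---------------------------------------------------------------------------

def _side_direction(path: np.ndarray, i: int) -> np.ndarray:
    lo, hi = max(i - 1, 0), min(i + 1, len(path) - 1)
    t = path[hi] - path[lo]
    t = t / np.linalg.norm(t)
    left = np.array([-t[1], t[0]])
    return left * (1.0 if i % 2 == 0 else -1.0)


def _build_layer(spec: FibrilSpec, chain_id: str = "A") -> Layer:
    path3 = np.column_stack([spec.fold_path, np.zeros(len(spec.fold_path))])
    m = len(path3)
    d2 = np.linalg.norm(path3[:, None, :] - path3[None, :, :], axis=-1)
    np.fill_diagonal(d2, np.inf)
    for k in (1,):
        idx = np.arange(m - k)
        d2[idx, idx + k] = np.inf
        d2[idx + k, idx] = np.inf
    if d2.min() < 3.0:
        raise StructureError("fold path self-intersects (non-adjacent CA < 3.0 Å)")

    z = np.array([0.0, 0.0, 1.0])
    residues = []
    for i, aa in enumerate(spec.sequence.upper()):
        ca = path3[i]
        u_fwd = path3[min(i + 1, m - 1)] - path3[min(i + 1, m - 1) - 1]
        u_fwd = u_fwd / np.linalg.norm(u_fwd)
        u_back = path3[max(i, 1)] - path3[max(i, 1) - 1]
        u_back = u_back / np.linalg.norm(u_back)
        w_i = z * (1.0 if i % 2 == 0 else -1.0)
        w_prev = z * (1.0 if (i - 1) % 2 == 0 else -1.0)
        n_at = ca - _N_PAR * u_back + _PERP * w_prev
        c_at = ca + _C_PAR * u_fwd + _PERP * w_i
        o_at = c_at + 1.23 * w_i
        atoms = [
            Atom("N", "N", n_at),
            Atom("CA", "C", ca.copy()),
            Atom("C", "C", c_at),
            Atom("O", "O", o_at),
        ]
        if aa != "G":
            s2 = _side_direction(spec.fold_path, i)
            s3 = np.array([s2[0], s2[1], 0.0])
            cb = ca + 1.53 * s3
            atoms.append(Atom("CB", "C", cb))
            atoms.extend(sidechain_atoms(aa, n_at, ca, cb))
        residues.append(Residue(author_number=spec.author_start + i,
                                aa_type=aa, atoms=atoms))
    return Layer(chain_id=chain_id, residues=residues)


def generate_fibril(spec: FibrilSpec) -> FibrilAssembly:
    """Idealised protofilament stack from a fold-path recipe.

    Layer k is layer 0 rotated by ``k·twist`` about the vertical axis
    through the path centroid and translated ``k·rise`` along it, so
    :func:`~fibrilscan.model.estimate_layer_transform` recovers (rise,
    twist) exactly at zero jitter.
    """
    from .model import CHAIN_ALPHABET

    base = _build_layer(spec)
    centroid = np.array([*spec.fold_path.mean(axis=0), 0.0])
    layers = []
    for k in range(spec.n_layers):
        ang = np.radians(spec.twist * k)
        R = np.array([[np.cos(ang), -np.sin(ang), 0.0],
                      [np.sin(ang), np.cos(ang), 0.0],
                      [0.0, 0.0, 1.0]])
        shift = np.array([0.0, 0.0, spec.rise * k])
        residues = []
        for res in base.residues:
            atoms = [Atom(a.name, a.element,
                          R @ (a.coords - centroid) + centroid + shift)
                     for a in res.atoms]
            residues.append(Residue(res.author_number, res.aa_type, atoms))
        layers.append(Layer(chain_id=CHAIN_ALPHABET[k], residues=residues))
    asm = FibrilAssembly(layers=layers)
    if spec.jitter_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        tab = asm.atom_table()
        asm.set_coords(tab["coords"]
                       + rng.normal(0.0, spec.jitter_sigma, tab["coords"].shape))
    asm.log("generate_fibril", sequence=spec.sequence, n_layers=spec.n_layers,
            rise=spec.rise, twist=spec.twist, jitter_sigma=spec.jitter_sigma,
            rng_seed=spec.rng_seed)
    return asm


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def fold_presets(n_layers: int = 5) -> dict[str, FibrilSpec]:
    """Deterministic fold-topology presets.

    ``straight``: single-strand control; ``one_sided``: hairpin whose core
    strand packs against one partner sheet (AD-like topology class);
    ``two_sided``: three-strand serpentine whose central strand is buried
    on both faces (CBD-like topology class).
    """
    return {
        "straight": FibrilSpec("SVSLSVSLSVSL", straight_path(12),
                               n_layers=n_layers),
        "one_sided": FibrilSpec("SVLSISGGSSLSVS", hairpin_path(5, 4),
                                n_layers=n_layers),
        "two_sided": FibrilSpec("SVLSSGGSSILFSGGSSVLS",
                                meander_path(3, 4, 4), n_layers=n_layers),
    }


def planted_hotspot_spec(n_layers: int = 9, rng_seed: int = 0,
                         jitter_sigma: float = 0.0
                         ) -> tuple[FibrilSpec, list[int]]:
    """Two-sided serpentine with buried Ile/Leu/Phe planted on the core strand.

    Returns the spec and the author numbers of the three planted positions
    (all on the central strand, facing both neighbouring sheets), against a
    serine background with glycine turns.
    """
    path = meander_path(3, 4, 4)  # 20 residues: strands of 4, turns of 4
    seq = list("SSSS" + "SGGS" + "SSSS" + "SGGS" + "SSSS")
    core = [8, 9, 10, 11]  # 0-based central-strand indices
    planted_idx = core[:3]
    for idx, aa in zip(planted_idx, "ILF"):
        seq[idx] = aa
    spec = FibrilSpec("".join(seq), path, n_layers=n_layers,
                      jitter_sigma=jitter_sigma, rng_seed=rng_seed)
    return spec, [spec.author_start + i for i in planted_idx]


# ---------------------------------------------------------------------------
# replicate-structured profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileSpec:
    """Planted class structure for replicate-level energy profiles."""

    class_means: dict[str, np.ndarray]  # class -> per-residue mean, same length
    residues: np.ndarray  # author numbers, shared across classes
    n_structures_per_class: int = 2
    n_replicates: int = 35
    noise_sigma: float = 1.0
    rng_seed: int = 0
    aa_types: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues = np.asarray(self.residues, dtype=int)
        self.class_means = {k: np.asarray(v, dtype=float)
                            for k, v in self.class_means.items()}
        m = len(self.residues)
        for k, v in self.class_means.items():
            if v.shape != (m,):
                raise ValueError(f"class {k}: mean profile length != {m}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


POLYMORPH_CLASSES = ("AD", "CBD", "CTE", "PiD", "PSP", "GGT", "GPT")


def planted_class_profile_spec(n_classes: int = 7, n_distinctive: int = 3,
                               n_residues: int = 30, delta: float = 9.0,
                               noise_sigma: float = 3.0,
                               n_structures_per_class: int = 2,
                               n_replicates: int = 35, rng_seed: int = 0,
                               author_start: int = 301
                               ) -> tuple[ProfileSpec, dict[str, list[int]]]:
    """Planted class structure over a base ramp profile (Δmean = 3σ default).

    Each class elevates ``n_distinctive`` consecutive interior residues by
    ``delta`` above a linear base ramp.  The ramp ends are left unplanted
    so the min–max normalization anchors are class-independent.  Returns
    the spec and the distinctive author numbers per class.
    """
    if n_classes > len(POLYMORPH_CLASSES):
        raise ValueError(f"at most {len(POLYMORPH_CLASSES)} classes available")
    need = 2 + n_classes * n_distinctive
    if n_residues < need + 1:
        raise ValueError(f"n_residues must be at least {need + 1}")
    residues = np.arange(author_start, author_start + n_residues)
    base = np.linspace(5.0, 65.0, n_residues)
    class_means, distinctive = {}, {}
    for i, cls in enumerate(POLYMORPH_CLASSES[:n_classes]):
        mean = base.copy()
        idx = [n_distinctive * i + 2 + j for j in range(n_distinctive)]
        mean[idx] += delta
        class_means[cls] = np.clip(mean, 0.0, 100.0)
        distinctive[cls] = [int(residues[j]) for j in idx]
    spec = ProfileSpec(class_means=class_means, residues=residues,
                       n_structures_per_class=n_structures_per_class,
                       n_replicates=n_replicates, noise_sigma=noise_sigma,
                       rng_seed=rng_seed)
    return spec, distinctive


def generate_profiles(spec: ProfileSpec) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Replicate score tables (ingest schema) with planted class means.

    Returns ``(tables, labels)``: one DataFrame per structure with columns
    structure_id, residue, replicate, bound_mut, bound_wt (wild-type score
    fixed at 0 so ΔREU equals the emitted value), and the structure→class
    label map.  Replicate values are class mean + Gaussian noise, clipped
    at zero.
    """
    rng = np.random.default_rng(spec.rng_seed)
    tables: dict[str, pd.DataFrame] = {}
    labels: dict[str, str] = {}
    for cls in sorted(spec.class_means):
        mean = spec.class_means[cls]
        for s in range(spec.n_structures_per_class):
            sid = f"{cls}_T{s + 1}"
            rows = []
            noise = rng.normal(0.0, spec.noise_sigma,
                               (spec.n_replicates, len(spec.residues)))
            values = np.clip(mean[None, :] + noise, 0.0, None)
            for rep in range(spec.n_replicates):
                for j, res in enumerate(spec.residues):
                    rows.append((sid, int(res), rep, values[rep, j], 0.0))
            tables[sid] = pd.DataFrame(
                rows, columns=["structure_id", "residue", "replicate",
                               "bound_mut", "bound_wt"])
            labels[sid] = cls
    return tables, labels
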