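"""Atomic data model for layered amyloid protofilaments.

A protofilament is modelled as an ordered stack of *layers* (one folded
monomer per chain), index 0 at the top.  All layers share one sequence and
author residue numbering, which is preserved verbatim from the input file so
that hotspots map directly onto motifs such as 306-311 (VQIVYK) of tau
2N4R numbering.  Readers/writers go through gemmi; heteroatoms, waters and
alternate locations other than 'A' are dropped on input.
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from ._aa import BACKBONE_ATOMS, ONE_TO_THREE, THREE_TO_ONE
from ._rigid import kabsch, mean_rotation, rotation_axis_angle

CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

_ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S"}


class StructureError(ValueError):
    """Raised when a coordinate file or assembly violates the model contract."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    author_number: int
    aa_type: str  # one-letter code
    atoms: list[Atom]
    insertion_code: str = ""

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.author_number} has no atom {name}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class Layer:
    chain_id: str
    residues: list[Residue]

    def residue(self, author_number: int) -> Residue:
        for r in self.residues:
            if r.author_number == author_number:
                return r
        raise KeyError(f"chain {self.chain_id} has no residue {author_number}")

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coords for r in self.residues])

    def backbone_coords(self) -> np.ndarray:
        out = []
        for r in self.residues:
            for name in BACKBONE_ATOMS:
                out.append(r.atom(name).coords)
        return np.array(out)

    def all_coords(self) -> np.ndarray:
        return np.concatenate([r.coords for r in self.residues])


@dataclass
class LayerTransform:
    """Rigid map carrying layer i onto layer i+1 of a stack."""

    rotation: np.ndarray
    translation: np.ndarray
    rise: float  # Å, projection of the translation on the helical axis
    twist: float  # degrees

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class FibrilAssembly:
    layers: list[Layer]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise StructureError("assembly has no layers")
        ids = [l.chain_id for l in self.layers]
        if len(set(ids)) != len(ids):
            raise StructureError(f"duplicate chain ids: {ids}")
        ref = [(r.author_number, r.aa_type) for r in self.layers[0].residues]
        for layer in self.layers[1:]:
            got = [(r.author_number, r.aa_type) for r in layer.residues]
            if got != ref:
                raise StructureError(
                    f"chain {layer.chain_id} sequence/numbering differs from "
                    f"chain {self.layers[0].chain_id}"
                )

    # -- basic properties -------------------------------------------------
    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def residues_per_layer(self) -> int:
        return len(self.layers[0].residues)

    @property
    def chain_ids(self) -> list[str]:
        return [l.chain_id for l in self.layers]

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.layers[0].residues)

    @property
    def author_numbers(self) -> list[int]:
        return [r.author_number for r in self.layers[0].residues]

    def layer_by_chain(self, chain_id: str) -> Layer:
        for l in self.layers:
            if l.chain_id == chain_id:
                return l
        raise KeyError(f"no chain {chain_id}")

    def copy(self) -> "FibrilAssembly":
        return _copy.deepcopy(self)

    def log(self, event: str, **info) -> None:
        self.provenance.append({"event": event, **info})

    def provenance_jsonl(self) -> str:
        return "\n".join(json.dumps(e) for e in self.provenance)

    # -- flattened numeric views ------------------------------------------
    def atom_table(self):
        """Flattened atom arrays for numeric code.

        Returns a dict with parallel arrays: coords (N,3), element (N,) str,
        name (N,) str, residue_index (N,) int (flat residue index),
        chain_index (N,) int, author_number (N,) int, aa (N,) str.
        """
        coords, elem, name, res_idx, chain_idx, author, aa = [], [], [], [], [], [], []
        ri = 0
        for ci, layer in enumerate(self.layers):
            for res in layer.residues:
                for a in res.atoms:
                    coords.append(a.coords)
                    elem.append(a.element)
                    name.append(a.name)
                    res_idx.append(ri)
                    chain_idx.append(ci)
                    author.append(res.author_number)
                    aa.append(res.aa_type)
                ri += 1
        return {
            "coords": np.array(coords),
            "element": np.array(elem),
            "name": np.array(name),
            "residue_index": np.array(res_idx),
            "chain_index": np.array(chain_idx),
            "author_number": np.array(author),
            "aa": np.array(aa),
        }

    def set_coords(self, coords: np.ndarray) -> None:
        """Overwrite atom coordinates from a flat (N,3) array in atom order."""
        i = 0
        for layer in self.layers:
            for res in layer.residues:
                for a in res.atoms:
                    a.coords = np.asarray(coords[i], dtype=float)
                    i += 1
        if i != len(coords):
            raise StructureError("coordinate array length mismatch")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "FibrilAssembly":
        out = self.copy()
        for layer in out.layers:
            for res in layer.residues:
                for a in res.atoms:
                    a.coords = rotation @ a.coords + translation
        return out


# ---------------------------------------------------------------------------
# layer ordering helpers
# ---------------------------------------------------------------------------

def _principal_axis(ca: np.ndarray) -> np.ndarray:
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] >= 0 else -axis


def _stacking_axis(layers: list[Layer]) -> np.ndarray:
    """First principal axis of the layer centroids (the fibril axis)."""
    cents = np.array([l.ca_coords().mean(axis=0) for l in layers])
    return _principal_axis(cents)


def order_layers(layers: list[Layer]) -> list[Layer]:
    """Sort chains along the fibril axis; 'top' = smaller projection.

    The axis is the first principal axis of the chain centroids (which
    lie on the helical axis for a regular stack).  Any consistent
    convention works downstream (all profile quantities are
    order-symmetric).
    """
    if len(layers) == 1:
        return list(layers)
    axis = _stacking_axis(layers)
    proj = [float(l.ca_coords().mean(axis=0) @ axis) for l in layers]
    order = np.argsort(proj, kind="stable")
    return [layers[i] for i in order]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, model_index: int = 0) -> FibrilAssembly:
    """Read a PDB or mmCIF coordinate file into a layered assembly.

    One layer per chain, ordered along the fibril axis.  Author residue
    numbering is preserved; waters/heteroatoms are dropped; of alternate
    locations only 'A' is kept.  A missing backbone atom is a structured
    error naming the chain and residue.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if model_index >= len(st):
        raise StructureError(f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]
    layers: list[Layer] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            one = THREE_TO_ONE.get(res.name)
            if one is None:
                continue  # heteroatoms, waters, ligands
            atoms: list[Atom] = []
            seen = set()
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue
                if at.element.name == "H" or at.name in seen:
                    continue
                seen.add(at.name)
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name or _ELEMENT_FROM_NAME.get(at.name[:1], "C"),
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=at.occ if at.occ > 0 else 1.0,
                        b_factor=at.b_iso,
                    )
                )
            r = Residue(
                author_number=res.seqid.num,
                aa_type=one,
                atoms=atoms,
                insertion_code=(res.seqid.icode or "").strip(),
            )
            for bb in BACKBONE_ATOMS:
                if not r.has_atom(bb):
                    raise StructureError(
                        f"chain {chain.name} residue {res.seqid.num} is missing "
                        f"backbone atom {bb}"
                    )
            residues.append(r)
        if residues:
            layers.append(Layer(chain_id=chain.name, residues=residues))
    if not layers:
        raise StructureError(f"{path}: no protein chains found")
    for layer in layers:
        if len(layer.residues) < 3:
            raise StructureError(f"chain {layer.chain_id} has fewer than 3 residues")
    asm = FibrilAssembly(layers=order_layers(layers))
    asm.log("read_structure", path=str(path), model_index=model_index,
            n_layers=asm.n_layers, residues_per_layer=asm.residues_per_layer)
    return asm


def write_structure(assembly: FibrilAssembly, path: str | Path) -> None:
    """Write the assembly as standard PDB records (coordinates to 3 decimals)."""
    if assembly.n_layers > len(CHAIN_ALPHABET):
        raise StructureError(
            f"{assembly.n_layers} chains exceed the PDB chain-id space "
            f"({len(CHAIN_ALPHABET)})"
        )
    st = gemmi.Structure()
    st.name = "fibrilscan"
    model = gemmi.Model("1")
    for layer in assembly.layers:
        chain = gemmi.Chain(layer.chain_id)
        for res in layer.residues:
            g = gemmi.Residue()
            g.name = ONE_TO_THREE[res.aa_type]
            g.seqid = gemmi.SeqId(res.author_number, res.insertion_code or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                g.add_atom(ga)
            chain.add_residue(g)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# protofilament selection
# ---------------------------------------------------------------------------

def _chain_contacts(layers: list[Layer], cutoff: float = 6.0) -> set[tuple[int, int]]:
    cas = [l.ca_coords() for l in layers]
    edges = set()
    for i in range(len(layers)):
        for j in range(i + 1, len(layers)):
            d = np.linalg.norm(cas[i][:, None, :] - cas[j][None, :, :], axis=-1)
            if d.min() < cutoff:
                edges.add((i, j))
    return edges


def select_protofilament(assembly: FibrilAssembly, chain_subset) -> FibrilAssembly:
    """Restrict the assembly to one protofilament's chains.

    The retained chains must form a single stack: mutually connected by
    inter-layer contacts, with distinct positions along one stacking axis.
    A subset spanning both protofilaments of a paired fibril fails both
    checks and raises :class:`StructureError`.
    """
    wanted = list(chain_subset)
    layers = [assembly.layer_by_chain(c) for c in wanted]
    if len(layers) < 2:
        asm = FibrilAssembly(layers=[_copy.deepcopy(l) for l in layers],
                             provenance=list(assembly.provenance))
        asm.log("select_protofilament", chains=wanted)
        return asm
    edges = _chain_contacts(layers)
    # connectivity over the subset
    seen = {0}
    frontier = [0]
    adj = {i: set() for i in range(len(layers))}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    while frontier:
        k = frontier.pop()
        for m in adj[k]:
            if m not in seen:
                seen.add(m)
                frontier.append(m)
    if len(seen) != len(layers):
        raise StructureError(
            "selected chains do not form a single connected protofilament"
        )
    ordered = order_layers(layers)
    axis = _stacking_axis(ordered)
    proj = np.array([float(l.ca_coords().mean(axis=0) @ axis) for l in ordered])
    gaps = np.diff(proj)
    if np.any(gaps < 1.0):
        raise StructureError(
            "selected chains do not stack along a single axis "
            "(two chains occupy the same level; subset may span both "
            "protofilaments)"
        )
    asm = FibrilAssembly(layers=[_copy.deepcopy(l) for l in ordered],
                         provenance=list(assembly.provenance))
    asm.log("select_protofilament", chains=wanted)
    return asm


# ---------------------------------------------------------------------------
# inter-layer transform and stack extension
# ---------------------------------------------------------------------------

def _matched_coords(a: Layer, b: Layer) -> tuple[np.ndarray, np.ndarray]:
    pa, pb = [], []
    if [r.author_number for r in a.residues] != [r.author_number for r in b.residues]:
        raise StructureError(
            f"layers {a.chain_id} and {b.chain_id} have mismatched residue sets"
        )
    for ra, rb in zip(a.residues, b.residues):
        names_b = {at.name for at in rb.atoms}
        for at in ra.atoms:
            if at.name in names_b:
                pa.append(at.coords)
                pb.append(rb.atom(at.name).coords)
    return np.array(pa), np.array(pb)


def estimate_layer_transform(assembly: FibrilAssembly) -> LayerTransform:
    """Average rigid transform mapping layer i onto layer i+1.

    Least-squares (Kabsch) per consecutive pair, then a chordal mean of the
    rotations and the mean translation.  Rise is the projection of the
    translation on the rotation axis, sign-normalised to be non-negative
    (the twist sign follows the same axis choice).
    """
    if assembly.n_layers < 2:
        raise StructureError("need at least 2 layers to estimate a transform")
    rots, trans = [], []
    for i in range(assembly.n_layers - 1):
        P, Q = _matched_coords(assembly.layers[i], assembly.layers[i + 1])
        R, t, _ = kabsch(P, Q)
        rots.append(R)
        trans.append(t)
    R = mean_rotation(rots)
    t = np.mean(trans, axis=0)
    axis, angle = rotation_axis_angle(R)
    if angle < 1e-10:
        rise = float(np.linalg.norm(t))
        twist = 0.0
    else:
        rise = float(t @ axis)
        twist = float(np.degrees(angle))
        if rise < 0:
            rise, twist = -rise, -twist
    return LayerTransform(rotation=R, translation=t, rise=rise, twist=twist)


def build_stack(assembly: FibrilAssembly, n_target: int,
                overlap_rmsd_tol: float = 0.5) -> FibrilAssembly:
    """Extend (or trim) a protofilament stack to ``n_target`` layers.

    Extension duplicates the assembly, superposes the duplicate's top two
    chains onto the current bottom two chains on backbone atoms, discards
    the two overlapping duplicate chains and appends the rest — preserving
    the stack geometry exactly for helically regular input.  Trimming keeps
    the central window.  Output chains are relettered A… top-to-bottom.
    """
    if n_target < 2:
        raise StructureError("n_target must be at least 2")
    if assembly.n_layers < 2:
        raise StructureError("need at least 2 layers to extend a stack")
    current = [_copy.deepcopy(l) for l in assembly.layers]
    template = [_copy.deepcopy(l) for l in assembly.layers]
    log_events = []
    while len(current) < n_target:
        dup = _copy.deepcopy(template)
        # superpose duplicate top two chains onto current bottom two chains
        P = np.concatenate([dup[0].backbone_coords(), dup[1].backbone_coords()])
        Q = np.concatenate([current[-2].backbone_coords(), current[-1].backbone_coords()])
        R, t, rmsd = kabsch(P, Q)
        if rmsd > overlap_rmsd_tol:
            raise StructureError(
                f"two-chain overlap superposes at RMSD {rmsd:.3f} Å "
                f"(> {overlap_rmsd_tol} Å): geometry is not stack-extensible"
            )
        for layer in dup:
            for res in layer.residues:
                for a in res.atoms:
                    a.coords = R @ a.coords + t
        current.extend(dup[2:])  # first two duplicate chains overlap; drop
        log_events.append({"event": "extend", "overlap_rmsd": rmsd,
                           "n_layers": len(current)})
    if len(current) > n_target:
        start = (len(current) - n_target) // 2
        current = current[start : start + n_target]
        log_events.append({"event": "trim_central", "n_layers": n_target})
    relabelled = []
    for i, layer in enumerate(current):
        relabelled.append(Layer(chain_id=CHAIN_ALPHABET[i], residues=layer.residues))
    out = FibrilAssembly(layers=relabelled, provenance=list(assembly.provenance))
    for e in log_events:
        out.provenance.append(e)
    out.log("build_stack", n_target=n_target)
    return out
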