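"""Solvent-accessible surface area and two-state folding burial metrics.

SASA uses the Shrake–Rupley sphere-point method with a deterministic
golden-section spiral lattice, so results are bit-stable across runs.
Hydrogens are never considered (inputs are heavy-atom models).  The burial
metrics compare three states of one monomer layer: a fully extended chain,
the folded layer alone, and the folded layer sandwiched in the central
three layers of the fibril:

    dsasa_single_layer = SASA(extended) − SASA(folded monomer)
    dsasa_fibril       = SASA(extended) − SASA(monomer inside the fibril)

Extra layers only ever bury, so ``dsasa_fibril >= dsasa_single_layer``
residue by residue.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources

import numba
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .construct import build_peptide
from .model import FibrilAssembly, Layer, StructureError

DEFAULT_PROBE = 1.4  # Å water probe
DEFAULT_N_POINTS = 960

# extended-state backbone torsions (conventional β-extended reference)
EXTENDED_PHI = -120.0
EXTENDED_PSI = 120.0


@functools.lru_cache(maxsize=8)
def _atom_param_table() -> pd.DataFrame:
    path = resources.files("fibrilscan") / "data" / "atom_params.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#").set_index("element")


def element_radius(element: str) -> float:
    """Van der Waals radius for an element, from the shipped table."""
    table = _atom_param_table()
    if element not in table.index:
        raise KeyError(f"no radius for element {element!r}")
    return float(table.loc[element, "radius"])


@functools.lru_cache(maxsize=16)
def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice of n unit vectors."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@numba.njit(cache=True)
def _areas_kernel(coords, ext, idx, nb_flat, nb_start, nb_count, pts):  # pragma: no cover
    npts = pts.shape[0]
    out = np.empty(len(idx))
    for k in range(len(idx)):
        i = idx[k]
        ri = ext[i]
        n = nb_count[k]
        if n == 0:
            out[k] = 4.0 * np.pi * ri * ri
            continue
        buried = 0
        for p in range(npts):
            sx = coords[i, 0] + ri * pts[p, 0]
            sy = coords[i, 1] + ri * pts[p, 1]
            sz = coords[i, 2] + ri * pts[p, 2]
            for t in range(n):
                j = nb_flat[nb_start[k] + t]
                dx = sx - coords[j, 0]
                dy = sy - coords[j, 1]
                dz = sz - coords[j, 2]
                if dx * dx + dy * dy + dz * dz < ext[j] * ext[j]:
                    buried += 1
                    break
        out[k] = 4.0 * np.pi * ri * ri * (npts - buried) / npts
    return out


def atom_areas(coords: np.ndarray, radii: np.ndarray,
               probe_radius: float = DEFAULT_PROBE,
               n_points: int = DEFAULT_N_POINTS,
               subset: np.ndarray | None = None,
               neighbor_lists: tuple | None = None) -> np.ndarray:
    """Per-atom solvent-accessible area (Å²).

    ``subset`` restricts which atoms' areas are computed (all atoms still
    occlude); the returned array is then aligned with ``subset``.
    ``neighbor_lists`` (nb_flat, nb_start, nb_count) may supply
    precomputed candidate occluders per subset atom — supersets are safe
    because the kernel re-checks true distances.
    """
    coords = np.ascontiguousarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    pts = sphere_points(n_points)
    ext = radii + probe_radius
    idx = (np.arange(n) if subset is None
           else np.asarray(subset, dtype=np.int64))
    m = len(idx)
    if neighbor_lists is not None:
        nb_flat, nb_start, nb_count = neighbor_lists
        return _areas_kernel(coords, ext, idx, nb_flat, nb_start, nb_count,
                             np.ascontiguousarray(pts))
    # neighbour lists (row-major flat layout): atoms occluding each subset atom
    if m * n <= 4_000_000:
        d2 = ((coords[idx][:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
        close = d2 < (ext[idx][:, None] + ext[None, :]) ** 2
        close[np.arange(m), idx] = False
        rows, nb_flat = np.nonzero(close)
        nb_count = np.bincount(rows, minlength=m).astype(np.int64)
    else:
        tree = cKDTree(coords)
        raw = tree.query_ball_point(coords[idx], ext[idx] + float(ext.max()))
        counts0 = np.array([len(l) for l in raw], dtype=np.int64)
        flat = (np.concatenate([np.asarray(l, dtype=np.int64) for l in raw])
                if counts0.sum() else np.empty(0, dtype=np.int64))
        rowid = np.repeat(np.arange(m), counts0)
        owners = idx[rowid]
        dd = np.linalg.norm(coords[flat] - coords[owners], axis=1)
        mask = (flat != owners) & (dd < ext[owners] + ext[flat])
        nb_flat = flat[mask]
        nb_count = np.bincount(rowid[mask], minlength=m).astype(np.int64)
    nb_start = np.concatenate([[0], np.cumsum(nb_count)[:-1]]).astype(np.int64)
    nb_flat = np.ascontiguousarray(nb_flat, dtype=np.int64)
    return _areas_kernel(coords, ext, idx, nb_flat, nb_start, nb_count,
                         np.ascontiguousarray(pts))


def _residue_atom_arrays(residues) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords, radii, owner = [], [], []
    for ri, res in enumerate(residues):
        for a in res.atoms:
            coords.append(a.coords)
            radii.append(element_radius(a.element))
            owner.append(ri)
    return np.array(coords), np.array(radii), np.array(owner)


def residue_sasa(residues, probe_radius: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> dict[int, float]:
    """Per-residue SASA (Å²) for a list of residues, keyed by author number."""
    residues = list(residues)
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    nums = [r.author_number for r in residues]
    if len(set(nums)) != len(nums):
        raise ValueError("duplicate author numbers; use atom_areas for multi-chain input")
    coords, radii, owner = _residue_atom_arrays(residues)
    areas = atom_areas(coords, radii, probe_radius, n_points)
    out = {}
    for ri, num in enumerate(nums):
        out[num] = float(areas[owner == ri].sum())
    return out


def build_extended_monomer(sequence: str, author_start: int = 1,
                           phi: float = EXTENDED_PHI,
                           psi: float = EXTENDED_PSI) -> Layer:
    """Idealised extended chain used as the unfolded reference state."""
    return build_peptide(sequence, phi=phi, psi=psi, author_start=author_start,
                         chain_id="A", sidechains=True)


@dataclass
class SasaReport:
    """Per-residue areas of the three states and their differences (Å²)."""

    per_residue_extended: dict[int, float]
    per_residue_monomer: dict[int, float]
    per_residue_in_fibril: dict[int, float]
    probe_radius: float = DEFAULT_PROBE
    aa_types: dict[int, str] = field(default_factory=dict)

    @property
    def dsasa_single_layer(self) -> dict[int, float]:
        return {k: self.per_residue_extended[k] - self.per_residue_monomer[k]
                for k in self.per_residue_extended}

    @property
    def dsasa_fibril(self) -> dict[int, float]:
        return {k: self.per_residue_extended[k] - self.per_residue_in_fibril[k]
                for k in self.per_residue_extended}

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(self.per_residue_extended)
        return pd.DataFrame({
            "residue": keys,
            "aa": [self.aa_types.get(k, "") for k in keys],
            "sasa_extended": [self.per_residue_extended[k] for k in keys],
            "sasa_monomer": [self.per_residue_monomer[k] for k in keys],
            "sasa_fibril": [self.per_residue_in_fibril[k] for k in keys],
            "dsasa_single_layer": [self.dsasa_single_layer[k] for k in keys],
            "dsasa_fibril": [self.dsasa_fibril[k] for k in keys],
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def delta_sasa_folding(assembly: FibrilAssembly,
                       probe_radius: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> SasaReport:
    """Two-state folding burial per residue of the central layer.

    Requires at least three layers (the in-fibril state is the middle
    chain of the central trimer).
    """
    if assembly.n_layers < 3:
        raise StructureError("delta_sasa_folding needs at least 3 layers")
    mid = assembly.n_layers // 2
    middle = assembly.layers[mid]
    extended = build_extended_monomer(
        assembly.sequence, author_start=middle.residues[0].author_number)
    ext = residue_sasa(extended.residues, probe_radius, n_points)
    mono = residue_sasa(middle.residues, probe_radius, n_points)

    trimer_layers = assembly.layers[mid - 1 : mid + 2]
    coords, radii, owner_res, owner_layer = [], [], [], []
    for li, layer in enumerate(trimer_layers):
        for res in layer.residues:
            for a in res.atoms:
                coords.append(a.coords)
                radii.append(element_radius(a.element))
                owner_res.append(res.author_number)
                owner_layer.append(li)
    coords, radii = np.array(coords), np.array(radii)
    owner_res, owner_layer = np.array(owner_res), np.array(owner_layer)
    central = np.where(owner_layer == 1)[0]
    areas = atom_areas(coords, radii, probe_radius, n_points, subset=central)
    fib = {}
    for num in [r.author_number for r in middle.residues]:
        fib[num] = float(areas[owner_res[central] == num].sum())

    # extended numbering must line up with author numbering of the layer
    assert set(ext) == set(mono) == set(fib)
    return SasaReport(
        per_residue_extended=ext,
        per_residue_monomer=mono,
        per_residue_in_fibril=fib,
        probe_radius=probe_radius,
        aa_types={r.author_number: r.aa_type for r in middle.residues},
    )


def buried_nonpolar_area(assembly: FibrilAssembly,
                         probe_radius: float = DEFAULT_PROBE,
                         n_points: int = DEFAULT_N_POINTS) -> dict[int, float]:
    """Per-residue buried *carbon/sulfur* area going extended → in-fibril.

    The nonpolar share of ``dsasa_fibril``: area of C and S atoms in the
    extended state minus their area in the fibril context.
    """
    if assembly.n_layers < 3:
        raise StructureError("buried_nonpolar_area needs at least 3 layers")
    mid = assembly.n_layers // 2
    middle = assembly.layers[mid]
    extended = build_extended_monomer(
        assembly.sequence, author_start=middle.residues[0].author_number)

    def _nonpolar_by_residue(layers, target_layer_index):
        coords, radii, owner_res, owner_layer, nonpolar = [], [], [], [], []
        for li, layer in enumerate(layers):
            for res in layer.residues:
                for a in res.atoms:
                    coords.append(a.coords)
                    radii.append(element_radius(a.element))
                    owner_res.append(res.author_number)
                    owner_layer.append(li)
                    nonpolar.append(a.element in ("C", "S"))
        coords, radii = np.array(coords), np.array(radii)
        owner_res = np.array(owner_res)
        sel = np.where((np.array(owner_layer) == target_layer_index)
                       & np.array(nonpolar))[0]
        areas = atom_areas(coords, radii, probe_radius, n_points, subset=sel)
        out: dict[int, float] = {}
        for num in np.unique(owner_res):
            out[int(num)] = float(areas[owner_res[sel] == num].sum())
        return out

    ext = _nonpolar_by_residue([extended], 0)
    fib = _nonpolar_by_residue(assembly.layers[mid - 1 : mid + 2], 1)
    return {num: ext.get(num, 0.0) - fib.get(num, 0.0) for num in ext}
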