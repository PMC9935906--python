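"""Rigid superposition, backbone RMSD, torsions and permissibility.

Dihedral angles follow the IUPAC convention, reported in degrees on
(−180, 180].  Torsion-angle permissibility is judged against shipped
φ/ψ density grids (one for alanine-like residues, one for glycine) using a
highest-density-region contour: a conformation is *allowed* if its grid
cell lies inside the region holding the requested fraction of probability
mass (default 99.5%).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from ._aa import BACKBONE_ATOMS
from ._rigid import kabsch
from .model import FibrilAssembly, StructureError

PEPTIDE_BOND_BREAK = 2.5  # Å C(i)–N(i+1) distance beyond which the chain is broken


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


def superpose(mobile, target) -> SuperpositionResult:
    """Least-squares optimal proper rigid superposition (Kabsch).

    Mirror-image solutions are excluded; degenerate (collinear) or
    length-mismatched inputs raise :class:`ValueError`.
    """
    R, t, rmsd = kabsch(np.asarray(mobile, float), np.asarray(target, float))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def backbone_rmsd(a: FibrilAssembly, b: FibrilAssembly, chain_subset=None) -> float:
    """Fitted RMSD over the four backbone atom types of the chain subset."""
    chains = list(chain_subset) if chain_subset is not None else a.chain_ids
    pa, pb = [], []
    for cid in chains:
        la, lb = a.layer_by_chain(cid), b.layer_by_chain(cid)
        nums_a = [r.author_number for r in la.residues]
        nums_b = [r.author_number for r in lb.residues]
        if nums_a != nums_b:
            raise StructureError(f"chain {cid}: residue sets differ between assemblies")
        for ra, rb in zip(la.residues, lb.residues):
            for name in BACKBONE_ATOMS:
                pa.append(ra.atom(name).coords)
                pb.append(rb.atom(name).coords)
    return superpose(np.array(pa), np.array(pb)).rmsd


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees on (−180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


@dataclass
class TorsionRecord:
    residue: int  # author number
    chain_id: str
    aa_type: str
    phi: float | None
    psi: float | None
    omega: float | None  # omega of the bond preceding this residue


def backbone_torsions(assembly: FibrilAssembly) -> list[TorsionRecord]:
    """Backbone φ/ψ/ω per residue, per layer.

    Terminal residues carry ``None`` for the undefined angle; torsions
    across a chain break (C–N distance > 2.5 Å) are likewise ``None``.
    """
    records = []
    for layer in assembly.layers:
        res = layer.residues
        m = len(res)
        linked = []
        for i in range(m - 1):
            d = np.linalg.norm(res[i].atom("C").coords - res[i + 1].atom("N").coords)
            linked.append(d <= PEPTIDE_BOND_BREAK)
        for i, r in enumerate(res):
            n, ca, c = (r.atom(x).coords for x in ("N", "CA", "C"))
            phi = psi = omega = None
            if i > 0 and linked[i - 1]:
                cp = res[i - 1].atom("C").coords
                phi = dihedral(cp, n, ca, c)
                omega = dihedral(res[i - 1].atom("CA").coords, cp, n, ca)
            if i < m - 1 and linked[i]:
                psi = dihedral(n, ca, c, res[i + 1].atom("N").coords)
            records.append(TorsionRecord(residue=r.author_number,
                                         chain_id=layer.chain_id,
                                         aa_type=r.aa_type,
                                         phi=phi, psi=psi, omega=omega))
    return records


# ---------------------------------------------------------------------------
# torsion permissibility
# ---------------------------------------------------------------------------

class PermissibilityTable:
    """φ/ψ density grids for alanine-like and glycine residues.

    Grids are plain-text matrices (rows = φ bins, columns = ψ bins) with
    bin edges in a header comment; values are probabilities summing to 1.
    The shipped default grids are synthetic stand-ins built from a
    Gaussian-mixture model of the canonical Ramachandran basins (see the
    data-file headers); any grid in the same format can be swapped in.
    """

    def __init__(self, grid_ala: np.ndarray, grid_gly: np.ndarray,
                 phi_edges: np.ndarray, psi_edges: np.ndarray):
        self.grids = {"ala": grid_ala / grid_ala.sum(),
                      "gly": grid_gly / grid_gly.sum()}
        self.phi_edges = phi_edges
        self.psi_edges = psi_edges

    @staticmethod
    def _parse(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        phi_edges = psi_edges = None
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                if "phi_edges:" in line:
                    phi_edges = np.array([float(x) for x in line.split(":")[1].split()])
                elif "psi_edges:" in line:
                    psi_edges = np.array([float(x) for x in line.split(":")[1].split()])
                continue
            if line.strip():
                rows.append([float(x) for x in line.split()])
        if phi_edges is None or psi_edges is None:
            raise ValueError(f"{path}: missing phi/psi bin-edge header")
        return np.array(rows), phi_edges, psi_edges

    @classmethod
    def from_files(cls, ala_path, gly_path) -> "PermissibilityTable":
        ga, pe, se = cls._parse(ala_path)
        gg, pe2, se2 = cls._parse(gly_path)
        if not (np.allclose(pe, pe2) and np.allclose(se, se2)):
            raise ValueError("ala and gly grids use different bin edges")
        return cls(ga, gg, pe, se)

    @classmethod
    @functools.lru_cache(maxsize=1)
    def default(cls) -> "PermissibilityTable":
        data = resources.files("fibrilscan") / "data"
        return cls.from_files(data / "rama_density_ala_synthetic.tsv",
                              data / "rama_density_gly_synthetic.tsv")

    def _threshold(self, which: str, quantile: float) -> float:
        g = np.sort(self.grids[which].ravel())[::-1]
        cum = np.cumsum(g)
        idx = int(np.searchsorted(cum, quantile))
        return float(g[min(idx, len(g) - 1)])

    def density(self, which: str, phi: float, psi: float) -> float:
        i = int(np.clip(np.searchsorted(self.phi_edges, phi, side="right") - 1,
                        0, len(self.phi_edges) - 2))
        j = int(np.clip(np.searchsorted(self.psi_edges, psi, side="right") - 1,
                        0, len(self.psi_edges) - 2))
        return float(self.grids[which][i, j])

    def allowed(self, which: str, phi: float, psi: float,
                quantile: float = 0.995) -> bool:
        return self.density(which, phi, psi) >= self._threshold(which, quantile)

    def grid_maximum(self, which: str) -> tuple[float, float]:
        g = self.grids[which]
        i, j = np.unravel_index(np.argmax(g), g.shape)
        phi = 0.5 * (self.phi_edges[i] + self.phi_edges[i + 1])
        psi = 0.5 * (self.psi_edges[j] + self.psi_edges[j + 1])
        return float(phi), float(psi)


def classify_torsion_permissibility(record: TorsionRecord,
                                    reference: PermissibilityTable | None = None,
                                    quantile: float = 0.995) -> dict:
    """Whether a residue's φ/ψ pair is permissible for alanine and glycine."""
    if record.phi is None or record.psi is None:
        raise ValueError(
            f"residue {record.residue}: undefined torsions cannot be classified"
        )
    ref = reference if reference is not None else PermissibilityTable.default()
    return {
        "allowed_for_ala": ref.allowed("ala", record.phi, record.psi, quantile),
        "allowed_for_gly": ref.allowed("gly", record.phi, record.psi, quantile),
    }
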