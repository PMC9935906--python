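"""Torsion-driven peptide construction with idealised geometry.

Backbones are grown atom by atom with the NeRF internal-coordinate scheme;
side chains use the package's simplified pseudo-atom representation (shells
of heavy atoms along a kinked side-chain axis, see
:mod:`fibrilscan._aa`).  Construction and torsion measurement are mutual
inverses on ideal geometry, which the test-suite exploits.
"""

from __future__ import annotations

import numpy as np

from ._aa import CANONICAL, SIDECHAIN_TEMPLATE
from .model import Atom, Layer, Residue, StructureError

# idealised backbone internal coordinates (Å, degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

SIDECHAIN_SHELL = 1.3  # Å between pseudo-atom shells
SIDECHAIN_FAN = 0.65  # Å lateral fan of branch atoms
SIDECHAIN_KINK = 35.0  # degrees off the CA->CB axis, so chi moves atoms


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from A-B-C internal coordinates (NeRF)."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal CB position from backbone N, CA, C (L-amino-acid chirality)."""
    b = ca - n
    c_v = c - ca
    a = np.cross(b, c_v)
    return ca - 0.58273431 * a + 0.56802827 * b - 0.54067466 * c_v


def sidechain_atoms(aa: str, n: np.ndarray, ca: np.ndarray,
                    cb: np.ndarray) -> list[Atom]:
    """Pseudo side-chain heavy atoms beyond CB for residue type ``aa``."""
    template = SIDECHAIN_TEMPLATE[aa]
    if not template:
        return []
    d = cb - ca
    d = d / np.linalg.norm(d)
    p = (n - ca) - ((n - ca) @ d) * d
    p = p / np.linalg.norm(p)
    kink = np.radians(SIDECHAIN_KINK)
    axis = np.cos(kink) * d + np.sin(kink) * p
    axis /= np.linalg.norm(axis)
    lat = np.cross(d, p)
    lat /= np.linalg.norm(lat)
    out = []
    for name, element, level, lateral in template:
        pos = cb + SIDECHAIN_SHELL * level * axis + SIDECHAIN_FAN * lateral * lat
        out.append(Atom(name=name, element=element, coords=pos))
    return out


def _per_residue(value, n: int, what: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{what} must be scalar or length {n}")
    return arr


def build_peptide(sequence: str, phi=-120.0, psi=120.0, omega=180.0,
                  author_start: int = 1, chain_id: str = "A",
                  sidechains: bool = True) -> Layer:
    """Build a peptide chain at the given backbone torsions.

    ``phi``/``psi``/``omega`` may be scalars or per-residue arrays (the
    first phi and last psi are geometrically inert but accepted).  Returns
    a single :class:`~fibrilscan.model.Layer`.
    """
    seq = sequence.upper()
    bad = set(seq) - CANONICAL
    if bad:
        raise StructureError(f"non-canonical residues in sequence: {sorted(bad)}")
    m = len(seq)
    if m < 1:
        raise StructureError("empty sequence")
    phis = _per_residue(phi, m, "phi")
    psis = _per_residue(psi, m, "psi")
    omegas = _per_residue(omega, m, "omega")

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, m):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1],
                            BOND_C_N, ANGLE_CA_C_N, psis[i - 1]))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i],
                             BOND_N_CA, ANGLE_C_N_CA, omegas[i]))
        C.append(place_atom(C[i - 1], N[i], CA[i],
                            BOND_CA_C, ANGLE_N_CA_C, phis[i]))
    residues = []
    for i, aa in enumerate(seq):
        atoms = [
            Atom("N", "N", N[i]),
            Atom("CA", "C", CA[i]),
            Atom("C", "C", C[i]),
            Atom("O", "O", place_atom(N[i], CA[i], C[i],
                                      BOND_C_O, ANGLE_CA_C_O, psis[i] + 180.0)),
        ]
        if aa != "G":
            cb = place_cb(N[i], CA[i], C[i])
            atoms.append(Atom("CB", "C", cb))
            if sidechains:
                atoms.extend(sidechain_atoms(aa, N[i], CA[i], cb))
        residues.append(Residue(author_number=author_start + i, aa_type=aa,
                                atoms=atoms))
    return Layer(chain_id=chain_id, residues=residues)
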