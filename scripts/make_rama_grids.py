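"""Regenerate the shipped synthetic φ/ψ permissibility grids.

The grids are Gaussian-mixture stand-ins over the canonical Ramachandran
basins (β, polyproline-II, right-handed α for alanine-like residues; those
plus the left-handed α and mirror regions for glycine), evaluated on a
5°×5° lattice with periodic wrapping.  Run from the repository root:

    python scripts/make_rama_grids.py
"""

from pathlib import Path

import numpy as np

BIN = 5.0
EDGES = np.arange(-180.0, 180.0 + BIN, BIN)
CENTERS = EDGES[:-1] + BIN / 2

# (phi_mean, psi_mean, phi_sigma, psi_sigma, weight)
ALA_BASINS = [
    (-120.0, 130.0, 25.0, 25.0, 0.35),
    (-70.0, 150.0, 15.0, 20.0, 0.25),
    (-63.0, -43.0, 12.0, 12.0, 0.38),
    (-95.0, 5.0, 10.0, 15.0, 0.02),
]
GLY_BASINS = [
    (-63.0, -43.0, 15.0, 15.0, 0.22),
    (63.0, 43.0, 15.0, 15.0, 0.22),
    (-120.0, 140.0, 30.0, 30.0, 0.18),
    (120.0, -140.0, 30.0, 30.0, 0.18),
    (-70.0, 150.0, 15.0, 20.0, 0.08),
    (70.0, -150.0, 15.0, 20.0, 0.08),
    (180.0, 180.0, 30.0, 30.0, 0.04),
]


def wrap(delta):
    return (delta + 180.0) % 360.0 - 180.0


def mixture_grid(basins):
    phi, psi = np.meshgrid(CENTERS, CENTERS, indexing="ij")
    g = np.zeros_like(phi)
    for mp, ms, sp, ss, w in basins:
        z = (wrap(phi - mp) / sp) ** 2 + (wrap(psi - ms) / ss) ** 2
        g += w * np.exp(-0.5 * z) / (2 * np.pi * sp * ss)
    return g / g.sum()


def write_grid(path, grid, label):
    lines = [
        f"# synthetic phi/psi density grid ({label}); Gaussian-mixture stand-in",
        "# over canonical Ramachandran basins, NOT derived from experimental",
        "# structures.  rows = phi bins, columns = psi bins; probabilities sum to 1",
        "# phi_edges: " + " ".join(f"{e:g}" for e in EDGES),
        "# psi_edges: " + " ".join(f"{e:g}" for e in EDGES),
    ]
    for row in grid:
        lines.append(" ".join(f"{v:.3e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "fibrilscan" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_grid(out / "rama_density_ala_synthetic.tsv", mixture_grid(ALA_BASINS),
               "alanine-like")
    write_grid(out / "rama_density_gly_synthetic.tsv", mixture_grid(GLY_BASINS),
               "glycine")
    print("wrote grids to", out)
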