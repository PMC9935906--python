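"""In silico alanine-scan engine with a pluggable energy backend.

The protocol mirrors ensemble-based interface ΔΔG estimation adapted to
fibrils: the assembly is restrained to its input coordinates, an ensemble
of replicates is generated by seeded side-chain perturbation plus greedy
relaxation, each replicate branches into an alanine-mutant and a wild-type
arm (mutate → repack → relax vs repack → relax), and both arms are scored
as a bound assembly and as an unbound split (central trimer rigidly
separated, no re-optimisation):

    ΔREU_assembly  = bound_mut − bound_wt
    ΔΔG_interface  = [bound − unbound]_mut − [bound − unbound]_wt

Per-residue attributions of the bound scores give the exact edge/internal
layer decomposition (cross terms split half/half between partners).

The built-in :class:`CrossBetaPotential` is a documented surrogate for a
molecular-mechanics energy function: it preserves the interpreted term
structure (attractive / repulsive / solvation / electrostatic) and the
orderings that drive the analysis, not absolute magnitudes.  Score tables
from an external engine can be ingested instead.
"""

from __future__ import annotations

import functools
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._aa import BACKBONE_ATOMS, CHARGE_ATOMS
from ._rigid import rotation_about_axis
from .model import FibrilAssembly
from .sasa import atom_areas, sphere_points  # noqa: F401  (re-export for backends)

UNBOUND_SEPARATION = 512.0  # Å; any value beyond all cutoffs is equivalent


class ScanError(ValueError):
    pass


class PositionExcluded(ScanError):
    """A position cannot be scanned; carries a structured reason."""

    def __init__(self, position: int, reason: str):
        super().__init__(f"position {position} excluded: {reason}")
        self.position = position
        self.reason = reason


# ---------------------------------------------------------------------------
# energy backend
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _atom_params() -> dict[str, tuple[float, float, float]]:
    path = resources.files("fibrilscan") / "data" / "atom_params.tsv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return {row.element: (row.radius, row.epsilon, row.sigma_solv)
            for row in df.itertuples()}


class _System:
    """Flattened numeric view of an assembly for the potential."""

    def __init__(self, assembly: FibrilAssembly):
        tab = assembly.atom_table()
        self.coords = tab["coords"].copy()
        self.name = tab["name"]
        self.res_idx = tab["residue_index"]
        self.chain_idx = tab["chain_index"]
        self.author = tab["author_number"]
        self.aa = tab["aa"]
        params = _atom_params()
        try:
            trip = np.array([params[e] for e in tab["element"]])
        except KeyError as e:
            raise ScanError(f"no parameters for element {e}") from None
        self.radius = trip[:, 0]
        self.eps = trip[:, 1]
        self.sigma_solv = trip[:, 2]
        charge = np.zeros(len(self.coords))
        for i, (aa, nm) in enumerate(zip(tab["aa"], tab["name"])):
            ca = CHARGE_ATOMS.get(aa)
            if ca is not None and ca[0] == nm:
                charge[i] = ca[1]
        self.charge = charge
        self.n_chains = int(self.chain_idx.max()) + 1
        # flat residue-index bookkeeping
        self.n_res = int(self.res_idx.max()) + 1
        self.res_chain = np.zeros(self.n_res, dtype=int)
        self.res_author = np.zeros(self.n_res, dtype=int)
        self.res_chain[self.res_idx] = self.chain_idx
        self.res_author[self.res_idx] = self.author
        self.is_backbone = np.isin(self.name, BACKBONE_ATOMS)
        self.is_sidechain = ~self.is_backbone & (self.name != "CB")

    def excluded(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Pairs not scored: same residue, or adjacent residues in a chain."""
        same_res = self.res_idx[i] == self.res_idx[j]
        adjacent = (self.chain_idx[i] == self.chain_idx[j]) & \
                   (np.abs(self.author[i] - self.author[j]) == 1)
        return same_res | adjacent


@dataclass
class EnergyBreakdown:
    total: float
    terms: dict[str, float]
    per_residue: dict[tuple[int, int], float]  # (chain_index, author_number)

    def per_chain(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for (ci, _), v in self.per_residue.items():
            out[ci] = out.get(ci, 0.0) + v
        return out


class CrossBetaPotential:
    """Deterministic pairwise + solvation surrogate potential.

    attractive: switched Lennard-Jones 6 well (floored at −ε inside the
    minimum, smoothly cut at 6 Å); repulsive: capped LJ-12 excess inside
    the minimum; solvation: per-atom (exposed area − fully-exposed
    reference area) × atomic solvation parameter, so burying nonpolar
    atoms is rewarded, burying polar ones penalised, and a free atom
    contributes zero; electrostatic: screened Coulomb between charged
    side-chain group centroids (cut 8 Å).  Pairs within a residue or
    between adjacent residues of a chain are excluded (bonded
    neighbourhood).
    """

    term_names = ("attractive", "repulsive", "solvation", "electrostatic")

    def __init__(self, lj_cut: float = 6.0, lj_switch_start: float = 5.0,
                 elec_cut: float = 8.0, repulsive_cap: float = 20.0,
                 coulomb_k: float = 30.0, screening_length: float = 3.0,
                 probe_radius: float = 1.4, sasa_n_points: int = 92,
                 weights: dict[str, float] | None = None):
        self.lj_cut = lj_cut
        self.lj_switch_start = lj_switch_start
        self.elec_cut = elec_cut
        self.repulsive_cap = repulsive_cap
        self.coulomb_k = coulomb_k
        self.screening_length = screening_length
        self.probe_radius = probe_radius
        self.sasa_n_points = sasa_n_points
        self.weights = {t: 1.0 for t in self.term_names}
        if weights:
            self.weights.update(weights)

    # -- pair terms --------------------------------------------------------
    def _switch(self, r: np.ndarray) -> np.ndarray:
        s = np.clip((self.lj_cut - r) / (self.lj_cut - self.lj_switch_start),
                    0.0, 1.0)
        return s * s * (3.0 - 2.0 * s)

    def pair_terms(self, r: np.ndarray, rm: np.ndarray, eps: np.ndarray,
                   qq: np.ndarray) -> dict[str, np.ndarray]:
        """Per-pair attractive/repulsive/electrostatic energies."""
        r = np.asarray(r, dtype=float)
        with np.errstate(divide="ignore", over="ignore"):
            x6 = (rm / np.maximum(r, 1e-6)) ** 6
        lj = eps * (x6 * x6 - 2.0 * x6)
        inside = r < rm
        attractive = np.where(inside, -eps, lj) * self._switch(r)
        repulsive = np.where(inside, np.minimum(lj + eps, self.repulsive_cap), 0.0)
        elec = np.where(
            (r < self.elec_cut) & (qq != 0.0),
            self.coulomb_k * qq * np.exp(-r / self.screening_length)
            / np.maximum(r, 1e-6),
            0.0,
        )
        return {
            "attractive": self.weights["attractive"] * attractive,
            "repulsive": self.weights["repulsive"] * repulsive,
            "electrostatic": self.weights["electrostatic"] * elec,
        }

    def _pair_list(self, sys: _System, coords: np.ndarray):
        tree = cKDTree(coords)
        pairs = tree.query_pairs(max(self.lj_cut, self.elec_cut),
                                 output_type="ndarray")
        if len(pairs) == 0:
            return np.empty((0, 2), dtype=int)
        keep = ~sys.excluded(pairs[:, 0], pairs[:, 1])
        return pairs[keep]

    # -- full score --------------------------------------------------------
    def score_system(self, sys: _System,
                     coords: np.ndarray | None = None) -> EnergyBreakdown:
        coords = sys.coords if coords is None else coords
        pairs = self._pair_list(sys, coords)
        i, j = pairs[:, 0], pairs[:, 1]
        r = np.linalg.norm(coords[i] - coords[j], axis=1)
        terms = self.pair_terms(r, sys.radius[i] + sys.radius[j],
                                np.sqrt(sys.eps[i] * sys.eps[j]),
                                sys.charge[i] * sys.charge[j])
        # reference-shifted solvation: a fully exposed atom contributes 0,
        # so removing an exposed side chain is solvation-neutral while
        # removing a buried nonpolar one costs its burial bonus
        areas = atom_areas(coords, sys.radius, self.probe_radius,
                           self.sasa_n_points)
        area_max = 4.0 * np.pi * (sys.radius + self.probe_radius) ** 2
        solv = self.weights["solvation"] * sys.sigma_solv * (areas - area_max)

        per_res = np.zeros(sys.n_res)
        for t in ("attractive", "repulsive", "electrostatic"):
            half = 0.5 * terms[t]
            np.add.at(per_res, sys.res_idx[i], half)
            np.add.at(per_res, sys.res_idx[j], half)
        np.add.at(per_res, sys.res_idx, solv)

        term_totals = {
            "attractive": float(terms["attractive"].sum()),
            "repulsive": float(terms["repulsive"].sum()),
            "solvation": float(solv.sum()),
            "electrostatic": float(terms["electrostatic"].sum()),
        }
        per_residue = {
            (int(sys.res_chain[k]), int(sys.res_author[k])): float(per_res[k])
            for k in range(sys.n_res)
        }
        return EnergyBreakdown(total=float(per_res.sum()), terms=term_totals,
                               per_residue=per_residue)

    def score(self, assembly: FibrilAssembly) -> EnergyBreakdown:
        return self.score_system(_System(assembly))

    # -- local (delta) evaluation for coordinate descent -------------------
    def local_deltas(self, sys: _System, coords: np.ndarray,
                     moved: np.ndarray, trial_pos: list[np.ndarray]
                     ) -> np.ndarray:
        """Exact changes in total energy for each trial move of ``moved``.

        Every affected pair involves a moved atom, and every atom whose
        exposed area can change lies within occlusion reach of a moved
        atom in some state; sets are enumerated against the union of all
        states, so each delta equals the full-score delta.
        """
        moved = np.asarray(moved, dtype=int)
        anchors = np.vstack([coords[moved]] + list(trial_pos))
        d = np.linalg.norm(coords[:, None, :] - anchors[None, :, :],
                           axis=-1).min(axis=1)

        cut = max(self.lj_cut, self.elec_cut)
        near = np.where(d <= cut)[0]
        ii, jj = np.meshgrid(moved, near, indexing="ij")
        ii, jj = ii.ravel(), jj.ravel()
        both_moved = np.isin(jj, moved)
        keep = (~both_moved) | (ii < jj)
        ii, jj = ii[keep], jj[keep]
        if len(ii):
            keep2 = ~sys.excluded(ii, jj)
            ii, jj = ii[keep2], jj[keep2]
        rm = sys.radius[ii] + sys.radius[jj]
        eps = np.sqrt(sys.eps[ii] * sys.eps[jj])
        qq = sys.charge[ii] * sys.charge[jj]

        reach = 2.0 * sys.radius.max() + 2.0 * self.probe_radius
        affected = np.where(d <= reach)[0]
        w = self.weights["solvation"] * sys.sigma_solv[affected]

        # candidate occluder lists shared by all trial states: a margin of
        # the maximal trial displacement keeps them supersets in every state
        ext = sys.radius + self.probe_radius
        disp = max(float(np.abs(p - coords[moved]).max())
                   for p in trial_pos) if trial_pos else 0.0
        D = np.linalg.norm(coords[affected][:, None, :] - coords[None, :, :],
                           axis=-1)
        close = D < ext[affected][:, None] + ext[None, :] + 2.0 * disp
        close[np.arange(len(affected)), affected] = False
        rows, nb_flat = np.nonzero(close)
        nb_count = np.bincount(rows, minlength=len(affected)).astype(np.int64)
        nb_start = np.concatenate([[0], np.cumsum(nb_count)[:-1]]).astype(np.int64)
        nlists = (np.ascontiguousarray(nb_flat, dtype=np.int64),
                  nb_start, nb_count)

        def _energy(c: np.ndarray) -> float:
            e = 0.0
            if len(ii):
                r = np.linalg.norm(c[ii] - c[jj], axis=1)
                terms = self.pair_terms(r, rm, eps, qq)
                e += float(sum(t.sum() for t in terms.values()))
            areas = atom_areas(c, sys.radius, self.probe_radius,
                               self.sasa_n_points, subset=affected,
                               neighbor_lists=nlists)
            return e + float((w * areas).sum())

        e0 = _energy(coords)
        out = np.empty(len(trial_pos))
        work = coords.copy()
        for k, pos in enumerate(trial_pos):
            work[moved] = pos
            out[k] = _energy(work) - e0
            work[moved] = coords[moved]
        return out


def get_backend(name: str = "crossbeta", **kwargs) -> CrossBetaPotential:
    if name != "crossbeta":
        raise ScanError(f"unknown backend {name!r}")
    return CrossBetaPotential(**kwargs)


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    """Protocol parameters; defaults follow the published scan conditions."""

    n_replicates: int = 35
    neighborhood_radius: float = 8.0  # Å around the mutation site
    restraint_pair_cutoff: float = 9.0  # Å pairwise restraints to input
    restraint_weight: float = 1.0
    perturb_sigma_chi: float = 8.0  # degrees of side-chain jitter
    chi_step: float = 10.0  # degrees, coordinate-descent trial step
    max_sweeps: int = 5
    convergence_tol: float = 1.0  # energy-unit change per sweep
    rng_seed: int = 0
    backend: str = "crossbeta"
    exclude_glycine: bool = True
    include_interface: bool = True
    # external-engine parameters recorded for provenance, unused here
    sampler_note: dict = field(default_factory=lambda: {
        "backrub_temperature_kT": 1.2, "backrub_steps": 35000})

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ScanError("n_replicates must be >= 1")
        if self.neighborhood_radius <= 0 or self.restraint_pair_cutoff <= 0:
            raise ScanError("radii must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class InterfaceResult:
    dg_mut: float
    dg_wt: float

    @property
    def ddg_interface(self) -> float:
        return self.dg_mut - self.dg_wt


@dataclass
class ReplicateRecord:
    replicate: int
    delta_reu_assembly: float
    delta_reu_edge: float
    delta_reu_internal: float
    bound_mut: float
    bound_wt: float
    unbound_mut: float = float("nan")
    unbound_wt: float = float("nan")
    ddg_interface: float = float("nan")
    term_deltas: dict[str, float] = field(default_factory=dict)


@dataclass
class PositionScan:
    position: int
    aa_type: str
    records: list[ReplicateRecord]

    @property
    def mean_delta_reu(self) -> float:
        return float(np.mean([r.delta_reu_assembly for r in self.records]))

    @property
    def mean_ddg_interface(self) -> float:
        return float(np.mean([r.ddg_interface for r in self.records]))


@dataclass
class ScanResult:
    structure_id: str
    positions: dict[int, PositionScan]
    excluded_positions: dict[int, str]
    config: ScanConfig | None = None

    def mean_delta_reu(self) -> dict[int, float]:
        return {p: ps.mean_delta_reu for p, ps in self.positions.items()}

    def profile_with_na(self) -> dict[int, float | None]:
        """Mean ΔREU keyed by author number, None for excluded positions."""
        out: dict[int, float | None] = dict(self.mean_delta_reu())
        for p in self.excluded_positions:
            out[p] = None
        return dict(sorted(out.items()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p, ps in sorted(self.positions.items()):
            for r in ps.records:
                rows.append({
                    "structure_id": self.structure_id, "residue": p,
                    "aa": ps.aa_type, "replicate": r.replicate,
                    "bound_mut": r.bound_mut, "bound_wt": r.bound_wt,
                    "delta_reu_assembly": r.delta_reu_assembly,
                    "delta_reu_edge": r.delta_reu_edge,
                    "delta_reu_internal": r.delta_reu_internal,
                    "unbound_mut": r.unbound_mut, "unbound_wt": r.unbound_wt,
                    "ddg_interface": r.ddg_interface,
                    **{f"d_{k}": v for k, v in r.term_deltas.items()},
                })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        """Write the replicate table plus a JSON config sidecar."""
        self.to_frame().to_csv(path, sep="\t", index=False)
        if self.config is not None:
            sidecar = Path(str(path) + ".config.json")
            sidecar.write_text(self.config.to_json())
        if self.excluded_positions:
            Path(str(path) + ".excluded.json").write_text(
                json.dumps({str(k): v for k, v in
                            sorted(self.excluded_positions.items())}))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

ALA_ATOMS = frozenset(BACKBONE_ATOMS) | {"CB"}


def mutate_to_alanine(assembly: FibrilAssembly, position: int,
                      override_glycine: bool = False) -> FibrilAssembly:
    """Alanine substitution at one author position in every layer.

    The side chain is truncated to CB at its native geometry.  Glycine
    positions raise :class:`PositionExcluded` unless overridden (a glycine
    has no CB to keep; the override relabels without adding atoms).
    """
    try:
        aa = assembly.layers[0].residue(position).aa_type
    except KeyError:
        raise ScanError(f"position {position} absent from the assembly") from None
    if aa == "G" and not override_glycine:
        raise PositionExcluded(position, "glycine")
    out = assembly.copy()
    for layer in out.layers:
        res = layer.residue(position)
        res.atoms = [a for a in res.atoms if a.name in ALA_ATOMS]
        res.aa_type = "A"
    out.log("mutate_to_alanine", position=position, from_aa=aa)
    return out


def _site_coords(sys: _System, position: int) -> np.ndarray:
    """CB (CA for glycine) coordinates of the site in every chain."""
    mask = (sys.author == position) & (sys.name == "CB")
    if not mask.any():
        mask = (sys.author == position) & (sys.name == "CA")
    if not mask.any():
        raise ScanError(f"position {position} absent")
    return sys.coords[mask]


def _movable_residues(sys: _System, position: int, radius: float) -> list[int]:
    """Flat residue indices with side-chain atoms near the mutation site."""
    sites = _site_coords(sys, position)
    anchor = np.where((sys.name == "CB")
                      | ((sys.name == "CA") & (sys.aa == "G")))[0]
    d = np.linalg.norm(sys.coords[anchor][:, None, :] - sites[None, :, :],
                       axis=-1).min(axis=1)
    near_res = set(sys.res_idx[anchor[d <= radius]].tolist())
    return sorted(r for r in near_res
                  if np.any((sys.res_idx == r) & sys.is_sidechain))


def _rotate_sidechain(coords: np.ndarray, sys: _System, res: int,
                      angle_deg: float) -> np.ndarray:
    """New coordinates for the residue's side-chain atoms, rotated about CA→CB."""
    sel = (sys.res_idx == res)
    ca = coords[sel & (sys.name == "CA")][0]
    cb_mask = sel & (sys.name == "CB")
    cb = coords[cb_mask][0]
    axis = cb - ca
    R = rotation_about_axis(axis, np.radians(angle_deg))
    side = np.where(sel & sys.is_sidechain)[0]
    return side, (coords[side] - ca) @ R.T + ca


def relax(assembly: FibrilAssembly, config: ScanConfig, site: int,
          rng: np.random.Generator,
          backend: CrossBetaPotential | None = None) -> FibrilAssembly:
    """Perturb and greedily relax side chains near the mutation site.

    Side-chain χ angles of residues whose CB lies within
    ``neighborhood_radius`` of the site are jittered (Gaussian,
    ``perturb_sigma_chi``) and then relaxed by greedy coordinate descent
    on backend energy plus harmonic pair restraints to the *input*
    coordinates (pairs within ``restraint_pair_cutoff``, weight
    ``restraint_weight``).  The backbone is fixed throughout.  Descent
    stops when a sweep improves the objective by less than
    ``convergence_tol`` (one energy unit by default).
    """
    backend = backend or get_backend(config.backend)
    sys = _System(assembly)
    ref = sys.coords.copy()
    coords = sys.coords.copy()
    residues = _movable_residues(sys, site, config.neighborhood_radius)
    if not residues:
        return assembly.copy()

    movable_atoms = np.where(np.isin(sys.res_idx, residues)
                             & sys.is_sidechain)[0]
    # restraint pairs: involve a movable atom, within cutoff in the input
    tree = cKDTree(ref)
    cand = tree.query_ball_point(ref[movable_atoms],
                                 config.restraint_pair_cutoff)
    rpairs = set()
    for a, lst in zip(movable_atoms, cand):
        for b in lst:
            if b != a:
                rpairs.add((min(a, int(b)), max(a, int(b))))
    rp = np.array(sorted(rpairs), dtype=int).reshape(-1, 2)
    rp_ref = np.linalg.norm(ref[rp[:, 0]] - ref[rp[:, 1]], axis=1) \
        if len(rp) else np.empty(0)

    def restraint_delta(c: np.ndarray, moved: np.ndarray,
                        new_pos: np.ndarray) -> float:
        if len(rp) == 0:
            return 0.0
        sel = np.isin(rp[:, 0], moved) | np.isin(rp[:, 1], moved)
        if not sel.any():
            return 0.0
        nc = c.copy()
        nc[moved] = new_pos
        d_old = np.linalg.norm(c[rp[sel, 0]] - c[rp[sel, 1]], axis=1)
        d_new = np.linalg.norm(nc[rp[sel, 0]] - nc[rp[sel, 1]], axis=1)
        return config.restraint_weight * float(
            ((d_new - rp_ref[sel]) ** 2).sum() - ((d_old - rp_ref[sel]) ** 2).sum())

    # -- perturbation ------------------------------------------------------
    # angles are drawn for every residue in a fixed order so the random
    # stream is identical between the mutant and wild-type branches even
    # though the mutated residue itself has no side chain to perturb
    if config.perturb_sigma_chi > 0:
        movable_set = set(residues)
        for res in range(sys.n_res):
            ang = rng.normal(0.0, config.perturb_sigma_chi)
            if res in movable_set:
                side, newpos = _rotate_sidechain(coords, sys, res, ang)
                coords[side] = newpos

    # -- greedy coordinate descent -----------------------------------------
    # bounded chi trial steps (coarse and fine, both senses); the input
    # geometry is a strong attractor through the restraints, so descent
    # ends near — but not bit-identically at — the input, which is what
    # gives the replicate ensemble its spread
    candidates = [-config.chi_step, config.chi_step,
                  -config.chi_step / 3.0, config.chi_step / 3.0]
    for _ in range(config.max_sweeps):
        sweep_gain = 0.0
        for res in residues:
            side = np.where((sys.res_idx == res) & sys.is_sidechain)[0]
            trials = [_rotate_sidechain(coords, sys, res, ang)[1]
                      for ang in candidates]
            deltas = backend.local_deltas(sys, coords, side, trials)
            deltas = deltas + np.array([restraint_delta(coords, side, pos)
                                        for pos in trials])
            k = int(np.argmin(deltas))
            if deltas[k] < -1e-12:
                coords[side] = trials[k]
                sweep_gain += -float(deltas[k])
        if sweep_gain < config.convergence_tol:
            break
    else:
        warnings.warn(f"relax at site {site}: descent not converged after "
                      f"{config.max_sweeps} sweeps; returning best-so-far",
                      RuntimeWarning, stacklevel=2)

    out = assembly.copy()
    out.set_coords(coords)
    return out


def score_assembly(assembly: FibrilAssembly,
                   backend: CrossBetaPotential | None = None) -> EnergyBreakdown:
    """Full-assembly energy with per-term and per-residue attribution."""
    return (backend or CrossBetaPotential()).score(assembly)


def _edge_internal(bd: EnergyBreakdown, n_chains: int) -> tuple[float, float]:
    per_chain = bd.per_chain()
    edge = per_chain.get(0, 0.0) + (per_chain.get(n_chains - 1, 0.0)
                                    if n_chains > 1 else 0.0)
    return edge, bd.total - edge


def _unbound_coords(sys: _System, coords: np.ndarray) -> np.ndarray:
    """Rigidly separate the central trimer from the remaining layers."""
    n = sys.n_chains
    mid = n // 2
    trimer = np.isin(sys.chain_idx, [mid - 1, mid, mid + 1])
    out = coords.copy()
    out[trimer] = out[trimer] + np.array([UNBOUND_SEPARATION, 0.0, 0.0])
    return out


def _branch_scores(assembly: FibrilAssembly, config: ScanConfig, site: int,
                   backend: CrossBetaPotential, seed_list: list[int]
                   ) -> tuple[EnergyBreakdown, float]:
    """Repack + relax one branch and score bound (and unbound) states."""
    rng = np.random.default_rng(np.random.SeedSequence(seed_list))
    relaxed = relax(assembly, config, site, rng, backend)
    sys = _System(relaxed)
    bound = backend.score_system(sys)
    unbound_total = float("nan")
    if config.include_interface:
        if sys.n_chains < 5:
            raise ScanError("interface ΔΔG needs at least 5 layers "
                            "(central trimer vs the rest)")
        unbound = backend.score_system(sys, _unbound_coords(sys, sys.coords))
        unbound_total = unbound.total
    return bound, unbound_total


def scan_position(wt: FibrilAssembly, position: int, config: ScanConfig,
                  backend: CrossBetaPotential | None = None) -> PositionScan:
    """Full replicate ensemble for one position (ΔREU and interface ΔΔG)."""
    backend = backend or get_backend(config.backend)
    aa = wt.layers[0].residue(position).aa_type
    if aa == "G" and config.exclude_glycine:
        raise PositionExcluded(position, "glycine")
    n_chains = wt.n_layers
    # branch arms repack + relax without fresh perturbation: replicate
    # diversity comes from the shared ensemble step, as in a sampler-then-
    # minimise protocol, and identical branch treatment keeps Ala→Ala at
    # exactly zero
    branch_cfg = ScanConfig(**{**asdict(config), "perturb_sigma_chi": 0.0})
    records = []
    for rep in range(config.n_replicates):
        seed = [config.rng_seed & 0x7FFFFFFF, position, rep]
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        ensemble = relax(wt, config, position, rng, backend)
        mutant = mutate_to_alanine(ensemble, position)
        branch_seed = seed + [1]
        b_mut, u_mut = _branch_scores(mutant, branch_cfg, position, backend,
                                      branch_seed)
        b_wt, u_wt = _branch_scores(ensemble, branch_cfg, position, backend,
                                    branch_seed)
        edge_mut, internal_mut = _edge_internal(b_mut, n_chains)
        edge_wt, internal_wt = _edge_internal(b_wt, n_chains)
        ddg = float("nan")
        if config.include_interface:
            ddg = InterfaceResult(b_mut.total - u_mut,
                                  b_wt.total - u_wt).ddg_interface
        records.append(ReplicateRecord(
            replicate=rep,
            delta_reu_assembly=b_mut.total - b_wt.total,
            delta_reu_edge=edge_mut - edge_wt,
            delta_reu_internal=internal_mut - internal_wt,
            bound_mut=b_mut.total, bound_wt=b_wt.total,
            unbound_mut=u_mut, unbound_wt=u_wt, ddg_interface=ddg,
            term_deltas={k: b_mut.terms[k] - b_wt.terms[k]
                         for k in b_mut.terms},
        ))
    return PositionScan(position=position, aa_type=aa, records=records)


def delta_reu_assembly(wt: FibrilAssembly, position: int, config: ScanConfig,
                       backend: CrossBetaPotential | None = None
                       ) -> PositionScan:
    """Replicate ΔREU_assembly values (no interface split) for one position."""
    cfg = ScanConfig(**{**asdict(config), "include_interface": False})
    return scan_position(wt, position, cfg, backend)


def ddg_interface(wt: FibrilAssembly, position: int, config: ScanConfig,
                  backend: CrossBetaPotential | None = None
                  ) -> list[InterfaceResult]:
    """Replicate interface ΔΔG of the central trimer against the stack."""
    if wt.n_layers < 5:
        raise ScanError("interface ΔΔG needs at least 5 layers")
    cfg = ScanConfig(**{**asdict(config), "include_interface": True})
    ps = scan_position(wt, position, cfg, backend)
    return [InterfaceResult(r.bound_mut - r.unbound_mut,
                            r.bound_wt - r.unbound_wt) for r in ps.records]


def run_alanine_scan(assembly: FibrilAssembly, config: ScanConfig | None = None,
                     backend: CrossBetaPotential | None = None,
                     structure_id: str = "structure") -> ScanResult:
    """Scan every position of the assembly; deterministic under one seed.

    Per-position failures (glycines, missing side chains) are recorded as
    structured exclusions without aborting the scan.
    """
    config = config or ScanConfig()
    backend = backend or get_backend(config.backend)
    positions: dict[int, PositionScan] = {}
    excluded: dict[int, str] = {}
    for pos in assembly.author_numbers:
        try:
            positions[pos] = scan_position(assembly, pos, config, backend)
        except PositionExcluded as e:
            excluded[pos] = e.reason
        except ScanError as e:
            excluded[pos] = str(e)
    return ScanResult(structure_id=structure_id, positions=positions,
                      excluded_positions=excluded, config=config)


def layer_decomposition(scan: ScanResult) -> pd.DataFrame:
    """Per-position mean edge/internal/assembly ΔREU decomposition.

    Edge = the two terminal layers; internal = the rest.  By construction
    edge + internal equals the assembly value exactly for every replicate.
    """
    rows = []
    for p, ps in sorted(scan.positions.items()):
        rows.append({
            "residue": p,
            "aa": ps.aa_type,
            "delta_reu_assembly": ps.mean_delta_reu,
            "delta_reu_edge": float(np.mean([r.delta_reu_edge
                                             for r in ps.records])),
            "delta_reu_internal": float(np.mean([r.delta_reu_internal
                                                 for r in ps.records])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# external score ingestion
# ---------------------------------------------------------------------------

REQUIRED_SCORE_COLUMNS = ("structure_id", "residue", "replicate",
                          "bound_mut", "bound_wt")


def ingest_external_scores(path) -> ScanResult:
    """Build a ScanResult from an external engine's per-replicate table.

    Expects a TSV with header columns structure_id, residue, replicate,
    bound_mut, bound_wt (extra columns are carried as term deltas).
    ΔREU = bound_mut − bound_wt per row.
    """
    return scan_result_from_frame(pd.read_csv(path, sep="\t"), origin=str(path))


def scan_result_from_frame(df: pd.DataFrame, origin: str = "<frame>") -> ScanResult:
    """As :func:`ingest_external_scores`, from an in-memory table."""
    path = origin
    missing = [c for c in REQUIRED_SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ScanError(f"{path}: missing columns {missing}")
    for col in ("residue", "replicate", "bound_mut", "bound_wt"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.where(bad | df[col].isna())[0][0]) + 2  # header is row 1
            raise ScanError(f"{path}: non-numeric or missing {col} at row {row}")
    dup = df.duplicated(subset=["structure_id", "residue", "replicate"])
    if dup.any():
        row = int(np.where(dup)[0][0]) + 2
        raise ScanError(f"{path}: duplicate (residue, replicate) key at row {row}")
    sids = df["structure_id"].unique()
    if len(sids) != 1:
        raise ScanError(f"{path}: expected one structure_id, got {list(sids)}")
    positions: dict[int, PositionScan] = {}
    extra = [c for c in df.columns if c not in REQUIRED_SCORE_COLUMNS
             and c != "aa"]
    for pos, grp in df.groupby("residue"):
        records = []
        for row in grp.itertuples():
            bm, bw = float(row.bound_mut), float(row.bound_wt)
            records.append(ReplicateRecord(
                replicate=int(row.replicate),
                delta_reu_assembly=bm - bw,
                delta_reu_edge=float("nan"), delta_reu_internal=float("nan"),
                bound_mut=bm, bound_wt=bw,
                term_deltas={c: float(getattr(row, c)) for c in extra},
            ))
        aa = grp["aa"].iloc[0] if "aa" in grp.columns else "X"
        positions[int(pos)] = PositionScan(position=int(pos), aa_type=aa,
                                           records=records)
    return ScanResult(structure_id=str(sids[0]), positions=positions,
                      excluded_positions={}, config=None)
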