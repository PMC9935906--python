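"""Alanine-scan engine: potential shape, mutation, relaxation, identities."""

import numpy as np
import pandas as pd
import pytest

from fibrilscan import (
    CrossBetaPotential,
    PositionExcluded,
    ScanConfig,
    ScanError,
    ingest_external_scores,
    layer_decomposition,
    mutate_to_alanine,
    relax,
    run_alanine_scan,
    scan_position,
    score_assembly,
)
from fibrilscan.energetics import _System, _rotate_sidechain
from fibrilscan.model import Atom, FibrilAssembly, Layer, Residue
from fibrilscan.synthetic import FibrilSpec, generate_fibril, hairpin_path, \
    straight_path

FAST = dict(n_replicates=1, include_interface=False, perturb_sigma_chi=0.0)


def _backend64():
    """Cheaper point density for unit tests; orderings are unaffected."""
    return CrossBetaPotential(sasa_n_points=92)


class TestPotentialShape:
    def test_pair_at_minimum_attracts_without_repulsion(self, backend):
        rm, eps = np.array([3.4]), np.array([0.12])
        t = backend.pair_terms(np.array([3.4]), rm, eps, np.zeros(1))
        assert t["attractive"][0] == pytest.approx(-0.12)
        assert t["repulsive"][0] == 0.0

    def test_clash_is_capped(self, backend):
        rm, eps = np.array([3.4]), np.array([0.12])
        t = backend.pair_terms(np.array([1.0]), rm, eps, np.zeros(1))
        assert t["repulsive"][0] == pytest.approx(backend.repulsive_cap * 1.0,
                                                  rel=1e-9)

    def test_beyond_cutoff_vanishes(self, backend):
        t = backend.pair_terms(np.array([7.0]), np.array([3.4]),
                               np.array([0.12]), np.zeros(1))
        assert t["attractive"][0] == 0.0 and t["repulsive"][0] == 0.0

    def test_three_atom_closed_form(self, backend):
        """Two carbons at the LJ minimum plus one distant: LJ well + caps."""
        layer = Layer("A", [
            Residue(1, "A", [Atom("CA", "C", [0.0, 0.0, 0.0])]),
            Residue(3, "A", [Atom("CA", "C", [3.4, 0.0, 0.0])]),
            Residue(9, "A", [Atom("CA", "C", [200.0, 0.0, 0.0])]),
        ])
        bd = score_assembly(FibrilAssembly(layers=[layer]), backend)
        ext = 1.7 + 1.4
        sphere = 4.0 * np.pi * ext ** 2
        h = ext - 3.4 / 2.0
        cap = 2.0 * np.pi * ext * h
        sigma_c = 0.016
        expect_solv = 2.0 * sigma_c * (-cap)  # far atom contributes 0
        assert bd.terms["attractive"] == pytest.approx(-0.12, abs=1e-9)
        assert bd.terms["repulsive"] == 0.0
        assert bd.terms["solvation"] == pytest.approx(expect_solv, rel=0.02)
        assert bd.total == pytest.approx(-0.12 + expect_solv, rel=0.02)
        _ = sphere

    def test_distant_layers_have_pairless_energy(self):
        spec = FibrilSpec("SVL", straight_path(3), rise=100.0, twist=0.0,
                          n_layers=2)
        bd = score_assembly(generate_fibril(spec), _backend64())
        assert bd.terms["electrostatic"] == 0.0
        # within-layer pairs remain, but duplicating a non-interacting
        # layer exactly doubles every term (energy extensivity)
        spec4 = FibrilSpec("SVL", straight_path(3), rise=100.0, twist=0.0,
                           n_layers=4)
        bd4 = score_assembly(generate_fibril(spec4), _backend64())
        assert bd4.total == pytest.approx(2.0 * bd.total, abs=1e-9)

    def test_breakdown_identities(self, two_sided5, backend):
        bd = score_assembly(two_sided5, backend)
        assert bd.total == pytest.approx(sum(bd.terms.values()), abs=1e-9)
        assert sum(bd.per_residue.values()) == pytest.approx(bd.total,
                                                             abs=1e-9)

    def test_score_is_deterministic(self, two_sided5, backend):
        a = score_assembly(two_sided5, backend)
        b = score_assembly(two_sided5, backend)
        assert a.total == b.total
        assert a.terms == b.terms


class TestMutate:
    def test_alanine_is_identity(self, small_straight):
        # position 4 is S; make an Ala fibril first
        spec = FibrilSpec("SALS", straight_path(4), n_layers=2)
        asm = generate_fibril(spec)
        out = mutate_to_alanine(asm, 2)
        assert np.array_equal(out.atom_table()["coords"],
                              asm.atom_table()["coords"])

    def test_leucine_truncates_to_cb(self, small_straight):
        out = mutate_to_alanine(small_straight, 3)  # L
        for layer in out.layers:
            res = layer.residue(3)
            assert sorted(a.name for a in res.atoms) == sorted(
                ["N", "CA", "C", "O", "CB"])
            assert res.aa_type == "A"
        # native CB geometry is kept
        orig_cb = small_straight.layers[0].residue(3).atom("CB").coords
        assert np.array_equal(out.layers[0].residue(3).atom("CB").coords,
                              orig_cb)

    def test_glycine_excluded_with_reason(self):
        spec = FibrilSpec("SGLS", straight_path(4), n_layers=2)
        asm = generate_fibril(spec)
        with pytest.raises(PositionExcluded) as exc:
            mutate_to_alanine(asm, 2)
        assert exc.value.reason == "glycine"
        # override relabels without crashing
        out = mutate_to_alanine(asm, 2, override_glycine=True)
        assert out.layers[0].residue(2).aa_type == "A"

    def test_absent_position_rejected(self, small_straight):
        with pytest.raises(ScanError):
            mutate_to_alanine(small_straight, 99)


class TestRelax:
    def _fixed_point(self, asm, cfg, backend, site):
        rng = np.random.default_rng(0)
        for _ in range(6):
            nxt = relax(asm, cfg, site, rng, backend)
            if np.array_equal(nxt.atom_table()["coords"],
                              asm.atom_table()["coords"]):
                return asm
            asm = nxt
        return asm

    def test_zero_perturbation_fixed_point(self, small_straight):
        backend = _backend64()
        cfg = ScanConfig(perturb_sigma_chi=0.0, convergence_tol=1e-12,
                         max_sweeps=10)
        asm = self._fixed_point(small_straight, cfg, backend, 3)
        out = relax(asm, cfg, 3, np.random.default_rng(1), backend)
        assert np.array_equal(out.atom_table()["coords"],
                              asm.atom_table()["coords"])

    def test_descent_never_raises_energy(self, small_straight):
        backend = _backend64()
        # perturb side chains, then pure descent (sigma 0): the relaxed
        # energy must not exceed the perturbed input's energy
        perturbed = small_straight.copy()
        sys = _System(perturbed)
        coords = sys.coords.copy()
        rng = np.random.default_rng(5)
        for res in range(sys.n_res):
            if np.any((sys.res_idx == res) & sys.is_sidechain):
                side, pos = _rotate_sidechain(coords, sys, res,
                                              rng.normal(0, 25))
                coords[side] = pos
        perturbed.set_coords(coords)
        e_in = score_assembly(perturbed, backend).total
        cfg = ScanConfig(perturb_sigma_chi=0.0)
        out = relax(perturbed, cfg, 3, np.random.default_rng(0), backend)
        e_out = score_assembly(out, backend).total
        assert e_out <= e_in + 1e-9

    def test_backbone_is_never_moved(self, small_straight):
        backend = _backend64()
        cfg = ScanConfig(perturb_sigma_chi=20.0)
        out = relax(small_straight, cfg, 3, np.random.default_rng(2), backend)
        for la, lb in zip(small_straight.layers, out.layers):
            for ra, rb in zip(la.residues, lb.residues):
                for name in ("N", "CA", "C", "O"):
                    assert np.array_equal(ra.atom(name).coords,
                                          rb.atom(name).coords)


class TestScan:
    def test_alanine_position_gives_exact_zero(self):
        spec = FibrilSpec("SALS", straight_path(4), n_layers=3)
        asm = generate_fibril(spec)
        cfg = ScanConfig(n_replicates=2, include_interface=False,
                         perturb_sigma_chi=8.0, rng_seed=3)
        ps = scan_position(asm, 2, cfg, _backend64())
        for rec in ps.records:
            assert rec.delta_reu_assembly == 0.0
            assert rec.delta_reu_edge == 0.0
            assert rec.delta_reu_internal == 0.0
            assert all(v == 0.0 for v in rec.term_deltas.values())

    def test_disjoint_layers_are_additive(self):
        """ΔREU of n disjoint layers is n × the isolated-layer ΔREU."""
        mono = generate_fibril(FibrilSpec("SVIS", straight_path(4),
                                          rise=100.0, twist=0.0, n_layers=1))
        tri = generate_fibril(FibrilSpec("SVIS", straight_path(4),
                                         rise=100.0, twist=0.0, n_layers=3))
        backend = _backend64()
        cfg = ScanConfig(**FAST, rng_seed=0)
        d1 = scan_position(mono, 3, cfg, backend).records[0]
        d3 = scan_position(tri, 3, cfg, backend).records[0]
        assert d3.delta_reu_assembly == pytest.approx(
            3.0 * d1.delta_reu_assembly, abs=1e-8)
        # internal (middle layer) equals the isolated-layer value
        assert d3.delta_reu_internal == pytest.approx(d1.delta_reu_assembly,
                                                      abs=1e-8)

    def test_buried_hydrophobic_dominates_serine_background(self):
        """A single fully buried Ile tops the ΔREU ranking."""
        path = hairpin_path(5, 3)  # ~9.2 Å spacing: buried but clash-free
        spec = FibrilSpec("SSISS" + "GGS" + "SSSSS", path, n_layers=5)
        asm = generate_fibril(spec)
        cfg = ScanConfig(**FAST, rng_seed=0)
        scan = run_alanine_scan(asm, cfg, _backend64())
        mean = scan.mean_delta_reu()
        assert max(mean, key=mean.get) == 3
        # direct term computation confirms the attraction loss at the site
        mut = mutate_to_alanine(asm, 3)
        d_attr = (score_assembly(mut, _backend64()).terms["attractive"]
                  - score_assembly(asm, _backend64()).terms["attractive"])
        assert d_attr > 0

    def test_edge_internal_decomposition(self, two_sided9, backend):
        asm, planted = two_sided9
        cfg = ScanConfig(**FAST, rng_seed=0)
        ps = scan_position(asm, planted[0], cfg, backend)
        rec = ps.records[0]
        assert rec.delta_reu_edge + rec.delta_reu_internal == pytest.approx(
            rec.delta_reu_assembly, abs=1e-9)
        # per-layer ordering: the buried hotspot destabilises interior
        # layers more than the terminal ones
        assert rec.delta_reu_edge / 2.0 < rec.delta_reu_internal / 7.0
        assert rec.delta_reu_internal > 0

    def test_noncontacting_interface_ddg_is_zero(self):
        spec = FibrilSpec("SVIS", straight_path(4), rise=100.0, twist=0.0,
                          n_layers=5)
        asm = generate_fibril(spec)
        cfg = ScanConfig(n_replicates=1, include_interface=True,
                         perturb_sigma_chi=0.0, rng_seed=0)
        ps = scan_position(asm, 3, cfg, _backend64())
        assert abs(ps.records[0].ddg_interface) < 1e-9

    def test_interface_ddg_identity(self, two_sided9, backend):
        asm, planted = two_sided9
        cfg = ScanConfig(n_replicates=1, include_interface=True,
                         perturb_sigma_chi=0.0, rng_seed=0)
        rec = scan_position(asm, planted[1], cfg, backend).records[0]
        assert rec.ddg_interface == pytest.approx(
            (rec.bound_mut - rec.unbound_mut)
            - (rec.bound_wt - rec.unbound_wt), abs=1e-12)

    def test_interface_needs_five_layers(self, small_straight):
        cfg = ScanConfig(n_replicates=1, include_interface=True,
                         perturb_sigma_chi=0.0)
        with pytest.raises(ScanError, match="5 layers"):
            scan_position(small_straight, 3, cfg, _backend64())

    def test_scan_structure_and_determinism(self):
        spec = FibrilSpec("SVGLS", straight_path(5), n_layers=3)
        asm = generate_fibril(spec)
        cfg = ScanConfig(n_replicates=3, include_interface=False,
                         perturb_sigma_chi=8.0, rng_seed=11)
        backend = _backend64()
        scan1 = run_alanine_scan(asm, cfg, backend, structure_id="toy")
        scan2 = run_alanine_scan(asm, cfg, backend, structure_id="toy")
        assert scan1.to_frame().equals(scan2.to_frame())
        assert scan1.excluded_positions == {3: "glycine"}
        assert set(scan1.positions) == {1, 2, 4, 5}
        assert all(len(ps.records) == 3 for ps in scan1.positions.values())

    def test_protocol_defaults_match_published_conditions(self):
        cfg = ScanConfig()
        assert cfg.n_replicates == 35
        assert cfg.neighborhood_radius == 8.0
        assert cfg.restraint_pair_cutoff == 9.0
        assert cfg.restraint_weight == 1.0
        assert cfg.convergence_tol == 1.0
        assert cfg.exclude_glycine

    def test_layer_decomposition_table(self, two_sided9, backend):
        asm, planted = two_sided9
        cfg = ScanConfig(**FAST, rng_seed=0)
        ps = scan_position(asm, planted[0], cfg, backend)
        from fibrilscan.energetics import ScanResult
        res = ScanResult("t", {planted[0]: ps}, {})
        table = layer_decomposition(res)
        row = table.iloc[0]
        assert row["delta_reu_edge"] + row["delta_reu_internal"] == \
            pytest.approx(row["delta_reu_assembly"], abs=1e-9)


class TestIngest:
    def _toy_frame(self):
        return pd.DataFrame({
            "structure_id": ["t"] * 3,
            "residue": [7, 7, 7],
            "replicate": [0, 1, 2],
            "bound_mut": [11.0, 12.0, 13.0],
            "bound_wt": [10.0, 10.0, 10.0],
        })

    def test_toy_table_mean(self, tmp_path):
        p = tmp_path / "scores.tsv"
        self._toy_frame().to_csv(p, sep="\t", index=False)
        res = ingest_external_scores(p)
        assert res.mean_delta_reu() == {7: 2.0}

    def test_round_trip(self, tmp_path):
        spec = FibrilSpec("SVLS", straight_path(4), n_layers=3)
        asm = generate_fibril(spec)
        cfg = ScanConfig(n_replicates=2, include_interface=False,
                         perturb_sigma_chi=0.0, rng_seed=1)
        scan = run_alanine_scan(asm, cfg, _backend64(), structure_id="rt")
        p = tmp_path / "scan.tsv"
        scan.to_tsv(p)
        back = ingest_external_scores(p)
        for pos in scan.positions:
            got = [r.delta_reu_assembly for r in back.positions[pos].records]
            want = [r.delta_reu_assembly for r in scan.positions[pos].records]
            assert got == pytest.approx(want, abs=1e-12)

    def test_duplicate_key_names_row(self, tmp_path):
        df = self._toy_frame()
        df.loc[2, "replicate"] = 1
        p = tmp_path / "dup.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ScanError, match="row 4"):
            ingest_external_scores(p)

    def test_missing_column_rejected(self, tmp_path):
        df = self._toy_frame().drop(columns=["bound_wt"])
        p = tmp_path / "missing.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ScanError, match="bound_wt"):
            ingest_external_scores(p)

    def test_non_numeric_cell_names_row(self, tmp_path):
        df = self._toy_frame().astype(object)
        df.loc[1, "bound_mut"] = "oops"
        p = tmp_path / "bad.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ScanError, match="row 3"):
            ingest_external_scores(p)
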