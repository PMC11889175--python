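"""Cofactor detection, ligand geometry, ET-chain search and iron accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rnfpump import structure_cofactors as sc


def make_record(rec_id, kind, positions, elements=None, names=None):
    """Minimal CofactorRecord from raw coordinates (test helper)."""
    positions = np.atleast_2d(np.asarray(positions, float))
    n = len(positions)
    elements = elements or ["FE"] * n
    names = names or [f"A{k}" for k in range(n)]
    atoms = pd.DataFrame(
        {
            "chain": ["Z"] * n, "resname": [kind] * n, "resseq": [1] * n,
            "icode": [""] * n, "atom": names, "element": elements,
            "het": [True] * n,
            "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2],
        }
    )
    return sc.CofactorRecord(rec_id, kind, atoms, int(elements.count("FE")))


class TestLoadStructure:
    def test_atom_count_matches_generator_manifest(self, toy_atoms):
        atoms, manifest = toy_atoms
        assert len(atoms) == manifest["n_atoms"]

    def test_both_cluster_types_present(self, toy_atoms):
        atoms, _ = toy_atoms
        het_names = set(atoms.loc[atoms["het"], "resname"])
        assert {"SF4", "FES"} <= het_names

    def test_author_numbering_preserved(self, toy_atoms):
        atoms, _ = toy_atoms
        cys = atoms[(atoms["resname"] == "CYS") & (atoms["chain"] == "A")]
        assert set(cys["resseq"]) == {25, 113}

    def test_empty_file_is_a_parse_error(self, tmp_path):
        bad = tmp_path / "empty.pdb"
        bad.write_text("")
        with pytest.raises(ValueError):
            sc.load_structure(bad)


class TestDetectCofactors:
    def test_full_toy_inventory(self, toy_atoms):
        atoms, manifest = toy_atoms
        records = sc.detect_cofactors(atoms)
        kinds = pd.Series([r.kind for r in records]).value_counts().to_dict()
        assert kinds == manifest["counts"]
        assert len(records) == 15

    def test_fes_carries_two_irons(self, toy_network):
        net, manifest = toy_network
        assert net.record(manifest["ae1_id"]).iron_atoms == 2

    def test_no_hetatm_gives_empty_list(self, toy_atoms):
        atoms, _ = toy_atoms
        assert sc.detect_cofactors(atoms[~atoms["het"]]) == []

    def test_unknown_iron_residue_kept_with_warning(self, toy_atoms):
        atoms, _ = toy_atoms
        odd = atoms.head(1).copy()
        odd.loc[:, ["resname", "element", "het"]] = ["XFE", "FE", True]
        with pytest.warns(UserWarning, match="unknown Fe-containing"):
            records = sc.detect_cofactors(pd.concat([atoms, odd], ignore_index=True))
        assert any(r.kind == "unknown" for r in records)


class TestClusterLigands:
    def test_four_cysteines_ligate_the_membrane_cluster(self, toy_network):
        net, manifest = toy_network
        ligands = sc.cluster_ligands(net, manifest["ae1_id"])
        assert [list(t) for t in ligands] == manifest["ae1_ligands"]

    def test_tiny_cutoff_finds_nothing(self, toy_network):
        net, manifest = toy_network
        assert sc.cluster_ligands(net, manifest["ae1_id"], cutoff_A=0.1) == []

    def test_missing_cluster_id_is_a_lookup_error(self, toy_network):
        net, _ = toy_network
        with pytest.raises(KeyError):
            sc.cluster_ligands(net, "Z/SF4999")

    def test_over_ligation_warns_but_returns_all(self, toy_atoms):
        atoms, manifest = toy_atoms
        # add a fifth cysteine sulfur right next to the AE1 cluster
        extra = atoms[(atoms["resname"] == "CYS")].head(4).copy()
        extra["resseq"] = 999
        fe = atoms[(atoms["resname"] == "FES") & (atoms["element"] == "FE")].iloc[0]
        extra.loc[extra["atom"] == "SG", ["x", "y", "z"]] = [
            fe["x"], fe["y"], fe["z"] + 2.3
        ]
        aug = pd.concat([atoms, extra], ignore_index=True)
        net = sc.build_network(aug)
        with pytest.warns(UserWarning, match="over-ligation"):
            ligands = sc.cluster_ligands(net, manifest["ae1_id"])
        assert len(ligands) == 5

    def test_result_invariant_to_atom_order(self, toy_atoms):
        atoms, manifest = toy_atoms
        shuffled = atoms.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = sc.cluster_ligands(sc.build_network(atoms), manifest["ae1_id"])
        b = sc.cluster_ligands(sc.build_network(shuffled), manifest["ae1_id"])
        assert a == b


class TestEdgeToEdgeDistance:
    def test_two_single_atoms_ten_angstroms_apart(self):
        a = make_record("a", "SF4", [[0, 0, 0]])
        b = make_record("b", "SF4", [[0, 0, 10]])
        assert sc.edge_to_edge_distance(a, b) == pytest.approx(10.0)

    def test_identical_records_are_at_zero(self):
        a = make_record("a", "FES", [[1, 2, 3], [4, 5, 6]])
        assert sc.edge_to_edge_distance(a, a) == 0.0

    def test_matches_brute_force_on_toy_pair(self, toy_network):
        net, manifest = toy_network
        a = net.record(manifest["b8_id"])
        b = net.record(manifest["ae1_id"])
        pa = a.atoms[["x", "y", "z"]].to_numpy()
        pb = b.atoms[["x", "y", "z"]].to_numpy()
        brute = min(
            float(np.linalg.norm(x - y)) for x in pa for y in pb
        )
        assert sc.edge_to_edge_distance(a, b) == pytest.approx(brute, rel=1e-12)
        # manifest truth is exact; parsed PDB coordinates carry 3 decimals
        assert brute == pytest.approx(manifest["b8_ae1_edge_A"], abs=5e-3)

    def test_symmetric_distance_matrix(self, toy_network):
        net, _ = toy_network
        m = net.distances.to_numpy()
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)

    def test_hydrogens_are_excluded(self):
        a = make_record("a", "FMN", [[0, 0, 0], [0, 0, 4]], ["C", "H"], ["C1", "H1"])
        b = make_record("b", "FMN", [[0, 0, 10]], ["C"], ["C2"])
        assert sc.edge_to_edge_distance(a, b) == pytest.approx(10.0)

    def test_conjugated_only_filters_to_core(self):
        a = make_record(
            "a", "FES", [[0, 0, 0], [0, 0, 5]], ["FE", "C"], ["FE1", "C99"]
        )
        b = make_record("b", "FES", [[0, 0, 10]], ["FE"], ["FE1"])
        assert sc.edge_to_edge_distance(a, b, "conjugated-only") == pytest.approx(10.0)
        assert sc.edge_to_edge_distance(a, b, "all-heavy") == pytest.approx(5.0)


def linear_network(positions, decoy=None):
    """Single-atom cofactors on a line, optionally plus a decoy node."""
    records = [
        make_record(f"n{k}", "SF4", [p]) for k, p in enumerate(positions)
    ]
    if decoy is not None:
        records.append(make_record("decoy", "SF4", [decoy]))
    ids = [r.id for r in records]
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = sc.edge_to_edge_distance(records[i], records[j])
    return sc.CofactorNetwork(records, pd.DataFrame(mat, index=ids, columns=ids))


class TestEtChain:
    def test_linear_chain_keeps_identity_ordering(self):
        # 15 A spacing: consecutive edges pass the 25 A ceiling, skips do not
        net = linear_network([[0, 0, 15 * k] for k in range(5)])
        res = sc.build_et_chain(net, "n0", "n4")
        assert res.connected and res.path == ["n0", "n1", "n2", "n3", "n4"]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 30, size=(6, 3))
        net = linear_network(list(pts))
        res = sc.build_et_chain(net, "n0", "n5", ceiling_A=28.0)
        # exhaustive oracle over all simple paths
        import networkx as nx

        g = nx.Graph()
        ids = list(net.distances.index)
        for i, j in itertools.combinations(ids, 2):
            d = net.distances.loc[i, j]
            if d <= 28.0:
                g.add_edge(i, j, weight=d)
        best = min(
            (
                sum(g[u][v]["weight"] for u, v in zip(p, p[1:]))
                for p in nx.all_simple_paths(g, "n0", "n5")
            ),
            default=None,
        )
        if best is None:
            assert not res.connected
        else:
            assert res.connected
            assert res.total_distance_A == pytest.approx(best, rel=1e-12)

    def test_decoy_long_edge_is_excluded(self):
        net = linear_network(
            [[0, 0, 0], [0, 0, 10], [0, 0, 20]], decoy=[0, 40, 10]
        )
        res = sc.build_et_chain(net, "n0", "n2")
        assert "decoy" not in res.path

    def test_ceiling_below_all_edges_reports_gap(self):
        net = linear_network([[0, 0, 0], [0, 0, 12]])
        res = sc.build_et_chain(net, "n0", "n1", ceiling_A=5.0)
        assert not res.connected
        assert res.largest_gap_A == pytest.approx(12.0)

    def test_unknown_node_is_an_error(self, toy_network):
        net, manifest = toy_network
        with pytest.raises(KeyError):
            sc.build_et_chain(net, "nope", manifest["ae1_id"])

    def test_toy_complex_chain_walks_the_fes_ladder(self, toy_network):
        net, manifest = toy_network
        res = sc.build_et_chain(net, manifest["b8_id"], manifest["ae1_id"])
        assert res.connected
        assert res.path == [manifest["b8_id"], manifest["ae1_id"]]


class TestIronAccounting:
    def test_full_toy_inventory_is_42(self, toy_network):
        net, manifest = toy_network
        assert sc.iron_inventory(net) == 42 == manifest["total_fe"]

    def test_conservation_identity(self, toy_network):
        net, _ = toy_network
        n_sf4 = sum(1 for r in net.cofactors if r.kind == "SF4")
        n_fes = sum(1 for r in net.cofactors if r.kind == "FES")
        assert sc.iron_inventory(net) == 4 * n_sf4 + 2 * n_fes

    def test_empty_and_single_cluster(self):
        empty = sc.CofactorNetwork([], pd.DataFrame())
        assert sc.iron_inventory(empty) == 0
        one = make_record("s", "SF4", [[0, 0, 0]] * 4)
        net = sc.CofactorNetwork([one], pd.DataFrame([[0.0]], index=["s"], columns=["s"]))
        assert sc.iron_inventory(net) == 4

    @pytest.mark.parametrize(
        "removed_kind, expected_delta",
        [("FES", -2), ("SF4", -4), ("FMN", 0)],
    )
    def test_variant_iron_deltas(self, toy_network, removed_kind, expected_delta):
        net, manifest = toy_network
        target = next(r.id for r in net.cofactors if r.kind == removed_kind)
        variant = sc.VariantSpec(f"delta-{removed_kind}", [target])
        assert sc.variant_fe_delta(net, variant) == expected_delta

    def test_unknown_cofactor_in_variant_is_an_error(self, toy_network):
        net, _ = toy_network
        with pytest.raises(KeyError):
            sc.variant_fe_delta(net, sc.VariantSpec("bad", ["Q/SF4999"]))


class TestRelativeActivity:
    @pytest.mark.parametrize(
        "variant, wildtype, pct, rounded",
        [
            (0.7, 7.1, 9.86, 10),   # R67A
            (0.8, 7.1, 11.27, 11),  # L103G
            (3.4, 7.1, 47.89, 48),  # Y105A
            (7.1, 7.1, 100.0, 100),
        ],
    )
    def test_measured_activities(self, variant, wildtype, pct, rounded):
        value, as_int = sc.relative_activity(variant, wildtype)
        assert value == pytest.approx(pct, abs=0.01)
        assert as_int == rounded

    def test_nonpositive_wildtype_is_an_error(self):
        with pytest.raises(ValueError):
            sc.relative_activity(0.7, 0.0)
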