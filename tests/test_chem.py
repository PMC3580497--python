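"""Fingerprints, Tanimoto similarity and the similarity network."""

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algscreen import chem
from algscreen.acute import MOTILITY_INHIBITED, MOTILITY_NORMAL, PhenotypeCall
from algscreen.chem import (
    Fingerprint,
    annotate_network,
    build_network,
    cluster_summary,
    compute_fingerprint,
    phenotype_color,
    tanimoto,
)
from algscreen.fitness import FitnessResult

# feature-set sizes for a fixed 10-molecule panel, frozen from a sparse
# Morgan radius-2 reference run (rdkit 2024.09)
REFERENCE_FP_SIZES = {
    "C": 1,
    "CCO": 6,
    "c1ccccc1": 3,
    "CC(=O)O": 8,
    "c1ccc2ccccc2c1": 8,
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O": 26,
    "CN1C=NC2=C1C(=O)N(C(=O)N2C)C": 25,
    "NS(=O)(=O)c1ccccc1": 16,
    "OCC(O)CO": 9,
    "Clc1ccc(Cl)cc1": 8,
}


class TestFingerprint:
    def test_canonicalization_invariance(self):
        assert compute_fingerprint("OCC").features == compute_fingerprint("CCO").features

    def test_methane_non_empty(self):
        assert len(compute_fingerprint("C")) >= 1

    def test_reference_feature_set_sizes(self):
        for smiles, n in REFERENCE_FP_SIZES.items():
            assert len(compute_fingerprint(smiles)) == n, smiles

    def test_unparseable_smiles_names_record(self):
        with pytest.raises(ValueError, match="XYZ-1"):
            compute_fingerprint("not_a_molecule", compound_id="XYZ-1")

    def test_folded_mode_within_bit_range(self):
        fp = compute_fingerprint("CC(=O)Oc1ccccc1C(=O)O", folded=True)
        assert all(0 <= b < chem.FOLDED_SIZE for b in fp.features)


def _fp(cid, feats):
    return Fingerprint(compound_id=cid, features=frozenset(feats))


class TestTanimoto:
    def test_identical_is_one(self):
        a = compute_fingerprint("CCO", "a")
        assert tanimoto(a, a) == 1.0

    def test_disjoint_is_zero(self):
        assert tanimoto(_fp("a", {1, 2}), _fp("b", {3, 4})) == 0.0

    def test_hand_computed(self):
        assert tanimoto(_fp("a", {1, 2, 3}), _fp("b", {2, 3, 4})) == 0.5

    @settings(max_examples=40, deadline=None)
    @given(
        st.sets(st.integers(0, 50), min_size=1, max_size=20),
        st.sets(st.integers(0, 50), min_size=1, max_size=20),
    )
    def test_symmetry_bounds_and_identity(self, xs, ys):
        a, b = _fp("a", xs), _fp("b", ys)
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)
        assert (s == 1.0) == (a.features == b.features)


class TestNetwork:
    def test_identical_molecules_edge_weight_one(self):
        fps = [compute_fingerprint("CCO", "a"), compute_fingerprint("OCC", "b")]
        net = build_network(fps, cutoff=0.5)
        assert net.number_of_edges() == 1
        assert net.edges["a", "b"]["similarity"] == 1.0

    def test_cutoff_is_strict(self):
        # similarity exactly 0.5 must NOT create an edge ("greater than 0.5")
        fps = [_fp("a", {1, 2, 3}), _fp("b", {2, 3, 4})]
        assert build_network(fps, cutoff=0.5).number_of_edges() == 0
        assert build_network(fps, cutoff=0.49).number_of_edges() == 1

    def test_cutoff_one_keeps_only_exact_duplicates(self):
        fps = [_fp("a", {1, 2}), _fp("b", {1, 2}), _fp("c", {1, 2, 3})]
        net = build_network(fps, cutoff=1.0)
        assert net.number_of_edges() == 0  # strict: nothing exceeds 1.0
        net = build_network(fps, cutoff=0.99)
        assert set(map(frozenset, net.edges())) == {frozenset({"a", "b"})}

    def test_singletons_retained_and_flagged(self):
        fps = [_fp("a", {1, 2}), _fp("b", {1, 2}), _fp("z", {9})]
        net = build_network(fps, cutoff=0.5)
        assert net.nodes["z"]["singleton"] is True
        assert net.nodes["a"]["singleton"] is False

    def test_order_invariance(self):
        fps = [_fp(c, {i, i + 1, 5}) for i, c in enumerate("abcdef")]
        e1 = set(map(frozenset, build_network(fps, 0.3).edges()))
        e2 = set(map(frozenset, build_network(fps[::-1], 0.3).edges()))
        assert e1 == e2

    def test_edge_monotonicity_in_cutoff(self):
        fps = [_fp(c, set(range(i, i + 6))) for i, c in enumerate("abcdefgh")]
        hi = set(map(frozenset, build_network(fps, 0.5).edges()))
        lo = set(map(frozenset, build_network(fps, 0.2).edges()))
        assert hi <= lo

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            build_network([_fp("a", {1})], cutoff=1.5)


class TestAnnotation:
    @pytest.mark.parametrize(
        "photo,motil,color",
        [
            (True, True, "green"),
            (True, False, "red"),
            (False, True, "blue"),
            (False, False, "white"),
        ],
    )
    def test_color_mapping(self, photo, motil, color):
        assert phenotype_color(photo, motil) == color

    def test_node_attributes(self):
        fps = [_fp("a", {1, 2}), _fp("b", {1, 2}), _fp("c", {1, 2})]
        net = build_network(fps, cutoff=0.5)
        fit = [FitnessResult("a", 0.4, None, 3, True), FitnessResult("b", 0.9, None, 3, False)]
        acute = [
            PhenotypeCall("a", MOTILITY_NORMAL, photosynthesis_hit=False),
            PhenotypeCall("b", MOTILITY_INHIBITED, photosynthesis_hit=True),
        ]
        with pytest.warns(chem.ChemWarning, match="c"):
            annotate_network(net, fit, acute)
        assert net.nodes["a"]["color"] == "white" and net.nodes["a"]["shape"] == "circle"
        assert net.nodes["b"]["color"] == "green" and net.nodes["b"]["shape"] == "diamond"

    def test_cluster_summary_percentages(self):
        fps = [_fp(c, {1, 2, 3}) for c in "abcd"]
        net = build_network(fps, cutoff=0.5)
        acute = [
            PhenotypeCall(c, MOTILITY_NORMAL, photosynthesis_hit=(c in "ab")) for c in "abcd"
        ]
        annotate_network(net, [], acute)
        df = cluster_summary(net)
        assert len(df) == 1 and df.loc[0, "size"] == 4
        assert df.loc[0, "pct_photosynthesis"] == 50.0


class TestExport:
    def test_sif_and_graphml_roundtrip(self, tmp_path):
        fps = [_fp("a", {1, 2}), _fp("b", {1, 2}), _fp("z", {9})]
        net = build_network(fps, cutoff=0.5)
        annotate_network(net, [FitnessResult("a", 0.4, None, 3, True)], [])
        sif = tmp_path / "net.sif"
        chem.write_sif(net, sif)
        assert sif.read_text().splitlines() == ["a\tpp\tb", "z"]
        gml = tmp_path / "net.graphml"
        chem.write_graphml(net, gml)
        back = nx.read_graphml(gml)
        assert set(back.nodes) == {"a", "b", "z"}
        assert back.nodes["a"]["shape"] == "circle"
        attrs = tmp_path / "nodes.csv"
        chem.write_node_attributes(net, attrs)
        assert "compound_id" in attrs.read_text().splitlines()[0]
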