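import json
import os

import numpy as np
import pytest
from rdkit import Chem

from synthspace.chem_model import (
    AromaticityModel,
    mass_microdaltons,
    molecular_weight,
    standardize_collection,
)
from synthspace.fixtures import FixtureSpec, generate_building_blocks
from synthspace.space import (
    PRODUCT_DESCRIPTORS,
    assemble_product,
    build_space,
    contains,
    count_products,
    coverage_estimate,
    enumerate_products,
    load,
    property_histograms,
    retro_validate,
    serialize,
)
from synthspace.transpiler import translate_transform


def _mini_bbs(**counts):
    spec = FixtureSpec(seed=7, counts=counts, adversarial={})
    rows = generate_building_blocks(spec)
    mols = [(Chem.MolFromSmiles(s), i) for s, i, _ in rows]
    retained, _ = standardize_collection(mols)
    return retained


@pytest.fixture(scope="module")
def mini_amide_space(suite_by_id):
    bbs = _mini_bbs(primary_amine=3, carboxylic_acid=4)
    space, _ = build_space([suite_by_id[9001].text], bbs, name="mini")
    return space


class TestCounting:
    def test_three_by_four_synthons_give_twelve(self, mini_amide_space):
        assert count_products(mini_amide_space) == 12

    def test_count_equals_full_enumeration(self, toy_space, enumerated):
        assert count_products(toy_space) == len(enumerated)
        assert len({(p["graph_id"], p["pair_index"]) for _, p in enumerated}) == len(
            enumerated
        )

    def test_empty_side_counts_zero(self, bbs, suite_by_id):
        # the symmetric alkene pattern leaves side 1 empty under SPACE rules
        space, _ = build_space([suite_by_id[9005].text], bbs, policy="space")
        assert count_products(space) == 0


class TestEnumeration:
    def test_same_seed_identical_sample(self, toy_space):
        a = list(enumerate_products(toy_space, limit=25, seed=11))
        b = list(enumerate_products(toy_space, limit=25, seed=11))
        assert a == b
        c = list(enumerate_products(toy_space, limit=25, seed=12))
        assert a != c

    def test_amide_space_products_contain_amide_bond(self, mini_amide_space):
        amide = Chem.MolFromSmarts("[NX3]-[CX3]=[OX1]")
        for smiles, _prov in enumerate_products(mini_amide_space, limit=10**6, seed=0):
            assert Chem.MolFromSmiles(smiles).HasSubstructMatch(amide)

    def test_mass_conservation_and_water_loss(self, mini_amide_space, bbs, suite_by_id):
        graph = mini_amide_space.graphs[0]
        mol_of = dict((bb_id, mol) for mol, bb_id in _mini_bbs(primary_amine=3, carboxylic_acid=4))
        for s1 in graph.side1:
            for s2 in graph.side2:
                product = assemble_product(s1, s2)
                assert mass_microdaltons(product) == s1.mass_u + s2.mass_u
                delta = (
                    molecular_weight(mol_of[s1.bb_id])
                    + molecular_weight(mol_of[s2.bb_id])
                    - molecular_weight(product)
                )
                assert delta == pytest.approx(18.015, abs=1e-3)


class TestSynthons:
    def test_boc_protected_amine_stored_deprotected(self, toy_space, class_of):
        boc = Chem.MolFromSmarts("[NX3]C(=O)OC(C)(C)C")
        found = False
        for graph in toy_space.graphs:
            for syn in graph.side1 + graph.side2:
                if class_of[syn.bb_id] == "boc_amine":
                    found = True
                    assert not syn.fragment.HasSubstructMatch(boc)
        assert found

    def test_invalid_product_valence_drops_reactant(self, suite_by_id):
        # imine formation: a secondary amine would end up as uncharged N(4)
        text = (
            "TRANSFORM 9100\nNAME Toy imine formation\n"
            "PATTERN N^1[HS>0][HETS:0] + C^2[FGS:KETONE](=O) => N(=C)\n"
        )
        bbs = _mini_bbs(primary_amine=2, secondary_amine=2)
        extra = [(Chem.MolFromSmiles("CCC(=O)CC"), "ketone_0")]
        space, log = build_space([text], bbs + extra, name="imine")
        side1_ids = {s.bb_id for g in space.graphs for s in g.side1}
        assert any("primary" in i for i in side1_ids)
        assert not any("secondary" in i for i in side1_ids)
        dropped = [d for drops in log["dropped_synthons"].values() for d in drops]
        assert any(reason == "valence" for _bb, reason in dropped)


class TestRetroValidation:
    def test_all_enumerated_products_validate(self, toy_space, enumerated):
        graph_of = {g.graph_id: g for g in toy_space.graphs}
        for smiles, prov in enumerated:
            product = Chem.MolFromSmiles(smiles)
            assert retro_validate(
                product,
                graph_of[prov["graph_id"]],
                (prov["bb1"], prov["bb2"]),
                toy_space.model,
            )

    def test_perturbed_product_fails(self, toy_space, enumerated):
        smiles, prov = enumerated[0]
        graph = next(g for g in toy_space.graphs if g.graph_id == prov["graph_id"])
        mol = Chem.RWMol(Chem.MolFromSmiles(smiles))
        anchor = next(
            a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() >= 1
        )
        new_idx = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(anchor, new_idx, Chem.BondType.SINGLE)
        perturbed = mol.GetMol()
        Chem.SanitizeMol(perturbed)
        assert not retro_validate(
            perturbed, graph, (prov["bb1"], prov["bb2"]), toy_space.model
        )

    def test_wrong_regiochemistry_fails(self, bbs, suite_by_id):
        # the pyrazole product pattern anchors the methyl on the ring carbon
        # bonded to N2; the swapped regioisomer must not validate
        space, _ = build_space(
            [suite_by_id[9003].text], bbs, name="pz",
        )
        graph = space.graphs[0]
        smiles, prov = next(iter(enumerate_products(space, limit=1, seed=0)))
        good = Chem.MolFromSmiles(smiles)
        assert retro_validate(good, graph, (prov["bb1"], prov["bb2"]), space.model)
        # regio-swapped analogue: substituents exchanged between the 3- and
        # 5-positions; it is not decomposable into the recorded synthons
        s1 = next(s for s in graph.side1 if s.bb_id == prov["bb1"])
        tail = s1.smiles  # labeled fragment of the hydrazine side
        alt = Chem.MolFromSmiles("Cc1cc(CC)n(CC)n1")
        assert alt is not None
        assert not retro_validate(alt, graph, (prov["bb1"], prov["bb2"]), space.model)


class TestContains:
    def test_round_trip_over_full_enumeration(self, toy_space, enumerated):
        for smiles, prov in enumerated:
            hits = contains(toy_space, smiles)
            assert any(
                h["graph_id"] == prov["graph_id"]
                and h["bb1"] == prov["bb1"]
                and h["bb2"] == prov["bb2"]
                for h in hits
            ), f"round-trip miss for {smiles}"

    def test_unconstructible_query_is_empty(self, toy_space):
        assert contains(toy_space, "C1CC1C1CC1") == []
        assert contains(toy_space, "not-a-smiles") == []

    def test_overlapping_transforms_give_multiple_provenances(
        self, toy_space, enumerated
    ):
        # plain biaryls are constructible via both the plain and the
        # fusion-split coupling transforms
        multi = [
            smiles
            for smiles, prov in enumerated
            if prov["transform_id"] == 9002
            and len({h["transform_id"] for h in contains(toy_space, smiles)}) >= 2
        ]
        assert multi, "expected at least one product shared by two transforms"


class TestHistograms:
    @pytest.mark.parametrize("descriptor", ["MW", "HBD", "HBA"])
    def test_convolution_equals_enumeration(self, toy_space, enumerated, descriptor):
        values = [
            PRODUCT_DESCRIPTORS[descriptor](Chem.MolFromSmiles(s))
            for s, _ in enumerated
        ]
        if descriptor == "MW":
            values = [v / 1e6 for v in values]
            edges = np.linspace(min(values) - 1, max(values) + 1, 24)
        else:
            edges = np.arange(0, max(values) + 2)
        hist = property_histograms(toy_space, descriptor, list(edges))
        reference, _ = np.histogram(values, bins=edges)
        assert hist.counts == list(reference)
        assert hist.total() == count_products(toy_space)

    def test_rotatable_proxy_on_open_chain_rule(self, bbs, suite_by_id, kill_rulesets):
        space, _ = build_space(
            [suite_by_id[9002].text], bbs,
            kill_rulesets={9002: kill_rulesets[9002]},
        )
        products = list(enumerate_products(space, limit=10**6, seed=0))
        values = [
            PRODUCT_DESCRIPTORS["ROT"](Chem.MolFromSmiles(s)) for s, _ in products
        ]
        edges = list(range(0, max(values) + 2))
        hist = property_histograms(space, "ROT", edges)
        reference, _ = np.histogram(values, bins=edges)
        assert hist.counts == list(reference)

    def test_ring_forming_rule_rejects_rotatable_proxy(self, bbs, suite_by_id):
        space, _ = build_space([suite_by_id[9003].text], bbs)
        with pytest.raises(ValueError, match="single-link"):
            property_histograms(space, "ROT", [0, 10])

    def test_unsupported_descriptor_raises(self, toy_space):
        with pytest.raises(ValueError, match="unsupported"):
            property_histograms(toy_space, "clogP", [0, 10])

    def test_single_pair_space_single_bin(self, suite_by_id):
        bbs = _mini_bbs(primary_amine=1, carboxylic_acid=1)
        space, _ = build_space([suite_by_id[9001].text], bbs)
        assert count_products(space) == 1
        hist = property_histograms(space, "MW", [0.0, 1000.0])
        assert hist.counts == [1]


class TestCoverage:
    def test_space_covers_itself(self, toy_space):
        fractions = coverage_estimate(toy_space, toy_space, per_transform_n=20, seed=5)
        assert fractions and all(f == 1.0 for f in fractions.values())

    def test_disjoint_spaces_have_zero_coverage(self, suite_by_id):
        amide_bbs = _mini_bbs(primary_amine=2, carboxylic_acid=2)
        biaryl_bbs = _mini_bbs(aryl_halide=2, boronic_acid=2)
        a, _ = build_space([suite_by_id[9001].text], amide_bbs)
        b, _ = build_space([suite_by_id[9002].text], biaryl_bbs)
        fractions = coverage_estimate(a, b, per_transform_n=10, seed=5)
        assert all(f == 0.0 for f in fractions.values())

    def test_subset_space_is_fully_covered(self, suite_by_id):
        big = _mini_bbs(primary_amine=4, carboxylic_acid=4)
        small = [bb for bb in big if not bb[1].endswith("3")]
        a, _ = build_space([suite_by_id[9001].text], small)
        b, _ = build_space([suite_by_id[9001].text], big)
        up = coverage_estimate(a, b, per_transform_n=100, seed=5)
        down = coverage_estimate(b, a, per_transform_n=100, seed=5)
        assert up[9001] == 1.0
        # the deficit matches the construction: 16 pairs, 9 from the subset
        assert down[9001] == pytest.approx(9 / 16)


class TestSerialization:
    def test_round_trip_preserves_behavior(self, toy_space, enumerated, tmp_path):
        path = str(tmp_path / "space")
        serialize(toy_space, path)
        loaded = load(path)
        assert count_products(loaded) == count_products(toy_space)
        edges = [0.0, 200.0, 400.0, 600.0, 1000.0]
        assert (
            property_histograms(loaded, "MW", edges).counts
            == property_histograms(toy_space, "MW", edges).counts
        )
        smiles, prov = enumerated[0]
        hits = contains(loaded, smiles)
        assert any(
            h["bb1"] == prov["bb1"] and h["bb2"] == prov["bb2"] for h in hits
        )

    def test_tampered_manifest_fails_to_load(self, toy_space, tmp_path):
        path = str(tmp_path / "space")
        serialize(toy_space, path)
        with open(os.path.join(path, "manifest.json")) as handle:
            manifest = json.load(handle)
        del manifest["graphs"]
        with open(os.path.join(path, "manifest.json"), "w") as handle:
            json.dump(manifest, handle)
        with pytest.raises(ValueError):
            load(path)

    def test_missing_synthon_file_fails_to_load(self, toy_space, tmp_path):
        path = str(tmp_path / "space")
        serialize(toy_space, path)
        victim = os.path.join(path, toy_space.graphs[0].graph_id, "side1.smi")
        os.remove(victim)
        with pytest.raises(ValueError, match="missing"):
            load(path)
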