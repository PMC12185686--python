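import itertools

import pytest
from rdkit import Chem

from synthspace.chem_model import AromaticityModel, perceive_aromaticity
from synthspace.reactant_filter import (
    KILLED,
    MatchPolicy,
    evaluate_kills,
    filter_reactants,
    joint_verdict,
    match_building_blocks,
    prepare_masked_variants,
    split_subreactions,
)
from synthspace.transpiler import ISOTOPE_OFFSET, load_kill_ruleset, translate_transform


def mol(s):
    return Chem.MolFromSmiles(s)


@pytest.fixture(scope="module")
def amide_rule(suite_by_id):
    return translate_transform(suite_by_id[9001].text)[0]


@pytest.fixture(scope="module")
def chanlam_rule(suite_by_id):
    return translate_transform(suite_by_id[9004].text)[0]


@pytest.fixture(scope="module")
def alkene_rule(suite_by_id):
    return translate_transform(suite_by_id[9005].text)[0]


class TestSingleMatchRule:
    def test_exclusion_reasons(self, amide_rule):
        blocks = [
            (mol("CCO"), "no_hit"),  # matches neither side
            (mol("CCN"), "amine"),
            (mol("CCC(=O)O"), "acid"),
            (mol("OC(=O)CCC(=O)O"), "diacid"),  # two acid matches
            (mol("NCCC(=O)O"), "amino_acid"),  # matches both sides
        ]
        records, excluded = match_building_blocks(
            amide_rule, blocks, policy=MatchPolicy.SPACE
        )
        reasons = {e.bb_id: e.reason for e in excluded}
        assert reasons == {
            "no_hit": "no_match",
            "diacid": "multi_match",
            "amino_acid": "both_sides",
        }
        assert {(r.bb_id, r.pattern_side) for r in records} == {
            ("amine", 1),
            ("acid", 2),
        }

    def test_kill_rescue_keeps_surviving_side(self, amide_rule, suite_by_id):
        ruleset = suite_by_id[9001].ruleset()
        # amine side carries an alpha-nitrile (killed); acid side is clean
        blocks = [(mol("NC(C#N)CC(=O)O"), "rescued")]
        records, excluded = match_building_blocks(
            amide_rule, blocks, policy=MatchPolicy.SPACE, ruleset=ruleset
        )
        assert len(records) == 1 and records[0].pattern_side == 2
        # without the ruleset the same block is a plain both-sides exclusion
        records, excluded = match_building_blocks(
            amide_rule, blocks, policy=MatchPolicy.SPACE
        )
        assert records == [] and excluded[0].reason == "both_sides"


class TestDuplicatePolicies:
    def test_secondary_amine_policy_split(self, chanlam_rule):
        # the pattern's context carbon matches either flank of a secondary
        # amine: two matches for LIB2020, one role-unified match for SPACE
        blocks = [(mol("CCNCC"), "sec")]
        records, excluded = match_building_blocks(
            chanlam_rule, blocks, policy=MatchPolicy.LIB2020
        )
        assert records == [] and excluded[0].reason == "multi_match"
        records, _ = match_building_blocks(
            chanlam_rule, blocks, policy=MatchPolicy.SPACE
        )
        assert len(records) == 1

    def test_symmetric_alkene_policy_split(self, alkene_rule):
        # both ends of the symmetric pattern match: same atom set (LIB2020
        # unifies) but two distinct role assignments (SPACE: mixture)
        blocks = [(mol("CCC=CC"), "alkene")]
        records, _ = match_building_blocks(
            alkene_rule, blocks, policy=MatchPolicy.LIB2020
        )
        assert len(records) == 1
        records, excluded = match_building_blocks(
            alkene_rule, blocks, policy=MatchPolicy.SPACE
        )
        assert records == [] and excluded[0].reason == "multi_match"


class TestMaskedVariants:
    def test_leaving_group_masked_and_backbone_labeled(self, amide_rule):
        blocks = [(mol("CCC(=O)O"), "acid")]
        records, _ = match_building_blocks(amide_rule, blocks)
        variants = prepare_masked_variants(records[0], amide_rule)
        # the hydroxyl oxygen became a mask atom
        assert any(a.GetAtomicNum() == 0 for a in variants.variant_a.GetAtoms())
        labels = sorted(
            a.GetIsotope() - ISOTOPE_OFFSET
            for a in variants.variant_a.GetAtoms()
            if a.GetIsotope() > ISOTOPE_OFFSET
        )
        assert labels == [2, 3]

    def test_fully_mapped_reactant_is_just_labeled(self, suite_by_id):
        rule = translate_transform(suite_by_id[9003].text)[0]
        blocks = [(mol("CCNN"), "hydrazine")]
        records, _ = match_building_blocks(rule, blocks)
        variants = prepare_masked_variants(records[0], rule)
        assert all(a.GetAtomicNum() != 0 for a in variants.variant_a.GetAtoms())

    def test_variant_b_cuts_all_backbone_bonds(self, suite_by_id):
        rule = translate_transform(suite_by_id[9003].text)[0]
        blocks = [(mol("CC(=O)CC(=O)CC"), "diketone")]
        records, _ = match_building_blocks(rule, blocks)
        variants = prepare_masked_variants(records[0], rule)
        labeled = [
            a.GetIdx()
            for a in variants.variant_b.GetAtoms()
            if a.GetIsotope() > ISOTOPE_OFFSET
        ]
        assert len(labeled) == 4  # maps 3, 4, 5, 6
        for i, j in itertools.combinations(labeled, 2):
            assert variants.variant_b.GetBondBetweenAtoms(i, j) is None

    def test_masking_conserves_non_leaving_heavy_atoms(self, amide_rule):
        source = mol("CCC(=O)O")
        records, _ = match_building_blocks(amide_rule, [(source, "acid")])
        variants = prepare_masked_variants(records[0], amide_rule)
        n_masks = sum(
            1 for a in variants.variant_a.GetAtoms() if a.GetAtomicNum() == 0
        )
        real = variants.variant_a.GetNumAtoms() - n_masks
        assert real == source.GetNumHeavyAtoms() - 1  # one leaving O
        assert n_masks == 1


def _variants_for(rule, smiles, side=None):
    records, _ = match_building_blocks(rule, [(mol(smiles), "bb")])
    assert records, f"{smiles} did not match"
    rec = records[0]
    if side is not None:
        assert rec.pattern_side == side
    return rec, prepare_masked_variants(rec, rule)


class TestKillEvaluation:
    def test_empty_ruleset_never_kills(self, amide_rule):
        ruleset = load_kill_ruleset({"transform": 9001, "statements": []})
        _, variants = _variants_for(amide_rule, "CCN")
        result = evaluate_kills(variants, ruleset, side=1)
        assert result != KILLED and result.locals == ()

    def test_heteroatom_alpha_to_mapped_atom_kills(self, amide_rule):
        ruleset = load_kill_ruleset(
            {
                "transform": 9001,
                "statements": [
                    {"index": 0, "smarts": ["[101#7]-[#6]-[!#6;!#1]"],
                     "scope": "ONPATH", "participants": [1], "goto": None}
                ],
            }
        )
        ruleset.bind_sides(amide_rule.side_of_map)
        _, variants = _variants_for(amide_rule, "NCOC", side=1)
        assert evaluate_kills(variants, ruleset, 1, amide_rule.side_of_map) == KILLED
        _, variants = _variants_for(amide_rule, "NCCC", side=1)
        assert evaluate_kills(variants, ruleset, 1, amide_rule.side_of_map) != KILLED

    def test_goto_skips_a_kill_statement(self, amide_rule):
        # 0: trigger jumps over the unconditional kill at 1
        ruleset = load_kill_ruleset(
            {
                "transform": 9001,
                "statements": [
                    {"index": 0, "smarts": ["[101#7]-[#6]-[#6]=[#6]"],
                     "scope": "ONPATH", "participants": [1], "goto": 2},
                    {"index": 1, "smarts": ["[101#7]"],
                     "scope": "ONPATH", "participants": [1], "goto": None},
                    {"index": 2, "smarts": ["[101#7]-[#6]#[#6]"],
                     "scope": "ONPATH", "participants": [1], "goto": None},
                ],
            }
        )
        ruleset.bind_sides(amide_rule.side_of_map)
        _, variants = _variants_for(amide_rule, "NCC=C", side=1)  # triggers 0
        assert evaluate_kills(variants, ruleset, 1, amide_rule.side_of_map) != KILLED
        _, variants = _variants_for(amide_rule, "NCCC", side=1)  # falls into 1
        assert evaluate_kills(variants, ruleset, 1, amide_rule.side_of_map) == KILLED

    def test_offpath_ignores_reaction_path_bonds(self, suite_by_id):
        # hydrazine N-N is the reaction path: the OFFPATH N-N pattern must
        # not fire on it, only on an extra hydrazine motif elsewhere
        rule = translate_transform(suite_by_id[9003].text)[0]
        ruleset = suite_by_id[9003].ruleset()
        ruleset.bind_sides(rule.side_of_map)
        _, variants = _variants_for(rule, "CCNN", side=1)
        assert evaluate_kills(variants, ruleset, 1, rule.side_of_map) != KILLED
        # methyltriazane: single pattern match, extra N-N off the path
        _, variants = _variants_for(rule, "CNNN", side=1)
        assert evaluate_kills(variants, ruleset, 1, rule.side_of_map) == KILLED


class TestSubReactionSplitting:
    def test_no_cross_statements_single_subreaction(self, amide_rule, bbs):
        subreactions, _ = filter_reactants(amide_rule, bbs, ruleset=None)
        assert len(subreactions) == 1

    def test_cross_statement_splits_both_sides(self, amide_rule, bbs, suite_by_id):
        ruleset = suite_by_id[9001].ruleset()
        subreactions, _ = filter_reactants(amide_rule, bbs, ruleset=ruleset)
        assert len(subreactions) == 2
        # the gamma-ether amines are isolated from the benzylic acids
        small = min(subreactions, key=lambda s: len(s.group_1))
        assert all("gamma_ether" in r.bb_id for r in small.group_1)
        assert not any("benzylic" in r.bb_id for r in small.group_2)

    def test_pairs_unique_and_exactly_the_kill_consistent_set(
        self, amide_rule, bbs, suite_by_id
    ):
        ruleset = suite_by_id[9001].ruleset()
        subreactions, _ = filter_reactants(amide_rule, bbs, ruleset=ruleset)
        seen = set()
        for sub in subreactions:
            for r1 in sub.group_1:
                for r2 in sub.group_2:
                    pair = (r1.bb_id, r2.bb_id)
                    assert pair not in seen, "pair generated twice"
                    seen.add(pair)
        # oracle: joint traversal over every surviving signature pair
        from synthspace.reactant_filter import evaluate_kills, prepare_masked_variants

        ruleset.bind_sides(amide_rule.side_of_map)
        sides = {1: [], 2: []}
        records, _ = match_building_blocks(amide_rule, bbs, ruleset=ruleset)
        for rec in records:
            v = prepare_masked_variants(rec, amide_rule)
            res = evaluate_kills(v, ruleset, rec.pattern_side, amide_rule.side_of_map)
            if res != KILLED:
                sides[rec.pattern_side].append((rec, res))
        expected = set()
        for r1, s1 in sides[1]:
            for r2, s2 in sides[2]:
                if joint_verdict(ruleset.statements, dict(s1.locals), dict(s2.locals)):
                    expected.add((r1.bb_id, r2.bb_id))
        assert seen == expected

    def test_two_cross_statements_split_into_compatibility_classes(
        self, amide_rule, bbs
    ):
        # Hantzsch-style: two independent cross-reactant conditions
        ruleset = load_kill_ruleset(
            {
                "transform": 9001,
                "statements": [
                    {"index": 0,
                     "smarts": ["[101#7]-[#6]-[#6]-[#8]", "[102#6]-[#6]-c"],
                     "scope": "ONPATH", "participants": [1, 2], "goto": None},
                    {"index": 1,
                     "smarts": ["[101#7]-[#6]-[#6;H3]", "[102#6]-[#6]-[#6]-[F,Cl,Br,I]"],
                     "scope": "ONPATH", "participants": [1, 2], "goto": None},
                ],
            }
        )
        subreactions, _ = filter_reactants(amide_rule, bbs, ruleset=ruleset)
        assert len(subreactions) >= 2
        # distinct compatibility rows only
        rows = [
            frozenset(r2.bb_id for r2 in sub.group_2) for sub in subreactions
        ]
        assert len(rows) == len(set(rows))
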