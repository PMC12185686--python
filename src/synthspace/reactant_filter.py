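"""Building-block selection, KILL filtering and sub-reaction splitting.

The combinatorial encoding of a reaction requires that every selected
reactant of side 1 may pair with every reactant of side 2.  Three mechanisms
enforce this at the reactant level:

* the single-match rule -- a building block is usable only if it matches
  exactly one reactant pattern, and that one exactly once (after the
  policy-dependent unification of duplicate matches);
* KILL statements -- translated SMARTS filters evaluated on masked reactant
  variants: ONPATH patterns on the reactant with its leaving group masked
  and the backbone labeled, OFFPATH patterns on a variant whose
  backbone-internal bonds are additionally cut, so the pattern cannot run
  along the reaction-defined substructure;
* sub-reaction splitting -- statements whose participants span both
  reactants cannot yield a per-reactant verdict; reactants are grouped by
  their KILL-path signature and groups are paired exactly when every
  cross-side statement lets all their pairs survive.

Duplicate-match policies:

``LIB2020``
    matches covering the same atom set are unified before counting (the
    historical behavior: a symmetric alkene pattern double-matching the
    same two atoms is kept; a secondary amine matched once per flank is
    excluded as a double match).
``SPACE``
    matches are unified by the assignment of distinct-role atoms (atoms
    whose bonding changes in the reaction); multiple distinct role
    assignments mean real product mixtures and exclude the block (the
    symmetric alkene), while duplicates that lead to the same product are
    kept (the secondary amine).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from rdkit import Chem

from .chem_model import check_valence
from .transpiler import ISOTOPE_OFFSET, KillRuleSet, KillStatement, ReactionRule

logger = logging.getLogger("synthspace")

__all__ = [
    "MatchPolicy",
    "MatchRecord",
    "Exclusion",
    "MaskedVariants",
    "KillPathSignature",
    "KILLED",
    "SubReaction",
    "match_building_blocks",
    "prepare_masked_variants",
    "evaluate_kills",
    "split_subreactions",
    "filter_reactants",
]


class MatchPolicy(enum.Enum):
    LIB2020 = "lib2020"
    SPACE = "space"


@dataclass
class MatchRecord:
    """One building block accepted for one reactant side of a rule."""

    bb: Chem.Mol
    bb_id: str
    pattern_side: int
    match_atoms: tuple[int, ...]  # pattern node index -> molecule atom index
    match_maps: dict[int, int] = field(default_factory=dict)  # map -> atom


@dataclass(frozen=True)
class Exclusion:
    bb_id: str
    transform_id: int
    reason: str


@dataclass
class MaskedVariants:
    """The two reactant representations used for KILL evaluation.

    ``variant_a``: leaving group replaced by mask (dummy) atoms, backbone
    atoms labeled with their map number in the isotope slot (offset 100).
    ``variant_b``: additionally, all bonds between labeled atoms are cut.
    """

    variant_a: Chem.Mol
    variant_b: Chem.Mol
    label_of_map: dict[int, int] = field(default_factory=dict)


class _Killed:
    """Kill verdict; carries a representative killing statement index."""

    def __init__(self, stmt_index: Optional[int] = None):
        self.stmt_index = stmt_index

    def __repr__(self) -> str:  # pragma: no cover
        return "KILLED"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Killed)

    def __hash__(self) -> int:  # pragma: no cover
        return hash(_Killed)


KILLED = _Killed()


@dataclass(frozen=True)
class KillPathSignature:
    """All possible traversals of the KILL list for one reactant.

    ``locals`` holds the reactant's own (statement index, triggered) facts;
    ``paths`` the branching traversals (branch points arise from statements
    that depend on the partner reactant), each ending in a survive/kill
    verdict.  Reactants with equal ``locals`` behave identically against
    any partner.
    """

    side: int
    locals: tuple[tuple[int, bool], ...]
    paths: tuple[tuple[tuple[tuple[int, bool], ...], bool], ...]  # (path, survived)

    @property
    def key(self) -> tuple[tuple[int, bool], ...]:
        return self.locals


@dataclass
class SubReaction:
    """A block of the pairing matrix on which pure combination is valid."""

    rule: ReactionRule
    group_1: list[MatchRecord]
    group_2: list[MatchRecord]
    pairing_reason: str
    signature_1: Optional[KillPathSignature] = None
    signatures_2: tuple[KillPathSignature, ...] = ()


def _match_query(mol: Chem.Mol, rule: ReactionRule, side: int) -> list[tuple[int, ...]]:
    query = rule.reactant_queries()[side - 1]
    return list(mol.GetSubstructMatches(query, uniquify=False, maxMatches=4096))


def _unify_matches(
    matches: list[tuple[int, ...]],
    rule: ReactionRule,
    side: int,
    policy: MatchPolicy,
) -> list[tuple[int, ...]]:
    """One representative match per unification class."""
    if policy is MatchPolicy.LIB2020:
        seen: dict[frozenset[int], tuple[int, ...]] = {}
        for m in matches:
            seen.setdefault(frozenset(m), m)
        return list(seen.values())
    node_map = rule.reactant_node_maps[side - 1]
    roles = rule.role_maps.get(side, frozenset())
    seen_roles: dict[tuple, tuple[int, ...]] = {}
    for m in matches:
        key = tuple(
            sorted((mn, m[ni]) for ni, mn in node_map.items() if mn in roles)
        )
        seen_roles.setdefault(key, m)
    return list(seen_roles.values())


def _record_for(
    mol: Chem.Mol, bb_id: str, rule: ReactionRule, side: int, match: tuple[int, ...]
) -> MatchRecord:
    node_map = rule.reactant_node_maps[side - 1]
    match_maps = {mn: match[ni] for ni, mn in node_map.items()}
    return MatchRecord(
        bb=mol, bb_id=bb_id, pattern_side=side, match_atoms=match, match_maps=match_maps
    )


def match_building_blocks(
    rule: ReactionRule,
    bbs: Sequence[tuple[Chem.Mol, str]],
    policy: MatchPolicy = MatchPolicy.SPACE,
    ruleset: Optional[KillRuleSet] = None,
) -> tuple[list[MatchRecord], list[Exclusion]]:
    """Select building blocks per reactant side under the single-match rule.

    Blocks matching both sides are excluded -- unless a ruleset is given and
    all matches on one side are KILLed, in which case the surviving side is
    kept (the kill-rescue exception).
    """
    if rule.n_sides > 2:
        raise ValueError("rules with more than two reactant sides are unsupported")
    if ruleset is not None:
        ruleset.bind_sides(rule.side_of_map)
    records: list[MatchRecord] = []
    excluded: list[Exclusion] = []
    for mol, bb_id in bbs:
        per_side = {
            side: _unify_matches(_match_query(mol, rule, side), rule, side, policy)
            for side in range(1, rule.n_sides + 1)
        }
        sides_hit = [s for s, m in per_side.items() if m]
        if not sides_hit:
            excluded.append(Exclusion(bb_id, rule.transform_id, "no_match"))
            continue
        if len(sides_hit) == 1:
            side = sides_hit[0]
            if len(per_side[side]) > 1:
                excluded.append(Exclusion(bb_id, rule.transform_id, "multi_match"))
            else:
                records.append(_record_for(mol, bb_id, rule, side, per_side[side][0]))
            continue
        # both sides matched
        if any(len(per_side[s]) > 1 for s in sides_hit) or ruleset is None:
            excluded.append(Exclusion(bb_id, rule.transform_id, "both_sides"))
            continue
        survivors = []
        for side in sides_hit:
            rec = _record_for(mol, bb_id, rule, side, per_side[side][0])
            variants = prepare_masked_variants(rec, rule)
            verdict = evaluate_kills(variants, ruleset, side, rule.side_of_map)
            if verdict != KILLED:
                survivors.append(rec)
        if len(survivors) == 1:
            records.append(survivors[0])
        elif len(survivors) == 0:
            excluded.append(Exclusion(bb_id, rule.transform_id, "killed:both_sides"))
        else:
            excluded.append(Exclusion(bb_id, rule.transform_id, "both_sides"))
    return records, excluded


def _partial_sanitize(mol: Chem.Mol) -> None:
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)


def prepare_masked_variants(record: MatchRecord, rule: ReactionRule) -> MaskedVariants:
    """Build the masked representations of a matched reactant.

    Leaving-group atoms (matched pattern atoms absent from the product
    pattern) are replaced by mask atoms -- dummies, so KILL SMARTS cannot
    match into them; backbone atoms are labeled with map number + 100 in the
    isotope slot.
    """
    side = record.pattern_side
    graph = rule.reactant_graphs[side - 1]
    node_map = rule.reactant_node_maps[side - 1]
    mol = Chem.RWMol(record.bb)

    label_of_map: dict[int, int] = {}
    leaving_atoms: list[int] = []
    for node in graph.nodes:
        atom_idx = record.match_atoms[node.index]
        map_number = node_map.get(node.index)
        if map_number is not None and map_number in rule.product_maps:
            mol.GetAtomWithIdx(atom_idx).SetIsotope(ISOTOPE_OFFSET + map_number)
            label_of_map[map_number] = atom_idx
        else:
            leaving_atoms.append(atom_idx)
    for atom_idx in leaving_atoms:
        atom = mol.GetAtomWithIdx(atom_idx)
        atom.SetAtomicNum(0)
        atom.SetFormalCharge(0)
        atom.SetIsotope(0)
        atom.SetNumExplicitHs(0)
        atom.SetNoImplicit(True)
        atom.SetIsAromatic(False)
        for bond in atom.GetBonds():
            if bond.GetBondType() == Chem.BondType.AROMATIC:
                bond.SetBondType(Chem.BondType.SINGLE)
            bond.SetIsAromatic(False)
    variant_a = mol.GetMol()
    try:
        Chem.SanitizeMol(variant_a)
    except Exception:
        _partial_sanitize(variant_a)

    vb = Chem.Mol(variant_a)
    try:
        Chem.Kekulize(vb, clearAromaticFlags=True)
    except Exception:
        pass
    vb = Chem.RWMol(vb)
    labeled = sorted(label_of_map.values())
    for i, ai in enumerate(labeled):
        for aj in labeled[i + 1:]:
            if vb.GetBondBetweenAtoms(ai, aj) is not None:
                vb.RemoveBond(ai, aj)
    variant_b = vb.GetMol()
    try:
        _partial_sanitize(variant_b)
    except Exception:
        pass
    return MaskedVariants(variant_a=variant_a, variant_b=variant_b, label_of_map=label_of_map)


def _entry_value(entry: str, target: Chem.Mol) -> bool:
    negated = entry.startswith("!")
    body = entry[1:] if negated else entry
    query = Chem.MolFromSmarts(body)
    matched = target.HasSubstructMatch(query)
    return (not matched) if negated else matched


def _local_bools(
    variants: MaskedVariants,
    ruleset: KillRuleSet,
    side: int,
    side_of_map: Optional[dict[int, int]],
) -> dict[int, bool]:
    """Evaluate this side's sub-conditions for every statement touching it."""
    values: dict[int, bool] = {}
    for stmt in ruleset.statements:
        if side not in stmt.sides:
            continue
        target = variants.variant_a if stmt.scope == "ONPATH" else variants.variant_b
        value = False
        for entry, maps in zip(stmt.smarts, stmt.entry_maps()):
            if maps:
                entry_sides = {side_of_map[m] for m in maps} if side_of_map else {side}
                if entry_sides != {side}:
                    continue
            elif stmt.sides != {side}:
                continue
            if _entry_value(entry, target):
                value = True
                break
        values[stmt.index] = value
    return values


def _traverse_branching(
    statements: list[KillStatement],
    local: dict[int, bool],
    side: int,
) -> list[tuple[tuple[tuple[int, bool], ...], bool]]:
    """All possible paths through the statement list for one reactant.

    Statements depending (partly or wholly) on the partner reactant branch;
    a triggered statement without GOTO is a kill verdict on that path.
    """
    pos_of_index = {s.index: i for i, s in enumerate(statements)}
    results: list[tuple[tuple[tuple[int, bool], ...], bool]] = []

    def walk(pos: int, path: tuple[tuple[int, bool], ...]) -> None:
        if pos >= len(statements):
            results.append((path, True))
            return
        stmt = statements[pos]
        if stmt.sides == {side}:
            options = [local[stmt.index]]
        elif side in stmt.sides:
            # cross-side: can only trigger if our local part holds
            options = [False] if not local[stmt.index] else [False, True]
        else:
            options = [False, True]
        for value in set(options):
            step = path + ((stmt.index, value),)
            if value:
                if stmt.goto is None:
                    results.append((step, False))
                else:
                    walk(pos_of_index[stmt.goto], step)
            else:
                walk(pos + 1, step)

    walk(0, ())
    return results


def evaluate_kills(
    variants: MaskedVariants,
    ruleset: KillRuleSet,
    side: int,
    side_of_map: Optional[dict[int, int]] = None,
) -> Union[KillPathSignature, _Killed]:
    """Run the KILL statements for one masked reactant.

    Returns :data:`KILLED` when every possible traversal ends in a kill
    verdict (no partner could save this reactant), otherwise the reactant's
    path signature for sub-reaction grouping.
    """
    if not ruleset.statements:
        return KillPathSignature(side=side, locals=(), paths=(((), True),))
    local = _local_bools(variants, ruleset, side, side_of_map)
    paths = _traverse_branching(ruleset.statements, local, side)
    if all(not survived for _, survived in paths):
        first_path = paths[0][0]
        return _Killed(first_path[-1][0] if first_path else None)
    return KillPathSignature(
        side=side,
        locals=tuple(sorted(local.items())),
        paths=tuple(paths),
    )


def joint_verdict(
    statements: list[KillStatement],
    local1: dict[int, bool],
    local2: dict[int, bool],
) -> bool:
    """Deterministic traversal for a concrete (side-1, side-2) pair.

    Returns True when the pair survives.  Cross-side statements trigger only
    when both sides' sub-conditions hold.
    """
    pos_of_index = {s.index: i for i, s in enumerate(statements)}
    pos = 0
    while pos < len(statements):
        stmt = statements[pos]
        if stmt.sides == {1}:
            value = local1[stmt.index]
        elif stmt.sides == {2}:
            value = local2[stmt.index]
        else:
            value = local1.get(stmt.index, True) and local2.get(stmt.index, True)
        if value:
            if stmt.goto is None:
                return False
            pos = pos_of_index[stmt.goto]
        else:
            pos += 1
    return True


def split_subreactions(
    rule: ReactionRule,
    side1: Sequence[tuple[MatchRecord, KillPathSignature]],
    side2: Sequence[tuple[MatchRecord, KillPathSignature]],
    ruleset: Optional[KillRuleSet] = None,
) -> list[SubReaction]:
    """Group reactants by KILL signature and pair compatible groups.

    The union of the sub-reactions' pair sets equals the KILL-consistent
    pair set, and no pair occurs in two sub-reactions: every side-1
    signature class belongs to exactly one compatibility row.
    """
    if ruleset is None or not ruleset.statements:
        g1 = [r for r, _ in side1]
        g2 = [r for r, _ in side2]
        if not g1 or not g2:
            return []
        return [SubReaction(rule, g1, g2, "no cross-side constraints")]

    def group(side_data):
        groups: dict[tuple, tuple[KillPathSignature, list[MatchRecord]]] = {}
        for rec, sig in side_data:
            entry = groups.setdefault(sig.key, (sig, []))
            entry[1].append(rec)
        return list(groups.values())

    groups1 = group(side1)
    groups2 = group(side2)
    statements = ruleset.statements

    rows: dict[tuple[bool, ...], tuple[list[MatchRecord], list[KillPathSignature]]] = {}
    row_sigs: dict[tuple[bool, ...], KillPathSignature] = {}
    for sig1, recs1 in groups1:
        row = tuple(
            joint_verdict(statements, dict(sig1.locals), dict(sig2.locals))
            for sig2, _ in groups2
        )
        bucket = rows.setdefault(row, ([], []))
        bucket[0].extend(recs1)
        row_sigs.setdefault(row, sig1)

    subreactions: list[SubReaction] = []
    for row, (recs1, _) in sorted(rows.items(), key=lambda kv: kv[0], reverse=True):
        recs2: list[MatchRecord] = []
        sigs2: list[KillPathSignature] = []
        for compatible, (sig2, group2_recs) in zip(row, groups2):
            if compatible:
                recs2.extend(group2_recs)
                sigs2.append(sig2)
        if not recs1 or not recs2:
            continue
        reason = "compatible with side-2 signature classes " + ",".join(
            str(i) for i, c in enumerate(row) if c
        )
        subreactions.append(
            SubReaction(
                rule,
                recs1,
                recs2,
                reason,
                signature_1=row_sigs[row],
                signatures_2=tuple(sigs2),
            )
        )
    return subreactions


def filter_reactants(
    rule: ReactionRule,
    bbs: Sequence[tuple[Chem.Mol, str]],
    policy: MatchPolicy = MatchPolicy.SPACE,
    ruleset: Optional[KillRuleSet] = None,
) -> tuple[list[SubReaction], list[Exclusion]]:
    """Full per-rule pipeline: match, mask, kill, split into sub-reactions."""
    if ruleset is not None:
        ruleset.bind_sides(rule.side_of_map)
    records, excluded = match_building_blocks(rule, bbs, policy=policy, ruleset=ruleset)
    empty = KillRuleSet(transform_id=rule.transform_id)
    sides: dict[int, list[tuple[MatchRecord, KillPathSignature]]] = {1: [], 2: []}
    for rec in records:
        variants = prepare_masked_variants(rec, rule)
        result = evaluate_kills(
            variants, ruleset if ruleset is not None else empty, rec.pattern_side,
            rule.side_of_map,
        )
        if isinstance(result, _Killed):
            reason = "killed" if result.stmt_index is None else f"killed:{result.stmt_index}"
            excluded.append(Exclusion(rec.bb_id, rule.transform_id, reason))
        else:
            sides[rec.pattern_side].append((rec, result))
    if rule.n_sides == 1:
        g1 = [r for r, _ in sides[1]]
        return ([SubReaction(rule, g1, [], "single-reactant rule")] if g1 else []), excluded
    return split_subreactions(rule, sides[1], sides[2], ruleset), excluded
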