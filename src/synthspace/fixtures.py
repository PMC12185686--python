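"""Synthetic building-block panels, toy transforms, and the brute-force
enumeration oracle.

Every other module is tested against data produced here, with no downloads:
the generator emits deterministic SMILES collections per functional class
(amines, acids, boronic acids, halides, hydrazines, 1,3-diketones, ...)
decorated with controlled fractions of adversarial cases -- KILL-triggering
motifs, protecting groups, organometallics, overweight molecules, blocks
matching both reactant sides, and symmetric matchers.

The brute-force oracle is the independent reference for the combinatorial
machinery: it assembles every reactant pair directly by graph surgery on the
matched molecules, applies the KILL statements to the assembled *products*
(the historical, enumerated-library semantics), and returns the surviving
pair and product sets.  Space-level counting, histogram convolution,
membership and retro-validation are asserted against it.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

from rdkit import Chem

from .chem_model import (
    AromaticityModel,
    check_valence,
    perceive_aromaticity,
    remove_protecting_groups,
)
from .reactant_filter import MatchPolicy, match_building_blocks
from .transpiler import (
    ISOTOPE_OFFSET,
    KillRuleSet,
    ReactionRule,
    bond_type_for,
    load_kill_ruleset,
)

__all__ = [
    "FixtureSpec",
    "ToyTransform",
    "generate_building_blocks",
    "toy_transform_suite",
    "brute_force_products",
]

_TAILS = [
    "CC",
    "CCC",
    "CCCC",
    "CC(C)C",
    "CCCCC",
    "C1CCCCC1",
    "CCc1ccccc1",
    "c1ccccc1",
    "CC(C)CC",
    "CCCCCC",
]

_ARYL_TAILS = ["C", "CC", "CCC", "OC", "C(C)C", "CCCC", "F", "CC(C)C", "CCO", "CCCCC"]


@dataclass
class FixtureSpec:
    """Composition of one synthetic building-block panel.

    ``counts`` gives the number of clean members per functional class;
    ``adversarial`` mixes in the named trouble cases.  Defaults are sized so
    each toy space stays well under 10^5 products while every filtering
    mechanism is exercised.
    """

    seed: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "primary_amine": 8,
            "secondary_amine": 4,
            "carboxylic_acid": 8,
            "aryl_halide": 6,
            "boronic_acid": 6,
            "alkyne": 2,
            "azide": 2,
            "alkene": 5,
            "hydrazine": 5,
            "diketone": 6,
        }
    )
    adversarial: dict[str, int] = field(
        default_factory=lambda: {
            "amine_beta_halide": 2,
            "amine_gamma_ether": 2,
            "amine_alpha_nitrile": 2,
            "acid_alpha_halide": 2,
            "acid_benzylic": 2,
            "boronic_aldehyde": 1,
            "boc_amine": 2,
            "fused_aryl_halide": 3,
            "triketone": 1,
            "diamine_hydrazine": 1,
            "triazane": 1,
            "organometallic": 2,
            "overweight": 1,
            "both_side": 1,
            "both_side_rescued": 1,
        }
    )


def _tails(rng: random.Random, pool: Sequence[str], n: int) -> list[str]:
    """Distinct substituent tails: building blocks within a class must not
    alias each other, or product provenance becomes ambiguous."""
    tails = list(pool)
    rng.shuffle(tails)
    suffix = "C"
    while len(tails) < n:
        tails.extend(t + suffix for t in pool)
        suffix += "C"
    return tails[:n]


def generate_building_blocks(spec: FixtureSpec) -> list[tuple[str, str, str]]:
    """Deterministic (smiles, id, class) triples for the given spec."""
    rng = random.Random(spec.seed)
    out: list[tuple[str, str, str]] = []

    def emit(cls: str, smiles_list: list[str]) -> None:
        for i, smi in enumerate(smiles_list):
            out.append((smi, f"{cls}_{i}", cls))

    c = spec.counts
    a = spec.adversarial
    emit("primary_amine", [f"N{t}" for t in _tails(rng, _TAILS, c.get("primary_amine", 0))])
    emit(
        "secondary_amine",
        [
            f"{t}NC{u}"
            for t, u in zip(
                _tails(rng, _TAILS, c.get("secondary_amine", 0)),
                _tails(rng, _TAILS, c.get("secondary_amine", 0)),
            )
        ],
    )
    emit("carboxylic_acid", [f"OC(=O){t}" for t in _tails(rng, _TAILS, c.get("carboxylic_acid", 0))])
    emit("aryl_halide", [f"Brc1ccc({t})cc1" for t in _tails(rng, _ARYL_TAILS, c.get("aryl_halide", 0))])
    emit("boronic_acid", [f"OB(O)c1ccc({t})cc1" for t in _tails(rng, _ARYL_TAILS, c.get("boronic_acid", 0))])
    emit("alkyne", [f"C#C{t}" for t in _tails(rng, _TAILS, c.get("alkyne", 0))])
    emit("azide", [f"{t}N=[N+]=[N-]" for t in _tails(rng, _TAILS, c.get("azide", 0))])
    emit("alkene", [f"CC=C{t}" for t in _tails(rng, _TAILS, c.get("alkene", 0))])
    emit("hydrazine", [f"NN{t}" for t in _tails(rng, _TAILS, c.get("hydrazine", 0))])
    emit(
        "diketone",
        [f"CC(=O)CC(=O)C{t}" for t in _tails(rng, _TAILS, c.get("diketone", 0))],
    )

    emit("amine_beta_halide", [f"NC(Cl){t}" for t in _tails(rng, _TAILS, a.get("amine_beta_halide", 0))])
    emit("amine_gamma_ether", [f"NCCO{t}" for t in _tails(rng, _TAILS, a.get("amine_gamma_ether", 0))])
    emit("amine_alpha_nitrile", [f"NC(C#N){t}" for t in _tails(rng, _TAILS, a.get("amine_alpha_nitrile", 0))])
    emit("acid_alpha_halide", [f"OC(=O)C(Cl){t}" for t in _tails(rng, _TAILS, a.get("acid_alpha_halide", 0))])
    emit("acid_benzylic", [f"OC(=O)C{t}" for t in ["c1ccccc1", "c1ccc(C)cc1"][: a.get("acid_benzylic", 0)]])
    emit("boronic_aldehyde", ["OB(O)c1ccc(C=O)cc1"][: a.get("boronic_aldehyde", 0)])
    emit("boc_amine", [f"CC(C)(C)OC(=O)N{t}" for t in _tails(rng, _TAILS, a.get("boc_amine", 0))])
    emit(
        "fused_aryl_halide",
        # 2-bromonaphthalene, 1-bromonaphthalene, 9-bromoanthracene (the
        # last matches only the fusion variant annotating the ipso atom)
        ["Brc1ccc2ccccc2c1", "Brc1cccc2ccccc12", "Brc1c2ccccc2cc2ccccc12"][
            : a.get("fused_aryl_halide", 0)
        ],
    )
    emit("triketone", ["CC(=O)CC(=O)CCC(C)=O"][: a.get("triketone", 0)])
    # double hydrazine: excluded as a double match; methyltriazane: matches
    # once but the extra N-N triggers the OFFPATH kill
    emit("diamine_hydrazine", ["NNCCNN"][: a.get("diamine_hydrazine", 0)])
    emit("triazane", ["CNNN"][: a.get("triazane", 0)])
    emit("organometallic", ["CC[Mg]Br", "[Li]CCCC"][: a.get("organometallic", 0)])
    emit("overweight", ["C" * 60][: a.get("overweight", 0)])
    emit("both_side", ["NCCC(=O)O"][: a.get("both_side", 0)])
    emit("both_side_rescued", ["NC(C#N)CC(=O)O"][: a.get("both_side_rescued", 0)])
    return out


def write_fixture(spec: FixtureSpec, smi_path: str, sidecar_path: Optional[str] = None) -> None:
    rows = generate_building_blocks(spec)
    with open(smi_path, "w") as handle:
        for smi, bb_id, _cls in rows:
            handle.write(f"{smi}\t{bb_id}\n")
    if sidecar_path:
        with open(sidecar_path, "w") as handle:
            json.dump({bb_id: cls for _smi, bb_id, cls in rows}, handle, indent=1)


@dataclass
class ToyTransform:
    transform_id: int
    text: str
    kill_ruleset: Optional[dict] = None
    description: str = ""

    def ruleset(self) -> Optional[KillRuleSet]:
        if self.kill_ruleset is None:
            return None
        return load_kill_ruleset(self.kill_ruleset)


def toy_transform_suite() -> list[ToyTransform]:
    """The shipped toy corpus: plain coupling, ring-forming with explicit
    product aromaticity, negated-fusion duplication, cross-reactant KILL
    with GOTO, and the symmetric-pattern zero-product case."""
    data = resources.files("synthspace.data")
    suite = []
    for tid, fname, kill, desc in [
        (9001, "9001_amide.txt", "9001.json", "amide coupling; cross-reactant KILL with GOTO"),
        (9002, "9002_biaryl.txt", "9002.json", "biaryl coupling; side-2 KILL"),
        (9003, "9003_pyrazole.txt", "9003.json", "ring-forming condensation; OFFPATH KILL"),
        (9004, "9004_chanlam.txt", None, "amine arylation; policy-dependent secondary amines"),
        (9005, "9005_alkene.txt", None, "symmetric alkene pattern; zero products under SPACE"),
        (9006, "9006_fusion.txt", None, "negated fusion bond; two pattern variants"),
    ]:
        text = data.joinpath("transforms").joinpath(fname).read_text()
        kill_dict = (
            json.loads(data.joinpath("kills").joinpath(kill).read_text())
            if kill
            else None
        )
        suite.append(ToyTransform(tid, text, kill_dict, desc))
    return suite


# ---------------------------------------------------------------------------
# brute-force oracle


def _oracle_assemble(
    rule: ReactionRule,
    mol1: Chem.Mol,
    match1: tuple[int, ...],
    mol2: Chem.Mol,
    match2: tuple[int, ...],
) -> Optional[Chem.Mol]:
    """Assemble one product directly from a matched reactant pair.

    Mapped atoms keep their map number in the isotope slot (offset 100) so
    product-level KILL SMARTS can anchor on them.  Independent of the
    synthon encoding: no masking, no link atoms.
    """
    combo = Chem.RWMol(Chem.CombineMols(mol1, mol2))
    offset = mol1.GetNumAtoms()
    matches = [match1, tuple(offset + i for i in match2)]

    atom_of_map: dict[int, int] = {}
    leaving: set[int] = set()
    for side_i, match in enumerate(matches):
        graph = rule.reactant_graphs[side_i]
        node_map = rule.reactant_node_maps[side_i]
        for node in graph.nodes:
            atom_idx = match[node.index]
            mn = node_map.get(node.index)
            if mn is not None and mn in rule.product_maps:
                atom_of_map[mn] = atom_idx
                combo.GetAtomWithIdx(atom_idx).SetIsotope(ISOTOPE_OFFSET + mn)
            else:
                leaving.add(atom_idx)

    for ma, mb, order in rule.intra_changes:
        bond = combo.GetBondBetweenAtoms(atom_of_map[ma], atom_of_map[mb])
        if bond is None:
            return None
        bond.SetBondType(bond_type_for(order))
    for ma, mb, order in rule.formed_bonds:
        combo.AddBond(atom_of_map[ma], atom_of_map[mb], bond_type_for(order))

    for idx in sorted(leaving, reverse=True):
        combo.RemoveAtom(idx)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception:
        return None
    # drop disconnected leaving-group remnants, keep the mapped component
    comps = Chem.GetMolFrags(product, asMols=False)
    if len(comps) > 1:
        keep = None
        for comp in comps:
            if any(product.GetAtomWithIdx(i).GetIsotope() > ISOTOPE_OFFSET for i in comp):
                keep = set(comp)
        rw = Chem.RWMol(product)
        for idx in sorted(range(product.GetNumAtoms()), reverse=True):
            if idx not in keep:
                rw.RemoveAtom(idx)
        product = rw.GetMol()
        Chem.SanitizeMol(product)
    return product


def _product_kill_verdict(
    product: Chem.Mol, ruleset: KillRuleSet, side_of_map: dict[int, int]
) -> bool:
    """Product-level KILL evaluation (enumerated-library semantics).

    ONPATH patterns run on the labeled product; OFFPATH patterns on a copy
    with all bonds between mapped atoms cut.  Returns True when the product
    survives.
    """
    onpath = product
    rw = Chem.Mol(product)
    try:
        Chem.Kekulize(rw, clearAromaticFlags=True)
    except Exception:
        pass
    rw = Chem.RWMol(rw)
    labeled = [
        a.GetIdx() for a in rw.GetAtoms() if a.GetIsotope() > ISOTOPE_OFFSET
    ]
    for i, ai in enumerate(labeled):
        for aj in labeled[i + 1:]:
            if rw.GetBondBetweenAtoms(ai, aj) is not None:
                rw.RemoveBond(ai, aj)
    offpath = rw.GetMol()
    try:
        Chem.SanitizeMol(
            offpath,
            Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    except Exception:
        pass

    pos_of_index = {s.index: i for i, s in enumerate(ruleset.statements)}
    pos = 0
    while pos < len(ruleset.statements):
        stmt = ruleset.statements[pos]
        target = onpath if stmt.scope == "ONPATH" else offpath
        # group entries by the side their labels belong to; AND across
        # sides, OR within one side
        by_side: dict[frozenset, list[bool]] = {}
        for entry, maps in zip(stmt.smarts, stmt.entry_maps()):
            negated = entry.startswith("!")
            body = entry[1:] if negated else entry
            query = Chem.MolFromSmarts(body)
            hit = target.HasSubstructMatch(query)
            value = (not hit) if negated else hit
            sides = (
                frozenset(side_of_map[m] for m in maps) if maps else stmt.sides
            )
            by_side.setdefault(sides, []).append(value)
        triggered = all(any(vals) for vals in by_side.values())
        if triggered:
            if stmt.goto is None:
                return False
            pos = pos_of_index[stmt.goto]
        else:
            pos += 1
    return True


def brute_force_products(
    rule: ReactionRule,
    bbs: Sequence[tuple[Chem.Mol, str]],
    ruleset: Optional[KillRuleSet] = None,
    policy: MatchPolicy = MatchPolicy.SPACE,
    model: AromaticityModel = AromaticityModel.DEFAULT,
) -> tuple[set[tuple[str, str]], dict[tuple[str, str], str]]:
    """Enumerate all surviving pairs of one rule, product-level KILLs.

    Returns the pair set {(bb1, bb2)} and a pair -> canonical product
    SMILES mapping (deprotected, valence-checked, aromaticity under
    ``model``).
    """
    if ruleset is not None:
        ruleset.bind_sides(rule.side_of_map)
    perceived = [(perceive_aromaticity(m, model), i) for m, i in bbs]
    records, _excluded = match_building_blocks(
        rule, perceived, policy=policy, ruleset=ruleset
    )
    side1 = [r for r in records if r.pattern_side == 1]
    side2 = [r for r in records if r.pattern_side == 2]
    pairs: set[tuple[str, str]] = set()
    products: dict[tuple[str, str], str] = {}
    for r1 in side1:
        for r2 in side2:
            product = _oracle_assemble(
                rule, r1.bb, r1.match_atoms, r2.bb, r2.match_atoms
            )
            if product is None:
                continue
            if ruleset is not None and not _product_kill_verdict(
                product, ruleset, rule.side_of_map
            ):
                continue
            clean = Chem.Mol(product)
            for atom in clean.GetAtoms():
                if atom.GetIsotope() > ISOTOPE_OFFSET:
                    atom.SetIsotope(0)
            clean, _ = remove_protecting_groups(clean)
            if not check_valence(clean):
                continue
            clean = perceive_aromaticity(clean, model)
            pairs.add((r1.bb_id, r2.bb_id))
            products[(r1.bb_id, r2.bb_id)] = Chem.MolToSmiles(clean)
    return pairs, products
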