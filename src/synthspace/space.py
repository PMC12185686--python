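"""Combinatorial fragment space: synthons, counting, search, histograms.

Products are never materialized.  Each sub-reaction contributes a two-node
topology graph: the two synthon sets (pre-processed reactants carrying typed
link atoms) and the link-type pairing between them.  On this structure the
space supports

* exact product counting (big-integer sum of |side1| x |side2|),
* seeded sampling without replacement over the pair lattice,
* membership testing by retro-decomposition of a query molecule,
* retro-validation of assembled products against the product pattern, and
* exact histograms of additive descriptors by convolving the per-side value
  multisets -- counts are computed without enumerating pairs.

Masses are carried as integer microdaltons from a fixed atomic-mass table,
so a product's mass equals the sum of its synthon masses bit-exactly; that
makes the convolution histograms identical to enumerated histograms
including at bin edges.
"""

from __future__ import annotations

import json
import logging
import os
import random
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from rdkit import Chem

from .chem_model import (
    AromaticityModel,
    check_valence,
    mass_microdaltons,
    perceive_aromaticity,
    remove_protecting_groups,
)
from .reactant_filter import MatchRecord, SubReaction
from .transpiler import ISOTOPE_OFFSET, ReactionRule, bond_type_for

logger = logging.getLogger("synthspace")

__all__ = [
    "Synthon",
    "TopologyGraph",
    "FragmentSpace",
    "PropertyHistogram",
    "build_synthons",
    "build_topology_graph",
    "build_space",
    "assemble_product",
    "count_products",
    "enumerate_products",
    "retro_validate",
    "contains",
    "property_histograms",
    "coverage_estimate",
    "serialize",
    "load",
    "DESCRIPTORS",
]


@dataclass
class Synthon:
    """A masked fragment with typed link atoms and provenance."""

    fragment: Chem.Mol
    smiles: str
    bb_id: str
    transform_id: int
    side: int
    variant_tag: str
    mass_u: int  # integer microdaltons, dummies excluded

    @property
    def mass_contribution(self) -> float:
        return self.mass_u / 1e6

    @property
    def provenance(self) -> tuple[str, int, int, str]:
        return (self.bb_id, self.transform_id, self.side, self.variant_tag)


@dataclass
class TopologyGraph:
    """Two synthon sets joined by typed links: one per sub-reaction."""

    graph_id: str
    rule: ReactionRule
    side1: list[Synthon]
    side2: list[Synthon]
    link_bonds: list[tuple[int, int, int, str]]  # (link_type, map1, map2, order)
    pairing_reason: str = ""

    @property
    def n_products(self) -> int:
        return len(self.side1) * len(self.side2)


@dataclass
class FragmentSpace:
    name: str
    graphs: list[TopologyGraph]
    manifest: dict = field(default_factory=dict)

    @property
    def model(self) -> AromaticityModel:
        return AromaticityModel(self.manifest.get("aromaticity_model", "default"))


@dataclass
class PropertyHistogram:
    descriptor: str
    bin_edges: list[float]
    counts: list[int]

    def total(self) -> int:
        return sum(self.counts)


_LINK_COUNTER: dict[str, int] = {}


def _link_type(graph_id: str, slot: int) -> int:
    # stable small integers: hash-free, derived from registration order
    key = f"{graph_id}#{slot}"
    if key not in _LINK_COUNTER:
        _LINK_COUNTER[key] = len(_LINK_COUNTER) + 1
    return _LINK_COUNTER[key]


def build_synthons(
    subreaction: SubReaction,
    model: AromaticityModel = AromaticityModel.DEFAULT,
    graph_id: str = "g",
) -> tuple[list[Synthon], list[Synthon], list[tuple[str, str]]]:
    """Convert a sub-reaction's surviving reactants into synthons.

    Per reactant: leaving-group atoms (and fragments connected only through
    them) are deleted, intra-side product bond-order edits applied, typed
    link atoms attached with the formed bond's order, and protecting groups
    removed from the fragment.  Reactants whose product environment fails
    the valence model are dropped with a reason.
    """
    rule = subreaction.rule
    link_specs = []
    for slot, (ma, mb, order) in enumerate(rule.formed_bonds):
        link_specs.append((_link_type(graph_id, slot), ma, mb, order))

    dropped: list[tuple[str, str]] = []
    sides: list[list[Synthon]] = [[], []]
    for side_i, records in ((1, subreaction.group_1), (2, subreaction.group_2)):
        for rec in records:
            syn = _build_one_synthon(rec, rule, side_i, link_specs, model)
            if isinstance(syn, str):
                dropped.append((rec.bb_id, syn))
            else:
                sides[side_i - 1].append(syn)
    return sides[0], sides[1], dropped


def _build_one_synthon(
    record: MatchRecord,
    rule: ReactionRule,
    side: int,
    link_specs: list[tuple[int, int, int, str]],
    model: AromaticityModel,
) -> "Synthon | str":
    graph = rule.reactant_graphs[side - 1]
    node_map = rule.reactant_node_maps[side - 1]
    mol = Chem.RWMol(record.bb)

    atom_of_map: dict[int, int] = {}
    leaving: set[int] = set()
    for node in graph.nodes:
        atom_idx = record.match_atoms[node.index]
        map_number = node_map.get(node.index)
        if map_number is not None and map_number in rule.product_maps:
            atom_of_map[map_number] = atom_idx
        else:
            leaving.add(atom_idx)

    # intra-side bond-order edits from the product pattern
    for ma, mb, order in rule.intra_changes:
        if rule.side_of_map[ma] != side:
            continue
        bond = mol.GetBondBetweenAtoms(atom_of_map[ma], atom_of_map[mb])
        if bond is None:
            return "pattern_bond_missing"
        bond.SetBondType(bond_type_for(order))

    # attach typed link atoms with the formed bond's order
    for link_type, ma, mb, order in link_specs:
        my_map = ma if rule.side_of_map[ma] == side else mb
        dummy = Chem.Atom(0)
        dummy.SetAtomMapNum(link_type)
        dummy_idx = mol.AddAtom(dummy)
        mol.AddBond(atom_of_map[my_map], dummy_idx, bond_type_for(order))

    # delete leaving atoms, then anything no longer connected to the backbone
    for atom_idx in sorted(leaving, reverse=True):
        mol.RemoveAtom(atom_idx)
    frag = mol.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        # distinguish a non-favored valence state (expected drop) from a
        # genuinely broken fragment
        try:
            frag.UpdatePropertyCache(strict=False)
        except Exception:
            return "sanitize_failed"
        return "valence" if not check_valence(frag) else "sanitize_failed"
    frags = Chem.GetMolFrags(frag, asMols=False)
    if len(frags) > 1:
        keep = None
        for comp in frags:
            if any(frag.GetAtomWithIdx(i).GetAtomicNum() == 0 for i in comp):
                keep = set(comp)
                break
        rw = Chem.RWMol(frag)
        for idx in sorted(range(frag.GetNumAtoms()), reverse=True):
            if idx not in keep:
                rw.RemoveAtom(idx)
        frag = rw.GetMol()
        Chem.SanitizeMol(frag)

    frag, _removed = remove_protecting_groups(frag)
    if not check_valence(frag):
        return "valence"
    frag = perceive_aromaticity(frag, model)
    smiles = Chem.MolToSmiles(frag)
    return Synthon(
        fragment=frag,
        smiles=smiles,
        bb_id=record.bb_id,
        transform_id=rule.transform_id,
        side=side,
        variant_tag=rule.variant_tag,
        mass_u=mass_microdaltons(frag),
    )


def build_topology_graph(
    subreaction: SubReaction,
    model: AromaticityModel = AromaticityModel.DEFAULT,
    graph_id: str = "g",
) -> tuple[Optional[TopologyGraph], list[tuple[str, str]]]:
    side1, side2, dropped = build_synthons(subreaction, model, graph_id)
    if not side1 or not side2:
        return None, dropped
    link_bonds = [
        (_link_type(graph_id, slot), ma, mb, order)
        for slot, (ma, mb, order) in enumerate(subreaction.rule.formed_bonds)
    ]
    graph = TopologyGraph(
        graph_id=graph_id,
        rule=subreaction.rule,
        side1=side1,
        side2=side2,
        link_bonds=link_bonds,
        pairing_reason=subreaction.pairing_reason,
    )
    return graph, dropped


def assemble_product(
    s1: Synthon, s2: Synthon, model: AromaticityModel = AromaticityModel.DEFAULT
) -> Chem.Mol:
    """Join two synthons at their paired link atoms.

    A valence failure here is a hard error: invalid products must have been
    excluded when the synthons were built.
    """
    combo = Chem.RWMol(Chem.CombineMols(s1.fragment, s2.fragment))
    by_type: dict[int, list[int]] = {}
    for atom in combo.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            by_type.setdefault(atom.GetAtomMapNum(), []).append(atom.GetIdx())
    to_remove: list[int] = []
    for link_type, idxs in by_type.items():
        if len(idxs) != 2:
            raise ValueError(f"link type {link_type} is not paired")
        i, j = idxs
        ai = combo.GetAtomWithIdx(i)
        aj = combo.GetAtomWithIdx(j)
        order = ai.GetBonds()[0].GetBondType()
        ni = ai.GetNeighbors()[0].GetIdx()
        nj = aj.GetNeighbors()[0].GetIdx()
        combo.AddBond(ni, nj, order)
        to_remove.extend((i, j))
    for idx in sorted(to_remove, reverse=True):
        combo.RemoveAtom(idx)
    product = combo.GetMol()
    Chem.SanitizeMol(product)
    return perceive_aromaticity(product, model)


def count_products(space: FragmentSpace) -> int:
    """Exact product count: sum over graphs of |side1| x |side2|."""
    return sum(g.n_products for g in space.graphs)


def enumerate_products(
    space: FragmentSpace,
    limit: int,
    seed: int = 0,
) -> Iterator[tuple[str, dict]]:
    """Sample up to ``limit`` products per sub-reaction, without replacement.

    Sampling is uniform over the pair lattice via index arithmetic (pair k
    maps to (k // |side2|, k % |side2|)); no pair list is materialized.
    Fixed seed implies byte-identical output.
    """
    rng = random.Random(seed)
    model = space.model
    for graph in space.graphs:
        n = graph.n_products
        if n == 0:
            continue
        k = min(limit, n)
        indices = rng.sample(range(n), k) if k < n else list(range(n))
        for idx in indices:
            i, j = divmod(idx, len(graph.side2))
            s1, s2 = graph.side1[i], graph.side2[j]
            product = assemble_product(s1, s2, model)
            smiles = Chem.MolToSmiles(product)
            yield smiles, {
                "graph_id": graph.graph_id,
                "transform_id": graph.rule.transform_id,
                "variant_tag": graph.rule.variant_tag,
                "bb1": s1.bb_id,
                "bb2": s2.bb_id,
                "pair_index": idx,
            }


def _decompose(
    query: Chem.Mol, graph: TopologyGraph, model: AromaticityModel
) -> Iterator[tuple[str, str]]:
    """Cut a query at the formed bonds per product-pattern match.

    Yields (side1 SMILES, side2 SMILES) candidate decompositions with link
    atoms installed, canonicalized like stored synthons.
    """
    rule = graph.rule
    pq = rule.product_query()
    # uniquify=False: both orientations of a symmetric match must be tried,
    # since they assign the cut fragments to opposite sides
    for match in query.GetSubstructMatches(pq, uniquify=False, maxMatches=512):
        atom_of_map = {i + 1: match[i] for i in range(len(match))}
        rw = Chem.RWMol(query)
        try:
            Chem.Kekulize(rw, clearAromaticFlags=True)
        except Exception:
            pass
        ok = True
        side_anchor: dict[int, list[tuple[int, int, Chem.BondType]]] = {1: [], 2: []}
        for link_type, ma, mb, order in graph.link_bonds:
            ai, bi = atom_of_map[ma], atom_of_map[mb]
            bond = rw.GetBondBetweenAtoms(ai, bi)
            if bond is None:
                ok = False
                break
            side_anchor[rule.side_of_map[ma]].append((link_type, ai, bond_type_for(order)))
            side_anchor[rule.side_of_map[mb]].append((link_type, bi, bond_type_for(order)))
            rw.RemoveBond(ai, bi)
        if not ok:
            continue
        for side in (1, 2):
            for link_type, anchor, order in side_anchor[side]:
                dummy = Chem.Atom(0)
                dummy.SetAtomMapNum(link_type)
                di = rw.AddAtom(dummy)
                rw.AddBond(anchor, di, order)
        cut = rw.GetMol()
        try:
            Chem.SanitizeMol(cut)
        except Exception:
            continue
        frags = Chem.GetMolFrags(cut, asMols=True, sanitizeFrags=False)
        if len(frags) != 2:
            continue
        # assign fragments to sides via a representative mapped atom
        rep_atom = {s: side_anchor[s][0][1] for s in (1, 2)}
        frag_indices = Chem.GetMolFrags(cut, asMols=False)
        by_side: dict[int, Chem.Mol] = {}
        for comp, fmol in zip(frag_indices, frags):
            for s in (1, 2):
                if rep_atom[s] in comp:
                    by_side[s] = fmol
        if len(by_side) != 2:
            continue
        try:
            smi1 = Chem.MolToSmiles(perceive_aromaticity(by_side[1], model))
            smi2 = Chem.MolToSmiles(perceive_aromaticity(by_side[2], model))
        except Exception:
            continue
        yield smi1, smi2


def retro_validate(
    product: Chem.Mol,
    graph: TopologyGraph,
    expected: tuple[str, str],
    model: Optional[AromaticityModel] = None,
) -> bool:
    """Apply the rule backwards: True iff the product matches the product
    pattern and decomposes into exactly the recorded synthons.

    ``expected`` is the (bb1_id, bb2_id) provenance pair.
    """
    model = model or AromaticityModel.DEFAULT
    want1 = {s.smiles for s in graph.side1 if s.bb_id == expected[0]}
    want2 = {s.smiles for s in graph.side2 if s.bb_id == expected[1]}
    product = perceive_aromaticity(product, model)
    if not product.HasSubstructMatch(graph.rule.product_query()):
        return False
    for smi1, smi2 in _decompose(product, graph, model):
        if smi1 in want1 and smi2 in want2:
            return True
    return False


def _synthon_index(graph: TopologyGraph, side: int) -> dict[str, list[Synthon]]:
    cache_attr = f"_index_{side}"
    index = getattr(graph, cache_attr, None)
    if index is None:
        index = {}
        for syn in graph.side1 if side == 1 else graph.side2:
            index.setdefault(syn.smiles, []).append(syn)
        setattr(graph, cache_attr, index)
    return index


def contains(space: FragmentSpace, query_smiles: str) -> list[dict]:
    """Membership by retro-decomposition, exact on canonical SMILES.

    The query is cut at bonds matching each sub-reaction's formed-bond
    environment; the pieces are canonicalized as labeled synthons and looked
    up in the per-side indexes.  Returns one provenance per constructible
    route.
    """
    model = space.model
    query = Chem.MolFromSmiles(query_smiles)
    if query is None:
        return []
    query = perceive_aromaticity(query, model)
    results: list[dict] = []
    seen: set[tuple] = set()
    for graph in space.graphs:
        index1 = _synthon_index(graph, 1)
        index2 = _synthon_index(graph, 2)
        for smi1, smi2 in _decompose(query, graph, model):
            for s1 in index1.get(smi1, ()):
                for s2 in index2.get(smi2, ()):
                    key = (graph.graph_id, s1.bb_id, s2.bb_id)
                    if key not in seen:
                        seen.add(key)
                        results.append(
                            {
                                "graph_id": graph.graph_id,
                                "transform_id": graph.rule.transform_id,
                                "variant_tag": graph.rule.variant_tag,
                                "bb1": s1.bb_id,
                                "bb2": s2.bb_id,
                            }
                        )
    return results


# ---------------------------------------------------------------------------
# additive descriptors


def _descr_mass(syn: Synthon) -> int:
    return syn.mass_u


def _count_nhoh(mol: Chem.Mol) -> int:
    return sum(
        a.GetTotalNumHs() for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8)
    )


def _count_no(mol: Chem.Mol) -> int:
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() in (7, 8))


_ROT_QUERY = Chem.MolFromSmarts("[!D1]-&!@[!D1]")


def _count_rotatable(mol: Chem.Mol) -> int:
    """Proxy: acyclic single bonds between non-terminal heavy atoms.

    Bonds incident to a dummy (link/mask) atom are not counted; the dummy
    still contributes to the degree of its neighbor, mirroring the partner
    fragment it stands for.
    """
    n = 0
    for i, j in mol.GetSubstructMatches(_ROT_QUERY):
        ai, aj = mol.GetAtomWithIdx(i), mol.GetAtomWithIdx(j)
        if ai.GetAtomicNum() == 0 or aj.GetAtomicNum() == 0:
            continue
        n += 1
    return n


DESCRIPTORS = {
    "MW": lambda syn: syn.mass_u,
    "HBD": lambda syn: _count_nhoh(syn.fragment),
    "HBA": lambda syn: _count_no(syn.fragment),
    "ROT": lambda syn: _count_rotatable(syn.fragment),
}

PRODUCT_DESCRIPTORS = {
    "MW": mass_microdaltons,
    "HBD": _count_nhoh,
    "HBA": _count_no,
    "ROT": _count_rotatable,
}


def _link_atom_nonterminal(syn: Synthon) -> bool:
    """True iff every link atom's neighbor has degree > 1 (incl. the dummy)."""
    for atom in syn.fragment.GetAtoms():
        if atom.GetAtomicNum() == 0 and atom.GetAtomMapNum():
            if atom.GetNeighbors()[0].GetDegree() <= 1:
                return False
    return True


def _pair_sum_histogram(
    values1: Sequence[int],
    values2: Sequence[int],
    edges_u: Sequence[int],
    shift: int = 0,
) -> list[int]:
    """Exact histogram of {v1 + v2 + shift} over the pair lattice.

    O((|v1| + bins) log |v2|): for each edge, pairs below it are counted by
    binary search in the sorted side-2 values.
    """
    sorted2 = sorted(values2)

    def pairs_below(edge: int) -> int:
        total = 0
        for v1 in values1:
            total += bisect_left(sorted2, edge - shift - v1)
        return total

    cuts = [pairs_below(e) for e in edges_u]
    return [cuts[i + 1] - cuts[i] for i in range(len(cuts) - 1)]


def property_histograms(
    space: FragmentSpace,
    descriptor: str,
    bins: Sequence[float],
) -> PropertyHistogram:
    """Exact descriptor histogram by per-side convolution.

    Supported additive descriptors: ``MW`` (g/mol), ``HBD`` (H on N/O),
    ``HBA`` (N+O count), ``ROT`` (rotatable-bond proxy; open-chain rules
    only).  Bins follow numpy convention: last bin closed, others
    right-open.  The counts sum to the space's product count: values
    outside the bin range raise, so histograms stay exact.
    """
    if descriptor not in DESCRIPTORS:
        raise ValueError(f"unsupported descriptor {descriptor!r}; additive "
                         f"descriptors are {sorted(DESCRIPTORS)}")
    scale = 1_000_000 if descriptor == "MW" else 1
    edges_u = [round(b * scale) for b in bins]
    if descriptor == "MW":
        # right-open integer bins: shift the final edge to close the last bin
        edges_u[-1] += 1
    else:
        edges_u[-1] += 1
    value_of = DESCRIPTORS[descriptor]
    counts = [0] * (len(edges_u) - 1)
    for graph in space.graphs:
        if descriptor == "ROT":
            if len(graph.link_bonds) != 1:
                raise ValueError(
                    "ROT proxy is additive only for single-link (open-chain) "
                    f"rules; graph {graph.graph_id} forms {len(graph.link_bonds)} bonds"
                )
            order = graph.link_bonds[0][3]
            # the formed bond counts when acyclic single between non-terminal
            # atoms; split each side by link-atom terminality and convolve
            # the four blocks with their exact corrections
            for flag1 in (False, True):
                for flag2 in (False, True):
                    v1 = [
                        value_of(s)
                        for s in graph.side1
                        if _link_atom_nonterminal(s) == flag1
                    ]
                    v2 = [
                        value_of(s)
                        for s in graph.side2
                        if _link_atom_nonterminal(s) == flag2
                    ]
                    if not v1 or not v2:
                        continue
                    shift = 1 if (flag1 and flag2 and order == "-") else 0
                    block = _pair_sum_histogram(v1, v2, edges_u, shift)
                    expected = len(v1) * len(v2)
                    if sum(block) != expected:
                        raise ValueError("histogram bins do not cover the value range")
                    counts = [c + b for c, b in zip(counts, block)]
            continue
        v1 = [value_of(s) for s in graph.side1]
        v2 = [value_of(s) for s in graph.side2]
        if not v1 or not v2:
            continue
        block = _pair_sum_histogram(v1, v2, edges_u)
        if sum(block) != len(v1) * len(v2):
            raise ValueError("histogram bins do not cover the value range")
        counts = [c + b for c, b in zip(counts, block)]
    return PropertyHistogram(descriptor=descriptor, bin_edges=list(bins), counts=counts)


def coverage_estimate(
    space_a: FragmentSpace,
    space_b: FragmentSpace,
    per_transform_n: int = 1000,
    seed: int = 0,
) -> dict[int, float]:
    """Per-transform fraction of sampled products of A contained in B."""
    hits: dict[int, int] = {}
    totals: dict[int, int] = {}
    for smiles, prov in enumerate_products(space_a, per_transform_n, seed=seed):
        tid = prov["transform_id"]
        totals[tid] = totals.get(tid, 0) + 1
        if contains(space_b, smiles):
            hits[tid] = hits.get(tid, 0) + 1
    return {tid: hits.get(tid, 0) / n for tid, n in totals.items()}


def build_space(
    transform_texts: Sequence[str],
    bbs: Sequence[tuple[Chem.Mol, str]],
    kill_rulesets: Optional[dict[int, "KillRuleSet"]] = None,
    policy: "MatchPolicy | str" = "space",
    model: AromaticityModel = AromaticityModel.DEFAULT,
    name: str = "space",
) -> tuple[FragmentSpace, dict]:
    """Run the whole construction: translate, filter, split, encode.

    ``bbs`` must already be standardized; aromaticity is perceived here
    under ``model`` so patterns and building blocks agree.  Returns the
    space plus a build log (exclusions and dropped synthons per rule).
    """
    from .reactant_filter import MatchPolicy, filter_reactants
    from .transpiler import translate_transform

    if isinstance(policy, str):
        policy = MatchPolicy(policy)
    kill_rulesets = kill_rulesets or {}
    perceived = [(perceive_aromaticity(mol, model), bb_id) for mol, bb_id in bbs]
    graphs: list[TopologyGraph] = []
    log: dict = {"exclusions": {}, "dropped_synthons": {}, "subreactions": 0}
    # a block matched by two fusion variants of one transform belongs to the
    # first variant only, so no pair is produced by two variants
    claimed: dict[tuple, set[str]] = {}
    for text in transform_texts:
        for rule in translate_transform(text):
            ruleset = kill_rulesets.get(rule.transform_id)
            subreactions, excluded = filter_reactants(
                rule, perceived, policy=policy, ruleset=ruleset
            )
            log["exclusions"].setdefault(rule.rule_id, []).extend(
                (e.bb_id, e.reason) for e in excluded
            )
            tag_parts = rule.variant_tag.split(".")
            fusion_sides = {
                int(p[1]) for p in tag_parts if p.startswith("f") and len(p) > 1
            }
            if fusion_sides:
                alt = tuple(p for p in tag_parts if p.startswith("p"))
                for sub in subreactions:
                    for side_attr, side_i in (("group_1", 1), ("group_2", 2)):
                        if side_i not in fusion_sides:
                            continue  # this side's pattern is shared by variants
                        key = (rule.transform_id, alt, side_i)
                        taken = claimed.setdefault(key, set())
                        kept = [
                            r for r in getattr(sub, side_attr) if r.bb_id not in taken
                        ]
                        taken.update(r.bb_id for r in kept)
                        setattr(sub, side_attr, kept)
            for k, sub in enumerate(subreactions):
                graph_id = f"t{rule.transform_id}_{rule.variant_tag or 'base'}_{k}"
                graph, dropped = build_topology_graph(sub, model, graph_id)
                if dropped:
                    log["dropped_synthons"].setdefault(graph_id, []).extend(dropped)
                if graph is not None:
                    graphs.append(graph)
    log["subreactions"] = len(graphs)
    space = FragmentSpace(
        name=name,
        graphs=graphs,
        manifest={
            "aromaticity_model": model.value,
            "policy": policy.value,
            "n_building_blocks": len(bbs),
        },
    )
    return space, log


# ---------------------------------------------------------------------------
# serialization


def serialize(space: FragmentSpace, path: str) -> None:
    """Write the space as a directory of text files.

    ``manifest.json`` carries policies and per-graph metadata; each
    sub-reaction stores its synthons as SMILES (link atoms as mapped dummy
    atoms) with provenance ids.
    """
    os.makedirs(path, exist_ok=True)
    manifest = dict(space.manifest)
    manifest["name"] = space.name
    manifest["graphs"] = []
    for graph in space.graphs:
        gdir = os.path.join(path, graph.graph_id)
        os.makedirs(gdir, exist_ok=True)
        for side in (1, 2):
            synthons = graph.side1 if side == 1 else graph.side2
            with open(os.path.join(gdir, f"side{side}.smi"), "w") as handle:
                for syn in synthons:
                    handle.write(f"{syn.smiles}\t{syn.bb_id}\n")
        rule = graph.rule
        sidecar = {
            "graph_id": graph.graph_id,
            "transform_id": rule.transform_id,
            "name": rule.name,
            "variant_tag": rule.variant_tag,
            "reactant_smarts": rule.reactant_smarts,
            "product_smarts": rule.product_smarts,
            "side_of_map": {str(k): v for k, v in rule.side_of_map.items()},
            "product_maps": sorted(rule.product_maps),
            "formed_bonds": rule.formed_bonds,
            "intra_changes": rule.intra_changes,
            "link_bonds": graph.link_bonds,
            "pairing_reason": graph.pairing_reason,
            "counts": {"side1": len(graph.side1), "side2": len(graph.side2)},
        }
        with open(os.path.join(gdir, "subreaction.json"), "w") as handle:
            json.dump(sidecar, handle, indent=1)
        manifest["graphs"].append(graph.graph_id)
    with open(os.path.join(path, "manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=1)


def load(path: str) -> FragmentSpace:
    """Load a serialized space; counts, histograms and membership reproduce."""
    with open(os.path.join(path, "manifest.json")) as handle:
        manifest = json.load(handle)
    if "graphs" not in manifest or "name" not in manifest:
        raise ValueError("manifest.json lacks required keys")
    graphs: list[TopologyGraph] = []
    for graph_id in manifest["graphs"]:
        gdir = os.path.join(path, graph_id)
        sidecar_path = os.path.join(gdir, "subreaction.json")
        if not os.path.exists(sidecar_path):
            raise ValueError(f"missing sidecar for graph {graph_id}")
        with open(sidecar_path) as handle:
            sidecar = json.load(handle)
        rule = ReactionRule(
            transform_id=sidecar["transform_id"],
            name=sidecar["name"],
            reactant_smarts=sidecar["reactant_smarts"],
            product_smarts=sidecar["product_smarts"],
            variant_tag=sidecar["variant_tag"],
            side_of_map={int(k): v for k, v in sidecar["side_of_map"].items()},
            product_maps=frozenset(sidecar["product_maps"]),
            formed_bonds=[tuple(b) for b in sidecar["formed_bonds"]],
            intra_changes=[tuple(b) for b in sidecar["intra_changes"]],
        )
        sides: dict[int, list[Synthon]] = {1: [], 2: []}
        for side in (1, 2):
            fname = os.path.join(gdir, f"side{side}.smi")
            if not os.path.exists(fname):
                raise ValueError(f"missing synthon file {fname}")
            with open(fname) as handle:
                for line in handle:
                    line = line.rstrip("\n")
                    if not line:
                        continue
                    smiles, bb_id = line.split("\t")
                    frag = Chem.MolFromSmiles(smiles)
                    if frag is None:
                        raise ValueError(f"bad synthon SMILES in {fname}: {smiles}")
                    sides[side].append(
                        Synthon(
                            fragment=frag,
                            smiles=Chem.MolToSmiles(frag),
                            bb_id=bb_id,
                            transform_id=rule.transform_id,
                            side=side,
                            variant_tag=rule.variant_tag,
                            mass_u=mass_microdaltons(frag),
                        )
                    )
        graphs.append(
            TopologyGraph(
                graph_id=sidecar["graph_id"],
                rule=rule,
                side1=sides[1],
                side2=sides[2],
                link_bonds=[tuple(b) for b in sidecar["link_bonds"]],
                pairing_reason=sidecar.get("pairing_reason", ""),
            )
        )
    return FragmentSpace(name=manifest["name"], graphs=graphs, manifest=manifest)
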