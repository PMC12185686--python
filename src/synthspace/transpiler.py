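"""Translate pattern graphs into reaction SMARTS and load KILL rulesets.

The translation is category-driven: atoms, atom properties, functional
groups, bonds and bond properties each resolve through the shipped
translation map (``data/translation_map.json``).  Properties without a
direct SMARTS counterpart become recursive expressions; numeric ranges
("more/fewer than n hydrogens/heteroatoms") are enumerated, since classic
SMARTS has no range syntax; bond properties that SMARTS cannot express on
bonds (the fusion-bond family) are transferred to the adjacent atoms as
ring-connectivity annotations.

The negated fusion-bond property cannot be placed on both incident atoms at
once without contradictions in fused systems, so each such edge doubles the
pattern: one variant annotates one incident atom, the second variant the
other.  Every variant becomes its own reaction rule (a sub-reaction).

KILL statements are hand-translated data (JSON, one file per transform);
this module validates and loads them: SMARTS must compile, GOTO indices
must resolve, and untranslatable keywords are carried as explicit markers
so the filter can log each skip instead of silently passing.
"""

from __future__ import annotations

import copy
import itertools
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

from rdkit import Chem

from .patran import (
    PatternEdge,
    PatternGraph,
    PatternNode,
    parse_pattern,
    parse_transform_file,
)

logger = logging.getLogger("synthspace")

__all__ = [
    "TranslationMap",
    "TranslationError",
    "ProductPatternError",
    "translate_atom",
    "translate_bond",
    "expand_fusion_variants",
    "emit_smarts",
    "ReactionRule",
    "translate_transform",
    "KillStatement",
    "KillRuleSet",
    "load_kill_ruleset",
]

# Open ranges ("more than n") enumerate up to the maximal organic
# connectivity of four.
ENUMERATION_CAP = 4

# Map numbers are carried on masked reactants in the isotope slot with this
# offset, so KILL SMARTS can anchor on participants without colliding with
# natural isotopes.
ISOTOPE_OFFSET = 100


class TranslationError(KeyError):
    """A pattern keyword has no entry in the translation map."""


class ProductPatternError(ValueError):
    """The product pattern uses a property other than the H count."""


class TranslationMap:
    """Keyword -> SMARTS tables for each pattern category."""

    _default: Optional["TranslationMap"] = None

    def __init__(self, raw: dict):
        self.atom: dict[str, str] = raw["atom"]
        self.atom_property: dict[str, dict] = raw["atom_property"]
        self.functional_group: dict[str, str] = raw["functional_group"]
        self.bond: dict[str, str] = raw["bond"]
        self.bond_property: dict[str, dict] = raw["bond_property"]
        self.fusion_atom: str = raw["fusion_atom"]
        self.fusion_atom_aromatic: str = raw["fusion_atom_aromatic"]

    @classmethod
    def default(cls) -> "TranslationMap":
        if cls._default is None:
            text = resources.files("synthspace.data").joinpath("translation_map.json").read_text()
            cls._default = cls(json.loads(text))
        return cls._default


def _hetero_at_least(k: int) -> str:
    """Recursive SMARTS: atom with at least k heteroatom neighbors."""
    if k <= 0:
        return ""
    return "$([*]" + "(~[!#6;!#1])" * k + ")"


def _hcount_constraint(args: tuple[str, ...]) -> str:
    if len(args) == 1:
        return f"H{int(args[0])}"
    op, n = args[0], int(args[1])
    if op == ">":
        values = range(n + 1, ENUMERATION_CAP + 1)
    elif op == "<":
        values = range(0, n)
    else:
        raise TranslationError(f"unsupported HS comparator {op!r}")
    options = [f"H{v}" for v in values]
    if not options:
        raise TranslationError(f"empty HS range for {args!r}")
    return ",".join(options)


def _hetcount_constraints(args: tuple[str, ...]) -> list[str]:
    if len(args) == 1:
        n = int(args[0])
        parts = []
        if n > 0:
            parts.append(_hetero_at_least(n))
        parts.append("!" + _hetero_at_least(n + 1))
        return parts
    op, n = args[0], int(args[1])
    if op == ">":
        return [_hetero_at_least(n + 1)]
    if op == "<":
        return ["!" + _hetero_at_least(n)]
    raise TranslationError(f"unsupported HETS comparator {op!r}")


def _resolve_groups(tmap: TranslationMap, names: Sequence[str], context: str) -> list[str]:
    templates = []
    for name in names:
        try:
            templates.append(tmap.functional_group[name])
        except KeyError:
            raise TranslationError(f"unknown functional group {name!r} in {context}")
    return templates


def translate_atom(
    node: PatternNode,
    tmap: TranslationMap,
    product_side: bool = False,
    context: str = "",
) -> str:
    """Atom expression (without brackets or map suffix) for one node.

    Presence of functional groups joins recursive templates with OR;
    absence joins the negated templates with AND.  On the product side only
    the hydrogen count and the aromatic flag are admitted.
    """
    try:
        primitive = tmap.atom[node.atom_text]
    except KeyError:
        raise TranslationError(f"unknown atom keyword {node.atom_text!r} in {context}")
    constraints = [primitive]
    for keyword, args in node.properties:
        if keyword == "_ANNOT":
            constraints.extend(args)
            continue
        if product_side and keyword not in ("HS", "AROM"):
            raise ProductPatternError(
                f"property {keyword!r} not allowed in a product pattern ({context})"
            )
        spec = tmap.atom_property.get(keyword)
        if spec is None:
            raise TranslationError(f"unknown atom property {keyword!r} in {context}")
        mode = spec.get("mode")
        if mode == "hcount":
            constraints.append(_hcount_constraint(args))
        elif mode == "hetcount":
            constraints.extend(_hetcount_constraints(args))
        elif mode == "fgs":
            groups = _resolve_groups(tmap, args, context)
            constraints.append(",".join(f"$({g})" for g in groups))
        elif mode == "fgs_absent":
            groups = _resolve_groups(tmap, args, context)
            constraints.extend(f"!$({g})" for g in groups)
        elif mode == "arom":
            constraints.append("a")
        else:
            constraints.append(spec["smarts"])
    return ";".join(c for c in constraints if c)


def translate_bond(
    edge: PatternEdge,
    tmap: TranslationMap,
    context: str = "",
) -> tuple[str, dict[int, list[str]]]:
    """Bond expression plus annotations to transfer to adjacent atoms.

    Fusion-bond properties have no bond-level SMARTS counterpart: both
    incident atoms receive a ring-connectivity annotation instead.  Negated
    fusion edges must have been expanded beforehand
    (:func:`expand_fusion_variants`).
    """
    try:
        parts = [tmap.bond[edge.bond_text]]
    except KeyError:
        raise TranslationError(f"unknown bond keyword {edge.bond_text!r} in {context}")
    annotations: dict[int, list[str]] = {}
    for prop in edge.properties:
        spec = tmap.bond_property.get(prop)
        if spec is None:
            raise TranslationError(f"unknown bond property {prop!r} in {context}")
        mode = spec["mode"]
        if mode == "append":
            parts.append(spec["smarts"])
        elif mode == "fusion":
            annot = tmap.fusion_atom_aromatic if spec.get("aromatic") else tmap.fusion_atom
            annotations.setdefault(edge.start, []).append(annot)
            annotations.setdefault(edge.end, []).append(annot)
        elif mode == "fusion_neg":
            raise TranslationError(
                f"negated fusion property on an unexpanded edge in {context}; "
                "call expand_fusion_variants first"
            )
        else:  # pragma: no cover - data error
            raise TranslationError(f"bad bond-property mode {mode!r}")
    return ";".join(parts), annotations


def _negated_fusion_edges(graph: PatternGraph) -> list[int]:
    out = []
    for i, edge in enumerate(graph.edges):
        if any(p.startswith("NOT ") and p.endswith("FUSION") for p in edge.properties):
            out.append(i)
    return out


def expand_fusion_variants(
    graph: PatternGraph, tmap: Optional[TranslationMap] = None
) -> list[tuple[PatternGraph, str]]:
    """Duplicate the pattern per negated-fusion edge.

    For each such edge two variants are produced: the negated annotation on
    the start atom only, or on the end atom only.  Variants multiply across
    edges; a graph without negated fusion edges passes through unchanged
    with an empty tag.
    """
    tmap = tmap or TranslationMap.default()
    targets = _negated_fusion_edges(graph)
    if not targets:
        return [(graph, "")]
    variants: list[tuple[PatternGraph, str]] = []
    for choices in itertools.product("ab", repeat=len(targets)):
        g = copy.deepcopy(graph)
        for edge_i, choice in zip(targets, choices):
            edge = g.edges[edge_i]
            keep = []
            annot = None
            for prop in edge.properties:
                if prop.startswith("NOT ") and prop.endswith("FUSION"):
                    aromatic = "DIARYL" in prop
                    base = tmap.fusion_atom_aromatic if aromatic else tmap.fusion_atom
                    annot = "!" + base
                else:
                    keep.append(prop)
            edge.properties = keep
            target_node = edge.start if choice == "a" else edge.end
            g.nodes[target_node].properties.append(("_ANNOT", (annot,)))
        variants.append((g, "".join(choices)))
    return variants


def emit_smarts(
    graph: PatternGraph,
    tmap: Optional[TranslationMap] = None,
    maps: Optional[dict[int, int]] = None,
    product_side: bool = False,
    context: str = "",
) -> str:
    """Emit a SMARTS string by replaying the pattern's reading order.

    Node order equals appearance order, branches become parentheses, ring
    closures become SMARTS ring-bond digits.  On the product side, bonds
    between two explicitly aromatic atoms additionally admit the aromatic
    bond so the emitted pattern matches the assembled (aromatized) product.
    """
    tmap = tmap or TranslationMap.default()
    maps = maps or {}
    bond_exprs: dict[int, str] = {}
    annotations: dict[int, list[str]] = {}
    for i, edge in enumerate(graph.edges):
        expr, annots = translate_bond(edge, tmap, context=context)
        if product_side:
            a, b = graph.nodes[edge.start], graph.nodes[edge.end]
            if any(k == "AROM" for k, _ in a.properties) and any(
                k == "AROM" for k, _ in b.properties
            ):
                expr = expr + ",:"
        bond_exprs[i] = expr
        for node_i, extra in annots.items():
            annotations.setdefault(node_i, []).extend(extra)

    atom_exprs: dict[int, str] = {}
    for node in graph.nodes:
        expr = translate_atom(node, tmap, product_side=product_side, context=context)
        for extra in annotations.get(node.index, []):
            expr += ";" + extra
        map_number = maps.get(node.index)
        atom_exprs[node.index] = (
            f"[{expr}:{map_number}]" if map_number is not None else f"[{expr}]"
        )

    out: list[str] = []
    for event in graph.events:
        if event[0] == "atom":
            out.append(atom_exprs[event[1]])
        elif event[0] == "open":
            out.append("(")
        elif event[0] == "close":
            out.append(")")
        elif event[0] == "bond":
            out.append(bond_exprs[event[1]])
        elif event[0] == "ring":
            digit, edge_i = event[1], event[2]
            if edge_i is None:
                out.append(digit)
            else:
                out.append(bond_exprs[edge_i] + digit)
    smarts = "".join(out)
    if Chem.MolFromSmarts(smarts) is None:
        raise TranslationError(f"emitted SMARTS does not parse ({context}): {smarts}")
    return smarts


@dataclass
class ReactionRule:
    """One translated reaction: a (pattern alternative x fusion variant).

    ``side_of_map`` locates each map number on reactant side 1 or 2;
    ``formed_bonds`` are product-pattern bonds whose ends lie on different
    sides (the link bonds of the fragment space); ``intra_changes`` are
    product bonds within one side, applied as local bond-order edits when
    synthons are built.
    """

    transform_id: int
    name: str
    reactant_smarts: list[str]
    product_smarts: str
    variant_tag: str
    link_mass_delta: float = 0.0
    side_of_map: dict[int, int] = field(default_factory=dict)
    product_maps: frozenset[int] = frozenset()
    formed_bonds: list[tuple[int, int, str]] = field(default_factory=list)
    intra_changes: list[tuple[int, int, str]] = field(default_factory=list)
    role_maps: dict[int, frozenset[int]] = field(default_factory=dict)
    reactant_graphs: list[PatternGraph] = field(default_factory=list)
    product_graph: Optional[PatternGraph] = None
    reactant_node_maps: list[dict[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._queries: Optional[list[Chem.Mol]] = None
        self._product_query: Optional[Chem.Mol] = None

    @property
    def n_sides(self) -> int:
        return len(self.reactant_smarts)

    @property
    def rule_id(self) -> str:
        return f"{self.transform_id}{('.' + self.variant_tag) if self.variant_tag else ''}"

    def reactant_queries(self) -> list[Chem.Mol]:
        if self._queries is None:
            self._queries = [Chem.MolFromSmarts(s) for s in self.reactant_smarts]
            if any(q is None for q in self._queries):
                raise TranslationError(f"reactant SMARTS of {self.rule_id} does not parse")
        return self._queries

    def product_query(self) -> Chem.Mol:
        if self._product_query is None:
            self._product_query = Chem.MolFromSmarts(self.product_smarts)
            if self._product_query is None:
                raise TranslationError(f"product SMARTS of {self.rule_id} does not parse")
        return self._product_query

    def leaving_maps(self) -> frozenset[int]:
        return frozenset(self.side_of_map) - self.product_maps


_BOND_ORDER = {
    "-": Chem.BondType.SINGLE,
    "=": Chem.BondType.DOUBLE,
    "#": Chem.BondType.TRIPLE,
    ":": Chem.BondType.AROMATIC,
    "~": Chem.BondType.SINGLE,
}


def bond_type_for(text: str) -> Chem.BondType:
    return _BOND_ORDER[text]


def _compute_roles(
    rule_sides: list[PatternGraph],
    node_maps: list[dict[int, int]],
    product_maps: frozenset[int],
    formed: list[tuple[int, int, str]],
    intra: list[tuple[int, int, str]],
) -> dict[int, frozenset[int]]:
    """Distinct-role maps per side: atoms whose bonding changes.

    A map is a role if it is incident to a formed (cross-side) bond, to an
    intra-side product bond-order change, or to a leaving atom in the
    reactant pattern.  Matches that agree on role atoms yield the same
    product; matches that differ yield product mixtures.
    """
    roles: dict[int, set[int]] = {1: set(), 2: set()}
    side_of: dict[int, int] = {}
    for side_i, node_map in enumerate(node_maps, start=1):
        for m in node_map.values():
            side_of[m] = side_i
    for a, b, _ in formed:
        roles[side_of[a]].add(a)
        roles[side_of[b]].add(b)
    # reactant-pattern bond orders between mapped atoms, for change detection
    reactant_bond: dict[frozenset[int], str] = {}
    for graph, node_map in zip(rule_sides, node_maps):
        for edge in graph.edges:
            ma, mb = node_map.get(edge.start), node_map.get(edge.end)
            if ma is not None and mb is not None:
                reactant_bond[frozenset((ma, mb))] = edge.bond_text
    for a, b, order in intra:
        if reactant_bond.get(frozenset((a, b))) == order:
            continue  # unchanged context bond, not a distinct role
        roles[side_of[a]].add(a)
        roles[side_of[b]].add(b)
    for side_i, (graph, node_map) in enumerate(zip(rule_sides, node_maps), start=1):
        leaving_nodes = {
            n.index
            for n in graph.nodes
            if node_map.get(n.index) is None or node_map[n.index] not in product_maps
        }
        for edge in graph.edges:
            for here, there in ((edge.start, edge.end), (edge.end, edge.start)):
                if there in leaving_nodes and here not in leaving_nodes:
                    m = node_map.get(here)
                    if m is not None and m in product_maps:
                        roles[side_i].add(m)
    return {s: frozenset(v) for s, v in roles.items()}


def translate_transform(
    transform_text: str,
    tmap: Optional[TranslationMap] = None,
    adjustments: Optional[dict[int, list[dict]]] = None,
) -> list[ReactionRule]:
    """Translate one transform file into reaction rules.

    One rule is produced per (pattern alternative x fusion variant).
    Registered adjustments -- declarative per-transform pattern patches --
    are applied to the emitted SMARTS before compilation.
    """
    tmap = tmap or TranslationMap.default()
    adjustments = adjustments or {}
    src = parse_transform_file(transform_text)
    context = f"transform {src.transform_id}"
    rules: list[ReactionRule] = []
    for alt_i, (sides_text, product_text) in enumerate(src.alternatives):
        side_graphs = [parse_pattern(s) for s in sides_text]
        product_graph = parse_pattern(product_text)

        node_maps: list[dict[int, int]] = []
        side_of_map: dict[int, int] = {}
        for side_i, graph in enumerate(side_graphs, start=1):
            node_map: dict[int, int] = {}
            for node in graph.nodes:
                if node.map_number is not None:
                    if node.map_number in side_of_map:
                        raise ProductPatternError(
                            f"duplicate map number {node.map_number} in {context}"
                        )
                    node_map[node.index] = node.map_number
                    side_of_map[node.map_number] = side_i
            node_maps.append(node_map)

        # product maps are implicit by node order, starting at one
        for node in product_graph.nodes:
            if node.map_number is not None:
                raise ProductPatternError(f"explicit map in product pattern of {context}")
        product_maps = frozenset(range(1, len(product_graph.nodes) + 1))
        missing = product_maps - set(side_of_map)
        if missing:
            raise ProductPatternError(
                f"product maps {sorted(missing)} missing from reactants in {context}"
            )

        formed: list[tuple[int, int, str]] = []
        intra: list[tuple[int, int, str]] = []
        for edge in product_graph.edges:
            ma, mb = edge.start + 1, edge.end + 1
            if side_of_map[ma] != side_of_map[mb]:
                formed.append((ma, mb, edge.bond_text))
            else:
                intra.append((ma, mb, edge.bond_text))

        roles = _compute_roles(side_graphs, node_maps, product_maps, formed, intra)
        product_smarts = emit_smarts(
            product_graph,
            tmap,
            maps={i: i + 1 for i in range(len(product_graph.nodes))},
            product_side=True,
            context=context,
        )

        variant_lists = [expand_fusion_variants(g, tmap) for g in side_graphs]
        multi = len(src.alternatives) > 1
        for combo in itertools.product(*variant_lists):
            graphs = [c[0] for c in combo]
            tags = [c[1] for c in combo]
            tag_parts = ([f"p{alt_i}"] if multi else []) + [
                f"f{side_i}{t}" for side_i, t in enumerate(tags, start=1) if t
            ]
            variant_tag = ".".join(tag_parts)
            reactant_smarts = [
                emit_smarts(g, tmap, maps=node_maps[i], context=context)
                for i, g in enumerate(graphs)
            ]
            for patch in adjustments.get(src.transform_id, []):
                target = patch["target"]
                if target == "product":
                    product_patched = product_smarts.replace(patch["old"], patch["new"])
                else:
                    idx = int(target.replace("reactant", "")) - 1
                    reactant_smarts[idx] = reactant_smarts[idx].replace(
                        patch["old"], patch["new"]
                    )
                if target == "product":
                    product_smarts = product_patched
            rule = ReactionRule(
                transform_id=src.transform_id,
                name=src.name,
                reactant_smarts=reactant_smarts,
                product_smarts=product_smarts,
                variant_tag=variant_tag,
                side_of_map=dict(side_of_map),
                product_maps=product_maps,
                formed_bonds=formed,
                intra_changes=intra,
                role_maps=roles,
                reactant_graphs=graphs,
                product_graph=product_graph,
                reactant_node_maps=node_maps,
            )
            rule.reactant_queries()
            rule.product_query()
            rules.append(rule)
    return rules


@dataclass
class KillStatement:
    """One translated KILL statement.

    ``smarts`` entries are alternatives (OR) within one side; entries
    anchored on different sides are conjoined (AND) at pairing time.  A
    leading ``!`` on an entry negates it ("absence of ...").  ``goto``
    redirects traversal to the given statement index when the statement
    triggers; without a goto, triggering is a KILL verdict.
    """

    index: int
    smarts: list[str]
    scope: str  # 'ONPATH' | 'OFFPATH'
    participants: list[int]
    goto: Optional[int] = None
    sides: frozenset[int] = frozenset()

    def entry_maps(self) -> list[frozenset[int]]:
        """Map numbers referenced by each SMARTS entry (via isotope labels)."""
        out = []
        for entry in self.smarts:
            body = entry[1:] if entry.startswith("!") else entry
            query = Chem.MolFromSmarts(body)
            labels = frozenset(
                a.GetIsotope() - ISOTOPE_OFFSET
                for a in query.GetAtoms()
                if a.GetIsotope() > ISOTOPE_OFFSET
            )
            out.append(labels)
        return out


@dataclass
class KillRuleSet:
    transform_id: int
    statements: list[KillStatement] = field(default_factory=list)
    untranslatable: list[str] = field(default_factory=list)

    def bind_sides(self, side_of_map: dict[int, int]) -> None:
        """Derive each statement's reactant sides from its participants."""
        for stmt in self.statements:
            sides = set()
            for p in stmt.participants:
                if p not in side_of_map:
                    raise ValueError(
                        f"KILL statement {stmt.index} of transform "
                        f"{self.transform_id} references unknown map {p}"
                    )
                sides.add(side_of_map[p])
            stmt.sides = frozenset(sides)
        for kw in self.untranslatable:
            logger.warning(
                "transform %s: KILL keyword %r is untranslatable; statements "
                "using it are skipped",
                self.transform_id,
                kw,
            )


def load_kill_ruleset(source: Union[str, dict]) -> KillRuleSet:
    """Load and validate a KILL ruleset from a JSON file path or dict.

    Schema: ``{"transform": int, "statements": [{"index": int,
    "smarts": [str], "scope": "ONPATH"|"OFFPATH", "participants": [int],
    "goto": int|null}], "untranslatable": [str]}``.
    """
    if isinstance(source, str):
        with open(source) as handle:
            raw = json.load(handle)
    else:
        raw = source
    statements = []
    seen: set[int] = set()
    for s in raw.get("statements", []):
        stmt = KillStatement(
            index=int(s["index"]),
            smarts=list(s["smarts"]),
            scope=s["scope"],
            participants=[int(p) for p in s["participants"]],
            goto=s.get("goto"),
        )
        if stmt.scope not in ("ONPATH", "OFFPATH"):
            raise ValueError(f"bad scope {stmt.scope!r} in statement {stmt.index}")
        if not stmt.smarts:
            raise ValueError(f"statement {stmt.index} has no SMARTS entries")
        for entry in stmt.smarts:
            body = entry[1:] if entry.startswith("!") else entry
            if Chem.MolFromSmarts(body) is None:
                raise ValueError(
                    f"statement {stmt.index}: SMARTS does not compile: {entry!r}"
                )
        if stmt.index in seen:
            raise ValueError(f"duplicate statement index {stmt.index}")
        seen.add(stmt.index)
        statements.append(stmt)
    statements.sort(key=lambda s: s.index)
    indices = {s.index for s in statements}
    for stmt in statements:
        if stmt.goto is not None and stmt.goto not in indices:
            raise ValueError(
                f"statement {stmt.index}: GOTO {stmt.goto} does not target an "
                "existing statement"
            )
        if stmt.goto is not None and stmt.goto <= stmt.index:
            # forward jumps only: backward jumps would allow traversal cycles
            raise ValueError(
                f"statement {stmt.index}: backward GOTO {stmt.goto} is unsupported"
            )
    return KillRuleSet(
        transform_id=int(raw["transform"]),
        statements=statements,
        untranslatable=list(raw.get("untranslatable", [])),
    )
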