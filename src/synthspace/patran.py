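"""Tokenizer and graph builder for PATRAN-style transform patterns.

A transform pattern side is broken into classified components (ATOM,
PROPERTY, BOND, FUSION, START_SIDECHAIN, END_SIDECHAIN, RING) and assembled
into a pattern graph: an ordered node list (atoms with their properties,
branch level and optional map number) and an edge list (bonds with their
properties).  Edge orientation distinguishes bond roles: sequential bonds
run from a lower to a higher node index, ring closures from a higher to a
lower one.

The token syntax itself lives in ``data/patran_grammar.json`` and is applied
table-driven, so the grammar can be corrected without touching code.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

__all__ = [
    "ComponentKind",
    "Component",
    "PatternNode",
    "PatternEdge",
    "PatternGraph",
    "PatternError",
    "tokenize_pattern",
    "build_pattern_graph",
    "parse_pattern",
    "TransformSource",
    "parse_transform_file",
]


class ComponentKind(Enum):
    ATOM = "ATOM"
    PROPERTY = "PROPERTY"
    BOND = "BOND"
    FUSION = "FUSION"
    START_SIDECHAIN = "START_SIDECHAIN"
    END_SIDECHAIN = "END_SIDECHAIN"
    RING = "RING"


@dataclass(frozen=True)
class Component:
    kind: ComponentKind
    text: str
    position: int


@dataclass
class PatternNode:
    index: int
    atom_text: str
    properties: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    branch_level: int = 0
    map_number: Optional[int] = None


@dataclass
class PatternEdge:
    start: int
    end: int
    bond_text: str
    properties: list[str] = field(default_factory=list)

    @property
    def is_ring_closure(self) -> bool:
        return self.start > self.end


@dataclass
class PatternGraph:
    """Node/edge representation of one pattern side.

    ``events`` records the linear reading order (atoms, branch markers,
    bonds, ring digits) so SMARTS emission can replay the source layout:
    the pattern and its translation keep the same element order.
    """

    nodes: list[PatternNode] = field(default_factory=list)
    edges: list[PatternEdge] = field(default_factory=list)
    events: list[tuple] = field(default_factory=list)


class PatternError(ValueError):
    """Tokenization or graph-construction failure, carrying a position."""


class _Grammar:
    _instance: Optional["_Grammar"] = None

    def __init__(self) -> None:
        raw = json.loads(
            resources.files("synthspace.data").joinpath("patran_grammar.json").read_text()
        )
        self.tokens = [(ComponentKind(t["kind"]), re.compile(t["regex"])) for t in raw["tokens"]]

    @classmethod
    def get(cls) -> "_Grammar":
        if cls._instance is None:
            cls._instance = cls()
        return cls._instance


def tokenize_pattern(pattern: str) -> list[Component]:
    """Break one pattern side into classified components.

    Concatenating component texts in order reproduces the input up to
    whitespace.  Unknown segments raise :class:`PatternError` with the
    offending position.
    """
    grammar = _Grammar.get()
    components: list[Component] = []
    pos = 0
    n = len(pattern)
    while pos < n:
        if pattern[pos].isspace():
            pos += 1
            continue
        for kind, regex in grammar.tokens:
            match = regex.match(pattern, pos)
            if match:
                components.append(Component(kind, match.group(0), pos))
                pos = match.end()
                break
        else:
            raise PatternError(f"unknown token at position {pos}: {pattern[pos:pos + 8]!r}")
    return components


_PROP_RE = re.compile(r"^(NOT\s+)?([A-Z][A-Z*]*)\s*(?:([:<>])\s*(.*))?$")


def _parse_property(text: str) -> tuple[str, tuple[str, ...]]:
    """``[NOT FGS:KETONE,ESTER]`` -> ("NOT FGS", ("KETONE", "ESTER")).

    Comparator forms keep the operator as the first argument:
    ``[HS>1]`` -> ("HS", (">", "1")).
    """
    inner = text[1:-1].strip()
    m = _PROP_RE.match(inner)
    if not m:
        raise PatternError(f"malformed property {text!r}")
    neg, keyword, op, args = m.groups()
    keyword = ("NOT " if neg else "") + keyword
    if op is None:
        return keyword, ()
    if op == ":":
        return keyword, tuple(a.strip() for a in args.split(","))
    return keyword, (op, args.strip())


def build_pattern_graph(components: list[Component]) -> PatternGraph:
    """Assemble the pattern graph from a component list.

    Properties attach to the preceding atom (or, for bond/fusion
    properties, to the pending bond); side-chain markers adjust the branch
    level; RING components pair up into ring-closure edges with start node
    succeeding end node.
    """
    graph = PatternGraph()
    branch_stack: list[int] = []
    prev_atom: Optional[int] = None
    pending_bond: Optional[tuple[str, list[str]]] = None
    after_bond = False
    ring_open: dict[str, tuple[int, str, list[str]]] = {}
    depth = 0

    def close_bond(start: int, end: int) -> int:
        text, props = pending_bond if pending_bond is not None else ("-", [])
        graph.edges.append(PatternEdge(start=start, end=end, bond_text=text, properties=props))
        return len(graph.edges) - 1

    for comp in components:
        if comp.kind is ComponentKind.ATOM:
            text = comp.text
            map_number = None
            if "^" in text:
                text, map_text = text.split("^")
                map_number = int(map_text)
            node = PatternNode(
                index=len(graph.nodes),
                atom_text=text,
                branch_level=depth,
                map_number=map_number,
            )
            graph.nodes.append(node)
            if prev_atom is not None:
                ei = close_bond(prev_atom, node.index)
                graph.events.append(("bond", ei))
            pending_bond = None
            after_bond = False
            prev_atom = node.index
            graph.events.append(("atom", node.index))
        elif comp.kind is ComponentKind.BOND:
            if pending_bond is not None:
                raise PatternError(f"consecutive bonds at position {comp.position}")
            pending_bond = (comp.text, [])
            after_bond = True
        elif comp.kind is ComponentKind.FUSION:
            if pending_bond is None:
                raise PatternError(f"fusion property without a bond at position {comp.position}")
            keyword = comp.text[1:-1].strip()
            pending_bond[1].append(keyword)
        elif comp.kind is ComponentKind.PROPERTY:
            if after_bond and pending_bond is not None:
                keyword, args = _parse_property(comp.text)
                pending_bond[1].append(keyword)
            else:
                if prev_atom is None:
                    raise PatternError(
                        f"property before any atom at position {comp.position}"
                    )
                graph.nodes[prev_atom].properties.append(_parse_property(comp.text))
        elif comp.kind is ComponentKind.START_SIDECHAIN:
            if prev_atom is None:
                raise PatternError(f"branch before any atom at position {comp.position}")
            branch_stack.append(prev_atom)
            depth += 1
            graph.events.append(("open",))
        elif comp.kind is ComponentKind.END_SIDECHAIN:
            if not branch_stack:
                raise PatternError(f"unbalanced ')' at position {comp.position}")
            prev_atom = branch_stack.pop()
            depth -= 1
            pending_bond = None
            after_bond = False
            graph.events.append(("close",))
        elif comp.kind is ComponentKind.RING:
            digit = comp.text[1]
            if prev_atom is None:
                raise PatternError(f"ring digit before any atom at position {comp.position}")
            if digit in ring_open:
                open_atom, text, props = ring_open.pop(digit)
                if open_atom == prev_atom:
                    raise PatternError(f"ring closure to itself at position {comp.position}")
                bond_text, bond_props = (
                    pending_bond if pending_bond is not None else (text, props)
                )
                graph.edges.append(
                    PatternEdge(
                        start=prev_atom,
                        end=open_atom,
                        bond_text=bond_text,
                        properties=bond_props,
                    )
                )
                pending_bond = None
                graph.events.append(("ring", digit, len(graph.edges) - 1))
            else:
                text, props = pending_bond if pending_bond is not None else ("-", [])
                ring_open[digit] = (prev_atom, text, props)
                pending_bond = None
                graph.events.append(("ring", digit, None))
    if branch_stack:
        raise PatternError("unbalanced '(' in pattern")
    if ring_open:
        raise PatternError(f"unclosed ring digits: {sorted(ring_open)}")
    if pending_bond is not None:
        raise PatternError("dangling bond at end of pattern")
    return graph


def parse_pattern(pattern: str) -> PatternGraph:
    """Tokenize and build in one step."""
    return build_pattern_graph(tokenize_pattern(pattern))


@dataclass
class TransformSource:
    """One transform file: id, name and pattern alternatives.

    Each alternative is ``(reactant_sides, product_side)`` where
    ``reactant_sides`` holds one or two pattern strings.  A file may carry
    several PATTERN lines; each is translated to its own reaction rule.
    """

    transform_id: int
    name: str
    alternatives: list[tuple[list[str], str]] = field(default_factory=list)


def parse_transform_file(text: str) -> TransformSource:
    transform_id: Optional[int] = None
    name = ""
    alternatives: list[tuple[list[str], str]] = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("TRANSFORM"):
            transform_id = int(line.split(None, 1)[1])
        elif line.startswith("NAME"):
            name = line.split(None, 1)[1]
        elif line.startswith("PATTERN"):
            body = line.split(None, 1)[1]
            if "=>" not in body:
                raise PatternError(f"PATTERN line without '=>': {line!r}")
            lhs, product = (part.strip() for part in body.split("=>"))
            sides = [s.strip() for s in lhs.split(" + ")]
            if not 1 <= len(sides) <= 2:
                raise PatternError(f"expected 1-2 reactant sides, got {len(sides)}")
            alternatives.append((sides, product))
        else:
            raise PatternError(f"unrecognized transform line: {line!r}")
    if transform_id is None:
        raise PatternError("transform file lacks a TRANSFORM id line")
    if not alternatives:
        raise PatternError("transform file lacks PATTERN lines")
    return TransformSource(transform_id=transform_id, name=name, alternatives=alternatives)
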