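"""Molecule standardization and the switchable aromaticity model.

Building blocks pass through this module before any pattern matching:
explicit hydrogens and disconnected salt/metal components are removed,
charge conventions are normalized (carboxylates protonated, charge-separated
sulfoxides neutralized), organometallics and overweight molecules are
rejected, protecting groups can be stripped, and aromaticity is perceived
under one of two models:

* ``DEFAULT`` -- RDKit's default perception, in which rings bearing an
  exocyclic double bond to O, N or S (2-pyridone and friends) stay aromatic.
* ``CACTVS`` -- a stricter model in which any fused ring system carrying an
  exocyclic double bond is treated as non-aromatic and written with
  alternating single/double bonds, so valence states remain explicit.

The choice of model changes what the emitted reaction SMARTS match, because
translated patterns constrain elements (``[#6]``) rather than aromaticity:
the perception step, not the pattern, decides whether ``-`` and ``=`` bonds
are present.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional, Union

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "AromaticityModel",
    "Rejection",
    "StandardizationReport",
    "AromaticityError",
    "standardize",
    "standardize_collection",
    "perceive_aromaticity",
    "check_valence",
    "remove_protecting_groups",
    "molecular_weight",
    "mass_microdaltons",
    "read_molecules",
    "write_smiles",
    "canonical_smiles",
]


class AromaticityModel(enum.Enum):
    """Which aromaticity perception is applied before matching."""

    CACTVS = "cactvs"
    DEFAULT = "default"


class AromaticityError(ValueError):
    """No consistent Kekulé assignment exists for a ring system."""


@dataclass(frozen=True)
class Rejection:
    """A building block removed during standardization."""

    source_id: str
    reason: str  # 'organometallic' | 'overweight' | 'parse_error'


@dataclass
class StandardizationReport:
    input_count: int = 0
    retained_count: int = 0
    rejections: list[Rejection] = field(default_factory=list)

    def check(self) -> None:
        assert self.input_count == self.retained_count + len(self.rejections)


# Average atomic masses (standard atomic weights) in integer microdaltons.
# Integer masses make synthon-sum and whole-product mass computations
# bit-identical, which the histogram convolution relies on.
ATOMIC_MASS_U: dict[str, int] = {
    "H": 1_008_000, "Li": 6_940_000, "B": 10_810_000, "C": 12_011_000,
    "N": 14_007_000, "O": 15_999_000, "F": 18_998_403, "Na": 22_989_769,
    "Mg": 24_305_000, "Al": 26_981_538, "Si": 28_085_000, "P": 30_973_762,
    "S": 32_060_000, "Cl": 35_450_000, "K": 39_098_300, "Ca": 40_078_000,
    "Ti": 47_867_000, "Cr": 51_996_100, "Mn": 54_938_044, "Fe": 55_845_000,
    "Co": 58_933_194, "Ni": 58_693_400, "Cu": 63_546_000, "Zn": 65_380_000,
    "Ga": 69_723_000, "Ge": 72_630_000, "As": 74_921_595, "Se": 78_971_000,
    "Br": 79_904_000, "Zr": 91_224_000, "Mo": 95_950_000, "Ru": 101_070_000,
    "Pd": 106_420_000, "Ag": 107_868_200, "Cd": 112_414_000,
    "In": 114_818_000, "Sn": 118_710_000, "Sb": 121_760_000,
    "I": 126_904_470, "Pt": 195_084_000, "Au": 196_966_569,
    "Hg": 200_592_000, "Pb": 207_200_000, "Bi": 208_980_400,
}

_ALKALI = {"Li", "Na", "K", "Rb", "Cs"}
_ALKALINE_EARTH = {"Be", "Mg", "Ca", "Sr", "Ba"}
_TRANSITION = {
    "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Y", "Zr", "Nb",
    "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "Hf", "Ta", "W", "Re", "Os",
    "Ir", "Pt", "Au", "Hg",
}
_POST_TRANSITION = {"Al", "Ga", "In", "Tl", "Pb", "Bi"}

# Zn, Sn and B are deliberately NOT metals here: boronic acids must survive
# (cross-coupling transforms consume them) and organozinc/organotin reagents
# are treated as carbon reagents rather than discarded.
DEFAULT_METAL_SET: frozenset[str] = frozenset(
    (_ALKALI | _ALKALINE_EARTH | _TRANSITION | _POST_TRANSITION) - {"Zn"}
)

# Allowed total valence per (element symbol, formal charge).  A NAOMI-like
# organic subset: an uncharged nitrogen with four bonds or a carbon with five
# is invalid.  Elements without an entry are not constrained.
DEFAULT_VALENCE_TABLE: dict[tuple[str, int], frozenset[int]] = {
    ("C", 0): frozenset({4}),
    ("C", -1): frozenset({3}),
    ("N", 0): frozenset({3}),
    ("N", 1): frozenset({4}),
    ("N", -1): frozenset({2}),
    ("O", 0): frozenset({2}),
    ("O", -1): frozenset({1}),
    ("O", 1): frozenset({3}),
    ("S", 0): frozenset({2, 4, 6}),
    ("S", 1): frozenset({3}),
    ("P", 0): frozenset({3, 5}),
    ("B", 0): frozenset({3}),
    ("B", -1): frozenset({4}),
    ("Si", 0): frozenset({4}),
    ("F", 0): frozenset({1}),
    ("Cl", 0): frozenset({1}),
    ("Br", 0): frozenset({1}),
    ("I", 0): frozenset({1}),
    ("H", 0): frozenset({1}),
}


def mass_microdaltons(mol: Chem.Mol) -> int:
    """Average molecular mass in integer microdaltons (implicit H included).

    Dummy (link/mask) atoms contribute zero mass.
    """
    total = 0
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        sym = atom.GetSymbol()
        try:
            total += ATOMIC_MASS_U[sym]
        except KeyError:
            raise KeyError(f"no mass tabulated for element {sym!r}")
        total += atom.GetTotalNumHs() * ATOMIC_MASS_U["H"]
    return total


def molecular_weight(mol: Chem.Mol) -> float:
    """Molecular weight in g/mol from the package mass table."""
    return mass_microdaltons(mol) / 1e6


def _is_metal(atom: Chem.Atom, metal_set: frozenset[str]) -> bool:
    return atom.GetSymbol() in metal_set


def _neutralize_charges(mol: Chem.Mol) -> Chem.Mol:
    """Protonate carboxylates; convert charge-separated sulfoxides to S=O."""
    rw = Chem.RWMol(mol)
    # carboxylate O(-) -> OH
    patt = Chem.MolFromSmarts("[CX3](=[OX1])[O-]")
    for match in rw.GetMol().GetSubstructMatches(patt):
        o = rw.GetAtomWithIdx(match[2])
        if o.GetFormalCharge() == -1:
            o.SetFormalCharge(0)
            o.SetNumExplicitHs(o.GetTotalNumHs() + 1)
    # S(+)-O(-) single bond -> S=O
    patt = Chem.MolFromSmarts("[S+1]-[O-1]")
    for match in rw.GetMol().GetSubstructMatches(patt):
        s = rw.GetAtomWithIdx(match[0])
        o = rw.GetAtomWithIdx(match[1])
        bond = rw.GetBondBetweenAtoms(match[0], match[1])
        s.SetFormalCharge(0)
        o.SetFormalCharge(0)
        bond.SetBondType(Chem.BondType.DOUBLE)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def standardize(
    mol: Optional[Chem.Mol],
    mw_cap: float = 700.0,
    metal_set: Optional[frozenset[str]] = None,
    source_id: str = "",
) -> Union[Chem.Mol, Rejection]:
    """Standardize one building block or reject it with a reason code.

    Explicit hydrogens are removed, disconnected metal/salt components are
    stripped (the largest organic component is kept), carboxylates are
    protonated, charge-separated sulfoxides neutralized.  Molecules with a
    carbon-metal bond are rejected as ``organometallic``; molecules heavier
    than ``mw_cap`` (strict ``>``) as ``overweight``.
    """
    if metal_set is None:
        metal_set = DEFAULT_METAL_SET
    if mol is None:
        return Rejection(source_id, "parse_error")
    try:
        mol = Chem.RemoveHs(mol)
        Chem.SanitizeMol(mol)
    except Exception:
        return Rejection(source_id, "parse_error")

    # organometallic: any carbon-metal bond anywhere in the input
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if (a.GetAtomicNum() == 6 and _is_metal(b, metal_set)) or (
            b.GetAtomicNum() == 6 and _is_metal(a, metal_set)
        ):
            return Rejection(source_id, "organometallic")

    # salt stripping: a component is metal/salt if it has no carbon or only
    # metal atoms; keep the largest organic component
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = []
    for frag in frags:
        has_carbon = any(a.GetAtomicNum() == 6 for a in frag.GetAtoms())
        all_metal = all(_is_metal(a, metal_set) for a in frag.GetAtoms())
        if has_carbon and not all_metal:
            organic.append(frag)
    if not organic:
        return Rejection(source_id, "organometallic")
    organic.sort(key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))
    kept = organic[-1]
    Chem.SanitizeMol(kept)
    kept = _neutralize_charges(kept)
    if molecular_weight(kept) > mw_cap:
        return Rejection(source_id, "overweight")
    if mol.HasProp("_Name"):
        kept.SetProp("_Name", mol.GetProp("_Name"))
    return kept


def standardize_collection(
    mols: Iterable[tuple[Optional[Chem.Mol], str]],
    mw_cap: float = 700.0,
    metal_set: Optional[frozenset[str]] = None,
) -> tuple[list[tuple[Chem.Mol, str]], StandardizationReport]:
    """Standardize a collection; returns retained (mol, id) pairs + report."""
    report = StandardizationReport()
    retained: list[tuple[Chem.Mol, str]] = []
    for mol, mid in mols:
        report.input_count += 1
        result = standardize(mol, mw_cap=mw_cap, metal_set=metal_set, source_id=mid)
        if isinstance(result, Rejection):
            report.rejections.append(result)
        else:
            retained.append((result, mid))
            report.retained_count += 1
    report.check()
    return retained, report


def _ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Fused ring systems as atom-index sets (rings sharing an atom merge)."""
    systems: list[set[int]] = []
    for ring in mol.GetRingInfo().AtomRings():
        rs = set(ring)
        merged = [s for s in systems if s & rs]
        for s in merged:
            rs |= s
            systems.remove(s)
        systems.append(rs)
    return systems


def perceive_aromaticity(mol: Chem.Mol, model: AromaticityModel) -> Chem.Mol:
    """Re-perceive aromaticity under the chosen model.

    Under ``CACTVS``, any fused ring system in which a ring atom carries an
    exocyclic double bond is de-aromatized: its bonds are written as the
    Kekulé single/double assignment, so downstream SMARTS see explicit bond
    orders.  Under ``DEFAULT`` the RDKit perception is kept as-is.
    """
    mol = Chem.Mol(mol)
    Chem.SanitizeMol(mol)
    if model is AromaticityModel.DEFAULT:
        return mol

    kek = Chem.Mol(mol)
    try:
        Chem.Kekulize(kek, clearAromaticFlags=True)
    except Chem.KekulizeException as exc:
        raise AromaticityError(f"no Kekulé assignment: {exc}") from exc

    systems = _ring_systems(mol)
    deactivate: set[int] = set()
    for system in systems:
        for ai in system:
            atom = kek.GetAtomWithIdx(ai)
            for bond in atom.GetBonds():
                other = bond.GetOtherAtom(atom)
                if (
                    other.GetIdx() not in system
                    and bond.GetBondType() == Chem.BondType.DOUBLE
                ):
                    deactivate |= system
    if not deactivate:
        return mol

    out = kek
    for atom in out.GetAtoms():
        idx = atom.GetIdx()
        if mol.GetAtomWithIdx(idx).GetIsAromatic() and idx not in deactivate:
            atom.SetIsAromatic(True)
    for bond in out.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src = mol.GetBondBetweenAtoms(i, j)
        if src.GetIsAromatic() and i not in deactivate and j not in deactivate:
            bond.SetBondType(Chem.BondType.AROMATIC)
            bond.SetIsAromatic(True)
    Chem.SanitizeMol(
        out,
        Chem.SanitizeFlags.SANITIZE_ALL
        ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
    )
    return out


def check_valence(
    mol: Chem.Mol,
    table: Optional[dict[tuple[str, int], frozenset[int]]] = None,
) -> bool:
    """True iff every constrained atom is in an allowed valence state.

    Dummy (mask/link) atoms are skipped; elements without a table entry are
    not constrained.
    """
    if table is None:
        table = DEFAULT_VALENCE_TABLE
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            continue
        key = (atom.GetSymbol(), atom.GetFormalCharge())
        allowed = table.get(key)
        if allowed is None:
            continue
        if atom.GetTotalValence() not in allowed:
            return False
    return True


def _load_protecting_groups() -> list[dict]:
    text = resources.files("synthspace.data").joinpath("protecting_groups.json").read_text()
    return json.loads(text)


_PG_CACHE: Optional[list[tuple[str, AllChem.ChemicalReaction]]] = None


def _protecting_group_reactions() -> list[tuple[str, AllChem.ChemicalReaction]]:
    global _PG_CACHE
    if _PG_CACHE is None:
        _PG_CACHE = []
        for entry in _load_protecting_groups():
            rxn = AllChem.ReactionFromSmarts(entry["smirks"])
            _PG_CACHE.append((entry["name"], rxn))
    return _PG_CACHE


def remove_protecting_groups(mol: Chem.Mol) -> tuple[Chem.Mol, list[str]]:
    """Strip Boc/Fmoc/Cbz, t-Bu and benzyl esters, t-Bu ether and benzoate.

    Removal is exhaustive: the molecule is re-scanned until no group matches.
    Returns the deprotected molecule and the names of removed groups, in
    removal order.
    """
    removed: list[str] = []
    current = Chem.Mol(mol)
    changed = True
    while changed:
        changed = False
        for name, rxn in _protecting_group_reactions():
            products = rxn.RunReactants((current,))
            if not products:
                continue
            cand = products[0][0]
            try:
                Chem.SanitizeMol(cand)
            except Exception:  # pragma: no cover - malformed deprotection
                continue
            current = cand
            removed.append(name)
            changed = True
            break
    return current, removed


def canonical_smiles(mol: Chem.Mol, model: AromaticityModel = AromaticityModel.DEFAULT) -> str:
    """Canonical SMILES under the given aromaticity model."""
    return Chem.MolToSmiles(perceive_aromaticity(mol, model))


def read_molecules(path: str) -> Iterator[tuple[Optional[Chem.Mol], str]]:
    """Read (mol, id) pairs from a .smi (SMILES [tab id]) or .sdf file.

    Unparsable records yield ``(None, id)`` so standardization can report
    them as ``parse_error`` instead of dropping them silently.
    """
    if path.endswith((".sdf", ".mol")):
        supplier = Chem.SDMolSupplier(path, removeHs=True)
        for i, mol in enumerate(supplier):
            mid = mol.GetProp("_Name") if mol is not None and mol.HasProp("_Name") else f"sdf_{i}"
            yield mol, mid
        return
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mid = parts[1] if len(parts) > 1 else f"smi_{i}"
            yield Chem.MolFromSmiles(smiles), mid


def write_smiles(mols: Iterable[tuple[Chem.Mol, str]], path: str) -> None:
    with open(path, "w") as handle:
        for mol, mid in mols:
            handle.write(f"{Chem.MolToSmiles(mol)}\t{mid}\n")
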