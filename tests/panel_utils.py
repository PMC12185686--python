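"""Shared harness: run the semantic molecule panel for the translation map."""

import json
from importlib import resources

from rdkit import Chem

from synthspace.patran import parse_pattern
from synthspace.transpiler import TranslationMap, emit_smarts, expand_fusion_variants


def load_panel():
    text = resources.files("synthspace.data").joinpath("fg_panel.json").read_text()
    return json.loads(text)


def panel_queries(entry, tmap: TranslationMap):
    if entry["kind"] == "group":
        return [Chem.MolFromSmarts(f"[$({tmap.functional_group[entry['key']]})]")]
    graph = parse_pattern(entry["pattern"])
    if entry["kind"] == "fusion_neg":
        return [
            Chem.MolFromSmarts(emit_smarts(v, tmap))
            for v, _tag in expand_fusion_variants(graph, tmap)
        ]
    return [Chem.MolFromSmarts(emit_smarts(graph, tmap))]


def run_semantic_panel():
    """Returns a list of (entry key, kind, smiles) failures; empty = pass."""
    tmap = TranslationMap.default()
    failures = []
    for entry in load_panel():
        queries = panel_queries(entry, tmap)
        if any(q is None for q in queries):
            failures.append((entry["key"], "compile", entry.get("pattern", "")))
            continue
        for smi in entry["positives"]:
            mol = Chem.MolFromSmiles(smi)
            if mol is None or not any(mol.HasSubstructMatch(q) for q in queries):
                failures.append((entry["key"], "positive", smi))
        for smi in entry["negatives"]:
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                failures.append((entry["key"], "parse", smi))
            elif entry["kind"] == "fusion_neg":
                if all(mol.HasSubstructMatch(q) for q in queries):
                    failures.append((entry["key"], "negative", smi))
            elif any(mol.HasSubstructMatch(q) for q in queries):
                failures.append((entry["key"], "negative", smi))
    return failures


def covered_keys():
    panel = load_panel()
    return {e["key"] for e in panel}
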