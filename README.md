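# synthspace

Reaction-driven combinatorial fragment spaces built from retrosynthesis-style
transform rules.

Make-on-demand compound collections reach billions of molecules; storing and
searching them as explicit product lists does not scale. A *fragment space*
stores the same library implicitly: each two-component reaction contributes
two sets of pre-processed reactants ("synthons", fragments carrying typed
dummy link atoms) plus a connection rule, and products exist only on demand.
`synthspace` implements the full construction pipeline for rule sets written
in a PATRAN-style pattern language with CHMTRN-style KILL filter statements
(the LHASA transform tradition), targeting users who want to turn a
curated reaction corpus plus a building-block catalog into a searchable
virtual library on a desktop machine.

The pipeline:

1. **Transpile** — tokenize each transform pattern into classified components,
   build a node/edge pattern graph, and translate it category-by-category
   (atoms, atom properties, functional groups, bonds, bond properties) into
   reaction SMARTS. Properties without a SMARTS counterpart become recursive
   expressions; open numeric ranges are enumerated; fusion-bond properties are
   transferred to the incident atoms as ring-connectivity annotations, with
   negated fusion edges splitting the rule into two sub-reaction variants.
2. **Filter reactants** — standardize building blocks (salt stripping,
   carboxylate protonation, organometallic and >700 g/mol rejection), perceive
   aromaticity under a switchable model, apply the single-match rule under one
   of two duplicate policies, and evaluate the translated KILL statements on
   masked reactant variants (ONPATH on the leaving-group-masked reactant,
   OFFPATH on a variant with backbone bonds cut). Statements spanning both
   reactants split the reaction into sub-reactions grouped by KILL-path
   signature, so that within each sub-reaction pure combinatorial pairing is
   valid.
3. **Encode the space** — convert survivors into synthons with typed link
   atoms and support exact big-integer counting, seeded sampling without
   replacement, membership tests by retro-decomposition, retro-validation of
   products, and bin-exact histograms of additive descriptors (molecular
   weight, H-bond donors/acceptors, a rotatable-bond proxy) computed by
   convolving the per-side value multisets — never enumerating the space.

For a sub-reaction with synthon sets $S_1, S_2$ the product count is
$|S_1|\cdot|S_2|$, a space's count is the sum over its sub-reactions, and an
additive descriptor $d$ with per-side values $d(s)$ has the exact histogram

$$H[b] \;=\; \sum_{s_1\in S_1}\sum_{s_2\in S_2}
\mathbf{1}\{\,d(s_1)+d(s_2)+\delta_{\text{link}} \in b\,\},$$

evaluated in $O((|S_1|+\text{bins})\log|S_2|)$ by sorting and binary search.
Masses are carried as integer microdaltons so fragment sums equal
whole-product recomputation bit-exactly.

## Worked example

The package ships a toy transform corpus (amide coupling, biaryl coupling,
pyrazole condensation, amine arylation, a symmetric alkene pattern and a
fusion-split coupling, with hand-translated KILL rulesets) and a synthetic
building-block generator, so the whole pipeline runs without downloads:

```bash
synthspace fixtures-generate --seed 5 --out bbs.smi
synthspace build-space --transforms transforms/ --kills kills/ \
    --bbs bbs.smi --policy space --aromaticity default --out demo_space
# standardized 76 blocks: 73 retained, 3 rejected
# built 4 sub-reactions; 278 products
synthspace count --space demo_space
# 278
synthspace enumerate --space demo_space --limit 2 --seed 1
# CCNC(=O)c1ccccc1      t9001_base_0  primary_amine_3      carboxylic_acid_1
# CCC(=O)NCCOc1ccccc1   t9001_base_1  amine_gamma_ether_0  carboxylic_acid_2
# ...
synthspace props --space demo_space --descriptor MW --bins 0,150,250,350,1000
# [0, 150): 13
# [150, 250): 178
# [250, 350): 85
# [350, 1000): 2
# total 278
```

The three rejected blocks are two organometallics and one overweight
molecule. The amide transform appears as *two* sub-reactions
(`t9001_base_0/1`) because one of its KILL statements couples both reactants:
amines carrying a γ-ether are only compatible with non-benzylic acids, and the
signature grouping keeps exactly those pairings apart. Product counts equal
the number of synthon pairs, the histogram total equals the count, and every
enumerated product can be looked up again:

```bash
synthspace contains --space demo_space --smiles 'CCNC(=O)c1ccccc1'
# {"graph_id": "t9001_base_0", "transform_id": 9001, ... "bb1": "primary_amine_3", "bb2": "carboxylic_acid_1"}
```

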