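# Methods

This note records the model the package implements, the choices made where
the design was genuinely open, and what the tests do and do not demonstrate.

## Pattern language and transpilation

Transform files carry one reaction per file: an id, a name, and one or more
`PATTERN` lines of the form `side1 + side2 => product`. The tokenizer is
table-driven from `data/patran_grammar.json`; the token syntax (bracketed
properties, `^n` map labels on reactant atoms, `%d` ring closures, SMILES-like
parentheses) is this package's own fixing of the pattern micro-grammar, while
the keyword vocabulary — `HS` (bonded hydrogens), `HETS` (neighboring
heteroatoms), `FGS`/`NOT FGS` (functional-group presence/absence), `ARYL`,
`RING`, `TRIALKYL`, the `FUSION` family — is the transform language's.
Product-side atom maps are implicit by node order starting at one; reactant
maps must be a superset of product maps, and reactant atoms without a product
counterpart are the leaving group.

Translation is category-driven from `data/translation_map.json`:

* **Atoms** translate to atomic-number primitives (`C` → `#6`), deliberately
  aromaticity-neutral: whether a pattern bond matches depends on the
  *perceived* structure, so the aromaticity model (below), not the pattern,
  decides borderline matches.
* **Atom properties.** Exact H counts become `Hn`; open ranges are enumerated
  to the maximal organic connectivity of 4 (`HS>1` → `H2,H3,H4`), since
  classic SMARTS has no range syntax. Heteroatom-neighbor counts are built
  from recursive "at least k" expressions; exact k is "at least k and not at
  least k+1". Functional-group presence OR-joins recursive templates,
  absence AND-joins their negations.
* **Bond properties.** SMARTS bonds express only type and cyclicity, so the
  fusion-bond property ("shared by two rings") is approximated on the
  incident atoms as ring-connectivity `x3,x4`. This over-matches: on
  phenanthrene the pattern finds three bonds where only two are true fusion
  bonds (the bridgehead–bridgehead bond of the central ring is the false
  positive). The suite pins this as expected behavior rather than silently
  "fixing" it — the approximation is inherent to SMARTS. A *negated* fusion
  annotation on both incident atoms would be contradictory in fused systems,
  so each negated-fusion edge duplicates the pattern (annotation on one atom,
  then on the other); the variants multiply across edges and each becomes its
  own sub-reaction. A building block matched by several variants of one
  transform is assigned to the first variant only, which the pair-uniqueness
  oracle enforces.
* **Emission** replays the pattern's reading order, so pattern and SMARTS
  keep the same element order; every emitted string must compile, and the
  unit surface for the whole map is a molecule panel (`data/fg_panel.json`)
  with positive and negative examples per entry.

Per-transform **adjustments** are declarative patches (string rewrites keyed
by transform id) applied to emitted SMARTS, so rule-set variants are data,
not code. In the product pattern only the H count and an explicit aromatic
flag are admitted; the aromatic flags are required when a ring is formed, so
the emitted product SMARTS matches the aromatized assembled product.

## Chemistry model

Standardization removes explicit hydrogens, strips disconnected metal/salt
components (a component with no carbon, or only metal atoms; the largest
organic component is kept), protonates carboxylates, neutralizes
charge-separated sulfoxides, rejects molecules with a carbon–metal bond and
molecules heavier than 700 g/mol (strict `>`; the cap is applied to the
desalted, still-protected structure). The metal set excludes B, Zn and Sn so
boronic acids and common organozinc/organotin reagents survive; it is
configurable. Valence checking is table-driven over (element, charge) →
allowed total valences, a NAOMI-like organic subset in which uncharged N(4)
and C(5) are invalid.

Two aromaticity models are supported. `DEFAULT` keeps RDKit's perception
(2-pyridone aromatic). `CACTVS` de-aromatizes any fused ring *system* in
which a ring atom carries an exocyclic double bond and writes it in the
Kekulé single/double assignment, so atomic valence states stay explicit; a
ring system with no consistent Kekulé assignment raises. System-level (not
per-ring) treatment was chosen because partial flag-clearing on fused systems
produces chemically inconsistent flag sets.

Protecting groups (Boc, Fmoc, Cbz on N; t-Bu and benzyl esters on carboxyl;
t-Bu ether and benzoate on hydroxyl) are bundled as anchored SMIRKS in
`data/protecting_groups.json` and removed exhaustively by re-scanning until
no group matches. In space construction, deprotection is applied to the
*fragment* after matching and masking — the protected form is what the
pattern matched, the free form is what the synthon stores.

## KILL statements

Translated KILL statements are hand-curated data in a JSON schema
(`{"transform", "statements": [{"index", "smarts", "scope", "participants",
"goto"}], "untranslatable"}`). Loading validates SMARTS compilation and GOTO
targets (forward jumps only; backward jumps would allow cycles and are
rejected). Keywords that cannot be expressed in SMARTS at all (e.g.
comparative steric conditions) are recorded in `untranslatable` and logged at
load, never silently dropped.

Statement semantics, fixed here because the source language has examples but
no grammar: within one statement, SMARTS entries anchored on the same
reactant side are alternatives (OR — e.g. the several positional cases of an
electron-withdrawing-group condition); entries on different sides are
conjoined (AND — "H on atom 2 *and* no carbon alpha to atom 4"); a leading
`!` negates an entry. Participant atoms are referenced by isotope labels at
map + 100, matching the masked-reactant labeling.

Evaluation per reactant builds two representations: variant **a** with the
leaving group replaced by dummy mask atoms (so patterns cannot match into
what will not exist in the product) and the backbone labeled; variant **b**
with all backbone-internal bonds additionally cut, used for OFFPATH
statements, which must not match along the reaction-defined substructure.
Traversal follows statement order; a triggered statement jumps to its GOTO
target or kills. Statements that depend on the partner reactant branch the
traversal: a reactant is killed outright only if *every* branch dies, and
otherwise its branch outcomes form a KILL-path signature. Reactants with
equal signatures are interchangeable, so sub-reactions are built by grouping
side-1 signatures into rows of their compatibility with side-2 signature
groups (compatibility = deterministic joint traversal survives); each
distinct row becomes one sub-reaction. Every side-1 reactant lies in exactly
one row, so no pair is generated twice, and the union over sub-reactions is
exactly the KILL-consistent pair set.

**Known approximation class.** A KILL pattern that only exists once the two
reactants are joined (its atoms span the formed bond through unmapped
environment) cannot trigger at the reactant level; product-level filtering
would remove such pairs while the space keeps them. The suite constructs
such a case deliberately and pins the exact divergence. Similarly, OFFPATH
patterns that depend on ring context created or destroyed by the reaction
(ring perception differs between the cut reactant variant and the product)
can diverge; the toy rulesets avoid this class, and real rulesets should
document statements of this kind.

## Fragment space

Synthons are built from the surviving match: leaving atoms (and fragments
connected only through them) are deleted, intra-side bond-order edits from
the product pattern applied, and one typed dummy link atom attached per
formed bond, with the product pattern's bond order. Link types pair the two
sides of each sub-reaction; ring-forming transforms use two link atoms per
synthon with paired types. A fragment whose implied product environment
violates the valence table is dropped with a reason. Counting is exact
integer arithmetic; sampling without replacement uses index arithmetic over
the pair lattice (pair k ↦ (k ÷ |S₂|, k mod |S₂|)) and a seeded RNG, so a
fixed seed reproduces the sample byte-for-byte.

Membership (`contains`) cuts the query at bonds matching the product
pattern's formed-bond environment — both orientations of symmetric matches
are tried — installs link atoms, canonicalizes the two pieces under the
space's aromaticity model and looks them up in per-side SMILES indexes; on
the fixture spaces this is exact (no false positives or negatives against
full enumeration). Retro-validation additionally requires the product to
match the product pattern and to decompose into exactly the recorded
synthons, which rejects regiochemistry the product pattern forbids.

Histograms support descriptors that are additive over synthons: MW (integer
microdaltons from a fixed standard-atomic-weight table, so fragment sums and
whole-product recomputation are bit-equal and bin edges cannot flip), HBD
(H on N/O), HBA (N+O count) and a rotatable-bond proxy (acyclic single bonds
between non-terminal heavy atoms, the dummy counting toward its neighbor's
degree). The formed bond's own rotatability depends on both partners, so the
proxy convolves four blocks split by link-atom terminality; it is defined
only for single-link (open-chain) rules — joining two fragments into a ring
changes ring membership of existing bonds and breaks additivity, so
ring-forming rules raise an unsupported-descriptor error, as would
non-additive descriptors like clogP or TPSA. Counts are exact integers and
must sum to the space's product count; bins not covering the value range are
an error rather than a silent truncation.

Product counts are *not* deduplicated across transforms or across
sub-reactions of one transform: identical products reachable by two routes
count twice, matching the per-transform bookkeeping the construction reports.
Within a sub-reaction, uniqueness is by construction and oracle-checked.

Serialization is a plain-text directory: `manifest.json` (name, policies,
aromaticity model, graph list), per-sub-reaction synthon SMILES files with
link atoms as atom-mapped dummies, and a JSON sidecar with the rule's SMARTS
and link metadata. Loading reproduces counts, histograms and membership
exactly; missing files or manifest keys fail loudly.

## Duplicate policies

`LIB2020` unifies matches covering the same atom set before counting — the
historical behavior: a symmetric alkene pattern double-matching the same two
atoms is unified and kept (an arbitrary orientation is used), while a
secondary amine matched once per flank counts as a double match and is
excluded. `SPACE` unifies by the assignment of *distinct-role* atoms — maps
incident to a formed bond, to an intra-side bond-order change, or adjacent
to a leaving atom: multiple distinct role assignments mean genuinely
different products (mixtures) and exclude the block, while duplicates that
lead to one product are kept. Hence secondary amines are retained under
`SPACE`, and symmetric alkene patterns yield zero products there. A block
matching both reactant sides is excluded unless all matches on one side are
killed, in which case the surviving side is kept (the kill-rescue
exception, applied after per-side KILL evaluation).

## Synthetic fixtures

The generator emits deterministic per-class panels (primary/secondary
amines, acids, aryl halides, boronic acids, alkynes, azides, 1,2-disubstituted
alkenes, monosubstituted hydrazines, methyl-anchored 1,3-diketones) with
distinct substituent tails, plus controlled adversarial members: KILL
triggers for each shipped statement (β-halide, γ-ether and α-nitrile amines,
α-halide and benzylic acids, an aldehyde boronic acid, a triketone, a
triazane with an off-path N–N bond), Boc-protected amines, fused aryl
halides including one that only the second fusion variant matches,
organometallics, an overweight chain, and both-side matchers with and
without a kill-rescue. Default sizes keep every toy space in the hundreds of
products so full enumeration stays the oracle. What the fixtures do **not**
emulate: catalog-scale diversity, stereochemistry, tautomerism, charged
building blocks beyond the standardization rules, and multi-pattern
transform files at scale — passing tests show the machinery is exact under
its stated semantics, not that a particular real rule corpus is translated
correctly.

The brute-force oracle is an independent second route: it assembles every
selected reactant pair by direct graph surgery (no synthon encoding, no link
atoms) and applies KILL statements to the assembled, labeled products — the
enumerated-library semantics. Counting, product SMILES, histogram,
membership and retro-validation claims are all asserted against it.

## Problem sizes and numerics

The shipped study conditions are the fixture defaults (≈75 building blocks,
six transforms, ~500–550 products per build), chosen so the full suite and
the acceptance script each run in well under a minute on one core while
every code path — fusion variants, cross-reactant splitting, GOTO, rescue,
ring formation — is exercised. Tolerances: all counting, histogram and
round-trip checks are exact (integer or set equality); the only approximate
comparison is the condensation mass delta (10⁻³ g/mol, the printing
precision of the mass table). Ties in salt stripping (equal component sizes)
are broken by canonical SMILES order; RNG use is confined to `random.Random`
instances seeded from the caller's seed.
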