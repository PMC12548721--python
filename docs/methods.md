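# Methods

## The encoding

A mononuclear complex is described by its ligand set and its metal; no
3-D geometry, charges on the metal, or bond orders to the metal enter
the representation.

**Ligand part.** For each ligand, every heavy atom seeds an integer
identifier hashed from five atom invariants: atomic number, heavy-atom
degree, formal charge, total attached hydrogens, and ring membership.
Identifiers are refined iteratively: at radius *r* an atom's new
identifier is the hash of (r, its previous identifier, the sorted list
of (bond-order code, neighbour identifier) pairs). Sorting makes the
result independent of atom ordering in the input SMILES. An atom emits
one identifier at radius 0 and one per larger radius at which its
environment's atom set strictly grows (default maximum radius 2 bonds),
so at most 3·N identifiers are produced for N heavy atoms and the cost
is linear in N. Identifiers are folded by `id mod B` into a count
vector of length B (default 512; 256 and 1024 supported). Counts are
kept rather than bits: an environment present twice contributes two.
Per-ligand vectors are summed element-wise over the complex, which makes
the descriptor permutation-invariant over ligands and exactly k-linear
in k repeats of the same ligand. There is no cross-atom deduplication
of identical environments; conservation (vector sum = identifier count)
holds exactly.

The hash is an 8-byte BLAKE2b digest of the little-endian-packed
invariant tuple, pinned as `HASH_VERSION = "blake2b8-v1"`. Fingerprints
are comparable only within one hash version; the version is printed by
`electrum --version`. No bit-compatibility with any other toolkit's
circular fingerprints is claimed.

**Metal part.** 86 bits, one per electron slot of the fifteen subshells
1s 2s 2p 3s 3p 4s 3d 4p 5s 4d 5p 6s 4f 5d 6p in Madelung filling order
(capacities 2/2/6/2/6/2/10/6/2/10/6/2/14/10/6, totalling 86 — the
electron count of radon). Within each subshell block the first k bits
are set, k being the tabulated neutral ground-state occupancy, so the
popcount equals min(Z, 86) and the encoding is injective over Z ≤ 86.
The embedded table (`src/electrum/data/electron_configurations.csv`,
regenerable via `scripts/build_element_table.py`) stores tabulated
ground states including the aufbau exceptions Cr, Cu, Nb, Mo, Ru, Rh,
Pd, Ag, La, Ce, Gd, Pt, Au. The *neutral* atom is always encoded: any
charge on the metal token is parsed and ignored, both because oxidation
state is a prediction target (encoding it would leak labels) and because
formal charges in deposited SMILES are unreliable. For elements beyond
radon (protactinium, Z = 91, is in the supported metal set) only the 86
in-window electrons are encoded — for Pa that is exactly the radon core,
so its five 7s/5f/6d electrons are dropped with a logged warning.

**Parsing.** All SMILES parsing is sanitisation-free (RDKit
`MolFromSmiles(sanitize=False)` followed by a non-strict property-cache
update and fast ring perception). Ligands cut out of complexes
routinely carry valences an organic sanitiser rejects; the non-strict
path keeps them intact. A consequence worth knowing: implicit hydrogen
counts on unusual valences follow RDKit's fill-to-next-allowed-valence
rule (the carbon of neutral `C#O` carries one implicit H under this
convention). The convention is applied uniformly on both sides of every
comparison, so it cancels in all invariants.

## Decomposition

Full complex SMILES are curated graph-side: disconnected fragments
without the metal are dropped as counterions/solvent (logged), the
single metal atom is deleted from the graph, and each remaining
connected component is written back to SMILES as one ligand. The
coordination number is the metal's degree — the count of metal-incident
edges — so an η⁴-bound ligand contributes 4 and a bidentate chelate 2.
Bond-type labels of the deleted edges are recorded per ligand but never
consumed by the fingerprint. Ligand atoms keep the formal charges the
input declared; nothing is re-perceived. Zero metals or two-plus metals
are hard errors (multinuclear complexes and metalloligands are out of
scope). Class-support filtering (`filter_by_class_support`, default
threshold 1000 examples per class) reproduces the dataset-curation rule
of keeping only well-populated coordination-number classes.

## Nearest neighbours

Chemical-space maps are built on the k-NN graph under the Manhattan
metric, which on count vectors is the total absolute difference in
substructure occurrences. The search is exact — block-wise all-pairs
distances, top-k per row — rather than an approximate index: the
datasets handled here are desk-scale and exactness permits brute-force
oracle testing. Ties at equal distance break toward the lower index;
`k` defaults to 20. The edge list exports as delimited text for
external layout tools (e.g. tree-map style minimum-spanning-tree
layouts); layout itself is out of scope.

## Evaluation harness

Classification uses a scikit-learn `MLPClassifier` with hidden layers
(512, 256, 128, 64, 32) under stratified 5-fold cross-validation;
regression an `MLPRegressor` with the same architecture under 3-fold
CV. No hyperparameter tuning is performed: everything but the layer
sizes and the iteration cap (`max_iter=400`, raised from the library
default so small datasets converge) is the library default. Folds are
stratified because real complex datasets are severely class-imbalanced.
Metrics are macro-averaged: AUROC and AUPRC one-vs-rest per class
(step-wise average precision, no interpolation), precision/recall/F1
unweighted over classes; a class absent from a fold's true labels is
excluded from the AUC macros and logged rather than averaged in as
zero. The scrambled-label control applies a single global permutation
of the labels (same seed) before folding; a model's margin over its
control, not its absolute score, is the evidence of learned signal.
Feature scaling is off by default (counts plus a raw atomic-number
column differ in scale; standardisation is available behind a flag but
is not part of the default protocol).

## Synthetic data

The generator assembles complexes from a 20-entry pool of small real
ligands (halides, aqua, ammine, sulfide, cyanide, carbonyl,
acetonitrile, pyridine, trimethylphosphine, η²-ethylene, and chelates
up to denticity 3) with declared donor atoms. A metal is drawn
uniformly from the 50-element supported set, a target coordination
number uniformly from 2–6 (bracketing the square-planar and octahedral
geometries that dominate real crystallographic data, while keeping
complexes small), and ligands are sampled until denticities sum to the
target. Each record carries both the component string and a bonded
complex SMILES, so the coordination-number label is recoverable through
decomposition as an end-to-end check; ligand atoms are written with
frozen explicit hydrogen counts (`allHsExplicit`) so text round-trips
cannot re-derive hydrogens on hypervalent donors. Label injection
produces metal-dependent, ligand-dependent, or pure-noise labels: the
metal-dependent mode is learnable only through the metal block, giving a
directional test that the full encoding beats the ligands-only control.

What the generator does **not** emulate: real abundance distributions
(no Cu/Ru/Fe dominance, no class imbalance unless requested), geometric
or thermodynamic plausibility, counterions, and the long tail of large
polyhapto ligands. The synthetic oxidation-state column is a
deterministic stand-in derived from the metal index, not a chemical
assignment. Passing tests on this data therefore demonstrate the
correctness and invariances of the machinery — not predictive
performance on crystallographic datasets, which requires the external
curated tables the harness also accepts.

## Numerical and design notes

* Fold size must divide nothing: folding to 2B and re-summing halves
  equals folding to B (tested); identifier space is 64-bit so collisions
  below ~10⁹ identifiers are negligible at desk scale.
* Degenerate inputs: empty SMILES components, metal-free strings and
  multinuclear inputs are errors, never silently empty vectors.
* The problem sizes used by the default test and acceptance runs (500
  synthetic complexes, 200-point k-NN oracles, 200 permutation trials)
  were chosen as the smallest sizes at which the stochastic checks are
  stable across seeds.
* Determinism: every stochastic component (generator, label injection,
  fold shuffling, MLP initialisation) is driven by one integer seed;
  identical seeds give bit-identical datasets and per-fold metrics.

## Known limitations

* No stereochemistry: stereoisomers of equal constitution (cisplatin /
  transplatin) are indistinguishable by construction. A chiral-tag
  extension on coordinating atoms would lift this without changing the
  architecture.
* Mononuclear only; bridged and multimetallic systems are rejected.
* The metal block ignores oxidation state and spin state; the neutral
  ground-state configuration is a deliberate simplification.
* Hash identifiers are package-specific; models trained on these
  fingerprints are not transferable to other circular-fingerprint
  implementations.
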