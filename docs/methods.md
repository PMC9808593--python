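# Methods

## Torsion angles from coordinates

All seven angles (α, β, γ, δ, ε, ζ, χ) are computed from raw atomic
coordinates with the atan2 form of the signed dihedral (two bond-plane
normals; cis = 0°, trans = 180°, IUPAC sign), then wrapped to **[0, 360)**.
The unsigned interval is a deliberate convention: the classification
thresholds of interest (α near 252°, β near 150°, the split domain
0 ≤ θ ≤ 360) live on that scale, and a (−180, 180] representation would
cut the right-handed α cluster (~250–325°, conventionally ≈ −60°) in
half. Collinear quadruples are rejected at a cross-product-norm tolerance
of 1e-8 — real structures sit many orders of magnitude above it; when a
deposited structure does contain degenerate or missing atoms the angle is
recorded as *missing* (never silently zero) and the nucleotide is later
excluded by the completeness filter.

Backbone connectivity is established geometrically: a nucleotide's O3′
within 2.0 Å of another's P makes a 5′→3′ link, independent of residue
numbering (covalent O3′–P bonds are ~1.6 Å). Consequently a 5′-terminal
residue has no α (and, for the usual 5′-OH terminus, no β) and a
3′-terminal residue no ε/ζ. A residue counts as a nucleotide iff it has
the C1′, O4′ and C4′ sugar atoms. Alternate locations collapse to the
highest-occupancy copy (ties prefer altloc 'A'); model 1 of multi-model
(NMR) files is used unless another model is requested. Modified bases
(bromo-cytosine, 5-methyl-cytosine, inosine, …) map to a parent base for
the χ quadruple; unknown residue names fall back on ring content (N9
present ⇒ purine).

Which residues of which structure enter the dataset is driven by a
per-structure manifest rather than computed: tetrad membership is a
curation decision (loop and overhang nucleotides are excluded for
quadruplexes, everything passes for duplexes), and automated tetrad
detection is out of scope. The shipped manifest covers the 33 curated
crystal/NMR entries; its explicit quadruplex residue lists are
reconstructed from the deposited sequences assuming single-chain 1-based
numbering and are expected to be edited against the actual files (chains
of the asymmetric unit, deposited numbering offsets). Duplex entries use
the `all-complete` keyword — terminal residues then drop out through the
completeness filter, which is why usable nucleotide counts sit below raw
residue counts.

## The classifier

The tree is a from-scratch binary ID3-style learner. Node impurity is the
two-class Shannon entropy E(S) = −Σ pᵢ log₂ pᵢ with 0·log₂ 0 = 0 (0 bits
for a pure node, 1 bit for an even split). The split search is exhaustive:
candidate thresholds are midpoints between consecutive distinct sorted
values of each angle, the chosen split maximizes information gain
(parent entropy minus size-weighted mean child entropy), and exact ties
resolve by the fixed feature order α, β, γ, δ, ε, ζ, χ, then by the
smallest threshold, making training fully deterministic. Angles are
treated as plain linear features on [0, 360); a circular (wrap-around)
split would change the method. Growth stops at pure nodes or when no
split has positive gain (an optional `min_gain` floor provides the
alternative early-stopping rule). A gain floor of 1e-12 guards against
float-noise splits.

Pruning is minimal (weakest-link) cost-complexity pruning with
misclassification-rate impurity: each internal node t carries an
effective alpha g(t) = (R(t) − R(T_t)) / (|leaves(T_t)| − 1), and
subtrees are collapsed weakest-first while min g(t) **<** the complexity
parameter (default 0.04). The strict inequality is a deliberate
convention so that a complexity parameter of 0 is the identity (subtrees
with g = 0 — entropy-useful but error-neutral splits — survive), while ∞
collapses to the majority leaf; pruning is idempotent. Prediction routes
left iff feature ≤ θ; leaf ties predict left-handed (label 0), and the
distilled two-angle rule (α < 252° and β > 150° ⇒ left-handed, strict
comparisons) is exposed separately as `rule_classifier`.

## Validation protocol

Repeated random holdout: the test split takes ⌈0.3 N⌉ samples (64 of 213,
leaving 149 for training), assignment is uniform given the seed, and
iteration i of an experiment uses seed `base_seed + i`, so reports are
bit-reproducible and the k = 0 column of the transfer experiment equals
the plain holdout accuracies exactly. Accuracy is correct/total on the
held-out split; summaries report the mean and the population standard
deviation (ddof = 0) over iterations. Train/test disjointness is asserted
on every split.

The transfer experiment draws k duplex samples uniformly *without*
replacement (no class balancing) into the quadruplex training split and
evaluates the duplex accuracy on the duplex pool **minus** the drawn
samples — the evaluation set is reduced rather than reused to avoid
train/test leakage; with the default pool (251) and k ≤ 50 at least 201
duplex samples always remain. Root-split statistics take the modal root
feature over iterations whose tree actually split (ties to the canonical
angle order) and average θ over the modal-feature iterations.

## PCA

Two components, mean-centering only (all features share the same unit,
degrees; no variance scaling), computed by SVD of the centered matrix
with the sign convention that each component's largest-magnitude loading
is positive. Explained-variance ratios are squared singular values over
their total. Angles enter linearly, consistent with the classifier;
circular PCA is out of scope.

## The synthetic generator

The generator emulates the class-conditional torsion structure of the
four families as independent wrapped-normal mixtures per angle, with
subpopulations cycled in order to realize within-class alternation:

* **LHG4** (125 samples): guanosine α ~ N(180°, 12.5°) so the 150–200°
  range holds ≈94% of the mass; β ~ N(210°, 18°) (mass above 150°);
  ε and ζ bimodal across the two tract positions (ε 210°/260°,
  ζ 255°/305°, sd 10–15°) reflecting the first-vs-second guanosine
  clusters; χ anti (240°).
* **RHG4** (88): α ~ N(300°, 18°) (mass ≈250–335°, peak 300°); the other
  angles broad (sd 25–40°), modeling the wide right-handed spread.
* **Z-DNA** (76): alternating dinucleotide step — syn guanosine
  (χ ≈ 60°, α ≈ 65°) and anti cytidine (χ ≈ 240°, α ~ N(180°, 12.5°)).
* **B-DNA** (175): α ~ N(300°, 25°) (240–360°) with canonical B-form
  means elsewhere (sd 20°).

Default per-class counts mirror the curated-structure dataset
(125/88/76/175). Where only a range or a peak is reported for a family,
the standard deviation is back-solved so ~95% of the component's mass
falls in the stated range; angles with no reported constraint get broad
class-typical components chosen *not* to drive classification. The
cluster locations of the LHG4 ε/ζ bimodality are not constrained beyond
"bimodal", so the 50° inter-cluster gap is a package choice — large
enough to be unambiguously bimodal, small enough that the left-handed
family stays tightly clustered in the PC plane, matching the qualitative
geometry the method is meant to expose. All parameters live in the
editable `data/default_torsion_spec.yaml`.

What the generator deliberately does **not** model: covariation between
angles within a nucleotide (real backbones are strongly correlated along
the chain), sequence context, crystal-packing effects, and measurement
noise heterogeneity between structures. Passing tests on the generator
therefore demonstrate that the pipeline recovers the encoded
class-conditional structure — near-perfect holdout accuracy and unanimous
α root splits are properties of the emulated distributions, not claims
about deposited structures, where class overlap and correlated angles
lower accuracy to around the 90% regime.

The PDB fixture builder constructs small chains by natural-extension
reference frames from idealized bond lengths/angles, with every backbone
and glycosidic torsion settable per residue, so computed angles can be
checked against exact generating values (to 1e-6° in memory; PDB text
truncates coordinates to 3 decimals, ≈0.1° after a file round trip).
The first residue is built as a 5′-OH terminus.

## Numerical conventions and degenerate inputs

* wrap to [0, 360) via modulo with an explicit guard for the float case
  where a tiny negative rounds to exactly 360.0;
* holdout sizing subtracts 1e-9 before the ceiling to absorb float
  artifacts like (1 − 0.7) × 10 = 3.0000000000000004;
* empty datasets, all-zero class counts, rank-0 PCA input, branching
  O3′–P connectivity, and manifest selections absent from a structure all
  raise typed errors rather than degrading silently;
* experiment sizes in the test suite are scaled (tens of holdout
  iterations, 20–50 generator seeds) — the package's own choice of
  problem sizes for its property checks; the library defaults remain
  1000 iterations.

## Known limitations

* The decision tree is greedy: on adversarial label patterns (XOR-like
  structure) it can be worse than the best threshold tree of equal depth;
  on class-structured torsion data this does not arise.
* The shipped manifest's quadruplex residue lists are sequence-based
  reconstructions (see above) and must be reviewed before quantitative
  claims about specific deposited structures.
* Only the PDB dialect is read (every curated entry is available as PDB);
  mmCIF is a non-goal, as are sugar-pucker parameters, imputation of
  missing angles, and automatic handedness detection from geometry.
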