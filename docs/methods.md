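# Methods

## Scope and model

mc4rkit treats the melanocortin-4 receptor as a standard class A GPCR:
seven transmembrane helices (TMH1–7) joined by intra- and extracellular
loops, an extracellular N-terminal tail, an amphipathic helix 8 and a
C-terminal tail. All residue numbering is 1-based on the mature 332-
residue human sequence, so literature landmarks keep their names (D90,
D122/D126, C271–C277, D298). The package deliberately stops at geometry:
no molecular dynamics, energy minimization, side-chain packing, or pose
search is performed anywhere. Threading output is a backbone-faithful
geometric model; contact and span analyses are distance computations on
whatever coordinates they are given.

## Sequence analysis

Alignment is global Needleman–Wunsch under BLOSUM62 with affine gaps,
delegated to Biopython's `PairwiseAligner`. Gap penalties default to
open −10 / extend −1, the common BLOSUM62 pairing; only the matrix
choice is dictated by the comparison levels this package reproduces, so
both penalties are exposed as parameters. Tie-breaking takes the
aligner's first traceback, which is deterministic and prefers aligned
pairs over gaps.

Percent identity divides identical columns by *aligned* (gap-free)
columns; an `include_gaps` flag switches the denominator to full
alignment length. Percent similarity counts columns whose substitution
score is positive. Similarity can never fall below identity because the
BLOSUM62 diagonal is positive.

Ballesteros–Weinstein numbering anchors each helix at its x.50 consensus
position: N1.50, D2.50, R3.50 (DRY), W4.50, P6.50 (CWxP), P7.50
(D/NPxxY). These six are found by motif search inside the topology's
helix spans. Melanocortin receptors lack P5.50 — hMC4R has a methionine,
which is why TMH5 is expected to be a regular α-helix — so the 5.50
anchor cannot come from a motif; the shipped table fixes it at M204, the
column that pairs with the template's L5.50 in the threading alignment.
All anchors are data, not code, and can be overridden.

The default region-boundary table is calibrated to the receptor's
hallmark loop sizes — ICL1 of 8 residues (70–77, containing K73 and
H76), ICL2 of 13 (151–163, containing A154/Y157/H158/M161), ECL2 of 4
(186–189) — and places every verified landmark in its expected region
(the DRY motif at the TMH3 cytoplasmic end, CWxP in TMH6, the ECL3
cysteines 271/277/279, the DPxxY motif in TMH7). Boundaries between
helix ends and loop starts elsewhere are conventional choices of a few
residues either way and are configurable; only the three calibrated loop
sizes carry scientific weight here.

## Threading

`thread_sequence` substitutes a target sequence onto a template chain
through an explicit alignment: backbone N/CA/C/O are copied unchanged
for every aligned column (the backbone never moves — this is asserted,
not approximated), conserved residues keep all template atoms,
substituted residues are truncated to a Cβ rebuilt at ideal tetrahedral
geometry (bond 1.521 Å, N-CA-CB 110.4°), template-only residues are
dropped, and target-only residues are reported as unmodeled rather than
invented. Because substituted side chains end at Cβ, downstream contact
analysis measures distances over whatever atoms exist and flags records
involving truncated residues.

## Superposition

Rigid superposition is the Kabsch algorithm via SVD with a determinant
correction guaranteeing a proper rotation; degenerate (collinear) inputs
and fewer than three pairs are errors. The test suite checks it against
an independently implemented Horn quaternion fit and against the
analytic noise floor σ·√((3n−6)/n) for Gaussian perturbations.

## Contacts

A contact is a residue pair from two chains whose minimum heavy-atom
distance is within the cutoff (default 4.0 Å). Hydrogens are ignored —
the models carry none. Classes, in precedence order: salt bridge (basic
side-chain N within 4.0 Å of acidic side-chain O), hydrogen-bond
candidate (any N/O–N/O pair within 3.5 Å; no angle term, since the
models are unrefined), aromatic (both residues aromatic), generic. The
implementation uses a k-d tree; tests require exact agreement with an
O(n²) all-pairs scan on every fixture.

## Dimers and bivalent linkers

Two packings are modeled, following the arrangements recurring in class
A GPCR crystal dimers: a compact interface through TMH4/ICL2/TMH5
(CXCR4-like) and an opposed interface through TMH1/TMH2/H8 (KOR-like).
Because the orthosteric pocket faces the TMH3–6 side, the two
arrangements separate the pocket pair very differently, and that
separation decides whether one homobivalent ligand can occupy both
protomers. The span endpoint is the heavy-atom centroid of a pocket
residue set in each protomer — without released ligand poses the pocket
centroid is the reproducible proxy for "between the ligand moieties" —
and linker reach is the extended-chain approximation of 1.25 Å per
spacer atom (20 atoms → 25 Å), both configurable. Dimers are assembled
by superposing protomer copies onto template chains; steric overlap
below 2.0 Å is counted and reported, never repacked.

## Variant curation

The variant grammar accepts `D90N` (substitution), `Y35X`/`Y35*` (stop),
`ΔI125`/`I125del` (deletion) and `D37V/I102T` (double substitution);
only single substitutions survive curation, matching how the clinical
collections count. Rows are merged per substitution with evidence
pooled across sources. Functional classes derive from three separate
defect columns (α-MSH binding, cAMP accumulation, surface expression),
kept separate so either counting convention is computable: a variant
with any like-wild-type report counts toward the like-WT tally, any
loss report toward the decreased tally, and both kinds of report make
it contradictory — so the tallies intentionally overlap and satisfy
`no_data + like_wt + decreased − contradictory = total`. A variant whose
only evidence is raised basal activity is classed `increased_basal`;
a constitutively activating variant that also has a like-wild-type cAMP
report (the H158R pattern) stays in the like-WT tally and carries the
basal flag, which keeps the overlap identity exact while still reporting
CAMs separately.

Structural context is assigned by precedence: membership in the
ligand-pocket set → `ligand_binding`; an intracellular loop, helix 8, or
an explicit G-protein interface set → `gprotein_interface`; any TM
region → `TM_microdomain` (with the 2.50/7.49 sodium-site positions
noted); otherwise `other`. The precedence makes the classification
deterministic and total on annotated positions.

## Synthetic fixtures: what they emulate, and what they do not

Every pipeline input has a seeded generator, and every generator writes
a manifest whose quantities the analysis stages must recover exactly.
Streams are separated per generator (`default_rng([seed, stream_id])`)
so adding one generator never shifts another's output.

* **Bundles** are ideal α-helices (φ/ψ = −57°/−47°, giving the textbook
  1.5 Å rise and 3.8 Å CA–CA spacing) standing on a 10 Å ring with
  antiparallel alternation, carrying the real hMC4R sequence and
  topology; loops are bowed connectors with ~3 Å spacing and tails are
  straight extensions. Side chains are a Cβ plus, for polar/charged/
  aromatic-donor types, a single named tip atom (NH1, OD1, SG, …) so
  contact chemistry is classifiable. The ECL3 disulfide is planted at
  2.05 Å.
* **Poses** come in two modes. The strict α-MSH-like mode plants exactly
  *k* contacts at recorded distances on the extracellular helix tips and
  verifies by brute force that nothing else slips under the cutoff; it
  requires a helix-only bundle, because loop connectors crowd the
  extracellular mouth. The AgRP-core-like anchor mode reproduces the
  published hot-spot pairs (R111 wedged between D122/D126; F112/F184,
  F113/F261, F116/F284, Y109/Y268, R120/D189) and deliberately allows
  the mid-helix spillover a real pose would have, which is what pushes
  its pocket beyond twenty receptor residues.
* **Dimers** place a second protomer by a recorded rigid transform
  (180° about the membrane normal, then translation along the interface
  helix direction; default separation 27.5 Å, the closest clash-free
  packing of these bundles). On these fixtures the compact arrangement
  spans ≈18 Å between pocket centroids and the opposed one ≈38 Å —
  smaller absolute values than full-size receptor models give, because
  the toy bundle is leaner than a real receptor, but with the same
  ordering and the same 20-atom-linker verdict (feasible vs not).
* **Variant tables** plant exact class tallies and region quotas,
  including the named literature variants with their reported behavior,
  plus stop/deletion/double rows that curation must discard.
* **Sequence surrogates** stand in for the zebrafish MC4R/MC2R orthologs
  and the S1PR1 template, which are not redistributable here: they are
  mutated derivatives of hMC4R with the comparison levels planted by
  construction (68% identity; ~60% similarity; ~50% TM similarity with
  L at 5.50) and the six agonist-pocket residues protected, mirroring
  their conservation across these receptors.

Passing tests on these fixtures demonstrates that the analysis
operations are correct and self-consistent — that contact maps equal
their oracle, manifests round-trip, arithmetic identities hold. They do
not validate homology-model quality, binding poses, or dimer energetics
against experiment; nothing here refines geometry, and the surrogate
sequences reproduce comparison levels, not evolutionary history.

## Numerical choices

Alignment ties → first traceback. PDB altloc → highest occupancy, ties
toward 'A'. Coordinates round-trip through PDB format at 10⁻³ Å.
Disulfide search: Sγ–Sγ ≤ 2.5 Å, greedy nearest-first, each cysteine in
at most one bond; Cβ–Cβ ≤ 5.5 Å fallback for truncated models. Span and
feasibility are exact arithmetic; feasibility at zero margin counts as
feasible (a 20-atom spacer exactly reaches a 25 Å span). Degenerate
inputs (empty sequences, missing chains, non-contiguous boundary tables,
collinear superposition, non-positive cutoffs) raise errors rather than
guess.

## Known limitations

* The boundary table's helix/loop borders outside the three calibrated
  loop sizes are conventional, and BW numbers inherit any border shift.
* Cβ-truncated side chains bias contact distances long and salt-bridge
  detection conservative on threaded models; affected records are
  flagged.
* The toy bundle's ring geometry compresses absolute distances; span
  values on it are ordering-faithful, not structure-faithful.
* Variant functional classes reduce heterogeneous assay literature to
  three evidence columns; the loader keeps the columns separate so other
  conventions remain computable, but no attempt is made to adjudicate
  between conflicting reports beyond the contradictory label.
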