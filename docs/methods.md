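# Methods

## Model

The package scores each residue of a target protein for *hydropathy
contradiction*: disagreement between the residue's hydrophobicity and the
hydrophobicity its context expects. Two independent definitions of
"context" are implemented.

### Conservation context: the HiSol score

The Kyte–Doolittle hydropathy index is standardized to mean 0 and
variance 1 over the 20 amino acids, giving *h(a)*. For target position
*j* with wild-type residue *wt_j*, and per-column percent appearance
rates *r_ij* derived from a multiple alignment,

    score(j) = h(wt_j) − Σ_i h(i) · r_ij / 100.

The subtrahend is the expected hydropathy of the column under the
empirical residue distribution, so the score is a residual in normalized
hydropathy units: negative when the target residue is more hydrophilic
than its family expects, positive when more hydrophobic. Standardization
makes the score invariant to affine rescaling of the raw index, so any
hydropathy scale expressed as `a·raw + b` gives identical scores.

Assumptions: homologs are treated as independent observations (no
phylogenetic down-weighting), and the distribution over canonical
residues in a column — gaps and ambiguity codes excluded, rates
renormalized to 100 — is taken as the expectation's measure. Per-position
coverage is recorded so thin columns are visible; a zero-coverage
position has *no* score (an explicit absent marker, never 0), and can
therefore never rank as a hotspot.

Ranking follows two conventions: `signed_rank` ranks within sign classes
(1 = most negative among negatives; 1 = most positive among
non-negatives; exact zeros join the non-negative class so ranks remain a
permutation within each class), and `abs_rank` orders all scored
positions by descending |score|. Ties break by ascending position.

### Structural context: the α-helix rule

Predicted α-helices (maximal runs of H of length ≥ 7, i.e. two full
turns) are projected onto the helical wheel at 100°/residue. The
hydrophobic moment is the vector sum of unit vectors at each residue's
wheel angle weighted by normalized hydropathy; its direction defines the
hydrophobic face (residues within 90° of it), the rest the hydrophilic
face. A residue mismatches when its raw-index class (positive =
hydrophobic) disagrees with its face. Trp and Pro are exempt: their side
chains behave hydrophobically despite negative index values, so calling
them would generate systematic false positives.

The face partition is a deliberate formalization of what is usually read
off wheel plots by eye: the moment-semicircle rule is deterministic and
parameter-light, and it reproduces the documented mismatch calls on both
reference segments used in the tests (Val455 of the 443–460 flavin-
oxidase helix; Lys441 of the 430–446 decarboxylase helix).

When the mean moment per residue falls below the **amphipathicity floor**
(default 0.15 normalized-hydropathy units) the helix has no meaningful
axis — a poly-Leu helix is the limiting case — and faces are reported as
undetermined, which implies zero mismatches. The floor is configurable;
0.15 was chosen as roughly 10% of the scale's spread, low enough to keep
genuinely amphipathic natural helices (both reference segments sit above
0.3) and high enough to silence near-uniform ones.

## Candidate selection and suggestions

The contradiction rule selects positions with |score| > threshold
(default 1.0). When more than `max_candidates` (default 10) qualify,
only the `max_candidates` largest-|score| positions are kept (condition
A); otherwise all qualifying positions are kept (condition B). Ties at
the cap break by ascending position, making selection deterministic. A
`signed` mode compares the raw score to the threshold instead, for
experiments where only one contradiction direction is of interest.
Absolute-value thresholding is the default because hydrophilic-in-core
and hydrophobic-on-surface contradictions are physically symmetric and
both directions of correction are known to rescue solubility.

The combined rule ("contradiction on α-helix") intersects the
contradiction candidates with helix membership from the secondary-
structure annotation; it always returns a subset of the contradiction
output. Replacement suggestions at a selected position are the consensus
residues — conservation strictly above `consensus_min_rate` (default
10%) — excluding the wild type, in descending-rate order; a suggestion
whose hydropathy sign opposes the wild type's is flagged preferred.

## Synthetic families

Real homolog libraries cannot be shipped, so the generator draws
alignment columns i.i.d. from controlled compositions:

* background columns keep a randomly chosen consensus residue at 60%
  ("mildly conserved"), with the residual 40% split equally over the
  four residues nearest the consensus on the raw hydropathy axis — this
  emulates the mixed, hydropathy-coherent conservation of natural
  families and keeps background scores near zero;
* planted columns hold a chosen consensus at a chosen rate (e.g. Ile at
  90%) while the target record carries a contradicting residue (e.g.
  Lys), producing a large-|score| position whose location is known.

The target is the first record and holds the column's consensus residue
at unplanted positions. A single seeded `numpy` generator drives all
draws; identical specs give byte-identical families. What the generator
does **not** emulate: phylogenetic correlation between sequences,
indel structure beyond the target's own gaps, alignment error, and
column–column dependence. Passing the recovery tests therefore shows the
scorer ranks genuine composition contradictions correctly, not that real
alignments are this clean; on real data, thin coverage and redundant
homologs are the main caveats (coverage is logged; no redundancy
weighting is applied).

Recovery experiments use 259-residue, 200-sequence families with one
planted Lys-against-90%-Ile column — the scale of the motivating
hydroxynitrile-lyase case — and 50 replicates; these sizes keep the full
suite and the acceptance script under a few seconds while leaving the
statistical margin (planted |score| ≈ 2.9 vs background < ≈ 1) wide.

## Numerical choices

* Variance convention: population (divide by 20) by default; sample
  (divide by 19) selectable. All frozen test values use population.
* The column expectation divides rates by 100 *before* the dot product,
  so a 100%-conserved column reproduces h(wt) exactly and scores a true
  floating-point zero.
* All CLI floats print at fixed 6-decimal precision; reruns on identical
  inputs are byte-identical.
* Wheel face assignment uses cos(Δangle) > 0; a residue exactly on the
  boundary (measure-zero for 100° steps and a generic moment direction)
  falls to the hydrophilic face.
* Duplicate target identifiers are an error, never a silent merge; the
  target's own residue is excluded from column counts by default (the
  profile should describe the homologs, not the query), with a flag to
  include it.

## Known limitations

* Scores depend on the homolog library: thresholds are comparable within
  one alignment, not across proteins with different families.
* No sequence weighting: heavily redundant libraries bias rates toward
  the over-represented clade.
* The α-helix rule inherits secondary-structure prediction errors and
  says nothing about sheets or coils; contradictions there are only
  visible to the conservation route.
* The package predicts candidate positions and replacements; it does not
  predict whether a given mutation will actually solubilize a protein —
  that remains an experimental question.
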