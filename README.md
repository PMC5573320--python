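# hisol

Sequence-only identification of **aggregation hotspots** — residues whose
hydrophobicity contradicts their context and drives a recombinant protein
into inclusion bodies — together with consensus-residue replacement
suggestions for solubility engineering. The package is aimed at protein
engineers who have a target sequence, a homolog alignment (optional), and
a secondary-structure prediction (optional), but no 3D structure.

## The two rules

**Hydropathy contradiction (HiSol score).** Let *h(a)* be the
Kyte–Doolittle hydropathy index of residue *a*, standardized to mean 0 and
variance 1 over the 20 amino acids, and let *r<sub>ij</sub>* be the percent
appearance rate of amino acid *i* at target position *j* among aligned
homologs. The score of position *j* with wild-type residue *wt<sub>j</sub>* is

```
score(j) = h(wt_j) − Σ_i  h(i) · r_ij / 100
```

— the gap between the target residue's hydropathy and the rate-weighted
mean hydropathy of its aligned column. Strongly negative: a hydrophilic
residue where the family keeps hydrophobic ones; strongly positive: the
reverse. Candidates are positions with |score| above a threshold
(default 1.0), capped at the 10 largest when more than 10 qualify.

**α-helix rule.** Project each predicted helix onto the helical wheel
(100° per residue, 3.6 residues/turn) and compute the hydrophobic moment
from the standardized hydropathies. A hydrophobic residue on the
hydrophilic face (or vice versa) breaks the amphipathic pattern of a
solvent-exposed helix and is flagged — no homolog alignment required, so
this route works for proteins with no close relatives. Trp and Pro are
exempt (their side chains act hydrophobic despite negative index values).

Flagged positions are paired with **consensus residues** (conservation
above 10% at the position, wild type excluded) as replacement suggestions;
suggestions whose hydropathy sign opposes the wild type's are marked
preferred, since they correct the contradiction.

## Worked example

Generate a synthetic 80-sequence family with two planted contradictions
(a Lys against an 85%-Ile column at position 45, a Leu against an
80%-Asp column at 88), then score and select:

```
$ hisol simulate --length 120 --n-seqs 80 --seed 11 \
      --plant 45:K:I:85 --plant 88:L:D:80 --out-dir fam
$ hisol score --alignment fam/family.fasta --target target --out scores.tsv
$ sed -n '1p;46p;89p' scores.tsv
position  wt_residue  score      signed_rank  abs_rank  coverage
45        K           -2.862226  1            1         79
88        L           2.503523   1            2         79
$ hisol candidates --alignment fam/family.fasta --target target
position  wt_residue  score      rules                     in_helix  suggestions
45        K           -2.862226  hydropathy_contradiction  NA        I:92.405063*
88        L           2.503523   hydropathy_contradiction  NA        D:86.075949*
```

Position 45 carries the most negative score of the protein (signed rank 1
among negatives): a hydrophilic Lys where 92% of homologs keep Ile — the
suggested fix is K45I (the `*` marks an opposite-sign, contradiction-
correcting replacement). Position 88 is the mirror case, suggesting L88D.

The wheel subcommand analyzes a single helix with no alignment at all:

```
$ hisol wheel --sequence RVDIDTMVRGVHVALNFG --start 443 | tail -1
mismatches  444,445,450,452,455,460
```

The hydrophobic Val at 455 sits on the hydrophilic face of this helix —
the classic mismatch the α-helix rule exists to catch.

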