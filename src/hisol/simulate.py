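"""Seeded synthetic alignment families with planted hydropathy contradictions.

Real homolog libraries cannot be bundled, so test families are drawn
column-wise from controlled compositions: each background column keeps a
randomly chosen consensus residue at a moderate rate with the residual
mass spread over its hydropathy near-neighbors (emulating the mixed
conservation of natural families), and planted columns hold a chosen
consensus at a chosen rate while the target carries a contradicting
residue.  No phylogeny is simulated — column composition is all the
scoring method sees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, MultipleAlignment, _AA_POS0, build_profile, write_alignment
from .hydropathy import KYTE_DOOLITTLE, hisol_profile, kyte_doolittle_scale

TARGET_ID = "target"

# Residual mass in a conserved column goes to the residues closest to the
# consensus on the raw hydropathy axis (ties alphabetical).
N_NEIGHBORS = 4
BACKGROUND_CONSENSUS_RATE = 60.0


@dataclass(frozen=True)
class PlantedSite:
    position: int          # 1-based
    target_residue: str
    consensus_residue: str
    consensus_rate: float  # percent in (0, 100]


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of one synthetic family.

    ``n_seqs`` counts all records including the target.  ``background``
    optionally fixes the full L×20 column composition (percent rows);
    when None a mildly conserved random consensus is drawn from ``seed``.
    """

    length: int
    n_seqs: int
    planted: tuple[PlantedSite, ...] = ()
    seed: int = 0
    background: Optional[np.ndarray] = None
    background_rate: float = BACKGROUND_CONSENSUS_RATE

    def __post_init__(self) -> None:
        if self.length < 1 or self.n_seqs < 2:
            raise ValueError("need length >= 1 and n_seqs >= 2")
        positions = [p.position for p in self.planted]
        if len(set(positions)) != len(positions):
            raise ValueError("planted positions must be distinct")
        for p in self.planted:
            if not 1 <= p.position <= self.length:
                raise ValueError(f"planted position {p.position} outside 1..{self.length}")
            if not 0 < p.consensus_rate <= 100:
                raise ValueError("consensus_rate must be in (0, 100]")
            if p.target_residue == p.consensus_residue:
                raise ValueError("target and consensus residue must differ")
            for r in (p.target_residue, p.consensus_residue):
                if r not in _AA_POS0:
                    raise ValueError(f"non-canonical residue {r!r}")
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (self.length, 20):
                raise ValueError("background must be L x 20")
            if (bg < 0).any() or not np.allclose(bg.sum(axis=1), 100.0):
                raise ValueError("background rows must be rates summing to 100")


def hydropathy_neighbors(residue: str, n: int = N_NEIGHBORS) -> list[str]:
    """The ``n`` residues closest to ``residue`` in raw hydropathy."""
    ref = KYTE_DOOLITTLE[residue]
    others = [aa for aa in AMINO_ACIDS if aa != residue]
    others.sort(key=lambda aa: (abs(KYTE_DOOLITTLE[aa] - ref), aa))
    return others[:n]


def column_composition(consensus: str, rate: float) -> np.ndarray:
    """Percent composition: ``consensus`` at ``rate``, residual mass split
    equally over its hydropathy neighbors."""
    comp = np.zeros(20)
    comp[_AA_POS0[consensus]] = rate
    residual = 100.0 - rate
    if residual > 0:
        for aa in hydropathy_neighbors(consensus):
            comp[_AA_POS0[aa]] += residual / N_NEIGHBORS
    return comp


def generate_family(
    spec: SyntheticFamilySpec,
) -> tuple[MultipleAlignment, pd.DataFrame]:
    """Draw a family and return it with its truth table.

    The target record holds the planted residues at planted positions and
    the column's consensus (modal) residue elsewhere; homologs are drawn
    i.i.d. per column from the column composition.  Byte-identical output
    for identical specs.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length

    if spec.background is not None:
        comp = np.asarray(spec.background, dtype=float).copy()
        bg_consensus = [AMINO_ACIDS[i] for i in comp.argmax(axis=1)]
    else:
        bg_consensus = [
            AMINO_ACIDS[i] for i in rng.integers(0, 20, size=L)
        ]
        comp = np.stack(
            [column_composition(c, spec.background_rate) for c in bg_consensus]
        )

    target = list(bg_consensus)
    for site in spec.planted:
        comp[site.position - 1] = column_composition(
            site.consensus_residue, site.consensus_rate
        )
        target[site.position - 1] = site.target_residue

    n_hom = spec.n_seqs - 1
    columns = np.empty((n_hom, L), dtype="U1")
    aa_arr = np.array(AMINO_ACIDS)
    for j in range(L):
        columns[:, j] = rng.choice(aa_arr, size=n_hom, p=comp[j] / 100.0)

    records = [(TARGET_ID, "".join(target))]
    width = len(str(n_hom))
    for k in range(n_hom):
        records.append((f"hom_{k + 1:0{width}d}", "".join(columns[k])))

    truth = pd.DataFrame(
        {
            "position": [s.position for s in spec.planted],
            "target_residue": [s.target_residue for s in spec.planted],
            "consensus_residue": [s.consensus_residue for s in spec.planted],
            "consensus_rate": [s.consensus_rate for s in spec.planted],
        }
    )
    return MultipleAlignment(tuple(records)), truth


def write_family(
    alignment: MultipleAlignment, truth: pd.DataFrame, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the family as aligned FASTA plus a truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "family.fasta"
    truth_path = out_dir / "truth.tsv"
    write_alignment(alignment, fasta)
    truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6f")
    return fasta, truth_path


def planted_recovery_rate(
    spec: SyntheticFamilySpec,
    n_replicates: int,
    top_k: int,
    variance_convention: str = "population",
) -> float:
    """Fraction of replicate families whose planted positions all land in
    the top ``top_k`` absolute HiSol ranks.

    Replicate r reuses ``spec`` with seed ``spec.seed + r``.  With no
    planted positions the conjunction is vacuous and the rate is 1.
    """
    if top_k < len(spec.planted):
        raise ValueError("top_k must cover all planted positions")
    scale = kyte_doolittle_scale(variance_convention)
    planted = {s.position for s in spec.planted}
    hits = 0
    for r in range(n_replicates):
        rep = SyntheticFamilySpec(
            length=spec.length,
            n_seqs=spec.n_seqs,
            planted=spec.planted,
            seed=(spec.seed + r) % (2**31),
            background=spec.background,
            background_rate=spec.background_rate,
        )
        alignment, _ = generate_family(rep)
        profile = build_profile(alignment, TARGET_ID)
        hp = hisol_profile(profile, scale)
        top = {
            s.position
            for s in hp.scores
            if s.abs_rank is not None and s.abs_rank <= top_k
        }
        if planted <= top:
            hits += 1
    return hits / n_replicates if n_replicates else 1.0
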