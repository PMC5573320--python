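"""Alignment reading and per-position residue appearance-rate profiles.

A multiple sequence alignment of a target protein and its homologs is
reduced, column by column, to the percentage of homologs carrying each of
the 20 canonical amino acids at every position of the (ungapped) target
sequence.  These appearance rates are the conservation signal that the
hydropathy-contradiction score consumes, and they also drive
consensus-residue replacement suggestions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

logger = logging.getLogger("hisol")

# The 20 canonical residues in alphabetical one-letter order.  Profile
# columns, scale vectors and score sums all index residues in this order
# (Ala first, Tyr last), so i = 1 for A, 2 for C, 3 for D, ...
AMINO_ACIDS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
AA_INDEX: dict[str, int] = {aa: i + 1 for i, aa in enumerate(AMINO_ACIDS)}
_AA_POS0: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

GAP = "-"

_FORMAT_ALIASES = {
    "fasta": "fasta",
    "aligned-fasta": "fasta",
    "afa": "fasta",
    "clustal": "clustal",
    "aln": "clustal",
    "stockholm": "stockholm",
    "sto": "stockholm",
}


class AlignmentError(ValueError):
    """Raised for unreadable, ragged, empty or otherwise invalid alignments."""


@dataclass(frozen=True)
class MultipleAlignment:
    """An in-memory alignment: (identifier, gapped sequence) records."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths differ ({sorted(lengths)})"
            )

    @property
    def aligned_length(self) -> int:
        return len(self.records[0][1])

    @property
    def identifiers(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_alignment(path: str | Path, format: str = "fasta") -> MultipleAlignment:
    """Read an aligned FASTA, Clustal or Stockholm file.

    Record order is preserved.  Sequences are upper-cased; '.' gap
    characters (Stockholm convention) are mapped to '-'.
    """
    fmt = _FORMAT_ALIASES.get(format.lower())
    if fmt is None:
        raise AlignmentError(f"unknown alignment format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"alignment file not found: {path}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentError(f"could not parse {path} as {fmt}: {exc}") from exc
    records = tuple(
        (rec.id, str(rec.seq).upper().replace(".", GAP)) for rec in msa
    )
    if not records:
        raise AlignmentError(f"empty alignment: {path}")
    return MultipleAlignment(records)


@dataclass
class AlignmentProfile:
    """Per-target-position amino-acid appearance rates.

    ``composition[j-1, i-1]`` is the percentage of usable (canonical,
    non-gap) residues in the alignment column behind target position ``j``
    that are amino acid ``i`` (alphabetical order).  Rows with nonzero
    coverage sum to 100; a column with no usable residue has coverage 0
    and an all-zero row.
    """

    target_id: str
    target_sequence: str
    column_of_position: np.ndarray  # 1-based alignment column per position
    composition: np.ndarray         # (L, 20) percent
    counts: np.ndarray              # (L, 20) raw counts
    coverage: np.ndarray            # (L,) usable residues per column
    n_sequences: int = 0
    target_in_counts: bool = False

    @property
    def length(self) -> int:
        return len(self.target_sequence)

    def rates(self, position: int) -> dict[str, float]:
        """Appearance rates (percent) at a 1-based target position."""
        self._check_position(position)
        row = self.composition[position - 1]
        return {aa: float(row[i]) for i, aa in enumerate(AMINO_ACIDS)}

    def _check_position(self, position: int) -> None:
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside 1..{self.length}"
            )

    def to_frame(self) -> pd.DataFrame:
        """Profile as a table: position, wt_residue, coverage, 20 rate columns."""
        df = pd.DataFrame(self.composition, columns=list(AMINO_ACIDS))
        df.insert(0, "coverage", self.coverage)
        df.insert(0, "wt_residue", list(self.target_sequence))
        df.insert(0, "position", np.arange(1, self.length + 1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def build_profile(
    alignment: MultipleAlignment,
    target_id: str,
    exclude_target_from_counts: bool = True,
) -> AlignmentProfile:
    """Convert alignment columns to appearance rates over the target positions.

    Columns where the target has a gap are dropped: positions are numbered
    1..L along the ungapped target sequence.  Gaps and ambiguity codes
    (X, B, Z, ...) are excluded from the denominator and the rates are
    renormalized to sum to 100, so the rate-weighted hydropathy sum is a
    proper expectation over observed canonical residues.  By default the
    target's own residue is left out of the counts so the profile reflects
    the homologs, not the query.
    """
    hits = [idx for idx, (rid, _) in enumerate(alignment.records) if rid == target_id]
    if not hits:
        raise AlignmentError(f"target not found: {target_id!r}")
    if len(hits) > 1:
        raise AlignmentError(f"target identifier duplicated: {target_id!r}")
    t_idx = hits[0]
    target_gapped = alignment.records[t_idx][1]

    mat = np.array([list(seq) for _, seq in alignment.records])
    target_cols = np.flatnonzero(np.array(list(target_gapped)) != GAP)
    target_sequence = "".join(target_gapped[c] for c in target_cols)
    bad = sorted({r for r in target_sequence if r not in _AA_POS0})
    if bad:
        raise AlignmentError(
            f"target sequence contains non-canonical residues: {bad}"
        )

    sub = mat[:, target_cols]
    if exclude_target_from_counts:
        sub = np.delete(sub, t_idx, axis=0)

    L = len(target_cols)
    counts = np.zeros((L, 20), dtype=np.int64)
    for i, aa in enumerate(AMINO_ACIDS):
        counts[:, i] = (sub == aa).sum(axis=0)
    coverage = counts.sum(axis=1)

    composition = np.zeros((L, 20), dtype=float)
    nz = coverage > 0
    composition[nz] = 100.0 * counts[nz] / coverage[nz, None]
    if not nz.all():
        for j in np.flatnonzero(~nz):
            logger.warning(
                "position %d has no usable homolog residue (coverage 0)", j + 1
            )

    return AlignmentProfile(
        target_id=target_id,
        target_sequence=target_sequence,
        column_of_position=target_cols + 1,
        composition=composition,
        counts=counts,
        coverage=coverage,
        n_sequences=len(alignment),
        target_in_counts=not exclude_target_from_counts,
    )


def consensus_residues(
    profile: AlignmentProfile,
    position: int,
    min_rate: float = 10.0,
) -> list[tuple[str, float]]:
    """Residues conserved above ``min_rate`` percent at a target position.

    Returns (residue, rate) pairs with rate strictly greater than
    ``min_rate``, sorted by descending rate with alphabetical tie-break.
    """
    profile._check_position(position)
    row = profile.composition[position - 1]
    hits = [(aa, float(row[i])) for i, aa in enumerate(AMINO_ACIDS) if row[i] > min_rate]
    hits.sort(key=lambda p: (-p[1], p[0]))
    return hits


def write_alignment(alignment: MultipleAlignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (60-column wrapping)."""
    with open(path, "w") as fh:
        for rid, seq in alignment.records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
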