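"""Hydropathy scale normalization and the HiSol contradiction score.

The HiSol score of target position j is

    score(j) = h(wt_j) - sum_i h(i) * r_ij / 100

where h is the hydropathy index standardized to mean 0 and variance 1
over the 20 amino acids, wt_j is the target's residue at j, and r_ij is
the percent appearance rate of amino acid i at j among the homologs.
The score is the gap between the target residue's hydropathy and the
rate-weighted mean hydropathy of its aligned column: strongly negative
when a hydrophilic residue sits where the family keeps hydrophobic ones,
strongly positive in the opposite direction.  Residues with large
absolute scores are aggregation-hotspot candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .alignment import AMINO_ACIDS, AlignmentProfile, _AA_POS0

# Kyte & Doolittle (1982) hydropathy index, J Mol Biol 157:105-132.
# Positive = hydrophobic, negative = hydrophilic.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

VarianceConvention = Literal["population", "sample"]


class ZeroCoverageError(ValueError):
    """A score was requested at a position with no usable column residues."""


@dataclass(frozen=True)
class HydropathyScale:
    """A residue hydropathy scale together with its standardized form.

    ``normalized`` has mean 0 and variance 1 over the 20 residues under
    the stated convention (population: divide by 20; sample: by 19).
    Standardization is affine, so it preserves the hydrophobicity order
    and absorbs any affine rescaling of the raw values.
    """

    raw: Mapping[str, float]
    normalized: Mapping[str, float]
    variance_convention: VarianceConvention = "population"

    @property
    def normalized_vector(self) -> np.ndarray:
        """Normalized values in alphabetical residue order."""
        return np.array([self.normalized[aa] for aa in AMINO_ACIDS])

    @property
    def raw_vector(self) -> np.ndarray:
        return np.array([self.raw[aa] for aa in AMINO_ACIDS])

    def is_hydrophobic(self, residue: str) -> bool:
        """Hydrophobicity class by the sign of the raw value."""
        return self.raw[residue] > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": list(AMINO_ACIDS),
                "raw": [self.raw[aa] for aa in AMINO_ACIDS],
                "normalized": [self.normalized[aa] for aa in AMINO_ACIDS],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def normalize_scale(
    raw: Mapping[str, float],
    variance_convention: VarianceConvention = "population",
) -> HydropathyScale:
    """Standardize a 20-residue scale to mean 0, variance 1."""
    missing = set(AMINO_ACIDS) - set(raw)
    extra = set(raw) - set(AMINO_ACIDS)
    if missing or extra:
        raise ValueError(
            f"scale must cover exactly the 20 canonical residues "
            f"(missing={sorted(missing)}, extra={sorted(extra)})"
        )
    values = np.array([raw[aa] for aa in AMINO_ACIDS], dtype=float)
    ddof = 0 if variance_convention == "population" else 1
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("scale is constant; cannot standardize")
    norm = (values - values.mean()) / sd
    return HydropathyScale(
        raw=dict(zip(AMINO_ACIDS, values.tolist())),
        normalized=dict(zip(AMINO_ACIDS, norm.tolist())),
        variance_convention=variance_convention,
    )


def kyte_doolittle_scale(
    variance_convention: VarianceConvention = "population",
) -> HydropathyScale:
    """The standardized Kyte-Doolittle scale (the default throughout)."""
    return normalize_scale(KYTE_DOOLITTLE, variance_convention)


@dataclass
class PositionScore:
    """Score and ranks of one target position.

    ``score`` is None at coverage-0 positions (absent, never 0), and such
    positions carry no ranks, so they can never surface as hotspots.
    ``signed_rank`` ranks within the position's sign class (1 = most
    negative among negatives, 1 = most positive among non-negatives);
    ``abs_rank`` orders all scored positions by descending ``|score|``.
    Ties break by ascending position.
    """

    position: int
    wt_residue: str
    score: Optional[float]
    signed_rank: Optional[int] = None
    abs_rank: Optional[int] = None
    coverage: int = 0


def hisol_score(
    profile: AlignmentProfile,
    scale: HydropathyScale,
    position: int,
) -> float:
    """HiSol score of a single target position.

    Raises :class:`ZeroCoverageError` when the column has no usable
    residues (the score is undefined there, not zero).
    """
    profile._check_position(position)
    cov = int(profile.coverage[position - 1])
    if cov == 0:
        raise ZeroCoverageError(f"position {position} has coverage 0")
    wt = profile.target_sequence[position - 1]
    if wt not in _AA_POS0:
        raise ValueError(f"non-canonical target residue {wt!r} at {position}")
    hvec = scale.normalized_vector
    # divide rates first so a 100%-conserved column reproduces h(wt)
    # exactly and the score is a true zero
    column_mean = float((profile.composition[position - 1] / 100.0) @ hvec)
    return float(scale.normalized[wt]) - column_mean


@dataclass
class HiSolProfile:
    """Per-position HiSol scores with sign-class and absolute ranks."""

    scores: list[PositionScore]
    scale: HydropathyScale
    source_profile: AlignmentProfile

    @property
    def length(self) -> int:
        return len(self.scores)

    def score_array(self) -> np.ndarray:
        """Scores as floats, NaN at coverage-0 positions."""
        return np.array(
            [np.nan if s.score is None else s.score for s in self.scores]
        )

    def __getitem__(self, position: int) -> PositionScore:
        return self.scores[position - 1]

    def top_negative(self) -> Optional[PositionScore]:
        neg = [s for s in self.scores if s.score is not None and s.score < 0]
        return min(neg, key=lambda s: (s.score, s.position)) if neg else None

    def top_positive(self) -> Optional[PositionScore]:
        pos = [s for s in self.scores if s.score is not None and s.score > 0]
        return max(pos, key=lambda s: (s.score, -s.position)) if pos else None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": [s.position for s in self.scores],
                "wt_residue": [s.wt_residue for s in self.scores],
                "score": [s.score for s in self.scores],
                "signed_rank": [s.signed_rank for s in self.scores],
                "abs_rank": [s.abs_rank for s in self.scores],
                "coverage": [s.coverage for s in self.scores],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df["score"] = df["score"].map(
            lambda v: "NA" if pd.isna(v) else f"{v:.6f}"
        )
        for col in ("signed_rank", "abs_rank"):
            df[col] = df[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
        df.to_csv(path, sep="\t", index=False)


def hisol_profile(
    profile: AlignmentProfile,
    scale: HydropathyScale,
) -> HiSolProfile:
    """Score every target position and assign ranks.

    Vectorized over positions; equivalent to calling :func:`hisol_score`
    per position.  Scores of exactly 0 rank in the non-negative class.
    """
    hvec = scale.normalized_vector
    wt_idx = np.array([_AA_POS0[r] for r in profile.target_sequence])
    raw_scores = hvec[wt_idx] - (profile.composition / 100.0) @ hvec
    covered = profile.coverage > 0

    scores = [
        PositionScore(
            position=j + 1,
            wt_residue=profile.target_sequence[j],
            score=float(raw_scores[j]) if covered[j] else None,
            coverage=int(profile.coverage[j]),
        )
        for j in range(profile.length)
    ]

    present = [s for s in scores if s.score is not None]
    negatives = sorted(
        (s for s in present if s.score < 0), key=lambda s: (s.score, s.position)
    )
    nonneg = sorted(
        (s for s in present if s.score >= 0), key=lambda s: (-s.score, s.position)
    )
    for rank, s in enumerate(negatives, start=1):
        s.signed_rank = rank
    for rank, s in enumerate(nonneg, start=1):
        s.signed_rank = rank
    by_abs = sorted(present, key=lambda s: (-abs(s.score), s.position))
    for rank, s in enumerate(by_abs, start=1):
        s.abs_rank = rank

    return HiSolProfile(scores=scores, scale=scale, source_profile=profile)
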