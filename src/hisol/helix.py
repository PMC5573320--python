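"""Helical-wheel geometry and the hydropathy-mismatch rule for α-helices.

An ideal α-helix advances 100° per residue when projected down its axis
(3.6 residues per turn).  Summing unit vectors at each residue's wheel
angle, weighted by normalized hydropathy, gives the hydrophobic moment;
its direction marks the hydrophobic face.  A hydrophobic residue sitting
on the hydrophilic face (or vice versa) contradicts the amphipathic
pattern of a solvent-exposed helix and is a candidate aggregation
hotspot.  This path needs no homolog alignment at all.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .hydropathy import HydropathyScale

WHEEL_STEP_DEG = 100.0
MIN_HELIX_LENGTH = 7          # two full turns
AMPHIPATHICITY_FLOOR = 0.15   # mean moment per residue, normalized units

# Trp and Pro side chains behave hydrophobically despite negative
# hydropathy index values; they are exempt from mismatch calls.
MISMATCH_EXEMPT = frozenset("WP")

VALID_SS_LABELS = frozenset("HEC")


class SecondaryStructureError(ValueError):
    """Unparseable annotation or annotation/sequence disagreement."""


@dataclass(frozen=True)
class SecondaryStructure:
    """Per-residue H/E/C labels, optionally with ss2 confidences.

    ``confidences`` rows are (coil, helix, strand) probabilities as
    printed by PSIPRED's vertical format.
    """

    labels: str
    confidences: Optional[np.ndarray] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        bad = set(self.labels) - VALID_SS_LABELS
        if bad:
            raise SecondaryStructureError(
                f"unknown secondary-structure labels: {sorted(bad)}"
            )
        if self.confidences is not None and len(self.confidences) != len(self.labels):
            raise SecondaryStructureError("confidences length mismatch")

    def __len__(self) -> int:
        return len(self.labels)

    def label(self, position: int) -> str:
        if not 1 <= position <= len(self.labels):
            raise IndexError(f"position {position} outside 1..{len(self.labels)}")
        return self.labels[position - 1]


def parse_secondary_structure(
    source: str | Path,
    format: str = "plain",
    target_sequence: Optional[str] = None,
) -> SecondaryStructure:
    """Parse a PSIPRED ss2 / horiz file or a plain H/E/C string.

    ``source`` is a path for file formats and the literal string for
    ``plain``.  When ``target_sequence`` is given, its length (and, for
    file formats, the residue letters in the file) must match.
    """
    fmt = format.lower()
    if fmt == "plain":
        ss = SecondaryStructure(labels=str(source).strip().upper())
    elif fmt == "ss2":
        ss = _parse_ss2(Path(source))
    elif fmt == "horiz":
        ss = _parse_horiz(Path(source))
    else:
        raise SecondaryStructureError(f"unknown annotation format: {format!r}")

    if target_sequence is not None:
        if len(ss) != len(target_sequence):
            raise SecondaryStructureError(
                f"annotation length {len(ss)} != target length {len(target_sequence)}"
            )
        if ss.sequence is not None and ss.sequence != target_sequence:
            diffs = [
                i + 1
                for i, (a, b) in enumerate(zip(ss.sequence, target_sequence))
                if a != b
            ]
            raise SecondaryStructureError(
                f"annotation residues disagree with target at positions {diffs[:5]}"
            )
    return ss


def _parse_ss2(path: Path) -> SecondaryStructure:
    # Vertical format: index, residue, label, then coil/helix/strand scores.
    labels, residues, confs = [], [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 6:
            raise SecondaryStructureError(f"malformed ss2 line: {line!r}")
        residues.append(parts[1])
        labels.append(parts[2])
        confs.append([float(x) for x in parts[3:6]])
    if not labels:
        raise SecondaryStructureError(f"no records in ss2 file: {path}")
    return SecondaryStructure(
        labels="".join(labels),
        confidences=np.array(confs),
        sequence="".join(residues),
    )


def _parse_horiz(path: Path) -> SecondaryStructure:
    pred, aa = [], []
    for line in path.read_text().splitlines():
        if line.startswith("Pred:"):
            pred.append(line[5:].strip())
        elif line.startswith("  AA:") or line.startswith("AA:"):
            aa.append(line.split(":", 1)[1].strip())
    if not pred:
        raise SecondaryStructureError(f"no Pred: lines in horiz file: {path}")
    return SecondaryStructure(
        labels="".join(pred),
        sequence="".join(aa) if aa else None,
    )


def extract_helices(
    ss: SecondaryStructure, min_length: int = MIN_HELIX_LENGTH
) -> list[tuple[int, int]]:
    """Maximal runs of H of at least ``min_length``, as 1-based (start, end)."""
    return [
        (m.start() + 1, m.end())
        for m in re.finditer("H+", ss.labels)
        if m.end() - m.start() >= min_length
    ]


@dataclass
class HelixSegment:
    """One α-helix laid onto the wheel, with faces and mismatch calls.

    ``moment_magnitude`` is the mean hydrophobic moment per residue
    (normalized hydropathy units); below the amphipathicity floor the
    helix has no meaningful axis and ``face`` is None (undetermined),
    which implies no mismatches.  ``face`` otherwise assigns each residue
    to the hydrophobic semicircle (within 90° of the moment direction) or
    the hydrophilic one.
    """

    start: int
    end: int
    residues: str
    wheel_angles: np.ndarray            # degrees, first residue at 0
    moment_magnitude: float             # per residue
    moment_angle: Optional[float]       # degrees in [0, 360)
    face: Optional[list[str]]           # "hydrophobic" / "hydrophilic"
    mismatches: list[int]               # 1-based target positions

    @property
    def determined(self) -> bool:
        return self.face is not None

    def __len__(self) -> int:
        return self.end - self.start + 1


def wheel_angle(offset: int) -> float:
    """Wheel angle in degrees of the residue ``offset`` steps from the start."""
    return (offset * WHEEL_STEP_DEG) % 360.0


def analyze_helix(
    sequence: str,
    start: int,
    scale: HydropathyScale,
    min_length: int = MIN_HELIX_LENGTH,
    amphipathicity_floor: float = AMPHIPATHICITY_FLOOR,
) -> HelixSegment:
    """Wheel-project a helix and flag hydropathy/face mismatches.

    A residue mismatches when its raw-hydropathy class (positive =
    hydrophobic) disagrees with the face it occupies; Trp and Pro are
    never called.  ``start`` is the 1-based target position of the first
    residue, used only to report positions.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < min_length:
        raise ValueError(
            f"segment of length {n} is below the helix floor ({min_length})"
        )
    bad = sorted(set(sequence) - set(scale.raw))
    if bad:
        raise ValueError(f"non-canonical residues in helix: {bad}")

    angles_deg = np.array([wheel_angle(k) for k in range(n)])
    angles = np.deg2rad(angles_deg)
    h = np.array([scale.normalized[r] for r in sequence])
    mx = float((h * np.cos(angles)).sum())
    my = float((h * np.sin(angles)).sum())
    magnitude = math.hypot(mx, my) / n

    if magnitude < amphipathicity_floor:
        return HelixSegment(
            start=start,
            end=start + n - 1,
            residues=sequence,
            wheel_angles=angles_deg,
            moment_magnitude=magnitude,
            moment_angle=None,
            face=None,
            mismatches=[],
        )

    moment_angle = math.atan2(my, mx)
    on_phobic_face = np.cos(angles - moment_angle) > 0.0
    face = ["hydrophobic" if p else "hydrophilic" for p in on_phobic_face]

    mismatches = []
    for k, r in enumerate(sequence):
        if r in MISMATCH_EXEMPT:
            continue
        hydrophobic_residue = scale.is_hydrophobic(r)
        if hydrophobic_residue and face[k] == "hydrophilic":
            mismatches.append(start + k)
        elif not hydrophobic_residue and face[k] == "hydrophobic":
            mismatches.append(start + k)

    return HelixSegment(
        start=start,
        end=start + n - 1,
        residues=sequence,
        wheel_angles=angles_deg,
        moment_magnitude=magnitude,
        moment_angle=math.degrees(moment_angle) % 360.0,
        face=face,
        mismatches=mismatches,
    )
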