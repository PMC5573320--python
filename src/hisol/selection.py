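"""Hotspot candidate selection and consensus-replacement suggestion.

Two selection routes are combined here:

* the hydropathy-contradiction rule — extreme HiSol scores, with a
  count-dependent cap: when more than ``max_candidates`` positions exceed
  the threshold (condition A) only the ``max_candidates`` largest are
  kept, otherwise (condition B) every supra-threshold position is kept;
* the α-helix rule — wheel-face mismatches inside predicted helices,
  which requires no alignment and therefore works for proteins with no
  close homologs.

The combined rule intersects the first with helix membership.  Selected
positions are then paired with consensus residues (conservation above a
cutoff, wild type excluded) as replacement suggestions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, NamedTuple, Optional

from .alignment import AlignmentProfile, consensus_residues
from .helix import (
    AMPHIPATHICITY_FLOOR,
    MIN_HELIX_LENGTH,
    SecondaryStructure,
    analyze_helix,
    extract_helices,
)
from .hydropathy import HiSolProfile, HydropathyScale

logger = logging.getLogger("hisol")

RULE_CONTRADICTION = "hydropathy_contradiction"
RULE_ALPHA_HELIX = "alpha_helix"
RULE_COMBINED = "combined"


@dataclass(frozen=True)
class SelectionConfig:
    """Knobs of the contradiction rule.

    ``threshold`` applies to ``|score|`` in the default absolute mode;
    ``mode="signed"`` compares the raw score (a literal reading of the
    published "> 1.0" wording, exposed for fidelity experiments).
    """

    threshold: float = 1.0
    max_candidates: int = 10
    consensus_min_rate: float = 10.0
    require_helix: bool = False
    mode: Literal["absolute", "signed"] = "absolute"

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")


class Suggestion(NamedTuple):
    residue: str
    rate: float
    preferred: bool  # hydropathy sign opposes the wild type's


@dataclass
class CandidateMutation:
    """A hotspot position with the rule(s) that selected it."""

    position: int
    wt_residue: str
    score: Optional[float]
    rules: set[str] = field(default_factory=set)
    in_helix: Optional[bool] = None
    suggestions: list[Suggestion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("a candidate must carry at least one rule tag")


def select_candidates(
    hisol: HiSolProfile, config: SelectionConfig = SelectionConfig()
) -> list[CandidateMutation]:
    """Apply the contradiction rule's condition A/B selection.

    Returns candidates ordered by decreasing extremity (``|score|`` in
    absolute mode), ties broken by ascending position.  Coverage-0
    positions never qualify.
    """
    key = abs if config.mode == "absolute" else float
    qualifying = [
        s
        for s in hisol.scores
        if s.score is not None and key(s.score) > config.threshold
    ]
    qualifying.sort(key=lambda s: (-key(s.score), s.position))
    if len(qualifying) > config.max_candidates:  # condition A
        qualifying = qualifying[: config.max_candidates]
    return [
        CandidateMutation(
            position=s.position,
            wt_residue=s.wt_residue,
            score=s.score,
            rules={RULE_CONTRADICTION},
        )
        for s in qualifying
    ]


def apply_combined_rule(
    candidates: list[CandidateMutation], ss: SecondaryStructure
) -> list[CandidateMutation]:
    """Keep contradiction-rule candidates that sit on an α-helix.

    Every input candidate gets its ``in_helix`` flag set; the retained
    ones additionally carry the combined tag.  The output is always a
    subset of the input.
    """
    retained = []
    for cand in candidates:
        label = ss.label(cand.position)  # raises if beyond annotation
        cand.in_helix = label == "H"
        if cand.in_helix:
            cand.rules.add(RULE_COMBINED)
            retained.append(cand)
    return retained


def alpha_helix_rule_candidates(
    target_sequence: str,
    ss: SecondaryStructure,
    scale: HydropathyScale,
    min_helix_length: int = MIN_HELIX_LENGTH,
    amphipathicity_floor: float = AMPHIPATHICITY_FLOOR,
) -> list[CandidateMutation]:
    """Wheel-mismatch candidates over all predicted helices.

    Needs only the target sequence and its secondary structure — no
    homolog alignment — so the returned candidates carry no score.
    """
    if len(ss) != len(target_sequence):
        raise ValueError(
            f"annotation length {len(ss)} != target length {len(target_sequence)}"
        )
    candidates = []
    for start, end in extract_helices(ss, min_length=min_helix_length):
        segment = analyze_helix(
            target_sequence[start - 1 : end],
            start,
            scale,
            min_length=min_helix_length,
            amphipathicity_floor=amphipathicity_floor,
        )
        for pos in segment.mismatches:
            candidates.append(
                CandidateMutation(
                    position=pos,
                    wt_residue=target_sequence[pos - 1],
                    score=None,
                    rules={RULE_ALPHA_HELIX},
                    in_helix=True,
                )
            )
    return candidates


def suggest_mutations(
    candidate: CandidateMutation,
    profile: AlignmentProfile,
    scale: HydropathyScale,
    config: SelectionConfig = SelectionConfig(),
) -> CandidateMutation:
    """Attach consensus-replacement suggestions to a candidate.

    Suggestions are the residues conserved above ``consensus_min_rate``
    at the position, wild type excluded, in descending rate order.  A
    suggestion whose hydropathy sign opposes the wild type's is flagged
    preferred: it is the replacement that corrects the contradiction.
    """
    if profile.coverage[candidate.position - 1] == 0:
        logger.warning(
            "no suggestions for position %d: coverage 0", candidate.position
        )
        candidate.suggestions = []
        return candidate
    wt_hydrophobic = scale.is_hydrophobic(candidate.wt_residue)
    candidate.suggestions = [
        Suggestion(
            residue=res,
            rate=rate,
            preferred=scale.is_hydrophobic(res) != wt_hydrophobic,
        )
        for res, rate in consensus_residues(
            profile, candidate.position, min_rate=config.consensus_min_rate
        )
        if res != candidate.wt_residue
    ]
    return candidate


def find_hotspots(
    hisol: HiSolProfile,
    config: SelectionConfig = SelectionConfig(),
    ss: Optional[SecondaryStructure] = None,
) -> list[CandidateMutation]:
    """Full selection pipeline: condition A/B, optional helix filter,
    consensus suggestions."""
    candidates = select_candidates(hisol, config)
    if config.require_helix:
        if ss is None:
            raise ValueError("require_helix set but no secondary structure given")
        candidates = apply_combined_rule(candidates, ss)
    elif ss is not None:
        for cand in candidates:
            cand.in_helix = ss.label(cand.position) == "H"
    for cand in candidates:
        suggest_mutations(cand, hisol.source_profile, hisol.scale, config)
    return candidates
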