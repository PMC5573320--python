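import numpy as np
import pytest

from hisol import (
    AMINO_ACIDS,
    CandidateMutation,
    RULE_ALPHA_HELIX,
    RULE_COMBINED,
    RULE_CONTRADICTION,
    SecondaryStructure,
    SelectionConfig,
    alpha_helix_rule_candidates,
    apply_combined_rule,
    find_hotspots,
    hisol_profile,
    select_candidates,
    suggest_mutations,
)

from conftest import profile_from_rates


def _profile_with_scores(scale, score_map, L=None):
    """Build a HiSol profile whose per-position score signs/magnitudes are
    controlled via pure columns.

    score_map: position -> (wt, consensus) pure-column pair; remaining
    positions are fully conserved (score 0).
    """
    L = L or max(score_map)
    target = []
    rates = {}
    for j in range(1, L + 1):
        if j in score_map:
            wt, cons = score_map[j]
            target.append(wt)
            rates[j] = {cons: 100.0}
        else:
            target.append("A")
            rates[j] = {"A": 100.0}
    prof = profile_from_rates("".join(target), rates)
    return hisol_profile(prof, scale)


# pure-column wt/consensus pairs sorted by decreasing |score| under the
# standardized Kyte-Doolittle scale
EXTREME_PAIRS = [
    ("R", "I"), ("I", "R"), ("K", "I"), ("I", "K"), ("Q", "I"),
    ("I", "Q"), ("D", "I"), ("I", "D"), ("H", "I"), ("I", "H"),
    ("R", "L"), ("L", "R"), ("K", "L"), ("L", "K"), ("Q", "L"),
    ("L", "Q"), ("D", "L"), ("L", "D"), ("H", "L"), ("L", "H"),
]


class TestSelectCandidates:
    @pytest.mark.parametrize("n_supra", range(0, 21))
    def test_condition_a_b_boundary_sweep(self, scale, n_supra):
        score_map = {j + 1: EXTREME_PAIRS[j] for j in range(n_supra)}
        hp = _profile_with_scores(scale, score_map, L=30)
        config = SelectionConfig(threshold=1.0, max_candidates=10)
        cands = select_candidates(hp, config)
        expected = n_supra if n_supra <= 10 else 10
        assert len(cands) == expected
        assert all(RULE_CONTRADICTION in c.rules for c in cands)
        # condition A keeps the largest-|score| positions
        if n_supra > 10:
            kept = {c.position for c in cands}
            scores = {s.position: abs(s.score) for s in hp.scores}
            dropped = {j + 1 for j in range(n_supra)} - kept
            assert max(scores[p] for p in dropped) <= min(scores[p] for p in kept)

    def test_ties_at_cap_resolved_by_position(self, scale):
        # 12 identical |score| positions, cap 10 -> first 10 by position
        score_map = {j: ("K", "I") for j in range(1, 13)}
        hp = _profile_with_scores(scale, score_map, L=15)
        cands = select_candidates(hp, SelectionConfig())
        assert [c.position for c in cands] == list(range(1, 11))

    def test_empty_when_nothing_qualifies(self, scale):
        hp = _profile_with_scores(scale, {1: ("A", "G")}, L=5)
        assert select_candidates(hp, SelectionConfig()) == []

    def test_signed_mode_keeps_only_positive(self, scale):
        hp = _profile_with_scores(scale, {1: ("K", "I"), 2: ("I", "K")}, L=5)
        cands = select_candidates(hp, SelectionConfig(mode="signed"))
        assert [c.position for c in cands] == [2]
        both = select_candidates(hp, SelectionConfig(mode="absolute"))
        assert {c.position for c in both} == {1, 2}

    def test_determinism(self, scale):
        score_map = {j + 1: EXTREME_PAIRS[j] for j in range(15)}
        hp = _profile_with_scores(scale, score_map, L=20)
        runs = [select_candidates(hp, SelectionConfig()) for _ in range(3)]
        assert all(
            [c.position for c in run] == [c.position for c in runs[0]]
            for run in runs
        )


class TestCombinedRule:
    def test_helix_positions_retained_and_tagged(self, scale):
        hp = _profile_with_scores(scale, {2: ("K", "I"), 5: ("I", "K")}, L=8)
        cands = select_candidates(hp, SelectionConfig())
        ss = SecondaryStructure("CHHHCCCC")
        kept = apply_combined_rule(cands, ss)
        assert [c.position for c in kept] == [2]
        assert RULE_COMBINED in kept[0].rules and kept[0].in_helix
        # the coil candidate was flagged but removed
        dropped = [c for c in cands if c.position == 5][0]
        assert dropped.in_helix is False

    def test_subset_property(self, scale):
        rng = np.random.default_rng(9)
        score_map = {j + 1: EXTREME_PAIRS[j] for j in range(12)}
        hp = _profile_with_scores(scale, score_map, L=20)
        cands = select_candidates(hp, SelectionConfig())
        labels = "".join(rng.choice(list("HEC"), 20))
        kept = apply_combined_rule(cands, SecondaryStructure(labels))
        assert {c.position for c in kept} <= {c.position for c in cands}

    def test_empty_input(self):
        assert apply_combined_rule([], SecondaryStructure("CCC")) == []

    def test_position_beyond_annotation(self, scale):
        hp = _profile_with_scores(scale, {4: ("K", "I")}, L=4)
        cands = select_candidates(hp, SelectionConfig())
        with pytest.raises(IndexError):
            apply_combined_rule(cands, SecondaryStructure("CC"))


class TestAlphaHelixRule:
    def test_published_segment_yields_candidate_without_msa(self, scale):
        # embed the flavin-oxidase helix in a coil context: positions
        # 443-460 of a synthetic target
        segment = "RVDIDTMVRGVHVALNFG"
        target = "A" * 442 + segment + "A" * 5
        labels = "C" * 442 + "H" * 18 + "C" * 5
        cands = alpha_helix_rule_candidates(
            target, SecondaryStructure(labels), scale
        )
        positions = {c.position for c in cands}
        assert 455 in positions
        for c in cands:
            assert c.rules == {RULE_ALPHA_HELIX}
            assert c.in_helix and c.score is None

    def test_all_coil_empty(self, scale):
        cands = alpha_helix_rule_candidates(
            "MKILVAQWED", SecondaryStructure("C" * 10), scale
        )
        assert cands == []

    def test_non_amphipathic_helix_empty(self, scale):
        cands = alpha_helix_rule_candidates(
            "L" * 18, SecondaryStructure("H" * 18), scale
        )
        assert cands == []


class TestSuggestMutations:
    def test_consensus_replacement_like_published_rows(self, scale):
        # Ile target over Lys 53% / Ile 17% -> top suggestion Lys (I->K)
        prof = profile_from_rates(
            "I", {1: {"K": 53.0, "I": 17.0, "R": 10.0, "L": 20.0}}
        )
        cand = CandidateMutation(1, "I", 1.9, {RULE_CONTRADICTION})
        suggest_mutations(cand, prof, scale)
        assert cand.suggestions[0].residue == "K"
        assert cand.suggestions[0].rate == pytest.approx(53.0)
        assert cand.suggestions[0].preferred  # opposite hydropathy sign

    def test_single_conserved_residue(self, scale):
        prof = profile_from_rates("Q", {1: {"V": 73.0, "Q": 27.0}})
        cand = CandidateMutation(1, "Q", -2.2, {RULE_CONTRADICTION})
        suggest_mutations(cand, prof, scale)
        assert [s.residue for s in cand.suggestions] == ["V", "Q"][:1]

    def test_wild_type_excluded(self, scale):
        prof = profile_from_rates("K", {1: {"K": 100.0}})
        cand = CandidateMutation(1, "K", 0.1, {RULE_CONTRADICTION})
        suggest_mutations(cand, prof, scale)
        assert cand.suggestions == []

    def test_sorted_by_rate_on_random_profiles(self, scale):
        rng = np.random.default_rng(31)
        for _ in range(20):
            comp = rng.dirichlet(np.ones(20) * 0.3) * 100
            wt = AMINO_ACIDS[rng.integers(20)]
            prof = profile_from_rates(wt, {1: dict(zip(AMINO_ACIDS, comp))})
            cand = CandidateMutation(1, wt, 1.5, {RULE_CONTRADICTION})
            suggest_mutations(cand, prof, scale)
            rates = [s.rate for s in cand.suggestions]
            assert rates == sorted(rates, reverse=True)
            assert wt not in {s.residue for s in cand.suggestions}

    def test_candidate_requires_rule_tag(self):
        with pytest.raises(ValueError):
            CandidateMutation(1, "K", 0.5, set())


class TestFindHotspots:
    def test_require_helix_pipeline(self, scale):
        hp = _profile_with_scores(scale, {2: ("K", "I"), 5: ("I", "K")}, L=8)
        cands = find_hotspots(
            hp, SelectionConfig(require_helix=True), SecondaryStructure("CHHHCCCC")
        )
        assert [c.position for c in cands] == [2]
        assert cands[0].suggestions[0].residue == "I"
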