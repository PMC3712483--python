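"""Cosegregation search: expected patterns, dropout/gain scoring, the
candidate filter on the published patterns, split-locus rescue, orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cepmap.coseg_search import (
    LocusPatterns,
    SearchThresholds,
    SegregationPattern,
    alignment_identity,
    expected_pattern,
    find_candidates,
    infer_orientation,
    rescue_split_loci,
    score_pattern,
)
from cepmap.datasets import MARKER_PATTERNS

S = SegregationPattern.from_string

BANDING_EXPECTED = "100000000000001111111111"
COLOUR_EXPECTED = "101111111111110000000000"


class TestExpectedPattern:
    def test_banding_in_phase(self, panel):
        assert (
            expected_pattern("banding", "in_phase_dominant", panel).to_string()
            == BANDING_EXPECTED
        )

    def test_colour_in_phase(self, panel):
        assert (
            expected_pattern("colour", "in_phase_dominant", panel).to_string()
            == COLOUR_EXPECTED
        )

    def test_alternative_allele_present_in_all(self, panel):
        assert expected_pattern("banding", "alternative", panel).to_string() == "1" * 24

    def test_unknown_phase_rejected(self, panel):
        with pytest.raises(ValueError):
            expected_pattern("spread-band", "in_phase_dominant", panel)

    def test_phase_expectations_far_apart(self, panel):
        # no pattern within the allowances can match both phases
        colour = expected_pattern("colour", "in_phase_dominant", panel)
        banding = expected_pattern("banding", "in_phase_dominant", panel)
        assert int(np.sum(colour.presence != banding.presence)) == 22


class TestScorePattern:
    @pytest.mark.parametrize(
        "marker, allele_idx, phase, expected_score",
        [
            ("Cne_RAD08", 0, "banding", (0, 0)),
            ("Cne_RAD05", 0, "colour", (1, 0)),
            ("Cne_RAD04", 0, "banding", (1, 1)),
            ("Cne_RAD01", 0, "banding", (0, 2)),
            ("Cne_RAD06", 0, "colour", (2, 0)),
        ],
    )
    def test_published_marker_scores(self, panel, marker, allele_idx, phase, expected_score):
        pattern = S(MARKER_PATTERNS[marker][allele_idx][1])
        expected = expected_pattern(phase, "in_phase_dominant", panel)
        assert score_pattern(pattern, expected) == expected_score

    def test_self_score_is_zero(self, panel):
        exp = expected_pattern("colour", "in_phase_dominant", panel)
        assert score_pattern(exp, exp) == (0, 0)

    def test_confirmed_x_counts_as_dropout_in_search(self, panel):
        # Cne_RAD02's in-phase allele has one 'x': sequence-absent at search time
        pattern = S(MARKER_PATTERNS["Cne_RAD02"][0][1])
        expected = expected_pattern("banding", "in_phase_dominant", panel)
        assert score_pattern(pattern, expected) == (1, 0)

    def test_length_mismatch_rejected(self, panel):
        with pytest.raises(ValueError, match="length"):
            score_pattern(S("10"), expected_pattern("colour", "in_phase_dominant", panel))

    @given(st.lists(st.integers(0, 1), min_size=24, max_size=24))
    @settings(max_examples=100, deadline=None)
    def test_dropouts_plus_gains_equal_hamming_distance(self, bits):
        observed = SegregationPattern.from_presence(bits)
        expected = S(BANDING_EXPECTED)
        d, g = score_pattern(observed, expected)
        assert d + g == int(np.sum(observed.presence != expected.presence))


class TestFindCandidates:
    def test_all_eleven_published_markers_accepted(self, panel, marker_loci):
        accepted = find_candidates(marker_loci, panel)
        assert {c.locus_id for c in accepted} == set(MARKER_PATTERNS)

    def test_published_phase_calls(self, panel, marker_loci):
        phases = {c.locus_id: c.phase for c in find_candidates(marker_loci, panel)}
        banding = {f"Cne_RAD{i:02d}" for i in (1, 2, 3, 4, 8, 9, 10)}
        colour = {f"Cne_RAD{i:02d}" for i in (5, 6, 7, 11)}
        assert {m for m, p in phases.items() if p == "banding"} == banding
        assert {m for m, p in phases.items() if p == "colour"} == colour

    def test_three_gains_rejected(self, panel):
        pattern = list(BANDING_EXPECTED)
        for i in (2, 3, 4):
            pattern[i] = "1"
        locus = LocusPatterns("noisy", [("a1", S("".join(pattern))), ("a2", S("1" * 24))])
        assert find_candidates([locus], panel) == []

    def test_excess_alternative_dropouts_rejected(self, panel):
        alt = "1" * 18 + "0" * 6  # six dropouts in an allele expected everywhere
        locus = LocusPatterns("altbad", [("a1", S(BANDING_EXPECTED)), ("a2", S(alt))])
        assert find_candidates([locus], panel) == []

    def test_monotone_in_thresholds(self, panel, marker_loci, rng):
        # raising any allowance never removes a candidate
        base_thresholds = SearchThresholds()
        noisy = []
        for i in range(60):
            bits = rng.integers(0, 2, size=24)
            noisy.append(
                LocusPatterns(
                    f"rand{i}",
                    [("a1", SegregationPattern.from_presence(bits)), ("a2", S("1" * 24))],
                )
            )
        pool = list(marker_loci) + noisy
        base = {c.locus_id for c in find_candidates(pool, panel, base_thresholds)}
        raised = {
            c.locus_id
            for c in find_candidates(pool, panel, base_thresholds.raised(2))
        }
        assert base <= raised

    def test_planted_loci_recovered_exactly_among_unlinked(self, panel, rng):
        # 1,000 unlinked random biallelic loci + 5 planted linked (no dropout)
        loci = []
        for i in range(1000):
            a1 = rng.integers(0, 2, size=24)
            a2 = rng.integers(0, 2, size=24)
            loci.append(
                LocusPatterns(
                    f"unlinked{i}",
                    [
                        ("a1", SegregationPattern.from_presence(a1)),
                        ("a2", SegregationPattern.from_presence(a2)),
                    ],
                )
            )
        for i, phase in enumerate(("colour", "banding", "colour", "banding", "colour")):
            loci.append(
                LocusPatterns(
                    f"planted{i}",
                    [
                        ("a1", expected_pattern(phase, "in_phase_dominant", panel)),
                        ("a2", S("1" * 24)),
                    ],
                )
            )
        accepted = {c.locus_id for c in find_candidates(loci, panel)}
        assert accepted == {f"planted{i}" for i in range(5)}

    def test_false_positive_rate_matches_direct_scoring_oracle(self, panel, rng):
        # oracle: independent plain-loop scorer over the same null patterns
        thresholds = SearchThresholds()
        colour = [c == "1" for c in COLOUR_EXPECTED]
        banding = [c == "1" for c in BANDING_EXPECTED]
        n_loci = 4000
        accepted_impl = 0
        accepted_oracle = 0
        for i in range(n_loci):
            bits = rng.integers(0, 2, size=24)
            bits[0] = 1
            bits[1] = 0  # father-specific allele under the unlinked null
            locus = LocusPatterns(
                f"null{i}",
                [
                    ("a1", SegregationPattern.from_presence(bits)),
                    ("a2", S("1" * 24)),
                ],
            )
            if find_candidates([locus], panel, thresholds):
                accepted_impl += 1
            ok = False
            for exp in (colour, banding):
                drop = sum(1 for b, e in zip(bits, exp) if e and not b)
                gain = sum(1 for b, e in zip(bits, exp) if b and not e)
                if drop <= 2 and gain <= 2:
                    ok = True
            if ok:
                accepted_oracle += 1
        p = accepted_oracle / n_loci
        se = max((p * (1 - p) / n_loci) ** 0.5, 1 / n_loci)
        assert abs(accepted_impl - accepted_oracle) / n_loci <= 3 * se


class TestRescueSplitLoci:
    def _with_seq(self, locus_id, allele_id, pattern, seq):
        return LocusPatterns(
            locus_id, [(allele_id, S(pattern))], sequences={allele_id: seq}
        )

    def test_indel_split_pair_regrouped(self, panel, rng):
        base = "".join(rng.choice(list("ACGT"), 96))
        shifted = base[:40] + "GGA" + base[40:93]  # 3-base insertion
        singleton = self._with_seq("single", "a1", BANDING_EXPECTED, base)
        other = self._with_seq("other", "a1", "1" * 24, shifted)
        (regrouped,) = rescue_split_loci([singleton], [singleton, other])
        assert len(regrouped.alleles) == 2
        assert find_candidates([regrouped], panel)

    def test_distant_alleles_not_grouped(self, panel, rng):
        base = "".join(rng.choice(list("ACGT"), 96))
        chars = list(base)
        for i in rng.choice(96, size=15, replace=False):
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        singleton = self._with_seq("single", "a1", BANDING_EXPECTED, base)
        other = self._with_seq("other", "a1", "1" * 24, "".join(chars))
        (regrouped,) = rescue_split_loci([singleton], [singleton, other])
        assert len(regrouped.alleles) == 1

    def test_six_substitutions_beyond_cluster_distance_rescued(self, panel, rng):
        base = "".join(rng.choice(list("ACGT"), 96))
        chars = list(base)
        for i in rng.choice(96, size=6, replace=False):
            chars[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[i]]
        singleton = self._with_seq("single", "a1", BANDING_EXPECTED, base)
        other = self._with_seq("other", "a1", "1" * 24, "".join(chars))
        (regrouped,) = rescue_split_loci([singleton], [singleton, other])
        assert len(regrouped.alleles) == 2
        accepted = find_candidates([regrouped], panel)
        assert accepted and accepted[0].phase == "banding"

    def test_identity_values(self, rng):
        base = "".join(rng.choice(list("ACGT"), 96))
        indel = base[:40] + "GGA" + base[40:93]
        assert alignment_identity(base, indel) >= 0.95
        assert alignment_identity(base, base) == 1.0


class TestInferOrientation:
    def test_shared_recombinant_same_side(self, panel):
        # Cne_RAD04's in-phase allele switches at panel positions 3 and 21
        pattern = S(MARKER_PATTERNS["Cne_RAD04"][0][1])
        calls = infer_orientation(
            {"cand": ("banding", pattern)},
            {"Cne_RAD04": [3, 21]},
            panel,
            reference_id="Cne_RAD04",
        )
        assert calls[0].side == "same_as"

    def test_switch_on_other_flank_opposite_side(self, panel):
        pattern = S(MARKER_PATTERNS["Cne_RAD04"][0][1])
        calls = infer_orientation(
            {"cand": ("banding", pattern)},
            {"ref": [5], "flank_b": [3, 21]},
            panel,
            reference_id="ref",
        )
        assert calls[0].side == "opposite_to"

    def test_perfect_pattern_undetermined(self, panel):
        pattern = expected_pattern("banding", "in_phase_dominant", panel)
        calls = infer_orientation(
            {"cand": ("banding", pattern)}, {"ref": [3]}, panel, reference_id="ref"
        )
        assert calls[0].side == "undetermined"
        assert "closest mapped interval" in calls[0].linkage_bound

    def test_no_recombinants_all_undetermined(self, panel):
        pattern = S(MARKER_PATTERNS["Cne_RAD04"][0][1])
        calls = infer_orientation({"cand": ("banding", pattern)}, {}, panel)
        assert calls[0].side == "undetermined"
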