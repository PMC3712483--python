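"""Dropout-tolerant cosegregation search for supergene-linked RAD loci.

In a repulsion pseudo-testcross the father's two supergene haplotypes
(``CP-Bb`` and ``Cy-BO``) segregate cleanly into pink-banded and
yellow-unbanded offspring, so a RAD allele riding either haplotype shows a
characteristic presence/absence pattern over the sequencing panel.  Low,
PCR-duplicate-inflated coverage causes allelic dropout, so the search allows
a bounded number of dropouts (allele expected but unseen) and putative
recombinants (allele seen where unexpected) when matching each observed
pattern against the two in-phase expectations, and checks every alternative
allele of the locus against its own expectation with looser dropout budgets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from Bio import Align

__all__ = [
    "Individual",
    "IndividualPanel",
    "default_panel",
    "SegregationPattern",
    "SearchThresholds",
    "LocusPatterns",
    "CandidateMarker",
    "OrientationCall",
    "expected_pattern",
    "score_pattern",
    "find_candidates",
    "alignment_identity",
    "rescue_split_loci",
    "infer_orientation",
]


@dataclass(frozen=True)
class Individual:
    id: str
    role: str  # "father" | "mother" | "offspring"
    phenotype_class: str  # e.g. "pink-banded"


class IndividualPanel:
    """Ordered panel of sequenced individuals.

    The order is part of the pattern serialization contract: father, mother,
    then offspring grouped by phenotype class.
    """

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals = tuple(individuals)
        roles = [i.role for i in self.individuals]
        if roles.count("father") != 1 or roles.count("mother") != 1:
            raise ValueError("panel needs exactly one father and one mother")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(i.id for i in self.individuals)

    def mask(self, predicate) -> np.ndarray:
        return np.array([bool(predicate(i)) for i in self.individuals])


def default_panel() -> IndividualPanel:
    """The study's 24-individual panel: father, mother, 12 pink-banded and
    10 yellow-unbanded offspring."""
    from .datasets import PANEL_SPEC

    return IndividualPanel([Individual(*row) for row in PANEL_SPEC])


@dataclass(frozen=True)
class SegregationPattern:
    """Binary presence vector over the panel, with a mask of positions where
    the allele was sequence-absent but later confirmed present ('x')."""

    presence: np.ndarray  # int8 0/1
    dropout_mask: np.ndarray  # bool; True where 'x'

    @classmethod
    def from_string(cls, s: str) -> "SegregationPattern":
        s = s.strip()
        bad = set(s) - set("01x")
        if bad:
            raise ValueError(f"pattern cells must be 0/1/x, got {sorted(bad)}")
        presence = np.array([1 if c == "1" else 0 for c in s], dtype=np.int8)
        mask = np.array([c == "x" for c in s])
        return cls(presence=presence, dropout_mask=mask)

    @classmethod
    def from_presence(cls, presence: Sequence[int]) -> "SegregationPattern":
        arr = np.asarray(presence, dtype=np.int8)
        return cls(presence=arr, dropout_mask=np.zeros(arr.shape, dtype=bool))

    def to_string(self) -> str:
        return "".join(
            "x" if m else str(int(p))
            for p, m in zip(self.presence, self.dropout_mask)
        )

    def __len__(self) -> int:
        return len(self.presence)


@dataclass(frozen=True)
class SearchThresholds:
    """Dropout / recombinant allowances of the candidate search."""

    max_inphase_dropouts: int = 2
    max_putative_recombinants: int = 2
    max_alt_dropouts_all: int = 5
    max_alt_dropouts_small: int = 2
    small_expected_cutoff: int = 14

    def raised(self, by: int) -> "SearchThresholds":
        return SearchThresholds(
            self.max_inphase_dropouts + by,
            self.max_putative_recombinants + by,
            self.max_alt_dropouts_all + by,
            self.max_alt_dropouts_small + by,
            self.small_expected_cutoff,
        )


STRICT_THRESHOLDS = SearchThresholds(0, 0, 0, 0, 14)


@dataclass
class LocusPatterns:
    """Observed patterns of one locus: (allele_id, pattern) pairs, optionally
    with allele sequences for the split-locus rescue."""

    locus_id: str
    alleles: list[tuple[str, SegregationPattern]]
    sequences: dict[str, str] = field(default_factory=dict)


@dataclass
class CandidateMarker:
    locus_id: str
    phase: str  # "colour" | "banding" | "unknown"
    in_phase_allele: str
    inphase_dropouts: int
    putative_recombinants: int
    alt_allele_dropouts: dict[str, int]
    accepted: bool = True


def _dominant_class(phase: str) -> str:
    if phase == "colour":
        return "pink-banded"
    if phase == "banding":
        return "yellow-unbanded"
    raise ValueError(f"unknown phase {phase!r}")


def expected_pattern(
    phase: str, allele_role: str, panel: IndividualPanel
) -> SegregationPattern:
    """Expected presence pattern for an allele linked to the supergene.

    ``in_phase_dominant``: the allele rides the father haplotype carrying the
    dominant allele of ``phase`` (colour → present in father and pink
    offspring; banding → father and unbanded offspring).  ``alternative``: a
    recessive-phase allele shared by the father's other haplotype and the
    mother — present in every individual.
    """
    if allele_role == "alternative":
        ones = np.ones(len(panel), dtype=np.int8)
        return SegregationPattern.from_presence(ones)
    if allele_role != "in_phase_dominant":
        raise ValueError(f"unknown allele role {allele_role!r}")
    dom = _dominant_class(phase)
    present = panel.mask(
        lambda ind: ind.role == "father"
        or (ind.role == "offspring" and ind.phenotype_class == dom)
    )
    return SegregationPattern.from_presence(present.astype(np.int8))


def score_pattern(
    observed: SegregationPattern, expected: SegregationPattern
) -> tuple[int, int]:
    """(dropouts, gains) of an observed pattern against an expectation.

    Dropouts: expected present, observed absent (positions confirmed present
    only by follow-up PCR — the mask — still count: they were sequence-absent
    at search time).  Gains: observed present where absence was expected
    (putative recombinants).
    """
    if len(observed) != len(expected):
        raise ValueError(
            f"pattern length {len(observed)} != expectation length {len(expected)}"
        )
    obs = observed.presence
    exp = expected.presence
    dropouts = int(np.sum((exp == 1) & (obs == 0)))
    gains = int(np.sum((exp == 0) & (obs == 1)))
    return dropouts, gains


def _alternative_expectations(
    panel: IndividualPanel, in_phase: str
) -> list[tuple[str, SegregationPattern]]:
    """Plausible expectations for a non-in-phase allele of a candidate locus.

    Biallelic loci have an alternative allele shared by the father's other
    haplotype and the mother (present everywhere).  Tri/tetra-allelic loci can
    also carry a father-only allele expected in the father plus the offspring
    class complementary to the in-phase allele, or a mother allele expected in
    the mother and all offspring.
    """
    n = len(panel)
    out = [("all", SegregationPattern.from_presence(np.ones(n, dtype=np.int8)))]
    other = "pink-banded" if in_phase == "banding" else "yellow-unbanded"
    father_other = panel.mask(
        lambda ind: ind.role == "father"
        or (ind.role == "offspring" and ind.phenotype_class == other)
    )
    out.append(
        ("father_other", SegregationPattern.from_presence(father_other.astype(np.int8)))
    )
    mother_all = panel.mask(lambda ind: ind.role != "father")
    out.append(
        ("mother_all", SegregationPattern.from_presence(mother_all.astype(np.int8)))
    )
    return out


def _score_alternative(
    pattern: SegregationPattern,
    panel: IndividualPanel,
    in_phase: str,
    thresholds: SearchThresholds,
) -> tuple[bool, int]:
    """Best-matching alternative expectation; returns (ok, dropouts)."""
    best_ok, best_drop = False, len(panel) + 1
    for _, exp in _alternative_expectations(panel, in_phase):
        n_expected = int(exp.presence.sum())
        limit = (
            thresholds.max_alt_dropouts_small
            if n_expected <= thresholds.small_expected_cutoff
            else thresholds.max_alt_dropouts_all
        )
        drop, gain = score_pattern(pattern, exp)
        ok = drop <= limit and gain <= thresholds.max_putative_recombinants
        if (ok, -drop) > (best_ok, -best_drop):
            best_ok, best_drop = ok, drop
    return best_ok, best_drop


def find_candidates(
    loci: Iterable[LocusPatterns],
    panel: IndividualPanel,
    thresholds: SearchThresholds = SearchThresholds(),
) -> list[CandidateMarker]:
    """Loci whose allele patterns cosegregate with the supergene.

    A locus is accepted when some allele matches a colour- or banding-phase
    in-phase expectation within the dropout/recombinant allowances and every
    other allele matches an alternative-allele expectation within the
    alternative dropout budgets.
    """
    expectations = {
        phase: expected_pattern(phase, "in_phase_dominant", panel)
        for phase in ("colour", "banding")
    }
    out: list[CandidateMarker] = []
    for locus in loci:
        matches = []  # (allele_id, phase, dropouts, gains)
        for allele_id, pattern in locus.alleles:
            for phase, exp in expectations.items():
                drop, gain = score_pattern(pattern, exp)
                if (
                    drop <= thresholds.max_inphase_dropouts
                    and gain <= thresholds.max_putative_recombinants
                ):
                    matches.append((allele_id, phase, drop, gain))
        if not matches:
            continue
        # Best in-phase match: fewest mismatches, ties by allele id.
        matches.sort(key=lambda m: (m[2] + m[3], m[0]))
        allele_id, phase, drop, gain = matches[0]
        phases_matched = {m[1] for m in matches if m[0] == allele_id}
        alt_dropouts: dict[str, int] = {}
        all_ok = True
        for other_id, pattern in locus.alleles:
            if other_id == allele_id:
                continue
            ok, alt_drop = _score_alternative(pattern, panel, phase, thresholds)
            alt_dropouts[other_id] = alt_drop
            all_ok = all_ok and ok
        if not all_ok:
            continue
        out.append(
            CandidateMarker(
                locus_id=locus.locus_id,
                phase="unknown" if len(phases_matched) > 1 else phase,
                in_phase_allele=allele_id,
                inphase_dropouts=drop,
                putative_recombinants=gain,
                alt_allele_dropouts=alt_dropouts,
            )
        )
    return out


def _make_aligner() -> Align.PairwiseAligner:
    # Global alignment with free end gaps; scores chosen so gaps are opened
    # only when substitutions cannot explain the difference.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    aligner.end_gap_score = 0.0
    return aligner


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Identity of the best global alignment with free end gaps:
    matches / alignment columns, end-gap columns excluded."""
    aligner = _make_aligner()
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    a, b = str(alignment[0]), str(alignment[1])
    # Trim columns where either sequence has an end gap.
    start = max(len(a) - len(a.lstrip("-")), len(b) - len(b.lstrip("-")))
    end = len(a) - max(len(a) - len(a.rstrip("-")), len(b) - len(b.rstrip("-")))
    if end <= start:
        return 0.0
    cols = end - start
    matches = sum(1 for x, y in zip(a[start:end], b[start:end]) if x == y and x != "-")
    return matches / cols


def rescue_split_loci(
    singleton_loci: Iterable[LocusPatterns],
    all_loci: Iterable[LocusPatterns],
    min_identity: float = 0.90,
) -> list[LocusPatterns]:
    """Regroup single-allele candidate loci with alleles split off by indels
    or excess polymorphism.

    Each singleton allele is aligned (indel-aware, free end gaps) against
    every allele of every other locus; partners at ≥ ``min_identity`` are
    folded into a new locus, which can then be re-scored by
    :func:`find_candidates`.
    """
    all_list = list(all_loci)
    out: list[LocusPatterns] = []
    for singleton in singleton_loci:
        if len(singleton.alleles) != 1:
            raise ValueError(f"{singleton.locus_id} is not a singleton locus")
        (allele_id,) = [a for a, _ in singleton.alleles]
        seq = singleton.sequences.get(allele_id)
        if seq is None:
            raise ValueError(f"no sequence stored for {singleton.locus_id}/{allele_id}")
        grouped = LocusPatterns(
            locus_id=f"{singleton.locus_id}+rescued",
            alleles=list(singleton.alleles),
            sequences=dict(singleton.sequences),
        )
        for other in all_list:
            if other.locus_id == singleton.locus_id:
                continue
            for other_id, pattern in other.alleles:
                other_seq = other.sequences.get(other_id)
                if other_seq is None:
                    continue
                if alignment_identity(seq, other_seq) >= min_identity:
                    key = f"{other.locus_id}/{other_id}"
                    grouped.alleles.append((key, pattern))
                    grouped.sequences[key] = other_seq
        out.append(grouped)
    return out


@dataclass
class OrientationCall:
    candidate_id: str
    reference_id: str | None
    side: str  # "same_as" | "opposite_to" | "undetermined"
    linkage_bound: str = ""


def _switch_set(
    pattern: SegregationPattern,
    phase: str,
    panel: IndividualPanel,
    offspring_idx: set[int],
) -> set[int]:
    exp = expected_pattern(phase, "in_phase_dominant", panel)
    mism = pattern.presence != exp.presence
    return {int(i) for i in np.nonzero(mism)[0] if i in offspring_idx}


def infer_orientation(
    candidates: Mapping[str, tuple[str, SegregationPattern]],
    recombinant_individuals: Mapping[str, Sequence[int]],
    panel: IndividualPanel,
    reference_id: str | None = None,
) -> list[OrientationCall]:
    """Orient unassayed candidates relative to a mapped reference marker.

    ``recombinant_individuals`` lists, per mapped marker, the panel indices of
    offspring validated as carrying a crossover between that marker and the
    supergene.  A candidate whose pattern switches in a validated recombinant
    individual of the reference marker lies on the same side of the supergene
    as the reference; a candidate that is parental there but switches in a
    recombinant of a marker on the other flank lies on the opposite side; a
    candidate with no informative mismatch is left undetermined, bounded by
    the closest mapped interval.
    """
    validated: dict[str, set[int]] = {
        ref: set(map(int, idxs)) for ref, idxs in recombinant_individuals.items()
    }
    all_validated = set().union(*validated.values()) if validated else set()
    if reference_id is None and validated:
        reference_id = sorted(validated)[0]
    offspring = {i for i, ind in enumerate(panel) if ind.role == "offspring"}
    calls: list[OrientationCall] = []
    for cand_id, (phase, pattern) in candidates.items():
        if not all_validated:
            calls.append(OrientationCall(cand_id, reference_id, "undetermined"))
            continue
        switches = _switch_set(pattern, phase, panel, offspring)
        if switches & validated[reference_id]:
            calls.append(OrientationCall(cand_id, reference_id, "same_as"))
        elif switches & all_validated:
            calls.append(OrientationCall(cand_id, reference_id, "opposite_to"))
        else:
            bound = "<= closest mapped interval"
            calls.append(OrientationCall(cand_id, reference_id, "undetermined", bound))
    return calls
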