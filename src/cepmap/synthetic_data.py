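"""Synthetic data with the statistical structure the pipeline assumes.

The generator emulates the study design end to end: a repulsion
pseudo-testcross segregating a non-recombining colour/banding supergene,
RAD marker loci at known map positions in known phase on the informative
parent's haplotypes, Poisson fragment coverage with depth-driven allelic
dropout, PCR duplication of paired-end reads, and in-silico SbfI digestion
of toy genomes into barcoded 101-base read pairs.  Every run is reproducible:
all randomness flows from one seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cross_genetics import (
    BandAllele,
    ColourAllele,
    CrossDesign,
    SupergeneDiplotype,
    SupergeneHaplotype,
    phenotype_of,
)
from .coseg_search import Individual, IndividualPanel, LocusPatterns, SegregationPattern
from .linkage_map import kosambi_inverse
from .rad_loci import ReadPair, SBFI_MOTIF, SBFI_REMNANT, TAG_LENGTH

__all__ = [
    "SimulationConfig",
    "CrossTruth",
    "PresenceTruth",
    "ToyGenome",
    "ReadSimTruth",
    "FIG3_LIKE_POSITIONS",
    "FIG3_LIKE_PHASES",
    "simulate_cross",
    "simulate_presence_matrix",
    "make_toy_genome",
    "simulate_reads",
    "make_barcodes",
    "make_paper_fixtures",
]


def _default_cross() -> CrossDesign:
    # The RAD-sequenced mapping cross: doubly heterozygous repulsion father,
    # double homozygous recessive mother.
    return CrossDesign(
        mother=SupergeneDiplotype.from_tokens("Cy-Bb", "Cy-Bb"),
        father=SupergeneDiplotype.from_tokens("CP-Bb", "Cy-BO"),
        label="mapping-cross",
    )


# A local map shaped like the published one: eleven markers spanning 35.8 cM
# around the supergene, three of them co-located 0.98 cM proximal, banding-
# phase markers on one flank and colour-phase markers on the other.  The
# exact published inter-marker spacings are not recoverable, so round values
# at the same scale are used.
FIG3_LIKE_POSITIONS: tuple[float, ...] = (
    0.0, 4.0, 8.0, 12.0, 15.6, 15.6, 15.6, 21.0, 25.5, 30.5, 35.8
)
FIG3_LIKE_PHASES: tuple[str, ...] = (
    "banding", "banding", "banding", "banding", "banding", "banding", "banding",
    "colour", "colour", "colour", "colour",
)
FIG3_LIKE_SUPERGENE_CM = 16.58  # 0.98 cM from the co-located marker trio


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition defaults: 22 sequenced offspring, mean fragment
    coverage 6.6 per allele, 66.7% PCR duplicates, presence requires depth ≥ 2."""

    seed: int = 0
    n_offspring: int = 22
    marker_positions_cm: tuple[float, ...] = FIG3_LIKE_POSITIONS
    marker_phases: tuple[str, ...] = FIG3_LIKE_PHASES
    supergene_position_cm: float = FIG3_LIKE_SUPERGENE_CM
    coverage_lambda: float = 6.6
    pcr_duplicate_rate: float = 0.667
    min_depth_for_presence: int = 2
    base_error_rate: float = 0.0
    supergene_r: float = 0.0  # recombination fraction between C and B
    cross: CrossDesign = field(default_factory=_default_cross)

    def __post_init__(self) -> None:
        if len(self.marker_positions_cm) != len(self.marker_phases):
            raise ValueError("one phase per marker position required")
        bad = set(self.marker_phases) - {"colour", "banding", "unlinked"}
        if bad:
            raise ValueError(f"unknown marker phases: {sorted(bad)}")
        if not 0 <= self.pcr_duplicate_rate < 1:
            raise ValueError("pcr_duplicate_rate must be in [0, 1)")
        if self.coverage_lambda <= 0:
            raise ValueError("coverage_lambda must be positive")
        if any(p < 0 for p in self.marker_positions_cm):
            raise ValueError("marker positions must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class CrossTruth:
    """Ground truth of one simulated cross.

    ``father_gametes[i, j]`` is the father haplotype index (0/1) transmitted
    to offspring ``i`` at locus ``j``; loci are the markers in config order
    followed by the supergene as the last column.  Unlinked markers carry an
    independent coin flip.
    """

    marker_names: list[str]
    marker_phases: list[str]
    marker_positions_cm: list[float]
    father_gametes: np.ndarray
    mother_gametes: np.ndarray
    phenotype_classes: list[str]
    inphase_haplotype: dict[str, int]  # phase -> father haplotype index

    @property
    def supergene_column(self) -> int:
        return len(self.marker_names) - 1


def _haplotype_index(diplotype: SupergeneDiplotype, phase: str) -> int:
    """Index of the haplotype carrying the dominant allele of ``phase``."""
    for idx, hap in enumerate(diplotype.haplotypes):
        if phase == "colour" and hap.colour is ColourAllele.CP:
            return idx
        if phase == "banding" and hap.band is BandAllele.BO:
            return idx
    raise ValueError(f"parent carries no dominant {phase} allele")


def _simulate_gametes(
    rng: np.random.Generator,
    n: int,
    positions: np.ndarray,
    linked: np.ndarray,
) -> np.ndarray:
    """Haplotype-index vectors for n gametes over ordered loci.

    At most one crossover per adjacent interval, with probability equal to the
    Kosambi-inverse of the interval length; unlinked loci segregate as
    independent coin flips.
    """
    k = len(positions)
    out = np.zeros((n, k), dtype=np.int8)
    linked_idx = np.nonzero(linked)[0]
    if linked_idx.size:
        order = linked_idx[np.argsort(positions[linked_idx], kind="stable")]
        current = rng.integers(0, 2, size=n).astype(np.int8)
        out[:, order[0]] = current
        for prev, nxt in zip(order, order[1:]):
            r = kosambi_inverse(abs(positions[nxt] - positions[prev]))
            flip = rng.random(n) < r
            current = np.where(flip, 1 - current, current).astype(np.int8)
            out[:, nxt] = current
    for j in np.nonzero(~linked)[0]:
        out[:, j] = rng.integers(0, 2, size=n)
    return out


def simulate_cross(config: SimulationConfig) -> CrossTruth:
    """Simulate offspring gametes and phenotypes for the configured cross."""
    rng = config.rng()
    father = config.cross.father
    mother = config.cross.mother
    inphase = {}
    for phase in ("colour", "banding"):
        try:
            inphase[phase] = _haplotype_index(father, phase)
        except ValueError:
            inphase[phase] = -1
    for phase in set(config.marker_phases) - {"unlinked"}:
        if inphase.get(phase, -1) < 0:
            raise ValueError(
                f"father cannot anchor {phase}-phase markers: no dominant allele"
            )
    names = [f"M{i+1:02d}" for i in range(len(config.marker_phases))] + ["CB"]
    positions = np.array(list(config.marker_positions_cm) + [config.supergene_position_cm])
    linked = np.array(
        [ph != "unlinked" for ph in config.marker_phases] + [True]
    )
    father_gametes = _simulate_gametes(rng, config.n_offspring, positions, linked)
    mother_gametes = _simulate_gametes(rng, config.n_offspring, positions, linked)
    sg = len(names) - 1
    # The gamete column tracks the C locus; the B allele recombines away from
    # it with probability supergene_r (zero by default: one Mendelian unit).
    n = config.n_offspring
    band_f = father_gametes[:, sg].copy()
    band_m = mother_gametes[:, sg].copy()
    if config.supergene_r > 0:
        flip_f = rng.random(n) < config.supergene_r
        flip_m = rng.random(n) < config.supergene_r
        band_f = np.where(flip_f, 1 - band_f, band_f).astype(np.int8)
        band_m = np.where(flip_m, 1 - band_m, band_m).astype(np.int8)
    classes = []
    for i in range(n):
        hap_f = SupergeneHaplotype(
            father.haplotypes[father_gametes[i, sg]].colour,
            father.haplotypes[band_f[i]].band,
        )
        hap_m = SupergeneHaplotype(
            mother.haplotypes[mother_gametes[i, sg]].colour,
            mother.haplotypes[band_m[i]].band,
        )
        dip = SupergeneDiplotype(hap_f, hap_m)
        classes.append(phenotype_of(dip).class_name)
    return CrossTruth(
        marker_names=names,
        marker_phases=list(config.marker_phases) + ["supergene"],
        marker_positions_cm=list(positions),
        father_gametes=father_gametes,
        mother_gametes=mother_gametes,
        phenotype_classes=classes,
        inphase_haplotype=inphase,
    )


@dataclass
class PresenceTruth:
    """True allele presence before dropout, plus the cross ground truth."""

    cross: CrossTruth
    panel: IndividualPanel
    true_presence: dict[str, dict[str, np.ndarray]]  # locus -> allele -> 0/1
    linked: dict[str, bool]
    phases: dict[str, str]


_CLASS_ORDER = ("pink-banded", "yellow-unbanded", "pink-unbanded", "yellow-banded")


def _panel_from_truth(truth: CrossTruth) -> tuple[IndividualPanel, list[int]]:
    """Panel in canonical order (father, mother, offspring grouped by class)
    plus the offspring indices in panel order."""
    order = sorted(
        range(len(truth.phenotype_classes)),
        key=lambda i: (_CLASS_ORDER.index(truth.phenotype_classes[i]), i),
    )
    individuals = [
        Individual("father", "father", "pink-unbanded"),
        Individual("mother", "mother", "yellow-banded"),
    ]
    for rank, i in enumerate(order, start=1):
        individuals.append(
            Individual(f"off{rank:02d}", "offspring", truth.phenotype_classes[i])
        )
    return IndividualPanel(individuals), order


def _true_presence_vectors(
    truth: CrossTruth, offspring_order: list[int]
) -> dict[str, dict[str, np.ndarray]]:
    n_panel = 2 + len(offspring_order)
    out: dict[str, dict[str, np.ndarray]] = {}
    for j, name in enumerate(truth.marker_names[:-1]):
        phase = truth.marker_phases[j]
        carrier = truth.inphase_haplotype.get(phase, 0) if phase != "unlinked" else 0
        inphase = np.zeros(n_panel, dtype=np.int8)
        inphase[0] = 1  # father carries the in-phase allele
        for pos, i in enumerate(offspring_order, start=2):
            inphase[pos] = 1 if truth.father_gametes[i, j] == carrier else 0
        alt = np.ones(n_panel, dtype=np.int8)  # shared by mother + other hap
        out[name] = {"inphase": inphase, "alt": alt}
    return out


def simulate_presence_matrix(
    config: SimulationConfig,
) -> tuple[list[LocusPatterns], PresenceTruth]:
    """Presence/absence pattern matrix over the panel with Poisson dropout.

    Each marker locus is biallelic: the in-phase allele rides the father
    haplotype given by the marker's phase; the alternative allele is shared by
    the father's other haplotype and the mother, hence truly present in every
    individual.  Observed presence requires fragment depth ≥
    ``min_depth_for_presence`` with depth ~ Poisson(coverage_lambda); absence
    is never spuriously converted to presence.
    """
    truth = simulate_cross(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    panel, order = _panel_from_truth(truth)
    true_pres = _true_presence_vectors(truth, order)
    loci: list[LocusPatterns] = []
    linked: dict[str, bool] = {}
    phases: dict[str, str] = {}
    for j, name in enumerate(truth.marker_names[:-1]):
        alleles = []
        for allele_name, vec in true_pres[name].items():
            depth = rng.poisson(config.coverage_lambda, size=len(vec))
            observed = (vec == 1) & (depth >= config.min_depth_for_presence)
            alleles.append(
                (allele_name, SegregationPattern.from_presence(observed.astype(np.int8)))
            )
        loci.append(LocusPatterns(locus_id=name, alleles=alleles))
        linked[name] = truth.marker_phases[j] != "unlinked"
        phases[name] = truth.marker_phases[j]
    return loci, PresenceTruth(
        cross=truth, panel=panel, true_presence=true_pres, linked=linked,
        phases=phases,
    )


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class ToyGenome:
    sequence: str
    site_positions: list[int]  # start index of each SbfI motif


def make_toy_genome(
    seed: int,
    n_sites: int,
    spacing: int = 1500,
    flank: int = 800,
) -> ToyGenome:
    """Random genome containing exactly ``n_sites`` SbfI sites at known,
    well-separated positions (accidental motifs are scrubbed)."""
    rng = np.random.default_rng(seed)
    length = 2 * flank + max(n_sites - 1, 0) * spacing + len(SBFI_MOTIF)
    seq = rng.choice(_BASES, size=length)
    genome = "".join(seq)
    # scrub accidental motifs (forward strand; the simulator reads both flanks
    # of planted sites only)
    while SBFI_MOTIF in genome:
        at = genome.find(SBFI_MOTIF)
        genome = genome[:at] + "".join(rng.choice(_BASES, size=len(SBFI_MOTIF))) + genome[at + len(SBFI_MOTIF):]
    positions = [flank + i * spacing for i in range(n_sites)]
    chars = list(genome)
    for pos in positions:
        chars[pos : pos + len(SBFI_MOTIF)] = SBFI_MOTIF
    return ToyGenome(sequence="".join(chars), site_positions=positions)


@dataclass
class ReadSimTruth:
    cross: CrossTruth
    panel: IndividualPanel
    barcodes: dict[str, str]  # individual -> barcode
    locus_tags: dict[str, dict[str, str]]  # locus -> allele -> tag sequence
    polymorphic_loci: dict[str, str]  # locus -> phase
    n_fragments: int
    n_reads: int

    @property
    def duplicate_fraction(self) -> float:
        return 1.0 - self.n_fragments / self.n_reads if self.n_reads else 0.0


def make_barcodes(individual_ids: Sequence[str]) -> dict[str, str]:
    """Deterministic 5-base barcodes, pairwise ≥ 2 mismatches apart."""
    import itertools as it

    chosen: list[str] = []
    out: dict[str, str] = {}
    ids = list(individual_ids)
    for code in ("".join(c) for c in it.product("ACGT", repeat=5)):
        if all(sum(a != b for a, b in zip(code, prev)) >= 2 for prev in chosen):
            chosen.append(code)
            out[ids[len(chosen) - 1]] = code
            if len(chosen) == len(ids):
                return out
    raise ValueError("too many individuals for the barcode space")


def _mutate_tag(rng: np.random.Generator, tag: str, n_subs: int, start: int = 6) -> str:
    """Substitute ``n_subs`` bases after ``start`` (keeps the remnant intact)."""
    chars = list(tag)
    sites = rng.choice(np.arange(start, len(chars)), size=n_subs, replace=False)
    for i in sites:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def simulate_reads(
    genome: ToyGenome,
    config: SimulationConfig,
    variant_substitutions: int = 3,
    shear_range: tuple[int, int] = (300, 600),
) -> tuple[list[ReadPair], ReadSimTruth]:
    """Barcoded paired-end RAD library from a toy genome.

    Each SbfI site yields two 96-base tags (one per flank, each beginning with
    the ``TGCAGG`` remnant).  The first ``len(config.marker_phases)`` sites are
    polymorphic markers: their right-flank tag carries substitutions on the
    father haplotype dictated by the marker's phase, while the reference tag is
    shared by the father's other haplotype and the mother.  Fragment depth per
    allele per individual is Poisson(coverage_lambda); each fragment gets an
    independent shear point (read2), and PCR duplication re-reads a fragment
    with probability ``pcr_duplicate_rate`` per copy (geometric read counts).
    """
    n_markers = len(config.marker_phases)
    if len(genome.site_positions) < n_markers:
        raise ValueError("toy genome has fewer sites than configured markers")
    if not genome.site_positions:
        import warnings

        warnings.warn("genome contains no restriction sites; empty library")
        truth = simulate_cross(config)
        panel, _ = _panel_from_truth(truth)
        return [], ReadSimTruth(truth, panel, {}, {}, {}, 0, 0)

    truth = simulate_cross(config)
    panel, order = _panel_from_truth(truth)
    true_pres = _true_presence_vectors(truth, order)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
    )
    barcodes = make_barcodes(panel.ids)
    g = genome.sequence
    motif_len = len(SBFI_MOTIF)

    locus_tags: dict[str, dict[str, str]] = {}
    polymorphic: dict[str, str] = {}
    reads: list[ReadPair] = []
    n_fragments = n_reads = 0
    lo, hi = shear_range
    qual = "I" * (5 + TAG_LENGTH)

    for s, pos in enumerate(genome.site_positions):
        right_ref = g[pos + 2 : pos + 2 + TAG_LENGTH]
        left_ref = _revcomp(g[pos + motif_len - 2 - TAG_LENGTH : pos + motif_len - 2])
        assert right_ref.startswith(SBFI_REMNANT) and left_ref.startswith(SBFI_REMNANT)
        is_marker = s < n_markers
        marker_name = truth.marker_names[s] if is_marker else None
        site_id = f"site{s:02d}"
        if is_marker:
            variant = _mutate_tag(rng, right_ref, variant_substitutions)
            locus_tags[f"{site_id}R"] = {"inphase": variant, "alt": right_ref}
            polymorphic[f"{site_id}R"] = truth.marker_phases[s]
        else:
            locus_tags[f"{site_id}R"] = {"alt": right_ref}
        locus_tags[f"{site_id}L"] = {"alt": left_ref}

        for p_idx, ind in enumerate(panel):
            carried: list[tuple[str, str, str]] = []  # (allele_key, tag, flank)
            if is_marker:
                if true_pres[marker_name]["inphase"][p_idx]:
                    carried.append(("inphase", locus_tags[f"{site_id}R"]["inphase"], "R"))
                carried.append(("alt", right_ref, "R"))
            else:
                carried.append(("alt", right_ref, "R"))
            carried.append(("alt", left_ref, "L"))

            for allele_key, tag, flank in carried:
                depth = rng.poisson(config.coverage_lambda)
                for f_idx in range(depth):
                    u = int(rng.integers(lo, hi + 1))
                    if flank == "R":
                        end = pos + 2 + u
                        read2 = _revcomp(g[end - 101 : end])
                    else:
                        start = pos + motif_len - 2 - u
                        read2 = g[start : start + 101]
                    n_fragments += 1
                    n_copies = int(rng.geometric(1.0 - config.pcr_duplicate_rate))
                    for c in range(n_copies):
                        seq1 = barcodes[ind.id] + _apply_errors(
                            rng, tag, config.base_error_rate
                        )
                        reads.append(
                            ReadPair(
                                read_id=f"{ind.id}:{site_id}{flank}:{allele_key}:{f_idx}:{c}",
                                seq1=seq1,
                                qual1=qual,
                                seq2=_apply_errors(rng, read2, config.base_error_rate),
                                qual2="I" * len(read2),
                            )
                        )
                        n_reads += 1
    return reads, ReadSimTruth(
        cross=truth,
        panel=panel,
        barcodes=barcodes,
        locus_tags=locus_tags,
        polymorphic_loci=polymorphic,
        n_fragments=n_fragments,
        n_reads=n_reads,
    )


def make_paper_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the packaged study tables as byte-stable pipeline-format files.

    Emits the cross designs, the per-cross phenotype counts, the panel
    definition, and the marker segregation-pattern matrix.
    """
    from . import io as cio
    from .datasets import CROSS_COUNTS, CROSSES, MARKER_ASSAYS, MARKER_PATTERNS, PANEL_SPEC

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["crosses"] = out / "crosses.tsv"
    cio.write_crosses(paths["crosses"], CROSSES)

    paths["table1"] = out / "table1.tsv"
    cio.write_phenotype_counts(paths["table1"], CROSS_COUNTS)

    paths["panel"] = out / "panel.tsv"
    cio.write_panel(paths["panel"], [Individual(*row) for row in PANEL_SPEC])

    paths["table3_patterns"] = out / "table3_patterns.tsv"
    panel_ids = [row[0] for row in PANEL_SPEC]
    loci = [
        LocusPatterns(
            locus_id=marker,
            alleles=[
                (allele, SegregationPattern.from_string(pattern))
                for allele, pattern in rows
            ],
        )
        for marker, rows in MARKER_PATTERNS.items()
    ]
    comments = [f"assay {m}: {a}" for m, a in MARKER_ASSAYS.items()]
    cio.write_pattern_matrix(paths["table3_patterns"], loci, panel_ids, comments)
    return paths
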