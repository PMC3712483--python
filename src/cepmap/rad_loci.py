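"""RAD locus construction from barcoded paired-end reads.

Reads carry a 5-base inline barcode followed by the SbfI restriction-site
remnant (``TGCAGG``) and genomic tag sequence.  The pipeline demultiplexes by
exact barcode, trims to 96-base tags, clusters tag variants into alleles and
loci within each individual (quality-aware Hamming distance, single linkage),
collapses PCR duplicates by distinct paired-end shear signatures to estimate
fragment counts, merges loci across individuals, and applies the
repeat/singleton filters.  A closed-form prediction of the expected number of
RAD loci from genome size and GC content is included for sanity checks.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ReadPair",
    "BarcodeSet",
    "DemuxResult",
    "RadAllele",
    "RadLocus",
    "DigestPrediction",
    "SBFI_MOTIF",
    "SBFI_REMNANT",
    "TAG_LENGTH",
    "demultiplex",
    "estimate_fragment_counts",
    "cluster_alleles",
    "merge_across_individuals",
    "expected_locus_count",
    "build_loci",
]

SBFI_MOTIF = "CCTGCAGG"
SBFI_REMNANT = "TGCAGG"  # left on the read after the SbfI cut
BARCODE_LENGTH = 5
TAG_LENGTH = 96


@dataclass(frozen=True)
class ReadPair:
    """One paired-end read: read1 = barcode + remnant + tag, read2 = the
    sheared fragment end."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.read_id}: sequence/quality length mismatch")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class BarcodeSet:
    """Barcode → individual map; barcodes must be unique, uniform-length and
    pairwise ≥ 2 mismatches apart so single errors cannot cross-assign."""

    def __init__(self, mapping: Mapping[str, str]):
        if len(set(mapping.values())) != len(mapping):
            raise ValueError("duplicate individual in barcode set")
        lengths = {len(b) for b in mapping}
        if len(lengths) > 1:
            raise ValueError("barcodes must have uniform length")
        codes = list(mapping)
        for i, a in enumerate(codes):
            for b in codes[i + 1 :]:
                if _hamming(a, b) < 2:
                    raise ValueError(
                        f"barcodes {a} and {b} differ at fewer than 2 bases"
                    )
        self.mapping = dict(mapping)
        self.length = lengths.pop() if lengths else BARCODE_LENGTH

    def __len__(self) -> int:
        return len(self.mapping)

    def assign(self, barcode: str, allow_one_mismatch: bool = False) -> str | None:
        """Individual for a barcode; exact match by default.  The optional
        1-mismatch rescue is unambiguous because barcodes are ≥ 2 apart."""
        hit = self.mapping.get(barcode)
        if hit is not None or not allow_one_mismatch:
            return hit
        for code, ind in self.mapping.items():
            if _hamming(code, barcode) == 1:
                return ind
        return None


@dataclass
class TaggedRead:
    """A demultiplexed read: the 96-base tag (remnant + genomic sequence),
    its qualities, and the paired-end shear signature."""

    tag: str
    tag_qual: str
    read2: str


@dataclass
class DemuxResult:
    by_individual: dict[str, list[TaggedRead]]
    n_input: int
    n_assigned: int
    n_discarded: int


def demultiplex(
    reads: Iterable[ReadPair],
    barcodes: BarcodeSet,
    motif_remnant: str = SBFI_REMNANT,
    allow_one_mismatch: bool = False,
) -> DemuxResult:
    """Assign read pairs to individuals and trim barcodes.

    Reads whose barcode is not in the set, or whose restriction-site remnant
    does not match exactly, are discarded and counted.
    """
    bl = barcodes.length
    out: dict[str, list[TaggedRead]] = {ind: [] for ind in barcodes.mapping.values()}
    n_input = n_assigned = 0
    for pair in reads:
        n_input += 1
        individual = barcodes.assign(pair.seq1[:bl], allow_one_mismatch)
        if individual is None:
            continue
        tag = pair.seq1[bl:]
        if not tag.startswith(motif_remnant):
            continue
        out[individual].append(
            TaggedRead(tag=tag, tag_qual=pair.qual1[bl:], read2=pair.seq2)
        )
        n_assigned += 1
    return DemuxResult(
        by_individual=out,
        n_input=n_input,
        n_assigned=n_assigned,
        n_discarded=n_input - n_assigned,
    )


def estimate_fragment_counts(read2_sequences: Iterable[str]) -> int:
    """Fragment count for one allele in one individual: the number of
    distinct paired-end shear signatures (PCR duplicates share a read2)."""
    return len(set(read2_sequences))


@dataclass
class ClusteredAllele:
    tag: str
    read_count: int
    fragment_count: int


@dataclass
class IndividualLocus:
    """A within-individual cluster of allele tags."""

    alleles: list[ClusteredAllele]

    @property
    def representative(self) -> str:
        return self.alleles[0].tag


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def _masked_distance(
    tag_a: str, qual_a: Sequence[int], tag_b: str, qual_b: Sequence[int],
    min_quality: int,
) -> int:
    """Hamming distance over positions where both bases exceed ``min_quality``.

    Low-quality positions are treated as matching; N never matches anything.
    """
    dist = 0
    for xa, qa, xb, qb in zip(tag_a, qual_a, tag_b, qual_b):
        if qa <= min_quality or qb <= min_quality:
            continue
        if xa == "N" or xb == "N" or xa != xb:
            dist += 1
    return dist


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_alleles(
    reads: Sequence[TaggedRead],
    max_distance: int = 5,
    min_quality: int = 20,
    min_depth: int = 2,
) -> list[IndividualLocus]:
    """Cluster one individual's tags into candidate loci.

    Identical tags form candidate alleles (depth < ``min_depth`` discarded;
    per-position quality is the best seen across the allele's reads); alleles
    within ``max_distance`` mismatches over mutually high-quality positions
    are joined into one locus by single linkage.  Fragment counts collapse
    PCR duplicates via distinct read2 sequences.  Output ordering is
    canonical (depth-desc, then tag) and independent of input order.
    """
    lengths = {len(r.tag) for r in reads}
    if len(lengths) > 1:
        raise ValueError(f"mixed tag lengths {sorted(lengths)}; indels unsupported")
    groups: dict[str, list[TaggedRead]] = defaultdict(list)
    for r in reads:
        groups[r.tag].append(r)
    alleles: list[tuple[str, list[int], int, int]] = []  # tag, qual, depth, frags
    for tag, members in groups.items():
        if len(members) < min_depth:
            continue
        best_qual = [0] * len(tag)
        for m in members:
            for i, q in enumerate(_phred(m.tag_qual)):
                if q > best_qual[i]:
                    best_qual[i] = q
        frags = estimate_fragment_counts(m.read2 for m in members)
        alleles.append((tag, best_qual, len(members), frags))
    # canonical order: depth desc, then tag
    alleles.sort(key=lambda a: (-a[2], a[0]))
    uf = _UnionFind(len(alleles))
    for i in range(len(alleles)):
        for j in range(i + 1, len(alleles)):
            if (
                _masked_distance(
                    alleles[i][0], alleles[i][1], alleles[j][0], alleles[j][1],
                    min_quality,
                )
                <= max_distance
            ):
                uf.union(i, j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(alleles)):
        clusters[uf.find(i)].append(i)
    loci = []
    for root in sorted(clusters, key=lambda r: (-alleles[r][2], alleles[r][0])):
        members = clusters[root]
        members.sort(key=lambda i: (-alleles[i][2], alleles[i][0]))
        loci.append(
            IndividualLocus(
                alleles=[
                    ClusteredAllele(
                        tag=alleles[i][0],
                        read_count=alleles[i][2],
                        fragment_count=alleles[i][3],
                    )
                    for i in members
                ]
            )
        )
    return loci


@dataclass
class RadAllele:
    """One allele of a merged RAD locus with per-individual counts."""

    allele_id: str
    tag: str
    read_counts: dict[str, int] = field(default_factory=dict)
    fragment_counts: dict[str, int] = field(default_factory=dict)

    @property
    def individuals(self) -> set[str]:
        return set(self.read_counts)


@dataclass
class RadLocus:
    locus_id: str
    alleles: list[RadAllele]

    @property
    def individuals(self) -> set[str]:
        out: set[str] = set()
        for a in self.alleles:
            out |= a.individuals
        return out

    def presence_vector(self, allele: RadAllele, panel_ids: Sequence[str]) -> list[int]:
        return [1 if ind in allele.individuals else 0 for ind in panel_ids]


def merge_across_individuals(
    per_individual: Mapping[str, Sequence[IndividualLocus]],
    max_mismatch: int = 3,
    max_alleles: int = 4,
) -> list[RadLocus]:
    """Merge per-individual loci into cross-individual RAD loci.

    Single linkage joins loci whose closest allele pair is ≤ ``max_mismatch``
    (plain Hamming; N matches nothing).  Loci seen in only one individual, or
    with more than ``max_alleles`` distinct allele sequences (presumed repeat
    regions), are discarded.
    """
    items: list[tuple[str, IndividualLocus]] = [
        (ind, locus)
        for ind in sorted(per_individual)
        for locus in per_individual[ind]
    ]
    if not items:
        return []

    def allele_dist(a: str, b: str) -> int:
        if len(a) != len(b):
            return max(len(a), len(b))
        return sum(x != y or x == "N" for x, y in zip(a, b))

    uf = _UnionFind(len(items))
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            dij = min(
                allele_dist(ai.tag, aj.tag)
                for ai in items[i][1].alleles
                for aj in items[j][1].alleles
            )
            if dij <= max_mismatch:
                uf.union(i, j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(items)):
        clusters[uf.find(i)].append(i)

    merged: list[RadLocus] = []
    for members in clusters.values():
        allele_map: dict[str, RadAllele] = {}
        individuals: set[str] = set()
        for idx in members:
            ind, locus = items[idx]
            individuals.add(ind)
            for ca in locus.alleles:
                allele = allele_map.get(ca.tag)
                if allele is None:
                    allele = RadAllele(allele_id="", tag=ca.tag)
                    allele_map[ca.tag] = allele
                allele.read_counts[ind] = allele.read_counts.get(ind, 0) + ca.read_count
                allele.fragment_counts[ind] = (
                    allele.fragment_counts.get(ind, 0) + ca.fragment_count
                )
        if len(individuals) < 2 or len(allele_map) > max_alleles:
            continue
        alleles = sorted(
            allele_map.values(),
            key=lambda a: (-sum(a.read_counts.values()), a.tag),
        )
        merged.append(RadLocus(locus_id="", alleles=alleles))
    # canonical ids by representative tag
    merged.sort(key=lambda loc: loc.alleles[0].tag)
    for i, locus in enumerate(merged, start=1):
        locus.locus_id = f"locus{i:05d}"
        for j, allele in enumerate(locus.alleles, start=1):
            allele.allele_id = f"a{j}"
    return merged


@dataclass(frozen=True)
class DigestPrediction:
    genome_size_bp: float
    gc_fraction: float
    motif: str = SBFI_MOTIF
    tags_per_site: int = 2


def expected_locus_count(prediction: DigestPrediction) -> float:
    """Expected RAD locus count under an independent-base genome model.

    Each motif site contributes ``tags_per_site`` loci (one per flank);
    the per-position motif probability uses p(G)=p(C)=gc/2 and
    p(A)=p(T)=(1−gc)/2.
    """
    if not prediction.motif:
        raise ValueError("empty recognition motif")
    if not 0 < prediction.gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    gc = prediction.gc_fraction
    p = {"G": gc / 2, "C": gc / 2, "A": (1 - gc) / 2, "T": (1 - gc) / 2}
    motif_p = math.prod(p[base] for base in prediction.motif)
    return prediction.genome_size_bp * motif_p * prediction.tags_per_site


def build_loci(
    reads: Iterable[ReadPair],
    barcodes: BarcodeSet,
    max_distance: int = 5,
    min_quality: int = 20,
    min_depth: int = 2,
    max_mismatch: int = 3,
    max_alleles: int = 4,
    allow_one_mismatch: bool = False,
) -> tuple[list[RadLocus], DemuxResult]:
    """Full read→locus pipeline: demultiplex, cluster per individual, merge."""
    demux = demultiplex(reads, barcodes, allow_one_mismatch=allow_one_mismatch)
    per_individual = {
        ind: cluster_alleles(
            tagged, max_distance=max_distance, min_quality=min_quality,
            min_depth=min_depth,
        )
        for ind, tagged in demux.by_individual.items()
        if tagged
    }
    loci = merge_across_individuals(
        per_individual, max_mismatch=max_mismatch, max_alleles=max_alleles
    )
    return loci, demux
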