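"""Supergene cross genetics for *Cepaea nemoralis*.

The shell ground-colour locus (*C*) and the band-presence locus (*B*) sit in a
non-recombining supergene.  Pink (``CP``) is dominant to yellow (``Cy``) and
unbanded (``BO``) is dominant to banded (``Bb``), so a two-locus diplotype maps
onto one of four phenotype classes.  This module represents crosses between
known diplotypes, infers offspring genotype classes back from phenotypes,
counts recombinant offspring, tests Mendelian segregation ratios, places a
posterior upper bound on the recombination fraction between *C* and *B*, and
computes the probability that a set of loci would cluster on one chromosome
by chance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Sequence

from scipy import stats

__all__ = [
    "ColourAllele",
    "BandAllele",
    "SupergeneHaplotype",
    "SupergeneDiplotype",
    "CrossDesign",
    "Phenotype",
    "PhenotypeCounts",
    "PHENOTYPE_CLASSES",
    "Chi2Result",
    "RecombinationEstimate",
    "ClusterProbabilityQuery",
    "GenotypeCall",
    "phenotype_of",
    "infer_offspring_genotypes",
    "count_recombinants",
    "pool_recombinant_counts",
    "chi2_segregation",
    "recombination_upper_limit",
    "supergene_cluster_probability",
]


class ColourAllele(str, Enum):
    """Ground-colour alleles; ``CP`` (pink) is dominant to ``Cy`` (yellow)."""

    CP = "CP"
    Cy = "Cy"


class BandAllele(str, Enum):
    """Band-presence alleles; ``BO`` (unbanded) is dominant to ``Bb`` (banded)."""

    BO = "BO"
    Bb = "Bb"


# Canonical phenotype-class order used for every count vector and table.
PHENOTYPE_CLASSES = (
    "pink-unbanded",
    "pink-banded",
    "yellow-unbanded",
    "yellow-banded",
)


@dataclass(frozen=True)
class SupergeneHaplotype:
    """One supergene haplotype: a colour allele and a band allele in cis."""

    colour: ColourAllele
    band: BandAllele

    @classmethod
    def from_token(cls, token: str) -> "SupergeneHaplotype":
        """Parse a ``"CP-BO"``-style token."""
        try:
            colour_s, band_s = token.strip().split("-")
            return cls(ColourAllele(colour_s), BandAllele(band_s))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed haplotype token {token!r}") from exc

    def token(self) -> str:
        return f"{self.colour.value}-{self.band.value}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


@dataclass(frozen=True)
class Phenotype:
    colour: str  # "pink" | "yellow"
    banded: bool

    @property
    def class_name(self) -> str:
        return f"{self.colour}-{'banded' if self.banded else 'unbanded'}"


@dataclass(frozen=True)
class SupergeneDiplotype:
    """An unordered pair of supergene haplotypes."""

    haplotype_1: SupergeneHaplotype
    haplotype_2: SupergeneHaplotype

    @classmethod
    def from_tokens(cls, token_1: str, token_2: str) -> "SupergeneDiplotype":
        return cls(
            SupergeneHaplotype.from_token(token_1),
            SupergeneHaplotype.from_token(token_2),
        )

    @property
    def haplotypes(self) -> tuple[SupergeneHaplotype, SupergeneHaplotype]:
        return (self.haplotype_1, self.haplotype_2)

    @property
    def is_doubly_heterozygous(self) -> bool:
        h1, h2 = self.haplotypes
        return h1.colour != h2.colour and h1.band != h2.band

    @property
    def phase(self) -> str | None:
        """``"coupling"`` (both dominant alleles in cis), ``"repulsion"``
        (dominants in trans), or ``None`` if not doubly heterozygous.

        Derived from the haplotypes — never stored independently.
        """
        if not self.is_doubly_heterozygous:
            return None
        for hap in self.haplotypes:
            if hap.colour is ColourAllele.CP:
                return "coupling" if hap.band is BandAllele.BO else "repulsion"
        raise AssertionError("unreachable")

    def gametes(self) -> list[tuple[SupergeneHaplotype, bool]]:
        """All gamete haplotypes with a flag marking recombinant gametes.

        Parental gametes are the two haplotypes as carried; recombinant
        gametes swap alleles between them.  For parents not heterozygous at
        both loci, "recombinant" gametes coincide with parental ones and are
        reported as non-recombinant.
        """
        h1, h2 = self.haplotypes
        parental = {h1, h2}
        out: list[tuple[SupergeneHaplotype, bool]] = [(h, False) for h in parental]
        for rec in (
            SupergeneHaplotype(h1.colour, h2.band),
            SupergeneHaplotype(h2.colour, h1.band),
        ):
            if rec not in parental:
                out.append((rec, True))
        return out

    # Keep frozen-dataclass hashing stable under haplotype order.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SupergeneDiplotype):
            return NotImplemented
        return frozenset_with_count(self.haplotypes) == frozenset_with_count(
            other.haplotypes
        )

    def __hash__(self) -> int:
        return hash(frozenset_with_count(self.haplotypes))


def frozenset_with_count(haps: Sequence[SupergeneHaplotype]):
    """Multiset key so that e.g. CP-BO/CP-BO hashes distinctly from CP-BO alone."""
    return frozenset((h, haps.count(h)) for h in haps)


@dataclass(frozen=True)
class CrossDesign:
    """A mother × father cross between known supergene diplotypes."""

    mother: SupergeneDiplotype
    father: SupergeneDiplotype
    label: str = ""

    @property
    def informative_parent(self) -> SupergeneDiplotype | None:
        """The parent heterozygous at both loci (informative for C–B
        recombination), or ``None``."""
        for parent in (self.father, self.mother):
            if parent.is_doubly_heterozygous:
                return parent
        return None


def phenotype_of(diplotype: SupergeneDiplotype) -> Phenotype:
    """Phenotype under full dominance: pink iff ≥1 ``CP``; unbanded iff ≥1 ``BO``."""
    colours = {h.colour for h in diplotype.haplotypes}
    bands = {h.band for h in diplotype.haplotypes}
    return Phenotype(
        colour="pink" if ColourAllele.CP in colours else "yellow",
        banded=BandAllele.BO not in bands,
    )


@dataclass(frozen=True)
class GenotypeCall:
    """An offspring diplotype compatible with a phenotype, flagged when every
    gamete combination producing it involves a recombinant gamete."""

    diplotype: SupergeneDiplotype
    requires_recombinant: bool


def infer_offspring_genotypes(
    cross: CrossDesign, phenotype: Phenotype
) -> list[GenotypeCall]:
    """All offspring diplotypes compatible with ``phenotype`` under ``cross``.

    One gamete is drawn from each parent (recombinant gametes included).  An
    empty list signals a phenotype incompatible with the cross, i.e. a
    mis-scored individual.
    """
    seen: dict[SupergeneDiplotype, bool] = {}
    for (gm, rec_m), (gf, rec_f) in itertools.product(
        cross.mother.gametes(), cross.father.gametes()
    ):
        dip = SupergeneDiplotype(gm, gf)
        if phenotype_of(dip) != phenotype:
            continue
        needs_rec = rec_m or rec_f
        # requires_recombinant only if *every* route to this diplotype does.
        seen[dip] = seen.get(dip, True) and needs_rec
    return [GenotypeCall(d, r) for d, r in seen.items()]


@dataclass
class PhenotypeCounts:
    """Offspring counts in the four canonical phenotype classes."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(PHENOTYPE_CLASSES)
        if unknown:
            raise ValueError(f"unknown phenotype classes: {sorted(unknown)}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in PHENOTYPE_CLASSES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative phenotype count")

    @classmethod
    def from_vector(cls, vector: Sequence[int]) -> "PhenotypeCounts":
        if len(vector) != 4:
            raise ValueError("expected four counts (canonical class order)")
        return cls(dict(zip(PHENOTYPE_CLASSES, vector)))

    def as_vector(self) -> list[int]:
        return [self.counts[c] for c in PHENOTYPE_CLASSES]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "PhenotypeCounts") -> "PhenotypeCounts":
        return PhenotypeCounts(
            {c: self.counts[c] + other.counts[c] for c in PHENOTYPE_CLASSES}
        )


def _classify_classes(cross: CrossDesign) -> dict[str, str]:
    """Map each phenotype class to 'parental', 'recombinant', or 'impossible'."""
    out = {}
    for cls_name in PHENOTYPE_CLASSES:
        colour, banded = cls_name.split("-")
        pheno = Phenotype(colour=colour, banded=(banded == "banded"))
        calls = infer_offspring_genotypes(cross, pheno)
        if not calls:
            out[cls_name] = "impossible"
        elif all(c.requires_recombinant for c in calls):
            out[cls_name] = "recombinant"
        else:
            out[cls_name] = "parental"
    return out


def count_recombinants(
    cross: CrossDesign, counts: PhenotypeCounts
) -> tuple[int, int]:
    """(n_recombinant, n_informative) for a cross informative at C–B.

    Recombinant offspring are those in phenotype classes only reachable via a
    recombinant gamete from the doubly heterozygous parent.
    """
    if cross.informative_parent is None:
        raise ValueError(
            f"cross {cross.label or '<unlabelled>'} is uninformative for C-B "
            "recombination: no parent is heterozygous at both loci"
        )
    kinds = _classify_classes(cross)
    n_rec = 0
    for cls_name, kind in kinds.items():
        n = counts.counts[cls_name]
        if kind == "impossible" and n > 0:
            raise ValueError(
                f"{n} offspring scored {cls_name} are incompatible with cross "
                f"{cross.label or '<unlabelled>'} (mis-scoring?)"
            )
        if kind == "recombinant":
            n_rec += n
    return n_rec, counts.total


def pool_recombinant_counts(
    crosses_and_counts: Iterable[tuple[CrossDesign, PhenotypeCounts]],
) -> tuple[int, int]:
    """Pool recombinant / informative counts over several crosses."""
    total_rec = total_n = 0
    for cross, counts in crosses_and_counts:
        r, n = count_recombinants(cross, counts)
        total_rec += r
        total_n += n
    return total_rec, total_n


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def chi2_segregation(
    counts: PhenotypeCounts | Sequence[int],
    expected_ratio: Sequence[float],
) -> Chi2Result:
    """Pearson goodness-of-fit of observed class counts to a Mendelian ratio.

    Classes with zero ratio weight must have zero observed count; they are
    excluded from the statistic and from the degrees of freedom.
    """
    observed = (
        counts.as_vector() if isinstance(counts, PhenotypeCounts) else list(counts)
    )
    if len(observed) != len(expected_ratio):
        raise ValueError("one ratio entry per class required")
    total = sum(observed)
    if total <= 0:
        raise ValueError("no observations")
    weight_sum = float(sum(expected_ratio))
    if weight_sum <= 0:
        raise ValueError("ratio weights must sum to > 0")
    obs, exp = [], []
    for o, w in zip(observed, expected_ratio):
        if w < 0:
            raise ValueError("negative ratio weight")
        if w == 0:
            if o > 0:
                raise ValueError(
                    "observed count in a class with zero expected frequency"
                )
            continue
        obs.append(o)
        exp.append(total * w / weight_sum)
    statistic = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    df = len(obs) - 1
    if df < 1:
        raise ValueError("need at least two classes with positive weight")
    p = float(stats.chi2.sf(statistic, df))
    return Chi2Result(statistic=float(statistic), df=df, p_value=p)


@dataclass(frozen=True)
class RecombinationEstimate:
    n_meioses: int
    n_recombinant: int
    confidence_level: float
    upper_limit: float


def recombination_upper_limit(
    n_meioses: int, n_recombinant: int = 0, level: float = 0.95
) -> RecombinationEstimate:
    """Posterior upper bound on the C–B recombination fraction θ.

    With zero recombinants in ``n`` meioses the likelihood is (1−θ)^n; under a
    flat prior truncated to θ ∈ [0, 0.5] the posterior CDF is
    ``[1−(1−u)^(n+1)] / [1−0.5^(n+1)]`` and the ``level`` quantile has the
    closed form ``u = 1 − [1 − level·(1 − 0.5^(n+1))]^(1/(n+1))``.
    """
    if n_recombinant != 0:
        raise NotImplementedError(
            "upper bound implemented for the zero-recombinant case only"
        )
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n_meioses < 0:
        raise ValueError("n_meioses must be non-negative")
    n1 = n_meioses + 1
    u = 1.0 - (1.0 - level * (1.0 - 0.5**n1)) ** (1.0 / n1)
    return RecombinationEstimate(
        n_meioses=n_meioses,
        n_recombinant=0,
        confidence_level=level,
        upper_limit=u,
    )


@dataclass(frozen=True)
class ClusterProbabilityQuery:
    n_chromosomes: int
    m_loci: int
    k_min: int
    probability: float = field(default=float("nan"), compare=False)


def supergene_cluster_probability(
    n_chromosomes: int, m_loci: int, k_min: int
) -> float:
    """P(some chromosome receives ≥ k_min of m loci) under uniform independent
    assignment of loci to chromosomes.

    Computed exactly: the number of assignments in which every chromosome
    receives < k_min loci is ``m! · [x^m] (Σ_{j<k} x^j/j!)^n`` (exponential
    generating function over chromosomes), evaluated in exact rational
    arithmetic; the complement is returned as a float.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if not 1 <= k_min <= m_loci:
        raise ValueError("require 1 <= k_min <= m_loci")
    if n_chromosomes == 1:
        return 1.0
    # poly[j] = coefficient of x^j in (sum_{i<k_min} x^i/i!)^n, truncated at m.
    base = [Fraction(1, math.factorial(j)) for j in range(min(k_min, m_loci + 1))]
    poly = [Fraction(1)]
    for _ in range(n_chromosomes):
        new = [Fraction(0)] * min(len(poly) + len(base) - 1, m_loci + 1)
        for i, a in enumerate(poly):
            if a == 0:
                continue
            for j, b in enumerate(base):
                if i + j <= m_loci:
                    new[i + j] += a * b
        poly = new
        if len(poly) <= 1 and poly[0] == 0:  # pragma: no cover - degenerate
            break
    n_ok = poly[m_loci] * math.factorial(m_loci) if m_loci < len(poly) else Fraction(0)
    p_none = Fraction(n_ok, Fraction(n_chromosomes) ** m_loci)
    return float(1 - p_none)
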