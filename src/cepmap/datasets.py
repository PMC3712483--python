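"""Published study data packaged as in-memory constants.

Six laboratory crosses of *Cepaea nemoralis* (phenotype counts in the
canonical class order pink-unbanded, pink-banded, yellow-unbanded,
yellow-banded), and the segregation patterns of the eleven assayed RAD
markers over the 24-individual sequencing panel (pink-unbanded father,
yellow-banded mother, 12 pink-banded offspring, 10 yellow-unbanded
offspring).  In a pattern string '1' is allele presence, '0' absence, and
'x' marks an allele that was absent from the sequence data (insufficient
coverage) but later confirmed present by PCR.
"""

from __future__ import annotations

from .cross_genetics import CrossDesign, PhenotypeCounts, SupergeneDiplotype

__all__ = [
    "CROSSES",
    "CROSS_COUNTS",
    "REPULSION_CROSS_IDS",
    "COUPLING_CROSS_IDS",
    "INFORMATIVE_CROSS_IDS",
    "MARKER_PATTERNS",
    "MARKER_ASSAYS",
    "PANEL_SPEC",
]


def _cross(label, mother_h1, mother_h2, father_h1, father_h2) -> CrossDesign:
    return CrossDesign(
        mother=SupergeneDiplotype.from_tokens(mother_h1, mother_h2),
        father=SupergeneDiplotype.from_tokens(father_h1, father_h2),
        label=label,
    )


# Cross designs.  The doubly heterozygous (informative) parent is listed as the
# father; for cross 1 this matches the described pedigree (pink-unbanded
# father C100, yellow-banded mother C101).
CROSSES: dict[str, CrossDesign] = {
    "cross1": _cross("cross1", "Cy-Bb", "Cy-Bb", "CP-Bb", "Cy-BO"),
    "cross2": _cross("cross2", "Cy-Bb", "Cy-Bb", "CP-Bb", "Cy-BO"),
    "cross3": _cross("cross3", "Cy-Bb", "Cy-Bb", "CP-Bb", "Cy-BO"),
    "cross4": _cross("cross4", "Cy-Bb", "Cy-Bb", "CP-Bb", "Cy-BO"),
    "cross5": _cross("cross5", "Cy-Bb", "Cy-Bb", "CP-BO", "Cy-Bb"),
    # cross6 segregates for colour only (father C119 = an F1 of cross 1).
    "cross6": _cross("cross6", "Cy-Bb", "Cy-Bb", "CP-Bb", "Cy-Bb"),
}

# Offspring phenotype counts per cross, canonical class order.
CROSS_COUNTS: dict[str, PhenotypeCounts] = {
    "cross1": PhenotypeCounts.from_vector([0, 56, 47, 0]),
    "cross2": PhenotypeCounts.from_vector([0, 27, 23, 0]),
    "cross3": PhenotypeCounts.from_vector([0, 17, 10, 0]),
    "cross4": PhenotypeCounts.from_vector([0, 56, 53, 0]),
    "cross5": PhenotypeCounts.from_vector([18, 0, 0, 16]),
    "cross6": PhenotypeCounts.from_vector([0, 37, 0, 38]),
}

REPULSION_CROSS_IDS = ("cross1", "cross2", "cross3", "cross4")
COUPLING_CROSS_IDS = ("cross5",)
INFORMATIVE_CROSS_IDS = REPULSION_CROSS_IDS + COUPLING_CROSS_IDS

# Sequencing panel: (individual_id, role, phenotype class), fixed order.
PANEL_SPEC: tuple[tuple[str, str, str], ...] = (
    ("father", "father", "pink-unbanded"),
    ("mother", "mother", "yellow-banded"),
    *(
        (f"pb{i:02d}", "offspring", "pink-banded")
        for i in range(1, 13)
    ),
    *(
        (f"yu{i:02d}", "offspring", "yellow-unbanded")
        for i in range(1, 11)
    ),
)

# Segregation patterns of the eleven assayed markers: for each marker the
# allele putatively in phase with a dominant supergene allele, then the
# alternative allele.  Allele names follow the shell phenotype the in-phase
# allele tracks.
MARKER_PATTERNS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "Cne_RAD01": (
        ("unbanded", "100000000010011111111111"),
        ("banded", "111111111111111111111111"),
    ),
    "Cne_RAD02": (
        ("unbanded", "10000000000000111x111111"),
        ("banded", "11111111111111xxx1111111"),
    ),
    "Cne_RAD03": (
        ("unbanded", "100000010000011111111111"),
        ("banded", "111111111111111111111111"),
    ),
    "Cne_RAD04": (
        ("unbanded", "100100000000001111111011"),
        ("banded", "111111111111111111111111"),
    ),
    "Cne_RAD05": (
        ("pink", "101011111111110000000000"),
        ("yellow", "11x11x11xx1111x111111111"),
    ),
    "Cne_RAD06": (
        ("pink", "101111111101100000000000"),
        ("yellow", "11x111111x1x111111111111"),
    ),
    "Cne_RAD07": (
        ("pink", "101011111111110000000100"),
        ("yellow", "111111111111111111111111"),
    ),
    "Cne_RAD08": (
        ("unbanded", "100000000000001111111111"),
        ("banded", "x11111111111111111111111"),
    ),
    "Cne_RAD09": (
        ("unbanded", "100000000000001111111111"),
        ("banded", "111111111x1111x111111111"),
    ),
    "Cne_RAD10": (
        ("unbanded", "100000000000001111111111"),
        ("banded", "x1x111111111111111111111"),
    ),
    # For Cne_RAD11 the assay SNP is in phase with colour; that is the
    # pattern shown (the RAD-tag polymorphism itself tracks banding).
    "Cne_RAD11": (
        ("pink", "101111111101100000000000"),
        ("yellow", "111111111111111111111111"),
    ),
}

# Assay metadata kept only as fixture annotation (assay type, enzyme/indel).
MARKER_ASSAYS: dict[str, str] = {
    "Cne_RAD01": "CAPS RsaI",
    "Cne_RAD02": "CAPS AvaII",
    "Cne_RAD03": "indel length polymorphism",
    "Cne_RAD04": "CAPS MspA1I",
    "Cne_RAD05": "CAPS AluI",
    "Cne_RAD06": "CAPS DdeI",
    "Cne_RAD07": "CAPS DraI",
    "Cne_RAD08": "CAPS HinfI",
    "Cne_RAD09": "CAPS BstUI",
    "Cne_RAD10": "CAPS DpnII",
    "Cne_RAD11": "CAPS BstUI",
}
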