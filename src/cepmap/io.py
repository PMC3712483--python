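"""Plain-text file formats tying the pipeline stages together.

All tabular formats are UTF-8, tab-separated, with '#' comment lines and '-'
for missing values; matrices use individuals as columns in fixed panel order.
Reads and writes round-trip byte-identically for canonical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .coseg_search import Individual, LocusPatterns, SegregationPattern
from .cross_genetics import (
    CrossDesign,
    PHENOTYPE_CLASSES,
    PhenotypeCounts,
    SupergeneDiplotype,
)
from .linkage_map import GeneticMap, MarkerGenotypes
from .rad_loci import RadLocus, ReadPair

__all__ = [
    "RunLog",
    "write_crosses",
    "read_crosses",
    "write_phenotype_counts",
    "read_phenotype_counts",
    "write_panel",
    "read_panel",
    "write_pattern_matrix",
    "read_pattern_matrix",
    "write_genotype_matrix",
    "read_genotype_matrix",
    "write_locus_table",
    "write_map_table",
    "write_fastq_pairs",
    "read_fastq_pairs",
    "write_run_config",
]


@dataclass
class RunLog:
    """Per-stage record counts and warnings; counts must reconcile."""

    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, **counts: int) -> None:
        self.stage_counts[stage] = {k: int(v) for k, v in counts.items()}

    def to_json(self) -> str:
        return json.dumps(
            {"stages": self.stage_counts, "warnings": self.warnings}, indent=2
        )


def _read_table(path: Path) -> tuple[list[str], list[list[str]], list[str]]:
    comments, rows = [], []
    header: list[str] | None = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            comments.append(line[1:].strip())
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
            continue
        if len(cells) != len(header):
            raise ValueError(
                f"{path}: row {lineno} has {len(cells)} cells, expected {len(header)}"
            )
        rows.append(cells)
    if header is None:
        raise ValueError(f"{path}: empty table")
    return header, rows, comments


def write_crosses(path: str | Path, crosses: Mapping[str, CrossDesign]) -> None:
    lines = ["cross_id\tparent\thaplotype_1\thaplotype_2"]
    for cross_id in crosses:
        c = crosses[cross_id]
        for role, dip in (("mother", c.mother), ("father", c.father)):
            lines.append(
                f"{cross_id}\t{role}\t{dip.haplotype_1.token()}\t{dip.haplotype_2.token()}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_crosses(path: str | Path) -> dict[str, CrossDesign]:
    header, rows, _ = _read_table(Path(path))
    if header != ["cross_id", "parent", "haplotype_1", "haplotype_2"]:
        raise ValueError(f"{path}: unexpected cross-table header {header}")
    parents: dict[str, dict[str, SupergeneDiplotype]] = {}
    for cross_id, role, h1, h2 in rows:
        parents.setdefault(cross_id, {})[role] = SupergeneDiplotype.from_tokens(h1, h2)
    out = {}
    for cross_id, p in parents.items():
        if set(p) != {"mother", "father"}:
            raise ValueError(f"{path}: cross {cross_id} needs a mother and a father")
        out[cross_id] = CrossDesign(mother=p["mother"], father=p["father"], label=cross_id)
    return out


def write_phenotype_counts(
    path: str | Path, counts: Mapping[str, PhenotypeCounts]
) -> None:
    cols = "\t".join(c.replace("-", "_") for c in PHENOTYPE_CLASSES)
    lines = [f"cross_id\t{cols}\ttotal"]
    for cross_id in counts:
        vec = counts[cross_id].as_vector()
        lines.append(
            f"{cross_id}\t" + "\t".join(str(v) for v in vec) + f"\t{sum(vec)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotype_counts(path: str | Path) -> dict[str, PhenotypeCounts]:
    header, rows, _ = _read_table(Path(path))
    expected = ["cross_id"] + [c.replace("-", "_") for c in PHENOTYPE_CLASSES] + ["total"]
    if header != expected:
        raise ValueError(f"{path}: unexpected phenotype-count header {header}")
    out = {}
    for row in rows:
        cross_id, *cells = row
        vec = [int(v) for v in cells[:4]]
        total = int(cells[4])
        if total != sum(vec):
            raise ValueError(f"{path}: cross {cross_id} total {total} != {sum(vec)}")
        out[cross_id] = PhenotypeCounts.from_vector(vec)
    return out


def write_panel(path: str | Path, individuals: Sequence[Individual]) -> None:
    lines = ["individual_id\trole\tphenotype"]
    for ind in individuals:
        lines.append(f"{ind.id}\t{ind.role}\t{ind.phenotype_class}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_panel(path: str | Path) -> list[Individual]:
    header, rows, _ = _read_table(Path(path))
    if header != ["individual_id", "role", "phenotype"]:
        raise ValueError(f"{path}: unexpected panel header {header}")
    return [Individual(*row) for row in rows]


def write_pattern_matrix(
    path: str | Path,
    loci: Sequence[LocusPatterns],
    panel_ids: Sequence[str],
    comments: Sequence[str] = (),
) -> None:
    lines = [f"# {c}" for c in comments]
    lines.append("locus_id\tallele_id\t" + "\t".join(panel_ids))
    for locus in loci:
        for allele_id, pattern in locus.alleles:
            if len(pattern) != len(panel_ids):
                raise ValueError(
                    f"{locus.locus_id}/{allele_id}: pattern length {len(pattern)} "
                    f"!= panel size {len(panel_ids)}"
                )
            cells = "\t".join(pattern.to_string())
            lines.append(f"{locus.locus_id}\t{allele_id}\t{cells}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pattern_matrix(
    path: str | Path,
) -> tuple[list[LocusPatterns], list[str], list[str]]:
    header, rows, comments = _read_table(Path(path))
    if header[:2] != ["locus_id", "allele_id"]:
        raise ValueError(f"{path}: pattern matrix must start with locus_id, allele_id")
    panel_ids = header[2:]
    by_locus: dict[str, LocusPatterns] = {}
    for row in rows:
        locus_id, allele_id, *cells = row
        bad = set(cells) - {"0", "1", "x"}
        if bad:
            raise ValueError(f"{path}: invalid pattern cells {sorted(bad)}")
        pattern = SegregationPattern.from_string("".join(cells))
        by_locus.setdefault(
            locus_id, LocusPatterns(locus_id=locus_id, alleles=[])
        ).alleles.append((allele_id, pattern))
    return list(by_locus.values()), panel_ids, comments


def write_genotype_matrix(
    path: str | Path,
    genotypes: Sequence[MarkerGenotypes],
    offspring_ids: Sequence[str],
) -> None:
    lines = ["marker_id\t" + "\t".join(offspring_ids)]
    symbols = {1: "1", 0: "0", -1: "-"}
    for g in genotypes:
        if len(g.calls) != len(offspring_ids):
            raise ValueError(
                f"{g.marker_id}: {len(g.calls)} calls != {len(offspring_ids)} offspring"
            )
        lines.append(g.marker_id + "\t" + "\t".join(symbols[int(c)] for c in g.calls))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotype_matrix(
    path: str | Path,
) -> tuple[list[MarkerGenotypes], list[str]]:
    header, rows, _ = _read_table(Path(path))
    if header[0] != "marker_id":
        raise ValueError(f"{path}: genotype matrix must start with marker_id")
    offspring_ids = header[1:]
    out = [MarkerGenotypes.from_strings(row[0], row[1:]) for row in rows]
    return out, offspring_ids


def write_locus_table(
    path: str | Path, loci: Sequence[RadLocus], panel_ids: Sequence[str]
) -> None:
    """Locus table: one row per allele, per-individual cells hold
    "read_count/fragment_count" ('-' when absent)."""
    lines = ["locus_id\tallele_id\ttag\t" + "\t".join(panel_ids)]
    for locus in loci:
        for allele in locus.alleles:
            cells = []
            for ind in panel_ids:
                if ind in allele.read_counts:
                    cells.append(
                        f"{allele.read_counts[ind]}/{allele.fragment_counts.get(ind, 0)}"
                    )
                else:
                    cells.append("-")
            lines.append(
                f"{locus.locus_id}\t{allele.allele_id}\t{allele.tag}\t" + "\t".join(cells)
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_map_table(path: str | Path, genetic_map: GeneticMap) -> None:
    Path(path).write_text(genetic_map.to_text())


def write_fastq_pairs(
    path1: str | Path, path2: str | Path, reads: Iterable[ReadPair]
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in reads:
            f1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")


def _read_fastq(path: Path) -> list[tuple[str, str, str]]:
    records = []
    lines = path.read_text().splitlines()
    if len(lines) % 4:
        raise ValueError(f"{path}: truncated FASTQ (line count not divisible by 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: sequence/quality mismatch at line {i + 1}")
        records.append((head[1:].split("/")[0].split()[0], seq, qual))
    return records


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    r1 = _read_fastq(Path(path1))
    r2 = _read_fastq(Path(path2))
    if len(r1) != len(r2):
        shorter = path1 if len(r1) < len(r2) else path2
        raise ValueError(
            f"mate files differ in record count ({len(r1)} vs {len(r2)}); "
            f"{shorter} is shorter"
        )
    out = []
    for (id1, s1, q1), (id2, s2, q2) in zip(r1, r2):
        if id1 != id2:
            raise ValueError(f"mate id mismatch: {id1!r} vs {id2!r}")
        out.append(ReadPair(read_id=id1, seq1=s1, qual1=q1, seq2=s2, qual2=q2))
    return out


def write_run_config(path: str | Path, config: Mapping[str, object]) -> None:
    """Persist the resolved stage parameters beside the outputs."""
    Path(path).write_text(json.dumps(dict(config), indent=2, default=str) + "\n")
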