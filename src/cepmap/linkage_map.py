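"""Two-point linkage analysis and local map construction for a backcross.

Genotypes are phase-anchored presence calls of the informative parent's
alleles in each offspring (a pseudo-testcross: the other parent is homozygous
recessive and contributes nothing).  Pairwise recombination fractions and LOD
scores form linkage groups at a LOD threshold; marker order is found by
maximising the multipoint log-likelihood (adjacent intervals treated
independently, exhaustive for small groups, seriation plus window-flip
refinement otherwise); distances are Kosambi-transformed adjacent two-point
estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "MarkerGenotypes",
    "TwoPointResult",
    "LinkageGroup",
    "GeneticMap",
    "OrderingResult",
    "twopoint",
    "kosambi_cm",
    "kosambi_inverse",
    "form_groups",
    "order_markers",
    "build_map",
    "pool_recombination",
]

MISSING = -1


@dataclass
class MarkerGenotypes:
    """Per-offspring calls for one marker: 1 = carries the scored (in-phase)
    parental allele, 0 = lacks it, -1 = missing."""

    marker_id: str
    calls: np.ndarray
    phase_anchor: str = ""

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        bad = set(np.unique(self.calls)) - {0, 1, MISSING}
        if bad:
            raise ValueError(f"calls must be 0/1/-1, got {sorted(bad)}")

    @classmethod
    def from_strings(cls, marker_id: str, cells: Sequence[str]) -> "MarkerGenotypes":
        mapping = {"1": 1, "0": 0, "-": MISSING}
        try:
            calls = [mapping[c] for c in cells]
        except KeyError as exc:
            raise ValueError(f"genotype cells must be 0/1/-, got {exc}") from exc
        return cls(marker_id, np.array(calls, dtype=np.int8))


@dataclass(frozen=True)
class TwoPointResult:
    marker_a: str
    marker_b: str
    n_informative: int
    n_recombinant: int
    r_hat: float
    lod: float


def _lod(n_rec: int, n: int) -> float:
    """LOD of linkage at r̂ = R/N against free recombination (r = 0.5).

    Symmetric in R ↔ N−R, so globally flipping one marker's phase leaves the
    score unchanged.
    """
    r = n_rec / n
    ll = n * math.log10(2.0)
    if 0 < n_rec:
        ll += n_rec * math.log10(r)
    if n_rec < n:
        ll += (n - n_rec) * math.log10(1.0 - r)
    return ll


def twopoint(a: MarkerGenotypes, b: MarkerGenotypes) -> TwoPointResult:
    """Two-point recombination fraction and LOD between two markers.

    N is the pairwise-complete offspring count; R counts phase-anchored call
    disagreements.
    """
    ok = (a.calls != MISSING) & (b.calls != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(
            f"no shared informative offspring for {a.marker_id} / {b.marker_id}"
        )
    n_rec = int(np.sum(a.calls[ok] != b.calls[ok]))
    return TwoPointResult(
        marker_a=a.marker_id,
        marker_b=b.marker_id,
        n_informative=n,
        n_recombinant=n_rec,
        r_hat=n_rec / n,
        lod=_lod(n_rec, n),
    )


def kosambi_cm(r: float) -> float:
    """Kosambi map distance d = 25·ln((1+2r)/(1−2r)) in centimorgans."""
    if not 0 <= r < 0.5:
        raise ValueError(f"recombination fraction {r} outside [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d_cm: float) -> float:
    """Recombination fraction for a Kosambi distance: r = tanh(d/50)/2."""
    if d_cm < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(d_cm / 50.0)


@dataclass
class LinkageGroup:
    markers: list[str]
    lod_threshold: float


def form_groups(
    genotypes: Sequence[MarkerGenotypes], lod_threshold: float = 3.0
) -> list[LinkageGroup]:
    """Single-linkage connected components of the pairwise-LOD graph."""
    graph = nx.Graph()
    graph.add_nodes_from(g.marker_id for g in genotypes)
    for a, b in itertools.combinations(genotypes, 2):
        tp = twopoint(a, b)
        if tp.lod >= lod_threshold:
            graph.add_edge(a.marker_id, b.marker_id)
    groups = [sorted(c) for c in nx.connected_components(graph)]
    groups.sort(key=lambda g: (-len(g), g))
    return [LinkageGroup(markers=g, lod_threshold=lod_threshold) for g in groups]


def _pairwise_tables(
    genotypes: Sequence[MarkerGenotypes],
) -> tuple[np.ndarray, np.ndarray]:
    """(R', N) matrices with phase-free recombinant counts R' = min(R, N−R)."""
    k = len(genotypes)
    R = np.zeros((k, k), dtype=int)
    N = np.zeros((k, k), dtype=int)
    for i, j in itertools.combinations(range(k), 2):
        tp = twopoint(genotypes[i], genotypes[j])
        r_eff = min(tp.n_recombinant, tp.n_informative - tp.n_recombinant)
        R[i, j] = R[j, i] = r_eff
        N[i, j] = N[j, i] = tp.n_informative
    return R, N


def _interval_ll(R: np.ndarray, N: np.ndarray, i: int, j: int) -> float:
    """Backcross log10-likelihood of the interval between markers i and j at
    its MLE recombination fraction."""
    r_count, n = R[i, j], N[i, j]
    if n == 0:
        return -math.inf
    r = r_count / n
    ll = 0.0
    if r_count > 0:
        ll += r_count * math.log10(r)
    if r_count < n:
        ll += (n - r_count) * math.log10(1.0 - r)
    return ll


def _order_ll(order: Sequence[int], R: np.ndarray, N: np.ndarray) -> float:
    return sum(
        _interval_ll(R, N, order[i], order[i + 1]) for i in range(len(order) - 1)
    )


def _obligate_crossovers(order: Sequence[int], R: np.ndarray) -> int:
    return int(sum(R[order[i], order[i + 1]] for i in range(len(order) - 1)))


def _canonical(order: list[int], ids: Sequence[str]) -> list[int]:
    return order if ids[order[0]] <= ids[order[-1]] else order[::-1]


@dataclass
class OrderingResult:
    order: list[str]
    log10_likelihood: float
    method: str
    unresolved: bool = False
    flips: list[tuple[list[str], float]] = field(default_factory=list)


EXHAUSTIVE_LIMIT = 8


def order_markers(
    genotypes: Sequence[MarkerGenotypes],
    flips_window: int = 3,
    flips_margin: float = 3.0,
) -> OrderingResult:
    """Maximum-likelihood marker order for one linkage group.

    Exhaustive over all orders (up to reversal) for ≤ 8 markers; above that a
    seriation seed (markers sorted by distance from an extreme marker) is
    refined by exhaustive permutation of every sliding window of ≤ 3 markers
    until no improvement.  Likelihood ties break toward fewer obligate
    crossovers, then lexicographic marker ids.  ``flips`` lists local
    reorderings within ``flips_margin`` log10 units of the optimum.
    """
    ids = [g.marker_id for g in genotypes]
    k = len(ids)
    if k < 2:
        raise ValueError("ordering needs at least two markers")
    R, N = _pairwise_tables(genotypes)
    unresolved = bool(np.all(R[np.triu_indices(k, 1)] == 0))

    def key(order: list[int]) -> tuple:
        return (
            -_order_ll(order, R, N),
            _obligate_crossovers(order, R),
            [ids[i] for i in order],
        )

    if k <= EXHAUSTIVE_LIMIT:
        method = "exhaustive"
        best = min(
            (
                list(perm)
                for perm in itertools.permutations(range(k))
                if perm[0] < perm[-1]  # one representative per reversal pair
            ),
            key=key,
        )
    else:
        method = "insertion+flips"
        # Seed with the most distant pair as ends, then greedy best-position
        # insertion of the remaining markers under the full likelihood.
        dist = np.where(N > 0, R / np.maximum(N, 1), 0.0)
        i0, j0 = np.unravel_index(int(np.argmax(dist)), dist.shape)
        best = [int(i0), int(j0)]
        remaining = sorted(
            (i for i in range(k) if i not in best),
            key=lambda i: (min(dist[i, i0], dist[i, j0]), ids[i]),
        )
        for m in remaining:
            best = min(
                (best[:slot] + [m] + best[slot:] for slot in range(len(best) + 1)),
                key=key,
            )
        improved = True
        while improved:
            improved = False
            # 2-opt segment reversals catch globally misplaced runs ...
            for i in range(k - 1):
                for j in range(i + 2, k + 1):
                    cand = best[:i] + best[i:j][::-1] + best[j:]
                    if key(cand) < key(best):
                        best = cand
                        improved = True
            # ... and window permutations polish local order.
            for w in (2, 3):
                for start in range(k - w + 1):
                    head, tail = best[:start], best[start + w :]
                    window = best[start : start + w]
                    for perm in itertools.permutations(window):
                        cand = head + list(perm) + tail
                        if key(cand) < key(best):
                            best = cand
                            improved = True
    best = _canonical(best, ids)
    best_ll = _order_ll(best, R, N)

    flips: list[tuple[list[str], float]] = []
    seen = {tuple(best)}
    for w in range(2, min(flips_window, k) + 1):
        for start in range(k - w + 1):
            head, tail = best[:start], best[start + w :]
            window = best[start : start + w]
            for perm in itertools.permutations(window):
                cand = _canonical(head + list(perm) + tail, ids)
                tc = tuple(cand)
                if tc in seen:
                    continue
                seen.add(tc)
                delta = best_ll - _order_ll(cand, R, N)
                if delta <= flips_margin:
                    flips.append(([ids[i] for i in cand], delta))
    flips.sort(key=lambda f: f[1])
    return OrderingResult(
        order=[ids[i] for i in best],
        log10_likelihood=best_ll,
        method=method,
        unresolved=unresolved,
        flips=flips,
    )


@dataclass
class GeneticMap:
    markers: list[str]
    adjacent_cm: list[float]
    positions_cm: list[float]

    @property
    def total_length_cm(self) -> float:
        return float(sum(self.adjacent_cm))

    def to_text(self) -> str:
        lines = ["marker\tposition_cM"]
        for m, pos in zip(self.markers, self.positions_cm):
            lines.append(f"{m}\t{pos:.2f}")
        lines.append(f"# total length: {self.total_length_cm:.2f} cM")
        return "\n".join(lines) + "\n"


def build_map(genotypes: Sequence[MarkerGenotypes]) -> GeneticMap:
    """Kosambi map over markers taken in the given (resolved) order.

    Adjacent distances come from adjacent two-point estimates with phase-free
    r̂ = min(R, N−R)/N; co-segregating markers land at distance zero.
    """
    if len(genotypes) < 2:
        raise ValueError("a map needs at least two markers")
    distances = []
    for a, b in zip(genotypes, genotypes[1:]):
        tp = twopoint(a, b)
        r = min(tp.n_recombinant, tp.n_informative - tp.n_recombinant) / tp.n_informative
        if r >= 0.5:  # pragma: no cover - min() keeps r <= 0.5; equality only
            raise ValueError(
                f"adjacent markers {a.marker_id}/{b.marker_id} appear unlinked"
            )
        distances.append(kosambi_cm(r))
    positions = [0.0]
    for d in distances:
        positions.append(positions[-1] + d)
    return GeneticMap(
        markers=[g.marker_id for g in genotypes],
        adjacent_cm=distances,
        positions_cm=positions,
    )


@dataclass(frozen=True)
class PooledEstimate:
    n_recombinant: int
    n_informative: int
    r_hat: float
    distance_cm: float


def pool_recombination(
    estimates: Iterable[tuple[int, int] | TwoPointResult],
) -> PooledEstimate:
    """Pool recombinant counts for one interval across crosses:
    r̂ = ΣR/ΣN, distance via Kosambi."""
    total_r = total_n = 0
    for est in estimates:
        if isinstance(est, TwoPointResult):
            r_count, n = est.n_recombinant, est.n_informative
        else:
            r_count, n = est
        total_r += int(r_count)
        total_n += int(n)
    if total_n == 0:
        raise ValueError("nothing to pool")
    r = total_r / total_n
    return PooledEstimate(total_r, total_n, r, kosambi_cm(r))
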