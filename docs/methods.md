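# Methods

## The genetic model

Shell ground colour (*C*) and band presence (*B*) are modelled as two
biallelic loci with full dominance (pink `CP` > yellow `Cy`; unbanded `BO` >
banded `Bb`) carried on a pair of supergene haplotypes. A diplotype maps to
one of four phenotype classes, always reported in the canonical order
pink-unbanded, pink-banded, yellow-unbanded, yellow-banded. Phase
(repulsion: dominant alleles in trans; coupling: in cis) is derived from the
haplotypes and never stored separately. Offspring draw one gamete per listed
parent; hermaphrodite selfing is not modelled. Brown shell colour, the
multi-allelic colour series and the *S*, *P*, *I*, *O* modifier loci are
deliberately outside the model: no packaged cross segregates for them.

Recombinant counting treats a phenotype class as recombinant when every
gamete combination producing it requires a non-parental (recombinant) gamete
from the doubly heterozygous parent; a class incompatible with any gamete
combination raises an error, since a nonzero count there indicates
mis-scoring. χ² goodness-of-fit uses the plain Pearson statistic with
df = classes − 1; classes given zero ratio weight must be empty and are
excluded from both the statistic and df.

With zero recombinants in *n* meioses the likelihood for the recombination
fraction θ is (1−θ)ⁿ. Under a flat prior truncated to θ ∈ [0, 0.5] (a
backcross recombination fraction cannot exceed ½), the posterior quantile has
the closed form u = 1 − [1 − q·(1 − 0.5ⁿ⁺¹)]^{1/(n+1)}; at n = 0 this is the
prior quantile (0.475 at q = 0.95). The nonzero-recombinant case is
deliberately not implemented — the pipeline's crosses produced none, and a
silent numeric fallback would invite misuse.

The chromosome-clustering probability — P(some chromosome receives ≥ k of m
loci assigned independently and uniformly to n chromosomes) — is computed
exactly from the exponential generating function (Σ_{j<k} x^j/j!)ⁿ in
rational arithmetic, so it agrees with brute-force enumeration wherever
enumeration is feasible. For 2k > m it coincides with the disjoint-event
binomial sum n·Σ_{j≥k} C(m,j)(1/n)^j(1−1/n)^{m−j}.

## RAD locus construction

Read 1 is laid out as 5-base barcode + SbfI remnant (`TGCAGG`) + genomic
sequence; trimming the barcode leaves a 96-base tag. Barcode matching is
exact by default — barcodes are pairwise ≥ 2 mismatches apart, so a
1-mismatch rescue (available behind a flag) is unambiguous, but exactness is
the reproducible default. Reads whose remnant does not match are discarded
and counted; demultiplexing conserves record counts.

Within an individual, identical tags form candidate alleles; alleles with
read depth < 2 are discarded. Alleles are joined into loci by single linkage
on Hamming distance ≤ 5 computed only over positions where both alleles have
base quality > 20 (per-position quality of an allele is the best seen among
its reads); low-quality positions are treated as matching, and `N` matches
nothing, not even another `N`. Single linkage is the most permissive reading
of a clustering radius and makes the operation order-independent together
with the canonical allele ordering (depth descending, then tag
lexicographic).

PCR duplicates are collapsed by paired-end shear signature: the fragment
count of an allele in an individual is the number of distinct read-2
sequences among its read pairs. Exact read-2 identity is used rather than
alignment-derived start positions because no reference genome exists for
this species. Fragment counts are therefore ≤ read counts, with equality
exactly when no read 2 is duplicated.

Cross-individual merging is single linkage on the closest allele pair
(plain Hamming ≤ 3); loci observed in a single individual are dropped, as
are merged loci with more than four distinct allele sequences (at most four
alleles can segregate in one cross; more indicates collapsed repeats).
Whether the merge should compare allele pairs or locus consensus sequences
is a genuinely open choice; allele-pair single linkage was chosen as the
more permissive and simpler rule.

The expected locus yield of a digest is genome_size × Π p(base) ×
tags_per_site with p(G) = p(C) = gc/2, an independent-base genome model.
For a 6.6 Gb diploid genome at 37 % GC and the 8-base SbfI site this gives
≈ 52,508 loci.

## Cosegregation search

In the mapping cross the father is doubly heterozygous in repulsion, so a
RAD allele riding his `Cy-BO` haplotype should be present in the father and
all yellow-unbanded offspring (banding phase), and one riding `CP-Bb` in the
father and all pink-banded offspring (colour phase). These two expectations
differ at 22 of 24 panel positions, so no observed pattern within the
allowances can match both — phase calls are mutually exclusive.

Scoring counts dropouts (expected present, observed absent) and gains
(observed present where absence was expected; putative recombinants). The
budgets are independent, not pooled: ≤ 2 dropouts and ≤ 2 gains for the
in-phase allele. Every other allele of the locus must match an
alternative-allele expectation within ≤ 5 dropouts when expected in all
individuals, or ≤ 2 when expected in ≤ 14. For multi-allelic loci the
alternative expectation is chosen per allele from the configurations the
cross allows (shared by both parents → everywhere; father-only → father plus
the offspring class complementary to the in-phase allele; mother allele →
mother plus all offspring), taking the best-fitting one — a deliberately
charitable reading, since the locus is rejected if even that fails.
Pattern positions marked `x` (allele confirmed present by follow-up PCR but
sequence-absent) count as dropouts during the search, because the search
operates on sequence data alone; they are reported as present in validation
output.

Loci split by indels or by polymorphism beyond the clustering radius are
rescued by aligning accepted single-allele loci against all other alleles
with a global aligner with free end gaps (match +1, mismatch −1, gap open
−2, extend −0.5); identity = matched columns / alignment columns excluding
end-gap overhangs, threshold 0.90. Regrouped loci are re-scored by the same
candidate rules. The strict (zero-allowance) search and the rescue are
implemented as separate, composable passes.

Orientation of unassayed candidates uses validated recombinant offspring: a
candidate whose pattern switches in the same validated recombinant
individual as a mapped reference marker lies on the same side of the
supergene; switching only in recombinants of other markers implies the
opposite side; with no informative mismatch the side is undetermined and
bounded by the closest mapped interval.

## Linkage mapping

Genotypes are phase-anchored presence calls of the informative parent's
alleles. Two-point estimates use pairwise-complete offspring (missing calls
excluded per pair); r̂ = R/N and LOD = R·log₁₀ r̂ + (N−R)·log₁₀(1−r̂) +
N·log₁₀ 2, which is symmetric under R ↔ N−R and hence invariant to flipping
a marker's phase anchor. Linkage groups are single-linkage connected
components of the LOD ≥ 3 graph.

Marker order maximises a multipoint log-likelihood that treats adjacent
intervals as independent binomials at their MLE recombination fractions —
the standard two-point/crimap-style approximation; interference enters only
through the Kosambi transform of distances, and a full multipoint EM is out
of scope. Orders are searched exhaustively (up to reversal) for ≤ 8 markers;
above that, the most distant pair seeds a greedy best-insertion order which
is refined by 2-opt segment reversals and exhaustive permutation of sliding
windows of ≤ 3 markers until no move improves. Likelihood ties break toward
fewer obligate crossovers, then lexicographic marker ids, and the `flips`
report lists all local reorderings within a stated log₁₀-likelihood margin
(default 3). Markers with identical call vectors are genuinely unorderable;
the result is flagged unresolved when no pair recombines.

Map distances are Kosambi-transformed adjacent two-point estimates
(d = 25·ln((1+2r)/(1−2r))), summed for the total length; co-segregating
markers sit at 0 cM. Summed-adjacent Kosambi is one of two conventions the
total length could use (the other being a multipoint fit); both are simple
deterministic functions of the adjacent r̂ here, and the summed convention is
reported. Interval estimates from different crosses pool as ΣR/ΣN.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions as defaults: the repulsion
mapping cross (doubly heterozygous father × double homozygous recessive
mother), 22 sequenced offspring, mean fragment coverage λ = 6.6 per allele
per individual, 66.7 % PCR duplicates, presence requiring fragment depth ≥ 2,
and 101-base paired reads with 5-base barcodes. The default marker layout
places eleven markers over 35.8 cM with a co-segregating trio 0.98 cM from
the supergene — the published map's shape; the exact published inter-marker
spacings are not recoverable from the printed material, so round values at
the same scale are used.

Gametes place at most one crossover per adjacent interval, with probability
given by the Kosambi inverse of the interval length — adequate at the ≤ 36 cM
scale of the map and consistent with the two-point estimator's assumptions.
Coverage is Poisson per allele per individual (dropout acts on alleles, and
per-copy depth is not resolved), so the dropout probability has the closed
form P(Poisson(λ) ≤ d−1); absence is never converted to spurious presence.
PCR duplication draws geometric read counts per fragment (mean 1/(1−ρ)),
giving duplicate proportion ρ in expectation. Read 2 is taken at a uniform
300–600 bp shear point, so distinct fragments have distinct shear
signatures with high probability. Quality strings are constant high quality
by default; a base-error rate is configurable. Read-level simulation digests
a toy genome at `CCTGCAGG` and plants allele variants (3 substitutions, within
the clustering radius) on the father haplotype dictated by each marker's
phase, the reference allele being shared by his other haplotype and the
mother — the biallelic configuration that dominates the real search.

Not emulated: realistic base-error and quality profiles, adapter
read-through, non-uniform shear/size-selection, restriction-site
polymorphism, repeat-induced over-merging, and selfing. Passing tests
therefore demonstrate correctness of the inference given the model's
statistical structure (Mendelian segregation, Poisson dropout, duplicate
inflation), not robustness to every artefact of real libraries.

## Validation studies and problem sizes

The test suite runs the full stack at sizes chosen to keep the suite fast
while leaving the statistical checks well-powered:

- End-to-end recovery: 20 seeded replicates of reads → loci → search at
  λ = 10 with four planted linked markers within ~1 cM of the supergene and
  four monomorphic background sites per replicate; precision and recall are
  measured against the planted truth. Monomorphic loci dominate real RAD
  data sets and are the background the search must reject outright.
- Marker-order recovery: 200 seeded replicates of a 13-locus panel
  (11 markers + C + B) with 102 offspring. Recovery is judged up to whole-map
  reversal and up to permutation within runs of markers with identical call
  vectors, which no estimator can order.
- False-positive rate: the search on 10,000 unlinked null loci (father-
  carried allele segregating 50:50) compared within 3 SE against a direct
  loop-based scoring oracle.
- Exhaustive-vs-heuristic ordering agreement on 6-marker panels, the Poisson
  dropout closed form, Mendelian class frequencies for every packaged cross
  design, and exact brute-force enumeration of the clustering probability on
  small parameter sets.

## Known discrepancies and limitations

Two printed statistics of the source data set are not reproducible from the
printed tables and are intentionally not asserted: the coupling-cross χ²
(printed 14.2; Pearson on the printed counts under 1:1:1:1 gives 34.24 —
the ratio actually tested there is not stated), and the 95 % upper limit for
θ (printed 0.5 %; the stated posterior with n = 323 gives 0.92 %, and 0.5 %
corresponds to n = 646, i.e. counting each offspring as two meioses). The
implementation reports the formula's value together with n so the convention
is explicit. Likewise the published 35.8 cM total, candidate counts and read
statistics depend on the archived raw data and are validated here only in
distribution, via the simulation studies above.
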