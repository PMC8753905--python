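# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `tadrisk`, and states what the synthetic-data
experiments do and do not establish.

## TAD calling

**Insulation signal.** For a binned, symmetric contact matrix and a window
half-size *k* (bins), the signal at inter-bin position *b* is the mean of
`counts[i, j]` over `i ∈ [b−k, b)`, `j ∈ [b, b+k)` — the *k*×*k* diamond
straddling *b*. Windows shrink at chromosome edges and are clipped to the
current non-gap run rather than padded: fabricating counts would bias the
signal near telomeres and assembly gaps. The diagonal never enters the
signal (self-contacts carry no insulation information). Candidate
demarcations are strict local minima against the nearest defined
neighbors; a plateau of equal values collapses to its leftmost position so
calls are deterministic.

**Gap masking.** A bin is a gap when its off-diagonal row sum is zero or
below `gap_zero_fraction` (default 0.05) times the median positive row
sum. The rule is iterated to a fixed point with already-flagged rows
excluded from the sums, which makes the mask idempotent. No TAD ever
spans a gap run.

**Statistical boundary filter.** A candidate at *b* is kept only when the
contacts inside the two flanking *k*×*k* triangles stochastically dominate
the contacts of the diamond at *b* (one-sided Mann–Whitney). Two details
matter:

* the test runs on *distance-normalized* counts (each entry divided by the
  mean count at its genomic distance, gap pairs excluded). Raw counts
  decay with distance, and diamond pairs span larger distances (up to
  2k−1) than triangle pairs (< k), so on raw counts the triangles dominate
  at *every* position and the filter is vacuous. Per-diagonal scaling is
  the standard normalization for this family of insulation tests;
* the per-candidate p-values of one non-gap run are Benjamini–Hochberg
  corrected and thresholded at `filter_alpha` (default 0.05), so the FDR
  of retained demarcations is controlled. Without the correction, ~5% of
  noise minima survive, which is enough to push boundary precision on
  simulated matrices from ≈ 0.99 down to ≈ 0.9.

TADs shorter than `min_tad_bins` (default 2) are merged across their
weakest demarcation — the one with the *higher* insulation signal, i.e.,
toward the neighbor with more cross-contacts — so strong demarcations are
never sacrificed to absorb a fragment.

With ideal flat block structure the caller is nearly invariant in *k*; the
empirical tendency of small windows to return more domains arises from
hierarchical (nested) structure, where small *k* resolves sub-domains and
large *k* only the outer blocks. The test suite exercises this with an
explicit two-level construction.

**Borders.** A TAD `[s, e)` (bp) contributes a left border
`[s, min(s+20000, mid))` and a right border `[max(e−20000, mid), e)` with
`mid = (s+e)//2`: borders lie *inside* the TAD, and TADs shorter than
40 kb are tiled exactly without overlap. Border membership and bp
accounting always use the merged union per chromosome, so overlapping
borders are never double-counted in the null parameter *n*. The 20-kb
width is below the median human gene length, making "border SNP" a
locally architectural rather than genic notion.

Coordinates are 0-based, half-open everywhere internally and in BED
output; catalog input positions are 1-based and converted at load time.

## Enrichment statistics

For a disease with *Q* (deduplicated) SNPs, *q* of them in the border
union, the p-value is `P(X ≥ q)` for `X ~ Hypergeometric(N, n, Q)`;
`q = 0` returns exactly 1. The implementation delegates the tail to
`scipy.stats.hypergeom.sf`, which is stable at genome-scale *N* (~3×10⁹);
the test suite checks it against an exact big-integer combinatorial sum
for all small populations and against the symmetry `H(q|N,n,Q) =
H(q|N,Q,n)` at large parameters.

Null models: *genome-based* (N = genome bp, n = border-union bp; a locus
is any base pair) and *SNP-based* (N = distinct catalog SNPs, n = those in
borders, each counted once). The genome length *N* includes gap regions —
the literal "all base pairs" population — though callers can pass a
gap-excluded length for sensitivity analysis. Two SNPs in the same border
count as two units.

BH correction is applied separately for cancers and non-cancer diseases
(the two groups are defined on independent biological grounds and have
very different sizes: pooling would let the large group dominate the small
one's threshold), and within each (dataset, k, category-filter,
null-model) stratum — each *k* is a distinct TAD landscape, hence a
distinct family of tests. A `bh_global` scheme and `none` are provided
for sensitivity analyses. The enrichment call threshold is p_adj ≤ 0.05.

The majority rule requires significance for strictly more than half of
the scanned *k* values; missing (disease, k) results count against the
majority. Category filters (exonic / intronic / intergenic) restrict both
*q* and *Q* before testing; diseases left with Q = 0 are skipped.

Histograms of −log₁₀(p_adj) use bin width 0.1, truncation at 4 with an
explicit tail count, and per-group unit-sum normalization. The Fisher
comparison is two-sided (sum of tables with point probability ≤ observed);
a zero margin yields p = 1 with a `degenerate` flag rather than a silent
number. Star levels: * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.

## Diseasome and network coherence

The diseasome is the disease-node projection of the disease–SNP bipartite
graph, filtered to border SNPs (majority rule) or their complement, and
optionally to intergenic SNPs; nodes with an empty filtered SNP set are
dropped, and an edge requires at least `edge_threshold` (default 1) shared
SNPs. Raising the threshold can only remove edges.

Network coherence of a node subset is
`z = (m_obs − μ) / σ`, where μ and σ are the mean and population standard
deviation of the induced edge count over random same-size node subsets of
the *same* network (not the full disease universe — the question is
whether this group is special within the network it inhabits). When
`C(nodes, size) ≤ 10⁵` the null is enumerated exactly; otherwise 1000
independent uniform draws (without replacement within a draw) are used,
seeded for reproducibility. σ = 0 (edgeless network, full node set) makes
z undefined; it is reported as NaN with a flag, never as 0.

## Synthetic-data generator

The generator emulates exactly the features the pipeline consumes:

* **TAD planting** tiles each chromosome's non-gap extent with TADs of
  uniform random size in `tad_size_range`; a final remainder shorter than
  the minimum is absorbed into the preceding TAD (no degenerate slivers).
* **Contacts**: one Poisson draw per unordered bin pair with rate
  `A·(1+d)^(−α)·B^{[same TAD]}` (defaults A = 10, α = 1, B = 4), zero
  diagonal and gap rows. Poisson rather than negative-binomial noise is
  deliberate: it is the simplest count model that exercises the caller;
  overdispersion is out of scope.
* **Gene model**: non-overlapping genes covering `1 − intergenic_fraction`
  of the genome (default 60%), exons sized so that uniformly placed SNPs
  classify ≈ 40% intergenic / 55% intronic / 5% exonic — the typical
  category proportions of disease-associated SNPs.
* **Catalog**: each disease draws `Q ~ max(1, Poisson(47))` SNPs (≈ 18 of
  them intergenic at the default gene model). For a planted *enriched*
  disease each SNP lands uniformly in the planted border union with
  probability ρ (`border_placement_prob`), else uniformly in the genome.
  With probability `snp_sharing_prob` (default 0.10) a SNP is instead
  reused from the pool of previously drawn SNPs of the same class
  (cancer / non-cancer), planting the within-class assortativity the
  coherence analysis must detect. Positions are deduplicated per disease.

With B = 1 and ρ = 0 the entire pipeline sees an exchangeable global null.
All draws derive from a single seed; matrices, catalogs and output tables
are bit-reproducible.

**What the generator does not emulate:** hierarchical/nested TADs (except
in the dedicated caller test), overdispersed counts, ICE/KR normalization
artifacts, realistic linkage disequilibrium among SNPs, chromosome length
heterogeneity, or the ontology structure of real disease vocabularies.
Passing the synthetic validation therefore shows the *statistical
machinery* is correct and calibrated under the stated model — not that
real Hi-C or catalog idiosyncrasies are handled optimally.

## Calibration experiments and problem sizes

The standard study conditions (module `tadrisk.experiments`, reused by
`scripts/acceptance.py`):

* **Boundary recovery** — 20 single-chromosome studies, 500 bins of
  10 kb, TADs 5–50 bins, A = 10, α = 1, B = 4, caller at k = 5 with the
  filter on; precision and recall of demarcations within ±1 bin.
* **Type-I error** — 50 studies, two 5-Mb chromosomes, TADs 20–60 bins,
  100 diseases (30 cancers), ρ = 0; per-k fraction of enriched calls at
  BH 0.05, k = 3…10.
* **Power/FDR** — 20 studies, 400 diseases (100 cancers), 60 planted
  (30 + 30) with ρ = 0.5; border fraction ≈ 0.1 at the chosen TAD sizes.
  SNP sharing is *disabled* here: with sharing on, non-planted diseases
  inherit planted border SNPs from their class pool and become genuinely
  enriched, so the planted/non-planted labels would no longer define the
  truth an FDR can be counted against (empirically, the apparent FDR is
  ≈ 0.10–0.13 with sharing and ≤ 0.06 without, at unchanged power 1.0).
  Sharing keeps its default wherever the diseasome is analyzed — there it
  *is* the signal.
* **Group comparison** — 20 studies, one 5-Mb chromosome, 40 cancers
  (half planted, ρ = 0.5) and 100 non-cancers (none planted), k = 3…8;
  detection rate of Fisher p ≤ 0.05, plus a label-permutation control on
  the same enrichment flags.
* **Coherence estimator** — sampled (1000 draws) vs exactly enumerated
  z on random graphs of 12–16 nodes, and the null behavior of z for
  random subsets of a 40-node graph.

The k-ranges and study sizes above are the package's chosen experiment
scale; they keep a full validation run in the minutes range on a single
core while leaving every Monte-Carlo bound several standard errors away
from its threshold.

## Known limitations

* The caller over-segments when the window half-size exceeds typical TAD
  size (every diamond then straddles several domains and looks
  insulating); with flat planted structure this surfaces as a mild excess
  of calls at large k. Scanning k and using the majority rule — the
  pipeline's standard mode — absorbs this.
* The rank-sum filter is underpowered at k ≤ 3 for weak contrast
  (B ≲ 2): with 6-vs-9 samples its smallest attainable p-value is
  ≈ 2×10⁻⁴ and moderate boundaries are pruned.
* Reading `.cool` files is not supported; matrices enter as dense TSV or
  in-memory arrays.
* EFO ontology traversal is upstream: the loader consumes precomputed
  disease/cancer id lists (subtree roots EFO_0000408 and EFO_0000311).
* No LD modeling, proxy-SNP expansion, assembly liftover, nested-TAD
  calling, or inter-chromosomal contacts.
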