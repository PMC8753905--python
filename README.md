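# tadrisk

**Are the risk loci of a disease preferentially located in the border
regions of topologically associating domains?**

Genome-wide association studies link thousands of SNPs to human diseases,
but most of these variants fall outside coding sequence. One mechanistic
hypothesis is architectural: a variant near the limit of a topologically
associating domain (TAD) can weaken the insulation between adjacent
domains and mis-wire enhancer–promoter contacts. `tadrisk` implements a
genome-wide statistical pipeline for this question, aimed at computational
genomicists who have binned Hi-C contact matrices and a GWAS-style
disease–SNP catalog:

1. **TAD calling** — a TopDom-style insulation-minimum caller. For each
   inter-bin position *b* it averages the contacts in the *k*×*k* diamond
   straddling *b* (window half-size *k* in bins, scanned over *k* = 3…20),
   places candidate demarcations at local minima, and retains a candidate
   only when the flanking within-window contacts stochastically dominate
   the cross-window contacts (one-sided rank-sum on distance-normalized
   counts, BH-controlled at α = 0.05). Bins with near-zero coverage are
   masked as gaps.
2. **TAD borders** — the 20-kb stretches just *inside* each TAD end
   (distinct from inter-TAD linker "boundaries"); their merged union is
   the success population of the enrichment test.
3. **Enrichment** — for a disease with *Q* associated SNPs of which *q*
   fall in borders, the p-value is the upper tail of the hypergeometric
   distribution *H(q | N, n, Q)*, where (*N*, *n*) are either genome bp
   and border-union bp (genome-based null) or all distinct catalog SNPs
   and those in borders (SNP-based null). Raw p-values are
   Benjamini–Hochberg adjusted separately for cancers and non-cancer
   diseases; a disease is *enriched* when p_adj ≤ 0.05 for a strict
   majority of the scanned *k* values.
4. **Group comparison** — Fisher's exact test on the 2×2 table of
   enriched/not × cancer/non-cancer, per dataset and pooled.
5. **Diseasome** — the projection of the disease–SNP bipartite graph onto
   disease nodes (edge = shared SNP of a prescribed class: border or
   non-border, optionally intergenic-only), scored by *network coherence*:
   the z-score of a node subset's induced edge count against random
   same-size subsets (exact enumeration on small graphs, 1000 draws
   otherwise).

A first-class synthetic-data generator plants ground-truth TADs (Poisson
contact counts with power-law distance decay and an intra-TAD boost), a
toy gene model (exonic/intronic/intergenic classification), and diseases
with a configurable probability ρ of placing SNPs inside planted borders —
so every stage of the pipeline can be validated against a known truth.

## Worked example

Simulate a study of 100 diseases (30 cancers, half of them planted
border-enriched with ρ = 0.5) on two 5-Mb chromosomes, call TADs for
*k* = 3…10, and run the full analysis:

```yaml
# example.yaml
k_min: 3
k_max: 10
n_chromosomes: 2
bins_per_chromosome: 500
tad_size_range: [20, 60]
n_cancers: 30
n_noncancers: 70
frac_enriched_cancers: 0.5
border_placement_prob: 0.5
coherence_draws: 500
```

```
$ tadrisk all --config example.yaml --out-dir out --seed 11
100 diseases, 4259 SNPs; majority-enriched: 17; Fisher p=1.549e-09 ****
```

Seventeen diseases are majority-enriched — essentially the planted
cancers — and the cancer excess is detected by the Fisher comparison at
p ≈ 1.5 × 10⁻⁹. The per-(disease, k) table `out/enrichment_synthetic.tsv`
holds the raw ingredients, e.g.

```
efoId      isCancer  k  q   Q   n        N         p_raw     p_adj    enriched
EFO_C0000  True      3  27  48  1080000  10000000  1.78e-14  5.9e-14  True
```

— 27 of this cancer's 48 SNPs fall in the 1.08 Mb of called borders of a
10-Mb genome, against a null expectation of ≈ 5.2. The coherence report
(`out/coherence.tsv`, border-SNP network) shows the planted within-class
SNP sharing: the enriched-cancer subset is far more internally connected
than random subsets (z ≈ +15.1), while non-cancer subsets sit at or below
their null (z ≈ −2.2).

Other entry points: `tadrisk simulate` (write matrices/catalog/truth),
`tadrisk call-tads` (TAD + border BEDs from a dense-TSV matrix),
`tadrisk diseasome` (edge lists). Matrices are read from dense TSV
fixtures; all outputs are TSV/BED/JSON and byte-reproducible for a given
(config, seed).

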