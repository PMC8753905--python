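"""Synthetic Hi-C matrices and GWAS-catalog-like disease/SNP tables.

Every downstream stage of the pipeline needs a ground truth: this module
plants a TAD partition on each chromosome, draws Poisson contact counts with
power-law distance decay and a within-TAD intensity boost, lays a toy gene
model over the genome, and samples diseases whose associated SNPs are either
uniform over the genome or preferentially placed inside the planted TAD
borders.

Model summary
-------------
* Contacts: for bins ``i != j``,
  ``count ~ Poisson(A * (1 + |i-j|)**(-alpha) * (B if same TAD else 1))``
  with a single draw per unordered pair (the matrix is symmetric by
  construction); gap rows/columns and the diagonal are zero.
* Catalog: each disease carries ``Q ~ Poisson(Q_mean)`` (min 1) SNPs
  (default Q_mean = 47, of which roughly 40% fall outside genes, matching
  typical GWAS-catalog proportions).  For an *enriched* disease each SNP
  lands uniformly inside the planted border union with probability ``rho``,
  otherwise uniformly in the genome.  SNPs are shared between diseases of
  the same class (cancer / non-cancer) with probability
  ``snp_sharing_prob``, which plants the assortative clustering the
  diseasome analysis must detect.

With ``B = 1`` and ``rho = 0`` the whole pipeline sees a global null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tads import TAD, ContactMatrix, extract_borders

__all__ = ["SimConfig", "TruthSet", "GeneModel", "plant_tads",
           "simulate_contact_matrix", "simulate_gene_model",
           "simulate_catalog", "simulate_study"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Contact-model parameters: ``baseline_intensity`` (A) is the expected
    count at distance 0, ``decay_exponent`` (alpha > 0) the power-law decay,
    ``within_tad_factor`` (B >= 1) the intra-TAD boost.  Catalog parameters:
    ``snps_per_disease`` (Q_mean) defaults to 47 SNPs per disease with an
    ``intergenic_fraction`` of 0.40 (about 18 intergenic SNPs per disease);
    ``border_placement_prob`` (rho) is the probability that a SNP of an
    enriched disease is placed inside a planted TAD border.
    """

    n_chromosomes: int = 2
    bins_per_chromosome: int = 500
    bin_size: int = 10_000
    tad_size_range: tuple[int, int] = (5, 50)
    baseline_intensity: float = 10.0
    decay_exponent: float = 1.0
    within_tad_factor: float = 4.0
    gap_bins: dict[str, list[int]] = field(default_factory=dict)
    n_cancers: int = 30
    n_noncancers: int = 70
    frac_enriched_cancers: float = 0.0
    frac_enriched_noncancers: float = 0.0
    snps_per_disease: float = 47.0
    intergenic_fraction: float = 0.40
    exonic_fraction: float = 0.05
    border_placement_prob: float = 0.0
    snp_sharing_prob: float = 0.10
    border_bp: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tad_size_range
        if lo < 1 or lo > hi:
            raise ValueError("tad_size_range must satisfy 1 <= min <= max")
        if self.bins_per_chromosome < 2 * lo:
            raise ValueError("bins_per_chromosome must be >= 2 * tad_size_range.min")
        for name in ("frac_enriched_cancers", "frac_enriched_noncancers",
                     "intergenic_fraction", "exonic_fraction",
                     "border_placement_prob", "snp_sharing_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.baseline_intensity <= 0 or self.decay_exponent <= 0:
            raise ValueError("baseline_intensity and decay_exponent must be positive")
        if self.within_tad_factor < 1:
            raise ValueError("within_tad_factor must be >= 1")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def layout(self) -> dict[str, int]:
        return {c: self.bins_per_chromosome for c in self.chrom_names}

    @property
    def genome_bp(self) -> int:
        return self.n_chromosomes * self.bins_per_chromosome * self.bin_size


@dataclass
class GeneModel:
    """Non-overlapping gene intervals with exon sub-intervals (bp, half-open)."""

    genes: pd.DataFrame  # chrom, start, end
    exons: pd.DataFrame  # chrom, start, end

    def to_bed(self, path) -> None:
        """Write genes as BED12 rows with exon blocks."""
        exons = self.exons.sort_values(["chrom", "start"])
        with open(path, "w") as fh:
            for i, g in enumerate(self.genes.sort_values(["chrom", "start"]).itertuples()):
                sub = exons[(exons["chrom"] == g.chrom)
                            & (exons["start"] >= g.start)
                            & (exons["end"] <= g.end)]
                sizes = ",".join(str(e - s) for s, e in zip(sub["start"], sub["end"]))
                starts = ",".join(str(s - g.start) for s in sub["start"])
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\tgene{i}\t0\t+\t{g.start}"
                    f"\t{g.end}\t0\t{len(sub)}\t{sizes}\t{starts}\n"
                )


@dataclass
class TruthSet:
    """Ground truth of one synthetic study."""

    planted_tads: dict[str, np.ndarray]  # chrom -> (m, 2) bin intervals
    planted_border_union: dict[str, np.ndarray]  # chrom -> (m, 2) bp intervals
    enriched_disease_ids: set[str] = field(default_factory=set)
    gene_model: GeneModel | None = None

    def boundaries(self, chrom: str) -> np.ndarray:
        """Internal planted demarcations (bin positions) for one chromosome."""
        tads = self.planted_tads[chrom]
        return tads[1:, 0].copy()

    @property
    def border_union_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum()
                       for iv in self.planted_border_union.values()))


# ---------------------------------------------------------------------------
# TAD planting


def _plant_one_run(lo: int, hi: int, size_range: tuple[int, int],
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    lo_sz, hi_sz = size_range
    edges = [lo]
    while hi - edges[-1] > hi_sz:
        edges.append(edges[-1] + int(rng.integers(lo_sz, hi_sz + 1)))
    remainder = hi - edges[-1]
    if remainder >= lo_sz or len(edges) == 1:
        edges.append(hi)
    else:
        # remainder shorter than the minimum TAD: absorb into the last TAD
        edges[-1] = hi
    return list(zip(edges[:-1], edges[1:]))


def plant_tads(layout: dict[str, int], size_range: tuple[int, int], seed: int,
               gap_bins: dict[str, list[int]] | None = None,
               bin_size: int = 10_000, border_bp: int = 20_000) -> TruthSet:
    """Tile each chromosome's non-gap extent with TADs of random size.

    Sizes are drawn uniformly in ``size_range`` (bins); a final remainder
    shorter than the minimum size is merged into the preceding TAD so every
    planted TAD keeps at least the minimum size where feasible.  The planted
    border union is derived from the planted TADs with the same 20-kb border
    rule the caller uses downstream.
    """
    lo_sz, hi_sz = size_range
    if lo_sz < 1 or lo_sz > hi_sz:
        raise ValueError("size_range must satisfy 1 <= min <= max")
    rng = np.random.default_rng(seed)
    gap_bins = gap_bins or {}
    planted: dict[str, np.ndarray] = {}
    border_union: dict[str, np.ndarray] = {}
    all_tads: list[TAD] = []
    for chrom, n_bins in layout.items():
        if n_bins < lo_sz:
            raise ValueError(
                f"{chrom}: {n_bins} bins is shorter than the minimum TAD size {lo_sz}"
            )
        gaps = sorted(set(gap_bins.get(chrom, [])))
        mask = np.zeros(n_bins, dtype=bool)
        mask[gaps] = True
        tads: list[tuple[int, int]] = []
        i = 0
        while i < n_bins:
            if mask[i]:
                i += 1
                continue
            j = i
            while j < n_bins and not mask[j]:
                j += 1
            tads.extend(_plant_one_run(i, j, size_range, rng))
            i = j
        planted[chrom] = np.asarray(tads, dtype=np.int64).reshape(-1, 2)
        all_tads.extend(TAD(chrom, s, e, k=0) for s, e in tads)
    borders = extract_borders(all_tads, border_bp=border_bp, bin_size=bin_size)
    for chrom in layout:
        border_union[chrom] = borders.union.get(
            chrom, np.empty((0, 2), dtype=np.int64)
        )
    return TruthSet(planted_tads=planted, planted_border_union=border_union)


# ---------------------------------------------------------------------------
# Contact matrices


def simulate_contact_matrix(truth: TruthSet, config: SimConfig, seed: int,
                            chrom: str | None = None) -> ContactMatrix:
    """Draw one chromosome's Poisson contact matrix around the planted TADs."""
    chrom = chrom or config.chrom_names[0]
    n = config.layout[chrom]
    rng = np.random.default_rng(seed)
    tad_id = np.full(n, -1, dtype=np.int64)
    for t, (s, e) in enumerate(truth.planted_tads[chrom]):
        tad_id[s:e] = t
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = config.baseline_intensity * (1.0 + d) ** (-config.decay_exponent)
    same = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
    lam = np.where(same, lam * config.within_tad_factor, lam)
    iu = np.triu_indices(n, 1)
    counts = np.zeros((n, n))
    draws = rng.poisson(lam[iu])
    counts[iu] = draws
    counts += counts.T
    gaps = np.array(config.gap_bins.get(chrom, []), dtype=np.int64)
    if gaps.size:
        counts[gaps, :] = 0
        counts[:, gaps] = 0
    gap_mask = np.zeros(n, dtype=bool)
    gap_mask[gaps] = True
    return ContactMatrix(chrom=chrom, bin_size=config.bin_size,
                         counts=counts, gap_mask=gap_mask)


# ---------------------------------------------------------------------------
# Gene model


def simulate_gene_model(layout_bp: dict[str, int], seed: int,
                        gene_fraction: float = 0.60,
                        exon_fraction_of_gene: float = 0.0833,
                        mean_gene_bp: int = 25_000) -> GeneModel:
    """Lay non-overlapping genes along each chromosome.

    Genes cover about ``gene_fraction`` of each chromosome; each gene holds
    one exon block per ~5 kb of gene length so that exons make up about
    ``exon_fraction_of_gene`` of gene bp.  A SNP will later classify as
    exonic / intronic / intergenic by containment, so these two knobs set
    the expected category fractions of uniformly placed SNPs.
    """
    rng = np.random.default_rng(seed)
    gene_rows, exon_rows = [], []
    mean_gap = mean_gene_bp * (1 - gene_fraction) / max(gene_fraction, 1e-9)
    for chrom, length in layout_bp.items():
        pos = int(rng.exponential(mean_gap))
        while pos < length:
            glen = int(rng.uniform(0.5, 1.5) * mean_gene_bp)
            g_end = min(pos + glen, length)
            if g_end - pos >= 200:
                gene_rows.append((chrom, pos, g_end))
                n_ex = max(1, (g_end - pos) // 5000)
                ex_len = max(1, int((g_end - pos) * exon_fraction_of_gene / n_ex))
                starts = np.sort(rng.choice(
                    np.arange(pos, g_end - ex_len + 1), size=int(n_ex), replace=False
                )) if g_end - pos > ex_len else np.array([pos])
                prev_end = pos
                for s in starts:
                    s = max(int(s), prev_end)
                    e = min(s + ex_len, g_end)
                    if e > s:
                        exon_rows.append((chrom, s, e))
                        prev_end = e
            pos = g_end + int(rng.exponential(mean_gap)) + 1
    cols = ["chrom", "start", "end"]
    return GeneModel(
        genes=pd.DataFrame(gene_rows, columns=cols),
        exons=pd.DataFrame(exon_rows, columns=cols),
    )


# ---------------------------------------------------------------------------
# Catalog


def _draw_position(rng: np.random.Generator, config: SimConfig,
                   truth: TruthSet, in_border: bool) -> tuple[str, int]:
    """Uniform bp position, either in the planted border union or genome-wide."""
    if in_border:
        chroms, weights, intervals = [], [], []
        for chrom, iv in truth.planted_border_union.items():
            if iv.shape[0]:
                chroms.append(chrom)
                intervals.append(iv)
                weights.append((iv[:, 1] - iv[:, 0]).sum())
        w = np.asarray(weights, dtype=float)
        ci = rng.choice(len(chroms), p=w / w.sum())
        iv = intervals[ci]
        lens = iv[:, 1] - iv[:, 0]
        ii = rng.choice(len(iv), p=lens / lens.sum())
        return chroms[ci], int(rng.integers(iv[ii, 0], iv[ii, 1]))
    chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
    return chrom, int(rng.integers(0, config.bins_per_chromosome * config.bin_size))


def simulate_catalog(truth: TruthSet, config: SimConfig, seed: int) -> pd.DataFrame:
    """Sample the disease / SNP association table.

    Returns a tidy table with columns ``snpId, chrom, pos, efoId,
    diseaseLabel, isCancer, category`` (``pos`` is 1-based, catalog
    convention).  Enrichment in planted borders is confined to the diseases
    selected by ``frac_enriched_*``; shared SNPs are reused within the same
    cancer / non-cancer class.  Positions are de-duplicated per disease.
    """
    if config.genome_bp <= 0:
        raise ValueError("empty genome")
    any_enriched = (config.frac_enriched_cancers > 0
                    or config.frac_enriched_noncancers > 0)
    if any_enriched and truth.border_union_bp == 0:
        raise ValueError("planted border union is empty but enrichment requested")
    rng = np.random.default_rng(seed)
    gene_model = truth.gene_model
    rows = []
    pools: dict[bool, list[tuple[str, int]]] = {True: [], False: []}
    specs = ([("cancer", i, True) for i in range(config.n_cancers)]
             + [("disease", i, False) for i in range(config.n_noncancers)])
    n_enr_c = round(config.frac_enriched_cancers * config.n_cancers)
    n_enr_n = round(config.frac_enriched_noncancers * config.n_noncancers)
    enriched_ids = {f"EFO_C{i:04d}" for i in range(n_enr_c)}
    enriched_ids |= {f"EFO_N{i:04d}" for i in range(n_enr_n)}
    truth.enriched_disease_ids = set(enriched_ids)
    for kind, i, is_cancer in specs:
        efo = f"EFO_{'C' if is_cancer else 'N'}{i:04d}"
        enriched = efo in enriched_ids
        q_total = max(1, int(rng.poisson(config.snps_per_disease)))
        seen: set[tuple[str, int]] = set()
        for _ in range(q_total):
            pool = pools[is_cancer]
            if pool and rng.random() < config.snp_sharing_prob:
                chrom, pos = pool[int(rng.integers(len(pool)))]
            else:
                in_border = enriched and rng.random() < config.border_placement_prob
                chrom, pos = _draw_position(rng, config, truth, in_border)
                pool.append((chrom, pos))
            if (chrom, pos) in seen:
                continue
            seen.add((chrom, pos))
            rows.append({
                "snpId": f"rs_{chrom}_{pos}",
                "chrom": chrom,
                "pos": pos + 1,  # 1-based output
                "efoId": efo,
                "diseaseLabel": f"{kind} {i}",
                "isCancer": is_cancer,
            })
    df = pd.DataFrame(rows)
    if gene_model is not None:
        from .catalog import classify_positions
        df["category"] = classify_positions(df["chrom"].to_numpy(),
                                            df["pos"].to_numpy() - 1, gene_model)
    else:
        df["category"] = "intergenic"
    return df


def simulate_study(config: SimConfig):
    """Generate truth, per-chromosome matrices, gene model, and catalog.

    Returns ``(truth, matrices, catalog)`` where ``matrices`` maps
    chromosome name to :class:`~tadrisk.tads.ContactMatrix`.  All draws
    derive from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(3 + config.n_chromosomes) % (2**31)
    truth = plant_tads(config.layout, config.tad_size_range, int(seeds[0]),
                       gap_bins=config.gap_bins, bin_size=config.bin_size,
                       border_bp=config.border_bp)
    gene_fraction = 1.0 - config.intergenic_fraction
    exon_frac = (config.exonic_fraction / gene_fraction) if gene_fraction > 0 else 0.0
    layout_bp = {c: n * config.bin_size for c, n in config.layout.items()}
    truth.gene_model = simulate_gene_model(layout_bp, int(seeds[1]),
                                           gene_fraction=gene_fraction,
                                           exon_fraction_of_gene=exon_frac)
    matrices = {
        chrom: simulate_contact_matrix(truth, config, int(seeds[3 + i]), chrom)
        for i, chrom in enumerate(config.chrom_names)
    }
    catalog = simulate_catalog(truth, config, int(seeds[2]))
    return truth, matrices, catalog
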