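"""Calibration experiments on synthetic data with known ground truth.

Each function runs a self-contained simulation study and measures one
operating characteristic of the pipeline: boundary recovery of the TAD
caller, type-I error of the enrichment test under a global null, power and
false-discovery rate with planted border-enriched diseases, detection of a
cancer-confined enrichment difference, and the sampling accuracy of the
network-coherence estimator.  The same functions back the test-bench and
the ``scripts/acceptance.py`` reproduction script.

Problem sizes (chromosome lengths, disease counts, seed counts) are the
package's standard study conditions; they are stated in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .diseasome import network_coherence
from .pipeline import run_study
from .simulate import SimConfig, plant_tads, simulate_contact_matrix
from .tads import TADCallConfig, call_tads

__all__ = [
    "boundary_recovery",
    "type_i_error",
    "power_fdr",
    "group_comparison_detection",
    "coherence_estimator_check",
]


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# TAD caller


@dataclass
class RecoveryResult:
    precision: list[float]
    recall: list[float]

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))


def boundary_recovery(
    n_seeds: int = 20,
    seed: int = 0,
    n_bins: int = 500,
    tad_size_range: tuple[int, int] = (5, 50),
    baseline_intensity: float = 10.0,
    decay_exponent: float = 1.0,
    within_tad_factor: float = 4.0,
    k: int = 5,
    tolerance_bins: int = 1,
    statistical_filter: bool = True,
) -> RecoveryResult:
    """Precision/recall of called vs planted demarcations within a bin
    tolerance, over independent simulated chromosomes."""
    seeds = _derive_seeds(seed, 2 * n_seeds)
    precision, recall = [], []
    for i in range(n_seeds):
        cfg = SimConfig(
            seed=int(seeds[i]), n_chromosomes=1, bins_per_chromosome=n_bins,
            tad_size_range=tad_size_range,
            baseline_intensity=baseline_intensity,
            decay_exponent=decay_exponent,
            within_tad_factor=within_tad_factor,
        )
        truth = plant_tads(cfg.layout, tad_size_range, int(seeds[i]))
        m = simulate_contact_matrix(truth, cfg, int(seeds[n_seeds + i]))
        tads = call_tads(m, TADCallConfig(k=k, statistical_filter=statistical_filter))
        called = np.array(sorted(t.start_bin for t in tads if t.start_bin > 0))
        planted = truth.boundaries("chr1")
        if called.size == 0 or planted.size == 0:
            precision.append(0.0)
            recall.append(0.0)
            continue
        recall.append(
            float(np.mean([np.abs(called - b).min() <= tolerance_bins for b in planted]))
        )
        precision.append(
            float(np.mean([np.abs(planted - b).min() <= tolerance_bins for b in called]))
        )
    return RecoveryResult(precision=precision, recall=recall)


# ---------------------------------------------------------------------------
# Enrichment test calibration


def _study_config(seed: int, **overrides) -> SimConfig:
    base = dict(
        n_chromosomes=2, bins_per_chromosome=500, tad_size_range=(20, 60),
        n_cancers=30, n_noncancers=70, border_placement_prob=0.0,
    )
    base.update(overrides)
    return SimConfig(seed=seed, **base)


@dataclass
class TypeIResult:
    per_k_fraction: dict[int, float]
    per_k_se: dict[int, float]

    @property
    def worst_excess(self) -> float:
        """max over k of (fraction - (0.05 + 3 SE)); negative means controlled."""
        return max(
            self.per_k_fraction[k] - (0.05 + 3 * self.per_k_se[k])
            for k in self.per_k_fraction
        )


def type_i_error(n_seeds: int = 50, seed: int = 0,
                 k_range=tuple(range(3, 11))) -> TypeIResult:
    """Fraction of diseases called enriched (BH 0.05) per window size when
    SNP placement is uniform (global null, rho = 0)."""
    seeds = _derive_seeds(seed, n_seeds)
    frac = {k: [] for k in k_range}
    for s in seeds:
        res = run_study(_study_config(int(s)), k_range=k_range)
        per_k = res.results.groupby("k")["enriched"].mean()
        for k in k_range:
            frac[k].append(float(per_k.get(k, 0.0)))
    return TypeIResult(
        per_k_fraction={k: float(np.mean(v)) for k, v in frac.items()},
        per_k_se={k: float(np.std(v) / np.sqrt(n_seeds)) for k, v in frac.items()},
    )


@dataclass
class PowerFDRResult:
    power: list[float]
    fdr: list[float]

    @property
    def mean_power(self) -> float:
        return float(np.mean(self.power))

    @property
    def mean_fdr(self) -> float:
        return float(np.mean(self.fdr))


def power_fdr(n_seeds: int = 20, seed: int = 0, rho: float = 0.5,
              k_range=tuple(range(3, 11))) -> PowerFDRResult:
    """Majority-rule recovery of planted border-enriched diseases.

    60 of 400 diseases are planted (30 of 100 cancers, 30 of 300
    non-cancers) with SNP border-placement probability ``rho``.  SNP sharing
    is disabled here: shared SNPs would hand planted border SNPs to
    non-planted diseases of the same class, making them genuinely enriched
    and the planted/non-planted truth labels meaningless for an FDR count.
    """
    seeds = _derive_seeds(seed, n_seeds)
    power, fdr = [], []
    for s in seeds:
        cfg = _study_config(
            int(s), n_cancers=100, n_noncancers=300,
            frac_enriched_cancers=0.3, frac_enriched_noncancers=0.1,
            border_placement_prob=rho, snp_sharing_prob=0.0,
        )
        res = run_study(cfg, k_range=k_range)
        planted = res.truth.enriched_disease_ids
        called = set(res.majority.index[res.majority])
        tp = len(called & planted)
        power.append(tp / len(planted))
        fdr.append((len(called) - tp) / max(1, len(called)))
    return PowerFDRResult(power=power, fdr=fdr)


@dataclass
class GroupDetectionResult:
    fisher_p: list[float]
    shuffled_p: list[float]

    @property
    def detection_rate(self) -> float:
        return float(np.mean(np.asarray(self.fisher_p) <= 0.05))

    @property
    def shuffled_rate(self) -> float:
        return float(np.mean(np.asarray(self.shuffled_p) <= 0.05))


def group_comparison_detection(n_seeds: int = 20, seed: int = 0,
                               k_range=tuple(range(3, 9))) -> GroupDetectionResult:
    """Fisher detection of a cancer-confined enrichment excess.

    Half of 40 cancers are planted border-enriched (rho = 0.5), none of 100
    non-cancers.  The label-shuffled control permutes the cancer labels over
    the same majority-enrichment flags.
    """
    from scipy.stats import fisher_exact

    seeds = _derive_seeds(seed, 2 * n_seeds)
    ps, shuffled = [], []
    for i in range(n_seeds):
        cfg = _study_config(
            int(seeds[i]), n_chromosomes=1, n_cancers=40, n_noncancers=100,
            frac_enriched_cancers=0.5, frac_enriched_noncancers=0.0,
            border_placement_prob=0.5,
        )
        res = run_study(cfg, k_range=k_range)
        ps.append(res.comparison["aggregated"]["fisher_p"])
        flags = res.majority
        is_cancer = res.catalog.diseases.set_index("efoId")["isCancer"]
        labels = is_cancer.reindex(flags.index).to_numpy(bool)
        rng = np.random.default_rng(int(seeds[n_seeds + i]))
        perm = rng.permutation(labels)
        f = flags.to_numpy(bool)
        table = [[int((f & perm).sum()), int((~f & perm).sum())],
                 [int((f & ~perm).sum()), int((~f & ~perm).sum())]]
        shuffled.append(float(fisher_exact(table)[1]))
    return GroupDetectionResult(fisher_p=ps, shuffled_p=shuffled)


# ---------------------------------------------------------------------------
# Coherence estimator


@dataclass
class CoherenceCheckResult:
    max_discrepancy_se: float  # |z_sampled - z_exact| in SE units, worst graph
    mean_abs_null_z: float

    @property
    def ok(self) -> bool:
        return self.max_discrepancy_se <= 3.0 and self.mean_abs_null_z < 0.3


def coherence_estimator_check(seed: int = 0, n_graphs: int = 5,
                              n_draws: int = 1000) -> CoherenceCheckResult:
    """Sampled vs exact coherence on small random graphs, plus the null
    behavior of z for random subsets of a larger graph."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for g_i in range(n_graphs):
        g = nx.gnp_random_graph(12 + g_i, 0.3, seed=int(rng.integers(2**31)))
        if g.number_of_edges() == 0:
            continue
        subset = list(g.nodes)[: 4 + g_i % 3]
        exact = network_coherence(g, subset, exact=True)
        if not exact.defined:
            continue
        sampled = network_coherence(g, subset, n_draws=n_draws,
                                    seed=int(rng.integers(2**31)), exact=False)
        if not sampled.defined:
            continue
        # standard error of the sampled z, dominated by the error of mu
        se_z = (sampled.sigma / np.sqrt(n_draws)) / exact.sigma
        worst = max(worst, abs(sampled.z - exact.z) / max(se_z, 1e-12))
    big = nx.gnp_random_graph(40, 0.2, seed=int(rng.integers(2**31)))
    zs = []
    for i in range(100):
        subset = rng.choice(40, size=8, replace=False).tolist()
        res = network_coherence(big, subset, n_draws=400,
                                seed=int(rng.integers(2**31)), exact=False)
        if res.defined:
            zs.append(res.z)
    return CoherenceCheckResult(
        max_discrepancy_se=float(worst),
        mean_abs_null_z=float(abs(np.mean(zs))),
    )
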