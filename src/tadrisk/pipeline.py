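"""End-to-end orchestration: simulate/ingest -> TAD calling -> annotation ->
enrichment -> group comparison -> diseasome, with a machine-readable bundle.

Every run is fully determined by (config, seed): output TSVs are
byte-identical across repeated runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .catalog import (DiseaseCatalog, catalog_from_dataframe,
                      majority_border_snp_set, pairwise_close_counts,
                      snp_border_membership)
from .diseasome import coherence_report
from .enrichment import (adjust_pvalues, aggregate_over_datasets,
                         enrichment_histogram, fisher_group_comparison,
                         majority_enriched, test_all_diseases)
from .simulate import SimConfig, simulate_study
from .tads import (ContactMatrix, TADCallConfig, borders_to_bed, call_tads_multi_k,
                   extract_borders, read_dense_matrix, tads_to_bed)

log = logging.getLogger("tadrisk")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run (YAML-serializable)."""

    input_mode: str = "synthetic"  # synthetic | dense_tsv
    dataset_ids: tuple[str, ...] = ("synthetic",)
    matrix_paths: dict = field(default_factory=dict)  # dataset -> {chrom: path}
    catalog_path: str | None = None
    k_min: int = 3
    k_max: int = 20
    border_bp: int = 20_000
    null_model: str = "genome_based"
    category_filters: tuple[str, ...] = ("all",)
    mt_scheme: str = "bh_within_group"
    alpha: float = 0.05
    statistical_filter: bool = True
    min_tad_bins: int = 2
    coherence_draws: int = 1000
    edge_threshold: int = 1
    out_dir: str = "tadrisk_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    @property
    def k_range(self) -> tuple[int, ...]:
        return tuple(range(self.k_min, self.k_max + 1))


def validate_config(raw: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Normalize a flat dict into a PipelineConfig, collecting all errors."""
    errors: list[str] = []
    raw = dict(raw or {})
    sim_keys = {f.name for f in dataclasses.fields(SimConfig)}
    sim_raw = {k: v for k, v in raw.items() if k in sim_keys}
    cfg_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
    cfg_raw = {k: v for k, v in raw.items() if k in cfg_keys and k != "sim"}
    unknown = set(raw) - sim_keys - cfg_keys
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    if "tad_size_range" in sim_raw:
        sim_raw["tad_size_range"] = tuple(sim_raw["tad_size_range"])
    try:
        sim = SimConfig(**sim_raw)
    except (TypeError, ValueError) as e:
        errors.append(f"sim: {e}")
        sim = None
    cfg = PipelineConfig(**cfg_raw, sim=sim or SimConfig())
    if cfg.k_max < cfg.k_min:
        errors.append(f"k_max={cfg.k_max} < k_min={cfg.k_min}")
    if cfg.k_min < 1:
        errors.append("k_min must be >= 1")
    if cfg.border_bp <= 0:
        errors.append(f"border_bp={cfg.border_bp} must be positive")
    if not 0 < cfg.alpha < 1:
        errors.append(f"alpha={cfg.alpha} must lie in (0, 1)")
    if cfg.input_mode not in ("synthetic", "dense_tsv"):
        errors.append(f"unknown input_mode {cfg.input_mode!r}")
    if cfg.null_model not in ("genome_based", "snp_based"):
        errors.append(f"unknown null_model {cfg.null_model!r}")
    if cfg.mt_scheme not in ("bh_within_group", "bh_global", "none"):
        errors.append(f"unknown mt_scheme {cfg.mt_scheme!r}")
    for f in cfg.category_filters:
        if f not in ("all", "exonic", "intronic", "intergenic"):
            errors.append(f"unknown category filter {f!r}")
    if errors:
        return None, errors
    return cfg, []


def load_config(path) -> tuple[PipelineConfig | None, list[str]]:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    """In-memory view of the bundle written to out_dir."""

    catalog: DiseaseCatalog
    borders_by_k: dict
    membership: pd.DataFrame
    results: pd.DataFrame
    majority: pd.Series
    comparison: dict
    coherence: pd.DataFrame
    truth: object | None = None


def _call_dataset(matrices: dict[str, ContactMatrix], cfg: PipelineConfig):
    """TADs and borders for every k, pooled over chromosomes."""
    call_cfg = TADCallConfig(
        k_range=cfg.k_range,
        statistical_filter=cfg.statistical_filter,
        min_tad_bins=cfg.min_tad_bins,
    )
    tads_by_k: dict[int, list] = {k: [] for k in cfg.k_range}
    for chrom in sorted(matrices):
        per_k = call_tads_multi_k(matrices[chrom], call_cfg)
        for k, tads in per_k.items():
            tads_by_k[k].extend(tads)
    bin_size = next(iter(matrices.values())).bin_size
    borders_by_k = {
        k: extract_borders(tads, border_bp=cfg.border_bp, bin_size=bin_size)
        for k, tads in tads_by_k.items()
    }
    return tads_by_k, borders_by_k


def run_study(sim: SimConfig, k_range=(3, 4, 5, 6, 7, 8, 9, 10),
              null_model: str = "genome_based",
              category_filter: str = "all",
              mt_scheme: str = "bh_within_group",
              alpha: float = 0.05,
              statistical_filter: bool = True) -> PipelineResult:
    """Simulate one synthetic study and run the analysis in memory.

    Convenience wrapper around the library stages (no files written):
    simulate -> call TADs per k -> borders -> membership -> hypergeometric
    tests -> BH -> majority rule.  Used by the test-bench and the
    reproduction script.
    """
    truth, matrices, catalog_df = simulate_study(sim)
    catalog = catalog_from_dataframe(catalog_df)
    call_cfg = TADCallConfig(k_range=tuple(k_range),
                             statistical_filter=statistical_filter)
    tads_by_k: dict[int, list] = {k: [] for k in call_cfg.k_range}
    for chrom in sorted(matrices):
        for k, tads in call_tads_multi_k(matrices[chrom], call_cfg).items():
            tads_by_k[k].extend(tads)
    borders_by_k = {
        k: extract_borders(t, border_bp=sim.border_bp, bin_size=sim.bin_size)
        for k, t in tads_by_k.items()
    }
    membership = snp_border_membership(catalog, borders_by_k)
    results = test_all_diseases(
        catalog, borders_by_k, membership, null_model=null_model,
        category_filter=category_filter, genome_bp=sim.genome_bp,
    )
    results = adjust_pvalues(results, mt_scheme)
    results["enriched"] = results["p_adj"] <= alpha
    majority = majority_enriched(results, call_cfg.k_range, alpha)
    border_set = majority_border_snp_set(membership, call_cfg.k_range)
    is_cancer = catalog.diseases.set_index("efoId")["isCancer"]
    flags_c = majority[is_cancer.reindex(majority.index).fillna(False).astype(bool)]
    flags_n = majority[~is_cancer.reindex(majority.index).fillna(False).astype(bool)]
    comp = fisher_group_comparison(flags_c.to_numpy(), flags_n.to_numpy())
    return PipelineResult(
        catalog=catalog, borders_by_k=borders_by_k, membership=membership,
        results=results, majority=majority,
        comparison={"aggregated": dataclasses.asdict(comp)},
        coherence=pd.DataFrame(), truth=truth,
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the results bundle to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = cfg.dataset_ids[0]
    truth = None
    if cfg.input_mode == "synthetic":
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed, border_bp=cfg.border_bp)
        truth, matrices, catalog_df = simulate_study(sim)
        catalog = catalog_from_dataframe(catalog_df)
        genome_bp = sim.genome_bp
        log.info("simulated %d diseases, %d SNPs, %d chromosomes",
                 catalog.n_diseases, catalog.n_snps, sim.n_chromosomes)
    else:
        if not cfg.matrix_paths or cfg.catalog_path is None:
            raise ValueError("dense_tsv mode needs matrix_paths and catalog_path")
        matrices = {
            chrom: read_dense_matrix(path, chrom=chrom)
            for chrom, path in cfg.matrix_paths[dataset].items()
        }
        catalog = catalog_from_dataframe(pd.read_csv(cfg.catalog_path, sep="\t"))
        genome_bp = sum(m.length_bp for m in matrices.values())

    tads_by_k, borders_by_k = _call_dataset(matrices, cfg)
    bin_size = next(iter(matrices.values())).bin_size
    for k in cfg.k_range:
        tads_to_bed(tads_by_k[k], bin_size, out / f"tads_{dataset}_k{k}.bed")
        borders_to_bed(borders_by_k[k], out / f"borders_{dataset}_k{k}.bed")
    log.info("called TADs for %d window sizes", len(cfg.k_range))

    normalized = catalog.associations.merge(catalog.snps, on="snpId").merge(
        catalog.diseases, on="efoId")
    normalized.to_csv(out / f"catalog_{dataset}.tsv", sep="\t", index=False)
    if truth is not None and truth.gene_model is not None:
        truth.gene_model.to_bed(out / "gene_model.bed")
    pairwise_close_counts(
        catalog, thresholds=(10_000, 100_000, 1_000_000)
    ).to_csv(out / f"pairwise_distances_{dataset}.tsv", sep="\t", index=False)

    membership = snp_border_membership(catalog, borders_by_k)
    membership.to_csv(out / f"membership_{dataset}.tsv", sep="\t")
    border_set = majority_border_snp_set(membership, cfg.k_range)
    pd.Series(sorted(border_set)).to_csv(
        out / f"majority_border_snps_{dataset}.tsv", sep="\t",
        index=False, header=["snpId"],
    )

    frames = []
    for filt in cfg.category_filters:
        res = test_all_diseases(
            catalog, borders_by_k, membership,
            null_model=cfg.null_model, category_filter=filt,
            genome_bp=genome_bp, dataset=dataset,
        )
        frames.append(res)
    results = adjust_pvalues(pd.concat(frames, ignore_index=True), cfg.mt_scheme)
    results["enriched"] = results["p_adj"] <= cfg.alpha
    results.to_csv(out / f"enrichment_{dataset}.tsv", sep="\t", index=False)

    primary = results[results["filter"] == cfg.category_filters[0]]
    majority = majority_enriched(primary, cfg.k_range, cfg.alpha)
    majority.rename_axis("efoId").to_csv(out / f"majority_calls_{dataset}.tsv", sep="\t")

    hist = enrichment_histogram(primary)
    hist.to_csv(out / f"histogram_{dataset}.tsv", sep="\t", index=False)

    is_cancer = catalog.diseases.set_index("efoId")["isCancer"]
    cancer_flags = majority[is_cancer.reindex(majority.index).fillna(False).astype(bool)]
    noncancer_flags = majority[~is_cancer.reindex(majority.index).fillna(False).astype(bool)]
    comp = fisher_group_comparison(cancer_flags.to_numpy(), noncancer_flags.to_numpy())
    comparison = {
        "per_dataset": {dataset: dataclasses.asdict(comp)},
        "aggregated": dataclasses.asdict(aggregate_over_datasets([comp])),
    }
    with open(out / "comparison.json", "w") as fh:
        json.dump(comparison, fh, indent=2, sort_keys=True)
    log.info("Fisher comparison p=%.4g (%s)", comp.fisher_p, comp.stars or "ns")

    coh = coherence_report(
        catalog, border_set, majority,
        n_draws=cfg.coherence_draws, seed=cfg.seed,
        edge_threshold=cfg.edge_threshold,
    )
    coh.to_csv(out / "coherence.tsv", sep="\t", index=False)

    prov = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(_config_dict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_diseases": int(catalog.n_diseases),
        "n_snps": int(catalog.n_snps),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)

    return PipelineResult(
        catalog=catalog, borders_by_k=borders_by_k, membership=membership,
        results=results, majority=majority, comparison=comparison,
        coherence=coh, truth=truth,
    )


def _config_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
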