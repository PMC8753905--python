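"""Hypergeometric TAD-border enrichment tests and group comparisons.

For each disease, the test asks whether its associated SNPs fall in TAD
borders more often than expected when the same number of loci is drawn at
random from a null population.  With ``H(q | N, n, Q)`` the hypergeometric
distribution of the number ``q`` of border hits among ``Q`` draws without
replacement from a population of ``N`` elements of which ``n`` are in
borders, the p-value is the upper tail ``P(X >= q)``.

Two null models:

* genome-based -- ``N`` is the genome size in bp and ``n`` the bp inside
  the border union (every genomic position an equally likely locus);
* SNP-based  -- ``N`` is the number of distinct disease-associated SNPs in
  the catalog (each counted once) and ``n`` those inside borders.

Raw p-values are Benjamini--Hochberg adjusted, by default separately for
cancers and non-cancer diseases and within each (dataset, k,
category-filter, null-model) stratum.  A disease counts as enriched when
the adjusted p-value is <= 0.05 for strictly more than half of the window
sizes k (majority rule).  Cancer vs non-cancer enrichment fractions are
compared with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog import DiseaseCatalog
from .tads import BorderSet

__all__ = [
    "NullModelParams",
    "GroupComparison",
    "hypergeom_upper_tail",
    "make_null_params",
    "test_all_diseases",
    "adjust_pvalues",
    "majority_enriched",
    "enrichment_histogram",
    "fisher_group_comparison",
    "aggregate_over_datasets",
    "significance_stars",
]

ALPHA = 0.05


@dataclass(frozen=True)
class NullModelParams:
    """Population of the hypergeometric null: ``n`` successes out of ``N``."""

    model: str  # "genome_based" | "snp_based"
    N: int
    n: int

    def __post_init__(self) -> None:
        if self.model not in ("genome_based", "snp_based"):
            raise ValueError(f"unknown null model {self.model!r}")
        if self.N <= 0 or not 0 <= self.n <= self.N:
            raise ValueError(f"need 0 <= n <= N and N > 0, got n={self.n}, N={self.N}")


@dataclass
class GroupComparison:
    """2x2 Fisher comparison of enrichment fractions (cancer vs non-cancer)."""

    cancer_enriched: int
    cancer_not: int
    noncancer_enriched: int
    noncancer_not: int
    fisher_p: float
    stars: str
    degenerate: bool = False

    @property
    def table(self) -> list[list[int]]:
        return [
            [self.cancer_enriched, self.cancer_not],
            [self.noncancer_enriched, self.noncancer_not],
        ]


def hypergeom_upper_tail(q: int, N: int, n: int, Q: int) -> float:
    """Upper-tail hypergeometric probability ``P(X >= q)``.

    ``X`` counts successes among ``Q`` draws without replacement from ``N``
    elements of which ``n`` are successes.  Symmetric in ``n`` and ``Q``;
    stable up to genome-scale ``N``.  ``q = 0`` returns exactly 1.
    """
    for name, v in (("q", q), ("N", N), ("n", n), ("Q", Q)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v}")
    q, N, n, Q = int(q), int(N), int(n), int(Q)
    if N <= 0 or not (0 <= n <= N) or not (0 <= Q <= N):
        raise ValueError(f"invalid population: q={q}, N={N}, n={n}, Q={Q}")
    if not 0 <= q <= min(n, Q):
        raise ValueError(f"q={q} outside [0, min(n={n}, Q={Q})]")
    if q == 0:
        return 1.0
    return float(stats.hypergeom.sf(q - 1, N, n, Q))


def make_null_params(
    model: str,
    *,
    border_union_bp: int | None = None,
    genome_bp: int | None = None,
    all_dasnps: int | None = None,
    dasnps_in_borders: int | None = None,
) -> NullModelParams:
    """Assemble (N, n) for one dataset and one k under the chosen null."""
    if model == "genome_based":
        if genome_bp is None or border_union_bp is None:
            raise ValueError("genome_based null needs genome_bp and border_union_bp")
        return NullModelParams(model, N=int(genome_bp), n=int(border_union_bp))
    if model == "snp_based":
        if all_dasnps is None or dasnps_in_borders is None:
            raise ValueError("snp_based null needs all_dasnps and dasnps_in_borders")
        return NullModelParams(model, N=int(all_dasnps), n=int(dasnps_in_borders))
    raise ValueError(f"unknown null model {model!r}")


def test_all_diseases(
    catalog: DiseaseCatalog,
    borders_by_k: dict[int, BorderSet],
    membership: pd.DataFrame,
    null_model: str = "genome_based",
    category_filter: str = "all",
    genome_bp: int | None = None,
    dataset: str = "dataset",
) -> pd.DataFrame:
    """Hypergeometric enrichment test for every (disease, k).

    ``membership`` is the boolean snpId x k table from
    :func:`tadrisk.catalog.snp_border_membership`.  The category filter
    restricts both the disease draw ``Q`` and the hit count ``q`` to SNPs of
    that category; diseases left with ``Q = 0`` are skipped.  Returns one
    row per (disease, k) with columns efoId, isCancer, dataset, k, filter,
    nullModel, q, Q, n, N, p_raw.
    """
    if category_filter not in ("all", "exonic", "intronic", "intergenic"):
        raise ValueError(f"unknown category filter {category_filter!r}")
    snps = catalog.snps
    if category_filter != "all":
        keep_ids = set(snps.loc[snps["category"] == category_filter, "snpId"])
    else:
        keep_ids = set(snps["snpId"])
    assoc = catalog.associations[catalog.associations["snpId"].isin(keep_ids)]
    is_cancer = catalog.diseases.set_index("efoId")["isCancer"]
    rows = []
    for k, borders in sorted(borders_by_k.items()):
        flags = membership[k]
        if null_model == "genome_based":
            if genome_bp is None:
                raise ValueError("genome_bp required for the genome-based null")
            params = make_null_params(
                "genome_based", genome_bp=genome_bp, border_union_bp=borders.union_bp
            )
        else:
            in_border = flags[flags.index.isin(keep_ids)]
            params = make_null_params(
                "snp_based",
                all_dasnps=int(len(in_border)),
                dasnps_in_borders=int(in_border.sum()),
            )
        for efo, grp in assoc.groupby("efoId"):
            ids = grp["snpId"].to_numpy()
            Q = len(ids)
            if Q == 0:
                continue
            q = int(flags.loc[ids].sum())
            p = hypergeom_upper_tail(q, params.N, params.n, Q)
            rows.append(
                {
                    "efoId": efo,
                    "isCancer": bool(is_cancer.loc[efo]),
                    "dataset": dataset,
                    "k": k,
                    "filter": category_filter,
                    "nullModel": null_model,
                    "q": q,
                    "Q": Q,
                    "n": params.n,
                    "N": params.N,
                    "p_raw": p,
                }
            )
    return pd.DataFrame(rows)


def adjust_pvalues(results: pd.DataFrame, scheme: str = "bh_within_group") -> pd.DataFrame:
    """Benjamini--Hochberg adjustment of the raw enrichment p-values.

    ``bh_within_group`` corrects cancers and non-cancer diseases separately
    (they form biologically distinct groups); ``bh_global`` pools them.
    Both operate within each (dataset, k, filter, nullModel) stratum;
    ``none`` passes raw p-values through.
    """
    if results.empty:
        out = results.copy()
        out["p_adj"] = pd.Series(dtype=float)
        return out
    strata = ["dataset", "k", "filter", "nullModel"]
    if scheme == "bh_within_group":
        strata = strata + ["isCancer"]
    elif scheme == "none":
        out = results.copy()
        out["p_adj"] = out["p_raw"]
        return out
    elif scheme != "bh_global":
        raise ValueError(f"unknown adjustment scheme {scheme!r}")
    out = results.copy()
    out["p_adj"] = np.nan
    for _, idx in out.groupby(strata).groups.items():
        p = out.loc[idx, "p_raw"].to_numpy()
        out.loc[idx, "p_adj"] = multipletests(p, method="fdr_bh")[1]
    return out


def majority_enriched(
    results: pd.DataFrame, k_range, alpha: float = ALPHA
) -> pd.Series:
    """Per-disease flag: adjusted p <= alpha for > half of the k values.

    Missing (disease, k) combinations count as not enriched.
    """
    k_range = list(k_range)
    need = len(k_range) / 2
    sub = results[results["k"].isin(k_range)]
    hits = (
        sub.assign(sig=sub["p_adj"] <= alpha)
        .groupby("efoId")["sig"]
        .sum()
    )
    all_efo = results["efoId"].unique()
    return pd.Series(
        {efo: bool(hits.get(efo, 0) > need) for efo in all_efo}, name="majority_enriched"
    )


def enrichment_histogram(
    results: pd.DataFrame,
    truncation: float = 4.0,
    bin_width: float = 0.1,
    normalize_by_group: bool = True,
) -> pd.DataFrame:
    """Histogram of ``-log10(p_adj)`` per group (cancer / non-cancer).

    One entry per (disease, dataset, k) row is pooled; values beyond
    ``truncation`` are kept in a separate tail count instead of the binned
    range.  Returns tidy rows: group, bin_left, bin_right, count, frac,
    plus one ``tail`` row per group.  Normalization (to unit sum including
    the tail) is per group and skipped for empty groups.
    """
    edges = np.arange(0.0, truncation + bin_width / 2, bin_width)
    rows = []
    for is_cancer, grp in results.groupby("isCancer"):
        group = "cancer" if is_cancer else "non_cancer"
        with np.errstate(divide="ignore"):
            v = -np.log10(grp["p_adj"].to_numpy(float))
        tail = int((v > truncation).sum())
        counts, _ = np.histogram(v[v <= truncation], bins=edges)
        total = counts.sum() + tail
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {
                    "group": group,
                    "bin_left": left,
                    "bin_right": right,
                    "count": int(c),
                    "frac": c / total if (normalize_by_group and total) else np.nan,
                }
            )
        rows.append(
            {
                "group": group,
                "bin_left": truncation,
                "bin_right": np.inf,
                "count": tail,
                "frac": tail / total if (normalize_by_group and total) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def fisher_group_comparison(
    cancer_flags: pd.Series | np.ndarray, noncancer_flags: pd.Series | np.ndarray
) -> GroupComparison:
    """Two-sided Fisher exact test on enriched/not x cancer/non-cancer.

    A zero margin makes the table degenerate; p = 1 is reported with the
    ``degenerate`` flag set.
    """
    c = np.asarray(cancer_flags, dtype=bool)
    nc = np.asarray(noncancer_flags, dtype=bool)
    table = np.array(
        [[int(c.sum()), int((~c).sum())], [int(nc.sum()), int((~nc).sum())]]
    )
    degenerate = bool((table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any())
    if degenerate:
        p = 1.0
    else:
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return GroupComparison(
        cancer_enriched=int(table[0, 0]),
        cancer_not=int(table[0, 1]),
        noncancer_enriched=int(table[1, 0]),
        noncancer_not=int(table[1, 1]),
        fisher_p=p,
        stars=significance_stars(p),
        degenerate=degenerate,
    )


def aggregate_over_datasets(comparisons: list[GroupComparison]) -> GroupComparison:
    """Pool the 2x2 counts over datasets (a disease contributes once per
    dataset) and recompute the Fisher test on the summed table."""
    t = np.sum([np.array(c.table) for c in comparisons], axis=0)
    degenerate = bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())
    p = 1.0 if degenerate else float(stats.fisher_exact(t, alternative="two-sided")[1])
    return GroupComparison(
        cancer_enriched=int(t[0, 0]),
        cancer_not=int(t[0, 1]),
        noncancer_enriched=int(t[1, 0]),
        noncancer_not=int(t[1, 1]),
        fisher_p=p,
        stars=significance_stars(p),
        degenerate=degenerate,
    )
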