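"""Disease--SNP association tables: loading, SNP classification, border
membership, and the pairwise-distance audit.

The catalog is a tidy table of (disease, SNP) associations in the style of
the GWAS catalog: each row carries a SNP identifier, its genomic position
(1-based in input files, 0-based internally) and the EFO identifier of the
associated trait.  Diseases are the traits under the EFO disease subtree
(EFO_0000408); cancers are the subset under the cancer subtree
(EFO_0000311).  Ontology traversal itself is upstream of this package: the
loader consumes precomputed EFO id lists.

A SNP associated with a disease in several studies counts once per disease
(duplicates of its snpId are dropped).  Two distinct SNPs falling in the
same border still count as two units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GeneModel
from .tads import BorderSet

__all__ = [
    "DiseaseCatalog",
    "load_gwas_catalog",
    "catalog_from_dataframe",
    "classify_positions",
    "classify_snps",
    "snp_border_membership",
    "majority_border_snp_set",
    "pairwise_close_counts",
]

CATEGORIES = ("exonic", "intronic", "intergenic")

DEFAULT_COLUMN_MAP = {
    "snpId": "snpId",
    "chrom": "chrom",
    "pos": "pos",
    "efoId": "efoId",
    "diseaseLabel": "diseaseLabel",
}


@dataclass
class DiseaseCatalog:
    """Normalized association catalog.

    ``associations``: one row per distinct (efoId, snpId) pair.
    ``snps``: one row per distinct snpId with 0-based position and category.
    ``diseases``: one row per efoId with label and cancer flag.
    """

    associations: pd.DataFrame  # efoId, snpId
    snps: pd.DataFrame  # snpId, chrom, pos0, category
    diseases: pd.DataFrame  # efoId, diseaseLabel, isCancer
    dropped_missing_coords: int = 0
    dropped_malformed: int = 0

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_ids(self, efo_id: str) -> set[str]:
        sel = self.associations["efoId"] == efo_id
        return set(self.associations.loc[sel, "snpId"])

    def category_fractions(self) -> pd.Series:
        return self.snps["category"].value_counts(normalize=True)


def catalog_from_dataframe(df: pd.DataFrame) -> DiseaseCatalog:
    """Build a catalog from a tidy table with columns
    snpId, chrom, pos (1-based), efoId, diseaseLabel, isCancer[, category]."""
    df = df.copy()
    if "category" not in df:
        df["category"] = "intergenic"
    assoc = df[["efoId", "snpId"]].drop_duplicates().reset_index(drop=True)
    snps = (
        df[["snpId", "chrom", "pos", "category"]]
        .drop_duplicates("snpId")
        .assign(pos0=lambda d: d["pos"].astype(np.int64) - 1)
        .drop(columns="pos")
        .reset_index(drop=True)
    )
    diseases = (
        df[["efoId", "diseaseLabel", "isCancer"]]
        .drop_duplicates("efoId")
        .reset_index(drop=True)
    )
    return DiseaseCatalog(associations=assoc, snps=snps, diseases=diseases)


def load_gwas_catalog(
    path,
    efo_disease_ids: set[str],
    efo_cancer_ids: set[str],
    column_map: dict[str, str] | None = None,
    sep: str = "\t",
) -> DiseaseCatalog:
    """Load an association table and restrict it to disease EFO terms.

    ``efo_disease_ids`` / ``efo_cancer_ids`` are the precomputed id sets of
    the EFO disease and cancer subtrees; traits outside the disease subtree
    (e.g., non-pathological traits) are excluded.  Rows with missing or
    non-numeric coordinates, or unknown chromosome names starting without
    'chr', are dropped and counted, not fatal.

    Raises
    ------
    ValueError
        If no disease survives the filters.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [v for v in cmap.values() if v not in raw.columns and v != cmap["diseaseLabel"]]
    if missing:
        raise ValueError(f"catalog is missing columns: {missing}")
    df = pd.DataFrame(
        {
            "snpId": raw[cmap["snpId"]],
            "chrom": raw[cmap["chrom"]],
            "pos": raw[cmap["pos"]],
            "efoId": raw[cmap["efoId"]],
            "diseaseLabel": raw.get(cmap["diseaseLabel"], raw[cmap["efoId"]]),
        }
    )
    n0 = len(df)
    df = df.dropna(subset=["snpId", "chrom", "pos", "efoId"])
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df = df.dropna(subset=["pos"])
    dropped_coords = n0 - len(df)
    df = df[df["efoId"].isin(efo_disease_ids)]
    if df.empty:
        raise ValueError("no disease-associated rows after EFO filtering")
    df["isCancer"] = df["efoId"].isin(efo_cancer_ids)
    df["pos"] = df["pos"].astype(np.int64)
    cat = catalog_from_dataframe(df)
    cat.dropped_missing_coords = dropped_coords
    return cat


# ---------------------------------------------------------------------------
# SNP classification


def _containment(chroms: np.ndarray, pos0: np.ndarray, table: pd.DataFrame) -> np.ndarray:
    """Boolean: position inside any half-open interval of ``table``."""
    hit = np.zeros(len(pos0), dtype=bool)
    for chrom, sub in table.groupby("chrom"):
        starts = np.sort(sub["start"].to_numpy(np.int64))
        ends = sub.sort_values("start")["end"].to_numpy(np.int64)
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        idx = np.searchsorted(starts, pos0[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[sel][ok] < ends[idx[ok]]
        hit[sel] = ok
    return hit


def classify_positions(chroms: np.ndarray, pos0: np.ndarray, gene_model: GeneModel) -> np.ndarray:
    """Category per position: exonic > intronic > intergenic precedence."""
    chroms = np.asarray(chroms)
    pos0 = np.asarray(pos0, dtype=np.int64)
    out = np.full(len(pos0), "intergenic", dtype=object)
    if len(gene_model.genes):
        in_gene = _containment(chroms, pos0, gene_model.genes)
        out[in_gene] = "intronic"
    if len(gene_model.exons):
        in_exon = _containment(chroms, pos0, gene_model.exons)
        out[in_exon] = "exonic"
    return out


def classify_snps(catalog: DiseaseCatalog, gene_model: GeneModel) -> DiseaseCatalog:
    """Assign exonic / intronic / intergenic categories to every SNP in place."""
    catalog.snps["category"] = classify_positions(
        catalog.snps["chrom"].to_numpy(),
        catalog.snps["pos0"].to_numpy(),
        gene_model,
    )
    return catalog


# ---------------------------------------------------------------------------
# Border membership


def _in_union(chroms: np.ndarray, pos0: np.ndarray, union: dict[str, np.ndarray]) -> np.ndarray:
    hit = np.zeros(len(pos0), dtype=bool)
    for chrom, iv in union.items():
        if iv.shape[0] == 0:
            continue
        sel = np.flatnonzero(chroms == chrom)
        if sel.size == 0:
            continue
        idx = np.searchsorted(iv[:, 0], pos0[sel], side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos0[sel][ok] < iv[idx[ok], 1]
        hit[sel] = ok
    return hit


def snp_border_membership(
    catalog: DiseaseCatalog, borders_by_k: dict[int, BorderSet]
) -> pd.DataFrame:
    """In-border flag per SNP and window size, for one dataset.

    Returns a boolean DataFrame indexed by snpId with one column per k.  A
    SNP on a chromosome absent from the border set counts as not-in-border.
    Membership uses the half-open convention: a SNP at the border's end
    coordinate is outside.
    """
    chroms = catalog.snps["chrom"].to_numpy()
    pos0 = catalog.snps["pos0"].to_numpy(np.int64)
    data = {
        k: _in_union(chroms, pos0, borders.union)
        for k, borders in sorted(borders_by_k.items())
    }
    return pd.DataFrame(data, index=catalog.snps["snpId"].to_numpy())


def majority_border_snp_set(membership: pd.DataFrame,
                            k_range=None) -> set[str]:
    """SNPs in a border for strictly more than half of the window sizes."""
    cols = list(k_range) if k_range is not None else list(membership.columns)
    counts = membership[cols].sum(axis=1)
    return set(membership.index[counts > len(cols) / 2])


# ---------------------------------------------------------------------------
# Pairwise-distance audit


def pairwise_close_counts(catalog: DiseaseCatalog, thresholds,
                          efo_ids=None) -> pd.DataFrame:
    """Per disease, the number of same-chromosome SNP pairs closer than each
    threshold (bp).  Counts are non-decreasing in the threshold."""
    thresholds = sorted(int(t) for t in thresholds)
    snp_pos = catalog.snps.set_index("snpId")[["chrom", "pos0"]]
    efo_ids = efo_ids if efo_ids is not None else catalog.diseases["efoId"]
    rows = []
    for efo in efo_ids:
        ids = sorted(catalog.snp_ids(efo))
        sub = snp_pos.loc[ids]
        counts = dict.fromkeys(thresholds, 0)
        for _, grp in sub.groupby("chrom"):
            p = np.sort(grp["pos0"].to_numpy(np.int64))
            for t in thresholds:
                hi = np.searchsorted(p, p + t, side="left")
                counts[t] += int((hi - np.arange(len(p)) - 1).sum())
        rows.append({"efoId": efo, **{f"lt_{t}": counts[t] for t in thresholds}})
    return pd.DataFrame(rows)
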