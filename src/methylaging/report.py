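"""Reporting surfaces for significant age-associated positions (aDMPs).

Summaries mirror how longitudinal methylation findings are usually
tabulated: per-interval differences of per-time-point means (subjects
pooled per time point, so the three interval columns are additive by
construction), direction tallies over the end-point interval, CpG-island /
gene annotation from BED intervals, hierarchical clustering orders for
heatmaps, and a ranked gene list for external enrichment tools.

A packaged reference table of 26 direct-effect aDMPs from a childhood
whole-blood cohort (ages 2/10/16) ships with the module as a worked
example and test fixture.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .methmatrix import MethMatrix

__all__ = ["load_admp_reference", "interval_mean_differences",
           "direction_and_summary", "annotate_features", "cluster_order",
           "export_gene_list"]


def load_admp_reference() -> pd.DataFrame:
    """The packaged 26-row direct-effect aDMP reference table."""
    with resources.files("methylaging.data") \
            .joinpath("admp_direct_effect_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def interval_mean_differences(m: MethMatrix, site_idx=None) -> pd.DataFrame:
    """Differences of per-time-point mean methylation for each CpG.

    Means pool all subjects observed at a time point (not paired), and all
    interval columns are computed from the same per-time-point means, so
    first->last equals the sum of the consecutive differences exactly.
    Time points are ordered by age.
    """
    if site_idx is None:
        site_idx = np.arange(m.n_sites)
    site_idx = np.asarray(site_idx)
    order = (m.samples[["timepoint", "age"]].drop_duplicates()
             .sort_values("age"))
    tps = order["timepoint"].tolist()
    beta = m.beta[site_idx]
    means = {}
    for tp in tps:
        cols = m.samples.index[m.samples["timepoint"] == tp].to_numpy()
        block = beta[:, cols]
        with np.errstate(invalid="ignore"):
            means[tp] = np.nanmean(block, axis=1)
    out = pd.DataFrame({
        "chrom": m.sites["chrom"].to_numpy()[site_idx],
        "pos": m.sites["pos"].to_numpy()[site_idx]})
    for tp in tps:
        out[f"mean_{tp}"] = means[tp]
    for a, b in zip(tps, tps[1:]):
        out[f"diff_{a}_{b}"] = means[b] - means[a]
    out[f"diff_{tps[0]}_{tps[-1]}"] = means[tps[-1]] - means[tps[0]]
    return out


def direction_and_summary(records: pd.DataFrame,
                          endpoint_col: str | None = None) -> dict:
    """Direction tallies and per-interval summaries of an aDMP table.

    ``records`` must carry interval difference columns named diff_*; the
    end-point column (defaulting to the last diff_* column) sets the
    direction.  Percentages are reported to one decimal.  If an ``in_cgi``
    column is present, a CGI x direction cross-tabulation is included.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    diff_cols = [c for c in records.columns if c.startswith("diff_")]
    if not diff_cols:
        raise ValueError("records lack diff_* columns")
    endpoint = endpoint_col or diff_cols[-1]
    sign = np.sign(records[endpoint].to_numpy(dtype=float))
    n = len(records)
    n_inc = int((sign > 0).sum())
    n_dec = int((sign < 0).sum())
    out = {
        "n": n,
        "n_increasing": n_inc,
        "n_decreasing": n_dec,
        "pct_increasing": round(100.0 * n_inc / n, 1),
        "pct_decreasing": round(100.0 * n_dec / n, 1),
        "intervals": {},
    }
    for col in diff_cols:
        vals = records[col].astype(float)
        out["intervals"][col] = {
            "median": float(vals.median()),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    if "in_cgi" in records.columns:
        direction = np.where(sign > 0, "increase",
                             np.where(sign < 0, "decrease", "flat"))
        out["cgi_by_direction"] = pd.crosstab(
            records["in_cgi"], pd.Series(direction, index=records.index,
                                         name="direction"))
    return out


def _read_bed(path) -> pd.DataFrame:
    """BED (0-based, half-open): chrom, start, end[, name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    if df.shape[1] >= 4:
        df = df.iloc[:, :4].copy()
        df.columns = ["chrom", "start", "end", "name"]
    else:
        df = df.iloc[:, :3].copy()
        df.columns = ["chrom", "start", "end"]
        df["name"] = "."
    for col, i in (("start", 1), ("end", 2)):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 1
            raise ValueError(f"{path}: malformed BED line {line}")
        df[col] = vals.astype(int)
    if (df["end"] <= df["start"]).any():
        line = int(df.index[df["end"] <= df["start"]][0]) + 1
        raise ValueError(f"{path}: empty/negative interval at line {line}")
    return df


def _trees(bed: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    # sort so that ties resolve to the first interval in sort order
    bed = bed.sort_values(["chrom", "start", "end", "name"], kind="stable")
    for chrom, grp in bed.groupby("chrom", sort=False):
        trees[chrom] = IntervalTree.from_tuples(
            (s, e, nm) for s, e, nm in
            zip(grp["start"], grp["end"], grp["name"]))
    return trees


def annotate_features(sites: pd.DataFrame, cgi_bed=None,
                      gene_bed=None) -> pd.DataFrame:
    """Per-CpG in-CGI flag and gene label from BED interval files.

    Sites carry 1-based positions; BED intervals are 0-based half-open, so
    a site at 1-based position p overlaps [start, end) iff
    start < p <= end.  On overlapping gene intervals the first by
    (start, end, name) sort order wins.
    """
    out = sites[["chrom", "pos"]].copy()
    if cgi_bed is not None:
        trees = _trees(_read_bed(cgi_bed))
        out["in_cgi"] = [
            bool(trees[c][p - 1]) if c in trees else False
            for c, p in zip(out["chrom"], out["pos"])]
    if gene_bed is not None:
        trees = _trees(_read_bed(gene_bed))

        def label(c, p):
            if c not in trees:
                return None
            hits = trees[c][p - 1]
            if not hits:
                return None
            best = min(hits, key=lambda iv: (iv.begin, iv.end, iv.data))
            return best.data

        out["gene"] = [label(c, p)
                       for c, p in zip(out["chrom"], out["pos"])]
    return out


def cluster_order(m: MethMatrix, site_idx=None, metric: str = "euclidean",
                  method: str = "average") -> dict:
    """Hierarchical clustering orders for an aDMP heatmap.

    Remaining missing values are mean-imputed per CpG for the distance
    computation only.  Returns leaf orders and linkage matrices for both
    samples and CpGs; deterministic for a given matrix.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples to cluster")
    if site_idx is None:
        site_idx = np.arange(m.n_sites)
    beta = m.beta[np.asarray(site_idx)]
    if np.isnan(beta).all(axis=1).any() or np.isnan(beta).all(axis=0).any():
        raise ValueError("fully missing row or column in the aDMP matrix")
    row_means = np.nanmean(beta, axis=1)
    filled = np.where(np.isnan(beta), row_means[:, None], beta)
    sample_link = hierarchy.linkage(pdist(filled.T, metric=metric),
                                    method=method)
    cpg_link = hierarchy.linkage(pdist(filled, metric=metric),
                                 method=method)
    return {
        "sample_order": hierarchy.leaves_list(sample_link),
        "cpg_order": hierarchy.leaves_list(cpg_link),
        "sample_linkage": sample_link,
        "cpg_linkage": cpg_link,
    }


def export_gene_list(results: pd.DataFrame, fdr_cutoff: float = 0.25,
                     q_col: str = "q", gene_col: str = "gene"
                     ) -> tuple[pd.DataFrame, list[str]]:
    """Ranked unique gene list at a liberal FDR cutoff, plus background.

    Genes of CpGs with q <= cutoff, each listed once with its best q and
    ranked by it; the background is every annotated gene in the results.
    """
    ann = results.dropna(subset=[gene_col])
    ann = ann[ann[gene_col] != "."]
    background = sorted(ann[gene_col].unique())
    hits = ann[ann[q_col] <= fdr_cutoff]
    ranked = (hits.groupby(gene_col, sort=False)[q_col].min()
              .sort_values(kind="stable").reset_index()
              .rename(columns={q_col: "best_q"}))
    return ranked, background
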