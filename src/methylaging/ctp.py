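"""Cell-type proportions and the PC1 composition mediator.

Whole blood is a mixture of five leukocyte types whose shares shift with
age, so cell-type composition can mediate apparent age effects on blood
methylation.  This module turns raw differential cell counts into imputed
proportions (complement rule first, then stratum means) and summarizes the
five proportions into a single mediator score: the first principal
component, which in childhood cohorts is essentially the
lymphocyte-vs-neutrophil axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CTPMatrix", "PC1Summary", "counts_to_proportions_imputed",
           "compute_pc1"]

KEYS = ["subject", "timepoint"]


@dataclass
class CTPMatrix:
    """Imputed cell-type proportions (rows sum to 1) with provenance.

    proportions : DataFrame keyed by (subject, timepoint) with one column
        per cell type plus any passthrough columns (e.g. age).
    provenance : same shape over the cell-type columns, entries in
        {"observed", "complement", "stratum_mean"}.
    """

    proportions: pd.DataFrame
    provenance: pd.DataFrame
    celltypes: tuple[str, ...]

    def values(self) -> np.ndarray:
        return self.proportions[list(self.celltypes)].to_numpy(dtype=float)


def _full_row_scale(df: pd.DataFrame, cts: list[str]) -> pd.Series:
    """Per-row divisor turning raw entries into proportions.

    Complete rows are divided by their own sum (the usual counts->CTP
    normalization).  Incomplete rows lack their true total, so they are
    divided by the mean complete-row sum in the same time point (falling
    back to the overall mean) — exact whenever entries share a common scale
    such as percent-of-leukocytes differentials.
    """
    vals = df[cts]
    rowsum = vals.sum(axis=1, skipna=False)
    complete = rowsum.notna()
    if complete.any():
        by_tp = rowsum[complete].groupby(df.loc[complete, "timepoint"]).mean()
        fallback = float(rowsum[complete].mean())
    else:
        raise ValueError("no complete cell-count rows to set the scale")
    scale = df["timepoint"].map(by_tp).fillna(fallback)
    return rowsum.where(complete, scale)


def counts_to_proportions_imputed(
    counts: pd.DataFrame,
    complement_celltype: str = "lymphocytes",
    complement_timepoint: str | None = None,
    celltypes: tuple[str, ...] | None = None,
) -> CTPMatrix:
    """Convert differential cell counts to imputed proportions.

    Imputation order: (1) at ``complement_timepoint`` the missing
    ``complement_celltype`` is set to 1 minus the sum of the other four
    proportions; (2) any remaining missing entry is replaced by the mean of
    its (cell type, time point) stratum; rows touched by stratum-mean
    imputation are renormalized to sum to 1 (logged).

    Raises if a stratum is entirely missing, if the complement rule would
    need more than one missing cell type in a row, or if it produces a
    value outside [0, 1].
    """
    df = counts.reset_index(drop=True).copy()
    if celltypes is None:
        reserved = set(KEYS) | {"age", "group", "sample_id"}
        celltypes = tuple(c for c in df.columns if c not in reserved)
    cts = list(celltypes)
    if complement_celltype not in cts:
        raise ValueError(f"unknown cell type {complement_celltype!r}")
    if df.duplicated(subset=KEYS).any():
        raise ValueError("duplicate (subject, timepoint) rows")
    if (df[cts] < 0).any().any():
        raise ValueError("negative cell counts")
    if complement_timepoint is None:
        # default to the earliest time point by age if available
        if "age" in df.columns:
            complement_timepoint = df.loc[df["age"].idxmin(), "timepoint"]
        else:
            complement_timepoint = sorted(df["timepoint"].unique())[0]

    scale = _full_row_scale(df, cts)
    props = df[cts].div(scale, axis=0)
    prov = pd.DataFrame("observed", index=df.index, columns=cts)
    prov = prov.mask(props.isna(), "missing")

    # (1) complement rule at the designated time point
    at_tp = df["timepoint"] == complement_timepoint
    need = at_tp & props[complement_celltype].isna()
    others = [c for c in cts if c != complement_celltype]
    bad = need & props[others].isna().any(axis=1)
    if bad.any():
        rows = df.loc[bad, KEYS].to_records(index=False).tolist()
        raise ValueError("complement rule needs the other four cell types; "
                         f"rows also missing others: {rows}")
    comp = 1.0 - props.loc[need, others].sum(axis=1)
    out_of_range = (comp < 0) | (comp > 1)
    if out_of_range.any():
        rows = df.loc[comp.index[out_of_range], KEYS] \
            .to_records(index=False).tolist()
        raise ValueError(f"complement imputation outside [0, 1] for {rows}")
    props.loc[need, complement_celltype] = comp
    prov.loc[need, complement_celltype] = "complement"

    # (2) stratum (cell type x time point) mean imputation
    still = props.isna()
    if still.any().any():
        for ct in cts:
            col_missing = still[ct]
            if not col_missing.any():
                continue
            for tp in df.loc[col_missing, "timepoint"].unique():
                sel = col_missing & (df["timepoint"] == tp)
                obs = props[ct][(df["timepoint"] == tp) & ~still[ct]]
                if obs.empty:
                    raise ValueError(
                        f"stratum ({ct!r}, {tp!r}) entirely missing")
                props.loc[sel, ct] = obs.mean()
                prov.loc[sel, ct] = "stratum_mean"

    # renormalize only rows whose sum drifted (stratum-mean imputed rows)
    sums = props.sum(axis=1)
    off = (sums - 1.0).abs() > 1e-9
    if off.any():
        logger.info("renormalizing %d rows after stratum-mean imputation",
                    int(off.sum()))
        props.loc[off] = props.loc[off].div(sums[off], axis=0)
    if ((props < -1e-12) | (props > 1 + 1e-12)).any().any():
        raise ValueError("imputed proportions outside [0, 1]")

    result = df[[c for c in df.columns if c not in cts]].copy()
    for ct in cts:
        result[ct] = np.clip(props[ct], 0.0, 1.0)
    prov.insert(0, "timepoint", df["timepoint"])
    prov.insert(0, "subject", df["subject"])
    return CTPMatrix(proportions=result, provenance=prov,
                     celltypes=tuple(cts))


@dataclass
class PC1Summary:
    """First principal component of the proportion matrix.

    scores are per-sample (mean 0 when centered); loadings are the
    eigenvector entries per cell type; representation is |corr(proportion
    column, score)| — the share of each cell type's variation captured by
    the axis; the sign is fixed so the neutrophil loading is positive.
    """

    scores: pd.Series
    loadings: pd.Series
    representation: pd.Series
    explained_variance_fraction: float
    sign_reference: str


def compute_pc1(ctps: CTPMatrix, center: bool = True, scale: bool = False,
                sign_celltype: str = "neutrophils") -> PC1Summary:
    """PC1 of the cell-type proportion matrix as the mediator score.

    Centering only by default (all columns already share the proportion
    scale); unit-variance scaling is available by flag.
    """
    X = ctps.values()
    if np.isnan(X).any():
        raise ValueError("proportions contain missing values; impute first")
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} rows, got {n}")
    mu = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mu
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("zero-variance column; cannot scale")
        Xc = Xc / sd
    if not np.any(Xc):
        raise ValueError("zero-variance proportion matrix")
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    v = vt[0]
    if sign_celltype in ctps.celltypes:
        k = ctps.celltypes.index(sign_celltype)
        if v[k] < 0:
            v = -v
    scores = Xc @ v
    var = s ** 2
    rep = np.zeros(p)
    for j in range(p):
        col = X[:, j]
        if col.std() > 0 and scores.std() > 0:
            rep[j] = abs(np.corrcoef(col, scores)[0, 1])
    index = ctps.proportions.set_index(KEYS).index
    return PC1Summary(
        scores=pd.Series(scores, index=index, name="pc1"),
        loadings=pd.Series(v, index=list(ctps.celltypes), name="loading"),
        representation=pd.Series(rep, index=list(ctps.celltypes),
                                 name="representation"),
        explained_variance_fraction=float(var[0] / var.sum()),
        sign_reference=sign_celltype,
    )
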