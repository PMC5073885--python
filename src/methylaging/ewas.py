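"""Per-CpG total-effect testing of age on methylation.

The total effect (TE) of age at each CpG is the fixed age slope of a linear
mixed model with a per-subject random intercept,

    beta_ij = b0 + b_age * age_ij + u_i + eps_ij,

fitted by maximum likelihood so that unbalanced/missing longitudinal
observations are handled naturally.  P-values come from a likelihood-ratio
test of the age term by default (a Wald option is exposed), and q-values
are Benjamini-Hochberg across all tested CpGs.  Per-interval paired t-tests
complement the longitudinal model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, fit_random_intercept
from .methmatrix import MethMatrix, filter_pairwise, paired_differences

__all__ = ["TEResult", "fit_te_model", "run_te_ewas", "bh_adjust",
           "pairwise_test"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


class TEResult(pd.DataFrame):
    """Thin marker: per-CpG TE table (slope, se, p, q, n_subjects, flag)."""

    @property
    def _constructor(self):
        return TEResult


def fit_te_model(y, age, subject, pvalue_method: str = "lrt",
                 time_categorical: bool = False) -> dict:
    """Age slope, standard error, p-value and convergence flag for one CpG.

    ``pvalue_method`` is "lrt" (likelihood ratio under ML, default) or
    "wald".  ``time_categorical`` tests time as an unordered factor (LRT
    with k-1 df); the slope reported is then the numeric-age slope from the
    same data for direction only.
    """
    y = np.asarray(y, dtype=float)
    age = np.asarray(age, dtype=float)
    subject = np.asarray(subject)
    ok = ~np.isnan(y)
    y, age, subject = y[ok], age[ok], subject[ok]
    n_subj = len(np.unique(subject))
    out = {"slope": np.nan, "se": np.nan, "p": np.nan,
           "n_subjects": n_subj, "converged": False}
    if y.size < 3 or n_subj < 2:
        return out
    if np.ptp(y) < 1e-14:
        out.update(slope=0.0, se=0.0, p=1.0, converged=True)
        return out
    X = np.c_[np.ones_like(age), age]
    full = fit_random_intercept(y, X, subject)
    if not np.isfinite(full.loglik):
        return out
    out.update(slope=float(full.beta[1]), se=float(full.se[1]),
               converged=full.converged)
    if time_categorical:
        levels = np.unique(age)
        D = np.c_[np.ones_like(age)] if levels.size < 2 else np.column_stack(
            [np.ones_like(age)] + [(age == a).astype(float)
                                   for a in levels[1:]])
        fac = fit_random_intercept(y, D, subject)
        null = fit_random_intercept(y, X[:, :1], subject)
        lr = max(2.0 * (fac.loglik - null.loglik), 0.0)
        out["p"] = float(stats.chi2.sf(lr, df=max(levels.size - 1, 1)))
        out["converged"] = fac.converged and null.converged
        return out
    if pvalue_method == "wald":
        if full.se[1] > 0:
            z = full.beta[1] / full.se[1]
            out["p"] = float(2.0 * stats.norm.sf(abs(z)))
    elif pvalue_method == "lrt":
        null = fit_random_intercept(y, X[:, :1], subject)
        if np.isfinite(null.loglik):
            lr = max(2.0 * (full.loglik - null.loglik), 0.0)
            out["p"] = float(stats.chi2.sf(lr, df=1))
            out["converged"] = full.converged and null.converged
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    return out


def run_te_ewas(m: MethMatrix, alpha_fdr: float = 0.05,
                pvalue_method: str = "lrt",
                min_subjects: int = 10) -> TEResult:
    """Total-effect scan over every CpG in the (already filtered) matrix.

    Returns one row per CpG with BH q-values across all CpGs that produced
    a p-value; non-convergent or under-observed CpGs are flagged and
    excluded from the adjustment.  ``significant`` marks q <= alpha_fdr.
    """
    beta = m.beta
    age = m.samples["age"].to_numpy(dtype=float)
    subject = m.samples["subject"].to_numpy()
    rows = []
    for i in range(m.n_sites):
        y = beta[i]
        n_subj = len(np.unique(subject[~np.isnan(y)]))
        if n_subj < min_subjects:
            rows.append({"slope": np.nan, "se": np.nan, "p": np.nan,
                         "n_subjects": n_subj, "converged": False})
            continue
        rows.append(fit_te_model(y, age, subject,
                                 pvalue_method=pvalue_method))
    res = pd.DataFrame(rows)
    res.insert(0, "chrom", m.sites["chrom"].to_numpy())
    res.insert(1, "pos", m.sites["pos"].to_numpy())
    res["p"] = np.where(res["converged"], res["p"], np.nan)
    res["q"] = bh_adjust(res["p"])
    res["significant"] = res["q"] <= alpha_fdr
    return TEResult(res)


def pairwise_test(m: MethMatrix, timepoint_a: str, timepoint_b: str,
                  min_pairs: int = 10, alpha_fdr: float = 0.05
                  ) -> pd.DataFrame:
    """Paired t-tests of within-subject differences for one age interval.

    Only CpGs with >= min_pairs complete pairs and positive difference
    variance are tested; q-values are BH across the tested set.
    """
    idx = filter_pairwise(m, timepoint_a, timepoint_b, min_pairs=min_pairs)
    diffs = paired_differences(m, timepoint_a, timepoint_b).to_numpy()[idx]
    mean_diff = np.nanmean(diffs, axis=1) if len(idx) else np.array([])
    pvals = np.empty(len(idx))
    npairs = np.empty(len(idx), dtype=int)
    for k, row in enumerate(diffs):
        d = row[~np.isnan(row)]
        npairs[k] = d.size
        pvals[k] = stats.ttest_1samp(d, 0.0).pvalue
    out = pd.DataFrame({
        "chrom": m.sites["chrom"].to_numpy()[idx],
        "pos": m.sites["pos"].to_numpy()[idx],
        "interval": f"{timepoint_a}->{timepoint_b}",
        "mean_diff": mean_diff, "p": pvals, "n_pairs": npairs})
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else pd.Series(
        dtype=float)
    out["significant"] = out["q"] <= alpha_fdr
    return out
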