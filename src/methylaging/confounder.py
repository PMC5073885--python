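"""Subgroup representativeness by exhaustive subset resampling.

Tests whether a designated subgroup (e.g. the disease-free controls) is
representative of the whole cohort at each significant CpG and time point.
The statistic is mean(subgroup) - mean(all subjects); its exact null
distribution under exchangeability is obtained by enumerating every
k-of-n subject subset (75,582 subsets for 8 of 19) — or, beyond a cap, by
seeded uniform subset sampling — and the observed difference is called
extreme when its two-sided empirical tail probability is at most alpha,
with ties counted as extreme (conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .methmatrix import MethMatrix

logger = logging.getLogger(__name__)

__all__ = ["SubsetNull", "subgroup_mean_diff", "subset_null_distribution",
           "representativeness_positive_rate"]


def subgroup_mean_diff(values, subgroup_mask) -> float:
    """mean(subgroup) - mean(all), dropping missing subjects from both."""
    v = np.asarray(values, dtype=float)
    mask = np.asarray(subgroup_mask, dtype=bool)
    if v.shape != mask.shape:
        raise ValueError("values and subgroup mask differ in length")
    ok = ~np.isnan(v)
    if (mask & ok).sum() == 0:
        raise ValueError("empty subgroup after dropping missing values")
    return float(v[mask & ok].mean() - v[ok].mean())


@dataclass
class SubsetNull:
    """Empirical null of subgroup-vs-whole mean differences.

    mode is "exhaustive" (all C(n, k) subsets) or "sampled"; ``diffs`` is
    the sorted multiset of null differences.
    """

    n: int
    k: int
    diffs: np.ndarray
    mode: str
    n_subsets: int
    seed: int | None = None

    def pvalue(self, observed: float) -> float:
        """Two-sided empirical p, ties counted as extreme."""
        lo = np.sum(self.diffs <= observed) / self.n_subsets
        hi = np.sum(self.diffs >= observed) / self.n_subsets
        return float(min(1.0, 2.0 * min(lo, hi)))


def _subset_index_matrix(n: int, k: int) -> np.ndarray:
    return np.fromiter(
        (i for c in combinations(range(n), k) for i in c),
        dtype=np.intp).reshape(-1, k)


_INDEX_CACHE: dict[tuple[int, int], np.ndarray] = {}


def subset_null_distribution(values, k: int, cap: int = 10 ** 6,
                             n_sampled: int = 10 ** 5,
                             seed: int | None = 0) -> SubsetNull:
    """Null distribution of mean(subset of size k) - mean(all).

    Exhaustive when C(n, k) <= cap, otherwise ``n_sampled`` seeded uniform
    draws.  Missing values must be removed by the caller.
    """
    v = np.asarray(values, dtype=float)
    if np.isnan(v).any():
        raise ValueError("values contain NaN; drop missing subjects first")
    n = v.size
    if not 0 < k < n:
        raise ValueError(f"need 0 < k < n, got k={k}, n={n}")
    total = comb(n, k)
    grand = v.mean()
    if total <= cap:
        key = (n, k)
        if key not in _INDEX_CACHE:
            _INDEX_CACHE[key] = _subset_index_matrix(n, k)
        idx = _INDEX_CACHE[key]
        diffs = v[idx].mean(axis=1) - grand
        mode, n_subsets, used_seed = "exhaustive", total, None
    else:
        rng = np.random.default_rng(seed)
        idx = np.array([rng.choice(n, size=k, replace=False)
                        for _ in range(n_sampled)])
        diffs = v[idx].mean(axis=1) - grand
        mode, n_subsets, used_seed = "sampled", n_sampled, seed
    return SubsetNull(n=n, k=k, diffs=np.sort(diffs), mode=mode,
                      n_subsets=n_subsets, seed=used_seed)


def representativeness_positive_rate(
    m: MethMatrix, subgroup_subjects, admp_idx, alpha: float = 0.05,
    cap: int = 10 ** 6, n_sampled: int = 10 ** 5, seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of aDMPs with an extreme subgroup difference per time point.

    For each CpG in ``admp_idx`` and each time point, the per-subject mean
    methylation feeds ``subgroup_mean_diff`` and its own subset null; the
    positive rate per time point is the fraction of aDMPs with p <= alpha.
    Under exchangeability of the subgroup this rate is ~alpha.
    Returns (per-site table, per-time-point summary).
    """
    admp_idx = np.asarray(admp_idx)
    if admp_idx.size == 0:
        raise ValueError("empty aDMP set")
    subgroup = set(subgroup_subjects)
    subjects = list(pd.unique(m.samples["subject"]))
    unknown = subgroup - set(subjects)
    if unknown:
        raise ValueError(f"unknown subjects in subgroup: {sorted(unknown)}")
    mask_all = np.array([s in subgroup for s in subjects])
    beta = m.beta
    timepoints = list(pd.unique(m.samples["timepoint"]))
    records = []
    for tp in timepoints:
        tp_beta = np.full((m.n_sites, len(subjects)), np.nan)
        sel = m.samples.index[m.samples["timepoint"] == tp]
        for j in sel:
            kk = subjects.index(m.samples.loc[j, "subject"])
            tp_beta[:, kk] = beta[:, j]
        for i in admp_idx:
            v = tp_beta[i]
            ok = ~np.isnan(v)
            k_eff = int((mask_all & ok).sum())
            n_eff = int(ok.sum())
            if k_eff == 0 or k_eff == n_eff:
                continue
            obs = subgroup_mean_diff(v, mask_all)
            null = subset_null_distribution(
                v[ok], k_eff, cap=cap, n_sampled=n_sampled, seed=seed)
            p = null.pvalue(obs)
            if n_eff < len(subjects):
                logger.debug("CpG %d tp %s: effective n %d of %d",
                             i, tp, n_eff, len(subjects))
            records.append({
                "site_idx": int(i),
                "chrom": m.sites["chrom"].iloc[i],
                "pos": int(m.sites["pos"].iloc[i]),
                "timepoint": tp, "observed_diff": obs, "p": p,
                "extreme": p <= alpha, "n_subjects": n_eff,
                "k_subgroup": k_eff, "mode": null.mode})
    per_site = pd.DataFrame(records)
    summary = (per_site.groupby("timepoint", sort=False)
               .agg(n_admps=("extreme", "size"),
                    n_extreme=("extreme", "sum"),
                    positive_rate=("extreme", "mean"))
               .reset_index())
    return per_site, summary
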