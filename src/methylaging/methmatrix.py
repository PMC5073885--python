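"""CpG x sample methylation matrices from bisulfite coverage files.

Reads the common coverage dialect (chrom, 1-based position, position,
methylation %, methylated count, unmethylated count; tab-separated, no
header), aligns samples on the union of sites, and applies the standard
filters for a longitudinal RRBS analysis: minimum read depth, autosomes
only, a minimum number of subjects observed at every time point, paired
completeness for interval tests, PCA-based sample QC, and the bisulfite
conversion-rate estimate.

Counts are never altered by a filter — filters only change which cells are
*usable*, so audits can always recover the raw data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MethMatrix",
    "read_coverage",
    "write_coverage",
    "apply_depth_filter",
    "filter_longitudinal",
    "filter_pairwise",
    "pca_outlier_qc",
    "bisulfite_conversion_rate",
    "is_autosome",
]

_COV_COLUMNS = ["chrom", "start", "end", "meth_pct", "count_meth",
                "count_unmeth"]
_AUTOSOME_NAMES = {str(i) for i in range(1, 23)}


def is_autosome(chrom: str) -> bool:
    """chr1..chr22, tolerant of a missing/present 'chr' prefix."""
    name = str(chrom)
    if name.lower().startswith("chr"):
        name = name[3:]
    return name in _AUTOSOME_NAMES


@dataclass
class MethMatrix:
    """Aligned methylated/total read counts with sample metadata.

    sites : DataFrame with columns chrom, pos (1-based), indexed 0..n-1.
    samples : DataFrame with columns sample_id, subject, timepoint, age,
        group, aligned with the columns of the count arrays.
    meth / total : float arrays (n_sites, n_samples), NaN where a site was
        not covered in a sample.
    usable : boolean mask of cells that pass the filters applied so far.
    min_depth : the depth threshold currently reflected in ``usable``.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    meth: np.ndarray
    total: np.ndarray
    usable: np.ndarray
    min_depth: int = 1

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def beta(self) -> np.ndarray:
        """Methylation fractions; NaN wherever the cell is not usable."""
        with np.errstate(invalid="ignore", divide="ignore"):
            b = self.meth / self.total
        return np.where(self.usable, b, np.nan)

    def site_ids(self) -> pd.Index:
        return pd.Index(self.sites["chrom"].astype(str) + ":"
                        + self.sites["pos"].astype(str))

    def subset_sites(self, idx) -> "MethMatrix":
        idx = np.asarray(idx)
        return replace(self,
                       sites=self.sites.iloc[idx].reset_index(drop=True),
                       meth=self.meth[idx], total=self.total[idx],
                       usable=self.usable[idx])

    def subset_samples(self, idx) -> "MethMatrix":
        idx = np.asarray(idx)
        return replace(self,
                       samples=self.samples.iloc[idx].reset_index(drop=True),
                       meth=self.meth[:, idx], total=self.total[:, idx],
                       usable=self.usable[:, idx])


def _read_one(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS,
                         dtype={"chrom": str})
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty coverage file, all sites missing")
        return pd.DataFrame(columns=_COV_COLUMNS)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed coverage file: {exc}") from exc
    if df.empty:
        warnings.warn(f"{path}: empty coverage file, all sites missing")
        return df
    for col in ("start", "count_meth", "count_unmeth"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 1
            raise ValueError(f"{path}: malformed line {line}: "
                             f"non-numeric {col!r}")
        df[col] = vals.astype(int)
    if (df["start"] < 1).any():
        line = int(df.index[df["start"] < 1][0]) + 1
        raise ValueError(f"{path}: malformed line {line}: position < 1")
    if (df[["count_meth", "count_unmeth"]] < 0).to_numpy().any():
        raise ValueError(f"{path}: negative read counts")
    dup = df.duplicated(subset=["chrom", "start"])
    if dup.any():
        line = int(df.index[dup][0]) + 1
        raise ValueError(f"{path}: duplicate site at line {line}")
    return df


def read_coverage(paths: dict[str, str | Path],
                  sample_sheet: pd.DataFrame | str | Path) -> MethMatrix:
    """Load per-sample coverage files aligned on the union of CpG sites.

    ``paths`` maps sample_id -> coverage file; the sample sheet (DataFrame
    or CSV path) must contain sample_id, subject, timepoint, age, group.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = pd.read_csv(sample_sheet)
    required = {"sample_id", "subject", "timepoint", "age", "group"}
    missing_cols = required - set(sample_sheet.columns)
    if missing_cols:
        raise ValueError(f"sample sheet lacks columns: {sorted(missing_cols)}")
    samples = sample_sheet.reset_index(drop=True).copy()
    missing_files = [s for s in samples["sample_id"] if s not in paths]
    if missing_files:
        raise ValueError(f"no coverage file for samples: {missing_files}")

    per_sample: dict[str, pd.DataFrame] = {}
    for sid in samples["sample_id"]:
        df = _read_one(Path(paths[sid]))
        df = df.set_index(["chrom", "start"])
        per_sample[sid] = df

    all_sites: set[tuple[str, int]] = set()
    for df in per_sample.values():
        all_sites.update(df.index)
    site_df = pd.DataFrame(sorted(all_sites), columns=["chrom", "pos"])
    union = pd.MultiIndex.from_frame(
        site_df.rename(columns={"pos": "start"})) if len(site_df) else None

    n, s = len(site_df), len(samples)
    meth = np.full((n, s), np.nan)
    total = np.full((n, s), np.nan)
    for j, sid in enumerate(samples["sample_id"]):
        df = per_sample[sid]
        if df.empty:
            continue
        aligned = df.reindex(union)
        meth[:, j] = aligned["count_meth"].to_numpy(dtype=float)
        total[:, j] = (aligned["count_meth"]
                       + aligned["count_unmeth"]).to_numpy(dtype=float)
    usable = ~np.isnan(total)
    return MethMatrix(sites=site_df, samples=samples, meth=meth, total=total,
                      usable=usable, min_depth=1)


def write_coverage(m: MethMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write one coverage file per sample (inverse of read_coverage)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    for j, sid in enumerate(m.samples["sample_id"]):
        obs = ~np.isnan(m.total[:, j])
        mm = m.meth[obs, j].astype(int)
        tt = m.total[obs, j].astype(int)
        with np.errstate(invalid="ignore"):
            pct = np.where(tt > 0, 100.0 * mm / np.maximum(tt, 1), 0.0)
        df = pd.DataFrame({
            "chrom": m.sites["chrom"].to_numpy()[obs],
            "start": m.sites["pos"].to_numpy()[obs],
            "end": m.sites["pos"].to_numpy()[obs],
            "meth_pct": np.round(pct, 6),
            "count_meth": mm, "count_unmeth": tt - mm})
        path = outdir / f"{sid}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        out[sid] = path
    return out


def apply_depth_filter(m: MethMatrix, min_depth: int = 10) -> MethMatrix:
    """Mark cells with fewer than ``min_depth`` total reads as unusable."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    with np.errstate(invalid="ignore"):
        usable = m.usable & (m.total >= min_depth)
    return replace(m, usable=usable, min_depth=min_depth)


def _complete_by_subject(m: MethMatrix) -> tuple[np.ndarray, list[str]]:
    """(n_sites, n_subjects) bool: subject usable at every time point."""
    timepoints = list(pd.unique(m.samples["timepoint"]))
    subjects = list(pd.unique(m.samples["subject"]))
    complete = np.ones((m.n_sites, len(subjects)), dtype=bool)
    for tp in timepoints:
        present = np.zeros((m.n_sites, len(subjects)), dtype=bool)
        sel = m.samples.index[m.samples["timepoint"] == tp]
        for j in sel:
            k = subjects.index(m.samples.loc[j, "subject"])
            present[:, k] |= m.usable[:, j]
        complete &= present
    return complete, subjects


def filter_longitudinal(m: MethMatrix, min_subjects: int = 10,
                        autosomes_only: bool = True) -> MethMatrix:
    """Keep CpGs usable at every time point in >= min_subjects subjects.

    Optionally drops non-autosomal sites first.
    """
    keep = np.ones(m.n_sites, dtype=bool)
    if autosomes_only:
        keep &= m.sites["chrom"].map(is_autosome).to_numpy()
    complete, _ = _complete_by_subject(m)
    keep &= complete.sum(axis=1) >= min_subjects
    logger.info("longitudinal filter: %d of %d CpGs kept",
                int(keep.sum()), m.n_sites)
    return m.subset_sites(np.flatnonzero(keep))


def paired_differences(m: MethMatrix, timepoint_a: str, timepoint_b: str
                       ) -> pd.DataFrame:
    """Per-subject beta differences (b - a); NaN where either is missing."""
    beta = m.beta
    subjects = list(pd.unique(m.samples["subject"]))
    a = np.full((m.n_sites, len(subjects)), np.nan)
    b = np.full((m.n_sites, len(subjects)), np.nan)
    for tp, target in ((timepoint_a, a), (timepoint_b, b)):
        sel = m.samples.index[m.samples["timepoint"] == tp]
        for j in sel:
            k = subjects.index(m.samples.loc[j, "subject"])
            target[:, k] = beta[:, j]
    return pd.DataFrame(b - a, columns=subjects)


def filter_pairwise(m: MethMatrix, timepoint_a: str, timepoint_b: str,
                    min_pairs: int = 10) -> np.ndarray:
    """Indices of CpGs with >= min_pairs complete pairs and some variation.

    'Some variation' means strictly positive variance of the within-subject
    paired differences.
    """
    for tp in (timepoint_a, timepoint_b):
        if tp not in set(m.samples["timepoint"]):
            raise ValueError(f"unknown time point {tp!r}")
    diffs = paired_differences(m, timepoint_a, timepoint_b).to_numpy()
    n_pairs = np.sum(~np.isnan(diffs), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var = np.nanvar(diffs, axis=1)
    keep = (n_pairs >= min_pairs) & (var > 0)
    return np.flatnonzero(keep)


def pca_outlier_qc(m: MethMatrix, n_components: int = 2,
                   threshold_sd: float = 3.0) -> pd.DataFrame:
    """Flag samples with extreme scores on the leading principal components.

    The decomposition uses only CpGs usable in every sample.  Returns one
    row per sample with its component scores and an ``outlier`` flag; the
    caller decides whether to exclude flagged samples.
    """
    if m.n_samples < 4:
        raise ValueError("need at least 4 samples for PCA QC")
    beta = m.beta
    complete = ~np.isnan(beta).any(axis=1)
    if not complete.any():
        raise ValueError("no CpGs observed in every sample")
    data = beta[complete].T  # samples x CpGs
    data = data - data.mean(axis=0)
    n_components = min(n_components, m.n_samples - 1, data.shape[1])
    u, s_vals, _ = np.linalg.svd(data, full_matrices=False)
    scores = u[:, :n_components] * s_vals[:n_components]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    z = np.abs(scores - scores.mean(axis=0)) / sd
    flagged = (z > threshold_sd).any(axis=1)
    out = m.samples[["sample_id"]].copy()
    for k in range(n_components):
        out[f"pc{k + 1}"] = scores[:, k]
    out["outlier"] = flagged
    logger.info("PCA QC: %d of %d samples flagged at %.1f SD",
                int(flagged.sum()), m.n_samples, threshold_sd)
    return out


def bisulfite_conversion_rate(non_cpg_counts: pd.DataFrame) -> pd.Series:
    """Per-sample conversion rate from non-CpG cytosine counts.

    Expects columns ``converted`` and ``unconverted`` indexed by sample;
    rate = converted / (converted + unconverted), NaN (with a warning) for
    samples with no informative cytosines.
    """
    conv = non_cpg_counts["converted"].astype(float)
    unconv = non_cpg_counts["unconverted"].astype(float)
    total = conv + unconv
    if (total == 0).any():
        warnings.warn("samples with zero non-CpG cytosines: "
                      f"{list(non_cpg_counts.index[total == 0])}")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = conv / total
    rate[total == 0] = np.nan
    return rate
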