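"""Synthetic longitudinal whole-blood methylation cohorts.

Whole-blood methylation at a CpG is modelled as a proportion-weighted mixture
of five leukocyte methylomes (lymphocytes, neutrophils, monocytes,
eosinophils, basophils).  Age can move blood-level methylation through two
routes that the downstream pipeline must disentangle:

* a *direct* route — the CpG's methylation changes within every cell type at
  a common rate (fraction per year), and
* a *mediated* route — within-cell-type methylation is constant, but cell
  types with different baselines change their share of whole blood with age
  (lymphocytes fall, neutrophils rise through childhood), dragging the blood
  average along.

Each simulated CpG belongs to one of four classes: ``null`` (neither route),
``direct``, ``mediated``, or ``mixed`` (both, exercising partial mediation).
Read counts are binomial at a negative-binomial depth, observations drop out
completely at random, and the per-CpG ground truth is emitted alongside the
dataset so every pipeline stage can be tested against known effects.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CELLTYPES",
    "DEFAULT_CTP_AGE_PROFILE",
    "SimConfig",
    "SimulatedDataset",
    "simulate_ctps",
    "simulate_cell_methylomes",
    "mix_whole_blood",
    "sample_reads",
    "generate_dataset",
]

CELLTYPES = ("lymphocytes", "neutrophils", "monocytes", "eosinophils",
             "basophils")

#: Mean cell-type proportions at ages 2/10/16: lymphocytes decline and
#: neutrophils rise through childhood, the two together averaging ~89 % of
#: leukocytes, with minor monocyte/eosinophil/basophil fractions.
DEFAULT_CTP_AGE_PROFILE = {
    2.0: (0.55, 0.33, 0.07, 0.04, 0.01),
    10.0: (0.42, 0.47, 0.06, 0.04, 0.01),
    16.0: (0.35, 0.55, 0.06, 0.03, 0.01),
}

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


@dataclass
class SimConfig:
    """Generator settings; defaults emulate a 19-subject ages-2/10/16 cohort.

    direct_slope_range is the |slope| band (fraction/year) for direct-class
    CpGs; mediated_spread_range is the lymphocyte-vs-neutrophil baseline
    methylation gap for mediated-class CpGs.  ctp_concentration is the total
    Dirichlet concentration for per-sample proportions (inf = no variation).
    """

    n_subjects: int = 19
    ages: tuple[float, ...] = (2.0, 10.0, 16.0)
    n_cpgs: int = 2000
    cpg_class_fractions: dict[str, float] = field(
        default_factory=lambda: {"null": 0.85, "direct": 0.05,
                                 "mediated": 0.07, "mixed": 0.03})
    direct_slope_range: tuple[float, float] = (0.005, 0.02)
    celltype_names: tuple[str, ...] = CELLTYPES
    ctp_age_profile: dict[float, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CTP_AGE_PROFILE))
    ctp_concentration: float = 200.0
    mediated_spread_range: tuple[float, float] = (0.2, 0.5)
    subject_sd: float = 0.02
    depth_mean: float = 30.0
    depth_shape: float = 8.0
    depth_min: int = 1
    missing_rate_sample: float = 0.1
    missing_rate_celltype_count: float = 0.05
    lymphocyte_missing_youngest: bool = True
    n_controls: int = 8
    baseline_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        self.ages = tuple(float(a) for a in self.ages)
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("ages must be strictly increasing")
        if abs(sum(self.cpg_class_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("cpg_class_fractions must sum to 1")
        if len(self.celltype_names) != 5:
            raise ValueError("exactly five cell types are modelled")
        for age in self.ages:
            if age not in self.ctp_age_profile:
                raise ValueError(f"ctp_age_profile missing age {age}")
            prof = self.ctp_age_profile[age]
            if len(prof) != len(self.celltype_names):
                raise ValueError("profile length != number of cell types")
            if abs(sum(prof) - 1.0) > 1e-9:
                raise ValueError(f"profile means at age {age} must sum to 1")
        if self.ctp_concentration <= 0:
            raise ValueError("ctp_concentration must be positive")
        for rate in (self.missing_rate_sample,
                     self.missing_rate_celltype_count):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("missing rates must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "ages" in raw:
            raw["ages"] = tuple(float(a) for a in raw["ages"])
        if "ctp_age_profile" in raw:
            raw["ctp_age_profile"] = {
                float(k): tuple(v) for k, v in raw["ctp_age_profile"].items()}
        for key in ("direct_slope_range", "mediated_spread_range",
                    "baseline_range", "celltype_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["ages"] = list(self.ages)
        d["ctp_age_profile"] = {float(k): list(v)
                                for k, v in self.ctp_age_profile.items()}
        for key in ("direct_slope_range", "mediated_spread_range",
                    "baseline_range", "celltype_names"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    """Independent child generators so each stage is reproducible alone."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(n)]


def _sample_id(subject: int, age: float) -> str:
    a = int(age) if float(age).is_integer() else age
    return f"s{subject:02d}_y{a}"


def sample_sheet(config: SimConfig) -> pd.DataFrame:
    """One row per (subject, age); first n_controls subjects are controls."""
    rows = []
    for s in range(1, config.n_subjects + 1):
        group = "control" if s <= config.n_controls else "case"
        for age in config.ages:
            rows.append({"sample_id": _sample_id(s, age),
                         "subject": f"s{s:02d}",
                         "timepoint": f"y{int(age)}",
                         "age": age, "group": group})
    return pd.DataFrame(rows)


def _true_proportions(config: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Dirichlet draws around the age profile, one row per (subject, age)."""
    rows = []
    for s in range(1, config.n_subjects + 1):
        for age in config.ages:
            mean = np.asarray(config.ctp_age_profile[age], dtype=float)
            if np.isinf(config.ctp_concentration):
                props = mean.copy()
            else:
                props = rng.dirichlet(mean * config.ctp_concentration)
            rows.append([f"s{s:02d}", f"y{int(age)}", age, *props])
    return pd.DataFrame(
        rows, columns=["subject", "timepoint", "age", *config.celltype_names])


def simulate_ctps(config: SimConfig,
                  rng: np.random.Generator | None = None,
                  return_truth: bool = False):
    """Differential cell counts (percent of leukocytes) with missingness.

    Counts are reported to one decimal, as clinical differentials are.  When
    ``lymphocyte_missing_youngest`` is set, every lymphocyte entry at the
    youngest age is blanked (that column of the differential is simply not
    recorded then), and random blanking applies only at the later ages so the
    complement-imputation rule stays well-posed.
    """
    if rng is None:
        rng = _rngs(config, 5)[0]
    truth = _true_proportions(config, rng)
    counts = truth.copy()
    pct = np.round(truth[list(config.celltype_names)].to_numpy() * 100.0, 1)
    counts[list(config.celltype_names)] = pct

    youngest = config.ages[0]
    older = counts["age"] > youngest
    if config.missing_rate_celltype_count > 0:
        mask = rng.random((counts.shape[0], 5)) \
            < config.missing_rate_celltype_count
        mask[~older.to_numpy(), :] = False
        vals = counts[list(config.celltype_names)].to_numpy()
        vals[mask] = np.nan
        counts[list(config.celltype_names)] = vals
    if config.lymphocyte_missing_youngest:
        counts.loc[~older, config.celltype_names[0]] = np.nan
    if return_truth:
        return counts, truth
    return counts


def simulate_cell_methylomes(config: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> pd.DataFrame:
    """Per-CpG ground truth: class, cell-type baselines and age slopes.

    Baselines are intermediate (uniform on ``baseline_range``) — the regime
    where age-associated blood methylation changes are observed and where
    binomial read noise is well-behaved.  Slopes are clipped so methylation
    stays inside [0.02, 0.98] over the age span.
    """
    if rng is None:
        rng = _rngs(config, 5)[1]
    n = config.n_cpgs
    classes = list(config.cpg_class_fractions)
    fracs = np.array([config.cpg_class_fractions[c] for c in classes])
    counts = np.floor(fracs * n).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(fracs * n - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    lo, hi = config.baseline_range
    span = config.ages[-1] - config.ages[0]
    base = np.zeros((n, 5))
    slope = np.zeros((n, 5))
    common = rng.uniform(lo, hi, n)
    base[:] = common[:, None]

    spread_cls = np.isin(labels, ("mediated", "mixed"))
    delta = rng.uniform(*config.mediated_spread_range, n) \
        * rng.choice([-1.0, 1.0], n)
    delta[~spread_cls] = 0.0
    # split the gap between lymphocytes (+d/2) and neutrophils (-d/2),
    # keeping both inside [0.02, 0.98]
    half = delta / 2.0
    shift = np.clip(common + np.abs(half), None, 0.98) - np.abs(half)
    shift = np.maximum(shift, 0.02 + np.abs(half))
    center = np.where(spread_cls, shift, common)
    base[:, 0] = center + half
    base[:, 1] = center - half
    base[:, 2:] = center[:, None]

    slope_cls = np.isin(labels, ("direct", "mixed"))
    mag = rng.uniform(*config.direct_slope_range, n)
    sign = rng.choice([-1.0, 1.0], n)
    s = mag * sign
    # clip so every cell type stays in [0.02, 0.98] across the age span
    room_up = (0.98 - base.max(axis=1)) / span
    room_dn = (base.min(axis=1) - 0.02) / span
    s = np.clip(s, -room_dn, room_up)
    s[~slope_cls] = 0.0
    slope[:] = s[:, None]

    chrom = np.array(_AUTOSOMES)[np.arange(n) % len(_AUTOSOMES)]
    pos = 10_000 + (np.arange(n) // len(_AUTOSOMES)) * 1_000 \
        + rng.integers(0, 500, n)
    truth = pd.DataFrame({"cpg_id": [f"cpg{i:06d}" for i in range(n)],
                          "chrom": chrom, "pos": pos, "cpg_class": labels,
                          "direct_slope": np.where(slope_cls, s, 0.0)})
    for j, ct in enumerate(config.celltype_names):
        truth[f"baseline_{ct}"] = base[:, j]
    for j, ct in enumerate(config.celltype_names):
        truth[f"slope_{ct}"] = slope[:, j]
    return truth


def mix_whole_blood(proportions, cell_betas, atol: float = 1e-6) -> float:
    """Whole-blood methylation as the proportion-weighted cell-type mixture.

    Implements sum_c p_c * beta_c; e.g. a 0.50 methylation change in a cell
    type occupying 5 % of blood moves the blood level by 0.5 * 0.05 = 0.025.
    """
    p = np.asarray(proportions, dtype=float)
    b = np.asarray(cell_betas, dtype=float)
    if p.shape[-1] != b.shape[-1]:
        raise ValueError("proportions and betas differ in length")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > atol):
        raise ValueError("proportions must sum to 1")
    if np.any((b < 0) | (b > 1)):
        raise ValueError("cell-type methylation must lie in [0, 1]")
    out = (p * b).sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def sample_reads(expected_beta, depth_mean: float = 30.0,
                 depth_shape: float = 8.0, depth_min: int = 1,
                 rng: np.random.Generator | None = None):
    """Draw (methylated, total) read counts at the expected methylation.

    Total depth is negative binomial (mean ``depth_mean``, shape
    ``depth_shape``) floored at ``depth_min``; methylated reads are binomial.
    """
    if rng is None:
        rng = np.random.default_rng()
    beta = np.asarray(expected_beta, dtype=float)
    if np.any((beta < 0) | (beta > 1)):
        raise ValueError("expected_beta must lie in [0, 1]")
    p = depth_shape / (depth_shape + depth_mean)
    total = rng.negative_binomial(depth_shape, p, size=beta.shape)
    total = np.maximum(total, depth_min)
    meth = rng.binomial(total, beta)
    return meth, total


def expected_blood_beta(config: SimConfig, truth: pd.DataFrame,
                        true_ctps: pd.DataFrame,
                        subject_effects: np.ndarray) -> pd.DataFrame:
    """Noise-free blood methylation per CpG x sample (before read sampling)."""
    cts = list(config.celltype_names)
    base = truth[[f"baseline_{c}" for c in cts]].to_numpy()
    slope = truth[[f"slope_{c}" for c in cts]].to_numpy()
    out = np.empty((len(truth), len(true_ctps)))
    subj_codes = pd.Categorical(
        true_ctps["subject"],
        categories=sorted(true_ctps["subject"].unique())).codes
    for j, (_, row) in enumerate(true_ctps.iterrows()):
        dt = row["age"] - config.ages[0]
        cell_beta = np.clip(base + slope * dt, 0.0, 1.0)
        p = row[cts].to_numpy(dtype=float)
        out[:, j] = cell_beta @ p + subject_effects[:, subj_codes[j]]
    cols = [_sample_id(int(s[1:]), a)
            for s, a in zip(true_ctps["subject"], true_ctps["age"])]
    return pd.DataFrame(np.clip(out, 0.0, 1.0), columns=cols,
                        index=truth["cpg_id"])


@dataclass
class SimulatedDataset:
    """File paths of one generated dataset."""

    outdir: Path
    coverage_files: dict[str, Path]
    sample_sheet: Path
    cell_counts: Path
    truth_table: Path
    true_ctps: Path


def generate_dataset(config: SimConfig, outdir: str | Path
                     ) -> SimulatedDataset:
    """Write a complete synthetic dataset in the pipeline's input formats.

    Emits one bisulfite coverage file per sample (chrom, start, end,
    methylation %, methylated count, unmethylated count), a sample sheet and
    a cell-count CSV, plus the ground-truth tables.  Bit-identical under the
    same config/seed.
    """
    outdir = Path(outdir)
    (outdir / "coverage").mkdir(parents=True, exist_ok=True)
    rng_ctp, rng_meth, rng_subj, rng_reads, rng_miss = _rngs(config, 5)

    sheet = sample_sheet(config)
    counts, true_ctps = simulate_ctps(config, rng_ctp, return_truth=True)
    truth = simulate_cell_methylomes(config, rng_meth)
    subject_effects = rng_subj.normal(
        0.0, config.subject_sd, (config.n_cpgs, config.n_subjects))
    betas = expected_blood_beta(config, truth, true_ctps, subject_effects)

    meth, total = sample_reads(
        betas.to_numpy(), config.depth_mean, config.depth_shape,
        config.depth_min, rng_reads)
    observed = rng_miss.random(meth.shape) >= config.missing_rate_sample

    cov_files: dict[str, Path] = {}
    chrom = truth["chrom"].to_numpy()
    pos = truth["pos"].to_numpy()
    for j, sid in enumerate(betas.columns):
        keep = observed[:, j]
        m, t = meth[keep, j], total[keep, j]
        df = pd.DataFrame({
            "chrom": chrom[keep], "start": pos[keep], "end": pos[keep],
            "meth_pct": np.round(100.0 * m / t, 6),
            "count_meth": m, "count_unmeth": t - m})
        path = outdir / "coverage" / f"{sid}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        cov_files[sid] = path

    sheet_path = outdir / "sample_sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    counts_path = outdir / "cell_counts.csv"
    counts.to_csv(counts_path, index=False)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    tctp_path = outdir / "true_ctps.csv"
    true_ctps.to_csv(tctp_path, index=False)
    config.to_yaml(outdir / "sim_config.yaml")
    return SimulatedDataset(outdir, cov_files, sheet_path, counts_path,
                            truth_path, tctp_path)
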