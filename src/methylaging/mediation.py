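"""Causal mediation of the age effect through cell-type composition.

For each CpG the total effect of age on blood methylation is decomposed
into a direct effect (DE, age acting within cell types) and an indirect
effect (IE, age shifting the cell-type mix, summarized by the PC1 score M)
using the linear product-of-coefficients identity:

    mediator model:  M   = a0 + alpha * age          (+ subject intercept)
    outcome model:   Y   = b0 + b_DE * age + b_M * M (+ subject intercept)

    DE = b_DE * (a - a*),   IE = alpha * b_M * (a - a*),   TE = DE + IE,
    proportion mediated = IE / TE,

for an age contrast a* -> a (default 2 -> 16 years).  Uncertainty is
quasi-Bayesian: coefficients are drawn from their asymptotic normal
distributions (jointly within each model, independently across models),
effects are recomputed per draw, and two-sided p-values / percentile CIs
are read off the draws.  No exposure-mediator interaction is modelled, so
the average direct and mediated effects coincide with DE and IE above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ewas import bh_adjust
from .lmm import fit_random_intercept
from .methmatrix import MethMatrix

__all__ = ["AgeContrast", "MediationCoefficients", "fit_mediation_models",
           "decompose_effects", "quasi_bayesian_inference",
           "run_mediation_ewas", "classify_prop_mediated"]

#: |TE| below this (fraction scale) leaves the proportion mediated undefined
TE_EPS = 1e-8


@dataclass(frozen=True)
class AgeContrast:
    """Control and treated ages (years) for reporting effects."""

    control: float = 2.0
    treated: float = 16.0

    def __post_init__(self):
        if self.treated <= self.control:
            raise ValueError("treated age must exceed control age")

    @property
    def delta(self) -> float:
        return self.treated - self.control


@dataclass
class MediationCoefficients:
    """Fitted coefficients of the mediator and outcome models.

    alpha : age slope of the mediator model, with variance var_alpha.
    beta_de / beta_m : age and mediator coefficients of the outcome model,
        with their 2x2 covariance block cov_outcome.
    """

    alpha: float
    var_alpha: float
    beta_de: float
    beta_m: float
    cov_outcome: np.ndarray
    converged: bool


def fit_mediator_model(mediator, age, subject,
                       random_intercept: bool = True):
    """ML fit of M ~ age (optionally with a subject random intercept)."""
    mediator = np.asarray(mediator, dtype=float)
    age = np.asarray(age, dtype=float)
    X = np.c_[np.ones_like(age), age]
    if random_intercept:
        fit = fit_random_intercept(mediator, X, np.asarray(subject))
        return float(fit.beta[1]), float(fit.cov_beta[1, 1]), fit.converged
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ mediator)
    resid = mediator - X @ beta
    s2 = float(resid @ resid) / (len(mediator) - 2)
    return float(beta[1]), float(s2 * XtX_inv[1, 1]), True


def fit_mediation_models(y, mediator, age, subject,
                         random_intercept: bool = True
                         ) -> MediationCoefficients:
    """Fit both mediation models on the rows where y is observed.

    The mediator must be available for every used sample.  Returns flagged
    (non-converged) coefficients rather than raising on degenerate data.
    """
    y = np.asarray(y, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    age = np.asarray(age, dtype=float)
    subject = np.asarray(subject)
    ok = ~np.isnan(y)
    if np.isnan(mediator[ok]).any():
        raise ValueError("mediator missing for samples with methylation")
    y, mediator, age, subject = y[ok], mediator[ok], age[ok], subject[ok]
    alpha, var_alpha, conv_m = fit_mediator_model(
        mediator, age, subject, random_intercept)
    X = np.c_[np.ones_like(age), age, mediator]
    if random_intercept:
        fit = fit_random_intercept(y, X, subject)
        beta_de, beta_m = float(fit.beta[1]), float(fit.beta[2])
        cov = fit.cov_beta[1:, 1:].copy()
        conv_y = fit.converged and np.isfinite(fit.loglik)
    else:
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ (X.T @ y)
        resid = y - X @ beta
        s2 = float(resid @ resid) / max(len(y) - 3, 1)
        beta_de, beta_m = float(beta[1]), float(beta[2])
        cov = s2 * XtX_inv[1:, 1:]
        conv_y = True
    return MediationCoefficients(alpha=alpha, var_alpha=var_alpha,
                                 beta_de=beta_de, beta_m=beta_m,
                                 cov_outcome=np.asarray(cov),
                                 converged=conv_m and conv_y)


def decompose_effects(coeffs: MediationCoefficients,
                      contrast: AgeContrast = AgeContrast()) -> dict:
    """Point estimates of DE, IE, TE and the proportion mediated."""
    d = contrast.delta
    de = coeffs.beta_de * d
    ie = coeffs.alpha * coeffs.beta_m * d
    te = de + ie
    prop = ie / te if abs(te) >= TE_EPS else np.nan
    return {"DE": de, "IE": ie, "TE": te, "prop_mediated": prop}


def _empirical_p(draws: np.ndarray) -> float:
    """Two-sided draw-based p with the +1 continuity correction."""
    n = draws.size
    p_pos = (1 + np.sum(draws <= 0)) / (n + 1)
    p_neg = (1 + np.sum(draws >= 0)) / (n + 1)
    return float(min(1.0, 2.0 * min(p_pos, p_neg)))


def quasi_bayesian_inference(coeffs: MediationCoefficients,
                             contrast: AgeContrast = AgeContrast(),
                             n_draws: int = 1000,
                             seed: int | np.random.Generator = 0,
                             ci_level: float = 0.95) -> dict:
    """Draw-based p-values and percentile CIs for DE, IE and TE.

    (beta_de, beta_m) are drawn jointly from the outcome model's normal
    approximation, alpha independently from the mediator model's; effects
    are recomputed per draw.  Fully reproducible under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    cov = np.asarray(coeffs.cov_outcome, dtype=float)
    # guard: symmetrize and allow a zero matrix (degenerate point mass)
    cov = (cov + cov.T) / 2.0
    if not cov.any():
        chol = np.zeros((2, 2))  # degenerate point mass
    else:
        jitter = 1e-15 * np.trace(cov) * np.eye(2)
        try:
            chol = np.linalg.cholesky(cov + jitter)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "outcome covariance not positive-definite") from exc
    z = rng.standard_normal((n_draws, 2))
    bd, bm = (np.array([coeffs.beta_de, coeffs.beta_m]) + z @ chol.T).T
    if coeffs.var_alpha < 0:
        raise ValueError("negative mediator-model variance")
    a = coeffs.alpha + np.sqrt(coeffs.var_alpha) \
        * rng.standard_normal(n_draws)
    d = contrast.delta
    de, ie = bd * d, a * bm * d
    te = de + ie
    lo, hi = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    out = {}
    for name, draws in (("DE", de), ("IE", ie), ("TE", te)):
        out[f"p_{name}"] = _empirical_p(draws)
        out[f"ci_{name}"] = (float(np.percentile(draws, lo)),
                             float(np.percentile(draws, hi)))
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(np.abs(te) >= TE_EPS, ie / te, np.nan)
    prop = prop[~np.isnan(prop)]
    if prop.size:
        out["ci_prop_mediated"] = (float(np.percentile(prop, lo)),
                                   float(np.percentile(prop, hi)))
    else:
        out["ci_prop_mediated"] = (np.nan, np.nan)
    out["n_draws"] = n_draws
    return out


def run_mediation_ewas(m: MethMatrix, pc1: pd.Series,
                       contrast: AgeContrast = AgeContrast(),
                       alpha_fdr: float = 0.05, n_draws: int = 1000,
                       seed: int = 0, min_subjects: int = 10,
                       random_intercept: bool = True) -> pd.DataFrame:
    """Mediation decomposition for every CpG in the matrix.

    ``pc1`` is indexed by (subject, timepoint) (as produced by
    ``compute_pc1``).  The mediator model is fitted once on all samples;
    the outcome model is refitted per CpG on its observed samples.  BH
    adjustment is applied separately to the DE and IE p-value columns
    across all tested CpGs, and ``significant_DE`` marks q_DE <= alpha_fdr.
    """
    key = pd.MultiIndex.from_frame(m.samples[["subject", "timepoint"]])
    mediator = pc1.reindex(key).to_numpy(dtype=float)
    if np.isnan(mediator).any():
        missing = m.samples.loc[np.isnan(mediator), "sample_id"].tolist()
        raise ValueError(f"no PC1 score for samples: {missing}")
    age = m.samples["age"].to_numpy(dtype=float)
    subject = m.samples["subject"].to_numpy()
    alpha_hat, var_alpha, conv_med = fit_mediator_model(
        mediator, age, subject, random_intercept)

    beta = m.beta
    root = np.random.SeedSequence(seed)
    rows = []
    for i in range(m.n_sites):
        y = beta[i]
        ok = ~np.isnan(y)
        rec = {"DE": np.nan, "IE": np.nan, "TE": np.nan,
               "prop_mediated": np.nan, "p_DE": np.nan, "p_IE": np.nan,
               "p_TE": np.nan, "converged": False,
               "n_subjects": len(np.unique(subject[ok]))}
        if rec["n_subjects"] >= min_subjects and np.ptp(y[ok]) > 1e-14:
            X = np.c_[np.ones(ok.sum()), age[ok], mediator[ok]]
            fit = fit_random_intercept(y[ok], X, subject[ok]) \
                if random_intercept else None
            if random_intercept and np.isfinite(fit.loglik):
                coeffs = MediationCoefficients(
                    alpha=alpha_hat, var_alpha=var_alpha,
                    beta_de=float(fit.beta[1]), beta_m=float(fit.beta[2]),
                    cov_outcome=fit.cov_beta[1:, 1:].copy(),
                    converged=conv_med and fit.converged)
            else:
                coeffs = fit_mediation_models(
                    y, mediator, age, subject,
                    random_intercept=random_intercept)
            if coeffs.converged:
                rec.update(decompose_effects(coeffs, contrast))
                rng = np.random.default_rng(root.spawn(1)[0])
                inf = quasi_bayesian_inference(
                    coeffs, contrast, n_draws=n_draws, seed=rng)
                rec.update({k: v for k, v in inf.items()
                            if k.startswith("p_")})
                for nm in ("DE", "IE", "TE"):
                    rec[f"ci_{nm}_lo"], rec[f"ci_{nm}_hi"] = inf[f"ci_{nm}"]
                rec["converged"] = True
        rows.append(rec)
    base_cols = ["DE", "IE", "TE", "prop_mediated", "p_DE", "p_IE",
                 "p_TE", "converged", "n_subjects"]
    res = pd.DataFrame(rows, columns=None if rows else base_cols)
    res.insert(0, "chrom", m.sites["chrom"].to_numpy())
    res.insert(1, "pos", m.sites["pos"].to_numpy())
    for eff in ("DE", "IE"):
        p = np.where(res["converged"], res[f"p_{eff}"], np.nan)
        res[f"q_{eff}"] = bh_adjust(p)
    res["significant_DE"] = res["q_DE"] <= alpha_fdr
    res["mediation_class"] = _class_labels(res["prop_mediated"])
    res["n_draws"] = n_draws
    res["seed"] = seed
    return res


def _class_labels(prop: pd.Series) -> pd.Series:
    lab = pd.Series("undefined", index=prop.index, dtype=object)
    lab[prop < 0] = "inconsistent"
    lab[(prop >= 0) & (prop <= 1)] = "partial"
    lab[prop > 1] = "amplified"
    return lab


def classify_prop_mediated(results: pd.DataFrame) -> pd.DataFrame:
    """Tally proportion-mediated categories with per-class summaries.

    partial: proportion in [0, 1]; inconsistent: < 0 (mediated path opposes
    the total effect); amplified: > 1.  Rows with undefined proportions are
    excluded.  Returns count, mean, min and max per class.
    """
    prop = results["prop_mediated"].dropna()
    labels = _class_labels(prop)
    out = []
    for cls in ("partial", "inconsistent", "amplified"):
        vals = prop[labels == cls]
        out.append({"class": cls, "count": int(vals.size),
                    "mean": float(vals.mean()) if vals.size else np.nan,
                    "min": float(vals.min()) if vals.size else np.nan,
                    "max": float(vals.max()) if vals.size else np.nan})
    return pd.DataFrame(out).set_index("class")
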