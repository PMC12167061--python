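"""Liability-threshold calculus: maximum achievable AUC and best-fit alpha.

Under the liability-threshold model a disease with prevalence K arises when a
standard-normal liability exceeds T = Phi^-1(1-K). With heritability h² on the
liability scale, the Wray approximation gives the ceiling on discrimination by
any genetic predictor:

    AUC_max = Phi( (i - v) h² / sqrt( h² [ (1 - h² i (i - T)) + (1 - h² v (v - T)) ] ) )

where z = phi(T), i = z/K is the mean liability of cases and v = -z/(1-K) the
mean of controls. Substituting h²_G or h²_I for h² yields conditional ceilings
for array-based and imputation-based predictors.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .gwas_tools import auc_with_se

__all__ = [
    "LiabilityModel",
    "liability_params",
    "auc_max",
    "simulate_liability_auc",
    "validate_auc_max",
    "conditional_auc_max",
    "BestFitAlpha",
    "best_fit_alpha",
    "DiseaseConfig",
    "load_disease_configs",
    "CeilingReport",
    "ceiling_report",
]


@dataclass(frozen=True)
class LiabilityModel:
    """Threshold quantities for prevalence K (and optionally h²).

    i_mean/v_mean are the mean liabilities of cases and controls (truncated
    normal means above/below the threshold T).
    """

    K: float
    T: float
    z: float
    i_mean: float
    v_mean: float
    h2: float | None = None


def liability_params(K: float) -> LiabilityModel:
    if not (0 < K < 1):
        raise ValueError("prevalence K must lie in (0, 1)")
    T = norm.ppf(1.0 - K)
    z = norm.pdf(T)
    return LiabilityModel(K=K, T=T, z=z, i_mean=z / K, v_mean=-z / (1.0 - K))


def auc_max(h2: float, K: float) -> float:
    """Maximum achievable AUC for liability heritability h² and prevalence K."""
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must lie in [0, 1]")
    lm = liability_params(K)
    if h2 == 0:
        return 0.5
    T, i, v = lm.T, lm.i_mean, lm.v_mean
    inner = (1.0 - h2 * i * (i - T)) + (1.0 - h2 * v * (v - T))
    denom2 = h2 * inner
    if denom2 <= 0:
        raise FloatingPointError(
            f"degenerate liability variance term ({denom2:.3g}) for h2={h2}, K={K}"
        )
    return float(norm.cdf((i - v) * h2 / np.sqrt(denom2)))


def simulate_liability_auc(
    h2: float,
    K: float,
    n_sim: int,
    rng: np.random.Generator,
) -> float:
    """Empirical AUC of the true genetic liability component vs case status.

    Simulates g ~ N(0, h²), liability = g + N(0, 1-h²), case iff liability > T.
    """
    g = rng.standard_normal(n_sim) * np.sqrt(h2)
    e = rng.standard_normal(n_sim) * np.sqrt(1.0 - h2)
    t = norm.ppf(1.0 - K)
    labels = (g + e > t).astype(np.int8)
    if labels.min() == labels.max():
        raise ValueError("simulation produced a single class; increase n_sim")
    return auc_with_se(g, labels).auc


def validate_auc_max(
    h2_grid,
    K_grid,
    n_sim: int = 500_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Formula-vs-simulation agreement over a (h², K) grid.

    Returns one row per cell with the closed-form value, the empirical AUC of
    the true genetic score, and their absolute difference.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for h2 in np.asarray(h2_grid, dtype=float):
        for K in np.asarray(K_grid, dtype=float):
            if n_sim * K < 50:
                import warnings

                warnings.warn(
                    f"expected cases {n_sim * K:.0f} < 50 for K={K}; empirical AUC unstable"
                )
            formula = auc_max(h2, K)
            if h2 == 0:
                empirical = 0.5
            else:
                empirical = simulate_liability_auc(h2, K, n_sim, rng)
            rows.append((h2, K, formula, empirical, abs(formula - empirical)))
    return pd.DataFrame(
        rows, columns=["h2", "K", "auc_formula", "auc_empirical", "abs_diff"]
    )


def conditional_auc_max(h2_total: float, captured_proportion: float, K: float) -> float:
    """Ceiling when only a proportion of h² is captured by the predictor panel."""
    if not (0 <= captured_proportion <= 1):
        raise ValueError("captured_proportion must lie in [0, 1]")
    return auc_max(h2_total * captured_proportion, K)


# ---------------------------------------------------------------------------
# Best-fit alpha
# ---------------------------------------------------------------------------


@dataclass
class BestFitAlpha:
    alpha: float
    target: float  # median of the GWAS-based heritability estimates
    attained: float  # h2_total * prop_G(alpha) at the solution
    bracket: tuple[float, float]
    attainable: tuple[float, float]  # range of h2_total * prop_G over the bracket
    iterations: int


def _interp_curve(curve: pd.DataFrame, column: str):
    alphas = curve["alpha"].to_numpy(dtype=float)
    vals = curve[column].to_numpy(dtype=float)
    order = np.argsort(alphas)
    alphas, vals = alphas[order], vals[order]

    def f(a: float) -> float:
        return float(np.interp(a, alphas, vals))

    return f, (float(alphas[0]), float(alphas[-1]))


def best_fit_alpha(
    h2_total: float,
    h2_gwas_estimates,
    capture_curve: pd.DataFrame,
    bracket: tuple[float, float] = (-1.5, 0.0),
    tol: float = 1e-4,
) -> BestFitAlpha:
    """Solve h2_total * prop_G(alpha) = median(h2_gwas_estimates) by bisection.

    ``capture_curve`` is a tabulated (alpha, prop_G) frame, consumed through
    monotone linear interpolation; prop_G is increasing in alpha when capture
    qualities rise with MAF, which bisection exploits.
    """
    med = float(np.median(np.asarray(h2_gwas_estimates, dtype=float)))
    prop_g, table_range = _interp_curve(capture_curve, "prop_G")
    lo = max(bracket[0], table_range[0])
    hi = min(bracket[1], table_range[1])
    f_lo = h2_total * prop_g(lo) - med
    f_hi = h2_total * prop_g(hi) - med
    attainable = (h2_total * prop_g(lo), h2_total * prop_g(hi))
    if f_lo == 0:
        return BestFitAlpha(lo, med, med, (lo, hi), attainable, 0)
    if f_hi == 0:
        return BestFitAlpha(hi, med, med, (lo, hi), attainable, 0)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"median GWAS heritability {med:.4g} is outside the attainable range "
            f"[{attainable[0]:.4g}, {attainable[1]:.4g}] over alpha in [{lo}, {hi}]"
        )
    it = 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        f_mid = h2_total * prop_g(mid) - med
        if f_mid == 0:
            lo = hi = mid
            break
        if f_lo * f_mid < 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
        it += 1
        if it > 200:
            raise RuntimeError("bisection failed to converge")
    alpha = 0.5 * (lo + hi)
    return BestFitAlpha(alpha, med, h2_total * prop_g(alpha), bracket, attainable, it)


# ---------------------------------------------------------------------------
# Disease ceiling report
# ---------------------------------------------------------------------------


@dataclass
class DiseaseConfig:
    label: str
    K: float
    h2_twin: float
    h2_gwas: list[float]


@dataclass
class CeilingReport:
    disease: str
    K: float
    h2_twin: float
    h2_gwas_median: float
    alpha_fit: float
    h2_imputed: float
    auc_twin: float
    auc_gwas: float
    auc_imputed: float


def load_disease_configs(path=None) -> list[DiseaseConfig]:
    """Load disease parameters from YAML (packaged defaults if no path).

    The packaged file carries twin-study heritabilities for the six diseases
    and placeholder prevalence / GWAS-heritability values (see the file's
    comments for what is editable).
    """
    if path is None:
        text = (
            importlib.resources.files("prscap").joinpath("data/diseases.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return [
        DiseaseConfig(
            label=d["label"],
            K=float(d["prevalence"]),
            h2_twin=float(d["h2_twin"]),
            h2_gwas=[float(x) for x in d["h2_gwas"]],
        )
        for d in raw["diseases"]
    ]


def ceiling_report(
    configs: list[DiseaseConfig],
    capture_curve: pd.DataFrame,
) -> pd.DataFrame:
    """Three AUC ceilings per disease: twin, GWAS-median, and imputed-panel.

    alpha is fit per disease so the genotyped-panel capture matches the median
    GWAS heritability; the imputed ceiling uses h2_twin * prop_I(alpha_fit).
    """
    prop_i, _ = _interp_curve(capture_curve, "prop_I")
    rows = []
    for cfg in configs:
        fit = best_fit_alpha(cfg.h2_twin, cfg.h2_gwas, capture_curve)
        h2_imp = cfg.h2_twin * prop_i(fit.alpha)
        rows.append(
            CeilingReport(
                disease=cfg.label,
                K=cfg.K,
                h2_twin=cfg.h2_twin,
                h2_gwas_median=fit.target,
                alpha_fit=fit.alpha,
                h2_imputed=h2_imp,
                auc_twin=auc_max(cfg.h2_twin, cfg.K),
                auc_gwas=auc_max(fit.target, cfg.K),
                auc_imputed=auc_max(h2_imp, cfg.K),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
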