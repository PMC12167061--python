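"""GWAS bookkeeping and PRS evaluation: Neff, filters, scoring, AUC, meta-analysis.

Also provides a desk-scale emulation of PRS training in the independent-variant
regime: marginal effect estimates with N(0, 1/N) sampling noise, shrunk by the
infinitesimal posterior-mean factor h²/(h² + M/N), which is what drives the
AUC-vs-sample-size convergence curves toward the liability-threshold ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .effects import EffectProfile

__all__ = [
    "GwasStudy",
    "effective_sample_size",
    "per_variant_neff_filter",
    "PrsWeights",
    "prs_score",
    "AucEstimate",
    "auc_with_se",
    "meta_auc",
    "strata_odds_ratio",
    "simulate_gwas_effects",
    "shrink_weights",
    "convergence_curve",
]


# ---------------------------------------------------------------------------
# Effective sample size
# ---------------------------------------------------------------------------


def effective_sample_size(n_case: int, n_control: int) -> float:
    """Neff = 4 / (1/Ncase + 1/Ncontrols).

    Rescales unbalanced case-control studies to a common unit; a balanced
    study of n cases and n controls has Neff = 2n. Report with
    ``round(effective_sample_size(...))``.
    """
    if n_case <= 0 or n_control <= 0:
        raise ValueError("case and control counts must be positive")
    return 4.0 / (1.0 / n_case + 1.0 / n_control)


@dataclass
class GwasStudy:
    label: str
    n_case: int
    n_control: int
    per_variant_neff: np.ndarray | None = None

    @property
    def n_eff(self) -> float:
        return effective_sample_size(self.n_case, self.n_control)


def per_variant_neff_filter(
    neff_snp: np.ndarray,
    expected_max: float,
    lower: float = 0.5,
    upper: float = 1.1,
) -> np.ndarray:
    """Keep-mask for per-variant effective sample sizes.

    Variants whose Neff falls below 50% or above 110% of the expected maximum
    are flagged for removal (guards against miscalibrated meta-analysed
    coefficients).
    """
    if expected_max <= 0:
        raise ValueError("expected_max must be positive")
    v = np.asarray(neff_snp, dtype=float)
    return (v >= lower * expected_max) & (v <= upper * expected_max)


# ---------------------------------------------------------------------------
# PRS scoring
# ---------------------------------------------------------------------------


@dataclass
class PrsWeights:
    """Per-variant weights with allele orientation relative to the scored panel.

    ``orientation`` is +1 where the weight's coded allele matches the panel's
    and -1 where it is flipped; a flipped variant contributes gamma * (2 - x).
    """

    gamma: np.ndarray
    orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("weights must be finite")
        if self.orientation is None:
            self.orientation = np.ones_like(self.gamma)
        else:
            self.orientation = np.asarray(self.orientation, dtype=float)
            if self.orientation.shape != self.gamma.shape:
                raise ValueError("orientation must align with gamma")
            if not np.all(np.isin(self.orientation, (-1.0, 1.0))):
                raise ValueError("orientation entries must be +1 or -1 (unresolved otherwise)")


def prs_score(weights: PrsWeights, dosage: np.ndarray) -> np.ndarray:
    """PRS = gamma' X per individual, honoring allele orientation.

    ``dosage`` is an (n, M) matrix aligned with the weights; flipped variants
    are scored on 2 - x (equivalently the weight contribution is negated up to
    a constant shift common to all individuals).
    """
    x = np.asarray(dosage, dtype=float)
    if x.ndim != 2 or x.shape[1] != weights.gamma.size:
        raise ValueError("dosage matrix must be (n_individuals, M) aligned with weights")
    flipped = weights.orientation < 0
    x_oriented = x.copy()
    if flipped.any():
        x_oriented[:, flipped] = 2.0 - x_oriented[:, flipped]
    return x_oriented @ weights.gamma


# ---------------------------------------------------------------------------
# AUC with uncertainty, meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class AucEstimate:
    auc: float
    variance: float
    n_case: int
    n_control: int
    group: str = ""

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))


def auc_with_se(scores: np.ndarray, labels: np.ndarray, method: str = "hanley") -> AucEstimate:
    """AUC by the Mann-Whitney rank statistic with midrank tie handling.

    Variance by Hanley-McNeil (default) or DeLong (``method="delong"``).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both cases and controls are required to compute an AUC")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    if method == "hanley":
        a = auc
        q1 = a / (2.0 - a)
        q2 = 2.0 * a * a / (1.0 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
    elif method == "delong":
        # placement values: V10 for cases, V01 for controls
        case_ranks = rankdata(s[y])
        ctrl_ranks = rankdata(s[~y])
        v10 = (ranks[y] - case_ranks) / n0
        v01 = 1.0 - (ranks[~y] - ctrl_ranks) / n1
        var = np.var(v10, ddof=1) / n1 + np.var(v01, ddof=1) / n0
    else:
        raise ValueError("method must be 'hanley' or 'delong'")
    var = max(float(var), np.finfo(float).tiny)
    return AucEstimate(auc=float(auc), variance=var, n_case=n1, n_control=n0)


def meta_auc(estimates: list[AucEstimate]) -> AucEstimate:
    """Inverse-variance meta-analysis: AUC = Σ(AUC_i/σ_i²) / Σ(1/σ_i²)."""
    if len(estimates) == 0:
        raise ValueError("need at least one AUC estimate")
    w = np.array([1.0 / e.variance for e in estimates])
    a = np.array([e.auc for e in estimates])
    combined = float(np.sum(w * a) / np.sum(w))
    var = float(1.0 / np.sum(w))
    return AucEstimate(
        auc=combined,
        variance=var,
        n_case=sum(e.n_case for e in estimates),
        n_control=sum(e.n_control for e in estimates),
        group="combined",
    )


# ---------------------------------------------------------------------------
# Top-strata odds ratios
# ---------------------------------------------------------------------------


def strata_odds_ratio(
    scores: np.ndarray,
    labels: np.ndarray,
    top_fraction: float = 0.05,
    seed: int = 0,
) -> tuple[float, tuple[float, float]]:
    """Odds ratio comparing the top PRS stratum to the remaining population.

    2x2 contingency OR with a Woolf (log-scale normal) 95% CI; ties at the
    cutoff are broken by a seeded random rank so the stratum size is exact.
    """
    if not (0 < top_fraction < 1):
        raise ValueError("top_fraction must lie in (0, 1)")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n = s.size
    k = max(1, int(round(top_fraction * n)))
    rng = np.random.default_rng(seed)
    order = np.lexsort((rng.uniform(size=n), -s))
    top = np.zeros(n, dtype=bool)
    top[order[:k]] = True
    a = int(np.sum(top & y))  # cases in top stratum
    b = int(np.sum(top & ~y))
    c = int(np.sum(~top & y))
    d = int(np.sum(~top & ~y))
    cells = {"cases_top": a, "controls_top": b, "cases_rest": c, "controls_rest": d}
    zeros = [name for name, v in cells.items() if v == 0]
    if zeros:
        raise ZeroDivisionError(f"degenerate 2x2 table; zero cells: {', '.join(zeros)}")
    or_ = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = norm.ppf(0.975)
    ci = (float(or_ * np.exp(-zq * se_log)), float(or_ * np.exp(zq * se_log)))
    return float(or_), ci


# ---------------------------------------------------------------------------
# Simulated GWAS -> shrunk PRS -> convergence curves
# ---------------------------------------------------------------------------


def simulate_gwas_effects(
    effects: EffectProfile,
    n_gwas: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Marginal effect estimates: beta_hat = beta + N(0, 1/N) per variant.

    Valid in the independent-variant regime, where the marginal estimator's
    sampling variance on standardized genotypes is 1/N.
    """
    if n_gwas < 1:
        raise ValueError("n_gwas must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return effects.beta + rng.standard_normal(effects.beta.size) / np.sqrt(n_gwas)


def shrink_weights(
    beta_hat: np.ndarray,
    n_gwas: int,
    m_variants: int,
    h2: float,
) -> PrsWeights:
    """Infinitesimal posterior-mean shrinkage: gamma = beta_hat * h²/(h² + M/N)."""
    if not (0 <= h2 <= 1):
        raise ValueError("h2 must lie in [0, 1]")
    b = 0.0 if h2 == 0 else h2 / (h2 + m_variants / n_gwas)
    return PrsWeights(gamma=np.asarray(beta_hat, dtype=float) * b)


def convergence_curve(
    effects: EffectProfile,
    K: float,
    n_grid,
    n_test: int = 4000,
    reps: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean test-set AUC of the shrunk PRS as a function of GWAS sample size.

    Independent-variant mode: each replicate draws a fresh test cohort of
    standardized genotypes and liability-threshold labels, then scores it with
    weights trained at every N in ``n_grid``. Reusing the cohort across N
    within a replicate removes between-N cohort noise, so monotone convergence
    toward auc_max(h², K) is visible at modest replicate counts.
    """
    n_grid = np.asarray(n_grid, dtype=int)
    if np.any(np.diff(n_grid) <= 0):
        raise ValueError("n_grid must be strictly increasing")
    beta = effects.beta
    m = beta.size
    h2 = effects.h2
    t = norm.ppf(1.0 - K)
    rng = np.random.default_rng(seed)
    aucs = np.empty((reps, n_grid.size))
    for r in range(reps):
        z = rng.standard_normal((n_test, m))
        g = z @ beta
        liab = g + rng.standard_normal(n_test) * np.sqrt(max(0.0, 1.0 - h2))
        labels = (liab > t).astype(np.int8)
        if labels.min() == labels.max():
            raise ValueError("test cohort contains a single class; increase n_test")
        for j, n_gwas in enumerate(n_grid):
            beta_hat = simulate_gwas_effects(effects, int(n_gwas), rng)
            w = shrink_weights(beta_hat, int(n_gwas), m, h2)
            scores = z @ w.gamma
            aucs[r, j] = auc_with_se(scores, labels).auc
    mean = aucs.mean(axis=0)
    se = aucs.std(axis=0, ddof=1) / np.sqrt(reps)
    return pd.DataFrame({"n_gwas": n_grid, "auc_mean": mean, "auc_se": se})
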