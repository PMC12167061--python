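"""Captured-heritability metrics: imputation r², tagging ρ², h²_G and h²_I.

Two complementary views of how much additive genetic variance a variant panel
can recover at infinite GWAS sample size:

* ``h2_I = Σ_M beta_i² r²_imput,i`` — variance captured by all variants once
  imputed, weighting each causal effect by the squared correlation between its
  sequenced and imputed dosages.
* ``h2_G = Σ_S beta_i² + Σ_{j∉S} beta_j² ρ_j²`` — variance captured by the
  genotyped subset S alone, crediting untyped variants through LD via the
  adjusted squared multiple correlation ρ² with genotyped neighbours in a
  ±1.5 Mb window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lstsq

from .effects import Attenuation, EffectProfile, expected_beta2_weights, sample_alpha_effects
from .synthgeno import GenotypePanel

__all__ = [
    "ConstantInputError",
    "CaptureTable",
    "CaptureSummary",
    "imputation_r2",
    "tagging_rho2",
    "build_capture_table",
    "h2_genotyped",
    "h2_imputed",
    "capture_summary",
    "maf_filter",
    "capture_proportion_curve",
    "expected_capture_curve",
]

DEFAULT_WINDOW_BP = 1_500_000


class ConstantInputError(ValueError):
    """A dosage vector with zero variance makes the correlation undefined."""


@dataclass
class CaptureTable:
    """Per-variant capture qualities; genotyped variants get ρ² = r² = 1."""

    r2_imput: np.ndarray
    rho2: np.ndarray
    maf: np.ndarray
    is_genotyped: np.ndarray
    screened: np.ndarray | None = None  # True where predictor screening kicked in
    no_predictor: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("r2_imput", "rho2"):
            v = getattr(self, name)
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if not np.all(self.rho2[self.is_genotyped] == 1.0):
            raise ValueError("genotyped variants must have rho2 = 1 by convention")

    @property
    def m(self) -> int:
        return self.r2_imput.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "maf": self.maf,
                "is_genotyped": self.is_genotyped,
                "r2_imput": self.r2_imput,
                "rho2": self.rho2,
            }
        )


@dataclass
class CaptureSummary:
    h2_G: float
    h2_I: float
    h2_total: float

    @property
    def prop_G(self) -> float:
        return self.h2_G / self.h2_total if self.h2_total > 0 else 0.0

    @property
    def prop_I(self) -> float:
        return self.h2_I / self.h2_total if self.h2_total > 0 else 0.0


def imputation_r2(true_col: np.ndarray, imputed_col: np.ndarray) -> float:
    """Squared Pearson correlation between sequenced and imputed dosages.

    Equivalent to the R² of the univariate regression of one on the other.
    """
    t = np.asarray(true_col, dtype=float)
    i = np.asarray(imputed_col, dtype=float)
    if t.shape != i.shape or t.ndim != 1 or t.size < 3:
        raise ValueError("need two aligned 1-D vectors of length >= 3")
    t_c = t - t.mean()
    if np.allclose(t_c, 0):
        raise ConstantInputError("true dosage vector is constant; r² undefined")
    i_c = i - i.mean()
    denom = float(np.sum(t_c**2) * np.sum(i_c**2))
    if denom == 0:
        return 0.0
    r2 = float(np.sum(t_c * i_c) ** 2 / denom)
    return min(max(r2, 0.0), 1.0)


def _adjusted_r2_regression(y: np.ndarray, x: np.ndarray) -> float:
    """Adjusted R² of y ~ x with intercept, negatives clamped to 0."""
    n, k = x.shape
    y_c = y - y.mean()
    x_c = x - x.mean(axis=0)
    sst = float(np.sum(y_c**2))
    if sst == 0:
        raise ConstantInputError("response vector is constant; ρ² undefined")
    coef, _, rank, _ = lstsq(x_c, y_c, lapack_driver="gelsy")
    resid = y_c - x_c @ coef
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    dof = n - rank - 1
    if dof <= 0:
        return min(max(r2, 0.0), 1.0)
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    return min(max(adj, 0.0), 1.0)


def tagging_rho2(
    panel: GenotypePanel,
    j: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    screen_warn: bool = True,
) -> float:
    """Adjusted R² of untyped variant j regressed on genotyped neighbours.

    Predictors are all genotyped variants within ±``window_bp``. If their count
    reaches n−2 the regression is ill-posed, so predictors are screened down to
    the n/10 with largest marginal correlation (flagged via warning).
    """
    rho2, _, _ = _tagging_rho2_flags(panel, j, window_bp, screen_warn)
    return rho2


def _tagging_rho2_flags(
    panel: GenotypePanel,
    j: int,
    window_bp: int,
    warn: bool,
) -> tuple[float, bool, bool]:
    geno = panel.is_genotyped
    if geno[j]:
        raise ValueError(f"variant {j} is genotyped; ρ² applies to untyped variants")
    pos = panel.pos
    in_window = (np.abs(pos - pos[j]) <= window_bp) & geno
    idx = np.flatnonzero(in_window)
    if idx.size == 0:
        if warn:
            warnings.warn(f"no genotyped variant within ±{window_bp} bp of variant {j}")
        return 0.0, False, True

    y = panel.true_dosage[:, j].astype(float)
    if np.allclose(y, y[0]):
        raise ConstantInputError(f"variant {j} has constant dosage; ρ² undefined")
    n = panel.n_individuals
    screened = False
    if idx.size >= n - 2:
        keep = max(1, n // 10)
        x = panel.true_dosage[:, idx].astype(float)
        x_c = x - x.mean(axis=0)
        y_c = y - y.mean()
        sd = x_c.std(axis=0)
        sd[sd == 0] = np.inf
        marg = np.abs(x_c.T @ y_c) / sd
        idx = idx[np.argsort(marg)[::-1][:keep]]
        screened = True
        if warn:
            warnings.warn(
                f"variant {j}: {in_window.sum()} predictors for n={n}; "
                f"screened to top {keep} by marginal correlation"
            )
    x = panel.true_dosage[:, idx].astype(float)
    return _adjusted_r2_regression(y, x), screened, False


def build_capture_table(panel: GenotypePanel, window_bp: int = DEFAULT_WINDOW_BP) -> CaptureTable:
    """Per-variant r²_imput (univariate) and ρ² (windowed multiple regression)."""
    if panel.imputed_dosage is None:
        raise ValueError("panel has no imputed dosages; run emulate_imputation first")
    m = panel.m_variants
    geno = panel.is_genotyped
    r2 = np.ones(m)
    rho2 = np.ones(m)
    screened = np.zeros(m, dtype=bool)
    no_pred = np.zeros(m, dtype=bool)
    for v in range(m):
        if geno[v]:
            continue
        try:
            r2[v] = imputation_r2(panel.true_dosage[:, v], panel.imputed_dosage[:, v])
        except ConstantInputError:
            r2[v] = 0.0
        try:
            rho2[v], screened[v], no_pred[v] = _tagging_rho2_flags(
                panel, v, window_bp, warn=False
            )
        except ConstantInputError:
            rho2[v] = 0.0
    return CaptureTable(
        r2_imput=r2,
        rho2=rho2,
        maf=panel.maf,
        is_genotyped=geno,
        screened=screened,
        no_predictor=no_pred,
    )


def _check_aligned(effects: EffectProfile, capture: CaptureTable) -> None:
    if effects.beta.size != capture.m:
        raise ValueError(
            f"effect vector ({effects.beta.size}) and capture table ({capture.m}) differ in length"
        )


def h2_genotyped(effects: EffectProfile, capture: CaptureTable) -> float:
    """h²_G = Σ_S beta² + Σ_{∉S} beta² ρ²."""
    _check_aligned(effects, capture)
    b2 = effects.beta2
    s = capture.is_genotyped
    return float(np.sum(b2[s]) + np.sum(b2[~s] * capture.rho2[~s]))


def h2_imputed(effects: EffectProfile, capture: CaptureTable) -> float:
    """h²_I = Σ_M beta² r²_imput."""
    _check_aligned(effects, capture)
    return float(np.sum(effects.beta2 * capture.r2_imput))


def capture_summary(effects: EffectProfile, capture: CaptureTable) -> CaptureSummary:
    return CaptureSummary(
        h2_G=h2_genotyped(effects, capture),
        h2_I=h2_imputed(effects, capture),
        h2_total=effects.h2,
    )


def maf_filter(
    panel: GenotypePanel, threshold: float = 1e-5
) -> tuple[GenotypePanel, int]:
    """Drop variants with MAF below ``threshold``; returns (panel, n_removed)."""
    if not (0 < threshold < 0.5):
        raise ValueError("threshold must lie in (0, 0.5)")
    keep = panel.maf >= threshold
    removed = int(np.sum(~keep))
    return panel.subset_variants(keep), removed


def capture_proportion_curve(
    panel_or_capture: GenotypePanel | CaptureTable,
    alphas: np.ndarray,
    n_rep: int = 200,
    seed: int = 0,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Monte-Carlo E[prop_G], E[prop_I] over effect draws for each alpha.

    Averages the captured-heritability proportions over ``n_rep`` draws of
    alpha-model effects; h² cancels, so the curves depend only on the capture
    qualities and the MAF spectrum.
    """
    capture = _as_capture(panel_or_capture, window_bp)
    rng = np.random.default_rng(seed)
    rows = []
    for alpha in np.asarray(alphas, dtype=float):
        props_g = np.empty(n_rep)
        props_i = np.empty(n_rep)
        for r in range(n_rep):
            eff = sample_alpha_effects(capture.maf, alpha, h2_target=0.5, seed=rng)
            summ = capture_summary(eff, capture)
            props_g[r] = summ.prop_G
            props_i[r] = summ.prop_I
        rows.append((alpha, props_g.mean(), props_i.mean(), props_g.std(ddof=1) / np.sqrt(n_rep)))
    return pd.DataFrame(rows, columns=["alpha", "prop_G", "prop_I", "se_prop_G"])


def expected_capture_curve(
    panel_or_capture: GenotypePanel | CaptureTable,
    alphas: np.ndarray,
    attenuation: Attenuation | None = None,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Deterministic large-M capture curves from expected per-variant h² shares.

    prop(α) = Σ_i w_i(α) c_i with w the normalized alpha-model prior variances
    and c the capture quality (ρ² mix for prop_G, r²_imput for prop_I). This is
    the smooth curve the best-fit-alpha solver bisects.
    """
    capture = _as_capture(panel_or_capture, window_bp)
    s = capture.is_genotyped
    cg = np.where(s, 1.0, capture.rho2)
    ci = capture.r2_imput
    rows = []
    for alpha in np.asarray(alphas, dtype=float):
        w = expected_beta2_weights(capture.maf, alpha, attenuation)
        rows.append((alpha, float(np.sum(w * cg)), float(np.sum(w * ci))))
    return pd.DataFrame(rows, columns=["alpha", "prop_G", "prop_I"])


def _as_capture(obj: GenotypePanel | CaptureTable, window_bp: int) -> CaptureTable:
    if isinstance(obj, CaptureTable):
        return obj
    return build_capture_table(obj, window_bp=window_bp)
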