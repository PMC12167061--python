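"""Per-variant genetic effects under the alpha model and an attenuated variant.

The alpha model couples effect size to allele frequency: the effect of a
standardized variant i is drawn as

    beta_i | p_i ~ N(0, sigma2_g_alpha * [2 p_i (1 - p_i)]**alpha),

so alpha = 0 spreads heritability evenly over variants while alpha < 0 shifts
it toward rare variants. ``beta`` is the effect on the standardized genotype,
so heritability is h² = Σ beta_i² (the per-allele effect is beta/√(2pq)).
Realized Σ beta² is rescaled to the target h² exactly, which makes the
capture-metric identities exactly testable downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Attenuation",
    "EffectProfile",
    "sample_alpha_effects",
    "sample_attenuated_effects",
    "expected_beta2_weights",
]


@dataclass(frozen=True)
class Attenuation:
    """Multiplicative cap on alpha-model prior variances.

    Variances are multiplied by w_i = min(1, (p_i/p0)**tau) and renormalized to
    the target h² by fixed-point iteration; tau = 0 disables the attenuation.
    """

    p0: float
    tau: float
    tol: float = 1e-10
    max_iter: int = 100

    def weights(self, maf: np.ndarray) -> np.ndarray:
        if not (0 < self.p0 <= 0.5):
            raise ValueError("p0 must lie in (0, 0.5]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        return np.minimum(1.0, (np.asarray(maf, dtype=float) / self.p0) ** self.tau)


@dataclass
class EffectProfile:
    beta: np.ndarray
    alpha: float
    sigma2_g_alpha: float
    h2_target: float
    maf: np.ndarray
    attenuation: Attenuation | None = None

    @property
    def beta2(self) -> np.ndarray:
        return self.beta**2

    @property
    def h2(self) -> float:
        return float(np.sum(self.beta**2))


def _prior_variances(maf: np.ndarray, alpha: float) -> np.ndarray:
    het = 2.0 * maf * (1.0 - maf)
    return het**alpha


def _check_args(maf: np.ndarray, alpha: float, h2_target: float) -> np.ndarray:
    maf = np.asarray(maf, dtype=float)
    if maf.size == 0:
        raise ValueError("empty MAF vector")
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if not (0 <= h2_target <= 1):
        raise ValueError("h2_target must lie in [0, 1]")
    if not (-1.5 <= alpha <= 0):
        warnings.warn(
            f"alpha={alpha} is outside the standard [-1.5, 0] grid", stacklevel=3
        )
    return maf


def _draw_and_rescale(
    variances: np.ndarray,
    sigma2: float,
    h2_target: float,
    alpha: float,
    maf: np.ndarray,
    rng: np.random.Generator,
    attenuation: Attenuation | None,
) -> EffectProfile:
    beta = rng.standard_normal(variances.size) * np.sqrt(sigma2 * variances)
    ss = float(np.sum(beta**2))
    if h2_target == 0 or ss == 0:
        beta = np.zeros_like(beta)
        scale2 = 0.0
    else:
        scale2 = h2_target / ss
        beta = beta * np.sqrt(scale2)
    return EffectProfile(
        beta=beta,
        alpha=alpha,
        sigma2_g_alpha=sigma2 * scale2,  # recorded post-rescaling
        h2_target=h2_target,
        maf=maf,
        attenuation=attenuation,
    )


def sample_alpha_effects(
    maf: np.ndarray,
    alpha: float,
    h2_target: float,
    seed: int | np.random.Generator = 0,
) -> EffectProfile:
    """Draw standardized effects with Var(beta_i) ∝ [2 p_i (1-p_i)]**alpha.

    The scale parameter is drawn uniformly on [0, 1] before rescaling, and the
    realized Σ beta² is rescaled to ``h2_target`` exactly.
    """
    maf = _check_args(maf, alpha, h2_target)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = float(rng.uniform())
    variances = _prior_variances(maf, alpha)
    return _draw_and_rescale(variances, sigma2, h2_target, alpha, maf, rng, None)


def sample_attenuated_effects(
    maf: np.ndarray,
    alpha: float,
    h2_target: float,
    p0: float,
    tau: float,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> EffectProfile:
    """Alpha-model effects with the rare-variant contribution attenuated.

    Prior variances are capped by w_i = min(1, (p_i/p0)**tau) and renormalized
    to the target by fixed-point iteration; tau = 0 reproduces the plain alpha
    model in distribution.
    """
    maf = _check_args(maf, alpha, h2_target)
    att = Attenuation(p0=p0, tau=tau, tol=tol, max_iter=max_iter)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma2 = float(rng.uniform())

    w = att.weights(maf)
    v = _prior_variances(maf, alpha)
    target_sum = float(np.sum(v))  # keep overall scale comparable to alpha model
    for _ in range(max_iter):
        v_new = w * _prior_variances(maf, alpha)
        total = float(np.sum(v_new))
        if total == 0:
            raise RuntimeError("attenuation annihilated all prior variances")
        v_new = v_new * (target_sum / total)
        rel = np.max(np.abs(v_new - v) / np.maximum(np.abs(v), 1e-300))
        v = v_new
        if rel < tol:
            break
    else:
        raise RuntimeError(f"attenuation renormalization did not converge in {max_iter} iterations")
    return _draw_and_rescale(v, sigma2, h2_target, alpha, maf, rng, att)


def expected_beta2_weights(
    maf: np.ndarray,
    alpha: float,
    attenuation: Attenuation | None = None,
) -> np.ndarray:
    """Expected share of h² carried by each variant (sums to 1).

    Because realized Σ beta² is rescaled to h² exactly, the expected per-variant
    share is the normalized prior variance; this closed form is what the
    deterministic capture curves and the best-fit-alpha solver consume.
    """
    maf = np.asarray(maf, dtype=float)
    v = _prior_variances(maf, alpha)
    if attenuation is not None:
        v = v * attenuation.weights(maf)
    total = float(np.sum(v))
    if total == 0:
        raise ValueError("all prior variances are zero")
    return v / total
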