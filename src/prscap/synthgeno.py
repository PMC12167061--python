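"""Synthetic genotype panels with controllable LD, MAF spectrum, and imputation quality.

The generator emulates the statistical structure that the captured-heritability
analyses assume: a rare-skewed allele-frequency spectrum, local LD that decays
with physical distance, an array-like genotyped subset biased toward common
variants, imputed dosages whose accuracy rises with MAF, interval annotation
tracks, and liability-threshold case/control phenotypes.

Haplotypes come from a latent Gaussian AR(1) process thresholded at the
MAF-matched quantile; two haplotypes sum to a dosage in {0, 1, 2}. Imputed
dosages are a noisy linear blend of the standardized true dosage,
``r·z + sqrt(1−r²)·ε``, mapped back to dosage units and clipped to [0, 2], with
the per-variant target r² drawn from a logistic-in-log10(MAF) quality model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "MafSpectrum",
    "one_over_f_spectrum",
    "uniform_spectrum",
    "GenotypePanel",
    "AnnotationSet",
    "PhenotypeSet",
    "generate_panel",
    "fraction",
    "maf_biased",
    "designate_genotyped",
    "logistic_quality_model",
    "emulate_imputation",
    "generate_annotations",
    "simulate_liability_phenotype",
    "default_panel",
]

ANNOTATION_CATEGORIES = (
    "gencode",
    "tfbs",
    "fantom5",
    "promoter",
    "enhancer",
    "dyadic",
    "dhs",
    "super-enhancer",
)

# Fixed substream labels so that one top-level seed fans out reproducibly
# per component regardless of call order.
_STREAMS = {"panel": 11, "subset": 23, "imputation": 37, "annotations": 53, "phenotype": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# MAF spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MafSpectrum:
    """Allele-frequency spectrum descriptor.

    ``one_over_f`` has density proportional to 1/p on [low, high], mimicking the
    rare-skewed spectrum of sequencing data; ``uniform`` is flat on [low, high].
    """

    kind: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.kind not in ("one_over_f", "uniform"):
            raise ValueError(f"unknown MAF spectrum kind {self.kind!r}")
        if not (0 < self.low <= self.high <= 0.5):
            raise ValueError("MAF spectrum bounds must satisfy 0 < low <= high <= 0.5")

    def sample(self, m: int, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(size=m)
        if self.kind == "uniform":
            return self.low + u * (self.high - self.low)
        # inverse CDF of the 1/p density on [low, high]
        return self.low * (self.high / self.low) ** u

    def cdf(self, p: np.ndarray) -> np.ndarray:
        p = np.clip(np.asarray(p, dtype=float), self.low, self.high)
        if self.kind == "uniform":
            return (p - self.low) / (self.high - self.low)
        return np.log(p / self.low) / np.log(self.high / self.low)


def one_over_f_spectrum(low: float = 1e-4, high: float = 0.5) -> MafSpectrum:
    return MafSpectrum("one_over_f", low, high)


def uniform_spectrum(low: float, high: float) -> MafSpectrum:
    return MafSpectrum("uniform", low, high)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """Variant metadata plus aligned true/imputed dosage matrices.

    ``meta`` columns: chrom, pos (1-based), maf, is_genotyped, and after
    imputation emulation a per-variant target r2 (``r2_target``).
    """

    meta: pd.DataFrame
    true_dosage: np.ndarray
    imputed_dosage: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_dosage.ndim != 2:
            raise ValueError("true_dosage must be 2-D (individuals x variants)")
        if len(self.meta) != self.true_dosage.shape[1]:
            raise ValueError("meta rows must match dosage columns")
        if self.imputed_dosage is not None and self.imputed_dosage.shape != self.true_dosage.shape:
            raise ValueError("imputed_dosage shape must match true_dosage")
        pos = self.meta["pos"].to_numpy()
        for _, grp in self.meta.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
        maf = self.meta["maf"].to_numpy(dtype=float)
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")

    @property
    def n_individuals(self) -> int:
        return self.true_dosage.shape[0]

    @property
    def m_variants(self) -> int:
        return self.true_dosage.shape[1]

    @property
    def maf(self) -> np.ndarray:
        return self.meta["maf"].to_numpy(dtype=float)

    @property
    def is_genotyped(self) -> np.ndarray:
        return self.meta["is_genotyped"].to_numpy(dtype=bool)

    @property
    def pos(self) -> np.ndarray:
        return self.meta["pos"].to_numpy(dtype=np.int64)

    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        return GenotypePanel(
            meta=self.meta.loc[mask].reset_index(drop=True),
            true_dosage=self.true_dosage[:, mask],
            imputed_dosage=None if self.imputed_dosage is None else self.imputed_dosage[:, mask],
            seed=self.seed,
        )


@dataclass
class AnnotationSet:
    """Named interval tracks in 1-based inclusive coordinates.

    ``tracks`` maps a track name to an (n_intervals, 2) integer array of
    [start, end] pairs on ``chrom``; ``categories`` maps each name to one of
    the eight annotation classes.
    """

    tracks: dict[str, np.ndarray]
    categories: dict[str, str]
    chrom: str = "22"
    span: tuple[int, int] | None = None

    def coverage_fraction(self, name: str) -> float:
        if self.span is None:
            raise ValueError("span unknown; cannot compute coverage fraction")
        lo, hi = self.span
        ivals = merge_intervals(self.tracks[name])
        covered = int(np.sum(ivals[:, 1] - ivals[:, 0] + 1)) if len(ivals) else 0
        return covered / (hi - lo + 1)

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class PhenotypeSet:
    """Liability-threshold phenotypes: latent liability, binary labels."""

    liability: np.ndarray
    labels: np.ndarray
    prevalence_target: float
    h2_used: float
    genetic_score: np.ndarray | None = None


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent 1-based inclusive intervals."""
    if len(intervals) == 0:
        return np.empty((0, 2), dtype=np.int64)
    ivals = np.asarray(intervals, dtype=np.int64)
    order = np.argsort(ivals[:, 0])
    ivals = ivals[order]
    merged = [ivals[0].tolist()]
    for s, e in ivals[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64)


# ---------------------------------------------------------------------------
# Panel generation
# ---------------------------------------------------------------------------


def generate_panel(
    n: int,
    m: int,
    ld_strength: float = 0.8,
    maf_spec: MafSpectrum | None = None,
    seed: int = 0,
    span_bp: int = 8_000_000,
    chrom: str = "22",
) -> GenotypePanel:
    """Generate ``n`` individuals x ``m`` variants of true dosages with local LD.

    ``ld_strength`` in [0, 1) is the latent-haplotype correlation between
    variants one mean-spacing apart; correlation decays geometrically with
    physical distance, so squared correlation (LD) decays with distance too.
    """
    if n < 2 or m < 1:
        raise ValueError("need n >= 2 individuals and m >= 1 variants")
    if not (0 <= ld_strength < 1):
        raise ValueError("ld_strength must lie in [0, 1)")
    if maf_spec is None:
        maf_spec = one_over_f_spectrum()
    rng = _rng(seed, "panel")

    pos = np.sort(rng.choice(span_bp, size=m, replace=False)) + 1
    maf = maf_spec.sample(m, rng)

    # latent AR(1) over 2n haplotypes, step coefficient tied to bp distance
    z = np.empty((2 * n, m))
    z[:, 0] = rng.standard_normal(2 * n)
    if m > 1:
        mean_spacing = span_bp / m
        gaps = np.diff(pos)
        phi = ld_strength ** (gaps / mean_spacing) if ld_strength > 0 else np.zeros(m - 1)
        noise = rng.standard_normal((2 * n, m - 1))
        for j in range(1, m):
            f = phi[j - 1]
            z[:, j] = f * z[:, j - 1] + np.sqrt(1.0 - f * f) * noise[:, j - 1]

    thresh = norm.ppf(1.0 - maf)  # P(z > t) = maf per haplotype
    alleles = (z > thresh[None, :]).astype(np.int8)
    dosage = alleles[:n] + alleles[n:]

    meta = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "maf": maf,
            "is_genotyped": False,
        }
    )
    return GenotypePanel(meta=meta, true_dosage=dosage, seed=seed)


# ---------------------------------------------------------------------------
# Genotyped-subset designation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class fraction:
    """Select a uniform random fraction of variants as genotyped."""

    value: float


@dataclass(frozen=True)
class maf_biased:
    """Array-like selection favoring common variants.

    Variants with MAF >= ``threshold`` are selected with probability
    ``p_common``; rarer variants with probability ``p_common * maf/threshold``.
    """

    threshold: float
    p_common: float = 0.9


def designate_genotyped(panel: GenotypePanel, rule, seed: int = 0) -> GenotypePanel:
    rng = _rng(seed, "subset")
    maf = panel.maf
    m = panel.m_variants
    if isinstance(rule, fraction):
        if not (0 <= rule.value <= 1):
            raise ValueError("fraction must lie in [0, 1]")
        k = int(round(rule.value * m))
        if k == 0:
            raise ValueError("genotyped-subset rule selected no variants")
        chosen = rng.choice(m, size=k, replace=False)
        mask = np.zeros(m, dtype=bool)
        mask[chosen] = True
    elif isinstance(rule, maf_biased):
        prob = np.where(maf >= rule.threshold, rule.p_common, rule.p_common * maf / rule.threshold)
        mask = rng.uniform(size=m) < prob
        if not mask.any():
            raise ValueError("genotyped-subset rule selected no variants")
    else:
        raise TypeError("rule must be fraction(...) or maf_biased(...)")
    meta = panel.meta.copy()
    meta["is_genotyped"] = mask
    return dataclasses.replace(panel, meta=meta)


# ---------------------------------------------------------------------------
# Imputation emulation
# ---------------------------------------------------------------------------


def logistic_quality_model(
    low: float = 0.02,
    high: float = 0.98,
    midpoint_log10_maf: float = -2.15,
    slope: float = 1.8,
) -> Callable[[np.ndarray], np.ndarray]:
    """Target imputation r² as a logistic function of log10(MAF).

    Defaults are calibrated so that under the default 1/p spectrum on
    [1e-4, 0.5] the mean target r² is ~0.5 and quality rises steeply with MAF,
    the qualitative pattern real imputation pipelines show.
    """

    def model(maf: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(maf, dtype=float))
        return low + (high - low) * expit(slope * (x - midpoint_log10_maf))

    return model


def emulate_imputation(
    panel: GenotypePanel,
    quality_model: Callable[[np.ndarray], np.ndarray] | float | np.ndarray | None = None,
    seed: int = 0,
) -> GenotypePanel:
    """Attach imputed dosages whose per-variant accuracy follows ``quality_model``.

    Genotyped variants are their own perfect imputations (r² = 1 exactly).
    """
    if quality_model is None:
        quality_model = logistic_quality_model()
    maf = panel.maf
    if callable(quality_model):
        target_r2 = np.asarray(quality_model(maf), dtype=float)
    else:
        target_r2 = np.broadcast_to(np.asarray(quality_model, dtype=float), (panel.m_variants,)).copy()
    if np.any(target_r2 < 0) or np.any(target_r2 > 1):
        raise ValueError("quality model must return target r² values in [0, 1]")

    rng = _rng(seed, "imputation")
    target_r2 = target_r2.copy()
    target_r2[panel.is_genotyped] = 1.0

    mu = 2.0 * maf
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    z_true = (panel.true_dosage - mu[None, :]) / sd[None, :]
    r = np.sqrt(target_r2)
    eps = rng.standard_normal(panel.true_dosage.shape)
    z_imp = r[None, :] * z_true + np.sqrt(1.0 - target_r2)[None, :] * eps
    raw = mu[None, :] + sd[None, :] * z_imp
    imputed = _mean_preserving_clip(raw, mu, panel.true_dosage.mean(axis=0))

    exact = target_r2 >= 1.0
    imputed[:, exact] = panel.true_dosage[:, exact]

    meta = panel.meta.copy()
    meta["r2_target"] = target_r2
    return dataclasses.replace(panel, meta=meta, imputed_dosage=imputed)


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------


def _mean_preserving_clip(
    raw: np.ndarray, mu: np.ndarray, observed_mean: np.ndarray
) -> np.ndarray:
    """Clip to [0, 2] without biasing the expected dosage.

    Naive clipping piles the lower noise tail of rare variants at 0, inflating
    both their mean dosage and their realized r². Shrinking each column's
    deviations around the expected dosage, clip(mu + lam*(raw - mu), 0, 2),
    scales signal and noise alike — so the pre-clip correlation is untouched —
    while reducing the clipped mass; lam is bisected per variant until the
    clip-induced mean bias is gone.
    """
    target = np.maximum(observed_mean, mu)  # below-mu means are pure sampling noise
    dev = raw - mu[None, :]
    bias_full = np.clip(raw, 0.0, 2.0).mean(axis=0) - target
    lo = np.full(raw.shape[1], 1e-3)
    hi = np.ones(raw.shape[1])
    for _ in range(40):
        mid = np.where(bias_full <= 0, 1.0, 0.5 * (lo + hi))
        mean = np.clip(mu[None, :] + mid[None, :] * dev, 0.0, 2.0).mean(axis=0)
        over = mean > target
        lo = np.where(over, lo, mid)
        hi = np.where(over, mid, hi)
    lam = np.where(bias_full <= 0, 1.0, 0.5 * (lo + hi))
    return np.clip(mu[None, :] + lam[None, :] * dev, 0.0, 2.0)


def generate_annotations(
    panel: GenotypePanel,
    k: int,
    coverage_range: tuple[float, float] = (1e-5, 0.647),
    seed: int = 0,
    max_intervals: int = 40,
) -> AnnotationSet:
    """Generate ``k`` interval tracks with coverage fractions spanning the range.

    Intervals are anchored on variant positions (so even tiny tracks hit at
    least one variant), with target coverages log-uniform over the range.
    """
    lo, hi = coverage_range
    if not (0 < lo <= hi < 1):
        raise ValueError("coverage bounds must satisfy 0 < lo <= hi < 1")
    rng = _rng(seed, "annotations")
    pos = panel.pos
    span_lo, span_hi = int(pos.min()), int(pos.max())
    span = span_hi - span_lo + 1
    chrom = str(panel.meta["chrom"].iloc[0])

    tracks: dict[str, np.ndarray] = {}
    categories: dict[str, str] = {}
    if k == 0:
        return AnnotationSet(tracks, categories, chrom=chrom, span=(span_lo, span_hi))

    if k == 1:
        coverages = np.array([np.sqrt(lo * hi)])
    else:
        # deterministic log-spaced grid guarantees the range is spanned
        coverages = np.exp(np.linspace(np.log(lo), np.log(hi), k))
    order = rng.permutation(k)
    for idx in range(k):
        cov = float(coverages[idx])
        total_len = max(1, int(round(cov * span)))
        n_int = int(min(max_intervals, max(1, rng.integers(1, max_intervals + 1))))
        n_int = min(n_int, total_len, len(pos))
        lengths = rng.dirichlet(np.ones(n_int)) * total_len
        lengths = np.maximum(1, np.round(lengths)).astype(np.int64)
        anchors = rng.choice(pos, size=n_int, replace=False)
        starts = np.maximum(span_lo, anchors - lengths // 2)
        ends = np.minimum(span_hi, starts + lengths - 1)
        ivals = merge_intervals(np.column_stack([starts, ends]))
        cat = ANNOTATION_CATEGORIES[order[idx] % len(ANNOTATION_CATEGORIES)]
        name = f"{cat}_{idx:04d}"
        tracks[name] = ivals
        categories[name] = cat
    return AnnotationSet(tracks, categories, chrom=chrom, span=(span_lo, span_hi))


# ---------------------------------------------------------------------------
# Liability-threshold phenotypes
# ---------------------------------------------------------------------------


def simulate_liability_phenotype(
    panel: GenotypePanel,
    effects,
    k_prev: float,
    seed: int = 0,
) -> PhenotypeSet:
    """Simulate case/control labels under the liability-threshold model.

    Liability = genetic score on standardized dosages + N(0, 1−h²) noise;
    an individual is a case iff liability exceeds T = Phi^-1(1−K).
    """
    if not (0 < k_prev < 1):
        raise ValueError("prevalence must lie in (0, 1)")
    beta = np.asarray(effects.beta, dtype=float)
    if beta.shape[0] != panel.m_variants:
        raise ValueError("effect vector length must match panel size")
    h2 = float(np.sum(beta**2))
    if h2 > 1 + 1e-12:
        raise ValueError("sum of squared effects (h²) exceeds 1")
    h2 = min(h2, 1.0)

    maf = panel.maf
    mu = 2.0 * maf
    sd = np.sqrt(2.0 * maf * (1.0 - maf))
    z = (panel.true_dosage - mu[None, :]) / sd[None, :]
    g = z @ beta
    # LD between causal variants makes Var(g) differ from sum(beta^2); rescale
    # the realized score to variance h2 so the liability is standard normal and
    # the threshold reproduces the prevalence exactly
    sd_g = float(np.std(g))
    if h2 > 0 and sd_g > 0:
        g = g * (np.sqrt(h2) / sd_g)

    rng = _rng(seed, "phenotype")
    e = rng.standard_normal(panel.n_individuals) * np.sqrt(max(0.0, 1.0 - h2))
    liability = g + e
    t = norm.ppf(1.0 - k_prev)
    labels = (liability > t).astype(np.int8)
    return PhenotypeSet(
        liability=liability,
        labels=labels,
        prevalence_target=k_prev,
        h2_used=h2,
        genetic_score=g,
    )


# ---------------------------------------------------------------------------
# Calibrated default preset
# ---------------------------------------------------------------------------


def default_panel(
    seed: int = 0,
    n: int = 1000,
    m: int = 1200,
    ld_strength: float = 0.97,
    span_bp: int = 8_000_000,
) -> GenotypePanel:
    """The calibrated preset every downstream analysis runs on by default.

    Rare-skewed 1/p MAF spectrum, block LD, an array-like genotyped subset
    (common variants preferred), and logistic-in-log10(MAF) imputation quality
    with mean target r² near 0.5 — reproducing the qualitative structure the
    capture metrics rely on: imputation r² above tagging ρ² on average, and the
    two positively correlated.
    """
    panel = generate_panel(n=n, m=m, ld_strength=ld_strength, seed=seed, span_bp=span_bp)
    panel = designate_genotyped(panel, maf_biased(0.05), seed=seed)
    panel = emulate_imputation(panel, logistic_quality_model(), seed=seed)
    return panel
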