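"""Association between imputation quality and functional-annotation membership.

Each annotation A is a binary per-variant indicator (does the position fall in
any interval of the track). The primary model is the univariate OLS
``r2_imput ~ delta * A``; for a binary predictor the unstandardized slope is
exactly the difference of in-track vs out-of-track group means, and the
standardized coefficient (both sides z-scored) is the Pearson correlation. A
sensitivity model conditions on gene-structure (GENCODE-like) indicators, and
significance across a compendium of tracks is Bonferroni-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

from .coverage import ConstantInputError
from .synthgeno import AnnotationSet, GenotypePanel, merge_intervals

__all__ = [
    "EnrichmentResult",
    "annotate_variants",
    "univariate_enrichment",
    "enrichment_scan",
    "adjusted_enrichment",
    "multiple_testing",
    "maf_by_annotation",
]


@dataclass
class EnrichmentResult:
    annotation: str
    category: str
    delta: float  # unstandardized slope = mean_in - mean_out
    delta_std: float  # slope with response and predictor z-scored
    p_value: float
    mean_r2_in: float
    mean_r2_out: float
    n_in: int
    n_out: int
    adjusted: bool = False
    dropped_adjusters: tuple[str, ...] = ()


def annotate_variants(panel: GenotypePanel, annotations: AnnotationSet) -> pd.DataFrame:
    """M x K binary indicator table: variant position in any track interval.

    Coordinates are 1-based inclusive on both sides (BED input is converted on
    read).
    """
    chrom = str(panel.meta["chrom"].iloc[0])
    if annotations.chrom != chrom:
        raise ValueError(
            f"annotation chromosome {annotations.chrom!r} does not match panel {chrom!r}"
        )
    pos = panel.pos
    cols = {}
    for name, ivals in annotations.tracks.items():
        merged = merge_intervals(ivals)
        if len(merged) == 0:
            cols[name] = np.zeros(pos.size, dtype=np.int8)
            continue
        starts, ends = merged[:, 0], merged[:, 1]
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos <= ends[np.clip(idx, 0, len(ends) - 1)])
        cols[name] = inside.astype(np.int8)
    return pd.DataFrame(cols, index=pd.RangeIndex(pos.size))


def _ols_binary(r2: np.ndarray, indicator: np.ndarray) -> tuple[float, float, float]:
    """Slope, standardized slope, and p-value of r2 ~ indicator (closed form)."""
    n = r2.size
    x = indicator.astype(float)
    y = r2
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(np.sum(xc**2))
    syy = float(np.sum(yc**2))
    sxy = float(np.sum(xc * yc))
    slope = sxy / sxx
    if syy == 0:
        return slope, 0.0, 1.0
    r = sxy / np.sqrt(sxx * syy)
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return slope, r, 0.0
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(tstat), df=n - 2)
    return slope, float(r), float(p)


def univariate_enrichment(
    r2: np.ndarray,
    indicator: np.ndarray,
    name: str = "",
    category: str = "",
) -> EnrichmentResult:
    """OLS of imputation r² on a single binary annotation indicator."""
    r2 = np.asarray(r2, dtype=float)
    ind = np.asarray(indicator)
    if r2.shape != ind.shape or r2.ndim != 1:
        raise ValueError("r2 and indicator must be aligned 1-D vectors")
    n_in = int(np.sum(ind != 0))
    n_out = int(ind.size - n_in)
    if n_in == 0 or n_out == 0:
        raise ConstantInputError(
            "annotation indicator is constant (covers all or no variants); slope undefined"
        )
    slope, delta_std, p = _ols_binary(r2, ind)
    return EnrichmentResult(
        annotation=name,
        category=category,
        delta=slope,
        delta_std=delta_std,
        p_value=p,
        mean_r2_in=float(r2[ind != 0].mean()),
        mean_r2_out=float(r2[ind == 0].mean()),
        n_in=n_in,
        n_out=n_out,
    )


def enrichment_scan(
    r2: np.ndarray,
    indicators: pd.DataFrame | np.ndarray,
    categories: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Vectorized univariate enrichment over a whole indicator table.

    Identical fits to calling :func:`univariate_enrichment` per column, done in
    one pass of matrix arithmetic; constant columns are reported with NaN.
    """
    r2 = np.asarray(r2, dtype=float)
    if isinstance(indicators, pd.DataFrame):
        names = list(indicators.columns)
        x = indicators.to_numpy(dtype=float)
    else:
        x = np.asarray(indicators, dtype=float)
        names = [f"track_{j}" for j in range(x.shape[1])]
    n = r2.size
    yc = r2 - r2.mean()
    syy = float(np.sum(yc**2))
    xm = x.mean(axis=0)
    sxx = np.sum(x**2, axis=0) - n * xm**2
    sxy = x.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        rr = sxy / np.sqrt(sxx * syy)
        rr = np.clip(rr, -1.0, 1.0)
        tstat = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr**2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    constant = (sxx == 0) | (xm == 0) | (xm == 1)
    slope[constant] = np.nan
    p[constant] = np.nan
    n_in = np.round(xm * n).astype(int)
    cat = [categories.get(nm, "") if categories else "" for nm in names]
    return pd.DataFrame(
        {
            "annotation": names,
            "category": cat,
            "delta": slope,
            "delta_std": np.where(constant, np.nan, rr),
            "p_value": p,
            "n_in": n_in,
            "n_out": n - n_in,
        }
    )


def adjusted_enrichment(
    r2: np.ndarray,
    indicator: np.ndarray,
    gencode_indicators: pd.DataFrame | np.ndarray,
    name: str = "",
    category: str = "",
) -> EnrichmentResult:
    """Partial slope of the focal annotation conditioning on GENCODE indicators.

    Collinear adjuster columns are dropped (and reported); a focal indicator
    collinear with the adjusters is an error.
    """
    r2 = np.asarray(r2, dtype=float)
    ind = np.asarray(indicator, dtype=float)
    if isinstance(gencode_indicators, pd.DataFrame):
        adj_names = list(gencode_indicators.columns)
        adj = gencode_indicators.to_numpy(dtype=float)
    else:
        adj = np.atleast_2d(np.asarray(gencode_indicators, dtype=float))
        if adj.shape[0] != r2.size:
            adj = adj.T
        adj_names = [f"gencode_{j}" for j in range(adj.shape[1])]
    n_in = int(np.sum(ind != 0))
    n_out = int(ind.size - n_in)
    if n_in == 0 or n_out == 0:
        raise ConstantInputError("focal indicator is constant; slope undefined")

    # assemble adjusters first (dropping internally collinear columns), then
    # require the focal indicator to add rank on top of them
    base = np.ones((r2.size, 1))
    dropped: list[str] = []
    rank = 1
    for j in range(adj.shape[1]):
        cand = np.column_stack([base, adj[:, j]])
        cand_rank = np.linalg.matrix_rank(cand)
        if cand_rank > rank:
            base, rank = cand, cand_rank
        else:
            dropped.append(adj_names[j])
    with_focal = np.column_stack([base, ind])
    if np.linalg.matrix_rank(with_focal) == rank:
        raise ValueError("focal indicator is collinear with the GENCODE adjusters")
    design = np.column_stack([np.ones(r2.size), ind, base[:, 1:]])

    fit = sm.OLS(r2, design).fit()
    slope = float(fit.params[1])
    p = float(fit.pvalues[1])
    sy = r2.std(ddof=0)
    sx = ind.std(ddof=0)
    delta_std = slope * sx / sy if sy > 0 else 0.0
    return EnrichmentResult(
        annotation=name,
        category=category,
        delta=slope,
        delta_std=float(delta_std),
        p_value=p,
        mean_r2_in=float(r2[ind != 0].mean()),
        mean_r2_out=float(r2[ind == 0].mean()),
        n_in=n_in,
        n_out=n_out,
        adjusted=True,
        dropped_adjusters=tuple(dropped),
    )


def multiple_testing(
    p_values: np.ndarray,
    alpha_level: float = 0.05,
    method: str = "bonferroni",
) -> tuple[np.ndarray, float]:
    """Significance flags and the corrected threshold (Bonferroni default)."""
    p = np.asarray(p_values, dtype=float)
    if method != "bonferroni":
        raise ValueError("only 'bonferroni' is supported")
    threshold = alpha_level / p.size
    return p < threshold, float(threshold)


def maf_by_annotation(
    panel: GenotypePanel,
    annotations: AnnotationSet,
    rare_cutoff: float = 0.01,
    grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative MAF distributions per track and a rare-fraction comparison.

    Returns (cdf_table, tests): the CDF of variant MAFs on a fixed grid for
    each track plus the whole panel, and per-track two-proportion z-tests
    comparing the fraction of rare variants (MAF < ``rare_cutoff``) inside vs
    outside the track.
    """
    ind = annotate_variants(panel, annotations)
    maf = panel.maf
    if grid is None:
        grid = np.concatenate([[1e-5], np.geomspace(1e-4, 0.5, 40)])
    cdf = {"maf": grid, "all": [float(np.mean(maf <= g)) for g in grid]}
    rows = []
    for name in ind.columns:
        mask = ind[name].to_numpy(dtype=bool)
        if mask.all() or not mask.any():
            raise ConstantInputError(f"track {name!r} covers all or no variants")
        cdf[name] = [float(np.mean(maf[mask] <= g)) for g in grid]
        rare = maf < rare_cutoff
        count = np.array([np.sum(rare & mask), np.sum(rare & ~mask)])
        nobs = np.array([np.sum(mask), np.sum(~mask)])
        stat, p = proportions_ztest(count, nobs)
        rows.append(
            (
                name,
                annotations.categories.get(name, ""),
                count[0] / nobs[0],
                count[1] / nobs[1],
                float(stat),
                float(p),
            )
        )
    tests = pd.DataFrame(
        rows,
        columns=["annotation", "category", "rare_frac_in", "rare_frac_out", "z", "p_value"],
    )
    return pd.DataFrame(cdf), tests
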