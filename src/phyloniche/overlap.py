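"""Kernel occupancy grids, Schoener's D, and overlap regressions.

Species occupancy of the 2-D environmental space follows the kernel-smoothing
approach of Broennimann-style niche quantification: a Gaussian kernel density
of the species' deduplicated scores is evaluated on a regular grid spanning
the background scores, optionally divided by the background availability
density, and normalized to sum to one.  Overlap between two such grids is
Schoener's D = 1 - 0.5 * sum |z1 - z2|.

Overlap values for species pairs are then explained with ordinary least
squares (same pollination mode / same island and their interaction), compared
by AIC.  The regression is deliberately not phylogenetically corrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .envspace import EnvSpace, SpeciesNiche

__all__ = [
    "OccupancyGrid", "OverlapModelFit", "background_availability",
    "occupancy_grid", "schoener_D", "pairwise_overlap",
    "fit_overlap_models", "range_inclusion",
]


@dataclass
class OccupancyGrid:
    extent: np.ndarray       # 2 x (min, max), shared by all grids of an analysis
    z: np.ndarray            # R x R, nonnegative, sums to 1
    resolution: int
    corrected: bool

    def __post_init__(self):
        total = float(self.z.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"occupancy grid must sum to 1, got {total}")
        if (self.z < 0).any():
            raise ValueError("occupancy grid must be nonnegative")


def _cell_centers(extent, R):
    cx = np.linspace(extent[0, 0], extent[0, 1], R + 1)
    cy = np.linspace(extent[1, 0], extent[1, 1], R + 1)
    return 0.5 * (cx[:-1] + cx[1:]), 0.5 * (cy[:-1] + cy[1:])


def _silverman(x: np.ndarray, fallback: float) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    return h if h > 0 else fallback


def _kde_grid(points, extent, R, bandwidth_rule="silverman"):
    """Gaussian KDE of 2-D points evaluated at the grid cell centers."""
    cx, cy = _cell_centers(extent, R)
    cell = np.array([cx[1] - cx[0] if R > 1 else 1.0,
                     cy[1] - cy[0] if R > 1 else 1.0])
    if bandwidth_rule == "silverman":
        hx = _silverman(points[:, 0], 0.5 * cell[0])
        hy = _silverman(points[:, 1], 0.5 * cell[1])
    else:
        hx, hy = float(bandwidth_rule[0]), float(bandwidth_rule[1])
    hx = max(hx, 0.5 * cell[0])
    hy = max(hy, 0.5 * cell[1])
    gx = np.exp(-0.5 * ((cx[None, :] - points[:, [0]]) / hx) ** 2)
    gy = np.exp(-0.5 * ((cy[None, :] - points[:, [1]]) / hy) ** 2)
    return gx.T @ gy / (2 * np.pi * hx * hy * len(points))


def background_availability(space: EnvSpace, R: int = 100,
                            bandwidth_rule="silverman"):
    """Extent and availability density of the background environmental space."""
    bg = np.asarray(space.background_scores)
    extent = np.column_stack([bg.min(axis=0), bg.max(axis=0)])
    dens = _kde_grid(bg, extent, R, bandwidth_rule)
    return extent, dens


def occupancy_grid(
    niche: SpeciesNiche,
    space: EnvSpace,
    R: int = 100,
    bandwidth_rule="silverman",
    corrected: bool = True,
    background=None,
) -> OccupancyGrid:
    """Kernel occupancy of one species over the gridded environmental space.

    When ``corrected``, the occurrence density in each cell is divided by the
    background availability density (floored at its 1st positive percentile to
    avoid blow-ups where almost no environment exists).
    """
    if len(niche.scores) < 2:
        raise ValueError("need at least 2 points for an occupancy grid")
    if background is None:
        background = background_availability(space, R, bandwidth_rule)
    extent, avail = background
    z = _kde_grid(np.asarray(niche.scores), extent, R, bandwidth_rule)
    if corrected:
        floor = np.percentile(avail[avail > 0], 1.0)
        z = z / np.maximum(avail, floor)
    total = z.sum()
    if total <= 0:
        raise ValueError("occupancy grid has zero total density")
    return OccupancyGrid(extent=extent, z=z / total, resolution=R,
                         corrected=corrected)


def schoener_D(g1: OccupancyGrid, g2: OccupancyGrid) -> float:
    """Schoener's D between two occupancy grids on the same extent."""
    if g1.resolution != g2.resolution or not np.allclose(g1.extent, g2.extent):
        raise ValueError("grids must share extent and resolution")
    return float(1.0 - 0.5 * np.abs(g1.z - g2.z).sum())


def _islands_of(value):
    if isinstance(value, (set, frozenset, list, tuple)):
        return set(value)
    if isinstance(value, str):
        return {s for s in value.split(";") if s}
    raise ValueError(f"cannot interpret island set {value!r}")


def pairwise_overlap(
    niches,
    metadata: pd.DataFrame,
    space: EnvSpace,
    R: int = 100,
    bandwidth_rule="silverman",
    corrected: bool = True,
    mode_col: str = "pollination_mode",
    unknown_value: str = "unknown",
) -> pd.DataFrame:
    """Schoener's D for all unordered species pairs, with pair covariates.

    ``same_pollination`` is missing (NA) when either species' mode is unknown;
    ``same_island`` is true when the two species' island sets intersect.
    """
    if len(niches) < 2:
        raise ValueError("need at least 2 species")
    meta = metadata.set_index("species")
    background = background_availability(space, R, bandwidth_rule)
    grids = {n.species: occupancy_grid(n, space, R, bandwidth_rule, corrected,
                                       background)
             for n in niches}
    rows = []
    for a, b in itertools.combinations(sorted(grids), 2):
        same_mode: object = pd.NA
        same_island: object = pd.NA
        if a in meta.index and b in meta.index:
            ma, mb = meta.loc[a, mode_col], meta.loc[b, mode_col]
            if not (pd.isna(ma) or pd.isna(mb)
                    or ma == unknown_value or mb == unknown_value):
                same_mode = bool(ma == mb)
            if "islands" in meta.columns:
                same_island = bool(_islands_of(meta.loc[a, "islands"])
                                   & _islands_of(meta.loc[b, "islands"]))
        rows.append({"species_a": a, "species_b": b,
                     "D": schoener_D(grids[a], grids[b]),
                     "same_pollination": same_mode, "same_island": same_island})
    return pd.DataFrame(rows)


@dataclass
class OverlapModelFit:
    label: str
    coefficients: dict
    pvalues: dict
    aic: float
    r_squared: float
    n: int
    is_best: bool = False
    within_2_aic: bool = False


def _design(pairs, terms, group_col):
    cols = {"const": np.ones(len(pairs))}
    if "group" in terms:
        cols["group"] = pairs[group_col].astype(float).to_numpy()
    if "island" in terms:
        cols["island"] = pairs["same_island"].astype(float).to_numpy()
    if "interaction" in terms:
        cols["interaction"] = cols["group"] * cols["island"]
    return pd.DataFrame(cols, index=pairs.index)


def fit_overlap_models(
    pairs: pd.DataFrame,
    group_col: str = "same_pollination",
    group_label: str = "pollination",
) -> list:
    """OLS model set for Schoener's D over species pairs, ranked by AIC.

    Five models: intercept-only, group, island, group+island, group*island.
    AIC uses the Gaussian log-likelihood with the ML variance estimate and
    counts the variance among the parameters (k = coefficients + 1).  Pairs
    with an unknown group are excluded from models that use the group term
    (listwise deletion per predictor); island-only and intercept-only models
    keep all pairs.  Models whose predictors are degenerate (constant) are
    dropped with a warning.
    """
    model_terms = {
        "D ~ 1": (),
        f"D ~ {group_label}": ("group",),
        "D ~ island": ("island",),
        f"D ~ {group_label} + island": ("group", "island"),
        f"D ~ {group_label} * island": ("group", "island", "interaction"),
    }
    if len(pairs) < 10:
        raise ValueError("need at least 10 species pairs")
    fits = []
    for label, terms in model_terms.items():
        sub = pairs
        if "group" in terms:
            sub = sub[sub[group_col].notna()]
        sub = sub[sub["same_island"].notna()] if "island" in terms else sub
        try:
            X = _design(sub, terms, group_col)
        except (TypeError, ValueError):
            warnings.warn(f"cannot build design for {label!r}; model dropped")
            continue
        pred = X.drop(columns="const")
        if any(pred[c].nunique() < 2 for c in pred.columns):
            warnings.warn(f"degenerate predictor in {label!r}; model dropped")
            continue
        res = sm.OLS(sub["D"].to_numpy(), X.to_numpy()).fit()
        k = X.shape[1] + 1          # coefficients + residual variance
        names = list(X.columns)
        degenerate = not len(pred.columns) or sub["D"].var() < 1e-30
        fits.append(OverlapModelFit(
            label=label,
            coefficients=dict(zip(names, res.params)),
            pvalues=dict(zip(names, res.pvalues)),
            aic=float(-2.0 * res.llf + 2.0 * k),
            r_squared=0.0 if degenerate else float(res.rsquared),
            n=len(sub),
        ))
    if not fits:
        raise ValueError("no overlap model could be fitted")
    best = min(f.aic for f in fits)
    seen_best = False
    for f in fits:
        f.within_2_aic = f.aic <= best + 2.0
        if not seen_best and f.aic == best:
            f.is_best = seen_best = True
    return fits


def overlap_models_to_frame(fits) -> pd.DataFrame:
    def stars(p):
        return ("***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05
                else "." if p < 0.1 else "")

    rows = []
    for f in fits:
        row = {"model": f.label, "AIC": f.aic, "R2": f.r_squared, "n": f.n,
               "is_best": f.is_best, "within_2_AIC": f.within_2_aic}
        for name in ("const", "group", "island", "interaction"):
            if name in f.coefficients:
                row[name] = f.coefficients[name]
                row[f"{name}_sig"] = stars(f.pvalues[name])
        rows.append(row)
    return pd.DataFrame(rows)


def range_inclusion(plant: SpeciesNiche, pollinator_group) -> dict:
    """Is the plant's niche range contained in its pollinator group's range?

    The group range per axis is the union (min of mins, max of maxs) over the
    group's species.  Margins are distances to the group bounds; negative
    margins flag the violating side.
    """
    if not pollinator_group:
        raise ValueError("pollinator group must be non-empty")
    lo = np.min([n.range[:, 0] for n in pollinator_group], axis=0)
    hi = np.max([n.range[:, 1] for n in pollinator_group], axis=0)
    out = {}
    included_all = True
    for ax, name in enumerate(("PC1", "PC2")):
        m_lo = float(plant.range[ax, 0] - lo[ax])
        m_hi = float(hi[ax] - plant.range[ax, 1])
        inc = m_lo >= 0 and m_hi >= 0
        included_all &= inc
        out[name] = {"included": inc, "margin_low": m_lo, "margin_high": m_hi}
    out["included"] = included_all
    return out
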