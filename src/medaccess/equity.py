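"""Population-weighted equity statistics for accessibility surfaces.

A Lorenz curve plots cumulative population share against cumulative
accessibility share (units sorted by accessibility); the Gini
coefficient is twice the area between the curve and the diagonal.
Because nearest-cost surfaces measure cost (lower = better) they are
first inverted and min-max normalised so that, like the catchment-based
surfaces, larger means better before any Lorenz accumulation.

County-level analyses aggregate cell values to population-weighted
county means, correlate them with group composition (aging share,
agricultural share) via Pearson's r, and tabulate group composition
across accessibility percentile bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .access import AccessibilitySurface

logger = logging.getLogger(__name__)


@dataclass
class LorenzResult:
    points: np.ndarray  # (k, 2): cumulative population share, cumulative value share
    gini: float
    region: str = ""
    surface: str = ""


def invert_normalize(surface: AccessibilitySurface) -> AccessibilitySurface:
    """Turn a cost surface into a 0-1 "higher is better" surface.

    Nearest-cost (Pri) surfaces are mapped through y = reciprocal then
    min-max normalisation; catchment surfaces (Sec/Ter) pass through
    unchanged since they already read "higher is better".
    """
    if not surface.label.startswith("Pri"):
        return surface
    x = surface.values
    if np.any(x <= 0):
        raise ValueError("invert_normalize requires strictly positive costs")
    r = 1.0 / x
    span = r.max() - r.min()
    if span <= 0:
        logger.warning("constant cost surface: normalised to all zeros")
        y = np.zeros_like(r)
    else:
        y = (r - r.min()) / span
    return AccessibilitySurface(surface.label + "_norm", list(surface.cell_ids), y, "0-1")


def lorenz_gini(values, populations, region: str = "", surface: str = "") -> LorenzResult:
    """Lorenz curve and Gini of population-weighted accessibility.

    Units are sorted ascending by value (ties broken by position for
    determinism); x accumulates population share, y accumulates
    population x value share; Gini = 1 - 2 * trapezoidal area under the
    curve.  Zero-population units carry no mass and are dropped.
    """
    v = np.asarray(values, dtype=float)
    p = np.asarray(populations, dtype=float)
    if np.any(p < 0) or np.any(v < 0):
        raise ValueError("values and populations must be non-negative")
    keep = p > 0
    v, p = v[keep], p[keep]
    if p.sum() <= 0:
        raise ValueError("no populated units")
    if np.sum(p * v) <= 0:
        raise ValueError("all accessibility mass is zero; Lorenz curve undefined")
    order = np.lexsort((np.arange(len(v)), v))
    v, p = v[order], p[order]
    cx = np.concatenate([[0.0], np.cumsum(p) / p.sum()])
    cy = np.concatenate([[0.0], np.cumsum(p * v) / np.sum(p * v)])
    area = float(np.sum((cx[1:] - cx[:-1]) * (cy[1:] + cy[:-1]) / 2.0))
    gini = 1.0 - 2.0 * area
    return LorenzResult(np.column_stack([cx, cy]), float(gini), region, surface)


def aggregate_to_county(surface: AccessibilitySurface, cells) -> pd.Series:
    """Population-weighted mean surface value per county."""
    df = pd.DataFrame(
        {
            "county": [c.county_id for c in cells],
            "pop": [c.population for c in cells],
            "value": surface.values,
        }
    )
    df["pv"] = df["pop"] * df["value"]
    g = df.groupby("county").agg(pop=("pop", "sum"), pv=("pv", "sum"))
    empty = g[g["pop"] <= 0]
    if len(empty):
        logger.warning("excluding %d zero-population counties: %s",
                       len(empty), list(empty.index))
        g = g[g["pop"] > 0]
    return g["pv"] / g["pop"]


def group_correlation(county_values: pd.Series, county_group_ratio: pd.Series):
    """Pearson correlation between county accessibility and a group's share.

    Returns (r, two-tailed p, significance stars at 0.05 / 0.01).
    """
    joined = pd.concat([county_values, county_group_ratio], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("need at least three counties")
    a = joined.iloc[:, 0].to_numpy(float)
    b = joined.iloc[:, 1].to_numpy(float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(a, b)
    stars = "**" if p < 0.01 else "*" if p < 0.05 else ""
    return float(r), float(p), stars


def county_group_ratios(cells, group: str) -> pd.Series:
    """Share of a stratum ('aging' or 'agricultural') in each county's population."""
    attr = {"aging": "aging_count", "agricultural": "agricultural_count"}[group]
    df = pd.DataFrame(
        {
            "county": [c.county_id for c in cells],
            "pop": [c.population for c in cells],
            "grp": [getattr(c, attr) for c in cells],
        }
    )
    g = df.groupby("county").sum()
    g = g[g["pop"] > 0]
    return g["grp"] / g["pop"]


def quantile_composition(
    surface: AccessibilitySurface,
    cells,
    group: str = "agricultural",
    bins: list[tuple[float, float]] | None = None,
    weighting: str = "population",
) -> pd.DataFrame:
    """Group composition across accessibility percentile bins.

    Cells are ranked by surface value; ``weighting='population'`` places
    bin boundaries on cumulative population percentiles (default),
    ``'count'`` on cell-count percentiles.  For each bin the table
    reports the within-bin composition (group vs complement share of the
    bin's population, summing to 1) and the across-bin distribution of
    each group (share of the group's total population falling in the
    bin).  A top-10% readout is always appended.
    """
    if weighting not in ("population", "count"):
        raise ValueError("weighting must be 'population' or 'count'")
    if bins is None:
        bins = [(10 * i, 10 * (i + 1)) for i in range(10)]
    lo = min(b[0] for b in bins)
    hi = max(b[1] for b in bins)
    if lo != 0 or hi != 100:
        raise ValueError("bins must partition [0, 100]")

    attr = {"aging": "aging_count", "agricultural": "agricultural_count"}[group]
    pop = np.array([c.population for c in cells], dtype=float)
    grp = np.array([getattr(c, attr) for c in cells], dtype=float)
    v = surface.values
    order = np.lexsort((np.arange(len(v)), v))
    pop, grp, v = pop[order], grp[order], v[order]

    if weighting == "population":
        w = pop
    else:
        w = np.ones_like(pop)
    cum = np.cumsum(w)
    # percentile position of each cell = midpoint of its mass interval
    pct = 100.0 * (cum - w / 2.0) / cum[-1]

    total_grp = grp.sum()
    total_comp = pop.sum() - total_grp
    rows = []
    labelled = [(a, b, f"{a:g}-{b:g}") for a, b in bins] + [(90.0, 100.0, "top10")]
    for a, b, name in labelled:
        mask = (pct >= a) & (pct < b) if b < 100 else (pct >= a) & (pct <= 100)
        bp = pop[mask].sum()
        bg = grp[mask].sum()
        if bp <= 0:
            rows.append({"bin": name, "group_share": np.nan, "complement_share": np.nan,
                         "group_dist": np.nan, "complement_dist": np.nan})
            continue
        rows.append(
            {
                "bin": name,
                "group_share": bg / bp,
                "complement_share": (bp - bg) / bp,
                "group_dist": bg / total_grp if total_grp > 0 else np.nan,
                "complement_dist": (bp - bg) / total_comp if total_comp > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("bin")
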