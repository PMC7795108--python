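"""Accessibility surfaces for three tiers of medical service.

Residents use services differently by disease severity, so three
engines coexist:

- **Primary** (common ailments): nearest-cost. The surface value is the
  minimum travel cost to *any* facility; lower is better.
- **Secondary** (difficult cases): two-step floating catchment area
  (2SFCA) over secondary + tertiary facilities. Step one computes each
  facility's supply-to-decayed-demand ratio within a catchment, step two
  sums the decayed ratios reachable from each cell; higher is better.
- **Tertiary** (serious cases): residents go to tertiary hospitals in
  their own city or the provincial capital, with no catchment limit.
  The surface is the sum of an own-city gravity term (friction 1.5,
  capacity weight 1, competition pool = the city's cells) and a capital
  term (friction 1, capacity weight 2, competition pool = all cells).

Distance decay is the power kernel d^-beta with a small floor ``eps``
to keep co-located pairs finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import SPACE_METRIC, TIME_METRIC, TravelCostMatrix

logger = logging.getLogger(__name__)

LEVELS = ("primary", "secondary", "tertiary")

SURFACE_LABELS = ("Pri_T", "Pri_S", "Sec_T", "Sec_S", "Ter_T", "Ter_S")


@dataclass
class DemandCell:
    """One grid cell of the demand surface (planar metres)."""

    id: int
    x: float
    y: float
    population: float
    aging_count: float = 0.0
    agricultural_count: float = 0.0
    county_id: str = "C0"
    city_id: int = 0
    subdivision: str = ""

    def __post_init__(self):
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if self.aging_count > self.population or self.agricultural_count > self.population:
            raise ValueError("stratum count exceeds population")


@dataclass
class Facility:
    """A medical facility with staff-count service capacity."""

    id: int
    x: float
    y: float
    level: str
    staff: float
    capacity_weight: float | None = None
    city_id: int = 0

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown facility level {self.level!r}")
        if self.staff <= 0:
            raise ValueError("staff must be positive")
        if self.capacity_weight is None:
            self.capacity_weight = 2.0 if self.level == "tertiary" else 1.0
        if self.capacity_weight <= 0:
            raise ValueError("capacity weight must be positive")


@dataclass(frozen=True)
class FCAParams:
    """Gravity/2SFCA parameters in the native units of the cost metric.

    ``d0`` is the catchment threshold (strict: interactions require
    d < d0); 120 min for time costs, 10 km for space costs — both the
    cost of a two-hour trip at walking speed or on the network.
    ``beta`` is the friction exponent of the decay kernel d^-beta.
    ``beta_own``/``beta_capital`` are the tertiary-model frictions for
    the own-city and capital terms.  ``eps`` floors the distance before
    decay so that self-cell facilities stay finite.
    """

    d0: float = 120.0
    beta: float = 1.0
    beta_own: float = 1.5
    beta_capital: float = 1.0
    eps: float = 1.0
    suppress_capital_own_term: bool = False

    def __post_init__(self):
        if self.d0 <= 0 or self.eps <= 0:
            raise ValueError("d0 and eps must be positive")
        if min(self.beta, self.beta_own, self.beta_capital) < 0:
            raise ValueError("decay exponents must be non-negative")

    @classmethod
    def time_defaults(cls, **kw) -> "FCAParams":
        """Two-hour catchment on travel minutes."""
        return cls(d0=kw.pop("d0", 120.0), eps=kw.pop("eps", 1.0), **kw)

    @classmethod
    def space_defaults(cls, **kw) -> "FCAParams":
        """Ten-kilometre catchment on straight/network metres."""
        return cls(d0=kw.pop("d0", 10_000.0), eps=kw.pop("eps", 1000.0), **kw)


@dataclass
class AccessibilitySurface:
    """Per-cell accessibility values under one label."""

    label: str
    cell_ids: list
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids),):
            raise ValueError("surface length mismatch")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("surface values must be finite and non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"cell_id": self.cell_ids, self.label: self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_geojson(self, path, cells) -> None:
        from .io import surface_to_geojson

        surface_to_geojson(self, cells, path)


def decay_weights(d: np.ndarray, beta: float, eps: float) -> np.ndarray:
    """Power decay d^-beta with the distance floored at eps."""
    return np.maximum(np.asarray(d, dtype=float), eps) ** (-beta)


def _subset_matrix(costs: TravelCostMatrix, facilities) -> tuple[np.ndarray, list]:
    ids = [f.id for f in facilities]
    idx = [costs.dest_ids.index(i) for i in ids]
    return costs.values[:, idx], ids


def nearest_cost(costs: TravelCostMatrix, facilities) -> AccessibilitySurface:
    """Minimum travel cost from each cell to the facility subset (Pri)."""
    if not facilities:
        raise ValueError("facility subset is empty")
    sub, _ = _subset_matrix(costs, facilities)
    label = "Pri_T" if costs.metric == TIME_METRIC else "Pri_S"
    units = "min" if costs.metric == TIME_METRIC else "m"
    return AccessibilitySurface(label, list(costs.origin_ids), sub.min(axis=1), units)


def supply_demand_ratio(
    facility: Facility,
    costs: TravelCostMatrix,
    cells,
    params: FCAParams,
) -> float:
    """Step one of 2SFCA for one facility: S_j P_j over decayed in-catchment demand."""
    col = costs.column(facility.id)
    demand = np.array([c.population for c in cells], dtype=float)
    mask = col < params.d0
    denom = float(np.sum(demand[mask] * decay_weights(col[mask], params.beta, params.eps)))
    if denom <= 0:
        logger.warning("facility %s has no demand within d0=%s; ratio set to 0",
                       facility.id, params.d0)
        return 0.0
    return facility.staff * facility.capacity_weight / denom


def two_step_fca(
    costs: TravelCostMatrix,
    cells,
    facilities,
    params: FCAParams | None = None,
    capacity_weights: dict | None = None,
    label: str | None = None,
) -> AccessibilitySurface:
    """Two-step floating catchment area accessibility (Sec surfaces).

    ``capacity_weights`` optionally overrides facility capacity weights
    by level (used by the sensitivity sweep).
    """
    if params is None:
        params = FCAParams.time_defaults() if costs.metric == TIME_METRIC else FCAParams.space_defaults()
    sub, _ = _subset_matrix(costs, facilities)
    demand = np.array([c.population for c in cells], dtype=float)
    supply = np.array(
        [
            f.staff * (capacity_weights.get(f.level, f.capacity_weight)
                       if capacity_weights else f.capacity_weight)
            for f in facilities
        ]
    )
    w = decay_weights(sub, params.beta, params.eps)
    in_range = sub < params.d0
    denom = (demand[:, None] * w * in_range).sum(axis=0)
    ratios = np.where(denom > 0, supply / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(denom <= 0):
        logger.warning("%d facilities have empty catchments", int(np.sum(denom <= 0)))
    values = (ratios[None, :] * w * in_range).sum(axis=1)
    if not np.any(values):
        logger.warning("2SFCA surface is identically zero")
    if label is None:
        label = "Sec_T" if costs.metric == TIME_METRIC else "Sec_S"
    return AccessibilitySurface(label, list(costs.origin_ids), values, "staff per person")


def tertiary_access(
    costs: TravelCostMatrix,
    cells,
    tertiary_facilities,
    capital_city_id: int,
    params: FCAParams | None = None,
    label: str | None = None,
) -> AccessibilitySurface:
    """Hierarchical tertiary-care accessibility (Ter surfaces).

    Own-city term: gravity sum over the cell's own city's tertiary
    hospitals with capacity weight 1, friction ``beta_own`` and the
    competition pool restricted to that city's cells.  Capital term:
    gravity sum over the capital's hospitals with capacity weight 2,
    friction ``beta_capital`` and a province-wide pool.  Neither term
    has a catchment threshold.  Capital residents receive both terms;
    set ``suppress_capital_own_term`` to drop their own-city term.
    """
    if params is None:
        params = FCAParams.time_defaults() if costs.metric == TIME_METRIC else FCAParams.space_defaults()
    if not tertiary_facilities:
        raise ValueError("no tertiary facilities")
    capitals = [f for f in tertiary_facilities if f.city_id == capital_city_id]
    if not capitals:
        logger.warning("capital city %s has no tertiary hospital", capital_city_id)

    sub, fac_ids = _subset_matrix(costs, tertiary_facilities)
    demand = np.array([c.population for c in cells], dtype=float)
    cell_city = np.array([c.city_id for c in cells])
    fac_city = np.array([f.city_id for f in tertiary_facilities])
    staff = np.array([f.staff for f in tertiary_facilities], dtype=float)

    values = np.zeros(len(cells))

    # own-city term, capacity weight 1, friction beta_own
    w_own = decay_weights(sub, params.beta_own, params.eps)
    for city in np.unique(cell_city):
        fmask = fac_city == city
        cmask = cell_city == city
        if params.suppress_capital_own_term and city == capital_city_id:
            continue
        if not fmask.any():
            logger.info("city %s has no tertiary hospital; own-city term is 0", city)
            continue
        denom = (demand[cmask, None] * w_own[np.ix_(cmask, fmask)]).sum(axis=0)
        ratios = np.where(denom > 0, staff[fmask] * 1.0 / np.where(denom > 0, denom, 1.0), 0.0)
        values[cmask] += (ratios[None, :] * w_own[np.ix_(cmask, fmask)]).sum(axis=1)

    # capital term, capacity weight 2, friction beta_capital, pool = province
    pmask = fac_city == capital_city_id
    if pmask.any():
        w_cap = decay_weights(sub[:, pmask], params.beta_capital, params.eps)
        denom = (demand[:, None] * w_cap).sum(axis=0)
        ratios = np.where(denom > 0, staff[pmask] * 2.0 / np.where(denom > 0, denom, 1.0), 0.0)
        values += (ratios[None, :] * w_cap).sum(axis=1)

    if label is None:
        label = "Ter_T" if costs.metric == TIME_METRIC else "Ter_S"
    return AccessibilitySurface(label, list(costs.origin_ids), values, "staff per person")
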