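"""Configuration-driven orchestration of the full accessibility analysis.

``run_all`` executes: region generation (or loading) -> travel-cost
matrices (road time, rail-enabled time, space) -> the six accessibility
surfaces -> spatial autocorrelation per region and subdivision ->
equity reports -> the sensitivity sweep, writing every artifact under
one output directory together with a manifest of parameters, warnings
and file checksums.  Every stage is a pure function of (inputs, config,
seed), so a repeated run yields identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .access import FCAParams, nearest_cost, tertiary_access, two_step_fca
from .autocorr import build_weights, global_moran, local_moran
from .equity import (
    aggregate_to_county,
    county_group_ratios,
    group_correlation,
    invert_normalize,
    lorenz_gini,
    quantile_composition,
)
from .network import SPACE_METRIC, TIME_METRIC, AccessParams, cost_matrix
from .sensitivity import SweepSpec, run_sweep
from .synthetic import RegionConfig, StudyRegion, generate_region

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    region: RegionConfig = field(default_factory=RegionConfig)
    region_dir: str | None = None  # load instead of generate when set
    access: AccessParams = field(default_factory=AccessParams)
    fca_time: FCAParams = field(default_factory=FCAParams.time_defaults)
    fca_space: FCAParams = field(default_factory=FCAParams.space_defaults)
    weights_scheme: str = "queen"
    row_standardize: bool = True
    n_permutations: int = 999
    alpha: float = 0.05
    sweep: SweepSpec = field(default_factory=SweepSpec)
    out_dir: str = "output"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "region" in doc:
            kw["region"] = RegionConfig.from_dict(doc["region"])
        if "access" in doc:
            kw["access"] = AccessParams(**doc["access"])
        if "fca_time" in doc:
            kw["fca_time"] = FCAParams(**doc["fca_time"])
        if "fca_space" in doc:
            kw["fca_space"] = FCAParams(**doc["fca_space"])
        if "sweep" in doc:
            sw = dict(doc["sweep"])
            for k in ("thresholds", "weights"):
                if k in sw:
                    sw[k] = tuple(sw[k])
            kw["sweep"] = SweepSpec(**sw)
        for k in ("region_dir", "weights_scheme", "row_standardize",
                  "n_permutations", "alpha", "out_dir", "seed"):
            if k in doc:
                kw[k] = doc[k]
        return cls(**kw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(self.format(record))


def get_region(config: PipelineConfig) -> StudyRegion:
    if config.region_dir:
        return StudyRegion.load(config.region_dir)
    region_cfg = replace(config.region, seed=config.seed)
    return generate_region(region_cfg)


def compute_costs(region: StudyRegion, access: AccessParams):
    """Road-time, rail-time (tertiary destinations) and space matrices."""
    cells, facs = region.cells, region.facilities
    time_road = cost_matrix(cells, facs, region.network, access, TIME_METRIC)
    tertiary = region.facilities_by_level("tertiary")
    time_rail = cost_matrix(cells, tertiary, region.network_with_rail, access, TIME_METRIC)
    space = cost_matrix(cells, facs, region.network, access, SPACE_METRIC)
    return time_road, time_rail, space


def compute_surfaces(region: StudyRegion, time_road, time_rail, space,
                     fca_time: FCAParams, fca_space: FCAParams) -> dict:
    cells = region.cells
    all_f = region.facilities
    sec_f = region.facilities_by_level("secondary", "tertiary")
    ter_f = region.facilities_by_level("tertiary")
    cap = region.capital_city_id
    return {
        "Pri_T": nearest_cost(time_road, all_f),
        "Pri_S": nearest_cost(space, all_f),
        "Sec_T": two_step_fca(time_road, cells, sec_f, fca_time),
        "Sec_S": two_step_fca(space, cells, sec_f, fca_space),
        "Ter_T": tertiary_access(time_rail, cells, ter_f, cap, fca_time),
        "Ter_S": tertiary_access(space.subset([f.id for f in ter_f]), cells, ter_f,
                                 cap, fca_space),
    }


def autocorr_reports(region: StudyRegion, surfaces: dict, config: PipelineConfig):
    """Global + local Moran per surface, for the region and each subdivision."""
    out_global = []
    local_frames = {}
    groups = {"province": region.cells}
    for sub in sorted(set(region.subdivisions.values())):
        members = [c for c in region.cells if c.subdivision == sub]
        if len(members) >= 9:  # need a workable grid
            groups[sub] = members
    for gname, cells in groups.items():
        idx = [c.id for c in cells]
        w = build_weights(cells, config.weights_scheme, config.row_standardize)
        for label, surf in surfaces.items():
            pos = [surf.cell_ids.index(i) for i in idx]
            vals = surf.values[pos]
            if vals.std() == 0:
                logger.warning("constant %s surface in %s; Moran skipped", label, gname)
                continue
            g = global_moran(vals, w, config.n_permutations, seed=config.seed)
            out_global.append(
                {"region": gname, "surface": label, "moran_I": g.global_I,
                 "expected_I": g.expected_I, "p": g.p_value,
                 "scheme": config.weights_scheme,
                 "permutations": config.n_permutations, "seed": config.seed}
            )
            if gname == "province":
                loc = local_moran(vals, w, config.n_permutations,
                                  config.alpha, seed=config.seed)
                local_frames[label] = pd.DataFrame(
                    {"cell_id": idx, "local_I": loc.local_I,
                     "p": loc.local_p, "cluster": loc.clusters}
                )
    return pd.DataFrame(out_global), local_frames


def equity_reports(region: StudyRegion, surfaces: dict):
    cells = region.cells
    pops = np.array([c.population for c in cells], dtype=float)
    gini_rows = []
    groups = {"province": np.ones(len(cells), bool)}
    subs = np.array([c.subdivision for c in cells])
    for sub in sorted(set(region.subdivisions.values())):
        groups[sub] = subs == sub
    for label, surf in surfaces.items():
        eq_surface = invert_normalize(surf)
        for gname, mask in groups.items():
            if not mask.any() or pops[mask].sum() <= 0:
                continue
            vals = eq_surface.values[mask]
            if np.sum(vals * pops[mask]) <= 0:
                logger.warning("zero accessibility mass for %s in %s", label, gname)
                continue
            lr = lorenz_gini(vals, pops[mask], region=gname, surface=label)
            gini_rows.append({"region": gname, "surface": label, "gini": lr.gini})
    gini_table = pd.DataFrame(gini_rows).pivot(index="region", columns="surface", values="gini")

    corr_rows = []
    comp_tables = {}
    for label, surf in surfaces.items():
        county_vals = aggregate_to_county(surf, cells)
        for group in ("aging", "agricultural"):
            ratios = county_group_ratios(cells, group)
            r, p, stars = group_correlation(county_vals, ratios)
            corr_rows.append({"surface": label, "group": group, "r": r, "p": p,
                              "stars": stars})
        comp_tables[label] = {
            g: quantile_composition(surf, cells, g) for g in ("aging", "agricultural")
        }
    return gini_table, pd.DataFrame(corr_rows), comp_tables


def run_all(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logging.getLogger("medaccess").addHandler(collector)
    artifacts: dict[str, str] = {}

    def write_csv(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, **kw)
        artifacts[name] = _sha256(path)

    try:
        stage = "generate"
        region = get_region(config)
        region_dir = out / "region"
        region.save(region_dir)
        for p in sorted(region_dir.iterdir()):
            artifacts[f"region/{p.name}"] = _sha256(p)

        stage = "costs"
        time_road, time_rail, space = compute_costs(region, config.access)
        for name, m in (("costs_time.csv", time_road),
                        ("costs_time_rail.csv", time_rail),
                        ("costs_space.csv", space)):
            m.to_csv(out / name)
            artifacts[name] = _sha256(out / name)

        stage = "access"
        surfaces = compute_surfaces(region, time_road, time_rail, space,
                                    config.fca_time, config.fca_space)
        for label, surf in surfaces.items():
            write_csv(surf.to_frame(), f"surface_{label}.csv", index=False)

        stage = "autocorr"
        moran_table, local_frames = autocorr_reports(region, surfaces, config)
        write_csv(moran_table, "moran_global.csv", index=False)
        for label, frame in local_frames.items():
            write_csv(frame, f"lisa_{label}.csv", index=False)

        stage = "equity"
        gini_table, corr_table, comp_tables = equity_reports(region, surfaces)
        write_csv(gini_table, "gini.csv")
        write_csv(corr_table, "correlations.csv", index=False)
        for label, by_group in comp_tables.items():
            for group, tbl in by_group.items():
                write_csv(tbl, f"composition_{label}_{group}.csv")

        stage = "sweep"
        sec_f = region.facilities_by_level("secondary", "tertiary")
        sweep = run_sweep(time_road, region.cells, sec_f, config.sweep, config.fca_time)
        write_csv(sweep.table, "sensitivity.csv")
        for (param, value), (dflt, var) in sweep.pairs.items():
            write_csv(
                pd.DataFrame({"default": dflt, "variant": var}),
                f"scatter_{param}_{value:g}.csv", index=False,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger("medaccess").removeHandler(collector)

    manifest = {
        "seed": config.seed,
        "weights_scheme": config.weights_scheme,
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "access": {"d_threshold_m": config.access.d_threshold_m,
                   "walk_speed_kmh": config.access.walk_speed_kmh,
                   "feeder_speed_kmh": config.access.feeder_speed_kmh,
                   "direct_rule": config.access.direct_rule},
        "fca_time": {"d0": config.fca_time.d0, "beta": config.fca_time.beta,
                     "beta_own": config.fca_time.beta_own,
                     "beta_capital": config.fca_time.beta_capital,
                     "eps": config.fca_time.eps},
        "fca_space": {"d0": config.fca_space.d0, "eps": config.fca_space.eps},
        "warnings": collector.records,
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
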