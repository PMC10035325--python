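"""File ingestion, validation, and the end-to-end pipeline driver.

All tabular interchange is CSV; geometries travel as GeoJSON
FeatureCollections in a projected equal-area CRS (metres).  The pipeline
refuses geographic (degree-valued) coordinates outright -- a 1 km buffer in
degrees is meaningless -- so reprojection is a documented pre-step, not
something this package attempts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from . import disparity as ds
from . import exposure as ex
from .synthetic import LandscapeConfig, generate_blockgroups, generate_tribal_lands, generate_wells
from .wells import (
    CANONICAL_PERIODS,
    DEFAULT_REFERENCE_YEAR,
    IDLE_YEARS,
    WELL_STATUSES,
    StageAssignment,
    StudyPeriod,
    WellRecord,
    assign_stages,
)

logger = logging.getLogger(__name__)

WELL_COLUMNS = [
    "well_id", "x", "y", "status", "spud_date", "completion_date",
    "first_prod_date", "last_prod_date", "abandonment_date", "well_type",
]
PRODUCTION_COLUMNS = ["well_id", "year", "boe"]

_YEAR_ONLY = re.compile(r"^\d{4}$")


def parse_date(value) -> Optional[date]:
    """ISO-8601 or bare-year date; a bare year maps to July 1 (midpoint)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "na", "none"):
        return None
    if _YEAR_ONLY.match(s):
        logger.warning("year-only date %s mapped to %s-07-01", s, s)
        return date(int(s), 7, 1)
    return date.fromisoformat(s)


def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


@dataclass
class ValidationReport:
    """Warnings accumulated while loading and validating one dataset."""

    warnings: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        logger.warning(msg)
        self.warnings.append(msg)

    def counts_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for w in self.warnings:
            key = w.split(":", 1)[0]
            out[key] = out.get(key, 0) + 1
        return out


def _check_projected(xs, ys, what: str) -> None:
    """Degree-valued coordinates are fatal: buffers need projected metres."""
    xs, ys = list(xs), list(ys)
    if xs and all(abs(x) <= 180 for x in xs) and all(abs(y) <= 90 for y in ys):
        raise ValueError(
            f"{what}: coordinates look geographic (degrees); reproject to an "
            "equal-area CRS in metres before running the pipeline"
        )


def read_wells(
    wells_csv: Path,
    production_csv: Path,
    report: Optional[ValidationReport] = None,
) -> list[WellRecord]:
    """Read the wells table and its companion long-format production table."""
    report = report if report is not None else ValidationReport()
    wdf = pd.read_csv(wells_csv, dtype={"well_id": str}, keep_default_na=False)
    missing = [c for c in WELL_COLUMNS if c not in wdf.columns]
    if missing:
        raise ValueError(f"wells table missing required columns {missing}")
    dups = wdf["well_id"][wdf["well_id"].duplicated()]
    if not dups.empty:
        raise ValueError(f"duplicate well_id {dups.iloc[0]!r} in wells table")

    pdf = pd.read_csv(production_csv, dtype={"well_id": str})
    pmissing = [c for c in PRODUCTION_COLUMNS if c not in pdf.columns]
    if pmissing:
        raise ValueError(f"production table missing required columns {pmissing}")
    boe_by_well: dict[str, dict[int, float]] = {}
    for wid, year, boe in pdf[PRODUCTION_COLUMNS].itertuples(index=False):
        if boe < 0:
            report.warn(f"clamped_boe: well {wid} year {year} volume {boe} -> 0")
            boe = 0.0
        boe_by_well.setdefault(wid, {})[int(year)] = float(boe)

    _check_projected(wdf["x"], wdf["y"], "wells table")
    wells = []
    for row in wdf.itertuples(index=False):
        status = row.status if row.status in WELL_STATUSES else "unknown"
        spud = parse_date(row.spud_date)
        comp = parse_date(row.completion_date)
        if spud is not None and comp is not None and spud > comp:
            report.warn(f"date_order: well {row.well_id} spud {spud} after completion {comp}")
        wells.append(
            WellRecord(
                well_id=row.well_id, x=float(row.x), y=float(row.y),
                status=status, spud_date=spud, completion_date=comp,
                first_prod_date=parse_date(row.first_prod_date),
                last_prod_date=parse_date(row.last_prod_date),
                abandonment_date=parse_date(row.abandonment_date),
                well_type=str(row.well_type),
                annual_boe=boe_by_well.get(row.well_id, {}),
            )
        )
    return wells


def write_wells(wells: Sequence[WellRecord], wells_csv: Path, production_csv: Path) -> None:
    rows = [
        {
            "well_id": w.well_id, "x": w.x, "y": w.y, "status": w.status,
            "spud_date": _fmt_date(w.spud_date),
            "completion_date": _fmt_date(w.completion_date),
            "first_prod_date": _fmt_date(w.first_prod_date),
            "last_prod_date": _fmt_date(w.last_prod_date),
            "abandonment_date": _fmt_date(w.abandonment_date),
            "well_type": w.well_type,
        }
        for w in wells
    ]
    pd.DataFrame(rows, columns=WELL_COLUMNS).to_csv(wells_csv, index=False)
    prod = [
        {"well_id": w.well_id, "year": y, "boe": b}
        for w in wells
        for y, b in sorted(w.annual_boe.items())
    ]
    pd.DataFrame(prod, columns=PRODUCTION_COLUMNS).to_csv(production_csv, index=False)


def read_geojson(path: Path) -> dict[str, dict]:
    """GeoJSON FeatureCollection -> {feature id: {geometry, properties}}."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties", {})
        fid = props.get("geoid") or props.get("name")
        if fid is None:
            raise ValueError(f"{path}: feature without a geoid/name property")
        out[str(fid)] = {"geometry": shape(feat["geometry"]), "properties": props}
    return out


def write_geojson(path: Path, features: dict[str, tuple[BaseGeometry, dict]]) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": props,
            }
            for geom, props in features.values()
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh)


def read_blockgroups(
    geojson_path: Path,
    demographics_csv: Path,
    report: Optional[ValidationReport] = None,
) -> list[ex.BlockGroupPeriod]:
    """Join block-group geometries with per-period demographic counts.

    The demographics table is keyed by (geoid, period); empty cells mean the
    field is unobserved in that period (e.g. voter data in the earliest
    window).
    """
    report = report if report is not None else ValidationReport()
    feats = read_geojson(geojson_path)
    for fid, feat in feats.items():
        geom = feat["geometry"]
        b = geom.bounds
        _check_projected([b[0], b[2]], [b[1], b[3]], f"geometry {fid}")
        if not geom.is_valid:
            report.warn(f"repaired_geometry: block group {fid}")
            feat["geometry"] = geom.buffer(0)

    ddf = pd.read_csv(demographics_csv, dtype={"geoid": str, "period": str})
    if "geoid" not in ddf.columns or "period" not in ddf.columns:
        raise ValueError("demographics table missing geoid/period columns")
    keys = list(zip(ddf["geoid"], ddf["period"]))
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"duplicate (geoid, period) {dup} in demographics table")

    value_cols = [
        c for c in ddf.columns if c not in ("geoid", "period", "county")
    ]
    bgs = []
    for row in ddf.itertuples(index=False):
        if row.geoid not in feats:
            raise ValueError(f"demographics geoid {row.geoid} has no geometry")
        demo = {}
        for c in value_cols:
            v = getattr(row, c)
            if pd.isna(v):
                continue
            demo[c] = float(v)
        race_sum = sum(demo.get(g, 0.0) for g in ex.RACE_GROUPS)
        total = demo.get("total_population", 0.0)
        if total > 0 and abs(race_sum - total) / total > 0.005:
            report.warn(
                f"race_partition: block group {row.geoid} {row.period} race sum "
                f"{race_sum:.0f} != total {total:.0f}"
            )
        bgs.append(
            ex.BlockGroupPeriod(
                geoid=row.geoid, period=row.period,
                geometry=feats[row.geoid]["geometry"],
                demographics=demo,
                county=str(getattr(row, "county", "") or
                           feats[row.geoid]["properties"].get("county", "")),
            )
        )
    return bgs


def write_blockgroups(
    bgs: Sequence[ex.BlockGroupPeriod], geojson_path: Path, demographics_csv: Path
) -> None:
    feats = {}
    for bg in bgs:
        feats[bg.geoid] = (bg.geometry, {"geoid": bg.geoid, "county": bg.county})
    write_geojson(geojson_path, feats)
    all_fields = sorted({f for bg in bgs for f in bg.demographics})
    rows = []
    for bg in bgs:
        row = {"geoid": bg.geoid, "period": bg.period, "county": bg.county}
        row.update({f: bg.demographics.get(f, "") for f in all_fields})
        rows.append(row)
    pd.DataFrame(rows, columns=["geoid", "period", "county"] + all_fields).to_csv(
        demographics_csv, index=False
    )


def write_assignments(assignments: Sequence[StageAssignment], path: Path) -> None:
    rows = [
        {
            "well_id": a.well_id, "period": a.period,
            "new": int("new" in a.stages),
            "active": int("active" in a.stages),
            "retired": int("retired" in a.stages),
            "plugged": int(a.plugged_flag),
            "retirement_source": a.retirement_source or "",
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows,
        columns=["well_id", "period", "new", "active", "retired", "plugged",
                 "retirement_source"],
    ).to_csv(path, index=False)


def write_exposures(exposures: Sequence[ex.ExposureEstimate], path: Path) -> None:
    fields = sorted({f for e in exposures for f in e.exposed_counts})
    rows = []
    for e in exposures:
        row = {
            "geoid": e.geoid, "period": e.period, "stage": e.stage,
            "exposed_fraction": e.exposed_fraction,
            "centroid_well_count": e.centroid_well_count,
            "centroid_boe": e.centroid_boe,
        }
        row.update({f: e.exposed_counts.get(f, "") for f in fields})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_rr(records: Sequence[ds.RiskRatioRecord], path: Path, round_rr: bool = False) -> None:
    rows = [
        {
            "group": r.group, "stage": r.stage, "period": r.period, "scope": r.scope,
            "group_exposed": r.group_exposed, "group_total": r.group_total,
            "pop_exposed": r.pop_exposed, "pop_total": r.pop_total,
            "rr": ("NA" if r.rr is None else
                   (round(r.rr, 2) if round_rr else r.rr)),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --- run configuration and pipeline ------------------------------------------

@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML file."""

    wells: Path
    production: Path
    geographies: Path
    demographics: Path
    out_dir: Path
    tribal: Optional[Path] = None
    radius_m: float = ex.DEFAULT_RADIUS_M
    periods: tuple[StudyPeriod, ...] = CANONICAL_PERIODS
    reference_year: int = DEFAULT_REFERENCE_YEAR
    idle_years: int = IDLE_YEARS
    scopes: tuple[str, ...] = ("state",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")
        if self.idle_years <= 0:
            raise ValueError("idle_years must be positive")
        years = sorted(self.periods, key=lambda p: p.start_year)
        for a, b in zip(years, years[1:]):
            if b.start_year <= a.end_year:
                raise ValueError(f"periods {a.label} and {b.label} overlap")

    @classmethod
    def from_yaml(cls, path: Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        base = Path(path).parent
        periods = raw.pop("periods", None)
        kwargs = {}
        for key in ("wells", "production", "geographies", "demographics",
                    "tribal", "out_dir"):
            if key in raw:
                p = Path(raw.pop(key))
                kwargs[key] = p if p.is_absolute() else base / p
        for key in ("radius_m", "reference_year", "idle_years", "seed"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        if "scopes" in raw:
            kwargs["scopes"] = tuple(raw.pop("scopes"))
        if periods:
            kwargs["periods"] = tuple(
                StudyPeriod(p["label"], int(p["start_year"]), int(p["end_year"]))
                for p in periods
            )
        raw.pop("landscape", None)  # consumed by `simulate`, not the pipeline
        if raw:
            raise ValueError(f"unknown config keys {sorted(raw)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "wells": str(self.wells), "production": str(self.production),
            "geographies": str(self.geographies),
            "demographics": str(self.demographics),
            "tribal": str(self.tribal) if self.tribal else None,
            "out_dir": str(self.out_dir), "radius_m": self.radius_m,
            "periods": [
                {"label": p.label, "start_year": p.start_year, "end_year": p.end_year}
                for p in self.periods
            ],
            "reference_year": self.reference_year, "idle_years": self.idle_years,
            "scopes": list(self.scopes), "seed": self.seed,
        }


@dataclass
class Dataset:
    wells: list[WellRecord]
    blockgroups: list[ex.BlockGroupPeriod]
    tribal: dict[str, BaseGeometry]
    report: ValidationReport


def load_and_validate(config: RunConfig) -> Dataset:
    """Read and schema-check every input; write a validation report."""
    report = ValidationReport()
    wells = read_wells(config.wells, config.production, report)
    bgs = read_blockgroups(config.geographies, config.demographics, report)
    keys = [(bg.geoid, bg.period) for bg in bgs]
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise ValueError(f"duplicate block group key {dup}")
    tribal: dict[str, BaseGeometry] = {}
    if config.tribal is not None:
        tribal = {
            fid: feat["geometry"]
            for fid, feat in read_geojson(config.tribal).items()
        }
    config.out_dir.mkdir(parents=True, exist_ok=True)
    with open(config.out_dir / "validation_report.json", "w") as fh:
        json.dump(
            {"warnings": report.warnings, "counts": report.counts_by_class()},
            fh, indent=2,
        )
    return Dataset(wells=wells, blockgroups=bgs, tribal=tribal, report=report)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run classification, exposure, and disparity stages end to end.

    Writes every output table plus a manifest carrying the effective config
    and its hash; byte-identical outputs for identical inputs and config.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    data = load_and_validate(config)
    outputs: dict[str, Path] = {"validation": out / "validation_report.json"}

    assignments = assign_stages(
        data.wells, config.periods, config.reference_year, config.idle_years
    )
    outputs["assignments"] = out / "stage_assignments.csv"
    write_assignments(assignments, outputs["assignments"])

    exposures = ex.assess_exposure(
        data.blockgroups, data.wells, assignments, config.periods, config.radius_m
    )
    outputs["exposures"] = out / "exposures.csv"
    write_exposures(exposures, outputs["exposures"])

    rr_records: list[ds.RiskRatioRecord] = []
    for scope in config.scopes:
        rr_records.extend(ds.rr_table(exposures, data.blockgroups, scope=scope))
    outputs["risk_ratios"] = out / "risk_ratios.csv"
    write_rr(rr_records, outputs["risk_ratios"])
    outputs["risk_ratios_report"] = out / "risk_ratios_report.csv"
    write_rr(rr_records, outputs["risk_ratios_report"], round_rr=True)

    quintile_records: list[ds.RiskRatioRecord] = []
    for period in sorted({bg.period for bg in data.blockgroups}):
        quintile_records.extend(
            ds.rr_by_quintile(exposures, data.blockgroups, period)
        )
    outputs["quintile_rr"] = out / "risk_ratios_quintile.csv"
    write_rr(quintile_records, outputs["quintile_rr"])

    labels = [p.label for p in sorted(config.periods, key=lambda p: p.start_year)]
    if len(labels) >= 2:
        p2, p3 = labels[-2], labels[-1]
        idx = {(e.geoid, e.period, e.stage): e for e in exposures}
        geoids_p2 = {bg.geoid for bg in data.blockgroups if bg.period == p2}
        geoids_p3 = {bg.geoid for bg in data.blockgroups if bg.period == p3}
        panel_rows = []
        if geoids_p2 == geoids_p3:
            bgs_later = [bg for bg in data.blockgroups if bg.period == p3]
            for metric, stage, attr in (
                ("new_well_count", "new", "centroid_well_count"),
                ("cumulative_boe", "active", "centroid_boe"),
            ):
                vals = {
                    lbl: {
                        g: float(getattr(idx[(g, lbl, stage)], attr))
                        for g in geoids_p2
                    }
                    for lbl in (p2, p3)
                }
                for rec in ds.panel_change(vals[p2], vals[p3], bgs_later, metric):
                    row = {"metric": rec.metric, "category": rec.category}
                    row.update(rec.demographic_sums)
                    panel_rows.append(row)
        else:
            logger.warning(
                "panel change skipped: block-group sets differ between %s and %s",
                p2, p3,
            )
        outputs["panel_change"] = out / "panel_change.csv"
        pd.DataFrame(panel_rows).to_csv(outputs["panel_change"], index=False)

    if data.tribal:
        counts = ds.tribal_overlay(data.wells, data.tribal)
        outputs["tribal"] = out / "tribal_counts.csv"
        pd.DataFrame(
            [{"polygon": k, "well_count": v} for k, v in counts.items()]
        ).to_csv(outputs["tribal"], index=False)

    trends = ds.summarize_trends(exposures, data.blockgroups)
    outputs["trends"] = out / "trends.csv"
    pd.DataFrame(trends).to_csv(outputs["trends"], index=False)

    cfg = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    outputs["manifest"] = out / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump({"config": cfg, "config_sha256": cfg_hash,
                   "n_wells": len(data.wells),
                   "n_blockgroup_periods": len(data.blockgroups),
                   "warnings": data.report.counts_by_class()}, fh, indent=2)
    return outputs


def simulate_to_dir(
    landscape: LandscapeConfig, out_dir: Path
) -> dict[str, Path]:
    """Generate a synthetic landscape and write it in the pipeline's formats."""
    out_dir.mkdir(parents=True, exist_ok=True)
    wells = generate_wells(landscape)
    bgs = generate_blockgroups(landscape)
    tribal = generate_tribal_lands(landscape)
    paths = {
        "wells": out_dir / "wells.csv",
        "production": out_dir / "production.csv",
        "geographies": out_dir / "blockgroups.geojson",
        "demographics": out_dir / "demographics.csv",
        "tribal": out_dir / "tribal.geojson",
        "manifest": out_dir / "sim_manifest.json",
    }
    write_wells(wells, paths["wells"], paths["production"])
    write_blockgroups(bgs, paths["geographies"], paths["demographics"])
    write_geojson(
        paths["tribal"],
        {k: (geom, {"name": k}) for k, geom in tribal.items()},
    )
    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in landscape.__dict__.items() if k != "periods"}
    cfg["base_shares"] = dict(landscape.base_shares)
    cfg["periods"] = [
        {"label": p.label, "start_year": p.start_year, "end_year": p.end_year}
        for p in landscape.periods
    ]
    with open(paths["manifest"], "w") as fh:
        json.dump({"landscape": cfg, "seed": landscape.seed}, fh, indent=2)
    return paths
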