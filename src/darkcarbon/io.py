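"""File formats, run configuration and pipeline orchestration.

CSV schemas
-----------
``stations.csv``
    station_id, lat, lon, bottom_depth_m, sub_basin
``samples.csv``
    station_id, depth_m, temp_c, salinity, dic_mmol_l, pa_cells_ml, pa_sd,
    php, php_sd, pr, pr_sd, abd, abd_sd, flags — one row per sampled
    depth; empty cells are "not determined" and become absent values,
    never zeros; ``flags`` is a ``;``-separated tag list.
``incubations.csv`` (long format)
    station_id, depth_m, assay ∈ {leu, bic, ets, pa, leu_dilution},
    role ∈ {sample, blank}, value, unit, plus assay-specific columns
    (volume, specific_activity, added_activity, incubation_h, hot_nM,
    cold_nM, added_dpm, dic_mmol_l, t_assay_c, t_insitu_c) — one row per
    replicate measurement.

Run configuration is YAML; the constants block is echoed verbatim into
every output header for provenance.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .constants import ConversionConstants, InvalidInputError
from .integration import integrate_profile
from .profiles import DHAL_FLAG, DepthSample, StationProfile
from .report import metrics_frame, regional_summary, render_station_tables
from .respiration import ETSMeasurement
from .simulate import CampaignObservations
from .tracer import BicarbonateIncubation, DilutionPoint, DilutionSeries, LeucineIncubation

logger = logging.getLogger(__name__)


class SchemaError(InvalidInputError):
    """A CSV did not conform to its documented schema."""


_SAMPLE_COLUMNS = [
    "station_id", "depth_m", "temp_c", "salinity", "dic_mmol_l",
    "pa_cells_ml", "pa_sd", "php", "php_sd", "pr", "pr_sd", "abd", "abd_sd", "flags",
]
_STATION_COLUMNS = ["station_id", "lat", "lon", "bottom_depth_m", "sub_basin"]


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def profiles_from_frames(
    samples: pd.DataFrame, stations: Optional[pd.DataFrame] = None
) -> list[StationProfile]:
    """Validated station profiles from samples (+ optional station metadata).

    Malformed rows are reported with their line numbers (header = line 1).
    """
    missing = [c for c in _SAMPLE_COLUMNS if c not in samples.columns and c != "flags"]
    if missing:
        raise SchemaError(f"samples table missing columns: {missing}")
    unknown = [c for c in samples.columns if c not in _SAMPLE_COLUMNS]
    if unknown:
        raise SchemaError(f"samples table has unknown columns: {unknown}")
    if samples.empty:
        raise SchemaError("samples table is empty")

    meta: dict[str, dict] = {}
    if stations is not None:
        missing = [c for c in _STATION_COLUMNS if c not in stations.columns]
        if missing:
            raise SchemaError(f"stations table missing columns: {missing}")
        meta = {str(r["station_id"]): r for r in stations.to_dict("records")}

    bad: list[str] = []
    profiles: list[StationProfile] = []
    for sid, group in samples.groupby("station_id", sort=False):
        depths = group["depth_m"].to_numpy(dtype=float)
        for offset, (idx, z) in enumerate(zip(group.index, depths)):
            line = int(idx) + 2  # header line + 1-based
            if z < 0:
                bad.append(f"line {line}: negative depth {z}")
            if offset > 0 and z <= depths[offset - 1]:
                bad.append(f"line {line}: depth {z} not strictly ascending within {sid}")
        if bad:
            continue
        station_meta = meta.get(str(sid), {})
        bottom = station_meta.get("bottom_depth_m", float(depths.max()))
        samples_list = []
        for rec in group.to_dict("records"):
            flags = str(rec.get("flags") or "")
            samples_list.append(
                DepthSample(
                    station_id=str(sid),
                    depth=float(rec["depth_m"]),
                    temperature=_opt(rec["temp_c"]),
                    salinity=_opt(rec["salinity"]),
                    dic=_opt(rec["dic_mmol_l"]),
                    pa=_opt(rec["pa_cells_ml"]),
                    pa_sd=_opt(rec["pa_sd"]),
                    php=_opt(rec["php"]),
                    php_sd=_opt(rec["php_sd"]),
                    pr=_opt(rec["pr"]),
                    pr_sd=_opt(rec["pr_sd"]),
                    abd=_opt(rec["abd"]),
                    abd_sd=_opt(rec["abd_sd"]),
                    flags=frozenset(f for f in flags.split(";") if f),
                )
            )
        profiles.append(
            StationProfile(
                station_id=str(sid),
                bottom_depth=float(bottom),
                samples=samples_list,
                latitude=_opt(station_meta.get("lat", np.nan)),
                longitude=_opt(station_meta.get("lon", np.nan)),
                sub_basin=station_meta.get("sub_basin"),
            )
        )
    if bad:
        raise SchemaError("samples table schema violations:\n  " + "\n  ".join(bad))
    return profiles


def load_campaign(
    samples_csv: str | Path, stations_csv: str | Path | None = None
) -> list[StationProfile]:
    """Read a campaign from its samples (and optional stations) CSV files."""
    try:
        samples = pd.read_csv(samples_csv, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{samples_csv}: empty file") from exc
    if "flags" not in samples.columns:
        samples["flags"] = ""
    samples["flags"] = samples["flags"].fillna("")
    stations = pd.read_csv(stations_csv, comment="#") if stations_csv else None
    return profiles_from_frames(samples, stations)


def profiles_to_frame(profiles: Iterable[StationProfile]) -> pd.DataFrame:
    """Inverse of :func:`profiles_from_frames` (samples table only)."""
    rows = []
    for p in profiles:
        for s in p.samples:
            rows.append(
                {
                    "station_id": s.station_id,
                    "depth_m": s.depth,
                    "temp_c": s.temperature,
                    "salinity": s.salinity,
                    "dic_mmol_l": s.dic,
                    "pa_cells_ml": s.pa,
                    "pa_sd": s.pa_sd,
                    "php": s.php,
                    "php_sd": s.php_sd,
                    "pr": s.pr,
                    "pr_sd": s.pr_sd,
                    "abd": s.abd,
                    "abd_sd": s.abd_sd,
                    "flags": ";".join(sorted(s.flags)),
                }
            )
    return pd.DataFrame(rows, columns=_SAMPLE_COLUMNS)


# ---------------------------------------------------------------------------
# Long-format incubation observations (simulation <-> analysis round trip)
# ---------------------------------------------------------------------------

_INCUBATION_COLUMNS = [
    "station_id", "depth_m", "assay", "role", "value", "unit",
    "volume", "specific_activity", "added_activity", "incubation_h",
    "hot_nM", "cold_nM", "added_dpm", "dic_mmol_l", "t_assay_c", "t_insitu_c",
    "bottom_depth_m",
]


def observations_to_frame(obs: CampaignObservations) -> pd.DataFrame:
    """Serialise a raw observation set to the long incubation table."""
    rows: list[dict] = []

    def add(depth, assay, role, value, unit, **extra):
        row = {c: None for c in _INCUBATION_COLUMNS}
        row.update(
            station_id=obs.station_id, depth_m=depth, assay=assay, role=role,
            value=value, unit=unit, bottom_depth_m=obs.bottom_depth, **extra,
        )
        rows.append(row)

    for i, z in enumerate(obs.depths):
        leu = obs.leucine[z]
        common = dict(
            volume=leu.sample_volume, specific_activity=leu.specific_activity,
            incubation_h=leu.incubation_time, hot_nM=leu.hot_leucine,
        )
        for v in leu.replicate_dpm:
            add(z, "leu", "sample", v, "DPM", **common)
        for v in leu.blank_dpm:
            add(z, "leu", "blank", v, "DPM", **common)

        bic = obs.bicarbonate[z]
        common = dict(
            volume=bic.sample_volume, specific_activity=bic.specific_activity,
            added_activity=bic.added_activity, incubation_h=bic.incubation_time,
            dic_mmol_l=bic.dic,
        )
        for v in bic.replicate_dpm:
            add(z, "bic", "sample", v, "DPM", **common)
        for v in bic.blank_dpm:
            add(z, "bic", "blank", v, "DPM", **common)

        for m in obs.ets[z]:
            add(z, "ets", "sample", m.ets_assay_rate, "umol O2 m-3 d-1",
                t_assay_c=m.assay_temperature, t_insitu_c=m.insitu_temperature)

        for v in obs.pa_counts[z]:
            add(z, "pa", "sample", v, "cells mL-1", t_insitu_c=obs.temperature[i])

    if obs.dilution_series is not None:
        s = obs.dilution_series
        common = dict(hot_nM=s.hot_conc, incubation_h=s.incubation_time, added_dpm=s.added_dpm)
        for p in s.points:
            for v in p.replicate_dpm:
                add(obs.depths[0], "leu_dilution", "sample", v, "DPM", cold_nM=p.cold_conc, **common)
            for v in p.blank_dpm:
                add(obs.depths[0], "leu_dilution", "blank", v, "DPM", cold_nM=p.cold_conc, **common)
    return pd.DataFrame(rows, columns=_INCUBATION_COLUMNS)


def observations_from_frame(df: pd.DataFrame) -> CampaignObservations:
    """Rebuild a raw observation set from the long incubation table."""
    missing = [c for c in _INCUBATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"incubation table missing columns: {missing}")
    sids = df["station_id"].unique()
    if len(sids) != 1:
        raise SchemaError(f"expected a single station per observation table, got {list(sids)}")
    sid = str(sids[0])
    bottom = float(df["bottom_depth_m"].iloc[0])

    leucine: dict[float, LeucineIncubation] = {}
    bicarbonate: dict[float, BicarbonateIncubation] = {}
    ets: dict[float, list[ETSMeasurement]] = {}
    pa_counts: dict[float, list[float]] = {}
    temperature: dict[float, float] = {}

    core = df[df["assay"] != "leu_dilution"]
    dic = None
    for (z, assay), g in core.groupby(["depth_m", "assay"]):
        z = float(z)
        samples = g[g["role"] == "sample"]["value"].astype(float).tolist()
        blanks = g[g["role"] == "blank"]["value"].astype(float).tolist()
        first = g.iloc[0]
        if assay == "leu":
            leucine[z] = LeucineIncubation(
                replicate_dpm=samples, blank_dpm=blanks,
                sample_volume=float(first["volume"]),
                hot_leucine=float(first["hot_nM"]),
                specific_activity=float(first["specific_activity"]),
                incubation_time=float(first["incubation_h"]),
            )
        elif assay == "bic":
            dic = float(first["dic_mmol_l"])
            bicarbonate[z] = BicarbonateIncubation(
                replicate_dpm=samples, blank_dpm=blanks, dic=dic,
                sample_volume=float(first["volume"]),
                added_activity=float(first["added_activity"]),
                specific_activity=float(first["specific_activity"]),
                incubation_time=float(first["incubation_h"]),
            )
        elif assay == "ets":
            ets[z] = [
                ETSMeasurement(
                    ets_assay_rate=float(r["value"]),
                    assay_temperature=float(r["t_assay_c"]),
                    insitu_temperature=float(r["t_insitu_c"]),
                )
                for _, r in g.iterrows()
            ]
        elif assay == "pa":
            pa_counts[z] = samples
            temperature[z] = float(first["t_insitu_c"])
        else:
            raise SchemaError(f"unknown assay {assay!r}")

    series = None
    dil = df[df["assay"] == "leu_dilution"]
    if not dil.empty:
        points = []
        for cold, g in dil.groupby("cold_nM"):
            points.append(
                DilutionPoint(
                    cold_conc=float(cold),
                    replicate_dpm=g[g["role"] == "sample"]["value"].astype(float).tolist(),
                    blank_dpm=g[g["role"] == "blank"]["value"].astype(float).tolist(),
                )
            )
        first = dil.iloc[0]
        series = DilutionSeries(
            points=points,
            hot_conc=float(first["hot_nM"]),
            incubation_time=float(first["incubation_h"]),
            added_dpm=float(first["added_dpm"]),
        )

    depths = sorted(leucine)
    return CampaignObservations(
        station_id=sid,
        bottom_depth=bottom,
        depths=depths,
        temperature=[temperature.get(z, float("nan")) for z in depths],
        dic=dic if dic is not None else float("nan"),
        leucine=leucine,
        bicarbonate=bicarbonate,
        ets=ets,
        pa_counts=pa_counts,
        dilution_series=series,
    )


# ---------------------------------------------------------------------------
# Run configuration and the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One pipeline run: inputs, constants overrides and output policy."""

    samples_csv: Optional[str] = None
    stations_csv: Optional[str] = None
    output_dir: str = "darkcarbon_out"
    constants: dict = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=lambda: [DHAL_FLAG])
    z_top: Optional[float] = None
    seed: int = 0
    log_level: str = "INFO"

    def resolve_constants(self) -> ConversionConstants:
        return ConversionConstants.from_dict(self.constants)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        data = {
            "samples_csv": self.samples_csv,
            "stations_csv": self.stations_csv,
            "output_dir": self.output_dir,
            "constants": self.resolve_constants().to_dict(),
            "exclusions": list(self.exclusions),
            "z_top": self.z_top,
            "seed": self.seed,
            "log_level": self.log_level,
        }
        return yaml.safe_dump(data, sort_keys=True)


def _provenance_header(config: RunConfig, inputs: dict[str, str]) -> str:
    """Comment block echoing the full configuration and input hashes."""
    lines = ["# darkcarbon results", "# configuration:"]
    lines += ["#   " + line for line in config.to_yaml().strip().splitlines()]
    for name, path in inputs.items():
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        lines.append(f"# input {name}: {path} sha256:{digest}")
    return "\n".join(lines) + "\n"


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, index=False)
    path.write_text(header + buf.getvalue())


@dataclass
class PipelineResult:
    """Paths and in-memory frames produced by one pipeline run."""

    profiles: list[StationProfile]
    rates: pd.DataFrame
    metrics: pd.DataFrame
    integrals: pd.DataFrame
    regional: Optional[pd.DataFrame]
    output_dir: Path


def run_pipeline(config: RunConfig, phpp: Optional[pd.DataFrame] = None) -> PipelineResult:
    """End to end: load → derive metrics → integrate → report.

    Writes ``rates.csv``, ``metrics.csv``, ``integrals.csv`` and (when a
    photic-production table is supplied) ``regional.csv`` under the
    configured output directory, each prefixed with a provenance header
    carrying the serialised configuration and input-file hashes. Outputs
    are deterministic given inputs + configuration. Station-level
    failures are isolated: a station that cannot be integrated is logged
    and skipped rather than aborting the run.
    """
    if config.samples_csv is None:
        raise InvalidInputError("config.samples_csv is required")
    constants = config.resolve_constants()
    profiles = load_campaign(config.samples_csv, config.stations_csv)

    tables = render_station_tables(profiles, constants)
    metrics = metrics_frame(profiles, constants, exclusions=tuple(config.exclusions))

    integral_rows = []
    for p in profiles:
        for variable in ("abd", "php", "pr"):
            try:
                res = integrate_profile(
                    p, variable, z_top=config.z_top,
                    exclusions=tuple(config.exclusions), constants=constants,
                )
            except InvalidInputError as exc:
                logger.warning("station %s: %s integral skipped: %s", p.station_id, variable, exc)
                continue
            integral_rows.append(
                {
                    "station_id": res.station_id,
                    "variable": res.variable,
                    "z_top_m": res.z_top,
                    "z_bottom_m": res.z_bottom,
                    "integral_mgC_m2_d": res.value,
                    "sd_mgC_m2_d": res.sd,
                    "n_points": res.n_points,
                    "excluded_depths": ";".join(f"{z:g}" for z in res.excluded),
                }
            )
    integrals = pd.DataFrame(integral_rows)

    regional = None
    if phpp is not None:
        regional = regional_summary(profiles, phpp, constants)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = {"samples": config.samples_csv}
    if config.stations_csv:
        inputs["stations"] = config.stations_csv
    header = _provenance_header(config, inputs)
    _write_csv(tables["rates"], out / "rates.csv", header)
    _write_csv(metrics, out / "metrics.csv", header)
    _write_csv(integrals, out / "integrals.csv", header)
    if regional is not None:
        _write_csv(regional, out / "regional.csv", header)

    return PipelineResult(
        profiles=profiles,
        rates=tables["rates"],
        metrics=metrics,
        integrals=integrals,
        regional=regional,
        output_dir=out,
    )
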