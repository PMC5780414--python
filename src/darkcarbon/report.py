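"""Basin-level aggregation and regenerated report tables.

Station integrals and per-depth metrics are rolled up into: the
dark-to-photic production ratio matrix (integrated ABD against both the
in-situ ¹⁴C and biogeochemical-model photic primary production columns),
range summaries with provenance (which station/depth carries the extremum),
and regenerated station tables mirroring the campaign's published layout —
every cell computed from the rate calculus, never copied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import ConversionConstants, DEFAULT_CONSTANTS, InvalidInputError
from .integration import integrate_profile
from .metrics import derive_metrics
from .profiles import DHAL_FLAG, StationProfile

logger = logging.getLogger(__name__)


def abd_to_phpp_ratio(abd_integral: float, phpp: float) -> Optional[float]:
    """Integrated dark DIC fixation as a percentage of photic production.

    Both arguments in mg C m⁻² d⁻¹; the ratio is scale-invariant.
    """
    if phpp <= 0:
        logger.warning("ABD:PhPP ratio undefined: PhPP <= 0")
        return None
    if abd_integral < 0:
        raise InvalidInputError("abd_integral must be >= 0")
    return 100.0 * abd_integral / phpp


@dataclass
class RangeSummary:
    """Extrema of one metric with provenance."""

    metric: str
    min: float
    max: float
    argmin: tuple[str, float]  # (station_id, depth)
    argmax: tuple[str, float]


def summarize_range(
    rows: pd.DataFrame,
    metric: str,
    rounding: Optional[int] = None,
) -> RangeSummary:
    """Min/max of a metric column with (station, depth) provenance.

    ``rows`` must carry ``station_id`` and ``depth`` columns; rows where
    the metric is absent are ignored. ``rounding`` formats the reported
    extrema to that many decimals (the underlying argmin/argmax are
    located on the unrounded values).
    """
    present = rows.dropna(subset=[metric])
    if present.empty:
        raise InvalidInputError(f"no rows with {metric!r} present")
    imin = present[metric].idxmin()
    imax = present[metric].idxmax()
    lo = float(present.loc[imin, metric])
    hi = float(present.loc[imax, metric])
    if rounding is not None:
        lo, hi = round(lo, rounding), round(hi, rounding)
    return RangeSummary(
        metric=metric,
        min=lo,
        max=hi,
        argmin=(str(present.loc[imin, "station_id"]), float(present.loc[imin, "depth"])),
        argmax=(str(present.loc[imax, "station_id"]), float(present.loc[imax, "depth"])),
    )


def metrics_frame(
    profiles: Iterable[StationProfile],
    constants: ConversionConstants = DEFAULT_CONSTANTS,
    exclusions: Sequence[str] = (DHAL_FLAG,),
) -> pd.DataFrame:
    """Per-depth derived metrics for a set of stations, one row per sample.

    Rows carrying an exclusion flag keep their per-depth values but are
    marked ``excluded=True`` so summaries can honour the flags.
    """
    rows = []
    for profile in profiles:
        for s in profile.samples:
            m = derive_metrics(s, constants)
            gt = m.generation_time
            rows.append(
                {
                    "station_id": s.station_id,
                    "depth": s.depth,
                    "pa": s.pa,
                    "php": s.php,
                    "pr": s.pr,
                    "abd": s.abd,
                    "pcd": m.pcd,
                    "pge": m.pge,
                    "cs_pcd": m.cs_pcd,
                    "cs_abd": m.cs_abd,
                    "abd_of_pcd": m.abd_of_pcd,
                    "generation_time_min": gt[0] if gt else None,
                    "generation_time_max": gt[1] if gt else None,
                    "excluded": bool(s.flags.intersection(exclusions)),
                }
            )
    return pd.DataFrame(rows)


def regional_summary(
    profiles: Iterable[StationProfile],
    phpp: pd.DataFrame,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> pd.DataFrame:
    """Dark:photic ratio matrix per station.

    ``phpp`` must carry ``station_id``, ``sub_basin``, ``phpp_insitu`` and
    ``phpp_model`` columns (mg C m⁻² d⁻¹). The returned frame holds the
    recomputed ABD integral and the ratio against *both* photic-production
    columns; published range statements that mix denominators can then be
    read off the full matrix instead of being reproduced silently.
    """
    by_id = {p.station_id: p for p in profiles}
    rows = []
    for rec in phpp.to_dict("records"):
        sid = rec["station_id"]
        if sid not in by_id:
            logger.warning("no profile for station %s; skipping", sid)
            continue
        integral = integrate_profile(by_id[sid], "abd", constants=constants)
        rows.append(
            {
                "station_id": sid,
                "sub_basin": rec.get("sub_basin"),
                "abd_integral": integral.value,
                "abd_integral_sd": integral.sd,
                "phpp_insitu": rec["phpp_insitu"],
                "phpp_model": rec["phpp_model"],
                "ratio_insitu": abd_to_phpp_ratio(integral.value, rec["phpp_insitu"]),
                "ratio_model": abd_to_phpp_ratio(integral.value, rec["phpp_model"]),
            }
        )
    return pd.DataFrame(rows)


def render_station_tables(
    profiles: Iterable[StationProfile],
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> dict[str, pd.DataFrame]:
    """Regenerate the campaign report tables from computed values.

    Returns two frames keyed ``"rates"`` (per-depth hydrography and the
    PHP/PR/ABD triplet) and ``"cell_specific"`` (abundance in 10³ cells
    mL⁻¹ and csPCD/csABD rounded to 2 decimals, the published layout).
    Every numeric cell is computed from the inputs; nothing is copied.
    """
    profiles = list(profiles)
    rate_rows = []
    cs_rows = []
    for profile in profiles:
        for s in profile.samples:
            m = derive_metrics(s, constants)
            rate_rows.append(
                {
                    "station_id": s.station_id,
                    "depth": s.depth,
                    "salinity": s.salinity,
                    "temp_c": s.temperature,
                    "php": s.php,
                    "php_sd": s.php_sd,
                    "pr": s.pr,
                    "pr_sd": s.pr_sd,
                    "abd": s.abd,
                    "abd_sd": s.abd_sd,
                }
            )
            cs_rows.append(
                {
                    "station_id": s.station_id,
                    "depth": s.depth,
                    "pa_1e3_cells_ml": None if s.pa is None else s.pa / 1.0e3,
                    "cs_pcd": None if m.cs_pcd is None else round(m.cs_pcd, 2),
                    "cs_abd": None if m.cs_abd is None else round(m.cs_abd, 2),
                }
            )
    return {
        "rates": pd.DataFrame(rate_rows),
        "cell_specific": pd.DataFrame(cs_rows),
    }
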