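"""Bundled deep-Mediterranean campaign tables.

The package ships, as plain CSV, the processed station tables of a
seven-station Atlantic → Levantine deep-sea transect: per-depth hydrography
and rate triplets (PHP, PR, ABD, µg C m⁻³ d⁻¹) with replicate sds, DAPI
prokaryotic abundances, the published cell-specific values (for regression
comparison), and the literature photic-zone primary production (PhPP) used
for dark:photic ratios. The 3,400 m sample of station ST6 sits at a deep
hypersaline anoxic lake (DHAL) interface and is flagged
``"DHAL-influenced"``: it is carried in the table but excluded from
water-column integrals and basin summaries.

The ambient dissolved inorganic carbon of the deep Mediterranean spans
2.19–2.47 mmol L⁻¹; :data:`MEDITERRANEAN_DIC_RANGE` records that envelope.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .profiles import StationProfile

#: Deep-Mediterranean ambient DIC envelope, mmol L⁻¹.
MEDITERRANEAN_DIC_RANGE: tuple[float, float] = (2.19, 2.47)

#: Default added activity (µCi mL⁻¹) and specific activity (mCi mmol⁻¹)
#: of the dark DIC-fixation incubations.
BICARBONATE_ADDED_ACTIVITY = 0.25
BICARBONATE_SPECIFIC_ACTIVITY = 56.0

#: Mediterranean stations (the Atlantic reference station ST1 is excluded
#: from "Mediterranean" range summaries).
MEDITERRANEAN_STATIONS: tuple[str, ...] = ("ST2", "ST3", "ST4", "ST5", "ST6", "ST7")


def _data_path(name: str):
    return resources.files("darkcarbon.data").joinpath(name)


def stations_table() -> pd.DataFrame:
    """Station metadata: coordinates, bottom depth, sub-basin."""
    with resources.as_file(_data_path("stations.csv")) as p:
        return pd.read_csv(p)


def samples_table() -> pd.DataFrame:
    """Per-depth hydrography, abundances and processed rates (long table)."""
    with resources.as_file(_data_path("samples.csv")) as p:
        df = pd.read_csv(p)
    df["flags"] = df["flags"].fillna("")
    return df


def cell_specific_published() -> pd.DataFrame:
    """As-published csPCD/csABD cells (fg C cell⁻¹ d⁻¹), for comparison only."""
    with resources.as_file(_data_path("cell_specific_published.csv")) as p:
        return pd.read_csv(p)


def phpp_table() -> pd.DataFrame:
    """Literature photic-zone primary production and published ABD integrals.

    One row per Mediterranean station: in-situ ¹⁴C and biogeochemical-model
    PhPP columns (mg C m⁻² d⁻¹ ± sd) and the as-published depth-integrated
    ABD (metadata; the package recomputes its own integrals).
    """
    with resources.as_file(_data_path("phpp.csv")) as p:
        return pd.read_csv(p)


def load_station_profiles() -> list[StationProfile]:
    """The bundled campaign as validated :class:`StationProfile` objects."""
    from .io import profiles_from_frames  # local import: io depends on profiles only

    return profiles_from_frames(samples_table(), stations_table())
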