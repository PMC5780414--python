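"""Depth integration of rate profiles over the aphotic water column.

The integral is the trapezoidal rule over the discrete usable samples at or
below the aphotic top (200 m by default), plus a constant extension from the
deepest sample to the seabed — i.e. rates at the bottom are assumed
identical to those at the deepest sampled depth. No extrapolation is
performed above the shallowest usable sample. Samples with an absent value
or a matching exclusion flag are skipped and recorded on the result.

Uncertainty propagates by the delta method: each sample's total trapezoid
weight w_i (half the span of its neighbouring intervals, plus the bottom
extension for the deepest point) scales its sd, and the weighted sds add in
quadrature — replicate errors at different depths are treated as
independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .constants import ConversionConstants, DEFAULT_CONSTANTS, InvalidInputError
from .profiles import DHAL_FLAG, StationProfile

logger = logging.getLogger(__name__)

_MG_PER_UG = 1.0e-3


@dataclass
class IntegratedRate:
    """Depth-integrated rate for one station and variable, mg C m⁻² d⁻¹."""

    station_id: str
    variable: str
    value: float
    sd: Optional[float]
    z_top: float
    z_bottom: float
    n_points: int
    excluded: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise InvalidInputError("integrated value must be >= 0")
        if not self.z_top < self.z_bottom:
            raise InvalidInputError("z_top must be shallower than z_bottom")
        if self.n_points < 1:
            raise InvalidInputError("need at least one integrated point")


def _usable(profile, variable, z_top, exclusions):
    usable, dropped = profile.usable_samples(variable, z_top=z_top, exclusions=exclusions)
    if not usable:
        raise InvalidInputError(
            f"station {profile.station_id}: no usable {variable} samples at or below {z_top} m"
        )
    if usable[0].depth > z_top:
        logger.warning(
            "station %s: shallowest usable %s sample at %.0f m is below the integration top "
            "%.0f m; integrating from %.0f m (no upward extrapolation)",
            profile.station_id, variable, usable[0].depth, z_top, usable[0].depth,
        )
    return usable, dropped


def trapezoid_weights(depths: Iterable[float], z_bottom: float) -> np.ndarray:
    """Total trapezoid weight of each sample, including the bottom extension.

    For depths z_1 < … < z_n and seabed z_b, the piecewise-linear integral
    Σ (r_i + r_{i+1})/2 · (z_{i+1} − z_i) + r_n · (z_b − z_n) is the dot
    product of the rates with these weights.
    """
    z = np.asarray(list(depths), dtype=float)
    w = np.zeros_like(z)
    if z.size == 1:
        w[0] = z_bottom - z[0]
        return w
    gaps = np.diff(z)
    w[0] = gaps[0] / 2.0
    w[-1] = gaps[-1] / 2.0 + (z_bottom - z[-1])
    if z.size > 2:
        w[1:-1] = (gaps[:-1] + gaps[1:]) / 2.0
    return w


def integrate_profile(
    profile: StationProfile,
    variable: str,
    z_top: Optional[float] = None,
    exclusions: Iterable[str] = (DHAL_FLAG,),
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> IntegratedRate:
    """Trapezoidal depth integral of one rate variable, mg C m⁻² d⁻¹.

    Parameters
    ----------
    profile:
        Station with its per-depth samples.
    variable:
        ``"abd"``, ``"php"`` or ``"pr"``.
    z_top:
        Top of the integration window, m (default: the constants'
        aphotic top, 200 m).
    exclusions:
        Flags whose carriers are dropped (default: DHAL-influenced rows).
    """
    if z_top is None:
        z_top = constants.aphotic_top
    usable, dropped = _usable(profile, variable, z_top, exclusions)
    depths = [s.depth for s in usable]
    rates = np.array([s.rate(variable) for s in usable], dtype=float)
    weights = trapezoid_weights(depths, profile.bottom_depth)
    value = float(rates @ weights) * _MG_PER_UG
    sd = propagate_integral_sd(profile, variable, z_top=z_top, exclusions=exclusions)
    return IntegratedRate(
        station_id=profile.station_id,
        variable=variable,
        value=value,
        sd=sd,
        z_top=float(depths[0]) if depths[0] > z_top else float(z_top),
        z_bottom=float(profile.bottom_depth),
        n_points=len(usable),
        excluded=dropped,
    )


def propagate_integral_sd(
    profile: StationProfile,
    variable: str,
    z_top: Optional[float] = None,
    exclusions: Iterable[str] = (DHAL_FLAG,),
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> Optional[float]:
    """Delta-method sd of the depth integral, mg C m⁻² d⁻¹.

    sqrt(Σ (w_i · sd_i)²) over the usable samples, with w_i the total
    trapezoid weight (bottom extension included). Returns ``None`` when
    any usable sample lacks an sd.
    """
    if z_top is None:
        z_top = constants.aphotic_top
    usable, _ = _usable(profile, variable, z_top, exclusions)
    sds = [s.rate_sd(variable) for s in usable]
    if any(sd is None for sd in sds):
        logger.warning(
            "station %s: missing %s sds; integral uncertainty not propagated",
            profile.station_id, variable,
        )
        return None
    weights = trapezoid_weights([s.depth for s in usable], profile.bottom_depth)
    return float(math.sqrt(float(np.sum((weights * np.asarray(sds, dtype=float)) ** 2)))) * _MG_PER_UG
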