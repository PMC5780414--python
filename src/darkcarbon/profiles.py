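"""Station/depth containers for processed campaign data.

A :class:`StationProfile` is an ordered set of :class:`DepthSample` rows for
one hydrographic station: hydrography, prokaryotic abundance (PA) and the
volumetric rate triplet PHP / PR / ABD, each with its replicate standard
deviation. Rates that were not determined ("ND" in a cruise table) are
``None``, never zero, and propagate as absent through every downstream
computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .constants import InvalidInputError

logger = logging.getLogger(__name__)

#: Flag marking samples taken under the influence of a deep hypersaline
#: anoxic lake (DHAL) interface; such rows are excluded from water-column
#: integrals and station-level summaries.
DHAL_FLAG = "DHAL-influenced"


@dataclass
class DepthSample:
    """One sampled depth at one station.

    Rates are µg C m⁻³ d⁻¹; ``pa`` is cells mL⁻¹; absent values are ``None``.
    ``flags`` carries analysis tags (e.g. ``"DHAL-influenced"``) that mark
    the row for exclusion from station-level summaries and integrals.
    """

    station_id: str
    depth: float
    temperature: Optional[float] = None
    salinity: Optional[float] = None
    dic: Optional[float] = None
    pa: Optional[float] = None
    pa_sd: Optional[float] = None
    php: Optional[float] = None
    php_sd: Optional[float] = None
    pr: Optional[float] = None
    pr_sd: Optional[float] = None
    abd: Optional[float] = None
    abd_sd: Optional[float] = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise InvalidInputError(f"depth must be >= 0, got {self.depth}")
        for name in ("pa", "pa_sd", "php", "php_sd", "pr", "pr_sd", "abd", "abd_sd"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InvalidInputError(f"{name} must be >= 0 when present, got {value}")
        if not isinstance(self.flags, frozenset):
            self.flags = frozenset(self.flags)

    def rate(self, variable: str) -> Optional[float]:
        """Return the named rate (``"php"``, ``"pr"`` or ``"abd"``), or None."""
        if variable not in ("php", "pr", "abd"):
            raise InvalidInputError(f"unknown rate variable {variable!r}")
        return getattr(self, variable)

    def rate_sd(self, variable: str) -> Optional[float]:
        if variable not in ("php", "pr", "abd"):
            raise InvalidInputError(f"unknown rate variable {variable!r}")
        return getattr(self, f"{variable}_sd")

    def is_excluded(self, exclusions: Iterable[str]) -> bool:
        """True if any of this sample's flags match the exclusion set.

        Matches are logged: a flagged row is never dropped silently.
        """
        hit = self.flags.intersection(exclusions)
        if hit:
            logger.info(
                "excluding %s @ %.0f m (flags: %s)", self.station_id, self.depth, ", ".join(sorted(hit))
            )
            return True
        return False


@dataclass
class StationProfile:
    """All samples of one station, strictly ascending in depth."""

    station_id: str
    bottom_depth: float
    samples: list[DepthSample]
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    sub_basin: Optional[str] = None

    def __post_init__(self) -> None:
        if self.bottom_depth <= 0:
            raise InvalidInputError(f"bottom_depth must be > 0, got {self.bottom_depth}")
        depths = [s.depth for s in self.samples]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise InvalidInputError(
                f"station {self.station_id}: sample depths must be strictly ascending, got {depths}"
            )
        if depths and depths[-1] > self.bottom_depth:
            raise InvalidInputError(
                f"station {self.station_id}: deepest sample {depths[-1]} m exceeds "
                f"bottom depth {self.bottom_depth} m"
            )

    @property
    def depths(self) -> list[float]:
        return [s.depth for s in self.samples]

    def sample_at(self, depth: float) -> DepthSample:
        for s in self.samples:
            if s.depth == depth:
                return s
        raise KeyError(f"station {self.station_id} has no sample at {depth} m")

    def usable_samples(
        self,
        variable: str,
        z_top: float = 0.0,
        exclusions: Iterable[str] = (),
    ) -> tuple[list[DepthSample], list[float]]:
        """Samples with the variable present, at/below ``z_top``, not excluded.

        Returns the usable samples and the depths of rows dropped for a
        missing value or a matching exclusion flag (within the depth window).
        """
        usable: list[DepthSample] = []
        dropped: list[float] = []
        exclusions = tuple(exclusions)
        for s in self.samples:
            if s.depth < z_top:
                continue
            if s.rate(variable) is None or s.is_excluded(exclusions):
                dropped.append(s.depth)
                continue
            usable.append(s)
        return usable, dropped
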