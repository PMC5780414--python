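"""Named constants and closed-form conversions of the dark-carbon rate calculus.

Every conversion applied downstream -- radiotracer disintegrations to carbon,
electron-transport activity to respiration, per-cell normalisations -- is
parameterised by a single :class:`ConversionConstants` record so that a run's
provenance is a matter of serialising one object.

Unit conventions used throughout the package:

* volumetric rates (PHP, PR, ABD) in µg C m⁻³ d⁻¹,
* depth-integrated rates in mg C m⁻² d⁻¹,
* cell abundances in cells mL⁻¹, cell-specific rates in fg C cell⁻¹ d⁻¹,
* depths in metres below the surface, positive downward,
* dissolved inorganic carbon (DIC) in mmol L⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any


class InvalidInputError(ValueError):
    """Raised when a physical precondition on an input is violated."""


@dataclass(frozen=True)
class ConversionConstants:
    """The named constants of the rate calculus, with units.

    Attributes
    ----------
    dpm_per_uci:
        Disintegrations per minute per µCi of tracer (2.22×10⁶; from
        1 Ci = 2.22×10¹² DPM).
    carbon_molar_mass:
        µg C per µmol C. Fixed at 12.0 rather than 12.011: that is the
        precision at which every derived quantity is reported.
    leu_to_carbon_base:
        kg C produced per mol leucine incorporated, before isotope
        dilution (the protein-synthesis stoichiometry of the leucine
        tracer method).
    mean_isotope_dilution_leu:
        Dimensionless isotope dilution (ID) of the leucine tracer;
        multiplies the base factor. Deep Mediterranean campaigns give a
        mean of 1.28 (observed range 1.0–1.33).
    ea_ets:
        Arrhenius activation energy for the electron-transport-system
        (ETS) temperature correction, kcal mol⁻¹.
    gas_constant:
        kcal mol⁻¹ K⁻¹.
    pr_to_ets:
        Ratio converting potential ETS activity to in-situ prokaryotic
        respiration (dimensionless).
    c_to_o2_molar:
        mol C respired per mol O₂ consumed (classical remineralisation
        stoichiometry 122/172).
    cell_carbon_range:
        (low, high) carbon content per prokaryotic cell, fg C cell⁻¹;
        used to bracket autotroph generation times.
    aphotic_top:
        Top of the dark water column, m; depth integrations start here.
    """

    dpm_per_uci: float = 2.22e6
    carbon_molar_mass: float = 12.0
    leu_to_carbon_base: float = 1.5
    mean_isotope_dilution_leu: float = 1.28
    ea_ets: float = 15.8
    gas_constant: float = 1.9872e-3
    pr_to_ets: float = 0.68
    c_to_o2_molar: float = 122.0 / 172.0
    cell_carbon_range: tuple[float, float] = (10.0, 20.0)
    aphotic_top: float = 200.0

    def __post_init__(self) -> None:
        for name in (
            "dpm_per_uci",
            "carbon_molar_mass",
            "leu_to_carbon_base",
            "mean_isotope_dilution_leu",
            "ea_ets",
            "gas_constant",
            "pr_to_ets",
            "c_to_o2_molar",
            "aphotic_top",
        ):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidInputError(f"{name} must be strictly positive, got {value!r}")
        low, high = self.cell_carbon_range
        if not (0 < low <= high):
            raise InvalidInputError(
                f"cell_carbon_range must satisfy 0 < low <= high, got {self.cell_carbon_range!r}"
            )
        if self.mean_isotope_dilution_leu < 1:
            raise InvalidInputError("isotope dilution cannot be below 1 (dilution cannot concentrate)")

    @property
    def leucine_cf(self) -> float:
        """Isotope-dilution-corrected leucine conversion factor, kg C mol⁻¹ leu."""
        return leucine_conversion_factor(self.leu_to_carbon_base, self.mean_isotope_dilution_leu)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["cell_carbon_range"] = list(self.cell_carbon_range)
        return d

    @classmethod
    def from_dict(cls, overrides: dict[str, Any] | None) -> "ConversionConstants":
        if not overrides:
            return cls()
        kwargs = dict(overrides)
        if "cell_carbon_range" in kwargs:
            kwargs["cell_carbon_range"] = tuple(kwargs["cell_carbon_range"])
        return cls(**kwargs)


#: Package-wide default constants.
DEFAULT_CONSTANTS = ConversionConstants()


def tracer_concentration(added_activity: float, specific_activity: float) -> float:
    """Concentration of tracer compound implied by an activity addition.

    Parameters
    ----------
    added_activity:
        Final activity in the incubation, µCi mL⁻¹.
    specific_activity:
        Specific activity of the labelled compound, mCi mmol⁻¹.

    Returns
    -------
    float
        Tracer concentration in µmol L⁻¹.

    Examples
    --------
    The standard ¹⁴C-bicarbonate addition of 0.25 µCi mL⁻¹ at
    56.0 mCi mmol⁻¹ corresponds to 4.464 µmol HCO₃⁻ L⁻¹.
    """
    if not added_activity > 0 or not specific_activity > 0:
        raise InvalidInputError("added_activity and specific_activity must both be > 0")
    # (µCi/mL) / (mCi/mmol) = 1e-6 mmol/mL = 1e-3 mmol/L = 1 µmol/L per 1e-3
    return added_activity / specific_activity * 1.0e3


def tracer_isotope_dilution(ambient_pool: float, tracer_conc: float) -> float:
    """Isotopic dilution of an added tracer by the ambient substrate pool.

    Parameters
    ----------
    ambient_pool:
        Ambient (unlabelled) substrate concentration, mmol L⁻¹.
    tracer_conc:
        Added tracer concentration, µmol L⁻¹.

    Returns
    -------
    float
        Dimensionless ratio ambient/tracer on a common unit scale.
    """
    if not ambient_pool > 0 or not tracer_conc > 0:
        raise InvalidInputError("ambient_pool and tracer_conc must both be > 0")
    return ambient_pool * 1.0e3 / tracer_conc


def leucine_conversion_factor(base: float, isotope_dilution: float) -> float:
    """Leucine-to-carbon conversion factor corrected for isotope dilution.

    ``base`` is in kg C mol⁻¹ leucine; the returned factor is
    ``base × ID`` in the same units (1.5 × 1.28 = 1.92 with defaults).
    """
    if not base > 0:
        raise InvalidInputError("base conversion factor must be > 0")
    if isotope_dilution < 1:
        raise InvalidInputError("isotope dilution must be >= 1 (dilution cannot concentrate)")
    return base * isotope_dilution
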