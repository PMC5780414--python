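"""Electron-transport-system (ETS) assays to prokaryotic respiration.

The ETS assay measures potential respiratory electron flux at the assay
temperature; in-situ respiration is obtained by (i) an Arrhenius correction
to the in-situ temperature, (ii) a calibrated PR:ETS ratio relating
potential to realised respiration, and (iii) a remineralisation O₂:C
stoichiometry converting oxygen consumption to carbon respired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import ConversionConstants, DEFAULT_CONSTANTS, InvalidInputError

_KELVIN_OFFSET = 273.15
_MIN_TEMP_C = -2.0
_MAX_TEMP_C = 40.0


@dataclass
class ETSMeasurement:
    """One ETS assay value with its temperature context.

    ``ets_assay_rate`` is in µmol O₂ m⁻³ d⁻¹ at ``assay_temperature``;
    ``filtered_volume`` (L) is retained as metadata only.
    """

    ets_assay_rate: float
    assay_temperature: float  # °C
    insitu_temperature: float  # °C
    filtered_volume: float | None = None

    def __post_init__(self) -> None:
        if self.ets_assay_rate < 0:
            raise InvalidInputError("ets_assay_rate must be >= 0")
        for t in (self.assay_temperature, self.insitu_temperature):
            if not (_MIN_TEMP_C <= t <= _MAX_TEMP_C):
                raise InvalidInputError(
                    f"temperature {t} °C outside the physical assay range "
                    f"[{_MIN_TEMP_C}, {_MAX_TEMP_C}]"
                )


def arrhenius_correct(
    rate: float,
    t_assay: float,
    t_insitu: float,
    ea: float = DEFAULT_CONSTANTS.ea_ets,
    gas_constant: float = DEFAULT_CONSTANTS.gas_constant,
) -> float:
    """Arrhenius temperature correction of a rate from assay to in-situ.

    rate × exp((Ea/R)·(1/T_assay − 1/T_insitu)), temperatures in kelvin.
    The factor is < 1 when the in-situ water is colder than the assay,
    and the correction is its own inverse when the temperatures swap.
    """
    if rate < 0:
        raise InvalidInputError("rate must be >= 0")
    if t_assay <= -_KELVIN_OFFSET or t_insitu <= -_KELVIN_OFFSET:
        raise InvalidInputError("temperatures must be above absolute zero")
    ta = t_assay + _KELVIN_OFFSET
    ti = t_insitu + _KELVIN_OFFSET
    return rate * math.exp((ea / gas_constant) * (1.0 / ta - 1.0 / ti))


def pr_from_ets(
    m: ETSMeasurement, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> float:
    """Prokaryotic respiration (µg C m⁻³ d⁻¹) from an ETS measurement.

    PR_O₂ = Arrhenius-corrected ETS × PR:ETS; PR_C = PR_O₂ × (C:O₂ molar
    ratio) × µg C per µmol.
    """
    corrected = arrhenius_correct(
        m.ets_assay_rate,
        m.assay_temperature,
        m.insitu_temperature,
        ea=constants.ea_ets,
        gas_constant=constants.gas_constant,
    )
    pr_o2 = corrected * constants.pr_to_ets
    return pr_o2 * constants.c_to_o2_molar * constants.carbon_molar_mass


def ets_from_pr(
    pr_c: float,
    assay_temperature: float,
    insitu_temperature: float,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
) -> float:
    """Inverse of :func:`pr_from_ets`: assay-temperature ETS rate implied by a PR.

    Used by the forward simulator to emit raw assay values whose
    processed respiration equals a prescribed truth.
    """
    if pr_c < 0:
        raise InvalidInputError("pr_c must be >= 0")
    pr_o2 = pr_c / (constants.c_to_o2_molar * constants.carbon_molar_mass)
    corrected = pr_o2 / constants.pr_to_ets
    # Undo the assay→in-situ correction by applying it in reverse.
    return arrhenius_correct(
        corrected,
        insitu_temperature,
        assay_temperature,
        ea=constants.ea_ets,
        gas_constant=constants.gas_constant,
    )
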