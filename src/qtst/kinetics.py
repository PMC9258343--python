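"""Transition-state-theory rate constants from log partition functions.

For a unimolecular reaction the TST rate constant is

    k(T) = (k_B T / h) * (Q_TS / Q_R) * exp(-beta * E_a),

with E_a the ground-state energy gap between transition state and reactant
and both partition functions carrying their zero-point energy.  Everything
is assembled on the natural-log scale; the transmission coefficient is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import ValidationError
from .statmech import ThermoState

_HARTREE_J = constants.physical_constants["Hartree energy"][0]
_KJ_PER_MOL_J = 1e3 / constants.N_A

#: accepted activation-energy unit tags -> conversion factor to J
EA_UNITS = {"J": 1.0, "hartree": _HARTREE_J, "kJ/mol": _KJ_PER_MOL_J}


@dataclass(frozen=True)
class RateResult:
    """ln k (k in s^-1) split into prefactor and Arrhenius term."""

    log_k: float
    temperature: float
    log_prefactor: float
    arrhenius_term: float


def ea_to_joule(ea: float, unit: str) -> float:
    """Convert an activation energy to J; the unit tag is mandatory."""
    try:
        return float(ea) * EA_UNITS[unit]
    except KeyError:
        raise ValidationError(
            f"unknown activation-energy unit {unit!r}; expected one of {sorted(EA_UNITS)}"
        ) from None


def log_prefactor_ratio(log_q_ts: float, log_q_r: float) -> float:
    """ln(Q_TS / Q_R), the partition-function part of the TST prefactor."""
    return float(log_q_ts) - float(log_q_r)


def tst_log_rate(
    log_q_ts: float,
    log_q_r: float,
    ea: float,
    state: ThermoState,
    ea_unit: str = "J",
) -> RateResult:
    """ln k^TST = ln(k_B T/h) + ln Q_TS - ln Q_R - E_a/(k_B T).

    Any common additive shift of the two log Q inputs cancels, so the
    translational volume convention does not affect the rate.
    """
    for name, value in (("log_q_ts", log_q_ts), ("log_q_r", log_q_r), ("ea", ea)):
        if not np.isfinite(value):
            raise ValidationError(f"{name} must be finite, got {value}")
    ea_j = ea_to_joule(ea, ea_unit)
    t = state.temperature
    log_prefactor = float(np.log(constants.k * t / constants.h)) + log_prefactor_ratio(
        log_q_ts, log_q_r
    )
    arrhenius = -state.beta * ea_j
    return RateResult(
        log_k=log_prefactor + arrhenius,
        temperature=t,
        log_prefactor=log_prefactor,
        arrhenius_term=arrhenius,
    )
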