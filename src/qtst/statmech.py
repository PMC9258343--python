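"""Rigid-rotor / harmonic-oscillator partition functions on the log scale.

The canonical partition function of a gas-phase species is factorized into
separable electronic, translational, rotational and vibrational terms,

    Q(T) = Q_el(T) * Q_trans(T) * Q_rot(T) * Q_vib(T),

and every term is evaluated as a natural logarithm: across 50-2000 K the
vibrational factor alone spans hundreds of log units, so linear-scale
arithmetic would overflow.  Conventions:

* Q_el is the spin multiplicity (excited electronic states ignored).
* Q_trans uses the ideal-gas volume V = k_B T / p0 with p0 = 1 bar by
  default (configurable; the choice cancels in unimolecular TST ratios).
* Q_rot is the classical rigid-rotor form divided by the symmetry number.
* Q_vib keeps the zero-point energy inside the product, so log Q_vib can be
  negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import constants

from .errors import ValidationError
from .molecular_data import (
    InertiaResult,
    Structure,
    VibrationalPartition,
    classify_modes,
    inertia_analysis,
)
from .symmetry import rotational_symmetry_number

_KB = constants.k
_H = constants.h
_HBAR = constants.hbar
_HC100 = constants.h * constants.c * 100.0  # J per cm^-1

#: standard pressure, Pa (1 bar)
DEFAULT_PRESSURE = 1.0e5
#: temperature range of the reference dataset, K
DATASET_T_RANGE = (50.0, 2000.0)


@dataclass(frozen=True)
class ThermoState:
    """A temperature point plus the translational volume convention."""

    temperature: float
    standard_pressure: float = DEFAULT_PRESSURE

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if self.standard_pressure <= 0:
            raise ValidationError("standard pressure must be > 0 Pa")

    @property
    def beta(self) -> float:
        """1/(k_B T) in 1/J."""
        return 1.0 / (_KB * self.temperature)

    @property
    def in_domain(self) -> bool:
        """Whether T lies inside the 50-2000 K training-data range."""
        lo, hi = DATASET_T_RANGE
        return lo <= self.temperature <= hi


@dataclass(frozen=True)
class PartitionFunctionResult:
    """log Q and its four factor components at one temperature."""

    log_q_el: float
    log_q_trans: float
    log_q_rot: float
    log_q_vib: float
    log_q_total: float
    temperature: float
    structure_id: str = ""


def log_q_electronic(multiplicity: int) -> float:
    """ln of the electronic partition function: the ground-state degeneracy."""
    if multiplicity < 1:
        raise ValidationError(f"multiplicity must be >= 1, got {multiplicity}")
    return float(np.log(multiplicity))


def log_q_translational(total_mass: float, state: ThermoState) -> float:
    """ln Q_trans for a particle of ``total_mass`` (kg) in V = k_B T / p0.

    Q_trans = (2 pi m k_B T / h^2)^{3/2} * V.
    """
    if total_mass <= 0:
        raise ValidationError(f"mass must be > 0 kg, got {total_mass}")
    t = state.temperature
    log_thermal = 1.5 * np.log(2.0 * np.pi * total_mass * _KB * t / _H**2)
    log_volume = np.log(_KB * t / state.standard_pressure)
    return float(log_thermal + log_volume)


def rotational_temperatures(inertia: InertiaResult) -> np.ndarray:
    """theta = hbar^2 / (2 I k_B) per principal moment, in K (inf for I=0)."""
    moments = np.asarray(inertia.principal_moments)
    with np.errstate(divide="ignore"):
        return _HBAR**2 / (2.0 * moments * _KB)


def log_q_rotational(inertia: InertiaResult, sigma: int, state: ThermoState) -> float:
    """ln Q_rot in the classical rigid-rotor approximation.

    Monatomic: 0.  Linear: ln[T / (sigma * theta)] with theta from the
    degenerate moment.  Nonlinear: ln[(sqrt(pi)/sigma) * sqrt(T^3 /
    (theta_A theta_B theta_C))].
    """
    if sigma < 1:
        raise ValidationError(f"sigma must be >= 1, got {sigma}")
    if inertia.is_monatomic:
        return 0.0
    t = state.temperature
    if inertia.is_linear:
        i_degenerate = inertia.principal_moments[2]  # the two large moments coincide
        theta = _HBAR**2 / (2.0 * i_degenerate * _KB)
        return float(np.log(t / (sigma * theta)))
    moments = np.asarray(inertia.principal_moments)
    if np.any(moments <= 0.0):
        raise ValidationError("nonlinear species with a zero principal moment")
    thetas = rotational_temperatures(inertia)
    return float(0.5 * np.log(np.pi) - np.log(sigma) + 0.5 * (3.0 * np.log(t) - np.log(thetas).sum()))


def log_q_vibrational(vp: VibrationalPartition, state: ThermoState) -> float:
    """ln Q_vib with the ZPE inside the product (so the value may be < 0).

    Per mode, with x = h c nu / (k_B T):  -x/2 - ln(1 - exp(-x)).
    """
    modes = np.asarray(vp.real_modes, dtype=float)
    if modes.size == 0:
        return 0.0
    if np.any(modes <= 0.0):
        raise ValidationError("vibrational modes must be positive wavenumbers")
    x = _HC100 * modes / (_KB * state.temperature)
    return float(np.sum(-0.5 * x - np.log1p(-np.exp(-x))))


def total_log_q(
    s: Structure,
    state: ThermoState,
    sigma: int | None = None,
    linear_tol: float = 1e-4,
    spurious_tol: float = 1.0,
) -> PartitionFunctionResult:
    """Assemble ln Q(T) and its components for one structure.

    ``sigma`` may be passed in (e.g. cached per structure); when ``None`` it
    is detected from the geometry.
    """
    inertia = inertia_analysis(s, linear_tol=linear_tol)
    if sigma is None:
        sigma = rotational_symmetry_number(s).sigma
    vp = classify_modes(s, spurious_tol=spurious_tol)
    lq_el = log_q_electronic(s.multiplicity)
    lq_trans = log_q_translational(s.total_mass_kg, state)
    lq_rot = log_q_rotational(inertia, sigma, state)
    lq_vib = log_q_vibrational(vp, state)
    return PartitionFunctionResult(
        log_q_el=lq_el,
        log_q_trans=lq_trans,
        log_q_rot=lq_rot,
        log_q_vib=lq_vib,
        log_q_total=lq_el + lq_trans + lq_rot + lq_vib,
        temperature=state.temperature,
        structure_id=s.id,
    )
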