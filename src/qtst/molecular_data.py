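"""Molecular domain types and geometry/frequency bookkeeping.

Structures are gas-phase species described by element symbols, Cartesian
coordinates in angstrom, harmonic wavenumbers in cm^-1 (a negative value
encodes an imaginary mode) and a ground-state electronic energy in hartree.
The module also provides XYZ round-trip I/O, the center-of-mass inertia
tensor with linearity classification, and the partitioning of the harmonic
spectrum into real modes (which carry zero-point energy) and dropped modes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy import constants

from .errors import ParseError, ValidationError

ROLES = ("reactant", "transition_state", "product")

#: unified atomic mass unit in kg
_AMU_KG = constants.atomic_mass
#: 1 angstrom in m
_ANGSTROM_M = 1e-10

_PERIODIC_TABLE = Chem.GetPeriodicTable()
_MASS_CACHE: dict[str, float] = {}


def atomic_mass(symbol: str) -> float:
    """Standard (isotope-averaged) atomic weight of ``symbol`` in amu.

    Raises :class:`ValidationError` for unknown element symbols.
    """
    try:
        return _MASS_CACHE[symbol]
    except KeyError:
        pass
    try:
        mass = float(_PERIODIC_TABLE.GetAtomicWeight(symbol))
    except Exception as exc:  # RDKit raises RuntimeError for unknown symbols
        raise ValidationError(f"unknown element symbol {symbol!r}") from exc
    _MASS_CACHE[symbol] = mass
    return mass


@dataclass
class Structure:
    """A molecular species: geometry plus optional harmonic frequencies.

    Parameters
    ----------
    atoms:
        Element symbols, one per atom.
    coords:
        ``(N, 3)`` Cartesian coordinates in angstrom.
    frequencies:
        Harmonic wavenumbers in cm^-1; ``None`` until attached.  Negative
        values encode imaginary modes (saddle-point curvature).
    electronic_energy:
        Ground-state electronic energy in hartree, or ``None``.
    multiplicity:
        Spin multiplicity (2S+1), a positive integer.
    role:
        One of ``reactant``, ``transition_state``, ``product``.
    id:
        Opaque identifier used to key dataset rows.
    comment:
        Free-text metadata (the XYZ comment line survives a round trip).
    """

    atoms: tuple[str, ...]
    coords: np.ndarray
    frequencies: tuple[float, ...] | None = None
    electronic_energy: float | None = None
    multiplicity: int = 1
    role: str = "reactant"
    id: str = ""
    comment: str = ""

    def __post_init__(self) -> None:
        self.atoms = tuple(str(a) for a in self.atoms)
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.atoms) < 1:
            raise ValidationError("a structure needs at least one atom")
        if self.coords.shape[0] != len(self.atoms):
            raise ValidationError(
                f"{len(self.atoms)} atoms but {self.coords.shape[0]} coordinate rows"
            )
        for sym in set(self.atoms):
            atomic_mass(sym)
        if self.frequencies is not None:
            self.frequencies = tuple(float(f) for f in self.frequencies)
        if int(self.multiplicity) != self.multiplicity or self.multiplicity < 1:
            raise ValidationError(f"multiplicity must be a positive integer, got {self.multiplicity}")
        self.multiplicity = int(self.multiplicity)
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        """Per-atom masses in amu."""
        return np.array([atomic_mass(a) for a in self.atoms])

    @property
    def total_mass_kg(self) -> float:
        return float(self.masses.sum()) * _AMU_KG

    def with_(self, **kwargs) -> "Structure":
        """A copy with the given fields replaced."""
        return replace(self, **kwargs)

    # --- JSON record round trip (the dataset interchange format) ---

    def to_record(self) -> dict:
        return {
            "id": self.id,
            "atoms": list(self.atoms),
            "coords": self.coords.tolist(),
            "frequencies": list(self.frequencies) if self.frequencies is not None else None,
            "energy": self.electronic_energy,
            "multiplicity": self.multiplicity,
            "role": self.role,
            "comment": self.comment,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Structure":
        return cls(
            atoms=tuple(rec["atoms"]),
            coords=np.asarray(rec["coords"], dtype=float),
            frequencies=tuple(rec["frequencies"]) if rec.get("frequencies") is not None else None,
            electronic_energy=rec.get("energy"),
            multiplicity=rec.get("multiplicity", 1),
            role=rec.get("role", "reactant"),
            id=rec.get("id", ""),
            comment=rec.get("comment", ""),
        )


@dataclass(frozen=True)
class VibrationalPartition:
    """Harmonic modes retained for the vibrational partition function.

    ``zpe`` is the zero-point energy sum(h c nu / 2) over ``real_modes``, in J.
    ``dropped_modes`` holds imaginary and near-zero (spurious) wavenumbers.
    """

    zpe: float
    real_modes: tuple[float, ...]
    dropped_modes: tuple[float, ...]


@dataclass(frozen=True)
class InertiaResult:
    """Principal moments of inertia and the derived shape class.

    ``principal_moments`` is the ascending triple (I_A, I_B, I_C) in kg m^2.
    ``principal_axes`` has the matching eigenvectors as columns.
    """

    principal_moments: tuple[float, float, float]
    is_linear: bool
    is_monatomic: bool
    principal_axes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def read_xyz(text: str) -> Structure:
    """Parse an XYZ-format string (count line, comment, ``symbol x y z`` rows).

    Coordinates are in angstrom.  Frequencies and energy stay unset; attach
    them afterwards (see :func:`read_frequencies`).  Errors name the
    offending line.
    """
    lines = text.splitlines()
    if not lines:
        raise ParseError("empty XYZ input")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise ParseError(f"line 1: expected an integer atom count, got {lines[0]!r}") from exc
    if n < 1:
        raise ParseError(f"line 1: atom count must be >= 1, got {n}")
    if len(lines) < n + 2:
        raise ParseError(f"expected {n + 2} lines for {n} atoms, got {len(lines)}")
    comment = lines[1]
    atoms: list[str] = []
    coords: list[list[float]] = []
    for k in range(n):
        line_no = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise ParseError(f"line {line_no}: expected 'symbol x y z', got {lines[k + 2]!r}")
        sym = parts[0]
        try:
            atomic_mass(sym)
        except ValidationError as exc:
            raise ParseError(f"line {line_no}: {exc}") from exc
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"line {line_no}: non-numeric coordinate in {lines[k + 2]!r}") from exc
        atoms.append(sym)
        coords.append(xyz)
    return Structure(atoms=tuple(atoms), coords=np.array(coords), comment=comment)


def write_xyz(s: Structure, precision: int = 8) -> str:
    """Serialize a structure to XYZ text; inverse of :func:`read_xyz`."""
    rows = [str(s.n_atoms), s.comment]
    for sym, (x, y, z) in zip(s.atoms, s.coords):
        rows.append(f"{sym} {x:.{precision}f} {y:.{precision}f} {z:.{precision}f}")
    return "\n".join(rows) + "\n"


def read_frequencies(text: str) -> tuple[float, ...]:
    """Parse a frequency sidecar: one wavenumber (cm^-1) per line."""
    freqs: list[float] = []
    for i, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        try:
            freqs.append(float(stripped))
        except ValueError as exc:
            raise ParseError(f"line {i}: non-numeric frequency {stripped!r}") from exc
    return tuple(freqs)


def load_structures(path) -> list[Structure]:
    """Load a JSON list of structure records from ``path``."""
    with open(path) as fh:
        records = json.load(fh)
    return [Structure.from_record(rec) for rec in records]


def save_structures(structures: Iterable[Structure], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_record() for s in structures], fh, indent=1)


def center_of_mass(s: Structure) -> np.ndarray:
    """Mass-weighted centroid in angstrom."""
    m = s.masses
    return (m[:, None] * s.coords).sum(axis=0) / m.sum()


def inertia_tensor(s: Structure) -> np.ndarray:
    """Center-of-mass inertia tensor in kg m^2."""
    m = s.masses * _AMU_KG
    r = (s.coords - center_of_mass(s)) * _ANGSTROM_M
    r2 = (r * r).sum(axis=1)
    return np.diag((m * r2).sum() * np.ones(3)) - np.einsum("i,ij,ik->jk", m, r, r)


def inertia_analysis(s: Structure, linear_tol: float = 1e-4) -> InertiaResult:
    """Principal moments of inertia with linear/monatomic classification.

    A species is linear when the smallest-to-largest moment ratio falls
    below ``linear_tol`` (and it has at least two atoms); the two large
    moments are then degenerate.  Moments are invariant under rigid
    rotation/translation of the input coordinates.
    """
    if s.n_atoms == 1:
        return InertiaResult(
            principal_moments=(0.0, 0.0, 0.0),
            is_linear=False,
            is_monatomic=True,
            principal_axes=np.eye(3),
        )
    moments, axes = np.linalg.eigh(inertia_tensor(s))
    moments = np.clip(moments, 0.0, None)
    i_max = moments[2]
    is_linear = bool(i_max > 0 and moments[0] / i_max < linear_tol)
    return InertiaResult(
        principal_moments=(float(moments[0]), float(moments[1]), float(moments[2])),
        is_linear=is_linear,
        is_monatomic=False,
        principal_axes=axes,
    )


def zero_point_energy(modes: Sequence[float]) -> float:
    """ZPE = sum(h c nu / 2) over wavenumbers in cm^-1, returned in J."""
    hc100 = constants.h * constants.c * 100.0  # J per cm^-1
    return 0.5 * hc100 * float(np.sum(modes)) if len(modes) else 0.0


def classify_modes(s: Structure, spurious_tol: float = 1.0) -> VibrationalPartition:
    """Split the harmonic spectrum into real and dropped modes.

    Negative wavenumbers (imaginary modes) are dropped, as are modes with
    ``|nu| < spurious_tol`` cm^-1.  A transition state must carry exactly one
    imaginary mode; a reactant or product must carry none beyond the
    spurious tolerance.  The retained modes define the zero-point energy.
    """
    if s.frequencies is None:
        raise ValidationError(f"structure {s.id!r} has no frequencies attached")
    freqs = np.asarray(s.frequencies, dtype=float)
    imaginary = freqs[freqs < 0.0]
    serious_imaginary = imaginary[np.abs(imaginary) >= spurious_tol]
    if s.role == "transition_state":
        if len(imaginary) != 1:
            raise ValidationError(
                f"transition state {s.id!r} must have exactly one imaginary mode, "
                f"found {len(imaginary)}"
            )
    elif len(serious_imaginary) > 0:
        raise ValidationError(
            f"{s.role} {s.id!r} has {len(serious_imaginary)} imaginary mode(s) "
            f"beyond the {spurious_tol} cm^-1 tolerance"
        )
    keep = (freqs > 0.0) & (np.abs(freqs) >= spurious_tol)
    real_modes = tuple(float(f) for f in freqs[keep])
    dropped = tuple(float(f) for f in freqs[~keep])
    max_real = max(0, 3 * s.n_atoms - 5)
    if len(real_modes) > max_real:
        raise ValidationError(
            f"{s.id!r}: {len(real_modes)} real modes exceeds 3N-5 = {max_real}"
        )
    return VibrationalPartition(
        zpe=zero_point_energy(real_modes),
        real_modes=real_modes,
        dropped_modes=dropped,
    )
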