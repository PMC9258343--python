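"""External rotational symmetry number from invariant point operations.

The rotational partition function is divided by sigma, the number of proper
rotations that map the molecule onto itself (identical nuclei onto identical
nuclei).  Here candidate orthogonal operations are generated from the
principal inertia axes plus axes through atoms, atom-pair midpoints and
atom-pair difference vectors; each candidate is kept when it maps the
centered, element-labeled point set onto itself within a distance tolerance.
Sigma counts the proper (determinant +1) survivors.

Linear molecules are special-cased: the operation set of a linear rotor is
continuous, and a perpendicular C2 of a centrosymmetric linear molecule can
surface as an improper reflection in generic detectors.  Sigma is therefore
decided at the geometry level for linear species: 2 when the atom pattern is
symmetric about the center, else 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .molecular_data import Structure, center_of_mass, inertia_analysis

#: default matching tolerance in angstrom (applied after centering)
DEFAULT_TOL = 0.05

#: rotation orders probed about each candidate axis
_ORDERS = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SymmetryOperation:
    """An orthogonal transform that leaves the molecule invariant."""

    matrix: np.ndarray
    is_proper: bool


@dataclass(frozen=True)
class SymmetryResult:
    """Sigma plus bookkeeping about the detected operation set."""

    sigma: int
    operations_found: int
    proper_count: int
    linear_class: str  # not_linear | linear_sigma1 | linear_sigma2


def _centered_coords(s: Structure) -> np.ndarray:
    return s.coords - center_of_mass(s)


def _maps_onto_itself(coords: np.ndarray, elements: np.ndarray, matrix: np.ndarray, tol: float) -> bool:
    """True when ``matrix`` permutes the labeled point set within ``tol``."""
    transformed = coords @ matrix.T
    n = len(coords)
    taken = np.zeros(n, dtype=bool)
    for i in range(n):
        d = np.linalg.norm(coords - transformed[i], axis=1)
        d[elements != elements[i]] = np.inf
        d[taken] = np.inf
        j = int(np.argmin(d))
        if d[j] > tol:
            return False
        taken[j] = True
    return True


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _reflection_matrix(normal: np.ndarray) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    return np.eye(3) - 2.0 * np.outer(normal, normal)


def _candidate_directions(coords: np.ndarray, axes: np.ndarray) -> list[np.ndarray]:
    """Axis candidates: inertia axes, atom vectors, pair midpoints/differences."""
    cands: list[np.ndarray] = [axes[:, k] for k in range(3)]
    for r in coords:
        cands.append(r)
    for i, j in itertools.combinations(range(len(coords)), 2):
        cands.append(0.5 * (coords[i] + coords[j]))
        cands.append(coords[i] - coords[j])
    unique: list[np.ndarray] = []
    for v in cands:
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        u = v / norm
        if u[np.argmax(np.abs(u))] < 0:  # canonical hemisphere so +-u collapse
            u = -u
        if not any(np.allclose(u, w, atol=1e-6) for w in unique):
            unique.append(u)
    return unique


def detect_invariant_operations(s: Structure, tol: float = DEFAULT_TOL) -> list[SymmetryOperation]:
    """Enumerate orthogonal operations that leave the molecule invariant.

    Candidates are the identity, the inversion, proper rotations C_k^j and
    improper rotations S_k^j about every candidate direction (orders 2..6),
    and reflections through planes normal to every candidate direction.
    Intended for nonlinear polyatomics; linear and monatomic species are
    handled directly by :func:`rotational_symmetry_number`.
    """
    coords = _centered_coords(s)
    if np.linalg.norm(coords, axis=1).max() < 1e-8 and s.n_atoms > 1:
        raise ValidationError("degenerate geometry: all atoms coincide")
    elements = np.asarray(s.atoms)
    axes = inertia_analysis(s).principal_axes

    candidates: list[np.ndarray] = [np.eye(3), -np.eye(3)]
    for direction in _candidate_directions(coords, axes):
        candidates.append(_reflection_matrix(direction))
        for k in _ORDERS:
            for j in range(1, k):
                rot = _rotation_matrix(direction, 2.0 * np.pi * j / k)
                candidates.append(rot)
                candidates.append(_reflection_matrix(direction) @ rot)  # S_k^j

    found: list[SymmetryOperation] = []
    seen: set[bytes] = set()
    for matrix in candidates:
        key = (np.round(matrix, 4) + 0.0).tobytes()  # +0.0 collapses -0.0
        if key in seen:
            continue
        seen.add(key)
        if _maps_onto_itself(coords, elements, matrix, tol):
            found.append(
                SymmetryOperation(matrix=matrix, is_proper=bool(np.linalg.det(matrix) > 0.0))
            )
    return found


def _is_centrosymmetric(s: Structure, tol: float) -> bool:
    coords = _centered_coords(s)
    elements = np.asarray(s.atoms)
    return _maps_onto_itself(coords, elements, -np.eye(3), tol)


def rotational_symmetry_number(s: Structure, tol: float = DEFAULT_TOL) -> SymmetryResult:
    """Sigma for any structure, with the linear-molecule exception.

    Monatomic species have sigma 1.  Linear species have sigma 2 exactly
    when the atom pattern is centrosymmetric (a perpendicular C2 exists),
    else sigma 1 — decided geometrically because the perpendicular C2 of a
    linear rotor is indistinguishable from an improper reflection at the
    level of point operations on collinear nuclei.  Nonlinear species count
    the proper operations found by :func:`detect_invariant_operations`.
    """
    if s.n_atoms == 1:
        return SymmetryResult(sigma=1, operations_found=1, proper_count=1, linear_class="not_linear")
    inertia = inertia_analysis(s)
    if inertia.is_linear:
        if _is_centrosymmetric(s, tol):
            return SymmetryResult(
                sigma=2, operations_found=2, proper_count=2, linear_class="linear_sigma2"
            )
        return SymmetryResult(
            sigma=1, operations_found=1, proper_count=1, linear_class="linear_sigma1"
        )
    ops = detect_invariant_operations(s, tol=tol)
    proper = sum(1 for op in ops if op.is_proper)
    return SymmetryResult(
        sigma=max(1, proper),
        operations_found=len(ops),
        proper_count=proper,
        linear_class="not_linear",
    )
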