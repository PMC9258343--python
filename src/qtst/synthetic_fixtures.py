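"""Desk-scale synthetic molecules, reactions and oracle computations.

Everything downstream (statmech, dataset assembly, featurization, the
estimators) is exercised on generated fixtures with known ground truth, so
no external dataset download is ever required.  The generators plant
structure deliberately — symmetry axes, centrosymmetric linear patterns,
ring scaffolds, linear feature->target maps — so tests can assert recovery
against a known answer.  Fixture geometries use plausible bond lengths but
make no claim of chemical realism: they exercise code paths, not chemistry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy import constants

from .dataset_builder import QDatasetRow, ReactionRecord, derive_seed, sample_temperatures
from .errors import TruncationError, ValidationError
from .featurization import FeatureConfig, difference_features, encoded_bond_features
from .molecular_data import Structure, inertia_analysis
from .statmech import ThermoState, log_q_electronic, log_q_translational

_KB = constants.k
_HBAR = constants.hbar
_HC100 = constants.h * constants.c * 100.0


@dataclass
class FixtureSpec:
    """Generator knobs; defaults mirror the reference-dataset conditions.

    Molecules carry at most ``atom_budget`` heavy atoms (C/N/O), harmonic
    wavenumbers are sampled inside ``frequency_range`` (cm^-1), activation
    energies inside ``ea_range`` (hartree), and each reaction receives
    ``n_temps`` temperatures uniform in 1/T over ``t_range`` (K).
    """

    n_reactions: int = 200
    atom_budget: int = 7
    seed: int = 0
    frequency_range: tuple[float, float] = (200.0, 3500.0)
    imaginary_range: tuple[float, float] = (400.0, 2000.0)
    ea_range: tuple[float, float] = (0.01, 0.12)
    t_range: tuple[float, float] = (50.0, 2000.0)
    n_temps: int = 50


_HEAVY = ("C", "N", "O")


def _sample_frequencies(rng: np.random.Generator, n_atoms: int, spec: FixtureSpec, linear: bool) -> tuple[float, ...]:
    n_modes = max(0, 3 * n_atoms - (5 if linear else 6))
    lo, hi = spec.frequency_range
    return tuple(sorted(rng.uniform(lo, hi, size=n_modes)))


def make_molecule(
    spec: FixtureSpec,
    kind: str,
    seed: int,
    centrosymmetric: bool = False,
) -> Structure:
    """A single structure of a requested symmetry class.

    ``kind`` is one of ``asymmetric`` (random cloud, sigma 1 with
    overwhelming probability), ``symmetric_top`` (planted C3 axis, sigma 3),
    ``linear`` (collinear chain; ``centrosymmetric=True`` plants the
    perpendicular C2 so sigma is 2) or ``monatomic``.
    """
    rng = np.random.default_rng(seed)
    if kind == "monatomic":
        sym = rng.choice(_HEAVY)
        return Structure(atoms=(str(sym),), coords=np.zeros((1, 3)), frequencies=(), id=f"mono{seed}")
    if kind == "linear":
        if centrosymmetric:
            outer = str(rng.choice(_HEAVY))
            center = str(rng.choice(_HEAVY))
            d = rng.uniform(1.1, 1.4)
            atoms = (outer, center, outer)
            coords = np.array([[0.0, 0.0, -d], [0.0, 0.0, 0.0], [0.0, 0.0, d]])
        else:
            atoms = tuple(rng.choice(_HEAVY, size=2, replace=True))
            while atoms[0] == atoms[1]:
                atoms = tuple(rng.choice(_HEAVY, size=2))
            coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, rng.uniform(1.1, 1.4)]])
        s = Structure(atoms=atoms, coords=coords, id=f"lin{seed}")
        return s.with_(frequencies=_sample_frequencies(rng, len(atoms), spec, linear=True))
    if kind == "symmetric_top":
        # central atom with three equivalent ligands 120 degrees apart, plus
        # an apex displacement breaking the horizontal mirror
        center = str(rng.choice(_HEAVY))
        ligand = str(rng.choice(_HEAVY))
        r = rng.uniform(1.2, 1.5)
        z = rng.uniform(0.2, 0.5)
        coords = [[0.0, 0.0, 0.0]]
        atoms = [center]
        for k in range(3):
            ang = 2.0 * math.pi * k / 3.0
            coords.append([r * math.cos(ang), r * math.sin(ang), -z])
            atoms.append(ligand)
        s = Structure(atoms=tuple(atoms), coords=np.array(coords), id=f"top{seed}")
        return s.with_(frequencies=_sample_frequencies(rng, len(atoms), spec, linear=False))
    if kind == "asymmetric":
        n = int(rng.integers(4, spec.atom_budget + 1))
        atoms = tuple(str(a) for a in rng.choice(_HEAVY + ("H",), size=n))
        coords = _random_cloud(rng, n)
        s = Structure(atoms=atoms, coords=coords, id=f"asym{seed}")
        return s.with_(frequencies=_sample_frequencies(rng, n, spec, linear=False))
    raise ValidationError(f"unknown molecule kind {kind!r}")


def _random_cloud(rng: np.random.Generator, n: int, min_dist: float = 0.9, box: float = 3.0) -> np.ndarray:
    coords = [rng.uniform(-box, box, size=3)]
    while len(coords) < n:
        cand = rng.uniform(-box, box, size=3)
        if min(np.linalg.norm(cand - c) for c in coords) >= min_dist:
            coords.append(cand)
    return np.array(coords)


# --- ring-template reactants (distinct Murcko scaffolds) --------------------


def _ring_template(n_ring: int, hetero: tuple[tuple[int, str], ...]) -> tuple[tuple[str, ...], np.ndarray]:
    """Planar ring of ``n_ring`` heavy atoms with radial hydrogens.

    ``hetero`` lists (position, element) substitutions; oxygen positions
    carry no hydrogen.  Ring bond length 1.5 A, X-H 1.09 A.
    """
    bond = 1.5
    radius = bond / (2.0 * math.sin(math.pi / n_ring))
    elems: list[str] = ["C"] * n_ring
    for pos, e in hetero:
        elems[pos] = e
    atoms: list[str] = []
    coords: list[list[float]] = []
    for k in range(n_ring):
        ang = 2.0 * math.pi * k / n_ring
        atoms.append(elems[k])
        coords.append([radius * math.cos(ang), radius * math.sin(ang), 0.0])
    for k in range(n_ring):
        if elems[k] == "O":
            continue
        ang = 2.0 * math.pi * k / n_ring
        r_h = radius + 1.09
        atoms.append("H")
        coords.append([r_h * math.cos(ang), r_h * math.sin(ang), 0.0])
    return tuple(atoms), np.array(coords)


def _chain_template(n_heavy: int) -> tuple[tuple[str, ...], np.ndarray]:
    """Tetrahedral zig-zag acyclic chain (empty Murcko scaffold).

    Bond lengths and H placement match the ring templates so that acyclic
    species occupy the same region of descriptor space as the rings.
    """
    bond = 1.5
    step_x = bond * math.sin(math.radians(109.5) / 2.0)
    step_y = bond * math.cos(math.radians(109.5) / 2.0)
    atoms: list[str] = []
    coords: list[list[float]] = []
    for k in range(n_heavy):
        atoms.append("C")
        coords.append([step_x * k, step_y * (k % 2), 0.0])
        atoms.append("H")
        coords.append([step_x * k, step_y * (k % 2) + (1.09 if k % 2 else -1.09), 0.4])
    return tuple(atoms), np.array(coords)


def _sample_reactant_template(
    rng: np.random.Generator, atom_budget: int
) -> tuple[tuple[str, ...], np.ndarray]:
    """Random ring (or chain) reactant with random heteroatom substitution.

    Every element-pair distance channel is populated across many different
    scaffolds, so a feature->target map planted on one scaffold group stays
    identifiable from the others — the property that makes whole-scaffold
    hold-outs a fair test of the estimators.  Ring scale is jittered, which
    varies distances within a scaffold group without changing its key.
    """
    if rng.random() < 0.12:
        atoms, coords = _chain_template(int(rng.integers(2, min(4, atom_budget) + 1)))
        return atoms, coords + rng.normal(0.0, 0.1, size=coords.shape)
    n_ring = int(rng.integers(3, min(6, atom_budget) + 1))
    hetero: list[tuple[int, str]] = []
    for pos in range(n_ring):
        u = rng.random()
        if u < 0.20:
            hetero.append((pos, "N"))
        elif u < 0.32:
            hetero.append((pos, "O"))
    atoms, coords = _ring_template(n_ring, tuple(hetero))
    coords = coords * rng.uniform(0.9, 1.1)
    # continuous conformational diversity: radial/in-plane jitter plus an
    # out-of-plane pucker, so geometries from different scaffold groups
    # overlap in descriptor space instead of sitting on rigid templates
    coords = coords + rng.normal(0.0, 0.08, size=coords.shape)
    coords[:, 2] += rng.normal(0.0, 0.18, size=len(coords))
    n_sub = int(rng.integers(0, max(1, atom_budget - n_ring) + 1))
    sub_atoms = list(atoms)
    sub_coords = list(coords)
    for _ in range(min(n_sub, 2)):
        anchor = int(rng.integers(n_ring))
        direction = coords[anchor] / max(np.linalg.norm(coords[anchor]), 0.5)
        elem = str(rng.choice(_HEAVY))
        pos = coords[anchor] + direction * rng.uniform(1.35, 1.55) + rng.normal(0.0, 0.08, size=3)
        sub_atoms.append(elem)
        sub_coords.append(pos)
    return tuple(sub_atoms), np.array(sub_coords)


def make_reaction_set(spec: FixtureSpec) -> list[ReactionRecord]:
    """Reactions with template reactants, perturbed products, midpoint TSs.

    The reactant is a lightly perturbed scaffold template (so Murcko keys
    vary across the set), the product shares its atoms with displaced
    coordinates, and the TS is the coordinate midpoint.  TS frequencies are
    the reactant's with one mode replaced by a sampled imaginary mode.
    """
    reactions: list[ReactionRecord] = []
    for i in range(spec.n_reactions):
        rid = f"rxn{i:05d}"
        rng = np.random.default_rng(derive_seed(spec.seed, rid))
        atoms, base = _sample_reactant_template(rng, spec.atom_budget)
        n = len(atoms)
        r_coords = base + rng.normal(0.0, 0.03, size=(n, 3))
        p_coords = r_coords + rng.normal(0.0, 0.12, size=(n, 3))
        ts_coords = 0.5 * (r_coords + p_coords) + rng.normal(0.0, 0.02, size=(n, 3))
        r_freqs = _sample_frequencies(rng, n, spec, linear=False)
        p_freqs = _sample_frequencies(rng, n, spec, linear=False)
        ts_freqs = list(r_freqs)
        ts_freqs.pop(int(rng.integers(len(ts_freqs))))
        ts_freqs.append(-float(rng.uniform(*spec.imaginary_range)))
        e_reactant = float(rng.uniform(-300.0, -100.0))
        ea = float(rng.uniform(*spec.ea_range))
        reactant = Structure(
            atoms=atoms, coords=r_coords, frequencies=r_freqs,
            electronic_energy=e_reactant, role="reactant", id=f"{rid}_r",
        )
        ts = Structure(
            atoms=atoms, coords=ts_coords, frequencies=tuple(ts_freqs),
            electronic_energy=e_reactant + ea, role="transition_state", id=f"{rid}_ts",
        )
        product = Structure(
            atoms=atoms, coords=p_coords, frequencies=p_freqs,
            electronic_energy=e_reactant + float(rng.uniform(-0.05, 0.05)), role="product", id=f"{rid}_p",
        )
        temps = sample_temperatures(spec.n_temps, *spec.t_range, seed=derive_seed(spec.seed, rid + ":T"))
        reactions.append(
            ReactionRecord(
                reaction_id=rid, reactant=reactant, ts=ts, product=product,
                ea=ea, temperatures=tuple(temps),
            )
        )
    return reactions


# --- brute-force state-sum oracle ------------------------------------------


def make_toy_rotor(seed: int, n_atoms: int = 2, min_inertia_amu_a2: float = 180.0) -> Structure:
    """A heavy toy diatomic or linear triatomic for oracle comparisons.

    Separations are drawn long (several angstrom) and resampled until the
    moment of inertia exceeds ``min_inertia_amu_a2``, keeping the
    rotational temperature near 0.1 K.  The classical rigid-rotor closed
    form then agrees with the quantum level sum to O(theta/3T) < 1e-3 even
    at 100 K, so the comparison isolates implementation error rather than
    the (physical) quantum correction.
    """
    if n_atoms not in (2, 3):
        raise ValidationError("toy rotors are diatomic or linear triatomic")
    rng = np.random.default_rng(seed)
    amu_a2 = constants.atomic_mass * 1e-20
    while True:
        atoms = tuple(str(a) for a in rng.choice(_HEAVY, size=n_atoms))
        if n_atoms == 2:
            z = np.array([0.0, rng.uniform(5.0, 6.5)])
        else:
            d1, d2 = rng.uniform(2.5, 3.5, size=2)
            z = np.array([0.0, d1, d1 + d2])
        coords = np.zeros((n_atoms, 3))
        coords[:, 2] = z
        s = Structure(atoms=atoms, coords=coords, id=f"toy{seed}")
        inertia = inertia_analysis(s)
        if inertia.principal_moments[2] / amu_a2 >= min_inertia_amu_a2:
            break
    n_modes = 3 * n_atoms - 5
    freqs = tuple(sorted(rng.uniform(300.0, 3000.0, size=n_modes)))
    return s.with_(frequencies=freqs)


def state_sum_oracle(
    s: Structure,
    temperature: float,
    v_max: int = 300,
    j_max: int = 3000,
    sigma: int = 1,
    standard_pressure: float = 1.0e5,
) -> float:
    """ln Q by direct Boltzmann summation over vibrational/rotational levels.

    Vibrational: product over modes of sum_n exp(-beta h c nu (n + 1/2)) up
    to ``v_max`` quanta (the ZPE-in-Q convention).  Rotational (linear
    species): sum_J (2J+1) exp(-theta J(J+1)/T) / sigma up to ``j_max``.
    Translational and electronic factors use their exact closed forms.
    Raises :class:`TruncationError` when the last retained term exceeds
    1e-12 of its sum.  Supports monatomic and linear species only — which
    is what makes it an independent check of the closed forms.
    """
    state = ThermoState(temperature, standard_pressure)
    total = log_q_electronic(s.multiplicity) + log_q_translational(s.total_mass_kg, state)
    inertia = inertia_analysis(s)
    if not (inertia.is_monatomic or inertia.is_linear):
        raise ValidationError("state-sum oracle handles monatomic and linear species only")

    if not inertia.is_monatomic:
        theta = _HBAR**2 / (2.0 * inertia.principal_moments[2] * _KB)
        j = np.arange(j_max + 1)
        log_terms = np.log(2.0 * j + 1.0) - theta * j * (j + 1.0) / temperature
        log_rot = logsumexp(log_terms)
        if log_terms[-1] - log_rot > math.log(1e-12):
            raise TruncationError(f"rotational sum not converged at j_max={j_max}")
        total += float(log_rot) - math.log(sigma)

    modes = () if s.frequencies is None else tuple(f for f in s.frequencies if f > 0)
    for nu in modes:
        x = _HC100 * nu / (_KB * temperature)
        n = np.arange(v_max + 1)
        log_terms = -x * (n + 0.5)
        log_vib = logsumexp(log_terms)
        if log_terms[-1] - log_vib > math.log(1e-12):
            raise TruncationError(f"vibrational sum not converged at v_max={v_max}")
        total += float(log_vib)
    return float(total)


# --- planted-structure datasets for estimator recovery ----------------------


def planted_q_dataset(
    reactions: list[ReactionRecord],
    fcfg: FeatureConfig,
    seed: int,
    structural_scale: float = 100.0,
    slope: float = 2000.0,
    intercept: float = 5.0,
) -> list[QDatasetRow]:
    """Rows whose ln Q is a known function of descriptor and temperature.

    ln Q := structural_scale * z + slope * (1/T) + intercept, where z is a
    fixed random smooth pair-distance functional of the geometry,
    standardized across the set: per element-pair channel c a random
    quadratic W_c, with z_raw = sum over atom pairs of W_c(d_ij).  On the
    descriptor grid this is (to kernel accuracy) a fixed low-frequency
    linear map of the encoded-bond vector, so it is learnable from the
    descriptors and — because it is the same functional for every scaffold
    — identifiable across whole-scaffold hold-outs.  Noiseless by
    construction; a temperature-only null model is left with the full
    structural variance.
    """
    rng = np.random.default_rng(seed)
    structures = {s.id: s for r in reactions for s in r.structures}
    ids = sorted(structures)
    coeffs = {
        pair: (rng.normal(0.0, 1.0), rng.normal(0.0, 0.5), rng.normal(0.0, 0.15))
        for pair in fcfg.pairs
    }

    def functional(s: Structure) -> float:
        total = 0.0
        for i in range(s.n_atoms):
            for j in range(i + 1, s.n_atoms):
                a, b, c = coeffs[tuple(sorted((s.atoms[i], s.atoms[j])))]
                d = float(np.linalg.norm(s.coords[i] - s.coords[j]))
                total += a + b * d + c * d * d
        return total

    t = np.array([functional(structures[i]) for i in ids])
    z = (t - t.mean()) / t.std()
    z_of = dict(zip(ids, z))
    rows: list[QDatasetRow] = []
    for r in reactions:
        for s in r.structures:
            for temp in r.temperatures:
                inv_t = 1.0 / temp
                rows.append(
                    QDatasetRow(
                        structure_id=s.id,
                        reaction_id=r.reaction_id,
                        role=s.role,
                        inverse_temperature=inv_t,
                        log_q=structural_scale * z_of[s.id] + slope * inv_t + intercept,
                    )
                )
    return rows


def plant_qests_targets(
    reactions: list[ReactionRecord],
    rows: list[QDatasetRow],
    fcfg: FeatureConfig,
    seed: int,
    diff_scale: float = 20.0,
) -> list[QDatasetRow]:
    """Replace TS rows so ln Q_TS is a known map of the QesTS inputs.

    ln Q_TS := (ln Q_R + ln Q_P)/2 + diff_scale * z_diff, with z_diff a
    fixed random projection of the product-minus-reactant descriptor.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(size=fcfg.length) / math.sqrt(fcfg.length)
    lookup = {(r.structure_id, round(r.inverse_temperature, 15)): r.log_q for r in rows}
    diffs = {}
    for r in reactions:
        fv_r = encoded_bond_features(r.reactant, fcfg)
        fv_p = encoded_bond_features(r.product, fcfg)
        diffs[r.reaction_id] = float(difference_features(fv_p, fv_r).values @ w)
    by_reaction = {r.reaction_id: r for r in reactions}
    out: list[QDatasetRow] = []
    for row in rows:
        if row.role != "transition_state":
            out.append(row)
            continue
        reaction = by_reaction[row.reaction_id]
        key_r = (reaction.reactant.id, round(row.inverse_temperature, 15))
        key_p = (reaction.product.id, round(row.inverse_temperature, 15))
        log_q_ts = 0.5 * (lookup[key_r] + lookup[key_p]) + diff_scale * diffs[row.reaction_id]
        out.append(
            QDatasetRow(
                structure_id=row.structure_id,
                reaction_id=row.reaction_id,
                role=row.role,
                inverse_temperature=row.inverse_temperature,
                log_q=log_q_ts,
            )
        )
    return out


# --- textbook reference geometries -----------------------------------------


def reference_geometries() -> dict[str, Structure]:
    """Named textbook geometries used in symmetry and statmech checks."""
    geoms: dict[str, Structure] = {}

    geoms["co"] = Structure(atoms=("C", "O"), coords=[[0, 0, 0], [0, 0, 1.128]], id="co")
    geoms["co2"] = Structure(
        atoms=("O", "C", "O"), coords=[[0, 0, -1.16], [0, 0, 0], [0, 0, 1.16]], id="co2"
    )

    # water: OH 0.9572 A, HOH 104.52 deg
    ang = math.radians(104.52 / 2.0)
    geoms["water"] = Structure(
        atoms=("O", "H", "H"),
        coords=[
            [0.0, 0.0, 0.0],
            [0.9572 * math.sin(ang), 0.0, 0.9572 * math.cos(ang)],
            [-0.9572 * math.sin(ang), 0.0, 0.9572 * math.cos(ang)],
        ],
        id="water",
    )

    # ammonia: NH 1.012 A, HNH 106.7 deg -> C3 axis along z
    r_nh = 1.012
    hnh = math.radians(106.7)
    # ligand polar angle from the C3 axis reproducing the HNH angle
    sin_theta = math.sqrt((1.0 - math.cos(hnh)) / 1.5)
    theta = math.asin(min(1.0, sin_theta))
    nh3 = [[0.0, 0.0, 0.0]]
    for k in range(3):
        phi = 2.0 * math.pi * k / 3.0
        nh3.append(
            [
                r_nh * math.sin(theta) * math.cos(phi),
                r_nh * math.sin(theta) * math.sin(phi),
                -r_nh * math.cos(theta),
            ]
        )
    geoms["ammonia"] = Structure(atoms=("N", "H", "H", "H"), coords=np.array(nh3), id="ammonia")

    # methane: tetrahedral, CH 1.089 A
    a = 1.089 / math.sqrt(3.0)
    geoms["methane"] = Structure(
        atoms=("C", "H", "H", "H", "H"),
        coords=[[0, 0, 0], [a, a, a], [a, -a, -a], [-a, a, -a], [-a, -a, a]],
        id="methane",
    )

    # ethene: CC 1.339 A, CH 1.087 A, HCC 121.3 deg, planar
    half_cc = 1.339 / 2.0
    hx = half_cc + 1.087 * math.cos(math.radians(180.0 - 121.3))
    hy = 1.087 * math.sin(math.radians(180.0 - 121.3))
    geoms["ethene"] = Structure(
        atoms=("C", "C", "H", "H", "H", "H"),
        coords=[
            [-half_cc, 0, 0],
            [half_cc, 0, 0],
            [-hx, hy, 0],
            [-hx, -hy, 0],
            [hx, hy, 0],
            [hx, -hy, 0],
        ],
        id="ethene",
    )

    # benzene: CC ring radius 1.397 A, CH 1.084 A, planar D6h
    atoms: list[str] = []
    coords: list[list[float]] = []
    for k in range(6):
        phi = 2.0 * math.pi * k / 6.0
        atoms.append("C")
        coords.append([1.397 * math.cos(phi), 1.397 * math.sin(phi), 0.0])
    for k in range(6):
        phi = 2.0 * math.pi * k / 6.0
        atoms.append("H")
        coords.append([(1.397 + 1.084) * math.cos(phi), (1.397 + 1.084) * math.sin(phi), 0.0])
    geoms["benzene"] = Structure(atoms=tuple(atoms), coords=np.array(coords), id="benzene")

    geoms["helium"] = Structure(atoms=("He",), coords=[[0.0, 0.0, 0.0]], id="helium")
    return geoms
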