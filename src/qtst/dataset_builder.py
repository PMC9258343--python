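"""Assembly of the partition-function training dataset.

A reaction record groups reactant, transition-state and product structures
with an activation energy and a per-reaction set of temperatures sampled
uniformly in 1/T.  The dataset has one row per (structure, temperature)
pair carrying ln Q.  Splitting into a hold-out test set and cross-validation
folds is done by the Bemis-Murcko scaffold of the reactant so that a
molecular backbone never appears on both sides of a split boundary.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ValidationError
from .molecular_data import Structure
from .statmech import ThermoState, total_log_q
from .symmetry import rotational_symmetry_number

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

#: covalent radii in angstrom for bond perception from 3D geometry
_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}
#: multiplicative slack on the radius-sum bond cutoff
DEFAULT_BOND_FACTOR = 1.2


@dataclass
class ReactionRecord:
    """One unimolecular reaction: three structures plus E_a and temperatures."""

    reaction_id: str
    reactant: Structure
    ts: Structure
    product: Structure
    ea: float  # hartree
    temperatures: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        expected = (("reactant", self.reactant), ("transition_state", self.ts), ("product", self.product))
        for want, s in expected:
            if s.role != want:
                raise ValidationError(
                    f"reaction {self.reaction_id!r}: structure {s.id!r} has role {s.role!r}, expected {want!r}"
                )
        self.temperatures = tuple(float(t) for t in self.temperatures)

    @property
    def structures(self) -> tuple[Structure, Structure, Structure]:
        return (self.reactant, self.ts, self.product)


@dataclass
class SplitPlan:
    """Scaffold-grouped hold-out and fold assignment."""

    test_ids: set[str]
    folds: dict[str, int]
    scaffold_key: dict[str, str]

    def to_manifest(self) -> dict:
        fold_lists: dict[str, list[str]] = {}
        for rid, f in sorted(self.folds.items()):
            fold_lists.setdefault(str(f), []).append(rid)
        return {"test": sorted(self.test_ids), "folds": fold_lists, "scaffolds": dict(sorted(self.scaffold_key.items()))}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_manifest(), fh, indent=1)


@dataclass(frozen=True)
class QDatasetRow:
    """One (structure, temperature) observation of ln Q."""

    structure_id: str
    reaction_id: str
    role: str
    inverse_temperature: float  # 1/K
    log_q: float


def rows_to_frame(rows: list[QDatasetRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "structure_id": [r.structure_id for r in rows],
            "reaction_id": [r.reaction_id for r in rows],
            "role": [r.role for r in rows],
            "inv_T_K": [r.inverse_temperature for r in rows],
            "log_q": [r.log_q for r in rows],
        }
    )


def derive_seed(master_seed: int, key: str) -> int:
    """Stable per-key child seed (< 2**31), identical across platforms."""
    digest = hashlib.sha256(f"{master_seed}:{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def sample_temperatures(n: int, t_min: float, t_max: float, seed: int) -> np.ndarray:
    """Draw ``n`` temperatures whose reciprocals are uniform on (1/t_max, 1/t_min)."""
    if not (0 < t_min < t_max):
        raise ValidationError(f"need 0 < t_min < t_max, got ({t_min}, {t_max})")
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    inv = rng.uniform(1.0 / t_max, 1.0 / t_min, size=n)
    return 1.0 / inv


def count_structures(reactions: list[ReactionRecord]) -> int:
    """Number of distinct structures across all reaction records."""
    ids = {s.id for r in reactions for s in r.structures}
    return len(ids)


def build_q_dataset(
    reactions: list[ReactionRecord],
    n_temps: int = 50,
    seed: int = 0,
    t_range: tuple[float, float] = (50.0, 2000.0),
    standard_pressure: float = 1.0e5,
) -> list[QDatasetRow]:
    """Compute ln Q rows: 3 structures x n_temps per reaction.

    Temperatures stored on a record are reused; otherwise each reaction
    samples its own set (uniform in 1/T) from a seed derived per reaction,
    so every reaction sees a unique temperature grid.  Reactions whose
    structures fail validation are skipped with a logged count.
    """
    rows: list[QDatasetRow] = []
    skipped = 0
    for reaction in reactions:
        temps = np.asarray(reaction.temperatures)
        if temps.size == 0:
            temps = sample_temperatures(n_temps, *t_range, seed=derive_seed(seed, reaction.reaction_id))
        try:
            reaction_rows = []
            for s in reaction.structures:
                sigma = rotational_symmetry_number(s).sigma
                for t in temps:
                    res = total_log_q(s, ThermoState(float(t), standard_pressure), sigma=sigma)
                    reaction_rows.append(
                        QDatasetRow(
                            structure_id=s.id,
                            reaction_id=reaction.reaction_id,
                            role=s.role,
                            inverse_temperature=1.0 / float(t),
                            log_q=res.log_q_total,
                        )
                    )
        except ValidationError as exc:
            skipped += 1
            logger.warning("skipping reaction %s: %s", reaction.reaction_id, exc)
            continue
        rows.extend(reaction_rows)
    if skipped:
        logger.warning("skipped %d of %d reactions", skipped, len(reactions))
    return rows


# --- Murcko scaffolds -------------------------------------------------------


def _bonds_from_geometry(s: Structure, factor: float = DEFAULT_BOND_FACTOR) -> list[tuple[int, int]]:
    """Perceive bonds: distance below factor * (sum of covalent radii)."""
    radii = []
    for sym in s.atoms:
        try:
            radii.append(_COVALENT_RADII[sym])
        except KeyError:
            raise ValidationError(f"no covalent radius tabulated for element {sym!r}") from None
    bonds = []
    for i, j in itertools.combinations(range(s.n_atoms), 2):
        cutoff = factor * (radii[i] + radii[j])
        if np.linalg.norm(s.coords[i] - s.coords[j]) <= cutoff:
            bonds.append((i, j))
    return bonds


def _mol_from_geometry(s: Structure, factor: float = DEFAULT_BOND_FACTOR) -> Chem.Mol:
    """RDKit mol with perceived single bonds; not sanitized (TS geometries
    have no well-defined bond orders)."""
    rw = Chem.RWMol()
    for sym in s.atoms:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for i, j in _bonds_from_geometry(s, factor):
        rw.AddBond(i, j, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def _prune_to_scaffold(mol: Chem.Mol) -> Chem.Mol:
    """Bemis-Murcko framework by iterative deletion of terminal atoms.

    Hydrogens go first, then degree-1 heavy atoms are removed until a fixed
    point; what survives is the ring systems plus the linkers between them
    (atoms on a path between rings never reach degree 1).  An acyclic
    molecule prunes to nothing.
    """
    rw = Chem.RWMol(mol)
    h_idx = [a.GetIdx() for a in rw.GetAtoms() if a.GetSymbol() == "H"]
    for idx in sorted(h_idx, reverse=True):
        rw.RemoveAtom(idx)
    while True:
        terminal = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() <= 1]
        if not terminal or rw.GetNumAtoms() == 0:
            break
        if len(terminal) == rw.GetNumAtoms():
            # fully acyclic remainder collapses to the empty scaffold
            return Chem.RWMol().GetMol()
        for idx in sorted(terminal, reverse=True):
            rw.RemoveAtom(idx)
    out = rw.GetMol()
    out.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(out)
    return out


def murcko_scaffold(s: Structure | str, bond_factor: float = DEFAULT_BOND_FACTOR) -> str:
    """Canonical scaffold string of a structure or SMILES.

    Geometry input: connectivity is perceived from covalent-radius distance
    cutoffs and the pruned framework is rendered as canonical SMILES with
    single bonds (bond orders are not assigned — transition states have
    none).  SMILES input keeps its parsed bond orders.  Acyclic molecules
    map to the empty string, which forms one shared split group.
    """
    if isinstance(s, str):
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            raise ValidationError(f"unparsable SMILES {s!r}")
        mol = Chem.AddHs(mol)
    else:
        mol = _mol_from_geometry(s, bond_factor)
    scaffold = _prune_to_scaffold(mol)
    if scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def reference_murcko_scaffold(smiles: str) -> str:
    """RDKit's own Murcko scaffold (SMILES in, canonical SMILES out).

    Used as an independent cross-check of :func:`murcko_scaffold`; note it
    retains bond orders and aromaticity, so compare via ring/atom structure
    or on single-bonded inputs.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparsable SMILES {smiles!r}")
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def scaffold_split(
    reactions: list[ReactionRecord],
    test_frac: float = 0.10,
    n_folds: int = 5,
    seed: int = 0,
    bond_factor: float = DEFAULT_BOND_FACTOR,
) -> SplitPlan:
    """Group reactions by reactant scaffold; assign whole groups to splits.

    Groups are taken largest first (ties shuffled by ``seed``) into the test
    set until it holds at least ``test_frac`` of the reactions; remaining
    groups fill ``n_folds`` folds, always topping up the currently smallest
    fold.  No scaffold ever crosses a split boundary.
    """
    if not (0.0 < test_frac < 1.0):
        raise ValidationError(f"test_frac must be in (0, 1), got {test_frac}")
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    scaffold_key = {r.reaction_id: murcko_scaffold(r.reactant, bond_factor) for r in reactions}
    groups: dict[str, list[str]] = {}
    for rid, key in scaffold_key.items():
        groups.setdefault(key, []).append(rid)
    if len(groups) < n_folds + 1:
        raise ValidationError(
            f"only {len(groups)} scaffold groups for {n_folds} folds plus a hold-out"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)  # random order within size ties
    keys.sort(key=lambda k: -len(groups[k]))  # stable sort keeps the shuffle inside ties

    n_total = len(reactions)
    test_ids: set[str] = set()
    remaining: list[str] = []
    for key in keys:
        if len(test_ids) < test_frac * n_total:
            test_ids.update(groups[key])
        else:
            remaining.append(key)
    fold_sizes = [0] * n_folds
    folds: dict[str, int] = {}
    for key in remaining:
        f = int(np.argmin(fold_sizes))
        for rid in groups[key]:
            folds[rid] = f
        fold_sizes[f] += len(groups[key])
    return SplitPlan(test_ids=test_ids, folds=folds, scaffold_key=scaffold_key)


# --- outlier filtering ------------------------------------------------------


@dataclass
class OutlierReport:
    """Envelope bounds and per-role removal counts."""

    lower_bound: float
    upper_bound: float
    removed_per_role: dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed_per_role.values())


def drop_outliers(
    rows: list[QDatasetRow],
    lower_q: float = 0.0005,
    upper_q: float = 0.9995,
    envelope_rows: list[QDatasetRow] | None = None,
) -> tuple[list[QDatasetRow], OutlierReport]:
    """Remove rows whose ln Q falls outside a quantile envelope.

    The envelope is fitted on ``envelope_rows`` (typically the development
    set) when given, else on ``rows`` themselves, and then applied to all
    rows — extrapolation-limiting, not per-split.
    """
    if not (0.0 <= lower_q < upper_q <= 1.0):
        raise ValidationError(f"need 0 <= lower_q < upper_q <= 1, got ({lower_q}, {upper_q})")
    fit_rows = envelope_rows if envelope_rows is not None else rows
    values = np.array([r.log_q for r in fit_rows])
    if values.size == 0:
        return list(rows), OutlierReport(lower_bound=-np.inf, upper_bound=np.inf)
    lo, hi = np.quantile(values, [lower_q, upper_q])
    if lower_q == 0.0:
        lo = -np.inf
    if upper_q == 1.0:
        hi = np.inf
    kept: list[QDatasetRow] = []
    removed: dict[str, int] = {}
    for r in rows:
        if lo <= r.log_q <= hi:
            kept.append(r)
        else:
            removed[r.role] = removed.get(r.role, 0) + 1
    return kept, OutlierReport(lower_bound=float(lo), upper_bound=float(hi), removed_per_role=removed)
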