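"""Fixed-length 3D featurization and data scaling.

The encoded-bond descriptor is a smoothed histogram of interatomic
distances: one channel per unordered element pair (H-H, H-C, ...), each a
grid of Gaussian kernels over distance.  It depends only on distances, so
it is invariant to rotation, translation and atom ordering, and its length
is fixed regardless of molecular size — which is what lets a single dense
network ingest molecules of different sizes.  A product-minus-reactant
difference vector describes the 3D change along a reaction.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .molecular_data import Structure


@dataclass(frozen=True)
class FeatureConfig:
    """Hyperparameters of the encoded-bond descriptor.

    ``elements`` is the ordered vocabulary; channels are the unordered
    element pairs in canonical (sorted) order.  Distances are binned on
    ``n_centers`` points spanning [r_min, r_max] angstrom with Gaussian
    kernel width ``kernel_width``.
    """

    elements: tuple[str, ...] = ("H", "C", "N", "O")
    r_min: float = 0.0
    r_max: float = 6.0
    n_centers: int = 32
    kernel_width: float = 0.2

    def __post_init__(self) -> None:
        if self.r_min >= self.r_max:
            raise ValidationError("r_min must be < r_max")
        if self.n_centers < 2:
            raise ValidationError("n_centers must be >= 2")
        if self.kernel_width <= 0:
            raise ValidationError("kernel_width must be > 0")

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        """Canonical unordered element pairs (channel order)."""
        return tuple(itertools.combinations_with_replacement(sorted(self.elements), 2))

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_max, self.n_centers)

    @property
    def length(self) -> int:
        return self.n_centers * len(self.pairs)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "elements": list(self.elements),
                "r_min": self.r_min,
                "r_max": self.r_max,
                "n_centers": self.n_centers,
                "kernel_width": self.kernel_width,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_dict(self) -> dict:
        return {
            "elements": list(self.elements),
            "r_min": self.r_min,
            "r_max": self.r_max,
            "n_centers": self.n_centers,
            "kernel_width": self.kernel_width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        return cls(
            elements=tuple(d["elements"]),
            r_min=d["r_min"],
            r_max=d["r_max"],
            n_centers=d["n_centers"],
            kernel_width=d["kernel_width"],
        )


@dataclass(frozen=True)
class FeatureVector:
    """A descriptor tied to its config; ``is_difference`` marks P-R vectors."""

    values: np.ndarray
    config_hash: str
    is_difference: bool = False


def encoded_bond_features(s: Structure, cfg: FeatureConfig) -> FeatureVector:
    """Encoded-bond descriptor of one structure.

    For each unordered element pair (A, B) and grid center r_k the value is
    sum over atom pairs {i, j} with elements {A, B} of
    exp(-(d_ij - r_k)^2 / (2 w^2)).
    """
    unknown = set(s.atoms) - set(cfg.elements)
    if unknown:
        raise ValidationError(
            f"element(s) {sorted(unknown)} outside the featurizer vocabulary {list(cfg.elements)}"
        )
    channel_of = {pair: k for k, pair in enumerate(cfg.pairs)}
    centers = cfg.centers
    out = np.zeros((len(cfg.pairs), cfg.n_centers))
    inv_2w2 = 1.0 / (2.0 * cfg.kernel_width**2)
    for i, j in itertools.combinations(range(s.n_atoms), 2):
        pair = tuple(sorted((s.atoms[i], s.atoms[j])))
        d = np.linalg.norm(s.coords[i] - s.coords[j])
        out[channel_of[pair]] += np.exp(-((d - centers) ** 2) * inv_2w2)
    return FeatureVector(values=out.ravel(), config_hash=cfg.config_hash)


def difference_features(product_fv: FeatureVector, reactant_fv: FeatureVector) -> FeatureVector:
    """Elementwise product-minus-reactant descriptor (the reaction's 3D change)."""
    if product_fv.config_hash != reactant_fv.config_hash:
        raise ValidationError("feature vectors come from different featurizer configs")
    if product_fv.is_difference or reactant_fv.is_difference:
        raise ValidationError("difference of difference vectors is not defined")
    return FeatureVector(
        values=product_fv.values - reactant_fv.values,
        config_hash=product_fv.config_hash,
        is_difference=True,
    )


# --- scalers ----------------------------------------------------------------

SCALER_KINDS = ("minmax_input", "target_norm", "identity")


@dataclass
class ScalerState:
    """Fitted scaling parameters.

    * ``minmax_input``: per-dimension map of the fitted range onto [0, 1];
      constant dimensions map to 0.
    * ``target_norm``: z-score standardization, exactly invertible.
    * ``identity``: pass-through (the no-standardization choice).
    """

    kind: str
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "params": {k: np.asarray(v).tolist() for k, v in self.params.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalerState":
        return cls(kind=d["kind"], params={k: np.asarray(v) for k, v in d["params"].items()})


def fit_scaler(kind: str, data: np.ndarray) -> ScalerState:
    """Fit a scaler on development data only (callers guard against leakage)."""
    if kind not in SCALER_KINDS:
        raise ValidationError(f"unknown scaler kind {kind!r}")
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValidationError("cannot fit a scaler on an empty set")
    if kind == "identity":
        return ScalerState(kind="identity")
    if kind == "minmax_input":
        lo = data.min(axis=0)
        hi = data.max(axis=0)
        span = hi - lo
        # dims numerically constant on the fit set map to 0 for any input:
        # dividing by a vanishing span would wildly amplify out-of-range
        # values on later data (e.g. kernel tails absent from training)
        active = span > 1e-3 * span.max() if span.max() > 0 else span > 0
        span_safe = np.where(active, span, 1.0)
        return ScalerState(
            kind=kind, params={"lo": lo, "span": span_safe, "active": active.astype(float)}
        )
    mean = data.mean()
    std = data.std()
    if std == 0.0:
        std = 1.0
    return ScalerState(kind=kind, params={"mean": np.asarray(mean), "std": np.asarray(std)})


def apply_scaler(state: ScalerState, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if state.kind == "identity":
        return data
    if state.kind == "minmax_input":
        return (data - state.params["lo"]) / state.params["span"] * state.params["active"]
    return (data - state.params["mean"]) / state.params["std"]


def invert_scaler(state: ScalerState, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if state.kind == "identity":
        return data
    if state.kind == "minmax_input":
        return data * state.params["span"] + state.params["lo"]
    return data * state.params["std"] + state.params["mean"]
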