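"""Partition-function regressors: Qest, QesTS, their Double composition,
and the temperature-only null baseline.

Qest maps [encoded-bond descriptor || 1/T] (min-max scaled) to ln Q for any
species.  QesTS maps [product-minus-reactant descriptor || ln Q_R || ln Q_P
|| 1/T] (no input standardization) to ln Q_TS.  Double chains them: Qest
supplies ln Q_R and ln Q_P so that a transition-state partition function —
and hence a TST rate constant — needs no transition-state geometry at all.
Both networks are dense feed-forward regressors trained on z-scored
targets; inference is a deterministic forward pass through stored weights,
so a saved bundle reproduces its predictions exactly.

The null model ln Q = m * (1/T) + b is the benchmark every structural model
must beat; using it for both TS and reactant is equivalent to assuming the
TST prefactor ratio Q_TS/Q_R is 1.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from .dataset_builder import QDatasetRow, ReactionRecord, SplitPlan
from .errors import LeakageError, ValidationError
from .featurization import (
    FeatureConfig,
    ScalerState,
    apply_scaler,
    difference_features,
    encoded_bond_features,
    fit_scaler,
    invert_scaler,
)
from .molecular_data import Structure


@dataclass(frozen=True)
class NetworkSpec:
    """Feed-forward network hyperparameters (recorded in every bundle)."""

    hidden_layers: tuple[int, ...] = (128, 128)
    activation: str = "tanh"
    alpha: float = 1e-3  # L2 regularization strength
    learning_rate: float = 1e-3
    max_iter: int = 600
    batch_size: int = 128
    early_stopping: bool = False
    validation_fraction: float = 0.1
    n_iter_no_change: int = 50
    tol: float = 1e-8
    seed: int = 0


@dataclass
class NullModel:
    """ln Q = m * (1/T) + b fitted by ordinary least squares."""

    slope: float  # K
    intercept: float

    def predict(self, inverse_temperature) -> np.ndarray:
        return self.slope * np.asarray(inverse_temperature, dtype=float) + self.intercept


@dataclass
class EvaluationReport:
    """MAE in absolute log units and as percent of the target spread."""

    mae: float
    mae_pct_of_std: float
    per_bin: list[tuple[float, float, float, int]]  # (bin lo, bin hi, mae, count)
    n_evaluated: int


_ACTIVATIONS = {
    "tanh": np.tanh,
    "relu": lambda x: np.maximum(x, 0.0),
    "logistic": lambda x: 1.0 / (1.0 + np.exp(-x)),
    "identity": lambda x: x,
}


@dataclass
class EstimatorBundle:
    """A trained regressor plus its scalers and provenance metadata.

    ``weights``/``biases`` hold the dense layers; inference is a plain
    forward pass (hidden activations, identity output), so predictions are
    bit-reproducible from a saved bundle.
    """

    kind: str  # qest | qests
    network_spec: NetworkSpec
    input_scaler: ScalerState
    target_scaler: ScalerState
    feature_config: FeatureConfig
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    training_manifest: dict = field(default_factory=dict)

    def predict_raw(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on already-assembled inputs; returns de-normalized values."""
        h = apply_scaler(self.input_scaler, np.atleast_2d(np.asarray(x, dtype=float)))
        act = _ACTIVATIONS[self.network_spec.activation]
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            h = act(h @ w + b)
        out = h @ self.weights[-1] + self.biases[-1]
        return invert_scaler(self.target_scaler, out.ravel())

    def save(self, directory) -> None:
        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "network_spec": asdict(self.network_spec),
                    "training_manifest": self.training_manifest,
                },
                fh,
                indent=1,
            )
        with open(os.path.join(directory, "scalers.json"), "w") as fh:
            json.dump(
                {"input": self.input_scaler.to_dict(), "target": self.target_scaler.to_dict()},
                fh,
            )
        with open(os.path.join(directory, "feature_config.json"), "w") as fh:
            json.dump(self.feature_config.to_dict(), fh)
        with open(os.path.join(directory, "weights.json"), "w") as fh:
            json.dump(
                {
                    "weights": [w.tolist() for w in self.weights],
                    "biases": [b.tolist() for b in self.biases],
                },
                fh,
            )

    @classmethod
    def load(cls, directory) -> "EstimatorBundle":
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        with open(os.path.join(directory, "scalers.json")) as fh:
            scalers = json.load(fh)
        with open(os.path.join(directory, "feature_config.json")) as fh:
            fcfg = FeatureConfig.from_dict(json.load(fh))
        with open(os.path.join(directory, "weights.json")) as fh:
            wb = json.load(fh)
        spec_dict = manifest["network_spec"]
        spec_dict["hidden_layers"] = tuple(spec_dict["hidden_layers"])
        return cls(
            kind=manifest["kind"],
            network_spec=NetworkSpec(**spec_dict),
            input_scaler=ScalerState.from_dict(scalers["input"]),
            target_scaler=ScalerState.from_dict(scalers["target"]),
            feature_config=fcfg,
            weights=[np.asarray(w) for w in wb["weights"]],
            biases=[np.asarray(b) for b in wb["biases"]],
            training_manifest=manifest.get("training_manifest", {}),
        )


def _fit_network(x: np.ndarray, y: np.ndarray, spec: NetworkSpec) -> tuple[list[np.ndarray], list[np.ndarray]]:
    model = MLPRegressor(
        hidden_layer_sizes=spec.hidden_layers,
        activation=spec.activation,
        alpha=spec.alpha,
        learning_rate_init=spec.learning_rate,
        max_iter=spec.max_iter,
        batch_size=min(spec.batch_size, len(x)),
        early_stopping=spec.early_stopping,
        validation_fraction=spec.validation_fraction,
        n_iter_no_change=spec.n_iter_no_change,
        tol=spec.tol,
        random_state=spec.seed,
        solver="adam",
    )
    model.fit(x, y)
    return [np.asarray(w) for w in model.coefs_], [np.asarray(b) for b in model.intercepts_]


def _guard_leakage(rows: Sequence[QDatasetRow], split: SplitPlan, what: str) -> None:
    leaked = sorted({r.reaction_id for r in rows} & split.test_ids)
    if leaked:
        raise LeakageError(f"{what}: hold-out reaction(s) {leaked[:5]} present in training data")


def _feature_cache(structures: Mapping[str, Structure], cfg: FeatureConfig) -> dict[str, np.ndarray]:
    return {sid: encoded_bond_features(s, cfg).values for sid, s in structures.items()}


def train_qest(
    structures: Mapping[str, Structure],
    rows: Sequence[QDatasetRow],
    split: SplitPlan,
    fcfg: FeatureConfig,
    spec: NetworkSpec = NetworkSpec(),
) -> EstimatorBundle:
    """Train the geometry -> ln Q regressor on development rows.

    Inputs are [descriptor || 1/T] under min-max scaling; targets are
    z-scored ln Q.  Any hold-out reaction id among ``rows`` aborts with
    :class:`LeakageError`.
    """
    if not rows:
        raise ValidationError("no training rows")
    _guard_leakage(rows, split, "train_qest")
    feats = _feature_cache(structures, fcfg)
    x = np.stack([np.concatenate([feats[r.structure_id], [r.inverse_temperature]]) for r in rows])
    y = np.array([r.log_q for r in rows])
    input_scaler = fit_scaler("minmax_input", x)
    target_scaler = fit_scaler("target_norm", y)
    weights, biases = _fit_network(apply_scaler(input_scaler, x), apply_scaler(target_scaler, y), spec)
    return EstimatorBundle(
        kind="qest",
        network_spec=spec,
        input_scaler=input_scaler,
        target_scaler=target_scaler,
        feature_config=fcfg,
        weights=weights,
        biases=biases,
        training_manifest={"n_rows": len(rows), "feature_config_hash": fcfg.config_hash},
    )


def predict_qest(bundle: EstimatorBundle, s: Structure, temperature: float) -> float:
    """De-normalized ln Q prediction for one structure at one temperature."""
    if bundle.kind != "qest":
        raise ValidationError(f"expected a qest bundle, got {bundle.kind!r}")
    fv = encoded_bond_features(s, bundle.feature_config)
    x = np.concatenate([fv.values, [1.0 / temperature]])
    return float(bundle.predict_raw(x)[0])


def _qests_design(
    reactions: Sequence[ReactionRecord],
    rows: Sequence[QDatasetRow],
    fcfg: FeatureConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble [diff descriptor || ln Q_R || ln Q_P || 1/T] -> ln Q_TS."""
    lookup = {(r.structure_id, round(r.inverse_temperature, 15)): r.log_q for r in rows}
    xs: list[np.ndarray] = []
    ys: list[float] = []
    for reaction in reactions:
        fv_r = encoded_bond_features(reaction.reactant, fcfg)
        fv_p = encoded_bond_features(reaction.product, fcfg)
        diff = difference_features(fv_p, fv_r).values
        for t in reaction.temperatures:
            inv_t = round(1.0 / t, 15)
            try:
                lq_r = lookup[(reaction.reactant.id, inv_t)]
                lq_p = lookup[(reaction.product.id, inv_t)]
                lq_ts = lookup[(reaction.ts.id, inv_t)]
            except KeyError:
                continue  # rows for this (structure, T) were filtered out
            xs.append(np.concatenate([diff, [lq_r, lq_p, inv_t]]))
            ys.append(lq_ts)
    if not xs:
        raise ValidationError("no (reaction, temperature) pairs with complete rows")
    return np.stack(xs), np.array(ys)


def train_qests(
    reactions: Sequence[ReactionRecord],
    rows: Sequence[QDatasetRow],
    split: SplitPlan,
    fcfg: FeatureConfig,
    spec: NetworkSpec = NetworkSpec(),
) -> EstimatorBundle:
    """Train the (reactant, product, their ln Q, 1/T) -> ln Q_TS regressor.

    Inputs are left unstandardized (identity scaler); targets are z-scored.
    """
    _guard_leakage(rows, split, "train_qests")
    dev_reactions = [r for r in reactions if r.reaction_id not in split.test_ids]
    x, y = _qests_design(dev_reactions, rows, fcfg)
    input_scaler = fit_scaler("identity", x)
    target_scaler = fit_scaler("target_norm", y)
    weights, biases = _fit_network(apply_scaler(input_scaler, x), apply_scaler(target_scaler, y), spec)
    return EstimatorBundle(
        kind="qests",
        network_spec=spec,
        input_scaler=input_scaler,
        target_scaler=target_scaler,
        feature_config=fcfg,
        weights=weights,
        biases=biases,
        training_manifest={"n_rows": len(y), "feature_config_hash": fcfg.config_hash},
    )


def predict_qests(
    bundle: EstimatorBundle,
    reactant: Structure,
    product: Structure,
    log_q_r: float,
    log_q_p: float,
    temperature: float,
) -> float:
    """ln Q_TS from reactant/product geometries and their ln Q values."""
    if bundle.kind != "qests":
        raise ValidationError(f"expected a qests bundle, got {bundle.kind!r}")
    fv_r = encoded_bond_features(reactant, bundle.feature_config)
    fv_p = encoded_bond_features(product, bundle.feature_config)
    diff = difference_features(fv_p, fv_r).values
    x = np.concatenate([diff, [log_q_r, log_q_p, 1.0 / temperature]])
    return float(bundle.predict_raw(x)[0])


def predict_double(
    qest_bundle: EstimatorBundle,
    qests_bundle: EstimatorBundle,
    reactant: Structure,
    product: Structure,
    temperature: float,
) -> float:
    """ln Q_TS from reactant and product geometries alone.

    Qest supplies ln Q_R and ln Q_P, which then feed QesTS together with
    the difference descriptor — no transition-state information anywhere.
    """
    log_q_r = predict_qest(qest_bundle, reactant, temperature)
    log_q_p = predict_qest(qest_bundle, product, temperature)
    return predict_qests(qests_bundle, reactant, product, log_q_r, log_q_p, temperature)


def fit_null_model(rows: Sequence[QDatasetRow]) -> NullModel:
    """OLS fit of ln Q on 1/T across all rows."""
    if len(rows) < 2:
        raise ValidationError("need at least two rows to fit the null model")
    inv_t = np.array([r.inverse_temperature for r in rows])
    y = np.array([r.log_q for r in rows])
    if np.ptp(inv_t) == 0.0:
        raise ValidationError("degenerate design: all rows share one temperature")
    design = np.column_stack([inv_t, np.ones_like(inv_t)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    return NullModel(slope=float(slope), intercept=float(intercept))


def evaluate(
    predictions: Sequence[float],
    truths: Sequence[float],
    inverse_temperatures: Sequence[float] | None = None,
    n_bins: int = 20,
) -> EvaluationReport:
    """MAE, MAE as percent of the truth standard deviation, and per-1/T bins.

    The percent convention divides the MAE by the standard deviation of the
    evaluated targets, so a model that always predicts the target mean of a
    normal population scores sqrt(2/pi) ~ 79.8%.
    """
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValidationError("predictions and truths must be equal-length and non-empty")
    errors = np.abs(predictions - truths)
    mae = float(errors.mean())
    std = float(truths.std())
    pct = float(mae / std * 100.0) if std > 0 else float("inf")
    per_bin: list[tuple[float, float, float, int]] = []
    if inverse_temperatures is not None:
        inv_t = np.asarray(inverse_temperatures, dtype=float)
        edges = np.linspace(inv_t.min(), inv_t.max(), n_bins + 1)
        idx = np.clip(np.digitize(inv_t, edges) - 1, 0, n_bins - 1)
        for b in range(n_bins):
            mask = idx == b
            if mask.any():
                per_bin.append((float(edges[b]), float(edges[b + 1]), float(errors[mask].mean()), int(mask.sum())))
    return EvaluationReport(mae=mae, mae_pct_of_std=pct, per_bin=per_bin, n_evaluated=len(truths))
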