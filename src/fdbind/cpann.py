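"""Counter-propagation ANN regression (CPANN).

A CPANN couples a Kohonen input layer, trained on descriptors, with an
output layer of identical geometry trained toward the targets.  The
winner is always selected in the input layer only; both layers receive
the same learning-rate x neighborhood correction per presentation.  Once
trained, the network acts as a lookup table: a query returns the output
weights of its winning neuron.

Fit quality is reported QSAR-style: R^2 is the squared Pearson
correlation of observed vs. predicted, and the predictive Q^2_cv uses
leave-one-out held-out predictions only.  The residual-based variant
1 - SS_res/SS_tot is carried alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError
from .som import (
    ColumnScaler,
    GridSpec,
    MappingResult,
    SOMModel,
    TrainConfig,
    _as_frame,
    _check_normalized,
    _train_layers,
    winner,
)

__all__ = [
    "CPANNModel",
    "FitMetrics",
    "CVResult",
    "train_cpann",
    "predict",
    "fit_metrics",
    "loo_cv",
    "fold_seed",
]


@dataclass
class CPANNModel:
    som: SOMModel
    output_weights: np.ndarray  # (n_neurons, n_targets) in normalized units
    target_names: list[str]
    target_scaler: ColumnScaler | None = None

    @property
    def n_targets(self) -> int:
        return self.output_weights.shape[1]


@dataclass(frozen=True)
class FitMetrics:
    """Goodness of fit on one set of (observed, predicted) pairs.

    ``r2`` is the squared Pearson correlation; ``r2_resid`` is the
    residual form 1 - SS_res/SS_tot (can be negative for poor fits).
    """

    r2: float
    rmse: float
    n: int
    r2_resid: float

    def summary(self) -> str:
        return (
            f"n={self.n}  R2={self.r2:.4f}  RMSE={self.rmse:.4f}  "
            f"R2_resid={self.r2_resid:.4f}"
        )


@dataclass
class CVResult:
    """Leave-one-out cross-validation output."""

    predictions: pd.DataFrame  # columns: observed, predicted; index: object ids
    q2_cv: float
    rmse_cv: float

    def summary(self) -> str:
        return (
            f"n={len(self.predictions)}  Q2_cv={self.q2_cv:.4f}  "
            f"RMSE_cv={self.rmse_cv:.4f}"
        )


def _as_targets(y) -> pd.DataFrame:
    if isinstance(y, pd.Series):
        return y.to_frame(name=y.name if y.name is not None else "target")
    return _as_frame(y, "targets")


def train_cpann(
    X,
    y,
    grid: GridSpec,
    config: TrainConfig,
    target_scaler: ColumnScaler | None = None,
) -> CPANNModel:
    """Train a CPANN on normalized descriptors X and normalized targets y."""
    Xdf = _as_frame(X, "descriptors")
    Ydf = _as_targets(y)
    if Xdf.shape[0] != Ydf.shape[0]:
        raise InputError(
            f"X has {Xdf.shape[0]} rows but y has {Ydf.shape[0]}; rows must align"
        )
    Xv = Xdf.to_numpy(dtype=float)
    Yv = Ydf.to_numpy(dtype=float)
    _check_normalized(Xv, "descriptor")
    try:
        _check_normalized(Yv, "target")
    except InputError as exc:
        raise InputError(f"{exc} (targets must be min-max normalized)") from None
    W, O = _train_layers(Xv, Yv, grid, config)
    som = SOMModel(
        grid=grid,
        weights=W,
        feature_names=[str(c) for c in Xdf.columns],
        train_config=config,
        trained=True,
    )
    return CPANNModel(
        som=som,
        output_weights=O,
        target_names=[str(c) for c in Ydf.columns],
        target_scaler=target_scaler,
    )


def predict(model: CPANNModel, x, denormalize: bool = False):
    """Look up the output weights of the input-layer winner.

    A 1-D vector returns a 1-D target array; a table returns a DataFrame
    of predictions indexed like the input.  With ``denormalize=True`` the
    stored target scaler maps predictions back to original units.
    """
    xv = np.asarray(x if not isinstance(x, pd.DataFrame) else x.to_numpy(), dtype=float)
    single = xv.ndim == 1
    frame = _as_frame(x) if not single else None
    rows = xv[None, :] if single else xv
    if rows.shape[1] != model.som.n_features:
        raise InputError(
            f"query has {rows.shape[1]} features, model expects {model.som.n_features}"
        )
    out = np.empty((rows.shape[0], model.n_targets))
    for i, row in enumerate(rows):
        res: MappingResult = winner(model.som, row)
        out[i] = model.output_weights[model.som.grid.index(res.neuron)]
    if denormalize:
        if model.target_scaler is None:
            raise InputError("model carries no target scaler; cannot de-normalize")
        frame_out = pd.DataFrame(out, columns=model.target_names)
        out = model.target_scaler.inverse_transform(frame_out).to_numpy()
    if single:
        return out[0]
    return pd.DataFrame(out, index=frame.index, columns=model.target_names)


def fit_metrics(observed, predicted) -> FitMetrics:
    """R^2 (squared Pearson), RMSE and the residual R^2 variant."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.shape[0] != pred.shape[0]:
        raise InputError("observed and predicted must have equal length")
    if obs.shape[0] < 3:
        raise InputError("need at least 3 pairs to compute fit metrics")
    if np.ptp(obs) == 0:
        raise InputError("observed values are constant; correlation undefined")
    cc = sps.pearsonr(obs, pred).statistic if np.ptp(pred) > 0 else 0.0
    resid = obs - pred
    sstot = float(np.sum((obs - obs.mean()) ** 2))
    return FitMetrics(
        r2=float(cc**2),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=int(obs.shape[0]),
        r2_resid=float(1.0 - np.sum(resid**2) / sstot),
    )


def fold_seed(master_seed: int, k: int) -> int:
    """Deterministic per-fold seed for LOO retraining."""
    return int(np.random.SeedSequence([int(master_seed), int(k)]).generate_state(1)[0] % (2**31))


def loo_cv(X, y, grid: GridSpec, config: TrainConfig) -> CVResult:
    """Leave-one-out cross-validation of a single-target CPANN.

    Each fold retrains from scratch on n-1 objects with a seed derived
    from (config.seed, fold index) and predicts the held-out object;
    Q^2_cv and RMSE_cv are computed on the held-out predictions only.
    """
    Xdf = _as_frame(X, "descriptors")
    Ydf = _as_targets(y)
    if Ydf.shape[1] != 1:
        raise InputError("loo_cv supports a single target column")
    if Xdf.shape[0] != Ydf.shape[0]:
        raise InputError("X and y must have the same number of rows")
    n = Xdf.shape[0]
    if n < 3:
        raise InputError(f"leave-one-out needs at least 3 objects, got {n}")
    held_out = np.empty(n)
    Xv = Xdf.to_numpy(dtype=float)
    for k in range(n):
        mask = np.ones(n, dtype=bool)
        mask[k] = False
        fold_config = TrainConfig(
            epochs=config.epochs,
            eta_start=config.eta_start,
            eta_end=config.eta_end,
            radius_start=config.radius_start,
            radius_end=config.radius_end,
            seed=fold_seed(config.seed, k),
        )
        model = train_cpann(Xdf.iloc[mask], Ydf.iloc[mask], grid, fold_config)
        held_out[k] = predict(model, Xv[k])[0]
    obs = Ydf.iloc[:, 0].to_numpy(dtype=float)
    metrics = fit_metrics(obs, held_out)
    predictions = pd.DataFrame(
        {"observed": obs, "predicted": held_out}, index=Xdf.index
    )
    return CVResult(predictions=predictions, q2_cv=metrics.r2, rmse_cv=metrics.rmse)
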