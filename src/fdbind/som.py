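"""Self-organizing (Kohonen) map engine.

A rectangular, planar (non-toroidal) grid of neurons, each carrying a
weight vector in the normalized descriptor space.  Training uses classic
competitive learning: for every presented object the Euclidean-nearest
neuron wins and all neurons within the current neighborhood radius are
pulled toward the object, with a triangular (linearly decaying)
neighborhood on the Chebyshev grid metric.  Learning rate and radius
interpolate linearly from their start to their end values over the
epochs.  All randomness (weight initialization, per-epoch presentation
order) flows from a single integer seed, so training is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InputError

__all__ = [
    "GridSpec",
    "TrainConfig",
    "SOMModel",
    "MappingResult",
    "ColumnScaler",
    "normalize_columns",
    "winner",
    "topo_distance",
    "neighborhood_weight",
    "train_som",
    "map_objects",
    "quantization_error",
]

# Tolerance on "data is normalized": inputs are expected in [0, 1] but a
# hair of slack absorbs round-tripping through text formats.
_NORM_SLACK = 1e-3


@dataclass(frozen=True)
class GridSpec:
    """Rectangular planar grid of ``nx`` rows by ``ny`` columns."""

    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise InputError(f"grid dimensions must be >= 1, got {self.nx}x{self.ny}")

    @property
    def n_neurons(self) -> int:
        return self.nx * self.ny

    def coords(self) -> np.ndarray:
        """Neuron coordinates (i, j) in row-major order, shape (n_neurons, 2)."""
        ii, jj = np.meshgrid(np.arange(self.nx), np.arange(self.ny), indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel()])

    def contains(self, neuron: tuple[int, int]) -> bool:
        i, j = neuron
        return 0 <= i < self.nx and 0 <= j < self.ny

    def index(self, neuron: tuple[int, int]) -> int:
        """Row-major flat index of a neuron; used for tie-breaking."""
        if not self.contains(neuron):
            raise InputError(f"neuron {neuron} outside {self.nx}x{self.ny} grid")
        return neuron[0] * self.ny + neuron[1]

    def neuron_at(self, flat: int) -> tuple[int, int]:
        return divmod(int(flat), self.ny)


@dataclass(frozen=True)
class TrainConfig:
    """Training schedule for SOM / CPANN layers.

    ``radius_start=None`` resolves to ``max(nx, ny) - 1`` at train time,
    so the initial neighborhood spans the whole map.  Learning rate eta
    and radius interpolate linearly from start to end across epochs.
    """

    epochs: int = 100
    eta_start: float = 0.5
    eta_end: float = 0.01
    radius_start: int | None = None
    radius_end: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise InputError(f"epochs must be >= 1, got {self.epochs}")
        if not (0.0 < self.eta_end <= self.eta_start <= 1.0):
            raise InputError(
                f"need 0 < eta_end <= eta_start <= 1, got {self.eta_start}, {self.eta_end}"
            )
        if self.radius_end < 0:
            raise InputError("radius_end must be non-negative")
        if self.radius_start is not None and self.radius_start < self.radius_end:
            raise InputError("radius_start must be >= radius_end")

    def resolved_radius_start(self, grid: GridSpec) -> int:
        if self.radius_start is None:
            return max(grid.nx, grid.ny) - 1
        return self.radius_start

    def schedule(self, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
        """Per-epoch (eta, radius) arrays; a single epoch uses the start values."""
        r0 = float(self.resolved_radius_start(grid))
        if self.epochs == 1:
            return np.array([self.eta_start]), np.array([r0])
        frac = np.arange(self.epochs) / (self.epochs - 1)
        eta = self.eta_start + frac * (self.eta_end - self.eta_start)
        rad = r0 + frac * (float(self.radius_end) - r0)
        return eta, rad


@dataclass(frozen=True)
class MappingResult:
    """Placement of one object on a trained map."""

    object_id: object
    neuron: tuple[int, int]
    distance: float


@dataclass
class SOMModel:
    grid: GridSpec
    weights: np.ndarray  # (n_neurons, n_features), row-major neuron order
    feature_names: list[str]
    train_config: TrainConfig
    trained: bool = False

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class ColumnScaler:
    """Per-column min/max record produced by :func:`normalize_columns`.

    Constant columns cannot be min-max scaled; they are mapped to 0.5 and
    flagged here so downstream stages can report degenerate descriptors.
    """

    mins: pd.Series
    maxs: pd.Series
    constant: pd.Series  # boolean flag per column

    def inverse_transform(self, normalized: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in normalized.columns if c not in self.mins.index]
        if missing:
            raise InputError(f"columns not covered by scaler: {missing}")
        span = self.maxs - self.mins
        out = normalized * span[normalized.columns] + self.mins[normalized.columns]
        for col in normalized.columns[self.constant[normalized.columns]]:
            out[col] = self.mins[col]
        return out

    def transform(self, raw: pd.DataFrame) -> pd.DataFrame:
        span = (self.maxs - self.mins).replace(0.0, np.nan)
        out = (raw - self.mins[raw.columns]) / span[raw.columns]
        for col in raw.columns[self.constant[raw.columns]]:
            out[col] = 0.5
        return out


def _as_frame(data, what: str = "matrix") -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    arr = np.asarray(data)
    if arr.ndim != 2:
        raise InputError(f"{what} must be 2-dimensional, got shape {arr.shape}")
    return pd.DataFrame(arr)


def normalize_columns(matrix) -> tuple[pd.DataFrame, ColumnScaler]:
    """Min-max scale each column of an objects x features table to [0, 1].

    Non-constant columns map as x' = (x - min) / (max - min); constant
    columns map to 0.5 everywhere and are flagged in the returned
    :class:`ColumnScaler`, which supports an exact inverse transform.
    """
    df = _as_frame(matrix)
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise InputError("matrix must have at least one row and one column")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any():
                row = df.index[coerced.isna()][0]
                raise InputError(f"non-numeric cell at row {row!r}, column {col!r}")
        values = df.astype(float).to_numpy()
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise InputError(
            f"missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    mins = df.min()
    maxs = df.max()
    constant = maxs == mins
    span = (maxs - mins).replace(0.0, np.nan)
    normed = (df - mins) / span
    for col in df.columns[constant]:
        normed[col] = 0.5
    scaler = ColumnScaler(mins=mins.astype(float), maxs=maxs.astype(float), constant=constant)
    return normed, scaler


def topo_distance(grid: GridSpec, a: tuple[int, int], b: tuple[int, int]) -> int:
    """Chebyshev distance between two neurons (square-ring neighborhoods)."""
    for neuron in (a, b):
        if not grid.contains(neuron):
            raise InputError(f"neuron {neuron} outside {grid.nx}x{grid.ny} grid")
    return int(max(abs(a[0] - b[0]), abs(a[1] - b[1])))


def neighborhood_weight(d_topo: float, radius: float) -> float:
    """Triangular neighborhood: 1 at the winner, 0 beyond the radius."""
    if d_topo < 0 or radius < 0:
        raise InputError("d_topo and radius must be non-negative")
    return max(0.0, 1.0 - d_topo / (radius + 1.0))


def _neuron_chebyshev(grid: GridSpec) -> np.ndarray:
    """(n_neurons, n_neurons) matrix of pairwise Chebyshev grid distances."""
    c = grid.coords()
    return np.maximum(
        np.abs(c[:, 0][:, None] - c[:, 0][None, :]),
        np.abs(c[:, 1][:, None] - c[:, 1][None, :]),
    ).astype(float)


def _check_normalized(values: np.ndarray, what: str) -> None:
    lo, hi = values.min(), values.max()
    if lo < -_NORM_SLACK or hi > 1.0 + _NORM_SLACK:
        raise InputError(
            f"{what} values outside [0, 1] (range {lo:.4g}..{hi:.4g}); "
            "apply normalize_columns first"
        )


def _train_layers(
    X: np.ndarray,
    Y: np.ndarray | None,
    grid: GridSpec,
    config: TrainConfig,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Shared competitive-learning loop for SOM and CPANN.

    The winner is always chosen from the input layer X-weights; the
    optional output layer receives the same eta * neighborhood factor.
    """
    n_obj, _ = X.shape
    rng = np.random.default_rng(config.seed)
    W = rng.random((grid.n_neurons, X.shape[1]))
    O = rng.random((grid.n_neurons, Y.shape[1])) if Y is not None else None
    topo = _neuron_chebyshev(grid)
    etas, radii = config.schedule(grid)
    for eta, radius in zip(etas, radii):
        order = rng.permutation(n_obj)
        inv_reach = 1.0 / (radius + 1.0)
        for k in order:
            x = X[k]
            diff = x - W
            win = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            a = 1.0 - topo[win] * inv_reach
            np.maximum(a, 0.0, out=a)
            f = (eta * a)[:, None]
            W += f * diff
            if O is not None:
                O += f * (Y[k] - O)
    return W, O


def train_som(data, grid: GridSpec, config: TrainConfig) -> SOMModel:
    """Train a Kohonen map on normalized objects x features data."""
    df = _as_frame(data)
    if df.shape[0] < 1:
        raise InputError("training data must contain at least one object")
    X = df.to_numpy(dtype=float)
    _check_normalized(X, "training data")
    W, _ = _train_layers(X, None, grid, config)
    return SOMModel(
        grid=grid,
        weights=W,
        feature_names=[str(c) for c in df.columns],
        train_config=config,
        trained=True,
    )


def winner(model: SOMModel, x: Sequence[float]) -> MappingResult:
    """Euclidean-nearest neuron for a single feature vector.

    Ties are broken toward the smallest row-major neuron index.
    """
    xv = np.asarray(x, dtype=float).ravel()
    if xv.shape[0] != model.n_features:
        raise InputError(
            f"feature vector has length {xv.shape[0]}, model expects {model.n_features}"
        )
    d2 = np.einsum("ij,ij->i", model.weights - xv, model.weights - xv)
    flat = int(np.argmin(d2))  # argmin returns the first (smallest flat index) minimum
    return MappingResult(
        object_id=None,
        neuron=model.grid.neuron_at(flat),
        distance=float(np.sqrt(d2[flat])),
    )


def map_objects(model: SOMModel, data) -> list[MappingResult]:
    """Place every object of a table on the trained map."""
    if not model.trained:
        raise InputError("model must be trained before mapping objects")
    df = _as_frame(data)
    if df.shape[1] != model.n_features:
        raise InputError(
            f"data has {df.shape[1]} features, model expects {model.n_features}"
        )
    dist = cdist(df.to_numpy(dtype=float), model.weights)
    flats = np.argmin(dist, axis=1)  # first minimum = smallest row-major index
    return [
        MappingResult(
            object_id=obj_id,
            neuron=model.grid.neuron_at(flat),
            distance=float(dist[row, flat]),
        )
        for row, (obj_id, flat) in enumerate(zip(df.index, flats))
    ]


def quantization_error(model: SOMModel, data) -> float:
    """Mean Euclidean distance from objects to their winning neurons."""
    df = _as_frame(data)
    if df.shape[0] == 0:
        raise InputError("quantization error of empty data is undefined")
    results = map_objects(model, df)
    return float(np.mean([r.distance for r in results]))
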