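"""Fullerene-derivative (FD) analysis procedures.

Operations on the compounds x proteins binding-score (Bscore) matrix and
the compounds x descriptors table: activity averaging, SOM-based
reduction of proteins or descriptors to per-neuron extreme
representatives, differences relative to a reference compound (pristine
C60), three-sector activity classification, and the saturated vs.
unsaturated split based on the sp3-atom count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError
from .som import (
    GridSpec,
    MappingResult,
    TrainConfig,
    _as_frame,
    map_objects,
    normalize_columns,
    train_som,
)

__all__ = [
    "SelectionResult",
    "ActivityThresholds",
    "average_bscores",
    "top_k_protein_average",
    "reduce_by_som",
    "select_descriptors",
    "consensus_feature_set",
    "delta_vs_reference",
    "classify_activity",
    "classify_saturation",
    "heatmap_table",
    "DEFAULT_EXTRAS",
]

DEFAULT_EXTRAS = ("QPpolrz", "TD")


@dataclass
class SelectionResult:
    """Per-neuron extreme members chosen on a trained map.

    ``per_neuron`` maps each occupied neuron (i, j) to the IDs of its
    closest and farthest member (identical for single-member neurons);
    ``selected`` is the deduplicated union in row-major neuron order.
    """

    per_neuron: dict[tuple[int, int], tuple[object, object]]
    selected: list
    mapping: list[MappingResult] = field(default_factory=list, repr=False)

    @property
    def n_occupied(self) -> int:
        return len(self.per_neuron)


@dataclass(frozen=True)
class ActivityThresholds:
    """Bscore sector boundaries: active above 5500, moderate above 5000.

    ``upper_active`` and ``low_floor`` describe the nominal range of the
    score axis; classification itself is unbounded at both ends, with
    boundary scores assigned to the lower sector.
    """

    upper_active: float = 8000.0
    active_floor: float = 5500.0
    moderate_floor: float = 5000.0
    low_floor: float = 4000.0

    def __post_init__(self) -> None:
        seq = (self.upper_active, self.active_floor, self.moderate_floor, self.low_floor)
        if not all(a > b for a, b in zip(seq, seq[1:])):
            raise InputError(f"activity thresholds must strictly decrease, got {seq}")


def _check_binding(B: pd.DataFrame) -> pd.DataFrame:
    if B.shape[0] < 1 or B.shape[1] < 1:
        raise InputError("binding matrix must be non-empty")
    values = B.to_numpy(dtype=float)
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise InputError(
            f"missing Bscore at row {B.index[r]!r}, column {B.columns[c]!r}"
        )
    if not np.isfinite(values).all():
        raise InputError("binding matrix contains non-finite Bscores")
    return B


def average_bscores(B) -> pd.Series:
    """Per-compound mean Bscore over all proteins ('Average sum')."""
    Bdf = _check_binding(_as_frame(B, "binding matrix"))
    out = Bdf.mean(axis=1)
    out.name = "average_sum"
    return out


def top_k_protein_average(B, k: int) -> tuple[list, pd.Series]:
    """Average over the k proteins with the highest overall binding.

    Proteins are ranked by their mean Bscore across all compounds,
    descending, with ties broken by protein ID; returns the selected
    protein IDs and the per-compound average over them.
    """
    Bdf = _check_binding(_as_frame(B, "binding matrix"))
    if not (1 <= k <= Bdf.shape[1]):
        raise InputError(f"k must lie in 1..{Bdf.shape[1]}, got {k}")
    ranking = (
        Bdf.mean(axis=0)
        .rename("mean")
        .to_frame()
        .assign(pid=lambda d: d.index.astype(str))
        .sort_values(["mean", "pid"], ascending=[False, True])
    )
    top = list(ranking.index[:k])
    avg = Bdf[top].mean(axis=1)
    avg.name = f"average_{k}"
    return top, avg


def reduce_by_som(profiles, grid: GridSpec, config: TrainConfig) -> SelectionResult:
    """Cluster object profiles on a SOM and keep per-neuron extremes.

    Trains a map on the normalized objects x features table, places each
    object, and for every occupied neuron keeps the member with the
    smallest and the member with the largest Euclidean distance to the
    neuron weights.  Distance ties are broken by input row order, and the
    deduplicated union is returned in row-major neuron order, bounding
    the selection at twice the number of occupied neurons.
    """
    df = _as_frame(profiles, "profiles")
    if df.shape[0] < 1:
        raise InputError("profiles must contain at least one object")
    model = train_som(df, grid, config)
    mapping = map_objects(model, df)
    members: dict[tuple[int, int], list[MappingResult]] = defaultdict(list)
    for res in mapping:
        members[res.neuron].append(res)
    per_neuron: dict[tuple[int, int], tuple[object, object]] = {}
    for neuron in sorted(members, key=model.grid.index):
        group = members[neuron]  # already in input row order
        dmin = min(r.distance for r in group)
        dmax = max(r.distance for r in group)
        member_min = next(r.object_id for r in group if r.distance == dmin)
        member_max = next(r.object_id for r in group if r.distance == dmax)
        per_neuron[neuron] = (member_min, member_max)
    selected: list = []
    for member_min, member_max in per_neuron.values():
        for obj in (member_min, member_max):
            if obj not in selected:
                selected.append(obj)
    return SelectionResult(per_neuron=per_neuron, selected=selected, mapping=mapping)


def select_descriptors(
    X, grid: GridSpec | None = None, config: TrainConfig | None = None
) -> list[str]:
    """Reduce a descriptor set with a small Kohonen map (default 2x2).

    The descriptor table is transposed (descriptors become the objects,
    compounds the features), normalized, and reduced via
    :func:`reduce_by_som`; a fully occupied 2x2 map with distinct
    extremes yields 8 descriptor names.
    """
    grid = grid or GridSpec(2, 2)
    config = config or TrainConfig()
    Xdf = _as_frame(X, "descriptor table")
    if Xdf.shape[1] < grid.n_neurons:
        raise InputError(
            f"need at least {grid.n_neurons} descriptors for a "
            f"{grid.nx}x{grid.ny} map, got {Xdf.shape[1]}"
        )
    profiles, _ = normalize_columns(Xdf.T)
    result = reduce_by_som(profiles, grid, config)
    return [str(name) for name in result.selected]


def consensus_feature_set(
    selected, extras=DEFAULT_EXTRAS, available=None
) -> list[str]:
    """Ordered union of SOM-selected descriptors and fixed extras.

    Duplicates are removed; the extras (by default the size descriptors
    QPpolrz and topological diameter) are appended last.  If
    ``available`` (e.g. the descriptor table columns) is given, each
    extra must appear in it.
    """
    if available is not None:
        pool = {str(a) for a in available}
        missing = [e for e in extras if str(e) not in pool]
        if missing:
            raise InputError(f"extras not present in descriptor table: {missing}")
    out: list[str] = []
    for name in list(selected) + list(extras):
        name = str(name)
        if name not in out:
            out.append(name)
    return out


def delta_vs_reference(av: pd.Series, ref_id) -> pd.Series:
    """Per-compound difference of average Bscores from a reference compound."""
    if ref_id not in av.index:
        raise InputError(f"reference compound {ref_id!r} not found")
    out = av - float(av.loc[ref_id])
    out.name = f"delta_vs_{ref_id}"
    return out


def classify_activity(av_bscore, thresholds: ActivityThresholds | None = None):
    """Three-sector activity label from an average Bscore.

    Scores above the active floor (5500) are 'active', scores above the
    moderate floor (5000) are 'moderate', everything else — including
    scores below the nominal 4000 axis floor — is 'low'.  Accepts a
    scalar or a Series.
    """
    th = thresholds or ActivityThresholds()

    def _one(score: float) -> str:
        if not np.isfinite(score):
            raise InputError(f"activity score must be finite, got {score}")
        if score > th.active_floor:
            return "active"
        if score > th.moderate_floor:
            return "moderate"
        return "low"

    if isinstance(av_bscore, pd.Series):
        return av_bscore.map(lambda s: _one(float(s))).rename("activity")
    return _one(float(av_bscore))


def classify_saturation(
    sp3_atoms, stereo_centers=None, saturated_threshold: float = 60
):
    """Saturation label from the sp3-atom count.

    Zero sp3 atoms marks an unsaturated (fully sp2) cage; counts above
    the threshold (default 60) mark a saturated derivative; everything
    in between is 'ambiguous' — the two populations overlap there.  The
    stereo-center count travels with the call for reporting but does not
    alter the label (it tracks sp3 saturation almost one-for-one).
    """

    def _one(sp3: float, stereo) -> str:
        if sp3 < 0 or (stereo is not None and stereo < 0):
            raise InputError("atom counts must be non-negative")
        if sp3 == 0:
            return "unsaturated"
        if sp3 > saturated_threshold:
            return "saturated"
        return "ambiguous"

    if isinstance(sp3_atoms, pd.Series):
        stereo = (
            stereo_centers
            if isinstance(stereo_centers, pd.Series)
            else pd.Series(0, index=sp3_atoms.index)
        )
        return pd.Series(
            [_one(float(s), float(c)) for s, c in zip(sp3_atoms, stereo)],
            index=sp3_atoms.index,
            name="saturation",
        )
    return _one(float(sp3_atoms), stereo_centers)


def heatmap_table(B, av: pd.Series | None = None) -> pd.DataFrame:
    """Binding matrix ordered by average Bscore with a three-bin class.

    Rows are sorted by decreasing average activity and annotated with
    'high' / 'moderate' / 'low' tertiles of the observed score range, the
    textual counterpart of a red-orange / yellow / green heatmap.
    """
    Bdf = _check_binding(_as_frame(B, "binding matrix"))
    av = average_bscores(Bdf) if av is None else av
    lo, hi = float(av.min()), float(av.max())
    edges = [lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0]

    def _bin(v: float) -> str:
        if v > edges[1]:
            return "high"
        if v > edges[0]:
            return "moderate"
        return "low"

    ordered = av.sort_values(ascending=False)
    out = Bdf.loc[ordered.index].copy()
    out.insert(0, "average_sum", ordered)
    out.insert(1, "activity_bin", ordered.map(_bin))
    return out
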