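"""End-to-end analysis workflow.

Chains the stages of the binding-activity study: normalization, activity
averaging, SOM reduction of the protein panel, top-k protein averaging,
the correlation table of activity summaries vs. size descriptors,
2x2-map descriptor selection, the full and consensus CPANN models with
leave-one-out validation, activity and saturation classification,
differences vs. the reference compound, and the heatmap export.  Every
stage draws its seed deterministically from the master seed and the
stage name, so reordering configuration blocks cannot change results.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pipeline as fd
from .cpann import fit_metrics, loo_cv, predict, train_cpann
from .errors import FdbindError, InputError
from .io import read_matrix, write_matrix
from .som import GridSpec, TrainConfig, normalize_columns
from .stats import correlation_matrix, high_cc_pairs

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived from the master seed and the stage name."""
    return int(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


@dataclass
class RunConfig:
    """Settings for :func:`run_pipeline`; defaults follow the study setup."""

    descriptors_path: str | Path = ""
    bscores_path: str | Path = ""
    outdir: str | Path = "fdbind_run"
    protein_map: tuple[int, int] = (5, 5)
    model_map: tuple[int, int] = (20, 20)
    descriptor_map: tuple[int, int] = (2, 2)
    epochs: int = 100
    top_k: int = 110
    cc_threshold: float = 0.6
    sp3_threshold: float = 60.0
    extras: tuple[str, ...] = fd.DEFAULT_EXTRAS
    reference_id: str | None = None  # default: least-active compound
    run_loo: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("protein_map", "model_map", "descriptor_map", "extras"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def train_config(self, stage: str) -> TrainConfig:
        return TrainConfig(epochs=self.epochs, seed=stage_seed(self.seed, stage))


def _write_series(series: pd.Series, path: Path) -> None:
    write_matrix(series.to_frame(), path)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow and write all artifacts to the run directory.

    Returns a mapping of artifact names to paths; aborts with the stage
    name on the first failing stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict[str, object] = {
        "seed": config.seed,
        "config": {k: str(v) for k, v in vars(config).items()},
        "stages": [],
    }
    state: dict[str, object] = {}

    def stage(name: str, func):
        t0 = time.perf_counter()
        try:
            func()
        except FdbindError as exc:
            raise FdbindError(f"stage {name!r} failed: {exc}") from exc
        log["stages"].append({"name": name, "seconds": round(time.perf_counter() - t0, 3)})

    def _load():
        state["X"] = read_matrix(config.descriptors_path)
        state["B"] = read_matrix(config.bscores_path)
        if not state["X"].index.equals(state["B"].index):
            raise InputError("descriptor and binding matrices list different compounds")

    def _average():
        state["avg"] = fd.average_bscores(state["B"])
        artifacts["averages"] = write_matrix(
            state["avg"].to_frame(), out / "averages.tsv"
        )

    def _reduce_proteins():
        profiles, _ = normalize_columns(state["B"].T)
        grid = GridSpec(*config.protein_map)
        sel = fd.reduce_by_som(profiles, grid, config.train_config("reduce_proteins"))
        state["protein_selection"] = sel
        rows = [
            {"neuron_i": n[0], "neuron_j": n[1], "member_min": mn, "member_max": mx}
            for n, (mn, mx) in sel.per_neuron.items()
        ]
        df = pd.DataFrame(rows).set_index(pd.Index(range(len(rows)), name="neuron_rank"))
        artifacts["selected_proteins"] = write_matrix(df, out / "selected_proteins.tsv")
        state["avg_selected"] = state["B"][sel.selected].mean(axis=1)

    def _top_k():
        k = config.top_k
        if not (1 <= k <= state["B"].shape[1]):
            raise InputError(
                f"top_k={k} outside 1..{state['B'].shape[1]} proteins"
            )
        _, avg_k = fd.top_k_protein_average(state["B"], k)
        state["avg_k"] = avg_k

    def _correlate():
        table = pd.DataFrame(
            {
                "Average sum": state["avg"],
                f"Average {config.top_k}": state["avg_k"],
                "Average selected": state["avg_selected"],
            }
        )
        for extra in config.extras:
            if extra in state["X"].columns:
                table[extra] = state["X"][extra]
        cm = correlation_matrix(table)
        artifacts["correlation_table"] = write_matrix(cm, out / "correlation_table.tsv")
        pairs = high_cc_pairs(cm, config.cc_threshold)
        pairs_df = pd.DataFrame(pairs, columns=["var_a", "var_b", "cc"]).set_index("var_a")
        artifacts["high_cc_pairs"] = write_matrix(pairs_df, out / "high_cc_pairs.tsv")

    def _select_descriptors():
        selected = fd.select_descriptors(
            state["X"],
            GridSpec(*config.descriptor_map),
            config.train_config("select_descriptors"),
        )
        consensus = fd.consensus_feature_set(
            selected, config.extras, available=state["X"].columns
        )
        state["selected_descriptors"] = selected
        state["consensus"] = consensus
        df = pd.DataFrame(
            {
                "descriptor": selected + [c for c in consensus if c not in selected],
                "role": ["selected"] * len(selected)
                + ["extra"] * (len(consensus) - len(selected)),
            }
        ).set_index("descriptor")
        artifacts["selected_descriptors"] = write_matrix(
            df, out / "selected_descriptors.tsv"
        )

    def _models():
        Xn, _ = normalize_columns(state["X"])
        yn, y_scaler = normalize_columns(state["avg"].to_frame())
        grid = GridSpec(*config.model_map)
        for tag, cols in (
            ("full", list(state["X"].columns)),
            ("consensus", state["consensus"]),
        ):
            cfg = config.train_config(f"cpann_{tag}")
            model = train_cpann(Xn[cols], yn, grid, cfg, target_scaler=y_scaler)
            pred = predict(model, Xn[cols]).iloc[:, 0]
            metrics = fit_metrics(yn.iloc[:, 0], pred)
            table = pd.DataFrame(
                {"observed": yn.iloc[:, 0], "predicted": pred}
            )
            summary = {"model": tag, "n_descriptors": len(cols), "r2": metrics.r2,
                       "rmse": metrics.rmse, "r2_resid": metrics.r2_resid}
            if config.run_loo:
                cv = loo_cv(Xn[cols], yn.iloc[:, 0], grid, cfg)
                table["predicted_loo"] = cv.predictions["predicted"]
                summary["q2_cv"] = cv.q2_cv
                summary["rmse_cv"] = cv.rmse_cv
            artifacts[f"model_{tag}_predictions"] = write_matrix(
                table, out / f"model_{tag}_predictions.tsv"
            )
            (out / f"model_{tag}_metrics.json").write_text(json.dumps(summary, indent=2))
            artifacts[f"model_{tag}_metrics"] = out / f"model_{tag}_metrics.json"
            state[f"metrics_{tag}"] = summary

    def _classify():
        labels = fd.classify_activity(state["avg"])
        table = pd.DataFrame({"average_sum": state["avg"], "activity": labels})
        if "sp3-atoms" in state["X"].columns:
            stereo = (
                state["X"]["stereo centers"]
                if "stereo centers" in state["X"].columns
                else None
            )
            table["saturation"] = fd.classify_saturation(
                state["X"]["sp3-atoms"], stereo, config.sp3_threshold
            )
            if stereo is not None:
                table["stereo centers"] = stereo
        artifacts["activity_classes"] = write_matrix(table, out / "activity_classes.tsv")

    def _deltas():
        ref = config.reference_id or state["avg"].idxmin()
        deltas = fd.delta_vs_reference(state["avg"], ref)
        table = deltas.sort_values().to_frame("delta")
        table.insert(0, "average_sum", state["avg"][table.index])
        artifacts["deltas"] = write_matrix(table, out / "deltas.tsv")
        state["reference_id"] = ref

    def _heatmap():
        artifacts["heatmap"] = write_matrix(
            fd.heatmap_table(state["B"], state["avg"]), out / "heatmap.tsv"
        )

    stage("load", _load)
    stage("average_bscores", _average)
    stage("reduce_proteins", _reduce_proteins)
    stage("top_k_protein_average", _top_k)
    stage("correlate", _correlate)
    stage("select_descriptors", _select_descriptors)
    stage("cpann_models", _models)
    stage("classify", _classify)
    stage("delta_vs_reference", _deltas)
    stage("heatmap", _heatmap)

    log["reference_id"] = str(state.get("reference_id"))
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2))
    artifacts["run_log"] = log_path
    return artifacts
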