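"""CSV/JSON readers and writers for the analysis CLIs.

All floating-point JSON output goes through :func:`write_json`, which
serialises floats with an explicit repr so fixture comparisons are
byte-stable across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import ActivityTrace
from .binding import TitrationSeries, DEFAULT_TARGET_MM
from .binodal import BinodalModel, BinodalPoint
from .dsc import Thermogram

__all__ = [
    "read_binodal_csv",
    "read_partition_csv",
    "read_titration_csv",
    "read_thermogram_csv",
    "read_activity_csv",
    "model_to_dict",
    "model_from_json",
    "write_json",
]


def _to_native(obj):
    if isinstance(obj, dict):
        return {k: _to_native(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_native(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_to_native(v) for v in obj]
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_native(payload), indent=2, sort_keys=True) + "\n")


def read_binodal_csv(path) -> list[BinodalPoint]:
    """Read titration points from a CSV with columns x_wt, y_wt."""
    df = pd.read_csv(path)
    return [BinodalPoint(float(r.x_wt), float(r.y_wt)) for r in df.itertuples()]


def model_to_dict(model: BinodalModel) -> dict:
    d = {
        "a": model.a,
        "b": model.b,
        "c": model.c,
        "form": model.form,
        "rss": model.fit_rss,
        "n_points": model.n_points,
        "max_abs_residual": model.max_abs_residual,
    }
    if model.stderr is not None:
        d["stderr"] = {"a": model.stderr[0], "b": model.stderr[1], "c": model.stderr[2]}
    return d


def model_from_json(path) -> BinodalModel:
    d = json.loads(Path(path).read_text())
    stderr = None
    if "stderr" in d:
        stderr = (d["stderr"]["a"], d["stderr"]["b"], d["stderr"]["c"])
    return BinodalModel(
        a=d["a"],
        b=d["b"],
        c=d["c"],
        form=d.get("form", "exponential"),
        fit_rss=d.get("rss", 0.0),
        n_points=d.get("n_points", 0),
        stderr=stderr,
        max_abs_residual=d.get("max_abs_residual", 0.0),
    )


def read_partition_csv(path) -> pd.DataFrame:
    """Partition records: system_id, replicate, phase, conc_mg_ml, volume_ml."""
    df = pd.read_csv(path)
    required = {"system_id", "replicate", "phase", "conc_mg_ml", "volume_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"partition CSV missing columns: {sorted(missing)}")
    bad = set(df["phase"]) - {"il_rich", "non_il_rich"}
    if bad:
        raise ValueError(f"unknown phase labels: {sorted(bad)}")
    return df


def read_titration_csv(path, target_conc: float = DEFAULT_TARGET_MM) -> list[TitrationSeries]:
    """Titration records (replicate, ligand_mM, fnorm) grouped by replicate."""
    df = pd.read_csv(path)
    series = []
    for rep, grp in df.groupby("replicate"):
        grp = grp.sort_values("ligand_mM", ascending=False)
        series.append(
            TitrationSeries(
                ligand_conc=tuple(grp["ligand_mM"].astype(float)),
                fnorm=tuple(grp["fnorm"].astype(float)),
                target_conc=target_conc,
                replicate_id=int(rep),
            )
        )
    return series


def read_thermogram_csv(path) -> Thermogram:
    df = pd.read_csv(path)
    return Thermogram(tuple(df["temp_C"].astype(float)), tuple(df["cp"].astype(float)))


def read_activity_csv(path) -> list[ActivityTrace]:
    """Activity records: condition, replicate, time_s, a450."""
    df = pd.read_csv(path)
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"]):
        grp = grp.sort_values("time_s")
        traces.append(
            ActivityTrace(
                time=tuple(grp["time_s"].astype(float)),
                a450=tuple(grp["a450"].astype(float)),
                condition=str(cond),
                replicate_id=int(rep),
            )
        )
    return traces
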