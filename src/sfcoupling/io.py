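"""Plain-text readers and writers for every artifact the pipeline touches.

Conventions: region metadata and per-region maps are tab-separated tables;
square matrices are whitespace-delimited text with a one-line ``#`` header
of region ids; time-series panels are R x T whitespace-delimited text;
ground truth and transition fields carry a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import CouplingMap, FunctionalConnectome, StructuralConnectome, VarianceMap
from .hurst import HurstMap
from .synthetic import GroundTruth, RegionSet, TimeSeriesPanel, TransitionField

__all__ = [
    "write_region_table", "read_region_table",
    "write_matrix", "read_matrix",
    "write_panel", "read_panel",
    "write_ground_truth", "read_ground_truth",
    "write_coupling_map", "write_variance_map", "write_hurst_map",
    "write_transition_field", "read_transition_field",
]


def write_region_table(regions: RegionSet, path) -> None:
    df = pd.DataFrame(
        {
            "region_id": regions.region_id,
            "hemisphere": regions.hemisphere,
            "x": regions.xyz[:, 0],
            "y": regions.xyz[:, 1],
            "z": regions.xyz[:, 2],
            "gradient": regions.gradient,
            "class_label": regions.class_label,
            "myelin": regions.myelin,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_region_table(path) -> RegionSet:
    df = pd.read_csv(path, sep="\t")
    return RegionSet(
        region_id=df["region_id"].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(),
        xyz=df[["x", "y", "z"]].to_numpy(float),
        gradient=df["gradient"].to_numpy(float),
        class_label=df["class_label"].to_numpy(),
        myelin=df["myelin"].to_numpy(float),
    )


def write_matrix(matrix, path, region_ids=None) -> None:
    m = matrix.weights if isinstance(matrix, StructuralConnectome) else (
        matrix.corr if isinstance(matrix, FunctionalConnectome) else np.asarray(matrix)
    )
    if region_ids is None:
        region_ids = np.arange(m.shape[0])
    header = " ".join(str(r) for r in region_ids)
    np.savetxt(path, m, header=header)


def read_matrix(path) -> tuple[np.ndarray, np.ndarray]:
    """Return (matrix, region_ids)."""
    with open(path) as fh:
        first = fh.readline()
    ids = np.array(first.lstrip("# ").split(), dtype=int) if first.startswith("#") else None
    m = np.loadtxt(path)
    if ids is None:
        ids = np.arange(m.shape[0])
    return m, ids


def write_panel(panel: TimeSeriesPanel, path) -> None:
    np.savetxt(path, panel.values, header=f"tr={panel.tr}")


def read_panel(path) -> TimeSeriesPanel:
    tr = 0.72
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "tr=" in first:
        tr = float(first.split("tr=")[1].strip())
    return TimeSeriesPanel(values=np.loadtxt(path), tr=tr)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "h_true": truth.h_true.tolist(),
        "coupling": truth.coupling.tolist(),
        "gradient_myelin_corr": truth.gradient_myelin_corr,
        "params": truth.params,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        h_true=np.asarray(d["h_true"], float),
        coupling=np.asarray(d["coupling"], float),
        gradient_myelin_corr=float(d["gradient_myelin_corr"]),
        params=d["params"],
        seed=int(d["seed"]),
    )


def _write_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_coupling_map(cmap: CouplingMap, path, region_ids=None) -> None:
    rid = np.arange(len(cmap.sfc)) if region_ids is None else region_ids
    _write_map(pd.DataFrame({"region_id": rid, "sfc": cmap.sfc, "n_valid": cmap.n_valid}), path)


def write_variance_map(vmap: VarianceMap, path, region_ids=None) -> None:
    rid = np.arange(len(vmap.var_sfc)) if region_ids is None else region_ids
    _write_map(
        pd.DataFrame(
            {"region_id": rid, "var_sfc": vmap.var_sfc, "n_windows": vmap.n_windows_used}
        ),
        path,
    )


def write_hurst_map(hmap: HurstMap, path, region_ids=None) -> None:
    rid = np.arange(len(hmap.H)) if region_ids is None else region_ids
    _write_map(
        pd.DataFrame(
            {
                "region_id": rid,
                "H": hmap.H,
                "fit_quality": hmap.fit_quality,
                "clipped": hmap.clipped.astype(int),
            }
        ),
        path,
    )


def write_transition_field(field: TransitionField, path) -> None:
    shape = field.shape
    header = json.dumps({"shape": list(shape), "n_neighbors": 26})
    flat = np.column_stack(
        [field.mask.reshape(-1).astype(float), field.probs.reshape(-1, 26)]
    )
    np.savetxt(path, flat, header=header)


def read_transition_field(path) -> TransitionField:
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# ").strip())
    flat = np.loadtxt(path)
    shape = tuple(meta["shape"])
    mask = flat[:, 0].reshape(shape).astype(bool)
    probs = flat[:, 1:].reshape(shape + (26,))
    return TransitionField(probs=probs, mask=mask)
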