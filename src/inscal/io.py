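"""On-disk formats: HDF5 datasets, delimited trace tables, TIFF stacks.

Canonical containers:

* dataset (HDF5): raw traces [neuron × trial × sample], the paradigm, the
  per-trial intensity order, and the neuron (ground-truth) table;
* trace table (CSV, long format): columns ``neuron_id, trial, time_s, F``;
* TIFF: registered image stacks, integer ROI label masks, and multi-page
  32-bit fluence maps with a YAML metadata sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .montecarlo import FluenceMap
from .paradigm import StimulusParadigm
from .synthetic import NeuronSpec, TraceSet

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_trace_table",
    "read_trace_table",
    "read_stack",
    "read_label_mask",
    "write_fluence_map",
    "read_fluence_map",
]

TRACE_TABLE_COLUMNS = ["neuron_id", "trial", "time_s", "F"]


def write_dataset(path: str | Path, ts: TraceSet) -> None:
    """Write a TraceSet (traces + paradigm + neuron table) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=ts.traces, compression="gzip")
        f.create_dataset("intensity_order", data=ts.intensity_order)
        f.attrs["sampling_rate"] = ts.sampling_rate
        for k, v in dataclasses.asdict(ts.paradigm).items():
            f.attrs[f"paradigm/{k}"] = v
        grp = f.create_group("neurons")
        specs = [dataclasses.asdict(n) for n in ts.neurons]
        grp.attrs["json"] = json.dumps(specs)


def read_dataset(path: str | Path) -> TraceSet:
    """Read a TraceSet written by :func:`write_dataset`."""
    with h5py.File(path, "r") as f:
        traces = f["traces"][...]
        intensity_order = f["intensity_order"][...]
        sampling_rate = float(f.attrs["sampling_rate"])
        pfields = {
            k.split("/", 1)[1]: v for k, v in f.attrs.items() if k.startswith("paradigm/")
        }
        pfields["label"] = str(pfields["label"])
        pfields["n_trains"] = int(pfields["n_trains"])
        for k in pfields:
            if k not in ("label", "n_trains"):
                pfields[k] = float(pfields[k])
        paradigm = StimulusParadigm(**pfields)
        specs = json.loads(f["neurons"].attrs["json"])
    neurons = [NeuronSpec(**{**s, "position": tuple(s["position"])}) for s in specs]
    return TraceSet(
        traces=traces,
        sampling_rate=sampling_rate,
        paradigm=paradigm,
        neurons=neurons,
        intensity_order=intensity_order,
    )


def write_trace_table(path: str | Path, ts: TraceSet) -> None:
    """Flat delimited export: one row per sample."""
    n_neurons, n_trials, n_samples = ts.traces.shape
    t = np.arange(n_samples) / ts.sampling_rate
    frames = []
    for i in range(n_neurons):
        for j in range(n_trials):
            frames.append(
                pd.DataFrame(
                    {
                        "neuron_id": ts.neurons[i].id if ts.neurons else i,
                        "trial": j,
                        "time_s": t,
                        "F": ts.traces[i, j],
                    }
                )
            )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=TRACE_TABLE_COLUMNS)
    )
    df.to_csv(path, index=False)


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format trace table, validating the documented header."""
    df = pd.read_csv(path)
    if list(df.columns) != TRACE_TABLE_COLUMNS:
        raise ValueError(
            f"trace table header {list(df.columns)} != expected {TRACE_TABLE_COLUMNS}"
        )
    return df


def trace_table_to_array(df: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Pivot a long trace table back to [neuron, trial, sample] order."""
    if df.empty:
        return np.zeros((0, 0, 0)), []
    neuron_ids = sorted(df["neuron_id"].unique())
    trials = sorted(df["trial"].unique())
    n_samples = df.groupby(["neuron_id", "trial"]).size().iloc[0]
    arr = np.empty((len(neuron_ids), len(trials), n_samples))
    for (nid, trial), grp in df.groupby(["neuron_id", "trial"]):
        g = grp.sort_values("time_s")
        if len(g) != n_samples:
            raise ValueError("ragged trace table: unequal samples per trace")
        arr[neuron_ids.index(nid), trials.index(trial)] = g["F"].to_numpy()
    return arr, [int(n) for n in neuron_ids]


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF stack as [frame, y, x]."""
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read an integer ROI label mask (label n > 0 is ROI n, 0 background)."""
    mask = tifffile.imread(path)
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.allclose(mask, np.round(mask)):
            raise ValueError("ROI mask must contain integer labels")
        mask = mask.astype(np.int32)
    return mask


def write_fluence_map(directory: str | Path, fmap: FluenceMap, name: str = "fluence") -> None:
    """Write a fluence map as multi-page 32-bit TIFF (one page per z-slice)
    plus a YAML sidecar with the run metadata and conservation ledger."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # pages along z: transpose so page k is the (x, y) plane at depth index k
    pages = np.ascontiguousarray(np.moveaxis(fmap.fluence().astype(np.float32), 2, 0))
    tifffile.imwrite(directory / f"{name}.tif", pages)
    meta = {
        "seed": int(fmap.seed),
        "n_photons": int(fmap.n_photons),
        "totals": {k: float(v) for k, v in fmap.totals.items()},
        "extent_mm": fmap.tissue.extent_mm,
        "voxel_pitch_mm": fmap.tissue.voxel_pitch_mm,
        "layers": [
            {
                "name": l.name,
                "thickness_mm": l.thickness_mm,
                "mu_a": l.properties.mu_a,
                "mu_s": l.properties.mu_s,
                "g": l.properties.g,
                "n": l.properties.n,
            }
            for l in fmap.tissue.layers
        ],
    }
    (directory / f"{name}.yaml").write_text(yaml.safe_dump(meta))


def read_fluence_map(directory: str | Path, name: str = "fluence") -> tuple[np.ndarray, dict]:
    """Read back the fluence TIFF (as [x, y, z]) and its metadata sidecar."""
    directory = Path(directory)
    pages = tifffile.imread(directory / f"{name}.tif")
    meta = yaml.safe_load((directory / f"{name}.yaml").read_text())
    return np.moveaxis(pages, 0, 2), meta
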