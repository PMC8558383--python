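"""Readers and writers for the toolkit's on-disk formats.

Two trace formats are supported:

* delimited text — comma separated, ``#``-prefixed comment lines,
  first column the time (ps) or frequency (THz) axis, one trace per
  subsequent column;
* a grouped HDF5 container with datasets ``time``, ``traces``,
  ``labels`` and ``split`` (int8; 1 = calibration) plus string
  attributes for label names and axis kind.

Image cubes are stored as an HDF5 dataset ``cube`` (nx x ny x n_time)
with ``time`` alongside and ``dx_mm``/``dy_mm`` attributes (0.2 mm
raster step by default).  Grayscale maps can be exported as delimited
text or 8-bit PNG.
"""

from __future__ import annotations

import json

import h5py
import imageio.v3 as iio
import numpy as np

from .errors import InvalidArgumentError
from .imaging import GrayscaleMap
from .spectra import LabeledSpectralSet
from .synthetic import THzImageCube


def save_traces_csv(path, axis, traces, labels=None, label_names=("tea", "insect")) -> None:
    """Write traces as columns after the shared axis column."""
    axis = np.asarray(axis, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] != axis.size:
        raise InvalidArgumentError("each trace must match the axis length")
    header_lines = ["# thzfb traces: first column axis, one trace per column"]
    if labels is not None:
        labels = np.asarray(labels)
        if labels.size != traces.shape[0]:
            raise InvalidArgumentError("one label per trace required")
        header_lines.append("# labels: " + ",".join(str(int(v)) for v in labels))
        header_lines.append("# label_names: " + ",".join(label_names))
    body = np.column_stack([axis, traces.T])
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        np.savetxt(fh, body, delimiter=",", fmt="%.12g")


def load_traces_csv(path):
    """Read a delimited-text trace file.

    Returns ``(axis, traces, labels)`` with traces as rows; ``labels``
    is None when the file carries no label header.
    """
    labels = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# labels:"):
                payload = line.split(":", 1)[1].strip()
                if payload:
                    labels = np.array([int(v) for v in payload.split(",")])
    data = np.loadtxt(path, delimiter=",", comments="#")
    data = np.atleast_2d(data)
    axis = data[:, 0]
    traces = data[:, 1:].T
    return axis, traces, labels


def save_dataset_h5(path, dataset: LabeledSpectralSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("time", data=dataset.variable_axis)
        fh.create_dataset("traces", data=dataset.features)
        fh.create_dataset("labels", data=dataset.labels.astype(np.int8))
        fh.create_dataset("split", data=dataset.split.astype(np.int8))
        fh.attrs["label_names"] = json.dumps(list(dataset.label_names))
        fh.attrs["axis_kind"] = dataset.metadata.get("axis_kind", "time_ps")


def load_dataset_h5(path) -> LabeledSpectralSet:
    with h5py.File(path, "r") as fh:
        label_names = tuple(json.loads(fh.attrs.get("label_names", '["tea", "insect"]')))
        return LabeledSpectralSet(
            features=fh["traces"][()],
            labels=fh["labels"][()].astype(int),
            variable_axis=fh["time"][()],
            split=fh["split"][()].astype(bool),
            label_names=label_names,
            metadata={"axis_kind": str(fh.attrs.get("axis_kind", "time_ps"))},
        )


def save_cube_h5(path, cube: THzImageCube) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=cube.cube)
        fh.create_dataset("time", data=cube.time)
        fh.attrs["dx_mm"] = float(cube.dx_mm)
        fh.attrs["dy_mm"] = float(cube.dy_mm)


def load_cube_h5(path) -> THzImageCube:
    with h5py.File(path, "r") as fh:
        return THzImageCube(
            cube=fh["cube"][()],
            time=fh["time"][()],
            dx_mm=float(fh.attrs.get("dx_mm", 0.2)),
            dy_mm=float(fh.attrs.get("dy_mm", 0.2)),
        )


def save_map_csv(path, gray: GrayscaleMap) -> None:
    np.savetxt(path, gray.values, delimiter=",", fmt="%.12g")


def save_map_png(path, gray: GrayscaleMap) -> None:
    """Export a map as 8-bit grayscale, min-max scaled."""
    lo, hi = gray.value_range
    span = hi - lo if hi > lo else 1.0
    scaled = np.round(255.0 * (gray.values - lo) / span).astype(np.uint8)
    iio.imwrite(path, scaled)
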