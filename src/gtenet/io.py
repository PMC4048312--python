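"""Readers and writers for networks, spike rasters and fluorescence data.

Plain-text formats are the default interchange (edge lists, two-column
rasters, delimited fluorescence matrices); HDF5 containers hold the same
content for larger runs.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .dynamics import SpikeRaster
from .errors import ValidationError
from .fluorescence import FluorescenceRecording
from .topology import EXCITATORY, INHIBITORY, GroundTruthNetwork

__all__ = [
    "write_network", "read_network",
    "write_raster", "read_raster",
    "write_fluorescence", "read_fluorescence",
    "write_scores", "read_scores",
]

_TYPE_NAME = {EXCITATORY: "excitatory", INHIBITORY: "inhibitory"}
_TYPE_CODE = {v: k for k, v in _TYPE_NAME.items()}


def write_network(net: GroundTruthNetwork, path: str | Path) -> None:
    """Edge list (`src dst` per line) + sidecar `<stem>.neurons.tsv`, or a
    single HDF5 container when the suffix is .h5/.hdf5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("adjacency", data=net.adjacency)
            f.create_dataset("types", data=net.neuron_type)
            f.create_dataset("positions", data=net.positions)
            f.attrs["frac_excitatory"] = net.frac_excitatory
            f.attrs["area_mm"] = net.area_mm
        return
    src, dst = np.nonzero(net.adjacency)
    with open(path, "w") as f:
        for s, d in zip(src, dst):
            f.write(f"{s} {d}\n")
    sidecar = path.with_suffix(path.suffix + ".neurons.tsv")
    with open(sidecar, "w") as f:
        f.write("id\ttype\tx_mm\ty_mm\n")
        for i in range(net.n_neurons):
            f.write(f"{i}\t{_TYPE_NAME[int(net.neuron_type[i])]}"
                    f"\t{net.positions[i, 0]:.6f}\t{net.positions[i, 1]:.6f}\n")


def read_network(path: str | Path) -> GroundTruthNetwork:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return GroundTruthNetwork(
                f["adjacency"][...], f["types"][...], f["positions"][...],
                float(f.attrs["frac_excitatory"]), float(f.attrs["area_mm"]))
    sidecar = path.with_suffix(path.suffix + ".neurons.tsv")
    if not sidecar.exists():
        raise ValidationError(f"missing neuron sidecar table {sidecar}")
    rows = np.genfromtxt(sidecar, names=True, dtype=None, encoding=None)
    rows = np.atleast_1d(rows)
    n = len(rows)
    types = np.array([_TYPE_CODE[str(r["type"])] for r in rows], dtype=np.int8)
    positions = np.column_stack([rows["x_mm"], rows["y_mm"]])
    adjacency = np.zeros((n, n), dtype=np.int8)
    edges = np.loadtxt(path, dtype=int, ndmin=2)
    if edges.size:
        adjacency[edges[:, 0], edges[:, 1]] = 1
    area = max(1.0, float(positions.max()) + 1e-9)
    frac = float((types == EXCITATORY).mean())
    return GroundTruthNetwork(adjacency, types, positions, frac, area)


def write_raster(raster: SpikeRaster, path: str | Path) -> None:
    """Two-column text `time_s neuron_id` sorted by time, or HDF5."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=raster.times)
            f.create_dataset("ids", data=raster.ids)
            f.attrs["duration"] = raster.duration
            f.attrs["n_neurons"] = raster.n_neurons
        return
    with open(path, "w") as f:
        f.write(f"# duration_s={raster.duration} n_neurons={raster.n_neurons}\n")
        for t, i in zip(raster.times, raster.ids):
            f.write(f"{t:.6f} {i}\n")


def read_raster(path: str | Path) -> SpikeRaster:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return SpikeRaster(f["times"][...], f["ids"][...],
                               float(f.attrs["duration"]), int(f.attrs["n_neurons"]))
    with open(path) as f:
        header = f.readline().strip().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        body = f.read()
    data = (np.loadtxt(body.splitlines(), ndmin=2) if body.strip()
            else np.zeros((0, 2)))
    times = data[:, 0] if data.size else np.zeros(0)
    ids = data[:, 1].astype(int) if data.size else np.zeros(0, dtype=int)
    return SpikeRaster(times, ids, float(meta["duration_s"]), int(meta["n_neurons"]))


def write_fluorescence(rec: FluorescenceRecording, path: str | Path) -> None:
    """One row per frame, one column per neuron; header carries the frame
    interval.  HDF5 alternative with datasets `F` and `dt`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("F", data=rec.values)
            f.create_dataset("dt", data=rec.frame_interval)
            f.create_dataset("neuron_ids", data=np.arange(rec.n_neurons))
        return
    np.savetxt(path, rec.values, fmt="%.6f",
               header=f"frame_interval_s={rec.frame_interval}")


def read_fluorescence(path: str | Path) -> FluorescenceRecording:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return FluorescenceRecording(f["F"][...], float(f["dt"][()]))
    with open(path) as f:
        header = f.readline().strip().lstrip("#").strip()
        dt = float(header.split("=")[1])
        values = np.loadtxt(f, ndmin=2)
    return FluorescenceRecording(values, dt)


def write_scores(scores: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("scores", data=np.asarray(scores, dtype=float))
        return
    np.savetxt(path, np.asarray(scores, dtype=float), fmt="%.8e")


def read_scores(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["scores"][...]
    return np.loadtxt(path, ndmin=2)
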