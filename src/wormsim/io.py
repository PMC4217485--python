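"""Trajectory and track I/O: HDF5 primary, CSV fallback.

Trajectory layout (HDF5): /positions [T, N, d], /velocities [T, N, d],
/kinds [N], /time [T], /midline [T, 49, d], /neural/V [T, M], /neural/s,
/muscle_activations [T, 95], /forces/muscle_tension [T].

Tracks are either a trajectory file carrying /midline and /time, or a wide
CSV with columns t, x1, y1, ..., x49, y49.
"""

from __future__ import annotations

import hashlib

import h5py
import numpy as np
import pandas as pd

from .behavior import MidlineTrack


def write_trajectory(path, datasets: dict) -> None:
    """Write a nested dict of arrays to HDF5 ('a/b' keys make groups)."""
    with h5py.File(path, "w") as f:
        for key, value in datasets.items():
            f.create_dataset(key, data=np.asarray(value))


def read_trajectory(path) -> dict:
    out = {}
    with h5py.File(path, "r") as f:

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[()]

        f.visititems(visit)
    return out


def trajectory_hash(path) -> str:
    """Order-stable SHA-256 over dataset names and contents (ignores HDF5
    container metadata such as creation times)."""
    data = read_trajectory(path)
    digest = hashlib.sha256()
    for name in sorted(data):
        digest.update(name.encode())
        digest.update(np.ascontiguousarray(data[name]).tobytes())
    return digest.hexdigest()


def load_track(path, label: str = "") -> MidlineTrack:
    """Load a midline track from a trajectory HDF5 or a wide CSV."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as f:
            times = f["time"][()]
            points = f["midline"][()]
        return MidlineTrack(times=times, points=points, label=label or path)
    df = pd.read_csv(path)
    times = df["t"].to_numpy(dtype=float)
    n_pts = (len(df.columns) - 1) // 2
    xs = df[[f"x{k}" for k in range(1, n_pts + 1)]].to_numpy(dtype=float)
    ys = df[[f"y{k}" for k in range(1, n_pts + 1)]].to_numpy(dtype=float)
    return MidlineTrack(
        times=times, points=np.stack([xs, ys], axis=-1), label=label or path
    )


def save_track_csv(track: MidlineTrack, path) -> None:
    n_pts = track.points.shape[1]
    data = {"t": track.times}
    for k in range(n_pts):
        data[f"x{k + 1}"] = track.points[:, k, 0]
        data[f"y{k + 1}"] = track.points[:, k, 1]
    pd.DataFrame(data).to_csv(path, index=False)
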