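"""Readers and writers for the package's on-disk formats.

Activity traces: CSV (columns frame_index, active_pixels, with the frame
interval recorded in a ``# dt_seconds=`` header comment) and HDF5 (dataset
"activity" with attribute "dt_seconds").  Residence series: CSV (columns
round_index, state, duration_s) and HDF5.  Frame stacks: multi-page TIFF or
a directory of PNG frames.  Spectra: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .activity import ActivityTimeSeries
from .errors import InputError
from .mfdfa import MultifractalSpectrum
from .residence import ResidenceTimeSeries
from .synthetic import FrameStack


# ---------------------------------------------------------------------------
# activity traces

def write_activity_csv(series: ActivityTimeSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dt_seconds={series.dt!r}\n")
        fh.write("frame_index,active_pixels\n")
        for i, c in enumerate(series.counts):
            fh.write(f"{i},{float(c)!r}\n")


def read_activity_csv(path, dt: float | None = None) -> ActivityTimeSeries:
    path = Path(path)
    if dt is None:
        with path.open() as fh:
            first = fh.readline()
        if first.startswith("# dt_seconds="):
            dt = float(first.split("=", 1)[1])
        else:
            dt = 0.05
    df = pd.read_csv(path, comment="#")
    if "active_pixels" not in df.columns:
        raise InputError(f"{path} lacks an active_pixels column")
    return ActivityTimeSeries(counts=df["active_pixels"].to_numpy(dtype=float),
                              dt=dt, meta={"path": str(path)})


def write_activity_hdf5(series: ActivityTimeSeries, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("activity", data=series.counts)
        ds.attrs["dt_seconds"] = series.dt


def read_activity_hdf5(path) -> ActivityTimeSeries:
    with h5py.File(path, "r") as fh:
        if "activity" not in fh:
            raise InputError(f"{path} lacks an 'activity' dataset")
        ds = fh["activity"]
        dt = float(ds.attrs.get("dt_seconds", 0.05))
        counts = ds[()]
    return ActivityTimeSeries(counts=np.asarray(counts, dtype=float), dt=dt,
                              meta={"path": str(path)})


# ---------------------------------------------------------------------------
# residence series

def write_residence_csv(res: ResidenceTimeSeries, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# dt_seconds={res.dt!r} first_state={res.first_state} "
                 f"boundary_policy={res.boundary_policy}\n")
        fh.write("round_index,state,duration_s\n")
        runs = {"active": res.active_runs, "inactive": res.inactive_runs}
        idx = {"active": 0, "inactive": 0}
        state = res.first_state
        while idx["active"] < runs["active"].size or idx["inactive"] < runs["inactive"].size:
            if idx[state] < runs[state].size:
                fh.write(f"{idx[state]},{state},"
                         f"{float(runs[state][idx[state]] * res.dt)!r}\n")
                idx[state] += 1
            state = "inactive" if state == "active" else "active"


def read_residence_csv(path, dt: float | None = None) -> ResidenceTimeSeries:
    path = Path(path)
    first_state, policy = "active", "drop_edges"
    with path.open() as fh:
        header = fh.readline()
    if header.startswith("#"):
        fields = dict(tok.split("=") for tok in header[1:].split() if "=" in tok)
        dt = float(fields.get("dt_seconds", dt or 0.05)) if dt is None else dt
        first_state = fields.get("first_state", first_state)
        policy = fields.get("boundary_policy", policy)
    dt = dt or 0.05
    df = pd.read_csv(path, comment="#")
    act = df.loc[df["state"] == "active", "duration_s"].to_numpy(dtype=float)
    ina = df.loc[df["state"] == "inactive", "duration_s"].to_numpy(dtype=float)
    return ResidenceTimeSeries(active_runs=np.rint(act / dt).astype(np.int64),
                               inactive_runs=np.rint(ina / dt).astype(np.int64),
                               first_state=first_state, dt=dt,
                               boundary_policy=policy,
                               meta={"path": str(path)})


def write_residence_hdf5(res: ResidenceTimeSeries, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("active_runs", data=res.active_runs)
        fh.create_dataset("inactive_runs", data=res.inactive_runs)
        fh.attrs["dt_seconds"] = res.dt
        fh.attrs["first_state"] = res.first_state
        fh.attrs["boundary_policy"] = res.boundary_policy


def read_residence_hdf5(path) -> ResidenceTimeSeries:
    with h5py.File(path, "r") as fh:
        return ResidenceTimeSeries(
            active_runs=fh["active_runs"][()],
            inactive_runs=fh["inactive_runs"][()],
            first_state=str(fh.attrs["first_state"]),
            dt=float(fh.attrs["dt_seconds"]),
            boundary_policy=str(fh.attrs["boundary_policy"]),
            meta={"path": str(path)})


# ---------------------------------------------------------------------------
# frame stacks

def write_frame_stack_tiff(stack: FrameStack, path) -> None:
    import tifffile
    tifffile.imwrite(path, stack.frames, photometric="minisblack",
                     metadata={"dt_seconds": stack.dt})


def read_frame_stack(path, dt: float = 0.05) -> FrameStack:
    """Read a multi-page TIFF file or a directory of PNG frames."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio
        files = sorted(path.glob("*.png"))
        if len(files) < 2:
            raise InputError(f"{path} holds fewer than 2 PNG frames")
        frames = np.stack([iio.imread(f) for f in files])
        if frames.ndim == 4:          # RGB(A) -> grayscale by channel mean
            frames = frames[..., :3].mean(axis=-1).astype(np.uint8)
    else:
        import tifffile
        frames = tifffile.imread(path)
    return FrameStack(frames=frames, dt=dt)


# ---------------------------------------------------------------------------
# spectra

def write_spectrum_json(spec: MultifractalSpectrum, path, config_echo=None) -> None:
    payload = spec.to_dict()
    if config_echo is not None:
        payload["config"] = config_echo
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_spectrum_json(path) -> MultifractalSpectrum:
    payload = json.loads(Path(path).read_text())
    return MultifractalSpectrum(
        q_values=np.asarray(payload["q"]), H=np.asarray(payload["H"]),
        h=np.asarray(payload["h"]), D=np.asarray(payload["D"]),
        h_peak=payload["h_peak"], width=payload["width"],
        quality_flags=payload.get("quality_flags", []),
        diagnostics=payload.get("diagnostics", {}))
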