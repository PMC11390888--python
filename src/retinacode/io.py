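"""HDF5 / CSV serialization for movies, spikes, encoders and results."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .encoding_models import CellFilters, PopulationEncoder, SpikeTrainSet
from .retina_simulator import RGCMosaic
from .synthetic_stimulus import EyeTrajectory, StimulusMovie

__all__ = [
    "save_movie",
    "load_movie",
    "save_spikes",
    "load_spikes",
    "save_encoder",
    "load_encoder",
    "save_mosaic_csv",
    "load_mosaic_csv",
    "save_image_png",
]


def save_movie(path, movie: StimulusMovie) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie.frames)
        f.attrs["frame_period_ms"] = movie.frame_period_ms
        f.attrs["pixel_pitch_um"] = movie.pixel_pitch_um
        f.attrs["background_level"] = movie.background_level
        if movie.trajectory is not None:
            f.create_dataset("trajectory_px", data=movie.trajectory.displacements_px)
            f.create_dataset("trajectory_um", data=movie.trajectory.displacements_um)


def load_movie(path) -> StimulusMovie:
    with h5py.File(path, "r") as f:
        traj = None
        if "trajectory_px" in f:
            traj = EyeTrajectory(
                displacements_px=f["trajectory_px"][...],
                displacements_um=f["trajectory_um"][...],
                frame_period_ms=float(f.attrs["frame_period_ms"]),
            )
        return StimulusMovie(
            frames=f["frames"][...],
            frame_period_ms=float(f.attrs["frame_period_ms"]),
            pixel_pitch_um=float(f.attrs["pixel_pitch_um"]),
            background_level=float(f.attrs["background_level"]),
            trajectory=traj,
        )


def save_spikes(path, spikes: SpikeTrainSet) -> None:
    events = spikes.to_events()
    with h5py.File(path, "w") as f:
        f.create_dataset("events", data=events)  # (cell_id, time_ms)
        f.create_dataset("cell_ids", data=np.asarray(spikes.cell_ids))
        f.attrs["n_bins"] = spikes.n_bins
        f.attrs["bin_ms"] = spikes.bin_ms


def load_spikes(path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        return SpikeTrainSet.from_events(
            f["events"][...], f["cell_ids"][...], int(f.attrs["n_bins"])
        )


def save_encoder(path, encoder: PopulationEncoder) -> None:
    with h5py.File(path, "w") as f:
        for cell in encoder.cells:
            g = f.create_group(f"cell/{cell.cell_id}")
            g.create_dataset("spatial_map", data=cell.spatial_map)
            g.attrs["crop_origin"] = cell.crop_origin
            g.attrs["bias"] = cell.bias
            g.create_dataset("temporal_kernel", data=cell.temporal_kernel)
            g.create_dataset("feedback_kernel", data=cell.feedback_kernel)
            for j, ck in cell.coupling_kernels.items():
                g.create_dataset(f"coupling/{j}", data=ck)
        if encoder.mosaic is not None:
            m = encoder.mosaic
            g = f.create_group("mosaic")
            g.create_dataset("cell_ids", data=np.asarray(m.cell_ids))
            g.create_dataset("cell_types",
                             data=np.asarray(m.cell_types, dtype="S"))
            g.create_dataset("centers_um", data=np.asarray(m.centers_um))
            g.create_dataset("radii_um", data=np.asarray(m.radii_um))
            g.attrs["field_size_um"] = m.field_size_um


def load_encoder(path) -> PopulationEncoder:
    with h5py.File(path, "r") as f:
        cells = []
        for cid in sorted(f["cell"], key=int):
            g = f[f"cell/{cid}"]
            coupling = {}
            if "coupling" in g:
                for j in g["coupling"]:
                    coupling[int(j)] = g[f"coupling/{j}"][...]
            cells.append(
                CellFilters(
                    cell_id=int(cid),
                    spatial_map=g["spatial_map"][...],
                    crop_origin=tuple(int(v) for v in g.attrs["crop_origin"]),
                    temporal_kernel=g["temporal_kernel"][...],
                    feedback_kernel=g["feedback_kernel"][...],
                    coupling_kernels=coupling,
                    bias=float(g.attrs["bias"]),
                )
            )
        mosaic = None
        if "mosaic" in f:
            g = f["mosaic"]
            mosaic = RGCMosaic(
                cell_ids=g["cell_ids"][...],
                cell_types=g["cell_types"][...].astype(str),
                centers_um=g["centers_um"][...],
                radii_um=g["radii_um"][...],
                field_size_um=tuple(g.attrs["field_size_um"]),
            )
        return PopulationEncoder(cells=cells, mosaic=mosaic)


def save_mosaic_csv(path, mosaic: RGCMosaic) -> None:
    pd.DataFrame(
        {
            "cell_id": mosaic.cell_ids,
            "type": mosaic.cell_types,
            "y_um": mosaic.centers_um[:, 0],
            "x_um": mosaic.centers_um[:, 1],
            "radius_um": mosaic.radii_um,
        }
    ).to_csv(path, index=False)


def load_mosaic_csv(path, field_size_um=(0.0, 0.0)) -> RGCMosaic:
    df = pd.read_csv(path)
    return RGCMosaic(
        cell_ids=df["cell_id"].to_numpy(),
        cell_types=df["type"].to_numpy(),
        centers_um=df[["y_um", "x_um"]].to_numpy(),
        radii_um=df["radius_um"].to_numpy(),
        field_size_um=tuple(field_size_um),
    )


def save_image_png(path, pixels: np.ndarray) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(pixels, 0, 1), cmap="gray", vmin=0, vmax=1)


def save_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
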