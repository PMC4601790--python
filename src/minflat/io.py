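"""Snapshot containers and run outputs.

Trajectories are written to HDF5 with one dataset per species, named
{rho_DADP, rho_DATP, rho_E, sigma_D, sigma_DE}, shaped (n_snapshots, nx, ny,
nz), plus grid metadata (dx, origin, axis convention) and time stamps.
Summary time series go to plain CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

_SPECIES = ("rho_DADP", "rho_DATP", "rho_E", "sigma_D", "sigma_DE")
_FIELDS = ("rho_dadp", "rho_datp", "rho_e", "sigma_d", "sigma_de")


def save_trajectory(trajectory, path) -> None:
    """Write a deterministic or stochastic trajectory to HDF5."""
    geom = trajectory.geometry
    with h5py.File(path, "w") as f:
        f.attrs["dx"] = geom.dx
        f.attrs["origin"] = geom.origin
        f.attrs["axes"] = "x, y (long axis), z (normal to flattened plane)"
        f.create_dataset("times", data=np.asarray(trajectory.times))
        shape = (len(trajectory),) + geom.mask.shape
        dsets = [
            f.create_dataset(name, shape=shape, dtype="f8", compression="gzip")
            for name in _SPECIES
        ]
        for i, snap in enumerate(trajectory):
            for ds, field in zip(dsets, _FIELDS):
                ds[i] = getattr(snap, field)


def load_times(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["times"][...]


def save_polar_csv(series, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"time_s": series.times, "n_top": series.n_top, "n_bottom": series.n_bottom}
    ).to_csv(path, index=False)


def save_correlation_csv(lags, c, path) -> None:
    import pandas as pd

    pd.DataFrame({"lag_s": lags, "correlation": c}).to_csv(path, index=False)


def save_arrows_csv(track, path) -> None:
    import pandas as pd

    pd.DataFrame(
        track.arrows, columns=["x0_um", "y0_um", "x1_um", "y1_um"]
    ).to_csv(path, index=False)


def write_report(path, entries: dict) -> None:
    """Key/value run report, one `key: value` per line."""
    with open(path, "w") as f:
        for k, v in entries.items():
            f.write(f"{k}: {v}\n")


def write_manifest(path, config_dict: dict, seed: int) -> None:
    from . import __version__

    manifest = {"config": config_dict, "seed": seed, "version": __version__}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def save_frame_png(image: np.ndarray, path, vmax: float | None = None) -> None:
    """16-bit grayscale PNG frame; shared ``vmax`` keeps panels comparable."""
    from skimage.io import imsave

    vmax = vmax if vmax is not None else (image.max() or 1.0)
    scaled = np.clip(image / vmax, 0.0, 1.0)
    imsave(path, (scaled * 65535).astype(np.uint16), check_contrast=False)
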