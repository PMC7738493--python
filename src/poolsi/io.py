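"""File I/O: kernels to/from HDF5, movies to/from TIFF/HDF5, tables to CSV."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .synth.kernels import ResponseKernel


def save_kernels(path, kernels: list[ResponseKernel]) -> None:
    with h5py.File(path, "w") as f:
        for i, k in enumerate(kernels):
            g = f.create_group(f"cell_{i:04d}")
            g.create_dataset("data", data=k.data)
            g.attrs["kind"] = k.kind
            g.attrs["fs"] = k.fs
            g.create_dataset("t", data=k.t)
            ax = g.create_group("axes")
            for name, vals in k.axes.items():
                ax.create_dataset(name, data=np.asarray(vals))


def load_kernels(path) -> list[ResponseKernel]:
    out = []
    with h5py.File(path, "r") as f:
        for key in sorted(f.keys()):
            g = f[key]
            axes = {name: g["axes"][name][...] for name in g["axes"]}
            out.append(ResponseKernel(
                kind=g.attrs["kind"], data=g["data"][...], axes=axes,
                t=g["t"][...], fs=float(g.attrs["fs"]),
            ))
    return out


def save_movie_tiff(path, frames: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32))


def load_movie(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            return f["frames"][...]
    return tifffile.imread(path)


def save_movie_h5(path, frames: np.ndarray, fs: float, pixel_size_um: float) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("frames", data=np.asarray(frames, dtype=np.float32))
        d.attrs["fs"] = fs
        d.attrs["pixel_size_um"] = pixel_size_um
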