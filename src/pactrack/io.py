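"""HDF5 / TIFF / CSV readers and writers for the package's containers.

All numeric metadata attribute names carry their unit as a suffix
(``fs_hz``, ``dz_mm``, ``c_mm_per_us``); round trips are lossless.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .fluence import FluenceMap, OpticalProperties, TissueModel
from .saft import AScanStack, ScanGeometry
from .tracking import FrameSeries


class MissingAttributeError(ValueError):
    """A required HDF5 attribute is absent from the file."""


_STACK_ATTRS = ("fs_hz", "dz_mm", "lf_mm", "w_mm", "c_mm_per_us", "n0")
_FRAME_ATTRS = ("frame_interval_s", "pixel_mm")


def _require(attrs, names, path):
    for name in names:
        if name not in attrs:
            raise MissingAttributeError(f"{path}: missing required attribute {name!r}")


def write_stack(path, stack: AScanStack) -> None:
    g = stack.geometry
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=stack.samples)
        d.attrs.update(
            fs_hz=g.fs_hz, dz_mm=g.dz_mm, lf_mm=g.lf_mm, w_mm=g.w_mm,
            c_mm_per_us=g.c_mm_per_us, n0=g.n0,
        )


def read_stack(path) -> AScanStack:
    with h5py.File(path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{path}: missing dataset 'data'")
        d = f["data"]
        _require(d.attrs, _STACK_ATTRS, path)
        geom = ScanGeometry(
            lf_mm=float(d.attrs["lf_mm"]), w_mm=float(d.attrs["w_mm"]),
            dz_mm=float(d.attrs["dz_mm"]), fs_hz=float(d.attrs["fs_hz"]),
            c_mm_per_us=float(d.attrs["c_mm_per_us"]), n0=float(d.attrs["n0"]),
        )
        return AScanStack(samples=d[()], geometry=geom)


def write_frames(path, series: FrameSeries) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(
            path, series.frames.astype(np.float32),
            metadata={"frame_interval_s": series.frame_interval_s,
                      "pixel_mm": series.pixel_mm},
        )
    else:
        with h5py.File(path, "w") as f:
            d = f.create_dataset("frames", data=series.frames)
            d.attrs.update(
                frame_interval_s=series.frame_interval_s, pixel_mm=series.pixel_mm
            )


def read_frames(path) -> FrameSeries:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        _require(meta, _FRAME_ATTRS, path)
        return FrameSeries(
            frames=np.asarray(frames, dtype=float),
            frame_interval_s=float(meta["frame_interval_s"]),
            pixel_mm=float(meta["pixel_mm"]),
        )
    with h5py.File(path, "r") as f:
        if "frames" not in f:
            raise ValueError(f"{path}: missing dataset 'frames'")
        d = f["frames"]
        _require(d.attrs, _FRAME_ATTRS, path)
        return FrameSeries(
            frames=d[()],
            frame_interval_s=float(d.attrs["frame_interval_s"]),
            pixel_mm=float(d.attrs["pixel_mm"]),
        )


def write_tissue(path, tissue: TissueModel) -> None:
    mu_a, mu_s, g = tissue.property_grids()
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=tissue.labels)
        f.create_dataset("mu_a", data=mu_a)
        f.create_dataset("mu_s", data=mu_s)
        f.create_dataset("g", data=g)
        f.attrs["spacing_mm"] = tissue.spacing_mm


def read_tissue(path) -> TissueModel:
    with h5py.File(path, "r") as f:
        for ds in ("labels", "mu_a", "mu_s", "g"):
            if ds not in f:
                raise ValueError(f"{path}: missing dataset {ds!r}")
        if "spacing_mm" not in f.attrs:
            raise MissingAttributeError(f"{path}: missing required attribute 'spacing_mm'")
        labels = f["labels"][()]
        mu_a, mu_s, g = f["mu_a"][()], f["mu_s"][()], f["g"][()]
        props = {}
        for lbl in np.unique(labels):
            m = labels == lbl
            props[int(lbl)] = OpticalProperties(
                mu_a=float(mu_a[m].flat[0]), mu_s=float(mu_s[m].flat[0]),
                g=float(g[m].flat[0]),
            )
        return TissueModel(
            labels=labels, properties=props, spacing_mm=float(f.attrs["spacing_mm"])
        )


def write_fluence(path, fmap: FluenceMap) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("fluence", data=fmap.fluence)
        d.attrs.update(n_photons=fmap.n_photons, seed=fmap.seed)
        for k, v in fmap.balance.items():
            d.attrs[f"balance_{k}"] = v


def read_fluence(path) -> FluenceMap:
    with h5py.File(path, "r") as f:
        if "fluence" not in f:
            raise ValueError(f"{path}: missing dataset 'fluence'")
        d = f["fluence"]
        _require(d.attrs, ("n_photons", "seed"), path)
        balance = {
            k[len("balance_"):]: float(v)
            for k, v in d.attrs.items()
            if k.startswith("balance_")
        }
        return FluenceMap(
            fluence=d[()], n_photons=int(d.attrs["n_photons"]),
            seed=int(d.attrs["seed"]), balance=balance,
        )
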