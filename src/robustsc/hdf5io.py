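"""HDF5 and image I/O for matrices, decompositions, dictionaries and codes.

Datasets are written with ``track_times=False`` so that identical inputs
produce byte-identical files, which the run manifest relies on.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np

from .dictionary import Dictionary
from .rpca import RPCAResult
from .solvers import SparseCode
from .synthetic import ImageStack, PatchMatrix

__all__ = [
    "save_patches", "load_patches",
    "save_decomposition", "load_decomposition",
    "save_dictionary", "load_dictionary",
    "save_codes", "load_codes",
    "read_image_stack", "save_filter_mosaic",
]

_DS_OPTS = dict(track_times=False)


def save_patches(path, P: PatchMatrix) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=P.data, **_DS_OPTS)
        d.attrs["patch_shape"] = np.asarray(P.patch_shape, dtype=np.int64)
        d.attrs["normalized"] = bool(P.normalized)


def load_patches(path) -> PatchMatrix:
    with h5py.File(path, "r") as f:
        d = f["data"]
        return PatchMatrix(
            data=d[()],
            patch_shape=tuple(int(v) for v in d.attrs["patch_shape"]),
            normalized=bool(d.attrs.get("normalized", False)),
        )


def save_decomposition(path, res: RPCAResult) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("L", data=res.L, **_DS_OPTS)
        f.create_dataset("S", data=res.S, **_DS_OPTS)
        f.attrs["lambda_abs"] = res.lambda_abs
        f.attrs["lambda_norm"] = res.lambda_norm
        f.attrs["iterations"] = res.iterations
        f.attrs["constraint_violation"] = res.constraint_violation
        f.attrs["converged"] = bool(res.converged)


def load_decomposition(path) -> RPCAResult:
    with h5py.File(path, "r") as f:
        return RPCAResult(
            L=f["L"][()], S=f["S"][()],
            lambda_abs=float(f.attrs["lambda_abs"]),
            lambda_norm=float(f.attrs["lambda_norm"]),
            iterations=int(f.attrs["iterations"]),
            constraint_violation=float(f.attrs["constraint_violation"]),
            converged=bool(f.attrs["converged"]),
        )


def save_dictionary(path, D: Dictionary) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("A", data=D.A, **_DS_OPTS)
        d.attrs["n"] = D.n
        d.attrs["m"] = D.m
        if D.seed is not None:
            d.attrs["seed"] = int(D.seed)


def load_dictionary(path) -> Dictionary:
    with h5py.File(path, "r") as f:
        d = f["A"]
        seed = int(d.attrs["seed"]) if "seed" in d.attrs else None
        return Dictionary(A=d[()], seed=seed)


def save_codes(path, codes: list[SparseCode]) -> None:
    """Store codes as sparse triplets (column, atom index, value)."""
    cols, idxs, vals = [], [], []
    for t, code in enumerate(codes):
        for j, v in zip(code.support, code.coefficients):
            cols.append(t)
            idxs.append(int(j))
            vals.append(float(v))
    with h5py.File(path, "w") as f:
        f.create_dataset("column", data=np.asarray(cols, dtype=np.int64),
                         **_DS_OPTS)
        f.create_dataset("index", data=np.asarray(idxs, dtype=np.int64),
                         **_DS_OPTS)
        f.create_dataset("value", data=np.asarray(vals, dtype=float), **_DS_OPTS)
        f.create_dataset(
            "residual_norm",
            data=np.asarray([c.residual_norm for c in codes], dtype=float),
            **_DS_OPTS)


def load_codes(path) -> list[SparseCode]:
    with h5py.File(path, "r") as f:
        cols = f["column"][()]
        idxs = f["index"][()]
        vals = f["value"][()]
        res = f["residual_norm"][()]
    codes = []
    for t in range(res.size):
        mask = cols == t
        codes.append(SparseCode(support=idxs[mask], coefficients=vals[mask],
                                residual_norm=float(res[t])))
    return codes


def read_image_stack(paths, provenance: str = "") -> ImageStack:
    """Read grayscale PNG/PGM images of a common size into a stack."""
    imgs = []
    for p in paths:
        arr = np.asarray(iio.imread(Path(p)), dtype=float)
        if arr.ndim == 3:  # collapse RGB(A) to luminance
            arr = arr[..., :3].mean(axis=2)
        imgs.append(arr)
    return ImageStack(pixels=np.stack(imgs, axis=2),
                      provenance=provenance or ",".join(str(p) for p in paths))


def save_filter_mosaic(path, filters, patch_side: int,
                       n_cols: int = 8, pad: int = 1) -> None:
    """Write a PNG mosaic; each filter is min-max scaled into [0, 1]."""
    mat = np.asarray(getattr(filters, "A", filters), dtype=float)
    n_filters = mat.shape[1]
    n_rows = int(np.ceil(n_filters / n_cols))
    tile = patch_side + pad
    canvas = np.full((n_rows * tile + pad, n_cols * tile + pad), 0.5)
    for j in range(n_filters):
        patch = mat[:, j].reshape(patch_side, patch_side)
        lo, hi = patch.min(), patch.max()
        scaled = (patch - lo) / (hi - lo) if hi > lo else np.full_like(patch, 0.5)
        r, c = divmod(j, n_cols)
        canvas[pad + r * tile: pad + r * tile + patch_side,
               pad + c * tile: pad + c * tile + patch_side] = scaled
    iio.imwrite(Path(path), (canvas * 255).astype(np.uint8))
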