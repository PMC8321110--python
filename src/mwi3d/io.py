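"""HDF5 / NIfTI / JSON serialization of pipeline artifacts."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .csi import ReconstructionStack
from .forward import FieldDataSet, ProbeArray
from .grids import VoxelGrid
from .phantoms import PermittivityVolume, TissueMap

__all__ = [
    "save_phantom",
    "load_phantom",
    "save_fields",
    "load_fields",
    "save_stack",
    "load_stack",
    "save_training_pairs",
    "load_training_pairs",
    "save_mask_nifti",
    "write_json",
]


def _write_grid(group, grid: VoxelGrid):
    group.attrs["shape"] = grid.shape
    group.attrs["spacing"] = grid.spacing
    group.attrs["origin"] = grid.origin


def _read_grid(group) -> VoxelGrid:
    return VoxelGrid(shape=tuple(int(s) for s in group.attrs["shape"]),
                     spacing=float(group.attrs["spacing"]),
                     origin=tuple(float(o) for o in group.attrs["origin"]))


def save_phantom(path, tissue: TissueMap, eps: PermittivityVolume | None = None,
                 background: PermittivityVolume | None = None,
                 seed: int | None = None):
    """Phantom (labels, optional permittivities) in one HDF5 file."""
    with h5py.File(path, "w") as f:
        _write_grid(f, tissue.grid)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        f.create_dataset("labels", data=tissue.labels)
        for name, vol in (("eps", eps), ("background", background)):
            if vol is not None:
                f.create_dataset(f"{name}_real", data=vol.values.real)
                f.create_dataset(f"{name}_imag", data=vol.values.imag)


def load_phantom(path):
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        tissue = TissueMap(grid, f["labels"][...])
        out = {"tissue": tissue}
        for name in ("eps", "background"):
            if f"{name}_real" in f:
                vals = f[f"{name}_real"][...] + 1j * f[f"{name}_imag"][...]
                out[name] = PermittivityVolume(grid, vals, check_floor=False)
        if "seed" in f.attrs:
            out["seed"] = int(f.attrs["seed"])
    return out


def save_fields(path, datasets, probes: ProbeArray, seed: int | None = None):
    """Per-frequency multistatic matrices in one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("probes", data=probes.positions)
        if seed is not None:
            f.attrs["rng_seed"] = int(seed)
        for i, ds in enumerate(datasets):
            g = f.create_group(f"freq_{i}")
            g.attrs["frequency_hz"] = ds.frequency
            g.attrs["noise_level"] = ds.noise_level
            g.create_dataset("data", data=ds.matrix)


def load_fields(path):
    with h5py.File(path, "r") as f:
        probes = ProbeArray(f["probes"][...])
        datasets = []
        keys = sorted((k for k in f.keys() if k.startswith("freq_")),
                      key=lambda k: int(k.split("_")[1]))
        for key in keys:
            g = f[key]
            datasets.append(FieldDataSet(
                frequency=float(g.attrs["frequency_hz"]),
                matrix=g["data"][...],
                noise_level=float(g.attrs["noise_level"])))
    return datasets, probes


def save_stack(path, stack: ReconstructionStack):
    with h5py.File(path, "w") as f:
        _write_grid(f, stack.grid)
        for i, freq in enumerate(stack.frequencies):
            g = f.create_group(f"recon_f{i}")
            g.attrs["frequency_hz"] = freq
            g.create_dataset("eps_real", data=stack.volumes[i].real)
            g.create_dataset("eps_imag", data=stack.volumes[i].imag)
            if stack.cost_histories is not None:
                g.create_dataset("cost_history",
                                 data=stack.cost_histories[i])


def load_stack(path) -> ReconstructionStack:
    with h5py.File(path, "r") as f:
        grid = _read_grid(f)
        freqs, vols, costs = [], [], []
        keys = sorted((k for k in f.keys() if k.startswith("recon_f")),
                      key=lambda k: int(k.split("recon_f")[1]))
        for key in keys:
            g = f[key]
            freqs.append(float(g.attrs["frequency_hz"]))
            vols.append(g["eps_real"][...] + 1j * g["eps_imag"][...])
            costs.append(g["cost_history"][...] if "cost_history" in g else None)
    return ReconstructionStack(grid=grid, frequencies=tuple(freqs),
                               volumes=np.stack(vols), cost_histories=costs)


def save_training_pairs(path, x: np.ndarray, y: np.ndarray):
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=x, compression="gzip")
        f.create_dataset("y", data=y, compression="gzip")


def load_training_pairs(path):
    with h5py.File(path, "r") as f:
        return f["x"][...], f["y"][...]


def save_mask_nifti(path, mask: np.ndarray, spacing: float):
    """Detection mask as NIfTI (2-D masks become single-slice volumes)."""
    import nibabel as nib

    arr = np.asarray(mask, dtype=np.uint8)
    if arr.ndim == 2:
        arr = arr[..., None]
    affine = np.diag([spacing * 1e3] * 3 + [1.0])  # mm units
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_json(path, obj):
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True)
        f.write("\n")
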