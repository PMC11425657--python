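"""File formats: NIfTI/PNG phantoms, HDF5 sinograms and training sets,
checkpointed network weights with a JSON metadata sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from PIL import Image

from .errors import CheckpointError
from .phantoms import ActivityPhantom, TrainingPair
from .projection import ImageTensor, Sinogram

__all__ = [
    "save_phantom_nifti", "load_phantom_nifti", "save_phantom_png",
    "save_sinogram_h5", "load_sinogram_h5",
    "save_training_set_h5", "load_training_set_h5",
    "save_checkpoint", "load_checkpoint",
]


def save_phantom_nifti(phantom: ActivityPhantom, path) -> None:
    affine = np.diag([phantom.pixel_size_mm, phantom.pixel_size_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(phantom.values[:, :, None], affine), str(path))


def load_phantom_nifti(path) -> ActivityPhantom:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[:, :, 0]
    pixel = float(abs(img.affine[0, 0])) or 1.0
    return ActivityPhantom(np.clip(data, 0, None), pixel_size_mm=pixel)


def save_phantom_png(phantom: ActivityPhantom, path) -> None:
    """8-bit preview (min-max scaled)."""
    v = phantom.values
    span = v.max() - v.min()
    scaled = (255 * (v - v.min()) / span).astype(np.uint8) if span else np.zeros_like(v, np.uint8)
    Image.fromarray(scaled).save(str(path))


def save_sinogram_h5(sino: Sinogram, path) -> None:
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("values", data=sino.values)
        fh.create_dataset("angles_deg", data=sino.angles_deg)
        fh.attrs["radial_spacing_mm"] = sino.radial_spacing_mm
        fh.attrs["counts_flag"] = sino.counts_flag


def load_sinogram_h5(path) -> Sinogram:
    with h5py.File(str(path), "r") as fh:
        return Sinogram(
            fh["values"][()], fh["angles_deg"][()],
            radial_spacing_mm=float(fh.attrs.get("radial_spacing_mm", 1.0)),
            counts_flag=bool(fh.attrs.get("counts_flag", False)),
        )


def save_training_set_h5(pairs: list[TrainingPair], path, seed: int | None = None,
                         params: dict | None = None) -> None:
    """Datasets ``targets`` (N, H, W, 3) and ``sinograms`` (N, A, R), with
    per-pair normalization metadata and the generator seed as attributes."""
    targets = np.stack([p.target.values for p in pairs])
    sinos = np.stack([p.sinogram.values for p in pairs])
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("targets", data=targets)
        fh.create_dataset("sinograms", data=sinos)
        fh.create_dataset("angles_deg", data=pairs[0].sinogram.angles_deg)
        fh.create_dataset("target_vmin", data=[p.target.vmin for p in pairs])
        fh.create_dataset("target_vmax", data=[p.target.vmax for p in pairs])
        if seed is not None:
            fh.attrs["seed"] = seed
        fh.attrs["params"] = json.dumps(params or {})


def load_training_set_h5(path) -> list[TrainingPair]:
    with h5py.File(str(path), "r") as fh:
        targets = fh["targets"][()]
        sinos = fh["sinograms"][()]
        angles = fh["angles_deg"][()]
        vmins = fh["target_vmin"][()]
        vmaxs = fh["target_vmax"][()]
    return [
        TrainingPair(
            ImageTensor(t, role="target", vmin=float(lo), vmax=float(hi)),
            Sinogram(s, angles),
        )
        for t, s, lo, hi in zip(targets, sinos, vmins, vmaxs)
    ]


def save_checkpoint(model, path, metadata: dict | None = None) -> None:
    """Weights as an .npz plus a JSON sidecar (spec name, seed, step...)."""
    path = Path(path)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = dict(metadata or {})
    sidecar["n_arrays"] = len(arrays)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_checkpoint(model, path) -> dict:
    path = Path(path)
    npz_path = path.with_suffix(".npz")
    if not npz_path.exists():
        raise CheckpointError(f"no checkpoint at {npz_path}")
    with np.load(npz_path) as data:
        arrays = [data[f"p{i}"] for i in range(len(data.files))]
    try:
        model.load_state_arrays(arrays)
    except ValueError as exc:
        raise CheckpointError(str(exc)) from exc
    sidecar = path.with_suffix(".json")
    return json.loads(sidecar.read_text()) if sidecar.exists() else {}
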