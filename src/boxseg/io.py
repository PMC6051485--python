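"""Readers/writers for images, volumes and network checkpoints.

2D data goes through PNG/TIFF (8/16-bit grayscale scaled to [0, 1] on
read), 3D through NIfTI.  Checkpoints are numpy ``.npz`` archives holding
every parameter array plus the JSON-serialized network spec and its hash,
so a checkpoint can rebuild its own architecture and detect mismatches.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import tifffile

from .errors import InputError
from .networks import Network, NetworkSpec

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def read_image(path) -> np.ndarray:
    """Read a 2D image or 3D volume as a float array (intensities as stored;
    integer images are scaled to [0, 1])."""
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.asarray(data, dtype=np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float32) / float(np.iinfo(arr.dtype).max)
    return arr.astype(np.float32)


def read_labels(path) -> np.ndarray:
    """Read an integer label map (values kept verbatim)."""
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(str(path)).dataobj)
    elif path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
    else:
        data = iio.imread(str(path))
        if data.ndim == 3 and data.shape[-1] in (3, 4):
            data = data[..., 0]
    return np.asarray(np.rint(data), dtype=np.int32)


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.astype(np.uint8), np.eye(4)), str(path))
    elif path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), mask.astype(np.uint8))
    else:
        iio.imwrite(str(path), (mask.astype(np.uint8) * 255))


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(image.astype(np.float32), np.eye(4)), str(path))
    else:
        arr = np.clip(image, 0.0, 1.0)
        iio.imwrite(str(path), (arr * 255).astype(np.uint8))


def save_checkpoint(path, net: Network) -> None:
    payload = {f"param/{k}": v for k, v in net.parameters().items()}
    payload["spec_json"] = np.frombuffer(net.spec.to_json().encode(), dtype=np.uint8)
    payload["spec_hash"] = np.frombuffer(net.spec.hash().encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **payload)


def load_checkpoint(path) -> Network:
    with np.load(path) as data:
        spec_json = bytes(data["spec_json"]).decode()
        spec_hash = bytes(data["spec_hash"]).decode()
        spec = NetworkSpec.from_json(spec_json)
        if spec.hash() != spec_hash:
            raise InputError("checkpoint spec hash mismatch: file is corrupt")
        net = Network(spec)
        params = {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
    net.set_parameters(params)
    return net


def write_manifest(path, entries: list[dict]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2)
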