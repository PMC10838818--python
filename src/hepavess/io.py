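"""Reading and writing volumes in NIfTI and MetaImage containers.

SimpleITK does the format work; this module only adapts between its
``(z, y, x)`` array order and the package's ``(x, y, z)`` convention and
validates dimensionality.  Masks are stored as unsigned 8-bit, probability
and vesselness maps as float32.
"""

from __future__ import annotations

import os

import numpy as np
import SimpleITK as sitk

from .errors import DimensionalityError, FormatError, HepavessError
from .volume import Mask, Volume

__all__ = ["read_volume", "read_mask", "write_volume"]

_SUPPORTED = (".nii", ".nii.gz", ".mhd", ".mha")


def _check_suffix(path: str) -> None:
    if not any(str(path).endswith(s) for s in _SUPPORTED):
        raise FormatError(
            f"unsupported container for {path!r}; expected one of {_SUPPORTED}"
        )


def read_volume(path: str) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) file.

    Spacing and origin are taken from the file header; intensities are
    returned unmodified.
    """
    _check_suffix(path)
    if not os.path.exists(path) and not os.path.exists(str(path).replace(".mhd", ".raw")):
        raise FormatError(f"cannot read volume: no such file {path!r}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # sitk raises RuntimeError on garbage input
        raise FormatError(f"cannot read volume {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise DimensionalityError(
            f"{path!r} is {img.GetDimension()}D; a 3D volume is required"
        )
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(np.transpose(data, (2, 1, 0)))
    return Volume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def read_mask(path: str) -> Mask:
    """Read a binary mask; values must be {0, 1}."""
    v = read_volume(path)
    return Mask(np.rint(v.data).astype(np.uint8), v.spacing, v.origin)


def write_volume(v: Volume, path: str) -> None:
    """Write a volume; the container is chosen from the file suffix.

    Round-trips through :func:`read_volume` preserve grid metadata exactly,
    integer data bit-identically and float data within float32 precision.
    """
    _check_suffix(path)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise HepavessError(f"cannot write {path!r}: directory {parent!r} does not exist")
    data = v.data
    if isinstance(v, Mask) or data.dtype == np.uint8:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise HepavessError(f"cannot write volume to {path!r}: {exc}") from exc
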