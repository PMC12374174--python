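"""Volume input/output and Hounsfield-unit quantization.

Conventions used throughout the package:

* volumes are 3-D arrays indexed ``(x, y, z)`` (0-based, voxel-center
  convention), matching the NIfTI i/j/k axes as returned by nibabel;
* ``spacing`` is the physical voxel size ``(sx, sy, sz)`` in millimetres;
* all physical distances are millimetres, all intensities Hounsfield
  units (HU).

The quantizer maps HU to a small number of equal-width intensity levels
(default 32 levels over [-1000, 3000] HU, i.e. 125 HU per level) before
gray-level co-occurrence matrices are built, so the texture features are
insensitive to minor intensity fluctuations.  HU outside the range are
clamped to the range before binning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "VesselMask",
    "QuantizedVolume",
    "read_ct_volume",
    "read_mask",
    "quantize_hu",
    "quantize_values",
    "write_label_volume",
]

DEFAULT_HU_MIN = -1000.0
DEFAULT_HU_MAX = 3000.0
DEFAULT_N_LEVELS = 32


@dataclass
class CTVolume:
    """A 3-D scalar CT field in Hounsfield units with voxel geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            raise ValueError(f"volume contains {int(bad.sum())} non-finite voxels")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class VesselMask:
    """Binary vessel segmentation bound to a reference geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        vals = np.unique(arr)
        bad = [v for v in vals if v not in (0, 1)]
        if bad:
            raise ValueError(f"mask values must be in {{0,1}}, found {bad}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass
class QuantizedVolume:
    """Volume of integer intensity levels in ``[0, n_levels - 1]``."""

    data: np.ndarray
    n_levels: int
    hu_min: float
    hu_max: float
    spacing: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.data.min() < 0 or self.data.max() > self.n_levels - 1:
            raise ValueError("quantized levels out of range")

    @property
    def level_width_hu(self) -> float:
        return (self.hu_max - self.hu_min) / self.n_levels


def _spacing_from_header(img) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def read_ct_volume(path) -> CTVolume:
    """Read a 3-D NIfTI scalar image; values are assumed already in HU."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D image in {path}")
    data = np.asarray(data, dtype=np.float64)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return CTVolume(data=data, spacing=_spacing_from_header(img), origin=origin)


def read_mask(path, reference: CTVolume) -> VesselMask:
    """Read a binary NIfTI mask and bind it to ``reference``'s geometry."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such mask: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D mask, got {data.ndim}D image in {path}")
    if data.shape != reference.shape:
        raise ValueError(
            f"mask shape {data.shape} does not match reference {reference.shape}"
        )
    vals = np.unique(data)
    offending = [float(v) for v in vals if not (abs(v) < 1e-6 or abs(v - 1) < 1e-6)]
    if offending:
        raise ValueError(f"mask values must be in {{0,1}}, found {offending}")
    return VesselMask(data=(data > 0.5).astype(np.uint8), spacing=reference.spacing)


def quantize_values(
    values: np.ndarray,
    n_levels: int = DEFAULT_N_LEVELS,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> np.ndarray:
    """Map HU values to integer levels: floor((clamp(v) - hu_min) / w).

    ``w = (hu_max - hu_min) / n_levels``; values equal to ``hu_max`` map
    to ``n_levels - 1``.  Monotone nondecreasing in HU.
    """
    if hu_max <= hu_min:
        raise ValueError("degenerate quantization range (hu_max <= hu_min)")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    w = (hu_max - hu_min) / n_levels
    clamped = np.clip(np.asarray(values, dtype=np.float64), hu_min, hu_max)
    levels = np.floor((clamped - hu_min) / w).astype(np.int32)
    return np.minimum(levels, n_levels - 1)


def quantize_hu(
    vol: CTVolume,
    n_levels: int = DEFAULT_N_LEVELS,
    hu_min: float = DEFAULT_HU_MIN,
    hu_max: float = DEFAULT_HU_MAX,
) -> QuantizedVolume:
    """Quantize a CT volume into equal-width intensity levels."""
    levels = quantize_values(vol.data, n_levels=n_levels, hu_min=hu_min, hu_max=hu_max)
    return QuantizedVolume(
        data=levels, n_levels=n_levels, hu_min=hu_min, hu_max=hu_max,
        spacing=vol.spacing,
    )


def _affine(reference: CTVolume) -> np.ndarray:
    aff = np.diag(list(reference.spacing) + [1.0])
    aff[:3, 3] = reference.origin
    return aff


def write_ct_volume(vol: CTVolume, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), _affine(vol))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: VesselMask, path, origin=(0.0, 0.0, 0.0)) -> None:
    aff = np.diag(list(mask.spacing) + [1.0])
    aff[:3, 3] = origin
    img = nib.Nifti1Image(mask.data.astype(np.uint8), aff)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def write_label_volume(labels: np.ndarray, reference: CTVolume, path,
                       semantic: dict | None = None) -> None:
    """Write an integer label map with the reference geometry.

    Label dialect: 0 = background, 1..k = clusters in semantic order.  An
    optional ``semantic`` dict is written to a JSON sidecar next to the
    NIfTI file.  The round trip through :func:`read_ct_volume` is
    bit-exact for integer labels.
    """
    labels = np.asarray(labels)
    if labels.shape != reference.shape:
        raise ValueError(
            f"labels shape {labels.shape} does not match reference {reference.shape}"
        )
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.all(labels == np.round(labels)):
            raise ValueError("labels must be integer-valued")
        labels = labels.astype(np.int32)
    if labels.min() < 0:
        raise ValueError("labels must be nonnegative")
    img = nib.Nifti1Image(labels.astype(np.int32), _affine(reference))
    img.header.set_zooms(reference.spacing)
    nib.save(img, str(path))
    if semantic is not None:
        sidecar = Path(str(path)).with_suffix("").with_suffix("")
        sidecar = Path(str(sidecar) + ".labels.json")
        sidecar.write_text(json.dumps(semantic, indent=2, sort_keys=True))
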