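"""Reading and writing of diffusion-weighted datasets and tensor fields.

On-disk formats are the field's standard ones: NIfTI-1 images (via nibabel),
FSL-dialect ``.bval``/``.bvec`` text tables, and a JSON sidecar carrying the
acquisition bookkeeping (repetition and breath-hold indices, pixel spacing).

Conventions
-----------
* Images are single-slice 2D; an image stack has shape ``(n_images, H, W)``
  in memory and is stored as ``(H, W, n_images)`` in NIfTI.
* Pixel coordinates are 0-based ``(row, col)``.
* Gradient directions (``bvecs``) live in the image coordinate frame:
  x along +col, y along -row, z along the slice normal (toward the base).
* Tensor components are stored in units of 1e-3 mm^2/s in the fixed order
  ``[Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

#: Fixed channel order of the six unique components of the symmetric tensor.
TENSOR_COMPONENT_ORDER = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")

#: Tolerance on the norm of a diffusion-encoding direction at b > 0.
BVEC_NORM_TOL = 1e-4


@dataclass
class DWIDataset:
    """A stack of 2D diffusion-weighted magnitude images with its protocol.

    Attributes
    ----------
    images : (n, H, W) float array, arbitrary signal units.
    bvals : (n,) b-value per image, s/mm^2.
    bvecs : (n, 3) unit diffusion direction per image (ignored at b = 0).
    rep_index : (n,) int, repetition index of each (b, direction) acquisition.
    bh_index : (n,) int, breath-hold each image was acquired in.
    mask : (H, W) bool, LV myocardium.
    pixel_spacing_mm : (row, col) spacing in mm.
    corrupted : (n,) bool, images flagged by (manual) quality control.
    meta : free-form metadata (e.g. true motion shifts for phantoms).
    """

    images: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    rep_index: np.ndarray
    bh_index: np.ndarray
    mask: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (2.8, 2.8)
    corrupted: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.rep_index = np.asarray(self.rep_index, dtype=int)
        self.bh_index = np.asarray(self.bh_index, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.corrupted is None:
            self.corrupted = np.zeros(len(self.images), dtype=bool)
        else:
            self.corrupted = np.asarray(self.corrupted, dtype=bool)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n = self.images.shape[0]
        if self.images.ndim != 3:
            raise ValueError(f"images must be (n, H, W), got {self.images.shape}")
        if self.mask.shape != self.images.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} != image shape {self.images.shape[1:]}"
            )
        for name, arr in (
            ("bvals", self.bvals),
            ("bvecs", self.bvecs),
            ("rep_index", self.rep_index),
            ("bh_index", self.bh_index),
            ("corrupted", self.corrupted),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} entries for {n} images")
        if self.bvecs.shape != (n, 3):
            raise ValueError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if np.any(self.bh_index < 0):
            raise ValueError("bh_index must be nonnegative")
        dw = self.bvals > 0
        if np.any(dw):
            norms = np.linalg.norm(self.bvecs[dw], axis=1)
            if np.any(np.abs(norms - 1.0) > BVEC_NORM_TOL):
                worst = float(np.abs(norms - 1.0).max())
                raise ValueError(
                    f"non-unit bvec at b > 0 (max |norm-1| = {worst:.2e})"
                )

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.images.shape[1:])

    def select(self, indices) -> "DWIDataset":
        """Sub-dataset containing ``indices`` in the given order."""
        idx = np.asarray(indices, dtype=int)
        return DWIDataset(
            images=self.images[idx],
            bvals=self.bvals[idx],
            bvecs=self.bvecs[idx],
            rep_index=self.rep_index[idx],
            bh_index=self.bh_index[idx],
            mask=self.mask,
            pixel_spacing_mm=self.pixel_spacing_mm,
            corrupted=self.corrupted[idx],
            meta=dict(self.meta),
        )


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor as six components.

    ``components`` has shape ``(H, W, 6)`` ordered per
    :data:`TENSOR_COMPONENT_ORDER`, in units of 1e-3 mm^2/s. Components are
    exactly zero outside the mask and finite inside it.
    """

    components: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components.ndim != 3 or self.components.shape[2] != 6:
            raise ValueError(
                f"components must be (H, W, 6), got {self.components.shape}"
            )
        if self.mask.shape != self.components.shape[:2]:
            raise ValueError("mask/components shape mismatch")
        if not np.all(np.isfinite(self.components[self.mask])):
            raise ValueError("non-finite tensor components inside the mask")
        self.components[~self.mask] = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.components.shape[:2])

    def as_matrices(self) -> np.ndarray:
        """Full ``(H, W, 3, 3)`` symmetric matrices."""
        return components_to_matrices(self.components)


def components_to_matrices(components: np.ndarray) -> np.ndarray:
    """Expand ``(..., 6)`` components into ``(..., 3, 3)`` symmetric matrices."""
    c = np.asarray(components, dtype=float)
    m = np.empty(c.shape[:-1] + (3, 3), dtype=float)
    xx, yy, zz, xy, xz, yz = (c[..., i] for i in range(6))
    m[..., 0, 0] = xx
    m[..., 1, 1] = yy
    m[..., 2, 2] = zz
    m[..., 0, 1] = m[..., 1, 0] = xy
    m[..., 0, 2] = m[..., 2, 0] = xz
    m[..., 1, 2] = m[..., 2, 1] = yz
    return m


def matrices_to_components(matrices: np.ndarray) -> np.ndarray:
    """Inverse of :func:`components_to_matrices`."""
    m = np.asarray(matrices, dtype=float)
    return np.stack(
        [
            m[..., 0, 0],
            m[..., 1, 1],
            m[..., 2, 2],
            m[..., 0, 1],
            m[..., 0, 2],
            m[..., 1, 2],
        ],
        axis=-1,
    )


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

_DWI_NII = "dwi.nii.gz"
_BVAL = "dwi.bval"
_BVEC = "dwi.bvec"
_MASK_NII = "mask.nii.gz"
_SIDECAR = "dwi.json"


def _affine(pixel_spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = pixel_spacing_mm[0]
    aff[1, 1] = pixel_spacing_mm[1]
    return aff


def write_dataset(dataset: DWIDataset, out_dir) -> dict:
    """Write NIfTI stack + .bval/.bvec + mask + JSON sidecar; return the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(dataset.pixel_spacing_mm)
    # NIfTI stores (x, y, volume); memory layout is (volume, row, col).
    nib.save(
        nib.Nifti1Image(np.transpose(dataset.images, (1, 2, 0)), aff),
        out / _DWI_NII,
    )
    nib.save(nib.Nifti1Image(dataset.mask.astype(np.uint8), aff), out / _MASK_NII)
    np.savetxt(out / _BVAL, dataset.bvals[None, :], fmt="%.6g")
    # FSL dialect: three rows = x, y, z components.
    np.savetxt(out / _BVEC, dataset.bvecs.T, fmt="%.17g")
    sidecar = {
        "rep_index": dataset.rep_index.tolist(),
        "bh_index": dataset.bh_index.tolist(),
        "pixel_spacing_mm": list(dataset.pixel_spacing_mm),
        "corrupted": dataset.corrupted.astype(int).tolist(),
        "axis_order": "row, col, volume",
        "meta": _jsonable(dataset.meta),
    }
    (out / _SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return {
        "dwi": out / _DWI_NII,
        "bval": out / _BVAL,
        "bvec": out / _BVEC,
        "mask": out / _MASK_NII,
        "sidecar": out / _SIDECAR,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def read_dataset(in_dir) -> DWIDataset:
    """Load and validate a dataset written by :func:`write_dataset`.

    Raises on volume/bval/bvec count mismatch or shape mismatch. A missing
    sidecar is tolerated: each volume is then assigned its own breath-hold
    (logged as a warning).
    """
    src = Path(in_dir)
    img = np.asarray(nib.load(src / _DWI_NII).dataobj, dtype=float)
    if img.ndim != 3:
        raise ValueError(f"expected a 3D (x, y, volume) NIfTI, got shape {img.shape}")
    images = np.transpose(img, (2, 0, 1))
    n = images.shape[0]
    bvals = np.atleast_1d(np.loadtxt(src / _BVAL, dtype=float).ravel())
    bvecs = np.loadtxt(src / _BVEC, dtype=float)
    bvecs = np.atleast_2d(bvecs)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    if len(bvals) != n:
        raise ValueError(f"{n} volumes but {len(bvals)} b-values")
    if bvecs.shape != (n, 3):
        raise ValueError(f"{n} volumes but bvec table of shape {bvecs.shape}")
    mask = np.asarray(nib.load(src / _MASK_NII).dataobj) > 0
    if mask.shape != images.shape[1:]:
        raise ValueError("mask/volume shape mismatch")
    sidecar_path = src / _SIDECAR
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        rep = np.asarray(sidecar["rep_index"], dtype=int)
        bh = np.asarray(sidecar["bh_index"], dtype=int)
        spacing = tuple(sidecar.get("pixel_spacing_mm", (2.8, 2.8)))
        corrupted = np.asarray(sidecar.get("corrupted", np.zeros(n)), dtype=bool)
        meta = sidecar.get("meta", {})
    else:
        logger.warning(
            "no JSON sidecar in %s; assigning each volume its own breath-hold", src
        )
        rep = np.zeros(n, dtype=int)
        bh = np.arange(n, dtype=int)
        spacing = (2.8, 2.8)
        corrupted = np.zeros(n, dtype=bool)
        meta = {}
    return DWIDataset(
        images=images,
        bvals=bvals,
        bvecs=bvecs,
        rep_index=rep,
        bh_index=bh,
        mask=mask,
        pixel_spacing_mm=spacing,
        corrupted=corrupted,
        meta=meta,
    )


def write_tensor(field: TensorField, path, pixel_spacing_mm=(2.8, 2.8)) -> Path:
    """Write a tensor field as a 6-channel NIfTI (x, y, component).

    Channels follow :data:`TENSOR_COMPONENT_ORDER`. The mask is not stored
    here; it travels as its own NIfTI (see :func:`write_dataset`) and can be
    passed back to :func:`read_tensor`.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(field.components, _affine(pixel_spacing_mm)), path)
    return path


def read_tensor(path, mask: np.ndarray | None = None) -> TensorField:
    """Inverse of :func:`write_tensor`; rejects unexpected channel counts.

    If ``mask`` is not given, the support of the stored components is used
    (a voxel is in-mask iff any component is nonzero).
    """
    data = np.asarray(nib.load(path).dataobj, dtype=float)
    if data.ndim != 3 or data.shape[2] != 6:
        got = data.shape[2] if data.ndim == 3 else None
        raise ValueError(f"expected 6 tensor channels, got {got} (shape {data.shape})")
    if mask is None:
        mask = np.any(data != 0.0, axis=2)
    return TensorField(components=data, mask=np.asarray(mask, bool))


def write_map(arr: np.ndarray, path, pixel_spacing_mm=(2.8, 2.8)) -> Path:
    """Write a scalar 2D map (NaN allowed) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(arr, float), _affine(pixel_spacing_mm)), path)
    return path


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj, dtype=float)
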