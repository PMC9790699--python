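"""Preprocessing: registration, breath-hold reduction, averaging, normalization.

The reduced-acquisition schemes are named by breath-hold count:

* ``5BH``: four repetitions of b0 and of the six-direction b600 set, plus
  one six-direction b150 set (34 images).
* ``3BH``: two repetitions of b0 and b600, one b150 set (20 images).
* ``1BH``: a single b0 plus one six-direction b600 set (7 images).

Selection uses the first breath-holds in acquisition order; an image flagged
as corrupted is replaced by its counterpart from the next breath-hold of the
same kind.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from skimage.transform import downscale_local_mean

from .io import DWIDataset

logger = logging.getLogger(__name__)

#: (number of b600 breath-holds, number of b150 breath-holds) per scheme.
SCHEME_COMPOSITION = {"5BH": (4, 1), "3BH": (2, 1), "1BH": (1, 0)}

#: Fixed tensor normalization factor used for network-scale components.
TENSOR_NORM_FACTOR = 500.0

#: Physical unit (mm^2/s) in which components are expressed before dividing
#: by the factor; internal storage is 1e-3 mm^2/s. On this scale the factor
#: of 500 maps typical myocardial tensors (MD ~ 1e-3 mm^2/s) well inside
#: [-1, 1], which is the stated purpose of the normalization.
TENSOR_NORM_UNIT_MM2_S = 1e-5


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------


def register_translation(
    dataset: DWIDataset,
    reference_index: int = 0,
    levels: int = 3,
    upsample_factor: int = 10,
):
    """Rigid sub-pixel translation registration to a reference image.

    Multiresolution: integer shifts are estimated coarse-to-fine on a
    2x-downsampled pyramid with ``levels`` levels, then refined at full
    resolution by upsampled cross-correlation (default 0.1-px precision).
    Images are resampled with cubic splines (zero padding).

    Returns ``(registered_dataset, shifts)`` where ``shifts[i]`` is the
    estimated (row, col) displacement of image i relative to the reference
    (the correction applied is its negative). A flat (zero-variance) image
    gets shift (0, 0) and a log entry.
    """
    if not 0 <= reference_index < dataset.n_images:
        raise ValueError(f"reference index {reference_index} out of range")
    ref = dataset.images[reference_index]
    shifts = np.zeros((dataset.n_images, 2))
    out = dataset.images.copy()
    pyramids_ref = _pyramid(ref, levels)
    for i in range(dataset.n_images):
        img = dataset.images[i]
        if np.ptp(img) == 0:
            logger.info("image %d is flat; shift set to (0, 0)", i)
            continue
        pyramids_img = _pyramid(img, levels)
        correction = np.zeros(2)  # shift to apply to the image to align it
        for lev in range(levels - 1, -1, -1):
            scale = 2**lev
            moving = pyramids_img[lev]
            moved = (
                ndimage.shift(moving, correction / scale, order=3, cval=0.0)
                if np.any(correction)
                else moving
            )
            usf = upsample_factor if lev == 0 else 1
            resid, _, _ = phase_cross_correlation(
                pyramids_ref[lev], moved, upsample_factor=usf, normalization=None
            )
            correction += np.asarray(resid) * scale
        # estimated displacement of the image relative to the reference
        shifts[i] = -correction
        if np.any(correction):
            out[i] = ndimage.shift(img, correction, order=3, cval=0.0)
    registered = DWIDataset(
        images=out,
        bvals=dataset.bvals,
        bvecs=dataset.bvecs,
        rep_index=dataset.rep_index,
        bh_index=dataset.bh_index,
        mask=dataset.mask,
        pixel_spacing_mm=dataset.pixel_spacing_mm,
        corrupted=dataset.corrupted,
        meta={**dataset.meta, "estimated_shifts_px": shifts.tolist()},
    )
    return registered, shifts


def _pyramid(img: np.ndarray, levels: int):
    pyr = [img]
    for _ in range(levels - 1):
        pyr.append(downscale_local_mean(pyr[-1], (2, 2)))
    return pyr


# ---------------------------------------------------------------------------
# breath-hold reduction
# ---------------------------------------------------------------------------


def _bh_kind(dataset: DWIDataset, bh: int) -> float:
    """The diffusion weighting of a breath-hold's six-direction set."""
    sel = (dataset.bh_index == bh) & (dataset.bvals > 0)
    bs = np.unique(dataset.bvals[sel])
    if len(bs) != 1:
        raise ValueError(f"breath-hold {bh} holds {len(bs)} distinct b > 0 values")
    return float(bs[0])


def _replace_corrupted(dataset: DWIDataset, idx: int, same_kind_bhs: list[int]) -> int:
    """Index of the counterpart image in the next clean same-kind breath-hold."""
    b, g = dataset.bvals[idx], dataset.bvecs[idx]
    bh = dataset.bh_index[idx]
    later = [h for h in same_kind_bhs if h > bh]
    for h in later:
        cand = np.nonzero(
            (dataset.bh_index == h)
            & (dataset.bvals == b)
            & (np.linalg.norm(dataset.bvecs - g, axis=1) < 1e-9)
            & ~dataset.corrupted
        )[0]
        if len(cand):
            return int(cand[0])
    raise ValueError(
        f"corrupted image {idx} (b={b:g}, breath-hold {bh}) has no clean "
        "replacement in a later breath-hold"
    )


def subset_breath_holds(dataset: DWIDataset, scheme: str) -> DWIDataset:
    """Reduced dataset from the first breath-holds, per the named scheme.

    The b0 images come from the selected b600 breath-holds; the b150
    breath-hold (5BH/3BH only) contributes its six diffusion-weighted images.
    Corrupted images are replaced by the next breath-hold's counterpart.
    Raises when there are not enough clean breath-holds, naming the shortfall.
    """
    if scheme not in SCHEME_COMPOSITION:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {list(SCHEME_COMPOSITION)}")
    need600, need150 = SCHEME_COMPOSITION[scheme]
    bh_order = sorted(set(dataset.bh_index.tolist()))
    kinds = {bh: _bh_kind(dataset, bh) for bh in bh_order}
    dw_bvals = sorted(set(kinds.values()))
    b600 = max(dw_bvals)
    b150 = min(dw_bvals) if len(dw_bvals) > 1 else None
    bhs_600 = [bh for bh in bh_order if kinds[bh] == b600]
    bhs_150 = [bh for bh in bh_order if b150 is not None and kinds[bh] == b150]
    if len(bhs_600) < need600:
        raise ValueError(
            f"scheme {scheme} needs {need600} b={b600:g} breath-holds, "
            f"dataset has {len(bhs_600)}"
        )
    if need150 and len(bhs_150) < need150:
        raise ValueError(
            f"scheme {scheme} needs {need150} low-b breath-hold(s), "
            f"dataset has {len(bhs_150)}"
        )
    indices = []
    for bh in bhs_600[:need600]:
        sel = np.nonzero(dataset.bh_index == bh)[0]
        for idx in sel:
            if dataset.corrupted[idx]:
                idx = _replace_corrupted(dataset, idx, bhs_600)
            indices.append(idx)
    for bh in bhs_150[:need150]:
        sel = np.nonzero((dataset.bh_index == bh) & (dataset.bvals > 0))[0]
        for idx in sel:
            if dataset.corrupted[idx]:
                idx = _replace_corrupted(dataset, idx, bhs_150)
            indices.append(idx)
    return dataset.select(indices)


# ---------------------------------------------------------------------------
# repetition averaging
# ---------------------------------------------------------------------------


@dataclass
class AveragedStack:
    """Repetition-averaged image stack with per-channel protocol metadata."""

    channels: np.ndarray  # (C, H, W)
    bvals: np.ndarray  # (C,)
    bvecs: np.ndarray  # (C, 3)
    mask: np.ndarray

    @property
    def n_channels(self) -> int:
        return int(self.channels.shape[0])


def average_repetitions(dataset: DWIDataset) -> AveragedStack:
    """Pixel-wise mean over repetitions, per b-value and direction.

    Channel order: the (single) averaged b0 first, then the six b600
    directions, then the six b150 directions when present - 13 channels with
    b150, 7 without. All repetitions must share the direction set (error on
    mismatch).
    """
    b0_sel = dataset.bvals == 0
    channels, bvals, bvecs = [], [], []
    if b0_sel.any():
        channels.append(dataset.images[b0_sel].mean(axis=0))
        bvals.append(float(dataset.bvals[b0_sel][0]))
        bvecs.append(np.zeros(3))
    dw_bs = sorted({float(b) for b in dataset.bvals[~b0_sel]}, reverse=True)
    ref_dirs = None
    for b in dw_bs:
        sel = np.nonzero(dataset.bvals == b)[0]
        dirs = []
        for idx in sel:
            g = dataset.bvecs[idx]
            if not any(np.allclose(g, d, atol=1e-9) for d in dirs):
                dirs.append(g)
        # canonical (lexicographic) direction order: the channel layout is
        # then independent of acquisition order
        dirs = np.asarray(dirs)
        key = np.round(dirs, 9)
        dirs = dirs[np.lexsort((key[:, 2], key[:, 1], key[:, 0]))]
        if ref_dirs is None:
            ref_dirs = dirs
        else:
            if dirs.shape != ref_dirs.shape or not np.allclose(
                dirs, ref_dirs, atol=1e-9
            ):
                raise ValueError(
                    f"direction set at b={b:g} differs from the other shells"
                )
            dirs = ref_dirs
        for g in dirs:
            rep_sel = sel[np.linalg.norm(dataset.bvecs[sel] - g, axis=1) < 1e-9]
            if len(rep_sel) == 0:
                raise ValueError(f"missing direction {g} at b={b:g}")
            channels.append(dataset.images[rep_sel].mean(axis=0))
            bvals.append(b)
            bvecs.append(g)
    return AveragedStack(
        channels=np.asarray(channels),
        bvals=np.asarray(bvals),
        bvecs=np.asarray(bvecs),
        mask=dataset.mask,
    )


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------


def normalize_input(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Joint [0, 1] normalization of an image stack.

    All channels are divided by the single maximum value found inside the
    heart (across channels); non-heart pixels are set exactly to zero.
    """
    stack = np.asarray(stack, float)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    m = float(stack[:, mask].max())
    if m <= 0:
        raise ValueError("in-mask maximum is not positive; cannot normalize")
    out = stack / m
    out[:, ~mask] = 0.0
    return out


def normalize_tensor(
    components: np.ndarray,
    factor: float = TENSOR_NORM_FACTOR,
    unit_mm2_s: float = TENSOR_NORM_UNIT_MM2_S,
) -> np.ndarray:
    """Scale tensor components to network range by a fixed factor.

    Components (stored in 1e-3 mm^2/s) are first expressed in ``unit_mm2_s``
    and then divided by ``factor`` (default 500).
    """
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    return np.asarray(components, float) * (1e-3 / unit_mm2_s) / factor


def denormalize_tensor(
    normalized: np.ndarray,
    factor: float = TENSOR_NORM_FACTOR,
    unit_mm2_s: float = TENSOR_NORM_UNIT_MM2_S,
) -> np.ndarray:
    """Exact inverse of :func:`normalize_tensor`."""
    if factor <= 0:
        raise ValueError("normalization factor must be positive")
    return np.asarray(normalized, float) * factor / (1e-3 / unit_mm2_s)
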