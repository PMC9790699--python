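"""Linear least-squares diffusion tensor estimation.

The monoexponential signal model ``S = S0 exp(-b g'Dg)`` is linearized by
taking logs, giving one equation per acquired image:

    ln S = ln S0 - b (gx^2 Dxx + gy^2 Dyy + gz^2 Dzz
                      + 2 gx gy Dxy + 2 gx gz Dxz + 2 gy gz Dyz)

Every acquired image enters individually (no pre-averaging) and the system
is solved per voxel in the least-squares sense via a QR factorization, with
no positivity constraint or noise suppression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .io import DWIDataset, TensorField

logger = logging.getLogger(__name__)

#: Relative floor (times the median in-mask b0 signal) applied to
#: non-positive magnitudes before the log transform.
CLAMP_EPS = 1e-6


def build_design_matrix(bvals, bvecs) -> np.ndarray:
    """Design matrix of the log-linearized tensor model.

    One row per image: ``[1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy,
    -2b gx gz, -2b gy gz]``, matching the unknown vector
    ``[ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]``. Rows at b = 0 reduce to
    ``[1, 0, 0, 0, 0, 0, 0]``.

    Raises when the matrix is rank-deficient (rank < 7), naming the likely
    cause.
    """
    bvals = np.asarray(bvals, float)
    bvecs = np.asarray(bvecs, float)
    if bvecs.ndim != 2 or bvecs.shape[1] != 3:
        raise ValueError("bvecs must be (n, 3)")
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    A = np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx * gx,
            -bvals * gy * gy,
            -bvals * gz * gz,
            -2.0 * bvals * gx * gy,
            -2.0 * bvals * gx * gz,
            -2.0 * bvals * gy * gz,
        ]
    )
    rank = np.linalg.matrix_rank(A)
    if rank < 7:
        n_dw = int(np.sum(bvals > 0))
        n_dirs = len(np.unique(np.round(bvecs[bvals > 0], 12), axis=0)) if n_dw else 0
        raise ValueError(
            f"design matrix rank {rank} < 7: {n_dw} diffusion-weighted images "
            f"over {n_dirs} distinct directions cannot determine the tensor"
        )
    return A


@dataclass
class FitResult:
    """LLS fit output: tensor field, ln(S0) map and per-voxel QC flags."""

    tensor: TensorField
    ln_s0: np.ndarray
    clamped: np.ndarray  # voxels where at least one signal hit the log floor
    failed: np.ndarray  # voxels where every signal was clamped (tensor zeroed)


def lls_fit(dataset: DWIDataset) -> FitResult:
    """Per-voxel linear least-squares tensor fit via QR factorization.

    Non-positive magnitudes are clamped to ``CLAMP_EPS`` times the median
    in-mask b0 signal before the log (the voxel is flagged); a voxel whose
    signals are all clamped gets a zero tensor and a ``failed`` flag.
    Components are returned in 1e-3 mm^2/s.
    """
    if not dataset.mask.any():
        raise ValueError("empty mask")
    A = build_design_matrix(dataset.bvals, dataset.bvecs)
    S = dataset.images[:, dataset.mask]  # (n_images, n_voxels)
    b0_sel = dataset.bvals == dataset.bvals.min()
    med_b0 = float(np.median(dataset.images[b0_sel][:, dataset.mask]))
    floor = CLAMP_EPS * max(med_b0, np.finfo(float).tiny)
    bad = S <= 0.0
    clamped_vox = bad.any(axis=0)
    failed_vox = bad.all(axis=0)
    if clamped_vox.any():
        logger.info(
            "%d voxels had non-positive signals clamped (floor %.3g); %d voxels "
            "fully clamped and zeroed",
            int(clamped_vox.sum()),
            floor,
            int(failed_vox.sum()),
        )
    Sc = np.where(bad, floor, S)
    Q, R = np.linalg.qr(A)
    x = solve_triangular(R, Q.T @ np.log(Sc), lower=False)  # (7, n_voxels)

    H, W = dataset.shape
    comps = np.zeros((H, W, 6))
    ln_s0 = np.full((H, W), np.nan)
    comps[dataset.mask] = x[1:].T * 1e3  # mm^2/s -> 1e-3 mm^2/s
    ln_s0[dataset.mask] = x[0]
    clamped = np.zeros((H, W), bool)
    failed = np.zeros((H, W), bool)
    clamped[dataset.mask] = clamped_vox
    failed[dataset.mask] = failed_vox
    comps[failed] = 0.0
    return FitResult(
        tensor=TensorField(components=comps, mask=dataset.mask),
        ln_s0=ln_s0,
        clamped=clamped,
        failed=failed,
    )
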