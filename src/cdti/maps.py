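"""Cardiac tensor parameter maps.

Eigendecomposition of the fitted tensor field and the derived cardiac
measures: fractional anisotropy (FA), mean diffusivity (MD), helix angle
(HA) and sheetlet angle (E2A), plus the transmural helix-angle line-profile
statistics and regional summaries.

Angle conventions
-----------------
All orientation angles live on the half-circle and are folded to
``[-90, 90]`` degrees:

* HA is the angle of the primary eigenvector's projection onto the
  tangential (circumferential-longitudinal) plane, measured from the
  circumferential direction, positive toward +longitudinal.
* E2A is the signed angle, within the cross-myocyte plane (the plane
  orthogonal to E1), between the secondary eigenvector and the
  wall-tangential reference direction ``t = normalize(E1 x radial)``,
  positive toward the radial direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import TensorField

logger = logging.getLogger(__name__)

_EPS_PROJ = 1e-9  # minimum projection norm before an angle is declared undefined


@dataclass
class CardiacFrame:
    """Per-voxel orthonormal local wall coordinate system.

    ``radial`` points outward from the LV center, ``circumferential`` is the
    counter-clockwise in-plane tangent and ``longitudinal`` is the constant
    slice normal (+z, toward the base). Shapes are ``(H, W, 3)``.
    """

    radial: np.ndarray
    circumferential: np.ndarray
    longitudinal: np.ndarray
    center: tuple[float, float]

    def triads(self) -> np.ndarray:
        return np.stack(
            [self.radial, self.circumferential, self.longitudinal], axis=-2
        )


def local_frame(mask: np.ndarray, center, pixel_spacing_mm=(2.8, 2.8)) -> CardiacFrame:
    """Radial/circumferential/longitudinal unit vectors at every pixel.

    World axes: x along +col, y along -row (so that z = x cross y points out
    of the image toward the base), z the slice normal. The radial vector at
    a pixel is the in-plane unit vector from ``center`` to the pixel;
    circumferential = longitudinal x radial.

    Raises if the mask is empty or contains the exact center pixel (where
    the radial direction is undefined).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    H, W = mask.shape
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    dx = (cols - center[1]) * pixel_spacing_mm[1]
    dy = -(rows - center[0]) * pixel_spacing_mm[0]
    r = np.hypot(dx, dy)
    if np.any((r < 1e-12) & mask):
        raise ValueError("mask contains the center voxel; radial direction undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        rad = np.stack([dx / r, dy / r, np.zeros_like(r)], axis=-1)
    rad[r < 1e-12] = np.array([1.0, 0.0, 0.0])  # arbitrary off-mask filler
    lon = np.zeros_like(rad)
    lon[..., 2] = 1.0
    circ = np.cross(lon, rad)
    return CardiacFrame(
        radial=rad, circumferential=circ, longitudinal=lon, center=tuple(center)
    )


def cavity_center(mask: np.ndarray) -> tuple[float, float]:
    """Centroid of the cavity enclosed by an annular myocardial mask."""
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    outside = ~mask
    # connected background components; the cavity is the one not touching the border
    labels, n = ndimage.label(outside)
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]
    ])))
    cavity = np.isin(labels, [l for l in range(1, n + 1) if l not in border_labels])
    if not cavity.any():
        # fall back to the mask centroid
        rr, cc = np.nonzero(mask)
        return float(rr.mean()), float(cc.mean())
    rr, cc = np.nonzero(cavity)
    return float(rr.mean()), float(cc.mean())


# ---------------------------------------------------------------------------
# eigensystem and scalar invariants
# ---------------------------------------------------------------------------


def eigensystem(field: TensorField, frame: CardiacFrame | None = None):
    """Per-voxel eigendecomposition, eigenvalues sorted descending.

    Returns ``(eigenvalues, eigenvectors, defined)`` with shapes
    ``(H, W, 3)``, ``(H, W, 3, 3)`` (``eigenvectors[..., i, :]`` is the i-th
    eigenvector) and a boolean map of voxels that were decomposed (in-mask,
    finite). With a ``frame``, eigenvector signs are disambiguated: E1 is
    flipped so its circumferential component is >= 0 and E2 so that
    (E1, E2, E3) is right-handed.
    """
    H, W = field.shape
    evals = np.zeros((H, W, 3))
    evecs = np.zeros((H, W, 3, 3))
    defined = field.mask & np.all(np.isfinite(field.components), axis=-1)
    n_bad = int(field.mask.sum() - defined.sum())
    if n_bad:
        logger.warning("%d in-mask voxels with non-finite tensors excluded", n_bad)
    mats = field.as_matrices()[defined]
    if len(mats):
        w, v = np.linalg.eigh(mats)  # ascending; v[:, :, i] is i-th eigenvector
        w = w[:, ::-1]
        v = np.transpose(v, (0, 2, 1))[:, ::-1, :]  # rows = eigenvectors, descending
        if frame is not None:
            circ = frame.circumferential[defined]
            flip1 = np.sum(v[:, 0, :] * circ, axis=1) < 0
            v[flip1, 0, :] *= -1
            det = np.einsum(
                "ni,ni->n", v[:, 0, :], np.cross(v[:, 1, :], v[:, 2, :])
            )
            v[det < 0, 1, :] *= -1
        evals[defined] = w
        evecs[defined] = v
    return evals, evecs, defined


def md(eigenvalues: np.ndarray) -> np.ndarray:
    """Mean diffusivity: arithmetic mean of the three eigenvalues."""
    return np.mean(np.asarray(eigenvalues, float), axis=-1)


def fa(eigenvalues: np.ndarray) -> np.ndarray:
    """Fractional anisotropy, ``sqrt(3/2) * ||lam - MD|| / ||lam||``.

    Defined as 0 where the eigenvalue vector is identically zero. Negative
    eigenvalues are allowed (no noise suppression upstream) so values may
    exceed 1; they are reported as-is.
    """
    lam = np.asarray(eigenvalues, float)
    mean = np.mean(lam, axis=-1, keepdims=True)
    num = np.linalg.norm(lam - mean, axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    out = np.zeros(lam.shape[:-1])
    nz = den > 0
    out[nz] = np.sqrt(1.5) * num[nz] / den[nz]
    return out


def fold_angle(deg):
    """Fold angles in degrees to the half-circle [-90, 90)."""
    return (np.asarray(deg, float) + 90.0) % 180.0 - 90.0


def helix_angle(e1: np.ndarray, frame: CardiacFrame, defined: np.ndarray | None = None):
    """Helix-angle map from the (sign-disambiguated) primary eigenvector.

    Returns ``(ha_deg, ok)``; voxels whose E1 projects onto the tangential
    plane with norm below 1e-9 (purely radial fiber) are flagged undefined
    and set to NaN.
    """
    comp_c = np.sum(e1 * frame.circumferential, axis=-1)
    comp_l = np.sum(e1 * frame.longitudinal, axis=-1)
    norm = np.hypot(comp_c, comp_l)
    ok = norm >= _EPS_PROJ
    if defined is not None:
        ok &= defined
    ha = np.full(comp_c.shape, np.nan)
    ha[ok] = fold_angle(np.degrees(np.arctan2(comp_l[ok], comp_c[ok])))
    return ha, ok


def sheetlet_angle(
    e1: np.ndarray,
    e2: np.ndarray,
    frame: CardiacFrame,
    defined: np.ndarray | None = None,
):
    """Sheetlet-angle (E2A) map.

    Within the cross-myocyte plane orthogonal to E1, E2A is the signed angle
    between E2 and the wall-tangential reference ``t = normalize(E1 x radial)``,
    positive toward the radial direction, folded to [-90, 90]. Returns
    ``(e2a_deg, abs_e2a_deg, ok)``; voxels with E1 parallel to the radial
    direction have no reference and are flagged undefined.
    """
    t = np.cross(e1, frame.radial)
    tnorm = np.linalg.norm(t, axis=-1)
    ok = tnorm >= _EPS_PROJ
    if defined is not None:
        ok &= defined
    t = np.where(ok[..., None], t / np.where(ok, tnorm, 1.0)[..., None], 0.0)
    # radial direction projected into the cross-myocyte plane
    r_dot_e1 = np.sum(frame.radial * e1, axis=-1, keepdims=True)
    r_ip = frame.radial - r_dot_e1 * e1
    rnorm = np.linalg.norm(r_ip, axis=-1)
    ok &= rnorm >= _EPS_PROJ
    r_ip = np.where(ok[..., None], r_ip / np.where(ok, rnorm, 1.0)[..., None], 0.0)
    x = np.sum(e2 * t, axis=-1)
    y = np.sum(e2 * r_ip, axis=-1)
    e2a = np.full(x.shape, np.nan)
    e2a[ok] = fold_angle(np.degrees(np.arctan2(y[ok], x[ok])))
    return e2a, np.abs(e2a), ok


@dataclass
class ParameterMaps:
    """All cardiac parameter maps derived from one tensor field."""

    fa: np.ndarray
    md: np.ndarray
    ha: np.ndarray
    e2a: np.ndarray
    abs_e2a: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mask: np.ndarray
    defined: np.ndarray
    ha_defined: np.ndarray
    e2a_defined: np.ndarray
    frame: CardiacFrame


def parameter_maps(
    field: TensorField,
    center=None,
    pixel_spacing_mm=(2.8, 2.8),
) -> ParameterMaps:
    """Full map derivation: eigensystem -> FA, MD, HA, E2A.

    ``center`` defaults to the centroid of the cavity enclosed by the mask.
    FA/MD are NaN outside the decomposable mask; HA/E2A additionally NaN
    where their reference directions are undefined.
    """
    if center is None:
        center = cavity_center(field.mask)
    frame = local_frame(field.mask, center, pixel_spacing_mm)
    evals, evecs, defined = eigensystem(field, frame)
    fa_map = np.where(defined, fa(evals), np.nan)
    md_map = np.where(defined, md(evals), np.nan)
    ha_map, ha_ok = helix_angle(evecs[..., 0, :], frame, defined)
    e2a_map, abs_e2a, e2a_ok = sheetlet_angle(
        evecs[..., 0, :], evecs[..., 1, :], frame, defined
    )
    return ParameterMaps(
        fa=fa_map,
        md=md_map,
        ha=ha_map,
        e2a=e2a_map,
        abs_e2a=abs_e2a,
        eigenvalues=evals,
        eigenvectors=evecs,
        mask=field.mask,
        defined=defined,
        ha_defined=ha_ok,
        e2a_defined=e2a_ok,
        frame=frame,
    )


# ---------------------------------------------------------------------------
# transmural helix-angle line profiles
# ---------------------------------------------------------------------------


@dataclass
class TransmuralProfiles:
    """Per-ray HA samples and the subject-level summary statistics.

    One profile per epicardial border voxel: HA sampled by nearest-neighbor
    lookup at 0.5-pixel steps along the ray from the LV center. Summaries use
    only profiles with at least 3 in-mask samples.
    """

    profiles: list  # list of (distances_mm, depths, ha_deg) arrays
    mean_gradient_deg_per_mm: float
    median_iqr_deg: float
    median_range_deg: float
    n_profiles: int
    n_excluded: int
    slopes_deg_per_mm: np.ndarray = field(default_factory=lambda: np.empty(0))


def _epicardial_border_voxels(mask: np.ndarray, center) -> np.ndarray:
    """In-mask voxels whose outward (radially next) neighbor is out of mask."""
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    rr, cc = np.nonzero(mask)
    d = np.stack([rr - center[0], cc - center[1]], axis=1).astype(float)
    norm = np.linalg.norm(d, axis=1)
    norm[norm == 0] = 1.0
    step = np.rint(d / norm[:, None]).astype(int)
    nr, nc = rr + step[:, 0], cc + step[:, 1]
    outside = (nr < 0) | (nr >= H) | (nc < 0) | (nc >= W)
    border = outside.copy()
    inb = ~outside
    border[inb] = ~mask[nr[inb], nc[inb]]
    return np.stack([rr[border], cc[border]], axis=1)


def ha_profiles(
    ha_map: np.ndarray,
    mask: np.ndarray,
    center,
    pixel_spacing_mm=(2.8, 2.8),
    slope_aggregation: str = "mean",
) -> TransmuralProfiles:
    """Transmural HA line-profile statistics.

    For each epicardial border voxel, HA is sampled every 0.5 px along the
    ray from ``center`` through that voxel (nearest-neighbor lookup, in-mask
    and defined samples only). Per profile: least-squares slope of HA vs
    distance (deg/mm), IQR of the samples, and endo-to-epi range (|first -
    last|). Subject summaries: mean (or median, per ``slope_aggregation``)
    of absolute slopes, median per-profile IQR, median range.
    """
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    sp = float(pixel_spacing_mm[0])
    if abs(pixel_spacing_mm[0] - pixel_spacing_mm[1]) > 1e-9:
        raise ValueError("anisotropic in-plane spacing not supported for profiles")
    borders = _epicardial_border_voxels(mask, center)
    profiles, slopes, iqrs, ranges = [], [], [], []
    n_excluded = 0
    for r, c in borders:
        d = np.array([r - center[0], c - center[1]], float)
        dist = np.linalg.norm(d)
        if dist == 0:
            n_excluded += 1
            continue
        u = d / dist
        s = np.arange(0.0, dist + 0.5, 0.5)
        pr = np.rint(center[0] + s * u[0]).astype(int)
        pc = np.rint(center[1] + s * u[1]).astype(int)
        ok = (pr >= 0) & (pr < H) & (pc >= 0) & (pc < W)
        pr, pc, s = pr[ok], pc[ok], s[ok]
        keep = mask[pr, pc] & np.isfinite(ha_map[pr, pc])
        s, pr, pc = s[keep], pr[keep], pc[keep]
        if len(s) < 3:
            n_excluded += 1
            continue
        dist_mm = s * sp
        ha = ha_map[pr, pc]
        depth = (dist_mm - dist_mm[0]) / max(dist_mm[-1] - dist_mm[0], 1e-12)
        profiles.append((dist_mm, depth, ha))
        slope = np.polyfit(dist_mm, ha, 1)[0]
        slopes.append(slope)
        iqrs.append(np.subtract(*np.percentile(ha, [75, 25])))
        ranges.append(abs(ha[0] - ha[-1]))
    if n_excluded:
        logger.info("%d transmural profiles excluded (<3 samples)", n_excluded)
    if not profiles:
        raise ValueError("no usable transmural profiles (all rays < 3 samples)")
    slopes = np.asarray(slopes)
    agg = np.mean if slope_aggregation == "mean" else np.median
    return TransmuralProfiles(
        profiles=profiles,
        mean_gradient_deg_per_mm=float(agg(np.abs(slopes))),
        median_iqr_deg=float(np.median(iqrs)),
        median_range_deg=float(np.median(ranges)),
        n_profiles=len(profiles),
        n_excluded=n_excluded,
        slopes_deg_per_mm=slopes,
    )


# ---------------------------------------------------------------------------
# regional summaries
# ---------------------------------------------------------------------------


def regional_stats(map_values: np.ndarray, region_labels: dict) -> pd.DataFrame:
    """Median/mean/std/count of a map per named region.

    ``region_labels`` maps region name -> boolean mask. NaN map values are
    ignored; an empty (or all-NaN) region yields NaN summaries and a flag.
    """
    rows = []
    for name, region in region_labels.items():
        vals = np.asarray(map_values, float)[np.asarray(region, bool)]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            logger.warning("region %r empty; summary undefined", name)
            rows.append((name, np.nan, np.nan, np.nan, 0, True))
        else:
            rows.append(
                (name, np.median(vals), vals.mean(), vals.std(ddof=0), len(vals), False)
            )
    return pd.DataFrame(
        rows, columns=["region", "median", "mean", "std", "n", "empty"]
    ).set_index("region")


def myocardial_std(map_values: np.ndarray, mask: np.ndarray) -> float:
    """Standard deviation of a map over all in-mask, defined voxels."""
    vals = np.asarray(map_values, float)[np.asarray(mask, bool)]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no defined in-mask voxels")
    return float(vals.std(ddof=0))
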