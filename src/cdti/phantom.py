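"""Synthetic short-axis left-ventricular cDTI phantoms.

The phantom is an annular LV myocardium with a known, fully controlled
microstructure, so that every downstream stage (fitting, CNN prediction,
map derivation, evaluation) can be tested against ground truth:

* a transmural helix-angle ramp, linear in transmural depth, from
  ``ha_endo_deg`` at the endocardium to ``ha_epi_deg`` at the epicardium;
* a fixed sheetlet angle ``e2a_deg`` (systole-like by default);
* a mesocardial band of elevated FA (eigenvalue spread widened in the
  middle third of the wall at constant MD);
* an optional transmural infarct sector with all eigenvalues scaled by
  ``md_scale`` (elevated MD, unchanged FA);
* the monoexponential diffusion signal S = S0 exp(-b g'Dg) per image,
  Rician magnitude noise at a configurable SNR, and optional per-breath-hold
  in-plane translation (respiratory motion).

The acquisition protocol mirrors a breath-hold cardiac DTI exam: b = 0 /
150 / 600 s/mm^2, six diffusion directions, and ~12 breath-holds each
holding one b0 image plus one six-direction set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import DWIDataset, TensorField, matrices_to_components
from .maps import fa as _fa_of, fold_angle, local_frame

logger = logging.getLogger(__name__)

#: Default six-direction dual-gradient diffusion encoding scheme.
DEFAULT_DIRECTIONS = np.array(
    [
        (1, 0, 1),
        (-1, 0, 1),
        (0, 1, 1),
        (0, 1, -1),
        (1, 1, 0),
        (-1, 1, 0),
    ],
    dtype=float,
) / np.sqrt(2.0)

#: Reference breath-hold sequence: the diffusion weighting of each
#: breath-hold's six-direction set (10x b600, 2x b150). Each breath-hold
#: additionally holds one b0 image.
DEFAULT_BH_BVALUES = (600, 600, 150, 600, 600, 600, 600, 600, 150, 600, 600, 600)


@dataclass
class Protocol:
    """Acquisition protocol: b-values, directions and breath-hold grouping."""

    b0: float = 0.0
    b_dw_per_bh: tuple = DEFAULT_BH_BVALUES
    directions: np.ndarray = field(default_factory=lambda: DEFAULT_DIRECTIONS.copy())
    b0_per_bh: bool = True

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-unit diffusion direction in protocol")

    @property
    def n_breath_holds(self) -> int:
        return len(self.b_dw_per_bh)


@dataclass
class InfarctSpec:
    """Transmural infarct sector: angular span (degrees, CCW from +x) and MD scaling."""

    theta_start_deg: float = 0.0
    theta_end_deg: float = 90.0
    md_scale: float = 1.27


@dataclass
class PhantomConfig:
    """All phantom generation parameters; defaults emulate the study protocol."""

    grid_size: tuple[int, int] = (128, 128)
    pixel_spacing_mm: float = 2.8
    center: tuple[float, float] | None = None
    endo_radius_mm: float = 21.0
    epi_radius_mm: float = 33.0
    ha_endo_deg: float = 60.0
    ha_epi_deg: float = -60.0
    e2a_deg: float = 60.0
    eigenvalues_mm2_per_s: tuple[float, float, float] = (1.8e-3, 0.8e-3, 0.6e-3)
    meso_fa_boost: float = 0.15
    infarct: InfarctSpec | None = None
    snr: float = 25.0
    s0: float = 1000.0
    protocol: Protocol = field(default_factory=Protocol)
    motion_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (self.epi_radius_mm > self.endo_radius_mm > 0):
            raise ValueError("need epi_radius_mm > endo_radius_mm > 0")
        lam = self.eigenvalues_mm2_per_s
        if not (lam[0] >= lam[1] >= lam[2]) or lam[2] <= 0:
            raise ValueError("eigenvalues must be positive and descending")
        if not self.snr > 0:
            raise ValueError("snr must be positive (np.inf disables noise)")
        for a in (self.ha_endo_deg, self.ha_epi_deg, self.e2a_deg):
            if not np.isfinite(a):
                raise ValueError("angles must be finite")
        if self.center is None:
            self.center = (
                (self.grid_size[0] - 1) / 2.0,
                (self.grid_size[1] - 1) / 2.0,
            )


@dataclass
class Geometry:
    """Annular LV geometry: mask, transmural depth and region labels."""

    mask: np.ndarray
    depth: np.ndarray  # transmural depth in [0, 1], NaN outside mask
    region_labels: dict  # name -> boolean mask (endo/meso/epi, remote/infarct)
    center: tuple[float, float]
    theta_deg: np.ndarray  # polar angle of each pixel, [0, 360)


@dataclass
class PhantomTruth:
    """Ground-truth tensors, labels and parameter maps for one phantom."""

    tensor_truth: TensorField
    mask: np.ndarray
    region_labels: dict
    ha_truth_deg: np.ndarray
    e2a_truth_deg: np.ndarray
    fa_truth: np.ndarray
    md_truth: np.ndarray  # 1e-3 mm^2/s
    config: PhantomConfig
    geometry: Geometry


def make_lv_geometry(config: PhantomConfig) -> Geometry:
    """Annulus mask, transmural depth map and region labels.

    A pixel is in-mask iff its center's distance r from the LV center
    satisfies ``endo_radius <= r <= epi_radius`` (in mm). Transmural depth is
    ``(r - endo) / (epi - endo)``; the wall is split into three equally wide
    regions (endo/meso/epi) at depths 1/3 and 2/3.
    """
    H, W = config.grid_size
    rows, cols = np.mgrid[0:H, 0:W].astype(float)
    dx = (cols - config.center[1]) * config.pixel_spacing_mm
    dy = -(rows - config.center[0]) * config.pixel_spacing_mm
    r = np.hypot(dx, dy)
    mask = (r >= config.endo_radius_mm) & (r <= config.epi_radius_mm)
    if not mask.any():
        raise ValueError("degenerate annulus: no in-mask pixels for this geometry")
    depth = np.full((H, W), np.nan)
    depth[mask] = (r[mask] - config.endo_radius_mm) / (
        config.epi_radius_mm - config.endo_radius_mm
    )
    endo = mask & (depth < 1.0 / 3.0)
    meso = mask & (depth >= 1.0 / 3.0) & (depth < 2.0 / 3.0)
    epi = mask & (depth >= 2.0 / 3.0)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    if config.infarct is not None:
        spec = config.infarct
        span = (spec.theta_end_deg - spec.theta_start_deg) % 360.0
        in_sector = (theta - spec.theta_start_deg) % 360.0 <= span
        infarct = mask & in_sector
        remote = mask & ~in_sector
    else:
        infarct = np.zeros_like(mask)
        remote = mask.copy()
    labels = {"endo": endo, "meso": meso, "epi": epi, "remote": remote, "infarct": infarct}
    return Geometry(
        mask=mask, depth=depth, region_labels=labels, center=config.center, theta_deg=theta
    )


def _meso_spread(lam: np.ndarray, boost: float) -> float:
    """Half-spread s such that (lam1, m+s, m-s) has FA boosted by ``boost``.

    Keeps lam1 and MD fixed; m = (lam2 + lam3)/2. Closed form from
    FA^2 = 3/2 (a + 2 s^2) / (b + 2 s^2) with a = (lam1-MD)^2 + 2 (m-MD)^2
    and b = lam1^2 + 2 m^2.
    """
    lam1, lam2, lam3 = lam
    m = 0.5 * (lam2 + lam3)
    mean = (lam1 + lam2 + lam3) / 3.0
    fa0 = float(_fa_of(np.asarray(lam)))
    target = (1.0 + boost) * fa0
    F = (2.0 / 3.0) * target**2
    if F >= 1.0:
        raise ValueError(f"meso FA target {target:.3f} is unattainable (FA >= sqrt(3/2))")
    a = (lam1 - mean) ** 2 + 2.0 * (m - mean) ** 2
    b = lam1**2 + 2.0 * m**2
    s2 = (F * b - a) / (2.0 * (1.0 - F))
    if s2 < 0:
        raise ValueError("meso FA boost would require shrinking the eigenvalue spread")
    s = float(np.sqrt(s2))
    if m - s <= 0:
        raise ValueError(
            f"meso_fa_boost={boost} forces a non-positive third eigenvalue "
            f"(lambda3 = {m - s:.3e} mm^2/s)"
        )
    return s


def ground_truth_tensors(geometry: Geometry, config: PhantomConfig) -> PhantomTruth:
    """Per-voxel ground-truth tensors and parameter maps.

    The primary eigenvector is the circumferential direction rotated by the
    local helix angle toward the longitudinal axis; the secondary eigenvector
    sits in the cross-myocyte plane at ``e2a_deg`` from the wall-tangential
    reference. Mesocardial eigenvalue spread is widened at constant MD;
    infarct voxels have all eigenvalues scaled by ``md_scale``.
    """
    H, W = config.grid_size
    mask = geometry.mask
    frame = local_frame(
        mask, config.center, (config.pixel_spacing_mm, config.pixel_spacing_mm)
    )
    depth = geometry.depth
    ha = np.full((H, W), np.nan)
    ha[mask] = config.ha_endo_deg + depth[mask] * (
        config.ha_epi_deg - config.ha_endo_deg
    )
    ha_rad = np.radians(ha)

    e1 = (
        np.cos(ha_rad)[..., None] * frame.circumferential
        + np.sin(ha_rad)[..., None] * frame.longitudinal
    )
    t = np.cross(e1, frame.radial)  # unit: e1 is orthogonal to radial
    e2a_rad = np.radians(config.e2a_deg)
    e2 = np.cos(e2a_rad) * t + np.sin(e2a_rad) * frame.radial
    e3 = np.cross(e1, e2)

    # eigenvalues in 1e-3 mm^2/s
    lam_base = np.asarray(config.eigenvalues_mm2_per_s, float) * 1e3
    lam = np.zeros((H, W, 3))
    lam[mask] = lam_base
    if config.meso_fa_boost != 0.0:
        s = _meso_spread(lam_base, config.meso_fa_boost)
        m = 0.5 * (lam_base[1] + lam_base[2])
        meso = geometry.region_labels["meso"]
        lam[meso] = (lam_base[0], m + s, m - s)
    infarct = geometry.region_labels["infarct"]
    if infarct.any():
        lam[infarct] *= config.infarct.md_scale

    D = (
        lam[..., 0, None, None] * e1[..., :, None] * e1[..., None, :]
        + lam[..., 1, None, None] * e2[..., :, None] * e2[..., None, :]
        + lam[..., 2, None, None] * e3[..., :, None] * e3[..., None, :]
    )
    comps = matrices_to_components(D)
    comps[~mask] = 0.0
    tensor = TensorField(components=comps, mask=mask)

    fa_map = np.where(mask, _fa_of(lam), np.nan)
    md_map = np.where(mask, lam.mean(axis=-1), np.nan)
    e2a_map = np.where(mask, fold_angle(config.e2a_deg), np.nan)
    return PhantomTruth(
        tensor_truth=tensor,
        mask=mask,
        region_labels=geometry.region_labels,
        ha_truth_deg=fold_angle(ha) if np.isfinite(ha).any() else ha,
        e2a_truth_deg=e2a_map,
        fa_truth=fa_map,
        md_truth=md_map,
        config=config,
        geometry=geometry,
    )


def _protocol_images(protocol: Protocol):
    """Expand the protocol into per-image (b, bvec, rep, bh) records."""
    records = []
    b0_rep = 0
    dw_rep = {}
    for bh, b_dw in enumerate(protocol.b_dw_per_bh):
        if protocol.b0_per_bh:
            records.append((protocol.b0, np.zeros(3), b0_rep, bh))
            b0_rep += 1
        rep = dw_rep.get(b_dw, 0)
        for g in protocol.directions:
            records.append((float(b_dw), g, rep, bh))
        dw_rep[b_dw] = rep + 1
    return records


def synthesize_dwi(truth: PhantomTruth, seed: int | None = None) -> DWIDataset:
    """Simulate the diffusion-weighted acquisition of a phantom.

    Per image, the noiseless signal is ``S0 exp(-b g'Dg)`` in-mask and 0 in
    the background. A per-breath-hold in-plane translation (drawn from
    N(0, motion_sigma_px), applied to all images of the breath-hold by cubic
    spline interpolation) precedes Rician noise: the magnitude of
    (S + N(0, sigma), N(0, sigma)) with sigma = S0/snr. ``snr = inf``
    disables noise. Fully reproducible for a fixed seed.
    """
    config = truth.config
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    records = _protocol_images(config.protocol)
    mask = truth.mask
    D = truth.tensor_truth.as_matrices() * 1e-3  # mm^2/s

    n_bh = config.protocol.n_breath_holds
    if config.motion_sigma_px > 0:
        shifts = rng.normal(0.0, config.motion_sigma_px, size=(n_bh, 2))
    else:
        shifts = np.zeros((n_bh, 2))

    images, bvals, bvecs, reps, bhs = [], [], [], [], []
    for b, g, rep, bh in records:
        if b > 0:
            if abs(np.linalg.norm(g) - 1.0) > 1e-6:
                raise ValueError("non-unit diffusion direction")
            att = np.exp(-b * np.einsum("i,hwij,j->hw", g, D, g))
            S = np.where(mask, config.s0 * att, 0.0)
        else:
            S = np.where(mask, config.s0, 0.0)
        if np.any(shifts[bh] != 0.0):
            S = ndimage.shift(S, shifts[bh], order=3, cval=0.0)
        if np.isfinite(config.snr):
            sigma = config.s0 / config.snr
            re = S + rng.normal(0.0, sigma, S.shape)
            im = rng.normal(0.0, sigma, S.shape)
            S = np.hypot(re, im)
        images.append(S)
        bvals.append(b)
        bvecs.append(g)
        reps.append(rep)
        bhs.append(bh)

    return DWIDataset(
        images=np.asarray(images),
        bvals=np.asarray(bvals),
        bvecs=np.asarray(bvecs),
        rep_index=np.asarray(reps),
        bh_index=np.asarray(bhs),
        mask=mask,
        pixel_spacing_mm=(config.pixel_spacing_mm, config.pixel_spacing_mm),
        meta={
            "true_shifts_px": shifts.tolist(),
            "s0": config.s0,
            "snr": config.snr,
            "seed": int(seed),
        },
    )


def simulate(config: PhantomConfig, seed: int | None = None):
    """Convenience: geometry -> truth -> dataset. Returns (truth, dataset)."""
    truth = ground_truth_tensors(make_lv_geometry(config), config)
    return truth, synthesize_dwi(truth, seed=seed)


def split_stratified(dataset_ids, strata_labels, fractions, seed):
    """Stratified train/validation/test split with largest-remainder rounding.

    Within each stratum, ids are shuffled (seeded) and partitioned according
    to ``fractions`` (must sum to 1): each part first gets the floor of its
    share, remaining members go to the parts with the largest fractional
    remainders (ties broken by larger fraction, then part order). A stratum
    smaller than the number of parts goes entirely to the largest-fraction
    part (logged).

    Returns a list of id lists, one per fraction (train, validation, test).
    """
    fractions = np.asarray(fractions, float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fractions.sum()}, expected 1")
    ids = list(dataset_ids)
    labels = list(strata_labels)
    if len(ids) != len(labels):
        raise ValueError("dataset_ids and strata_labels length mismatch")
    rng = np.random.default_rng(seed)
    n_parts = len(fractions)
    parts = [[] for _ in range(n_parts)]
    largest = int(np.argmax(fractions))
    for stratum in sorted(set(labels), key=str):
        members = [i for i, s in zip(ids, labels) if s == stratum]
        order = rng.permutation(len(members))
        members = [members[j] for j in order]
        n = len(members)
        if n < n_parts:
            logger.warning(
                "stratum %r has %d members (< %d parts); all assigned to part %d",
                stratum, n, n_parts, largest,
            )
            parts[largest].extend(members)
            continue
        exact = fractions * n
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        leftover = n - counts.sum()
        # largest remainder; ties -> larger fraction, then part order
        order_keys = sorted(
            range(n_parts), key=lambda k: (-remainder[k], -fractions[k], k)
        )
        for k in order_keys[:leftover]:
            counts[k] += 1
        start = 0
        for k in range(n_parts):
            parts[k].extend(members[start : start + counts[k]])
            start += counts[k]
    return parts
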