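"""Comparison metrics between reference and reduced-data tensor results.

Pixel-wise errors use a mean absolute error for the rotationally invariant
measures (FA, MD) and a mean absolute angular distance, with folding at
+/-90 degrees, for the orientation measures (HA, E2A). Subject-level
agreement uses a Bland-Altman-style analysis of differences (median, 5/95%
quantiles, bootstrap CI of the median). Scan quality is summarized by the
mean Dice overlap of the displaced myocardial masks, and group comparisons
use nonparametric tests (Wilcoxon signed-rank / rank-sum, Kruskal-Wallis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)


def angular_distance(a_deg, b_deg):
    """Distance between angles on the half-circle (folding at +/-90 deg).

    ``d = min(|delta|, 180 - |delta|)`` with ``delta = a - b`` reduced
    modulo 180; always in [0, 90] and symmetric in its arguments.
    """
    delta = np.abs(np.asarray(a_deg, float) - np.asarray(b_deg, float)) % 180.0
    return np.minimum(delta, 180.0 - delta)


@dataclass
class ErrorSummary:
    """Per-subject pixel-wise errors of one method/scheme vs the reference."""

    fa_mae: float
    md_mae: float
    ha_maae: float
    e2a_maae: float
    error_maps: dict = field(default_factory=dict)
    n_excluded: dict = field(default_factory=dict)


def error_maps(test_maps, ref_maps, mask) -> ErrorSummary:
    """Pixel-wise absolute error maps and their in-mask means.

    ``test_maps``/``ref_maps`` are dicts with keys among {fa, md, ha, e2a};
    HA and E2A use the folded angular distance. Voxels undefined (NaN) in
    either map are excluded and counted.
    """
    mask = np.asarray(mask, bool)
    angular = {"ha", "e2a"}
    maps, means, excluded = {}, {}, {}
    for key in ("fa", "md", "ha", "e2a"):
        if key not in test_maps or key not in ref_maps:
            continue
        t = np.asarray(test_maps[key], float)
        r = np.asarray(ref_maps[key], float)
        ok = mask & np.isfinite(t) & np.isfinite(r)
        if not ok.any():
            raise ValueError(f"no voxel where both {key} maps are defined")
        err = np.full(t.shape, np.nan)
        if key in angular:
            err[ok] = angular_distance(t[ok], r[ok])
        else:
            err[ok] = np.abs(t[ok] - r[ok])
        maps[key] = err
        means[key] = float(err[ok].mean())
        excluded[key] = int(mask.sum() - ok.sum())
    return ErrorSummary(
        fa_mae=means.get("fa", np.nan),
        md_mae=means.get("md", np.nan),
        ha_maae=means.get("ha", np.nan),
        e2a_maae=means.get("e2a", np.nan),
        error_maps=maps,
        n_excluded=excluded,
    )


@dataclass
class BlandAltman:
    """Agreement summary of paired test-minus-reference differences."""

    bias_median: float
    q05: float
    q95: float
    ci_low: float
    ci_high: float
    significant_bias: bool
    mean_bias: float
    loa_low: float  # classical mean +/- 1.96 sd limits, for reference
    loa_high: float
    n: int


def bland_altman(ref_values, test_values, n_boot: int = 10_000, seed: int = 0) -> BlandAltman:
    """Median-based Bland-Altman analysis of ``test - ref`` differences.

    Reports the median bias, the empirical 5%/95% quantiles, and a seeded
    percentile-bootstrap 95% confidence interval of the median (default
    10,000 resamples). The bias is flagged significant when 0 lies outside
    the CI. Classical mean +/- 1.96 SD limits of agreement are included as a
    secondary summary.
    """
    ref = np.asarray(ref_values, float)
    test = np.asarray(test_values, float)
    if ref.shape != test.shape:
        raise ValueError("ref/test length mismatch")
    if len(ref) < 3:
        raise ValueError("need at least 3 paired values")
    d = test - ref
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boot_medians = np.median(d[idx], axis=1)
    ci_low, ci_high = np.percentile(boot_medians, [2.5, 97.5])
    q05, q95 = np.percentile(d, [5, 95])
    sd = d.std(ddof=1)
    return BlandAltman(
        bias_median=float(np.median(d)),
        q05=float(q05),
        q95=float(q95),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant_bias=bool(ci_low > 0 or ci_high < 0),
        mean_bias=float(d.mean()),
        loa_low=float(d.mean() - 1.96 * sd),
        loa_high=float(d.mean() + 1.96 * sd),
        n=len(d),
    )


# ---------------------------------------------------------------------------
# Dice-based scan quality
# ---------------------------------------------------------------------------


def dice(mask_a, mask_b) -> float:
    """Dice coefficient ``2|A n B| / (|A| + |B|)``; 1 (with a warning) if both empty."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shape mismatch")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        logger.warning("both masks empty; Dice defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _shift_mask(mask: np.ndarray, shift_rc) -> np.ndarray:
    """Displace a boolean mask by an integer (row, col) shift, zero-filled."""
    dr, dc = int(round(shift_rc[0])), int(round(shift_rc[1]))
    out = np.zeros_like(mask)
    H, W = mask.shape
    rs = slice(max(dr, 0), min(H + dr, H))
    cs = slice(max(dc, 0), min(W + dc, W))
    rs_src = slice(max(-dr, 0), min(H - dr, H))
    cs_src = slice(max(-dc, 0), min(W - dc, W))
    out[rs, cs] = mask[rs_src, cs_src]
    return out


def mean_dice_quality(reference_mask, residual_shifts) -> float:
    """Mean Dice score of the per-image masks against the reference mask.

    ``residual_shifts`` is the (n_images, 2) array of true-minus-estimated
    shifts; each image's mask is the reference mask displaced by its rounded
    residual shift. A perfectly registered scan scores 1.
    """
    mask = np.asarray(reference_mask, bool)
    scores = [dice(mask, _shift_mask(mask, s)) for s in np.atleast_2d(residual_shifts)]
    return float(np.mean(scores))


def quality_regression(errors, dice_scores):
    """OLS regression of per-scan errors against mean Dice quality.

    Returns ``(slope, intercept, pearson_r)``; requires >= 3 scans.
    """
    errors = np.asarray(errors, float)
    dice_scores = np.asarray(dice_scores, float)
    if len(errors) != len(dice_scores) or len(errors) < 3:
        raise ValueError("need >= 3 paired (error, dice) observations")
    res = stats.linregress(dice_scores, errors)
    return float(res.slope), float(res.intercept), float(res.rvalue)


# ---------------------------------------------------------------------------
# nonparametric statistics
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    test: str
    statistic: float
    pvalue: float
    degenerate: bool = False
    pairwise: dict = field(default_factory=dict)


def nonparametric_tests(groups, paired: bool = False, bonferroni: bool = False) -> TestResult:
    """Dispatch the appropriate nonparametric comparison.

    Two paired groups -> Wilcoxon signed-rank; two unpaired -> Wilcoxon
    rank-sum; more than two -> Kruskal-Wallis with pairwise rank-sum
    follow-ups (unadjusted p by default, Bonferroni optional). All tests are
    two-sided; the reporting threshold used elsewhere is alpha = 0.05.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 observations")
    if len(groups) == 2:
        a, b = groups
        if paired:
            if len(a) != len(b):
                raise ValueError("paired groups must have equal length")
            diffs = a - b
            if np.all(diffs == 0):
                logger.warning("all paired differences tied; signed-rank p undefined")
                return TestResult("wilcoxon-signed-rank", 0.0, np.nan, degenerate=True)
            stat, p = stats.wilcoxon(a, b)
            return TestResult("wilcoxon-signed-rank", float(stat), float(p))
        stat, p = stats.ranksums(a, b)
        return TestResult("wilcoxon-rank-sum", float(stat), float(p))
    stat, p = stats.kruskal(*groups)
    pairwise = {}
    m = len(groups) * (len(groups) - 1) // 2
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            s, pp = stats.ranksums(groups[i], groups[j])
            if bonferroni:
                pp = min(1.0, pp * m)
            pairwise[(i, j)] = (float(s), float(pp))
    return TestResult("kruskal-wallis", float(stat), float(p), pairwise=pairwise)


def region_md_compare(md_map, region_labels) -> dict:
    """Remote vs infarct MD medians and their difference for one subject.

    Raises KeyError if a region mask is missing; raises ValueError when a
    region is empty (the caller should exclude the subject and log it).
    """
    out = {}
    for name in ("remote", "infarct"):
        region = np.asarray(region_labels[name], bool)
        vals = np.asarray(md_map, float)[region]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"region {name!r} empty; subject excluded")
        out[name] = float(np.median(vals))
    out["difference"] = out["infarct"] - out["remote"]
    out["ratio"] = out["infarct"] / out["remote"] if out["remote"] != 0 else np.nan
    return out
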