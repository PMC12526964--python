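"""Image-quality metrics and ROI line-profile analysis.

All image metrics operate on the 8-bit 0-255 intensity scale (MAE is then
in gray levels, PSNR uses MAX = 255), matching how decomposition quality
is conventionally tabulated.  Aggregates report mean +/- sample (n-1)
standard deviation over the evaluated image set, and paired t-tests
compare per-image metric lists between two methods.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.ndimage as ndi
import scipy.stats

# canonical 5-scale weights; renormalized when fewer scales are used
MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


def _check_pair(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a, b


def mae(pred, gt) -> float:
    """Mean absolute error in gray levels."""
    p, g = _check_pair(pred, gt)
    return float(np.mean(np.abs(p - g)))


def psnr(pred, gt, max_value: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    p, g = _check_pair(pred, gt)
    mse = float(np.mean((p - g) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_value ** 2 / mse)


def pearson_r(pred, gt) -> float:
    """Product-moment correlation over flattened pixels; NaN if either
    image is constant (undefined, deliberately not reported as 0)."""
    p, g = _check_pair(pred, gt)
    if p.std() == 0.0 or g.std() == 0.0:
        return float("nan")
    return float(scipy.stats.pearsonr(p.ravel(), g.ravel()).statistic)


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    k = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return k / k.sum()


def _ssim_components(x, y, kernel, k1=0.01, k2=0.03, max_value=255.0):
    """Windowed luminance and contrast-structure maps on the valid region."""
    c1 = (k1 * max_value) ** 2
    c2 = (k2 * max_value) ** 2

    def filt(im):
        out = ndi.correlate1d(im, kernel, axis=0, mode="constant")
        return ndi.correlate1d(out, kernel, axis=1, mode="constant")

    r = len(kernel) // 2
    sl = (slice(r, -r or None), slice(r, -r or None))
    mx, my = filt(x)[sl], filt(y)[sl]
    mxx, myy, mxy = filt(x * x)[sl], filt(y * y)[sl], filt(x * y)[sl]
    vx = mxx - mx * mx
    vy = myy - my * my
    cov = mxy - mx * my
    lum = (2 * mx * my + c1) / (mx ** 2 + my ** 2 + c1)
    cs = (2 * cov + c2) / (vx + vy + c2)
    return lum, cs


def _downsample2(x):
    h, w = (x.shape[0] // 2) * 2, (x.shape[1] // 2) * 2
    x = x[:h, :w]
    return 0.25 * (x[0::2, 0::2] + x[1::2, 0::2] + x[0::2, 1::2] + x[1::2, 1::2])


def ms_ssim(pred, gt, scales: int = 5, window: int = 11, sigma: float = 1.5,
            max_value: float = 255.0) -> float:
    """Multi-scale structural similarity in [0, 1] (1 iff identical).

    Contrast-structure terms are accumulated across dyadic scales
    (2x2 average pooling between them) and the luminance term enters at
    the coarsest scale only; negative component means are clipped at 0
    so the weighted geometric product stays real.
    """
    p, g = _check_pair(pred, gt)
    min_dim = min(p.shape)
    need = window * 2 ** (scales - 1)
    if min_dim < need:
        raise ValueError(
            f"image too small for {scales} scales: min dimension {min_dim} < {need}")
    weights = np.asarray(MSSSIM_WEIGHTS[:scales], dtype=np.float64)
    weights = weights / weights.sum()
    kernel = _gaussian_kernel(window, sigma)
    result = 1.0
    for j in range(scales):
        lum, cs = _ssim_components(p, g, kernel, max_value=max_value)
        mcs = max(float(cs.mean()), 0.0)
        if j == scales - 1:
            ml = max(float((lum * cs).mean()), 0.0)
            result *= ml ** weights[j]
        else:
            result *= mcs ** weights[j]
            p, g = _downsample2(p), _downsample2(g)
    return float(result)


@dataclasses.dataclass
class MetricsReport:
    """Per-image metric lists plus mean +/- sample-std aggregates."""

    per_image: dict[str, list[float]]
    aggregates: dict[str, tuple[float, float]]
    n: int


def evaluate_pairs(pred_set, gt_set, scales: int = 5) -> MetricsReport:
    """MAE / MS-SSIM / Pearson-R / PSNR for aligned prediction/reference sets."""
    preds = list(pred_set)
    gts = list(gt_set)
    if len(preds) != len(gts):
        raise ValueError("prediction and reference sets differ in length")
    per = {"mae": [], "ms_ssim": [], "pearson_r": [], "psnr": []}
    for p, g in zip(preds, gts):
        per["mae"].append(mae(p, g))
        per["ms_ssim"].append(ms_ssim(p, g, scales=scales))
        per["pearson_r"].append(pearson_r(p, g))
        per["psnr"].append(psnr(p, g))
    agg = {}
    with np.errstate(invalid="ignore"):  # psnr may be +inf for identical pairs
        for k, vals in per.items():
            arr = np.asarray(vals, dtype=np.float64)
            std = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            agg[k] = (float(arr.mean()), std)
    return MetricsReport(per_image=per, aggregates=agg, n=len(preds))


@dataclasses.dataclass
class TTestResult:
    t: float
    df: int
    p_value: float
    labels: tuple[str, str] = ("a", "b")
    tie: bool = False

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05

    @property
    def extremely_significant(self) -> bool:
        return self.p_value < 1e-4


def paired_t_test(metric_a, metric_b, labels=("a", "b")) -> TTestResult:
    """Two-sided paired t-test on per-image metric differences.

    Zero-variance nonzero differences (every pair differs by the same
    amount) are reported as an exact-tie sentinel with infinite t.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-d lists with n >= 2")
    d = a - b
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(t=0.0, df=n - 1, p_value=1.0, labels=tuple(labels))
        return TTestResult(t=float(np.sign(d.mean()) * np.inf), df=n - 1,
                           p_value=0.0, labels=tuple(labels), tie=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), df=n - 1, p_value=float(p), labels=tuple(labels))


@dataclasses.dataclass
class LineProfile:
    """Bilinear intensity samples along a straight segment (row, col) space."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    t: np.ndarray
    values: np.ndarray


def line_profile(image, p0, p1, n_samples: int) -> LineProfile:
    """n equally spaced bilinear samples from p0 to p1 (inclusive)."""
    img = np.asarray(image, dtype=np.float64)
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    for pt in (p0, p1):
        if not (0 <= pt[0] <= img.shape[0] - 1 and 0 <= pt[1] <= img.shape[1] - 1):
            raise ValueError(f"endpoint {pt} outside image bounds {img.shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0[0] + t * (p1[0] - p0[0])
    cols = p0[1] + t * (p1[1] - p0[1])
    vals = ndi.map_coordinates(img, np.vstack([rows, cols]), order=1, mode="nearest")
    return LineProfile(p0=tuple(p0), p1=tuple(p1), t=t, values=vals)


def separation_report(conv, bone_pred, iodine_pred, bone_line, iodine_line,
                      n_samples: int = 64) -> dict:
    """Retention/suppression scores along single-material ROI lines.

    Along a bone-only line the target head should retain the conventional
    image's signal (small mean |conv - bone_pred|) while the other head
    stays flat (small variance of iodine_pred); and symmetrically along
    an iodine-only line.  ``bone_line``/``iodine_line`` are ((r0,c0),(r1,c1)).
    """
    out = {}
    for name, line, target, other in (
            ("bone", bone_line, bone_pred, iodine_pred),
            ("iodine", iodine_line, iodine_pred, bone_pred)):
        conv_prof = line_profile(conv, *line, n_samples).values
        targ_prof = line_profile(target, *line, n_samples).values
        other_prof = line_profile(other, *line, n_samples).values
        out[f"{name}_retention"] = float(np.mean(np.abs(conv_prof - targ_prof)))
        out[f"{name}_suppression_var"] = float(np.var(other_prof))
    return out
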