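"""Synthetic photon-counting projection simulator with known material ground truth.

A digital rodent-like phantom is defined directly in the detector plane as
per-pixel path-length maps (cm) of three basis materials: soft tissue
(cylindrical body), bone (spine vertebrae + rib arcs) and an iodinated
vascular tree with a cardiac blood pool.  A two-bin photon-counting
acquisition is simulated with Beer–Lambert attenuation and optional Poisson
counting noise; the low threshold collects all counts, the high threshold
only the high-energy bin.  Weighted log-domain energy subtraction then
produces bone-preserving and iodine-preserving projections, which together
with the conventional projection form the aligned 8-bit training triplets.

Rotation is emulated parametrically: every internal structure carries
axial-plane coordinates (x, y) and its lateral position at gantry angle θ
is x·cosθ + y·sinθ, so views at θ and θ+180° are mirror images about the
body axis, as for a real projection of a rotating subject.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "subject", "angle", "conv_path", "bone_path", "iodine_path", "seed",
    "window_bone_lo", "window_bone_hi", "window_iodine_lo", "window_iodine_hi",
    "window_conv_lo", "window_conv_hi",
]


@dataclasses.dataclass(frozen=True)
class AttenuationTable:
    """Linear attenuation coefficients (1/cm) per material in two energy bins.

    The low bin is the 10–30 keV band, the high bin everything above the
    30 keV threshold; iodine's K-edge (33.2 keV) is what keeps its
    high-bin attenuation large relative to bone's, making the 2x2
    bone/iodine system well conditioned.  ``n0_low``/``n0_high`` are the
    incident fluences (counts/pixel/bin).  Defaults are representative
    diagnostic-energy values, not measurements.
    """

    mu_soft: tuple[float, float] = (0.77, 0.25)
    mu_bone: tuple[float, float] = (4.00, 0.60)
    mu_iodine: tuple[float, float] = (2.50, 1.80)
    n0_low: float = 5.0e3
    n0_high: float = 5.0e3

    def __post_init__(self):
        for name in ("mu_soft", "mu_bone", "mu_iodine"):
            mu = getattr(self, name)
            if not (mu[0] > 0 and mu[1] > 0):
                raise ValueError(f"{name} must be positive in both bins")
        if not (self.n0_low > 0 and self.n0_high > 0):
            raise ValueError("incident fluences must be positive")
        m = self.basis_matrix()
        det = abs(np.linalg.det(m))
        row_norms = np.linalg.norm(m, axis=1)
        if det <= 1e-6 * row_norms[0] * row_norms[1]:
            raise ValueError("bone/iodine basis matrix is numerically singular")

    def basis_matrix(self) -> np.ndarray:
        """2x2 matrix [[mu_bone_low, mu_iodine_low], [mu_bone_high, mu_iodine_high]]."""
        return np.array([[self.mu_bone[0], self.mu_iodine[0]],
                         [self.mu_bone[1], self.mu_iodine[1]]], dtype=np.float64)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Parametric anatomy of one projection view.

    Geometric parameters are fractions of the image extent so the same
    spec scales from full resolution down to test size; thicknesses are
    in cm of traversed material.  ``subject_seed`` fixes the anatomy
    (vessel-tree randomness, jitter); ``angle`` only rotates it.
    """

    shape: tuple[int, int] = (1024, 512)       # (rows, cols)
    pixel_size_um: float = 100.0
    subject_seed: int = 0
    angle: int = 0
    body_halfwidth_frac: float = 0.35          # of cols
    n_vertebrae: int = 9
    vertebra_len_frac: float = 0.035           # of rows (semi-axis)
    vertebra_width_frac: float = 0.22          # of body half-width (semi-axis)
    vertebra_thickness_cm: float = 0.15
    n_rib_pairs: int = 6
    rib_span_frac: float = 0.75                # of body half-width
    rib_curvature: float = 0.35
    rib_thickness_cm: float = 0.08
    rib_width_frac: float = 0.015              # of cols (gaussian sigma)
    vessel_depth: int = 4
    vessel_width_frac: float = 0.012           # of cols (gaussian sigma, trunk)
    iodine_scale_cm: float = 0.05
    heart_row_frac: float = 0.35
    heart_size_frac: float = 0.10              # of cols (semi-axis)
    heart_thickness_cm: float = 0.08

    def __post_init__(self):
        r, c = self.shape
        if r < 32 or c < 32:
            raise ValueError("image shape too small to contain the anatomy (min 32x32)")
        if not (0 <= self.angle < 360):
            raise ValueError("angle index must lie in [0, 360)")
        if not (0 < self.body_halfwidth_frac < 1):
            raise ValueError("body_halfwidth_frac must be in (0, 1)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_vertebrae < 0 or self.vessel_depth < 0 or self.n_rib_pairs < 0:
            raise ValueError("structure counts must be nonnegative")


@dataclasses.dataclass
class MaterialMap:
    """Per-pixel traversed thickness (cm) of each basis material."""

    t_soft: np.ndarray
    t_bone: np.ndarray
    t_iodine: np.ndarray

    def __post_init__(self):
        if not (self.t_soft.shape == self.t_bone.shape == self.t_iodine.shape):
            raise ValueError("material grids must share one shape")
        for t in (self.t_soft, self.t_bone, self.t_iodine):
            if not np.all(np.isfinite(t)) or np.any(t < 0):
                raise ValueError("thickness maps must be finite and nonnegative")

    @property
    def shape(self):
        return self.t_soft.shape


@dataclasses.dataclass
class CountImage:
    """Photon counts at the two thresholds plus the incident fluences.

    ``counts_thr10`` is every detected photon (low + high bin),
    ``counts_thr30`` only the high-energy bin, so the former dominates
    the latter pixel-wise by construction.
    """

    counts_thr10: np.ndarray
    counts_thr30: np.ndarray
    n0_low: float
    n0_high: float

    def __post_init__(self):
        if np.any(self.counts_thr10 < self.counts_thr30):
            raise ValueError("low-threshold counts must dominate high-threshold counts")
        if np.any(self.counts_thr30 < 0):
            raise ValueError("counts must be nonnegative")


# ---------------------------------------------------------------------------
# phantom generation


def _stamp_ellipsoid(grid: np.ndarray, row0: float, col0: float,
                     a_row: float, b_col: float, peak: float):
    """Add the chord profile of an ellipsoid: peak*sqrt(1 - u^2 - v^2)."""
    rows, cols = grid.shape
    r_lo = max(0, int(math.floor(row0 - a_row)))
    r_hi = min(rows, int(math.ceil(row0 + a_row)) + 1)
    c_lo = max(0, int(math.floor(col0 - b_col)))
    c_hi = min(cols, int(math.ceil(col0 + b_col)) + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr = (np.arange(r_lo, r_hi) - row0) / a_row
    cc = (np.arange(c_lo, c_hi) - col0) / b_col
    q = 1.0 - rr[:, None] ** 2 - cc[None, :] ** 2
    grid[r_lo:r_hi, c_lo:c_hi] += peak * np.sqrt(np.clip(q, 0.0, None))


def _stamp_tube(grid: np.ndarray, rows_pts: np.ndarray, cols_pts: np.ndarray,
                sigmas: np.ndarray, amounts: np.ndarray):
    """Accumulate gaussian cross-sections at polyline sample points."""
    nrows, ncols = grid.shape
    for r0, c0, s, a in zip(rows_pts, cols_pts, sigmas, amounts):
        rad = max(1, int(math.ceil(3.0 * s)))
        r_lo, r_hi = int(round(r0)) - rad, int(round(r0)) + rad + 1
        c_lo, c_hi = int(round(c0)) - rad, int(round(c0)) + rad + 1
        r_lo, r_hi = max(0, r_lo), min(nrows, r_hi)
        c_lo, c_hi = max(0, c_lo), min(ncols, c_hi)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        dr = np.arange(r_lo, r_hi) - r0
        dc = np.arange(c_lo, c_hi) - c0
        d2 = dr[:, None] ** 2 + dc[None, :] ** 2
        grid[r_lo:r_hi, c_lo:c_hi] += a * np.exp(-d2 / (2.0 * s * s))


def _grow_vessel_tree(rng: np.random.Generator, start_row: float, depth: int,
                      rows: int, halfwidth: float, sigma0: float):
    """Recursive branching tree in (row, x, y) body coordinates.

    Returns a list of (row, x, y, sigma, rel_amount) sample points.  The
    trunk (aorta-like) runs along the body axis; each generation splits
    in two with narrowing calibre.
    """
    points = []

    def branch(row, x, y, direction, sigma, level):
        n_steps = max(6, int(rows * 0.10))
        step = rows * 0.012 + rng.uniform(0, rows * 0.004)
        drow = -abs(step) if direction[0] < 0 else abs(step)
        dx, dy = direction[1], direction[2]
        for _ in range(n_steps):
            row += drow
            x += dx * step + rng.normal(0, 0.15 * step)
            y += dy * step + rng.normal(0, 0.15 * step)
            x = float(np.clip(x, -0.85 * halfwidth, 0.85 * halfwidth))
            y = float(np.clip(y, -0.85 * halfwidth, 0.85 * halfwidth))
            if not (0 <= row < rows):
                return
            points.append((row, x, y, sigma, 1.0))
        if level + 1 < depth:
            for sgn in (-1.0, 1.0):
                spread = rng.uniform(0.3, 0.9)
                child_dir = (direction[0], dx + sgn * spread, dy + rng.normal(0, 0.3))
                branch(row, x, y, child_dir, sigma * 0.72, level + 1)

    if depth >= 1:
        branch(start_row, 0.0, 0.12 * halfwidth, (-1.0, 0.0, 0.0), sigma0, 0)
        branch(start_row, 0.0, 0.12 * halfwidth, (+1.0, 0.05, 0.0), sigma0 * 0.9, 0)
    return points


def generate_phantom(spec: PhantomSpec) -> MaterialMap:
    """Render the three material thickness maps for one view.

    Deterministic in (subject_seed, angle): the anatomy is drawn from
    ``subject_seed`` alone and the view angle enters only through the
    parametric lateral projection x·cosθ + y·sinθ.
    """
    rows, cols = spec.shape
    px_cm = spec.pixel_size_um * 1e-4
    cx = (cols - 1) / 2.0
    theta = math.radians(spec.angle)
    cos_t, sin_t = math.cos(theta), math.sin(theta)
    rng = np.random.default_rng(spec.subject_seed)
    halfwidth = spec.body_halfwidth_frac * cols / 2.0   # px

    def project(x, y):
        return cx + x * cos_t + y * sin_t

    # soft tissue: chord through a cylinder of radius `halfwidth`
    u = np.arange(cols) - cx
    chord = 2.0 * np.sqrt(np.clip(halfwidth ** 2 - u ** 2, 0.0, None))
    t_soft = np.broadcast_to(chord * px_cm, (rows, cols)).copy()

    t_bone = np.zeros((rows, cols))
    t_iodine = np.zeros((rows, cols))

    # spine: evenly spaced vertebrae with per-subject jitter, near the axis
    if spec.n_vertebrae > 0:
        a_row = spec.vertebra_len_frac * rows
        b_col = max(1.5, spec.vertebra_width_frac * halfwidth)
        centers = np.linspace(0.12 * rows, 0.88 * rows, spec.n_vertebrae)
        centers = centers + rng.normal(0, 0.006 * rows, spec.n_vertebrae)
        spine_y = rng.uniform(-0.1, 0.1) * halfwidth
        for row0 in centers:
            col0 = project(0.0, spine_y)
            _stamp_ellipsoid(t_bone, row0, col0, a_row, b_col,
                             spec.vertebra_thickness_cm)

        # ribs: symmetric arc pairs hanging off a subset of vertebrae
        n_pairs = min(spec.n_rib_pairs, spec.n_vertebrae)
        rib_sigma = max(0.6, spec.rib_width_frac * cols)
        for k in range(n_pairs):
            row0 = centers[int(k * spec.n_vertebrae / max(1, n_pairs))]
            span = spec.rib_span_frac * halfwidth * rng.uniform(0.85, 1.0)
            curv = spec.rib_curvature * rng.uniform(0.8, 1.2)
            s = np.linspace(0.08, 1.0, 14)
            for sgn in (-1.0, 1.0):
                xs = sgn * span * s
                ys = spine_y + 0.35 * halfwidth * np.sin(math.pi * s) * curv
                rr = row0 + 0.12 * rows * curv * s ** 2
                cc = project(xs, ys)
                amt = spec.rib_thickness_cm * (1.0 - 0.5 * s)
                _stamp_tube(t_bone, rr, cc,
                            np.full_like(s, rib_sigma), amt * (s[1] - s[0]) * 8.0)

    # iodinated vasculature: heart blood pool + branching tree
    if spec.vessel_depth > 0:
        heart_row = spec.heart_row_frac * rows + rng.normal(0, 0.01 * rows)
        heart_x = rng.uniform(-0.15, 0.15) * halfwidth
        heart_y = rng.uniform(0.05, 0.25) * halfwidth
        hs = spec.heart_size_frac * cols
        _stamp_ellipsoid(t_iodine, heart_row, project(heart_x, heart_y),
                         1.3 * hs, hs, spec.heart_thickness_cm)
        sigma0 = max(0.6, spec.vessel_width_frac * cols)
        pts = _grow_vessel_tree(rng, heart_row, spec.vessel_depth,
                                rows, halfwidth, sigma0)
        if pts:
            arr = np.array(pts)
            cc = project(arr[:, 1], arr[:, 2])
            sig = arr[:, 3]
            amt = spec.iodine_scale_cm * arr[:, 4] * (sig / sigma0) * 0.5
            _stamp_tube(t_iodine, arr[:, 0], cc, sig, amt)

    # contrast only exists inside the body; bone likewise
    body = t_soft > 0
    t_bone *= body
    t_iodine *= body
    # displaced bone/iodine thickness replaces soft tissue, not adds to it
    t_soft = np.clip(t_soft - t_bone - t_iodine, 0.0, None)
    return MaterialMap(t_soft=t_soft, t_bone=t_bone, t_iodine=t_iodine)


# ---------------------------------------------------------------------------
# forward model


def forward_counts(mmap: MaterialMap, table: AttenuationTable,
                   rng_seed: int = 0, noise: bool = True) -> CountImage:
    """Beer–Lambert expected counts per bin, optionally Poisson sampled."""
    att_low = (table.mu_soft[0] * mmap.t_soft + table.mu_bone[0] * mmap.t_bone
               + table.mu_iodine[0] * mmap.t_iodine)
    att_high = (table.mu_soft[1] * mmap.t_soft + table.mu_bone[1] * mmap.t_bone
                + table.mu_iodine[1] * mmap.t_iodine)
    lam_low = table.n0_low * np.exp(-att_low)
    lam_high = table.n0_high * np.exp(-att_high)
    if noise:
        rng = np.random.default_rng(rng_seed)
        low = rng.poisson(lam_low).astype(np.float64)
        high = rng.poisson(lam_high).astype(np.float64)
    else:
        low, high = lam_low, lam_high
    return CountImage(counts_thr10=low + high, counts_thr30=high,
                      n0_low=table.n0_low, n0_high=table.n0_high)


def counts_to_log_projection(counts: CountImage) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin log-attenuation images −ln(counts/N0), clamping zero counts to 1."""
    low_bin = counts.counts_thr10 - counts.counts_thr30
    p_low = -np.log(np.maximum(low_bin, 1.0) / counts.n0_low)
    p_high = -np.log(np.maximum(counts.counts_thr30, 1.0) / counts.n0_high)
    return p_low, p_high


def conv_projection(counts: CountImage) -> np.ndarray:
    """Conventional (all-counts) log projection, the GAN's input channel."""
    n0 = counts.n0_low + counts.n0_high
    return -np.log(np.maximum(counts.counts_thr10, 1.0) / n0)


def energy_subtraction(p_low: np.ndarray, p_high: np.ndarray,
                       table: AttenuationTable) -> tuple[np.ndarray, np.ndarray]:
    """Weighted log-domain subtraction nulling the contaminant material.

    bone_raw cancels iodine exactly in the noiseless linear model (weight
    mu_iodine_low/mu_iodine_high); iodine_raw cancels bone.  The
    soft-tissue term is retained and absorbed by the quantization window.
    """
    if table.mu_iodine[1] <= 0 or table.mu_bone[1] <= 0:
        raise ValueError("high-bin attenuation must be positive for subtraction weights")
    bone_raw = p_low - (table.mu_iodine[0] / table.mu_iodine[1]) * p_high
    iodine_raw = p_low - (table.mu_bone[0] / table.mu_bone[1]) * p_high
    return bone_raw, iodine_raw


def exact_decompose(p_low: np.ndarray, p_high: np.ndarray, table: AttenuationTable,
                    t_soft_known: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel 2x2 linear inversion for (t_bone, t_iodine), soft tissue known.

    The analytic oracle: on noiseless data it inverts the forward model
    exactly and serves as the reference the learned decomposition is
    judged against.
    """
    m = table.basis_matrix()
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    b_low = p_low - table.mu_soft[0] * t_soft_known
    b_high = p_high - table.mu_soft[1] * t_soft_known
    t_bone = (m[1, 1] * b_low - m[0, 1] * b_high) / det
    t_iodine = (-m[1, 0] * b_low + m[0, 0] * b_high) / det
    return t_bone, t_iodine


def quantize_to_png8(grid: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Affine window [lo, hi] -> [0, 255], clip, round half-up, uint8."""
    lo, hi = float(window[0]), float(window[1])
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    scaled = (np.asarray(grid, dtype=np.float64) - lo) / (hi - lo) * 255.0
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset assembly


def _calibration_windows(spec_template: PhantomSpec, table: AttenuationTable,
                         subject_seeds: list[int]) -> dict[str, float]:
    """Dataset-wide quantization windows from noiseless calibration views.

    The 0.5th/99.5th percentiles of each channel over a small batch of
    noiseless projections are frozen so all images share one intensity
    scale (per-image windows would break cross-image MAE/PSNR
    comparability).
    """
    convs, bones, iodines = [], [], []
    for seed in subject_seeds:
        for angle in (0, 45, 90, 135):
            spec = dataclasses.replace(spec_template, subject_seed=seed, angle=angle)
            counts = forward_counts(generate_phantom(spec), table, noise=False)
            p_low, p_high = counts_to_log_projection(counts)
            bone_raw, iodine_raw = energy_subtraction(p_low, p_high, table)
            convs.append(conv_projection(counts))
            bones.append(bone_raw)
            iodines.append(iodine_raw)

    def win(stack):
        a = np.concatenate([s.ravel() for s in stack])
        lo, hi = np.percentile(a, [0.5, 99.5])
        if hi - lo < 1e-9:
            hi = lo + 1.0
        return float(lo), float(hi)

    cw, bw, iw = win(convs), win(bones), win(iodines)
    return {"window_conv_lo": cw[0], "window_conv_hi": cw[1],
            "window_bone_lo": bw[0], "window_bone_hi": bw[1],
            "window_iodine_lo": iw[0], "window_iodine_hi": iw[1]}


def render_triplet(spec: PhantomSpec, table: AttenuationTable, windows: dict,
                   noise_seed: int, noise: bool = True):
    """One aligned (conv, bone, iodine) uint8 triplet for a single view."""
    mmap = generate_phantom(spec)
    counts = forward_counts(mmap, table, rng_seed=noise_seed, noise=noise)
    p_low, p_high = counts_to_log_projection(counts)
    bone_raw, iodine_raw = energy_subtraction(p_low, p_high, table)
    conv8 = quantize_to_png8(conv_projection(counts),
                             (windows["window_conv_lo"], windows["window_conv_hi"]))
    bone8 = quantize_to_png8(bone_raw,
                             (windows["window_bone_lo"], windows["window_bone_hi"]))
    iodine8 = quantize_to_png8(iodine_raw,
                               (windows["window_iodine_lo"], windows["window_iodine_hi"]))
    return conv8, bone8, iodine8, mmap


def make_triplet_arrays(n_subjects: int, angles_per_subject: int,
                        spec_template: PhantomSpec, table: AttenuationTable,
                        master_seed: int, noise: bool = True):
    """In-memory dataset: stacked uint8 (conv, bone, iodine) arrays.

    Same seeding scheme and windows as :func:`make_dataset`, without the
    PNG round trip; returns (conv, bone, iodine, subject_ids, windows).
    """
    ss = np.random.SeedSequence(master_seed)
    subject_seeds = [int(s) for s in ss.generate_state(n_subjects)]
    noise_root = np.random.SeedSequence([master_seed, 1])
    noise_seeds = noise_root.generate_state(n_subjects * angles_per_subject)
    windows = _calibration_windows(spec_template, table, subject_seeds)
    step = 360 // angles_per_subject if angles_per_subject <= 360 else 1
    convs, bones, iodines, subjects = [], [], [], []
    k = 0
    for si, sseed in enumerate(subject_seeds):
        for ai in range(angles_per_subject):
            angle = (ai * step) % 360
            spec = dataclasses.replace(spec_template, subject_seed=sseed, angle=angle)
            c8, b8, i8, _ = render_triplet(spec, table, windows,
                                           noise_seed=int(noise_seeds[k]) % (2 ** 31),
                                           noise=noise)
            k += 1
            convs.append(c8)
            bones.append(b8)
            iodines.append(i8)
            subjects.append(si)
    return (np.stack(convs), np.stack(bones), np.stack(iodines),
            np.asarray(subjects), windows)


def make_dataset(n_subjects: int, angles_per_subject: int,
                 spec_template: PhantomSpec, table: AttenuationTable,
                 master_seed: int, out_dir, noise: bool = True,
                 force: bool = False) -> Path:
    """Write one ProjectionTriplet per (subject, angle) plus a TSV manifest.

    Fully reproducible from ``master_seed``: subject anatomy seeds and
    per-view Poisson seeds are spawned from it deterministically.
    Returns the manifest path.
    """
    from PIL import Image

    if n_subjects < 1 or angles_per_subject < 1:
        raise ValueError("need at least one subject and one angle")
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.tsv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"manifest already exists: {manifest_path} (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(master_seed)
    subject_seeds = [int(s) for s in ss.generate_state(n_subjects)]
    noise_root = np.random.SeedSequence([master_seed, 1])
    noise_seeds = noise_root.generate_state(n_subjects * angles_per_subject)

    windows = _calibration_windows(spec_template, table, subject_seeds)
    step = 360 // angles_per_subject if angles_per_subject <= 360 else 1
    rows = []
    k = 0
    for si, sseed in enumerate(subject_seeds):
        subject = f"s{si:02d}"
        for ai in range(angles_per_subject):
            angle = (ai * step) % 360
            spec = dataclasses.replace(spec_template, subject_seed=sseed, angle=angle)
            nseed = int(noise_seeds[k]) % (2 ** 31)
            k += 1
            conv8, bone8, iodine8, _ = render_triplet(spec, table, windows,
                                                      noise_seed=nseed, noise=noise)
            names = {}
            for channel, img in (("conv", conv8), ("bone", bone8), ("iodine", iodine8)):
                fname = f"{subject}_{angle:03d}_{channel}.png"
                Image.fromarray(img, mode="L").save(out_dir / fname)
                names[channel] = fname
            rows.append({"subject": subject, "angle": angle,
                         "conv_path": names["conv"], "bone_path": names["bone"],
                         "iodine_path": names["iodine"], "seed": nseed, **windows})

    df = pd.DataFrame(rows)[MANIFEST_COLUMNS]
    df.to_csv(manifest_path, sep="\t", index=False)
    return manifest_path
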