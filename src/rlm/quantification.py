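"""Statistical surface of the analysis: decay-count model, decay-corrected
sensitivity ratios, ROI counting with background correction, dual-vs-single
regression, line profiles, 2-D Gaussian FWHM and the efflux difference image.

The number of decays D detected from a cell holding N₀ tracer molecules at
the reference time is

    D = S·Y·N₀·(1 − exp(−ln2·t/τ½))

with S the system detection sensitivity, Y the particulate-radiation yield
(0.97 for ¹⁸F) and τ½ the half-life (~110 min).  Comparing two acquisitions
Δt apart, the later measurement is rescaled to the earlier reference time by
the decay-correction factor exp(ln2·Δt/τ½) (= 1.14 for Δt = 21 min), so the
sensitivity ratio is S₂/S₁ = D₂·exp(ln2·Δt/τ½)/D₁.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, stats

from .errors import FitFailureError, InvalidArgumentError, UndefinedRatioError
from .reconstruction import EventImage

LN2 = float(np.log(2.0))
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * LN2)


@dataclass(frozen=True)
class RoiMeasurement:
    """Event count inside one circular ROI, with background correction."""

    center_um: tuple[float, float]
    diameter_um: float
    raw_count: float
    background_corrected_count: float
    label: str = "cell"


@dataclass(frozen=True)
class SensitivityEstimate:
    """Dual/single sensitivity ratio with decay correction and CI."""

    ratio: float
    delta_t_min: float
    correction_factor: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class GaussianFit2D:
    """Circularly symmetric 2-D Gaussian fit of an event image."""

    center_um: tuple[float, float]
    sigma_um: float
    amplitude: float
    offset: float

    @property
    def fwhm_um(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_um


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float = float("nan")


def expected_counts(n_molecules: float, sensitivity: float, yield_beta: float,
                    elapsed_min: float, half_life_min: float) -> float:
    """Expected detected decays D = S·Y·N₀·(1 − exp(−ln2·t/τ½))."""
    for name, v in [("n_molecules", n_molecules), ("sensitivity", sensitivity),
                    ("yield_beta", yield_beta), ("elapsed", elapsed_min),
                    ("half_life", half_life_min)]:
        if v < 0:
            raise InvalidArgumentError(f"{name} must be >= 0")
    return sensitivity * yield_beta * n_molecules * (-np.expm1(-LN2 * elapsed_min / half_life_min))


def decay_correction_factor(delta_t_min: float, half_life_min: float) -> float:
    """Multiplicative correction exp(ln2·Δt/τ½) applied to the later measurement."""
    if half_life_min <= 0:
        raise InvalidArgumentError("half_life must be > 0")
    return float(np.exp(LN2 * delta_t_min / half_life_min))


def sensitivity_ratio(d_double: float, d_single: float, delta_t_min: float,
                      half_life_min: float, alpha: float = 0.05) -> SensitivityEstimate:
    """Decay-corrected sensitivity ratio with a counting-statistics CI.

    Treats both totals as Poisson counts; the CI comes from the conditional
    binomial (Clopper–Pearson / Beta quantile) method for a ratio of Poisson
    means, then scales by the decay-correction factor.
    """
    if d_single <= 0:
        raise UndefinedRatioError("single-configuration count must be > 0")
    corr = decay_correction_factor(delta_t_min, half_life_min)
    ratio = d_double * corr / d_single
    x, y = float(d_double), float(d_single)
    p_lo = stats.beta.ppf(alpha / 2.0, x, y + 1.0) if x > 0 else 0.0
    p_hi = stats.beta.ppf(1.0 - alpha / 2.0, x + 1.0, y)
    ci_low = corr * p_lo / (1.0 - p_lo)
    ci_high = corr * p_hi / (1.0 - p_hi) if p_hi < 1 else np.inf
    return SensitivityEstimate(float(ratio), delta_t_min, corr, float(ci_low), float(ci_high))


def _roi_mask(image: EventImage, center_um, diameter_um: float) -> np.ndarray:
    from .optics import pixel_centers_um

    h, w = image.counts.shape
    x, y = pixel_centers_um((h, w), image.pixel_pitch_object_um)
    dx = x[None, :] - center_um[0]
    dy = y[:, None] - center_um[1]
    return dx * dx + dy * dy <= (diameter_um / 2.0) ** 2


def roi_counts(image: EventImage, centers, diameter_um: float = 90.0,
               background_rois=()) -> list[RoiMeasurement]:
    """Sum event counts in circular ROIs and subtract the mean background ROI.

    Pixel membership is pixel-center-in-circle.  Background ROIs use the same
    diameter; their mean raw count is subtracted from every cell ROI.
    """
    h, w = image.counts.shape
    pitch = image.pixel_pitch_object_um
    half_x, half_y = w * pitch / 2.0, h * pitch / 2.0
    r = diameter_um / 2.0
    for cx, cy in list(centers) + list(background_rois):
        if abs(cx) + r > half_x + pitch / 2 or abs(cy) + r > half_y + pitch / 2:
            raise InvalidArgumentError(f"ROI at ({cx}, {cy}) extends outside the image")
    bg_counts = [float(image.counts[_roi_mask(image, c, diameter_um)].sum())
                 for c in background_rois]
    bg_mean = float(np.mean(bg_counts)) if bg_counts else 0.0
    out = []
    for c in centers:
        raw = float(image.counts[_roi_mask(image, c, diameter_um)].sum())
        out.append(RoiMeasurement(tuple(c), diameter_um, raw, raw - bg_mean, "cell"))
    for c, raw in zip(background_rois, bg_counts):
        out.append(RoiMeasurement(tuple(c), diameter_um, raw, raw - bg_mean, "background"))
    return out


def fit_gaussian2d(image: EventImage, min_counts: int = 50) -> GaussianFit2D:
    """Least-squares circularly symmetric Gaussian fit in object-space μm.

    Model: A·exp(−((x−x₀)² + (y−y₀)²)/(2σ²)) + offset.  Initialized from the
    image centroid and second-moment radius; σ is bounded to (0.1 px,
    field/2).
    """
    from .optics import pixel_centers_um

    counts = np.asarray(image.counts, dtype=float)
    total = counts.sum()
    if total < min_counts:
        raise InvalidArgumentError(f"need at least {min_counts} counts to fit")
    h, w = counts.shape
    pitch = image.pixel_pitch_object_um
    x, y = pixel_centers_um((h, w), pitch)
    xx, yy = np.meshgrid(x, y)
    cx = float((counts * xx).sum() / total)
    cy = float((counts * yy).sum() / total)
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    sigma0 = float(np.sqrt(np.maximum((counts * r2).sum() / total / 2.0, (0.2 * pitch) ** 2)))
    p0 = [counts.max(), cx, cy, sigma0, float(np.median(counts))]
    lo = [0.0, x.min(), y.min(), 0.1 * pitch, -np.inf]
    hi = [np.inf, x.max(), y.max(), max(h, w) * pitch / 2.0, np.inf]

    def model(p):
        a, x0, y0, s, off = p
        return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s * s)) + off

    res = optimize.least_squares(lambda p: (model(p) - counts).ravel(), p0,
                                 bounds=(lo, hi), method="trf")
    if not res.success:
        raise FitFailureError("2-D Gaussian fit did not converge", res.status, res.message)
    a, x0, y0, s, off = res.x
    return GaussianFit2D((float(x0), float(y0)), float(s), float(a), float(off))


def line_profile(image: EventImage, p0_um, p1_um, width_um: float,
                 normalize: bool = False, n_samples: int | None = None) -> np.ndarray:
    """Counts integrated across a band of ``width_um`` along the p0→p1 segment.

    The profile is sampled at pixel-pitch steps along the segment; at each
    step the image is integrated perpendicular to the segment by bilinear
    interpolation on a fine transverse grid.  ``normalize`` divides by the
    profile maximum.
    """
    p0 = np.asarray(p0_um, dtype=float)
    p1 = np.asarray(p1_um, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0:
        raise InvalidArgumentError("profile endpoints coincide")
    h, w = image.counts.shape
    pitch = image.pixel_pitch_object_um
    half_x, half_y = (w - 1) * pitch / 2.0, (h - 1) * pitch / 2.0
    for p in (p0, p1):
        if abs(p[0]) > half_x + pitch / 2 or abs(p[1]) > half_y + pitch / 2:
            raise InvalidArgumentError("profile endpoint outside the image")
    u = (p1 - p0) / length
    v = np.array([-u[1], u[0]])
    n_along = n_samples or max(2, int(np.ceil(length / pitch)) + 1)
    t = np.linspace(0.0, length, n_along)
    dt_perp = pitch / 4.0
    n_perp = max(1, int(np.ceil(width_um / dt_perp)))
    s = (np.arange(n_perp) - (n_perp - 1) / 2.0) * (width_um / n_perp)
    pts = p0[None, None, :] + t[:, None, None] * u[None, None, :] + s[None, :, None] * v[None, None, :]
    cols = pts[..., 0] / pitch + (w - 1) / 2.0
    rows = pts[..., 1] / pitch + (h - 1) / 2.0
    vals = ndimage.map_coordinates(np.asarray(image.counts, dtype=float),
                                   [rows.ravel(), cols.ravel()], order=1, mode="constant")
    prof = vals.reshape(n_along, n_perp).sum(axis=1) * (width_um / n_perp) / pitch
    if normalize:
        m = prof.max()
        if m > 0:
            prof = prof / m
    return prof


def efflux_difference_image(double_img: EventImage, single_img: EventImage,
                            delta_t_min: float, half_life_min: float) -> np.ndarray:
    """Decay-corrected double image halved, minus the single image.

    Negative values mark cells whose activity dropped between acquisitions
    (tracer efflux); positive halos around them mark activity that moved into
    the surrounding medium.
    """
    if double_img.counts.shape != single_img.counts.shape:
        raise InvalidArgumentError("image shapes differ")
    if abs(double_img.pixel_pitch_object_um - single_img.pixel_pitch_object_um) > 1e-9:
        raise InvalidArgumentError("pixel pitches differ")
    corr = decay_correction_factor(delta_t_min, half_life_min)
    return double_img.counts * corr / 2.0 - single_img.counts.astype(float)


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares y = slope·x + intercept with r²."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise InvalidArgumentError("need >= 3 paired points")
    if np.ptp(x) == 0:
        raise InvalidArgumentError("x values are degenerate (zero variance)")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 0.0
    return RegressionResult(float(res.slope), float(res.intercept), r2,
                            float(res.stderr))
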