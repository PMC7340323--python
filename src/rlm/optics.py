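"""Optical model and EMCCD camera: energy deposits → image frames.

The microscope is modelled by a 2-D Gaussian point-spread function whose
in-focus width σ₀ = 0.21 λ/NA (Gaussian approximation to the Airy core)
grows with defocus dz as σ(dz) = √(σ₀² + (c·dz)²), c = NA/(2n).  A deposit of
E keV contributes light_yield·E·QE expected photoelectrons, spread over
pixels by the PSF; photoelectrons are Poisson-sampled, amplified through the
EM register (Gamma with scale = EM gain, which reproduces the √2 excess-noise
factor), Gaussian read noise is added and the result is quantized to uint16.

The depth-of-field criterion for a low-light microscope is

    d = n·λ/NA² + n·b·e/(M·NA)

(wave-optics term + geometric pixel term), ~24.5 μm for the default
20×/0.75 NA objective at 3.6× effective magnification with a 16 μm-pixel
camera at 4×4 binning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .errors import InvalidArgumentError
from .rng import as_rng

SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class OpticalSystem:
    """Microscope optics: emission wavelength, NA, magnification, focus."""

    wavelength_nm: float = 475.0
    refractive_index: float = 1.0
    numerical_aperture: float = 0.75
    effective_magnification: float = 3.6
    focal_plane_z_um: float = -5.0      # bottom slab top surface for default geometry
    system_blur_um: float = 10.0        # empirical instrument blur floor (see note)
    dual_plate_blur_um: float = 18.0    # aberration from imaging through the top crystal

    def __post_init__(self):
        if self.wavelength_nm <= 0:
            raise InvalidArgumentError("wavelength must be > 0")
        if not 0 < self.numerical_aperture < self.refractive_index * 1.52:
            raise InvalidArgumentError("NA must be in (0, 1.52 n)")
        if self.effective_magnification <= 0:
            raise InvalidArgumentError("magnification must be > 0")

    @property
    def airy_sigma_um(self) -> float:
        """Diffraction-limited PSF sigma (Gaussian fit to the Airy core)."""
        return 0.21 * (self.wavelength_nm / 1000.0) / self.numerical_aperture

    @property
    def sigma0_um(self) -> float:
        """In-focus effective PSF sigma: Airy core ⊕ instrument blur.

        ``system_blur_um`` is an empirical floor standing in for everything
        the diffraction limit misses in a scintillator-coupled low-light
        microscope (light spread inside the high-index crystal, surface
        scatter, residual aberrations); reconstructed point sources in such
        systems are tens of μm wide, far beyond the Airy core.
        """
        return float(np.hypot(self.airy_sigma_um, self.system_blur_um))

    @property
    def defocus_slope(self) -> float:
        return self.numerical_aperture / (2.0 * self.refractive_index)

    def psf_sigma_um(self, dz_um, through_plate: bool = False) -> np.ndarray:
        """Defocus-broadened PSF sigma at axial offset dz from the focal plane.

        ``through_plate=True`` adds the spherical-aberration blur of imaging
        through the top scintillator crystal (dual configuration: the
        objective views every flash through ~0.5 mm of n≈2.25 CdWO₄; the
        transverse aberration of a plane-parallel plate at NA 0.75 is tens
        of μm).  This is the mechanism that degrades dual-configuration
        resolution relative to the single-slab case.
        """
        dz = np.asarray(dz_um, dtype=float)
        s2 = self.sigma0_um**2 + (self.defocus_slope * dz) ** 2
        if through_plate:
            s2 = s2 + self.dual_plate_blur_um**2
        return np.sqrt(s2)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD camera parameters (defaults match a back-illuminated 16 μm-pixel
    camera run at 1,060 EM gain, 4×4 binning, 30 ms exposure)."""

    pixel_size_um: float = 16.0
    binning: int = 4
    em_gain: float = 1060.0
    exposure_s: float = 0.030
    read_noise_e: float = 30.0
    dark_rate_e_per_s: float = 0.001
    quantum_efficiency: float = 0.01    # end-to-end photon → photoelectron efficiency
    bias_offset_adu: float = 200.0      # camera baseline, keeps read noise off the 0 rail

    def __post_init__(self):
        if self.binning < 1 or int(self.binning) != self.binning:
            raise InvalidArgumentError("binning must be a positive integer")
        if self.exposure_s <= 0:
            raise InvalidArgumentError("exposure must be > 0")
        if self.em_gain < 1:
            raise InvalidArgumentError("EM gain must be >= 1")

    def pixel_pitch_object_um(self, optics: OpticalSystem) -> float:
        """Binned pixel size referred to object space: e·b/M."""
        return self.pixel_size_um * self.binning / optics.effective_magnification


@dataclass
class FrameStack:
    """Ordered 2-D frames plus acquisition metadata."""

    frames: np.ndarray                  # (n_frames, H, W), unsigned integers
    pixel_pitch_object_um: float
    timestamps_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidArgumentError("frames must be a (n, H, W) array")
        if len(self.timestamps_s) != len(self.frames):
            raise InvalidArgumentError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def depth_of_field(optics: OpticalSystem, camera: CameraModel) -> float:
    """Depth of field in μm: n·λ/NA² + n·b·e/(M·NA)."""
    na = optics.numerical_aperture
    if na == 0:
        raise InvalidArgumentError("NA must be nonzero")
    lam_um = optics.wavelength_nm / 1000.0
    n = optics.refractive_index
    wave = n * lam_um / na**2
    geom = n * camera.binning * camera.pixel_size_um / (optics.effective_magnification * na)
    return wave + geom


def pixel_centers_um(shape: tuple[int, int], pitch_um: float) -> tuple[np.ndarray, np.ndarray]:
    """Object-space coordinates of pixel centers; the field is centred on (0,0).

    x runs along columns, y along rows: pixel (i, j) sits at
    (x, y) = ((j − (W−1)/2)·pitch, (i − (H−1)/2)·pitch).
    """
    h, w = shape
    x = (np.arange(w) - (w - 1) / 2.0) * pitch_um
    y = (np.arange(h) - (h - 1) / 2.0) * pitch_um
    return x, y


def expected_flash_image(shape: tuple[int, int], pitch_um: float,
                         x_um, y_um, sigma_um, photoelectrons) -> np.ndarray:
    """Expected photoelectron image of Gaussian flashes (no noise, no gain).

    Each flash integrates its 2-D Gaussian over pixel areas via erf products.
    Used both by the renderer and as a test surface for shift invariance and
    depth symmetry.
    """
    h, w = shape
    lam = np.zeros((h, w))
    _accumulate_flashes(lam[None, ...], np.zeros(len(np.atleast_1d(x_um)), dtype=np.int64),
                        np.atleast_1d(x_um), np.atleast_1d(y_um),
                        np.atleast_1d(sigma_um), np.atleast_1d(photoelectrons), pitch_um)
    return lam


def _accumulate_flashes(stack_lam: np.ndarray, frame_idx: np.ndarray,
                        x_um: np.ndarray, y_um: np.ndarray, sigma_um: np.ndarray,
                        pe: np.ndarray, pitch_um: float, window_sigmas: float = 4.0) -> None:
    """Add erf-integrated Gaussian expectations into a (n, H, W) stack in place."""
    n_fr, h, w = stack_lam.shape
    if len(x_um) == 0:
        return
    # continuous position in fractional pixel units
    col = x_um / pitch_um + (w - 1) / 2.0
    row = y_um / pitch_um + (h - 1) / 2.0
    s_px = np.maximum(sigma_um / pitch_um, 1e-6)
    half = np.maximum(1, np.ceil(window_sigmas * s_px).astype(np.int64))
    # group by window half-size so each group vectorizes with a fixed window
    for hw in np.unique(half):
        sel = half == hw
        k = np.arange(-hw, hw + 1)
        # pixel (index i) spans [i-0.5, i+0.5] in fractional units
        c0 = np.floor(col[sel] + 0.5)
        r0 = np.floor(row[sel] + 0.5)
        cols = c0[:, None] + k[None, :]
        rows = r0[:, None] + k[None, :]
        sp = s_px[sel][:, None]
        fx = 0.5 * (erf((cols + 0.5 - col[sel][:, None]) / (SQRT2 * sp))
                    - erf((cols - 0.5 - col[sel][:, None]) / (SQRT2 * sp)))
        fy = 0.5 * (erf((rows + 0.5 - row[sel][:, None]) / (SQRT2 * sp))
                    - erf((rows - 0.5 - row[sel][:, None]) / (SQRT2 * sp)))
        weights = pe[sel][:, None, None] * fy[:, :, None] * fx[:, None, :]
        ri = np.clip(rows, 0, h - 1).astype(np.int64)
        ci = np.clip(cols, 0, w - 1).astype(np.int64)
        ok = ((rows >= 0) & (rows < h))[:, :, None] & ((cols >= 0) & (cols < w))[:, None, :]
        fi = np.broadcast_to(frame_idx[sel][:, None, None], weights.shape)
        rr = np.broadcast_to(ri[:, :, None], weights.shape)
        cc = np.broadcast_to(ci[:, None, :], weights.shape)
        np.add.at(stack_lam, (fi[ok], rr[ok], cc[ok]), weights[ok])


def _camera_noise(lam_pe: np.ndarray, camera: CameraModel, rng: np.random.Generator,
                  chunk: int = 512) -> np.ndarray:
    """Poisson + EM-register Gamma + Gaussian read noise, quantized to uint16."""
    out = np.empty(lam_pe.shape, dtype=np.uint16)
    dark = camera.dark_rate_e_per_s * camera.exposure_s
    for i in range(0, len(lam_pe), chunk):
        lam = lam_pe[i:i + chunk] + dark
        n_pe = rng.poisson(lam)
        signal = np.zeros(n_pe.shape)
        nz = n_pe > 0
        if np.any(nz):
            signal[nz] = rng.gamma(n_pe[nz], camera.em_gain)
        signal += camera.bias_offset_adu
        signal += rng.normal(0.0, camera.read_noise_e, size=n_pe.shape)
        out[i:i + chunk] = np.clip(np.rint(signal), 0, 65535).astype(np.uint16)
    return out


def dark_mean_adu(camera: CameraModel) -> float:
    """Closed-form expected dark-frame pixel value (bias + amplified dark current)."""
    return camera.bias_offset_adu + camera.dark_rate_e_per_s * camera.exposure_s * camera.em_gain


def render_frames(deposits: dict, times_s: np.ndarray, stack, optics: OpticalSystem,
                  camera: CameraModel, shape: tuple[int, int], n_frames: int,
                  seed=None) -> FrameStack:
    """Render transported deposits into a noisy EMCCD frame stack.

    ``deposits`` is the flat-array dict from ``simulator.transport_batch``;
    ``times_s`` gives each decay's absolute time, which selects the frame
    whose exposure window contains it (no dead time).  Deposits keep their
    expected light regardless of defocus — defocus only broadens the PSF —
    so light is conserved in expectation.
    """
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    if shape[0] < 1 or shape[1] < 1:
        raise InvalidArgumentError("field of view must be non-empty")
    rng = as_rng(seed)
    pitch = camera.pixel_pitch_object_um(optics)

    idx = deposits["event_index"]
    frame_idx = np.floor(np.asarray(times_s)[idx] / camera.exposure_s).astype(np.int64)
    keep = (frame_idx >= 0) & (frame_idx < n_frames) & (deposits["slab_id"] >= 0)
    frame_idx = frame_idx[keep]
    dz = deposits["z"][keep] - optics.focal_plane_z_um
    sigma = optics.psf_sigma_um(dz, through_plate=getattr(stack, "is_dual", False))
    pe = stack.light_yield_per_kev * deposits["energy_kev"][keep] * camera.quantum_efficiency
    x_um, y_um = deposits["x"][keep], deposits["y"][keep]

    # render in frame chunks to bound memory for 10,000-frame stacks
    chunk = max(1, int(64e6 // (shape[0] * shape[1] * 8)))
    frames = np.empty((n_frames,) + tuple(shape), dtype=np.uint16)
    for f0 in range(0, n_frames, chunk):
        f1 = min(f0 + chunk, n_frames)
        lam = np.zeros((f1 - f0,) + tuple(shape), dtype=np.float64)
        sel = (frame_idx >= f0) & (frame_idx < f1)
        _accumulate_flashes(lam, frame_idx[sel] - f0, x_um[sel], y_um[sel],
                            sigma[sel], pe[sel], pitch)
        frames[f0:f1] = _camera_noise(lam, camera, rng)
    ts = np.arange(n_frames) * camera.exposure_s
    meta = {"camera": camera.__dict__ | {}, "optics": optics.__dict__ | {}}
    return FrameStack(frames, pitch, ts, meta)


def make_dark_stack(camera: CameraModel, shape: tuple[int, int], n_frames: int,
                    seed=None, optics: OpticalSystem | None = None) -> FrameStack:
    """Dark reference frames: dark current + read noise only."""
    if n_frames < 1:
        raise InvalidArgumentError("n_frames must be >= 1")
    rng = as_rng(seed)
    optics = optics or OpticalSystem()
    lam = np.zeros((n_frames,) + tuple(shape))
    frames = _camera_noise(lam, camera, rng)
    ts = np.arange(n_frames) * camera.exposure_s
    return FrameStack(frames, camera.pixel_pitch_object_um(optics), ts,
                      {"dark": True, "camera": camera.__dict__ | {}})
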