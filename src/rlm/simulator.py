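"""Desk-scale Monte Carlo of ¹⁸F beta decay in a scintillator sandwich.

Models a point/extended ¹⁸F source on a plane between one (below) or two
(below + above) CdWO₄ scintillator slabs.  Positrons are emitted isotropically
with energies drawn from an allowed-transition Fermi beta spectrum
(endpoint 633.5 keV) and transported as straight rays; the path length
travelled inside slab material is sampled from an exponential whose
energy-dependent mean is calibrated so the spectrum-averaged deposit depth
below the slab surface is ~25 μm, the penetration scale of ¹⁸F positrons in
CdWO₄.  Energy is laid down as a chain of discrete deposits along the
intersected chord.

Coordinates are right-handed with z up; the source plane is z = 0 and the
bottom slab occupies z ∈ [−gap_bottom − thickness, −gap_bottom].  Lengths are
in μm, energies in keV, times in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidArgumentError, InvalidGeometryError
from .rng import as_rng, split_rngs

# ¹⁸F constants
E_MAX_KEV = 633.5          # beta endpoint energy
BETA_YIELD = 0.97          # positron branching fraction
HALF_LIFE_MIN = 110.0      # ~110 min
MEC2_KEV = 510.99895       # electron rest energy
ALPHA_FS = 1.0 / 137.035999084
Z_DAUGHTER = 8             # ¹⁸O

BOTTOM, TOP = 0, 1
SLAB_NAMES = {BOTTOM: "bottom", TOP: "top"}

# Reference energy and power of the range–energy law ℓ(E) = ℓ₀ (E/E_ref)^p.
# p ≈ 1.4 matches the slope of CSDA electron ranges over 50–600 keV.
RANGE_E_REF_KEV = 250.0
RANGE_POWER = 1.4
TARGET_MEAN_DEPTH_UM = 25.0


@dataclass(frozen=True)
class SourceModel:
    """A radioactive source: activity, particulate-radiation yield, half-life."""

    activity_bq: float
    yield_beta: float = BETA_YIELD
    half_life_min: float = HALF_LIFE_MIN

    def __post_init__(self):
        if self.activity_bq < 0:
            raise InvalidArgumentError("activity must be >= 0")
        if not 0 < self.yield_beta <= 1:
            raise InvalidArgumentError("yield_beta must be in (0, 1]")
        if self.half_life_min <= 0:
            raise InvalidArgumentError("half_life must be > 0")

    @property
    def decay_constant_per_s(self) -> float:
        return np.log(2.0) / (self.half_life_min * 60.0)


@dataclass(frozen=True)
class ScintillatorStack:
    """One or two parallel scintillator slabs flanking the source plane.

    ``gap_top=None`` means the single (bottom-only) configuration.
    ``range_scale_um`` is the exponential path-length mean at 250 keV; when
    None it is calibrated once so the spectrum-averaged deposit depth is
    ~25 μm for this slab thickness.
    """

    slab_thickness_um: float = 100.0
    gap_bottom_um: float = 5.0
    gap_top_um: float | None = None
    lateral_extent_um: float = 20000.0
    light_yield_per_kev: float = 20.0
    range_scale_um: float | None = None

    def __post_init__(self):
        if self.slab_thickness_um <= 0:
            raise InvalidGeometryError("slab thickness must be > 0")
        if self.gap_bottom_um < 0 or (self.gap_top_um is not None and self.gap_top_um < 0):
            raise InvalidGeometryError("gaps must be >= 0")
        if self.lateral_extent_um <= 0:
            raise InvalidGeometryError("lateral extent must be > 0")

    @property
    def is_dual(self) -> bool:
        return self.gap_top_um is not None

    def slab_bounds(self, slab_id: int) -> tuple[float, float]:
        """(z_low, z_high) of a slab; raises if the slab is absent."""
        if slab_id == BOTTOM:
            return (-self.gap_bottom_um - self.slab_thickness_um, -self.gap_bottom_um)
        if slab_id == TOP:
            if self.gap_top_um is None:
                raise InvalidGeometryError("no top slab in single configuration")
            return (self.gap_top_um, self.gap_top_um + self.slab_thickness_um)
        raise InvalidArgumentError(f"unknown slab id {slab_id}")

    def mirrored(self) -> "ScintillatorStack":
        """Swap top and bottom about the source plane (dual geometry only)."""
        if not self.is_dual:
            raise InvalidGeometryError("mirroring requires a dual stack")
        return replace(self, gap_bottom_um=self.gap_top_um, gap_top_um=self.gap_bottom_um)

    def effective_range_scale_um(self) -> float:
        if self.range_scale_um is not None:
            return self.range_scale_um
        return calibrated_range_scale(self.slab_thickness_um)


@dataclass(frozen=True)
class DecayEvent:
    """One disintegration: origin, emission direction, positron energy, time."""

    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    energy_kev: float
    time_s: float

    def __post_init__(self):
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            raise InvalidArgumentError("direction must be a unit vector")
        if not 0 < self.energy_kev <= E_MAX_KEV:
            raise InvalidArgumentError(f"energy must be in (0, {E_MAX_KEV}] keV")
        if self.time_s < 0:
            raise InvalidArgumentError("time must be >= 0")


@dataclass(frozen=True)
class EnergyDeposit:
    """A pointwise energy deposit inside one slab."""

    slab_id: int
    position: tuple[float, float, float]
    energy_kev: float


def sample_decay_times(source: SourceModel, duration_s: float, decay_clock: bool = False,
                       seed=None) -> np.ndarray:
    """Sample disintegration times in [0, duration).

    With ``decay_clock=False`` the process is homogeneous Poisson at the
    source activity; with ``decay_clock=True`` the rate decays exponentially
    with the source half-life (activity referenced to t = 0).
    """
    if duration_s <= 0:
        raise InvalidArgumentError("duration must be > 0")
    rng = as_rng(seed)
    lam = source.decay_constant_per_s
    if not decay_clock:
        n = rng.poisson(source.activity_bq * duration_s)
        times = rng.uniform(0.0, duration_s, size=n)
    else:
        expected = source.activity_bq / lam * (1.0 - np.exp(-lam * duration_s))
        n = rng.poisson(expected)
        u = rng.uniform(0.0, 1.0, size=n)
        # inverse CDF of the truncated exponential rate
        times = -np.log1p(-u * (1.0 - np.exp(-lam * duration_s))) / lam
    times.sort()
    return times


@lru_cache(maxsize=4)
def _beta_spectrum_grid(n_grid: int = 4000) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Energy grid, normalized density and CDF of the ¹⁸F β⁺ spectrum."""
    e = np.linspace(E_MAX_KEV / n_grid, E_MAX_KEV, n_grid)
    pdf = beta_spectrum_density(e)
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(e))])
    pdf /= cdf[-1]
    cdf /= cdf[-1]
    return e, pdf, cdf


def beta_spectrum_density(energy_kev: np.ndarray) -> np.ndarray:
    """Unnormalized allowed-transition β⁺ spectrum density for ¹⁸F.

    N(E) ∝ F(Z, W) · p · W · (Q − E)² with the nonrelativistic Coulomb
    (Fermi) factor for positrons, which suppresses the low-energy end.
    """
    e = np.asarray(energy_kev, dtype=float)
    w = 1.0 + e / MEC2_KEV                      # total energy, units of mec²
    p = np.sqrt(np.maximum(w * w - 1.0, 1e-300))
    eta = -ALPHA_FS * Z_DAUGHTER * w / p        # negative for β⁺
    fermi = 2 * np.pi * eta / -np.expm1(-2 * np.pi * eta)
    dens = fermi * p * w * (E_MAX_KEV - e) ** 2 / MEC2_KEV**2
    dens[(e <= 0) | (e > E_MAX_KEV)] = 0.0
    return dens


def beta_spectrum_mean_kev() -> float:
    """Mean positron energy of the implemented spectrum (numeric integral)."""
    e, pdf, _ = _beta_spectrum_grid()
    return float(np.trapezoid(e * pdf, e))


def sample_beta_spectrum(n: int, seed=None) -> np.ndarray:
    """Draw ``n`` positron kinetic energies (keV) by inverse-CDF lookup."""
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    rng = as_rng(seed)
    e, _, cdf = _beta_spectrum_grid()
    u = rng.uniform(0.0, 1.0, size=n)
    return np.interp(u, cdf, e)


def emit_direction(n: int, seed=None) -> np.ndarray:
    """``n`` isotropic unit vectors, shape (n, 3)."""
    if n < 0:
        raise InvalidArgumentError("n must be >= 0")
    rng = as_rng(seed)
    z = rng.uniform(-1.0, 1.0, size=n)
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def range_mean_um(energy_kev: np.ndarray, range_scale_um: float) -> np.ndarray:
    """Mean of the exponential in-slab path length at a given energy."""
    return range_scale_um * (np.asarray(energy_kev) / RANGE_E_REF_KEV) ** RANGE_POWER


@lru_cache(maxsize=8)
def calibrated_range_scale(thickness_um: float = 100.0,
                           target_depth_um: float = TARGET_MEAN_DEPTH_UM,
                           step_um: float = 5.0) -> float:
    """Solve for the range scale ℓ₀ giving the target mean deposit depth.

    Deterministic common-random-numbers Monte Carlo over the beta spectrum
    and the downward solid angle, root-bracketed with Brent's method.
    """
    rng = np.random.default_rng(20200707)
    n = 200_000
    e = sample_beta_spectrum(n, rng)
    mu = rng.uniform(0.0, 1.0, size=n)      # |cosθ| of downward directions
    eps = rng.exponential(1.0, size=n)      # unit-mean exponentials

    def pooled_mean_depth(l0: float) -> float:
        ell = range_mean_um(e, l0)
        chord = thickness_um / mu
        s = np.minimum(eps * ell, chord)
        ndep = np.ceil(s / step_um).clip(min=1)
        depth = mu * s / 2.0                # mean depth of a uniform chain
        return float(np.sum(ndep * depth) / np.sum(ndep))

    return float(brentq(lambda l0: pooled_mean_depth(l0) - target_depth_um, 0.5, 5000.0,
                        xtol=1e-6))


def _candidate_slab(dz: np.ndarray, stack: ScintillatorStack) -> np.ndarray:
    """Which slab (if any) each ray can hit: −1 none, else BOTTOM/TOP."""
    slab = np.full(dz.shape, -1, dtype=np.int64)
    slab[dz < 0] = BOTTOM
    if stack.is_dual:
        slab[dz > 0] = TOP
    return slab


def ray_slab_chord(origin: np.ndarray, direction: np.ndarray,
                   stack: ScintillatorStack) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic ray–slab intersection for rays starting between the slabs.

    Returns ``(slab_id, t_entry, t_exit)`` per ray, with ``slab_id = −1`` and
    zero parameters for rays that miss.  Parameters are path lengths (|d|=1).
    The chord is clipped laterally to the slab extent.
    """
    origin = np.atleast_2d(np.asarray(origin, dtype=float))
    direction = np.atleast_2d(np.asarray(direction, dtype=float))
    z0, dz = origin[:, 2], direction[:, 2]
    _check_between_slabs(z0, stack)
    slab = _candidate_slab(dz, stack)
    t1 = np.zeros(len(z0))
    t2 = np.zeros(len(z0))
    hit = slab >= 0
    for sid in (BOTTOM, TOP):
        sel = hit & (slab == sid)
        if not np.any(sel):
            continue
        lo, hi = stack.slab_bounds(sid)
        near, far = (hi, lo) if sid == BOTTOM else (lo, hi)
        t1[sel] = (near - z0[sel]) / dz[sel]
        t2[sel] = (far - z0[sel]) / dz[sel]
    # lateral clipping: stop the ray where it leaves the square extent
    half = stack.lateral_extent_um / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        for ax in (0, 1):
            d = direction[:, ax]
            x0 = origin[:, ax]
            t_lat = np.where(d > 0, (half - x0) / d,
                             np.where(d < 0, (-half - x0) / d, np.inf))
            t2 = np.minimum(t2, t_lat)
    miss = t2 <= t1
    slab[miss & hit] = -1
    t1[slab < 0] = 0.0
    t2[slab < 0] = 0.0
    return slab, t1, t2


def _check_between_slabs(z0: np.ndarray, stack: ScintillatorStack) -> None:
    z0 = np.atleast_1d(z0)
    if len(z0) == 0:
        return
    lo_b, hi_b = stack.slab_bounds(BOTTOM)
    if np.any((z0 >= lo_b) & (z0 <= hi_b)):
        raise InvalidGeometryError("origin lies inside the bottom slab")
    if stack.is_dual:
        lo_t, hi_t = stack.slab_bounds(TOP)
        if np.any((z0 >= lo_t) & (z0 <= hi_t)):
            raise InvalidGeometryError("origin lies inside the top slab")
        if np.any((z0 < hi_b) | (z0 > lo_t)):
            raise InvalidGeometryError("origin must lie between the slabs")


def transport_batch(origins: np.ndarray, directions: np.ndarray, energies: np.ndarray,
                    stack: ScintillatorStack, seed=None, step_um: float = 5.0):
    """Vectorized straight-ray transport of many positrons.

    Returns a dict of flat arrays over deposits: ``event_index``, ``slab_id``,
    ``x``, ``y``, ``z``, ``energy_kev``, plus per-event arrays ``hit_slab``
    (−1 for misses) and ``deposited_kev``.
    """
    rng = as_rng(seed)
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    n = len(energies)
    slab, t1, t2 = ray_slab_chord(origins, directions, stack)
    chord = t2 - t1
    ell = range_mean_um(energies, stack.effective_range_scale_um())
    path_len = rng.exponential(ell)                       # total range in slab material
    s = np.where(slab >= 0, np.minimum(path_len, chord), 0.0)
    frac = np.where(path_len > 0, np.minimum(1.0, s / np.maximum(path_len, 1e-300)), 0.0)
    e_dep = energies * frac                               # energy left in the slab
    ndep = np.where(s > 0, np.ceil(s / step_um).astype(np.int64).clip(min=1), 0)

    ev_idx = np.repeat(np.arange(n), ndep)
    within = np.concatenate([np.arange(k) for k in ndep]) if len(ev_idx) else np.array([], dtype=int)
    s_ev, n_ev = s[ev_idx], ndep[ev_idx]
    t_dep = t1[ev_idx] + s_ev * (within + 0.5) / n_ev
    pos = origins[ev_idx] + directions[ev_idx] * t_dep[:, None]
    return {
        "event_index": ev_idx,
        "slab_id": slab[ev_idx],
        "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2],
        "energy_kev": e_dep[ev_idx] / n_ev,
        "hit_slab": slab,
        "deposited_kev": e_dep,
        "n_events": n,
    }


def transport_positron(event: DecayEvent, stack: ScintillatorStack,
                       seed=None) -> list[EnergyDeposit]:
    """Transport a single positron; returns its chain of energy deposits."""
    out = transport_batch(np.array([event.origin]), np.array([event.direction]),
                          np.array([event.energy_kev]), stack, seed=seed)
    return [
        EnergyDeposit(int(s), (float(x), float(y), float(z)), float(e))
        for s, x, y, z, e in zip(out["slab_id"], out["x"], out["y"], out["z"],
                                 out["energy_kev"])
    ]


def infocus_depth(deposits: dict, stack: ScintillatorStack) -> np.ndarray:
    """Depth of each deposit below the slab surface facing the source plane."""
    z = deposits["z"]
    depth = np.empty_like(z)
    bot = deposits["slab_id"] == BOTTOM
    depth[bot] = -stack.gap_bottom_um - z[bot]
    if stack.is_dual:
        top = deposits["slab_id"] == TOP
        depth[top] = z[top] - stack.gap_top_um
    return depth


def detected_mask(deposits: dict, stack: ScintillatorStack,
                  focus_depth_um: float = 24.5,
                  threshold_kev: float = 10.0) -> np.ndarray:
    """Per-event, per-slab detection: shape (n_events, 2) booleans.

    An event is detectable in a slab when its energy deposited within the
    in-focus layer (the ``focus_depth_um`` of slab nearest the source-facing
    surface) exceeds ``threshold_kev``.
    """
    n = deposits["n_events"]
    e_focus = np.zeros((n, 2))
    depth = infocus_depth(deposits, stack)
    in_layer = depth <= focus_depth_um
    for sid in (BOTTOM, TOP):
        sel = (deposits["slab_id"] == sid) & in_layer
        np.add.at(e_focus[:, sid], deposits["event_index"][sel],
                  deposits["energy_kev"][sel])
    return e_focus > threshold_kev


@dataclass
class DecayBatchResult:
    deposits: dict
    detected: np.ndarray            # (n_events, 2) booleans
    tally_bottom: int
    tally_top: int
    energies: np.ndarray
    directions: np.ndarray
    origins: np.ndarray

    @property
    def tally_total(self) -> int:
        return self.tally_bottom + self.tally_top


def run_decay_batch(source: SourceModel, stack: ScintillatorStack, n_events: int,
                    seed=None, origin=(0.0, 0.0, 0.0), focus_depth_um: float = 24.5,
                    threshold_kev: float = 10.0) -> DecayBatchResult:
    """Simulate ``n_events`` decays of a point source and tally detections.

    Each straight ray intersects at most one slab, so the dual-configuration
    tally is the sum of per-slab tallies over the same emission sample; the
    single-configuration tally over that sample is the bottom tally alone.
    """
    if n_events <= 0:
        raise InvalidArgumentError("n_events must be > 0")
    r_dir, r_en, r_tr = split_rngs(seed, 3)
    directions = emit_direction(n_events, r_dir)
    energies = sample_beta_spectrum(n_events, r_en)
    origins = np.tile(np.asarray(origin, dtype=float), (n_events, 1))
    deposits = transport_batch(origins, directions, energies, stack, seed=r_tr)
    det = detected_mask(deposits, stack, focus_depth_um, threshold_kev)
    return DecayBatchResult(
        deposits=deposits, detected=det,
        tally_bottom=int(det[:, BOTTOM].sum()), tally_top=int(det[:, TOP].sum()),
        energies=energies, directions=directions, origins=origins,
    )


def deposits_to_table(deposits: dict, times_s: np.ndarray | None = None):
    """Flatten a transport result to a pandas DataFrame for CSV export."""
    import pandas as pd

    d = {
        "event_id": deposits["event_index"],
        "slab": np.array([SLAB_NAMES.get(int(s), "none") for s in deposits["slab_id"]]),
        "x": deposits["x"], "y": deposits["y"], "z": deposits["z"],
        "energy_keV": deposits["energy_kev"],
    }
    if times_s is not None:
        d["time_s"] = np.asarray(times_s)[deposits["event_index"]]
    return pd.DataFrame(d)
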