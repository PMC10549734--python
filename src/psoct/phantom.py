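"""Forward simulation of PS-OCT volumes of two-layer skin with known truth.

The phantom implements exactly the optical model the analysis pipeline
inverts: a non-birefringent epidermis over a birefringent dermis whose
fast axis is fixed with depth.  Light enters in a circular polarization
state; the dermis acts as a linear retarder whose cumulative round-trip
retardance grows linearly with physical depth below the dermal-epidermal
junction (DEJ):

    phi_rt(i) = 4*pi * dn_true * z_phys / lambda0,
    z_phys    = (i - dej) * dz / RI        for i >= dej, else 0.

Per voxel the emitted Jones vector is ``c(i) * a(i) * J(theta, phi_rt) * E_in``
with ``c`` unit-variance circular complex Gaussian speckle common to both
channels (so speckle cancels from normalized Stokes vectors), ``a`` an
exponential attenuation envelope, plus per-channel additive detector
noise.  With probability ``1 - dop`` a voxel's polarization state is
replaced by an independent uniform state on the Poincare sphere.

Realism knobs beyond the optical model: a bright stratum-corneum entry
band (so the surface carries the largest dark-to-bright edge, as in real
skin OCT), an epidermis/dermis backscatter contrast (giving the DEJ its
edge), hair artifacts (bright superficial streak + shadow) and horizontal
stripe artifacts, both recorded in the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import ComplexVolume, SystemConstants

__all__ = ["PhantomConfig", "SimulationTruth", "make_phantom_geometry",
           "simulate_ascan", "simulate_volume"]


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry, optics and noise settings.

    Depth quantities are in axial pixels (air-referenced), lateral ones in
    lateral pixels.  ``dn_true`` may be a scalar or an (nx, ny) array for
    laterally varying birefringence.  ``snr_db`` is the ratio of mean
    backscattered power at the surface to total detector-noise power;
    ``None`` disables detector noise.
    """

    shape: tuple[int, int, int] = (512, 600, 600)
    surface_depth: float = 50.0
    surface_amplitude: float = 3.0
    surface_corr: float = 50.0
    epidermis_thickness: float = 30.0
    epidermis_variation: float = 2.0
    epidermis_corr: float = 50.0
    dn_true: float | np.ndarray = 500e-6
    theta: float = np.pi / 6
    mu: float = 0.0092
    snr_db: float | None = 20.0
    dop: float = 0.95
    epi_reflectivity: float = 0.5
    surface_boost: float = 1.0
    speckle: bool = True
    hair_count: int = 0
    hair_brightness: float = 8.0
    hair_displacement: float = 15.0
    stripe_rows: tuple[int, ...] = ()
    stripe_frames: tuple[int, ...] | None = None
    stripe_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        nz, nx, ny = self.shape
        if min(nz, nx, ny) < 1:
            raise ValueError("grid shape must be positive")
        if not 0.0 <= self.dop <= 1.0:
            raise ValueError("dop must lie in [0, 1]")
        if np.any(np.asarray(self.dn_true) < 0):
            raise ValueError("dn_true must be non-negative")
        if self.epidermis_thickness <= 0:
            raise ValueError("epidermis thickness must be positive")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated volume."""

    surface_true: np.ndarray
    dej_true: np.ndarray
    dn_true: np.ndarray
    theta: float
    mu: float
    snr_db: float | None
    dop: float
    seed: int
    hair_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    stripe_rows: tuple[int, ...] = ()


def _smooth_field(shape, sd, corr, rng) -> np.ndarray:
    """Band-limited Gaussian random field with empirical SD ``sd``."""
    if sd <= 0:
        return np.zeros(shape)
    w = rng.standard_normal(shape)
    f = gaussian_filter(w, sigma=corr / 2.0, mode="wrap")
    f -= f.mean()
    s = f.std()
    return f * (sd / s) if s > 0 else np.zeros(shape)


def make_phantom_geometry(config: PhantomConfig, rng: np.random.Generator | None = None) -> SimulationTruth:
    """Draw smooth random surface/DEJ topography, reproducible from the seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    nz, nx, ny = config.shape
    surface = config.surface_depth + _smooth_field((nx, ny), config.surface_amplitude, config.surface_corr, rng)
    thickness = config.epidermis_thickness + _smooth_field(
        (nx, ny), config.epidermis_variation, config.epidermis_corr, rng)
    thickness = np.maximum(thickness, 1.0)
    dej = surface + thickness
    if surface.min() < 2.0 or dej.max() > nz - 2.0:
        raise ValueError(
            f"phantom geometry exceeds grid: surface in [{surface.min():.1f}, "
            f"{surface.max():.1f}], dej max {dej.max():.1f}, nz {nz}")
    dn = np.broadcast_to(np.asarray(config.dn_true, dtype=float), (nx, ny)).copy()
    return SimulationTruth(
        surface_true=surface, dej_true=dej, dn_true=dn, theta=config.theta,
        mu=config.mu, snr_db=config.snr_db, dop=config.dop, seed=config.seed,
        hair_mask=np.zeros((nx, ny), dtype=bool), stripe_rows=config.stripe_rows)


def _band_coverage(i, lo, hi):
    """Fraction of pixel i (spanning [i-0.5, i+0.5]) inside the band [lo, hi)."""
    return np.clip(np.minimum(i + 0.5, hi) - np.maximum(i - 0.5, lo), 0.0, 1.0)


def _simulate_block(surface, dej, dn, config: PhantomConfig,
                    constants: SystemConstants, rng: np.random.Generator,
                    hair_mask=None):
    """Simulate AH/AV for a block of columns; arrays are (nz, nx, ny)."""
    nz = config.shape[0]
    surface = np.atleast_2d(surface)
    dej = np.atleast_2d(dej)
    dn = np.broadcast_to(np.asarray(dn, dtype=float), surface.shape)
    i = np.arange(nz, dtype=float)[:, None, None]

    # cumulative round-trip retardance below the DEJ (rad)
    m = dn * constants.slope_per_dn
    phi = m[None] * np.clip(i - dej[None], 0.0, None)

    # amplitude envelope: surface coverage x reflectivity x entry boost x attenuation
    f_surf = np.clip(i - surface[None] + 0.5, 0.0, 1.0)
    refl = config.epi_reflectivity + (1.0 - config.epi_reflectivity) * np.clip(
        i - dej[None] + 0.5, 0.0, 1.0)
    boost = 1.0 + (config.surface_boost - 1.0) * _band_coverage(
        i, surface[None], surface[None] + 2.0)
    atten = np.exp(-config.mu * np.clip(i - surface[None], 0.0, None))
    amp = np.sqrt(f_surf * refl * boost) * atten

    if hair_mask is not None and hair_mask.any():
        hs = surface[None] - config.hair_displacement
        shadow = np.where(i >= hs + 2.0, np.sqrt(0.2), 1.0)
        streak = np.sqrt(config.hair_brightness) * _band_coverage(i, hs, hs + 2.0)
        amp = np.where(hair_mask[None], amp * shadow + streak, amp)

    # Jones vector of a linear retarder (fast axis theta) on circular input
    c, s = np.cos(config.theta), np.sin(config.theta)
    d1 = np.exp(-0.5j * phi)
    d2 = np.exp(+0.5j * phi)
    J11 = c * c * d1 + s * s * d2
    J12 = c * s * (d1 - d2)
    J22 = s * s * d1 + c * c * d2
    inv_sqrt2 = 1.0 / np.sqrt(2.0)
    EH = (J11 + 1j * J12) * inv_sqrt2
    EV = (J12 + 1j * J22) * inv_sqrt2

    # degree-of-polarization mechanism: replace some voxel states by
    # uniformly random pure states on the Poincare sphere
    if config.dop < 1.0:
        repl = rng.random(phi.shape) < (1.0 - config.dop)
        g = rng.standard_normal((2,) + phi.shape) + 1j * rng.standard_normal((2,) + phi.shape)
        norm = np.sqrt(np.abs(g[0]) ** 2 + np.abs(g[1]) ** 2)
        norm = np.where(norm == 0, 1.0, norm)
        EH = np.where(repl, g[0] / norm, EH)
        EV = np.where(repl, g[1] / norm, EV)

    # multiplicative complex speckle common to both channels
    if config.speckle:
        spk = (rng.standard_normal(phi.shape)
               + 1j * rng.standard_normal(phi.shape)) * inv_sqrt2
    else:
        spk = np.ones(phi.shape)
    AH = amp * spk * EH
    AV = amp * spk * EV

    if config.snr_db is not None and np.isfinite(config.snr_db):
        sigma = np.sqrt(10.0 ** (-config.snr_db / 10.0) / 2.0)  # per channel, total = 10^(-snr/10)
        for A in (AH, AV):
            A += sigma * inv_sqrt2 * (
                rng.standard_normal(phi.shape) + 1j * rng.standard_normal(phi.shape))
    return AH, AV


def simulate_ascan(surface: float, dej: float, dn: float, config: PhantomConfig,
                   constants: SystemConstants, rng: np.random.Generator):
    """Simulate one A-scan column; returns ``(AH, AV)`` of length nz."""
    AH, AV = _simulate_block(np.array([[surface]]), np.array([[dej]]),
                             np.array([[dn]]), config, constants, rng)
    return AH[:, 0, 0], AV[:, 0, 0]


def _place_hairs(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Choose ``hair_count`` disjoint 3x3 column groups."""
    _, nx, ny = config.shape
    mask = np.zeros((nx, ny), dtype=bool)
    placed = 0
    guard = 0
    while placed < config.hair_count:
        guard += 1
        if guard > 1000:
            raise RuntimeError("could not place disjoint hair artifacts")
        x0 = int(rng.integers(0, max(nx - 3, 1)))
        y0 = int(rng.integers(0, max(ny - 3, 1)))
        # keep one clear column around each hair so groups stay disjoint
        lo_x, hi_x = max(x0 - 1, 0), min(x0 + 4, nx)
        lo_y, hi_y = max(y0 - 1, 0), min(y0 + 4, ny)
        if mask[lo_x:hi_x, lo_y:hi_y].any():
            continue
        mask[x0:x0 + 3, y0:y0 + 3] = True
        placed += 1
    return mask


def simulate_volume(config: PhantomConfig,
                    constants: SystemConstants | None = None):
    """Simulate a full PS-OCT volume; returns ``(ComplexVolume, SimulationTruth)``.

    All stochastic draws derive from a single generator seeded with
    ``config.seed``, so identical configs give identical volumes.
    """
    if constants is None:
        constants = SystemConstants()
    rng = np.random.default_rng(config.seed)
    truth = make_phantom_geometry(config, rng=rng)
    if config.hair_count > 0:
        truth.hair_mask = _place_hairs(config, rng)
    AH, AV = _simulate_block(truth.surface_true, truth.dej_true, truth.dn_true,
                             config, constants, rng, hair_mask=truth.hair_mask)
    if config.stripe_rows:
        frames = (config.stripe_frames if config.stripe_frames is not None
                  else tuple(range(config.shape[2])))
        med = np.median(np.abs(AH))
        for r in config.stripe_rows:
            for f in frames:
                AH[r, :, f] += config.stripe_amplitude * med
    vol = ComplexVolume(AH=AH.astype(np.complex64), AV=AV.astype(np.complex64),
                        constants=constants,
                        meta={"phantom_seed": config.seed})
    return vol, truth
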