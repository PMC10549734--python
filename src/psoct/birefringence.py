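"""Stokes-vector phase retardance and effective dermal birefringence.

Per voxel the Stokes vector is formed from the two detection channels,

    I = |AV|^2 + |AH|^2,   Q = |AV|^2 - |AH|^2,
    U = 2 |AV||AH| cos(dtheta),  V = 2 |AV||AH| sin(dtheta),
    dtheta = arg(AV) - arg(AH),

normalized by I to a point on the Poincare sphere.  Tissue birefringence
rotates the state about an axis set by the collagen fast axis, so the dot
product with the surface reference state traces

    S_ref . S(z_i) = A(z_i) cos(phi_r(z_i)),

an amplitude-modulated cosine whose phase phi_r accrues with depth.  The
phase is evaluated from the analytic signal of this profile, unwrapped,
and regressed against depth over ~200 um (50 axial pixels) beneath the
local DEJ; the slope m converts to effective birefringence via

    dn = m * lambda0 * RI / (4 * pi * dz).

Fits above 600e-6 are almost certainly artifacts of noise-induced
erroneous unwrapping and are re-evaluated on the wrapped phase profile.

The analytic signal is constructed geometrically by default: the rotation
axis is estimated from lagged cross products of the Stokes trajectory and
the quadrature is the projection onto (axis x S_ref), which is exact for
the fixed-axis retarder model at any phase span.  An FFT-based Hilbert
construction (zeroed negative frequencies) is available as
``quadrature="hilbert"``; it requires several oscillation cycles within
the profile to be unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import hilbert

from .io import (BirefringenceMap, BoundarySet, ComplexVolume, ScanSummary,
                 SystemConstants)

__all__ = ["StokesField", "RetardanceProfile", "BirefringenceConfig",
           "compute_stokes", "reference_stokes", "retardance_profile",
           "unwrap_phase", "fit_birefringence", "mitigate_unwrap_noise",
           "birefringence_map", "frame_averaged_profile", "aggregate_scan"]

TWO_PI = 2.0 * np.pi


@dataclass
class StokesField:
    """Intensity and normalized Stokes components on the (z,x,y) grid."""

    I: np.ndarray
    Qn: np.ndarray
    Un: np.ndarray
    Vn: np.ndarray
    valid: np.ndarray

    def column(self, x: int, y: int) -> np.ndarray:
        """Normalized Stokes trajectory of one A-scan, shape (nz, 3)."""
        return np.stack([self.Qn[:, x, y], self.Un[:, x, y], self.Vn[:, x, y]], axis=1)


@dataclass
class RetardanceProfile:
    """Surface-referenced phase-retardance profile of one A-scan."""

    zi: np.ndarray              # absolute depth indices, axial pixels
    dot: np.ndarray             # S_ref . S(zi), in [-1, 1]
    envelope: np.ndarray        # A(zi) >= 0
    phi_wrapped: np.ndarray     # rad, in (-pi, pi]
    phi_unwrapped: np.ndarray   # rad
    valid: bool = True


@dataclass(frozen=True)
class BirefringenceConfig:
    """Tunable parameters of the retardance analysis.

    ``smooth`` applies a boxcar of ``smooth_size`` (z, x, y) to
    (I, Q, U, V) before normalization; linear filtering of the raw Stokes
    components preserves a linear retardance slope exactly while diluting
    speckle and isolated depolarized voxels.  Set False to skip any
    filtering (the paper-literal mode).  ``fit_window`` is the regression
    depth range beneath the DEJ in axial pixels (~200 um).
    ``mitigation_threshold`` triggers the wrapped-phase refit for strictly
    larger fitted dn.
    """

    smooth: bool = True
    smooth_size: tuple[int, int, int] = (3, 3, 3)
    ref_window: int = 3
    fit_window: int = 50
    min_fit_samples: int = 10
    min_profile_samples: int = 8
    mitigation_threshold: float = 600e-6
    quadrature: str = "geometric"      # or "hilbert"
    clamp_negative: bool = False
    snr_floor_percentile: float = 99.0


def compute_stokes(vol: ComplexVolume, smooth: bool = True,
                   noise_floor: float = 0.0,
                   smooth_size: tuple[int, int, int] = (3, 3, 3)) -> StokesField:
    """Stokes vectors from the dual-channel complex volume.

    Voxels with (smoothed) intensity at or below ``noise_floor`` are
    marked invalid rather than failing.
    """
    AH = np.asarray(vol.AH, dtype=np.complex128)
    AV = np.asarray(vol.AV, dtype=np.complex128)
    aH, aV = np.abs(AH), np.abs(AV)
    cross = AV * np.conj(AH)
    I = aH ** 2 + aV ** 2
    Q = aV ** 2 - aH ** 2
    U = 2.0 * np.real(cross)
    V = 2.0 * np.imag(cross)
    if smooth:
        I, Q, U, V = (uniform_filter(a, size=smooth_size, mode="nearest")
                      for a in (I, Q, U, V))
    valid = I > max(noise_floor, 0.0)
    denom = np.where(I > 0, I, 1.0)
    return StokesField(I=I, Qn=Q / denom, Un=U / denom, Vn=V / denom, valid=valid)


def reference_stokes(sf: StokesField, surface: np.ndarray, w: int = 3):
    """Surface reference state per column: normalized mean of S over the
    ``w`` voxels starting at the surface.  Returns ``(s_ref, ok)`` with
    ``s_ref`` of shape (nx, ny, 3)."""
    nz, nx, ny = sf.I.shape
    s_ref = np.full((nx, ny, 3), np.nan)
    ok = np.zeros((nx, ny), dtype=bool)
    for x in range(nx):
        for y in range(ny):
            s = surface[x, y]
            if not np.isfinite(s):
                continue
            i0 = int(np.ceil(s - 0.5))
            i0 = max(i0, 0)
            i1 = min(i0 + w, nz)
            if i1 <= i0:
                continue
            vox = np.stack([sf.Qn[i0:i1, x, y], sf.Un[i0:i1, x, y], sf.Vn[i0:i1, x, y]], axis=1)
            vmask = sf.valid[i0:i1, x, y]
            if not vmask.any():
                continue
            v = vox[vmask].mean(axis=0)
            n = np.linalg.norm(v)
            if n == 0:
                continue
            s_ref[x, y] = v / n
            ok[x, y] = True
    return s_ref, ok


def unwrap_phase(phi_wrapped: np.ndarray) -> np.ndarray:
    """1-D phase unwrapping by the minimal-jump rule.

    Wherever the jump between neighboring samples exceeds +-pi, multiples
    of 2*pi are added until it lies in (-pi, pi].  The first sample is
    unchanged and output - input is a multiple of 2*pi at every sample.
    """
    phi = np.asarray(phi_wrapped, dtype=np.float64)
    if phi.ndim != 1:
        raise ValueError("expected a 1-D phase sequence")
    if not np.isfinite(phi).all():
        raise ValueError("phase sequence must be finite")
    if phi.size < 2:
        return phi.copy()
    d = np.diff(phi)
    k = np.ceil((d - np.pi) / TWO_PI)   # d - 2*pi*k in (-pi, pi]
    out = phi.copy()
    out[1:] -= TWO_PI * np.cumsum(k)
    return out


def _geometric_quadrature(S: np.ndarray, s_ref: np.ndarray):
    """In-phase/quadrature pair from the Poincare-sphere trajectory.

    The rotation axis is the normalized sum of cross products of states a
    quarter-profile apart (long lags suppress noise; arcs stay below pi
    for physiological retardance over these windows).  The axis sign is
    chosen so the net phase change over the profile is non-negative.
    """
    n = S.shape[0]
    lag = max(1, n // 4)
    cr = np.cross(S[:-lag], S[lag:]).sum(axis=0)
    nrm = np.linalg.norm(cr)
    if nrm == 0:
        return S @ s_ref, np.zeros(n)
    axis = cr / nrm
    dot = S @ s_ref
    quad = S @ np.cross(axis, s_ref)
    ph = np.arctan2(quad, dot)
    if unwrap_phase(ph)[-1] < unwrap_phase(ph)[0]:
        quad = -quad
    return dot, quad


def retardance_profile(S: np.ndarray, s_ref: np.ndarray, surface: float,
                       zi: np.ndarray | None = None,
                       quadrature: str = "geometric",
                       min_samples: int = 8) -> RetardanceProfile:
    """Surface-referenced retardance profile of one A-scan.

    Parameters
    ----------
    S : (n, 3) array
        Normalized Stokes trajectory from the surface downward.
    s_ref : (3,) array
        Surface reference state.
    surface : float
        Sub-pixel surface depth; profile depth indices start at
        ``ceil(surface)`` unless ``zi`` is given explicitly.
    quadrature : {"geometric", "hilbert"}
        Analytic-signal construction (see module docstring).
    """
    S = np.asarray(S, dtype=np.float64)
    n = S.shape[0]
    if zi is None:
        zi = np.arange(int(np.ceil(surface)), int(np.ceil(surface)) + n)
    if n < min_samples:
        empty = np.zeros(n)
        return RetardanceProfile(zi=zi, dot=S @ s_ref if n else empty,
                                 envelope=empty, phi_wrapped=empty,
                                 phi_unwrapped=empty, valid=False)
    if quadrature == "geometric":
        dot, quad = _geometric_quadrature(S, s_ref)
        analytic = dot + 1j * quad
    elif quadrature == "hilbert":
        dot = S @ s_ref
        x = dot - dot.mean()
        analytic = hilbert(x)
        quad = np.imag(analytic)
    else:
        raise ValueError(f"unknown quadrature {quadrature!r}")
    phi_wrapped = np.arctan2(np.imag(analytic), np.real(analytic))
    # map the boundary value -pi to +pi so phases live in (-pi, pi]
    phi_wrapped = np.where(phi_wrapped == -np.pi, np.pi, phi_wrapped)
    return RetardanceProfile(
        zi=zi, dot=np.clip(S @ s_ref, -1.0, 1.0), envelope=np.abs(analytic),
        phi_wrapped=phi_wrapped, phi_unwrapped=unwrap_phase(phi_wrapped),
        valid=True)


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares slope, intercept and R^2."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    dy = y - ym
    sxx = (dx * dx).sum()
    if sxx == 0:
        return 0.0, ym, 0.0
    slope = (dx * dy).sum() / sxx
    intercept = ym - slope * xm
    ss_tot = (dy * dy).sum()
    if ss_tot == 0:
        return slope, intercept, 1.0
    resid = y - (slope * x + intercept)
    r2 = 1.0 - (resid * resid).sum() / ss_tot
    return float(slope), float(intercept), float(r2)


def fit_birefringence(profile: RetardanceProfile, dej: float,
                      constants: SystemConstants, window: int = 50,
                      min_samples: int = 10, *, use_wrapped: bool = False):
    """Regress phase against depth beneath the DEJ and convert to dn.

    The fit covers ``window`` axial pixels starting at ``ceil(dej)``;
    windows truncated below ``min_samples`` usable samples are flagged.
    Returns ``(dn, slope, r2, ok)``.
    """
    z0 = int(np.ceil(dej))
    sel = (profile.zi >= z0) & (profile.zi < z0 + window)
    phase = profile.phi_wrapped if use_wrapped else profile.phi_unwrapped
    x = profile.zi[sel].astype(float)
    y = phase[sel]
    if x.size < min_samples or not profile.valid:
        return np.nan, np.nan, np.nan, False
    slope, _, r2 = _ols_line(x, y)
    dn = float(constants.dn_from_slope(slope))
    return dn, slope, r2, True


def mitigate_unwrap_noise(dn: float, profile: RetardanceProfile, dej: float,
                          constants: SystemConstants, window: int = 50,
                          min_samples: int = 10,
                          threshold: float = 600e-6):
    """Re-evaluate implausibly high fits on the wrapped phase profile.

    Fitted values strictly greater than the threshold (600e-6) are almost
    certainly noise-induced erroneous unwrapping; they are replaced by a
    refit of the same window on the wrapped phase, flagged
    ``used_wrapped``.  Values at or below the threshold pass unchanged.
    """
    if not (np.isfinite(dn) and dn > threshold):
        return dn, False
    dn_w, _, _, ok = fit_birefringence(profile, dej, constants, window,
                                       min_samples, use_wrapped=True)
    if not ok:
        return dn, False
    return dn_w, True


def _column_dn(S, s_ref, surface, dej, constants, cfg: BirefringenceConfig):
    prof = retardance_profile(S, s_ref, surface, quadrature=cfg.quadrature,
                              min_samples=cfg.min_profile_samples)
    dn, slope, r2, ok = fit_birefringence(prof, dej, constants,
                                          cfg.fit_window, cfg.min_fit_samples)
    if not ok:
        return np.nan, np.nan, np.nan, False, False
    dn, used_wrapped = mitigate_unwrap_noise(dn, prof, dej, constants,
                                             cfg.fit_window, cfg.min_fit_samples,
                                             cfg.mitigation_threshold)
    if used_wrapped:
        slope = dn / float(constants.dn_from_slope(1.0))
    if cfg.clamp_negative and dn < 0:
        dn, slope = 0.0, 0.0
    return dn, slope, r2, used_wrapped, True


def _air_noise_floor(I: np.ndarray, surface: np.ndarray, pct: float) -> float:
    """SNR floor: percentile of above-surface (air) intensity.

    Capped at half the median below-surface intensity so a noise-dominated
    volume (air as bright as tissue) still flows through the pipeline and
    surfaces its noise through the mitigation statistics instead of an
    empty map.
    """
    nz = I.shape[0]
    zi = np.arange(nz)[:, None, None]
    air = zi < np.floor(surface)[None] - 1
    if not air.any():
        return 0.0
    floor = float(np.percentile(I[air], pct))
    tissue = ~air
    if tissue.any():
        floor = min(floor, 0.5 * float(np.median(I[tissue])))
    return floor


def birefringence_map(vol: ComplexVolume, boundaries: BoundarySet,
                      constants: SystemConstants | None = None,
                      config: BirefringenceConfig | None = None) -> BirefringenceMap:
    """Per-A-scan effective birefringence over all valid columns."""
    cfg = config or BirefringenceConfig()
    constants = constants or vol.constants
    nz, nx, ny = vol.shape
    floor = 0.0
    sf = compute_stokes(vol, smooth=cfg.smooth, smooth_size=cfg.smooth_size)
    if np.isfinite(boundaries.surface).any():
        floor = _air_noise_floor(sf.I, np.where(np.isfinite(boundaries.surface),
                                                boundaries.surface, nz), cfg.snr_floor_percentile)
        sf.valid = sf.I > floor
    s_ref, ref_ok = reference_stokes(sf, boundaries.surface, cfg.ref_window)

    dn = np.full((nx, ny), np.nan)
    slope = np.full((nx, ny), np.nan)
    r2 = np.full((nx, ny), np.nan)
    used_wrapped = np.zeros((nx, ny), dtype=bool)
    valid = np.zeros((nx, ny), dtype=bool)
    for x in range(nx):
        for y in range(ny):
            if not (boundaries.valid_mask[x, y] and ref_ok[x, y]):
                continue
            s = boundaries.surface[x, y]
            i0 = max(int(np.ceil(s)), 0)
            S = np.stack([sf.Qn[i0:, x, y], sf.Un[i0:, x, y], sf.Vn[i0:, x, y]], axis=1)
            d, m, r, w, ok = _column_dn(S, s_ref[x, y], s,
                                        boundaries.dej[x, y], constants, cfg)
            dn[x, y], slope[x, y], r2[x, y] = d, m, r
            used_wrapped[x, y] = w
            valid[x, y] = ok
    return BirefringenceMap(dn=dn, slope=slope, r2=r2,
                            used_wrapped=used_wrapped, valid_mask=valid)


def frame_averaged_profile(sf: StokesField, boundaries: BoundarySet, x: int,
                           constants: SystemConstants | None = None,
                           config: BirefringenceConfig | None = None):
    """Average unwrapped retardance across frames at one lateral x position.

    Per-frame unwrapped profiles are aligned to each frame's DEJ, averaged
    across frames, and fitted once over the standard window.  Returns
    ``(rel_depth, mean_phase, dn, slope, n_frames)``; flags (None result)
    when no frame at ``x`` is valid.
    """
    cfg = config or BirefringenceConfig()
    constants = constants or SystemConstants()
    nz, nx, ny = sf.I.shape
    s_ref, ref_ok = reference_stokes(sf, boundaries.surface, cfg.ref_window)
    aligned = []
    for y in range(ny):
        if not (boundaries.valid_mask[x, y] and ref_ok[x, y]):
            continue
        s = boundaries.surface[x, y]
        i0 = max(int(np.ceil(s)), 0)
        S = np.stack([sf.Qn[i0:, x, y], sf.Un[i0:, x, y], sf.Vn[i0:, x, y]], axis=1)
        prof = retardance_profile(S, s_ref[x, y], s, quadrature=cfg.quadrature,
                                  min_samples=cfg.min_profile_samples)
        if not prof.valid:
            continue
        z0 = int(np.ceil(boundaries.dej[x, y]))
        rel = prof.zi - z0
        sel = (rel >= 0) & (rel < cfg.fit_window)
        if sel.sum() < cfg.min_fit_samples:
            continue
        ph = np.full(cfg.fit_window, np.nan)
        ph[rel[sel]] = prof.phi_unwrapped[sel] - prof.phi_unwrapped[sel][0]
        aligned.append(ph)
    if not aligned:
        return None
    A = np.array(aligned)
    mean_phase = np.nanmean(A, axis=0)
    rel_depth = np.arange(cfg.fit_window)
    good = np.isfinite(mean_phase)
    slope, _, _ = _ols_line(rel_depth[good].astype(float), mean_phase[good])
    dn = float(constants.dn_from_slope(slope))
    return rel_depth, mean_phase, dn, slope, len(aligned)


def aggregate_scan(m: BirefringenceMap, subject: str = "", arm: str = "",
                   day: int = 0, repeat: int = 0) -> ScanSummary:
    """Scan-level mean/median/SD of dn over valid pixels."""
    vals = m.dn[m.valid_mask & np.isfinite(m.dn)]
    n = int(vals.size)
    if n == 0:
        return ScanSummary(subject=subject, arm=arm, day=day, repeat=repeat,
                           mean_dn=np.nan, median_dn=np.nan, sd_dn=np.nan,
                           n_valid=0, fraction_mitigated=np.nan, valid=False)
    frac = float(m.used_wrapped[m.valid_mask].mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ScanSummary(subject=subject, arm=arm, day=day, repeat=repeat,
                       mean_dn=float(vals.mean()), median_dn=float(np.median(vals)),
                       sd_dn=sd, n_valid=n, fraction_mitigated=frac, valid=True)
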