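"""Skin-surface and dermal-epidermal-junction (DEJ) segmentation.

Surfaces are detected per A-scan as the dark-to-bright intensity edge of
largest positive strength, localized to sub-pixel precision with a
partial-area model: the edge position inside the transition pixel is the
one whose ideal-step pixel areas reproduce the observed values.  The raw
depth map is then compared to a 40x40 median-filtered version of itself;
positions deviating by more than 10 axial pixels (hairs, ghost-surface
copies) are interpolated across from their neighbors, and finally every
lateral position is locked back onto the nearest detected sub-pixel edge.

The DEJ is found the same way after flattening the volume to the surface
and median filtering each en-face plane, which removes laterally narrow
dark structures (e.g. lymphatics) whose lower edge would otherwise mimic
the epidermis-to-dermis transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.ndimage import gaussian_filter1d, median_filter, uniform_filter

from .io import BoundarySet, IntensityVolume

__all__ = ["EdgeCandidate", "SegmentationConfig", "detect_subpixel_edges",
           "detect_surface", "flatten_volume", "unflatten_map", "detect_dej",
           "apply_manual_overrides"]


@dataclass(frozen=True)
class EdgeCandidate:
    """A dark-to-bright edge candidate on one A-scan."""

    depth: float            # sub-pixel axial position, pixels
    strength: float         # positive intensity step (bright minus dark)


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable segmentation parameters.

    ``median_kernel`` and ``outlier_px`` implement the 40x40 / 10-pixel
    artifact-rejection rule; ``ef_kernel`` is the en-face median kernel
    applied before DEJ detection; the DEJ is searched ``dej_min..dej_max``
    axial pixels below the local surface.
    """

    smooth_sigma: float = 1.0
    lateral_box: int = 3
    threshold_k: float = 4.0
    median_kernel: int = 40
    outlier_px: float = 10.0
    ef_kernel: int = 21
    dej_min: int = 10
    dej_max: int = 60
    relock_radius: float = 10.0


def detect_subpixel_edges(profile: np.ndarray, sigma: float = 1.0,
                          threshold_k: float = 4.0) -> list[EdgeCandidate]:
    """Locate dark-to-bright edges along one intensity profile.

    Candidates are local maxima of the Gaussian-smoothed derivative above
    a noise-adaptive threshold.  Each is refined by area balance: with
    dark/bright plateau levels L and H estimated beside the transition,
    the sub-pixel position is ``j_hi + 0.5 - sum((p - L)/(H - L))`` over
    the transition window, which is exact for an ideal step sampled by
    pixel areas and invariant to symmetric smoothing.
    """
    p = np.asarray(profile, dtype=np.float64)
    n = p.shape[0]
    if n < 5:
        raise ValueError("profile must have at least 5 samples")
    rng_p = np.nanmax(p) - np.nanmin(p)
    if rng_p == 0 or not np.isfinite(rng_p):
        return []
    ps = gaussian_filter1d(p, sigma, mode="nearest")
    d = np.gradient(ps)
    mad = np.median(np.abs(d - np.median(d)))
    thr = max(threshold_k * 1.4826 * mad, 0.02 * rng_p, 1e-12)

    # local maxima of the derivative above threshold
    idx = np.nonzero((d[1:-1] > thr) & (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:]))[0] + 1
    out: list[EdgeCandidate] = []
    half = 4
    for j in idx:
        lo, hi = max(j - half, 0), min(j + half, n - 1)
        L = float(np.median(ps[max(j - 2 * half, 0): max(j - half, 1)])) if j - half > 0 else float(ps[0])
        H = float(np.median(ps[min(j + half, n - 1): min(j + 2 * half, n)])) if j + half < n - 1 else float(ps[-1])
        if H <= L:
            continue
        frac = np.clip((ps[lo: hi + 1] - L) / (H - L), 0.0, 1.0)
        depth = hi + 0.5 - float(frac.sum())
        depth = float(np.clip(depth, 0.0, n - 1.0))
        out.append(EdgeCandidate(depth=depth, strength=H - L))
    return out


def _interpolate_invalid(depth: np.ndarray, good: np.ndarray) -> np.ndarray:
    """2-D linear interpolation of bad pixels from good ones (nearest fallback)."""
    out = depth.copy()
    bad = ~good
    if not bad.any():
        return out
    if not good.any():
        return out
    pts = np.argwhere(good)
    vals = depth[good]
    query = np.argwhere(bad)
    if pts.shape[0] >= 4:
        lin = LinearNDInterpolator(pts, vals)
        filled = lin(query)
    else:
        filled = np.full(query.shape[0], np.nan)
    nan = ~np.isfinite(filled)
    if nan.any():
        nearest = NearestNDInterpolator(pts, vals)
        filled[nan] = nearest(query[nan])
    out[bad] = filled
    return out


def _nearest_candidate(cands: list[EdgeCandidate], target: float,
                       radius: float) -> float | None:
    """Depth of the candidate nearest ``target`` within ``radius``.

    Equidistant ties break toward the shallower edge.
    """
    best = None
    best_key = None
    for c in cands:
        dist = abs(c.depth - target)
        if dist > radius:
            continue
        key = (dist, c.depth)
        if best_key is None or key < best_key:
            best_key = key
            best = c.depth
    return best


def _outlier_reject_and_relock(raw: np.ndarray, has_cand: np.ndarray,
                               cands: dict, cfg: SegmentationConfig):
    """Apply the median-filter outlier rule, interpolate, re-lock to edges."""
    filled = _interpolate_invalid(raw, has_cand)
    med = median_filter(filled, size=cfg.median_kernel, mode="reflect")
    outlier = np.abs(filled - med) > cfg.outlier_px
    good = has_cand & ~outlier
    interp = _interpolate_invalid(filled, good)
    # lock back onto the nearest detected sub-pixel edge where one is close
    out = interp.copy()
    nx, ny = raw.shape
    for x in range(nx):
        for y in range(ny):
            cand = _nearest_candidate(cands.get((x, y), []), interp[x, y],
                                      cfg.relock_radius)
            if cand is not None:
                out[x, y] = cand
    valid = np.isfinite(out)
    return out, valid, outlier


def detect_surface(ivol: IntensityVolume, config: SegmentationConfig | None = None):
    """Detect the skin surface.

    Returns ``(surface_map, valid_mask, candidates, outliers)``:
    ``candidates`` maps (x, y) to the column's edge-candidate list so
    manual overrides can re-lock without re-detection; ``outliers`` flags
    columns rejected by the median-filter/10-px rule (hairs, ghosts) and
    interpolated across.
    """
    cfg = config or SegmentationConfig()
    nz, nx, ny = ivol.shape
    # lateral boxcar for speckle reduction before per-column edge detection
    I = uniform_filter(ivol.I, size=(1, cfg.lateral_box, cfg.lateral_box),
                       mode="nearest") if cfg.lateral_box > 1 else ivol.I
    raw = np.full((nx, ny), np.nan)
    cands: dict[tuple[int, int], list[EdgeCandidate]] = {}
    for x in range(nx):
        for y in range(ny):
            cc = detect_subpixel_edges(I[:, x, y], cfg.smooth_sigma, cfg.threshold_k)
            cands[(x, y)] = cc
            if cc:
                raw[x, y] = max(cc, key=lambda c: c.strength).depth
    has_cand = np.isfinite(raw)
    surface, valid, outliers = _outlier_reject_and_relock(raw, has_cand, cands, cfg)
    return surface, valid, cands, outliers


def flatten_volume(data: np.ndarray, surface: np.ndarray):
    """Shift each column up by ``round(surface)`` so the surface sits at row 0.

    Returns ``(flattened, shifts, remainders)``; voxels shifted in from
    below the volume are NaN sentinels excluded from later statistics.
    ``surface - shifts`` (the remainders) preserve sub-pixel information.
    """
    nz = data.shape[0]
    shifts = np.round(np.nan_to_num(surface, nan=0.0)).astype(int)
    shifts = np.clip(shifts, 0, nz - 1)
    flat = np.full_like(np.asarray(data, dtype=np.float64), np.nan)
    nx, ny = surface.shape
    for x in range(nx):
        for y in range(ny):
            s = shifts[x, y]
            flat[: nz - s, x, y] = data[s:, x, y]
    return flat, shifts, surface - shifts


def unflatten_map(depth_map: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    """Convert a depth map in flattened coordinates back to volume coordinates."""
    return depth_map + shifts


def detect_dej(ivol: IntensityVolume, surface: np.ndarray,
               config: SegmentationConfig | None = None):
    """Detect the DEJ below a detected surface; returns ``(dej_map, valid_mask, outliers)``.

    The intensity volume is flattened to the surface, median filtered in
    the en-face plane, and the strongest dark-to-bright edge is selected
    within ``[dej_min, dej_max]`` pixels below the surface, followed by
    the same outlier rejection and re-locking as the surface stage.
    The returned map is in unflattened (volume) coordinates.
    """
    cfg = config or SegmentationConfig()
    if cfg.dej_min >= cfg.dej_max:
        raise ValueError("empty DEJ search window: dej_min must be < dej_max")
    nz, nx, ny = ivol.shape
    flat, shifts, _ = flatten_volume(ivol.I, surface)
    # en-face median filtering removes laterally narrow structures;
    # NaN sentinels are replaced by the plane median for filtering only
    zmax = min(cfg.dej_max + 8, nz)
    filt = np.empty((zmax, nx, ny))
    k = min(cfg.ef_kernel, nx, ny)
    for z in range(zmax):
        plane = flat[z]
        finite = np.isfinite(plane)
        fill = np.nanmedian(plane) if finite.any() else 0.0
        filt[z] = median_filter(np.where(finite, plane, fill), size=k, mode="reflect")

    raw = np.full((nx, ny), np.nan)
    cands: dict[tuple[int, int], list[EdgeCandidate]] = {}
    lo, hi = cfg.dej_min, min(cfg.dej_max, zmax - 1)
    for x in range(nx):
        for y in range(ny):
            cc = detect_subpixel_edges(filt[:, x, y], cfg.smooth_sigma, cfg.threshold_k)
            cc = [c for c in cc if lo <= c.depth <= hi]
            cands[(x, y)] = cc
            if cc:
                raw[x, y] = max(cc, key=lambda c: c.strength).depth
    has_cand = np.isfinite(raw)
    dej_flat, valid, outliers = _outlier_reject_and_relock(raw, has_cand, cands, cfg)
    dej = unflatten_map(dej_flat, shifts)
    valid = valid & (dej > surface) & (dej < nz)
    return dej, valid, outliers


def apply_manual_overrides(boundaries: BoundarySet, overrides,
                           ivol: IntensityVolume,
                           config: SegmentationConfig | None = None) -> BoundarySet:
    """Re-lock boundaries at operator-specified positions.

    Each override is ``(x, y, layer, depth_hint)``; the boundary at that
    lateral position is locked to the sub-pixel edge nearest the hint
    within +-``relock_radius`` pixels, and the surrounding
    ``median_kernel`` neighborhood is re-interpolated for continuity.
    Hints with no nearby edge are rejected with a warning.
    """
    import warnings

    cfg = config or SegmentationConfig()
    nz, nx, ny = ivol.shape
    I = uniform_filter(ivol.I, size=(1, cfg.lateral_box, cfg.lateral_box),
                       mode="nearest") if cfg.lateral_box > 1 else ivol.I
    surface = boundaries.surface.copy()
    dej = boundaries.dej.copy()
    valid = boundaries.valid_mask.copy()
    applied = list(boundaries.overrides)
    pinned: list[tuple[int, int, str]] = []
    for x, y, layer, hint in overrides:
        if not (0 <= x < nx and 0 <= y < ny):
            raise IndexError(f"override coordinates ({x}, {y}) out of range")
        if layer not in ("surface", "dej"):
            raise ValueError(f"unknown layer {layer!r}")
        cc = detect_subpixel_edges(I[:, x, y], cfg.smooth_sigma, cfg.threshold_k)
        depth = _nearest_candidate(cc, hint, cfg.relock_radius)
        if depth is None:
            warnings.warn(f"override at ({x}, {y}) rejected: no edge within "
                          f"+-{cfg.relock_radius} px of hint {hint}")
            continue
        target = surface if layer == "surface" else dej
        target[x, y] = depth
        valid[x, y] = True
        pinned.append((x, y, layer))
        applied.append((x, y, layer, hint))
        # re-interpolate the neighborhood around the corrected pixel
        h = cfg.median_kernel // 2
        sl = (slice(max(x - h, 0), min(x + h, nx)), slice(max(y - h, 0), min(y + h, ny)))
        sub = target[sl]
        med = median_filter(target, size=cfg.median_kernel, mode="reflect")[sl]
        bad = np.abs(sub - med) > cfg.outlier_px
        px, py = x - sl[0].start, y - sl[1].start
        bad[px, py] = False  # the override itself is pinned
        target[sl] = _interpolate_invalid(sub, ~bad)
        target[x, y] = depth
    out = BoundarySet(surface=surface, dej=dej, valid_mask=valid, overrides=applied)
    return out
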