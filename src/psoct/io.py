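"""Core volumetric data types and file I/O.

Defines the system constants of the PS-OCT instrument, the in-memory
containers passed between pipeline stages (complex dual-channel volumes,
intensity volumes, layer boundaries, birefringence maps, per-scan
summaries), and their on-disk representations: an HDF5 layout for volumes
and derived products, TIFF for en-face image exports and RFC-4180 CSV for
tabular exports.

Axis convention: all volumes are indexed ``(z, x, y)`` with ``z`` axis 0
and index 0 at the shallowest (air-side) pixel.  Depth positions are
continuous sub-pixel values in axial-pixel units with pixel centers at
integers.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import tifffile

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

__all__ = [
    "SystemConstants",
    "ComplexVolume",
    "IntensityVolume",
    "BoundarySet",
    "BirefringenceMap",
    "ScanSummary",
    "write_volume",
    "read_volume",
    "write_boundaries",
    "read_boundaries",
    "write_map",
    "read_map",
    "export_enface_map",
]


@dataclass(frozen=True)
class SystemConstants:
    """Physical constants of the imaging system.

    Parameters
    ----------
    lambda0 : float
        Center wavelength of the swept source, meters.
    dz : float
        Axial pixel size in air, meters.
    dx, dy : float
        Lateral pixel sizes, meters.
    RI : float
        Bulk refractive index of tissue used to convert air-referenced
        axial pixels to physical depth in tissue.
    """

    lambda0: float = 1301e-9
    dz: float = 4e-6
    dx: float = 10e-6
    dy: float = 10e-6
    RI: float = 1.4

    def __post_init__(self) -> None:
        for name in ("lambda0", "dz", "dx", "dy", "RI"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"SystemConstants.{name} must be strictly positive, got {v!r}")

    @property
    def slope_per_dn(self) -> float:
        """Retardance slope (rad per axial pixel) produced by unit birefringence.

        The round-trip phase accrues at ``4*pi*dn/lambda0`` per unit physical
        depth; one axial pixel in air corresponds to ``dz/RI`` of physical
        depth in tissue, so ``m = dn * 4*pi*dz / (lambda0*RI)``.
        """
        return 4.0 * np.pi * self.dz / (self.lambda0 * self.RI)

    def dn_from_slope(self, slope: float | np.ndarray) -> float | np.ndarray:
        """Convert a phase-retardance slope (rad/axial pixel) to birefringence."""
        return slope * self.lambda0 * self.RI / (4.0 * np.pi * self.dz)


@dataclass
class ComplexVolume:
    """Paired complex backscatter amplitudes from the two detection channels."""

    AH: np.ndarray
    AV: np.ndarray
    constants: SystemConstants = field(default_factory=SystemConstants)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.AH = np.asarray(self.AH)
        self.AV = np.asarray(self.AV)
        if self.AH.shape != self.AV.shape:
            raise ValueError(
                f"channel shape mismatch: AH {self.AH.shape} vs AV {self.AV.shape}"
            )
        if self.AH.ndim != 3:
            raise ValueError(f"expected 3-D (z,x,y) arrays, got ndim={self.AH.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.AH.shape

    def intensity(self) -> "IntensityVolume":
        """Backscattered intensity ``I = |AH|^2 + |AV|^2``."""
        I = (np.abs(self.AH) ** 2 + np.abs(self.AV) ** 2).astype(np.float64)
        return IntensityVolume(I=I, constants=self.constants)


@dataclass
class IntensityVolume:
    """Non-negative backscattered intensity on the same (z,x,y) grid."""

    I: np.ndarray
    constants: SystemConstants = field(default_factory=SystemConstants)

    def __post_init__(self) -> None:
        self.I = np.asarray(self.I, dtype=np.float64)
        if self.I.ndim != 3:
            raise ValueError(f"expected 3-D (z,x,y) intensity, got ndim={self.I.ndim}")
        if np.nanmin(self.I) < 0:
            raise ValueError("intensity must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.I.shape


@dataclass
class BoundarySet:
    """Sub-pixel surface and DEJ depth maps with validity flags.

    ``surface`` and ``dej`` are (nx, ny) arrays of continuous depth
    positions in axial-pixel units.  ``overrides`` is a list of
    ``(x, y, layer, depth_hint)`` operator corrections already applied
    (kept for provenance), with ``layer`` one of ``"surface"``/``"dej"``.
    """

    surface: np.ndarray
    dej: np.ndarray
    valid_mask: np.ndarray
    overrides: list[tuple[int, int, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.surface = np.asarray(self.surface, dtype=np.float64)
        self.dej = np.asarray(self.dej, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (self.surface.shape == self.dej.shape == self.valid_mask.shape):
            raise ValueError("surface, dej and valid_mask must share one (x,y) shape")

    def validate_ordering(self, nz: int) -> None:
        """Check 0 <= surface < dej < nz on valid pixels; raise on violation."""
        m = self.valid_mask
        s, d = self.surface[m], self.dej[m]
        if m.any():
            if not (np.isfinite(s).all() and np.isfinite(d).all()):
                raise ValueError("non-finite boundary depth on valid pixel")
            if (s < 0).any() or (s >= d).any() or (d >= nz).any():
                raise ValueError("boundary ordering violated: need 0 <= surface < dej < nz")


@dataclass
class BirefringenceMap:
    """Per-A-scan effective birefringence with fit diagnostics."""

    dn: np.ndarray
    slope: np.ndarray
    r2: np.ndarray
    used_wrapped: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.dn, self.slope, self.r2, self.used_wrapped, self.valid_mask)}
        if len(shapes) != 1:
            raise ValueError("all map fields must share one (x,y) shape")
        self.used_wrapped = np.asarray(self.used_wrapped, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)


@dataclass
class ScanSummary:
    """Scan-level descriptive statistics of the dermal birefringence map."""

    subject: str
    arm: str
    day: int
    repeat: int
    mean_dn: float
    median_dn: float
    sd_dn: float
    n_valid: int
    fraction_mitigated: float
    valid: bool = True


# ---------------------------------------------------------------------------
# HDF5 schema
# ---------------------------------------------------------------------------

def _write_constants_attrs(root: h5py.Group, c: SystemConstants) -> None:
    root.attrs["lambda0_m"] = c.lambda0
    root.attrs["dz_m"] = c.dz
    root.attrs["dx_m"] = c.dx
    root.attrs["dy_m"] = c.dy
    root.attrs["RI"] = c.RI
    root.attrs["schema_version"] = SCHEMA_VERSION


def _read_constants_attrs(root: h5py.Group) -> SystemConstants:
    defaults = SystemConstants()
    kw = {}
    for attr, name in [
        ("lambda0_m", "lambda0"), ("dz_m", "dz"), ("dx_m", "dx"), ("dy_m", "dy"), ("RI", "RI"),
    ]:
        if attr in root.attrs:
            kw[name] = float(root.attrs[attr])
        else:
            fallback = getattr(defaults, name)
            warnings.warn(
                f"attribute {attr!r} missing; falling back to default {fallback}",
                stacklevel=3,
            )
            logger.warning("attribute %r missing; using default %s", attr, fallback)
            kw[name] = fallback
    return SystemConstants(**kw)


def _check_schema(root: h5py.Group) -> None:
    ver = root.attrs.get("schema_version", SCHEMA_VERSION)
    major = str(ver).split(".")[0]
    if major != SCHEMA_VERSION.split(".")[0]:
        raise ValueError(f"unsupported schema major version {ver!r}")


def write_volume(vol: ComplexVolume, path: str | Path) -> None:
    """Write a ComplexVolume to the project HDF5 layout.

    Complex data are stored as separate float32 real/imag datasets
    (``/AH_real`` etc.); physical constants live in root attributes.
    """
    with h5py.File(path, "w") as f:
        for name, arr in [("AH", vol.AH), ("AV", vol.AV)]:
            f.create_dataset(f"{name}_real", data=np.real(arr).astype(np.float32), track_times=False)
            f.create_dataset(f"{name}_imag", data=np.imag(arr).astype(np.float32), track_times=False)
        _write_constants_attrs(f, vol.constants)
        for k, v in vol.meta.items():
            f.attrs[f"meta_{k}"] = v


def read_volume(path: str | Path) -> ComplexVolume:
    """Read a ComplexVolume; missing constant attributes fall back to defaults."""
    with h5py.File(path, "r") as f:
        _check_schema(f)
        parts = {}
        for ds in ("AH_real", "AH_imag", "AV_real", "AV_imag"):
            if ds not in f:
                raise KeyError(f"dataset /{ds} missing from {path}")
            parts[ds] = f[ds][()]
        constants = _read_constants_attrs(f)
        meta = {k[5:]: f.attrs[k] for k in f.attrs if k.startswith("meta_")}
    AH = parts["AH_real"].astype(np.complex64)
    AH.imag = parts["AH_imag"]
    AV = parts["AV_real"].astype(np.complex64)
    AV.imag = parts["AV_imag"]
    return ComplexVolume(AH=AH, AV=AV, constants=constants, meta=meta)


def write_boundaries(b: BoundarySet, path: str | Path) -> None:
    """Write a BoundarySet to /boundaries in an HDF5 file (created or appended)."""
    with h5py.File(path, "a") as f:
        if "boundaries" in f:
            del f["boundaries"]
        g = f.create_group("boundaries")
        g.create_dataset("surface", data=b.surface, track_times=False)
        g.create_dataset("dej", data=b.dej, track_times=False)
        g.create_dataset("valid_mask", data=b.valid_mask, track_times=False)
        if b.overrides:
            rows = np.array(
                [(x, y, 0 if layer == "surface" else 1, hint) for x, y, layer, hint in b.overrides],
                dtype=np.float64,
            )
        else:
            rows = np.zeros((0, 4))
        g.create_dataset("overrides", data=rows, track_times=False)
        f.attrs.setdefault("schema_version", SCHEMA_VERSION)


def read_boundaries(path: str | Path) -> BoundarySet:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        g = f["boundaries"]
        rows = g["overrides"][()]
        overrides = [
            (int(x), int(y), "surface" if layer == 0 else "dej", float(hint))
            for x, y, layer, hint in rows
        ]
        return BoundarySet(
            surface=g["surface"][()], dej=g["dej"][()],
            valid_mask=g["valid_mask"][()], overrides=overrides,
        )


def write_map(m: BirefringenceMap, path: str | Path) -> None:
    """Write a BirefringenceMap to /maps in an HDF5 file (created or appended)."""
    with h5py.File(path, "a") as f:
        if "maps" in f:
            del f["maps"]
        g = f.create_group("maps")
        for name in ("dn", "slope", "r2", "used_wrapped", "valid_mask"):
            g.create_dataset(name, data=getattr(m, name), track_times=False)
        f.attrs.setdefault("schema_version", SCHEMA_VERSION)


def read_map(path: str | Path) -> BirefringenceMap:
    with h5py.File(path, "r") as f:
        _check_schema(f)
        g = f["maps"]
        return BirefringenceMap(**{n: g[n][()] for n in ("dn", "slope", "r2", "used_wrapped", "valid_mask")})


# ---------------------------------------------------------------------------
# En-face exports
# ---------------------------------------------------------------------------

def export_enface_map(m: BirefringenceMap, path: str | Path) -> None:
    """Export an en-face birefringence map as TIFF + CSV.

    The TIFF holds ``dn`` scaled to units of 1e-6 (so 500e-6 exports as
    500.0), with NaN at invalid pixels.  The CSV lists one row per valid
    pixel: ``x,y,dn_e6,r2,used_wrapped``.
    """
    path = Path(path)
    dn_e6 = np.where(m.valid_mask, m.dn * 1e6, np.nan).astype(np.float32)
    tifffile.imwrite(path.with_suffix(".tiff"), dn_e6)
    with open(path.with_suffix(".csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "dn_e6", "r2", "used_wrapped"])
        xs, ys = np.nonzero(m.valid_mask)
        for x, y in zip(xs, ys):
            w.writerow([x, y, repr(float(m.dn[x, y] * 1e6)),
                        repr(float(m.r2[x, y])), int(m.used_wrapped[x, y])])
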