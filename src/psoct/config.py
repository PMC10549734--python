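"""Flat key=value run configuration shared by the CLI subcommands.

A run config is a plain text file of ``key = value`` lines (# comments
allowed).  Unknown keys are rejected so typos fail loudly; every run logs
the fully resolved configuration.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any

logger = logging.getLogger(__name__)

__all__ = ["DEFAULTS", "parse_config_file", "resolve_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


def _tuple_of_ints(s: str) -> tuple[int, ...]:
    s = s.strip()
    if not s:
        return ()
    return tuple(int(v) for v in s.replace(",", " ").split())


# key -> (default, parser)
DEFAULTS: dict[str, tuple[Any, Any]] = {
    # phantom
    "shape": ((128, 64, 64), _tuple_of_ints),
    "surface_depth": (20.0, float),
    "surface_amplitude": (3.0, float),
    "surface_corr": (16.0, float),
    "epidermis_thickness": (25.0, float),
    "epidermis_variation": (2.0, float),
    "epidermis_corr": (16.0, float),
    "dn_true": (500e-6, float),
    "theta": (0.5235987755982988, float),
    "mu": (0.0092, float),
    "snr_db": (20.0, lambda s: None if s.lower() in ("none", "inf") else float(s)),
    "dop": (0.95, float),
    "hair_count": (0, int),
    "stripe_rows": ((), _tuple_of_ints),
    "stripe_amplitude": (10.0, float),
    # destriping
    "destripe": (False, lambda s: s.lower() in ("1", "true", "yes")),
    "destripe_levels": (5, int),
    "destripe_sigma": (2.0, float),
    # segmentation
    "median_kernel": (40, int),
    "outlier_px": (10.0, float),
    "ef_kernel": (21, int),
    "dej_min": (10, int),
    "dej_max": (60, int),
    # birefringence
    "smooth_stokes": (True, lambda s: s.lower() in ("1", "true", "yes")),
    "ref_window": (3, int),
    "fit_window": (50, int),
    "mitigation_threshold": (600e-6, float),
    "quadrature": ("geometric", str),
    # system constants
    "lambda0": (1301e-9, float),
    "dz": (4e-6, float),
    "dx": (10e-6, float),
    "dy": (10e-6, float),
    "RI": (1.4, float),
    # bookkeeping
    "seed": (0, int),
    "subject": ("S00", str),
    "arm": ("none", str),
    "day": (1, int),
    "repeat": (0, int),
}


def parse_config_file(path: str | Path) -> dict[str, Any]:
    """Parse a flat key=value file, rejecting unknown keys."""
    out: dict[str, Any] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in DEFAULTS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        _, parser = DEFAULTS[key]
        try:
            out[key] = parser(value.strip())
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key}: {exc}") from exc
    return out


def resolve_config(file_values: dict[str, Any] | None = None,
                   overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Defaults <- config file <- explicit overrides; logs the result."""
    cfg = {k: v for k, (v, _) in DEFAULTS.items()}
    for src in (file_values or {}, overrides or {}):
        for k, v in src.items():
            if k not in DEFAULTS:
                raise ConfigError(f"unknown config key {k!r}")
            if v is not None:
                cfg[k] = v
    logger.info("resolved config: %s", cfg)
    return cfg
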