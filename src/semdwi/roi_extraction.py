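"""Coordinate-centered square ROIs on parameter maps.

Each biopsy target records the voxel coordinate of its sampling site; the
measurement ROI is an in-plane square of roughly 90-120 mm^2 centered on
that coordinate, from which per-parameter means are read. Two readers'
measurements are averaged before the correlation analysis; a simulated
second reader with additive jitter supports inter-reader agreement checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ClippedROIError, ConfigurationError, SemDwiError

log = logging.getLogger(__name__)

PARAMETER_NAMES = ("ddc1500", "alpha1500", "ddc5000", "alpha5000")

#: Nominal ROI-area window (mm^2) and the tolerance band a realized discrete
#: square must fall in. No integer square on a 1.875 mm grid lands inside
#: [90, 120] exactly (5 px -> 87.9 mm^2, 6 px -> 126.6 mm^2), so the band is
#: widened to [85, 130] with a logged warning for areas outside the nominal
#: window.
AREA_WINDOW = (90.0, 120.0)
AREA_TOLERANCE_BAND = (85.0, 130.0)


@dataclass(frozen=True)
class BiopsyTarget:
    """One biopsy sampling site, addressed by 0-based voxel index (i, j, k)."""

    target_id: str
    patient_id: str
    center: tuple[int, int, int]
    source_image: str = "T1C"

    def __post_init__(self) -> None:
        if self.source_image not in ("T1C", "T2FLAIR"):
            raise ConfigurationError("source_image must be 'T1C' or 'T2FLAIR'")


@dataclass(frozen=True)
class ROIMask:
    """In-plane square ROI on one slice."""

    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    area: float
    side_px: int

    def __len__(self) -> int:
        return self.indices[0].size


@dataclass(frozen=True)
class ReaderMeasurement:
    reader_id: str
    target_id: str
    parameter: str
    value: float

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETER_NAMES:
            raise ConfigurationError(f"unknown parameter {self.parameter!r}")
        if not np.isfinite(self.value):
            raise ConfigurationError("measurement value must be finite")


def place_roi(
    target: BiopsyTarget,
    pixel_size: float,
    area_target: float = 105.0,
    volume_shape: tuple[int, int, int] | None = None,
) -> ROIMask:
    """Square ROI centered on the target, sized to approximate ``area_target``.

    The side (in pixels) minimizes |side^2 * pixel_area - area_target|; the
    realized area must fall within the tolerance band, otherwise the
    next-best side is used (logged). For an even side the center is offset
    toward lower indices. An ROI reaching outside the volume raises
    :class:`ClippedROIError` rather than clipping silently.
    """
    if not AREA_WINDOW[0] <= area_target <= AREA_WINDOW[1]:
        raise ConfigurationError(
            f"area_target {area_target} outside the nominal window {AREA_WINDOW}"
        )
    pixel_area = pixel_size ** 2
    sides = np.arange(1, 21)
    errs = np.abs(sides ** 2 * pixel_area - area_target)
    order = np.argsort(errs, kind="stable")
    side_px = None
    for cand in sides[order]:
        area = cand ** 2 * pixel_area
        if AREA_TOLERANCE_BAND[0] <= area <= AREA_TOLERANCE_BAND[1]:
            side_px = int(cand)
            if cand != sides[order][0]:
                log.warning(
                    "ROI side %d (area %.1f mm^2) outside tolerance; using side %d",
                    int(sides[order][0]), float(sides[order][0] ** 2 * pixel_area), side_px,
                )
            break
    if side_px is None:
        raise ConfigurationError(
            f"no square side yields an area within {AREA_TOLERANCE_BAND} "
            f"for pixel size {pixel_size}"
        )
    area = side_px ** 2 * pixel_area
    if not AREA_WINDOW[0] <= area <= AREA_WINDOW[1]:
        log.warning("realized ROI area %.1f mm^2 outside nominal window %s",
                    area, AREA_WINDOW)

    ci, cj, ck = target.center
    half_lo = side_px // 2          # even side: offset toward lower indices
    lo_i, lo_j = ci - half_lo, cj - half_lo
    hi_i, hi_j = lo_i + side_px, lo_j + side_px
    if volume_shape is not None:
        nx, ny, nz = volume_shape
        if lo_i < 0 or lo_j < 0 or hi_i > nx or hi_j > ny or not 0 <= ck < nz:
            raise ClippedROIError(
                f"ROI for {target.target_id} at {target.center} extends "
                f"outside volume {volume_shape}"
            )
    ii, jj = np.meshgrid(np.arange(lo_i, hi_i), np.arange(lo_j, hi_j), indexing="ij")
    kk = np.full(ii.size, ck)
    return ROIMask(indices=(ii.ravel(), jj.ravel(), kk), area=float(area), side_px=side_px)


def extract_mean(map3d: np.ndarray, roi: ROIMask) -> tuple[float, int]:
    """Arithmetic mean over valid (non-NaN) ROI voxels.

    Returns ``(mean, n_missing)``; all-missing ROIs raise.
    """
    ii, jj, kk = roi.indices
    vals = np.asarray(map3d, dtype=float)[ii, jj, kk]
    valid = np.isfinite(vals)
    n_missing = int((~valid).sum())
    if not valid.any():
        raise SemDwiError("all ROI voxels are missing")
    return float(vals[valid].mean()), n_missing


def measure_targets(
    maps,
    targets: list[BiopsyTarget],
    pixel_size: float,
    area_target: float = 105.0,
    reader_id: str = "reader1",
) -> list[ReaderMeasurement]:
    """Read the four parameter means at every target for one reader."""
    out = []
    shape = maps["ddc1500"].shape
    for t in targets:
        roi = place_roi(t, pixel_size, area_target, shape)
        for p in PARAMETER_NAMES:
            value, n_missing = extract_mean(maps[p], roi)
            if n_missing:
                log.warning("%s/%s: %d missing ROI voxels", t.target_id, p, n_missing)
            out.append(ReaderMeasurement(reader_id, t.target_id, p, value))
    return out


def simulate_second_reader(
    measurements: list[ReaderMeasurement],
    jitter_sd: float | dict[str, float],
    seed: int = 0,
    reader_id: str = "reader2",
) -> list[ReaderMeasurement]:
    """Duplicate a reader's values with additive Gaussian jitter.

    ``jitter_sd`` may be a single scale or a per-parameter mapping, since
    DDC (~1e-3 mm^2/s) and alpha (~1) live on very different scales.
    """
    rng = np.random.default_rng(seed)
    out = []
    for m in measurements:
        sd = jitter_sd[m.parameter] if isinstance(jitter_sd, dict) else jitter_sd
        if sd < 0:
            raise ConfigurationError("jitter_sd must be non-negative")
        out.append(ReaderMeasurement(reader_id, m.target_id, m.parameter,
                                     m.value + rng.normal(0.0, sd) if sd else m.value))
    return out


def reader_average(
    measurements: list[ReaderMeasurement],
    n_readers: int = 2,
) -> dict[tuple[str, str], float]:
    """Mean across readers per (target, parameter).

    Every (target, parameter) pair must carry exactly ``n_readers``
    measurements; the error names the offending pair.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    readers: dict[tuple[str, str], set[str]] = {}
    for m in measurements:
        key = (m.target_id, m.parameter)
        groups.setdefault(key, []).append(m.value)
        readers.setdefault(key, set()).add(m.reader_id)
    for key, vals in groups.items():
        if len(vals) != n_readers or len(readers[key]) != n_readers:
            raise ConfigurationError(
                f"target {key[0]} parameter {key[1]}: expected {n_readers} "
                f"readers, found {sorted(readers[key])}"
            )
    return {key: float(np.mean(vals)) for key, vals in groups.items()}
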