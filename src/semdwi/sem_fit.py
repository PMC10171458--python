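"""Voxelwise stretched-exponential model fitting over two b-value subsets.

Each voxel's normalized decay S(b)/S(0) is fitted by bounded nonlinear least
squares to exp[-(b*DDC)^alpha]. Two subsets of the acquisition are fitted
independently -- b <= 1500 s/mm^2 and the full range to 5000 s/mm^2 --
yielding four parametric maps: DDC_1500, alpha_1500, DDC_5000, alpha_5000.

S(0) is taken as the measured b=0 signal, not a free parameter: the model
normalizes by S(0), so only (DDC, alpha) are estimated by default. A
free-S0 mode is available for sensitivity checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConfigurationError, DegenerateVoxelError, SemDwiError
from .model import sem_decay
from .scheme import BValueScheme, select_bvalues

__all__ = [
    "FitSettings",
    "DWIVolume",
    "SEMFitResult",
    "ParameterMaps",
    "fit_monoexp",
    "fit_voxel",
    "fit_volume",
    "select_bvalues",
    "BValueScheme",
]

log = logging.getLogger(__name__)

DDC_BOUNDS = (1e-6, 1e-2)   # mm^2/s
ALPHA_BOUNDS = (0.01, 1.0)
BOUND_TOL = 1e-9            # "at bound" when a parameter lands this close


@dataclass(frozen=True)
class FitSettings:
    """Tunables of the voxel fit; defaults are the documented pipeline values."""

    ddc_bounds: tuple[float, float] = DDC_BOUNDS
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS
    alpha_init: float = 0.8
    tol: float = 1e-10          # objective (ftol) convergence tolerance
    max_iter: int = 500
    free_s0: bool = False       # estimate S0 instead of fixing to measured S(0)
    nex_weighting: bool = False  # weight residuals by sqrt(NEX)


@dataclass(frozen=True)
class DWIVolume:
    """4-D diffusion-weighted signal (x, y, z, b) with its acquisition scheme."""

    data: np.ndarray
    scheme: BValueScheme
    voxel_size: tuple[float, float, float] = (1.875, 1.875, 4.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ConfigurationError("DWI data must be 4-D (x, y, z, b)")
        if data.shape[3] != len(self.scheme):
            raise ConfigurationError(
                f"4th axis length {data.shape[3]} does not match "
                f"{len(self.scheme)} b values"
            )
        if np.any(data < 0):
            raise ConfigurationError("DWI magnitude signal must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel_size must be positive")
        object.__setattr__(self, "data", data)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class SEMFitResult:
    """Per-voxel fit output."""

    ddc: float
    alpha: float
    s0_used: float
    rss: float
    n_iter: int
    converged: bool
    at_bound: bool
    subset_tag: str = ""


@dataclass
class ParameterMaps:
    """The four parametric maps plus per-subset quality maps.

    Voxels outside ``fit_mask`` (or degenerate ones removed from it)
    carry NaN.
    """

    ddc1500: np.ndarray
    alpha1500: np.ndarray
    ddc5000: np.ndarray
    alpha5000: np.ndarray
    fit_mask: np.ndarray
    rss1500: np.ndarray = field(default=None)  # type: ignore[assignment]
    rss5000: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged1500: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged5000: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __getitem__(self, name: str) -> np.ndarray:
        maps = {
            "ddc1500": self.ddc1500, "alpha1500": self.alpha1500,
            "ddc5000": self.ddc5000, "alpha5000": self.alpha5000,
        }
        return maps[name]

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return ("ddc1500", "alpha1500", "ddc5000", "alpha5000")


def fit_monoexp(signal, scheme: BValueScheme | np.ndarray) -> tuple[float, float]:
    """Log-linear ADC fit: OLS of ln(S) on b over strictly positive signals.

    Returns ``(adc, s0)`` where ``adc`` is the magnitude of the slope and
    ``s0 = exp(intercept)``. Zero or negative signal samples are excluded;
    fewer than two positive samples is a degenerate voxel.
    """
    b = scheme.b_values if isinstance(scheme, BValueScheme) else np.asarray(scheme, float)
    s = np.asarray(signal, dtype=float)
    if s.shape != b.shape:
        raise ConfigurationError("signal and scheme lengths differ")
    pos = s > 0
    if int(pos.sum()) < 2:
        raise DegenerateVoxelError("fewer than 2 positive signal values")
    slope, intercept = np.polyfit(b[pos], np.log(s[pos]), 1)
    return float(abs(slope)), float(np.exp(intercept))


def _residual_and_jac(params, b, y, weights, free_s0):
    """Residuals y - model and the analytic Jacobian of the model.

    For the fixed-S0 fit params = (ddc, alpha) and y = S(b)/S(0); with free
    S0 params = (ddc, alpha, c) and the model is c * exp[-(b*ddc)^alpha]
    with y = S(b)/S(0), c ~ 1.
    """
    ddc, alpha = params[0], params[1]
    c = params[2] if free_s0 else 1.0
    u = b * ddc
    decay = sem_decay(ddc, alpha, b)
    model = c * decay
    res = (model - y) * weights

    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.power(u, alpha)
        d_ddc = -model * alpha * np.power(u, alpha - 1.0) * b
        d_alpha = -model * ua * np.log(u)
    zero = u == 0.0
    d_ddc[zero] = 0.0
    d_alpha[zero] = 0.0
    cols = [d_ddc * weights, d_alpha * weights]
    if free_s0:
        cols.append(decay * weights)
    return res, np.stack(cols, axis=1)


def fit_voxel(
    signal,
    scheme: BValueScheme,
    settings: FitSettings | None = None,
    subset_tag: str = "",
) -> SEMFitResult:
    """Fit (DDC, alpha) to one voxel's signal by bounded least squares.

    The objective is sum_b (S(b)/S(0) - exp[-(b*DDC)^alpha])^2, minimized
    with a trust-region reflective solver using the analytic Jacobian.
    Initialization: DDC from the log-linear ADC (clipped to bounds),
    alpha = 0.8.
    """
    settings = settings or FitSettings()
    b = scheme.b_values
    s = np.asarray(signal, dtype=float)
    if s.shape != b.shape:
        raise ConfigurationError("signal and scheme lengths differ")
    if not np.all(np.isfinite(s)):
        raise SemDwiError("non-finite signal values")
    s0 = float(s[0])
    if s0 <= 0:
        raise DegenerateVoxelError("S(0) <= 0")
    y = s / s0

    weights = np.sqrt(scheme.nex.astype(float)) if settings.nex_weighting else np.ones_like(b)

    try:
        adc, _ = fit_monoexp(s, scheme)
    except DegenerateVoxelError:
        adc = 1e-3
    lo_d, hi_d = settings.ddc_bounds
    lo_a, hi_a = settings.alpha_bounds
    # keep the start strictly interior so the TRF solver has room to move
    x0 = [min(max(adc, lo_d * 1.01), hi_d * 0.99), settings.alpha_init]
    lower = [lo_d, lo_a]
    upper = [hi_d, hi_a]
    if settings.free_s0:
        x0.append(1.0)
        lower.append(0.0)
        upper.append(np.inf)

    res = least_squares(
        lambda p: _residual_and_jac(p, b, y, weights, settings.free_s0)[0],
        x0,
        jac=lambda p: _residual_and_jac(p, b, y, weights, settings.free_s0)[1],
        bounds=(lower, upper),
        method="trf",
        ftol=settings.tol,
        xtol=settings.tol,
        gtol=settings.tol,
        max_nfev=settings.max_iter,
        x_scale=[1e-3, 0.1] + ([1.0] if settings.free_s0 else []),
    )
    ddc, alpha = float(res.x[0]), float(res.x[1])
    at_bound = (
        min(ddc - lo_d, hi_d - ddc) <= BOUND_TOL
        or min(alpha - lo_a, hi_a - alpha) <= BOUND_TOL
    )
    return SEMFitResult(
        ddc=ddc,
        alpha=alpha,
        s0_used=s0 * (float(res.x[2]) if settings.free_s0 else 1.0),
        rss=float(2.0 * res.cost),
        n_iter=int(res.nfev),
        converged=bool(res.success),
        at_bound=bool(at_bound),
        subset_tag=subset_tag,
    )


def fit_volume(
    dwi: DWIVolume,
    mask: np.ndarray,
    settings: FitSettings | None = None,
    subset_bmax: tuple[float, float] = (1500.0, 5000.0),
) -> ParameterMaps:
    """Fit every masked voxel over both b-value subsets.

    Degenerate voxels (S(0) <= 0) are dropped from the fit mask and logged;
    their map entries are NaN.
    """
    settings = settings or FitSettings()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.spatial_shape:
        raise ConfigurationError("mask shape does not match DWI spatial shape")
    if not mask.any():
        raise ConfigurationError("empty fit mask")

    shape = dwi.spatial_shape
    nan = np.full(shape, np.nan)
    out = {
        "ddc1500": nan.copy(), "alpha1500": nan.copy(),
        "ddc5000": nan.copy(), "alpha5000": nan.copy(),
        "rss1500": nan.copy(), "rss5000": nan.copy(),
        "converged1500": np.zeros(shape, dtype=bool),
        "converged5000": np.zeros(shape, dtype=bool),
    }
    fit_mask = mask.copy()
    tags = ("b1500", "b5000")
    subsets = [(tag, dwi.scheme.select(bm)) for tag, bm in zip(tags, subset_bmax)]
    idx_by_tag = {
        tag: np.nonzero(np.isin(dwi.scheme.b_values, sub.b_values))[0]
        for tag, sub in subsets
    }

    n_degenerate = 0
    coords = np.argwhere(mask)
    for i, j, k in coords:
        sig = dwi.data[i, j, k, :]
        try:
            for (tag, sub), suffix in zip(subsets, ("1500", "5000")):
                r = fit_voxel(sig[idx_by_tag[tag]], sub, settings, subset_tag=tag)
                out[f"ddc{suffix}"][i, j, k] = r.ddc
                out[f"alpha{suffix}"][i, j, k] = r.alpha
                out[f"rss{suffix}"][i, j, k] = r.rss
                out[f"converged{suffix}"][i, j, k] = r.converged
        except DegenerateVoxelError:
            fit_mask[i, j, k] = False
            n_degenerate += 1
            for suffix in ("1500", "5000"):
                out[f"ddc{suffix}"][i, j, k] = np.nan
                out[f"alpha{suffix}"][i, j, k] = np.nan
                out[f"rss{suffix}"][i, j, k] = np.nan

    log.info(
        "fit_volume: %d voxels fitted, %d degenerate removed",
        int(fit_mask.sum()), n_degenerate,
    )
    return ParameterMaps(
        ddc1500=out["ddc1500"], alpha1500=out["alpha1500"],
        ddc5000=out["ddc5000"], alpha5000=out["alpha5000"],
        fit_mask=fit_mask,
        rss1500=out["rss1500"], rss5000=out["rss5000"],
        converged1500=out["converged1500"], converged5000=out["converged5000"],
    )
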