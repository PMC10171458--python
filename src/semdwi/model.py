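"""Closed-form stretched-exponential diffusion signal.

The model is S(b) = S(0) * exp[-(b*DDC)^alpha], where DDC (mm^2/s) is the
distributed diffusion coefficient -- an ADC-like mean intravoxel diffusion
rate -- and alpha in (0, 1] is the heterogeneity index: alpha = 1 recovers
mono-exponential decay, lower alpha means a broader intravoxel distribution
of diffusion coefficients.
"""

from __future__ import annotations

import numpy as np

from .errors import DomainError


def sem_signal(s0, ddc, alpha, b_values):
    """Evaluate S(b) = s0 * exp[-(b*ddc)^alpha] per b value.

    Parameters broadcast; ``b_values`` may be scalar or array. The product
    b*ddc is dimensionless, so the result is monotone non-increasing in b
    and equals ``s0`` at b = 0.
    """
    s0 = np.asarray(s0, dtype=float)
    ddc = np.asarray(ddc, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if np.any(s0 < 0):
        raise DomainError("s0 must be non-negative")
    if np.any(ddc < 0):
        raise DomainError("ddc must be non-negative")
    if np.any((alpha <= 0) | (alpha > 1)):
        raise DomainError("alpha must lie in (0, 1]")
    if np.any(b < 0):
        raise DomainError("b values must be non-negative")
    return s0 * sem_decay(ddc, alpha, b)


def sem_decay(ddc, alpha, b):
    """Normalized decay exp[-(b*ddc)^alpha]; no domain checks (hot path)."""
    u = np.asarray(b, dtype=float) * np.asarray(ddc, dtype=float)
    # 0^alpha = 0 for alpha > 0, so the b=0 point is exactly 1.
    with np.errstate(invalid="ignore"):
        out = np.exp(-np.power(u, alpha))
    return np.where(u == 0.0, 1.0, out)
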