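"""Diffusion-weighting protocol: b values with per-b NEX.

The default scheme is a 22-point acquisition spanning 0-5000 s/mm^2 with the
number of excitations (NEX) increasing from 1 to 4 with b, so that the
effective magnitude-image noise scale shrinks as 1/sqrt(NEX) at high
diffusion weighting where the signal is weakest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, FitInfeasibleError

#: Full 22-point b-value protocol (s/mm^2), ascending.
DEFAULT_B_VALUES: tuple[float, ...] = (
    0, 10, 20, 30, 50, 100, 150, 200, 300, 400, 500, 600, 800,
    1000, 1500, 2000, 2500, 3000, 3500, 4000, 4500, 5000,
)

#: Minimum number of b values for a two-parameter fit with any slack.
MIN_BVALUES_FOR_FIT = 4


def default_nex(b: float) -> int:
    """NEX schedule: 1 for b <= 600, 2 up to 1500, 3 up to 3000, 4 above."""
    if b <= 600:
        return 1
    if b <= 1500:
        return 2
    if b <= 3000:
        return 3
    return 4


@dataclass(frozen=True)
class BValueScheme:
    """Ascending, unique b values starting at 0, with aligned NEX counts."""

    b_values: np.ndarray
    nex: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size == 0:
            raise ConfigurationError("b_values must be a non-empty 1-D sequence")
        if b[0] != 0:
            raise ConfigurationError("first b value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ConfigurationError("b values must be strictly ascending and unique")
        if self.nex is None:
            nex = np.array([default_nex(bi) for bi in b], dtype=int)
        else:
            nex = np.asarray(self.nex, dtype=int)
            if nex.shape != b.shape:
                raise ConfigurationError(
                    f"nex length {nex.size} does not match {b.size} b values"
                )
            if np.any(nex < 1):
                raise ConfigurationError("NEX values must be positive integers")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "nex", nex)

    def __len__(self) -> int:
        return int(self.b_values.size)

    @classmethod
    def default(cls) -> "BValueScheme":
        return cls(np.array(DEFAULT_B_VALUES, dtype=float))

    def nex_for(self, b: float) -> int:
        """NEX at an acquired b value; error if b is not in the scheme."""
        idx = np.nonzero(self.b_values == b)[0]
        if idx.size == 0:
            raise ConfigurationError(f"b={b} not covered by the NEX schedule")
        return int(self.nex[idx[0]])

    def select(self, b_max: float) -> "BValueScheme":
        """Sub-scheme with b <= b_max, order preserved.

        Raises :class:`FitInfeasibleError` when fewer than four b values
        survive, since the two-parameter fit needs slack beyond exact
        interpolation.
        """
        if b_max < 0:
            raise ConfigurationError("b_max must be non-negative")
        keep = self.b_values <= b_max
        if int(keep.sum()) < MIN_BVALUES_FOR_FIT:
            raise FitInfeasibleError(
                f"only {int(keep.sum())} b values <= {b_max}; "
                f"need at least {MIN_BVALUES_FOR_FIT}"
            )
        return BValueScheme(self.b_values[keep], self.nex[keep])


def select_bvalues(scheme: BValueScheme, b_max: float) -> BValueScheme:
    """Functional alias for :meth:`BValueScheme.select`."""
    return scheme.select(b_max)
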