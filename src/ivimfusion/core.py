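"""Core containers for multi-b-value diffusion MRI and the IVIM signal model.

The intravoxel incoherent motion (IVIM) model describes diffusion-weighted
signal decay as a mixture of two exponentials: a fast, perfusion-related
compartment (capillary pseudo-diffusion, coefficient D*) and a slow,
molecular-diffusion compartment (coefficient D).  The perfusion fraction f
weights the fast compartment:

    S(b) / S0 = f * exp(-b * (D* + D)) + (1 - f) * exp(-b * D)

with b the diffusion weighting in s/mm^2 and S0 the signal at b = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AcquisitionScheme",
    "IVIMParameterMap",
    "DecayCurve",
    "ivim_signal",
    "ivim_signal_scalar",
    "DEFAULT_B_VALUES",
]

#: Ten-b-value prostate protocol (s/mm^2) used throughout as the default.
DEFAULT_B_VALUES = (0.0, 50.0, 100.0, 200.0, 400.0, 600.0, 1000.0, 1200.0, 1800.0, 2000.0)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Ordered set of diffusion weightings for one DWI acquisition.

    Parameters
    ----------
    b_values
        Strictly increasing b-values in s/mm^2; the first must be 0 and at
        least four values are required so that both stages of a segmented
        fit have two or more points.
    """

    b_values: tuple[float, ...] = DEFAULT_B_VALUES

    def __post_init__(self) -> None:
        b = tuple(float(v) for v in self.b_values)
        object.__setattr__(self, "b_values", b)
        if len(b) < 4:
            raise ValueError(f"need at least 4 b-values, got {len(b)}")
        if b[0] != 0.0:
            raise ValueError(f"first b-value must be 0, got {b[0]}")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("b-values must be strictly increasing")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.b_values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.b_values)

    def split_counts(self, b_threshold: float) -> tuple[int, int]:
        """Number of b-values below / at-or-above a segmentation threshold."""
        b = self.array
        return int(np.sum(b < b_threshold)), int(np.sum(b >= b_threshold))


@dataclass
class IVIMParameterMap:
    """Per-pixel IVIM parameters (ground truth or estimated) on a 2D grid.

    All maps share one shape.  ``f`` is dimensionless in [0, 1]; ``d`` and
    ``dstar`` are in mm^2/s; ``s0`` in arbitrary units; ``pixel_size`` in mm.
    Pixels may be NaN (e.g. outside a fitted ROI); invariants are enforced
    on the finite entries only.
    """

    f: np.ndarray
    d: np.ndarray
    dstar: np.ndarray
    s0: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.dstar = np.asarray(self.dstar, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        shapes = {a.shape for a in (self.f, self.d, self.dstar, self.s0)}
        if len(shapes) != 1:
            raise ValueError(f"parameter maps have mismatched shapes: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.validate()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.f.shape

    def validate(self) -> None:
        ok = np.isfinite(self.f)
        if np.any((self.f[ok] < 0) | (self.f[ok] > 1)):
            raise ValueError("perfusion fraction f must lie in [0, 1]")
        ok = np.isfinite(self.d)
        if np.any(self.d[ok] <= 0):
            raise ValueError("diffusion coefficient D must be positive")
        both = np.isfinite(self.dstar) & np.isfinite(self.d) & np.isfinite(self.f)
        perfused = both & (self.f > 0)
        if np.any(self.dstar[perfused] <= self.d[perfused]):
            raise ValueError("pseudo-diffusion D* must exceed D wherever f > 0")
        ok = np.isfinite(self.s0)
        if np.any(self.s0[ok] <= 0):
            raise ValueError("S0 must be positive")


@dataclass
class DecayCurve:
    """Signal values paired with b-values for one voxel or one ROI."""

    b_values: np.ndarray
    signals: np.ndarray
    ident: str = ""

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.b_values.shape != self.signals.shape:
            raise ValueError("b_values and signals must have equal length")
        if self.b_values.ndim != 1:
            raise ValueError("decay curve arrays must be 1-D")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")
        if not np.any(self.b_values == 0):
            raise ValueError("a b = 0 measurement is required")

    @property
    def s0_measured(self) -> float:
        return float(self.signals[self.b_values == 0][0])


def ivim_signal(b, f, d, dstar, s0=1.0):
    """Vectorized biexponential IVIM forward model.

    Broadcasts over any mix of array arguments.  ``b`` in s/mm^2, ``d`` and
    ``dstar`` in mm^2/s.
    """
    b = np.asarray(b, dtype=float)
    f = np.asarray(f, dtype=float)
    d = np.asarray(d, dtype=float)
    dstar = np.asarray(dstar, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    return s0 * (f * np.exp(-b * (dstar + d)) + (1.0 - f) * np.exp(-b * d))


def ivim_signal_scalar(b: float, f: float, d: float, dstar: float, s0: float = 1.0) -> float:
    """Scalar evaluation of the biexponential decay using ``math`` only.

    Kept deliberately independent of :func:`ivim_signal` (no numpy) so the
    two implementations can cross-check each other.
    """
    return s0 * (f * math.exp(-b * (dstar + d)) + (1.0 - f) * math.exp(-b * d))
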