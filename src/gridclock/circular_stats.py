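"""Circular statistics for grid orientations.

Grid orientations live on a 360/n-periodic domain, so before any circular
statistic the angles are projected into fold-space (multiplied by n); mean
directions are mapped back by dividing by n.  The Rayleigh test assesses
whether orientations cluster (e.g. anchoring of a square-like 4-fold code
to environment axes) or are uniformly distributed across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CircularSample:
    angles_deg: tuple[float, ...]
    fold: int = 1

    def __post_init__(self) -> None:
        if len(self.angles_deg) == 0:
            raise ValueError("empty circular sample")
        if self.fold < 1:
            raise ValueError("fold must be >= 1")

    @property
    def projected_rad(self) -> np.ndarray:
        return np.deg2rad(np.asarray(self.angles_deg) * self.fold % 360.0)


def resultant(sample: CircularSample) -> tuple[float, float]:
    """Mean direction (degrees, fundamental domain) and resultant length R."""
    z = np.exp(1j * sample.projected_rad).mean()
    R = float(np.abs(z))
    mean_deg = float(np.rad2deg(np.angle(z)) / sample.fold % (360.0 / sample.fold))
    return mean_deg, R


def rayleigh_test(sample: CircularSample) -> tuple[float, float]:
    """Rayleigh uniformity test on the fold-projected angles.

    Returns (Z, p) with Z = n R^2 and the standard small-sample
    approximation p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)),
    where Rn = n R.
    """
    n = len(sample.angles_deg)
    if n < 2:
        raise ValueError("Rayleigh test requires at least 2 angles")
    _, R = resultant(sample)
    Z = n * R**2
    Rn = n * R
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2.0 * n))
    return float(Z), float(min(max(p, 0.0), 1.0))
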