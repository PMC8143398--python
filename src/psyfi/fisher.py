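"""Nonparametric Fisher-information extraction via the Cramér–Rao bound.

For a (possibly biased) estimator of orientation with bias b(theta) and
standard deviation sigma(theta), the Cramér–Rao bound reads

    sqrt(I_F(theta)) >= (1 + b'(theta)) / sigma(theta),

and under the tight-bound assumption (the decoder attains the bound) the
right-hand side *is* the square root of the encoding Fisher information.
Under efficient coding sqrt(I_F) is proportional to the stimulus prior, so
its normalization yields the observer's prior over orientation, and its
integral is the total encoding resource.

Units: theta in radians on [0, pi); b in radians; sigma on the orientation
radian scale, i.e. sqrt(1/kappa)/2 with kappa from the doubled-angle von
Mises fit. sqrt(I_F) is then in 1/radian and its integral dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import deg_to_rad
from .circular import BiasVarianceProfile
from .config import get_logger

log = get_logger(__name__)


class DegenerateVarianceError(ValueError):
    """sigma = 0 (or kappa infinite) where the bound must be evaluated."""


@dataclass
class FisherProfile:
    """sqrt(I_F) on an orientation grid, its integral, and the implied prior."""

    grid_deg: np.ndarray
    sqrt_fi: np.ndarray          # 1/radian
    n_floored: int = 0
    window_deg: float = np.nan

    def __post_init__(self):
        self.grid_deg = np.asarray(self.grid_deg, dtype=float)
        self.sqrt_fi = np.asarray(self.sqrt_fi, dtype=float)
        if len(self.grid_deg) != len(self.sqrt_fi):
            raise ValueError("grid and sqrt_fi must have equal length")
        if np.any(self.sqrt_fi < 0):
            raise ValueError("sqrt_fi must be nonnegative (floor before constructing)")

    @property
    def grid_rad(self) -> np.ndarray:
        return deg_to_rad(self.grid_deg)

    @property
    def _step_rad(self) -> float:
        return float(self.grid_rad[1] - self.grid_rad[0])

    @property
    def total(self) -> float:
        """Total resource: integral of sqrt(I_F) over [0, pi).

        The grid covers a full period, so the periodic trapezoid rule
        reduces to a rectangle sum.
        """
        return float(np.sum(self.sqrt_fi) * self._step_rad)

    @property
    def total_fi(self) -> float:
        """Alternative reading: integral of I_F (not its square root)."""
        return float(np.sum(self.sqrt_fi ** 2) * self._step_rad)

    @property
    def prior(self) -> np.ndarray:
        """Efficient-coding prior: normalized sqrt(I_F), integrates to 1."""
        total = self.total
        if total <= 0:
            raise DegenerateVarianceError("total sqrt-FI is zero; no prior")
        return self.sqrt_fi / total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta_deg": self.grid_deg,
                             "sqrt_fi": self.sqrt_fi,
                             "prior": self.prior})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, window_deg: float = np.nan,
                   n_floored: int = 0) -> "FisherProfile":
        return cls(grid_deg=frame["theta_deg"].to_numpy(),
                   sqrt_fi=frame["sqrt_fi"].to_numpy(),
                   n_floored=n_floored, window_deg=window_deg)

    def metadata(self) -> dict:
        return {"window_deg": self.window_deg, "n_floored": self.n_floored}

    def summary(self) -> dict:
        return {"total_sqrt_fi": self.total, "total_fi": self.total_fi,
                "n_floored": self.n_floored}


def _circular_gradient(values: np.ndarray, step: float) -> np.ndarray:
    """Central difference of a periodic sequence."""
    return (np.roll(values, -1) - np.roll(values, 1)) / (2.0 * step)


def extract_sqrt_fi(profile: BiasVarianceProfile) -> FisherProfile:
    """Extract sqrt(I_F)(theta) = (1 + b'(theta)) / sigma(theta).

    b' is a circular central difference of the bias on the profile grid;
    sigma is sqrt(1/kappa)/2 on the orientation radian scale. Negative
    values of the bound (possible in noisy windows) are floored at zero and
    counted in ``n_floored``.
    """
    valid = ~np.isnan(profile.bias_deg) & ~np.isnan(profile.kappa)
    if valid.sum() < 3:
        raise ValueError("need at least 3 valid grid points to extract FI")
    sigma = profile.sigma_orientation_rad
    if np.any(np.isnan(sigma)) or np.any(sigma <= 0):
        raise DegenerateVarianceError(
            "sigma must be positive and finite on the whole grid "
            "(zero variance / infinite kappa is degenerate)")
    step = deg_to_rad(profile.grid_step_deg)
    b = deg_to_rad(profile.bias_deg)
    b_prime = _circular_gradient(b, step)
    raw = (1.0 + b_prime) / sigma
    n_floored = int(np.sum(raw < 0))
    if n_floored:
        log.debug("extract_sqrt_fi: floored %d negative grid values", n_floored)
    sqrt_fi = np.clip(raw, 0.0, None)
    return FisherProfile(grid_deg=profile.grid_deg, sqrt_fi=sqrt_fi,
                         n_floored=n_floored, window_deg=profile.window_deg)


def normalize_prior(fp: FisherProfile) -> np.ndarray:
    """Normalized sqrt(I_F): the efficient-coding prior density on [0, pi)."""
    return fp.prior


def total_resource(fp: FisherProfile) -> float:
    """Integral of sqrt(I_F) over orientation: the total encoding resource."""
    return fp.total
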