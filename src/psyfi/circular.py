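"""Sliding-window circular psychometrics: bias, variance and RMSE profiles.

Orientation is axial (period 180 deg), so every circular fit is done on
doubled angles (period 360 deg) and mapped back. Within each window a
von Mises distribution is fit to the doubled response angles; the window
bias is the circular mean minus the window center, and the variance proxy
is 1/kappa on the doubled-angle scale (the scale on which combined-
participant variances of order 0.2 live).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .angles import deg_to_rad, signed_diff_deg, wrap_orientation_deg
from .config import get_logger
from .io import Dataset, EmptyDatasetError

log = get_logger(__name__)

FLAG_OK = 0
FLAG_INTERPOLATED = 1
FLAG_KAPPA_CAPPED = 2


class InsufficientDataError(ValueError):
    """Fewer samples than the estimator needs."""


class DegenerateProfileError(ValueError):
    """Too many missing grid points for a usable profile."""


def _bessel_ratio(kappa: np.ndarray) -> np.ndarray:
    """A(kappa) = I1(kappa)/I0(kappa), numerically stable for large kappa."""
    kappa = np.asarray(kappa, dtype=float)
    return i1e(kappa) / i0e(kappa)


def kappa_from_resultant(rbar, kappa_cap: float = 1e4) -> np.ndarray:
    """Invert the mean resultant length R = A(kappa) for kappa.

    Uses the classic piecewise approximation (Fisher, Statistical Analysis of
    Circular Data) refined by two Newton steps on A(kappa) - R.
    """
    r = np.atleast_1d(np.asarray(rbar, dtype=float))
    kappa = np.empty_like(r)
    lo = r < 0.53
    mid = (r >= 0.53) & (r < 0.85)
    hi = r >= 0.85
    kappa[lo] = 2 * r[lo] + r[lo] ** 3 + 5 * r[lo] ** 5 / 6
    kappa[mid] = -0.4 + 1.39 * r[mid] + 0.43 / (1 - r[mid])
    rh = np.clip(r[hi], None, 1 - 1e-12)
    kappa[hi] = 1.0 / (rh ** 3 - 4 * rh ** 2 + 3 * rh)
    kappa = np.clip(kappa, 0.0, kappa_cap)

    for _ in range(2):  # Newton refinement; A'(k) = 1 - A/k - A^2
        with np.errstate(divide="ignore", invalid="ignore"):
            a = _bessel_ratio(kappa)
            deriv = 1 - a / np.where(kappa > 0, kappa, np.inf) - a ** 2
            step = np.where(deriv > 1e-14, (a - r) / np.where(deriv > 1e-14, deriv, 1.0), 0.0)
        kappa = np.clip(kappa - step, 0.0, kappa_cap)
    return kappa


@dataclass
class VonMisesFit:
    mu_deg: float
    kappa: float
    n: int
    degenerate: bool = False


def fit_von_mises_orientation(samples_deg, kappa_cap: float = 1e4) -> VonMisesFit:
    """Fit a von Mises to orientation samples (degrees, period 180).

    Estimation runs on doubled angles; the returned mean is mapped back to
    [0, 180). All-identical samples yield kappa clamped at ``kappa_cap`` and
    the ``degenerate`` flag set.
    """
    samples = np.atleast_1d(np.asarray(samples_deg, dtype=float))
    if samples.size < 2:
        raise InsufficientDataError(
            f"need >= 2 samples for a von Mises fit, got {samples.size}")
    doubled = deg_to_rad(2.0 * samples)
    z = np.exp(1j * doubled).mean()
    mu = wrap_orientation_deg(np.degrees(np.angle(z)) / 2.0)
    rbar = np.abs(z)
    kappa = float(kappa_from_resultant(rbar, kappa_cap)[0])
    degenerate = bool(rbar >= 1 - 1e-12 or kappa >= kappa_cap)
    if degenerate:
        kappa = kappa_cap
    return VonMisesFit(mu_deg=float(mu), kappa=kappa, n=samples.size,
                       degenerate=degenerate)


@dataclass
class BiasVarianceProfile:
    """b(theta), kappa(theta) and sigma^2 = 1/kappa on an orientation grid."""

    grid_deg: np.ndarray
    bias_deg: np.ndarray
    kappa: np.ndarray
    n_per_window: np.ndarray
    window_deg: float
    flags: np.ndarray = field(default=None)
    enforce_period_90: bool = True

    def __post_init__(self):
        self.grid_deg = np.asarray(self.grid_deg, dtype=float)
        self.bias_deg = np.asarray(self.bias_deg, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.n_per_window = np.asarray(self.n_per_window, dtype=int)
        if self.flags is None:
            self.flags = np.zeros_like(self.grid_deg, dtype=int)
        self.flags = np.asarray(self.flags, dtype=int)
        lengths = {len(self.grid_deg), len(self.bias_deg), len(self.kappa),
                   len(self.n_per_window), len(self.flags)}
        if lengths != {len(self.grid_deg)}:
            raise ValueError("profile arrays must share the grid length")

    @property
    def variance(self) -> np.ndarray:
        """1/kappa on the doubled-angle scale (dimensionless)."""
        with np.errstate(divide="ignore"):
            return np.where(self.kappa > 0, 1.0 / self.kappa, np.inf)

    @property
    def sigma_orientation_rad(self) -> np.ndarray:
        """Standard deviation on the orientation radian scale: sqrt(1/kappa)/2."""
        return np.sqrt(self.variance) / 2.0

    @property
    def grid_step_deg(self) -> float:
        return float(self.grid_deg[1] - self.grid_deg[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "theta_deg": self.grid_deg,
            "bias_deg": self.bias_deg,
            "kappa": self.kappa,
            "variance": self.variance,
            "n": self.n_per_window,
            "flags": self.flags,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, window_deg: float,
                   enforce_period_90: bool = True) -> "BiasVarianceProfile":
        return cls(grid_deg=frame["theta_deg"].to_numpy(),
                   bias_deg=frame["bias_deg"].to_numpy(),
                   kappa=frame["kappa"].to_numpy(),
                   n_per_window=frame["n"].to_numpy(),
                   window_deg=window_deg,
                   flags=frame["flags"].to_numpy(),
                   enforce_period_90=enforce_period_90)

    def metadata(self) -> dict:
        return {"window_deg": self.window_deg,
                "enforce_period_90": self.enforce_period_90}


def _interp_circular(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Linearly interpolate missing entries of a periodic sequence."""
    if not missing.any():
        return values
    n = len(values)
    idx = np.arange(n)
    good = ~missing
    # tile once on each side so interpolation wraps
    x = np.concatenate([idx[good] - n, idx[good], idx[good] + n])
    y = np.tile(values[good], 3)
    out = values.copy()
    out[missing] = np.interp(idx[missing], x, y)
    return out


def sliding_profile(trials: Dataset, window_deg: float,
                    grid_step_deg: float = 1.0,
                    enforce_period_90: bool = True,
                    kappa_cap: float = 1e4,
                    strict: bool = False) -> BiasVarianceProfile:
    """Sliding-window von Mises bias/variance estimation.

    For each grid center c the trials whose target lies in
    [c - window/2, c + window/2) (circularly, wrapping across 0/180) are
    pooled and a von Mises is fit to their doubled response angles; the
    window bias is the circular mean minus c, reduced to [-90, 90).

    With ``enforce_period_90`` the target (and the response, via its error
    relative to the target) is folded modulo 90 before windowing and the
    90-degree profile is tiled back onto [0, 180).
    """
    if len(trials) == 0:
        raise EmptyDatasetError("cannot profile an empty dataset")
    period = 90.0 if enforce_period_90 else 180.0
    target = trials.target_deg
    error = signed_diff_deg(trials.response_deg, trials.target_deg)
    folded = target % period

    grid = np.arange(0.0, period, grid_step_deg)
    half = window_deg / 2.0
    n_pts = len(grid)
    bias = np.full(n_pts, np.nan)
    kappa = np.full(n_pts, np.nan)
    counts = np.zeros(n_pts, dtype=int)
    flags = np.zeros(n_pts, dtype=int)

    for i, c in enumerate(grid):
        d = (folded - c + period / 2.0) % period - period / 2.0
        mask = (d >= -half) & (d < half)
        n = int(mask.sum())
        counts[i] = n
        if n < 2:
            continue
        # window-local pseudo-responses c + d + e keep wrap-around windows
        # contiguous; doubled-angle circular mean and resultant length
        doubled = deg_to_rad(2.0 * (d[mask] + error[mask]))
        z = np.exp(1j * doubled).mean()
        bias[i] = np.degrees(np.angle(z)) / 2.0  # in (-90, 90]
        rbar = np.abs(z)
        k = float(kappa_from_resultant(rbar, kappa_cap)[0])
        if rbar >= 1 - 1e-12 or k >= kappa_cap:
            k = kappa_cap
            flags[i] = FLAG_KAPPA_CAPPED
        kappa[i] = k

    missing = counts < 2
    n_missing = int(missing.sum())
    if n_missing == n_pts:
        raise DegenerateProfileError("no grid window contains >= 2 trials")
    if n_missing > 0.2 * n_pts:
        msg = (f"{n_missing}/{n_pts} grid points have fewer than 2 trials "
               f"in their {window_deg} deg window")
        if strict:
            raise DegenerateProfileError(msg)
        warnings.warn(msg, stacklevel=2)
    if n_missing:
        bias = _interp_circular(bias, missing)
        kappa = _interp_circular(kappa, missing)
        flags[missing] = FLAG_INTERPOLATED

    bias = (bias + 90.0) % 180.0 - 90.0  # reduce to [-90, 90)

    if enforce_period_90:
        grid = np.arange(0.0, 180.0, grid_step_deg)
        reps = 2
        bias = np.tile(bias, reps)[: len(grid)]
        kappa = np.tile(kappa, reps)[: len(grid)]
        counts = np.tile(counts, reps)[: len(grid)]
        flags = np.tile(flags, reps)[: len(grid)]

    return BiasVarianceProfile(grid_deg=grid, bias_deg=bias, kappa=kappa,
                               n_per_window=counts, window_deg=window_deg,
                               flags=flags, enforce_period_90=enforce_period_90)


@dataclass
class RMSEProfile:
    grid_deg: np.ndarray
    rmse_deg: np.ndarray
    n_per_window: np.ndarray
    overall_rmse_deg: float
    window_deg: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta_deg": self.grid_deg,
                             "rmse_deg": self.rmse_deg,
                             "n": self.n_per_window})

    def metadata(self) -> dict:
        return {"window_deg": self.window_deg,
                "overall_rmse_deg": self.overall_rmse_deg}

    @classmethod
    def from_frame(cls, frame, window_deg, overall_rmse_deg):
        return cls(frame["theta_deg"].to_numpy(), frame["rmse_deg"].to_numpy(),
                   frame["n"].to_numpy(), overall_rmse_deg, window_deg)


def rmse_profile(trials: Dataset, window_deg: float,
                 grid_step_deg: float = 1.0,
                 enforce_period_90: bool = True) -> RMSEProfile:
    """Root-mean-square signed circular error per window and overall."""
    if len(trials) == 0:
        raise EmptyDatasetError("cannot profile an empty dataset")
    period = 90.0 if enforce_period_90 else 180.0
    target = trials.target_deg
    error = signed_diff_deg(trials.response_deg, trials.target_deg)
    folded = target % period
    grid = np.arange(0.0, period, grid_step_deg)
    half = window_deg / 2.0
    rmse = np.full(len(grid), np.nan)
    counts = np.zeros(len(grid), dtype=int)
    for i, c in enumerate(grid):
        d = (folded - c + period / 2.0) % period - period / 2.0
        mask = (d >= -half) & (d < half)
        counts[i] = int(mask.sum())
        if counts[i] >= 1:
            rmse[i] = float(np.sqrt(np.mean(error[mask] ** 2)))
    missing = counts < 1
    if missing.any():
        rmse = _interp_circular(rmse, missing)
    overall = float(np.sqrt(np.mean(error ** 2)))
    if enforce_period_90:
        grid_out = np.arange(0.0, 180.0, grid_step_deg)
        rmse = np.tile(rmse, 2)[: len(grid_out)]
        counts = np.tile(counts, 2)[: len(grid_out)]
        grid = grid_out
    return RMSEProfile(grid_deg=grid, rmse_deg=rmse, n_per_window=counts,
                       overall_rmse_deg=overall, window_deg=window_deg)
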