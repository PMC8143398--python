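"""Efficient-coding encoder–decoder observer and cohort simulation.

The encoder follows the standard efficient-coding construction: the
stimulus prior p(theta) is mapped through its CDF F onto a uniform internal
space, where the measurement m carries homogeneous von Mises noise on the
unit circle (internal space [0, 1) scaled to 2*pi). The analytic square
root of the encoding Fisher information is then proportional to p(theta).

Decoders either invert the forward map (MLE-like), take the posterior
circular mean, or apply a smooth monotone remap to the inverted estimate;
all three attain the Cramér–Rao bound (the remap trades bias against
variance to first order), which is exactly the invariance the extraction
stage is designed to exploit. Optional stimulus-independent "late" noise
models post-decisional factors such as motor noise.

Internal-noise calibration: the internal concentration kappa_int is chosen
as (lam / (2*pi))**2 so that, for a homogeneous encoder, the doubled-angle
response distribution is exactly von Mises with concentration kappa_int and
the sliding-window pipeline (variance = 1/kappa, sigma = sqrt(1/kappa)/2)
extracts total sqrt-FI equal to lam in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .angles import rad_to_deg, wrap_orientation_rad
from .config import BLOCKS, get_logger
from .io import Dataset
from .model import CARDINAL_NORMALIZER, mixture_cdf, mixture_density

log = get_logger(__name__)

_PPF_GRID = 4096


def internal_kappa_for_lambda(lam: float) -> float:
    """Concentration of the internal von Mises noise matching resource lam."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    return (lam / (2.0 * np.pi)) ** 2


def lambda_for_internal_kappa(kappa: float) -> float:
    return 2.0 * np.pi * np.sqrt(kappa)


@dataclass
class EncoderSpec:
    """Stimulus prior, its cumulative map to internal space, and internal noise."""

    prior_density: Callable[[np.ndarray], np.ndarray]
    cum_map: Callable[[np.ndarray], np.ndarray]
    internal_kappa: float
    lam: Optional[float] = None
    omega: Optional[float] = None
    _ppf_theta: np.ndarray = field(default=None, repr=False)
    _ppf_u: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.internal_kappa <= 0:
            raise ValueError("internal_kappa must be positive")
        theta = np.linspace(0.0, np.pi, _PPF_GRID + 1)
        cdf = np.asarray(self.cum_map(theta), dtype=float)
        if abs(cdf[0]) > 1e-9 or abs(cdf[-1] - 1.0) > 1e-6:
            raise ValueError("cum_map must satisfy F(0)=0 and F(pi)=1")
        if np.any(np.diff(cdf) < -1e-12):
            raise ValueError("cum_map must be nondecreasing")
        dens = np.asarray(self.prior_density(theta[:-1]), dtype=float)
        mass = float(np.sum(dens) * (np.pi / _PPF_GRID))
        if abs(mass - 1.0) > 1e-6:
            raise ValueError(f"prior density integrates to {mass}, not 1")
        # strictly increasing version for inversion (collapse flat spans)
        u, idx = np.unique(cdf, return_index=True)
        self._ppf_u = u
        self._ppf_theta = theta[idx]

    def ppf(self, u) -> np.ndarray:
        """Inverse cumulative map, u in [0, 1) -> theta in [0, pi)."""
        u = np.asarray(u, dtype=float) % 1.0
        theta = np.interp(u, self._ppf_u, self._ppf_theta)
        # Newton polish where the density is well away from zero
        for _ in range(2):
            dens = np.asarray(self.prior_density(theta), dtype=float)
            resid = np.asarray(self.cum_map(theta), dtype=float) - u
            safe = dens > 1e-6
            theta = np.where(safe, theta - resid / np.where(safe, dens, 1.0), theta)
            theta = np.clip(theta, 0.0, np.pi)
        return theta

    def analytic_sqrt_fi(self, theta_rad) -> np.ndarray:
        """2*pi*p(theta)*sqrt(kappa_int): the encoder's true sqrt(I_F)."""
        dens = np.asarray(self.prior_density(theta_rad), dtype=float)
        return 2.0 * np.pi * dens * np.sqrt(self.internal_kappa)


def encoder_from_params(lam: float, omega: float,
                        internal_kappa: Optional[float] = None,
                        c: float = CARDINAL_NORMALIZER) -> EncoderSpec:
    """Efficient-coding encoder whose sqrt(I_F) is the (lam, omega) mixture.

    If ``internal_kappa`` is omitted it is derived from lam so that the
    pipeline-extracted total resource equals lam.
    """
    if not lam > 0:
        raise ValueError("lam must be positive")
    if not 0.0 <= omega <= 1.0:
        raise ValueError(f"omega must lie in [0, 1], got {omega}")
    if internal_kappa is None:
        internal_kappa = internal_kappa_for_lambda(lam)
    return EncoderSpec(
        prior_density=lambda th: mixture_density(th, omega, c),
        cum_map=lambda th: mixture_cdf(th, omega, c),
        internal_kappa=float(internal_kappa),
        lam=float(lam), omega=float(omega))


DECODER_KINDS = ("inverse_map", "posterior_mean", "remapped")


@dataclass(frozen=True)
class DecoderSpec:
    """Decoder family: all attain the bound, with different bias/variance."""

    kind: str = "inverse_map"
    remap_amplitude: float = 0.0     # g(th) = th + a*sin(4*th)/4; |a| < 1
    late_noise_sd_deg: float = 0.0   # wrapped Gaussian added after decoding

    def __post_init__(self):
        if self.kind not in DECODER_KINDS:
            raise ValueError(f"kind must be one of {DECODER_KINDS}")
        if not abs(self.remap_amplitude) < 1.0:
            raise ValueError("remap amplitude must satisfy |a| < 1 "
                             "(monotonicity of the remap)")
        if self.late_noise_sd_deg < 0:
            raise ValueError("late_noise_sd_deg must be >= 0")

    def remap(self, theta_rad) -> np.ndarray:
        """Smooth monotone period-90-preserving distortion of the estimate."""
        theta = np.asarray(theta_rad, dtype=float)
        return wrap_orientation_rad(
            theta + self.remap_amplitude * np.sin(4.0 * theta) / 4.0)


def _decode_posterior_mean(encoder: EncoderSpec, m: np.ndarray,
                           n_grid: int = 720, chunk: int = 2048) -> np.ndarray:
    """Posterior mean under squared orientation error, on a deterministic grid.

    The posterior over theta is evaluated on an n_grid quadrature; the
    estimate is the posterior expectation of theta unwrapped around the
    posterior's doubled-angle circular mean (the Bayes estimator for the
    task's squared-error loss on the orientation scale).
    """
    theta_g = (np.arange(n_grid) + 0.5) * (np.pi / n_grid)
    prior_g = np.asarray(encoder.prior_density(theta_g), dtype=float)
    mu_g = 2.0 * np.pi * np.asarray(encoder.cum_map(theta_g), dtype=float)
    kappa = encoder.internal_kappa
    z2 = np.exp(2j * theta_g)
    out = np.empty_like(m)
    for start in range(0, len(m), chunk):
        mm = m[start:start + chunk, None]
        logw = kappa * np.cos(mm - mu_g[None, :])
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw) * prior_g[None, :]
        w /= w.sum(axis=1, keepdims=True)
        center = np.mod(np.angle((w * z2[None, :]).sum(axis=1)) / 2.0, np.pi)
        dev = (theta_g[None, :] - center[:, None] + np.pi / 2) % np.pi - np.pi / 2
        out[start:start + chunk] = center + (w * dev).sum(axis=1)
    return np.mod(out, np.pi)


def simulate_trials(encoder: EncoderSpec, decoder: DecoderSpec,
                    theta_rad: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized encode–decode pipeline: orientations in, estimates out."""
    theta = wrap_orientation_rad(np.asarray(theta_rad, dtype=float))
    mu = 2.0 * np.pi * np.asarray(encoder.cum_map(theta), dtype=float)
    m = rng.vonmises(mu, encoder.internal_kappa, size=theta.shape)
    if decoder.kind == "posterior_mean":
        est = _decode_posterior_mean(encoder, np.asarray(m))
    else:
        est = encoder.ppf(np.mod(m / (2.0 * np.pi), 1.0))
        if decoder.kind == "remapped":
            est = decoder.remap(est)
    if decoder.late_noise_sd_deg > 0:
        sd = np.deg2rad(decoder.late_noise_sd_deg)
        est = est + rng.normal(0.0, sd, size=est.shape)
    return wrap_orientation_rad(est)


def simulate_trial(encoder: EncoderSpec, decoder: DecoderSpec,
                   theta_rad: float, rng: np.random.Generator) -> float:
    """Single-trial convenience wrapper around :func:`simulate_trials`."""
    return float(simulate_trials(encoder, decoder, np.atleast_1d(theta_rad), rng)[0])


# Per-block (lam, omega) schedules for the two cohorts, set to the study
# conditions: combined-participant totals ~14.7 (NT) / ~11.3 (ASD) before
# feedback, omega starting near the natural-scene value ~0.5 and flattening
# with feedback far more in the NT group.
DEFAULT_SCHEDULE: Dict[str, Dict[str, Tuple[float, float]]] = {
    "NT": {"woFB": (14.7, 0.50), "wFB1": (15.7, 0.40), "wFB2": (16.7, 0.31)},
    "ASD": {"woFB": (11.3, 0.55), "wFB1": (11.25, 0.50), "wFB2": (11.2, 0.46)},
}

DEFAULT_RT_MEDIANS: Dict[str, Dict[str, float]] = {
    "NT": {"woFB": 3.0, "wFB1": 2.65, "wFB2": 2.39},
    "ASD": {"woFB": 3.4, "wFB1": 3.0, "wFB2": 2.65},
}


@dataclass
class CohortSpec:
    """Study-shaped cohort: groups, per-block (lam, omega), heterogeneity.

    ``heterogeneity_sd`` is the SD of the lognormal multiplier on each
    observer's lam; ``flexibility_coupling`` makes an observer's block-to-
    block omega learning proportional to their relative capacity (higher lam
    -> more reallocation), the mechanism behind the capacity–flexibility
    correlation. ``omega_jitter_sd`` adds independent observer-level spread
    in the starting omega.
    """

    n_observers: Dict[str, int] = field(
        default_factory=lambda: {"NT": 25, "ASD": 17})
    schedule: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(b) for g, b in DEFAULT_SCHEDULE.items()})
    trials_per_block: int = 200
    heterogeneity_sd: float = 0.25
    omega_jitter_sd: float = 0.05
    flexibility_coupling: float = 2.0
    decoder: DecoderSpec = field(
        default_factory=lambda: DecoderSpec(kind="posterior_mean"))
    rt_medians: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {g: dict(b) for g, b in DEFAULT_RT_MEDIANS.items()})
    rt_lognormal_sd: float = 0.4
    simulate_rt: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.trials_per_block < 1:
            raise ValueError("trials_per_block must be >= 1")
        for group, blocks in self.schedule.items():
            for block, (lam, omega) in blocks.items():
                if lam <= 0 or not 0 <= omega <= 1:
                    raise ValueError(
                        f"invalid (lam, omega)=({lam}, {omega}) for {group}/{block}")


def observer_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Deterministic per-observer, per-block (lam, omega) draws for a cohort."""
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for group in sorted(spec.n_observers):
        blocks = spec.schedule[group]
        lam0, omega0 = blocks["woFB"]
        for i in range(spec.n_observers[group]):
            pid = f"{group.lower()}{i + 1:02d}"
            mult = float(np.exp(rng.normal(0.0, spec.heterogeneity_sd)))
            om_i0 = float(np.clip(omega0 + rng.normal(0.0, spec.omega_jitter_sd),
                                  0.02, 0.98))
            learn = max(0.0, 1.0 + spec.flexibility_coupling * (mult - 1.0))
            for block in BLOCKS:
                lam_b, omega_b = blocks[block]
                lam_i = lam_b * mult
                om_i = float(np.clip(om_i0 - learn * (omega0 - omega_b), 0.02, 0.98))
                rows.append((pid, group, block, lam_i, om_i))
    return pd.DataFrame(rows, columns=["participant_id", "group", "block",
                                       "lam", "omega"])


def simulate_cohort(spec: CohortSpec) -> Dataset:
    """Simulate the full experiment: uniform targets, 3 blocks, two groups."""
    params = observer_parameters(spec)
    rng = np.random.default_rng((spec.rng_seed, 1))
    frames = []
    t = spec.trials_per_block
    for row in params.itertuples(index=False):
        encoder = encoder_from_params(row.lam, row.omega)
        targets = rng.uniform(0.0, np.pi, size=t)
        responses = simulate_trials(encoder, spec.decoder, targets, rng)
        if spec.simulate_rt:
            med = spec.rt_medians[row.group][row.block]
            rt = np.exp(rng.normal(np.log(med), spec.rt_lognormal_sd, size=t))
        else:
            rt = np.full(t, np.nan)
        frames.append(pd.DataFrame({
            "participant_id": row.participant_id,
            "group": row.group,
            "block": row.block,
            "trial_index": np.arange(t),
            "target_deg": rad_to_deg(targets),
            "response_deg": rad_to_deg(responses),
            "rt_s": rt,
        }))
    frame = pd.concat(frames, ignore_index=True)
    log.info("simulate_cohort: %d trials, seed=%s", len(frame), spec.rng_seed)
    return Dataset(frame, provenance=f"simulate_cohort(seed={spec.rng_seed})")


def add_late_noise(data: Dataset, sd_deg: float,
                   rng: np.random.Generator) -> Dataset:
    """Perturb responses with wrapped zero-mean Gaussian noise; targets untouched."""
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    frame = data.frame.copy()
    if sd_deg > 0:
        noise = rng.normal(0.0, sd_deg, size=len(frame))
        frame["response_deg"] = (frame["response_deg"].to_numpy() + noise) % 180.0
    return Dataset._from_validated(frame, provenance=data.provenance)
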