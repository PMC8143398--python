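"""Group-level inference: pooling, bootstrap tests, regression, trends, RT.

All statistics are compositions of the earlier pipeline stages; the
bootstrap resamples trials within a pooled set (combined-participant
statistics) or participants-then-trials (per-participant summaries), with
two-sided p-values read off the bootstrap distribution and floored at
1/(n_reps + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import get_logger
from .io import Dataset, EmptyDatasetError

log = get_logger(__name__)


def combined_participant(data: Dataset, group: str, block: str) -> Dataset:
    """Pool every trial of a group x block into one pseudo-observer."""
    sub = data.select(group=group, block=block)
    if len(sub) == 0:
        raise EmptyDatasetError(f"no trials for group={group}, block={block}")
    frame = sub.frame.copy()
    frame["participant_id"] = f"combined_{group}"
    frame["trial_index"] = np.arange(len(frame))
    return Dataset._from_validated(frame, provenance=sub.provenance)


def _two_sided_p(samples: np.ndarray, n_reps: int) -> float:
    """2 * min tail probability of the bootstrap distribution around 0,
    with the +1 correction that floors p at 1/(n_reps + 1)."""
    le = int(np.sum(samples <= 0))
    ge = int(np.sum(samples >= 0))
    p = 2.0 * (min(le, ge) + 1) / (n_reps + 1)
    return float(min(1.0, p))


@dataclass
class BootstrapResult:
    statistic_name: str
    point: float
    samples: np.ndarray
    seed: int

    @property
    def ci95(self) -> tuple:
        lo, hi = np.percentile(self.samples, [2.5, 97.5])
        return (float(lo), float(hi))

    @property
    def se(self) -> float:
        return float(np.std(self.samples, ddof=1))

    @property
    def p_two_sided(self) -> float:
        return _two_sided_p(self.samples, len(self.samples))


def _resample_trials(frame: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    idx = rng.integers(0, len(frame), size=len(frame))
    return frame.take(idx)


def _resample_hierarchical(frame: pd.DataFrame,
                           rng: np.random.Generator) -> pd.DataFrame:
    pids = frame["participant_id"].unique()
    chosen = rng.choice(pids, size=len(pids), replace=True)
    parts = []
    for j, pid in enumerate(chosen):
        sub = frame[frame["participant_id"] == pid]
        idx = rng.integers(0, len(sub), size=len(sub))
        part = sub.take(idx).copy()
        part["participant_id"] = f"bs{j:03d}"  # keep resampled observers distinct
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def bootstrap_statistic(data: Dataset, statistic: Callable[[Dataset], float],
                        n_reps: int, seed: int, unit: str = "trials",
                        statistic_name: str = "statistic",
                        retry_cap: int = 5) -> BootstrapResult:
    """Bootstrap a scalar statistic of a Dataset.

    unit="trials" resamples trials with replacement within the pooled set;
    unit="participants" resamples participants, then their trials
    (hierarchical), for per-participant statistics.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if unit not in ("trials", "participants"):
        raise ValueError("unit must be 'trials' or 'participants'")
    resample = _resample_trials if unit == "trials" else _resample_hierarchical
    rng = np.random.default_rng(seed)
    point = float(statistic(data))
    frame = data.frame
    samples = np.empty(n_reps)
    for i in range(n_reps):
        for attempt in range(retry_cap):
            try:
                samples[i] = float(statistic(
                    Dataset._from_validated(resample(frame, rng).reset_index(drop=True))))
                break
            except Exception:
                if attempt == retry_cap - 1:
                    raise
    return BootstrapResult(statistic_name=statistic_name, point=point,
                           samples=samples, seed=seed)


@dataclass
class GroupContrast:
    """Difference of a statistic between two selections, with bootstrap SE/p."""

    statistic_name: str
    label_a: str
    label_b: str
    point_a: float
    point_b: float
    samples: np.ndarray
    seed: int

    @property
    def delta(self) -> float:
        return self.point_a - self.point_b

    @property
    def se(self) -> float:
        return float(np.std(self.samples, ddof=1))

    @property
    def ci95(self) -> tuple:
        lo, hi = np.percentile(self.samples, [2.5, 97.5])
        return (float(lo), float(hi))

    @property
    def p_two_sided(self) -> float:
        return _two_sided_p(self.samples, len(self.samples))


def bootstrap_contrast(data_a: Dataset, data_b: Dataset,
                       statistic: Callable[[Dataset], float],
                       n_reps: int, seed: int, unit: str = "trials",
                       statistic_name: str = "statistic",
                       label_a: str = "a", label_b: str = "b") -> GroupContrast:
    """Bootstrap distribution of statistic(a) - statistic(b).

    The two sides are resampled independently within each rep.
    """
    res_a = bootstrap_statistic(data_a, statistic, n_reps, seed=seed,
                                unit=unit, statistic_name=statistic_name)
    res_b = bootstrap_statistic(data_b, statistic, n_reps, seed=seed + 1,
                                unit=unit, statistic_name=statistic_name)
    return GroupContrast(statistic_name=statistic_name, label_a=label_a,
                         label_b=label_b, point_a=res_a.point,
                         point_b=res_b.point,
                         samples=res_a.samples - res_b.samples, seed=seed)


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int


def flexibility_regression(per_participant: pd.DataFrame,
                           x_col: str = "lam_woFB",
                           y_col: str = "omega_wFB2") -> RegressionResult:
    """OLS of post-feedback allocation (omega at wFB2) on initial capacity
    (lam at woFB): the capacity–flexibility relation across participants."""
    tab = per_participant[[x_col, y_col]].dropna()
    if len(tab) < 3:
        raise ValueError("need >= 3 participants with both quantities")
    x = tab[x_col].to_numpy(dtype=float)
    y = tab[y_col].to_numpy(dtype=float)
    if np.var(x) == 0:
        raise ValueError("degenerate regressor: zero variance in x")
    fit = sps.linregress(x, y)
    return RegressionResult(slope=float(fit.slope), intercept=float(fit.intercept),
                            r2=float(fit.rvalue ** 2), p_value=float(fit.pvalue),
                            n=len(tab))


def within_block_trends(data: Dataset, group: str, block: str,
                        segment_length: int = 100, segment_step: int = 25,
                        window_deg: float = 4.0, grid_step_deg: float = 1.0,
                        enforce_period_90: bool = True,
                        min_trials: int = 50) -> pd.DataFrame:
    """Full pipeline per overlapping trial-index segment within one block.

    Returns one row per segment with mean |bias|, mean sigma (doubled-angle
    scale), fitted lam/omega and R^2.
    """
    from .circular import sliding_profile
    from .model import fit_fi_params

    sub = data.select(group=group, block=block)
    if len(sub) == 0:
        raise EmptyDatasetError(f"no trials for group={group}, block={block}")
    max_index = int(sub.frame["trial_index"].max())
    starts = list(range(0, max_index - segment_length + 2, segment_step))
    if not starts:
        starts = [0]
    rows = []
    for start in starts:
        stop = start + segment_length
        mask = ((sub.frame["trial_index"] >= start)
                & (sub.frame["trial_index"] < stop)).to_numpy()
        seg = Dataset._from_validated(sub.frame.loc[mask].reset_index(drop=True))
        if len(seg) < min_trials:
            raise ValueError(
                f"segment [{start}, {stop}) has {len(seg)} trials; "
                f"need at least {min_trials} for profile estimation")
        prof = sliding_profile(seg, window_deg=window_deg,
                               grid_step_deg=grid_step_deg,
                               enforce_period_90=enforce_period_90)
        fit = fit_fi_params(prof)
        rows.append({
            "segment_start": start, "segment_stop": stop, "n_trials": len(seg),
            "mean_abs_bias_deg": float(np.mean(np.abs(prof.bias_deg))),
            "mean_sigma": float(np.mean(np.sqrt(prof.variance))),
            "lam": fit.lam, "omega": fit.omega, "r2": fit.r2,
        })
    return pd.DataFrame(rows)


@dataclass
class RTSummary:
    median_s: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n: int
    n_missing: int

    @property
    def available(self) -> bool:
        return self.n > 0


def rt_summary(data: Dataset, group: Optional[str] = None,
               block: Optional[str] = None,
               bin_width_s: float = 0.25) -> RTSummary:
    """Median response time and histogram over non-missing RTs.

    With no RT data at all an explicit missing-data result (median NaN,
    n = 0) is returned rather than a zero.
    """
    sub = data.select(group=group, block=block)
    rt = sub.rt_s
    present = rt[np.isfinite(rt)]
    n_missing = len(rt) - len(present)
    if len(present) == 0:
        return RTSummary(median_s=float("nan"), hist_counts=np.array([]),
                         hist_edges=np.array([]), n=0, n_missing=n_missing)
    hi = float(np.ceil(present.max() / bin_width_s) * bin_width_s)
    edges = np.arange(0.0, hi + bin_width_s, bin_width_s)
    counts, edges = np.histogram(present, bins=edges)
    return RTSummary(median_s=float(np.median(present)), hist_counts=counts,
                     hist_edges=edges, n=len(present), n_missing=n_missing)
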