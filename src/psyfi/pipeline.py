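"""End-to-end conveniences composing the pipeline stages.

Every Results-style statistic used in group contrasts is defined here once,
as a composition of sliding-window estimation, Cramér–Rao extraction and
parametric fitting — never as a second code path.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .circular import BiasVarianceProfile, rmse_profile, sliding_profile
from .config import AnalysisConfig, BLOCKS, get_logger
from .fisher import FisherProfile, extract_sqrt_fi
from .inference import combined_participant, rt_summary
from .io import Dataset
from .model import FIParams, fit_fi_params

log = get_logger(__name__)


def analyze_dataset(data: Dataset, window_deg: float,
                    config: Optional[AnalysisConfig] = None
                    ) -> tuple[BiasVarianceProfile, FisherProfile, FIParams]:
    """Profile -> extract -> fit for one (sub)dataset with a given window."""
    cfg = config or AnalysisConfig()
    profile = sliding_profile(data, window_deg=window_deg,
                              grid_step_deg=cfg.grid_step_deg,
                              enforce_period_90=cfg.enforce_period_90,
                              kappa_cap=cfg.kappa_cap)
    fp = extract_sqrt_fi(profile)
    params = fit_fi_params(profile)
    return profile, fp, params


# --- scalar statistics of a pooled Dataset (combined-participant scale) ---

def stat_mean_abs_bias_deg(data: Dataset, config: Optional[AnalysisConfig] = None) -> float:
    cfg = config or AnalysisConfig()
    prof = sliding_profile(data, cfg.window_combined_deg, cfg.grid_step_deg,
                           cfg.enforce_period_90, cfg.kappa_cap)
    return float(np.mean(np.abs(prof.bias_deg)))


def stat_overall_variance(data: Dataset, config: Optional[AnalysisConfig] = None) -> float:
    """Mean 1/kappa over the orientation grid (doubled-angle scale)."""
    cfg = config or AnalysisConfig()
    prof = sliding_profile(data, cfg.window_combined_deg, cfg.grid_step_deg,
                           cfg.enforce_period_90, cfg.kappa_cap)
    return float(np.mean(prof.variance))


def stat_overall_rmse_deg(data: Dataset, config: Optional[AnalysisConfig] = None) -> float:
    cfg = config or AnalysisConfig()
    return rmse_profile(data, cfg.window_combined_deg, cfg.grid_step_deg,
                        cfg.enforce_period_90).overall_rmse_deg


def stat_total_sqrt_fi(data: Dataset, config: Optional[AnalysisConfig] = None) -> float:
    cfg = config or AnalysisConfig()
    prof = sliding_profile(data, cfg.window_combined_deg, cfg.grid_step_deg,
                           cfg.enforce_period_90, cfg.kappa_cap)
    return extract_sqrt_fi(prof).total


def stat_lambda(data: Dataset, config: Optional[AnalysisConfig] = None) -> float:
    cfg = config or AnalysisConfig()
    prof = sliding_profile(data, cfg.window_combined_deg, cfg.grid_step_deg,
                           cfg.enforce_period_90, cfg.kappa_cap)
    return fit_fi_params(prof).lam


def stat_omega(data: Dataset, config: Optional[AnalysisConfig] = None) -> float:
    cfg = config or AnalysisConfig()
    prof = sliding_profile(data, cfg.window_combined_deg, cfg.grid_step_deg,
                           cfg.enforce_period_90, cfg.kappa_cap)
    return fit_fi_params(prof).omega


def block_summary(data: Dataset, group: str, block: str,
                  config: Optional[AnalysisConfig] = None) -> dict:
    """Combined-participant summary of one group x block cell."""
    cfg = config or AnalysisConfig()
    pooled = combined_participant(data, group, block)
    profile, fp, params = analyze_dataset(pooled, cfg.window_combined_deg, cfg)
    rmse = rmse_profile(pooled, cfg.window_combined_deg, cfg.grid_step_deg,
                        cfg.enforce_period_90)
    rts = rt_summary(pooled)
    return {
        "group": group, "block": block, "n_trials": len(pooled),
        "mean_abs_bias_deg": float(np.mean(np.abs(profile.bias_deg))),
        "overall_variance": float(np.mean(profile.variance)),
        "overall_rmse_deg": rmse.overall_rmse_deg,
        "total_sqrt_fi": fp.total,
        "total_fi": fp.total_fi,
        "lam": params.lam, "omega": params.omega, "r2": params.r2,
        "median_rt_s": rts.median_s,
    }


def participant_table(data: Dataset,
                      config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
    """Per participant x block fits with the individual-scale window.

    Tidy output: participant_id, group, block, lam, omega, r2, plus a wide
    lam_woFB / omega_wFB2 pair per participant for the flexibility
    regression.
    """
    cfg = config or AnalysisConfig()
    rows = []
    for pid in data.participants():
        sub_all = data.select(participant_id=pid)
        group = sub_all.frame["group"].iloc[0]
        for block in BLOCKS:
            sub = sub_all.select(block=block)
            if len(sub) == 0:
                continue
            _, fp, params = analyze_dataset(sub, cfg.window_individual_deg, cfg)
            rows.append({"participant_id": pid, "group": group, "block": block,
                         "lam": params.lam, "omega": params.omega,
                         "r2": params.r2, "total_sqrt_fi": fp.total})
    return pd.DataFrame(rows)


def flexibility_table(per_participant: pd.DataFrame) -> pd.DataFrame:
    """Wide (lam at woFB, omega at wFB2) table for the regression."""
    lam0 = per_participant.query("block == 'woFB'").set_index("participant_id")["lam"]
    om2 = per_participant.query("block == 'wFB2'").set_index("participant_id")["omega"]
    groups = per_participant.groupby("participant_id")["group"].first()
    out = pd.DataFrame({"lam_woFB": lam0, "omega_wFB2": om2, "group": groups})
    return out.dropna().reset_index()
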