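"""Analysis configuration shared by all pipeline stages."""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml

GROUPS = ("NT", "ASD")
BLOCKS = ("woFB", "wFB1", "wFB2")


@dataclass
class AnalysisConfig:
    """Tunable knobs of the analysis pipeline.

    window_individual_deg / window_combined_deg are the sliding-window widths
    used for single participants and for the pooled "combined participant".
    kappa_cap bounds the von Mises concentration reported for degenerate
    (zero-spread) windows. enforce_period_90 folds the bias pattern to a 90
    degree periodicity before windowing.
    """

    window_individual_deg: float = 18.0
    window_combined_deg: float = 4.0
    grid_step_deg: float = 1.0
    n_bootstrap: int = 5000
    rng_seed: int = 0
    kappa_cap: float = 1e4
    enforce_period_90: bool = True

    def __post_init__(self) -> None:
        if self.grid_step_deg <= 0:
            raise ValueError("grid_step_deg must be positive")
        if self.window_individual_deg <= self.grid_step_deg:
            raise ValueError("window_individual_deg must exceed grid_step_deg")
        if self.window_combined_deg <= self.grid_step_deg:
            raise ValueError("window_combined_deg must exceed grid_step_deg")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.kappa_cap <= 0:
            raise ValueError("kappa_cap must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def get_logger(name: str = "psyfi") -> logging.Logger:
    """Structured-ish logger writing to stderr (stage, counts, seeds)."""
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger
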