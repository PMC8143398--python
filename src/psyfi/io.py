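"""Trial-level data model and delimited-text readers/writers.

The canonical on-disk trial format is a delimited file with header
``participant_id,group,block,trial_index,target_deg,response_deg,rt_s``
(rt_s optional). Orientations are reduced modulo 180 into [0, 180) on read.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .angles import wrap_orientation_deg
from .config import BLOCKS, GROUPS, get_logger

log = get_logger(__name__)

REQUIRED_COLUMNS = ("participant_id", "group", "block", "trial_index",
                    "target_deg", "response_deg")
OPTIONAL_COLUMNS = ("rt_s",)


class SchemaError(ValueError):
    """The file header does not provide a required column."""


class TrialParseError(ValueError):
    """A row holds a value that cannot be validated; carries line numbers."""

    def __init__(self, message: str, lines: Optional[list] = None):
        super().__init__(message)
        self.lines = lines or []


class EmptyDatasetError(ValueError):
    """The file or selection contains no trials."""


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus-response pair of the estimation task."""

    participant_id: str
    group: str
    block: str
    trial_index: int
    target_deg: float
    response_deg: float
    rt_s: Optional[float] = None

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.block not in BLOCKS:
            raise ValueError(f"block must be one of {BLOCKS}, got {self.block!r}")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")
        object.__setattr__(self, "target_deg", float(wrap_orientation_deg(self.target_deg)))
        object.__setattr__(self, "response_deg", float(wrap_orientation_deg(self.response_deg)))
        if self.rt_s is not None and not np.isnan(self.rt_s) and self.rt_s < 0:
            raise ValueError("rt_s must be >= 0")


@dataclass
class Dataset:
    """Ordered collection of trials, stored as a validated DataFrame."""

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    @classmethod
    def _from_validated(cls, frame: pd.DataFrame, provenance: str = "") -> "Dataset":
        """Internal fast path: frame is already validated (e.g. a resample)."""
        obj = cls.__new__(cls)
        obj.frame = frame
        obj.provenance = provenance
        return obj

    @classmethod
    def from_records(cls, records: Iterable[TrialRecord], provenance: str = "") -> "Dataset":
        rows = [(r.participant_id, r.group, r.block, r.trial_index,
                 r.target_deg, r.response_deg,
                 np.nan if r.rt_s is None else r.rt_s) for r in records]
        frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
        return cls(frame, provenance)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))

    @property
    def target_deg(self) -> np.ndarray:
        return self.frame["target_deg"].to_numpy()

    @property
    def response_deg(self) -> np.ndarray:
        return self.frame["response_deg"].to_numpy()

    @property
    def rt_s(self) -> np.ndarray:
        return self.frame["rt_s"].to_numpy()

    def select(self, group: Optional[str] = None, block: Optional[str] = None,
               participant_id: Optional[str] = None) -> "Dataset":
        mask = np.ones(len(self.frame), dtype=bool)
        if group is not None:
            mask &= (self.frame["group"] == group).to_numpy()
        if block is not None:
            mask &= (self.frame["block"] == block).to_numpy()
        if participant_id is not None:
            mask &= (self.frame["participant_id"] == participant_id).to_numpy()
        sub = self.frame.loc[mask].reset_index(drop=True)
        return Dataset._from_validated(sub, self.provenance)

    def participants(self) -> list:
        return sorted(self.frame["participant_id"].unique().tolist())

    def records(self) -> list:
        out = []
        for row in self.frame.itertuples(index=False):
            rt = None if pd.isna(row.rt_s) else float(row.rt_s)
            out.append(TrialRecord(row.participant_id, row.group, row.block,
                                   int(row.trial_index), float(row.target_deg),
                                   float(row.response_deg), rt))
        return out


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    frame = frame.copy()
    if "rt_s" not in frame.columns:
        frame["rt_s"] = np.nan
    frame = frame[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)]
    if len(frame) == 0:
        raise EmptyDatasetError("dataset contains no trials")

    bad_lines = []
    for col in ("target_deg", "response_deg", "rt_s"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() & frame[col].notna()
        if col != "rt_s":
            bad |= frame[col].isna()
        if bad.any():
            bad_lines += [(int(i) + 2, col) for i in np.flatnonzero(bad.to_numpy())]
        frame[col] = vals
    if bad_lines:
        raise TrialParseError(
            f"non-numeric values in {sorted({c for _, c in bad_lines})} "
            f"at file line(s) {sorted({l for l, _ in bad_lines})[:10]}",
            lines=[l for l, _ in bad_lines])

    bad_group = ~frame["group"].isin(GROUPS)
    if bad_group.any():
        raise TrialParseError(
            f"invalid group labels at line(s) "
            f"{(np.flatnonzero(bad_group.to_numpy()) + 2).tolist()[:10]} "
            f"(allowed: {GROUPS})")
    bad_block = ~frame["block"].isin(BLOCKS)
    if bad_block.any():
        raise TrialParseError(
            f"invalid block labels at line(s) "
            f"{(np.flatnonzero(bad_block.to_numpy()) + 2).tolist()[:10]} "
            f"(allowed: {BLOCKS})")

    frame["participant_id"] = frame["participant_id"].astype(str)
    frame["trial_index"] = frame["trial_index"].astype(int)
    if (frame["trial_index"] < 0).any():
        raise TrialParseError("negative trial_index")
    if ((frame["rt_s"] < 0) & frame["rt_s"].notna()).any():
        raise TrialParseError("negative rt_s")

    frame["target_deg"] = wrap_orientation_deg(frame["target_deg"].to_numpy())
    frame["response_deg"] = wrap_orientation_deg(frame["response_deg"].to_numpy())

    dup = frame.duplicated(subset=["participant_id", "block", "trial_index"])
    if dup.any():
        raise TrialParseError(
            f"duplicate (participant_id, block, trial_index) at line(s) "
            f"{(np.flatnonzero(dup.to_numpy()) + 2).tolist()[:10]}")
    return frame.reset_index(drop=True)


def read_trials(path, delimiter: str = ",",
                column_map: Optional[Mapping[str, str]] = None) -> Dataset:
    """Read a trial CSV/TSV into a validated :class:`Dataset`.

    ``column_map`` maps canonical names to the file's header names (matched
    case-insensitively), to accommodate externally deposited layouts.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if len(raw) == 0:
        raise EmptyDatasetError(f"{path} contains no trials")
    lower = {str(c).lower(): c for c in raw.columns}
    rename = {}
    for canon in list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS):
        source = (column_map or {}).get(canon, canon)
        if source.lower() in lower:
            rename[lower[source.lower()]] = canon
    raw = raw.rename(columns=rename)
    ds = Dataset(raw, provenance=str(path))
    log.info("read_trials: %d trials from %s", len(ds), path)
    return ds


def write_trials(data: Dataset, path, delimiter: str = ",") -> None:
    data.frame.to_csv(path, sep=delimiter, index=False)


def write_profile(profile, path) -> None:
    """Write a BiasVariance or Fisher profile to CSV (full precision).

    Scalar metadata is carried on ``#key=value`` comment lines so a
    round-trip read reproduces the object exactly.
    """
    frame = profile.to_frame()
    if len(frame) == 0:
        raise ValueError("refusing to write an empty profile")
    num = frame.select_dtypes(include=[np.number]).to_numpy(dtype=float)
    if not np.all(np.isfinite(num)):
        raise ValueError("profile contains non-finite values")
    buf = _io.StringIO()
    for key, val in profile.metadata().items():
        buf.write(f"#{key}={val!r}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_profile(cls, path):
    """Read a profile written by :func:`write_profile` back as ``cls``."""
    text = Path(path).read_text().splitlines()
    meta = {}
    body_start = 0
    for i, line in enumerate(text):
        if line.startswith("#") and "=" in line:
            key, val = line[1:].split("=", 1)
            meta[key] = eval(val, {"__builtins__": {}})  # noqa: S307 - repr'd scalars
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(_io.StringIO("\n".join(text[body_start:])),
                        float_precision="round_trip")
    return cls.from_frame(frame, **meta)
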