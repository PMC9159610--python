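"""Canonical trial-level data structures, CSV I/O and preprocessing filters.

The atomic unit of every analysis stage is one behavioural trial: a subject,
their screening group (action- vs state-oriented), the task, the condition
factors of that task, the binary response, its correctness, the response time
in seconds and an ordinal confidence rating.  Trials are held in a pandas
DataFrame wrapped in a :class:`Dataset` together with the confidence-scale
convention and a provenance/filter log.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Columns every trial table must provide.  Additional columns are treated as
#: condition factors (or passed through untouched).
REQUIRED_COLUMNS = ("subject", "task", "response", "correct", "rt", "rating")

#: Non-factor columns of the canonical CSV layout.
RESERVED_COLUMNS = set(REQUIRED_COLUMNS) | {"group", "stimulus"}


class FormatError(ValueError):
    """Raised when a trial file violates the canonical column contract."""


@dataclass(frozen=True)
class ConfidenceScale:
    """Ordinal confidence-report convention of a task.

    ``level_values`` are the percent-confidence meanings of the rating keys in
    increasing order.  ``reversal_level`` marks a rating key that means
    "below 50% — I would reverse my choice" (used by the interrogation task,
    where key 0 plays that role); such ratings are candidates for removal
    during preprocessing, not confidence magnitudes.
    """

    n_levels: int
    level_values: tuple[float, ...]
    reversal_level: int | None = None

    def __post_init__(self) -> None:
        if len(self.level_values) != self.n_levels:
            raise ValueError("level_values length must equal n_levels")
        if any(b <= a for a, b in zip(self.level_values, self.level_values[1:])):
            raise ValueError("level_values must be strictly increasing")

    @property
    def rating_keys(self) -> tuple[int, ...]:
        """Integer keys a subject can press, including the reversal key."""
        keys = list(range(1, self.n_levels + 1))
        if self.reversal_level is not None:
            keys = [self.reversal_level] + keys if self.reversal_level == 0 else keys
        return tuple(keys)

    def to_percent(self, rating: np.ndarray | Sequence[int]) -> np.ndarray:
        """Map rating keys (1..n_levels) to percent confidence.

        Reversal ratings map to NaN — they carry no confidence magnitude.
        """
        rating = np.asarray(rating)
        out = np.full(rating.shape, np.nan, dtype=float)
        for i, val in enumerate(self.level_values, start=1):
            out[rating == i] = val
        return out


#: 6-point scale of the free-response tasks: 50% (guess) .. 100% in 10% steps.
EXP1_SCALE = ConfidenceScale(6, (50.0, 60.0, 70.0, 80.0, 90.0, 100.0))

#: 7-key scale of the interrogation task: key 0 = below-50% (choice reversal),
#: keys 1..6 = 50..100%.
EXP2_SCALE = ConfidenceScale(6, (50.0, 60.0, 70.0, 80.0, 90.0, 100.0), reversal_level=0)


@dataclass
class Dataset:
    """A trial table plus its confidence scale and provenance metadata."""

    trials: pd.DataFrame
    scale: ConfidenceScale
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.trials.columns]
        if missing:
            raise FormatError(f"trial table missing required column(s): {missing}")

    @property
    def factor_columns(self) -> list[str]:
        return [c for c in self.trials.columns if c not in RESERVED_COLUMNS]

    @property
    def filter_log(self) -> dict:
        return self.meta.setdefault("filter_log", {})

    def __len__(self) -> int:
        return len(self.trials)

    def copy(self) -> "Dataset":
        return Dataset(self.trials.copy(), self.scale, json.loads(json.dumps(self.meta)))


def load_trials(path: str | Path, scale: ConfidenceScale, rt_unit: str = "s") -> Dataset:
    """Read a canonical trial CSV into a :class:`Dataset`.

    Required columns: ``subject, task, response, correct, rt, rating``;
    ``group``, ``stimulus`` and any factor columns are carried along.  Rows
    with non-numeric ``rt`` are dropped and reported (with line numbers) in
    ``meta['bad_rows']``.  RTs are stored in seconds internally; a file
    recorded in milliseconds can declare ``rt_unit="ms"``.
    """
    if rt_unit not in ("s", "ms"):
        raise ValueError("rt_unit must be 's' or 'ms'")
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s): {missing}")

    rt = pd.to_numeric(df["rt"], errors="coerce")
    bad = rt.isna() & df["rt"].notna() | df["rt"].isna()
    bad_rows = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
    if bad_rows:
        warnings.warn(f"{path.name}: dropped {len(bad_rows)} row(s) with bad rt")
    df = df.loc[~bad].copy()
    df["rt"] = rt.loc[~bad].astype(float) / (1000.0 if rt_unit == "ms" else 1.0)
    df["correct"] = df["correct"].astype(int).astype(bool)
    df["rating"] = df["rating"].astype(int)

    meta: dict = {"source": str(path)}
    if bad_rows:
        meta["bad_rows"] = bad_rows
    return Dataset(df.reset_index(drop=True), scale, meta)


def write_trials(ds: Dataset, path: str | Path, sidecar: bool = True) -> None:
    """Write the trial table as CSV; generator/filter provenance to a JSON sidecar."""
    path = Path(path)
    df = ds.trials.copy()
    df["correct"] = df["correct"].astype(int)
    df.to_csv(path, index=False, float_format="%.6f")
    if sidecar:
        side = path.with_suffix(".meta.json")
        payload = dict(ds.meta)
        payload["scale"] = dataclasses.asdict(ds.scale)
        side.write_text(json.dumps(payload, indent=2, default=str))


@dataclass(frozen=True)
class FilterRules:
    """Preprocessing rules: RT floor, per-cell SD cut, reversal removal."""

    rt_floor_s: float = 0.200
    sd_cut: float = 3.0
    drop_reversals: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterRules":
        cfg = json.loads(Path(path).read_text())
        return cls(
            rt_floor_s=cfg.get("rt_floor_s", 0.2),
            sd_cut=cfg.get("sd_cut", 3.0),
            drop_reversals=cfg.get("drop_reversals", False),
        )


def _cell_keys(ds: Dataset) -> list[str]:
    return ["subject"] + ds.factor_columns


def preprocess_trials(ds: Dataset, rules: FilterRules = FilterRules()) -> Dataset:
    """Apply the standard trial filters, in order.

    1. remove responses faster than ``rt_floor_s`` (anticipations),
    2. optionally remove choice reversals (ratings at the reversal key),
    3. remove RTs more than ``sd_cut`` SDs from the per subject×condition mean,
       the mean and SD being computed on trials that survived steps 1–2.

    The filter log (in ``meta['filter_log']``) counts removals per rule, so the
    counts always sum to the difference in trial numbers.  Cells left empty by
    filtering are flagged, not errors.
    """
    df = ds.trials
    n0 = len(df)
    log: dict = {"input": n0}

    fast = df["rt"] < rules.rt_floor_s
    log["rt_floor"] = int(fast.sum())
    df = df.loc[~fast]

    if rules.drop_reversals and ds.scale.reversal_level is not None:
        rev = df["rating"] == ds.scale.reversal_level
        log["reversals"] = int(rev.sum())
        df = df.loc[~rev]
    else:
        log["reversals"] = 0

    keys = _cell_keys(ds)
    grp = df.groupby(keys, observed=True, sort=False)["rt"]
    mu = grp.transform("mean")
    # ddof=0 keeps single-trial cells finite (SD 0 -> nothing removed there).
    sd = grp.transform(lambda x: x.std(ddof=0))
    out = (df["rt"] - mu).abs() > rules.sd_cut * sd
    out &= sd > 0
    log["sd_outliers"] = int(out.sum())
    df = df.loc[~out]

    log["output"] = len(df)
    empty = _empty_cells(ds.trials, df, keys)
    result = Dataset(df.reset_index(drop=True), ds.scale, dict(ds.meta))
    result.meta["filter_log"] = log
    if empty:
        warnings.warn(f"{len(empty)} subject×condition cell(s) emptied by filtering")
        result.meta["empty_cells"] = empty
    return result


def _empty_cells(before: pd.DataFrame, after: pd.DataFrame, keys: list[str]) -> list:
    had = set(map(tuple, before[keys].drop_duplicates().itertuples(index=False)))
    have = set(map(tuple, after[keys].drop_duplicates().itertuples(index=False)))
    return sorted(had - have)


def summarize_cells(ds: Dataset) -> pd.DataFrame:
    """Per subject×condition summary: mean correct RT, accuracy, mean confidence, n.

    Confidence is expressed in percent via the dataset's scale; reversal
    ratings (which have no percent meaning) are excluded from the mean.
    """
    df = ds.trials.copy()
    df["conf_pct"] = ds.scale.to_percent(df["rating"].to_numpy())
    keys = _cell_keys(ds)
    if "group" in df.columns:
        keys = ["subject", "group"] + ds.factor_columns

    def _one(cell: pd.DataFrame) -> pd.Series:
        correct = cell.loc[cell["correct"], "rt"]
        return pd.Series(
            {
                "mean_rt_correct": correct.mean() if len(correct) else np.nan,
                "accuracy": cell["correct"].mean(),
                "mean_confidence": cell["conf_pct"].mean(),
                "n": len(cell),
            }
        )

    out = df.groupby(keys, observed=True, sort=True).apply(_one, include_groups=False)
    return out.reset_index()
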