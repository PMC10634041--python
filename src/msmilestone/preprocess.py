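"""EHR preprocessing: 4-hour clock-aligned binning, feature filtering,
min-max scaling, demographics encoding and milestone-label derivation.

Raw inputs are long-format event tables (one row per observation, with its
encounter's bounds), a per-visit EDSS table, and a demographics table.  The
model consumes per-patient binned matrices ``D_k`` (time bins x features):

* Observations are averaged within 4-hour windows anchored at clock midnight
  (00:00, 04:00, ...), intersected with encounter spans so a window never
  mixes encounters.  Bins with no observation of any schema feature are
  dropped; unobserved features within a kept bin are zero.
* Features observed in fewer than 10% of patients are discarded cohort-wide,
  fixing the per-table feature count ``f_k``.
* Continuous values are min-max scaled to [0, 1] with ranges learned on the
  training split only (out-of-range test values are clipped); binary
  medication indicators pass through.
* The milestone label is 1 iff the target visit's EDSS strictly exceeds the
  threshold (4.0 / 6.0 / 7.0).  For follow-up spans of at least the horizon
  (3 years) the index visit is the latest visit with a qualifying later
  visit; shorter histories fall back to first-visit -> last-visit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalTable",
    "LabelRecord",
    "FeatureScaler",
    "bin_observations",
    "filter_features",
    "derive_labels",
    "truncate_history",
    "DemographicsEncoder",
]

FOUR_HOURS = dt.timedelta(hours=4)
THREE_YEARS = dt.timedelta(days=3 * 365.25)

EVENT_COLUMNS = ["encounter_id", "encounter_start", "encounter_end",
                 "obs_time", "feature", "value"]


@dataclass
class LongitudinalTable:
    """One patient's binned matrix ``D_k`` for one table kind."""

    values: np.ndarray                 # (t_k, f_k)
    bin_starts: list[dt.datetime]
    encounter_ids: list[str]
    features: list[str]
    kind: str = "lab"

    @property
    def t_k(self) -> int:
        return self.values.shape[0]

    @property
    def f_k(self) -> int:
        return self.values.shape[1]

    def is_empty(self) -> bool:
        return self.t_k == 0


@dataclass
class LabelRecord:
    patient_id: str
    index_time: dt.datetime
    target_time: dt.datetime
    threshold: float
    label: int


def _floor_to_bin(t: dt.datetime, granularity: dt.timedelta) -> dt.datetime:
    """Largest clock-aligned bin start (anchored at midnight) not after t."""
    midnight = dt.datetime.combine(t.date(), dt.time())
    k = int((t - midnight) // granularity)
    return midnight + k * granularity


def bin_observations(stream: pd.DataFrame, features: list[str],
                     granularity: dt.timedelta = FOUR_HOURS,
                     kind: str = "lab") -> LongitudinalTable:
    """Bin one patient's event stream into a :class:`LongitudinalTable`.

    ``features`` is the cohort-wide schema (post-filter feature order) fixing
    ``f_k``; observations of features outside it are ignored.  Within each
    (encounter, clock-bin) cell each feature's value is the mean of its
    observations; rows with no observation of any schema feature are removed.
    """
    if granularity <= dt.timedelta(0):
        raise ValueError(f"granularity must be positive, got {granularity}")
    stream = stream.copy()
    for col in ("encounter_start", "encounter_end", "obs_time"):
        stream[col] = pd.to_datetime(stream[col])
    bad = stream[(stream.obs_time < stream.encounter_start)
                 | (stream.obs_time > stream.encounter_end)]
    if len(bad):
        rec = bad.iloc[0]
        raise ValueError(
            f"observation of {rec.feature!r} at {rec.obs_time} lies outside "
            f"encounter {rec.encounter_id} [{rec.encounter_start}, {rec.encounter_end}]"
        )
    stream = stream[stream.feature.isin(features)]
    if stream.empty:
        return LongitudinalTable(np.zeros((0, len(features))), [], [], list(features), kind)
    stream["bin_start"] = [
        _floor_to_bin(t.to_pydatetime(), granularity) for t in stream.obs_time
    ]
    grouped = (stream.groupby(["encounter_id", "bin_start", "feature"])["value"]
               .mean().reset_index())
    pivot = grouped.pivot_table(index=["encounter_id", "bin_start"],
                                columns="feature", values="value")
    pivot = pivot.reindex(columns=features).fillna(0.0)
    keep = ~(pivot == 0).all(axis=1)  # all-zero rows are deleted
    pivot = pivot[keep]
    pivot = pivot.sort_index(level="bin_start", sort_remaining=False)
    return LongitudinalTable(
        values=pivot.to_numpy(dtype=float),
        bin_starts=[b.to_pydatetime() if hasattr(b, "to_pydatetime") else b
                    for _, b in pivot.index],
        encounter_ids=[e for e, _ in pivot.index],
        features=list(features),
        kind=kind,
    )


def filter_features(cohort_stream: pd.DataFrame, n_patients: int,
                    min_fraction: float = 0.10) -> list[str]:
    """Retain features observed in at least ``min_fraction`` of patients.

    ``cohort_stream`` is the concatenated long-format table over the cohort
    (training split), with a ``patient_id`` column; ``n_patients`` is the
    number of patients in that cohort (patients with no events still count
    in the denominator).
    """
    if n_patients <= 0:
        raise ValueError("cohort must be non-empty")
    counts = cohort_stream.groupby("feature")["patient_id"].nunique()
    kept = counts[counts / n_patients >= min_fraction]
    return sorted(kept.index.tolist())


class FeatureScaler:
    """Per-feature min-max scaling to [0, 1] learned on the training split.

    Constant features map to 0; unseen-split values outside the learned range
    are clipped.  Binary indicator tables (medications) pass through.
    """

    def __init__(self, passthrough: bool = False):
        self.passthrough = passthrough
        self.ranges_: dict[str, tuple[float, float]] | None = None

    def fit(self, training_stream: pd.DataFrame) -> "FeatureScaler":
        if self.passthrough:
            self.ranges_ = {}
            return self
        agg = training_stream.groupby("feature")["value"].agg(["min", "max"])
        self.ranges_ = {f: (row["min"], row["max"]) for f, row in agg.iterrows()}
        return self

    def transform_value(self, feature: str, value: float) -> float:
        if self.ranges_ is None:
            raise RuntimeError("FeatureScaler.transform called before fit")
        if self.passthrough or feature not in self.ranges_:
            return value
        lo, hi = self.ranges_[feature]
        if hi == lo:
            return 0.0
        return float(np.clip((value - lo) / (hi - lo), 0.0, 1.0))

    def transform(self, stream: pd.DataFrame) -> pd.DataFrame:
        if self.ranges_ is None:
            raise RuntimeError("FeatureScaler.transform called before fit")
        out = stream.copy()
        if self.passthrough:
            return out
        out["value"] = [
            self.transform_value(f, v) for f, v in zip(out.feature, out.value)
        ]
        return out


def derive_labels(visits: pd.DataFrame, threshold: float,
                  horizon: dt.timedelta = THREE_YEARS,
                  index_policy: str = "latest") -> list[LabelRecord]:
    """One :class:`LabelRecord` per patient at the given EDSS milestone.

    If follow-up span >= horizon, the index visit is the latest visit having
    some later visit at least ``horizon`` after it (``index_policy='latest'``;
    ``'first'`` uses the first visit), and the target is the last such later
    visit.  Otherwise index = first visit and target = last visit.  The label
    is strict: target EDSS > threshold.
    """
    records = []
    visits = visits.copy()
    if visits.empty:
        raise ValueError("no EDSS-bearing visits provided")
    visits["visit_time"] = pd.to_datetime(visits["visit_time"])
    for pid, grp in visits.groupby("patient_id"):
        grp = grp.sort_values("visit_time")
        if grp.empty:
            raise ValueError(f"patient {pid} has no EDSS-bearing visits")
        times = [t.to_pydatetime() for t in grp.visit_time]
        scores = grp.edss.to_numpy(dtype=float)
        last_t = times[-1]
        span = last_t - times[0]
        if span >= horizon:
            if index_policy == "latest":
                qualifying = [i for i, t in enumerate(times) if last_t - t >= horizon]
                idx = qualifying[-1]
            elif index_policy == "first":
                idx = 0
            else:
                raise ValueError(f"unknown index_policy {index_policy!r}")
            later = [i for i, t in enumerate(times) if t - times[idx] >= horizon]
            tgt = later[-1]
        else:
            idx, tgt = 0, len(times) - 1
        records.append(LabelRecord(
            patient_id=pid, index_time=times[idx], target_time=times[tgt],
            threshold=threshold, label=int(scores[tgt] > threshold),
        ))
    return records


def truncate_history(table: LongitudinalTable,
                     index_time: dt.datetime) -> LongitudinalTable:
    """Keep exactly the bins whose start time is <= the index-visit time."""
    keep = [i for i, b in enumerate(table.bin_starts) if b <= index_time]
    return LongitudinalTable(
        values=table.values[keep] if len(keep) else np.zeros((0, table.f_k)),
        bin_starts=[table.bin_starts[i] for i in keep],
        encounter_ids=[table.encounter_ids[i] for i in keep],
        features=table.features,
        kind=table.kind,
    )


@dataclass
class DemographicsEncoder:
    """One-hot race/ethnicity, binary sex, min-max-normalized age.

    Category orders and the age range are learned on the training split; an
    unseen category contributes an all-zero one-hot group and out-of-range
    ages are clipped to [0, 1].
    """

    race_levels: list[str] = field(default_factory=list)
    ethnicity_levels: list[str] = field(default_factory=list)
    age_range: tuple[float, float] = (0.0, 1.0)

    def fit(self, demo: pd.DataFrame) -> "DemographicsEncoder":
        self.race_levels = sorted(demo["race"].astype(str).unique())
        self.ethnicity_levels = sorted(demo["ethnicity"].astype(str).unique())
        ages = demo["age"].astype(float)
        self.age_range = (float(ages.min()), float(ages.max()))
        return self

    @property
    def dim(self) -> int:
        return len(self.race_levels) + len(self.ethnicity_levels) + 2

    def transform_one(self, record: dict) -> np.ndarray:
        race = [1.0 if str(record["race"]) == lv else 0.0 for lv in self.race_levels]
        eth = [1.0 if str(record["ethnicity"]) == lv else 0.0
               for lv in self.ethnicity_levels]
        sex = [1.0 if str(record["sex"]) == "male" else 0.0]
        lo, hi = self.age_range
        age = 0.0 if hi == lo else float(np.clip(
            (float(record["age"]) - lo) / (hi - lo), 0.0, 1.0))
        return np.array(race + eth + sex + [age])
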