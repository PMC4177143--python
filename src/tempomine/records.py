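"""Data model and I/O for longitudinal clinical lab panels.

A cohort is a set of patients, each with an ordered series of temporal
observation points. At every point a panel of analyte values is recorded
(kidney panel: creatinine, BUN; liver panel: SGOT, SGPT; optionally
haemoglobin) together with an optional observed disease state.

Two encodings of a panel are used downstream:

* a continuous one, ``normalize_panel`` — each value mapped affinely so the
  reference interval becomes [-1, 1] (0 at the interval midpoint); this is
  the representation the state predictor differentiates, and it puts all
  analytes on a comparable scale regardless of units;
* a categorical one, ``discretize_panel`` — LOW / NORMAL / HIGH against the
  reference interval (boundary values count as NORMAL, the clinical
  "within range" convention); this feeds association mining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigurationError, FormatError, RowValidationError

#: Canonical analyte order: the kidney/liver parameters the state predictor
#: differentiates, in fixed (c, b, s, g) order, then haemoglobin which is
#: used in mining only.
PARAMETERS = ("creatinine", "bun", "sgot", "sgpt")
OPTIONAL_PARAMETERS = ("haemoglobin",)
ALL_PARAMETERS = PARAMETERS + OPTIONAL_PARAMETERS

#: Item-token prefix per analyte, mirroring the panel naming used in the
#: mined rule vocabulary (KFT = kidney functionality test, LFT = liver).
ITEM_PREFIX = {
    "creatinine": "KFT_Creatinine",
    "bun": "KFT_BUN",
    "sgot": "LFT_SGOT",
    "sgpt": "LFT_SGPT",
    "haemoglobin": "Haemoglobin_content",
}

_MANDATORY_COLUMNS = ("patient_id", "point_index")


@dataclass(frozen=True)
class ReferenceRange:
    """Clinical reference interval for one analyte."""

    parameter: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ConfigurationError(
                f"reference range for {self.parameter!r} must be finite"
            )
        if not self.low < self.high:
            raise ConfigurationError(
                f"reference range for {self.parameter!r}: low must be < high "
                f"(got {self.low} >= {self.high})"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def halfwidth(self) -> float:
        return 0.5 * (self.high - self.low)


def default_ranges() -> dict[str, ReferenceRange]:
    """Shipped default reference intervals (implementation defaults for
    common adult ranges; override via a YAML config for a local lab)."""
    return {
        "creatinine": ReferenceRange("creatinine", 0.6, 1.2, "mg/dL"),
        "bun": ReferenceRange("bun", 7.0, 20.0, "mg/dL"),
        "sgot": ReferenceRange("sgot", 8.0, 45.0, "U/L"),
        "sgpt": ReferenceRange("sgpt", 7.0, 56.0, "U/L"),
        "haemoglobin": ReferenceRange("haemoglobin", 12.0, 17.0, "g/dL"),
    }


def load_ranges(path) -> dict[str, ReferenceRange]:
    """Read a ``ranges:`` YAML block into ReferenceRange objects.

    Expected layout::

        ranges:
          creatinine: {low: 0.6, high: 1.2, units: mg/dL}
          ...
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ranges" not in doc:
        raise ConfigurationError(f"{path}: expected a top-level 'ranges:' block")
    out: dict[str, ReferenceRange] = {}
    for name, entry in doc["ranges"].items():
        try:
            out[name] = ReferenceRange(
                name, float(entry["low"]), float(entry["high"]),
                str(entry.get("units", "")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"{path}: bad range entry for {name!r}: {exc}")
    return out


@dataclass
class TemporalObservation:
    """One patient x temporal-point lab panel, with optional observed state."""

    patient_id: str
    point_index: int  # 1-based temporal point label T_k
    time: float  # days since the patient's first observation
    panel: dict[str, float]
    observed_state: Optional[int] = None

    def __post_init__(self) -> None:
        if self.point_index < 1:
            raise RowValidationError([(0, f"point_index must be >= 1, got {self.point_index}")])


@dataclass
class PatientSeries:
    """Ordered observation series for one patient."""

    patient_id: str
    observations: list[TemporalObservation]

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError(f"patient {self.patient_id!r}: empty series")
        times = [o.time for o in self.observations]
        points = [o.point_index for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"patient {self.patient_id!r}: observation times must strictly increase"
            )
        if any(b <= a for a, b in zip(points, points[1:])):
            raise ValueError(
                f"patient {self.patient_id!r}: point indices must strictly increase"
            )

    def __len__(self) -> int:
        return len(self.observations)


@dataclass
class Cohort:
    series: list[PatientSeries]
    ranges: dict[str, ReferenceRange] = field(default_factory=default_ranges)

    def __len__(self) -> int:
        return len(self.series)

    def patient(self, patient_id: str) -> PatientSeries:
        for s in self.series:
            if s.patient_id == patient_id:
                return s
        raise KeyError(patient_id)


def read_cohort(path, ranges: Optional[Mapping[str, ReferenceRange]] = None) -> Cohort:
    """Read a long-format cohort CSV into a :class:`Cohort`.

    Header: ``patient_id, point_index[, time_days], <analytes...>[, state]``.
    When ``time_days`` is absent, unit spacing per point index is assumed
    (the state predictor needs a time denominator). Rows failing validation
    are collected and raised together as :class:`RowValidationError`; they
    are never silently dropped.
    """
    ranges = dict(ranges) if ranges is not None else default_ranges()
    try:
        # only a truly empty field counts as missing; tokens like "NA" must
        # surface as row validation errors, not vanish into NaN
        frame = pd.read_csv(path, dtype={"patient_id": str},
                            keep_default_na=False, na_values=[""])
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc

    missing = [c for c in _MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    param_cols = [c for c in frame.columns if c in ALL_PARAMETERS]
    if not param_cols:
        raise FormatError(
            f"{path}: no recognised analyte column among {ALL_PARAMETERS}"
        )
    has_time = "time_days" in frame.columns
    has_state = "state" in frame.columns

    problems: list[tuple[int, str]] = []
    rows: list[tuple[str, int, float, dict, Optional[int]]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        rec = row._asdict()
        try:
            point = int(rec["point_index"])
        except (TypeError, ValueError):
            problems.append((i, f"non-integer point_index {rec['point_index']!r}"))
            continue
        panel: dict[str, float] = {}
        bad = False
        for col in param_cols:
            raw = rec[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue  # genuinely missing value: omitted from the panel
            try:
                val = float(raw)
            except (TypeError, ValueError):
                problems.append((i, f"non-numeric value {raw!r} for {col}"))
                bad = True
                continue
            if not math.isfinite(val) or val <= 0:
                problems.append((i, f"non-positive or non-finite {col} = {raw!r}"))
                bad = True
                continue
            panel[col] = val
        if has_time:
            try:
                t = float(rec["time_days"])
            except (TypeError, ValueError):
                problems.append((i, f"non-numeric time_days {rec['time_days']!r}"))
                bad = True
                t = float("nan")
        else:
            t = float(point - 1)  # unit spacing per step
        state: Optional[int] = None
        if has_state:
            raw = rec["state"]
            if raw is not None and not (isinstance(raw, float) and math.isnan(raw)):
                try:
                    state = int(raw)
                except (TypeError, ValueError):
                    problems.append((i, f"non-integer state {raw!r}"))
                    bad = True
        if not bad:
            rows.append((str(rec["patient_id"]), point, t, panel, state))

    if problems:
        raise RowValidationError(problems)

    by_patient: dict[str, list[TemporalObservation]] = {}
    seen: set[tuple[str, int]] = set()
    dupes: list[tuple[int, str]] = []
    for i, (pid, point, t, panel, state) in enumerate(rows, start=1):
        if (pid, point) in seen:
            dupes.append((i, f"duplicate (patient_id, point_index) = ({pid}, {point})"))
            continue
        seen.add((pid, point))
        by_patient.setdefault(pid, []).append(
            TemporalObservation(pid, point, t, panel, state)
        )
    if dupes:
        raise RowValidationError(dupes)

    series = []
    for pid, obs in by_patient.items():
        obs.sort(key=lambda o: o.time)
        t0 = obs[0].time
        for o in obs:
            o.time = o.time - t0  # re-anchor to days since first observation
        series.append(PatientSeries(pid, obs))
    return Cohort(series, ranges)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to the long-format CSV (inverse of read_cohort)."""
    params = [p for p in ALL_PARAMETERS
              if any(p in o.panel for s in cohort.series for o in s.observations)]
    has_state = any(o.observed_state is not None
                    for s in cohort.series for o in s.observations)
    records = []
    for s in cohort.series:
        for o in s.observations:
            rec = {"patient_id": o.patient_id, "point_index": o.point_index,
                   "time_days": o.time}
            for p in params:
                rec[p] = o.panel.get(p, "")
            if has_state:
                rec["state"] = "" if o.observed_state is None else o.observed_state
            records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def normalize_panel(panel: Mapping[str, float],
                    ranges: Mapping[str, ReferenceRange]) -> dict[str, float]:
    """Affine range normalization: v -> (v - mid) / halfwidth.

    Values inside the reference interval land in [-1, 1]; the midpoint maps
    to 0. Order-preserving per analyte.
    """
    out = {}
    for name, value in panel.items():
        rng = ranges.get(name)
        if rng is None:
            raise ConfigurationError(f"no reference range configured for {name!r}")
        out[name] = (value - rng.midpoint) / rng.halfwidth
    return out


def denormalize_panel(panel: Mapping[str, float],
                      ranges: Mapping[str, ReferenceRange]) -> dict[str, float]:
    """Inverse of :func:`normalize_panel`: x -> mid + halfwidth * x."""
    out = {}
    for name, value in panel.items():
        rng = ranges.get(name)
        if rng is None:
            raise ConfigurationError(f"no reference range configured for {name!r}")
        out[name] = rng.midpoint + rng.halfwidth * value
    return out


def discretize_panel(panel: Mapping[str, float],
                     ranges: Mapping[str, ReferenceRange]) -> dict[str, str]:
    """Categorize each analyte as LOW / NORMAL / HIGH against its range.

    Boundary values are NORMAL (closed interval). Consistent with
    normalization: HIGH iff normalized value > 1, LOW iff < -1.
    """
    out = {}
    for name, value in panel.items():
        rng = ranges.get(name)
        if rng is None:
            raise ConfigurationError(f"no reference range configured for {name!r}")
        if value < rng.low:
            out[name] = "LOW"
        elif value > rng.high:
            out[name] = "HIGH"
        else:
            out[name] = "NORMAL"
    return out


def observation_items(obs: TemporalObservation,
                      ranges: Mapping[str, ReferenceRange],
                      include_state: bool = True) -> frozenset[str]:
    """Item tokens ``<PANEL>_<Param>=<CATEGORY>`` (plus ``STATE=<s>``) for
    one observation, in the mined-rule vocabulary."""
    cats = discretize_panel(obs.panel, ranges)
    items = {f"{ITEM_PREFIX[p]}={c}" for p, c in cats.items() if p in ITEM_PREFIX}
    if include_state and obs.observed_state is not None:
        items.add(f"STATE={obs.observed_state}")
    return frozenset(items)
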