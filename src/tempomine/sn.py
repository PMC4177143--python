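"""Trajectory-derivative disease-state prediction (the SN predictor).

The predictor walks a patient's temporal points in order and asks, at each
new point T_k, whether the panel trajectory has stayed consistent with its
previous course or has broken direction. Concretely:

* At each point a *derivative vector* J_k is formed over the selected
  analytes (creatinine, BUN, SGOT, SGPT by default) in range-normalized
  space: for k >= 2 the finite-difference rate (P_k - P_{k-1}) / dt; at the
  baseline point, which has no predecessor, the normalized panel values
  themselves (deviation from the reference midpoints, dt = 1) so that the
  known initial state anchors the walk.
* Consecutive derivative vectors, re-scaled by their time increments
  (dx = J_{k-1} dt_{k-1}, dy = J_k dt_k — i.e. the realized normalized
  displacement over each interval), span a parallelogram whose area dA is
  the decision statistic. Collinear displacements (a trajectory continuing
  on course) give dA = 0; a direction break gives dA proportional to the
  transverse component of the new displacement.
* dA at or below a threshold θ means the state persists; above θ the
  state is advanced by one (progression).

With two selected analytes dA is the absolute 2x2 cross-product
determinant |dx1 dy2 - dx2 dy1|; with p analytes it is the Gram-determinant
generalization sqrt(|dx|^2 |dy|^2 - (dx . dy)^2), the parallelogram area in
p-space. θ is calibrated from labelled (dA, persisted) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InsufficientDataError, UndefinedInputError
from .records import PatientSeries, ReferenceRange, normalize_panel

#: Fixed analyte order (c, b, s, g) for derivative components.
SELECTED_PARAMETERS = ("creatinine", "bun", "sgot", "sgpt")


@dataclass(frozen=True)
class DerivativeVector:
    point_index: int
    components: np.ndarray  # one entry per selected analyte, fixed order
    dt: float  # time increment the derivative spans (1.0 at baseline)


@dataclass(frozen=True)
class DifferentialArea:
    pair: tuple[int, int]  # (k-1, k) point indices
    dA: float
    dx: np.ndarray  # J_{k-1} * dt_{k-1}
    dy: np.ndarray  # J_k * dt_k


@dataclass(frozen=True)
class StatePrediction:
    point_index: int
    predicted_state: int
    anchor_state: int
    dA: float
    threshold: float


def _observation_at(series: PatientSeries, k: int):
    for pos, obs in enumerate(series.observations):
        if obs.point_index == k:
            return pos, obs
    raise IndexError(
        f"patient {series.patient_id!r} has no temporal point {k} "
        f"(available: {[o.point_index for o in series.observations]})")


def _normalized_vector(obs, ranges, parameters) -> np.ndarray:
    missing = [p for p in parameters if p not in obs.panel]
    if missing:
        raise UndefinedInputError(
            f"patient {obs.patient_id!r} point {obs.point_index}: "
            f"missing selected parameter(s) {missing}; point unusable for prediction")
    norm = normalize_panel({p: obs.panel[p] for p in parameters}, ranges)
    return np.array([norm[p] for p in parameters], dtype=float)


def derivative_at(series: PatientSeries, k: int,
                  ranges: Mapping[str, ReferenceRange],
                  parameters: Sequence[str] = SELECTED_PARAMETERS,
                  ) -> DerivativeVector:
    """Finite-difference derivative of the normalized panel at point k.

    For k with a predecessor: (P_k - P_{k-1}) / dt per analyte, dt being
    the elapsed days. At the series' first point: the normalized values
    themselves with dt = 1 (deviation from the reference midpoint — the
    baseline anchor that the known initial state is mapped onto).
    """
    pos, obs = _observation_at(series, k)
    vec = _normalized_vector(obs, ranges, parameters)
    if pos == 0:
        return DerivativeVector(k, vec, 1.0)
    prev = series.observations[pos - 1]
    dt = obs.time - prev.time
    if dt <= 0:
        raise ValueError(
            f"patient {obs.patient_id!r}: non-positive time increment "
            f"{dt} into point {k}")
    prev_vec = _normalized_vector(prev, ranges, parameters)
    return DerivativeVector(k, (vec - prev_vec) / dt, dt)


def wedge_area(dx: np.ndarray, dy: np.ndarray) -> float:
    """Parallelogram area spanned by two p-vectors (p >= 2):
    sqrt(|dx|^2 |dy|^2 - (dx . dy)^2).

    Equals the absolute 2x2 determinant for p = 2; zero iff the vectors
    are linearly dependent.
    """
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    if dx.shape != dy.shape:
        raise ValueError(f"shape mismatch: {dx.shape} vs {dy.shape}")
    if dx.ndim != 1 or dx.size < 2:
        raise ValueError(f"need 1-d vectors of dimension >= 2, got shape {dx.shape}")
    # evaluated as |dx| * |dy - proj_dx(dy)| (one Gram-Schmidt step), which
    # is algebraically the Gram-determinant root but numerically stable for
    # nearly collinear vectors
    nx2 = float(dx @ dx)
    if nx2 == 0.0:
        return 0.0
    residual = dy - (float(dx @ dy) / nx2) * dx
    return float(np.sqrt(nx2) * np.linalg.norm(residual))


def differential_area(series: PatientSeries, k: int,
                      ranges: Mapping[str, ReferenceRange],
                      parameters: Sequence[str] = SELECTED_PARAMETERS,
                      ) -> DifferentialArea:
    """dA between point k and its predecessor.

    The two derivative vectors are re-scaled by their own time increments
    (dx = J_{k-1} dt_{k-1}, dy = J_k dt_k), so dA depends on the realized
    normalized displacements, not on the visit spacing: doubling both
    intervals with the same raw changes leaves dA unchanged.
    """
    pos, _ = _observation_at(series, k)
    if pos == 0:
        raise IndexError(f"point {k} is the series baseline; no predecessor pair")
    prev_k = series.observations[pos - 1].point_index
    j_prev = derivative_at(series, prev_k, ranges, parameters)
    j_cur = derivative_at(series, k, ranges, parameters)
    dx = j_prev.components * j_prev.dt
    dy = j_cur.components * j_cur.dt
    return DifferentialArea((prev_k, k), wedge_area(dx, dy), dx, dy)


def predict_state(anchor_state: int, dA: float, threshold: float,
                  point_index: int = 0) -> StatePrediction:
    """Persist/progress decision: dA <= θ keeps the anchor state, dA > θ
    advances it by one."""
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    if dA < 0:
        raise ValueError(f"dA must be >= 0, got {dA}")
    predicted = anchor_state if dA <= threshold else anchor_state + 1
    return StatePrediction(point_index, predicted, anchor_state, dA, threshold)


def calibrate_threshold(labelled_pairs: Iterable[tuple[float, bool]]) -> float:
    """Choose θ from labelled (dA, persisted) pairs.

    When the classes are separable, θ is the midpoint between the largest
    persisting dA and the smallest progressing dA (with no progressing
    pairs, θ = max persisting dA; with no persisting pairs, the lower end
    is taken as 0). Otherwise an exhaustive scan over candidate cut points
    picks the θ with fewest misclassifications, ties resolved toward the
    smallest θ.
    """
    pairs = [(float(d), bool(p)) for d, p in labelled_pairs]
    if not pairs:
        raise UndefinedInputError("cannot calibrate a threshold from no pairs")
    persisting = [d for d, p in pairs if p]
    progressing = [d for d, p in pairs if not p]
    if not progressing:
        return max(persisting)
    max_persist = max(persisting) if persisting else 0.0
    min_progress = min(progressing)
    if max_persist < min_progress:
        return 0.5 * (max_persist + min_progress)
    candidates = sorted({0.0, *(d for d, _ in pairs)})
    best_theta, best_err = None, None
    for theta in candidates:
        err = sum(1 for d, p in pairs if (d <= theta) != p)
        if best_err is None or err < best_err:
            best_theta, best_err = theta, err
    return best_theta


def predict_series(series: PatientSeries, threshold: float,
                   ranges: Mapping[str, ReferenceRange],
                   anchor: Optional[int] = None,
                   parameters: Sequence[str] = SELECTED_PARAMETERS,
                   evaluation_mode: bool = False,
                   ) -> list[StatePrediction]:
    """Sequential prediction along one patient's series.

    The baseline state S_1 is taken from ``anchor`` (or the baseline's
    observed state). For each later point, dA against the previous point
    decides persist/progress from the anchor state — the previous
    *prediction* when chaining (deployment), or the previous *observed*
    state where available in ``evaluation_mode`` (each point is then judged
    one step ahead of ground truth, mirroring evaluation against a hidden
    final state). Predictions never look past the predicted point.
    """
    usable = series.observations
    if len(usable) < 2:
        raise InsufficientDataError(
            f"patient {series.patient_id!r}: need >= 2 temporal points, "
            f"have {len(usable)}")
    if anchor is None:
        anchor = usable[0].observed_state
    if anchor is None:
        raise InsufficientDataError(
            f"patient {series.patient_id!r}: baseline state unknown and no anchor given")

    predictions: list[StatePrediction] = []
    current = int(anchor)
    for prev_obs, obs in zip(usable, usable[1:]):
        if evaluation_mode and prev_obs.observed_state is not None:
            current = int(prev_obs.observed_state)
        area = differential_area(series, obs.point_index, ranges, parameters)
        pred = predict_state(current, area.dA, threshold, obs.point_index)
        predictions.append(pred)
        current = pred.predicted_state
    return predictions


def labelled_pairs(cohort_series: Iterable[PatientSeries],
                   ranges: Mapping[str, ReferenceRange],
                   parameters: Sequence[str] = SELECTED_PARAMETERS,
                   ) -> list[tuple[float, bool]]:
    """Extract (dA, persisted) calibration pairs from series with observed
    states at consecutive points; input for :func:`calibrate_threshold`."""
    out = []
    for series in cohort_series:
        for prev_obs, obs in zip(series.observations, series.observations[1:]):
            if prev_obs.observed_state is None or obs.observed_state is None:
                continue
            area = differential_area(series, obs.point_index, ranges, parameters)
            out.append((area.dA, obs.observed_state == prev_obs.observed_state))
    return out
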