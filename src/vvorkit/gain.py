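"""Directional VVOR gain by area-under-curve and scatter-plot-slope methods.

Both methods first split the desaccaded trace by head-movement direction
(sign of head velocity) into contiguous runs, then estimate per-direction
gain — the ratio of compensatory eye velocity to head velocity:

* **AUC**: trapezoidal integrals of eye and head velocity are accumulated
  run by run (using the actual time stamps) and the gain is the ratio of the
  summed eye area to the summed head area.
* **SCP**: a no-intercept least-squares fit of eye on head velocity over all
  samples of the direction; the gain is the slope
  (``slope = sum(h*e) / sum(h**2)``).

A compensatory response (eye opposing head) yields **positive** gain under
both methods; an anti-compensatory response yields a negative gain, which is
reported as-is, never clipped — its sign is diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDirectionError, ParameterError
from .preprocess import DesaccadedTrace

#: Below this absolute summed head area (deg) a direction is degenerate.
MIN_HEAD_AREA = 1e-9


@dataclass
class DirectionalSubset:
    """Contiguous runs of samples with positive / negative head velocity.

    Samples with head velocity exactly zero belong to neither direction.
    Runs shorter than 2 samples are discarded (a single point supports
    neither a trapezoid nor a slope).
    """

    pos_runs: list[slice]
    neg_runs: list[slice]

    def runs(self, direction: str) -> list[slice]:
        return self.pos_runs if direction == "pos" else self.neg_runs


@dataclass
class GainResult:
    """Directional gains for one method ("AUC" or "SCP")."""

    method: str
    g_pos: float
    g_neg: float
    n_runs_pos: int
    n_runs_neg: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.g_pos) and np.isfinite(self.g_neg)):
            raise ParameterError(f"{self.method} gains must be finite")


def _sign_runs(mask: np.ndarray) -> list[slice]:
    """Maximal runs of True in mask, as slices, keeping runs of length >= 2."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [slice(a, b) for a, b in zip(starts, stops) if b - a >= 2]


def split_directions(dtrace: DesaccadedTrace) -> DirectionalSubset:
    """Split into positive- and negative-direction runs by head-velocity sign.

    Raises :class:`DegenerateDirectionError` naming the direction if either
    subset has no usable run.
    """
    head = dtrace.head_vel
    pos = _sign_runs(head > 0)
    neg = _sign_runs(head < 0)
    if not pos:
        raise DegenerateDirectionError("no usable positive-direction (head > 0) runs")
    if not neg:
        raise DegenerateDirectionError("no usable negative-direction (head < 0) runs")
    return DirectionalSubset(pos_runs=pos, neg_runs=neg)


def _auc_direction(dtrace: DesaccadedTrace, runs: list[slice], label: str) -> float:
    t, head, eye = dtrace.t, dtrace.head_vel, dtrace.eye_filtered
    head_area = sum(np.trapezoid(head[r], t[r]) for r in runs)
    eye_area = sum(np.trapezoid(eye[r], t[r]) for r in runs)
    if abs(head_area) < MIN_HEAD_AREA:
        raise DegenerateDirectionError(f"{label} head area ~ 0; gain undefined")
    return -eye_area / head_area


def auc_gain(dtrace: DesaccadedTrace, subset: DirectionalSubset | None = None) -> GainResult:
    """Area-under-curve gain per direction.

    Integration is trapezoidal over each contiguous run separately (never
    across run boundaries, which would fabricate spurious trapezoids) using
    the recorded time stamps; signed run integrals are summed per channel and
    the gain is ``-(sum eye areas) / (sum head areas)``.
    """
    if subset is None:
        subset = split_directions(dtrace)
    return GainResult(
        method="AUC",
        g_pos=_auc_direction(dtrace, subset.pos_runs, "positive-direction"),
        g_neg=_auc_direction(dtrace, subset.neg_runs, "negative-direction"),
        n_runs_pos=len(subset.pos_runs),
        n_runs_neg=len(subset.neg_runs),
    )


def _scp_direction(dtrace: DesaccadedTrace, runs: list[slice], label: str) -> float:
    idx = np.concatenate([np.arange(r.start, r.stop) for r in runs])
    if idx.size < 3:
        raise DegenerateDirectionError(f"{label} has fewer than 3 samples")
    h = dtrace.head_vel[idx]
    e = dtrace.eye_filtered[idx]
    denom = float(np.dot(h, h))
    if denom == 0.0:
        raise DegenerateDirectionError(f"{label} head velocities all zero")
    return -float(np.dot(h, e)) / denom

def scp_gain(dtrace: DesaccadedTrace, subset: DirectionalSubset | None = None) -> GainResult:
    """Scatter-plot slope gain per direction (no-intercept least squares)."""
    if subset is None:
        subset = split_directions(dtrace)
    return GainResult(
        method="SCP",
        g_pos=_scp_direction(dtrace, subset.pos_runs, "positive-direction"),
        g_neg=_scp_direction(dtrace, subset.neg_runs, "negative-direction"),
        n_runs_pos=len(subset.pos_runs),
        n_runs_neg=len(subset.neg_runs),
    )
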