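"""Representational similarity across groups with time generalization.

The reference group's trial-averaged RDM series is correlated (Spearman,
over the six below-diagonal RDM entries) with each comparison subject's
RDM series at every time-point combination (t_x, t_y), producing one
square time-generalization matrix per subject. Correlations are
variance-stabilized with the Fisher-z transform before averaging or
testing; the scalar summary is the mean Fisher-z over a closed late
window (600-1200 ms on a 20 ms grid = 31 x 31 = 961 cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .decoding import RDMSeries

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = (600.0, 1200.0)


def average_rdms(series: list[RDMSeries]) -> RDMSeries:
    """Element-wise mean of RDM series on identical grids."""
    if not series:
        raise ValueError("no RDM series to average")
    ref = series[0]
    for s in series[1:]:
        if len(s.times) != len(ref.times) or not np.allclose(s.times, ref.times):
            raise ValueError("RDM series time grids differ")
        if s.conditions != ref.conditions:
            raise ValueError("RDM series condition sets differ")
    values = np.mean([s.values for s in series], axis=0)
    return RDMSeries(times=ref.times.copy(), values=values,
                     conditions=ref.conditions)


def _rank_rows(v: np.ndarray) -> np.ndarray:
    """Average-tie ranks along the last axis."""
    return np.apply_along_axis(stats.rankdata, -1, v)


def spearman_rdm(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation over below-diagonal RDM entries.

    Ties receive average ranks; zero variance in either vector yields NaN
    with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    i, j = np.tril_indices(a.shape[0], k=-1)
    va, vb = a[i, j], b[i, j]
    if np.isnan(va).any() or np.isnan(vb).any():
        raise ValueError("RDMs must be complete below the diagonal")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        warnings.warn("zero variance in RDM entries; Spearman undefined")
        return float("nan")
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)


@dataclass
class TimeGenMatrix:
    """Spearman R (or Fisher-z) between two RDM series at all (t_x, t_y)."""

    times_x: np.ndarray           # reference times, rows
    times_y: np.ndarray           # comparison times, columns
    values: np.ndarray            # (len(times_x), len(times_y))
    subject: str = ""
    session: str = ""
    ear: str = ""
    scale: str = "r"              # "r" | "z"

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times_x), len(self.times_y)):
            raise ValueError("values shape does not match the time grids")


def timegen_similarity(reference: RDMSeries,
                       subjects: list[RDMSeries]) -> list[TimeGenMatrix]:
    """One time-generalization matrix per comparison subject.

    Cell (t_x, t_y) is the Spearman correlation between the reference RDM
    at t_x and the subject RDM at t_y. Computed via rank transform +
    matrix products; per-cell equivalence with :func:`spearman_rdm` is
    exercised in the tests.
    """
    if not subjects:
        raise ValueError("no comparison subjects given")
    for s in subjects:
        if len(s.times) != len(reference.times) or not np.allclose(
            s.times, reference.times
        ):
            raise ValueError("subject grid differs from the reference grid")

    def normalized_ranks(series: RDMSeries) -> np.ndarray:
        v = _rank_rows(series.lower_triangle_vectors())  # (T, n_pairs)
        v = v - v.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(v, axis=1, keepdims=True)
        degenerate = norms[:, 0] == 0
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} time point(s) with zero rank "
                "variance; correlations set to NaN"
            )
        norms[norms == 0] = np.nan
        return v / norms

    R = normalized_ranks(reference)
    out = []
    for s in subjects:
        S = normalized_ranks(s)
        out.append(
            TimeGenMatrix(
                times_x=reference.times.copy(),
                times_y=s.times.copy(),
                # guard against float error pushing |r| past 1
                values=np.clip(R @ S.T, -1.0, 1.0),
                subject=s.subject,
                session=s.session,
                ear=s.ear,
            )
        )
    return out


def fisher_z(r, clamp: float = 1.0 - 1e-7):
    """Fisher z = arctanh(r); |r| at or beyond 1 is clamped (logged)."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr[np.isfinite(r_arr)]) > 1.0 + 1e-9):
        raise ValueError("|r| > 1 is not a correlation")
    clipped = np.clip(r_arr, -clamp, clamp)
    n_clamped = int(np.sum(np.abs(r_arr) >= clamp))
    if n_clamped:
        logger.info("fisher_z clamped %d value(s) at |r| >= %g", n_clamped, clamp)
    z = np.arctanh(clipped)
    return float(z) if np.isscalar(r) or np.ndim(r) == 0 else z


def fisher_z_matrix(m: TimeGenMatrix) -> TimeGenMatrix:
    """Fisher-z transformed copy of a time-generalization matrix."""
    if m.scale == "z":
        raise ValueError("matrix is already on the Fisher-z scale")
    return TimeGenMatrix(
        times_x=m.times_x.copy(),
        times_y=m.times_y.copy(),
        values=fisher_z(m.values),
        subject=m.subject,
        session=m.session,
        ear=m.ear,
        scale="z",
    )


@dataclass
class WindowStat:
    """Mean value over all (t_x, t_y) cells inside a closed window."""

    window_ms: tuple
    mean_z: float
    n_cells: int
    subject: str = ""
    session: str = ""
    ear: str = ""


def window_mean(m: TimeGenMatrix,
                window_ms: tuple = DEFAULT_WINDOW_MS) -> WindowStat:
    """Average all cells with both coordinates inside the closed window."""
    lo, hi = window_ms
    eps = 1e-9
    mx = (m.times_x >= lo - eps) & (m.times_x <= hi + eps)
    my = (m.times_y >= lo - eps) & (m.times_y <= hi + eps)
    if not mx.any() or not my.any():
        raise ValueError(f"window {window_ms} outside the time grid")
    if lo < m.times_x[0] - eps or hi > m.times_x[-1] + eps:
        raise ValueError(f"window {window_ms} extends beyond the grid")
    sub = m.values[np.ix_(mx, my)]
    return WindowStat(
        window_ms=(float(lo), float(hi)),
        mean_z=float(sub.mean()),
        n_cells=int(sub.size),
        subject=m.subject,
        session=m.session,
        ear=m.ear,
    )
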