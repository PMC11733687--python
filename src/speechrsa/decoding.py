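"""Time-resolved within-subject pairwise decoding into RDM series.

At every time point the channel vector of each trial is a pattern; raw
trials of each condition are randomly binned into pseudo-trials (bin
averages) to raise SNR, and every unordered pair of the four comprehension
conditions is classified with a leave-one-pseudo-trial-out linear SVM
(C = 1). Pairwise accuracies (chance 0.5) are averaged over many binning
iterations and aggregated into a 4x4 representational dissimilarity
matrix (RDM) per time point — symmetric, diagonal undefined. The mean of
the six below-diagonal entries is the grand-average decoding accuracy
curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._svm import loo_pair_accuracy, pair_accuracy_over_time
from .epochs import Epochs
from .synthgen import CONDITIONS

logger = logging.getLogger(__name__)

DEFAULT_DT_MS = 20.0
DEFAULT_TIME_RANGE = (-500.0, 1500.0)
SVM_C = 1.0


# ---------------------------------------------------------------------------
# condition pooling


@dataclass
class ConditionScheme:
    """Mapping of the 9 degradation cells to 4 ordered categories.

    The cell with the highest mean comprehension rating is excluded; the
    remaining 8 cells are paired in rating-rank order into the four
    categories from easiest to hardest.
    """

    mapping: dict                 # (bands, cutoff) -> category label
    excluded: tuple               # (bands, cutoff)
    categories: tuple = CONDITIONS

    def __post_init__(self) -> None:
        per_cat = pd.Series(list(self.mapping.values())).value_counts()
        if sorted(self.mapping) != sorted(set(self.mapping)):
            raise ValueError("duplicate cells in mapping")
        if set(per_cat.index) != set(self.categories) or (per_cat != 2).any():
            raise ValueError("each category must pool exactly two cells")
        if self.excluded in self.mapping:
            raise ValueError("excluded cell must not be mapped")


def pool_conditions(ratings: pd.DataFrame,
                    categories: tuple = CONDITIONS) -> ConditionScheme:
    """Rank cells by mean rating, drop the best, pair the rest in order.

    Ties in cell means are broken deterministically by (bands, cutoff)
    lexicographic order and logged.
    """
    needed = {"spectral_level", "temporal_level", "rating"}
    if not needed.issubset(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(needed)}")
    means = (
        ratings.groupby(["spectral_level", "temporal_level"])["rating"]
        .mean()
        .reset_index()
    )
    n_cells = len(means)
    if (n_cells - 1) % 2 or n_cells < 3:
        raise ValueError(f"{n_cells} cells cannot form an excluded cell + pairs")
    if (n_cells - 1) // 2 != len(categories):
        raise ValueError("category count does not match the cell count")
    if means["rating"].duplicated().any():
        logger.warning("tied cell means; tie-broken by (bands, cutoff) order")
    means = means.sort_values(
        by=["rating", "spectral_level", "temporal_level"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    cells = [
        (int(r.spectral_level), float(r.temporal_level))
        for r in means.itertuples()
    ]
    excluded = cells[0]
    mapping = {}
    for c, cat in enumerate(categories):
        for cell in cells[1 + 2 * c: 3 + 2 * c]:
            mapping[cell] = cat
    return ConditionScheme(mapping=mapping, excluded=excluded,
                           categories=tuple(categories))


# ---------------------------------------------------------------------------
# pseudo-trials


@dataclass
class PseudoTrialSet:
    """Bin-averaged pseudo-trials of one condition."""

    data: np.ndarray              # (n_bins, channels, samples)
    assignments: list             # per bin, raw-trial indices
    condition: str = ""

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]


def make_pseudo_trials(trials: np.ndarray, n_bins: int,
                       seed=None, condition: str = "") -> PseudoTrialSet:
    """Randomly partition raw trials into near-equal bins and average them."""
    trials = np.asarray(trials)
    n = trials.shape[0]
    if n < n_bins:
        raise ValueError(f"cannot split {n} trials into {n_bins} bins")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(n)
    bins = np.array_split(order, n_bins)
    data = np.stack([trials[b].mean(axis=0) for b in bins])
    return PseudoTrialSet(data=data, assignments=[b.tolist() for b in bins],
                          condition=condition)


# ---------------------------------------------------------------------------
# decoding


def pairwise_decode_timepoint(A: np.ndarray, B: np.ndarray,
                              C: float = SVM_C) -> float:
    """Leave-one-pseudo-trial-out linear-SVM accuracy for one pair at one t.

    ``A``/``B``: (n_pseudo, n_features) with equal pseudo-trial counts.
    Each fold holds out one pseudo-trial per condition; ties in the
    decision value count as incorrect.
    """
    A = np.ascontiguousarray(A, dtype=np.float64)
    B = np.ascontiguousarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape != B.shape:
        raise ValueError("A and B must be matching (n_pseudo, n_features)")
    if A.shape[0] < 2:
        raise ValueError("need at least two pseudo-trials per condition")
    return float(loo_pair_accuracy(A, B, C))


@dataclass
class RDMSeries:
    """Per-time-point 4x4 dissimilarity matrices (pairwise accuracies)."""

    times: np.ndarray             # ms
    values: np.ndarray            # (T, n_cond, n_cond); NaN diagonal
    conditions: tuple = CONDITIONS
    subject: str = ""
    group: str = ""
    session: str = ""
    ear: str = ""

    def __post_init__(self) -> None:
        T, n, m = self.values.shape
        if n != m or T != len(self.times):
            raise ValueError("values must be (len(times), n_cond, n_cond)")

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    def lower_triangle_vectors(self) -> np.ndarray:
        """(T, n_pairs) below-diagonal entries in fixed row-major pair order."""
        i, j = np.tril_indices(self.n_conditions, k=-1)
        return self.values[:, i, j]

    def to_frame(self) -> pd.DataFrame:
        i, j = np.tril_indices(self.n_conditions, k=-1)
        rows = []
        for t_idx, t in enumerate(self.times):
            for a, b in zip(i, j):
                rows.append(
                    {
                        "time_ms": t,
                        "cond_a": self.conditions[a],
                        "cond_b": self.conditions[b],
                        "accuracy": self.values[t_idx, a, b],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DecodingCurve:
    """Grand-average accuracy over time (mean of below-diagonal entries)."""

    times: np.ndarray
    accuracy: np.ndarray
    chance: float = 0.5
    subject: str = ""
    group: str = ""
    session: str = ""
    ear: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "accuracy": self.accuracy})


def grand_average_accuracy(rdm: np.ndarray) -> float:
    """Mean of the below-diagonal entries of a single symmetric RDM."""
    rdm = np.asarray(rdm, dtype=float)
    i, j = np.tril_indices(rdm.shape[0], k=-1)
    vals = rdm[i, j]
    if np.isnan(vals).any():
        raise ValueError("RDM has missing below-diagonal entries")
    return float(vals.mean())


def decode_timecourse(
    epochs: Epochs,
    conditions: tuple = CONDITIONS,
    n_iter: int = 1000,
    dt_ms: float = DEFAULT_DT_MS,
    seed: int | None = 0,
    n_bins: int = 4,
    time_range: tuple = DEFAULT_TIME_RANGE,
) -> tuple[RDMSeries, DecodingCurve]:
    """Full time-resolved pairwise decoding of one recording.

    For every time point on the analysis grid and every unordered
    condition pair, accuracies are averaged over ``n_iter`` random
    binning iterations. Missing conditions raise an error naming them.
    """
    labels = epochs.trials["condition"].to_numpy()
    cond_trials = []
    for cond in conditions:
        idx = np.flatnonzero(labels == cond)
        if len(idx) == 0:
            raise ValueError(f"condition {cond!r} has no trials")
        cond_trials.append(idx)

    t0, t1 = time_range
    if t0 < epochs.times[0] - 1e-9 or t1 > epochs.times[-1] + 1e-9:
        raise ValueError("time_range outside the epoch window")
    grid = np.arange(t0, t1 + dt_ms / 2, dt_ms)
    sample_idx = np.array([epochs.time_index(t) for t in grid])
    grid = epochs.times[sample_idx]

    data_g = np.ascontiguousarray(epochs.data[:, :, sample_idx])
    n_cond = len(conditions)
    pairs = [(a, b) for a in range(n_cond) for b in range(a)]
    rng = np.random.default_rng(seed)

    acc = np.zeros((len(grid), len(pairs)))
    for _ in range(n_iter):
        pseudo = [
            make_pseudo_trials(data_g[idx], n_bins, seed=rng).data
            for idx in cond_trials
        ]
        for p, (a, b) in enumerate(pairs):
            acc[:, p] += pair_accuracy_over_time(pseudo[a], pseudo[b], SVM_C)
    acc /= n_iter

    values = np.full((len(grid), n_cond, n_cond), np.nan)
    for p, (a, b) in enumerate(pairs):
        values[:, a, b] = acc[:, p]
        values[:, b, a] = acc[:, p]
    meta = dict(subject=epochs.subject, group=epochs.group,
                session=epochs.session, ear=epochs.ear)
    rdms = RDMSeries(times=grid, values=values, conditions=tuple(conditions),
                     **meta)
    curve = DecodingCurve(times=grid, accuracy=acc.mean(axis=1), **meta)
    return rdms, curve


def apply_condition_scheme(epochs: Epochs, scheme: ConditionScheme) -> Epochs:
    """Relabel cell-level trials with pooled categories, dropping the
    excluded cell."""
    needed = {"spectral_level", "temporal_level"}
    if not needed.issubset(epochs.trials.columns):
        raise ValueError("epochs trials lack degradation-cell columns")
    cells = list(
        zip(
            epochs.trials["spectral_level"].astype(int),
            epochs.trials["temporal_level"].astype(float),
        )
    )
    keep = np.array([c in scheme.mapping for c in cells])
    out = epochs.select_trials(keep)
    kept_cells = [c for c, k in zip(cells, keep) if k]
    out.trials = out.trials.assign(
        condition=[scheme.mapping[c] for c in kept_cells]
    )
    return out
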