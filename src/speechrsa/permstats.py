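"""Non-parametric inference for one-sample curves and matrices.

Implements maximum-cluster-size sign-permutation tests (1D over time, 2D
over time x time), a permutation repeated-measures F-test for a session
effect, permutation paired t-tests with Bonferroni-adjusted alpha, and
paired Cohen's d.

The sign-flip unit is always an entire subject curve/matrix: under the
one-sample null the subject-level deviations from mu0 are symmetric, so
flipping whole subjects generates the exchangeable null. With n <= 12
subjects all 2^n flips are enumerated; otherwise flips are sampled and
the observed assignment is counted into the null set, so every p-value is
at least 1/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

EXHAUSTIVE_LIMIT = 4096  # enumerate all sign flips when 2^n <= this


# ---------------------------------------------------------------------------
# helpers


def _sign_flip_matrix(n: int, n_perm: int | None, rng: np.random.Generator,
                      exhaustive: bool | None = None) -> tuple[np.ndarray, bool]:
    """(P, n) matrix of +-1 flips; exhaustive enumeration when feasible."""
    if exhaustive is None:
        exhaustive = 2**n <= EXHAUSTIVE_LIMIT
    if exhaustive:
        bits = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
        return 1.0 - 2.0 * bits, True
    if n_perm is None:
        raise ValueError("n_perm required when not exhaustive")
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n))
    return flips, False


def _t_for_flips(d: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t statistics of sign-flipped data, vectorized.

    ``d``: (n_subjects, ...) deviations from mu0, flattened over trailing
    axes; ``flips``: (P, n_subjects). Returns (P, n_points). Sign flips
    leave sum(d^2) unchanged, which makes the permutation variance cheap.
    """
    n = d.shape[0]
    dd = d.reshape(n, -1)
    sumsq = np.sum(dd**2, axis=0)                       # (points,)
    mean = flips @ dd / n                               # (P, points)
    var = (sumsq[None, :] - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    t[~np.isfinite(t)] = 0.0                            # zero-variance points
    return t


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of a 1D mask as (start, stop) index pairs."""
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Per-row maximum run length of a (P, T) boolean matrix."""
    P, T = masks.shape
    padded = np.zeros((P, T + 2), dtype=np.int8)
    padded[:, 1:-1] = masks
    d = np.diff(padded, axis=1)
    starts = np.argwhere(d == 1)
    stops = np.argwhere(d == -1)
    out = np.zeros(P, dtype=np.int64)
    if len(starts):
        np.maximum.at(out, starts[:, 0], stops[:, 1] - starts[:, 1])
    return out


# ---------------------------------------------------------------------------
# results


@dataclass
class Cluster:
    indices: tuple                # run bounds (1D) or cell index arrays (2D)
    size: int
    p_value: float
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_threshold: float
    null_max_sizes: np.ndarray
    n_permutations: int
    exhaustive: bool
    cluster_alpha: float
    alpha: float

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)


@dataclass
class PermTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    effect_size: float | None = None
    alpha_adjusted: float | None = None
    exhaustive: bool = False
    significant: bool | None = field(default=None)


# ---------------------------------------------------------------------------
# cluster tests


def _cluster_pvalues(observed_sizes, null_max, exhaustive):
    P = len(null_max)
    ps = []
    for size in observed_sizes:
        count = int(np.sum(null_max >= size))
        # the observed assignment is part of the null set: under exhaustive
        # enumeration it is one of the flips, otherwise it is added in
        ps.append(count / P if exhaustive else (count + 1) / (P + 1))
    return ps


def cluster_test_1d(data: np.ndarray, mu0: float = 0.5,
                    cluster_alpha: float = 0.05, alpha: float = 0.05,
                    n_perm: int | None = None, seed: int | None = 0,
                    exhaustive: bool | None = None) -> ClusterResult:
    """Right-tailed maximum-cluster-size sign-permutation test over time.

    ``data`` is (subjects, time). Per time point a one-sample t against
    ``mu0`` is computed; points above the one-sided t critical value at
    ``cluster_alpha`` form contiguous clusters, and each observed
    cluster's size is compared to the permutation null of the maximum
    cluster size obtained by flipping whole subject curves.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("data must be (subjects >= 2, time)")
    n, T = data.shape
    d = data - mu0
    tcrit = stats.t.ppf(1.0 - cluster_alpha, df=n - 1)
    rng = np.random.default_rng(seed)
    flips, is_exh = _sign_flip_matrix(n, n_perm, rng, exhaustive)

    t_obs = _t_for_flips(d, np.ones((1, n)))[0]
    obs_runs = _runs(t_obs > tcrit)
    t_null = _t_for_flips(d, flips)
    null_max = _max_run_lengths(t_null > tcrit)

    sizes = [stop - start for start, stop in obs_runs]
    ps = _cluster_pvalues(sizes, null_max, is_exh)
    clusters = [
        Cluster(indices=(start, stop), size=size, p_value=p,
                significant=p < alpha)
        for (start, stop), size, p in zip(obs_runs, sizes, ps)
    ]
    return ClusterResult(
        clusters=clusters, t_threshold=float(tcrit), null_max_sizes=null_max,
        n_permutations=len(flips), exhaustive=is_exh,
        cluster_alpha=cluster_alpha, alpha=alpha,
    )


_CONN4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _max_component(mask2d: np.ndarray) -> int:
    lab, n = ndimage.label(mask2d, structure=_CONN4)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_test_2d(data: np.ndarray, mu0: float = 0.0,
                    cluster_alpha: float = 0.05, alpha: float = 0.05,
                    n_perm: int | None = None, seed: int | None = 0,
                    exhaustive: bool | None = None) -> ClusterResult:
    """As :func:`cluster_test_1d` on (subjects, rows, cols) data, with
    clusters as 4-connected components of supra-threshold cells."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[0] < 2:
        raise ValueError("data must be (subjects >= 2, rows, cols)")
    n, R, Ccols = data.shape
    d = data - mu0
    tcrit = stats.t.ppf(1.0 - cluster_alpha, df=n - 1)
    rng = np.random.default_rng(seed)
    flips, is_exh = _sign_flip_matrix(n, n_perm, rng, exhaustive)

    t_obs = _t_for_flips(d, np.ones((1, n)))[0].reshape(R, Ccols)
    lab, n_clu = ndimage.label(t_obs > tcrit, structure=_CONN4)
    obs = [(np.argwhere(lab == k), int(np.sum(lab == k)))
           for k in range(1, n_clu + 1)]

    t_null = _t_for_flips(d, flips).reshape(len(flips), R, Ccols)
    null_max = np.array([_max_component(tp > tcrit) for tp in t_null])

    ps = _cluster_pvalues([size for _, size in obs], null_max, is_exh)
    clusters = [
        Cluster(indices=tuple(map(tuple, cells)), size=size, p_value=p,
                significant=p < alpha)
        for (cells, size), p in zip(obs, ps)
    ]
    return ClusterResult(
        clusters=clusters, t_threshold=float(tcrit), null_max_sizes=null_max,
        n_permutations=len(flips), exhaustive=is_exh,
        cluster_alpha=cluster_alpha, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# permutation F / t tests


def _rm_anova_f(data: np.ndarray) -> float:
    """Classical repeated-measures F for a (subjects, sessions) table."""
    n, k = data.shape
    grand = data.mean()
    subj = data.mean(axis=1, keepdims=True)
    sess = data.mean(axis=0, keepdims=True)
    ss_sess = n * float(np.sum((sess - grand) ** 2))
    resid = data - subj - sess + grand
    ss_err = float(np.sum(resid**2))
    df_sess = k - 1
    df_err = (n - 1) * (k - 1)
    if ss_err == 0.0:
        warnings.warn("zero residual variance; F degenerate")
        return np.inf if ss_sess > 0 else 0.0
    return (ss_sess / df_sess) / (ss_err / df_err)


def perm_rm_anova(data: np.ndarray, n_perm: int = 10000,
                  seed: int | None = 0) -> PermTestResult:
    """Permutation repeated-measures F-test for a session effect.

    The null permutes session labels independently within each subject;
    p is the proportion of null F >= observed, observed included.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("data must be (subjects >= 2, sessions >= 2)")
    if np.isnan(data).any():
        raise ValueError("complete data required")
    f_obs = _rm_anova_f(data)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permuted(data, axis=1)
        if _rm_anova_f(perm) >= f_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermTestResult(statistic=float(f_obs), p_value=float(p),
                          n_permutations=n_perm)


def _paired_t(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0.0:
        return 0.0
    return float(d.mean() / (sd / np.sqrt(len(d))))


def perm_paired_t(x: np.ndarray, y: np.ndarray, n_perm: int = 10000,
                  alpha_adjusted: float = 0.05,
                  seed: int | None = 0) -> PermTestResult:
    """Two-sided permutation paired t-test via sign flips of differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors (n >= 2)")
    d = x - y
    t_obs = _paired_t(d)
    if np.all(d == 0):
        return PermTestResult(statistic=0.0, p_value=1.0,
                              n_permutations=0, effect_size=0.0,
                              alpha_adjusted=alpha_adjusted,
                              exhaustive=True, significant=False)
    rng = np.random.default_rng(seed)
    flips, is_exh = _sign_flip_matrix(len(d), n_perm, rng)
    t_null = _t_for_flips(d[:, None], flips)[:, 0]
    count = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-12))
    p = count / len(flips) if is_exh else (count + 1) / (len(flips) + 1)
    dz = cohens_d_paired(x, y)
    return PermTestResult(
        statistic=t_obs, p_value=float(p), n_permutations=len(flips),
        effect_size=dz, alpha_adjusted=alpha_adjusted, exhaustive=is_exh,
        significant=p < alpha_adjusted,
    )


def cohens_d_paired(x: np.ndarray, y: np.ndarray) -> float:
    """Paired Cohen's d: mean difference over SD of differences (n-1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors (n >= 2)")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0
        warnings.warn("zero SD of differences; Cohen's d undefined")
        return float("nan")
    return float(d.mean() / sd)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-comparison alpha."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m
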