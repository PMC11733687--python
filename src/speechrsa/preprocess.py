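"""Epoch-level cleaning.

Covers the cleaning contracts of the pipeline: zero-phase band-pass and
line-noise notch filtering, automatic trial rejection by a channel-summed
z-score, second-order blind identification (SOBI) for implant-artefact
suppression, detection/removal of onset- and offset-spike components, and
plain ERP averaging as a data-quality sanity check.

SOBI separates sources with distinct temporal autocorrelation by
whitening the data and approximately joint-diagonalizing a set of
time-lagged covariance matrices with iterated Jacobi rotations
(Cardoso-Souloumiac scheme).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .epochs import Epochs

logger = logging.getLogger(__name__)

DEFAULT_SOBI_LAGS = tuple(range(1, 51))  # 2-100 ms at 500 Hz


# ---------------------------------------------------------------------------
# filtering


def bandpass_epochs(epochs: Epochs, lo: float, hi: float,
                    notch: float | None = None) -> Epochs:
    """Zero-phase band-pass (Butterworth) with optional line-noise notch."""
    if not (0 < lo < hi < epochs.fs / 2):
        raise ValueError(f"need 0 < lo < hi < Nyquist, got ({lo}, {hi})")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=epochs.fs, output="sos")
    out = epochs.copy()
    out.data = sps.sosfiltfilt(sos, out.data, axis=-1)
    if notch is not None:
        if not (0 < notch < epochs.fs / 2):
            raise ValueError("notch frequency must be below Nyquist")
        b, a = sps.iirnotch(notch, Q=30.0, fs=epochs.fs)
        out.data = sps.filtfilt(b, a, out.data, axis=-1)
    return out


# ---------------------------------------------------------------------------
# automatic artefact rejection


@dataclass
class ArtifactReport:
    """Outcome of z-value trial rejection."""

    scores: np.ndarray          # per-trial max channel-summed z
    threshold: float
    rejected: np.ndarray        # indices into the input trial order

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def zvalue_trial_scores(data: np.ndarray) -> np.ndarray:
    """Per-trial artefact score.

    Each sample is z-scored against its channel's mean/SD pooled over all
    trials; z-values are summed over channels, normalized by sqrt(C), and
    a trial's score is the maximum over its samples. Zero-variance
    channels contribute zero (with a warning).
    """
    n_trials, n_channels, _ = data.shape
    mu = data.mean(axis=(0, 2), keepdims=True)
    sd = data.std(axis=(0, 2), keepdims=True)
    if np.any(sd == 0):
        warnings.warn("zero-variance channel(s); they contribute z = 0")
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (data - mu) / safe_sd
    z = np.where(sd == 0, 0.0, z)
    zsum = z.sum(axis=1) / np.sqrt(n_channels)   # (trials, samples)
    return zsum.max(axis=1)


def zvalue_artifact_reject(epochs: Epochs, threshold: float
                           ) -> tuple[Epochs, ArtifactReport]:
    """Drop trials whose z-value score exceeds ``threshold``."""
    if epochs.n_trials < 2:
        raise ValueError("need at least two trials to estimate channel stats")
    scores = zvalue_trial_scores(epochs.data)
    rejected = np.flatnonzero(scores > threshold)
    keep = np.setdiff1d(np.arange(epochs.n_trials), rejected)
    report = ArtifactReport(scores=scores, threshold=threshold, rejected=rejected)
    logger.info("z-rejection at %.0f: dropped %d/%d trials",
                threshold, len(rejected), epochs.n_trials)
    return epochs.select_trials(keep), report


# ---------------------------------------------------------------------------
# SOBI


@dataclass
class UnmixingModel:
    """Linear unmixing fitted by SOBI.

    ``unmixing`` rows are unit-norm component filters (components x
    channels); ``mixing`` is the pseudo-inverse (channels x components);
    components are ordered by decreasing variance in the data.
    """

    unmixing: np.ndarray
    mixing: np.ndarray
    lags: tuple
    component_variances: np.ndarray
    rank: int = field(default=0)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def activations(self, data: np.ndarray) -> np.ndarray:
        """Component time courses, (trials, components, samples)."""
        return np.einsum("kc,tcs->tks", self.unmixing, data)


def joint_diagonalize(matrices: np.ndarray, tol: float = 1e-10,
                      max_sweeps: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Approximate joint diagonalization by iterated Jacobi rotations.

    Returns ``(V, rotated)`` where ``V`` is orthogonal and ``rotated[l] =
    V.T @ matrices[l] @ V`` is as diagonal as possible in the
    least-squares sense. For a single symmetric matrix this is the
    classical Jacobi eigendecomposition. Sweeps stop when every rotation
    angle falls below ``tol``.
    """
    M = np.array(matrices, dtype=float, copy=True)
    if M.ndim == 2:
        M = M[None]
    L, k, _ = M.shape
    V = np.eye(k)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(k - 1):
            for q in range(p + 1, k):
                # closed-form optimal Givens rotation (Cardoso-Souloumiac)
                g1 = M[:, p, p] - M[:, q, q]
                g2 = M[:, p, q] + M[:, q, p]
                ton = g1 @ g1 - g2 @ g2
                toff = 2.0 * (g1 @ g2)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) <= tol:
                    continue
                biggest = max(biggest, abs(s))
                rows_p, rows_q = M[:, p, :].copy(), M[:, q, :].copy()
                M[:, p, :] = c * rows_p + s * rows_q
                M[:, q, :] = -s * rows_p + c * rows_q
                cols_p, cols_q = M[:, :, p].copy(), M[:, :, q].copy()
                M[:, :, p] = c * cols_p + s * cols_q
                M[:, :, q] = -s * cols_p + c * cols_q
                vp, vq = V[:, p].copy(), V[:, q].copy()
                V[:, p] = c * vp + s * vq
                V[:, q] = -s * vp + c * vq
        if biggest <= tol:
            break
    return V, M


def off_diagonal_energy(matrices: np.ndarray) -> float:
    """Sum of squared off-diagonal entries (SOBI objective)."""
    M = np.asarray(matrices, dtype=float)
    if M.ndim == 2:
        M = M[None]
    mask = ~np.eye(M.shape[1], dtype=bool)
    return float(np.sum(M[:, mask] ** 2))


def sobi_unmix(epochs: Epochs, lags=DEFAULT_SOBI_LAGS,
               rank_tol: float = 1e-10) -> UnmixingModel:
    """Fit SOBI on epoched data.

    Whitens the trial-concatenated data (reducing to numerical rank if
    needed), averages symmetrized lagged covariance matrices over trials,
    and joint-diagonalizes them.
    """
    lags = tuple(int(l) for l in lags)
    if not lags:
        raise ValueError("need at least one lag")
    data = epochs.data - epochs.data.mean(axis=2, keepdims=True)
    n_trials, C, S = data.shape
    if n_trials * S < C:
        raise ValueError("not enough samples to estimate the mixing")
    if max(lags) >= S:
        raise ValueError("largest lag exceeds the epoch length")

    C0 = np.zeros((C, C))
    for t in range(n_trials):
        C0 += data[t] @ data[t].T
    C0 /= n_trials * S
    evals, evecs = np.linalg.eigh(C0)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    rank = int(np.sum(evals > rank_tol * max(evals[0], 1e-300)))
    if rank < C:
        warnings.warn(f"rank-deficient data: retaining {rank}/{C} dimensions")
    W = evecs[:, :rank] / np.sqrt(evals[:rank])     # (C, rank)
    Z = np.einsum("cr,tcs->trs", W, data)           # whitened

    lagged = np.zeros((len(lags), rank, rank))
    for i, lag in enumerate(lags):
        acc = np.zeros((rank, rank))
        for t in range(n_trials):
            acc += Z[t, :, :-lag] @ Z[t, :, lag:].T / (S - lag)
        acc /= n_trials
        lagged[i] = 0.5 * (acc + acc.T)

    V, _ = joint_diagonalize(lagged)
    unmixing = V.T @ W.T                            # (rank, C)
    unmixing /= np.linalg.norm(unmixing, axis=1, keepdims=True)
    mixing = np.linalg.pinv(unmixing)
    variances = np.einsum("kc,tcs->tks", unmixing, data).var(axis=(0, 2))
    order = np.argsort(variances)[::-1]
    unmixing = unmixing[order]
    mixing = mixing[:, order]
    return UnmixingModel(
        unmixing=unmixing,
        mixing=mixing,
        lags=lags,
        component_variances=variances[order],
        rank=rank,
    )


# ---------------------------------------------------------------------------
# implant-artefact component handling


def detect_onset_spike_components(
    model: UnmixingModel,
    epochs: Epochs,
    onset_window_ms: tuple = (-20.0, 20.0),
    offset_window_ms: tuple = (780.0, 820.0),
    ratio_threshold: float = 5.0,
) -> list[int]:
    """Flag components spiking at stimulus onset and/or offset.

    A component is flagged when the peak of its trial-averaged absolute
    activation inside either window strictly exceeds ``ratio_threshold``
    times its RMS outside both windows.
    """
    times = epochs.times
    for w in (onset_window_ms, offset_window_ms):
        if w[0] < times[0] or w[1] > times[-1]:
            raise ValueError(f"window {w} outside the epoch")
    avg_act = model.unmixing @ epochs.data.mean(axis=0)   # (k, samples)
    inside = ((times >= onset_window_ms[0]) & (times <= onset_window_ms[1])) | (
        (times >= offset_window_ms[0]) & (times <= offset_window_ms[1])
    )
    flagged = []
    for k in range(model.n_components):
        a = np.abs(avg_act[k])
        peak = a[inside].max()
        base = np.sqrt(np.mean(a[~inside] ** 2))
        if base == 0.0:
            base = np.finfo(float).tiny
        if peak > ratio_threshold * base:
            flagged.append(k)
    return flagged


def remove_components(epochs: Epochs, model: UnmixingModel,
                      indices) -> Epochs:
    """Reproject the data with the flagged component activations zeroed."""
    indices = sorted(set(int(i) for i in indices))
    if any(i < 0 or i >= model.n_components for i in indices):
        raise IndexError("component index out of range")
    out = epochs.copy()
    if not indices:
        return out
    if len(indices) == model.n_components and model.rank == epochs.n_channels:
        warnings.warn("removing every component leaves all-zero data")
    sub_unmix = model.unmixing[indices]          # (m, C)
    sub_mix = model.mixing[:, indices]           # (C, m)
    act = np.einsum("mc,tcs->tms", sub_unmix, epochs.data)
    out.data = epochs.data - np.einsum("cm,tms->tcs", sub_mix, act)
    return out


# ---------------------------------------------------------------------------
# ERP


def erp_average(epochs: Epochs, condition: str) -> np.ndarray:
    """Trial-average (channels x samples) of one condition."""
    mask = epochs.condition_mask(condition)
    if not mask.any():
        known = sorted(epochs.trials["condition"].unique())
        raise ValueError(f"unknown condition {condition!r}; have {known}")
    return epochs.data[mask].mean(axis=0)
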