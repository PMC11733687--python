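"""Synthetic multi-subject EEG epoch generator.

Emulates the statistical structure the downstream analyses assume: two
groups (implanted / control), up to four longitudinal sessions, two
stimulated ears, 128-channel epochs from -1 to 1.5 s around word onset at
500 Hz, and four pooled comprehension conditions whose spatiotemporal
patterns switch on only in a late (600-1200 ms) window. Noise is
spatially correlated 1/f plus white sensor noise; an optional rank-1
implant-artefact transient can be injected at stimulus onset/offset.

Cross-group representational similarity is a controlled parameter: the
implanted group's condition topographies at session s are built as
``rho(s) * T_control + sqrt(1 - rho(s)^2) * T_independent`` with the
independent part orthogonalized against the control topography, so the
expected pattern correlation equals rho exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from .epochs import Epochs

CONDITIONS = ("very easy", "easy", "difficult", "very difficult")

# Session-wise cross-group pattern correlation. RDM-level similarity scales
# roughly with rho^2 (dissimilarities are quadratic in the patterns), so the
# default sessions are spaced equidistantly on the rho^2 scale to model a
# steady longitudinal normalization of the representational geometry.
DEFAULT_RHO = {"pre-op": 0.0, "3m": 0.45, "6m": 0.7, "12m": 0.9}


@dataclass
class SynthConfig:
    """Study-level parameters of the synthetic generator.

    Defaults mirror the emulated study: 10 subjects per group, 128
    channels at 500 Hz, epochs -1..1.5 s, four ordered comprehension
    conditions with 48 trials each (two pooled 24-word cells), and
    condition-dependent patterns confined to 600-1200 ms post-onset.
    """

    n_subjects_per_group: int = 10
    n_channels: int = 128
    fs: float = 500.0
    epoch_window: tuple = (-1.0, 1.5)       # seconds
    conditions: tuple = CONDITIONS
    trials_per_condition: int = 48
    signal_window_ms: tuple = (600.0, 1200.0)
    effect_scale: float = 1.0               # µV pattern amplitude
    cross_group_similarity: dict = field(default_factory=lambda: dict(DEFAULT_RHO))
    ears_implanted: tuple = ("CI", "non-CI")
    noise_exponent: float = 1.0             # 1/f^exponent spectral shape
    noise_white_sd: float = 1.0             # µV white sensor noise
    noise_spatial_mix: float = 0.5          # 0 = uncorrelated channels
    artefact_amplitude: float = 0.0         # µV; 0 disables injection
    artefact_onset_ms: float = 0.0
    artefact_offset_ms: float = 800.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s, rho in self.cross_group_similarity.items():
            if not 0.0 <= rho <= 1.0:
                raise ValueError(f"rho for session {s!r} must be in [0, 1]")
        if self.trials_per_condition < 4:
            raise ValueError("trials_per_condition must be >= 4 (binning)")
        lo, hi = (t * 1000.0 for t in self.epoch_window)
        if not (lo <= self.signal_window_ms[0] < self.signal_window_ms[1] <= hi):
            raise ValueError("signal window must lie inside the epoch window")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")

    @property
    def sessions(self) -> tuple:
        return tuple(self.cross_group_similarity.keys())

    @property
    def times_ms(self) -> np.ndarray:
        n = int(round((self.epoch_window[1] - self.epoch_window[0]) * self.fs)) + 1
        return self.epoch_window[0] * 1000.0 + np.arange(n) * 1000.0 / self.fs


@dataclass
class GroundTruth:
    """Everything needed to reproduce or score a generated dataset."""

    control_topographies: np.ndarray            # (n_cond, n_channels), unit norm
    implanted_topographies: dict                # (session, ear) -> (n_cond, C)
    rho: dict                                   # session -> rho
    artefact_topography: np.ndarray             # (n_channels,), unit norm
    artefact_onset_ms: float
    artefact_offset_ms: float
    spatial_kernel: np.ndarray                  # (C, C) noise mixing
    master_seed: int


def _unit_centered(v: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm version of v (so dot products are Pearson r)."""
    v = v - v.mean()
    return v / np.linalg.norm(v)


def _make_topographies(config: SynthConfig) -> GroundTruth:
    ss = np.random.SeedSequence([config.seed, 7001])
    rng = np.random.default_rng(ss)
    n_cond, C = len(config.conditions), config.n_channels
    ctrl = np.stack(
        [_unit_centered(rng.standard_normal(C)) for _ in range(n_cond)]
    )
    impl: dict = {}
    for ear in config.ears_implanted:
        # the implanted group's idiosyncratic component is a stable trait:
        # drawn once per ear/condition and shared across sessions, so that
        # longitudinal change reflects rho alone (gradual normalization),
        # not fresh topography draws every session
        idio = np.empty_like(ctrl)
        for k in range(n_cond):
            ind = rng.standard_normal(C)
            ind = ind - ind.mean()
            # orthogonalize against the control topography -> exact rho
            ind -= (ind @ ctrl[k]) * ctrl[k]
            idio[k] = ind / np.linalg.norm(ind)
        for session, rho in config.cross_group_similarity.items():
            impl[(session, ear)] = (
                rho * ctrl + np.sqrt(1.0 - rho**2) * idio
            )
    # spatially smoothed random kernel for correlated noise
    G = rng.standard_normal((C, C))
    G = ndimage.gaussian_filter(G, sigma=max(C / 16.0, 1.0))
    G /= np.linalg.norm(G, axis=1, keepdims=True)
    K = (1.0 - config.noise_spatial_mix) * np.eye(C) + config.noise_spatial_mix * G
    K /= np.linalg.norm(K, axis=1, keepdims=True)
    art = _unit_centered(rng.standard_normal(C))
    return GroundTruth(
        control_topographies=ctrl,
        implanted_topographies=impl,
        rho=dict(config.cross_group_similarity),
        artefact_topography=art,
        artefact_onset_ms=config.artefact_onset_ms,
        artefact_offset_ms=config.artefact_offset_ms,
        spatial_kernel=K,
        master_seed=config.seed,
    )


def _hann_activation(times_ms: np.ndarray, window_ms: tuple) -> np.ndarray:
    """Smooth activation: a Hann bump inside the signal window, 0 outside."""
    lo, hi = window_ms
    act = np.zeros_like(times_ms)
    inside = (times_ms >= lo) & (times_ms <= hi)
    n = int(inside.sum())
    if n > 0:
        act[inside] = np.hanning(n)
    return act


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                fs: float, exponent: float) -> np.ndarray:
    """Spectrally shaped (1/f^exponent) Gaussian noise, unit variance/channel."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = 1.0 / np.power(freqs + 1.0, exponent / 2.0)  # +1 Hz floor tames DC
    coeff = (
        rng.standard_normal((n_channels, len(freqs)))
        + 1j * rng.standard_normal((n_channels, len(freqs)))
    ) * shape
    x = np.fft.irfft(coeff, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _subject_seed(config: SynthConfig, group: str, subject_idx: int,
                  session: str, ear: str) -> np.random.SeedSequence:
    sessions = list(config.sessions) + ["reference"]
    ears = list(config.ears_implanted) + ["earphone"]
    return np.random.SeedSequence(
        [
            config.seed,
            0 if group == "implanted" else 1,
            subject_idx,
            sessions.index(session),
            ears.index(ear),
        ]
    )


def generate_subject(
    config: SynthConfig,
    truth: GroundTruth,
    group: str,
    subject_idx: int,
    session: str,
    ear: str,
) -> Epochs:
    """Generate one subject/session/ear recording (deterministic)."""
    rng = np.random.default_rng(
        _subject_seed(config, group, subject_idx, session, ear)
    )
    times = config.times_ms
    C, S = config.n_channels, len(times)
    n_cond = len(config.conditions)
    n_trials = n_cond * config.trials_per_condition
    if group == "control":
        topos = truth.control_topographies
    else:
        topos = truth.implanted_topographies[(session, ear)]
    act = _hann_activation(times, config.signal_window_ms)

    cond_idx = np.repeat(np.arange(n_cond), config.trials_per_condition)
    data = np.empty((n_trials, C, S))
    for t in range(n_trials):
        pink = _pink_noise(rng, C, S, config.fs, config.noise_exponent)
        noise = truth.spatial_kernel @ pink
        noise += config.noise_white_sd * rng.standard_normal((C, S))
        data[t] = noise + config.effect_scale * np.outer(topos[cond_idx[t]], act)
    order = rng.permutation(n_trials)
    data = data[order]
    trials = pd.DataFrame(
        {
            "condition": [config.conditions[k] for k in cond_idx[order]],
            "word_id": [f"w{i:03d}" for i in order],
        }
    )
    e = Epochs(
        data=data,
        fs=config.fs,
        times=times,
        ch_names=[f"E{c + 1:03d}" for c in range(C)],
        trials=trials,
        subject=f"{'P' if group == 'implanted' else 'C'}{subject_idx + 1:02d}",
        group=group,
        session=session,
        ear=ear,
    )
    if config.artefact_amplitude > 0 and group == "implanted" and ear == "CI":
        e = inject_ci_artefact(e, truth, amplitude=config.artefact_amplitude)
    return e


def iter_dataset(config: SynthConfig, truth: GroundTruth | None = None
                 ) -> Iterator[Epochs]:
    """Yield every recording of the study one at a time (memory friendly).

    Controls are measured once (session ``"reference"``, earphone);
    implanted subjects once per session per ear.
    """
    if truth is None:
        truth = _make_topographies(config)
    for i in range(config.n_subjects_per_group):
        yield generate_subject(config, truth, "control", i, "reference", "earphone")
    for i in range(config.n_subjects_per_group):
        for session in config.sessions:
            for ear in config.ears_implanted:
                yield generate_subject(config, truth, "implanted", i, session, ear)


def generate_dataset(config: SynthConfig) -> tuple[list[Epochs], GroundTruth]:
    """Materialize the whole study. Prefer :func:`iter_dataset` at scale."""
    truth = _make_topographies(config)
    return list(iter_dataset(config, truth)), truth


def make_ground_truth(config: SynthConfig) -> GroundTruth:
    return _make_topographies(config)


# ---------------------------------------------------------------------------
# ratings


def generate_ratings(
    config: SynthConfig,
    grid: pd.DataFrame,
    subject: str = "C01",
    session: str = "reference",
    ear: str = "earphone",
    seed: int | None = None,
) -> pd.DataFrame:
    """Ordinal 1-4 comprehension ratings for every manifest row.

    Proportional-odds model with equidistant thresholds: the latent
    comprehension mean increases with the number of spectral bands and
    with the temporal envelope cutoff, so more intact stimuli are rated
    higher on average.
    """
    if grid.empty:
        raise ValueError("stimulus manifest is empty")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7007]))
    bands = grid["spectral_level"].to_numpy(dtype=float)
    cutoff = grid["temporal_level"].to_numpy(dtype=float)
    # latent comprehension, centred on the middle cell (8 bands, 4 Hz)
    eta = 1.2 * (np.log2(bands) - 3.0) + 0.6 * (np.log2(cutoff) - 2.0)
    latent = eta + rng.logistic(size=len(grid))
    thresholds = np.array([-1.5, 0.0, 1.5])  # equidistant cut points
    rating = 1 + np.searchsorted(thresholds, latent)
    out = pd.DataFrame(
        {
            "subject": subject,
            "session": session,
            "ear": ear,
            "trial": np.arange(len(grid)),
            "word_id": grid["word_id"].to_numpy(),
            "spectral_level": grid["spectral_level"].to_numpy(),
            "temporal_level": grid["temporal_level"].to_numpy(),
            "rating": rating,
        }
    )
    return out


# ---------------------------------------------------------------------------
# implant artefact


def artefact_time_course(times_ms: np.ndarray, onset_ms: float,
                         offset_ms: float, width_ms: float = 4.0) -> np.ndarray:
    """Sharp biphasic transients at stimulus onset and offset.

    Gaussian-derivative pulses: narrow, spiky, and zero-mean, like the
    electrical switching transients of an implant processor.
    """
    tc = np.zeros_like(times_ms)
    for centre in (onset_ms, offset_ms):
        d = times_ms - centre
        pulse = -d * np.exp(-0.5 * (d / width_ms) ** 2)
        peak = np.abs(pulse).max()
        if peak > 0:
            tc += pulse / peak
    return tc


def inject_ci_artefact(epochs: Epochs, truth: GroundTruth,
                       amplitude: float | None = None) -> Epochs:
    """Add a rank-1 implant artefact (topography x transient) to every trial."""
    if amplitude is None:
        raise ValueError("amplitude must be given explicitly")
    if amplitude == 0:
        return epochs.copy()
    lo, hi = epochs.times[0], epochs.times[-1]
    for latency in (truth.artefact_onset_ms, truth.artefact_offset_ms):
        if not (lo <= latency <= hi):
            raise ValueError(f"artefact latency {latency} ms outside epoch")
    tc = artefact_time_course(
        epochs.times, truth.artefact_onset_ms, truth.artefact_offset_ms
    )
    out = epochs.copy()
    out.data += amplitude * np.outer(truth.artefact_topography, tc)[None, :, :]
    return out
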