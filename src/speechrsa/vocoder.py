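"""Noise-band vocoding of speech audio.

A noise vocoder degrades a speech waveform while keeping its band-wise
temporal envelopes: the signal is split by a band-pass filterbank, the
amplitude envelope of each band is extracted (half-wave rectification +
low-pass smoothing), optionally smoothed further to remove fast temporal
modulations, and finally imposed on band-limited white noise carriers.
Spectral degradation is controlled by the number of bands (fewer bands =
coarser spectrum), temporal degradation by the envelope low-pass cutoff
(lower cutoff = smoother envelope).

Band edges are spaced equidistantly along the Greenwood cochlear
position–frequency map, the standard choice for cochlear-implant
simulation vocoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

# Greenwood map constants for the human cochlea with relative position
# x in [0, 1]: f(x) = A (10^(a x) - k)
_GREENWOOD_A = 165.4
_GREENWOOD_ALPHA = 2.1
_GREENWOOD_K = 0.88

#: filter order of the Butterworth band-pass / low-pass designs
FILTER_ORDER = 4


def greenwood_frequency(x):
    """Characteristic frequency (Hz) at relative cochlear position x in [0, 1]."""
    x = np.asarray(x, dtype=float)
    return _GREENWOOD_A * (10.0 ** (_GREENWOOD_ALPHA * x) - _GREENWOOD_K)


def greenwood_position(f):
    """Inverse Greenwood map: relative cochlear position of frequency f (Hz)."""
    f = np.asarray(f, dtype=float)
    return np.log10(f / _GREENWOOD_A + _GREENWOOD_K) / _GREENWOOD_ALPHA


@dataclass(frozen=True)
class VocoderSpec:
    """One cell of the degradation grid.

    Parameters
    ----------
    n_bands : int
        Number of analysis bands (spectral degradation level).
    f_lo, f_hi : float
        Passband limits of the filterbank in Hz.
    env_smooth_hz : float
        Envelope smoothing low-pass cutoff that leaves intelligibility
        unaffected (default 400 Hz).
    temp_cutoff_hz : float
        Additional envelope low-pass for temporal degradation; must not
        exceed ``env_smooth_hz``.
    seed : int
        Seed of the noise carriers, for reproducible stimuli.
    """

    n_bands: int
    f_lo: float = 200.0
    f_hi: float = 7000.0
    env_smooth_hz: float = 400.0
    temp_cutoff_hz: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if self.temp_cutoff_hz > self.env_smooth_hz:
            raise ValueError("temp_cutoff_hz must be <= env_smooth_hz")

    def validate(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(f"f_hi={self.f_hi} must be < Nyquist ({fs / 2})")


@dataclass
class Filterbank:
    """Contiguous band-pass filterbank with Greenwood-spaced edges."""

    edges: np.ndarray          # (n_bands + 1,) Hz, strictly increasing
    fs: float
    order: int = FILTER_ORDER
    sos: list = field(default_factory=list)  # one SOS array per band

    @property
    def n_bands(self) -> int:
        return len(self.edges) - 1

    def band_filter(self, x: np.ndarray, band: int) -> np.ndarray:
        """Zero-phase band-pass of ``x`` through band ``band``."""
        return sps.sosfiltfilt(self.sos[band], x)


def make_filterbank(spec: VocoderSpec, fs: float) -> Filterbank:
    """Design the analysis/carrier filterbank for ``spec`` at rate ``fs``.

    Edges sit at equidistant Greenwood positions between ``f_lo`` and
    ``f_hi``; filters are zero-phase 4th-order Butterworth band-passes.
    """
    spec.validate(fs)
    x_lo, x_hi = greenwood_position([spec.f_lo, spec.f_hi])
    edges = greenwood_frequency(np.linspace(x_lo, x_hi, spec.n_bands + 1))
    # pin the limits exactly (the round trip is exact to float error)
    edges[0], edges[-1] = spec.f_lo, spec.f_hi
    sos = [
        sps.butter(FILTER_ORDER, [edges[b], edges[b + 1]], btype="bandpass",
                   fs=fs, output="sos")
        for b in range(spec.n_bands)
    ]
    return Filterbank(edges=edges, fs=fs, sos=sos)


def extract_envelope(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    """Amplitude envelope: half-wave rectify, zero-phase low-pass, clip at 0."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot extract the envelope of an empty signal")
    if cutoff >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    rect = np.maximum(x, 0.0)
    sos = sps.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, rect)
    return np.maximum(env, 0.0)


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x)))) if len(x) else 0.0


def vocode(x: np.ndarray, fs: float, spec: VocoderSpec) -> np.ndarray:
    """Noise-vocode a mono waveform.

    Per band: band-pass the input, extract the envelope at
    ``env_smooth_hz``, low-pass it again at ``temp_cutoff_hz``, and use it
    to modulate band-limited white noise (seeded per band). The band
    signals are summed and the output is rescaled to the input RMS.
    Silent input returns silence.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("vocode expects a mono waveform")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    spec.validate(fs)
    rms_in = rms(x)
    if rms_in == 0.0:
        return np.zeros_like(x)

    fb = make_filterbank(spec, fs)
    sos_temp = sps.butter(
        FILTER_ORDER, spec.temp_cutoff_hz, btype="lowpass", fs=fs, output="sos"
    )
    rng = np.random.default_rng(spec.seed)
    out = np.zeros_like(x)
    for b in range(fb.n_bands):
        band = fb.band_filter(x, b)
        env = extract_envelope(band, fs, spec.env_smooth_hz)
        env = np.maximum(sps.sosfiltfilt(sos_temp, env), 0.0)
        carrier = fb.band_filter(rng.standard_normal(len(x)), b)
        out += env * carrier
    rms_out = rms(out)
    if rms_out > 0.0:
        out *= rms_in / rms_out
    return out


SPECTRAL_LEVELS = (4, 8, 16)   # bands
TEMPORAL_LEVELS = (2.0, 4.0, 8.0)  # Hz envelope cutoffs


def build_stimulus_grid(
    word_ids,
    spectral_levels=SPECTRAL_LEVELS,
    temporal_levels=TEMPORAL_LEVELS,
    words_per_cell: int = 24,
    seed: int = 0,
    reuse_words: bool = False,
    out_dir: str | Path = "stimuli",
) -> pd.DataFrame:
    """Assign words to the degradation grid.

    Returns a manifest with one row per (word, cell) assignment and
    columns ``word_id, spectral_level, temporal_level, path, seed``. With
    3x3 levels and 24 words per cell this is the full 216-word design.
    """
    word_ids = list(word_ids)
    cells = [(int(s), float(t)) for s in spectral_levels for t in temporal_levels]
    needed = len(cells) * words_per_cell
    rng = np.random.default_rng(seed)
    if reuse_words:
        if len(word_ids) < words_per_cell:
            raise ValueError("need at least words_per_cell words to reuse")
        per_cell = [list(rng.permutation(word_ids))[:words_per_cell]
                    for _ in cells]
    else:
        if len(word_ids) < needed:
            raise ValueError(
                f"{needed} words needed for {len(cells)} cells x "
                f"{words_per_cell}, got {len(word_ids)} (set reuse_words=True "
                "to reuse words across cells)"
            )
        shuffled = list(rng.permutation(word_ids))
        per_cell = [
            shuffled[i * words_per_cell:(i + 1) * words_per_cell]
            for i in range(len(cells))
        ]
    rows = []
    i = 0
    for cell, words in zip(cells, per_cell):
        s, t = cell
        for w in words:
            rows.append(
                {
                    "word_id": w,
                    "spectral_level": s,
                    "temporal_level": t,
                    "path": str(Path(out_dir) / f"{w}_b{s}_t{t:g}.wav"),
                    "seed": seed + i,
                }
            )
            i += 1
    return pd.DataFrame(rows)
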