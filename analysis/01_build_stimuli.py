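"""Build the 3x3 degradation grid and vocode example stimuli.

No speech recordings ship with the repository, so this driver synthesizes
short formant-like tone complexes as word stand-ins, vocodes one example
per degradation cell (4/8/16 spectral bands x 2/4/8 Hz envelope cutoffs)
and writes the full 216-word manifest plus the example WAVs.

Outputs: results/stimuli/manifest.csv, results/stimuli/*.wav
"""

from pathlib import Path

import numpy as np
from scipy.io import wavfile

from speechrsa.vocoder import VocoderSpec, build_stimulus_grid, vocode

FS = 44100
OUT = Path("results/stimuli")


def synthetic_word(seed: int, duration: float = 0.6) -> np.ndarray:
    """Word-like stand-in: a few gliding 'formants' with a speech envelope."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * FS)) / FS
    x = np.zeros_like(t)
    for f0 in rng.uniform(300, 2500, size=4):
        glide = f0 * (1 + 0.2 * np.sin(2 * np.pi * rng.uniform(2, 5) * t))
        x += np.sin(2 * np.pi * np.cumsum(glide) / FS) / 4
    syllables = 1 + 0.9 * np.sin(2 * np.pi * rng.uniform(3, 6) * t - np.pi / 2)
    ramp = np.minimum(1.0, np.minimum(t, duration - t) / 0.05)
    return x * syllables * ramp


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    words = [f"word{i:03d}" for i in range(216)]
    grid = build_stimulus_grid(words, words_per_cell=24, seed=0, out_dir=OUT)
    grid.to_csv(OUT / "manifest.csv", index=False)
    print(f"manifest: {len(grid)} rows, "
          f"{grid.groupby(['spectral_level', 'temporal_level']).ngroups} cells")

    # vocode one example per cell so the degradation grid can be listened to
    examples = grid.groupby(["spectral_level", "temporal_level"]).head(1)
    for row in examples.itertuples():
        raw = synthetic_word(seed=int(row.word_id[-3:]))
        spec = VocoderSpec(
            n_bands=int(row.spectral_level),
            temp_cutoff_hz=float(row.temporal_level),
            seed=int(row.seed),
        )
        out = vocode(raw, FS, spec)
        wavfile.write(row.path, FS, (out / np.abs(out).max() * 0.9).astype(np.float32))
        print(f"  {Path(row.path).name}: {row.spectral_level} bands, "
              f"{row.temporal_level:g} Hz envelope")
    print(f"wrote {len(examples)} example WAVs under {OUT}")


if __name__ == "__main__":
    main()
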