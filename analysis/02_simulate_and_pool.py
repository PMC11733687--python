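"""Simulate comprehension ratings and derive the 9 -> 4 condition pooling.

Generates ordinal 1-4 ratings for every manifest row from the
proportional-odds model (comprehension rises with band count and envelope
cutoff), ranks the 9 degradation cells by mean rating, excludes the
best-understood cell and pools the remaining 8 into the four analysis
categories ("very easy" ... "very difficult").

Outputs: results/ratings.csv, results/condition_scheme.csv
"""

from pathlib import Path

import pandas as pd

from speechrsa.decoding import pool_conditions
from speechrsa.synthgen import SynthConfig, generate_ratings
from speechrsa.vocoder import build_stimulus_grid

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    words = [f"word{i:03d}" for i in range(216)]
    grid = build_stimulus_grid(words, words_per_cell=24, seed=0)
    ratings = generate_ratings(SynthConfig(seed=2024), grid)
    ratings.to_csv(OUT / "ratings.csv", index=False)

    cell_means = (
        ratings.groupby(["spectral_level", "temporal_level"])["rating"]
        .mean()
        .sort_values(ascending=False)
    )
    print("mean rating per degradation cell (bands, envelope Hz):")
    print(cell_means.round(2).to_string())

    scheme = pool_conditions(ratings)
    rows = [
        {"spectral_level": s, "temporal_level": t, "category": cat}
        for (s, t), cat in sorted(scheme.mapping.items())
    ]
    rows.append(
        {
            "spectral_level": scheme.excluded[0],
            "temporal_level": scheme.excluded[1],
            "category": "excluded",
        }
    )
    pd.DataFrame(rows).to_csv(OUT / "condition_scheme.csv", index=False)
    print(f"\nexcluded cell: {scheme.excluded}; "
          f"4 pooled categories written to {OUT / 'condition_scheme.csv'}")


if __name__ == "__main__":
    main()
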