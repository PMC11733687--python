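"""Track cross-group representational similarity across sessions.

Reads the window statistics the pipeline wrote (running it first if
needed): per control subject and session, the mean Fisher-z of the
time-generalized Spearman correlation between the implanted group's
average RDM series and that subject's series inside 600-1200 ms. If the
implant gradually normalizes cortical speech processing, this value
should rise across sessions.

Output: results/session_similarity.csv (+ console summary)
"""

from pathlib import Path

import pandas as pd

from speechrsa.pipeline import run_pipeline

WINDOW = Path("results/run/window_stats.csv")


def main() -> None:
    if not WINDOW.exists():
        run_pipeline("configs/demo.yaml")
    stats = pd.read_csv(WINDOW)
    order = ["pre-op", "3m", "6m", "12m"]
    summary = (
        stats.groupby("session")["mean_z"].agg(["mean", "std", "count"])
        .reindex(order)
        .round(4)
    )
    summary.to_csv("results/session_similarity.csv")
    print("window-mean Fisher-z (implanted reference vs controls), "
          "600-1200 ms:")
    print(summary.to_string())
    ordered = summary["mean"].is_monotonic_increasing
    print(f"\nmonotonically increasing across sessions: {ordered}")


if __name__ == "__main__":
    main()
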