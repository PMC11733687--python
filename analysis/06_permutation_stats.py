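"""Non-parametric inference on the demo study's similarity statistics.

From the per-subject window statistics: a permutation repeated-measures
F-test for the session effect, permutation paired t-tests between all
session pairs with a Bonferroni-adjusted alpha, and paired Cohen's d —
plus the 1D max-cluster-size sign-permutation test of the control group's
decoding curves against chance.

Output: results/permutation_stats.json
"""

import json
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from speechrsa.permstats import (
    bonferroni_alpha,
    cluster_test_1d,
    perm_paired_t,
    perm_rm_anova,
)
from speechrsa.pipeline import run_pipeline

RUN = Path("results/run")
ORDER = ["pre-op", "3m", "6m", "12m"]


def main() -> None:
    if not (RUN / "window_stats.csv").exists():
        run_pipeline("configs/demo.yaml")
    out: dict = {}

    # session effect on window-mean Fisher-z
    stats = pd.read_csv(RUN / "window_stats.csv")
    table = stats.pivot(index="subject", columns="session", values="mean_z")
    table = table[ORDER]
    f_res = perm_rm_anova(table.to_numpy(), n_perm=10000, seed=1)
    out["session_rm_anova"] = {
        "F": f_res.statistic, "p": f_res.p_value,
        "n_permutations": f_res.n_permutations,
    }
    print(f"session effect: F = {f_res.statistic:.3f}, "
          f"permutation p = {f_res.p_value:.4f}")

    # pairwise session contrasts, Bonferroni over the 6 comparisons
    alpha_adj = bonferroni_alpha(0.05, 6)
    out["pairwise"] = {}
    for a, b in combinations(ORDER, 2):
        res = perm_paired_t(
            table[b].to_numpy(), table[a].to_numpy(),
            n_perm=10000, alpha_adjusted=alpha_adj, seed=2,
        )
        out["pairwise"][f"{b} vs {a}"] = {
            "t": res.statistic, "p": res.p_value, "cohens_d": res.effect_size,
            "alpha_adjusted": alpha_adj, "significant": bool(res.significant),
        }
        mark = "*" if res.significant else " "
        print(f"  {b:>6} vs {a:<6}: t = {res.statistic:6.2f}, "
              f"p = {res.p_value:.4f}, d = {res.effect_size:5.2f} {mark}")

    # control decoding curves vs chance
    curves = pd.read_csv(RUN / "decoding_curves.csv")
    ctrl = curves[curves.group == "control"]
    mat = ctrl.pivot(index="subject", columns="time_ms", values="accuracy")
    res = cluster_test_1d(mat.to_numpy(), mu0=0.5, n_perm=1000, seed=3)
    times = mat.columns.to_numpy()
    out["control_chance_clusters"] = [
        {
            "start_ms": float(times[c.indices[0]]),
            "end_ms": float(times[c.indices[1] - 1]),
            "size": int(c.size),
            "p": float(c.p_value),
            "significant": bool(c.significant),
        }
        for c in res.clusters
    ]
    sig = [c for c in res.clusters if c.significant]
    print(f"control decoding vs chance: {len(sig)} significant cluster(s)")
    for c in sig:
        print(f"  {times[c.indices[0]]:.0f}-{times[c.indices[1] - 1]:.0f} ms, "
              f"p = {c.p_value:.4f}")

    (Path("results") / "permutation_stats.json").write_text(
        json.dumps(out, indent=2, sort_keys=True)
    )


if __name__ == "__main__":
    main()
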