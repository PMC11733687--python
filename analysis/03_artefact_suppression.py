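"""Measure implant-artefact suppression by SOBI + spike-component removal.

Simulates one implanted-ear recording, injects a rank-1 onset/offset
transient artefact, fits SOBI, flags components spiking around stimulus
onset/offset, removes them and reports how much onset-window power the
procedure eliminated.

Output: results/artefact_suppression.json
"""

import json
from pathlib import Path

import numpy as np

from speechrsa.preprocess import (
    DEFAULT_SOBI_LAGS,
    detect_onset_spike_components,
    remove_components,
    sobi_unmix,
    zvalue_artifact_reject,
)
from speechrsa.synthgen import (
    SynthConfig,
    generate_subject,
    inject_ci_artefact,
    make_ground_truth,
)

OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = SynthConfig(
        n_subjects_per_group=1, n_channels=24, trials_per_condition=6,
        effect_scale=1.0, ears_implanted=("CI",), seed=11,
    )
    truth = make_ground_truth(cfg)
    clean = generate_subject(cfg, truth, "implanted", 0, "3m", "CI")
    dirty = inject_ci_artefact(clean, truth, amplitude=80.0)

    dirty, report = zvalue_artifact_reject(dirty, threshold=100.0)
    print(f"z-rejection: {report.n_rejected} trials dropped")

    model = sobi_unmix(dirty, lags=DEFAULT_SOBI_LAGS)
    flagged = detect_onset_spike_components(model, dirty)
    cleaned = remove_components(dirty, model, flagged)

    win = np.abs(dirty.times) <= 20.0
    p_dirty = float(np.mean(dirty.data[:, :, win] ** 2))
    p_clean = float(np.mean(cleaned.data[:, :, win] ** 2))
    result = {
        "n_components": model.n_components,
        "flagged_components": [int(k) for k in flagged],
        "onset_power_contaminated": p_dirty,
        "onset_power_cleaned": p_clean,
        "suppression_fraction": 1.0 - p_clean / p_dirty,
    }
    (OUT / "artefact_suppression.json").write_text(json.dumps(result, indent=2))
    print(f"flagged {len(flagged)} of {model.n_components} components; "
          f"onset-window power suppressed by "
          f"{100 * result['suppression_fraction']:.1f}%")


if __name__ == "__main__":
    main()
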