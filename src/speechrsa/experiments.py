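"""Self-contained simulation experiments built from the pipeline stages.

These are the study-level computations the analysis drivers and the
acceptance checks run: chance-level calibration of the decoder, family-wise
error calibration of the 1D cluster test, and recovery of the generator's
session-wise cross-group similarity by the RSA window statistic.
"""

from __future__ import annotations

import numpy as np

from . import rsa
from .decoding import decode_timecourse
from .permstats import cluster_test_1d
from .synthgen import SynthConfig, generate_subject, make_ground_truth

RECOVERY_SESSIONS = ("pre-op", "3m", "6m", "12m")
RECOVERY_RHO = (0.0, 0.45, 0.7, 0.9)


def chance_decoding_accuracy(
    seed: int,
    n_channels: int = 128,
    trials_per_condition: int = 24,
    n_iter: int = 100,
    dt_ms: float = 20.0,
    time_range: tuple = (-500.0, 1500.0),
) -> dict:
    """Grand-average decoding accuracy of one no-signal subject.

    With ``effect_scale = 0`` the conditions are exchangeable, so the
    time-averaged accuracy estimates the decoder's chance level (0.5).
    """
    cfg = SynthConfig(
        n_subjects_per_group=1,
        n_channels=n_channels,
        trials_per_condition=trials_per_condition,
        effect_scale=0.0,
        ears_implanted=("non-CI",),
        seed=seed,
    )
    truth = make_ground_truth(cfg)
    e = generate_subject(cfg, truth, "control", 0, "reference", "earphone")
    _, curve = decode_timecourse(
        e, n_iter=n_iter, dt_ms=dt_ms, seed=seed + 1, time_range=time_range
    )
    return {
        "mean_accuracy": float(curve.accuracy.mean()),
        "n_timepoints": int(len(curve.times)),
        "n_iter": n_iter,
    }


def cluster_fwe_rate(
    seed: int,
    n_datasets: int = 200,
    n_subjects: int = 10,
    n_timepoints: int = 101,
    n_perm: int = 512,
    cluster_alpha: float = 0.05,
    alpha: float = 0.05,
) -> dict:
    """Family-wise false-positive rate of the 1D cluster test on null data."""
    rng = np.random.default_rng(seed)
    false_positives = 0
    for i in range(n_datasets):
        data = rng.standard_normal((n_subjects, n_timepoints))
        res = cluster_test_1d(
            data, mu0=0.0, cluster_alpha=cluster_alpha, alpha=alpha,
            n_perm=n_perm, seed=int(rng.integers(2**31)), exhaustive=False,
        )
        false_positives += res.any_significant
    return {
        "fwe_rate": false_positives / n_datasets,
        "n_datasets": n_datasets,
        "n_perm": n_perm,
    }


def session_similarity_estimates(
    seed: int,
    n_subjects: int = 6,
    n_channels: int = 24,
    trials_per_condition: int = 24,
    effect_scale: float = 1.3,
    n_iter: int = 32,
    window_ms: tuple = (600.0, 1200.0),
    sessions: tuple = RECOVERY_SESSIONS,
    rho: tuple = RECOVERY_RHO,
) -> dict:
    """Window-mean Fisher-z per session for one simulated study.

    Decoding is restricted to the analysis window (the statistic only uses
    those cells); returns ``{session: mean z across control subjects}``.
    """
    cfg = SynthConfig(
        n_subjects_per_group=n_subjects,
        n_channels=n_channels,
        trials_per_condition=trials_per_condition,
        effect_scale=effect_scale,
        cross_group_similarity=dict(zip(sessions, rho)),
        ears_implanted=("non-CI",),
        seed=seed,
    )
    truth = make_ground_truth(cfg)
    rng = np.random.default_rng(seed)

    def decode(group, idx, session, ear):
        e = generate_subject(cfg, truth, group, idx, session, ear)
        series, _ = decode_timecourse(
            e, n_iter=n_iter, seed=int(rng.integers(2**31)),
            time_range=window_ms,
        )
        return series

    controls = [
        decode("control", i, "reference", "earphone")
        for i in range(n_subjects)
    ]
    out = {}
    for session in sessions:
        impl = [
            decode("implanted", i, session, "non-CI")
            for i in range(n_subjects)
        ]
        reference = rsa.average_rdms(impl)
        mats = rsa.timegen_similarity(reference, controls)
        zs = [
            rsa.window_mean(rsa.fisher_z_matrix(m), window_ms).mean_z
            for m in mats
        ]
        out[session] = float(np.mean(zs))
    return out


def session_recovery(seed: int, n_replicates: int = 20, **kwargs) -> dict:
    """Replicate-averaged session similarity and its agreement with truth.

    Returns the per-session means over replicates and the Spearman rank
    correlation between the generator's rho sequence and those means.
    """
    from scipy.stats import spearmanr

    sessions = kwargs.get("sessions", RECOVERY_SESSIONS)
    rho = kwargs.get("rho", RECOVERY_RHO)
    per_session = {s: [] for s in sessions}
    for rep in range(n_replicates):
        est = session_similarity_estimates(seed=seed + 1000 * (rep + 1), **kwargs)
        for s in sessions:
            per_session[s].append(est[s])
    means = [float(np.mean(per_session[s])) for s in sessions]
    rank_corr = float(spearmanr(rho, means).statistic)
    return {
        "sessions": list(sessions),
        "rho": list(rho),
        "mean_window_z": means,
        "rank_correlation": rank_corr,
        "n_replicates": n_replicates,
    }
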