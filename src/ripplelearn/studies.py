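"""Desk-scale study presets: cohorts + multi-variant experiment runner.

These are the configurations the package's own validation studies use: a
6-animal cohort per group, 300 s (600 s for the AD-like group, whose ripple
rate is halved) of slow-wave sleep per recording, a 200-RCI-per-condition
fixed test pool, 50 training RCIs per animal per condition, the scaled CNN
profile at 100 epochs, and 3 cross-validation sessions (10 for the null
distribution study).  Variants sharing one cohort reuse the same detected
events and pools, as in the original protocol where all experiments draw
from one set of recordings.
"""

from __future__ import annotations

import numpy as np

from ._util import derive_seed
from .cnn import RippleCNN, TrainConfig, scaled_architecture, full_architecture
from .evaluation import (
    accuracy_rate,
    freq_ar_regression,
    hr_fraction,
    recognition_distribution,
    run_experiment,
)
from .pipeline import detect_cohort, pools_from_cohort, _VARIANT_MASK
from .rci import equalize_frequency
from .synthetic import GeneratorConfig, PeriSignatureSpec, generate_cohort

__all__ = [
    "wt_shift_cohort",
    "wt_signature_cohort",
    "signature_only_cohort",
    "ad_null_cohort",
    "run_study",
]

#: study sizing (scaled profile)
N_TEST = 200
N_TRAIN_PER_ANIMAL = 50
N_ANIMALS = 6
WT_DURATION_S = 300.0
AD_DURATION_S = 600.0  # halved ripple rate needs twice the sleep time


def wt_shift_cohort(seed: int, duration: float = WT_DURATION_S):
    """WT-like cohort: 10-Hz post-learning intrinsic-frequency shift only."""
    cfg = GeneratorConfig(duration=duration, seed=seed)
    return generate_cohort(cfg, N_ANIMALS, "WT_like")


def wt_signature_cohort(seed: int, duration: float = WT_DURATION_S):
    """WT-like cohort: frequency shift plus condition-dependent peri signature."""
    cfg = GeneratorConfig(
        duration=duration,
        seed=seed,
        peri_signature=PeriSignatureSpec(mode="condition_dependent"),
    )
    return generate_cohort(cfg, N_ANIMALS, "WT_like")


def signature_only_cohort(seed: int, duration: float = WT_DURATION_S):
    """No frequency shift; class information only in the peri-event signature."""
    cfg = GeneratorConfig(
        duration=duration,
        seed=seed,
        freq_mean_after=140.0,
        peri_signature=PeriSignatureSpec(mode="condition_dependent"),
    )
    return generate_cohort(cfg, N_ANIMALS, "WT_like")


def ad_null_cohort(seed: int, duration: float = AD_DURATION_S):
    """AD-like cohort: identical condition distributions, half ripple rate."""
    cfg = GeneratorConfig(duration=duration, seed=seed)
    return generate_cohort(cfg, N_ANIMALS, "AD_like")


def _summarize(matrix):
    records, per_animal, group_mean = accuracy_rate(matrix)
    out = {
        "matrix": matrix,
        "records": records,
        "per_animal": per_animal,
        "group_mean_ar": group_mean,
        "hr_fraction": hr_fraction(records, n_sessions=matrix.n_sessions),
        "distribution": recognition_distribution(matrix),
    }
    for cond in ("before", "after"):
        try:
            out[f"slope_{cond}"] = freq_ar_regression(records, "pooled", cond).slope
        except ValueError:
            out[f"slope_{cond}"] = np.nan
    return out


def run_study(
    recordings,
    variants=("full",),
    n_sessions: int = 3,
    master_seed: int = 0,
    n_test: int = N_TEST,
    n_train_per_animal: int = N_TRAIN_PER_ANIMAL,
    epochs: int = 100,
    profile: str = "scaled",
) -> dict:
    """Detect, build pools once, then run every variant on the same pools.

    Returns {variant: summary dict}; summaries carry the SessionMatrix, the
    per-RCI AR table, group mean AR, HR fraction, the recognition-count
    distribution and the pooled frequency-AR regression slopes.
    """
    detected = detect_cohort(recordings)
    test_pool, train_pools = pools_from_cohort(
        detected,
        n_test=n_test,
        n_train_per_animal=n_train_per_animal,
        master_seed=derive_seed(master_seed, "pools"),
        n_sessions=n_sessions,
    )
    arch = scaled_architecture() if profile == "scaled" else full_architecture()
    factory = lambda s: RippleCNN(arch, seed=s, dtype=np.float32)
    results = {}
    for variant in variants:
        pools_v = train_pools
        if variant == "equalized_freq":
            pools_v = [
                equalize_frequency(tp, seed=derive_seed(master_seed, "eq", s))
                for s, tp in enumerate(train_pools)
            ]
        cfg = TrainConfig(
            epochs=epochs, seed=derive_seed(master_seed, "train", variant)
        )
        matrix = run_experiment(
            test_pool,
            pools_v,
            factory,
            cfg,
            mask_mode=_VARIANT_MASK[variant],
            variant=variant,
            group=recordings[0].genotype,
        )
        results[variant] = _summarize(matrix)
    return results
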