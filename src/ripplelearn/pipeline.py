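"""End-to-end orchestration: simulate -> detect -> pools -> train -> evaluate.

``run_pipeline`` reproduces one deep-learning experiment variant (full,
equalized_freq, swr_only, surround_only) on a synthetic cohort and writes
the result tables (per-RCI AR, per-animal summary, recognition distribution,
regressions) plus a JSON manifest of seeds and configuration.  Everything is
reproducible from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._util import derive_seed
from .cnn import RippleCNN, TrainConfig, full_architecture, scaled_architecture
from .detection import detect_swrs, events_to_frame
from .evaluation import (
    accuracy_rate,
    freq_ar_regression,
    hr_fraction,
    hr_fraction_per_animal,
    recognition_distribution,
    run_experiment,
)
from .rci import equalize_frequency, extract_rcis, build_pools
from .synthetic import GeneratorConfig, PeriSignatureSpec, generate_cohort

__all__ = ["ExperimentConfig", "run_pipeline", "detect_cohort", "pools_from_cohort"]

VARIANTS = ("full", "equalized_freq", "swr_only", "surround_only")

#: mask applied per experiment variant
_VARIANT_MASK = {
    "full": "full",
    "equalized_freq": "full",
    "swr_only": "swr_only",
    "surround_only": "surround_only",
}


@dataclass
class ExperimentConfig:
    """One experiment run; profile 'scaled' is the desk-scale default."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    genotype_mode: str = "WT_like"  # WT_like | AD_like
    n_animals: int = 6
    variant: str = "full"
    profile: str = "scaled"  # scaled | full
    n_test: int = 200
    n_train_per_animal: int = 50
    n_sessions: int = 3
    epochs: int | None = None  # default by profile: 100 scaled / 900 full
    learning_rate: float = 0.01
    equalize_bin_hz: float = 2.0
    master_seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.profile not in ("scaled", "full"):
            raise ValueError("profile must be 'scaled' or 'full'")

    @property
    def resolved_epochs(self) -> int:
        if self.epochs is not None:
            return self.epochs
        return 100 if self.profile == "scaled" else 900

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        gen = d.pop("generator", {})
        if isinstance(gen, dict):
            gen = dict(gen)
            bg = gen.pop("background", {})
            sig = gen.pop("peri_signature", {})
            from .synthetic import BackgroundSpec

            gen["ripple_peak_z_target"] = tuple(
                gen.get("ripple_peak_z_target", (6.0, 9.0))
            )
            gen = GeneratorConfig(
                **gen,
                background=BackgroundSpec(**bg),
                peri_signature=PeriSignatureSpec(**sig),
            )
        return cls(generator=gen, **d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def detect_cohort(recordings, band=None, spec=None):
    """Run the detector on every recording; returns {recording: events}."""
    out = []
    for rec in recordings:
        events, filtered, _ = detect_swrs(
            rec.samples,
            rec.sampling_rate,
            rec.sws_intervals,
            band=band,
            spec=spec,
            recording_ref=f"{rec.animal_id}/{rec.condition}",
        )
        out.append((rec, events))
    return out


def pools_from_cohort(
    detected,
    n_test: int,
    n_train_per_animal: int,
    master_seed: int,
    n_sessions: int,
):
    by_key: dict = {}
    for rec, events in detected:
        rcis = extract_rcis(rec, events)
        by_key.setdefault((rec.animal_id, rec.condition), []).extend(rcis)
    return build_pools(
        by_key,
        n_test=n_test,
        n_train_per_animal=n_train_per_animal,
        master_seed=master_seed,
        n_sessions=n_sessions,
    )


def _model_factory(config: ExperimentConfig):
    arch = scaled_architecture() if config.profile == "scaled" else full_architecture()
    return lambda seed: RippleCNN(arch, seed=seed)


def run_pipeline(config: ExperimentConfig) -> dict:
    """Execute the full experiment and return (and optionally write) results."""
    t_start = time.time()
    timings = {}

    gen_cfg = dataclasses.replace(
        config.generator, seed=derive_seed(config.master_seed, "simulate")
    )
    recordings = generate_cohort(gen_cfg, config.n_animals, config.genotype_mode)
    timings["simulate_s"] = round(time.time() - t_start, 2)

    t0 = time.time()
    detected = detect_cohort(recordings)
    timings["detect_s"] = round(time.time() - t0, 2)

    t0 = time.time()
    test_pool, train_pools = pools_from_cohort(
        detected,
        n_test=config.n_test,
        n_train_per_animal=config.n_train_per_animal,
        master_seed=derive_seed(config.master_seed, "pools"),
        n_sessions=config.n_sessions,
    )
    if config.variant == "equalized_freq":
        train_pools = [
            equalize_frequency(
                tp,
                bin_width=config.equalize_bin_hz,
                seed=derive_seed(config.master_seed, "equalize", s),
            )
            for s, tp in enumerate(train_pools)
        ]
    timings["pools_s"] = round(time.time() - t0, 2)

    t0 = time.time()
    train_cfg = TrainConfig(
        epochs=config.resolved_epochs,
        learning_rate=config.learning_rate,
        seed=derive_seed(config.master_seed, "train"),
    )
    matrix = run_experiment(
        test_pool,
        train_pools,
        _model_factory(config),
        train_cfg,
        mask_mode=_VARIANT_MASK[config.variant],
        variant=config.variant,
        group=config.genotype_mode,
    )
    timings["train_eval_s"] = round(time.time() - t0, 2)

    records, per_animal, group_mean = accuracy_rate(matrix)
    hr = hr_fraction(records, n_sessions=matrix.n_sessions)
    dist = recognition_distribution(matrix)
    regressions = []
    for cond in ("before", "after"):
        regressions.append(freq_ar_regression(records, "pooled", cond))
        regressions.extend(freq_ar_regression(records, "per_animal", cond))
    reg_table = pd.DataFrame([asdict(r) for r in regressions])

    results = {
        "matrix": matrix,
        "records": records,
        "per_animal": per_animal,
        "per_animal_hr": hr_fraction_per_animal(records),
        "group_mean_ar": group_mean,
        "hr_fraction": hr,
        "distribution": dist,
        "regressions": reg_table,
        "timings": timings,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "ar_records.csv", index=False)
        per_animal.merge(results["per_animal_hr"], on="animal").to_csv(
            out / "per_animal.csv", index=False
        )
        pd.DataFrame(
            {"n_correct": np.arange(dist.size), "pct": dist}
        ).to_csv(out / "distribution.csv", index=False)
        reg_table.to_csv(out / "regressions.csv", index=False)
        truth_rows = []
        for rec, events in detected:
            truth_rows.append(
                events_to_frame(
                    events,
                    animal=rec.animal_id,
                    genotype=rec.genotype,
                    condition=rec.condition,
                    day=rec.day,
                )
            )
        pd.concat(truth_rows, ignore_index=True).to_csv(
            out / "events.csv", index=False
        )
        manifest = {
            "config": config.to_dict(),
            "group_mean_ar": group_mean,
            "hr_fraction": hr,
            "n_test_rcis": len(test_pool),
            "n_sessions": matrix.n_sessions,
            "timings": timings,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return results
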