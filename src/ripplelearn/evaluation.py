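"""Cross-validated recognizability statistics.

One deep-learning experiment = ``n_sessions`` independent sessions, each
training a freshly initialized CNN on a freshly drawn training pool and
testing on the same fixed test pool.  Per test window we record a boolean
correctness per session (the SessionMatrix) and reduce it to:

* AR (accuracy rate): percent of sessions in which the window was
  classified correctly;
* HR fraction: percent of windows correct in at least 8 of 10 sessions;
* the recognition-count distribution over 0..n_sessions;
* ordinary least-squares regressions of AR on the ripple's intrinsic
  frequency (per animal and pooled, per condition);
* equal-variance two-sample t-tests on per-animal means, with Bonferroni
  correction over the planned comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import derive_seed
from .cnn import RippleCNN, TrainConfig, predict_pool, train
from .rci import RCIPool, masked_waveform

__all__ = [
    "SessionMatrix",
    "RegressionResult",
    "run_experiment",
    "accuracy_rate",
    "hr_fraction",
    "recognition_distribution",
    "freq_ar_regression",
    "group_compare",
]


@dataclass
class SessionMatrix:
    """Per-RCI, per-session correctness over one experiment."""

    correct: np.ndarray  # (n_rci, n_sessions) bool
    rci_ids: list
    animal_ids: list
    conditions: list
    freqs: np.ndarray
    variant: str = "full"
    group: str = ""

    @property
    def n_sessions(self) -> int:
        return self.correct.shape[1]

    def column_accuracy(self) -> np.ndarray:
        """Per-session test accuracy, percent."""
        return self.correct.mean(axis=0) * 100.0


def _prepare(pool: RCIPool, normalization: str, mask_mode: str,
             mu: float | None = None, sd: float | None = None):
    """Normalize with the training pool's global stats, then mask.

    Masking comes after normalization so masked samples are exactly zero
    (carry no information) regardless of the pool statistics.
    """
    X = pool.waveforms()
    if normalization == "pool_z":
        if mu is None:
            mu, sd = float(X.mean()), float(X.std())
        X = (X - mu) / sd
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    if mask_mode != "full":
        bounds = pool.bounds()
        X = np.stack(
            [
                masked_waveform(x, i0, i1, mask_mode)
                for x, (i0, i1) in zip(X, bounds)
            ]
        )
    return X, mu, sd


def run_experiment(
    test_pool: RCIPool,
    train_pools: list[RCIPool],
    model_factory,
    train_config: TrainConfig,
    mask_mode: str = "full",
    variant: str = "full",
    group: str = "",
) -> SessionMatrix:
    """Train one fresh model per session, test all on the fixed pool.

    ``model_factory(seed)`` must return an initialized RippleCNN.  Session
    seeds (initialization and batch shuffling) are derived from
    ``train_config.seed`` and the session index, so a run is fully
    reproducible from one master seed.
    """
    if not train_pools:
        raise ValueError("need at least one training pool")
    y_test = test_pool.labels()
    columns = []
    for s, tp in enumerate(train_pools):
        Xtr, mu, sd = _prepare(tp, train_config.input_normalization, mask_mode)
        Xte, _, _ = _prepare(
            test_pool, train_config.input_normalization, mask_mode, mu=mu, sd=sd
        )
        model = model_factory(derive_seed(train_config.seed, "init", s))
        cfg = TrainConfig(
            epochs=train_config.epochs,
            batch_size=train_config.batch_size,
            learning_rate=train_config.learning_rate,
            seed=derive_seed(train_config.seed, "batches", s),
            input_normalization=train_config.input_normalization,
            drop_last=train_config.drop_last,
        )
        train(model, Xtr, tp.labels(), cfg)
        _, correct = predict_pool(model, Xte, y_test)
        columns.append(correct)
    return SessionMatrix(
        correct=np.stack(columns, axis=1),
        rci_ids=[r.rci_id for r in test_pool.rcis],
        animal_ids=[r.animal_id for r in test_pool.rcis],
        conditions=[r.condition for r in test_pool.rcis],
        freqs=test_pool.freqs(),
        variant=variant,
        group=group,
    )


def accuracy_rate(matrix: SessionMatrix):
    """Per-RCI AR records plus per-animal and group means (percent)."""
    n_correct = matrix.correct.sum(axis=1)
    records = pd.DataFrame(
        {
            "rci_id": matrix.rci_ids,
            "animal": matrix.animal_ids,
            "condition": matrix.conditions,
            "freq_hz": matrix.freqs,
            "n_correct": n_correct,
            "AR": 100.0 * n_correct / matrix.n_sessions,
        }
    )
    per_animal = (
        records.groupby("animal", as_index=False)["AR"].mean().rename(columns={"AR": "mean_AR"})
    )
    group_mean = float(records["AR"].mean())
    return records, per_animal, group_mean


def hr_fraction(
    records: pd.DataFrame, threshold_sessions: int = 8, n_sessions: int = 10
) -> float:
    """Percent of RCIs correctly classified in >= 8 of 10 sessions."""
    frac = (records["n_correct"] >= threshold_sessions).mean()
    return float(frac * 100.0)


def hr_fraction_per_animal(
    records: pd.DataFrame, threshold_sessions: int = 8
) -> pd.DataFrame:
    hr = (
        records.assign(hr=records["n_correct"] >= threshold_sessions)
        .groupby("animal", as_index=False)["hr"]
        .mean()
    )
    hr["hr"] *= 100.0
    return hr.rename(columns={"hr": "hr_pct"})


def recognition_distribution(matrix: SessionMatrix) -> np.ndarray:
    """Percent of RCIs per correct-count 0..n_sessions (sums to 100)."""
    n_correct = matrix.correct.sum(axis=1)
    counts = np.bincount(n_correct, minlength=matrix.n_sessions + 1)
    return counts / counts.sum() * 100.0


@dataclass(frozen=True)
class RegressionResult:
    slope: float  # percent AR per Hz
    intercept: float
    r_squared: float
    scope: str  # per_animal | pooled
    condition: str
    animal: str = ""
    n: int = 0


def freq_ar_regression(
    records: pd.DataFrame, scope: str = "pooled", condition: str = "before"
):
    """OLS of AR (%) on intrinsic frequency (Hz).

    ``scope='pooled'`` returns one RegressionResult; ``scope='per_animal'``
    returns a list with one result per animal.
    """
    sub = records[records["condition"] == condition]
    if scope == "pooled":
        return _ols(sub, scope, condition, "")
    if scope == "per_animal":
        return [
            _ols(g, scope, condition, animal)
            for animal, g in sub.groupby("animal")
        ]
    raise ValueError(f"unknown scope {scope!r}")


def _ols(sub: pd.DataFrame, scope: str, condition: str, animal: str) -> RegressionResult:
    if len(sub) < 3:
        raise ValueError("need at least 3 records for a regression")
    x = sub["freq_hz"].to_numpy()
    y = sub["AR"].to_numpy()
    if np.ptp(x) == 0:
        raise ValueError("zero frequency variance")
    if np.ptp(y) == 0:
        # constant response: flat line, no explained variance
        return RegressionResult(0.0, float(y[0]), 0.0, scope, condition, animal, len(sub))
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        scope=scope,
        condition=condition,
        animal=animal,
        n=len(sub),
    )


def group_compare(values_a, values_b, n_comparisons: int = 1):
    """Equal-variance two-sample t-test on per-animal means + Bonferroni."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and a.mean() == b.mean():
        return 0.0, 1.0, 1.0
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), float(min(1.0, p * n_comparisons))
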