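"""Ripple-centered intervals (RCIs) and pool construction.

An RCI is a 256-ms window (512 samples at 2 kHz) of raw LFP centered on one
detected ripple's envelope peak.  Windows must lie inside one SWS interval,
must not contain any other detected ripple, must keep a 10-ms guard from
every neighboring ripple's bounds, and must not overlap each other.  Pools
follow the cross-validation protocol: one fixed test pool per condition and
a freshly drawn training pool per session (n per animal per condition),
disjoint from the test pool.  The frequency-equalization step subsamples the
training pool so the pre/post intrinsic-frequency histograms match bin by
bin, and the masking step zeroes either the ripple or its surround.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import derive_rng
from .detection import SWREvent

__all__ = [
    "RCI",
    "RCIPool",
    "extract_rcis",
    "build_pools",
    "equalize_frequency",
    "apply_mask",
    "masked_waveform",
    "PoolError",
]

WINDOW_SAMPLES = 512
WINDOW_S = 0.256
GUARD_S = 0.010
MASK_MODES = ("full", "swr_only", "surround_only")


class PoolError(ValueError):
    """Raised when a pool cannot be filled from the available RCIs."""


@dataclass
class RCI:
    """One 256-ms ripple-centered window of raw LFP."""

    waveform: np.ndarray  # 512 samples
    rci_id: str
    animal_id: str
    condition: str  # before | after
    freq_hz: float
    onset_idx: int  # ripple bounds within the window (inclusive indices)
    offset_idx: int
    mask_mode: str = "full"

    def __post_init__(self) -> None:
        if self.waveform.size != WINDOW_SAMPLES:
            raise ValueError(f"RCI waveform must have {WINDOW_SAMPLES} samples")
        if self.mask_mode not in MASK_MODES:
            raise ValueError(f"unknown mask mode {self.mask_mode!r}")


@dataclass
class RCIPool:
    """A labeled collection of RCIs (fixed test pool or one training pool)."""

    rcis: list
    role: str  # test | train
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.rci_id for r in self.rcis]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate rci_id within one pool")

    def __len__(self) -> int:
        return len(self.rcis)

    def waveforms(self) -> np.ndarray:
        return np.stack([r.waveform for r in self.rcis])

    def labels(self) -> np.ndarray:
        """0 = before, 1 = after."""
        return np.array([int(r.condition == "after") for r in self.rcis])

    def freqs(self) -> np.ndarray:
        return np.array([r.freq_hz for r in self.rcis])

    def bounds(self) -> np.ndarray:
        """(N, 2) ripple onset/offset sample indices within each window."""
        return np.array([(r.onset_idx, r.offset_idx) for r in self.rcis])

    def condition_counts(self) -> dict:
        labels = self.labels()
        return {"before": int((labels == 0).sum()), "after": int((labels == 1).sum())}

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rci_id": [r.rci_id for r in self.rcis],
                "animal": [r.animal_id for r in self.rcis],
                "condition": [r.condition for r in self.rcis],
                "freq_hz": [r.freq_hz for r in self.rcis],
                "pool_role": self.role,
                "session": self.provenance.get("session", ""),
            }
        )


def extract_rcis(recording, events: list[SWREvent]) -> list[RCI]:
    """Greedy temporal admission of 256-ms windows around event peaks.

    ``recording`` needs .samples, .sampling_rate, .sws_intervals,
    .animal_id, .condition.  Events must be sorted by onset.  An event is
    skipped if its window would leave the recording or its SWS interval,
    would contain (or come within 10 ms of) another event, or would overlap
    an already-accepted window.
    """
    rate = recording.sampling_rate
    x = np.asarray(recording.samples)
    n = x.size
    half = WINDOW_SAMPLES // 2
    onsets = [ev.onset for ev in events]
    if onsets != sorted(onsets):
        raise ValueError("events must be sorted by onset")

    accepted: list[RCI] = []
    last_end = -1
    for j, ev in enumerate(events):
        c = int(round(ev.peak_time * rate))
        w0, w1 = c - half, c + half
        if w0 < 0 or w1 > n:
            continue
        t0, t1 = w0 / rate, w1 / rate
        if not any(s <= t0 and t1 <= e for s, e in recording.sws_intervals):
            continue
        clear = all(
            other.offset + GUARD_S <= t0 or other.onset - GUARD_S >= t1
            for k, other in enumerate(events)
            if k != j
        )
        if not clear:
            continue
        if w0 < last_end:
            continue
        accepted.append(
            RCI(
                waveform=x[w0:w1].astype(float).copy(),
                rci_id=f"{recording.animal_id}-{recording.condition}-{j:05d}",
                animal_id=recording.animal_id,
                condition=recording.condition,
                freq_hz=float(ev.intrinsic_freq),
                onset_idx=int(np.clip(round(ev.onset * rate) - w0, 0, WINDOW_SAMPLES - 1)),
                offset_idx=int(np.clip(round(ev.offset * rate) - w0, 0, WINDOW_SAMPLES - 1)),
            )
        )
        last_end = w1
    return accepted


def build_pools(
    rcis_by_animal_condition: dict,
    n_test: int = 2000,
    n_train_per_animal: int = 200,
    master_seed: int = 0,
    n_sessions: int = 10,
) -> tuple[RCIPool, list[RCIPool]]:
    """One fixed test pool (n_test per condition) + n_sessions training pools.

    ``rcis_by_animal_condition`` maps (animal_id, condition) -> list of RCI.
    The test pool is drawn once, without replacement, across animals; each
    session's training pool draws n_train_per_animal per animal per
    condition from the RCIs left over after the test draw (re-drawn fresh
    each session, so sessions may reuse RCIs across sessions).
    """
    conditions = ("before", "after")
    remaining: dict = {}
    test_rcis: list = []
    rng_test = derive_rng(master_seed, "test-pool")
    for cond in conditions:
        pool = [
            r
            for (animal, c), lst in sorted(rcis_by_animal_condition.items())
            for r in lst
            if c == cond
        ]
        if len(pool) < n_test:
            raise PoolError(
                f"condition {cond!r}: {len(pool)} RCIs available, "
                f"{n_test} needed for the test pool"
            )
        idx = rng_test.choice(len(pool), size=n_test, replace=False)
        chosen = set(idx.tolist())
        test_rcis.extend(pool[i] for i in idx)
        leftovers = [r for i, r in enumerate(pool) if i not in chosen]
        for r in leftovers:
            remaining.setdefault((r.animal_id, cond), []).append(r)

    for (animal, cond) in sorted(rcis_by_animal_condition):
        have = len(remaining.get((animal, cond), []))
        if have < n_train_per_animal:
            raise PoolError(
                f"animal {animal!r} condition {cond!r}: {have} RCIs left after "
                f"the test draw, {n_train_per_animal} needed per training pool"
            )

    test_pool = RCIPool(
        rcis=test_rcis, role="test",
        provenance={"seed": master_seed, "session": "fixed"},
    )
    train_pools = []
    for s in range(n_sessions):
        rng_s = derive_rng(master_seed, "train-pool", s)
        chosen = []
        for key in sorted(remaining):
            lst = remaining[key]
            idx = rng_s.choice(len(lst), size=n_train_per_animal, replace=False)
            chosen.extend(lst[i] for i in idx)
        train_pools.append(
            RCIPool(rcis=chosen, role="train",
                    provenance={"seed": master_seed, "session": s})
        )
    return test_pool, train_pools


def equalize_frequency(
    pool: RCIPool, bin_width: float = 2.0, seed: int = 0
) -> RCIPool:
    """Subsample so pre/post intrinsic-frequency histograms match per bin.

    Frequencies are binned at ``bin_width`` Hz; in every bin occupied by
    both conditions the larger side is randomly subsampled to the smaller
    side's count; bins occupied by a single condition are dropped.  The
    output order is shuffled.
    """
    rng = derive_rng(seed, "equalize")
    by_bin: dict = {}
    for r in pool.rcis:
        b = int(np.floor(r.freq_hz / bin_width))
        by_bin.setdefault(b, {"before": [], "after": []})[r.condition].append(r)

    kept = []
    any_overlap = False
    for b in sorted(by_bin):
        before, after = by_bin[b]["before"], by_bin[b]["after"]
        if not before or not after:
            continue
        any_overlap = True
        k = min(len(before), len(after))
        for side in (before, after):
            if len(side) == k:
                kept.extend(side)
            else:
                idx = rng.choice(len(side), size=k, replace=False)
                kept.extend(side[i] for i in idx)
    if not any_overlap:
        raise PoolError("no frequency bin is occupied by both conditions")
    order = rng.permutation(len(kept))
    return RCIPool(
        rcis=[kept[i] for i in order],
        role=pool.role,
        provenance={**pool.provenance, "equalized_bin_hz": bin_width},
    )


def masked_waveform(
    waveform: np.ndarray, onset_idx: int, offset_idx: int, mode: str
) -> np.ndarray:
    """Zero samples outside (swr_only) or inside (surround_only) the ripple.

    The ripple spans the inclusive index range [onset_idx, offset_idx].
    """
    if mode == "full":
        return waveform.copy()
    out = waveform.copy()
    if mode == "swr_only":
        out[: onset_idx] = 0.0
        out[offset_idx + 1 :] = 0.0
    elif mode == "surround_only":
        out[onset_idx : offset_idx + 1] = 0.0
    else:
        raise ValueError(f"unknown mask mode {mode!r}")
    return out


def apply_mask(rci: RCI, mode: str) -> RCI:
    """Return a masked copy; masking an already-masked RCI is an error."""
    if rci.mask_mode != "full":
        raise ValueError("RCI is already masked")
    return replace(
        rci,
        waveform=masked_waveform(rci.waveform, rci.onset_idx, rci.offset_idx, mode),
        mask_mode=mode,
    )
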