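"""RCI extraction geometry, pool construction, equalization, masking."""

from dataclasses import dataclass, field

import numpy as np
import pytest

from ripplelearn.detection import SWREvent
from ripplelearn.rci import (
    PoolError,
    RCI,
    RCIPool,
    WINDOW_SAMPLES,
    apply_mask,
    build_pools,
    equalize_frequency,
    extract_rcis,
)

RATE = 2000.0


@dataclass
class FakeRecording:
    samples: np.ndarray
    sampling_rate: float = RATE
    sws_intervals: list = field(default_factory=lambda: [(0.0, 10.0)])
    animal_id: str = "a0"
    condition: str = "before"


def ev(peak, half_dur=0.02, freq=150.0):
    return SWREvent(
        onset=peak - half_dur,
        offset=peak + half_dur,
        peak_time=peak,
        peak_z=6.0,
        intrinsic_freq=freq,
    )


def make_rci(i, animal="a0", condition="before", freq=150.0):
    return RCI(
        waveform=np.zeros(WINDOW_SAMPLES),
        rci_id=f"{animal}-{condition}-{i}",
        animal_id=animal,
        condition=condition,
        freq_hz=freq,
        onset_idx=224,
        offset_idx=288,
    )


class TestExtractRCIs:
    def test_single_event_window_geometry(self):
        x = np.arange(4000.0)  # 2 s ramp makes content checkable
        rec = FakeRecording(x, sws_intervals=[(0.0, 2.0)])
        (rci,) = extract_rcis(rec, [ev(1.0)])
        assert rci.waveform.size == 512
        # [0.872 s, 1.128 s) at 2 kHz = samples 1744..2256
        assert rci.waveform[0] == 1744.0
        assert rci.waveform[-1] == 2255.0

    def test_event_near_edge_excluded(self):
        rec = FakeRecording(np.zeros(4000), sws_intervals=[(0.0, 2.0)])
        assert extract_rcis(rec, [ev(0.05)]) == []

    def test_window_must_fit_in_one_sws_interval(self):
        rec = FakeRecording(np.zeros(8000), sws_intervals=[(0.0, 1.0), (1.05, 4.0)])
        assert extract_rcis(rec, [ev(0.95)]) == []  # window crosses interval end
        assert len(extract_rcis(rec, [ev(2.0)])) == 1

    def test_close_pair_yields_none(self):
        # 100 ms apart: each 256-ms window contains the other event, so the
        # exhaustive constraint check rejects both candidates
        rec = FakeRecording(np.zeros(8000), sws_intervals=[(0.0, 4.0)])
        got = extract_rcis(rec, [ev(1.0), ev(1.1)])
        assert got == []

    def test_guard_distance_boundary(self):
        rec = FakeRecording(np.zeros(16000), sws_intervals=[(0.0, 8.0)])
        # neighbor onset 5 ms after the first window's end: inside the 10 ms
        # guard, so neither candidate survives
        got = extract_rcis(rec, [ev(1.0), ev(1.0 + 0.128 + 0.005 + 0.02)])
        assert got == []
        # neighbor onset exactly 10 ms after the window end: first window is
        # admissible; the second overlaps an accepted window and is skipped
        got = extract_rcis(rec, [ev(1.0), ev(1.0 + 0.128 + 0.010 + 0.02)])
        assert len(got) == 1
        assert got[0].rci_id.endswith("00000")

    def test_far_events_all_admitted_and_disjoint(self):
        rec = FakeRecording(np.zeros(20000), sws_intervals=[(0.0, 10.0)])
        events = [ev(1.0 + 0.4 * k) for k in range(8)]
        got = extract_rcis(rec, events)
        assert len(got) == 8
        ids = [r.rci_id for r in got]
        assert len(set(ids)) == 8

    def test_unsorted_events_rejected(self):
        rec = FakeRecording(np.zeros(8000))
        with pytest.raises(ValueError):
            extract_rcis(rec, [ev(2.0), ev(1.0)])


class TestBuildPools:
    def _bank(self, n_per=120, animals=("a0", "a1", "a2")):
        bank = {}
        for a in animals:
            for c in ("before", "after"):
                bank[(a, c)] = [make_rci(i, a, c, 140.0 + i % 20) for i in range(n_per)]
        return bank

    def test_counts_and_disjointness(self):
        bank = self._bank()
        test_pool, train_pools = build_pools(
            bank, n_test=100, n_train_per_animal=30, master_seed=5, n_sessions=4
        )
        assert test_pool.condition_counts() == {"before": 100, "after": 100}
        assert len(train_pools) == 4
        test_ids = {r.rci_id for r in test_pool.rcis}
        for tp in train_pools:
            assert tp.condition_counts() == {"before": 90, "after": 90}
            assert test_ids.isdisjoint({r.rci_id for r in tp.rcis})

    def test_determinism(self):
        bank = self._bank()
        a = build_pools(bank, 50, 20, master_seed=9, n_sessions=2)
        b = build_pools(bank, 50, 20, master_seed=9, n_sessions=2)
        assert [r.rci_id for r in a[0].rcis] == [r.rci_id for r in b[0].rcis]
        for ta, tb in zip(a[1], b[1]):
            assert [r.rci_id for r in ta.rcis] == [r.rci_id for r in tb.rcis]

    def test_single_session(self):
        _, train_pools = build_pools(self._bank(), 50, 20, 0, n_sessions=1)
        assert len(train_pools) == 1

    def test_insufficient_rcis_names_culprit(self):
        bank = self._bank(n_per=40)
        with pytest.raises(PoolError, match="condition"):
            build_pools(bank, n_test=200, n_train_per_animal=10, master_seed=0)
        bank = self._bank(n_per=60)
        with pytest.raises(PoolError, match="a"):
            build_pools(bank, n_test=100, n_train_per_animal=50, master_seed=0)


class TestEqualizeFrequency:
    def _pool(self, before, after):
        rcis = [make_rci(i, "a0", "before", f) for i, f in enumerate(before)]
        rcis += [make_rci(100 + i, "a0", "after", f) for i, f in enumerate(after)]
        return RCIPool(rcis=rcis, role="train")

    def test_brute_force_bin_bookkeeping(self):
        # 2-Hz bins: [140,142) pairs 140/141; [150,152) pairs 150/151;
        # 142 and 149 sit in single-condition bins and are dropped
        pool = self._pool([140.0, 142.0, 150.0], [141.0, 149.0, 151.0])
        out = equalize_frequency(pool, bin_width=2.0, seed=0)
        freqs = sorted(r.freq_hz for r in out.rcis)
        assert freqs == [140.0, 141.0, 150.0, 151.0]
        assert out.condition_counts() == {"before": 2, "after": 2}

    def test_identical_multisets_fully_retained(self):
        pool = self._pool([140.0, 144.5, 150.0], [140.5, 144.0, 151.0])
        out = equalize_frequency(pool, bin_width=2.0, seed=1)
        assert len(out) == 6

    def test_per_bin_equality_on_random_pools(self, rng):
        before = rng.normal(140, 5, 300)
        after = rng.normal(150, 5, 300)
        pool = self._pool(before, after)
        out = equalize_frequency(pool, bin_width=2.0, seed=2)
        for b in {int(np.floor(r.freq_hz / 2.0)) for r in out.rcis}:
            n_b = sum(
                1 for r in out.rcis
                if int(np.floor(r.freq_hz / 2.0)) == b and r.condition == "before"
            )
            n_a = sum(
                1 for r in out.rcis
                if int(np.floor(r.freq_hz / 2.0)) == b and r.condition == "after"
            )
            assert n_b == n_a

    def test_idempotence_same_seed(self, rng):
        pool = self._pool(rng.normal(140, 5, 100), rng.normal(150, 5, 100))
        once = equalize_frequency(pool, seed=3)
        twice = equalize_frequency(once, seed=3)
        assert sorted(r.rci_id for r in once.rcis) == sorted(
            r.rci_id for r in twice.rcis
        )

    def test_disjoint_ranges_rejected(self):
        pool = self._pool([120.0, 122.0], [200.0, 202.0])
        with pytest.raises(PoolError):
            equalize_frequency(pool, seed=0)


class TestMasking:
    def _rci(self, rng):
        r = make_rci(0)
        r.waveform = rng.standard_normal(WINDOW_SAMPLES)
        r.onset_idx, r.offset_idx = 192, 320
        return r

    def test_full_is_identity(self, rng):
        r = self._rci(rng)
        out = apply_mask(r, "full")
        assert np.array_equal(out.waveform, r.waveform)

    def test_swr_only_zeroes_head_and_tail(self, rng):
        r = self._rci(rng)
        out = apply_mask(r, "swr_only")
        assert np.all(out.waveform[:192] == 0.0)
        assert np.all(out.waveform[321:] == 0.0)
        assert np.array_equal(out.waveform[192:321], r.waveform[192:321])

    def test_surround_only_zeroes_ripple(self, rng):
        r = self._rci(rng)
        out = apply_mask(r, "surround_only")
        assert np.all(out.waveform[192:321] == 0.0)
        assert np.array_equal(out.waveform[:192], r.waveform[:192])
        assert np.array_equal(out.waveform[321:], r.waveform[321:])

    def test_masks_are_complementary(self, rng):
        r = self._rci(rng)
        a = apply_mask(r, "swr_only").waveform
        b = apply_mask(r, "surround_only").waveform
        assert np.array_equal(a + b, r.waveform)

    def test_double_masking_rejected(self, rng):
        r = apply_mask(self._rci(rng), "swr_only")
        with pytest.raises(ValueError):
            apply_mask(r, "surround_only")
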