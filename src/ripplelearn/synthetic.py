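"""Synthetic slow-wave-sleep LFP with planted sharp-wave-ripple events.

The generator emulates the statistical structure a CA1 channel shows during
SWS: a 1/f ("pink") broadband floor plus a ~1 Hz slow oscillation, with
transient ripple-band bursts (Gaussian-windowed sinusoids, 100-250 Hz)
planted at Poisson times.  Two experimental conditions ("before" vs "after"
a learning session) can differ in the bursts' intrinsic-frequency mean and,
optionally, in the amplitude of a low-frequency deflection flanking each
burst (the peri-event signature).  A wild-type-like cohort carries a
post-learning frequency shift; an AD-like cohort has identical condition
distributions and half the ripple rate, providing a null.

Each planted burst is amplitude-calibrated so that its ripple-band envelope,
z-scored against the recording's own SWS baseline, peaks at a target z drawn
from a configured range - the downstream threshold detector is z-based, so
the z level is the quantity that must be controlled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from ._util import derive_seed
from .detection import BandpassSpec, analytic_envelope, _sws_mask

__all__ = [
    "BackgroundSpec",
    "PeriSignatureSpec",
    "GeneratorConfig",
    "TruthEvent",
    "SyntheticRecording",
    "synthesize_ripple",
    "generate_background",
    "generate_recording",
    "generate_cohort",
    "truth_frame",
]

#: minimum spacing between planted event peaks: one 256-ms window plus
#: 2 x 10 ms guard, so every planted event can yield an admissible RCI
MIN_EVENT_SPACING_S = 0.278
_EDGE_MARGIN_S = 0.25  # keep windows + signatures inside the SWS interval


@dataclass(frozen=True)
class BackgroundSpec:
    """SWS-like background: slow oscillation plus 1/f noise (arbitrary units)."""

    slow_osc_freq_hz: float = 1.0
    slow_osc_amp: float = 3.0
    pink_exponent: float = 1.0
    pink_amp: float = 1.0


@dataclass(frozen=True)
class PeriSignatureSpec:
    """Low-frequency deflection in the 40 ms flanking each ripple.

    In ``condition_dependent`` mode the deflection amplitude differs between
    conditions, planting class information *outside* the ripple bounds -
    the target of the head/tail masking experiments.
    """

    mode: str = "none"  # none | condition_dependent
    amp_before: float = 1.0
    amp_after: float = 2.0
    width_ms: float = 40.0
    offset_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "condition_dependent"):
            raise ValueError(f"unknown peri-signature mode {self.mode!r}")


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic recording, fully determined by ``seed``."""

    sampling_rate: float = 2000.0
    duration: float = 240.0
    ripple_rate: float = 0.5
    freq_mean_before: float = 140.0
    freq_mean_after: float = 150.0
    freq_sd: float = 5.0
    ripple_duration_mean: float = 64.0
    ripple_duration_sd: float = 10.0
    ripple_peak_z_target: tuple[float, float] = (6.0, 9.0)
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    peri_signature: PeriSignatureSpec = field(default_factory=PeriSignatureSpec)
    seed: int = 0


@dataclass(frozen=True)
class TruthEvent:
    """Ground truth for one planted ripple."""

    peak_s: float
    freq_hz: float
    duration_ms: float
    target_z: float


@dataclass
class SyntheticRecording:
    samples: np.ndarray
    sampling_rate: float
    sws_intervals: list[tuple[float, float]]
    truth_events: list[TruthEvent]
    animal_id: str = "wt00"
    genotype: str = "WT"  # WT | APPPS1
    condition: str = "before"  # before | after
    day: int = 1

    def save(self, path) -> None:
        truth = np.array(
            [(e.peak_s, e.freq_hz, e.duration_ms, e.target_z) for e in self.truth_events],
            dtype=float,
        ).reshape(-1, 4)
        meta = dict(
            animal_id=self.animal_id, genotype=self.genotype,
            condition=self.condition, day=self.day,
            sampling_rate=self.sampling_rate,
        )
        np.savez_compressed(
            path,
            samples=self.samples,
            sws_intervals=np.asarray(self.sws_intervals, dtype=float),
            truth=truth,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path) -> "SyntheticRecording":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            truth = [TruthEvent(*row) for row in z["truth"]]
            return cls(
                samples=z["samples"],
                sampling_rate=float(meta["sampling_rate"]),
                sws_intervals=[tuple(r) for r in z["sws_intervals"]],
                truth_events=truth,
                animal_id=meta["animal_id"],
                genotype=meta["genotype"],
                condition=meta["condition"],
                day=int(meta["day"]),
            )


def synthesize_ripple(
    frequency: float, duration_ms: float, amplitude: float, sampling_rate: float
) -> np.ndarray:
    """Gaussian-windowed sinusoid standing in for one SWR.

    sigma = duration/4, so the template is truncated at +/-2 sigma.  Note
    the detector's 2-z onset/offset crossings sit at roughly +/-1.3 sigma
    for typical peak amplitudes (6-9 z over a 1-z baseline), so a bout's
    *measured* duration is ~0.65x the nominal one; a sharper peak keeps
    the envelope argmax (the window anchor) tightly localized.  The phase
    is locked so the central sample sits on a cosine peak (peak amplitude
    equals ``amplitude`` exactly).
    """
    if not 100.0 < frequency < 250.0:
        raise ValueError(f"frequency {frequency} Hz outside the ripple band")
    if not 20.0 <= duration_ms <= 100.0:
        raise ValueError(f"duration {duration_ms} ms outside (20, 100) ms")
    n = int(round(duration_ms * sampling_rate / 1000.0))
    t = (np.arange(n) - n // 2) / sampling_rate
    sigma = duration_ms / 4000.0
    return amplitude * np.exp(-(t**2) / (2 * sigma**2)) * np.cos(2 * np.pi * frequency * t)


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n)
    return x / x.std()


def generate_background(
    n: int, rate: float, spec: BackgroundSpec, rng: np.random.Generator
) -> np.ndarray:
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    slow = spec.slow_osc_amp * np.sin(2 * np.pi * spec.slow_osc_freq_hz * t + phase)
    return spec.pink_amp * _pink_noise(n, spec.pink_exponent, rng) + slow


def _default_sws_intervals(duration: float) -> list[tuple[float, float]]:
    half = duration / 2.0
    return [(1.0, half - 0.5), (half + 0.5, duration - 1.0)]


def _plan_event_times(
    rng: np.random.Generator,
    sws_intervals,
    ripple_rate: float,
    spacing: float = MIN_EVENT_SPACING_S,
) -> np.ndarray:
    if ripple_rate < 0:
        raise ValueError("ripple_rate must be nonnegative")
    if ripple_rate * spacing > 0.5:
        raise ValueError(
            f"ripple_rate {ripple_rate}/s infeasible under the "
            f"{spacing * 1000:.0f} ms exclusion window"
        )
    usable = [
        (s + _EDGE_MARGIN_S, e - _EDGE_MARGIN_S)
        for s, e in sws_intervals
        if e - s > 2 * _EDGE_MARGIN_S
    ]
    total = sum(e - s for s, e in usable)
    n = rng.poisson(ripple_rate * total)
    if n == 0:
        return np.empty(0)
    u = rng.uniform(0, total, size=n)
    times = np.empty(n)
    offsets = np.cumsum([0.0] + [e - s for s, e in usable])
    for i, ui in enumerate(np.sort(u)):
        k = int(np.searchsorted(offsets[1:], ui, side="right"))
        k = min(k, len(usable) - 1)
        times[i] = usable[k][0] + (ui - offsets[k])
    kept = []
    for t in times:
        if not kept or t - kept[-1] > spacing:
            kept.append(t)
    return np.asarray(kept)


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _signature_bump(rate: float, width_ms: float) -> np.ndarray:
    """Monophasic low-frequency deflection (Gaussian, sigma = width/4)."""
    n = int(round(width_ms * rate / 1000.0))
    t = (np.arange(n) - n // 2) / rate
    sigma = width_ms / 4000.0
    return -np.exp(-(t**2) / (2 * sigma**2))


def _add_at(signal_arr: np.ndarray, waveform: np.ndarray, center_idx: int) -> None:
    start = center_idx - waveform.size // 2
    i0, i1 = max(0, start), min(signal_arr.size, start + waveform.size)
    if i1 > i0:
        signal_arr[i0:i1] += waveform[i0 - start : i1 - start]


def generate_recording(
    config: GeneratorConfig,
    condition: str,
    animal_id: str = "wt00",
    genotype: str = "WT",
    day: int = 1,
    seed: int | None = None,
) -> SyntheticRecording:
    """One condition's recording: background + signatures + calibrated ripples.

    Calibration iterates: compose the signal, run the same band-pass +
    envelope + SWS z-scoring the detector will use, then rescale each burst
    toward its target peak z until all bursts are within +/-0.4 z.
    """
    if config.duration < 10:
        raise ValueError("duration must be at least 10 s")
    if condition not in ("before", "after"):
        raise ValueError(f"unknown condition {condition!r}")
    rate = config.sampling_rate
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.duration * rate))
    sws = _default_sws_intervals(config.duration)

    base = generate_background(n, rate, config.background, rng)

    times = _plan_event_times(rng, sws, config.ripple_rate)
    m = times.size
    freq_mean = (
        config.freq_mean_before if condition == "before" else config.freq_mean_after
    )
    freqs = _truncnorm(rng, freq_mean, config.freq_sd, 100.0 + 1e-6, 250.0 - 1e-6, m)
    durs = _truncnorm(
        rng, config.ripple_duration_mean, config.ripple_duration_sd, 20.0, 100.0, m
    )
    z_lo, z_hi = config.ripple_peak_z_target
    z_targets = rng.uniform(z_lo, z_hi, size=m)

    sig_spec = config.peri_signature
    if sig_spec.mode == "condition_dependent" and m > 0:
        amp = sig_spec.amp_before if condition == "before" else sig_spec.amp_after
        bump = amp * _signature_bump(rate, sig_spec.width_ms)
        off = sig_spec.offset_ms / 1000.0
        for t, d in zip(times, durs):
            half = d / 2000.0
            _add_at(base, bump, int(round((t - half - off) * rate)))
            _add_at(base, bump, int(round((t + half + off) * rate)))

    sos = BandpassSpec().sos(rate)
    sws_mask = _sws_mask(n, rate, sws)
    ripples = [
        synthesize_ripple(f, d, 1.0, rate) for f, d in zip(freqs, durs)
    ]
    centers = np.round(times * rate).astype(int)

    if m > 0:
        env0 = analytic_envelope(sps.sosfiltfilt(sos, base))
        mu0, sd0 = env0[sws_mask].mean(), env0[sws_mask].std()
        amps = (mu0 + z_targets * sd0) / 0.85  # ~envelope gain of a burst
        half_w = int(round(0.010 * rate))
        for _ in range(4):
            sig = base.copy()
            for a, w, c in zip(amps, ripples, centers):
                _add_at(sig, a * w, c)
            env = analytic_envelope(sps.sosfiltfilt(sos, sig))
            mu, sd = env[sws_mask].mean(), env[sws_mask].std()
            peaks = np.array(
                [env[max(0, c - half_w) : c + half_w].max() for c in centers]
            )
            z = (peaks - mu) / sd
            if np.all(np.abs(z - z_targets) <= 0.4):
                break
            amps *= (mu + z_targets * sd) / np.maximum(peaks, 1e-12)
        samples = sig
    else:
        samples = base

    # Session-gain normalization: express the recording in units of its own
    # ripple-band envelope baseline SD.  Real pipelines absorb per-session
    # amplifier gain the same way; without it, each recording's composite
    # amplitude scale is a random fingerprint that confounds condition
    # (one before + one after recording per animal) and breaks the
    # no-class-information null.  Detection is z-scored, so it is unaffected.
    env_final = analytic_envelope(sps.sosfiltfilt(sos, samples))
    samples = samples / env_final[sws_mask].std()

    truth = [
        TruthEvent(peak_s=float(t), freq_hz=float(f), duration_ms=float(d), target_z=float(z))
        for t, f, d, z in zip(times, freqs, durs, z_targets)
    ]
    return SyntheticRecording(
        samples=samples,
        sampling_rate=rate,
        sws_intervals=sws,
        truth_events=truth,
        animal_id=animal_id,
        genotype=genotype,
        condition=condition,
        day=day,
    )


def generate_cohort(
    config: GeneratorConfig, n_animals: int, genotype_mode: str
) -> list[SyntheticRecording]:
    """Before/after recording pair for each animal of one genotype.

    WT_like keeps the configured condition contrast.  AD_like removes it:
    identical frequency means, half the ripple rate, and no
    condition-dependent peri-event signature (the AD-like cohort is the
    no-class-information null).
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    if genotype_mode == "WT_like":
        cfg, genotype, prefix = config, "WT", "wt"
    elif genotype_mode == "AD_like":
        cfg = replace(
            config,
            freq_mean_after=config.freq_mean_before,
            ripple_rate=config.ripple_rate / 2.0,
            peri_signature=replace(config.peri_signature, mode="none"),
        )
        genotype, prefix = "APPPS1", "ad"
    else:
        raise ValueError(f"unknown genotype_mode {genotype_mode!r}")

    recordings = []
    for i in range(n_animals):
        animal_id = f"{prefix}{i:02d}"
        for condition in ("before", "after"):
            rec_seed = derive_seed(cfg.seed, genotype_mode, animal_id, condition)
            recordings.append(
                generate_recording(
                    cfg, condition, animal_id=animal_id, genotype=genotype,
                    day=1, seed=rec_seed,
                )
            )
    return recordings


def truth_frame(recordings) -> pd.DataFrame:
    """Ground-truth event table (one row per planted ripple)."""
    rows = []
    for rec in recordings:
        for ev in rec.truth_events:
            rows.append(
                dict(
                    animal=rec.animal_id, genotype=rec.genotype,
                    condition=rec.condition, day=rec.day,
                    peak_s=ev.peak_s, freq_hz=ev.freq_hz,
                    duration_ms=ev.duration_ms,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["animal", "genotype", "condition", "day", "peak_s", "freq_hz", "duration_ms"],
    )
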