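"""Synthetic discontinuous neonatal EEG with planted interhemispheric synchrony.

Quiet-sleep EEG near term age alternates high-amplitude bursts lasting a few
seconds with low-amplitude inter-burst intervals (trace alternant / trace
discontinu).  Interhemispheric synchrony (IHS) manifests as temporal
co-incidence of those bursts across hemispheres.  This module synthesizes
two-hemisphere recordings in which the degree of co-incidence is a *planted*,
tunable parameter, so that synchrony metrics can be validated against ground
truth:

* a :class:`BurstModel` sets the burst statistics (rate, duration,
  inter-burst amplitude ratio, carrier band);
* a :class:`SynchronyPlant` shifts and jitters the right hemisphere's burst
  onsets relative to the left and optionally drops bursts unilaterally,
  moving the record along a synchronous -> asynchronous continuum;
* a :class:`CohortSpec` assembles whole labelled cohorts (normal vs.
  abnormal) with per-subject postmenstrual ages.

Burst onsets follow a renewal process: after each burst the off-gap is
exponential with mean chosen so the long-run burst-state fraction equals
``burst_rate * burst_duration_mean`` (capped near 1); bursts therefore never
overlap.  Burst edges are smoothed with a 0.5-s raised-cosine ramp, and each
channel carries independent band-limited Gaussian noise multiplied by its
hemisphere's envelope gate.  All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .records import Annotation, EEGRecord

__all__ = [
    "BurstModel",
    "SynchronyPlant",
    "CohortSpec",
    "BurstEvent",
    "draw_burst_events",
    "gate_from_events",
    "generate_burst_train",
    "generate_record",
    "generate_cohort",
    "inject_artifact",
    "LEFT_CHANNELS",
    "RIGHT_CHANNELS",
    "DEFAULT_CHANNELS",
]

#: Referential channels required so all five standard bipolar pairs exist.
LEFT_CHANNELS = ("Fp1", "C3", "O1", "T3")
RIGHT_CHANNELS = ("Fp2", "C4", "O2", "T4")
DEFAULT_CHANNELS = LEFT_CHANNELS + RIGHT_CHANNELS

#: Length of the raised-cosine ramp at burst edges, seconds.
EDGE_RAMP_S = 0.5


@dataclass(frozen=True)
class BurstModel:
    """Statistics of the discontinuous background pattern.

    Defaults give a trace-alternant-like pattern: ~6 bursts/min of ~5 s each
    (about half the time in burst state), carrier noise band-limited to
    0.5-10 Hz, ~200 uV peak-to-peak in bursts and 15% of that between bursts.
    """

    burst_rate: float = 6.0                  # bursts per minute
    burst_duration_mean: float = 5.0         # seconds
    burst_duration_sd: float = 1.5           # seconds
    interburst_amplitude_ratio: float = 0.15 # (0, 1)
    burst_band: tuple[float, float] = (0.5, 10.0)  # Hz
    fs: float = 256.0                        # Hz
    burst_amplitude_uv: float = 200.0        # peak-to-peak in burst, uV

    def __post_init__(self) -> None:
        if self.burst_duration_mean <= 0:
            raise ValueError("burst_duration_mean must be positive")
        if not 0 < self.interburst_amplitude_ratio <= 1:
            raise ValueError("interburst_amplitude_ratio must be in (0, 1]")
        lo, hi = self.burst_band
        if not 0 < lo < hi < self.fs / 2:
            raise ValueError("burst_band must satisfy 0 < low < high < fs/2")
        if self.burst_rate < 0:
            raise ValueError("burst_rate cannot be negative")


@dataclass(frozen=True)
class SynchronyPlant:
    """Planted interhemispheric timing relation.

    ``onset_lag_mean`` shifts every right-hemisphere burst by a fixed offset;
    ``onset_jitter_sd`` adds independent Gaussian jitter per burst;
    ``miss_prob`` drops a burst from the right hemisphere entirely.  The
    degenerate plant (0, 0, 0) yields perfectly mirrored hemispheres.
    """

    onset_lag_mean: float = 0.0   # seconds
    onset_jitter_sd: float = 0.0  # seconds
    miss_prob: float = 0.0        # [0, 1]

    def __post_init__(self) -> None:
        if self.onset_jitter_sd < 0:
            raise ValueError("onset_jitter_sd must be non-negative")
        if not 0 <= self.miss_prob <= 1:
            raise ValueError("miss_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """A labelled synthetic cohort: group sizes, plants, ages, seed.

    Defaults mirror a clinical study population of 14 normal and 17 abnormal
    recordings at postmenstrual ages 36-42 weeks, each long enough for two
    10-min quiet-sleep epochs.
    """

    n_normal: int = 14
    n_abnormal: int = 17
    plant_normal: SynchronyPlant = SynchronyPlant(0.0, 0.2, 0.0)
    plant_abnormal: SynchronyPlant = SynchronyPlant(0.0, 8.0, 0.0)
    burst_model: BurstModel = BurstModel()
    pma_range: tuple[float, float] = (36.0, 42.0)  # weeks
    seed: int = 0
    record_duration: float = 1200.0  # seconds; >= two 10-min epochs
    pma_jitter_slope: float = 0.0    # optional PMA -> extra jitter sd, s/week

    def __post_init__(self) -> None:
        if self.n_normal < 0 or self.n_abnormal < 0:
            raise ValueError("group sizes cannot be negative")
        if self.record_duration < 1200:
            raise ValueError("record_duration must allow two 10-min epochs (>= 1200 s)")
        if self.pma_range[0] > self.pma_range[1]:
            raise ValueError("pma_range must be (low, high)")


@dataclass(frozen=True)
class BurstEvent:
    """One burst: onset time and duration, seconds."""

    onset: float
    duration: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def draw_burst_events(model: BurstModel, duration: float,
                      rng: np.random.Generator) -> list[BurstEvent]:
    """Draw non-overlapping burst events over ``[0, duration)``.

    Renewal process: the off-gap after each burst is exponential with mean
    ``60/rate - duration_mean`` (floored at 0.5 s), so the expected fraction
    of time in burst state is ``min(~1, rate * duration_mean / 60)``.  Burst
    durations are Gaussian, truncated below at 0.5 s.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if model.burst_rate == 0:
        return []
    cycle = 60.0 / model.burst_rate
    gap_mean = max(cycle - model.burst_duration_mean, 0.5)
    events: list[BurstEvent] = []
    t = rng.exponential(gap_mean)
    while t < duration:
        d = max(0.5, rng.normal(model.burst_duration_mean, model.burst_duration_sd))
        events.append(BurstEvent(onset=t, duration=d))
        t += d + rng.exponential(gap_mean)
    return events


def gate_from_events(events: Sequence[BurstEvent], duration: float, fs: float,
                     floor: float, ramp_s: float = EDGE_RAMP_S) -> np.ndarray:
    """Per-sample envelope gate in ``[floor, 1]`` from a list of bursts.

    Inside a burst the gate is 1; between bursts it is ``floor``; edges are
    smoothed with a raised-cosine ramp of ``ramp_s`` seconds (half in, half
    out) so that band-pass filtering does not ring at the transitions.
    """
    n = int(round(duration * fs))
    gate = np.zeros(n)
    for ev in events:
        i0 = int(round(ev.onset * fs))
        i1 = int(round(ev.offset * fs))
        if i1 <= 0 or i0 >= n:
            continue
        gate[max(i0, 0):min(i1, n)] = 1.0
    n_ramp = int(round(ramp_s * fs))
    if n_ramp > 1:
        win = np.hanning(2 * n_ramp + 1)
        win /= win.sum()
        gate = np.convolve(gate, win, mode="same")
    return floor + (1.0 - floor) * np.clip(gate, 0.0, 1.0)


def generate_burst_train(model: BurstModel, duration: float,
                         rng_seed: int) -> np.ndarray:
    """Envelope gate sequence for one hemisphere (values in [floor, 1]).

    A convenience wrapper over :func:`draw_burst_events` and
    :func:`gate_from_events`; identical seeds give identical output.  With
    ``interburst_amplitude_ratio == 1`` the gate is constant 1 (continuous
    EEG); with ``burst_rate == 0`` it is constant at the floor.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if model.interburst_amplitude_ratio == 1.0:
        return np.ones(int(round(duration * model.fs)))
    rng = np.random.default_rng(rng_seed)
    events = draw_burst_events(model, duration, rng)
    return gate_from_events(events, duration, model.fs,
                            model.interburst_amplitude_ratio)


def _shifted_events(events: Sequence[BurstEvent], plant: SynchronyPlant,
                    rng: np.random.Generator) -> list[BurstEvent]:
    """Apply the plant to the left hemisphere's events: lag, jitter, misses."""
    out = []
    for ev in events:
        if plant.miss_prob > 0 and rng.random() < plant.miss_prob:
            continue
        shift = plant.onset_lag_mean
        if plant.onset_jitter_sd > 0:
            shift += rng.normal(0.0, plant.onset_jitter_sd)
        out.append(BurstEvent(onset=ev.onset + shift, duration=ev.duration))
    return out


def _carrier(n: int, fs: float, band: tuple[float, float],
             rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to ``band``."""
    x = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_record(model: BurstModel, plant: SynchronyPlant, duration: float,
                    channels: Sequence[str] = DEFAULT_CHANNELS,
                    rng_seed: int = 0,
                    annotations: Sequence[Annotation] | None = None) -> EEGRecord:
    """Two-hemisphere discontinuous EEG record with planted synchrony.

    All left-hemisphere channels (odd 10-20 indices) share one burst-onset
    train; right-hemisphere channels share the same train with the plant's
    lag/jitter/misses applied.  Each channel has an independent band-limited
    noise carrier, so bipolar derivations within a hemisphere do not cancel.
    Deterministic for a fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    missing = [c for c in DEFAULT_CHANNELS if c not in channels]
    if missing:
        from .errors import MontageError
        raise MontageError(
            f"channels must include all of {DEFAULT_CHANNELS}; missing {missing}")
    rng = np.random.default_rng(rng_seed)
    events_left = draw_burst_events(model, duration, rng)
    events_right = _shifted_events(events_left, plant, rng)
    floor = model.interburst_amplitude_ratio
    gate_left = gate_from_events(events_left, duration, model.fs, floor)
    gate_right = gate_from_events(events_right, duration, model.fs, floor)
    n = gate_left.size
    amp = model.burst_amplitude_uv / 6.0  # ~6 sigma spans peak-to-peak
    data = np.empty((len(channels), n))
    for i, ch in enumerate(channels):
        gate = gate_right if _is_right(ch) else gate_left
        data[i] = amp * gate * _carrier(n, model.fs, model.burst_band, rng)
    anns = list(annotations) if annotations is not None else _default_epochs(duration)
    return EEGRecord(
        data=data, fs=model.fs, labels=list(channels), annotations=anns,
        meta={
            "plant": {"onset_lag_mean": plant.onset_lag_mean,
                      "onset_jitter_sd": plant.onset_jitter_sd,
                      "miss_prob": plant.miss_prob},
            "rng_seed": int(rng_seed),
        },
    )


def _is_right(label: str) -> bool:
    """Right hemisphere by the 10-20 convention: even electrode index."""
    digits = "".join(c for c in label if c.isdigit())
    return bool(digits) and int(digits) % 2 == 0


def _default_epochs(duration: float) -> list[Annotation]:
    """Two subsequent 10-min quiet-sleep epochs, if the record allows them."""
    if duration >= 1200:
        return [Annotation(0.0, 600.0, "QS1"), Annotation(600.0, 1200.0, "QS2")]
    return []


def generate_cohort(spec: CohortSpec) -> list[tuple[EEGRecord, str, float]]:
    """Generate a labelled cohort: list of ``(record, group, pma_weeks)``.

    Per-record seeds are spawned deterministically from ``spec.seed``; the
    same spec always yields the identical cohort.  PMA is uniform over
    ``spec.pma_range`` and, by default, does not influence the signal; the
    ``pma_jitter_slope`` hook adds ``slope * (pma - pma_low)`` seconds of
    onset jitter for power studies of age effects.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = spec.n_normal + spec.n_abnormal
    children = ss.spawn(n_total)
    pma_rng = np.random.default_rng(ss.spawn(1)[0])
    cohort: list[tuple[EEGRecord, str, float]] = []
    groups = ["normal"] * spec.n_normal + ["abnormal"] * spec.n_abnormal
    for i, (group, child) in enumerate(zip(groups, children)):
        pma = float(pma_rng.uniform(*spec.pma_range))
        plant = spec.plant_normal if group == "normal" else spec.plant_abnormal
        if spec.pma_jitter_slope != 0.0:
            extra = spec.pma_jitter_slope * (pma - spec.pma_range[0])
            plant = replace(plant, onset_jitter_sd=max(0.0,
                            plant.onset_jitter_sd + extra))
        seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        rec = generate_record(spec.burst_model, plant, spec.record_duration,
                              rng_seed=seed)
        rec.meta.update({"subject_id": f"S{i:03d}", "group": group,
                         "pma_weeks": pma})
        cohort.append((rec, group, pma))
    return cohort


def inject_artifact(record: EEGRecord, start: float, duration: float,
                    amplitude_uv: float = 500.0, rng_seed: int = 0) -> EEGRecord:
    """Return a copy with a high-amplitude transient segment on all channels.

    The segment is annotated ``"artifact"`` so downstream window-quality
    policies can reject windows that touch it.
    """
    rec = record.copy()
    rng = np.random.default_rng(rng_seed)
    i0 = int(round(start * rec.fs))
    i1 = min(int(round((start + duration) * rec.fs)), rec.n_samples)
    rec.data[:, i0:i1] += amplitude_uv * rng.standard_normal((rec.data.shape[0],
                                                              i1 - i0))
    rec.annotations.append(Annotation(start, min(start + duration, rec.duration),
                                      "artifact"))
    return rec
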