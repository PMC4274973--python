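"""Activation synchrony index (ASI) for a pair of bipolar EEG derivations.

The ASI quantifies interhemispheric synchrony during discontinuous neonatal
EEG as the excess statistical dependency of the two hemispheres' amplitude
envelopes at (near-)zero lag, relative to the dependency at long lags where
only chance coincidence of bursts remains.  The computation proceeds in four
stages:

1. *Preprocessing*: zero-phase band-pass (default 0.5-20 Hz, 4th-order
   Butterworth) followed by a first-difference pre-emphasis that weights
   higher frequencies, ``y[t] = x[t] - alpha * x[t-1]``.
2. *Amplitude envelope*: full-wave rectification, 1-s moving-average
   smoothing, decimation to a coarse frame rate (default 16 Hz).
3. *Quantization*: equal-occupancy (quantile) binning of each envelope into
   ``Q`` discrete levels, computed on the analysis window itself.  Quantile
   binning makes the index exactly invariant to channel gain and to any
   strictly monotone amplitude transform.
4. *Lagged dependency*: plug-in mutual information ``I(tau)`` (bits) of the
   joint histogram of the two code sequences at relative lag ``tau``.  The
   scalar ASI is the mean of ``I(tau)`` over a small zero-centred numerator
   lag set divided by the mean over a distant baseline lag set.

Temporally co-incident bursting concentrates dependency at zero lag, giving
ASI >> 1; asynchronous bursting spreads it into the baseline, giving ASI
near (or below) 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    AnalysisError,
    DataQualityError,
    DegenerateSignalError,
    EpochLengthError,
)
from .records import DerivationPair, EEGRecord, make_bipolar

__all__ = [
    "ASIConfig",
    "QuantizedEnvelope",
    "ASIResult",
    "preprocess",
    "amplitude_envelope",
    "quantize",
    "lag_dependency_profile",
    "compute_asi",
    "asi_for_window",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ASIConfig:
    """Tunable parameters of the ASI computation.

    All defaults are configurable stand-ins for the published algorithm's
    internal constants; they can be overridden wholesale from a pipeline
    configuration file.
    """

    band: tuple[float, float] = (0.5, 20.0)  # band-pass edges, Hz
    filter_order: int = 4                    # Butterworth order (per pass)
    preemphasis: float | None = 0.95         # first-difference coefficient; None disables
    smooth_seconds: float = 1.0              # envelope moving-average length, s
    frame_rate: float = 16.0                 # envelope frame rate, Hz
    q_levels: int = 8                        # quantization levels Q
    numerator_max_lag: float = 0.5           # numerator lag set: |tau| <= this, s
    baseline_min_lag: float = 5.0            # baseline lag set: this <= |tau| ...
    baseline_max_lag: float = 30.0           # ... <= this, s
    baseline_floor: float = 1e-4             # floor on baseline mean, bits
    min_overlap_frames: int = 100            # minimum frames of overlap per lag

    def __post_init__(self) -> None:
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band edges must satisfy 0 < low < high")
        if self.q_levels < 2:
            raise ValueError("need at least 2 quantization levels")
        if not 0 < self.numerator_max_lag < self.baseline_min_lag < self.baseline_max_lag:
            raise ValueError("lag sets must satisfy 0 < numerator < baseline range")

    def numerator_lags(self) -> np.ndarray:
        """Numerator lags in seconds, on the frame grid, symmetric about 0."""
        k = int(math.floor(self.numerator_max_lag * self.frame_rate))
        return np.arange(-k, k + 1) / self.frame_rate

    def baseline_lags(self) -> np.ndarray:
        """Baseline lags in seconds on the frame grid, both signs."""
        k0 = int(math.ceil(self.baseline_min_lag * self.frame_rate))
        k1 = int(math.floor(self.baseline_max_lag * self.frame_rate))
        pos = np.arange(k0, k1 + 1)
        return np.concatenate([-pos[::-1], pos]) / self.frame_rate


@dataclass
class QuantizedEnvelope:
    """Equal-occupancy quantized amplitude envelope of one derivation."""

    codes: np.ndarray          # integers in {0..Q-1}
    frame_rate: float          # Hz
    q_levels: int
    bin_edges: np.ndarray      # envelope values at the Q-1 interior level boundaries

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)

    def __len__(self) -> int:
        return self.codes.size


@dataclass
class ASIResult:
    """Scalar ASI plus the lag-dependency profile it was computed from."""

    asi: float
    lag_profile: dict[float, float]          # lag (s) -> I(tau) (bits)
    numerator_lags: tuple[float, ...]
    baseline_lags: tuple[float, ...]
    pair: DerivationPair | None = None
    window: tuple[float, float] | None = None
    baseline_floored: bool = False

    def numerator_mean(self) -> float:
        return float(np.mean([self.lag_profile[t] for t in self.numerator_lags]))

    def baseline_mean(self) -> float:
        return float(np.mean([self.lag_profile[t] for t in self.baseline_lags]))


def preprocess(x: np.ndarray, fs: float, config: ASIConfig = ASIConfig()) -> np.ndarray:
    """Band-pass (zero-phase) then pre-emphasize one derivation signal.

    Raises :class:`EpochLengthError` for signals shorter than 10 s and
    :class:`DataQualityError` for signals containing NaNs.
    """
    x = np.asarray(x, dtype=float)
    if fs < 64:
        raise ValueError(f"sampling rate {fs} Hz too low (need >= 64 Hz)")
    if x.size < 10 * fs:
        raise EpochLengthError(
            f"signal of {x.size / fs:.1f} s too short to filter (need >= 10 s)")
    if np.isnan(x).any():
        raise DataQualityError("signal contains NaN samples")
    low, high = config.band
    nyq = fs / 2
    if high >= nyq:
        raise ValueError(f"band edge {high} Hz at or above Nyquist {nyq} Hz")
    sos = sps.butter(config.filter_order, [low, high], btype="bandpass",
                     fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    if config.preemphasis is not None:
        a = config.preemphasis
        y = sps.lfilter([1.0, -a], [1.0], y)
    return y


def amplitude_envelope(x: np.ndarray, fs: float,
                       config: ASIConfig = ASIConfig()) -> np.ndarray:
    """Rectified, smoothed, decimated amplitude envelope at the frame rate.

    The filtered signal is full-wave rectified, smoothed with a boxcar of
    ``smooth_seconds``, and one frame is emitted per ``1/frame_rate`` seconds
    (the mean of the smoothed rectified signal over that frame).
    """
    x = np.asarray(x, dtype=float)
    if config.frame_rate > fs:
        raise ValueError("frame_rate cannot exceed the sampling rate")
    rect = np.abs(x)
    n_smooth = max(1, int(round(config.smooth_seconds * fs)))
    kernel = np.full(n_smooth, 1.0 / n_smooth)
    smooth = sps.fftconvolve(rect, kernel, mode="same")
    step = fs / config.frame_rate
    n_frames = int(math.floor(x.size / step))
    idx = np.arange(n_frames)
    starts = np.round(idx * step).astype(int)
    stops = np.round((idx + 1) * step).astype(int)
    csum = np.concatenate([[0.0], np.cumsum(smooth)])
    env = (csum[stops] - csum[starts]) / np.maximum(stops - starts, 1)
    return np.maximum(env, 0.0)


def quantize(envelope: np.ndarray, q_levels: int = 8,
             frame_rate: float = 16.0) -> QuantizedEnvelope:
    """Equal-occupancy quantization of an envelope into ``q_levels`` codes.

    Codes are assigned by rank, so level occupancies are equal to within one
    frame for distinct-valued input, and any strictly monotone transform of
    the envelope yields identical codes.  Raises
    :class:`DegenerateSignalError` for a constant envelope (flat EEG cannot
    be scored) and :class:`EpochLengthError` if there are fewer than
    ``10 * q_levels`` frames.
    """
    env = np.asarray(envelope, dtype=float)
    n = env.size
    if n < 10 * q_levels:
        raise EpochLengthError(
            f"{n} envelope frames too few for Q={q_levels} (need >= {10 * q_levels})")
    if np.ptp(env) == 0:
        raise DegenerateSignalError("constant envelope cannot be quantized")
    order = np.argsort(env, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    codes = (ranks * q_levels) // n
    edges = np.quantile(env, np.arange(1, q_levels) / q_levels)
    return QuantizedEnvelope(codes=codes, frame_rate=frame_rate,
                             q_levels=q_levels, bin_edges=edges)


def _mutual_information_bits(a: np.ndarray, b: np.ndarray, q: int) -> float:
    """Plug-in mutual information (bits) of two aligned code sequences.

    The joint histogram is vectorized; the final reduction uses exact
    summation (``math.fsum``) of per-cell terms so the result does not
    depend on accumulation order and can be compared bit-for-bit against a
    naive reference.
    """
    n = a.size
    joint = np.bincount(a * q + b, minlength=q * q).reshape(q, q)
    row = joint.sum(axis=1)
    col = joint.sum(axis=0)
    terms = []
    for i, j in zip(*np.nonzero(joint)):
        p = joint[i, j] / n
        terms.append(p * math.log2(p / ((row[i] / n) * (col[j] / n))))
    return math.fsum(terms)


def lag_dependency_profile(qa: QuantizedEnvelope, qb: QuantizedEnvelope,
                           lags: np.ndarray,
                           min_overlap_frames: int = 100) -> dict[float, float]:
    """Mutual information I(tau), in bits, at each requested lag.

    Positive ``tau`` means ``qb`` is evaluated ``tau`` seconds *later* than
    ``qa``:  I(tau) = MI(qa[t], qb[t + tau]).  Lags whose shifted overlap is
    shorter than ``min_overlap_frames`` are dropped with a warning; if every
    lag is dropped an :class:`AnalysisError` is raised.
    """
    if qa.frame_rate != qb.frame_rate:
        raise ValueError("frame rates differ between the two envelopes")
    if qa.q_levels != qb.q_levels:
        raise ValueError("quantization levels differ between the two envelopes")
    fr, q = qa.frame_rate, qa.q_levels
    a, b = qa.codes, qb.codes
    n = min(a.size, b.size)
    profile: dict[float, float] = {}
    for tau in np.asarray(lags, dtype=float):
        k = int(round(tau * fr))
        overlap = n - abs(k)
        if overlap < min_overlap_frames:
            logger.warning("lag %.3f s dropped: only %d frames of overlap",
                           tau, max(overlap, 0))
            continue
        if k >= 0:
            aa, bb = a[: n - k], b[k:n]
        else:
            aa, bb = a[-k:n], b[: n + k]
        profile[float(tau)] = _mutual_information_bits(aa, bb, q)
    if not profile:
        raise AnalysisError("all requested lags were dropped for lack of overlap")
    return profile


def compute_asi(qa: QuantizedEnvelope, qb: QuantizedEnvelope,
                config: ASIConfig = ASIConfig(),
                pair: DerivationPair | None = None,
                window: tuple[float, float] | None = None) -> ASIResult:
    """Scalar ASI of two quantized envelopes.

    ASI = mean I(tau) over the zero-centred numerator lag set divided by the
    mean over the distant baseline lag set.  The baseline mean is floored at
    ``config.baseline_floor`` bits (the result is then flagged).
    """
    num_lags = config.numerator_lags()
    base_lags = config.baseline_lags()
    all_lags = np.concatenate([num_lags, base_lags])
    profile = lag_dependency_profile(qa, qb, all_lags, config.min_overlap_frames)
    num_used = tuple(t for t in num_lags if float(t) in profile)
    base_used = tuple(float(t) for t in base_lags if float(t) in profile)
    if not num_used or not base_used:
        raise AnalysisError("numerator or baseline lag set is empty after overlap check")
    num_mean = float(np.mean([profile[float(t)] for t in num_used]))
    base_mean = float(np.mean([profile[t] for t in base_used]))
    floored = base_mean < config.baseline_floor
    denom = max(base_mean, config.baseline_floor)
    return ASIResult(
        asi=num_mean / denom,
        lag_profile=profile,
        numerator_lags=tuple(float(t) for t in num_used),
        baseline_lags=base_used,
        pair=pair,
        window=window,
        baseline_floored=floored,
    )


def asi_for_window(record: EEGRecord, pair: DerivationPair,
                   window: tuple[float, float],
                   config: ASIConfig = ASIConfig()) -> ASIResult:
    """End-to-end ASI for one derivation pair over one ``[start, end)`` window.

    Slices the bipolar derivations to the window, then filters, envelopes,
    quantizes and scores them.  Windows shorter than 2.5 min
    are refused: the index only stabilizes for windows of a few minutes.
    """
    start, end = window
    if end - start < 150.0 - 1e-9:
        raise EpochLengthError(
            f"window of {end - start:.0f} s too short for a stable ASI "
            "(need >= 150 s)")
    if end > record.duration + 1e-9 or start < 0:
        raise EpochLengthError(f"window [{start}, {end}) outside record bounds")
    left, right = make_bipolar(record, pair)
    i0, i1 = int(round(start * record.fs)), int(round(end * record.fs))
    envs = []
    for x in (left[i0:i1], right[i0:i1]):
        y = preprocess(x, record.fs, config)
        env = amplitude_envelope(y, record.fs, config)
        envs.append(quantize(env, config.q_levels, config.frame_rate))
    return compute_asi(envs[0], envs[1], config, pair=pair, window=window)
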