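"""Segment extraction from annotated continuous recordings.

The pipeline turns each continuous recording block into clean, fixed-length
classification segments:

1. exclude a +/- 10 s guard window around every marked spike / abnormal
   discharge;
2. tile each remaining clean interval into non-overlapping 10-s cuts
   (anchored at the interval's left edge), keep a trailing partial cut only
   if it is at least 4 s long, and trim every kept cut to its first 4 s;
3. band-pass 1-70 Hz (zero-phase Butterworth) with a 50 Hz notch;
4. anti-alias low-pass at 40 Hz and decimate to 100 Hz;
5. drop segments with amplitude or gradient outliers (automated stand-in
   for manual jump/muscle artifact screening).

Zero-phase (forward-backward) filtering is used throughout: phase
distortion would corrupt the imaginary part of coherency downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "Interval",
    "Segment",
    "exclude_event_windows",
    "partition_segments",
    "filter_signal",
    "resample_to",
    "reject_artifact_segments",
    "preprocess_recording",
]


@dataclass(frozen=True)
class Interval:
    """Half-open time interval [start_s, end_s) in seconds."""
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(eq=False)
class Segment:
    """A fixed-length artifact-free window; the unit of classification."""
    subject_id: str
    group_label: str
    signals: np.ndarray  # (n_parcels, n_samples)
    sample_rate_hz: float
    origin: tuple[int, float] = field(default=(0, 0.0))  # (block, start_s)


def exclude_event_windows(
    block_duration_s: float,
    event_times_s,
    pad_s: float = 10.0,
) -> list[Interval]:
    """Maximal clean intervals of a block after excluding event windows.

    Every event at time t removes [t - pad_s, t + pad_s); the returned
    intervals are the block [0, duration) minus the union of these
    windows, sorted and disjoint.  Events outside the block still mask the
    part of their window that overlaps it.
    """
    if pad_s <= 0:
        raise ValueError("pad_s must be positive")
    windows = sorted(
        (max(0.0, t - pad_s), min(block_duration_s, t + pad_s))
        for t in event_times_s
    )
    clean: list[Interval] = []
    cursor = 0.0
    for lo, hi in windows:
        if hi <= 0 or lo >= block_duration_s:
            continue
        if lo > cursor:
            clean.append(Interval(cursor, lo))
        cursor = max(cursor, hi)
    if cursor < block_duration_s:
        clean.append(Interval(cursor, block_duration_s))
    return clean


def partition_segments(
    intervals: list[Interval],
    cut_len_s: float = 10.0,
    min_keep_s: float = 4.0,
    trim_len_s: float = 4.0,
) -> list[Interval]:
    """Tile clean intervals into trimmed fixed-length segment windows.

    Each interval is cut into consecutive non-overlapping ``cut_len_s``
    windows starting at its left edge; the final partial window survives
    only if it is at least ``min_keep_s`` long.  Every kept window is then
    trimmed to its first ``trim_len_s`` seconds.
    """
    if cut_len_s < trim_len_s:
        raise ValueError("cut_len_s must be >= trim_len_s")
    if min_keep_s > cut_len_s:
        raise ValueError("min_keep_s must be <= cut_len_s")
    if trim_len_s > min_keep_s:
        raise ValueError("trim_len_s must be <= min_keep_s "
                         "(trimmed windows must fit inside kept cuts)")
    out: list[Interval] = []
    for iv in intervals:
        start = iv.start_s
        while start < iv.end_s:
            end = min(start + cut_len_s, iv.end_s)
            if end - start >= min_keep_s - 1e-12:
                out.append(Interval(start, start + trim_len_s))
            start += cut_len_s
    return out


def filter_signal(signals: np.ndarray, sample_rate_hz: float,
                  band_hz: tuple[float, float] = (1.0, 70.0),
                  notch_hz: float = 50.0, notch_q: float = 30.0) -> np.ndarray:
    """Zero-phase 1-70 Hz band-pass with a 50 Hz notch.

    4th-order Butterworth band-pass and a Q=30 IIR notch, both applied
    forward-backward (``filtfilt``) along the last axis.  Output length
    equals input length.  Requires sample_rate_hz > 2 * upper band edge.
    """
    lo, hi = band_hz
    if sample_rate_hz <= 2 * hi:
        raise ValueError(
            f"sample rate {sample_rate_hz} Hz too low for a {hi} Hz low-pass"
        )
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sample_rate_hz,
                     output="sos")
    out = sps.sosfiltfilt(sos, signals, axis=-1)
    b, a = sps.iirnotch(notch_hz, notch_q, fs=sample_rate_hz)
    return sps.filtfilt(b, a, out, axis=-1)


def resample_to(signals: np.ndarray, sample_rate_hz: float,
                target_hz: float = 100.0,
                antialias_hz: float = 40.0) -> np.ndarray:
    """Anti-aliased downsampling to ``target_hz``.

    A zero-phase 8th-order Chebyshev-I low-pass at ``antialias_hz``
    (0.8 x the target Nyquist by default) precedes decimation.  Integer
    ratios decimate by slicing; other ratios use polyphase resampling.
    """
    if target_hz > sample_rate_hz:
        raise ValueError("target rate above the input rate")
    if target_hz == sample_rate_hz:
        return np.asarray(signals, dtype=float).copy()
    sos = sps.cheby1(8, 0.05, antialias_hz, btype="low", fs=sample_rate_hz,
                     output="sos")
    out = sps.sosfiltfilt(sos, signals, axis=-1)
    ratio = Fraction(sample_rate_hz / target_hz).limit_denominator(1000)
    if ratio.denominator == 1:
        return out[..., ::ratio.numerator]
    return sps.resample_poly(out, ratio.denominator, ratio.numerator, axis=-1)


def reject_artifact_segments(segments: list[Segment],
                             amp_z_max: float = 6.0,
                             grad_z_max: float = 6.0) -> list[Segment]:
    """Drop segments with extreme amplitudes or jumps.

    Per channel, amplitudes and first differences are z-scored against
    that channel's pooled statistics across the subject's segments; a
    segment is rejected when any sample exceeds ``amp_z_max`` (muscle
    proxy) or any first difference exceeds ``grad_z_max`` (SQUID-jump
    proxy).  Survivor order is preserved.
    """
    if amp_z_max <= 0 or grad_z_max <= 0:
        raise ValueError("thresholds must be positive")
    if not segments:
        return []
    stacked = np.concatenate([s.signals for s in segments], axis=-1)
    mu = stacked.mean(axis=-1, keepdims=True)
    sd = stacked.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    diffs = np.diff(stacked, axis=-1)
    dmu = diffs.mean(axis=-1, keepdims=True)
    dsd = diffs.std(axis=-1, keepdims=True)
    dsd[dsd == 0] = 1.0

    kept = []
    for seg in segments:
        amp_z = np.abs((seg.signals - mu) / sd)
        grad_z = np.abs((np.diff(seg.signals, axis=-1) - dmu) / dsd)
        if amp_z.max() <= amp_z_max and grad_z.max() <= grad_z_max:
            kept.append(seg)
    return kept


def preprocess_recording(
    recording,
    pad_s: float = 10.0,
    cut_len_s: float = 10.0,
    min_keep_s: float = 4.0,
    trim_len_s: float = 4.0,
    target_hz: float = 100.0,
    amp_z_max: float = 6.0,
    grad_z_max: float = 6.0,
) -> list[Segment]:
    """Full raw-mode pipeline: one Recording -> clean 4-s 100 Hz segments.

    Works block by block (exclusion windows never cross block boundaries).
    """
    fs = recording.sample_rate_hz
    n_block = int(round(recording.block_duration_s * fs))
    segments: list[Segment] = []
    for b in range(recording.n_blocks):
        block = recording.signals[:, b * n_block:(b + 1) * n_block]
        events = [t for blk, t in recording.events if blk == b]
        clean = exclude_event_windows(recording.block_duration_s, events, pad_s)
        windows = partition_segments(clean, cut_len_s, min_keep_s, trim_len_s)
        if not windows:
            continue
        filtered = filter_signal(block, fs)
        for iv in windows:
            i0 = int(round(iv.start_s * fs))
            i1 = i0 + int(round(trim_len_s * fs))
            down = resample_to(filtered[:, i0:i1], fs, target_hz)
            segments.append(Segment(
                subject_id=recording.subject_id,
                group_label=recording.group_label,
                signals=down,
                sample_rate_hz=target_hz,
                origin=(b, iv.start_s),
            ))
    return reject_artifact_segments(segments, amp_z_max, grad_z_max)
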