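"""Acquisition filtering, stimulation-artifact excision, threshold crossings.

Mirrors the front end of a Blackrock-style acquisition chain: a 0.3 Hz
first-order high-pass plus 7.5 kHz third-order low-pass Butterworth applied
causally; stimulation artifacts found as |v| >= 500 uV simultaneously on at
least 4 of 12 randomly chosen channels and excised in 3.5 ms windows with
the adjacent segments concatenated; threshold-crossing (TC) spike events
detected on a 250 Hz high-passed trace at -4.5x its RMS noise with a short
lockout, then binned at 100 ms.  No spike sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfilt

from gripdecode.synth import RawRecording


class InvalidInputError(ValueError):
    pass


@dataclass
class ArtifactLog:
    """Excised sample intervals and how cleaned time maps back to original.

    ``intervals`` are half-open (start, end) sample ranges in the *original*
    recording, non-overlapping after merging.  ``detection_channels`` is the
    seeded 12-channel subset used by the detector.
    """

    intervals: list
    fs_hz: float
    detection_channels: np.ndarray | None = None
    edge_truncations: int = 0

    @property
    def total_excised_s(self) -> float:
        return sum(e - s for s, e in self.intervals) / self.fs_hz

    def original_index(self, cleaned_idx: np.ndarray) -> np.ndarray:
        """Map sample indices in the cleaned trace back to original indices."""
        cleaned_idx = np.asarray(cleaned_idx)
        out = cleaned_idx.astype(np.int64).copy()
        # Walk intervals in order; each shifts subsequent cleaned samples.
        removed = 0
        bounds = []
        for s, e in self.intervals:
            bounds.append((s - removed, e - s))
            removed += e - s
        for start_clean, width in bounds:
            out[cleaned_idx >= start_clean] += width
        return out


@dataclass
class SpikeTrain:
    """Per-channel threshold-crossing times with the RMS estimates used."""

    times: list                      # list of per-channel float arrays (s)
    rms_uv: np.ndarray
    multiplier: float = -4.5
    flagged_channels: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_channels(self) -> int:
        return len(self.times)


@dataclass
class BinnedCounts:
    """Spike counts on a 100 ms grid: per-channel and summed over channels."""

    bin_edges_s: np.ndarray
    per_channel: np.ndarray          # channels x bins

    @property
    def global_counts(self) -> np.ndarray:
        return self.per_channel.sum(axis=0)


def apply_acquisition_filters(rec: RawRecording) -> RawRecording:
    """Causal hardware-equivalent filtering: 0.3 Hz 1st-order high-pass and
    7.5 kHz 3rd-order low-pass Butterworth.

    Requires the sampling rate to exceed 15 kHz so the low-pass corner is
    below Nyquist.
    """
    if rec.fs_hz <= 15_000:
        raise InvalidInputError(
            f"sampling rate {rec.fs_hz} Hz too low for the 7.5 kHz corner"
        )
    hp = butter(1, 0.3, btype="highpass", fs=rec.fs_hz, output="sos")
    lp = butter(3, 7_500.0, btype="lowpass", fs=rec.fs_hz, output="sos")
    volt = sosfilt(lp, sosfilt(hp, rec.voltage.astype(np.float64), axis=-1), axis=-1)
    return RawRecording(volt.astype(rec.voltage.dtype), rec.fs_hz,
                        rec.start_s, rec.layout, dict(rec.meta))


def detect_artifacts(
    rec: RawRecording,
    threshold_uv: float = 500.0,
    n_required: int = 4,
    subset_size: int = 12,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect stimulation-artifact onsets.

    A sample is artifact-positive when |v| >= ``threshold_uv`` on at least
    ``n_required`` of a seeded random subset of ``subset_size`` channels
    simultaneously.  Runs of consecutive positive samples collapse to their
    first sample.  Returns ``(detection_samples, subset_channels)``.
    """
    if subset_size > rec.n_channels:
        raise InvalidInputError("subset_size exceeds channel count")
    rng = np.random.default_rng(seed)
    subset = np.sort(rng.choice(rec.n_channels, size=subset_size, replace=False))
    over = np.abs(rec.voltage[subset]) >= threshold_uv
    hot = over.sum(axis=0) >= n_required
    if not hot.any():
        return np.empty(0, dtype=np.int64), subset
    # rising edges of the boolean series
    edges = np.flatnonzero(np.diff(np.concatenate([[False], hot]).astype(np.int8)) == 1)
    return edges.astype(np.int64), subset


def excise_artifacts(
    rec: RawRecording,
    detections: np.ndarray,
    window_ms: float = 3.5,
    pre_ms: float = 0.5,
    subset: np.ndarray | None = None,
) -> tuple[RawRecording, ArtifactLog]:
    """Remove a ``window_ms`` window around each detection and concatenate.

    Each window starts ``pre_ms`` before the detection sample (capturing the
    onset transient) and spans ``window_ms`` total; overlapping windows are
    merged; windows are truncated at the recording edges (logged).  The
    returned :class:`ArtifactLog` maps cleaned sample indices back to
    original ones so non-excised samples are conserved exactly.
    """
    detections = np.asarray(detections, dtype=np.int64)
    fs = rec.fs_hz
    n = rec.n_samples
    win = int(round(window_ms * 1e-3 * fs))
    pre = int(round(pre_ms * 1e-3 * fs))

    truncated = 0
    merged: list[list[int]] = []
    for d in np.sort(detections):
        s, e = d - pre, d - pre + win
        if s < 0 or e > n:
            truncated += 1
            s, e = max(s, 0), min(e, n)
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    log = ArtifactLog([(s, e) for s, e in merged], fs,
                      detection_channels=subset, edge_truncations=truncated)
    if not merged:
        return rec, log
    keep = np.ones(n, dtype=bool)
    for s, e in merged:
        keep[s:e] = False
    volt = rec.voltage[:, keep]
    meta = dict(rec.meta)
    meta["excised_intervals"] = [(s, e) for s, e in merged]
    return RawRecording(volt, fs, rec.start_s, rec.layout, meta), log


def detect_threshold_crossings(
    rec: RawRecording,
    hp_hz: float = 250.0,
    multiplier: float = -4.5,
    lockout_ms: float = 1.0,
    robust_rms: bool = False,
) -> SpikeTrain:
    """Threshold-crossing spike detection on the 250 Hz high-passed trace.

    Per channel the noise RMS is estimated over the whole analyzed trace
    (or, with ``robust_rms``, as a median-absolute-deviation based estimate
    insensitive to spikes) and an event is the first sample at which the
    trace drops below ``multiplier * RMS`` after having been above it, with
    ``lockout_ms`` enforced between consecutive events.  All-zero channels
    are flagged and return no events.
    """
    if rec.duration_s <= 1.0:
        raise InvalidInputError("recording must exceed 1 s for RMS estimation")
    if multiplier >= 0:
        raise InvalidInputError("multiplier must be negative")
    fs = rec.fs_hz
    sos = butter(4, hp_hz, btype="highpass", fs=fs, output="sos")
    x = sosfilt(sos, rec.voltage.astype(np.float64), axis=-1)
    if robust_rms:
        rms = np.median(np.abs(x), axis=-1) / 0.6745
    else:
        rms = np.sqrt(np.mean(x**2, axis=-1))
    lockout = max(int(round(lockout_ms * 1e-3 * fs)), 1)

    times, flagged = [], []
    for c in range(rec.n_channels):
        if rms[c] == 0.0:
            flagged.append(c)
            times.append(np.empty(0))
            continue
        thr = multiplier * rms[c]
        below = x[c] < thr
        onsets = np.flatnonzero(
            np.diff(np.concatenate([[False], below]).astype(np.int8)) == 1
        )
        kept = []
        last = -lockout
        for o in onsets:
            if o - last >= lockout:
                kept.append(o)
                last = o
        times.append(rec.start_s + np.asarray(kept, dtype=float) / fs)
    return SpikeTrain(times, rms, multiplier, np.asarray(flagged, dtype=int))


def bin_spike_counts(
    train: SpikeTrain,
    duration_s: float,
    bin_ms: float = 100.0,
    start_s: float = 0.0,
) -> BinnedCounts:
    """Bin crossing times on a 100 ms grid; trailing partial bin dropped."""
    width = bin_ms * 1e-3
    n_bins = int(np.floor((duration_s + 1e-12) / width))
    edges = start_s + np.arange(n_bins + 1) * width
    counts = np.zeros((train.n_channels, n_bins), dtype=np.int64)
    for c, t in enumerate(train.times):
        if len(t):
            counts[c] = np.histogram(t, bins=edges)[0]
    return BinnedCounts(edges, counts)
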