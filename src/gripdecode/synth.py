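"""Synthetic multielectrode recordings and cue schedules.

The generator emulates the statistical structure the downstream analysis
assumes: each of seven hand movements modulates multiunit-band (broadband
250 Hz–few kHz) power across the 96 active channels of a 10x10 Utah-style
array according to a movement-specific spatial pattern; biphasic spike
transients ride on the trace at a rate coupled to the same modulation
envelope; large-amplitude 50 Hz stimulation artifact pulses can be injected
over configured intervals.  Ground-truth spike times and artifact onsets are
carried in recording metadata so detection stages can be tested against
truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import butter, sosfilt

#: Canonical movement labels: one grasp per test object plus hand opening.
MOVEMENTS = (
    "hand_open",
    "can",
    "block",
    "peg",
    "fork",
    "paperweight",
    "vhs",
)

REST = "rest"


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class ArrayLayout:
    """Physical layout of the 10x10 array: 96 active channels, 4 corner refs.

    ``positions[c]`` is the (row, col) grid cell of active channel ``c``
    (0-based).  The four corners are non-active reference electrodes.
    """

    rows: int = 10
    cols: int = 10
    positions: tuple = ()
    reference_positions: tuple = ()

    def __post_init__(self):
        if not self.positions:
            corners = ((0, 0), (0, self.cols - 1), (self.rows - 1, 0),
                       (self.rows - 1, self.cols - 1))
            pos = tuple(
                (r, c)
                for r in range(self.rows)
                for c in range(self.cols)
                if (r, c) not in corners
            )
            object.__setattr__(self, "positions", pos)
            object.__setattr__(self, "reference_positions", corners)
        if len(self.positions) + len(self.reference_positions) != self.rows * self.cols:
            raise InvalidConfigError("active + reference positions must tile the grid")
        if len(set(self.positions) | set(self.reference_positions)) != self.rows * self.cols:
            raise InvalidConfigError("layout positions overlap or miss grid cells")

    @property
    def n_channels(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class CueSchedule:
    """Ordered, labeled, half-open [start, end) cue intervals in seconds."""

    labels: tuple
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "starts", np.asarray(self.starts, dtype=float))
        object.__setattr__(self, "ends", np.asarray(self.ends, dtype=float))
        if not (len(self.labels) == len(self.starts) == len(self.ends)):
            raise InvalidConfigError("schedule fields must have equal length")
        if np.any(self.ends <= self.starts):
            raise InvalidConfigError("cue intervals must have positive duration")
        if np.any(self.starts[1:] < self.ends[:-1] - 1e-12):
            raise InvalidConfigError("cue intervals must not overlap")

    @property
    def duration_s(self) -> float:
        return float(self.ends[-1]) if len(self.ends) else 0.0

    def label_at(self, t: float) -> str:
        """State label at time ``t`` (half-open intervals); rest outside."""
        idx = np.searchsorted(self.starts, t, side="right") - 1
        if idx >= 0 and t < self.ends[idx]:
            return self.labels[idx]
        return REST

    def labels_for_times(self, times: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`label_at` for an array of times."""
        times = np.asarray(times, dtype=float)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        idx_c = np.clip(idx, 0, len(self.labels) - 1)
        inside = (idx >= 0) & (times < self.ends[idx_c])
        out = np.where(inside, np.asarray(self.labels, dtype=object)[idx_c], REST)
        return out.astype(object)


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration.

    Amplitudes are in microvolts; rates in Hz.  ``patterns`` holds one
    unit-norm nonnegative 96-vector per movement: the per-channel weighting
    of added multiunit-band RMS during that movement's cues.  ``decline``
    multiplies the added band *power* by (1 - decline), emulating chronic
    signal-quality loss without touching the noise floor.
    """

    fs_hz: float = 30_000.0
    movements: tuple = MOVEMENTS
    patterns: np.ndarray | None = None
    base_correlation: float = 0.2
    pair_overlaps: Mapping[tuple, float] | None = None
    modulation_rms_uv: float = 15.0
    noise_sd_uv: float = 10.0
    spike_rate_hz: float = 5.0
    spike_amp_uv: float = 80.0
    spike_rate_gain: float = 6.0
    artifact_rate_hz: float = 50.0
    artifact_amp_uv: float = 800.0
    artifact_pulse_ms: float = 0.5
    artifact_settle_ms: float = 1.0
    artifact_channels: tuple | None = None
    decline: float = 0.0
    seed: int = 0
    layout: ArrayLayout = field(default_factory=ArrayLayout)

    def __post_init__(self):
        for name in ("fs_hz", "modulation_rms_uv", "noise_sd_uv", "spike_rate_hz",
                     "spike_amp_uv", "artifact_rate_hz", "artifact_amp_uv",
                     "artifact_pulse_ms", "artifact_settle_ms"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be nonnegative")
        if not 0.0 <= self.decline <= 1.0:
            raise InvalidConfigError("decline must lie in [0, 1]")
        if self.patterns is None:
            pats = make_pattern_vectors(
                len(self.movements), self.layout.n_channels,
                self.base_correlation, self.pair_overlaps, seed=self.seed,
            )
            object.__setattr__(self, "patterns", pats)
        pats = np.asarray(self.patterns, dtype=float)
        if pats.shape != (len(self.movements), self.layout.n_channels):
            raise InvalidConfigError(
                f"patterns shape {pats.shape} does not match "
                f"{len(self.movements)} movements x {self.layout.n_channels} channels"
            )
        norms = np.linalg.norm(pats, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise InvalidConfigError("pattern vectors must have unit norm")
        object.__setattr__(self, "patterns", pats)

    @property
    def n_channels(self) -> int:
        return self.layout.n_channels

    def config_hash(self) -> str:
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
            if k not in ("layout", "pair_overlaps")
        }
        if self.pair_overlaps:
            payload["pair_overlaps"] = sorted(
                (list(k), v) for k, v in self.pair_overlaps.items()
            )
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RawRecording:
    """Multichannel voltage trace (channels x samples, microvolts)."""

    voltage: np.ndarray
    fs_hz: float
    start_s: float = 0.0
    layout: ArrayLayout = field(default_factory=ArrayLayout)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voltage = np.asarray(self.voltage)
        if self.voltage.ndim != 2:
            raise InvalidConfigError("voltage must be channels x samples")
        if not np.all(np.isfinite(self.voltage)):
            raise InvalidConfigError("voltage must be finite")

    @property
    def n_channels(self) -> int:
        return self.voltage.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def make_pattern_vectors(
    n_movements: int,
    n_channels: int,
    base_correlation: float,
    pair_overlaps: Mapping[tuple, float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Unit-norm nonnegative spatial patterns with exact pairwise cosines.

    Every pair of movements attains cosine similarity ``base_correlation``;
    pairs listed in ``pair_overlaps`` (0-based movement index pairs) attain
    their own higher target instead.  The construction places a globally
    shared component, optional pair-shared components and per-movement
    individual components on disjoint channel supports, so the realized
    cosines equal the targets exactly (up to float rounding) and all entries
    are nonnegative — the vectors weight per-channel RMS gains.
    """
    if not 0.0 <= base_correlation < 1.0:
        raise InvalidConfigError("base_correlation must lie in [0, 1)")
    pair_overlaps = dict(pair_overlaps or {})
    for pair, rho in pair_overlaps.items():
        if len(pair) != 2 or pair[0] == pair[1]:
            raise InvalidConfigError(f"bad pair {pair}")
        if not base_correlation <= rho < 1.0:
            raise InvalidConfigError(
                "pair overlap must lie in [base_correlation, 1)"
            )
    touched = [m for pair in pair_overlaps for m in pair]
    if len(touched) != len(set(touched)):
        raise InvalidConfigError("pair_overlaps must name disjoint pairs")

    n_blocks = 1 + len(pair_overlaps) + n_movements
    if n_channels < n_blocks:
        raise InvalidConfigError("too few channels for requested structure")
    rng = np.random.default_rng(seed)
    # Partition channels into contiguous support blocks.
    edges = np.linspace(0, n_channels, n_blocks + 1).astype(int)
    blocks = [np.arange(edges[i], edges[i + 1]) for i in range(n_blocks)]

    def unit_block(idx):
        v = np.zeros(n_channels)
        x = np.abs(rng.standard_normal(len(idx))) + 1e-3
        v[idx] = x / np.linalg.norm(x)
        return v

    shared = unit_block(blocks[0])
    pair_shared = {pair: unit_block(blocks[1 + i])
                   for i, pair in enumerate(pair_overlaps)}
    indiv = [unit_block(blocks[1 + len(pair_overlaps) + m])
             for m in range(n_movements)]

    pats = np.zeros((n_movements, n_channels))
    for m in range(n_movements):
        rho_pair = 0.0
        pair_vec = None
        for pair, rho in pair_overlaps.items():
            if m in pair:
                rho_pair = rho - base_correlation
                pair_vec = pair_shared[pair]
        v = np.sqrt(base_correlation) * shared
        if pair_vec is not None:
            v = v + np.sqrt(rho_pair) * pair_vec
        v = v + np.sqrt(1.0 - base_correlation - rho_pair) * indiv[m]
        pats[m] = v / np.linalg.norm(v)
    return pats


def make_cue_schedule(
    movements: Sequence[str],
    cues_per_movement: int,
    cue_range: tuple = (3.0, 4.0),
    rest_range: tuple = (4.0, 5.0),
    seed: int = 0,
) -> CueSchedule:
    """Shuffled cue schedule: every movement cue bounded by rest cues.

    ``cues_per_movement`` repetitions of each movement label are globally
    shuffled, movement cue durations drawn uniformly from ``cue_range``
    (3–4 s by default) and interleaved rest cues from ``rest_range``
    (4–5 s), starting and ending with rest.
    """
    if cues_per_movement < 0:
        raise InvalidConfigError("cues_per_movement must be nonnegative")
    if cue_range[1] < cue_range[0] or rest_range[1] < rest_range[0]:
        raise InvalidConfigError("duration ranges must be nondecreasing")
    if cues_per_movement > 0 and len(movements) == 0:
        raise InvalidConfigError("no movements given but cues requested")

    rng = np.random.default_rng(seed)
    order = [m for m in movements for _ in range(cues_per_movement)]
    rng.shuffle(order)

    labels, durs = [], []
    labels.append(REST)
    durs.append(rng.uniform(*rest_range))
    for mov in order:
        labels.append(mov)
        durs.append(rng.uniform(*cue_range))
        labels.append(REST)
        durs.append(rng.uniform(*rest_range))
    ends = np.cumsum(durs)
    starts = ends - np.asarray(durs)
    return CueSchedule(tuple(labels), starts, ends)


def _mua_bandpass_sos(fs_hz: float):
    """Band-limited multiunit band used for modulation: (fs/2^7, fs/2^3)."""
    low, high = fs_hz / 2**7, fs_hz / 2**3
    return butter(4, [low, high], btype="band", fs=fs_hz, output="sos")


def _spike_template(fs_hz: float, amp_uv: float) -> np.ndarray:
    """Fixed 1 ms biphasic template.

    Sharp ~0.27 ms negative deflection followed by a slower, smaller
    positive rebound — sharp enough to survive the 250 Hz high-pass used
    by threshold-crossing detection, like a real extracellular spike.
    """
    n = max(int(round(1e-3 * fs_hz)), 2)
    # half-sample-centered so the negative lobe is hit at any sampling rate
    t = (np.arange(n) + 0.5) / n
    neg = -np.sin(np.pi * np.clip(t / 0.27, 0, 1)) * (t < 0.27)
    pos = 0.35 * np.sin(np.pi * np.clip((t - 0.27) / 0.73, 0, 1)) * (t >= 0.27)
    return amp_uv * (neg + pos)


def generate_recording(
    config: SimConfig, schedule: CueSchedule, seed: int | None = None
) -> RawRecording:
    """Synthesize a raw recording following a cue schedule.

    voltage = white noise (sd ``noise_sd_uv``)
            + band-limited modulation noise whose per-channel RMS during a
              movement cue is ``modulation_rms_uv * pattern[m, c] *
              sqrt(1 - decline)`` (zero during rest)
            + biphasic spikes at a Poisson rate coupled to the same envelope.

    Bit-for-bit reproducible for identical (config, schedule, seed).
    """
    if schedule.duration_s <= 0:
        raise InvalidConfigError("schedule duration must be positive")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    fs = config.fs_hz
    n_ch = config.n_channels
    n = int(round(schedule.duration_s * fs))

    # Movement-modulation envelope: per-channel added RMS per sample.
    mov_index = {m: i for i, m in enumerate(config.movements)}
    env = np.zeros((n_ch, n), dtype=np.float32)
    power_scale = np.sqrt(max(0.0, 1.0 - config.decline))
    cue_of_sample = np.full(n, -1, dtype=np.int32)
    for lab, s, e in zip(schedule.labels, schedule.starts, schedule.ends):
        if lab == REST or lab not in mov_index:
            continue
        i0, i1 = int(round(s * fs)), min(int(round(e * fs)), n)
        m = mov_index[lab]
        env[:, i0:i1] = (
            config.modulation_rms_uv * power_scale * config.patterns[m]
        )[:, None]
        cue_of_sample[i0:i1] = m

    noise = rng.standard_normal((n_ch, n)) * config.noise_sd_uv
    band = rng.standard_normal((n_ch, n))
    if config.modulation_rms_uv > 0:
        sos = _mua_bandpass_sos(fs)
        band = sosfilt(sos, band, axis=-1)
        band /= np.sqrt(np.mean(band**2, axis=-1, keepdims=True))
    else:
        band[:] = 0.0
    volt = noise + band * env
    del noise, band

    # Spikes: Poisson with rate coupled multiplicatively to the envelope so
    # threshold-crossing counts co-vary with MWP (shared drive).
    template = _spike_template(fs, config.spike_amp_uv)
    spike_log = []
    if config.spike_rate_hz > 0:
        ref = max(config.noise_sd_uv, 1e-9)
        for c in range(n_ch):
            rate = config.spike_rate_hz * np.ones(n)
            mask = cue_of_sample >= 0
            if mask.any():
                rate[mask] *= 1.0 + config.spike_rate_gain * env[c, mask] / ref
            p = rate / fs
            hits = np.flatnonzero(rng.random(n) < p)
            # enforce template-length separation so transients do not pile up
            keep = []
            last = -len(template)
            for h in hits:
                if h - last >= len(template):
                    keep.append(h)
                    last = h
            for h in keep:
                seg = template[: n - h]
                volt[c, h:h + len(seg)] += seg
                spike_log.append((c, h / fs))

    spike_times = np.asarray(spike_log, dtype=float).reshape(-1, 2)
    meta = {
        "seed": seed,
        "config_hash": config.config_hash(),
        "spike_times": spike_times,
        "artifact_onsets_s": np.empty(0, dtype=float),
    }
    return RawRecording(volt.astype(np.float32), fs, 0.0, config.layout, meta)


def inject_stim_artifacts(
    rec: RawRecording,
    on_intervals: Sequence[tuple],
    config: SimConfig,
) -> RawRecording:
    """Superpose periodic stimulation-artifact pulses over given intervals.

    Pulses fire at ``artifact_rate_hz`` (50 Hz default, matching the FES
    pulse rate) simultaneously on all channels (or ``artifact_channels``),
    each a rectangular biphasic pulse of ``artifact_pulse_ms`` followed by an
    exponential settle of ``artifact_settle_ms``.  Ground-truth onset times
    are appended to recording metadata.  An empty interval list returns the
    recording unchanged bit-for-bit.
    """
    if not on_intervals:
        return rec
    fs = rec.fs_hz
    n = rec.n_samples
    for s, e in on_intervals:
        if s < rec.start_s - 1e-9 or e > rec.start_s + rec.duration_s + 1e-9:
            raise InvalidConfigError(f"interval ({s}, {e}) outside recording span")

    channels = (
        np.arange(rec.n_channels)
        if config.artifact_channels is None
        else np.asarray(config.artifact_channels, dtype=int)
    )
    # Rectangular biphasic flat-top (amplifier-saturating: the pulse rails
    # the channel to +/-A) followed by an additive exponential settle.
    n_pulse = max(int(round(config.artifact_pulse_ms * 1e-3 * fs)), 2)
    n_settle = max(int(round(config.artifact_settle_ms * 1e-3 * fs)), 1)
    flat = np.concatenate([
        np.full(n_pulse // 2 + n_pulse % 2, 1.0),
        np.full(n_pulse // 2, -1.0),
    ]) * config.artifact_amp_uv
    settle = -config.artifact_amp_uv * np.exp(
        -np.arange(1, n_settle + 1) / (n_settle / 4.0))

    volt = rec.voltage.copy()
    onsets = []
    period = 1.0 / config.artifact_rate_hz
    for s, e in on_intervals:
        t = s
        while t < e - 1e-12:
            i0 = int(round((t - rec.start_s) * fs))
            if i0 >= n:
                break
            f = flat[: n - i0]
            volt[np.ix_(channels, np.arange(i0, i0 + len(f)))] = f
            j0 = i0 + len(flat)
            if j0 < n:
                sgm = settle[: n - j0]
                volt[np.ix_(channels, np.arange(j0, j0 + len(sgm)))] += sgm
            onsets.append(t)
            t += period

    meta = dict(rec.meta)
    prev = np.asarray(meta.get("artifact_onsets_s", np.empty(0)), dtype=float)
    meta["artifact_onsets_s"] = np.sort(np.concatenate([prev, np.asarray(onsets)]))
    return RawRecording(volt, fs, rec.start_s, rec.layout, meta)


def degraded_config(config: SimConfig, decline: float) -> SimConfig:
    """Convenience: same config with a different signal-decline factor."""
    return replace(config, decline=decline)
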