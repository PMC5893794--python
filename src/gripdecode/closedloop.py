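"""100 ms real-time loop and a simulated grasp-and-release task (GRT).

The loop consumes feature bins strictly causally at the 100 ms cadence,
emits one arbitration decision per bin, and raises a logical
stimulation-on flag for at most one movement at a time — functionally
equivalent to the offline decode of the same data, bit for bit.

The GRT simulation replaces the human participant with an intent script:
each transfer attempt is a sequence of phases (reach, optional hand-open
pre-positioning for the Can, grasp, hold/transfer, release) that drives the
synthetic generator; the decoded trace is scored against the script.  A
transfer succeeds when the correct grasp is acquired, held through the
whole transfer phase, and released; a dropped grip mid-transfer is a
failure; a grasp still active when the 30 s window closes is incomplete.
The Can additionally requires the hand-open class to activate during its
pre-positioning phase (two decoder classes per transfer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from gripdecode.decoder import DecoderModel, DecodeTrace, arbitrate, score_bins
from gripdecode.features import FeatureMatrix, WaveletSpec, extract_features
from gripdecode.synth import REST, CueSchedule, SimConfig, generate_recording


class LoopError(RuntimeError):
    pass


@dataclass
class LoopState:
    """Event log of the real-time loop: one entry per state transition."""

    transitions: list = field(default_factory=list)   # (t_s, new_state)

    def record(self, t_s: float, state: str, prev: str | None):
        if state != prev:
            self.transitions.append((float(t_s), state))


@dataclass
class GrtTrial:
    object_label: str
    duration_s: float
    attempts: list                    # per-attempt outcome dicts
    misclassified_bins: int
    trace: DecodeTrace
    intent: np.ndarray                # scripted state per bin

    @property
    def successes(self) -> int:
        return sum(a["outcome"] == "success" for a in self.attempts)

    @property
    def failures(self) -> int:
        return sum(a["outcome"] == "failure" for a in self.attempts)

    @property
    def incompletes(self) -> int:
        return sum(a["outcome"] == "incomplete" for a in self.attempts)


@dataclass
class TransferLog:
    trials: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, tr in enumerate(self.trials):
            for a in tr.attempts:
                rows.append({"trial": i, "object": tr.object_label, **a})
        return pd.DataFrame(rows)


def run_closed_loop(
    model: DecoderModel, feature_stream, expected_bins: int | None = None
) -> tuple[DecodeTrace, LoopState]:
    """Process (t_s, mwp_vector) bins causally, one decision per bin.

    ``feature_stream`` yields one 100 ms bin at a time; each bin is scored
    and arbitrated independently, so the emitted trace is identical to the
    offline decode of the same feature matrix.  If ``expected_bins`` is
    given and the stream ends early, the loop halts with the position in
    the raised error.
    """
    times, scores, states = [], [], []
    log = LoopState()
    prev = None
    n = 0
    for item in feature_stream:
        t_s, vec = item
        s = score_bins(model, np.asarray(vec, dtype=float)[None, :])[0]
        state = arbitrate(s, model.movements)
        log.record(t_s, state, prev)
        prev = state
        times.append(t_s)
        scores.append(s)
        states.append(state)
        n += 1
    if expected_bins is not None and n < expected_bins:
        raise LoopError(f"stream underrun after {n} of {expected_bins} bins")
    return (
        DecodeTrace(np.asarray(times), np.asarray(scores),
                    np.asarray(states, dtype=object), model.movements),
        log,
    )


#: Default phase durations (s) of one scripted transfer attempt.
DEFAULT_PHASES = {"reach": 1.0, "open": 1.0, "grasp": 0.5, "hold": 1.5,
                  "release": 0.5}


def build_intent_script(
    object_label: str,
    duration_s: float = 30.0,
    phases: dict | None = None,
    hand_open_label: str = "hand_open",
) -> list[tuple[str, str, float]]:
    """Scripted (phase, state, duration) sequence filling a trial window.

    The Can pre-positions with a hand-open phase before every grasp; other
    objects go straight from reach to grasp.  The final attempt may be
    truncated by the window.
    """
    ph = dict(DEFAULT_PHASES, **(phases or {}))
    one_attempt = [("reach", REST, ph["reach"])]
    if object_label == "can":
        one_attempt.append(("open", hand_open_label, ph["open"]))
    one_attempt += [
        ("grasp", object_label, ph["grasp"]),
        ("hold", object_label, ph["hold"]),
        ("release", REST, ph["release"]),
    ]
    script, t = [], 0.0
    while t < duration_s - 1e-9:
        for phase, state, dur in one_attempt:
            dur = min(dur, duration_s - t)
            if dur <= 1e-9:
                break
            script.append((phase, state, dur))
            t += dur
            if t >= duration_s - 1e-9:
                break
    return script


def _script_to_schedule(script) -> CueSchedule:
    labels, starts, ends = [], [], []
    t = 0.0
    for _, state, dur in script:
        labels.append(state)
        starts.append(t)
        ends.append(t + dur)
        t += dur
    return CueSchedule(tuple(labels), np.asarray(starts), np.asarray(ends))


def simulate_grt_trial(
    model: DecoderModel,
    object_label: str,
    sim_config: SimConfig,
    spec: WaveletSpec,
    duration_s: float = 30.0,
    phases: dict | None = None,
    seed: int = 0,
) -> GrtTrial:
    """Run one scripted 30 s GRT trial through the full loop.

    A synthetic recording is generated from the intent script with the same
    generator settings as training, featurized with the model's frozen
    standardization, decoded causally, and scored attempt by attempt.
    """
    if object_label not in model.movements:
        raise LoopError(f"unknown object {object_label!r}")
    script = build_intent_script(object_label, duration_s, phases)
    schedule = _script_to_schedule(script)
    rec = generate_recording(sim_config, schedule, seed=seed)
    feats = extract_features(rec, spec, params=model.params)
    trace, _ = run_closed_loop(
        model, zip(feats.bin_starts_s, feats.values)
    )
    intent = schedule.labels_for_times(trace.bin_starts_s)
    attempts = score_scripted_trace(trace, script, object_label)
    mis = int(np.sum(trace.states != intent))
    return GrtTrial(object_label, duration_s, attempts, mis, trace, intent)


def score_scripted_trace(
    trace: DecodeTrace, script, object_label: str,
    drop_tolerance_bins: int = 1,
) -> list[dict]:
    """Apply the transfer rules to a decoded trace against its intent script.

    The script is split into attempts at every 'reach' phase start; each
    attempt is scored independently (success / failure / incomplete with
    grasp-onset, release and transfer times).  A grip counts as dropped
    mid-transfer only when the grasp class stays inactive for more than
    ``drop_tolerance_bins`` consecutive hold bins: grip force persists
    through a single 100 ms decoder flicker, so the default tolerates one
    bin and fails on >= 200 ms dropouts.
    """
    phase_of_bin = np.empty(len(trace.bin_starts_s), dtype=object)
    t = 0.0
    bounds = []
    for phase, state, dur in script:
        bounds.append((phase, t, t + dur))
        t += dur
    for i, tb in enumerate(trace.bin_starts_s):
        phase_of_bin[i] = next(
            (p for p, s, e in bounds if s - 1e-9 <= tb < e - 1e-9), "reach"
        )
    attempt_starts = [0] + [
        i for i in range(1, len(phase_of_bin))
        if phase_of_bin[i] == "reach" and phase_of_bin[i - 1] != "reach"
    ]
    attempts = []
    for a0, a1 in zip(attempt_starts, attempt_starts[1:] + [len(phase_of_bin)]):
        attempts.append(_score_attempt(
            trace, phase_of_bin, object_label, a0, a1,
            truncated=(a1 == len(phase_of_bin)
                       and phase_of_bin[a1 - 1] in ("grasp", "hold", "open")),
            drop_tolerance_bins=drop_tolerance_bins,
        ))
    return attempts


def _score_attempt(trace, phase_of_bin, obj, a0, a1, truncated=False,
                   drop_tolerance_bins=1):
    idx = np.arange(a0, a1)
    phases = phase_of_bin[idx]
    states = trace.states[idx]
    times = trace.bin_starts_s[idx]
    rec = {"outcome": "failure", "t_grasp_s": np.nan, "t_release_s": np.nan,
           "transfer_time_s": np.nan}

    if obj == "can":
        open_bins = states[phases == "open"]
        if not np.any(open_bins == "hand_open"):
            return rec                          # two-class requirement unmet
    grasp_idx = idx[np.isin(phases, ("grasp", "hold"))]
    if len(grasp_idx) == 0:
        rec["outcome"] = "incomplete" if truncated else "failure"
        return rec
    on = trace.states[grasp_idx] == obj
    if not on.any():
        return rec                              # never acquired the grip
    onset_pos = int(np.argmax(on))
    onset_i = grasp_idx[onset_pos]
    rec["t_grasp_s"] = float(trace.bin_starts_s[onset_i])
    hold_idx = grasp_idx[grasp_idx >= onset_i]
    hold_phase = phase_of_bin[hold_idx]
    off = trace.states[hold_idx][hold_phase == "hold"] != obj
    # longest run of consecutive grip-off bins during the hold phase
    run = longest = 0
    for o in off:
        run = run + 1 if o else 0
        longest = max(longest, run)
    if longest > drop_tolerance_bins:
        return rec                              # grip lost mid-transfer
    release_idx = idx[phases == "release"]
    if len(release_idx) == 0:
        rec["outcome"] = "incomplete"
        return rec
    released = trace.states[release_idx] != obj
    if not released.any():
        rec["outcome"] = "incomplete"           # still gripping at window end
        return rec
    t_rel = float(trace.bin_starts_s[release_idx[np.argmax(released)]])
    rec.update(outcome="success", t_release_s=t_rel,
               transfer_time_s=t_rel - rec["t_grasp_s"])
    return rec


def score_transfers(log: TransferLog) -> pd.DataFrame:
    """Per-object mean successes, failures, incompletes and transfer time."""
    if not log.trials:
        raise LoopError("no trials to score")
    rows = []
    for tr in log.trials:
        times = [a["transfer_time_s"] for a in tr.attempts
                 if a["outcome"] == "success"]
        rows.append({
            "object": tr.object_label,
            "successes": tr.successes,
            "failures": tr.failures,
            "incompletes": tr.incompletes,
            "mean_transfer_time_s": np.mean(times) if times else np.nan,
        })
    df = pd.DataFrame(rows)
    return df.groupby("object").mean(numeric_only=True)


def compare_conditions(a, b) -> tuple[float, float]:
    """Paired t-test on trial-matched values from two conditions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise LoopError("conditions must be equal-length with >= 2 trials")
    d = a - b
    if np.isclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return 0.0, 1.0
        raise LoopError("zero-variance nonzero differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
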