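"""Shared fixtures: desk-scale synthetic sessions reused across test modules.

Heavy objects (multi-block sessions and trained decoders) are built once per
test session.  The "short" session uses compressed cue durations so unit
tests stay fast; the "default" session follows the full cue protocol
(3-4 s movement cues, 4-5 s rests, 3 cues per movement per block) at the
package's desk-scale 3 kHz sampling rate.
"""

import numpy as np
import pytest

from gripdecode import decoder as dec
from gripdecode import features as feat
from gripdecode import synth

DESK_FS = 3000.0


def build_session(sim, spec, n_blocks, cues_per_movement, cue_range,
                  rest_range, seed):
    """Generate blocks, fit standardization on block 0, featurize all."""
    schedules, fms, params = [], [], None
    for b in range(n_blocks):
        sched = synth.make_cue_schedule(
            sim.movements, cues_per_movement, cue_range, rest_range,
            seed=seed + b)
        rec = synth.generate_recording(sim, sched, seed=seed + 100 + b)
        coeffs, starts = feat.decompose_bins(rec, spec)
        if params is None:
            params = feat.fit_standardization(coeffs)
        fms.append(feat.compute_mwp(coeffs, params, starts))
        schedules.append(sched)
    return schedules, fms, params


def train_on_blocks(sim, schedules, fms, params, seed=0):
    X = np.vstack([f.values for f in fms])
    y = np.concatenate([s.labels_for_times(f.bin_starts_s)
                        for s, f in zip(schedules, fms)])
    t = np.concatenate([f.bin_starts_s for f in fms])
    train_fm = feat.FeatureMatrix(t, X, params)
    return dec.train(dec.LabeledBins(train_fm, y),
                     movements=sim.movements, seed=seed)


@pytest.fixture(scope="session")
def sim3k():
    return synth.SimConfig(fs_hz=DESK_FS, seed=11)


@pytest.fixture(scope="session")
def spec3k():
    return feat.WaveletSpec(fs_hz=DESK_FS)


@pytest.fixture(scope="session")
def short_session(sim3k, spec3k):
    """3 compressed blocks (2 cues/movement, ~1.3 s cues): fast shared data."""
    return build_session(sim3k, spec3k, n_blocks=3, cues_per_movement=2,
                         cue_range=(1.2, 1.5), rest_range=(1.0, 1.2),
                         seed=300)


@pytest.fixture(scope="session")
def short_model(sim3k, short_session):
    schedules, fms, params = short_session
    return train_on_blocks(sim3k, schedules[:2], fms[:2], params, seed=0)


#: Pair-overlap levels swept by the separability/accuracy recovery tests.
#: The overlapped pair is (block, paperweight) = movement indices (2, 5),
#: mirroring grips of similar hand shape; modulation is kept at 10 uV RMS,
#: an intermediate regime where pattern overlap (not noise) limits decoding.
SWEEP_LEVELS = (0.3, 0.45, 0.6, 0.75, 0.9)
SWEEP_PAIR = (2, 5)


@pytest.fixture(scope="session")
def overlap_sweep(spec3k):
    """Matched-seed sessions across pattern-overlap levels.

    Returns {level: (sim, per-movement held-out accuracy dict,
    RepresentationSummary)} for 3-block compressed sessions (train on 2,
    evaluate on the third).
    """
    from gripdecode import represent as rep

    results = {}
    for lvl in SWEEP_LEVELS:
        sim = synth.SimConfig(fs_hz=DESK_FS, seed=21, base_correlation=0.2,
                              pair_overlaps={SWEEP_PAIR: lvl},
                              modulation_rms_uv=10.0)
        schedules, fms, params = build_session(
            sim, spec3k, n_blocks=3, cues_per_movement=2,
            cue_range=(1.2, 1.5), rest_range=(1.0, 1.2), seed=900)
        model = train_on_blocks(sim, schedules[:2], fms[:2], params, seed=0)
        trace = dec.decode(model, fms[2])
        accs = {m: dec.individual_accuracy(trace, schedules[2], m)
                for m in sim.movements}
        summary = rep.summarize_representation(fms[2], trace, schedules[2])
        results[lvl] = (sim, accs, summary, model)
    return results


@pytest.fixture(scope="session")
def overlapped_summary(spec3k):
    """Default-SNR session with the pair's patterns at correlation 0.9:
    representation summary of the held-out block for distance recovery."""
    from gripdecode import represent as rep

    sim = synth.SimConfig(fs_hz=DESK_FS, seed=23, base_correlation=0.2,
                          pair_overlaps={SWEEP_PAIR: 0.9})
    schedules, fms, params = build_session(
        sim, spec3k, n_blocks=3, cues_per_movement=2,
        cue_range=(1.2, 1.5), rest_range=(1.0, 1.2), seed=950)
    model = train_on_blocks(sim, schedules[:2], fms[:2], params, seed=0)
    trace = dec.decode(model, fms[2])
    return sim, rep.summarize_representation(fms[2], trace, schedules[2])


@pytest.fixture(scope="session")
def default_session(sim3k, spec3k):
    """Full cue protocol at desk scale: 5 blocks, 3 cues/movement."""
    return build_session(sim3k, spec3k, n_blocks=5, cues_per_movement=3,
                         cue_range=(3.0, 4.0), rest_range=(4.0, 5.0),
                         seed=700)


@pytest.fixture(scope="session")
def default_model(sim3k, default_session):
    schedules, fms, params = default_session
    return train_on_blocks(sim3k, schedules[:4], fms[:4], params, seed=0)
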