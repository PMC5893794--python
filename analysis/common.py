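"""Shared session builder for the analysis drivers.

Builds the desk-scale synthetic session once (5 blocks, full cue protocol,
3 kHz) and caches schedules + MWP features under scratch/ so the numbered
drivers can be re-run independently.  All randomness derives from SEED.
"""

from pathlib import Path

import numpy as np

from gripdecode import decoder as dec
from gripdecode import features as feat
from gripdecode import synth

SEED = 11
DESK_FS = 3000.0
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
N_BLOCKS = 5


def sim_config(**overrides) -> synth.SimConfig:
    return synth.SimConfig(fs_hz=DESK_FS, seed=SEED, **overrides)


def wavelet_spec() -> feat.WaveletSpec:
    return feat.WaveletSpec(fs_hz=DESK_FS)


def load_or_build_session(tag="default", **overrides):
    """Return (sim, spec, schedules, feature matrices, params), cached."""
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    cache = SCRATCH / f"session_{tag}.npz"
    sim = sim_config(**overrides)
    spec = wavelet_spec()
    if cache.exists():
        z = np.load(cache, allow_pickle=True)
        schedules = [
            synth.CueSchedule(tuple(z[f"labels{b}"]), z[f"starts{b}"],
                              z[f"ends{b}"])
            for b in range(N_BLOCKS)
        ]
        params = feat.StandardizationParams(z["mean"], z["sd"])
        fms = [feat.FeatureMatrix(z[f"t{b}"], z[f"v{b}"], params)
               for b in range(N_BLOCKS)]
        return sim, spec, schedules, fms, params

    schedules, fms, params = [], [], None
    for b in range(N_BLOCKS):
        sched = synth.make_cue_schedule(sim.movements, 3, seed=SEED + b)
        rec = synth.generate_recording(sim, sched, seed=SEED + 100 + b)
        coeffs, starts = feat.decompose_bins(rec, spec)
        if params is None:
            params = feat.fit_standardization(coeffs)
        fms.append(feat.compute_mwp(coeffs, params, starts))
        schedules.append(sched)

    payload = {"mean": params.mean, "sd": params.sd}
    for b in range(N_BLOCKS):
        payload[f"labels{b}"] = np.asarray(schedules[b].labels, dtype=object)
        payload[f"starts{b}"] = schedules[b].starts
        payload[f"ends{b}"] = schedules[b].ends
        payload[f"t{b}"] = fms[b].bin_starts_s
        payload[f"v{b}"] = fms[b].values
    np.savez_compressed(cache, **payload)
    return sim, spec, schedules, fms, params


def train_default_model(sim, schedules, fms, params):
    X = np.vstack([f.values for f in fms[:4]])
    y = np.concatenate([s.labels_for_times(f.bin_starts_s)
                        for s, f in zip(schedules[:4], fms[:4])])
    t = np.concatenate([f.bin_starts_s for f in fms[:4]])
    return dec.train(dec.LabeledBins(feat.FeatureMatrix(t, X, params), y),
                     movements=sim.movements, seed=SEED)
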