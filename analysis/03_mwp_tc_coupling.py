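"""Correlate mean wavelet power with threshold-crossing counts.

On a 15 kHz coupled fixture (one cue per movement, ~65 s), extracts MWP,
detects threshold crossings at -4.5x RMS on the 250 Hz high-passed trace,
bins them at 100 ms, and computes the Pearson correlation between
channel-averaged MWP and global TC counts over the first 55 s.
Writes results/mwp_tc_correlation.csv.
"""

import pandas as pd

from common import RESULTS, SEED
from gripdecode import features as feat
from gripdecode import preprocess as pre
from gripdecode import represent as rep
from gripdecode import synth


def main():
    fs = 15_000.0
    sim = synth.SimConfig(fs_hz=fs, seed=SEED)
    sched = synth.make_cue_schedule(sim.movements, 1, seed=SEED + 77)
    rec = synth.generate_recording(sim, sched, seed=SEED + 78)
    fm = feat.extract_features(rec, feat.WaveletSpec(fs_hz=fs))
    train = pre.detect_threshold_crossings(rec)
    counts = pre.bin_spike_counts(train, rec.duration_s)
    r, p = rep.correlate_mwp_tc(fm, counts, window_s=55.0)

    n_tc = sum(len(t) for t in train.times)
    out = pd.DataFrame([{
        "pearson_r": round(r, 3), "p_value": p,
        "window_s": 55.0, "threshold_crossings": n_tc,
        "tc_rate_hz_per_channel": round(n_tc / 96 / rec.duration_s, 2),
    }])
    out.to_csv(RESULTS / "mwp_tc_correlation.csv", index=False)
    print(out.to_string(index=False))
    print(f"\nMWP and TC counts share the movement-modulation drive: "
          f"r = {r:.2f} (p = {p:.1e}) over the first 55 s — MWP tracks "
          f"multiunit spiking without spike sorting.")


if __name__ == "__main__":
    main()
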