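#!/usr/bin/env python
"""Time-resolved effective connectivity with surrogate testing.

Fits the dual-Kalman time-varying MVAR to a planted x -> y coupled
oscillator pair, reports the band/window TPDC summaries, and calls the
directionality of each pair against the time-reversal null.  Writes the
summary table under results/tpdc.
"""

import argparse
from pathlib import Path

import pandas as pd

from threatnet.io import write_table
from threatnet.preprocess import WindowScheme
from threatnet.synthdata import coupled_oscillator_pair
from threatnet.tpdc import (
    band_window_summary,
    default_freq_grid,
    fit_dekf_mvar,
    time_reversal_surrogate_test,
    tpdc_spectrum,
)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/tpdc"))
args = parser.parse_args()

freqs = default_freq_grid()
scheme = WindowScheme()
data = coupled_oscillator_pair(16, 438, coef=0.5, seed=args.seed)

# trial-averaged band/window summaries
tables = []
for trial in range(data.shape[0]):
    model = fit_dekf_mvar(data[trial], order=2, q=1e-3, fs=250.0)
    spec = tpdc_spectrum(model, freqs)
    tables.append(band_window_summary(spec.values, freqs, "theta", scheme,
                                      250.0, 62))
summary = (
    pd.concat(tables)
    .groupby(["source", "target", "band", "window"], as_index=False)["value"]
    .mean()
)
write_table(summary, args.out / "ec_summary.csv")

res = time_reversal_surrogate_test(
    data, n_surrogates=200, alpha=0.01, order=2, q=1e-3, fs=250.0,
    band="theta", seed=args.seed,
)
print("planted coupling: x -> y, coefficient 0.5 in the theta band")
print(f"observed TPDC x->y: {res.observed[0, 1]:.3f} "
      f"(null threshold {res.threshold[0, 1]:.3f})")
print(f"observed TPDC y->x: {res.observed[1, 0]:.3f} "
      f"(null threshold {res.threshold[1, 0]:.3f})")
print(f"directionality call: {res.direction_class[(0, 1)]}")
pairs = pd.DataFrame(
    [{"pair": f"{i}-{j}", "direction": d} for (i, j), d in
     res.direction_class.items()]
)
write_table(pairs, args.out / "directionality.csv")
print(f"tables written under {args.out}")
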