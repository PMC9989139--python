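#!/usr/bin/env python
"""Behavioural statistics and behaviour-network correlations.

Compares threat ratings and heart rate between conditions with paired
t-tests, correlates them with each other and with the measured network
flexibility, and writes the result tables under results/stats.
"""

import argparse
from pathlib import Path

import pandas as pd

from threatnet.io import write_table
from threatnet.stats import correlate_bonferroni, paired_ttest

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--network", type=Path, default=Path("results/network"))
parser.add_argument("--out", type=Path, default=Path("results/stats"))
args = parser.parse_args()

beh = pd.read_csv(args.cohort / "behaviour.csv")
wide = beh.pivot_table(index="subject", columns="condition")
rows = []
for var in ("rating", "heart_rate"):
    res = paired_ttest(wide[(var, "CS+")].to_numpy(),
                       wide[(var, "CS-")].to_numpy(), alpha=0.01)
    rows.append({"variable": var, "t": res.t, "p": res.p,
                 "significant": res.significant})
    print(f"{var:10s}: CS+ vs CS-  t = {res.t:6.2f}, p = {res.p:.2g}")
write_table(pd.DataFrame(rows), args.out / "behaviour_tests.csv")

flex = pd.read_csv(args.network / "flexibility.csv")
f_cs = (
    flex[(flex.condition == "CS+") & (flex.window != "baseline")]
    .groupby("subject")["value"].mean()
)
b_cs = beh[beh.condition == "CS+"].set_index("subject").loc[f_cs.index]
corr = correlate_bonferroni(
    [
        ("flexibility~rating", f_cs.to_numpy(), b_cs["rating"].to_numpy()),
        ("flexibility~heart_rate", f_cs.to_numpy(),
         b_cs["heart_rate"].to_numpy()),
        ("rating~heart_rate", b_cs["rating"].to_numpy(),
         b_cs["heart_rate"].to_numpy()),
    ]
)
write_table(corr, args.out / "correlations.csv")
for _, r in corr.iterrows():
    print(f"{r['pair']:24s} r = {r['r']:6.2f}, adjusted p = {r['p_adj']:.2g}")
print(f"tables written under {args.out}")
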