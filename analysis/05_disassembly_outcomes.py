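#!/usr/bin/env python
"""Estimate cycle-outcome probabilities from the stochastic disassembly model.

Simulates 10,000 molecules under the 50 mM KOAc outcome distribution,
estimates the first-cycle fate proportions with Wilson intervals, and
tabulates how many cycles molecules survive before full dissociation.
Writes results/disassembly/.
"""

import pathlib

import numpy as np
import pandas as pd

from nucspool.disassembly import (DisassemblyModel, estimate_outcomes,
                                  simulate_cycles)

SEED = 1
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "disassembly"
OUT.mkdir(parents=True, exist_ok=True)

model = DisassemblyModel()
seqs = simulate_cycles(model, 10_000, max_cycles=25, seed=SEED)

first = [s[0] for s in seqs if s]
est = estimate_outcomes(first)
tbl = pd.DataFrame([
    dict(outcome=sp, fraction=v["p"], wilson_lo=v["lo"], wilson_hi=v["hi"])
    for sp, v in est.items()])
tbl.to_csv(OUT / "first_cycle_outcomes.tsv", sep="\t", index=False,
           float_format="%.4f")

lifetimes = [len(s) for s in seqs]
life = pd.Series(lifetimes).value_counts().sort_index()
life.rename_axis("cycles_to_bare_dna").to_frame("molecules").to_csv(
    OUT / "lifetimes.tsv", sep="\t")

print("First-cycle outcome fractions (10,000 molecules, 95% Wilson CI):")
print(tbl.round(4).to_string(index=False))
print(f"\nMedian molecule survives {int(np.median(lifetimes))} cycles before "
      f"full dissociation; {100 * np.mean(np.array(lifetimes) >= 25):.1f}% "
      f"still assembled at the 25-cycle cap.")
print(f"Tables written to {OUT}")
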