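#!/usr/bin/env python
"""FRET-channel analyses on construct-tagged synthetic ensembles.

Generates ED2, INT and ED1 nucleosome ensembles, aligns the FRET traces on
their fiduciary events (high-force rip; sigmoid midpoint for the gradual
ED1 transitions), measures the extension-vs-FRET temporal offset, and
simulates the dimer-ejection delay distribution.  Histograms and summary
numbers go to results/fret/.
"""

import pathlib

import numpy as np
import pandas as pd

from nucspool.fret import (align_noncooperative, align_on_rip, ejection_delay,
                           fret_extension_offset)
from nucspool.simulate import GeneratorConfig, generate_cycle, \
    generate_ejection_trace
from nucspool.traces import detect_rips

SEED = 600
OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "fret"
OUT.mkdir(parents=True, exist_ok=True)


def dump_ensemble(ens, name):
    h, t_edges, e_edges = ens.histogram
    pd.DataFrame(h, index=np.round(t_edges[:-1], 4),
                 columns=np.round(e_edges[:-1], 3)).to_csv(
        OUT / f"{name}_hist.tsv", sep="\t", float_format="%.0f")
    pd.DataFrame({"rel_time_s": ens.rel_time, "mean_E": ens.mean_trace}
                 ).to_csv(OUT / f"{name}_mean.tsv", sep="\t", index=False,
                          float_format="%.4f")


# rip-aligned ensembles: the ED2 and INT FRET pairs lose signal at the rip
for construct in ("ED2", "INT"):
    cfg = GeneratorConfig(fret_construct=construct)
    traces, t0s = [], []
    for s in range(20):
        res = generate_cycle(cfg, "nucleosome", seed=SEED + s)
        rips = detect_rips(res.pull)
        traces.append(res.fluor_pull)
        t0s.append(rips[0].t_event if rips else None)
    ens = align_on_rip(traces, t0s)
    dump_ensemble(ens, construct.lower())
    m = ens.mean_trace
    k = np.flatnonzero(np.nan_to_num(m, nan=1.0) < 0.5)[0]
    print(f"{construct}: mean aligned E crosses 0.5 at "
          f"t = {ens.rel_time[k] * 1000:+.0f} ms relative to the rip "
          f"({len(traces) - len(ens.excluded)} traces)")

# ED1: gradual transitions aligned on the sigmoid midpoint; extension leads
cfg1 = GeneratorConfig(fret_construct="ED1", pulling_speed=25.0,
                       lf_kind_probs=(1.0, 0.0, 0.0))
fls, seps = [], []
for s in range(15):
    res = generate_cycle(cfg1, "nucleosome", seed=SEED + 100 + s)
    fls.append(res.fluor_pull)
    _d, _o, sep = fret_extension_offset(res.pull, res.fluor_pull)
    if sep is not None:
        seps.append(sep)
ens1 = align_noncooperative(fls)
dump_ensemble(ens1, "ed1_noncooperative")
print(f"ED1: aligned mean trace is gradual; extension divergence precedes "
      f"the FRET onset by {np.mean(seps) * 1000:.0f} ms on average "
      f"(range {min(seps) * 1000:.0f}..{max(seps) * 1000:.0f} ms, "
      f"n = {len(seps)})")

# dimer ejection: Cy3 drop delayed after the rip
cfgE = GeneratorConfig()
delays = []
for s in range(100):
    tr, _d = generate_ejection_trace(cfgE, rip_time=1.0, duration=3.0,
                                     seed=SEED + 200 + s)
    ev = ejection_delay(tr, rip_time=1.0)
    if ev is not None:
        delays.append(ev.delay_after_rip)
pd.DataFrame({"delay_s": delays}).to_csv(OUT / "ejection_delays.tsv",
                                         sep="\t", index=False,
                                         float_format="%.4f")
print(f"Dimer ejection: mean delay {np.mean(delays) * 1000:.0f} ms "
      f"(SD {np.std(delays) * 1000:.0f} ms, n = {len(delays)})")
print(f"Outputs written to {OUT}")
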