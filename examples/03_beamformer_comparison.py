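"""Comparing spatial filters on the synthetic bench.

Runs the full pipeline with the standard preset table and prints the
per-filter score table, then repeats two presets over several seeds to
show a known contrast: under strong correlated interference the nulling
beamformer outperforms plain LCMV.
"""

import numpy as np

import beamsim as bs
from beamsim.filters import FilterSpec

# --- 1. one full run with every preset ---------------------------------
cfg = bs.generate_default_config()
results = bs.run_experiment(cfg, seed=0)
cols = ["preset", "family", "cov", "rank", "euclidean_error", "correlation"]
print(results[cols].round(3).to_string(index=False))

# --- 2. LCMV vs nulling under strong interference (SINR = -10 dB) ------
cfg_hard = bs.generate_default_config()
cfg_hard.SINR = -10.0
presets = {"LCMV-R": FilterSpec("LCMV", "R"), "NL-R": FilterSpec("NL", "R")}
errs = {name: [] for name in presets}
for seed in range(1, 6):
    r = bs.run_experiment(cfg_hard, presets=presets, seed=seed)
    for name in presets:
        errs[name].append(
            float(r.loc[r["preset"] == name, "euclidean_error"].iloc[0]))
print("\nrelative error under SINR = -10 dB (5 seeds):")
for name, e in errs.items():
    print(f"  {name:7s} median {np.median(e):.3f}  values {np.round(e, 3)}")
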