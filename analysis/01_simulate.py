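"""Generate the synthetic mosquito body time course.

Three staggered courses (44/36/28 h) sampled every 4 h give 30 pooled-body
samples — five biological replicates in each of the six zeitgeber-time bins.
1,525 simulated proteins, 20% of them 24-h cosine-rhythmic, with
multiplicative lognormal noise and intensity-dependent detection dropout.
Writes the design, the per-bin replicate counts, and a truth-table summary.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from circaprot import fileio
from circaprot.pipeline import stage_simulate

cfg = cfg_mod.config()
out = Path(cfg_mod.RESULTS) / "simulate"
design, raw, truth, features = stage_simulate(cfg)

fileio.design_to_yaml(design, out / "design.yaml")
fileio.write_tsv(design.bin_counts().rename("n_replicates"), out / "zt_bin_counts.tsv")
summary = pd.Series({
    "n_proteins": len(raw),
    "n_samples": raw.shape[1],
    "n_rhythmic_planted": int(truth["is_rhythmic"].sum()),
    "n_feature_rows": len(features),
    "median_baseline": float(truth["baseline"].median()),
}, name="value")
fileio.write_tsv(summary, out / "simulation_summary.tsv")

print(f"design: {raw.shape[1]} samples over {len(design.courses)} staggered courses; "
      f"per-bin replicates {design.bin_counts().min()}-{design.bin_counts().max()}")
print(f"simulated {len(raw)} proteins ({int(truth['is_rhythmic'].sum())} planted "
      f"rhythmic) -> {len(features)} spectrum-level feature rows")
print(f"tables under {out}")
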