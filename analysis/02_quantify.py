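"""Label-free quantitation of the simulated feature table.

Charge 2+/3+/4+ filter, top-5 spectra per feature, per-sample median
normalization, ArcSinH-transformed protein abundances from unique-peptide
sums; proteins with fewer than two component peptides are not quantifiable.
Writes the quantitation funnel and per-sample summary.
"""

import importlib
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
cfg_mod = importlib.import_module("00_config")

from circaprot import fileio, quantify
from circaprot.pipeline import stage_quantify, stage_simulate

cfg = cfg_mod.config()
out = Path(cfg_mod.RESULTS) / "quantify"
design, raw, truth, features = stage_simulate(cfg)

filtered = quantify.filter_features(features, charges=cfg.quant.charges,
                                    top_k_spectra=cfg.quant.top_k_spectra)
matrix = stage_quantify(cfg, features, design.sample_meta())

funnel = pd.Series({
    "spectrum_rows_in": len(features),
    "spectrum_rows_after_charge_top5": len(filtered),
    "proteins_simulated": len(raw),
    "proteins_quantifiable": len(matrix.values),
}, name="value")
fileio.write_tsv(funnel, out / "quantitation_funnel.tsv")

per_sample = pd.DataFrame({
    "n_detected": matrix.detected.sum(axis=0),
    "median_abundance": matrix.values.where(matrix.detected).median(axis=0),
}).join(matrix.sample_meta)
fileio.write_tsv(per_sample, out / "per_sample_summary.tsv")

print(f"{len(features)} spectrum rows -> {len(filtered)} after charge/top-5 filters")
print(f"{len(matrix.values)} of {len(raw)} proteins quantifiable "
      f"(>= {cfg.quant.min_peptides} component peptides)")
print(f"tables under {out}")
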