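"""Label-free quantitation: feature filtering, normalization, protein roll-up, FDR.

Feature tables are long-format DataFrames with one row per spectrum
(columns ``feature_id, peptide_sequence, protein_id, charge, sample_id,
intensity``).  The quantitation chain is

1. keep only multi-charged features (2+, 3+, 4+) and, per feature and sample,
   the five most intense spectra;
2. per-sample median normalization of summed feature intensities, rescaled to
   the grand median so the global intensity scale is preserved;
3. per protein and sample, sum the intensities of peptides unique to that
   protein and apply the inverse hyperbolic sine (ArcSinH) transform — a
   log-like variance-stabilizing transform that is defined at zero, which
   matters because undetected measurements are stored as raw 0 with an
   explicit mask rather than imputed.

Proteins quantified from fewer than two distinct peptides are not considered
quantifiable and are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["feature_id", "peptide_sequence", "protein_id", "charge",
                   "sample_id", "intensity"]


def _check_features(features: pd.DataFrame) -> None:
    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    if (features["intensity"] < 0).any():
        raise ValueError("intensities must be >= 0")


def filter_features(features: pd.DataFrame, charges=(2, 3, 4),
                    top_k_spectra: int = 5) -> pd.DataFrame:
    """Charge filter and per-feature spectrum truncation.

    Keeps rows whose charge is in ``charges`` and, within each
    (feature, sample), only the ``top_k_spectra`` most intense spectra.
    """
    _check_features(features)
    if features.empty:
        return features.copy()
    out = features[features["charge"].isin(charges)]
    if out.empty:
        return out.copy()
    out = out.sort_values("intensity", ascending=False, kind="mergesort")
    rank = out.groupby(["feature_id", "sample_id"], sort=False).cumcount()
    return out[rank < top_k_spectra].sort_index().reset_index(drop=True)


def sum_features(features: pd.DataFrame) -> pd.DataFrame:
    """Collapse spectra to one row per (feature, sample) with summed intensity."""
    _check_features(features)
    if features.empty:
        return features.copy()
    keys = ["feature_id", "peptide_sequence", "protein_id", "charge", "sample_id"]
    return features.groupby(keys, as_index=False, sort=False)["intensity"].sum()


def normalize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Median normalization of summed feature intensities.

    Each sample's intensities are divided by that sample's median detected
    (positive) feature intensity and multiplied by the global median of those
    medians, so after normalization every sample has the same median detected
    feature intensity while the global scale is preserved.  Undetected
    features (intensity 0) carry no scale information and do not enter the
    medians.  Samples with no detected features are flagged and left unscaled.
    """
    _check_features(features)
    if features.empty:
        return features.copy()
    out = features.copy()
    detected = out[out["intensity"] > 0]
    medians = detected.groupby("sample_id")["intensity"].median().reindex(
        out["sample_id"].unique(), fill_value=0.0)
    good = medians[medians > 0]
    if good.empty:
        log.warning("normalize_features: no sample has detected features; left unscaled")
        return out
    grand = good.median()
    factors = grand / medians
    zero = medians[medians == 0].index
    if len(zero):
        log.warning("normalize_features: samples with no detected features left "
                    "unscaled: %s", list(zero))
        factors[zero] = 1.0
    out["intensity"] = out["intensity"] * out["sample_id"].map(factors).to_numpy()
    return out


@dataclass
class ProteinAbundanceMatrix:
    """Proteins x samples of ArcSinH-transformed abundances.

    ``values`` holds arcsinh(summed unique-peptide intensity); ``detected`` is
    True where the raw sum was > 0 (values are exactly 0 elsewhere, never
    imputed); ``peptide_counts`` counts distinct contributing peptides per
    protein and sample; ``sample_meta`` (indexed by sample_id) carries
    course_id, elapsed_h and zt.
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    peptide_counts: pd.DataFrame
    sample_meta: pd.DataFrame

    @property
    def zt(self) -> pd.Series:
        return self.sample_meta["zt"]

    def write(self, outdir: str | Path, prefix: str = "abundance") -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, df in [("matrix", self.values), ("detected", self.detected),
                         ("peptide_counts", self.peptide_counts)]:
            p = outdir / f"{prefix}_{name}.tsv"
            df.to_csv(p, sep="\t", index_label="protein_id")
            paths.append(p)
        p = outdir / f"{prefix}_samples.tsv"
        self.sample_meta.to_csv(p, sep="\t", index_label="sample_id")
        paths.append(p)
        return paths

    @classmethod
    def read(cls, outdir: str | Path, prefix: str = "abundance") -> "ProteinAbundanceMatrix":
        outdir = Path(outdir)
        values = pd.read_csv(outdir / f"{prefix}_matrix.tsv", sep="\t", index_col="protein_id")
        detected = pd.read_csv(outdir / f"{prefix}_detected.tsv", sep="\t",
                               index_col="protein_id").astype(bool)
        counts = pd.read_csv(outdir / f"{prefix}_peptide_counts.tsv", sep="\t",
                             index_col="protein_id")
        meta = pd.read_csv(outdir / f"{prefix}_samples.tsv", sep="\t", index_col="sample_id")
        return cls(values, detected, counts, meta)


def protein_abundance(features: pd.DataFrame, sample_meta: pd.DataFrame,
                      min_peptides: int = 2) -> ProteinAbundanceMatrix:
    """Roll normalized features up to protein abundances.

    Per protein and sample: sum the intensities of peptides that map to
    exactly one protein in the table, then ArcSinH-transform the sum.
    Proteins with fewer than ``min_peptides`` distinct unique peptides overall
    are dropped (not quantifiable).
    """
    _check_features(features)
    samples = list(sample_meta.index)
    pep_owner = features.groupby("peptide_sequence")["protein_id"].nunique()
    unique_peps = set(pep_owner[pep_owner == 1].index)
    shared = len(pep_owner) - len(unique_peps)
    if shared:
        log.info("protein_abundance: %d shared peptides excluded from sums", shared)
    feats = features[features["peptide_sequence"].isin(unique_peps)]

    n_pep_total = feats.groupby("protein_id")["peptide_sequence"].nunique()
    quant = n_pep_total[n_pep_total >= min_peptides].index
    feats = feats[feats["protein_id"].isin(quant)]

    raw = (feats.groupby(["protein_id", "sample_id"])["intensity"].sum()
           .unstack(fill_value=0.0).reindex(columns=samples, fill_value=0.0)
           .reindex(sorted(quant), fill_value=0.0))
    det_feats = feats[feats["intensity"] > 0]
    counts = (det_feats.groupby(["protein_id", "sample_id"])["peptide_sequence"].nunique()
              .unstack(fill_value=0).reindex(columns=samples, fill_value=0)
              .reindex(raw.index, fill_value=0))
    values = np.arcsinh(raw)
    detected = raw > 0
    return ProteinAbundanceMatrix(values, detected, counts, sample_meta.copy())


@dataclass(frozen=True)
class FdrSummary:
    """Target-decoy false discovery rate for a search result."""

    n_target: int
    n_decoy: int
    fdr_percent: float

    def __post_init__(self):
        if self.n_target <= 0:
            raise ValueError("n_target must be > 0")


def compute_fdr(n_target: int, n_decoy: int) -> FdrSummary:
    """Target-decoy FDR: 100 * n_decoy / n_target, rounded half-up to 2 dp."""
    if n_target <= 0:
        raise ValueError("FDR is undefined for n_target <= 0")
    if n_decoy < 0:
        raise ValueError("n_decoy must be >= 0")
    pct = Decimal(100 * n_decoy) / Decimal(n_target)
    pct = float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return FdrSummary(n_target, n_decoy, pct)
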