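"""Time-of-day detectability profiling of a protein abundance matrix.

Quantifies how the set of detectable proteins changes across the day:
per-ZT-bin detectable counts, per-protein detection breadth (how many ZT bins
a protein shows up in at all), abundance stratified by breadth (proteins seen
at more times of day tend to be the more abundant ones — detection is
intensity-dependent, not random), and the time-of-day at which each protein's
mean abundance peaks.  Undetected measurements never enter any mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import ProteinAbundanceMatrix

log = logging.getLogger(__name__)


def per_zt_detection(matrix: ProteinAbundanceMatrix, min_replicates: int = 1) -> pd.Series:
    """Detectable proteins per ZT bin (detected in >= ``min_replicates``
    replicates at that bin)."""
    det = matrix.detected
    zt = matrix.zt
    counts = {}
    for b in np.sort(zt.unique()):
        cols = zt.index[zt == b]
        counts[b] = int((det[cols].sum(axis=1) >= min_replicates).sum())
    return pd.Series(counts, name="n_detectable").rename_axis("zt")


def detection_breadth(matrix: ProteinAbundanceMatrix, min_replicates: int = 1) -> pd.Series:
    """Per protein, the number of ZT bins with >= ``min_replicates`` detections."""
    det = matrix.detected
    zt = matrix.zt
    k = pd.Series(0, index=det.index)
    for b in np.sort(zt.unique()):
        cols = zt.index[zt == b]
        k += (det[cols].sum(axis=1) >= min_replicates).astype(int)
    return k.rename("n_timepoints")


def breadth_histogram(breadth: pd.Series, n_bins: int) -> pd.DataFrame:
    """Counts of proteins by detection breadth k = 1..n_bins, with the
    cumulative curve (proteins detectable at <= k distinct times of day)."""
    ks = np.arange(1, n_bins + 1)
    counts = pd.Series({k: int((breadth == k).sum()) for k in ks})
    return pd.DataFrame({"n_proteins": counts, "cumulative": counts.cumsum()}
                        ).rename_axis("n_timepoints")


def abundance_by_breadth(matrix: ProteinAbundanceMatrix, breadth: pd.Series
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-protein mean transformed abundance over *detected* samples only,
    segmented by detection breadth; group medians summarize each stratum."""
    vals = matrix.values.where(matrix.detected)
    means = vals.mean(axis=1, skipna=True)
    per_protein = pd.DataFrame({"n_timepoints": breadth, "mean_abundance": means})
    per_protein = per_protein[per_protein["n_timepoints"] > 0]
    medians = per_protein.groupby("n_timepoints")["mean_abundance"].median()
    return per_protein, medians.rename("median_abundance")


def peak_time_histogram(matrix: ProteinAbundanceMatrix
                        ) -> tuple[pd.Series, pd.DataFrame]:
    """ZT bin of maximal mean detected abundance per protein.

    Ties are broken toward the earliest ZT and flagged.  Proteins never
    detected are excluded.  Returns (histogram over ZT, per-protein table).
    """
    zt = matrix.zt
    bins = np.sort(zt.unique())
    vals = matrix.values.where(matrix.detected)
    bin_means = pd.DataFrame(
        {b: vals[zt.index[zt == b]].mean(axis=1, skipna=True) for b in bins})
    rows = []
    for pid, row in bin_means.iterrows():
        if row.isna().all():
            continue
        best = row.max()
        winners = row.index[row >= best - 1e-12]
        tie = len(winners) > 1
        rows.append({"protein_id": pid, "peak_zt": float(min(winners)), "tie": tie})
    per_protein = pd.DataFrame(rows).set_index("protein_id") if rows else pd.DataFrame(
        columns=["peak_zt", "tie"])
    n_ties = int(per_protein["tie"].sum()) if len(per_protein) else 0
    if n_ties:
        log.info("peak_time_histogram: %d proteins with tied peak bins "
                 "(earliest ZT reported)", n_ties)
    hist = pd.Series({b: int((per_protein["peak_zt"] == b).sum()) for b in bins},
                     name="n_peaking").rename_axis("zt")
    return hist, per_protein


@dataclass
class DetectabilityReport:
    per_zt_counts: pd.Series
    breadth: pd.Series
    breadth_hist: pd.DataFrame
    abundance_by_k: pd.DataFrame
    group_medians: pd.Series
    peak_hist: pd.Series
    peak_zt: pd.DataFrame

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        items = [
            ("per_zt_counts.tsv", self.per_zt_counts),
            ("detection_breadth.tsv", self.breadth),
            ("breadth_histogram.tsv", self.breadth_hist),
            ("abundance_by_breadth.tsv", self.abundance_by_k),
            ("abundance_group_medians.tsv", self.group_medians),
            ("peak_time_histogram.tsv", self.peak_hist),
            ("peak_times.tsv", self.peak_zt),
        ]
        paths = []
        for name, obj in items:
            p = outdir / name
            obj.to_csv(p, sep="\t")
            paths.append(p)
        return paths


def detectability_report(matrix: ProteinAbundanceMatrix,
                         min_replicates: int = 1) -> DetectabilityReport:
    """All detectability summaries for one abundance matrix."""
    n_bins = matrix.zt.nunique()
    counts = per_zt_detection(matrix, min_replicates)
    breadth = detection_breadth(matrix, min_replicates)
    hist = breadth_histogram(breadth, n_bins)
    by_k, medians = abundance_by_breadth(matrix, breadth)
    peak_hist, peaks = peak_time_histogram(matrix)
    ever = int((breadth > 0).sum())
    assert hist["n_proteins"].sum() == ever, "breadth histogram must partition detected proteins"
    return DetectabilityReport(counts, breadth, hist, by_k, medians, peak_hist, peaks)
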