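"""End-to-end runner: simulate -> quantify -> detectability -> rhythm -> proteogenomics.

Each stage logs its record counts after filtering (the analysis funnel), and a
run with the same configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detectability as det
from . import fileio, quantify, rhythm, simulate
from . import proteogenomics as pg
from .config import PipelineConfig

log = logging.getLogger(__name__)


def stage_simulate(cfg: PipelineConfig):
    """Sampling design, protein-level truth, and the spectrum-level feature table."""
    d = cfg.design
    design = simulate.make_design(d.n_courses, d.durations, d.interval_h,
                                  pool_size=d.pool_size)
    s = cfg.simulation
    dropout = simulate.DropoutParams(s.dropout_midpoint, s.dropout_slope) if s.dropout else None
    raw, truth = simulate.simulate_abundance(
        design, n_proteins=s.n_proteins, frac_rhythmic=s.frac_rhythmic,
        noise_sd=s.noise_sd, dropout_params=dropout,
        phase_grid_h=s.phase_grid_h, seed=cfg.seed)
    features = simulate.features_from_abundance(raw, seed=cfg.seed + 1)
    log.info("simulate: %d proteins x %d samples, %d feature rows",
             len(raw), raw.shape[1], len(features))
    return design, raw, truth, features


def stage_quantify(cfg: PipelineConfig, features: pd.DataFrame,
                   sample_meta: pd.DataFrame) -> quantify.ProteinAbundanceMatrix:
    q = cfg.quant
    filtered = quantify.filter_features(features, charges=q.charges,
                                        top_k_spectra=q.top_k_spectra)
    log.info("quantify: charge/top-%d filter kept %d of %d spectrum rows",
             q.top_k_spectra, len(filtered), len(features))
    summed = quantify.sum_features(filtered)
    normed = quantify.normalize_features(summed) if q.normalize else summed
    matrix = quantify.protein_abundance(normed, sample_meta, min_peptides=q.min_peptides)
    log.info("quantify: %d quantifiable proteins (>= %d peptides)",
             len(matrix.values), q.min_peptides)
    return matrix


def stage_rhythm(cfg: PipelineConfig, matrix: quantify.ProteinAbundanceMatrix,
                 truth: pd.DataFrame | None = None):
    r = cfg.rhythm
    res, funnel = rhythm.rhythm_analysis(
        matrix, alpha_anova=r.alpha_anova, alpha_jtk=r.alpha_jtk,
        period=r.period_h, lag_step=r.lag_grid_step_h,
        min_reps_per_bin=r.min_reps_per_bin,
        min_peptides_per_sample=r.min_peptides_per_sample)
    summary = dict(funnel)
    if truth is not None and len(res):
        called = set(res.index[res["rhythmic"]])
        planted = set(truth.index[truth["is_rhythmic"]])
        quantified = set(matrix.values.index)
        tp = len(called & planted)
        summary["sensitivity"] = tp / max(1, len(planted & quantified))
        summary["realized_fdr"] = (len(called - planted) / len(called)) if called else 0.0
    return res, summary


@dataclass
class ProgenResult:
    target_proteome: dict
    genome: pg.GenomeSet
    planted: list
    collection: list
    taxonomy: pd.DataFrame
    psms_target: pd.DataFrame
    psms_collection: pd.DataFrame
    missing: set
    detail: pd.DataFrame
    groups: list
    taxon_counts: pd.Series
    classification: pd.DataFrame
    summary: dict = field(default_factory=dict)


def stage_progen(cfg: PipelineConfig, seed_offset: int = 10) -> ProgenResult:
    """Proteogenomics round trip on a planted toy genome.

    Builds a target proteome and a genome carrying the four defect classes,
    derives a reference collection (including a conspecific strain destined
    for exclusion), simulates identification-level PSM tables for the
    "detected" peptides (planted missing peptides plus planted decoys that
    the filters must remove), and runs the full missing-peptide ->
    containment-group -> taxon-summary -> genome-classification chain,
    scoring everything against the planted truth.
    """
    p = cfg.progen
    seed = cfg.seed + seed_offset
    base = simulate.random_proteome(p.n_base_proteins, p.base_protein_length, seed=seed)
    genome, planted = simulate.make_genome_with_planted_errors(
        base, p.n_overlap, p.n_uncalled, p.n_wobbly, p.n_gap, seed=seed + 1)

    rng = np.random.default_rng(np.random.SeedSequence(seed + 2))
    target_peps = sorted({pep for s in base.values()
                          for pep in pg.digest(s, p.max_missed_cleavages,
                                               p.min_peptide_length, p.max_peptide_length)})
    pool = [x for x in target_peps if 8 <= len(x) <= 14]
    same_score = [pool[i] for i in rng.permutation(len(pool))[: p.n_same_score_decoys]]
    il_pool = [x for x in pool if ("I" in x or "L" in x) and x not in same_score]
    il_decoys = []
    for x in il_pool:
        if len(il_decoys) >= p.n_il_decoys:
            break
        i = x.index("I") if "I" in x else x.index("L")
        v = x[:i] + ("L" if x[i] == "I" else "I") + x[i + 1:]
        if v not in target_peps:
            il_decoys.append(v)
    conspecific_only = simulate.random_tryptic_peptides(
        p.n_conspecific_only, rng, (10, 14),
        forbidden_norms={pg.il_normalize(s) for s in base.values()}
        | {pg.il_normalize(x) for x in planted})

    collection = simulate.make_proteome_collection(
        base, n_species=p.n_species, seed=seed + 3,
        extra_peptides=list(planted) + il_decoys + same_score,
        conspecific_only_peptides=conspecific_only)
    taxonomy = simulate.taxonomy_table(collection)
    target_db = simulate.ProteomeDB("target", "target species", "Anopheles species", base)

    detected = sorted(set(planted) | set(same_score) | set(il_decoys) | set(conspecific_only))
    score_params = simulate.ScoreParams(p.score_mean, p.score_sd,
                                        default_threshold=p.collection_threshold,
                                        thresholds={"target": p.target_threshold})
    psms_target = simulate.simulate_psms(detected, [target_db], score_params, seed=seed)
    psms_coll = simulate.simulate_psms(detected, collection, score_params, seed=seed)
    log.info("progen: %d detected peptides, %d target PSMs, %d collection PSMs",
             len(detected), len(psms_target), len(psms_coll))

    exclusions = ["conspecific_strain"]
    missing, detail = pg.find_missing(psms_target, psms_coll, exclusions,
                                      score_tol=p.score_tol)
    groups = pg.group_containment(missing, detail)
    taxon_counts = pg.taxon_summary(groups, taxonomy, exclusions=exclusions)
    classification = pg.classify_groups(groups, genome)
    log.info("progen funnel: %d detected -> %d missing -> %d groups",
             len(detected), len(missing), len(groups))

    truth = genome.truth_labels
    classified = classification[classification["representative"].isin(truth)]
    correct = sum(truth[r] == c for r, c in
                  zip(classified["representative"], classified["genome_class"]))
    decoys = set(same_score) | set(il_decoys) | set(conspecific_only)
    removed = decoys - missing
    summary = {
        "n_detected": len(detected),
        "n_missing": len(missing),
        "n_groups": len(groups),
        "n_planted": len(planted),
        "n_planted_recovered": int(classified.shape[0]),
        "classification_accuracy": correct / max(1, len(classified)),
        "n_decoys": len(decoys),
        "decoy_removal_rate": len(removed) / max(1, len(decoys)),
        "taxon_counts": taxon_counts.to_dict(),
    }
    return ProgenResult(base, genome, planted, collection, taxonomy, psms_target,
                        psms_coll, missing, detail, groups, taxon_counts,
                        classification, summary)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path,
                 write_features: bool = False) -> dict:
    """Execute every stage and write the report bundle + manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    design, raw, truth, features = stage_simulate(cfg)
    files.append(fileio.design_to_yaml(design, outdir / "design.yaml"))
    files.append(fileio.write_tsv(truth, outdir / "truth.tsv"))
    if write_features:
        files.append(fileio.write_tsv(features, outdir / "features.tsv", index=False))

    matrix = stage_quantify(cfg, features, design.sample_meta())
    files.extend(matrix.write(outdir / "quantify"))

    report = det.detectability_report(matrix)
    files.extend(report.write(outdir / "detectability"))

    res, rhythm_summary = stage_rhythm(cfg, matrix, truth)
    files.append(fileio.write_tsv(res, outdir / "rhythm" / "rhythm_results.tsv"))
    files.append(fileio.write_tsv(pd.Series(rhythm_summary, name="value"),
                                  outdir / "rhythm" / "rhythm_summary.tsv"))

    prog = stage_progen(cfg)
    pdir = outdir / "proteogenomics"
    files.extend(fileio.write_genome(prog.genome, pdir))
    files.append(fileio.write_tsv(prog.taxonomy, pdir / "taxonomy.tsv", index=False))
    files.append(fileio.write_tsv(prog.detail, pdir / "missing_peptides.tsv", index=False))
    files.append(fileio.write_tsv(prog.taxon_counts, pdir / "taxon_summary.tsv"))
    files.append(fileio.write_tsv(prog.classification, pdir / "classification.tsv", index=False))
    files.append(fileio.write_tsv(pd.Series(
        {k: v for k, v in prog.summary.items() if not isinstance(v, dict)},
        name="value"), pdir / "progen_summary.tsv"))

    manifest = fileio.write_manifest(outdir, cfg.to_dict(), cfg.seed, files)
    return {"outdir": outdir, "manifest": manifest, "matrix": matrix,
            "rhythm": res, "rhythm_summary": rhythm_summary, "progen": prog,
            "truth": truth}
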