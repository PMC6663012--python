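"""Synthetic study-condition generators.

This module stands in for the wet-lab side of a mosquito time-of-day
proteomics study so that every analysis stage has a ground-truth test
surface.  It generates:

* a staggered time-course sampling design (several courses of >= 24 h sampled
  every 4 h, so that pooling courses gives five biological replicates per
  zeitgeber-time bin);
* protein abundance time courses in which a chosen fraction of proteins
  follow a 24-h cosine (baseline * (1 + amplitude*cos(2*pi*(ZT-phase)/24)))
  with multiplicative lognormal noise, and detection drops out at low
  intensity through a decreasing logistic function of the true intensity
  (missing-not-at-random, as in label-free LC-MS);
* peptide/spectrum-level feature tables consistent with those abundances;
* proteome collections (a target proteome plus diverged relatives grouped
  into taxa) and identification-level PSM tables with Mascot-like scores and
  identity thresholds;
* toy genomes that faithfully encode a proteome and then plant annotation
  defects of four kinds: overlapping gene models in a shifted reading frame,
  uncalled genes on transcript-free scaffolds, "wobbly" genes carrying a
  single nucleotide substitution or 1-nt indel, and genes absent from the
  assembly altogether.

Everything is driven by one master seed; each generator derives independent
streams with a counter-based seed-sequence split, so identical arguments give
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .proteogenomics import GenomeSet, Transcript, il_normalize, PSM_COLUMNS

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_table = CodonTable.unambiguous_dna_by_id[1]
CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    CODONS_BY_AA.setdefault(aa, []).append(codon)
STOP_CODONS = tuple(sorted(_table.stop_codons))
_AA_BY_CODON = dict(_table.forward_table)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators from one master seed (counter split)."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _peptide_rng(seed: int, peptide: str) -> np.random.Generator:
    """Generator keyed by (seed, peptide) so the same evidence always draws
    the same score, in whichever database it is matched."""
    h = int.from_bytes(hashlib.sha256(peptide.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


# ---------------------------------------------------------------------------
# sampling design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Course:
    course_id: int
    start_zt: float
    duration_h: float


@dataclass(frozen=True)
class SamplePoint:
    sample_id: str
    course_id: int
    elapsed_h: float
    zt: float


@dataclass
class TimeCourseDesign:
    """Staggered collection schedule: each course starts at some zeitgeber
    time and is sampled every ``sampling_interval_h`` hours; ZT0 is lights on
    and ZT12 is lights off (12:12 LD)."""

    courses: list[Course]
    sampling_interval_h: float = 4.0
    lights_on_zt: float = 0.0
    lights_off_zt: float = 12.0
    pool_size: int = 10

    def samples(self) -> list[SamplePoint]:
        pts = []
        for c in self.courses:
            n = int(round(c.duration_h / self.sampling_interval_h)) + 1
            for i in range(n):
                el = i * self.sampling_interval_h
                pts.append(SamplePoint(f"c{c.course_id}_h{int(el):02d}", c.course_id,
                                       el, (c.start_zt + el) % 24.0))
        return pts

    def zt_bins(self) -> np.ndarray:
        return np.unique([p.zt for p in self.samples()])

    def sample_meta(self) -> pd.DataFrame:
        pts = self.samples()
        return pd.DataFrame(
            {"course_id": [p.course_id for p in pts],
             "elapsed_h": [p.elapsed_h for p in pts],
             "zt": [p.zt for p in pts]},
            index=pd.Index([p.sample_id for p in pts], name="sample_id"))

    def bin_counts(self) -> pd.Series:
        meta = self.sample_meta()
        return meta.groupby("zt").size()


def make_design(n_courses: int = 3, durations=(44, 36, 28), interval: float = 4.0,
                starts=None, pool_size: int = 10, seed: int | None = None
                ) -> TimeCourseDesign:
    """Build a staggered time-course design.

    Each course must last at least 24 h (otherwise it cannot cover every ZT
    bin) and a whole number of sampling intervals.  When ``starts`` is not
    given, start offsets are chosen by a deterministic grid search that
    balances the per-ZT-bin replicate counts (the default 44/36/28-h trio
    lands on starts ZT0/ZT0/ZT16, which gives exactly five replicates in each
    of the six 4-h bins).  ``seed`` is accepted for signature uniformity but
    the construction is fully deterministic.
    """
    durations = list(durations)
    if len(durations) != n_courses:
        raise ValueError("need one duration per course")
    if 24.0 % interval != 0:
        raise ValueError("interval must divide 24 h")
    for d in durations:
        if d < 24:
            raise ValueError(f"course duration {d} h < 24 h cannot cover all ZT bins")
        if d % interval != 0:
            raise ValueError(f"duration {d} h is not a multiple of the interval")
    if starts is None:
        starts = _balanced_starts(durations, interval)
    starts = list(starts)
    if len(starts) != n_courses:
        raise ValueError("need one start per course")
    courses = [Course(i + 1, float(s), float(d)) for i, (s, d) in enumerate(zip(starts, durations))]
    return TimeCourseDesign(courses, float(interval), pool_size=pool_size)


def _bin_counts_for(starts, durations, interval) -> np.ndarray:
    bins = np.arange(0, 24, interval)
    counts = np.zeros(len(bins))
    for s, d in zip(starts, durations):
        n = int(round(d / interval)) + 1
        for i in range(n):
            counts[int(((s + i * interval) % 24) / interval)] += 1
    return counts


def _balanced_starts(durations, interval) -> list[float]:
    cand = list(np.arange(0, 24, interval))
    best, best_key = None, None
    if len(durations) <= 4:
        combos = itertools.product(cand, repeat=len(durations))
    else:  # greedy beyond a grid-searchable number of courses
        starts = []
        for d in durations:
            opts = [(tuple(_bin_counts_for(starts + [s], durations[: len(starts) + 1],
                                           interval)), s) for s in cand]
            opts.sort(key=lambda o: (max(o[0]) - min(o[0]), o[1]))
            starts.append(opts[0][1])
        combos = [tuple(starts)]
    for combo in combos:
        counts = _bin_counts_for(combo, durations, interval)
        key = (counts.max() - counts.min(), counts.var(), combo)
        if best_key is None or key < best_key:
            best, best_key = list(combo), key
    return best


# ---------------------------------------------------------------------------
# abundance simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DropoutParams:
    """Intensity-dependent detection dropout: the probability a measurement
    is missed is logistic and decreasing in log true intensity, with
    probability 0.5 at ``midpoint``."""

    midpoint: float = 20_000.0
    slope: float = 1.2

    def p_missing(self, intensity) -> np.ndarray:
        x = np.log(np.maximum(np.asarray(intensity, dtype=float), 1e-300))
        return 1.0 / (1.0 + np.exp(self.slope * (x - np.log(self.midpoint))))


TRUTH_COLUMNS = ["protein_id", "is_rhythmic", "phase_zt", "amplitude",
                 "baseline", "dropout_midpoint"]


def simulate_abundance(design: TimeCourseDesign, n_proteins: int = 1525,
                       frac_rhythmic: float = 0.2, noise_sd: float = 0.2,
                       dropout_params: DropoutParams | None = DropoutParams(),
                       amplitude_range=(0.1, 0.6),
                       baseline_log_mean: float = float(np.log(3000.0)),
                       baseline_log_sd: float = 1.5,
                       phase_grid_h: float | None = 2.0,
                       seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw (pre-normalization) protein intensities with known truth.

    Rhythmic proteins follow ``baseline * (1 + amplitude*cos(2*pi*(ZT -
    phase)/24))`` with multiplicative lognormal noise; detection dropout
    (applied to the raw intensity, since detection happens at acquisition)
    zeroes a measurement with the :class:`DropoutParams` probability.  Exactly
    ``round(frac_rhythmic * n_proteins)`` proteins are rhythmic.  Returns
    (raw intensity matrix proteins x samples, truth table).
    """
    for name, v in [("frac_rhythmic", frac_rhythmic), ("noise_sd", noise_sd),
                    ("baseline_log_mean", baseline_log_mean),
                    ("baseline_log_sd", baseline_log_sd)]:
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if not 0 <= frac_rhythmic <= 1:
        raise ValueError("frac_rhythmic must be in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if dropout_params is not None and not (np.isfinite(dropout_params.midpoint)
                                           and np.isfinite(dropout_params.slope)):
        raise ValueError("dropout parameters must be finite")

    rng_base, rng_phase, rng_noise, rng_drop = _rng_streams(seed, 4)
    meta = design.sample_meta()
    zt = meta["zt"].to_numpy()
    n_rhythmic = int(round(frac_rhythmic * n_proteins))

    protein_ids = [f"P{i:05d}" for i in range(n_proteins)]
    baseline = np.exp(rng_base.normal(baseline_log_mean, baseline_log_sd, n_proteins))
    is_rhythmic = np.zeros(n_proteins, dtype=bool)
    is_rhythmic[rng_phase.permutation(n_proteins)[:n_rhythmic]] = True
    amplitude = np.where(is_rhythmic,
                         rng_phase.uniform(*amplitude_range, n_proteins), 0.0)
    if phase_grid_h:
        grid = np.arange(0, 24, phase_grid_h)
        phase = grid[rng_phase.integers(0, len(grid), n_proteins)].astype(float)
    else:
        phase = rng_phase.uniform(0, 24, n_proteins)
    phase = np.where(is_rhythmic, phase, np.nan)

    mod = 1.0 + amplitude[:, None] * np.cos(
        2 * np.pi * (zt[None, :] - np.where(np.isnan(phase), 0.0, phase)[:, None]) / 24.0)
    true_mean = baseline[:, None] * mod
    if noise_sd > 0:
        raw = true_mean * np.exp(rng_noise.normal(0.0, noise_sd, true_mean.shape))
    else:
        raw = true_mean.copy()
    if dropout_params is not None:
        p_miss = dropout_params.p_missing(raw)
        raw = np.where(rng_drop.random(raw.shape) < p_miss, 0.0, raw)

    raw_df = pd.DataFrame(raw, index=pd.Index(protein_ids, name="protein_id"),
                          columns=meta.index)
    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "is_rhythmic": is_rhythmic,
        "phase_zt": phase,
        "amplitude": amplitude,
        "baseline": baseline,
        "dropout_midpoint": (dropout_params.midpoint if dropout_params else np.nan),
    }).set_index("protein_id")
    return raw_df, truth


# ---------------------------------------------------------------------------
# peptide / feature generation
# ---------------------------------------------------------------------------

_INTERIOR = np.array(list(AMINO_ACIDS.replace("K", "").replace("R", "").replace("P", "")))


def random_tryptic_peptides(n: int, rng: np.random.Generator,
                            length_range=(8, 14),
                            forbidden_norms: set[str] | None = None) -> list[str]:
    """Distinct tryptic-like peptides (no internal K/R, C-terminal K/R) whose
    I/L-collapsed forms avoid ``forbidden_norms`` (no member is a substring of
    a forbidden sequence or of another member, in either direction)."""
    out: list[str] = []
    norms: list[str] = []
    forbidden = list(forbidden_norms or ())
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not generate enough distinct peptides")
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        body = "".join(rng.choice(_INTERIOR, L - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        nrm = il_normalize(pep)
        if any(nrm in f or f in nrm for f in forbidden):
            continue
        if any(nrm in m or m in nrm for m in norms):
            continue
        out.append(pep)
        norms.append(nrm)
    return out


def features_from_abundance(raw: pd.DataFrame, seed: int = 0,
                            n_peptides_range=(2, 5), n_spectra_range=(1, 7),
                            charges=(1, 2, 3, 4, 5),
                            charge_probs=(0.05, 0.45, 0.3, 0.15, 0.05)
                            ) -> pd.DataFrame:
    """Expand a protein-level raw intensity matrix to a spectrum-level
    feature table.

    Each protein gets a fixed set of peptide features; a feature's fraction of
    the protein signal and its split over spectra are drawn once and applied
    to every sample, so a protein's per-sample profile is preserved (up to the
    charge filter) through the quantitation chain.
    """
    rng = _rng_streams(seed, 1)[0]
    n_prot = len(raw)
    k = rng.integers(n_peptides_range[0], n_peptides_range[1] + 1, n_prot)
    n_feat = int(k.sum())
    peptides = random_tryptic_peptides(n_feat, rng)

    prot_of_feat = np.repeat(np.arange(n_prot), k)
    weights = np.concatenate([rng.dirichlet(np.ones(ki)) for ki in k])
    charge = rng.choice(charges, size=n_feat, p=charge_probs)
    n_spec = rng.integers(n_spectra_range[0], n_spectra_range[1] + 1, n_feat)
    fracs = np.concatenate([rng.dirichlet(np.ones(ns)) for ns in n_spec])

    feat_of_spec = np.repeat(np.arange(n_feat), n_spec)
    scale = weights[feat_of_spec] * fracs  # per spectrum, fraction of protein signal
    vals = raw.to_numpy()
    inten = scale[:, None] * vals[prot_of_feat[feat_of_spec], :]

    n_samples = raw.shape[1]
    n_spec_total = len(feat_of_spec)
    feature_ids = np.array([f"{peptides[f]}/{charge[f]}" for f in feat_of_spec])
    table = pd.DataFrame({
        "feature_id": np.repeat(feature_ids, n_samples),
        "peptide_sequence": np.repeat(np.array(peptides)[feat_of_spec], n_samples),
        "protein_id": np.repeat(raw.index.to_numpy()[prot_of_feat[feat_of_spec]], n_samples),
        "charge": np.repeat(charge[feat_of_spec], n_samples),
        "sample_id": np.tile(raw.columns.to_numpy(), n_spec_total),
        "intensity": inten.ravel(),
    })
    return table


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------

@dataclass
class ProteomeDB:
    """One searchable proteome with a species label and taxon group."""

    db_id: str
    species_name: str
    taxon_group: str
    entries: dict[str, str]

    def __post_init__(self):
        ok = set(AMINO_ACIDS)
        for acc, seq in self.entries.items():
            if not set(seq) <= ok:
                raise ValueError(f"{self.db_id}:{acc} contains non-standard residues")


def random_proteome(n_proteins: int = 200, length_range=(150, 350),
                    seed: int = 0, id_prefix: str = "TGT") -> dict[str, str]:
    """A random target proteome (accession -> sequence)."""
    rng = _rng_streams(seed, 1)[0]
    aas = np.array(list(AMINO_ACIDS))
    out = {}
    for i in range(n_proteins):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out[f"{id_prefix}{i:05d}"] = "".join(rng.choice(aas, L))
    return out


DEFAULT_TAXON_DIVERGENCE = {
    "Anopheles species": 0.08,
    "Other mosquito species": 0.20,
    "non-dipteran": 0.40,
}


def diverge_proteome(entries: dict[str, str], rate: float,
                     rng: np.random.Generator) -> dict[str, str]:
    """Apply i.i.d. residue substitutions (always to a different residue) at
    the given per-site rate."""
    if not 0 <= rate < 1:
        raise ValueError("divergence rate must be in [0, 1)")
    aas = np.array(list(AMINO_ACIDS))
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    out = {}
    for acc, seq in entries.items():
        arr = np.array(list(seq))
        hit = rng.random(len(arr)) < rate
        if hit.any():
            orig = np.array([aa_index[a] for a in arr[hit]])
            shift = rng.integers(1, len(aas), hit.sum())
            arr[hit] = aas[(orig + shift) % len(aas)]
        out[acc] = "".join(arr)
    return out


def make_proteome_collection(base_proteome: dict[str, str], n_species: int = 39,
                             divergence_per_taxon: dict[str, float] | None = None,
                             seed: int = 0,
                             extra_peptides: list[str] | None = None,
                             conspecific_db_id: str | None = "conspecific_strain",
                             conspecific_only_peptides: list[str] | None = None
                             ) -> list[ProteomeDB]:
    """Derive a reference proteome collection from a base proteome.

    Species are assigned round-robin to the taxon groups of
    ``divergence_per_taxon`` and mutated at the taxon's divergence rate.
    ``extra_peptides`` (e.g. peptides planted as missing from the target) are
    embedded verbatim, each into a random non-empty subset of species, so they
    can be matched in the collection.  When ``conspecific_db_id`` is set, the
    first database is an undiverged copy of the base proteome — a conspecific
    strain, the usual exclusion case — optionally carrying
    ``conspecific_only_peptides`` found nowhere else.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    div = dict(divergence_per_taxon or DEFAULT_TAXON_DIVERGENCE)
    for taxon, rate in div.items():
        if not 0 <= rate < 1:
            raise ValueError(f"divergence for {taxon!r} must be in [0, 1)")
    rng = _rng_streams(seed, 1)[0]
    taxa = list(div)
    dbs: list[ProteomeDB] = []
    species_rngs = _rng_streams(seed + 1, n_species)
    for i in range(n_species):
        taxon = taxa[i % len(taxa)]
        entries = diverge_proteome(base_proteome, div[taxon], species_rngs[i])
        dbs.append(ProteomeDB(f"sp{i:02d}", f"species_{i:02d}", taxon, entries))

    if extra_peptides:
        flank_aas = np.array(list(AMINO_ACIDS))
        for j, pep in enumerate(extra_peptides):
            n_in = int(rng.integers(1, n_species + 1))
            chosen = rng.permutation(n_species)[:n_in]
            for si in chosen:
                f1 = "".join(rng.choice(flank_aas, int(rng.integers(8, 16))))
                f2 = "".join(rng.choice(flank_aas, int(rng.integers(8, 16))))
                dbs[si].entries[f"PLANT{j:04d}"] = f1 + "R" + pep + f2

    if conspecific_db_id is not None:
        entries = dict(base_proteome)
        rng2 = _rng_streams(seed + 2, 1)[0]
        flank_aas = np.array(list(AMINO_ACIDS))
        for j, pep in enumerate(conspecific_only_peptides or ()):
            f1 = "".join(rng2.choice(flank_aas, int(rng2.integers(8, 16))))
            f2 = "".join(rng2.choice(flank_aas, int(rng2.integers(8, 16))))
            entries[f"STRAINONLY{j:04d}"] = f1 + "R" + pep + f2
        dbs.insert(0, ProteomeDB(conspecific_db_id, "target species (second strain)",
                                 taxa[0], entries))
    return dbs


def taxonomy_table(dbs: list[ProteomeDB]) -> pd.DataFrame:
    return pd.DataFrame({"db_id": [d.db_id for d in dbs],
                         "species": [d.species_name for d in dbs],
                         "taxon_group": [d.taxon_group for d in dbs]})


# ---------------------------------------------------------------------------
# PSM simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreParams:
    """Mascot-like score model: one normal score per peptide (the evidence is
    the spectrum, so the score does not depend on which database matched),
    compared against a per-database identity threshold."""

    score_mean: float = 38.0
    score_sd: float = 6.0
    default_threshold: float = 35.6
    thresholds: dict = field(default_factory=dict)

    def threshold_for(self, db_id: str) -> float:
        return float(self.thresholds.get(db_id, self.default_threshold))


def simulate_psms(peptides, dbs: list[ProteomeDB],
                  score_params: ScoreParams = ScoreParams(),
                  seed: int = 0) -> pd.DataFrame:
    """Identification-level PSMs for each peptide against each database where
    it occurs (I/L-equivalently) in some entry.

    The reported peptide sequence is the database's own subsequence, as a
    search engine would report it (so an I/L permutation in the target shows
    up under the target's spelling).  Scores are drawn once per peptide from
    N(mean, sd) truncated at 0; rank is 1 (one PSM per peptide per database).
    """
    if len(peptides) == 0:
        raise ValueError("peptides must be non-empty")
    concat = {}
    for db in dbs:
        accs, norm_parts, orig_parts = [], [], []
        for acc, seq in db.entries.items():
            accs.append(acc)
            norm_parts.append(il_normalize(seq))
            orig_parts.append(seq)
        norm = "#".join(norm_parts)
        orig = "#".join(orig_parts)
        bounds = np.cumsum([0] + [len(s) + 1 for s in norm_parts])
        concat[db.db_id] = (norm, orig, accs, bounds)

    rows = []
    for pep in peptides:
        score = max(0.0, float(_peptide_rng(seed, il_normalize(pep)).normal(
            score_params.score_mean, score_params.score_sd)))
        for db in dbs:
            norm, orig, accs, bounds = concat[db.db_id]
            pos = norm.find(il_normalize(pep))
            if pos < 0:
                continue
            entry_i = int(np.searchsorted(bounds, pos, side="right")) - 1
            reported = orig[pos: pos + len(pep)]
            rows.append((reported, db.db_id, accs[entry_i], score,
                         score_params.threshold_for(db.db_id), 1))
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


# ---------------------------------------------------------------------------
# toy genomes with planted annotation defects
# ---------------------------------------------------------------------------

_NT = np.array(list("ACGT"))


def reverse_translate(pep: str, rng: np.random.Generator) -> str:
    return "".join(CODONS_BY_AA[aa][int(rng.integers(len(CODONS_BY_AA[aa])))]
                   for aa in pep)


def _revcomp(nt: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return nt.translate(comp)[::-1]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _segment_ok(segment: str, pep: str, expect: str) -> bool:
    """Local sanity check of a planted segment against the six-frame scan."""
    from . import proteogenomics as pg
    g = GenomeSet({"seg": segment}, [])
    hits = pg.search_peptide(g, pep)
    exact = [h for h in hits if h.n_mismatches == 0 and h.frameshift == 0]
    wobbly = [h for h in hits if h.n_mismatches == 1 or h.frameshift != 0]
    if expect == "exact":
        return bool(exact)
    if expect == "wobbly":
        return bool(wobbly) and not exact
    raise ValueError(expect)


def _with_flanks(seg: str, rng: np.random.Generator) -> str:
    return (_random_nt(rng, int(rng.integers(40, 81))) + seg
            + _random_nt(rng, int(rng.integers(40, 81))))


def _plant_substitution(pep: str, rng: np.random.Generator) -> str:
    """Flanked peptide CDS with one nucleotide substitution that changes the
    encoded residue to a different (non-stop, non-I/L-equivalent) one.  The
    flanked segment is verified against the six-frame scan (wobbly, no exact
    full-length hit) before being accepted."""
    for _ in range(50):
        enc = reverse_translate(pep, rng)
        a = int(rng.integers(1, len(pep) - 1))
        codon = enc[3 * a: 3 * a + 3]
        cands = []
        for pos in range(3):
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                new = codon[:pos] + nt + codon[pos + 1:]
                aa = _AA_BY_CODON.get(new)
                if aa is not None and il_normalize(aa) != il_normalize(pep[a]):
                    cands.append(new)
        if not cands:
            continue
        new = cands[int(rng.integers(len(cands)))]
        seg = _with_flanks(enc[: 3 * a] + new + enc[3 * a + 3:], rng)
        if _segment_ok(seg, pep, "wobbly"):
            return seg
    raise RuntimeError(f"could not plant a substitution for {pep}")


def _plant_indel(pep: str, rng: np.random.Generator) -> str:
    """Flanked peptide CDS broken by a 1-nt frameshift: an inserted nucleotide
    at a codon boundary (+1), or a prefix/suffix encoding overlapping by one
    shared boundary nucleotide (-1, span 3L-1).  Verified against the
    six-frame scan so junction codons cannot accidentally restore a perfect
    full-length hit."""
    L = len(pep)
    for _ in range(50):
        k = int(rng.integers(1, L))
        if rng.random() < 0.5:  # insertion
            enc = reverse_translate(pep, rng)
            core = enc[: 3 * k] + _random_nt(rng, 1) + enc[3 * k:]
        else:  # deletion: shared boundary nucleotide
            pre = reverse_translate(pep[:k], rng)
            suf = None
            for _ in range(30):
                cand = reverse_translate(pep[k:], rng)
                if cand[0] == pre[-1]:
                    suf = cand
                    break
            if suf is None:
                continue
            core = pre + suf[1:]
        seg = _with_flanks(core, rng)
        if _segment_ok(seg, pep, "wobbly"):
            return seg
    raise RuntimeError(f"could not plant an indel for {pep}")


def make_genome_with_planted_errors(proteome: dict[str, str], n_overlap: int = 2,
                                    n_uncalled: int = 25, n_wobbly: int = 94,
                                    n_gap: int = 120, seed: int = 0,
                                    genes_per_scaffold: int = 8,
                                    peptide_length_range=(10, 14),
                                    wobbly_indel_fraction: float = 0.5,
                                    minus_strand_fraction: float = 0.3
                                    ) -> tuple[GenomeSet, list[str]]:
    """Encode a proteome on toy scaffolds and plant annotation defects.

    Returns the :class:`GenomeSet` (with truth labels for every planted
    peptide) and the list of planted peptides.  Categories:

    * ``transcript_frame_overlap`` — the peptide's CDS is written inside an
      annotated (plus-strand) transcript at a +1/+2 frame offset;
    * ``scaffold_hit`` — the peptide's CDS sits on a scaffold that carries no
      transcript model;
    * ``wobbly_scaffold`` — as scaffold_hit but with one planted nucleotide
      substitution or 1-nt indel inside the coding region
      (``wobbly_indel_fraction`` of plants are indels);
    * ``no_hit`` — the peptide is absent from the scaffolds entirely.
    """
    for name, n in [("n_overlap", n_overlap), ("n_uncalled", n_uncalled),
                    ("n_wobbly", n_wobbly), ("n_gap", n_gap)]:
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    if not proteome:
        raise ValueError("proteome must be non-empty")
    from .proteogenomics import (CLASS_OVERLAP, CLASS_SCAFFOLD, CLASS_WOBBLY,
                                 CLASS_NO_HIT)
    rng_pep, rng_genome, rng_plant = _rng_streams(seed, 3)

    # --- scaffolds encoding the annotated proteome
    scaffolds: dict[str, bytearray] = {}
    transcripts: list[Transcript] = []
    items = sorted(proteome.items())
    si = -1
    for gi, (acc, seq) in enumerate(items):
        if gi % genes_per_scaffold == 0:
            si += 1
            scaffolds[f"scaffold_{si:03d}"] = bytearray()
        sid = f"scaffold_{si:03d}"
        buf = scaffolds[sid]
        buf.extend(_random_nt(rng_genome, int(rng_genome.integers(60, 121))).encode())
        cds = reverse_translate(seq, rng_genome)
        strand = "-" if rng_genome.random() < minus_strand_fraction else "+"
        start = len(buf)
        buf.extend((cds if strand == "+" else _revcomp(cds)).encode())
        transcripts.append(Transcript(acc, sid, start, len(buf), strand, 0))
    for sid in scaffolds:
        scaffolds[sid].extend(_random_nt(rng_genome, 80).encode())

    # --- planted peptides, disjoint from the proteome under I/L collapse
    n_planted = n_overlap + n_uncalled + n_wobbly + n_gap
    forbidden = {il_normalize(s) for s in proteome.values()}
    planted = random_tryptic_peptides(n_planted, rng_pep, peptide_length_range,
                                      forbidden_norms=forbidden)
    it = iter(planted)
    overlap_peps = [next(it) for _ in range(n_overlap)]
    uncalled_peps = [next(it) for _ in range(n_uncalled)]
    wobbly_peps = [next(it) for _ in range(n_wobbly)]
    gap_peps = [next(it) for _ in range(n_gap)]
    truth: dict[str, str] = {}

    # overlap plants: overwrite inside a plus-strand transcript, shifted frame
    plus = [t for t in transcripts if t.strand == "+"]
    rng_plant.shuffle(plus)
    usable = [t for t in plus if (t.end - t.start) >= 3 * peptide_length_range[1] + 12]
    if n_overlap > len(usable):
        raise ValueError("insufficient scaffold space: not enough plus-strand "
                         f"transcripts ({len(usable)}) for {n_overlap} overlap plants")
    for pep, t in zip(overlap_peps, usable):
        span = 3 * len(pep)
        shift = int(rng_plant.integers(1, 3))
        max_m = (t.end - t.start - span - shift) // 3
        m = int(rng_plant.integers(1, max_m))
        o = t.start + 3 * m + shift
        enc = reverse_translate(pep, rng_plant)
        scaffolds[t.scaffold_id][o: o + span] = enc.encode()
        truth[pep] = CLASS_OVERLAP

    # transcript-free scaffolds for uncalled and wobbly plants
    def _free_scaffold(segments: list[str], name: str) -> None:
        scaffolds[name] = bytearray("".join(segments).encode())

    free_segments: list[str] = []
    for pep in uncalled_peps:
        free_segments.append(_with_flanks(reverse_translate(pep, rng_plant), rng_plant))
        truth[pep] = CLASS_SCAFFOLD
    for i, pep in enumerate(wobbly_peps):
        if rng_plant.random() < wobbly_indel_fraction:
            free_segments.append(_plant_indel(pep, rng_plant))
        else:
            free_segments.append(_plant_substitution(pep, rng_plant))
        truth[pep] = CLASS_WOBBLY
    per = 20
    for i in range(0, len(free_segments), per):
        _free_scaffold(free_segments[i: i + per], f"free_scaffold_{i // per:03d}")

    for pep in gap_peps:
        truth[pep] = CLASS_NO_HIT

    genome = GenomeSet({sid: buf.decode() for sid, buf in scaffolds.items()},
                       transcripts, truth)
    genome.validate()
    log.info("planted genome: %d scaffolds, %d transcripts, %d planted peptides "
             "(%d overlap / %d uncalled / %d wobbly / %d gap)",
             len(genome.scaffolds), len(transcripts), n_planted,
             n_overlap, n_uncalled, n_wobbly, n_gap)
    return genome, planted
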