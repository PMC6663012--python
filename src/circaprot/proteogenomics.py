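"""Cross-species proteogenomics: missing-peptide discovery and genome classification.

The procedure implemented here asks, for peptides confidently identified by a
database search: which of them are absent from the target species' predicted
proteome yet present in a collection of reference proteomes from related (and
not so related) taxa?  Each such "missing" peptide is evidence that the target
genome annotation — or the assembly itself — has a defect.  The surviving
peptides are collapsed into containment groups, summarized by the taxa that
support them, and finally located on the target genome by an exact /
one-mismatch six-frame translated search, which sorts each group into one of
four annotation-error categories:

``transcript_frame_overlap``
    a perfect full-length hit inside an annotated transcript but in a
    different reading frame or strand — an overlapping gene model that the
    annotation missed;
``scaffold_hit``
    a perfect full-length genomic hit outside every transcript model — a gene
    the prediction software never called;
``wobbly_scaffold``
    a near hit: exactly one amino-acid mismatch, or a full-length match split
    by a single-nucleotide frameshift (span = query length +- 1 nt) — a SNP,
    a sequencing error, or a 1-nt indel;
``no_hit``
    nothing at all — a suspected gap in the genome assembly.

Peptide comparisons throughout use isoleucine/leucine equivalence, because the
two residues are isobaric and indistinguishable by mass spectrometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from pyteomics import parser as _pyt_parser

log = logging.getLogger(__name__)

# genome classification categories, in precedence order
CLASS_ANNOTATED = "annotated"
CLASS_OVERLAP = "transcript_frame_overlap"
CLASS_SCAFFOLD = "scaffold_hit"
CLASS_WOBBLY = "wobbly_scaffold"
CLASS_NO_HIT = "no_hit"
GENOME_CLASSES = (CLASS_OVERLAP, CLASS_SCAFFOLD, CLASS_WOBBLY, CLASS_NO_HIT)

PSM_COLUMNS = [
    "peptide_sequence",
    "db_id",
    "accession",
    "score",
    "identity_threshold",
    "rank",
]


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-to-database match at the identification level."""

    peptide_sequence: str
    db_id: str
    accession: str
    score: float
    identity_threshold: float
    rank: int = 1

    def __post_init__(self):
        if self.score < 0:
            raise ValueError("PSM score must be >= 0")
        if self.rank < 1:
            raise ValueError("PSM rank must be >= 1")


def psms_to_frame(psms) -> pd.DataFrame:
    """Normalize a list of :class:`PSMRecord` (or a DataFrame) to a DataFrame."""
    if isinstance(psms, pd.DataFrame):
        return psms
    return pd.DataFrame(
        [(p.peptide_sequence, p.db_id, p.accession, p.score, p.identity_threshold, p.rank) for p in psms],
        columns=PSM_COLUMNS,
    )


@dataclass(frozen=True)
class Transcript:
    """A transcript model on a scaffold; coordinates are 0-based half-open
    on the forward strand.  ``frame`` is the offset of the first coding base
    from ``start`` (plus strand) or from ``end`` (minus strand)."""

    transcript_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int = 0


@dataclass
class GenomeSet:
    """Toy genome: scaffolds, transcript models, and (for synthetic genomes)
    the planted truth category of each planted peptide."""

    scaffolds: dict[str, str]
    transcripts: list[Transcript]
    truth_labels: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for t in self.transcripts:
            if t.scaffold_id not in self.scaffolds:
                raise ValueError(f"transcript {t.transcript_id} on unknown scaffold {t.scaffold_id}")
            if not (0 <= t.start < t.end <= len(self.scaffolds[t.scaffold_id])):
                raise ValueError(f"transcript {t.transcript_id} out of scaffold bounds")
        allowed = set(GENOME_CLASSES) | {CLASS_ANNOTATED}
        for pep, label in self.truth_labels.items():
            if label not in allowed:
                raise ValueError(f"unknown truth label {label!r} for {pep}")


@dataclass(frozen=True)
class GenomeHit:
    """One peptide-to-genome match from the six-frame search.

    ``start``/``end`` are 0-based half-open forward-strand nucleotide
    coordinates; minus-strand hits report the forward-strand interval with
    ``strand == '-'``.  ``frame`` is the frame offset (0/1/2) on the hit's own
    strand.  For frameshift hits the span is 3*len(peptide) +- 1.
    """

    scaffold_id: str
    start: int
    end: int
    strand: str
    frame: int
    n_mismatches: int
    frameshift: int = 0  # 0, +1 or -1 nt
    overlaps_transcript: bool = False
    contained_in_transcript: bool = False
    same_frame_as_transcript: bool = False
    transcript_id: str | None = None


# ---------------------------------------------------------------------------
# peptide-level primitives
# ---------------------------------------------------------------------------

def il_normalize(seq: str) -> str:
    """Collapse the isobaric residues I and L onto a single symbol (L)."""
    return seq.upper().replace("I", "L")


def il_equiv(a: str, b: str) -> bool:
    """True iff two peptides are indistinguishable under I/L equivalence."""
    return il_normalize(a) == il_normalize(b)


# cleave after K or R except when the next residue is P
TRYPSIN_RULE = r"[KR](?!P)"


def digest(protein_sequence: str, max_missed: int = 2,
           min_length: int = 6, max_length: int = 50) -> set[str]:
    """In-silico tryptic digest.

    Cleaves after K/R (not before P), keeps products with up to ``max_missed``
    internal missed cleavage sites, and applies a peptide length filter.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    peps = _pyt_parser.cleave(protein_sequence.upper(), TRYPSIN_RULE,
                              missed_cleavages=max_missed)
    return {p for p in peps if min_length <= len(p) <= max_length}


# ---------------------------------------------------------------------------
# missing-peptide discovery
# ---------------------------------------------------------------------------

def _confident(psms: pd.DataFrame) -> pd.DataFrame:
    """Rank-1 matches scoring above their identity threshold."""
    return psms[(psms["rank"] == 1) & (psms["score"] > psms["identity_threshold"])]


def find_missing(psms_target, psms_collection, exclusions=(),
                 score_tol: float = 0.0) -> tuple[set[str], pd.DataFrame]:
    """Peptides confidently matched in the collection but absent from the target.

    Filters, in order:

    1. keep collection PSMs that are rank 1 and score above the identity
       threshold; drop hits to excluded databases (e.g. a conspecific strain);
    2. drop any peptide that has a confident target-proteome match with an
       identical score (within ``score_tol``) — the same spectrum explained by
       both databases;
    3. drop any peptide whose target proteome contains an I/L-equivalent match
       (isobaric, hence indistinguishable);
    4. drop peptides left with no collection hit.

    Returns the missing peptide set and the per-hit detail table
    (peptide_sequence, db_id, accession, score).
    """
    tgt = _confident(psms_to_frame(psms_target))
    coll = _confident(psms_to_frame(psms_collection))
    coll = coll[~coll["db_id"].isin(set(exclusions))]
    if coll.empty:
        return set(), coll.iloc[0:0][["peptide_sequence", "db_id", "accession", "score"]]

    tgt_scores: dict[str, list[float]] = {}
    tgt_il: set[str] = set()
    for pep, score in zip(tgt["peptide_sequence"], tgt["score"]):
        tgt_scores.setdefault(pep, []).append(float(score))
        tgt_il.add(il_normalize(pep))

    def _removed(pep: str, score: float) -> bool:
        same = any(abs(score - s) <= score_tol for s in tgt_scores.get(pep, ()))
        return same or il_normalize(pep) in tgt_il

    keep = [
        not _removed(pep, float(score))
        for pep, score in zip(coll["peptide_sequence"], coll["score"])
    ]
    detail = coll[keep][["peptide_sequence", "db_id", "accession", "score"]].reset_index(drop=True)
    return set(detail["peptide_sequence"]), detail


# ---------------------------------------------------------------------------
# containment grouping
# ---------------------------------------------------------------------------

@dataclass
class MissingPeptideGroup:
    representative: str
    members: set[str]
    species_hits: dict[str, set[str]] = field(default_factory=dict)
    representative_tie: bool = False
    genome_class: str | None = None


def group_containment(peptides, hits: pd.DataFrame | None = None) -> list[MissingPeptideGroup]:
    """Collapse peptides that are I/L-equivalent substrings of longer peptides.

    Two peptides share a group iff one contains the other under I/L
    equivalence, closed transitively (union-find over all containing pairs).
    The representative is the longest member; length ties are broken
    lexicographically and flagged.  If ``hits`` (a find_missing detail table)
    is given, per-database accession hits are attached to each group.
    """
    peps = sorted(set(peptides))
    norm = {p: il_normalize(p) for p in peps}
    parent = {p: p for p in peps}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    by_len = sorted(peps, key=len)
    for i, a in enumerate(by_len):
        for b in by_len[i + 1:]:
            if len(b) > len(a) and norm[a] in norm[b]:
                union(a, b)
            elif len(b) == len(a) and norm[a] == norm[b]:
                union(a, b)

    clusters: dict[str, set[str]] = {}
    for p in peps:
        clusters.setdefault(find(p), set()).add(p)

    groups = []
    for members in clusters.values():
        longest = max(len(m) for m in members)
        cands = sorted(m for m in members if len(m) == longest)
        g = MissingPeptideGroup(
            representative=cands[0],
            members=set(members),
            representative_tie=len(cands) > 1,
        )
        if g.representative_tie:
            log.warning("representative tie in peptide group: %s", cands)
        if hits is not None:
            sub = hits[hits["peptide_sequence"].isin(members)]
            for db_id, acc in zip(sub["db_id"], sub["accession"]):
                g.species_hits.setdefault(db_id, set()).add(acc)
        groups.append(g)
    groups.sort(key=lambda g: g.representative)
    return groups


def taxon_summary(groups: list[MissingPeptideGroup], db_taxonomy: pd.DataFrame,
                  exclusions=()) -> pd.Series:
    """Count, per taxonomic group, the peptide groups with at least one hit.

    A peptide group counts once per taxon regardless of how many species in
    that taxon hit it.  Databases in ``exclusions`` contribute to no taxon.
    ``db_taxonomy`` maps db_id -> taxon_group (columns ``db_id`` and
    ``taxon_group``).  Unknown db_ids are rejected.
    """
    taxon_of = dict(zip(db_taxonomy["db_id"], db_taxonomy["taxon_group"]))
    counts: dict[str, int] = {t: 0 for t in dict.fromkeys(db_taxonomy["taxon_group"])}
    excluded = set(exclusions)
    for g in groups:
        taxa = set()
        for db_id in g.species_hits:
            if db_id in excluded:
                continue
            if db_id not in taxon_of:
                raise KeyError(f"db_id {db_id!r} has no taxonomy entry")
            taxa.add(taxon_of[db_id])
        for t in taxa:
            counts[t] += 1
    return pd.Series(counts, name="n_groups")


# ---------------------------------------------------------------------------
# six-frame peptide-to-genome search
# ---------------------------------------------------------------------------

def _revcomp(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def _translate_frame(nt: str, off: int) -> str:
    sub = nt[off:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


class _FrameIndex:
    """Per-scaffold, per-strand translated frames as byte arrays."""

    def __init__(self, scaffold_id: str, seq: str):
        self.scaffold_id = scaffold_id
        self.length = len(seq)
        self.frames = {}  # (strand, off) -> np.uint8 array of aa
        for strand, nt in (("+", seq), ("-", _revcomp(seq))):
            for off in range(3):
                aa = _translate_frame(nt, off)
                self.frames[(strand, off)] = np.frombuffer(aa.encode("ascii"), dtype=np.uint8)

    def fwd_interval(self, strand: str, off: int, aa_start: int, n_nt: int):
        """Forward-strand nt interval of a hit starting at aa index ``aa_start``
        in frame ``off`` of ``strand`` and spanning ``n_nt`` nucleotides."""
        p = off + 3 * aa_start
        if strand == "+":
            return p, p + n_nt
        return self.length - (p + n_nt), self.length - p


def _pep_array(pep: str) -> np.ndarray:
    return np.frombuffer(il_normalize(pep).encode("ascii"), dtype=np.uint8)


_STAR = ord("*")


def _match_matrix(frame: np.ndarray, pep: np.ndarray) -> np.ndarray | None:
    """EQ[p, c] = frame[p + c] matches pep[c] (under I/L collapse, applied
    to the frame on the fly).  Shape (n_windows, len(pep))."""
    L = len(pep)
    n = len(frame) - L + 1
    if n <= 0:
        return None
    fr = np.where(frame == ord("I"), ord("L"), frame)
    eq = np.empty((n, L), dtype=bool)
    for c in range(L):
        eq[:, c] = fr[c:c + n] == pep[c]
    return eq


class GenomeIndex:
    """Cached six-frame translations of every scaffold in a genome."""

    def __init__(self, genome: GenomeSet):
        self.genome = genome
        self.scaffolds = {sid: _FrameIndex(sid, seq) for sid, seq in genome.scaffolds.items()}


def search_peptide(genome: GenomeSet, peptide: str, max_mismatches: int = 1,
                   frameshift: bool = True, index: GenomeIndex | None = None) -> list[GenomeHit]:
    """Six-frame search of a peptide against all scaffolds.

    Finds full-length hits with 0 or up to ``max_mismatches`` amino-acid
    mismatches, and (optionally) single-nucleotide frameshift hits where the
    peptide splits into a prefix and suffix encoded at adjacent genomic
    positions offset by +-1 nt.  Windows containing a stop codon are invalid.
    Transcript overlap/frame annotations are filled in by the caller.
    """
    pep = _pep_array(peptide)
    L = len(pep)
    if index is None:
        index = GenomeIndex(genome)
    hits: list[GenomeHit] = []
    for sid in genome.scaffolds:
        idx = index.scaffolds[sid]
        for strand in ("+", "-"):
            eqs = {}
            for off in range(3):
                frame = idx.frames[(strand, off)]
                eq = _match_matrix(frame, pep)
                eqs[off] = (frame, eq)
                if eq is None:
                    continue
                n_mm = L - eq.sum(axis=1)
                cand = np.nonzero(n_mm <= max_mismatches)[0]
                for i in cand:
                    window = frame[i:i + L]
                    mm = int(n_mm[i])
                    if mm > 0 and np.any(window == _STAR):
                        continue  # stop codon inside the window invalidates it
                    start, end = idx.fwd_interval(strand, off, int(i), 3 * L)
                    hits.append(GenomeHit(sid, start, end, strand, off, mm))
            if frameshift:
                hits.extend(_frameshift_hits(idx, strand, eqs, pep))
    return hits


def _frameshift_hits(idx: _FrameIndex, strand: str, eqs, pep: np.ndarray) -> list[GenomeHit]:
    """Split-frame hits: pep[:k] exact at nt p, pep[k:] exact at p + 3k + d."""
    L = len(pep)
    out = []
    # prefix_all[off][i, k-1]: pep[:k] matches at aa index i of frame off
    prefix_all, suffix_all = {}, {}
    for off in range(3):
        frame, eq = eqs[off]
        prefix_all[off] = np.logical_and.accumulate(eq, axis=1) if eq is not None else None
        # R[j, c]: frame[j:] matches pep[c:] in full
        nfr = len(frame)
        fr = np.where(frame == ord("I"), ord("L"), frame)
        R = np.zeros((nfr + 1, L + 1), dtype=bool)
        R[:, L] = True
        for c in range(L - 1, -1, -1):
            ok = np.zeros(nfr, dtype=bool)
            m = fr == pep[c]
            ok[: nfr] = m & R[1: nfr + 1, c + 1]
            R[:nfr, c] = ok
        suffix_all[off] = R
    for off1 in range(3):
        pa = prefix_all[off1]
        if pa is None:
            continue
        n1 = pa.shape[0]
        for d in (1, -1):
            off2 = (off1 + d) % 3
            R2 = suffix_all[off2]
            for k in range(1, L):
                i = np.nonzero(pa[:, k - 1])[0]
                if i.size == 0:
                    continue
                p = off1 + 3 * i  # nt start
                q = p + 3 * k + d  # nt start of suffix
                j = (q - off2) // 3  # aa index in frame off2
                valid = (q >= 0) & ((q - off2) % 3 == 0) & (j >= 0) & (j < R2.shape[0] - 1)
                for ii, jj, pp in zip(i[valid], j[valid], p[valid]):
                    if R2[jj, k]:
                        n_nt = 3 * L + d
                        start, end = idx.fwd_interval(strand, off1, int(ii), n_nt)
                        out.append(GenomeHit(idx.scaffold_id, start, end, strand,
                                             off1, 0, frameshift=d))
    return out


def _annotate_hit(hit: GenomeHit, transcripts: list[Transcript]) -> GenomeHit:
    """Attach transcript containment/frame information to a hit."""
    for t in transcripts:
        if t.scaffold_id != hit.scaffold_id:
            continue
        if hit.start >= t.end or hit.end <= t.start:
            continue
        contained = hit.start >= t.start and hit.end <= t.end
        same = False
        if hit.strand == t.strand:
            if t.strand == "+":
                same = (hit.start - (t.start + t.frame)) % 3 == 0
            else:
                same = ((t.end - t.frame) - hit.end) % 3 == 0
        return GenomeHit(hit.scaffold_id, hit.start, hit.end, hit.strand, hit.frame,
                         hit.n_mismatches, hit.frameshift, overlaps_transcript=True,
                         contained_in_transcript=contained,
                         same_frame_as_transcript=same, transcript_id=t.transcript_id)
    return hit


def classify_against_genome(peptide_or_group, genome: GenomeSet,
                            index: GenomeIndex | None = None) -> tuple[str, GenomeHit | None]:
    """Assign one annotation-error category to a missing-peptide group.

    Searches the representative peptide in all six frames and applies, in
    precedence order: annotated-frame hit (consistency flag — such a peptide
    should have been filtered upstream), transcript overlap in a different
    frame, perfect scaffold hit outside transcripts, wobbly hit (1 mismatch or
    1-nt frameshift), no hit.
    """
    pep = peptide_or_group.representative if isinstance(peptide_or_group, MissingPeptideGroup) else peptide_or_group
    if not genome.scaffolds:
        log.warning("empty genome: classifying %s as %s", pep, CLASS_NO_HIT)
        return CLASS_NO_HIT, None
    hits = [_annotate_hit(h, genome.transcripts)
            for h in search_peptide(genome, pep, index=index)]
    exact = [h for h in hits if h.n_mismatches == 0 and h.frameshift == 0]
    annotated = [h for h in exact if h.contained_in_transcript and h.same_frame_as_transcript]
    if annotated:
        log.warning("peptide %s matches an annotated transcript in its annotated "
                    "frame; it should not have been flagged as missing", pep)
        return CLASS_ANNOTATED, annotated[0]
    overlap = [h for h in exact if h.contained_in_transcript]
    if overlap:
        return CLASS_OVERLAP, overlap[0]
    if exact:
        return CLASS_SCAFFOLD, exact[0]
    wobbly = [h for h in hits if h.n_mismatches == 1 or h.frameshift != 0]
    if wobbly:
        wobbly.sort(key=lambda h: (h.n_mismatches, abs(h.frameshift)))
        return CLASS_WOBBLY, wobbly[0]
    return CLASS_NO_HIT, None


def classify_groups(groups: list[MissingPeptideGroup], genome: GenomeSet) -> pd.DataFrame:
    """Classify every group; returns a table shaped like a per-peptide
    annotation-error report (representative, class, hit evidence)."""
    index = GenomeIndex(genome) if genome.scaffolds else None
    rows = []
    for g in groups:
        cls, hit = classify_against_genome(g, genome, index=index)
        g.genome_class = cls
        rows.append({
            "representative": g.representative,
            "n_members": len(g.members),
            "genome_class": cls,
            "scaffold_id": hit.scaffold_id if hit else "",
            "start": hit.start if hit else -1,
            "end": hit.end if hit else -1,
            "strand": hit.strand if hit else "",
            "n_mismatches": hit.n_mismatches if hit else -1,
            "frameshift": hit.frameshift if hit else 0,
            "transcript_id": (hit.transcript_id or "") if hit else "",
        })
    return pd.DataFrame(rows)
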