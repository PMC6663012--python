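"""Missing-peptide discovery, grouping, taxon summary and genome classification,
each checked against independent brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, strategies as st

from circaprot import proteogenomics as pg
from circaprot.simulate import (make_genome_with_planted_errors, random_proteome,
                                reverse_translate)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_digest(seq, max_missed=2, min_length=6, max_length=50):
    """Enumerate cleavage products directly from the cut-site list."""
    cuts = [0] + [i + 1 for i in range(len(seq))
                  if seq[i] in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P")]
    if cuts[-1] != len(seq):
        cuts.append(len(seq))
    peps = set()
    for a, b in itertools.combinations(range(len(cuts)), 2):
        if b - a - 1 <= max_missed:
            pep = seq[cuts[a]:cuts[b]]
            if min_length <= len(pep) <= max_length:
                peps.add(pep)
    return peps


def brute_groups(peptides):
    """Connected components of the pairwise-containment graph (networkx)."""
    g = nx.Graph()
    norm = {p: pg.il_normalize(p) for p in peptides}
    g.add_nodes_from(set(peptides))
    for a, b in itertools.combinations(set(peptides), 2):
        if norm[a] in norm[b] or norm[b] in norm[a]:
            g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


def naive_six_frame(genome, pep, max_mism=1):
    """Translate every candidate window on both strands and count mismatches."""
    pepn = pg.il_normalize(pep)
    L = len(pepn)
    out = set()
    for sid, seq in genome.scaffolds.items():
        for strand in "+-":
            nt = seq if strand == "+" else str(Seq(seq).reverse_complement())
            for p in range(len(nt) - 3 * L + 1):
                aa = pg.il_normalize(str(Seq(nt[p:p + 3 * L]).translate()))
                mism = sum(a != b for a, b in zip(aa, pepn))
                if mism <= max_mism and ("*" not in aa or mism == 0):
                    if strand == "+":
                        start, end = p, p + 3 * L
                    else:
                        start, end = len(seq) - (p + 3 * L), len(seq) - p
                    out.add((sid, start, end, strand, mism))
    return out


# ---------------------------------------------------------------------------
# digestion
# ---------------------------------------------------------------------------

class TestDigest:
    def test_no_cleavage_sites(self):
        assert pg.digest("AAAAAA", min_length=1) == {"AAAAAA"}

    def test_kp_rule_blocks_cleavage(self):
        assert pg.digest("AKPR", min_length=1) == {"AKPR"}

    def test_basic_cleavage_with_missed_cuts(self):
        got = pg.digest("AAKCCRDDD", max_missed=1, min_length=1)
        assert got == {"AAK", "CCR", "DDD", "AAKCCR", "CCRDDD"}

    def test_random_sequences_match_brute_force(self):
        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(40):
            seq = "".join(rng.choice(aas, 60))
            assert pg.digest(seq, 2, 4, 50) == brute_digest(seq, 2, 4, 50)

    def test_length_filter(self):
        peps = pg.digest("AAAAAAK" * 3, max_missed=2, min_length=6, max_length=10)
        assert all(6 <= len(p) <= 10 for p in peps)


class TestIlEquiv:
    @pytest.mark.parametrize("a,b,eq", [
        ("PEPTIDE", "PEPTLDE", True),
        ("PEPTIDE", "PEPTIDE", True),
        ("PEPTIDE", "PEPTIDS", False),
        ("ILLIK", "LILLK", True),
    ])
    def test_pairs(self, a, b, eq):
        assert pg.il_equiv(a, b) is eq


# ---------------------------------------------------------------------------
# find_missing
# ---------------------------------------------------------------------------

def psm(pep, db, score, thr, rank=1, acc="X1"):
    return (pep, db, acc, score, thr, rank)


def frame(rows):
    return pd.DataFrame(rows, columns=pg.PSM_COLUMNS)


class TestFindMissing:
    def test_planted_fixture_matches_hand_checked_truth(self):
        """Every filter rule exercised once; expected set checked by hand."""
        tgt = frame([
            psm("SHAREDPEPK", "target", 44.0, 19.0),     # same score as collection
            psm("VARIANTLDK", "target", 41.0, 19.0),     # I/L twin of VARIANTIDK
            psm("WEAKTGTPEK", "target", 10.0, 19.0),     # below target threshold
        ])
        coll = frame([
            psm("MISSINGAAK", "spA", 50.0, 35.6),        # genuinely missing -> kept
            psm("SHAREDPEPK", "spA", 44.0, 35.6),        # removed: same score in both
            psm("VARIANTIDK", "spB", 41.0, 35.6),        # removed: I/L match in target
            psm("LOWSCOREPK", "spA", 30.0, 35.6),        # removed: below identity
            psm("SECONDRNKK", "spA", 50.0, 35.6, rank=2),  # removed: not first hit
            psm("ONLYSTRAIN", "strain", 60.0, 35.6),     # removed: excluded database
            psm("WEAKTGTPEK", "spB", 48.0, 35.6),        # kept: target match not confident
        ])
        missing, detail = pg.find_missing(tgt, coll, exclusions=["strain"])
        assert missing == {"MISSINGAAK", "WEAKTGTPEK"}
        assert set(detail["db_id"]) == {"spA", "spB"}

    def test_score_tolerance(self):
        tgt = frame([psm("AAPEPTIDEK", "target", 40.0, 19.0)])
        coll = frame([psm("AAPEPTIDEK", "spA", 40.4, 35.6)])
        wide, _ = pg.find_missing(tgt, coll, score_tol=0.5)
        narrow, _ = pg.find_missing(tgt, coll, score_tol=0.0)
        assert wide == set()
        # identical peptide sequence still has an I/L-equivalent target match
        assert narrow == set()

    def test_empty_collection(self):
        missing, detail = pg.find_missing(frame([]), frame([]))
        assert missing == set() and detail.empty

    def test_anti_monotone_in_target(self):
        """Adding confident target matches never enlarges the missing set."""
        rng = np.random.default_rng(4)
        aas = list("ACDEFGHMNQSTVWY")
        peps = ["".join(rng.choice(aas, 9)) + "K" for _ in range(30)]
        coll = frame([psm(p, "spA", 50.0, 35.6) for p in peps])
        tgt_rows = [psm(p, "target", 50.0, 19.0) for p in peps[:15]]
        for cut in range(0, 16, 5):
            m_small, _ = pg.find_missing(frame(tgt_rows[:cut]), coll)
            m_large, _ = pg.find_missing(frame(tgt_rows[: cut + 5]), coll)
            assert m_large <= m_small


# ---------------------------------------------------------------------------
# containment grouping
# ---------------------------------------------------------------------------

class TestGrouping:
    def test_worked_example_one_group(self):
        groups = pg.group_containment(["ATAQLIESIK", "ATAQLIE", "ATAQL"])
        assert len(groups) == 1
        assert groups[0].representative == "ATAQLIESIK"
        assert groups[0].members == {"ATAQLIESIK", "ATAQLIE", "ATAQL"}

    def test_disjoint_peptides_stay_separate(self):
        assert len(pg.group_containment(["AAAA", "CCCC"])) == 2

    def test_il_equivalent_containment(self):
        groups = pg.group_containment(["ATAQLIESIK", "ATAQILESLK"])
        assert len(groups) == 1

    def test_transitive_bridging(self):
        # the short core links two longer peptides that do not contain each other
        groups = pg.group_containment(["QQQCORE", "COREWWW", "CORE"])
        assert len(groups) == 1

    def test_random_planted_substrings_match_union_find_oracle(self):
        rng = np.random.default_rng(11)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        longs = ["".join(rng.choice(aas, rng.integers(12, 20))) for _ in range(80)]
        peps = set(longs)
        for s in longs:
            if rng.random() < 0.8:
                a = rng.integers(0, len(s) - 6)
                peps.add(s[a: a + rng.integers(5, len(s) - a)])
        got = {frozenset(g.members) for g in pg.group_containment(peps)}
        assert got == brute_groups(peps)

    @given(st.lists(st.text(alphabet="ACDGIL", min_size=3, max_size=8), max_size=12))
    def test_idempotent_and_order_invariant(self, peps):
        a = {frozenset(g.members) for g in pg.group_containment(peps)}
        b = {frozenset(g.members) for g in pg.group_containment(sorted(peps, reverse=True))}
        reps = [g.representative for g in pg.group_containment(peps)]
        c = {frozenset(g.members) for g in pg.group_containment(
            [m for g in pg.group_containment(peps) for m in g.members])}
        assert a == b == c
        assert all(any(r in fs for fs in a) for r in reps)

    def test_members_are_substrings_of_representative_or_bridged(self):
        groups = pg.group_containment(["ATAQLIESIK", "ATAQLIE", "ATAQL"])
        g = groups[0]
        rep = pg.il_normalize(g.representative)
        assert all(pg.il_normalize(m) in rep for m in g.members)


class TestTaxonSummary:
    def _groups(self, hits_by_rep):
        groups = []
        for rep, hits in hits_by_rep.items():
            g = pg.MissingPeptideGroup(rep, {rep})
            g.species_hits = {db: {"acc"} for db in hits}
            groups.append(g)
        return groups

    def _taxonomy(self):
        return pd.DataFrame({
            "db_id": ["an1", "an2", "an3", "mo1", "ot1", "strain"],
            "taxon_group": ["Anopheles species"] * 3 + ["Other mosquito species",
                                                        "non-dipteran",
                                                        "Anopheles species"],
        })

    def test_group_counts_once_per_taxon(self):
        counts = pg.taxon_summary(self._groups({"PEPA": ["an1", "an2", "an3"]}),
                                  self._taxonomy())
        assert counts["Anopheles species"] == 1
        assert counts["Other mosquito species"] == 0

    def test_excluded_database_contributes_nothing(self):
        counts = pg.taxon_summary(self._groups({"PEPA": ["strain"]}),
                                  self._taxonomy(), exclusions=["strain"])
        assert counts.eq(0).all()

    def test_unknown_db_rejected(self):
        with pytest.raises(KeyError):
            pg.taxon_summary(self._groups({"PEPA": ["mystery"]}), self._taxonomy())

    def test_counts_match_brute_force_tabulation(self):
        rng = np.random.default_rng(3)
        tax = self._taxonomy()
        dbs = list(tax["db_id"])
        hits = {f"PEP{i}K": list(rng.choice(dbs, rng.integers(1, 5), replace=False))
                for i in range(25)}
        counts = pg.taxon_summary(self._groups(hits), tax, exclusions=["strain"])
        taxon_of = dict(zip(tax["db_id"], tax["taxon_group"]))
        expected = {t: 0 for t in tax["taxon_group"].unique()}
        for hit in hits.values():
            for t in {taxon_of[d] for d in hit if d != "strain"}:
                expected[t] += 1
        assert counts.to_dict() == expected


# ---------------------------------------------------------------------------
# six-frame search and classification
# ---------------------------------------------------------------------------

class TestSixFrame:
    def _genome_with(self, pep, mutate=None, minus=False, seed=0):
        rng = np.random.default_rng(seed)
        enc = reverse_translate(pep, rng)
        if mutate is not None:
            enc = mutate(enc)
        if minus:
            enc = str(Seq(enc).reverse_complement())
        nt = np.array(list("ACGT"))
        seq = ("".join(rng.choice(nt, 300)) + enc + "".join(rng.choice(nt, 300)))
        return pg.GenomeSet({"s1": seq}, [])

    def test_exact_hit_coordinates_plus_strand(self):
        pep = "MAGWINDYK"
        genome = self._genome_with(pep)
        hits = [h for h in pg.search_peptide(genome, pep) if h.n_mismatches == 0]
        assert hits
        h = hits[0]
        assert h.end - h.start == 3 * len(pep)
        sub = genome.scaffolds["s1"][h.start:h.end]
        assert pg.il_equiv(str(Seq(sub).translate()), pep)

    def test_minus_strand_reports_forward_interval(self):
        pep = "MAGWINDYK"
        genome = self._genome_with(pep, minus=True, seed=1)
        hits = [h for h in pg.search_peptide(genome, pep)
                if h.n_mismatches == 0 and h.strand == "-"]
        assert hits
        h = hits[0]
        sub = genome.scaffolds["s1"][h.start:h.end]
        assert pg.il_equiv(str(Seq(sub).reverse_complement().translate()), pep)

    def test_agrees_with_naive_translation_oracle(self):
        rng = np.random.default_rng(9)
        aas = list("ACDEFGHMNQSTVWY")
        peps = ["".join(rng.choice(aas, 8)) + "K" for _ in range(3)]

        def one_sub(enc):
            i = 4
            repl = {"A": "C", "C": "G", "G": "T", "T": "A"}[enc[i]]
            return enc[:i] + repl + enc[i + 1:]

        genome = pg.GenomeSet({}, [])
        parts = {}
        for i, pep in enumerate(peps):
            g1 = self._genome_with(pep, seed=20 + i)
            g2 = self._genome_with(pep, mutate=one_sub, minus=(i % 2 == 0), seed=40 + i)
            parts[f"a{i}"] = g1.scaffolds["s1"]
            parts[f"b{i}"] = g2.scaffolds["s1"]
        genome = pg.GenomeSet(parts, [])
        for pep in peps:
            got = {(h.scaffold_id, h.start, h.end, h.strand, h.n_mismatches)
                   for h in pg.search_peptide(genome, pep) if h.frameshift == 0}
            assert got == naive_six_frame(genome, pep)

    def test_stop_codon_invalidates_mismatch_window(self):
        pep = "MAGWINDYK"
        # replace one internal codon with a stop: the 1-mismatch window
        # contains '*' and must not be reported
        def stopify(enc):
            return enc[:12] + "TAA" + enc[15:]
        genome = self._genome_with(pep, mutate=stopify, seed=2)
        hits = [h for h in pg.search_peptide(genome, pep)
                if h.frameshift == 0 and h.n_mismatches <= 1]
        assert not any(h.end - h.start == 3 * len(pep) for h in hits)


@pytest.fixture(scope="module")
def planted():
    proteome = random_proteome(8, (80, 120), seed=2)
    genome, peps = make_genome_with_planted_errors(proteome, 2, 3, 6, 4, seed=2)
    return proteome, genome, peps


class TestClassification:

    def test_planted_truth_recovered_for_all_categories(self, planted):
        _, genome, peps = planted
        groups = pg.group_containment(peps)
        table = pg.classify_groups(groups, genome)
        for _, row in table.iterrows():
            assert row["genome_class"] == genome.truth_labels[row["representative"]]
        assert set(table["genome_class"]) == set(pg.GENOME_CLASSES)

    def test_wobbly_evidence_has_one_mismatch_or_frameshift(self, planted):
        _, genome, peps = planted
        table = pg.classify_groups(pg.group_containment(peps), genome)
        wob = table[table["genome_class"] == pg.CLASS_WOBBLY]
        assert ((wob["n_mismatches"] == 1) | (wob["frameshift"] != 0)).all()
        shift = wob[wob["frameshift"] != 0]
        for _, row in shift.iterrows():
            L = len(row["representative"])
            assert abs((row["end"] - row["start"]) - 3 * L) == 1

    def test_annotated_peptide_flagged_as_inconsistent(self, planted):
        proteome, genome, _ = planted
        pep = sorted(pg.digest(next(iter(proteome.values())), min_length=7))[0]
        cls, hit = pg.classify_against_genome(pep, genome)
        assert cls == pg.CLASS_ANNOTATED
        assert hit.same_frame_as_transcript

    def test_empty_genome_is_no_hit(self):
        cls, hit = pg.classify_against_genome("MAGWINDYK", pg.GenomeSet({}, []))
        assert cls == pg.CLASS_NO_HIT and hit is None

    def test_classes_mutually_exclusive_and_exhaustive(self, planted):
        _, genome, peps = planted
        table = pg.classify_groups(pg.group_containment(peps), genome)
        assert table["genome_class"].isin(pg.GENOME_CLASSES).all()
        assert len(table) == len(peps)
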