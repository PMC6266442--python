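"""Smallest-protein percent identity, global alignment, shared-protein sets."""

import pytest
from Bio.Align import substitution_matrices

from phagekit.compare import (
    HomologyHit,
    align_and_count,
    align_score,
    best_hits,
    genome_map_table,
    percent_identity,
    shared_proteins_at_cutoff,
)
from phagekit.datasets import load_feature_table, load_identity_hits
from phagekit.genome import FeatureTable
from phagekit.orfs import OrfCandidate
from phagekit.proteins import ProteinRecord
from conftest import random_protein

BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG = (float("-inf"), 0)


def oracle_align(a: str, b: str, open_=10, ext=1):
    """Independent affine-gap DP over (score, identities) tuples,
    lexicographic max — same scoring model, different implementation."""
    m, n = len(a), len(b)

    def add(t, ds, di):
        return (t[0] + ds, t[1] + di)

    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]
    M[0][0] = (0.0, 0)
    for i in range(1, m + 1):
        X[i][0] = (-(open_ + i * ext), 0)
    for j in range(1, n + 1):
        Y[0][j] = (-(open_ + j * ext), 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            ident = int(a[i - 1] == b[j - 1])
            M[i][j] = add(max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]), s, ident)
            X[i][j] = max(
                add(max(M[i - 1][j], Y[i - 1][j]), -(open_ + ext), 0),
                add(X[i - 1][j], -ext, 0),
            )
            Y[i][j] = max(
                add(max(M[i][j - 1], X[i][j - 1]), -(open_ + ext), 0),
                add(Y[i][j - 1], -ext, 0),
            )
    return max(M[m][n], X[m][n], Y[m][n])


class TestPercentIdentity:
    @pytest.mark.parametrize(
        "identical,la,lb,expected",
        [
            (667, 672, 671, 99),  # large terminase subunit vs its best hit
            (0, 50, 60, 0),
            (288, 288, 288, 100),
            (179, 200, 400, 90),  # 89.5 rounds half-up
        ],
    )
    def test_values(self, identical, la, lb, expected):
        assert percent_identity(identical, la, lb) == expected

    def test_preconditions(self):
        with pytest.raises(ValueError):
            percent_identity(51, 50, 60)
        with pytest.raises(ValueError):
            percent_identity(1, 0, 5)


class TestAlignAndCount:
    def test_identical_sequences(self, rng):
        seq = random_protein(rng, 25)
        h = align_and_count(seq, seq)
        assert h.percent_identity == 100 and h.identical_residues == len(seq)

    def test_unrelated_homopolymers(self):
        assert align_and_count("AAAA", "TTTT").identical_residues == 0

    def test_matches_dp_oracle(self, rng):
        for _ in range(30):
            a = random_protein(rng, int(rng.integers(1, 31)))
            b = random_protein(rng, int(rng.integers(1, 31)))
            score, ident = oracle_align(a, b)
            assert align_score(a, b) == score
            assert align_and_count(a, b).identical_residues == ident

    def test_score_matches_biopython(self, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -11  # open 10 + first extension 1
        aligner.extend_gap_score = -1
        for _ in range(15):
            a = random_protein(rng, int(rng.integers(5, 60)))
            b = random_protein(rng, int(rng.integers(5, 60)))
            assert align_score(a, b) == aligner.score(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_and_count("", "MK")


class TestBestHits:
    def test_self_comparison_all_self_hits(self, rng):
        prots = [ProteinRecord(f"p{i}", random_protein(rng, 30)) for i in range(6)]
        hits = best_hits(prots, prots)
        assert all(h.query_id == h.subject_id for h in hits)
        assert all(h.percent_identity == 100 for h in hits)

    def test_identity_floor_empties_disjoint_proteomes(self, rng):
        a = [ProteinRecord(f"a{i}", random_protein(rng, 40)) for i in range(4)]
        b = [ProteinRecord(f"b{i}", random_protein(rng, 40)) for i in range(4)]
        assert best_hits(a, b, min_identity=60) == []

    def test_planted_orthologs_recovered(self, rng):
        parents = [random_protein(rng, 50) for _ in range(5)]
        mutated = []
        for s in parents:
            pos = rng.choice(50, size=5, replace=False)  # ~90% identity
            chars = list(s)
            for p in pos:
                chars[p] = "W" if chars[p] != "W" else "Y"
            mutated.append("".join(chars))
        a = [ProteinRecord(f"a{i}", s) for i, s in enumerate(parents)]
        b = [ProteinRecord(f"b{i}", s) for i, s in enumerate(mutated)]
        hits = best_hits(a, b, min_identity=80)
        assert {(h.query_id, h.subject_id) for h in hits} == {
            (f"a{i}", f"b{i}") for i in range(5)
        }
        assert all(h.percent_identity == 90 for h in hits)

    def test_reciprocal_subset(self, rng):
        a = [ProteinRecord(f"a{i}", random_protein(rng, 30)) for i in range(4)]
        b = [ProteinRecord(f"b{i}", random_protein(rng, 30)) for i in range(4)]
        rec = best_hits(a, b, reciprocal=True)
        fwd = {(h.query_id, h.subject_id) for h in best_hits(a, b)}
        assert {(h.query_id, h.subject_id) for h in rec} <= fwd


class TestSharedSets:
    def test_reference_counts(self):
        """47 of 79 ORFs above 90% identity, eight of them fully identical."""
        hits = load_identity_hits()
        assert shared_proteins_at_cutoff(hits, 90, strict=True).count == 47
        assert shared_proteins_at_cutoff(hits, 100, strict=False).count == 8

    def test_cutoff_zero_keeps_all(self):
        hits = load_identity_hits()
        assert shared_proteins_at_cutoff(hits, 0, strict=False).count == len(hits)

    def test_counts_non_increasing_in_cutoff(self):
        hits = load_identity_hits()
        counts = [
            shared_proteins_at_cutoff(hits, c, strict=False).count
            for c in range(0, 101, 5)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_strict_at_most_non_strict(self):
        hits = load_identity_hits()
        for c in (70, 80, 90, 100):
            strict = shared_proteins_at_cutoff(hits, c, strict=True)
            loose = shared_proteins_at_cutoff(hits, c, strict=False)
            assert strict.pairs <= loose.pairs


class TestGenomeMapTable:
    def _tables(self):
        rows_a = [OrfCandidate(id=f"A{i}", start=10 + 90 * i, end=90 * i + 99,
                               strand="+", start_codon="ATG") for i in range(3)]
        rows_b = [OrfCandidate(id=f"B{i}", start=10 + 90 * i, end=90 * i + 99,
                               strand="+", start_codon="ATG") for i in range(3)]
        return (
            FeatureTable(genome_id="ga", rows=rows_a),
            FeatureTable(genome_id="gb", rows=rows_b),
        )

    def test_identical_genomes_top_band(self):
        ta, tb = self._tables()
        hits = {("ga", "gb"): [
            HomologyHit(f"A{i}", f"B{i}", 29, 29, 29) for i in range(3)
        ]}
        df = genome_map_table([ta, tb], hits)
        ga = df[df.genome_id == "ga"]
        assert list(ga.band) == [">90"] * 3

    def test_reference_map_links(self):
        table = load_feature_table()
        hits = {("ST32", "relatives"): load_identity_hits()}
        partner = FeatureTable(genome_id="relatives", rows=[])
        # subject ids live in a bare partner table: register them via rows
        partner.rows = [
            OrfCandidate(id=h.subject_id, start=1, end=6, strand="+",
                         start_codon="ATG")
            for h in load_identity_hits()
        ]
        df = genome_map_table([table, partner], hits, shade_cutoffs=(90.0,))
        assert (df[df.genome_id == "ST32"].band == ">90").sum() == 47

    def test_no_hits_rows_preserved(self):
        ta, tb = self._tables()
        df = genome_map_table([ta, tb], {})
        assert len(df) == 6 and (df.band == "").all()

    def test_unknown_ids_rejected(self):
        ta, tb = self._tables()
        hits = {("ga", "gb"): [HomologyHit("A0", "nope", 10, 29, 29)]}
        with pytest.raises(ValueError, match="unknown"):
            genome_map_table([ta, tb], hits)
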