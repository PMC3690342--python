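from itertools import combinations

import pytest
from hypothesis import given

from conftest import evidence_records, rec
from locrec.dualloc import (
    enumerate_dual_claims,
    matrix_to_lower_tsv,
    off_diagonal_sum,
    overlap_percent,
    overlap_report,
    pairwise_matrix,
    partition_by_publication,
    read_lower_tsv,
)
from locrec.evidence import build_claims
from locrec.vocab import COMPARTMENTS


def fp(*records):
    return build_claims(records).restrict("FP")


def protein_compartments(records):
    out = {}
    for r in records:
        if r.method == "FP":
            out.setdefault(r.protein_id, set()).add(r.compartment)
    return out


class TestMatrix:
    def test_single_dual_protein(self):
        mat = pairwise_matrix(fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "a"),
        ))
        assert mat.loc["plastid", "mitochondrion"] == 1
        assert mat.loc["mitochondrion", "plastid"] == 1
        assert mat.loc["plastid", "plastid"] == 1
        assert mat.loc["mitochondrion", "mitochondrion"] == 1
        assert mat.values.sum() == 4

    def test_triple_protein_fills_all_three_pairs(self):
        mat = pairwise_matrix(fp(
            rec("P1", "nucleus", "FP", "a"),
            rec("P1", "cytosol", "FP", "a"),
            rec("P1", "plasma_membrane", "FP", "a"),
        ))
        for a, b in combinations(("nucleus", "cytosol", "plasma_membrane"), 2):
            assert mat.loc[a, b] == 1
        assert off_diagonal_sum(mat) == 3

    @given(records=evidence_records())
    def test_matches_brute_force_and_invariants(self, records):
        mat = pairwise_matrix(fp(*records))
        comps = protein_compartments(records)
        for a in COMPARTMENTS:
            assert mat.loc[a, a] == sum(1 for s in comps.values() if a in s)
            for b in COMPARTMENTS:
                if a == b:
                    continue
                expected = sum(1 for s in comps.values() if {a, b} <= s)
                assert mat.loc[a, b] == expected
                assert mat.loc[a, b] == mat.loc[b, a]
                assert mat.loc[a, b] <= min(mat.loc[a, a], mat.loc[b, b])

    def test_lower_triangular_tsv_roundtrip(self, tmp_path):
        mat = pairwise_matrix(fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "a"),
            rec("P2", "nucleus", "FP", "b"),
        ))
        path = tmp_path / "matrix.tsv"
        matrix_to_lower_tsv(mat, path)
        assert read_lower_tsv(path).equals(mat)


class TestEnumerate:
    def test_two_compartments_one_claim(self):
        _, stats = enumerate_dual_claims(fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "a"),
        ))
        assert stats == (1, 1)

    def test_three_compartments_three_claims_one_protein(self):
        dual, stats = enumerate_dual_claims(fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "a"),
            rec("P1", "nucleus", "FP", "b"),
        ))
        assert stats == (3, 1)
        assert len({d.pair for d in dual}) == 3

    def test_single_compartment_corpus_has_no_dual_claims(self):
        _, stats = enumerate_dual_claims(fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P2", "plastid", "FP", "b"),
        ))
        assert stats == (0, 0)

    @given(records=evidence_records())
    def test_counts_match_pair_enumeration_and_matrix(self, records):
        claims = fp(*records)
        dual, stats = enumerate_dual_claims(claims)
        comps = protein_compartments(records)
        expected_claims = sum(
            len(list(combinations(s, 2))) for s in comps.values()
        )
        expected_proteins = sum(1 for s in comps.values() if len(s) >= 2)
        assert stats.n_claims == expected_claims == len(dual)
        assert stats.n_distinct_proteins == expected_proteins
        assert stats.n_distinct_proteins <= stats.n_claims
        # equality iff no protein claims three or more compartments
        if all(len(s) <= 2 for s in comps.values()):
            assert stats.n_distinct_proteins == stats.n_claims
        # the matrix aggregates exactly these claims
        assert off_diagonal_sum(pairwise_matrix(claims)) == stats.n_claims


class TestOverlap:
    def test_reference_overlaps(self, table2):
        assert overlap_percent(table2, "nucleus", "cytosol") == (31, 46)
        assert overlap_percent(table2, "mitochondrion", "plastid")[0] == 32

    def test_no_shared_proteins_is_zero_zero(self):
        mat = pairwise_matrix(fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P2", "nucleus", "FP", "b"),
        ))
        assert overlap_percent(mat, "plastid", "nucleus") == (0, 0)

    def test_zero_diagonal_is_undefined_not_zero(self):
        mat = pairwise_matrix(fp(rec("P1", "plastid", "FP", "a")))
        pct_vac, pct_pla = overlap_percent(mat, "vacuole", "plastid")
        assert pct_vac is None and pct_pla == 0

    def test_report_covers_all_55_pairs(self, table2):
        report = overlap_report(table2)
        assert len(report) == 55
        row = report[(report.compartment_a == "cytosol")
                     & (report.compartment_b == "nucleus")].iloc[0]
        assert (row.pct_of_a, row.pct_of_b) == (46, 31)


class TestPartition:
    def test_same_publication_pair(self):
        claims = fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "a"),
        )
        dual, _ = enumerate_dual_claims(claims)
        counts, flagged = partition_by_publication(dual, claims)
        assert counts["same_publication"] == 1
        assert counts["cross_publication_only"] == 0
        assert flagged[0][1] is True

    def test_cross_publication_conflict(self):
        claims = fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "b"),
        )
        dual, _ = enumerate_dual_claims(claims)
        counts, _ = partition_by_publication(dual, claims)
        assert counts["same_publication"] == 0
        assert counts["cross_publication_only"] == 1

    def test_publication_intersection_rescues_the_pair(self):
        # pub a saw both x and y; pub b saw only x: still same-publication
        claims = fp(
            rec("P1", "plastid", "FP", "a"),
            rec("P1", "mitochondrion", "FP", "a"),
            rec("P1", "plastid", "FP", "b"),
        )
        dual, _ = enumerate_dual_claims(claims)
        counts, _ = partition_by_publication(dual, claims)
        assert counts["same_publication"] == 1

    @given(records=evidence_records(methods=("FP",)))
    def test_partition_is_exhaustive_and_matches_brute_force(self, records):
        claims = fp(*records)
        dual, stats = enumerate_dual_claims(claims)
        counts, flagged = partition_by_publication(dual, claims)
        assert (counts["same_publication"]
                + counts["cross_publication_only"]) == stats.n_claims
        # brute force directly over the record list
        for dc, same in flagged:
            pubs_a = {r.publication_id for r in records
                      if r.protein_id == dc.protein_id
                      and r.compartment == dc.compartment_a}
            pubs_b = {r.publication_id for r in records
                      if r.protein_id == dc.protein_id
                      and r.compartment == dc.compartment_b}
            assert same == bool(pubs_a & pubs_b)
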