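import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifacecov import (PairwiseLocalAlignment, PlantedCurve,
                      alignment_identity_similarity, classify_fic,
                      compute_metrics, domain_coverage, filter_pool,
                      interface_coverage, interface_identity_similarity,
                      make_alignment_pool, subset_by_qmax, target_coverage)
from ifacecov.alignments import (parse_blast_xml, read_alignments_tsv,
                                 write_alignments_tsv)
from ifacecov.errors import AlignmentError, ParameterError
from ifacecov.synthetic import write_pool_blast_xml

from oracles import column_scan_metrics


def make_aln(target_aln, template_aln, start=1, e_value=1e-5,
             full_length=None, template_full_length=None, **kw):
    n_t = sum(c != "-" for c in target_aln)
    n_m = sum(c != "-" for c in template_aln)
    return PairwiseLocalAlignment(
        target_id=kw.get("target_id", "T"),
        template_id=kw.get("template_id", "H"),
        e_value=e_value,
        target_aln=target_aln, template_aln=template_aln,
        target_start=start, target_end=start + n_t - 1,
        template_start=1, template_end=n_m,
        target_full_length=full_length or (start + n_t - 1 + 10),
        template_full_length=template_full_length or (n_m + 30),
    )


# ---------------------------------------------------------------------------
# construction invariants

def test_mismatched_lengths_rejected():
    with pytest.raises(AlignmentError):
        make_aln("ACDE", "ACD")


def test_double_gap_column_rejected():
    with pytest.raises(AlignmentError):
        make_aln("AC-DE", "AC-DE")


def test_inconsistent_span_rejected():
    with pytest.raises(AlignmentError):
        PairwiseLocalAlignment("T", "H", 1e-3, "ACDE", "ACDE",
                               1, 3, 1, 4, 50, 50)


# ---------------------------------------------------------------------------
# coverage

def test_full_coverage_is_100():
    aln = make_aln("ACDEF", "ACDEF", start=1, full_length=5)
    assert target_coverage(aln) == 100.0


def test_direct_ratio_coverage():
    aln = make_aln("A" * 40, "A" * 40, start=1, full_length=100)
    assert target_coverage(aln) == pytest.approx(40.0)


def test_interface_coverage_all_inside():
    aln = make_aln("A" * 30, "A" * 30, start=1, full_length=60)
    q_int, missing = interface_coverage(aln, set(range(1, 11)))
    assert q_int == 100.0 and missing == 0


def test_interface_coverage_8_of_10():
    aln = make_aln("A" * 30, "A" * 30, start=1, full_length=60)
    iface = set(range(1, 9)) | {40, 50}
    q_int, missing = interface_coverage(aln, iface)
    assert q_int == pytest.approx(80.0) and missing == 2


def test_empty_interface_errors():
    aln = make_aln("ACDE", "ACDE")
    with pytest.raises(AlignmentError):
        interface_coverage(aln, set())


def test_domain_coverage_ratios():
    aln = make_aln("A" * 45, "A" * 45, start=1, full_length=200)
    assert domain_coverage(aln, set(range(1, 46))) == 100.0
    assert domain_coverage(aln, set(range(1, 51))) == pytest.approx(90.0)
    with pytest.raises(AlignmentError):
        domain_coverage(aln, set())


# ---------------------------------------------------------------------------
# FIC classification

@pytest.mark.parametrize("missing,expected", [(0, True), (1, True), (2, False)])
def test_classify_fic_tolerance_boundary(missing, expected):
    assert classify_fic(missing, tolerance=1) is expected


def test_classify_fic_custom_tolerance():
    assert classify_fic(2, tolerance=2) is True
    assert classify_fic(3, tolerance=2) is False


# ---------------------------------------------------------------------------
# identity / similarity

def test_identical_gapless_alignment(blosum62):
    aln = make_aln("ACDEFG", "ACDEFG")
    a_iden, a_sim = alignment_identity_similarity(aln, blosum62)
    assert a_iden == 100.0 and a_sim == 100.0


def test_worked_example_krde_vs_rrds(blosum62):
    # identities: R/R, D/D; positives: K/R (2), R/R, D/D; E/S scores 0
    aln = make_aln("KRDE", "RRDS")
    a_iden, a_sim = alignment_identity_similarity(aln, blosum62)
    assert a_iden == pytest.approx(50.0)
    assert a_sim == pytest.approx(75.0)


def test_target_side_gap_counts_toward_l_ali_only(blosum62):
    # L_ali = 5 (4 residues + 1 target gap); 4 identities
    aln = make_aln("AC-DE", "ACWDE")
    a_iden, a_sim = alignment_identity_similarity(aln, blosum62)
    assert a_iden == pytest.approx(80.0)
    assert a_sim == pytest.approx(80.0)


def test_template_side_gap_counts_in_n_ali_not_identity(blosum62):
    aln = make_aln("ACDE", "AC-E")
    a_iden, a_sim = alignment_identity_similarity(aln, blosum62)
    assert a_iden == pytest.approx(75.0)
    assert aln.n_ali == 4


def test_x_never_identical_never_positive(blosum62):
    aln = make_aln("XX", "XA")
    a_iden, a_sim = alignment_identity_similarity(aln, blosum62)
    assert a_iden == 0.0 and a_sim == 0.0


def test_invalid_character_raises(blosum62):
    aln = dataclasses.replace(make_aln("ACDE", "ACDE"), target_aln="AC*E")
    with pytest.raises(AlignmentError, match="column"):
        alignment_identity_similarity(aln, blosum62)


def test_interface_identity_zero_similarity_positive(blosum62):
    # interface columns aligned to non-identical but BLOSUM62-positive residues
    aln = make_aln("KRDE", "RKES", start=1, full_length=20)
    iface = {1, 2}  # K/R and R/K: both positive, neither identical
    i_iden, i_sim = interface_identity_similarity(aln, iface, blosum62)
    assert i_iden == 0.0
    assert i_sim == 100.0


def test_interface_identity_full(blosum62):
    aln = make_aln("KRDE", "KRDW", start=1, full_length=20)
    i_iden, i_sim = interface_identity_similarity(aln, {1, 2, 3}, blosum62)
    assert i_iden == 100.0 and i_sim == 100.0


def test_interface_identity_no_residues_in_alignment_errors(blosum62):
    aln = make_aln("KRDE", "KRDE", start=1, full_length=50)
    with pytest.raises(AlignmentError):
        interface_identity_similarity(aln, {40, 41}, blosum62)


# ---------------------------------------------------------------------------
# pool filters

def test_evalue_filter_strict_at_one():
    a1 = make_aln("KRDE" * 5, "RRDS" * 5, e_value=2.0)
    a2 = make_aln("KRDE" * 5, "RRDS" * 5, e_value=1.0)
    kept, excluded = filter_pool([a1, a2])
    assert a2 in kept
    assert (a1, "evalue") in excluded


def test_near_identical_excluded():
    # equal full lengths, fully aligned, 3 substitutions -> difference 3 < 10
    target = "ACDEFGHIKLMNPQRSTVWY"
    template = "ACDEFGHIKLMNPQRSTWYV"  # 3 trailing substitutions
    aln = PairwiseLocalAlignment("T", "H", 1e-8, target, template,
                                 1, 20, 1, 20, 20, 20)
    kept, excluded = filter_pool([aln])
    assert kept == []
    assert excluded[0][1] == "near-identical"


def test_difference_boundary_at_10():
    # exactly 10 differing positions -> kept (strict <)
    target = "A" * 30
    template = "C" * 10 + "A" * 20
    aln = PairwiseLocalAlignment("T", "H", 1e-8, target, template,
                                 1, 30, 1, 30, 30, 30)
    kept, _ = filter_pool([aln])
    assert kept == [aln]


def test_subset_by_qmax():
    pool = [make_aln("A" * n, "A" * n, start=1, full_length=100)
            for n in (30, 50, 70)]
    assert len(subset_by_qmax(pool, 100.0)) == 3
    assert len(subset_by_qmax(pool, 50.0)) == 2
    assert subset_by_qmax(pool, 40.0) == pool[:1]
    with pytest.raises(ParameterError):
        subset_by_qmax(pool, 0.0)


def test_qmax_40_empty_when_all_q50():
    pool = [make_aln("A" * 50, "A" * 50, start=1, full_length=100)]
    assert subset_by_qmax(pool, 40.0) == []


# ---------------------------------------------------------------------------
# oracle equivalence and properties

def test_metrics_match_column_scan_oracle(blosum62):
    pool = make_alignment_pool(PlantedCurve.constant(0.5), n=1200, seed=11,
                               gap_fraction=0.15)
    for rec in pool:
        m = compute_metrics(rec.alignment, rec.interface_positions, blosum62)
        ref = column_scan_metrics(rec.alignment, rec.interface_positions,
                                  blosum62)
        assert m.q == pytest.approx(ref["q"], abs=1e-12)
        assert m.a_iden == pytest.approx(ref["a_iden"], abs=1e-12)
        assert m.a_sim == pytest.approx(ref["a_sim"], abs=1e-12)
        assert m.q_int == pytest.approx(ref["q_int"], abs=1e-12)
        assert m.missing_interface_count == ref["missing"]
        if m.i_iden is not None:
            assert m.i_iden == pytest.approx(ref["i_iden"], abs=1e-12)
            assert m.i_sim == pytest.approx(ref["i_sim"], abs=1e-12)


def test_iden_never_exceeds_sim(alignment_pool_small, blosum62):
    for rec in alignment_pool_small:
        m = compute_metrics(rec.alignment, rec.interface_positions, blosum62)
        assert m.a_iden <= m.a_sim
        if m.i_iden is not None:
            assert m.i_iden <= m.i_sim
            if m.i_iden > 0:
                assert m.i_sim > 0


@settings(max_examples=30, deadline=None)
@given(extend=st.integers(min_value=0, max_value=10))
def test_qint_nondecreasing_under_extension(extend):
    base = make_aln("A" * 20, "A" * 20, start=11, full_length=60)
    iface = {5, 15, 25, 45}
    extended = PairwiseLocalAlignment(
        "T", "H", 1e-5,
        "A" * (20 + extend), "A" * (20 + extend),
        11 - min(extend, 10), 30, 1, 20 + extend, 60, 80)
    q0, _ = interface_coverage(base, iface)
    q1, _ = interface_coverage(extended, iface)
    assert q1 >= q0


# ---------------------------------------------------------------------------
# I/O

def test_parse_minimal_blast_xml(tmp_path, alignment_pool_small):
    alns = [rec.alignment for rec in alignment_pool_small[:40]]
    path = tmp_path / "pool.xml"
    write_pool_blast_xml(alns, path)
    parsed = parse_blast_xml(path)
    assert len(parsed) == len(alns)
    by_id = {(a.target_id, a.template_id): a for a in parsed}
    for orig in alns:
        got = by_id[(orig.target_id, orig.template_id)]
        assert got.target_aln == orig.target_aln
        assert got.template_aln == orig.template_aln
        assert got.target_start == orig.target_start
        assert got.e_value == pytest.approx(orig.e_value, rel=1e-12)
        assert got.target_full_length == orig.target_full_length


def test_parse_blast_xml_requires_known_length(tmp_path, alignment_pool_small):
    alns = [rec.alignment for rec in alignment_pool_small[:2]]
    path = tmp_path / "pool.xml"
    write_pool_blast_xml(alns, path)
    with pytest.raises(AlignmentError, match="full length"):
        parse_blast_xml(path, target_full_lengths={"nope": 10})


def test_two_hsps_for_one_target(tmp_path):
    a1 = make_aln("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWC",
                  target_id="T1", template_id="H1", full_length=60)
    a2 = make_aln("MNPQRSTVWYACDEFGHIKL", "MNPQRSTVWYACDEFGHIKC",
                  target_id="T1", template_id="H2", full_length=60)
    path = tmp_path / "two.xml"
    write_pool_blast_xml([a1, a2], path)
    parsed = parse_blast_xml(path)
    assert len(parsed) == 2
    assert {a.template_id for a in parsed} == {"H1", "H2"}


def test_tsv_round_trip_metrics_identical(tmp_path, alignment_pool_small,
                                          blosum62):
    alns = [rec.alignment for rec in alignment_pool_small[:50]]
    path = tmp_path / "pool.tsv"
    write_alignments_tsv(alns, path)
    parsed = read_alignments_tsv(path)
    for orig, back in zip(alns, parsed):
        m0 = compute_metrics(orig, None, blosum62)
        m1 = compute_metrics(back, None, blosum62)
        assert (m0.q, m0.a_iden, m0.a_sim) == (m1.q, m1.a_iden, m1.a_sim)
        assert orig.e_value == back.e_value
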