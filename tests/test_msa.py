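"""Best-hit selection and joint-MSA assembly."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiscreen.msa import (
    LabeledMSA,
    OrthologHit,
    build_joint_msa,
    clean_target_gap_columns,
    enumerate_domain_pairs,
    length_gate,
    read_labeled_msa,
    select_best_hits,
    write_joint_msa,
)


def hit(org="9606", sid="s1", ident=50.0, sim=100.0, ev=1e-10):
    return OrthologHit(org, sid, ident, sim, ev)


class TestBestHits:
    def test_highest_similarity_wins_within_organism(self):
        best = select_best_hits([hit(sim=100, sid="a"), hit(sim=200, sid="b")])
        assert best["9606"].sequence_id == "b"

    def test_identity_exactly_35_excluded(self):
        """The identity floor is strict: above 35%, not at it."""
        assert select_best_hits([hit(ident=35.0)]) == {}
        assert "9606" in select_best_hits([hit(ident=35.01)])

    def test_evalue_ceiling(self):
        assert select_best_hits([hit(ev=0.01)]) == {}
        assert "9606" in select_best_hits([hit(ev=0.001)])

    def test_per_organism_argmax_matches_scan(self):
        rng_hits = [
            hit(org=o, sid=f"{o}.{i}", ident=36 + i, sim=s, ev=1e-5)
            for o, sims in [("a", (10, 30)), ("b", (50, 20)), ("c", (7, 7))]
            for i, s in enumerate(sims)
        ]
        best = select_best_hits(rng_hits)
        for org in ("a", "b", "c"):
            survivors = [h for h in rng_hits if h.organism == org]
            assert best[org].similarity == max(h.similarity for h in survivors)


class TestCleanColumns:
    def test_target_gap_columns_removed_everywhere(self):
        msa = LabeledMSA("A-C", [("x", "ABC")])
        out = clean_target_gap_columns(msa)
        assert out.target_row == "AC" and out.rows == [("x", "AC")]

    def test_gapless_target_is_identity(self):
        msa = LabeledMSA("ACD", [("x", "A-D")])
        out = clean_target_gap_columns(msa)
        assert out.target_row == msa.target_row and out.rows == msa.rows

    def test_column_filter_oracle(self):
        target = "AB-C-D"
        rows = [("o1", "QWERTY"), ("o2", "ASDFGH"), ("o3", "--X--Y"), ("o4", "ZXCVBN"), ("o5", "POIUYT")]
        out = clean_target_gap_columns(LabeledMSA(target, rows))
        keep = [i for i, c in enumerate(target) if c != "-"]
        assert out.alignment_length == len(target) - 2
        for (org, seq), (_, orig) in zip(out.rows, rows):
            assert seq == "".join(orig[i] for i in keep)

    def test_idempotent(self):
        msa = LabeledMSA("A--B", [("x", "CDEF")])
        once = clean_target_gap_columns(msa)
        twice = clean_target_gap_columns(once)
        assert once.target_row == twice.target_row and once.rows == twice.rows


class TestJointMSA:
    def test_shared_organisms_fully_paired(self):
        m1 = LabeledMSA("AA", [("X", "CC"), ("Y", "DD")])
        m2 = LabeledMSA("GGG", [("X", "HHH"), ("Y", "III")])
        joint = build_joint_msa(m1, m2)
        assert len(joint.rows) == 3
        assert joint.pairing == ["target", "paired", "paired"]
        assert joint.rows[0] == ("target", "AAGGG")
        assert all("-" not in seq for _, seq in joint.rows)

    def test_missing_organisms_gap_padded_at_end(self):
        m1 = LabeledMSA("AA", [("X", "CC")])
        m2 = LabeledMSA("GGG", [("Y", "HHH")])
        joint = build_joint_msa(m1, m2)
        assert joint.pairing == ["target", "msa1_only", "msa2_only"]
        assert joint.rows[1] == ("X", "CC---")
        assert joint.rows[2] == ("Y", "--HHH")

    def test_set_algebra_on_organisms(self):
        m1 = LabeledMSA("AA", [("X", "CC"), ("Y", "DD"), ("Z", "EE")])
        m2 = LabeledMSA("GG", [("Y", "HH"), ("Z", "II"), ("W", "JJ")])
        joint = build_joint_msa(m1, m2)
        assert len(joint.rows) == 1 + 2 + 2
        paired = [org for (org, _), tag in zip(joint.rows, joint.pairing) if tag == "paired"]
        assert set(paired) == {"Y", "Z"}

    def test_uncleaned_target_rejected(self):
        with pytest.raises(ValueError):
            build_joint_msa(LabeledMSA("A-"), LabeledMSA("GG"))

    def test_residue_index_offset_recorded(self):
        joint = build_joint_msa(LabeledMSA("AA"), LabeledMSA("GG"), index_gap=200)
        assert joint.residue_index_offset == 200


class TestLengthGate:
    @pytest.mark.parametrize("L1,L2,expected", [(700, 800, True), (700, 801, False), (1, 1, True)])
    def test_combined_length_rule(self, L1, L2, expected):
        assert length_gate(L1, L2) is expected

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            length_gate(0, 5)


class TestDomainPairs:
    def test_cross_product(self):
        pairs = enumerate_domain_pairs([(1, 100), (101, 220)], [(1, 50), (51, 90), (91, 400)])
        assert len(pairs) == 6

    def test_oversize_pair_flagged(self):
        [pair] = enumerate_domain_pairs([(1, 900)], [(1, 700)])
        assert pair.combined_length == 1600 and not pair.within_limit

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            enumerate_domain_pairs([(1, 100), (50, 150)], [(1, 10)])


seq_chars = st.text(alphabet="ACDEFG-", min_size=4, max_size=4)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.tuples(st.sampled_from(["o1", "o2", "o3", "o4"]), seq_chars), max_size=4, unique_by=lambda r: r[0]),
    st.lists(st.tuples(st.sampled_from(["o2", "o3", "o5"]), seq_chars), max_size=3, unique_by=lambda r: r[0]),
)
def test_joint_msa_conservation(rows1, rows2):
    """Every joint row has length L1+L2; paired rows are exactly the organism
    intersection; unpaired rows are all-gap in exactly one block."""
    m1 = clean_target_gap_columns(LabeledMSA("ACDE", rows1))
    m2 = clean_target_gap_columns(LabeledMSA("FGAC", rows2))
    joint = build_joint_msa(m1, m2)
    L1, L2 = m1.alignment_length, m2.alignment_length
    for _, seq in joint.rows:
        assert len(seq) == L1 + L2
    paired = {org for (org, _), t in zip(joint.rows, joint.pairing) if t == "paired"}
    assert paired == set(m1.organisms) & set(m2.organisms)
    for (org, seq), tag in zip(joint.rows, joint.pairing):
        b1, b2 = seq[:L1], seq[L1:]
        if tag == "msa1_only":
            assert b2 == "-" * L2 and b1 != "-" * L1 or b2 == "-" * L2
            assert b2 == "-" * L2
        elif tag == "msa2_only":
            assert b1 == "-" * L1


def test_fasta_roundtrip_and_sidecar(tmp_path):
    fasta = tmp_path / "m1.fasta"
    fasta.write_text(">target\nACDE\n>h1 organism=10090\nacd-\n>h2 organism=7227\nWXYZ\n")
    msa = read_labeled_msa(fasta)
    assert msa.target_row == "ACDE"
    assert msa.rows == [("10090", "ACD-"), ("7227", "WXYZ")]

    m2 = LabeledMSA("GG", [("10090", "HH")])
    joint = build_joint_msa(clean_target_gap_columns(msa), m2)
    write_joint_msa(joint, tmp_path / "joint")
    out = (tmp_path / "joint.fasta").read_text()
    assert out.startswith(">target\nACDEGG\n")
    sidecar = (tmp_path / "joint.index_map.tsv").read_text()
    assert "205" in sidecar  # chain 2 numbering starts at L1 + 200 + 1 = 205


def test_joint_msa_emission_deterministic(tmp_path):
    m1 = LabeledMSA("ACDE", [("a", "WWWW"), ("b", "XXXX")])
    m2 = LabeledMSA("GG", [("b", "YY"), ("c", "ZZ")])
    outs = []
    for i in (1, 2):
        write_joint_msa(build_joint_msa(m1, m2), tmp_path / f"j{i}")
        outs.append((tmp_path / f"j{i}.fasta").read_bytes())
    assert outs[0] == outs[1]
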