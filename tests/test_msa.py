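"""MSA parsing, organism pairing, block diagonalization and Neff."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ppikit.msa import (
    MSA,
    AlignedRow,
    MSAFormatError,
    block_diagonalize,
    compute_neff,
    filter_gapped_rows,
    fuse_msas,
    pair_by_organism,
    read_a3m,
    write_a3m,
)


def _msa(seqs, organisms=None, headers=None):
    organisms = organisms or [None] * len(seqs)
    rows = [
        AlignedRow(
            header=(headers[i] if headers else f"seq{i}"),
            sequence=s,
            rank=i,
            organism_id=organisms[i],
        )
        for i, s in enumerate(seqs)
    ]
    return MSA(rows)


# ------------------------------------------------------------- parsing


def test_read_a3m_strips_insertions_and_parses_ox(tmp_path):
    path = tmp_path / "toy.a3m"
    path.write_text(
        ">query\nACDEF\n"
        ">tr|X|X_HUMAN OX=9606 GN=ABC\nAC-efgDE\n"
    )
    msa = read_a3m(path)
    assert msa.query_length == 5
    assert [r.sequence for r in msa] == ["ACDEF", "AC-DE"]
    assert msa.rows[0].organism_id is None
    assert msa.rows[1].organism_id == 9606
    assert [r.rank for r in msa] == [0, 1]


def test_read_a3m_empty_file_is_format_error(tmp_path):
    path = tmp_path / "empty.a3m"
    path.write_text("")
    with pytest.raises(MSAFormatError):
        read_a3m(path)


def test_read_a3m_ragged_rows_error_names_record(tmp_path):
    path = tmp_path / "bad.a3m"
    path.write_text(">q\nACDEF\n>short OX=1\nAC\n")
    with pytest.raises(MSAFormatError, match="short"):
        read_a3m(path)


def test_round_trip_preserves_rows_headers_and_organisms(tmp_path):
    msa = _msa(
        ["ACDEF", "AC-EF", "GGGG-"],
        organisms=[None, 9606, None],
        headers=["q", "hit1 OX=9606 tail", "hit2"],
    )
    path = tmp_path / "rt.a3m"
    write_a3m(msa, path)
    back = read_a3m(path)
    assert [r.sequence for r in back] == [r.sequence for r in msa]
    assert [r.header for r in back] == [r.header for r in msa]
    assert [r.organism_id for r in back] == [None, 9606, None]
    # byte-identical second round trip
    write_a3m(back, tmp_path / "rt2.a3m")
    assert (tmp_path / "rt2.a3m").read_bytes() == path.read_bytes()


def test_empty_msa_is_rejected():
    with pytest.raises(MSAFormatError):
        MSA([])


# ------------------------------------------------------------ filtering


@pytest.mark.parametrize(
    "n_gaps,kept",
    [(91, False), (90, True), (0, True)],
    ids=["91pct-removed", "90pct-retained", "ungapped-retained"],
)
def test_gap_filter_uses_strict_inequality(n_gaps, kept):
    hit = "-" * n_gaps + "A" * (100 - n_gaps)
    msa = _msa(["A" * 100, hit])
    out = filter_gapped_rows(msa, 0.9)
    assert (len(out) == 2) == kept


def test_gap_filter_exempts_query_and_is_idempotent():
    gappy_query = "-" * 95 + "AAAAA"
    msa = _msa([gappy_query, "-" * 99 + "A", "A" * 100])
    once = filter_gapped_rows(msa)
    assert once.rows[0].sequence == gappy_query
    assert len(once) == 2
    twice = filter_gapped_rows(once)
    assert [r.sequence for r in twice] == [r.sequence for r in once]


# -------------------------------------------------------------- pairing


def test_pair_by_organism_picks_best_hit_per_shared_organism():
    a = _msa(
        ["AAAA", "CCCC", "DDDD", "EEEE"],
        organisms=[None, 9606, 9606, 10090],
    )
    b = _msa(["WWW", "XXX", "YYY"], organisms=[None, 10090, 9606])
    paired = pair_by_organism(a, b)
    assert len(paired) == 3  # query + 2 shared organisms
    assert paired.rows[0].sequence == "AAAAWWW"
    assert paired.provenance == [(9606, 1, 2), (10090, 3, 1)]
    assert paired.rows[1].sequence == "CCCCYYY"
    assert paired.rows[2].sequence == "EEEEXXX"


def test_pair_disjoint_organisms_gives_query_only():
    a = _msa(["AAAA", "CCCC"], organisms=[None, 9606])
    b = _msa(["WWW", "XXX"], organisms=[None, 562])
    paired = pair_by_organism(a, b)
    assert len(paired) == 1
    assert paired.provenance == []


def test_pair_ignores_rows_without_organism():
    a = _msa(["AAAA", "CCCC", "DDDD"], organisms=[None, None, 9606])
    b = _msa(["WWW", "XXX"], organisms=[None, 9606])
    paired = pair_by_organism(a, b)
    assert len(paired) == 2
    assert paired.provenance == [(9606, 2, 1)]


def test_pair_count_bounded_by_shared_organisms():
    a = _msa(["AA"] + ["CC"] * 5, organisms=[None, 1, 1, 2, 2, 3])
    b = _msa(["GG"] + ["TT"] * 4, organisms=[None, 2, 3, 3, 4])
    paired = pair_by_organism(a, b)
    shared = {1, 2, 3} & {2, 3, 4}
    assert len(paired) == 1 + len(shared)


# ------------------------------------------------- block diagonalization


def test_block_diagonalize_shape_and_padding():
    a = _msa(["A" * 50, "C" * 50, "D" * 50])
    b = _msa(["W" * 70, "X" * 70, "Y" * 70, "Z" * 70])
    block = block_diagonalize(a, b)
    assert len(block) == 6  # 1 + 2 + 3
    assert block.query_length == 120
    for row in block.rows[1:3]:
        assert row.sequence.endswith("-" * 70)
    for row in block.rows[3:]:
        assert row.sequence.startswith("-" * 50)


@given(
    na=hst.integers(1, 6),
    nb=hst.integers(1, 6),
    la=hst.integers(1, 12),
    lb=hst.integers(1, 12),
    seed=hst.integers(0, 1000),
)
@settings(max_examples=40, deadline=None)
def test_block_diagonalize_conserves_residue_content(na, nb, la, lb, seed):
    import numpy as np

    rng = np.random.default_rng(seed)

    def rand_msa(n, length):
        alphabet = "ACDEFG-"
        seqs = ["A" * length]  # gap-free query
        for _ in range(n - 1):
            seqs.append(
                "".join(alphabet[rng.integers(6)] if rng.random() > 0.3
                        else "-" for _ in range(length))
            )
        return _msa(seqs)

    a, b = rand_msa(na, la), rand_msa(nb, lb)
    block = block_diagonalize(a, b)

    def residues(msa, skip_query=False):
        rows = msa.rows[1:] if skip_query else msa.rows
        return sum(r.ungapped_length for r in rows)

    expected = (
        a.query.ungapped_length + b.query.ungapped_length
        + residues(a, skip_query=True) + residues(b, skip_query=True)
    )
    assert residues(block) == expected


# --------------------------------------------------------------- fusing


def test_fuse_concatenates_sharing_single_query():
    base = _msa(["QQQQ"] + ["AAAA"] * 4)
    other = _msa(["QQQQ"] + ["CCCC"] * 7)
    fused = fuse_msas([base, other])
    assert len(fused) == 12  # 1 + 4 + 7
    assert fused.query.sequence == "QQQQ"


def test_fuse_single_part_is_identity():
    msa = _msa(["QQQQ", "AAAA"])
    fused = fuse_msas([msa])
    assert [r.sequence for r in fused] == [r.sequence for r in msa]


def test_fuse_query_mismatch_errors():
    with pytest.raises(ValueError, match="query"):
        fuse_msas([_msa(["QQQQ"]), _msa(["PPPP"])])


# ----------------------------------------------------------------- Neff


def test_neff_duplicates_collapse_to_one():
    msa = _msa(["ACDEFGHIKL"] * 10)
    result = compute_neff(msa)
    assert result.n_clusters == 1
    assert set(result.cluster_assignment.values()) == {0}


def test_neff_mutually_dissimilar_rows_stay_apart():
    seqs = ["AAAAAAAA", "CCCCCCCC", "DDDDDDDD", "EEEEEEEE", "FFFFFFFF"]
    assert compute_neff(_msa(seqs)).n_clusters == 5


def test_neff_clusters_by_62_percent_identity():
    # AAAT vs AAAA: identity 0.75 >= 0.62 -> same cluster; CCCC separate
    seqs = ["AAAA", "AAAA", "AAAA", "AAAT", "CCCC"]
    assert compute_neff(_msa(seqs)).n_clusters == 2


def test_neff_every_row_assigned_once():
    seqs = ["AAAA", "AAAT", "CCCC", "CCCT", "GGGG"]
    result = compute_neff(_msa(seqs))
    assert sorted(result.cluster_assignment) == list(range(5))
    assert 1 <= result.n_clusters <= 5


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_neff_nondecreasing_when_appending_rows(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    alphabet = "ACDE"
    seqs = [
        "".join(alphabet[rng.integers(4)] for _ in range(12))
        for _ in range(12)
    ]
    counts = [
        compute_neff(_msa(seqs[: k + 1])).n_clusters
        for k in range(len(seqs))
    ]
    assert all(b >= a for a, b in zip(counts, counts[1:]))


def test_neff_appending_duplicate_never_changes_count():
    seqs = ["AAAAAAAA", "AAAATTTT", "CCCCCCCC"]
    base = compute_neff(_msa(seqs)).n_clusters
    assert compute_neff(_msa(seqs + [seqs[1]])).n_clusters == base
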