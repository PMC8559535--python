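"""Count-table loading, filtering, spike-in attribution and family
classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kseqtools import (
    CountTable,
    SampleMeta,
    SpikeInConfig,
    analyzable_mask,
    classify_table,
    classify_to_family,
    edit_distance,
    filter_sequences,
    hamming_distance,
    load_counts,
    mean_counts,
)
from kseqtools.counts import CountFileError

dna = st.text(alphabet="ACGT", min_size=0, max_size=8)


def dp_levenshtein(a: str, b: str) -> int:
    """Classic dynamic-programming oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


@given(a=dna, b=dna)
def test_edit_distance_matches_dp_oracle(a, b):
    assert edit_distance(a, b) == dp_levenshtein(a, b)


def test_edit_distance_examples():
    assert edit_distance("ACGT", "ACGT") == 0
    assert edit_distance("ACGT", "AGT") == 1
    assert edit_distance("AAAA", "TTTT") == 4
    assert edit_distance("ACGT", "AGT") == edit_distance("AGT", "ACGT")


@given(a=st.text(alphabet="ACGT", min_size=4, max_size=4),
       b=st.text(alphabet="ACGT", min_size=4, max_size=4))
def test_hamming_bounds_levenshtein(a, b):
    # on equal-length strings, Levenshtein <= Hamming (substitution-only path)
    assert edit_distance(a, b) <= hamming_distance(a, b)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def metas(*ids, unreacted=None):
    return [
        SampleMeta(i, substrate_conc=0.0 if i == unreacted else 1e-5,
                   is_unreacted=(i == unreacted))
        for i in ids
    ]


def test_load_counts_union_semantics(tmp_path):
    p1 = write(tmp_path, "s1.txt", "ACGT\t3\n")
    p2 = write(tmp_path, "s2.txt", "# comment\nACGT 1\nAAAA 2\n")
    table = load_counts([p1, p2], metas("s1", "s2", unreacted="s1"))
    assert table.counts.shape == (2, 2)
    assert table.counts.loc["AAAA", "s1"] == 0
    assert table.counts.loc["ACGT", "s2"] == 1
    assert table.meta("s1").total_reads == 3
    assert table.meta("s2").total_reads == 3


def test_load_counts_normalizes_rna_alphabet(tmp_path):
    p = write(tmp_path, "s.txt", "acgu\t5\n")
    table = load_counts([p], metas("s", unreacted="s"))
    assert list(table.sequences) == ["ACGT"]


def test_load_counts_empty_file_is_zero_column(tmp_path):
    p1 = write(tmp_path, "s1.txt", "ACGT\t3\n")
    p2 = write(tmp_path, "s2.txt", "")
    table = load_counts([p1, p2], metas("s1", "s2", unreacted="s1"))
    assert table.counts["s2"].sum() == 0


@pytest.mark.parametrize(
    "content", ["ACGT\t-1\n", "ACGT\tx\n", "ACGT 1 2\n", "ACGT\t1\nACGT\t2\n"]
)
def test_load_counts_malformed_lines_raise_with_location(tmp_path, content):
    p = write(tmp_path, "bad.txt", content)
    with pytest.raises(CountFileError, match="bad.txt"):
        load_counts([p], metas("s", unreacted="s"))


def test_count_table_roundtrip(tmp_path):
    counts = pd.DataFrame(
        {"u": [5, 0, 2], "r1": [1, 9, 0]},
        index=pd.Index(["AAAA", "CCCC", "GGGG"], name="sequence"),
    )
    ms = [
        SampleMeta("u", is_unreacted=True, total_reads=10, measured_total_rna=2.0),
        SampleMeta("r1", substrate_conc=2e-6, replicate=1, total_reads=12),
    ]
    table = CountTable(counts, ms)
    path = tmp_path / "counts.tsv"
    table.write_tsv(path)
    back = CountTable.read_tsv(path)
    pd.testing.assert_frame_equal(back.counts, table.counts)
    assert back.samples == table.samples


def test_count_table_validation():
    idx = pd.Index(["AAAA"], name="sequence")
    with pytest.raises(ValueError, match="total_reads"):
        CountTable(pd.DataFrame({"s": [5]}, index=idx),
                   [SampleMeta("s", total_reads=3)])
    with pytest.raises(ValueError, match="non-negative"):
        CountTable(pd.DataFrame({"s": [-1]}, index=idx), [SampleMeta("s")])


# ---------------------------------------------------------------------------
# filtering and spike-in
# ---------------------------------------------------------------------------

SPIKE = SpikeInConfig("AAAAACAAAAACAAAAACAAA", max_edit_distance=2)


def make_table(rows, ids=("u", "r1"), unreacted="u"):
    # rows: {seq: (count in u, count in r1)}
    df = pd.DataFrame(
        {i: [rows[s][j] for s in rows] for j, i in enumerate(ids)},
        index=pd.Index(list(rows), name="sequence"),
    )
    return CountTable(df, metas(*ids, unreacted=unreacted))


def test_filter_rules_and_spike_attribution():
    good = "GGTCACAATGCGAATCTGGGA"
    short = "GGTCACAATGCGAATCTGGG"  # 20 nt
    ambig = "GGTCACAATGCGAATCTGGGN"
    spike_exact = SPIKE.sequence
    spike_near = "AAAAACAAAAACAAAAACATA"  # 1 substitution
    spike_indel = "AAAAACAAAAACAAAAACAAAT"  # 22 nt, 1 insertion
    table = make_table(
        {
            good: (5, 1),
            short: (2, 0),
            ambig: (1, 1),
            spike_exact: (10, 3),
            spike_near: (4, 0),
            spike_indel: (1, 1),
        }
    )
    res = filter_sequences(table, 21, SPIKE)
    assert list(res.table.sequences) == [good]
    assert res.spike_counts["u"] == 15
    assert res.spike_counts["r1"] == 4
    assert res.tally.loc["length", "u"] == 2
    assert res.tally.loc["ambiguous", "u"] == 1
    # read conservation per sample
    total = table.counts.sum(axis=0)
    kept = res.table.counts.sum(axis=0)
    assert ((kept + res.tally.sum(axis=0)) == total).all()


@given(seed=st.integers(0, 10_000))
def test_filter_conserves_reads_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    seqs = set()
    while len(seqs) < 12:
        L = rng.choice([20, 21, 22])
        seqs.add("".join(rng.choice(list("ACGTN"), size=L)))
    seqs = sorted(seqs)
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(len(seqs), 2)),
        index=pd.Index(seqs, name="sequence"),
        columns=["u", "r1"],
    )
    table = CountTable(counts, metas("u", "r1", unreacted="u"))
    res = filter_sequences(table, 21, SPIKE)
    total = table.counts.sum(axis=0)
    kept = res.table.counts.sum(axis=0)
    assert ((kept + res.tally.sum(axis=0)) == total).all()
    for seq in res.table.sequences:
        assert len(seq) == 21 and set(seq) <= set("ACGT")


# ---------------------------------------------------------------------------
# analyzable mask
# ---------------------------------------------------------------------------


def test_analyzable_mask_criteria():
    ids = ("u", "r1", "r2", "r3")
    df = pd.DataFrame(
        {
            "u": [5, 0, 5],
            "r1": [0, 9, 0],
            "r2": [0, 9, 0],
            "r3": [3, 9, 0],
        },
        index=pd.Index(["AAAA", "CCCC", "GGGG"], name="sequence"),
    )
    table = CountTable(df, metas(*ids, unreacted="u"))
    mask = analyzable_mask(table)
    assert mask.tolist() == [True, False, False]
    assert mean_counts(table)["AAAA"] == pytest.approx(2.0)


def test_analyzable_mask_requires_one_unreacted():
    df = pd.DataFrame({"a": [1], "b": [1]}, index=pd.Index(["AAAA"], name="sequence"))
    table = CountTable(df, metas("a", "b", unreacted=None))
    with pytest.raises(ValueError, match="unreacted"):
        analyzable_mask(table)


# ---------------------------------------------------------------------------
# family classification
# ---------------------------------------------------------------------------

CENTERS = ["AAAA", "CCCC", "GGGG", "TTTT"]


def test_classify_center_and_single_mutant():
    assert classify_to_family("CCCC", CENTERS) == (1, 0, False)
    fam, d, tie = classify_to_family("GGGT", CENTERS)
    assert (fam, d, tie) == (2, 1, False)


def test_classify_tie_goes_to_lowest_index_and_is_flagged():
    fam, d, tie = classify_to_family("AACC", CENTERS)
    assert (fam, d) == (0, 2)
    assert tie


def test_classify_length_mismatch():
    with pytest.raises(ValueError):
        classify_to_family("AAA", CENTERS)


@given(seqs=st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=1, max_size=20))
def test_classify_table_matches_scalar_version(seqs):
    df = classify_table(seqs, CENTERS)
    for seq, row in zip(seqs, df.itertuples()):
        fam, d, tie = classify_to_family(seq, CENTERS)
        assert (row.family, row.distance, row.tie) == (fam, d, tie)
        assert d <= 4
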