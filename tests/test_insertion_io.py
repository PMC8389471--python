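"""Insertion BED dialect, TA indexing, and gene annotation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sbds import (
    assign_insertions_to_genes,
    collapse_to_sites,
    genome_model_from_arrays,
    read_insertion_bed,
    write_insertion_bed,
)
from sbds.insertion_io import (
    INSERTION_COLUMNS,
    InsertionFormatError,
    find_ta_sites,
)
from conftest import random_insertion_table


# --- BED reading -----------------------------------------------------------

def test_read_bed_converts_zero_based_starts(tmp_path):
    bed = tmp_path / "in.bed"
    bed.write_text(
        "chr1\t999\t1001\ts1\t10\t+\n"
        "chr1\t0\t2\ts1\t3\t-\n"
        "chr2\t5\t7\ts2\t1\t+\n"
    )
    table = read_insertion_bed(bed)
    assert len(table) == 3
    assert table.loc[0, "pos"] == 1000  # 0-based 999 -> 1-based 1000
    assert table.loc[1, "pos"] == 1
    assert list(table.columns) == INSERTION_COLUMNS


@pytest.mark.parametrize(
    "line, fragment",
    [
        ("chr1\t10\t12\ts1\t5\t.", "strand"),
        ("chr1\t10\t12\ts1\tfive\t+", "read_count"),
        ("chr1\tx\t12\ts1\t5\t+", "coordinate"),
        ("chr1\t10\t12\ts1\t5", "6 columns"),
    ],
)
def test_read_bed_rejects_malformed_lines(tmp_path, line, fragment):
    bed = tmp_path / "bad.bed"
    bed.write_text("chr1\t0\t2\ts1\t1\t+\n" + line + "\n")
    with pytest.raises(InsertionFormatError, match="2") as err:
        read_insertion_bed(bed)
    assert fragment in str(err.value)


def test_bed_round_trip_preserves_fields(tmp_path):
    rng = np.random.default_rng(1)
    table = random_insertion_table(rng, 50).drop_duplicates(
        ["specimen_id", "chrom", "pos"]
    )
    out = tmp_path / "rt.bed"
    write_insertion_bed(table, out)
    back = read_insertion_bed(out)
    key = ["chrom", "pos", "specimen_id"]
    left = table.sort_values(key).reset_index(drop=True)
    right = back.sort_values(key).reset_index(drop=True)
    pd.testing.assert_frame_equal(left[INSERTION_COLUMNS], right[INSERTION_COLUMNS])
    # output is sorted on disk
    assert (back["chrom"].is_monotonic_increasing or back["chrom"].nunique() > 1)
    assert back.groupby("chrom")["pos"].apply(
        lambda s: s.is_monotonic_increasing
    ).all()


def test_empty_table_round_trip(tmp_path):
    empty = pd.DataFrame(columns=INSERTION_COLUMNS)
    out = tmp_path / "empty.bed"
    write_insertion_bed(empty, out)
    assert read_insertion_bed(out).empty


# --- collapse --------------------------------------------------------------

def test_collapse_sums_duplicate_reads():
    t = pd.DataFrame(
        [
            ("s1", "chr1", 100, "+", 5),
            ("s1", "chr1", 100, "+", 7),
            ("s2", "chr1", 100, "-", 2),  # distinct specimen kept apart
        ],
        columns=INSERTION_COLUMNS,
    )
    out = collapse_to_sites(t)
    assert len(out) == 2
    assert out.set_index("specimen_id").loc["s1", "read_count"] == 12
    assert out.set_index("specimen_id").loc["s2", "read_count"] == 2


def test_collapse_strand_from_max_read_duplicate_ties_plus():
    t = pd.DataFrame(
        [
            ("s1", "chr1", 7, "-", 9),
            ("s1", "chr1", 7, "+", 3),
            ("s1", "chr2", 8, "-", 4),
            ("s1", "chr2", 8, "+", 4),  # tie -> '+'
        ],
        columns=INSERTION_COLUMNS,
    )
    out = collapse_to_sites(t).set_index("chrom")
    assert out.loc["chr1", "strand"] == "-"
    assert out.loc["chr2", "strand"] == "+"


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(0, 200))
def test_collapse_matches_unique_key_oracle_and_is_idempotent(seed, n):
    rng = np.random.default_rng(seed)
    t = random_insertion_table(rng, n, max_pos=30)
    out = collapse_to_sites(t)
    # brute-force oracle: count of distinct (specimen, chrom, pos) keys
    oracle_keys = {tuple(r) for r in t[["specimen_id", "chrom", "pos"]].itertuples(index=False)}
    assert len(out) == len(oracle_keys)
    assert out["read_count"].sum() == t["read_count"].sum()
    again = collapse_to_sites(out)
    pd.testing.assert_frame_equal(
        out.sort_values(["specimen_id", "chrom", "pos"]).reset_index(drop=True),
        again.sort_values(["specimen_id", "chrom", "pos"]).reset_index(drop=True),
    )


# --- TA indexing -----------------------------------------------------------

def test_overlapping_ta_convention():
    assert find_ta_sites("TATA").tolist() == [1, 3]
    assert find_ta_sites("GGGG").tolist() == []
    assert find_ta_sites("ta").tolist() == [1]  # case-insensitive
    assert find_ta_sites("A").tolist() == []


@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ta_index_matches_character_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    oracle = [i + 1 for i in range(len(seq) - 1) if seq[i] == "T" and seq[i + 1] == "A"]
    assert find_ta_sites(seq).tolist() == oracle


def test_gene_ta_counts_match_window_scan(tiny_model):
    # chrA TA sites at 3, 7, 11, 13
    assert tiny_model.ta_index["chrA"].tolist() == [3, 7, 11, 13]
    assert tiny_model.ta_index["chrB"].tolist() == [4]
    genes = tiny_model.genes.set_index("gene_id")
    assert genes.loc["plusG", "ta_count"] == 2  # positions 3, 7 in [2, 8]
    assert genes.loc["minusG", "ta_count"] == 2  # positions 11, 13 in [10, 14]
    assert tiny_model.total_ta == 5


def test_gene_on_unknown_chromosome_raises():
    genes = pd.DataFrame(
        {"gene_id": ["bad"], "chrom": ["chrZ"], "start": [1], "end": [5],
         "gene_strand": ["+"]}
    )
    with pytest.raises(ValueError, match="bad"):
        genome_model_from_arrays({"chrA": "TATA"}, genes)


# --- gene assignment -------------------------------------------------------

def test_relative_orientation_definition(tiny_model):
    t = pd.DataFrame(
        [
            ("s1", "chrA", 3, "+", 5),   # inside plusG (+), strand + -> sense
            ("s1", "chrA", 7, "-", 5),   # inside plusG (+), strand - -> antisense
            ("s1", "chrA", 11, "+", 5),  # inside minusG (-), strand + -> antisense
            ("s1", "chrB", 4, "+", 5),   # intergenic
        ],
        columns=INSERTION_COLUMNS,
    )
    ann = assign_insertions_to_genes(t, tiny_model)
    assert ann["relative_orientation"].tolist() == [
        "sense", "antisense", "antisense", "intergenic"
    ]
    assert ann["gene_id"].isna().tolist() == [False, False, False, True]
    # relative position measured from the transcription start
    plus_rel = ann.loc[0, "relative_position"]
    assert plus_rel == pytest.approx((3 - 2) / (8 - 2))
    minus_rel = ann.loc[2, "relative_position"]
    assert minus_rel == pytest.approx((14 - 11) / (14 - 10))


def test_assignment_matches_brute_force_overlap_oracle():
    rng = np.random.default_rng(42)
    length = 50_000
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(20)],
            "chrom": "chr1",
            "start": (starts := np.sort(rng.choice(length - 800, 20, replace=False)) + 1),
            "end": starts + rng.integers(100, 800, 20),
            "gene_strand": rng.choice(["+", "-"], 20),
        }
    )
    model = genome_model_from_arrays(
        {"chr1": "TA" * (length // 2)}, genes
    )
    t = random_insertion_table(
        rng, 1000, specimens=("s1",), chroms=("chr1",), max_pos=length
    ).drop_duplicates(["specimen_id", "chrom", "pos"])
    ann = assign_insertions_to_genes(t, model)
    genic = ann[ann["gene_id"].notna()]
    oracle = set()
    for row in t.itertuples():
        for g in genes.itertuples():
            if g.start <= row.pos <= g.end:
                oracle.add((row.pos, g.gene_id))
    assert set(zip(genic["pos"], genic["gene_id"])) == oracle
    # multi-gene overlaps produce one annotated row per gene, flagged
    per_pos = genic.groupby("pos").size()
    flagged = set(genic.loc[genic["multi_hit"], "pos"])
    assert flagged == set(per_pos.index[per_pos > 1])
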