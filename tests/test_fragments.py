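import numpy as np
import pandas as pd
import pytest

from atacploidy import (
    FragmentSet,
    IntervalMask,
    barcode_qc_table,
    filter_fragments,
    read_fragments,
)
from atacploidy.fragments import FragmentFileError


class TestReadFragments:
    def test_min_frag_threshold_boundary(self, write_fragments_file):
        path = write_fragments_file(
            [
                ("chr1", 100, 200, "A"),
                ("chr1", 300, 400, "A"),
                ("chr1", 100, 200, "B"),
            ]
        )
        fs = read_fragments(path, min_frag=2)
        assert set(fs.barcodes) == {"A"}

    def test_pcr_duplicates_collapse(self, write_fragments_file):
        path = write_fragments_file(
            [("chr1", 100, 200, "A"), ("chr1", 100, 200, "A")]
        )
        fs = read_fragments(path)
        assert len(fs) == 1

    def test_duplicate_count_column_ignored(self, write_fragments_file):
        path = write_fragments_file(
            [("chr1", 100, 200, "A", 7), ("chr1", 300, 400, "A", 2)]
        )
        assert len(read_fragments(path)) == 2

    def test_atlas_preset_bounds_inclusive(self, write_fragments_file):
        counts = {"a": 500, "b": 1_000, "c": 50_000, "d": 100_000, "e": 200_000}
        rows = []
        for bc, n in counts.items():
            rows.extend(("chr1", 10 * i, 10 * i + 5, bc) for i in range(n))
        path = write_fragments_file(rows)
        fs = read_fragments(path, min_frag=1_000, max_frag=100_000)
        assert set(fs.barcodes) == {"b", "c", "d"}

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([("chr1", "x", 200, "A")], "line 1"),
            ([("chr1", 100, 200, "A"), ("chr1", 300, 200, "B")], "line 2"),
            ([("chr1", 100, 100, "A")], "line 1"),
            ([("chr1", 100)], "line 1"),
        ],
    )
    def test_malformed_line_names_line_number(self, write_fragments_file, rows, match):
        path = write_fragments_file(rows)
        with pytest.raises(FragmentFileError, match=match):
            read_fragments(path)

    def test_empty_file_rejected(self, write_fragments_file):
        path = write_fragments_file([("#", "comment", "only", "line")])
        with pytest.raises(FragmentFileError, match="no fragment"):
            read_fragments(path)

    def test_gzip_round_trip(self, tmp_path, toy_fragments):
        path = tmp_path / "frags.tsv.gz"
        toy_fragments.write(path)
        assert read_fragments(path) == toy_fragments


class TestFilterFragments:
    def test_non_autosome_removed(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chrX"],
                "start": [0, 0],
                "end": [10, 10],
                "barcode": ["A", "A"],
            }
        )
        out = filter_fragments(FragmentSet(df), autosomes={"chr1"})
        assert set(out.df["chrom"]) == {"chr1"}

    def test_three_prime_end_is_last_covered_base(self):
        # fragment [100, 200): 3' end position is 199, inside [150, 300)
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200], "barcode": ["A"]}
        )
        mask = IntervalMask.from_intervals({"chr1": [(150, 300)]})
        assert len(filter_fragments(FragmentSet(df), repeats=mask)) == 0
        # shifting the mask start past 199 keeps the fragment
        mask2 = IntervalMask.from_intervals({"chr1": [(200, 300)]})
        assert len(filter_fragments(FragmentSet(df), repeats=mask2)) == 1

    def test_empty_mask_is_identity_on_autosome_subset(self, toy_fragments):
        out = filter_fragments(
            toy_fragments, autosomes={"chr1"}, repeats=IntervalMask()
        )
        assert out == toy_fragments

    def test_unmasked_chromosome_warns_and_keeps(self, toy_fragments):
        mask = IntervalMask.from_intervals({"chr2": [(0, 10)]})
        with pytest.warns(UserWarning, match="chr1"):
            out = filter_fragments(toy_fragments, repeats=mask)
        assert out == toy_fragments

    def test_idempotent_and_count_conserving(self, rng):
        n = 500
        df = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2", "chrX"], n),
                "start": rng.integers(0, 10_000, n),
                "barcode": rng.choice(["A", "B", "C"], n),
            }
        )
        df["end"] = df["start"] + rng.integers(50, 300, n)
        fs = FragmentSet(df)
        mask = IntervalMask.from_intervals(
            {"chr1": [(1_000, 2_000), (5_000, 6_000)], "chr2": [(0, 500)]}
        )
        once = filter_fragments(fs, {"chr1", "chr2"}, mask)
        twice = filter_fragments(once, {"chr1", "chr2"}, mask)
        assert once == twice
        n_removed = len(fs) - len(once)
        assert n_removed >= 0 and len(once) + n_removed == len(fs)


class TestIntervalMask:
    def test_membership_half_open(self):
        mask = IntervalMask.from_intervals({"chr1": [(10, 20)]})
        assert list(mask.contains("chr1", [9, 10, 19, 20])) == [
            False,
            True,
            True,
            False,
        ]

    def test_overlapping_intervals_merge(self):
        mask = IntervalMask.from_intervals({"chr1": [(0, 15), (10, 20)]})
        starts, ends = mask.intervals["chr1"]
        assert list(starts) == [0] and list(ends) == [20]

    def test_complement_partitions_span(self):
        mask = IntervalMask.from_intervals({"chr1": [(10, 20), (30, 40)]})
        comp = mask.complement({"chr1": (0, 50)})
        assert mask.total_length() + comp.total_length() == 50
        pos = np.arange(0, 50)
        both = mask.contains("chr1", pos) & comp.contains("chr1", pos)
        either = mask.contains("chr1", pos) | comp.contains("chr1", pos)
        assert not both.any() and either.all()


def test_qc_table_flags_out_of_range_barcodes(write_fragments_file):
    path = write_fragments_file(
        [("chr1", i, i + 5, bc) for bc, n in [("A", 3), ("B", 1)] for i in range(0, 10 * n, 10)]
    )
    fs = read_fragments(path)
    qc = barcode_qc_table(fs, min_frag=2, max_frag=10)
    assert qc.set_index("barcode")["retained"].to_dict() == {"A": True, "B": False}
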