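"""Levenshtein-1 collapse, read-count filtering, template-artifact removal."""

import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mosaicbc.collapse import (
    ConfigurationError,
    FilterPolicy,
    collapse_barcodes,
    filter_counts,
    levenshtein1_neighborhood,
    remove_template_artifacts,
)
from mosaicbc.extract import DEFAULT_TEMPLATE
from _oracles import dp_levenshtein, trace_collapse


def table_from(counts: dict, sample: str = "s1") -> pd.DataFrame:
    df = pd.DataFrame({sample: pd.Series(counts, dtype="int64")})
    df.index.name = "barcode"
    return df


class TestNeighborhood:
    def test_neighborhood_is_exactly_the_levenshtein1_ball(self):
        barcode = "ACGTA"
        ball = set(levenshtein1_neighborhood(barcode))
        # every enumerated string is within distance 1 (checked independently)
        assert all(dp_levenshtein(barcode, s) <= 1 for s in ball)
        # and every length-5 string within distance 1 is enumerated
        rand = random.Random(0)
        for _ in range(2000):
            s = "".join(rand.choice("ACGT") for _ in range(rand.choice([4, 5, 6])))
            assert (s in ball) == (dp_levenshtein(barcode, s) <= 1)


class TestCollapse:
    def test_single_error_child_merges_into_parent(self):
        table = table_from({"AAAAAAAAAAAAAAA": 100, "AAAAAAAAAAAAAAT": 2})
        collapsed, cmap = collapse_barcodes(table)
        assert list(collapsed.index) == ["AAAAAAAAAAAAAAA"]
        assert collapsed.iloc[0, 0] == 102
        assert cmap.assignments["AAAAAAAAAAAAAAT"] == "AAAAAAAAAAAAAAA"

    def test_well_separated_barcodes_are_untouched(self):
        counts = {"AAAAA": 10, "CCCCC": 8, "GGGGG": 5}
        collapsed, cmap = collapse_barcodes(table_from(counts))
        assert collapsed.shape[0] == 3
        assert all(cmap.assignments[b] == b for b in counts)

    def test_chain_children_merge_only_into_finalized_parents(self):
        # d(A,B)=1, d(B,C)=1, d(A,C)=2: B merges into A; C survives because
        # B never became a parent.
        a, b, c = "AAAAA", "AAAAT", "AAATT"
        assert dp_levenshtein(a, b) == 1 and dp_levenshtein(b, c) == 1
        assert dp_levenshtein(a, c) == 2
        collapsed, cmap = collapse_barcodes(table_from({a: 10, b: 5, c: 3}))
        assert dict(collapsed["s1"]) == {a: 15, c: 3}
        assert cmap.assignments == {a: a, b: a, c: c}

    def test_per_sample_counts_preserved_through_global_collapse(self):
        table = pd.DataFrame(
            {"f1": [50, 3, 0], "f2": [0, 2, 7]},
            index=["AAAAA", "AAAAT", "AAATT"],
        )
        collapsed, _ = collapse_barcodes(table)
        # AAAAT joins AAAAA (d=1, most abundant); AAATT survives (d=2 to AAAAA)
        assert dict(collapsed.loc["AAAAA"]) == {"f1": 53, "f2": 2}
        assert dict(collapsed.loc["AAATT"]) == {"f1": 0, "f2": 7}
        assert collapsed.sum().sum() == table.sum().sum()

    def test_matches_exhaustive_rule_trace_on_random_sets(self):
        """Greedy collapse equals an independent trace of the stated rule on
        500 random barcode sets of <= 12 members."""
        rand = random.Random(99)
        for trial in range(500):
            n = rand.randint(1, 12)
            length = rand.randint(3, 5)
            barcodes = {
                "".join(rand.choice("ACGT") for _ in range(length + rand.choice([0, 0, 1])))
                for _ in range(n)
            }
            counts = {bc: rand.randint(1, 50) for bc in barcodes}
            _, cmap = collapse_barcodes(table_from(counts))
            assert cmap.assignments == trace_collapse(counts), counts

    def test_idempotence(self):
        rand = random.Random(5)
        barcodes = {"".join(rand.choice("ACGT") for _ in range(4)) for _ in range(30)}
        table = table_from({bc: rand.randint(1, 100) for bc in barcodes})
        once, _ = collapse_barcodes(table)
        twice, cmap = collapse_barcodes(once)
        assert twice.sort_index().equals(once.sort_index())
        assert all(cmap.assignments[p] == p for p in once.index)

    def test_parent_dominance_and_conservation(self):
        rand = random.Random(17)
        barcodes = list({"".join(rand.choice("ACGT") for _ in range(4)) for _ in range(40)})
        table = pd.DataFrame(
            {
                "f1": [rand.randint(0, 30) for _ in barcodes],
                "f2": [rand.randint(0, 30) for _ in barcodes],
            },
            index=barcodes,
        )
        table = table.loc[table.sum(axis=1) > 0]
        totals = table.sum(axis=1)
        collapsed, cmap = collapse_barcodes(table)
        assert collapsed.sum().sum() == table.sum().sum()  # grand total conserved
        for sample in table.columns:  # per-sample totals conserved too
            assert collapsed[sample].sum() == table[sample].sum()
        for child, parent in cmap.assignments.items():
            assert totals[parent] >= totals[child] or (
                totals[parent] == totals[child] and parent <= child
            )

    def test_empty_table(self):
        collapsed, cmap = collapse_barcodes(pd.DataFrame(dtype="int64"))
        assert collapsed.empty and cmap.assignments == {}


class TestFilterCounts:
    POLICY = FilterPolicy()

    def test_fish_threshold_is_per_cell(self):
        table = pd.DataFrame({"fish1": [5, 2], "fish2": [2, 3]}, index=["X", "Y"])
        out = filter_counts(table, self.POLICY, "fish")
        assert dict(out.loc["X"]) == {"fish1": 5, "fish2": 0}
        assert dict(out.loc["Y"]) == {"fish1": 0, "fish2": 3}

    def test_fish_boundary_values(self):
        table = table_from({"X": 2, "Y": 3}, sample="fish1")
        out = filter_counts(table, self.POLICY, "fish")
        assert list(out.index) == ["Y"] and out.loc["Y", "fish1"] == 3

    def test_library_singletons_removed(self):
        table = table_from({"X": 1, "Y": 2}, sample="library")
        out = filter_counts(table, self.POLICY, "source_library")
        assert list(out.index) == ["Y"]

    def test_all_zero_rows_dropped(self):
        table = table_from({"X": 2, "Y": 10}, sample="fish1")
        out = filter_counts(table, self.POLICY, "fish")
        assert "X" not in out.index

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_counts(table_from({"X": 5}), self.POLICY, "plasma")

    @settings(derandomize=True, max_examples=60)
    @given(
        counts=st.lists(st.integers(0, 20), min_size=1, max_size=15),
        low=st.integers(0, 5),
        high=st.integers(0, 5),
    )
    def test_raising_threshold_never_increases_counts(self, counts, low, high):
        low, high = min(low, high), max(low, high)
        table = table_from({f"B{i:02d}": c for i, c in enumerate(counts)})
        loose = filter_counts(table, FilterPolicy(min_reads_per_fish=low), "fish")
        strict = filter_counts(table, FilterPolicy(min_reads_per_fish=high), "fish")
        joined = loose.join(strict, how="outer", rsuffix="_strict").fillna(0)
        assert (joined["s1_strict"] <= joined["s1"]).all()


class TestTemplateArtifacts:
    def test_exact_template_window_removed(self):
        region = DEFAULT_TEMPLATE.conserved_regions[0]
        window = region[5:20]
        table = table_from({window: 50, "GATTACAGATTACAG": 20})
        out, log = remove_template_artifacts(table, DEFAULT_TEMPLATE)
        assert window not in out.index
        assert "GATTACAGATTACAG" in out.index
        assert log.loc[0, "distance"] == 0

    def test_random_barcodes_survive_brute_force_crosscheck(self):
        rng = np.random.default_rng(31)
        from mosaicbc.simulate import random_barcodes

        barcodes = random_barcodes(200, 15, rng)
        table = table_from({bc: 5 for bc in barcodes})
        out, log = remove_template_artifacts(table, DEFAULT_TEMPLATE)
        # independent window scan: min DP distance over all windows +/- 2 slack
        def min_window_dist(bc):
            best = 99
            for region in DEFAULT_TEMPLATE.conserved_regions:
                for wlen in range(13, 18):
                    for s in range(len(region) - wlen + 1):
                        best = min(best, dp_levenshtein(bc, region[s : s + wlen]))
            return best

        removed = set(log["barcode"])
        for bc in barcodes[:40]:  # cross-check a subset exhaustively
            assert (min_window_dist(bc) <= 2) == (bc in removed)
        assert len(removed) == 0  # random 15-mers are overwhelmingly retained

    def test_distance_three_barcode_retained(self):
        region = DEFAULT_TEMPLATE.conserved_regions[1]
        rand = random.Random(3)

        def min_dist(bc):
            return min(
                dp_levenshtein(bc, r[s : s + wlen])
                for r in DEFAULT_TEMPLATE.conserved_regions
                for wlen in range(13, 18)
                for s in range(len(r) - wlen + 1)
            )

        base = region[10:25]
        bc = None
        while bc is None:
            cand = list(base)
            for pos in rand.sample(range(15), 3):
                cand[pos] = rand.choice([b for b in "ACGT" if b != cand[pos]])
            cand = "".join(cand)
            if min_dist(cand) == 3:
                bc = cand
        out, _ = remove_template_artifacts(table_from({bc: 9}), DEFAULT_TEMPLATE)
        assert bc in out.index

    def test_empty_conserved_regions_warns_and_passes_through(self):
        import dataclasses

        tmpl = dataclasses.replace(DEFAULT_TEMPLATE, conserved_regions=())
        table = table_from({"GATTACAGATTACAG": 5})
        with pytest.warns(UserWarning):
            out, log = remove_template_artifacts(table, tmpl)
        assert out.equals(table) and log.empty
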