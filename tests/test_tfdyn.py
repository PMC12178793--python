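import numpy as np
import pytest

from credyn.catalog import ElementCatalog, GenomicInterval
from credyn.states import PeakSet
from credyn.tfdyn import (
    ActivityTable,
    FootprintRecord,
    build_activity_table,
    footprints_in_elements,
    group_signal_compare,
    partition_by_p53,
    rank_by_sd,
    top_overlap,
)

from conftest import base_set, make_element, random_intervals


def fp(tf, chrom, start, end, prot, tags, tp):
    return FootprintRecord(tf, GenomicInterval(chrom, start, end), prot, tags, tp)


class TestFootprintExtraction:
    def test_inside_and_outside(self, tiny_catalog):
        inside = fp("A", "chr1", 150, 170, 1.0, 5, "0h")
        outside = fp("B", "chr9", 150, 170, 1.0, 5, "0h")
        subset, counts = footprints_in_elements([inside, outside], tiny_catalog)
        assert subset == [inside]
        assert counts == {"0h": 1}

    def test_matches_per_base_oracle(self, rng, tiny_catalog):
        element_bases = set()
        for el in tiny_catalog:
            element_bases |= base_set(el.interval)
        fps = [
            fp(f"T{i}", iv.chrom, iv.start, iv.end, 1.0, 1, "0h")
            for i, iv in enumerate(random_intervals(rng, 200, max_pos=6000))
        ]
        subset, _ = footprints_in_elements(fps, tiny_catalog)
        expected = [f for f in fps if base_set(f.interval) & element_bases]
        assert subset == expected


class TestActivityTable:
    def test_single_footprint_equals_raw_score(self):
        fps = [fp("A", "chr1", 0, 20, float(t), 1, tp) for t, tp in enumerate(("0h", "8h", "16h"))]
        table = build_activity_table(fps, metric="protection")
        assert table.rows["A"] == (0.0, 1.0, 2.0)

    def test_mean_of_two(self):
        fps = [fp("A", "chr1", 0, 20, 1.0, 1, "0h"), fp("A", "chr1", 30, 50, 3.0, 1, "0h")]
        fps += [fp("A", "chr1", 0, 20, 5.0, 1, tp) for tp in ("8h", "16h")]
        table = build_activity_table(fps, metric="protection")
        assert table.rows["A"][0] == pytest.approx(2.0)

    def test_missing_timepoint_drops_row(self):
        fps = [fp("A", "chr1", 0, 20, 1.0, 1, "0h")]
        table = build_activity_table(fps)
        assert "A" not in table.rows

    def test_group_mean_matches_brute_force(self, rng):
        fps = []
        for i in range(120):
            tf = f"T{int(rng.integers(0, 8))}"
            tp = ("0h", "8h", "16h")[int(rng.integers(0, 3))]
            fps.append(fp(tf, "chr1", 0, 20, float(rng.random()), int(rng.integers(0, 50)), tp))
        table = build_activity_table(fps, metric="tag_count")
        for tf, triple in table.rows.items():
            for t, tp in enumerate(("0h", "8h", "16h")):
                vals = [f.tag_count for f in fps if f.tf_name == tf and f.timepoint == tp]
                assert triple[t] == pytest.approx(np.mean(vals))


class TestRanking:
    def test_constant_row_ranks_last(self):
        table = ActivityTable({"flat": (1.0, 1.0, 1.0), "var": (0.0, 2.0, 4.0)}, "protection")
        assert rank_by_sd(table, top_n=2) == ["var", "flat"]

    def test_closed_form_sd(self):
        table = ActivityTable({"a": (0.0, 2.0, 4.0)}, "protection")
        assert float(np.std(table.rows["a"], ddof=1)) == pytest.approx(2.0)

    def test_matches_brute_force_sort(self, rng):
        rows = {f"tf{i:03d}": tuple(rng.random(3)) for i in range(100)}
        table = ActivityTable(rows, "protection")
        ranked = rank_by_sd(table, top_n=100)
        expected = sorted(rows, key=lambda t: (-np.std(rows[t], ddof=1), t))
        assert ranked == expected

    def test_row_permutation_and_shift_invariance(self, rng):
        rows = {f"tf{i}": tuple(rng.random(3)) for i in range(20)}
        table = ActivityTable(rows, "protection")
        base = rank_by_sd(table, top_n=20)
        shuffled = dict(reversed(list(rows.items())))
        shifted = {t: tuple(v + 5.0 for v in tr) for t, tr in shuffled.items()}
        assert rank_by_sd(ActivityTable(shifted, "protection"), top_n=20) == base

    def test_planted_high_variance_recovery(self, rng):
        """Top-k recovers all planted TFs at >= 5x variance separation."""
        k = 6
        rows = {}
        for i in range(k):
            rows[f"hi{i}"] = tuple(10.0 * rng.random(3) + np.array([0.0, 20.0, 0.0]))
        for i in range(60):
            base = float(rng.random() * 5)
            rows[f"lo{i}"] = tuple(base + 0.3 * rng.random(3))
        ranked = rank_by_sd(ActivityTable(rows, "protection"), top_n=k)
        assert set(ranked) == {f"hi{i}" for i in range(k)}

    def test_top_overlap_verbatim_complex_names(self):
        shared, n = top_overlap(["JUNB", "FOSL1::JUN"], ["FOSL1::JUN", "TP53"])
        assert shared == {"FOSL1::JUN"} and n == 1
        assert top_overlap(["A"], ["B"])[1] == 0
        assert top_overlap(["A", "B"], ["A", "B"])[1] == 2


class TestP53Partition:
    def test_bound_and_free(self, tiny_catalog):
        peaks = PeakSet("p53", "static", [GenomicInterval("chr1", 400, 450)])
        part = partition_by_p53(tiny_catalog, peaks)
        assert "e1" in part.p53BER
        assert "e2" in part.p53FER
        assert "p1" in part.p53FPR and "p2" in part.p53FPR

    def test_sizes_sum(self, rng, tiny_catalog):
        peaks = PeakSet("p53", "static", random_intervals(rng, 10, max_pos=6000))
        part = partition_by_p53(tiny_catalog, peaks)
        assert len(part.p53BER) + len(part.p53FER) == len(tiny_catalog.enhancers)
        assert len(part.p53BPR) + len(part.p53FPR) == len(tiny_catalog.promoters)

    def test_matches_per_base_oracle(self, rng, tiny_catalog):
        peaks = PeakSet("p53", "static", random_intervals(rng, 12, max_pos=6000))
        part = partition_by_p53(tiny_catalog, peaks)
        for el in tiny_catalog:
            bound = any(base_set(el.interval) & base_set(p) for p in peaks.peaks)
            group = (
                (part.p53BER if bound else part.p53FER)
                if el.element_class == "enhancer"
                else (part.p53BPR if bound else part.p53FPR)
            )
            assert el.id in group

    def test_wrong_assay_rejected(self, tiny_catalog):
        with pytest.raises(ValueError):
            partition_by_p53(tiny_catalog, PeakSet("ATAC", "0h", []))


class TestGroupCompare:
    def test_identical_groups_d_zero(self):
        values = {f"e{i}": float(i) for i in range(6)}
        res = group_signal_compare({"e0", "e1", "e2"}, {"e0", "e1", "e2"}, values)
        assert res.statistic == 0.0

    def test_disjoint_support_d_one(self):
        values = {"a1": 1.0, "a2": 2.0, "b1": 10.0, "b2": 11.0}
        res = group_signal_compare({"a1", "a2"}, {"b1", "b2"}, values)
        assert res.statistic == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_signal_compare({"x"}, {"y"}, {"y": 1.0})
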