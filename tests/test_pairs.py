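import numpy as np
import pytest

from credyn.catalog import ElementCatalog, GenomicInterval
from credyn.pairs import (
    DETable,
    LoopSet,
    PairRecord,
    assign_by_domain,
    assign_by_loops,
    build_domains,
    consistent_de_genes,
    coordinated_pairs,
)

from conftest import make_element, make_gene


def de(contrast, **rows):
    return DETable(contrast, {g: v for g, v in rows.items()})


class TestConsistentDE:
    def test_up_in_both(self):
        up, down = consistent_de_genes(
            de("8v0", a=(2.0, 0.01)), de("16v0", a=(1.5, 0.001))
        )
        assert up == {"a"} and down == set()

    def test_sign_flip_excluded(self):
        up, down = consistent_de_genes(
            de("8v0", a=(2.0, 0.01)), de("16v0", a=(-2.0, 0.01))
        )
        assert up == down == set()

    def test_strict_threshold_boundary(self):
        up, down = consistent_de_genes(
            de("8v0", a=(1.0, 0.01)), de("16v0", a=(1.0, 0.01))
        )
        assert up == set()  # log2fc must exceed 1, not equal it

    def test_gene_missing_from_one_table(self):
        up, down = consistent_de_genes(de("8v0", a=(2.0, 0.01)), de("16v0", b=(2.0, 0.01)))
        assert up == set()

    def test_down_set(self):
        up, down = consistent_de_genes(
            de("8v0", a=(-2.0, 0.001), b=(-0.5, 0.001)),
            de("16v0", a=(-1.5, 0.01), b=(-2.0, 0.001)),
        )
        assert down == {"a"} and up == set()


class TestDomains:
    def test_single_gene_clipped_at_chromosome(self):
        g = make_gene("g", "chr1", 100_000, 150_000, "+")
        (d,) = build_domains([g], chrom_sizes={"chr1": 1_000_000})
        # basal [95,000, 101,000) extended 1 Mb each way, clipped to the chromosome
        assert (d.domain.start, d.domain.end) == (0, 1_000_000)

    def test_extension_stops_at_neighbor_basal(self):
        ga = make_gene("a", "chr1", 100_000, 150_000, "+")
        gb = make_gene("b", "chr1", 102_000, 160_000, "+")
        doms = {d.gene_id: d.domain for d in build_domains([ga, gb])}
        # b's basal starts at 97,000 > a's basal end 101,000 is false here:
        # basal(a) = [95,000, 101,000), basal(b) = [97,000, 103,000) overlap,
        # so a's rightward extension stops at its own basal end
        assert doms["a"].end == 101_000
        # and b's leftward extension stops at its basal start
        assert doms["b"].start == 97_000

    def test_disjoint_neighbors_bound_extension(self):
        ga = make_gene("a", "chr1", 100_000, 150_000, "+")
        gb = make_gene("b", "chr1", 300_000, 350_000, "+")
        doms = {d.gene_id: d.domain for d in build_domains([ga, gb])}
        assert doms["a"].end == 295_000  # neighbor basal start
        assert doms["b"].start == 101_000  # neighbor basal end

    def test_basal_clipped_at_zero(self):
        g = make_gene("g", "chr1", 1000, 5000, "+")
        (d,) = build_domains([g])
        assert d.domain.start == 0

    def test_monotone_in_max_ext(self):
        genes = [
            make_gene("a", "chr1", 50_000, 60_000, "+"),
            make_gene("b", "chr1", 400_000, 420_000, "-"),
        ]
        small = {d.gene_id: d.domain for d in build_domains(genes, max_ext=10_000)}
        big = {d.gene_id: d.domain for d in build_domains(genes, max_ext=1_000_000)}
        for gid in small:
            assert big[gid].start <= small[gid].start
            assert big[gid].end >= small[gid].end

    def test_domains_cover_basal_regions(self):
        rng = np.random.default_rng(3)
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 2000, "+" if i % 2 else "-")
            for i, s in enumerate(sorted(rng.integers(10_000, 900_000, size=10)))
        ]
        doms = {d.gene_id: d.domain for d in build_domains(genes)}
        for g in genes:
            tss = g.tss
            d = doms[g.gene_id]
            assert d.start <= tss < d.end


class TestAssignment:
    def test_domain_assignment_brute_force(self):
        rng = np.random.default_rng(11)
        genes = [
            make_gene(f"g{i}", "chr1", int(s), int(s) + 3000, "+")
            for i, s in enumerate(sorted(rng.integers(20_000, 500_000, size=6)))
        ]
        doms = build_domains(genes)
        for _ in range(100):
            start = int(rng.integers(0, 520_000))
            enh = make_element("e", "chr1", start, start + 400)
            mid = start + 200
            expected = sorted(
                d.gene_id for d in doms
                if d.domain.start <= mid < d.domain.end
            )
            assert assign_by_domain(enh, doms) == expected

    def test_loop_pairing(self):
        enh = make_element("e1", "chr1", 10_000, 10_400)
        prom = make_element("p1", "chr1", 50_000, 51_000, element_class="promoter")
        loops = LoopSet([
            (GenomicInterval("chr1", 9_900, 10_500), GenomicInterval("chr1", 49_900, 51_100)),
        ])
        out = assign_by_loops([enh], [prom], {"p1": "geneA"}, loops)
        assert [(p.enhancer_id, p.gene_id, p.evidence) for p in out] == [
            ("e1", "geneA", "loop")
        ]

    def test_loop_needs_both_sides(self):
        enh = make_element("e1", "chr1", 10_000, 10_400)
        prom = make_element("p1", "chr1", 50_000, 51_000, element_class="promoter")
        loops = LoopSet([
            (GenomicInterval("chr1", 9_900, 10_500), GenomicInterval("chr1", 10_000, 10_200)),
        ])
        assert assign_by_loops([enh], [prom], {"p1": "geneA"}, loops) == []

    def test_anchor_order_irrelevant_and_duplicates_collapsed(self):
        enh = make_element("e1", "chr1", 10_000, 10_400)
        prom = make_element("p1", "chr1", 50_000, 51_000, element_class="promoter")
        fwd = (GenomicInterval("chr1", 10_000, 10_400), GenomicInterval("chr1", 50_000, 51_000))
        out = assign_by_loops([enh], [prom], {"p1": "g"}, LoopSet([fwd, fwd[::-1]]))
        assert len(out) == 1


class TestCoordinated:
    def pairs(self):
        return [PairRecord("e", "g", "loop")]

    def test_monotone_down_both(self):
        out = coordinated_pairs(self.pairs(), {"e": (3, 2, 1)}, {"g": (30, 20, 10)})
        assert out[0].direction == "down"

    def test_monotone_up_both(self):
        out = coordinated_pairs(self.pairs(), {"e": (1, 2, 3)}, {"g": (5, 8, 9)})
        assert out[0].direction == "up"

    @pytest.mark.parametrize(
        "enh,gene",
        [
            ((3, 2, 1), (10, 20, 30)),  # opposite directions
            ((1, 2, 1.5), (1, 2, 1.5)),  # non-monotone
            ((1, 1, 1), (3, 2, 1)),  # flat enhancer
        ],
    )
    def test_dropped(self, enh, gene):
        assert coordinated_pairs(self.pairs(), {"e": enh}, {"g": gene}) == []

    def test_missing_member_dropped(self):
        assert coordinated_pairs(self.pairs(), {}, {"g": (3, 2, 1)}) == []

    def test_invariant_under_uniform_rescaling(self):
        enh = {"e": (3.0, 2.0, 1.0)}
        gene = {"g": (30.0, 20.0, 10.0)}
        base = coordinated_pairs(self.pairs(), enh, gene)
        scaled = coordinated_pairs(
            self.pairs(),
            {k: tuple(v * 7.5 for v in t) for k, t in enh.items()},
            {k: tuple(v * 7.5 for v in t) for k, t in gene.items()},
        )
        assert [(p.enhancer_id, p.direction) for p in base] == [
            (p.enhancer_id, p.direction) for p in scaled
        ]

    def test_eps_requires_minimum_step(self):
        out = coordinated_pairs(
            self.pairs(), {"e": (3.0, 2.9, 2.8)}, {"g": (30, 20, 10)}, eps=0.5
        )
        assert out == []
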