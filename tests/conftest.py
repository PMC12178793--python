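import numpy as np
import pytest

from credyn.catalog import ElementCatalog, ElementRecord, GeneModel, GenomicInterval


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_gene(gene_id, chrom, start, end, strand):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand, gene_id))


def make_element(eid, chrom, start, end, element_class="enhancer",
                 subclass="distal", strand="."):
    sub = subclass if element_class == "enhancer" else "not_applicable"
    return ElementRecord(GenomicInterval(chrom, start, end, strand, eid), element_class, sub)


@pytest.fixture
def tiny_catalog():
    return ElementCatalog(
        [
            make_element("e1", "chr1", 100, 500),
            make_element("e2", "chr1", 2000, 2400, subclass="proximal"),
            make_element("e3", "chr2", 300, 700),
            make_element("p1", "chr1", 5000, 6000, element_class="promoter"),
            make_element("p2", "chr2", 1000, 2000, element_class="promoter"),
        ]
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=500, max_len=60):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length, id=f"iv{i}"))
    return out


def base_set(iv):
    """Per-base oracle representation of an interval."""
    return {(iv.chrom, b) for b in range(iv.start, iv.end)}


def brute_force_overlaps(a, others):
    """Oracle: does interval a share >= 1 base with any interval in others."""
    bases = base_set(a)
    return any(bases & base_set(o) for o in others)
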