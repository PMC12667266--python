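"""Protein alignment, cluster comparison, core extraction, split genes."""

import numpy as np
import pytest

from micmob.clusters import (GeneCluster, align_proteins, compare_clusters,
                             detect_split_genes, extract_core)
from micmob.core_io import ContractViolation, GeneModel, translate
from micmob.synthgen import make_orf

AAS = "ARNDCQEGHILKMFPSWYV"


def _mutate(rng, prot, rate=0.05):
    out = list(prot)
    for i in range(1, len(out)):
        if rng.random() < rate:
            out[i] = AAS[int(rng.integers(len(AAS)))]
    return "".join(out)


def _cluster(genome_id, prots, prefix):
    genes, pos = [], 0
    for name, p in prots:
        L = 3 * (len(p) + 1)
        genes.append(GeneModel(f"{prefix}{name}", pos, pos + L, "+", "CDS",
                               translation=p))
        pos += L + 80
    return GeneCluster(genome_id, genes)


@pytest.fixture(scope="module")
def core_proteins():
    rng = np.random.default_rng(17)
    names = ["fohA", "fohB", "fohD", "tatA", "tatC", "fohE"]
    lens = [380, 240, 140, 70, 230, 170]
    return {n: translate(make_orf(rng, L)) for n, L in zip(names, lens)}


@pytest.fixture(scope="module")
def split_pair(core_proteins):
    """Mic1c10-like 6-gene cluster and an IM1-like cluster with fohE split."""
    rng = np.random.default_rng(18)
    c1 = _cluster("mic1c10", list(core_proteins.items()), "mic_")
    parts = []
    for n, p in list(core_proteins.items())[:5]:
        parts.append((n, _mutate(rng, p)))
    pe = core_proteins["fohE"]
    parts.append(("fohE", "M" + _mutate(rng, pe[1:85])))
    parts.append(("fohEp", "M" + _mutate(rng, pe[85:])))
    c2 = _cluster("im1", parts, "im1_")
    return c1, c2


class TestAlignProteins:
    def test_identical(self):
        ln = align_proteins("MKVLWAALLVT", "MKVLWAALLVT")
        assert ln.identity == 100.0
        assert ln.coverage_a == ln.coverage_b == 1.0

    def test_single_substitution(self):
        assert align_proteins("MKKL", "MKRL").identity == 75.0

    def test_constructed_93_percent(self):
        rng = np.random.default_rng(1)
        p = "".join(AAS[int(rng.integers(len(AAS)))] for _ in range(100))
        q = list(p)
        for i in rng.choice(100, size=7, replace=False):
            q[i] = next(a for a in AAS if a != q[i])
        assert align_proteins(p, "".join(q)).identity == 93.0

    def test_partial_homolog_coverage(self):
        rng = np.random.default_rng(2)
        p = "".join(AAS[int(rng.integers(len(AAS)))] for _ in range(200))
        half = p[:100]
        ln = align_proteins(p, half)
        assert ln.coverage_b > 0.95 and ln.coverage_a == pytest.approx(0.5, abs=0.05)


class TestCompareClusters:
    def test_cluster_vs_itself(self, split_pair):
        c1, _ = split_pair
        rep = compare_clusters(c1, c1)
        assert rep["synteny"] == 1.0
        own = [l for l in rep["links"] if l.gene_a == l.gene_b]
        assert len(own) == len(c1.genes)
        assert all(l.identity == 100.0 and l.reciprocal for l in own)

    def test_seven_query_genes_link_six_reference_genes(self, split_pair):
        c1, c2 = split_pair
        rep = compare_clusters(c2, c1)
        assert len({l.gene_a for l in rep["links"]}) == 7
        assert len({l.gene_b for l in rep["links"]}) == 6

    def test_unrelated_clusters_no_links(self):
        rng = np.random.default_rng(3)
        a = _cluster("a", [(f"g{i}", "M" + "".join(
            AAS[int(rng.integers(len(AAS)))] for _ in range(150)))
            for i in range(4)], "a_")
        b = _cluster("b", [(f"g{i}", "M" + "".join(
            AAS[int(rng.integers(len(AAS)))] for _ in range(150)))
            for i in range(4)], "b_")
        assert compare_clusters(a, b)["links"] == []


class TestSplitGenes:
    def test_split_called(self, split_pair):
        c1, c2 = split_pair
        rep = compare_clusters(c1, c2)
        calls = detect_split_genes(rep["links"], c1, c2)
        assert calls == [("mic_fohE", ["im1_fohE", "im1_fohEp"])]

    def test_swapped_parts_still_called(self, core_proteins):
        rng = np.random.default_rng(19)
        c1 = _cluster("one", list(core_proteins.items()), "one_")
        pe = core_proteins["fohE"]
        parts = [(n, _mutate(rng, p)) for n, p in list(core_proteins.items())[:5]]
        # C-terminal part listed before the N-terminal part
        parts.append(("fohEp", "M" + _mutate(rng, pe[85:])))
        parts.append(("fohE", "M" + _mutate(rng, pe[1:85])))
        c2 = _cluster("two", parts, "two_")
        rep = compare_clusters(c1, c2)
        calls = detect_split_genes(rep["links"], c1, c2)
        assert ("one_fohE", ["two_fohEp", "two_fohE"]) in calls

    def test_two_full_paralogs_not_split(self, core_proteins):
        rng = np.random.default_rng(20)
        pa = core_proteins["fohA"]
        c1 = _cluster("one", [("fohA", pa)], "one_")
        c2 = _cluster("two", [("fohA1", _mutate(rng, pa)),
                              ("fohA2", _mutate(rng, pa))], "two_")
        rep = compare_clusters(c1, c2)
        assert detect_split_genes(rep["links"], c1, c2) == []


class TestExtractCore:
    def test_three_identical_clusters(self, core_proteins):
        cs = [_cluster(f"s{i}", list(core_proteins.items()), f"s{i}_")
              for i in range(3)]
        core = extract_core(cs)
        assert len(core.groups) == 6

    def test_split_counts_as_single_membership(self, split_pair):
        c1, c2 = split_pair
        core = extract_core([c1, c2])
        assert len(core.groups) == 6
        fohe = next(g for g in core.groups if "mic_fohE" in g.get("mic1c10", []))
        assert sorted(fohe["im1"]) == ["im1_fohE", "im1_fohEp"]
        assert ("mic_fohE", ["im1_fohE", "im1_fohEp"]) in core.split_gene_calls

    def test_missing_gene_drops_to_near_core(self, core_proteins):
        rng = np.random.default_rng(21)
        full = list(core_proteins.items())
        cs = [_cluster("s0", full, "s0_"), _cluster("s1", full, "s1_"),
              _cluster("s2", full[:-1], "s2_")]       # fohE missing
        core = extract_core(cs)
        assert len(core.groups) == 5
        assert any("s0_fohE" in g.get("s0", []) for g in core.near_core)

    def test_core_size_monotone_in_clusters(self, core_proteins, split_pair):
        c1, c2 = split_pair
        rng = np.random.default_rng(22)
        third = _cluster("x1", [(n, _mutate(rng, p)) for n, p in
                                list(core_proteins.items())[:4]], "x1_")
        small = extract_core([c1, c2])
        bigger = extract_core([c1, c2, third])
        assert len(bigger.groups) <= len(small.groups)

    def test_requires_two_clusters(self, split_pair):
        with pytest.raises(ContractViolation):
            extract_core([split_pair[0]])
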