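"""Generator determinism, planted-feature geometry, and truth-ledger slicing."""

import numpy as np
import pytest

from micmob.core_io import ContractViolation, GeneModel, Genome, translate
from micmob.synthgen import (PlantRequest, SyntheticSpec, diverge,
                             generate_genome, make_orf_with_sequons,
                             plant_composite_transposon, plant_mmej_scenario,
                             plant_repeat_island, plant_tandem_dup,
                             plant_large_duplication, random_dna,
                             simulate_population_reads)


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


class TestGenerateGenome:
    def test_no_plants(self):
        spec = SyntheticSpec(seed=7, genome_length=1000)
        g, truth = generate_genome(spec)
        assert len(g) == 1000 and truth.features == []

    def test_determinism(self):
        spec = lambda: SyntheticSpec(seed=42, genome_length=30_000, planted=[
            PlantRequest("repeat_island", {"repeat_len": 60, "island_len": 9_000})])
        g1, t1 = generate_genome(spec())
        g2, t2 = generate_genome(spec())
        assert g1.seq == g2.seq
        assert t1.features[0].coords == t2.features[0].coords

    def test_gc_within_binomial_bound(self):
        g, _ = generate_genome(SyntheticSpec(seed=3, genome_length=100_000))
        gc = (g.seq.count("G") + g.seq.count("C")) / len(g)
        assert abs(gc - 0.33) < 0.01     # ~6.7 sigma for n=1e5

    def test_infeasible_packing_rejected(self):
        spec = SyntheticSpec(seed=1, genome_length=5_000, planted=[
            PlantRequest("repeat_island", {"island_len": 12_000})])
        with pytest.raises(ContractViolation):
            generate_genome(spec)

    def test_truth_slices_match_sequences(self):
        spec = SyntheticSpec(seed=11, genome_length=80_000, planted=[
            PlantRequest("repeat_island", {"repeat_len": 221, "island_len": 12_000,
                                           "mismatches": 2}),
            PlantRequest("composite_transposon", {}),
        ])
        g, truth = generate_genome(spec)
        for feat in truth.features:
            assert feat.verify(g)


class TestRepeatIsland:
    def test_geometry_and_identical_copies(self, island_scenario):
        g, t = island_scenario
        (s1, e1), (s2, e2) = t.coords["repeat1"], t.coords["repeat2"]
        assert e1 - s1 == e2 - s2 == 221
        assert t.coords["island"][1] - t.coords["island"][0] == 12_000
        assert g.slice(s1, e1) == g.slice(s2, e2)
        # cargo distance between copy midpoints is island - repeat
        assert (s2 + e2) // 2 - (s1 + e1) // 2 == 12_000 - 221

    def test_mismatch_count_exact(self, bg50k):
        g, t = plant_repeat_island(bg50k, 221, 12_000, mismatches=1, seed=3)
        r1 = g.slice(*t.coords["repeat1"])
        r2 = g.slice(*t.coords["repeat2"])
        assert hamming(r1, r2) == 1

    def test_cargo_carries_six_core_orfs(self, island_scenario):
        g, t = island_scenario
        cds = [f for f in g.features if f.kind == "CDS"
               and t.coords["cargo"][0] <= f.start < t.coords["cargo"][1]]
        assert len(cds) == 6
        for f in cds:
            prot = translate(g.slice(f.start, f.end))
            assert "*" not in prot and prot[0] == "M"


class TestCompositeTransposon:
    def test_tsd_flanks_and_itrs(self, bg20k):
        from micmob.core_io import revcomp
        g, t = plant_composite_transposon(bg20k, itr_len=25, itr_mismatches=0,
                                          tsd_len=8, seed=2)
        (e1s, e1e), (e2s, e2e) = t.coords["element1"], t.coords["element2"]
        assert g.seq[e1s - 8:e1s] == g.seq[e2e:e2e + 8] == t.expected["tsd"]
        el1 = g.slice(e1s, e1e)
        assert el1[:25] == revcomp(el1[-25:])

    def test_no_per_element_tsd(self, bg20k):
        g, t = plant_composite_transposon(bg20k, seed=4)
        for key in ("element1", "element2"):
            s, e = t.coords[key]
            # exhaustive flank comparison over the whole TSD length range
            for L in range(4, 17):
                assert g.seq[s - L:s] != g.seq[e:e + L]


class TestMmejScenario:
    def test_motifs_unique_and_at_truth(self, mmej_scenario):
        d, r, t = mmej_scenario
        m1, m2 = t.sequences["motif1"], t.sequences["motif2"]
        assert len(m1) == len(m2) == 9 and m1 != m2
        for genome, key1, key2 in ((d, "donor_motif1", "donor_motif2"),
                                   (r, "recipient_motif1", "recipient_motif2")):
            assert genome.slice(*t.coords[key1]) == m1
            assert genome.slice(*t.coords[key2]) == m2
            assert genome.seq.count(m1) == 1 and genome.seq.count(m2) == 1

    def test_short_motifs_refused(self, bg20k):
        with pytest.raises(ContractViolation):
            plant_mmej_scenario(bg20k, bg20k, motif_len=4, seed=1)

    def test_recipient_gene_translates_cleanly(self, mmej_scenario):
        _, r, t = mmej_scenario
        gene = next(f for f in r.features if f.kind == "CDS")
        prot = translate(r.slice(gene.start, gene.end))
        assert "*" not in prot and prot.startswith("M")


class TestTandemDup:
    @pytest.fixture()
    def host(self):
        rng = np.random.default_rng(8)
        orf = make_orf_with_sequons(rng, n_sequons=3)
        seq = random_dna(rng, 2_000) + orf + random_dna(rng, 500)
        return Genome("h", seq, features=[
            GeneModel("fohB", 2_000, 2_000 + len(orf), "+", "CDS")])

    def test_frameshifting_flag(self, host):
        _, t37 = plant_tandem_dup(host, "fohB", dup_len=37, dup_offset=99, seed=1)
        _, t36 = plant_tandem_dup(host, "fohB", dup_len=36, dup_offset=99, seed=1)
        assert t37.expected["frameshift"] is True
        assert t36.expected["frameshift"] is False

    def test_premature_stop_when_frameshifting(self, host):
        _, t = plant_tandem_dup(host, "fohB", dup_len=37, dup_offset=99, seed=2)
        wt = translate(t.expected["cds_before"])
        mut_full = translate(t.expected["cds_after"])
        assert "*" not in wt
        assert "*" in mut_full and mut_full.index("*") < len(wt)


class TestDiverge:
    def test_zero_rate_identity(self, bg20k):
        assert diverge(bg20k, 0.0, 0.0, seed=1).seq == bg20k.seq

    def test_substitution_rate_bound(self):
        rng = np.random.default_rng(2)
        g = Genome("g", random_dna(rng, 100_000))
        d = diverge(g, 0.02, 0.0, seed=3)
        ident = 1 - hamming(g.seq, d.seq) / len(g)
        assert abs(ident - 0.98) < 0.002   # ~4.5 sigma binomial bound

    def test_indels_change_length(self, bg20k):
        d = diverge(bg20k, 0.0, 0.001, seed=4)
        assert len(d) != len(bg20k)


class TestPopulationReads:
    @pytest.fixture()
    def pair(self):
        rng = np.random.default_rng(0)
        bg = Genome("bg", random_dna(rng, 40_000))
        carrier, t = plant_repeat_island(bg, 221, 12_000, seed=4)
        return carrier, bg, tuple(t.coords["island"])

    def _depth(self, track, region):
        bs = track.bin_size
        inside = [d for i, d in enumerate(track.depth)
                  if i * bs >= region[0] and (i + 1) * bs <= region[1]]
        outside = [d for i, d in enumerate(track.depth)
                   if (i + 1) * bs <= region[0] or i * bs >= region[1]]
        return np.mean(inside), np.mean(outside)

    def test_full_carriage(self, pair):
        carrier, bg, region = pair
        _, track = simulate_population_reads(carrier, bg, 1.0, 50, seed=1)
        din, dout = self._depth(track, region)
        assert abs(din / dout - 1.0) < 0.1

    def test_zero_carriage(self, pair):
        carrier, bg, region = pair
        _, track = simulate_population_reads(carrier, bg, 0.0, 50, seed=2)
        din, _ = self._depth(track, region)
        assert din == 0.0

    def test_one_third_within_poisson_bound(self, pair):
        carrier, bg, region = pair
        _, track = simulate_population_reads(carrier, bg, 1 / 3, 100, seed=3)
        din, dout = self._depth(track, region)
        # island spans ~11 full kb bins at ~33x: SE of the ratio ~ 0.02
        se = np.sqrt((100 / 3) * 150 / 1_000 / 11) / 100
        assert abs(din / dout - 1 / 3) < 3 * se + 0.01

    def test_large_duplication_plant(self):
        rng = np.random.default_rng(5)
        g = Genome("g", random_dna(rng, 80_000))
        g2, t = plant_large_duplication(g, dup_len=20_000, mismatches=1, seed=6)
        c1 = g2.slice(*t.coords["copy1"])
        c2 = g2.slice(*t.coords["copy2"])
        assert hamming(c1, c2) == 1 and len(c1) == 20_000
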