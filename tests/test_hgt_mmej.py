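"""Microhomology pairing, integration prediction, and coding consequences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micmob.core_io import ContractViolation, GeneModel, Genome, translate
from micmob.hgt_mmej import (analyze_tandem_dup, find_microhomology_pairs,
                             orf_consequences, predict_integration)
from micmob.repeat_mobilome import excise_island, find_direct_repeat_islands
from micmob.synthgen import (make_orf, make_orf_with_sequons,
                             plant_mmej_scenario, plant_tandem_dup, random_dna)


def _planted_pair(pairs, truth):
    want = (truth.coords["donor_motif1"][0], truth.coords["donor_motif2"][0],
            truth.coords["recipient_motif1"][0],
            truth.coords["recipient_motif2"][0])
    return [p for p in pairs
            if (p.donor_pos1, p.donor_pos2,
                p.recipient_pos1, p.recipient_pos2) == want]


class TestMotifSearch:
    def test_planted_nine_mer_found(self, mmej_scenario):
        d, r, t = mmej_scenario
        pairs = find_microhomology_pairs(d, r, region=tuple(t.coords["recipient_gene"]))
        hits = _planted_pair(pairs, t)
        assert len(hits) == 1 and hits[0].length == 9
        assert hits[0].motif1 == t.sequences["motif1"]

    def test_length_four_not_reported(self):
        # genomes small enough that a 4-mer can occur uniquely at all
        rng = np.random.default_rng(31)
        donor = Genome("d", random_dna(rng, 400))
        rec = Genome("r", random_dna(rng, 400))
        d2, r2, t = plant_mmej_scenario(donor, rec, motif_len=4,
                                        cargo_len=800, seed=31,
                                        enforce_mmej_range=False)
        pairs = find_microhomology_pairs(d2, r2,
                                         region=tuple(t.coords["recipient_gene"]))
        assert _planted_pair(pairs, t) == []

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        """Unique maximal shared substrings equal an O(n^2) enumeration."""
        rng = np.random.default_rng(seed)
        d = random_dna(rng, 160)
        shared = random_dna(rng, 7)
        r = random_dna(rng, 80) + shared + random_dna(rng, 80)
        dd = d[:60] + shared + d[60:]
        donor, rec = Genome("d", dd), Genome("r", r)

        def occs(hay, needle):
            out, k = [], hay.find(needle)
            while k >= 0:
                out.append(k)
                k = hay.find(needle, k + 1)
            return out

        # oracle: every (i,j,L) with 5<=L<=25, equal substrings, maximal both
        # ends, motif unique in both sequences
        oracle = set()
        for L in range(5, 26):
            for i in range(len(dd) - L + 1):
                sub = dd[i:i + L]
                if len(occs(dd, sub)) != 1 or len(occs(r, sub)) != 1:
                    continue
                j = r.find(sub)
                if j < 0:
                    continue
                if i > 0 and j > 0 and dd[i - 1] == r[j - 1]:
                    continue
                if i + L < len(dd) and j + L < len(r) and dd[i + L] == r[j + L]:
                    continue
                oracle.add((i, j, L))
        pairs = find_microhomology_pairs(donor, rec, max_span=(10_000, 10_000))
        got = set()
        for p in pairs:
            got.add((p.donor_pos1, p.recipient_pos1, len(p.motif1)))
            got.add((p.donor_pos2, p.recipient_pos2, len(p.motif2)))
        # every motif of every reported pair is an oracle match, and every
        # orderable oracle match pair is reported
        assert got <= oracle
        expected_pairs = {
            (a, b) for a in oracle for b in oracle
            if a[0] + a[2] <= b[0] and a[1] + a[2] <= b[1]
            and dd[a[0]:a[0] + a[2]] != dd[b[0]:b[0] + b[2]]}
        reported = {((p.donor_pos1, p.recipient_pos1, len(p.motif1)),
                     (p.donor_pos2, p.recipient_pos2, len(p.motif2)))
                    for p in pairs}
        assert reported == expected_pairs

    def test_ordering_longest_first(self, mmej_scenario):
        d, r, t = mmej_scenario
        pairs = find_microhomology_pairs(d, r, region=tuple(t.coords["recipient_gene"]))
        lens = [min(len(p.motif1), len(p.motif2)) for p in pairs]
        assert lens == sorted(lens, reverse=True)


class TestIntegration:
    def test_product_geometry_and_cross_module_recovery(self, mmej_scenario):
        d, r, t = mmej_scenario
        pairs = find_microhomology_pairs(d, r, region=tuple(t.coords["recipient_gene"]))
        pair = _planted_pair(pairs, t)[0]
        pred = predict_integration(r, d, pair)
        rep_len = pred.new_repeats[0][1] - pred.new_repeats[0][0]
        assert rep_len == 221          # 212 bp inter-motif + 9 bp motif
        cargo = d.seq[pair.donor_cargo[0]:pair.donor_cargo[1]]
        assert cargo in pred.product.seq
        calls = find_direct_repeat_islands(pred.product)
        assert len(calls) == 1
        assert (calls[0].repeat1, calls[0].repeat2) == pred.new_repeats

    def test_excision_inverts_integration(self, mmej_scenario):
        d, r, t = mmej_scenario
        pairs = find_microhomology_pairs(d, r, region=tuple(t.coords["recipient_gene"]))
        pred = predict_integration(r, d, _planted_pair(pairs, t)[0])
        isl = find_direct_repeat_islands(pred.product)[0]
        chrom, _ = excise_island(pred.product, isl)
        assert chrom.seq == r.seq

    def test_overlapping_recipient_motifs_refused(self, mmej_scenario):
        d, r, t = mmej_scenario
        pairs = find_microhomology_pairs(d, r, region=tuple(t.coords["recipient_gene"]))
        pair = _planted_pair(pairs, t)[0]
        pair.recipient_pos2 = pair.recipient_pos1 + 2
        with pytest.raises(ContractViolation):
            predict_integration(r, d, pair)


class TestOrfConsequences:
    def test_cterm_tetrapeptide_to_dipeptide(self, mmej_scenario):
        d, r, t = mmej_scenario
        pairs = find_microhomology_pairs(d, r, region=tuple(t.coords["recipient_gene"]))
        pred = predict_integration(r, d, _planted_pair(pairs, t)[0])
        genes = [f for f in r.features if f.kind == "CDS"]
        cons = orf_consequences(r, pred.product, genes)
        ev = [c for c in cons if c.event == "cterm_replaced"]
        assert len(ev) == 1
        assert ev[0].detail["old_len"] == 4 and ev[0].detail["new_len"] == 2

    def test_junction_stop_gained(self):
        rng = np.random.default_rng(7)
        orf = make_orf(rng, 120)
        before = Genome("b", random_dna(rng, 500) + orf + random_dna(rng, 200),
                        features=[GeneModel("g", 500, 500 + len(orf), "+", "CDS")])
        # insert an in-frame TAA 30 codons into the gene
        cut = 500 + 90
        after = Genome("a", before.seq[:cut] + "TAATAA" + before.seq[cut:])
        cons = orf_consequences(before, after,
                                [f for f in before.features if f.kind == "CDS"])
        assert any(c.event == "stop_gained" for c in cons)

    def test_synonymous_edit_no_consequences(self):
        rng = np.random.default_rng(8)
        orf = "ATG" + "CTT" * 50 + "TAA"    # Leu repeats
        before = Genome("b", random_dna(rng, 300) + orf + random_dna(rng, 100),
                        features=[GeneModel("g", 300, 300 + len(orf), "+", "CDS")])
        seq = before.seq[:330] + "CTG" + before.seq[333:]   # Leu -> Leu
        after = Genome("a", seq)
        cons = orf_consequences(before, after,
                                [f for f in before.features if f.kind == "CDS"])
        assert cons == []

    def test_frameshift_classified(self):
        rng = np.random.default_rng(9)
        orf = make_orf(rng, 150)
        before = Genome("b", random_dna(rng, 400) + orf + random_dna(rng, 100),
                        features=[GeneModel("g", 400, 400 + len(orf), "+", "CDS")])
        after = Genome("a", before.seq[:460] + "AC" + before.seq[460:])
        cons = orf_consequences(before, after,
                                [f for f in before.features if f.kind == "CDS"])
        assert any(c.event == "frameshift" for c in cons)


class TestTandemDup:
    @pytest.fixture()
    def host(self):
        rng = np.random.default_rng(12)
        orf = make_orf_with_sequons(rng, n_sequons=5)
        return Genome("h", random_dna(rng, 1_000) + orf + random_dna(rng, 300),
                      features=[GeneModel("fohB", 1_000, 1_000 + len(orf),
                                          "+", "CDS")]), orf

    def test_frameshifting_37bp_dup(self, host):
        genome, orf = host
        _, t = plant_tandem_dup(genome, "fohB", dup_len=37, dup_offset=60, seed=2)
        rec = analyze_tandem_dup(t.expected["cds_before"], t.expected["cds_after"])
        assert rec.length == 37 and rec.frameshift
        assert rec.premature_stop_codon is not None
        assert len(rec.lost_sequons) >= 1

    def test_in_frame_36bp_dup(self, host):
        genome, orf = host
        _, t = plant_tandem_dup(genome, "fohB", dup_len=36, dup_offset=60, seed=2)
        rec = analyze_tandem_dup(t.expected["cds_before"], t.expected["cds_after"])
        assert rec.length == 36 and not rec.frameshift
        assert rec.premature_stop_codon is None
        assert rec.lost_sequons == []

    @pytest.mark.parametrize("dup_len,offset", [(37, 45), (10, 12), (24, 99)])
    def test_against_edit_script_oracle(self, host, dup_len, offset):
        genome, orf = host
        _, t = plant_tandem_dup(genome, "fohB", dup_len=dup_len,
                                dup_offset=offset, seed=3)
        before, after = t.expected["cds_before"], t.expected["cds_after"]
        rec = analyze_tandem_dup(before, after)
        assert rec.length == dup_len
        # leftmost equivalent placement oracle by direct reconstruction
        placements = [i for i in range(dup_len, len(before) + 1)
                      if after == before[:i] + before[i - dup_len:i] + before[i:]]
        assert rec.offset == min(placements) - dup_len

    def test_no_dup_returns_none(self, host):
        genome, orf = host
        assert analyze_tandem_dup(orf, orf) is None
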