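"""Synthetic genomes with planted mobile-element features and a truth ledger.

The generator emulates the genomic situations the detectors are built for:
a low-GC (33 %) archaeal chromosome carrying a ~12 kb island bounded by
near-identical 221 bp direct repeats, a composite transposon pair with ITRs
and a single 8 nt target-site duplication flanking the composite, a
donor/recipient pair sharing two short microhomology motifs inside a
conserved gene, a frameshifting tandem duplication inside an ORF, a large
direct duplication, diverged strain pairs, and mixed populations in which
only a fraction of genome copies carry the island.

Every planted feature is recorded in a :class:`PlantedFeature` whose
coordinates slice out exactly the recorded sequences from the emitted genome
— the package's primary test oracle.

Planted boundaries are "clean": the generator adjusts the single background
base adjacent to each planted repeat/ITR/motif copy so that a seed-and-extend
detector cannot extend a copy beyond its planted extent by a chance match.
Real data offers no such guarantee; detectors must not rely on it (and do
not — it only makes exact-boundary assertions in tests meaningful).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .core_io import ContractViolation, DepthTrack, GeneModel, Genome, revcomp, translate

BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
_STOPS = {"TAA", "TAG", "TGA"}


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_dna(rng, n: int, gc: float = 0.33) -> str:
    """i.i.d. background sequence at the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _other_base(rng, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def mutate_positions(rng, seq: str, k: int) -> tuple[str, list[int]]:
    """Substitute k random distinct positions to a different base."""
    if k == 0:
        return seq, []
    pos = sorted(rng.choice(len(seq), size=k, replace=False).tolist())
    s = list(seq)
    for p in pos:
        s[p] = _other_base(rng, s[p])
    return "".join(s), pos


def make_orf(rng, aa_len: int, gc: float = 0.33, start: str = "ATG") -> str:
    """An ORF of aa_len residues: start codon, aa_len-1 sense codons, one stop."""
    codons = [start]
    while len(codons) < aa_len:
        c = random_dna(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def reverse_translate(rng, protein: str) -> str:
    """A random coding sequence for *protein* (table 11, ATG start, TAA stop)."""
    from Bio.Data.CodonTable import unambiguous_dna_by_id
    table = unambiguous_dna_by_id[11]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for i, aa in enumerate(protein):
        if i == 0 and aa == "M":
            out.append("ATG")
        else:
            cands = sorted(by_aa[aa])
            out.append(cands[int(rng.integers(len(cands)))])
    out.append("TAA")
    return "".join(out)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class PlantedFeature:
    kind: str
    coords: dict            # named 0-based half-open intervals
    sequences: dict         # named sequences (repeats, ITRs, TSD, motifs, ...)
    params: dict
    expected: dict          # summary of the expected detector output

    def verify(self, genome: Genome) -> bool:
        """Every named interval with a same-named sequence must slice exactly."""
        ok = True
        for name, iv in self.coords.items():
            if name in self.sequences and isinstance(iv, (tuple, list)) and len(iv) == 2:
                ok &= genome.slice(*iv) == self.sequences[name]
        return ok


@dataclass
class PlantedTruth:
    features: list = field(default_factory=list)

    def of_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    def to_json(self) -> str:
        return json.dumps([asdict(f) for f in self.features], indent=1)


@dataclass
class SyntheticSpec:
    seed: int
    genome_length: int = 1_700_000
    gc: float = 0.33
    planted: list = field(default_factory=list)   # list of PlantRequest

    def __post_init__(self):
        if not (0 < self.gc < 1):
            raise ContractViolation("gc must be in (0,1)")


@dataclass
class PlantRequest:
    kind: str
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome surgery helpers
# ---------------------------------------------------------------------------

def _insert(genome: Genome, pos: int, ins: str, new_features: Sequence[GeneModel] = ()) -> Genome:
    """Insert ``ins`` at pos; shift downstream features; add new ones."""
    if not (0 <= pos <= len(genome)):
        raise ContractViolation(f"insert position {pos} outside genome")
    L = len(ins)
    feats = []
    for f in genome.features:
        if f.end <= pos:
            feats.append(f)
        elif f.start >= pos:
            feats.append(GeneModel(f.id, f.start + L, f.end + L, f.strand,
                                   f.kind, f.product, f.translation, dict(f.attributes)))
        else:  # spans the insertion point: extend
            feats.append(GeneModel(f.id, f.start, f.end + L, f.strand,
                                   f.kind, f.product, f.translation, dict(f.attributes)))
    feats.extend(new_features)
    return Genome(genome.id, genome.seq[:pos] + ins + genome.seq[pos:],
                  genome.topology, sorted(feats, key=lambda f: f.start))


def _set_base(seq: str, pos: int, base: str) -> str:
    return seq[:pos] + base + seq[pos + 1:]


def _guard(rng, seq: str, pos: int, avoid: str) -> str:
    """Force seq[pos] to differ from ``avoid`` (clean planted boundary)."""
    if 0 <= pos < len(seq) and seq[pos] == avoid:
        return _set_base(seq, pos, _other_base(rng, avoid))
    return seq


def _guard_multi(rng, seq: str, pos: int, avoid: set) -> str:
    """Force seq[pos] outside the ``avoid`` set of bases."""
    if 0 <= pos < len(seq) and seq[pos] in avoid:
        choices = [b for b in "ACGT" if b not in avoid]
        return _set_base(seq, pos, choices[int(rng.integers(len(choices)))])
    return seq


# ---------------------------------------------------------------------------
# plants
# ---------------------------------------------------------------------------

#: gene complement of the miniature conserved core planted inside island cargo
CORE_GENES = [("fohA", 380), ("fohB", 240), ("fohD", 140),
              ("tatA", 70), ("tatC", 230), ("fohE", 170)]


def _core_cargo(rng, cargo_len: int, gc: float, id_prefix: str) -> tuple[str, list]:
    """Cargo sequence of exactly cargo_len bp carrying a 6-ORF mini core."""
    orf_nt = sum(3 * (aa + 1) for _, aa in CORE_GENES)
    n_gaps = len(CORE_GENES) + 1
    spare = cargo_len - orf_nt
    if spare < n_gaps:
        raise ContractViolation(f"cargo of {cargo_len} bp cannot hold the mini core")
    gaps = [spare // n_gaps] * n_gaps
    gaps[-1] += spare - sum(gaps)
    parts, feats, cursor = [], [], 0
    for (name, aa), gap in zip(CORE_GENES, gaps[:-1]):
        parts.append(random_dna(rng, gap, gc))
        cursor += gap
        orf = make_orf(rng, aa, gc)
        feats.append(GeneModel(f"{id_prefix}{name}", cursor, cursor + len(orf),
                               "+", "CDS", product=name,
                               translation=translate(orf)))
        parts.append(orf)
        cursor += len(orf)
    parts.append(random_dna(rng, gaps[-1], gc))
    return "".join(parts), feats


def plant_repeat_island(genome: Genome, repeat_len: int = 221,
                        island_len: int = 12_000, mismatches: int = 0,
                        seed=0, pos: Optional[int] = None,
                        gc: float = 0.33) -> tuple[Genome, PlantedFeature]:
    """Insert repeat + cargo + repeat; island span (repeat-inclusive) == island_len.

    The cargo carries a miniature 6-ORF conserved-core arrangement for the
    cluster-comparison tests. ``mismatches`` substitutions are placed in the
    second repeat copy.
    """
    rng = _rng(seed)
    if repeat_len < 20:
        raise ContractViolation("repeat_len must be >= 20")
    cargo_len = island_len - 2 * repeat_len
    if cargo_len <= 0:
        raise ContractViolation("island_len must exceed twice the repeat length")
    if pos is None:
        pos = int(rng.integers(1, len(genome) - 1))
    repeat = random_dna(rng, repeat_len, gc)
    cargo, feats = _core_cargo(rng, cargo_len, gc, f"{genome.id}_")
    repeat2, mm_pos = mutate_positions(rng, repeat, mismatches)
    # clean boundaries: three background bases on each side are forced to
    # mismatch the corresponding cargo-side flank of the other copy, so
    # seed-and-extend cannot creep past the planted repeat boundaries
    seq = genome.seq
    for i in range(3):
        seq = _guard(rng, seq, pos - 1 - i, cargo[cargo_len - 1 - i])
        seq = _guard(rng, seq, pos + i, cargo[i])
    genome = Genome(genome.id, seq, genome.topology, genome.features)
    ins = repeat + cargo + repeat2
    feats = [GeneModel(f.id, f.start + pos + repeat_len, f.end + pos + repeat_len,
                       f.strand, f.kind, f.product, f.translation)
             for f in feats]
    feats.append(GeneModel(f"{genome.id}_dr1", pos, pos + repeat_len, "+", "repeat_region"))
    feats.append(GeneModel(f"{genome.id}_dr2", pos + island_len - repeat_len,
                           pos + island_len, "+", "repeat_region"))
    out = _insert(genome, pos, ins, feats)
    truth = PlantedFeature(
        kind="repeat_island",
        coords={"repeat1": (pos, pos + repeat_len),
                "repeat2": (pos + island_len - repeat_len, pos + island_len),
                "island": (pos, pos + island_len),
                "cargo": (pos + repeat_len, pos + island_len - repeat_len)},
        sequences={"repeat1": repeat, "repeat2": repeat2},
        params={"repeat_len": repeat_len, "island_len": island_len,
                "mismatches": mismatches},
        expected={"repeat_len": repeat_len, "mismatches": mismatches,
                  "mismatch_positions": mm_pos,
                  "island_len": island_len, "cargo_len": cargo_len})
    assert truth.verify(out)
    return out, truth


def _transposon_element(rng, itr: str, itr_mismatches: int, element_len: int,
                        gc: float, tag: str) -> tuple[str, dict]:
    """ITR + reverse-strand transposase CDS + filler + revcomp(ITR').

    Five guard bases just inside each ITR are forced to break reverse
    complementarity so the planted ITR length is exactly recoverable at the
    default mismatch tolerance. ITR copy mismatches are interior (the two
    terminal bases of an ITR stay intact).
    """
    itr_len = len(itr)
    mm = sorted(rng.choice(np.arange(1, itr_len - 1), size=itr_mismatches,
                           replace=False).tolist()) if itr_mismatches else []
    right = list(itr)
    for p in mm:
        right[p] = _other_base(rng, right[p])
    right_itr = "".join(right)
    tase = revcomp(make_orf(rng, (element_len - 2 * itr_len - 60) // 3 - 2, gc))
    body = tase + random_dna(rng, element_len - 2 * itr_len - len(tase), gc)
    b = list(body)
    for i in range(5):
        want_not = revcomp(body[-1 - i])  # would pair with the far end
        if b[i] == want_not:
            b[i] = _other_base(rng, want_not)
    body = "".join(b)
    seq = itr + body + revcomp(right_itr)
    return seq, {"itr": itr, "itr_right": right_itr, "itr_mismatch_positions": mm,
                 "transposase_offset": itr_len, "transposase_len": len(tase),
                 "tag": tag}


def plant_composite_transposon(genome: Genome, itr_len: int = 25,
                               itr_mismatches: int = 0, tsd_len: int = 8,
                               cargo_len: int = 5_000, element_len: int = 1_300,
                               seed=0, pos: Optional[int] = None,
                               gc: float = 0.33) -> tuple[Genome, PlantedFeature]:
    """Two ITR-bounded elements flank a cargo; one tsd_len-mer is duplicated
    outside the composite and no per-element TSDs exist."""
    rng = _rng(seed)
    if pos is None:
        pos = int(rng.integers(1, len(genome) - 1))
    itr = random_dna(rng, itr_len, gc)
    e1, meta1 = _transposon_element(rng, itr, itr_mismatches, element_len, gc, "tnpA1")
    e2, meta2 = _transposon_element(rng, itr, itr_mismatches, element_len, gc, "tnpA2")
    tsd = random_dna(rng, tsd_len, gc)
    cargo, feats = _core_cargo(rng, cargo_len, gc, f"{genome.id}_tn_")

    def _no_per_element_tsd(up: str, down: str) -> bool:
        return all(up[-L:] != down[:L] for L in range(4, tsd_len + 1))

    def _no_outward_itr(left_flank: str, right_flank: str) -> bool:
        # flanking bases must not pair as a chance outward ITR extension
        return all(left_flank[-1 - i] != revcomp(right_flank[i])
                   for i in range(2))

    # redraw cargo edges until neither element carries its own TSD and no
    # element boundary can be extended outward by chance base pairing
    for _ in range(100):
        if (_no_per_element_tsd(tsd, cargo)           # element 1: up=tsd, down=cargo start
                and _no_per_element_tsd(cargo, tsd)   # element 2: up=cargo end, down=tsd
                and _no_outward_itr(tsd, cargo)
                and _no_outward_itr(cargo, tsd)):
            break
        cargo = random_dna(rng, 16, gc) + cargo[16:-16] + random_dna(rng, 16, gc)
    ins = tsd + e1 + cargo + e2 + tsd
    g = genome
    # the two tsd copies must not extend by flank chance into a longer repeat
    g = Genome(g.id, _guard(rng, g.seq, pos - 1, ins[-1]), g.topology, g.features)
    g = Genome(g.id, _guard(rng, g.seq, pos, ins[0]), g.topology, g.features)
    el1 = (pos + tsd_len, pos + tsd_len + len(e1))
    el2_start = pos + tsd_len + len(e1) + len(cargo)
    el2 = (el2_start, el2_start + len(e2))
    shifted = [GeneModel(f.id, f.start + el1[1], f.end + el1[1], f.strand, f.kind,
                         f.product, f.translation) for f in feats]
    for iv, meta in ((el1, meta1), (el2, meta2)):
        shifted.append(GeneModel(f"{genome.id}_{meta['tag']}",
                                 iv[0] + meta["transposase_offset"],
                                 iv[0] + meta["transposase_offset"] + meta["transposase_len"],
                                 "-", "CDS", product="transposase"))
        shifted.append(GeneModel(f"{genome.id}_{meta['tag']}_element", iv[0], iv[1],
                                 "+", "mobile_element"))
    out = _insert(g, pos, ins, shifted)
    truth = PlantedFeature(
        kind="composite_transposon",
        coords={"tsd1": (pos, pos + tsd_len), "element1": el1,
                "cargo": (el1[1], el2[0]), "element2": el2,
                "tsd2": (el2[1], el2[1] + tsd_len),
                "composite": (el1[0], el2[1])},
        sequences={"tsd1": tsd, "tsd2": tsd, "element1": e1, "element2": e2,
                   "itr": itr},
        params={"itr_len": itr_len, "itr_mismatches": itr_mismatches,
                "tsd_len": tsd_len, "cargo_len": len(cargo),
                "element_len": element_len},
        expected={"tsd": tsd, "tsd_len": tsd_len, "itr_len": itr_len,
                  "itr_mismatches": itr_mismatches,
                  "cargo": (el1[1], el2[0])})
    assert truth.verify(out)
    return out, truth


def _unique_motif(rng, length: int, contexts: Sequence[str], gc: float) -> str:
    """A motif absent from every context string (so planted copies are the
    only occurrences). For very short motifs absence is impossible in a large
    genome; the detector then has to cope with background hits, which is the
    realistic situation."""
    for _ in range(2000):
        m = random_dna(rng, length, gc)
        if all(c.count(m) == 0 and c.count(revcomp(m)) == 0 for c in contexts):
            return m
    return random_dna(rng, length, gc)


def _scrub_stops(rng, body: str, protected: list, gc: float = 0.33,
                 phase: int = 0) -> Optional[str]:
    """Remove in-frame stop codons from a codon-aligned sequence, leaving the
    ``protected`` intervals untouched; None if a stop sits fully inside one."""
    b = list(body)

    def is_protected(i: int) -> bool:
        return any(s <= i < e for s, e in protected)

    for c0 in range(phase, len(b) - 2, 3):
        guard = 0
        while "".join(b[c0:c0 + 3]) in _STOPS:
            free = [i for i in range(c0, c0 + 3) if not is_protected(i)]
            if not free or guard > 50:
                return None
            i = free[int(rng.integers(len(free)))]
            b[i] = _other_base(rng, b[i])
            guard += 1
    return "".join(b)


def plant_mmej_scenario(donor: Genome, recipient: Genome, motif_len: int = 9,
                        cargo_len: int = 2_000, inter_motif: int = 212,
                        seed=0, gc: float = 0.33,
                        enforce_mmej_range: bool = True
                        ) -> tuple[Genome, Genome, PlantedFeature]:
    """Plant two shared microhomology motifs: in the donor they flank a cargo;
    in the recipient they sit ``inter_motif`` bp apart (start-to-start) inside
    a conserved ycaO-like CDS.

    The recipient-derived direct repeats produced by
    :func:`micmob.hgt_mmej.predict_integration` then have length
    ``inter_motif + motif_len`` (221 at the defaults). The cargo's first nine
    bases are engineered so that, read in the recipient CDS frame, the mutant
    gene gains an unrelated dipeptide followed by a stop — replacing the
    original C-terminal tetrapeptide.
    """
    rng = _rng(seed)
    if enforce_mmej_range and not (5 <= motif_len <= 25):
        raise ContractViolation(
            f"motif_len {motif_len} outside the 5-25 nt microhomology range")
    if cargo_len < 12:
        raise ContractViolation("cargo too short")
    # insertion junctions can create a chance second motif occurrence; retry
    # the whole construction until each motif occurs exactly once per genome
    for _ in range(50):
        d2, r2, truth = _plant_mmej_once(donor, recipient, motif_len,
                                         cargo_len, inter_motif, rng, gc)
        m1, m2 = truth.sequences["motif1"], truth.sequences["motif2"]
        if all(g.seq.count(m) == 1 for g in (d2, r2) for m in (m1, m2)):
            return d2, r2, truth
    raise ContractViolation("could not plant unique motif occurrences")


def _plant_mmej_once(donor: Genome, recipient: Genome, motif_len: int,
                     cargo_len: int, inter_motif: int, rng, gc: float
                     ) -> tuple[Genome, Genome, PlantedFeature]:
    m1 = _unique_motif(rng, motif_len, [donor.seq, recipient.seq], gc)
    m2 = _unique_motif(rng, motif_len, [donor.seq, recipient.seq, m1], gc)

    # --- recipient: ycaO-like CDS containing m1 ... m2, m2 end on a codon
    # boundary, then exactly 4 sense codons + stop.
    o1 = 30 + (-(30 + inter_motif + motif_len) % 3)  # (o1+inter+len) % 3 == 0
    o2 = o1 + inter_motif
    head_len = o1 + inter_motif + motif_len
    tail = make_orf(rng, 5, gc)[3:-3]     # four sense codons
    protected = [(o1, o1 + motif_len), (o2, o2 + motif_len)]
    for _ in range(200):
        body = random_dna(rng, head_len, gc)
        body = body[:o1] + m1 + body[o1 + motif_len:o2] + m2 + body[o2 + motif_len:]
        body = _scrub_stops(rng, body, protected, gc=gc)
        if body is None:      # a motif itself spells an in-frame stop: redraw
            m1 = _unique_motif(rng, motif_len, [donor.seq, recipient.seq], gc)
            m2 = _unique_motif(rng, motif_len, [donor.seq, recipient.seq, m1], gc)
            continue
        cds = "ATG" + body + tail + "TAA"
        prot = translate(cds)
        if "*" not in prot and cds.count(m1) == 1 and cds.count(m2) == 1:
            break
    else:
        raise ContractViolation("could not embed motifs without internal stops")
    rpos = int(rng.integers(1, len(recipient) - 1))
    gene = GeneModel(f"{recipient.id}_ycaO", rpos, rpos + len(cds), "+", "CDS",
                     product="ycaO", translation=prot)
    recipient2 = _insert(recipient, rpos, cds, [gene])
    r1 = rpos + 3 + o1          # m1 start in recipient2 (after the ATG codon)
    r2 = rpos + 3 + o2

    # --- donor: m1 + cargo + m2, cargo starting with dipeptide + stop read in
    # the recipient CDS frame (the insertion lands on a codon boundary).
    stop_head = []
    while len(stop_head) < 2:
        c = random_dna(rng, 3, gc)
        if c not in _STOPS:
            stop_head.append(c)
    cargo = "".join(stop_head) + "TAA" + random_dna(rng, cargo_len - 9, gc)
    dpos = int(rng.integers(1, len(donor) - 1))
    # guards: motif occurrences must be maximal (not extendable) in both
    # genomes, and the direct repeats of the predicted integration product
    # must end exactly at the motif boundaries
    rs = recipient2.seq
    for i in range(2):
        # avoiding T at cargo[0] keeps the engineered dipeptide codon sense
        avoid = {rs[r1 + motif_len + i], rs[r2 + motif_len + i]}
        cargo = _guard_multi(rng, cargo, i, avoid | ({"T"} if i == 0 else set()))
        cargo = _guard_multi(rng, cargo, len(cargo) - 1 - i,
                             {rs[r2 - 1 - i], rs[r1 - 1 - i]})
    dseq = donor.seq
    dseq = _guard(rng, dseq, dpos - 1, rs[r1 - 1])
    dseq = _guard(rng, dseq, dpos, rs[r2 + motif_len])
    donor = Genome(donor.id, dseq, donor.topology, donor.features)
    ins = m1 + cargo + m2
    donor2 = _insert(donor, dpos, ins,
                     [GeneModel(f"{donor.id}_cargo", dpos + motif_len,
                                dpos + motif_len + len(cargo), "+", "misc")])
    d1, d2 = dpos, dpos + motif_len + len(cargo)
    truth = PlantedFeature(
        kind="mmej_pair",
        coords={"donor_motif1": (d1, d1 + motif_len),
                "donor_motif2": (d2, d2 + motif_len),
                "donor_cargo": (d1 + motif_len, d2),
                "recipient_motif1": (r1, r1 + motif_len),
                "recipient_motif2": (r2, r2 + motif_len),
                "recipient_gene": (rpos, rpos + len(cds))},
        sequences={"motif1": m1, "motif2": m2},
        params={"motif_len": motif_len, "cargo_len": len(cargo),
                "inter_motif": inter_motif},
        expected={"repeat_len": inter_motif + motif_len,
                  "gene_id": gene.id,
                  "old_cterm_len": 4, "new_cterm_len": 2})
    return donor2, recipient2, truth


def make_orf_with_sequons(rng, n_sequons: int = 5, head_aa: int = 180,
                          tail_gap: int = 4) -> str:
    """A CDS whose translation carries ``n_sequons`` N-X-(S/T) sequons in its
    C-terminal region — a synthetic stand-in for a small-subunit hydrogenase
    gene with a hydrophilic, potentially glycosylated C-terminus."""
    aas = "ARNDCQEGHILKMFPSWYV"  # T excluded from random draw; placed explicitly
    prot = ["M"] + [aas[int(rng.integers(len(aas)))] for _ in range(head_aa - 1)]
    # scrub accidental sequons in the head
    for i in range(len(prot) - 2):
        if prot[i] == "N" and prot[i + 1] != "P" and prot[i + 2] in "ST":
            prot[i] = "Q"
    for _ in range(n_sequons):
        x = aas[int(rng.integers(len(aas)))]
        while x in "PNST":
            x = aas[int(rng.integers(len(aas)))]
        prot.extend(["N", x, "T", "G"])
    prot.extend("GKL"[: tail_gap - 1] + "E")
    return reverse_translate(rng, "".join(prot))


def plant_tandem_dup(genome: Genome, cds_id: str, dup_len: int = 37,
                     dup_offset: Optional[int] = None, seed=0
                     ) -> tuple[Genome, PlantedFeature]:
    """Duplicate dup_len bases in tandem inside the CDS at dup_offset
    (offset of the duplicated unit's start within the CDS)."""
    rng = _rng(seed)
    cds = next((f for f in genome.features if f.id == cds_id), None)
    if cds is None or cds.kind != "CDS":
        raise ContractViolation(f"no CDS with id {cds_id!r}")
    if dup_offset is None:
        dup_offset = int(rng.integers(3, cds.length // 2))
    if not (0 < dup_offset and dup_offset + dup_len < cds.length):
        raise ContractViolation("duplication does not fit inside the CDS")
    before = genome.seq[cds.start:cds.end]
    unit_start = cds.start + dup_offset
    unit = genome.seq[unit_start:unit_start + dup_len]
    out = _insert(genome, unit_start + dup_len, unit, [])
    after = out.seq[cds.start:cds.end + dup_len]
    truth = PlantedFeature(
        kind="tandem_dup_orf",
        coords={"unit": (unit_start, unit_start + dup_len),
                "copy": (unit_start + dup_len, unit_start + 2 * dup_len)},
        sequences={"unit": unit, "copy": unit},
        params={"cds_id": cds_id, "dup_len": dup_len, "dup_offset": dup_offset},
        expected={"dup_len": dup_len, "frameshift": dup_len % 3 != 0,
                  "cds_before": before, "cds_after": after})
    assert truth.verify(out)
    return out, truth


def plant_large_duplication(genome: Genome, dup_len: int = 31_000,
                            mismatches: int = 1, seed=0,
                            pos: Optional[int] = None,
                            gc: float = 0.33) -> tuple[Genome, PlantedFeature]:
    """Duplicate a dup_len stretch of the genome as an adjacent direct repeat,
    with ``mismatches`` substitutions between the copies."""
    rng = _rng(seed)
    if dup_len >= len(genome) - 2:
        raise ContractViolation("duplication longer than the genome")
    if pos is None:
        pos = int(rng.integers(1, len(genome) - dup_len - 1))
    src = genome.seq[pos:pos + dup_len]
    copy, mm_pos = mutate_positions(rng, src, mismatches)
    seq = genome.seq
    for i in range(3):                    # left-extension guards
        seq = _guard(rng, seq, pos - 1 - i, src[dup_len - 1 - i])
    g = Genome(genome.id, seq, genome.topology, genome.features)
    out = _insert(g, pos + dup_len, copy, [])
    out_seq = out.seq
    for i in range(3):                    # right-extension guards
        out_seq = _guard(rng, out_seq, pos + 2 * dup_len + i, copy[i])
    out = Genome(out.id, out_seq, out.topology, out.features)
    truth = PlantedFeature(
        kind="large_duplication",
        coords={"copy1": (pos, pos + dup_len),
                "copy2": (pos + dup_len, pos + 2 * dup_len)},
        sequences={"copy1": out.seq[pos:pos + dup_len], "copy2": copy},
        params={"dup_len": dup_len, "mismatches": mismatches},
        expected={"length": dup_len, "mismatches": mismatches,
                  "mismatch_positions": mm_pos})
    assert truth.verify(out)
    return out, truth


def diverge(genome: Genome, sub_rate: float, indel_rate: float = 0.0,
            seed=0, max_indel: int = 10) -> Genome:
    """An independently evolved copy: i.i.d. substitutions at sub_rate and
    small indels (1-10 bp, geometric lengths) at indel_rate per base."""
    rng = _rng(seed)
    arr = np.frombuffer(genome.seq.encode(), dtype="S1").astype("U1")
    if sub_rate > 0:
        hits = np.nonzero(rng.random(len(arr)) < sub_rate)[0]
        for p in hits:
            arr[p] = _other_base(rng, arr[p])
    seq = "".join(arr)
    if indel_rate > 0:
        sites = sorted(np.nonzero(rng.random(len(seq)) < indel_rate)[0].tolist(),
                       reverse=True)
        for p in sites:
            ln = min(int(rng.geometric(0.5)), max_indel)
            if rng.random() < 0.5:
                seq = seq[:p] + random_dna(rng, ln) + seq[p:]
            else:
                seq = seq[:p] + seq[p + ln:]
    return Genome(genome.id + "_div", seq, genome.topology)


# ---------------------------------------------------------------------------
# population read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimRead:
    """A simulated read with its true origin on the island-bearing reference.

    ``intervals`` holds 1 interval for reads inside one reference block and 2
    for island-free reads spanning the excision junction.
    """
    id: str
    variant: str                # "carrier" or "noncarrier"
    intervals: list             # [(start, end), ...] on the carrier reference
    seq: str = ""

    @property
    def header(self) -> str:
        ivs = ",".join(f"{s}-{e}" for s, e in self.intervals)
        return f"{self.id} variant={self.variant} origin={ivs}"


def _single_insertion_diff(short: str, long: str) -> tuple[int, int]:
    """(position, length) of the single insertion turning ``short`` into ``long``."""
    if len(long) <= len(short):
        raise ContractViolation("second sequence must be the longer one")
    L = len(long) - len(short)
    p = 0
    while p < len(short) and short[p] == long[p]:
        p += 1
    s = 0
    while s < len(short) - p and short[-1 - s] == long[-1 - s]:
        s += 1
    return min(p, len(short) - s), L


def simulate_population_reads(genome_with_island: Genome, genome_without: Genome,
                              carrier_fraction: float, mean_depth: float,
                              read_len: int = 150, seed=0
                              ) -> tuple[list, DepthTrack]:
    """Uniform reads from a mixture of two genome variants.

    The expected depth over the island equals carrier_fraction x mean_depth,
    where mean_depth is the background (shared-sequence) depth. Read origins
    are mapped onto the island-bearing reference so depth tracks can be built
    without a mapper.
    """
    rng = _rng(seed)
    if not (0 <= carrier_fraction <= 1):
        raise ContractViolation("carrier_fraction must be in [0,1]")
    ipos, ilen = _single_insertion_diff(genome_without.seq, genome_with_island.seq)
    la, lb = len(genome_with_island), len(genome_without)
    f = carrier_fraction
    lmix = f * la + (1 - f) * lb
    n_reads = int(round(mean_depth * lmix / read_len))
    reads = []
    # a read comes from the pooled DNA: variant choice is DNA-mass-weighted,
    # which makes background depth == mean_depth and island depth == f * mean_depth.
    # Reads wrap the replication origin (circular chromosomes), so expected
    # coverage is exactly uniform.
    variants = rng.random(n_reads) < (f * la / lmix)

    def _wrap(start: int, length: int, L: int) -> list:
        end = start + length
        return [(start, end)] if end <= L else [(start, L), (0, end - L)]

    def _lift(iv: tuple) -> list:
        """Map a genome-without interval onto the island-bearing reference."""
        s, e = iv
        if e <= ipos:
            return [(s, e)]
        if s >= ipos:
            return [(s + ilen, e + ilen)]
        return [(s, ipos), (ipos + ilen, e + ilen)]

    for i in range(n_reads):
        if variants[i]:
            start = int(rng.integers(0, la))
            ivs = _wrap(start, read_len, la)
            seq = (genome_with_island.seq * 2)[start:start + read_len]
            reads.append(SimRead(f"r{i:07d}", "carrier", ivs, seq))
        else:
            start = int(rng.integers(0, lb))
            ivs = [m for iv in _wrap(start, read_len, lb) for m in _lift(iv)]
            seq = (genome_without.seq * 2)[start:start + read_len]
            reads.append(SimRead(f"r{i:07d}", "noncarrier", ivs, seq))
    from .coverage import depth_track
    track = depth_track(reads, genome_with_island, bin_size=1000)
    return reads, track


# ---------------------------------------------------------------------------
# spec-driven generation
# ---------------------------------------------------------------------------

_SINGLE_GENOME_PLANTS = {
    "repeat_island": plant_repeat_island,
    "composite_transposon": plant_composite_transposon,
    "large_duplication": plant_large_duplication,
}


def generate_genome(spec: SyntheticSpec) -> tuple[Genome, PlantedTruth]:
    """Background genome at the requested GC with all single-genome plant
    requests inserted at random non-overlapping positions. Deterministic for
    a fixed spec+seed. Pair-level kinds (mmej_pair, diverged_pair,
    mixed_population) are built by their dedicated functions on the result.
    """
    rng = _rng(spec.seed)
    for req in spec.planted:
        if req.kind not in _SINGLE_GENOME_PLANTS and req.kind != "tandem_dup_orf":
            raise ContractViolation(
                f"plant kind {req.kind!r} is pair/population-level; use its "
                "dedicated plant function")
    genome = Genome("synth", random_dna(rng, spec.genome_length, spec.gc))
    footprints = []
    for req in spec.planted:
        p = dict(req.params)
        if req.kind == "repeat_island":
            footprints.append(p.get("island_len", 12_000))
        elif req.kind == "composite_transposon":
            footprints.append(p.get("tsd_len", 8) * 2 + p.get("element_len", 1_300) * 2
                              + p.get("cargo_len", 5_000))
        elif req.kind == "large_duplication":
            footprints.append(p.get("dup_len", 31_000) * 2)
        else:  # tandem_dup_orf: host ORF + dup
            footprints.append(1_000)
    if sum(footprints) + 2 * len(footprints) > spec.genome_length:
        raise ContractViolation("planted features do not fit in the genome")
    # choose non-overlapping slots left to right, then insert right to left so
    # earlier truth coordinates stay valid
    free = spec.genome_length - sum(footprints)
    gaps = rng.dirichlet(np.ones(len(footprints) + 1)) * (free - len(footprints) - 1) if footprints else []
    positions, cursor = [], 0
    for i, fp in enumerate(footprints):
        cursor += int(gaps[i]) + 1
        positions.append(cursor)
        cursor += fp  # reserve the footprint so slots never overlap
    truth = PlantedTruth()
    offset = 0        # total length inserted so far, applied to later slots
    for i, req in enumerate(spec.planted):
        p = dict(req.params)
        sub = np.random.default_rng(rng.integers(2**31))
        slot = positions[i] + offset
        old_len = len(genome)
        if req.kind == "tandem_dup_orf":
            orf = make_orf(sub, p.pop("aa_len", 200), spec.gc)
            cds_id = f"synth_orf{i}"
            genome = _insert(genome, slot, orf,
                             [GeneModel(cds_id, slot, slot + len(orf),
                                        "+", "CDS")])
            genome, t = plant_tandem_dup(genome, cds_id, seed=sub, **p)
        else:
            genome, t = _SINGLE_GENOME_PLANTS[req.kind](
                genome, seed=sub, pos=slot, gc=spec.gc, **p)
        offset += len(genome) - old_len
        truth.features.append(t)
    for t in truth.features:
        if not t.verify(genome):
            raise ContractViolation(f"truth verification failed for {t.kind}")
    return genome, truth
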