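"""Direct-repeat-bounded islands and large duplications.

A genetic island flanked by two same-orientation copies of a repeat is
unstable: recombination between the copies excises the cargo as a circle
carrying one copy and leaves the other copy as a scar on the chromosome.
This module detects such repeat pairs by exact k-mer seeding with ungapped
mismatch-bounded extension, and models the excision/integration cycle as
exact sequence surgery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core_io import ContractViolation, GeneModel, Genome


@dataclass
class DirectRepeatIsland:
    """Two near-identical direct repeat copies and the cargo between them."""

    repeat1: tuple        # [start, end) of the upstream copy
    repeat2: tuple
    repeat_len: int
    mismatches: int
    island: tuple         # start of repeat1 .. end of repeat2 (repeat-inclusive)
    cargo: tuple          # between the copies (repeat-exclusive)

    def to_features(self, prefix: str = "island") -> list:
        attrs = {"repeat_len": self.repeat_len, "mismatches": self.mismatches}
        return [
            GeneModel(f"{prefix}", *self.island, "+", "mobile_element",
                      attributes=attrs),
            GeneModel(f"{prefix}_dr1", *self.repeat1, "+", "repeat_region"),
            GeneModel(f"{prefix}_dr2", *self.repeat2, "+", "repeat_region"),
        ]


@dataclass
class LargeDuplication:
    copy1: tuple
    copy2: tuple
    length: int
    mismatches: int


def _match(a: str, b: str) -> bool:
    return a == b and a != "N"


def _extend_pair(seq: str, p1: int, p2: int, k: int, max_mismatch_frac: float,
                 mismatch_penalty: int = 3, xdrop: int = 12):
    """Ungapped X-drop extension of an exact seed seq[p1:p1+k] == seq[p2:p2+k].

    Matches score +1 and mismatches -``mismatch_penalty``; each direction
    keeps its best-scoring endpoint (which always falls on a matching base)
    and aborts once the running score drops ``xdrop`` below the best. The
    final pair is accepted only if its cumulative mismatch fraction is within
    ``max_mismatch_frac``. Returns (start1, end1, start2, end2, mismatches)
    or None.
    """
    n = len(seq)

    def _dir(limit_check, index1, index2):
        best_off, best_mm = 0, 0
        score = best_score = 0
        mm = 0
        off = 0
        while True:
            off += 1
            i1, i2 = index1(off), index2(off)
            if not limit_check(i1, i2):
                break
            if _match(seq[i1], seq[i2]):
                score += 1
                if score > best_score:
                    best_score, best_off, best_mm = score, off, mm
            else:
                score -= mismatch_penalty
                mm += 1
                if score <= best_score - xdrop:
                    break
        return best_off, best_mm

    r_off, r_mm = _dir(lambda i1, i2: i1 < p2 and i2 < n,
                       lambda o: p1 + k - 1 + o, lambda o: p2 + k - 1 + o)
    l_off, l_mm = _dir(lambda i1, i2: i1 >= 0 and i2 > p1 + k - 1 + r_off,
                       lambda o: p1 - o, lambda o: p2 - o)
    s1, e1 = p1 - l_off, p1 + k + r_off
    s2, e2 = p2 - l_off, p2 + k + r_off
    length = e1 - s1
    mm = l_mm + r_mm
    if mm > max_mismatch_frac * length:
        return None
    if e1 > s2:
        return None
    return s1, e1, s2, e2, mm


def _seed_and_extend(seq: str, k: int, min_len: int, max_mismatch_frac: float,
                     min_sep: int = 0, max_sep: Optional[int] = None):
    """All maximal non-contained same-strand repeat pairs of length >= min_len."""
    index: dict[str, list] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    done: set = set()          # (diagonal, covered-start) pruning
    pairs = []
    for kmer, positions in index.items():
        if len(positions) < 2 or "N" in kmer:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                p1, p2 = positions[ai], positions[bi]
                diag = p2 - p1
                if max_sep is not None and diag > max_sep:
                    continue
                if diag < min_sep or diag < k:
                    continue
                key = (diag, p1 // k)
                if key in done:
                    continue
                ext = _extend_pair(seq, p1, p2, k, max_mismatch_frac)
                if ext is None:
                    done.add(key)
                    continue
                # mark the whole extended range on this diagonal as processed
                s1, e1, s2, e2, mm = ext
                for b in range(s1 // k, e1 // k + 1):
                    done.add((diag, b))
                if e1 - s1 >= min_len:
                    pairs.append((s1, e1, s2, e2, mm))
    # deduplicate and drop contained pairs
    uniq = sorted(set(pairs), key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    kept = []
    for cand in uniq:
        s1, e1, s2, e2, _ = cand
        contained = any(
            ks1 <= s1 and e1 <= ke1 and ks2 <= s2 and e2 <= ke2
            for ks1, ke1, ks2, ke2, _ in kept)
        if not contained:
            kept.append(cand)
    kept.sort()
    return kept


def find_direct_repeat_islands(genome: Genome, min_repeat_len: int = 50,
                               max_mismatch_frac: float = 0.02,
                               island_len_range: tuple = (1_000, 100_000),
                               k: int = 21) -> list:
    """Direct-repeat pairs whose repeat-inclusive span lies in island_len_range."""
    if len(genome) < 2 * min_repeat_len:
        raise ContractViolation("genome shorter than two repeat copies")
    lo, hi = island_len_range
    out = []
    for s1, e1, s2, e2, mm in _seed_and_extend(
            genome.seq, k=k, min_len=min_repeat_len,
            max_mismatch_frac=max_mismatch_frac, max_sep=hi):
        span = e2 - s1
        if lo <= span <= hi and (e1 - s1) >= min_repeat_len:
            out.append(DirectRepeatIsland(
                repeat1=(s1, e1), repeat2=(s2, e2), repeat_len=e1 - s1,
                mismatches=mm, island=(s1, e2), cargo=(e1, s2)))
    out.sort(key=lambda c: c.island)
    return out


def find_large_duplications(genome: Genome, min_len: int = 10_000,
                            max_mismatch_frac: float = 0.001,
                            k: int = 21) -> list:
    """Long duplicated stretches (direct orientation), e.g. assembly-scale
    terminal duplications; reports inter-copy mismatch counts."""
    out = []
    for s1, e1, s2, e2, mm in _seed_and_extend(
            genome.seq, k=k, min_len=min_len,
            max_mismatch_frac=max_mismatch_frac):
        if e1 - s1 >= min_len:
            out.append(LargeDuplication((s1, e1), (s2, e2), e1 - s1, mm))
    out.sort(key=lambda d: d.copy1)
    return out


# ---------------------------------------------------------------------------
# excision / integration
# ---------------------------------------------------------------------------

def excise_island(genome: Genome, island: DirectRepeatIsland) -> tuple:
    """Recombination between the repeat copies.

    Returns (chromosome, circle): the chromosome keeps the upstream copy as
    the scar; the circle carries the cargo plus the downstream copy and is
    marked circular. Total sequence length is conserved exactly.
    """
    (s1, e1), (s2, e2) = island.repeat1, island.repeat2
    if e1 > s2:
        raise ContractViolation("repeat copies overlap")
    chrom_seq = genome.seq[:e1] + genome.seq[e2:]
    circ_seq = genome.seq[e1:e2]          # cargo + repeat2
    feats = [f for f in genome.features if f.end <= e1] + [
        GeneModel(f.id, f.start - (e2 - e1), f.end - (e2 - e1), f.strand,
                  f.kind, f.product, f.translation, dict(f.attributes))
        for f in genome.features if f.start >= e2]
    chrom = Genome(genome.id + "_excised", chrom_seq, genome.topology, feats)
    circle = Genome(genome.id + "_circle", circ_seq, "circular")
    return chrom, circle


def integrate_island(genome: Genome, circle: Genome, target_repeat_interval: tuple,
                     max_mismatch_frac: float = 0.02) -> Genome:
    """Inverse of excision: insert the circle at a genomic repeat copy.

    The circle must contain a copy of the target repeat (within
    max_mismatch_frac); it is rotated so it reads cargo+repeat and inserted
    immediately after the genomic copy.
    """
    t0, t1 = target_repeat_interval
    target = genome.seq[t0:t1]
    doubled = circle.seq * 2
    idx = doubled.find(target)
    if idx < 0 or idx >= len(circle):
        idx = _approx_find(doubled, target, max_mismatch_frac, len(circle))
    if idx is None or idx < 0:
        raise ContractViolation("circle carries no copy of the target repeat")
    # rotate so the repeat copy is at the circle's end
    rot = (idx + len(target)) % len(circle.seq)
    cargo_plus_repeat = circle.seq[rot:] + circle.seq[:rot]
    seq = genome.seq[:t1] + cargo_plus_repeat + genome.seq[t1:]
    feats = [f for f in genome.features if f.end <= t1] + [
        GeneModel(f.id, f.start + len(circle.seq), f.end + len(circle.seq),
                  f.strand, f.kind, f.product, f.translation, dict(f.attributes))
        for f in genome.features if f.start >= t1]
    return Genome(genome.id + "_integrated", seq, genome.topology, feats)


def _approx_find(haystack: str, needle: str, max_frac: float, limit: int):
    max_mm = int(max_frac * len(needle))
    for i in range(min(limit, len(haystack) - len(needle) + 1)):
        mm = 0
        for a, b in zip(haystack[i:i + len(needle)], needle):
            if a != b or a == "N":
                mm += 1
                if mm > max_mm:
                    break
        else:
            return i
    return None
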