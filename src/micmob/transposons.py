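"""Transposon-like elements: terminal inverted repeats, target-site
duplications, and the composite-element rule.

A transposon moving on its own duplicates its target site, leaving the same
short sequence (here typically 8 nt) immediately on both sides of the
element. When two related elements and the cargo between them move as one
composite unit, the individual elements carry no TSDs — instead the bases
immediately upstream of the first element equal the bases immediately
downstream of the second.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core_io import ContractViolation, GeneModel, Genome, revcomp


@dataclass
class ItrRecord:
    itr_len: int
    mismatches: int
    match_string: str        # left ITR; matches uppercase, mismatches lowercase
    left_seq: str
    right_seq: str           # as written on the forward strand (element 3' end)


@dataclass
class TransposonElement:
    start: int
    end: int
    itr: Optional[ItrRecord]
    tsd: Optional[str] = None
    transposase_cds: Optional[GeneModel] = None
    id: str = ""

    @property
    def interval(self) -> tuple:
        return (self.start, self.end)

    @property
    def itr_left(self) -> tuple:
        return (self.start, self.start + self.itr.itr_len)

    @property
    def itr_right(self) -> tuple:
        return (self.end - self.itr.itr_len, self.end)


@dataclass
class CompositeElement:
    left: TransposonElement
    right: TransposonElement
    cargo: tuple
    composite_tsd: str
    tsd_len: int


def find_itrs(element_seq: str, max_itr_len: int = 60, min_itr_len: int = 10,
              max_mismatches: int = 4) -> Optional[ItrRecord]:
    """Longest terminal inverted repeat of an element sequence.

    The element's 5' prefix is compared against the reverse complement of its
    3' suffix, anchored at the termini. The longest length whose innermost
    base matches and whose mismatch count is within ``max_mismatches`` wins;
    requiring a matching inner base trims chance single-base extensions.
    """
    n = len(element_seq)
    if n < 2 * min_itr_len:
        raise ContractViolation("element shorter than two minimal ITRs")
    limit = min(max_itr_len, n // 2)
    left = element_seq[:limit]
    right_rc = revcomp(element_seq[-limit:])    # aligned to the left prefix
    pair_ok = [a == b and a != "N" for a, b in zip(left, right_rc)]
    mism = 0
    best = None
    for L in range(1, limit + 1):
        if not pair_ok[L - 1]:
            mism += 1
            continue
        if L >= min_itr_len and mism <= max_mismatches:
            best = (L, mism)
    if best is None:
        return None
    L, mm = best
    match_string = "".join(
        c.upper() if ok else c.lower() for c, ok in zip(left[:L], pair_ok[:L]))
    return ItrRecord(itr_len=L, mismatches=mm, match_string=match_string,
                     left_seq=left[:L], right_seq=element_seq[n - L:])


def check_tsd(genome: Genome, element_interval: tuple,
              tsd_len_range: tuple = (4, 16)) -> Optional[str]:
    """Longest exact direct repeat immediately flanking the element."""
    s, e = element_interval
    lo, hi = tsd_len_range
    for L in range(hi, lo - 1, -1):
        if s - L < 0 or e + L > len(genome):
            continue
        up = genome.seq[s - L:s]
        down = genome.seq[e:e + L]
        if up == down and "N" not in up:
            return up
    return None


def annotate_element(genome: Genome, interval: tuple, id: str = "",
                     transposase_cds: Optional[GeneModel] = None,
                     **itr_kwargs) -> TransposonElement:
    """Build a TransposonElement for a known (annotation-guided) interval."""
    s, e = interval
    itr = find_itrs(genome.seq[s:e], **itr_kwargs)
    return TransposonElement(start=s, end=e, itr=itr,
                             tsd=check_tsd(genome, interval),
                             transposase_cds=transposase_cds, id=id)


def itr_family_identity(a: ItrRecord, b: ItrRecord) -> float:
    """Ungapped percent identity between two elements' left ITR sequences."""
    n = min(len(a.left_seq), len(b.left_seq))
    if n == 0:
        return 0.0
    same = sum(1 for x, y in zip(a.left_seq[:n], b.left_seq[:n])
               if x == y and x != "N")
    return 100.0 * same / n


def find_composite_elements(genome: Genome, elements: list, tsd_len: int = 8,
                            min_family_identity: float = 70.0) -> list:
    """Composite (jointly mobilized) element calls.

    For each ordered pair of same-family elements (ITR identity at or above
    ``min_family_identity``): neither element may carry its own TSD, and the
    ``tsd_len`` bases immediately upstream of the first must equal the
    ``tsd_len`` bases immediately downstream of the second (exact match).
    """
    elements = sorted(elements, key=lambda e: e.start)
    out = []
    for i, e1 in enumerate(elements):
        for e2 in elements[i + 1:]:
            if e1.itr is None or e2.itr is None:
                continue
            if itr_family_identity(e1.itr, e2.itr) < min_family_identity:
                continue
            if e1.tsd is not None or e2.tsd is not None:
                continue  # moved separately
            s, e = e1.start, e2.end
            if s - tsd_len < 0 or e + tsd_len > len(genome):
                continue
            up = genome.seq[s - tsd_len:s]
            down = genome.seq[e:e + tsd_len]
            if up == down and "N" not in up:
                out.append(CompositeElement(
                    left=e1, right=e2, cargo=(e1.end, e2.start),
                    composite_tsd=up, tsd_len=tsd_len))
    return out


def scan_for_elements(genome: Genome, min_len: int = 500, max_len: int = 5_000,
                      seed_len: int = 12, **itr_kwargs) -> list:
    """De novo ITR-based element discovery (lower confidence than
    annotation-guided detection: no transposase evidence is required).

    Looks for seed-length inverted-repeat word pairs at a plausible element
    spacing, then validates candidates with :func:`find_itrs`.
    """
    seq = genome.seq
    index: dict[str, list] = {}
    for i in range(len(seq) - seed_len + 1):
        index.setdefault(seq[i:i + seed_len], []).append(i)
    seen = set()
    out = []
    for i in range(len(seq) - seed_len + 1):
        word = seq[i:i + seed_len]
        if "N" in word:
            continue
        for j in index.get(revcomp(word), ()):
            end = j + seed_len
            if not (min_len <= end - i <= max_len):
                continue
            key = (i, end)
            if key in seen:
                continue
            seen.add(key)
            itr = find_itrs(seq[i:end], **itr_kwargs)
            if itr is not None:
                out.append(TransposonElement(
                    start=i, end=end, itr=itr,
                    tsd=check_tsd(genome, (i, end)),
                    id=f"denovo_{i}_{end}"))
    # keep maximal, non-duplicated candidates
    out.sort(key=lambda e: (e.start, -(e.end - e.start)))
    kept = []
    for e in out:
        if not any(k.start <= e.start and e.end <= k.end for k in kept):
            kept.append(e)
    return kept
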