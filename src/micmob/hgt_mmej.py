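"""Microhomology-mediated end joining (MMEJ) junction analysis.

MMEJ repairs double-strand breaks by annealing short (5-25 nt) exact
microhomologies. When a donor fragment bounded by two motifs integrates into
a recipient gene that carries the same two motifs a short distance apart,
the recipient segment spanning the motifs ends up duplicated as direct
repeats flanking the cargo — the signature of an unstable repeat-bounded
island. This module finds candidate motif pairs, constructs the predicted
integration product, and analyzes the coding consequences at the junctions,
plus tandem-duplication (frameshift) analysis within single ORFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core_io import ContractViolation, GeneModel, Genome, translate
from .glyco import scan_sequons


@dataclass
class MicrohomologyPair:
    motif1: str
    motif2: str
    donor_pos1: int
    donor_pos2: int
    recipient_pos1: int
    recipient_pos2: int

    @property
    def length(self) -> int:
        return len(self.motif1)

    @property
    def donor_cargo(self) -> tuple:
        return (self.donor_pos1 + len(self.motif1), self.donor_pos2)

    def __post_init__(self):
        if self.donor_pos1 >= self.donor_pos2:
            raise ContractViolation("donor motif order violated")
        if self.recipient_pos1 >= self.recipient_pos2:
            raise ContractViolation("recipient motif order violated")


@dataclass
class IntegrationPrediction:
    product: Genome
    new_repeats: tuple        # two intervals on the product
    junctions: tuple          # cut positions on the product


@dataclass
class OrfConsequence:
    gene_id: str
    event: str    # stop_gained | start_gained | frameshift | cterm_replaced | overlap_created
    position: int             # 0-based genomic (after-genome) position of the event
    detail: dict = field(default_factory=dict)


def _count_overlapping(hay: str, needle: str) -> int:
    count = start = 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def _maximal_matches(donor: str, region: str, region_off: int,
                     min_len: int, max_len: int) -> list:
    """Maximal exact shared substrings (donor_pos, region_pos, length)."""
    k = min_len
    index: dict[str, list] = {}
    for i in range(len(region) - k + 1):
        index.setdefault(region[i:i + k], []).append(i)
    seen = set()
    out = []
    for d in range(len(donor) - k + 1):
        for r in index.get(donor[d:d + k], ()):
            # extend to the maximal match and dedupe by its left end
            dl, rl = d, r
            while dl > 0 and rl > 0 and donor[dl - 1] == region[rl - 1] != "N":
                dl -= 1
                rl -= 1
            key = (dl, rl)
            if key in seen:
                continue
            seen.add(key)
            L = 0
            while (dl + L < len(donor) and rl + L < len(region)
                   and donor[dl + L] == region[rl + L] != "N"):
                L += 1
            if min_len <= L <= max_len:
                out.append((dl, rl + region_off, L))
    return out


def find_microhomology_pairs(donor: Genome, recipient: Genome,
                             region: Optional[tuple] = None,
                             min_len: int = 5, max_len: int = 25,
                             max_span: tuple = (1_000, 500_000),
                             unique_only: bool = True) -> list:
    """Ordered pairs of distinct microhomology motifs shared by donor and
    recipient.

    ``region`` restricts the recipient side (a gene interval; genome-wide
    search is allowed but slower). ``max_span`` is
    (max recipient span, max donor span): the recipient motifs must be close
    together (they seed the future direct repeats inside one gene) while the
    donor motifs may bracket a long cargo. With ``unique_only`` (default)
    motifs must occur exactly once in the donor and once in the recipient
    region — the unambiguous-breakpoint situation; short motifs shared many
    times carry no localization signal.
    Pairs are reported longest-first, then leftmost.
    """
    r0, r1 = region if region is not None else (0, len(recipient))
    reg = recipient.seq[r0:r1]
    rec_max_span, don_max_span = max_span
    matches = _maximal_matches(donor.seq, reg, r0, min_len, max_len)
    if unique_only:
        matches = [
            (d, r, L) for d, r, L in matches
            if _count_overlapping(donor.seq, donor.seq[d:d + L]) == 1
            and _count_overlapping(reg, donor.seq[d:d + L]) == 1]
    pairs = []
    for i, (d1, p1, L1) in enumerate(matches):
        for d2, p2, L2 in matches:
            if d1 + L1 > d2 or p1 + L1 > p2:
                continue          # must be ordered and non-overlapping in both
            m1 = donor.seq[d1:d1 + L1]
            m2 = donor.seq[d2:d2 + L2]
            if m1 == m2:
                continue
            if (p2 + L2) - p1 > rec_max_span:
                continue
            if (d2 + L2) - d1 > don_max_span:
                continue
            pairs.append(MicrohomologyPair(m1, m2, d1, d2, p1, p2))
    pairs.sort(key=lambda p: (-min(len(p.motif1), len(p.motif2)),
                              p.recipient_pos1, p.donor_pos1))
    return pairs


def predict_integration(recipient: Genome, donor: Genome,
                        pair: MicrohomologyPair) -> IntegrationPrediction:
    """Integration product of the donor cargo into the recipient.

    The cut is placed at the motif boundaries: the donor contributes the
    cargo between its motifs; the recipient segment spanning motif1..motif2
    (motif-inclusive) appears twice, as direct repeats flanking the cargo —
    the geometry that reproduces observed island-bounding repeats.
    """
    L1, L2 = len(pair.motif1), len(pair.motif2)
    r1, r2 = pair.recipient_pos1, pair.recipient_pos2
    if r1 + L1 > r2:
        raise ContractViolation("recipient motifs overlap")
    if recipient.seq[r1:r1 + L1] != pair.motif1 or \
            recipient.seq[r2:r2 + L2] != pair.motif2:
        raise ContractViolation("motifs absent at recipient coordinates")
    cargo = donor.seq[pair.donor_pos1 + L1:pair.donor_pos2]
    repeat = recipient.seq[r1:r2 + L2]
    cut = r2 + L2
    ins = cargo + repeat
    seq = recipient.seq[:cut] + ins + recipient.seq[cut:]
    feats = []
    for f in recipient.features:
        if f.start >= cut:
            feats.append(GeneModel(f.id, f.start + len(ins), f.end + len(ins),
                                   f.strand, f.kind, f.product, f.translation,
                                   dict(f.attributes)))
        elif f.end <= cut:
            feats.append(f)
        else:
            feats.append(GeneModel(f.id, f.start, f.end + len(ins), f.strand,
                                   f.kind, f.product, f.translation,
                                   dict(f.attributes)))
    product = Genome(recipient.id + "_integrated", seq, recipient.topology, feats)
    rep1 = (r1, r2 + L2)
    rep2 = (cut + len(cargo), cut + len(cargo) + len(repeat))
    return IntegrationPrediction(product=product, new_repeats=(rep1, rep2),
                                 junctions=(cut, cut + len(cargo)))


# ---------------------------------------------------------------------------
# coding consequences
# ---------------------------------------------------------------------------

def _single_edit(before: str, after: str) -> tuple:
    """(position, removed_len, inserted_len) of the single contiguous edit."""
    p = 0
    nmin = min(len(before), len(after))
    while p < nmin and before[p] == after[p]:
        p += 1
    s = 0
    while s < nmin - p and before[len(before) - 1 - s] == after[len(after) - 1 - s]:
        s += 1
    return p, len(before) - p - s, len(after) - p - s


def _translate_from(seq: str, start: int, strand: str, max_codons: int,
                    start_policy: str = "alt") -> str:
    """Translation from a fixed start until the first stop (or max_codons)."""
    if strand == "+":
        sub = seq[start:start + 3 * max_codons]
    else:
        from .core_io import revcomp
        sub = revcomp(seq[max(0, start - 3 * max_codons):start])
    prot = translate(sub + "NNN"[: (3 - len(sub) % 3) % 3], start_policy=start_policy) \
        if len(sub) >= 3 else ""
    stop = prot.find("*")
    return prot if stop < 0 else prot[:stop]


def orf_consequences(before: Genome, after: Genome, genes: list,
                     cterm_window: int = 10, start_policy: str = "alt",
                     upstream_scan: int = 90) -> list:
    """Coding changes caused by a single insertion/replacement edit.

    ``genes`` are CDS models on the *before* genome; coordinates are lifted
    linearly across the edit. Genes that cannot be mapped are reported as
    skipped in the returned records (event ``"skipped"``), not fatal.
    """
    pos, removed, inserted = _single_edit(before.seq, after.seq)
    shift = inserted - removed
    out = []
    for g in genes:
        if g.kind != "CDS":
            continue
        if g.strand != "+":
            out.append(OrfConsequence(g.id, "skipped", g.start,
                                      {"reason": "reverse-strand liftover not supported"}))
            continue
        if g.start >= pos + removed:
            new_start = g.start + shift
        elif g.end <= pos:
            new_start = g.start
        elif g.start < pos:
            new_start = g.start          # gene spans the edit; start unmoved
        else:
            out.append(OrfConsequence(g.id, "skipped", g.start,
                                      {"reason": "gene start inside the edit"}))
            continue
        old_prot = _translate_from(before.seq, g.start, "+",
                                   max_codons=(g.length // 3) + 2)
        max_c = (g.length + max(0, shift)) // 3 + 400
        new_prot = _translate_from(after.seq, new_start, "+", max_codons=max_c)
        if new_prot == old_prot:
            continue
        k = 0
        while k < min(len(old_prot), len(new_prot)) and old_prot[k] == new_prot[k]:
            k += 1
        old_tail, new_tail = old_prot[k:], new_prot[k:]
        if len(old_tail) <= cterm_window and len(new_tail) <= cterm_window:
            # a short terminal swap, even when the edit shifts downstream
            # non-coding phase (a 3'-end replacement is not a frameshift of
            # the translated region)
            out.append(OrfConsequence(
                g.id, "cterm_replaced", new_start + 3 * k,
                {"old_cterm": old_tail, "new_cterm": new_tail,
                 "old_len": len(old_tail), "new_len": len(new_tail)}))
        elif (g.start < pos < g.end) and shift % 3 != 0:
            out.append(OrfConsequence(
                g.id, "frameshift", pos,
                {"shift": shift, "divergence_residue": k + 1,
                 "old_tail": old_tail[:20], "new_tail": new_tail[:20]}))
        else:
            event = "stop_gained" if len(new_prot) < len(old_prot) else "cterm_replaced"
            out.append(OrfConsequence(
                g.id, event, new_start + 3 * len(new_prot),
                {"old_len": len(old_prot), "new_len": len(new_prot),
                 "old_tail": old_tail[:20], "new_tail": new_tail[:20]}))
    out.extend(_novel_starts(before, after, genes, pos, removed, inserted,
                             start_policy, upstream_scan))
    return out


def _novel_starts(before: Genome, after: Genome, genes: list, pos: int,
                  removed: int, inserted: int, start_policy: str,
                  upstream_scan: int) -> list:
    """start_gained / overlap_created: an in-frame alternative start inside
    newly inserted sequence upstream of a gene whose start lies just after
    the edit."""
    from .core_io import START_POLICIES
    starts = START_POLICIES[start_policy]
    shift = inserted - removed
    out = []
    for g in genes:
        if g.kind != "CDS" or g.strand != "+":
            continue
        if not (pos <= g.start <= pos + removed + upstream_scan):
            continue
        new_start = g.start + shift if g.start >= pos + removed else g.start
        limit = max(pos, new_start - upstream_scan)
        for s in range(new_start - 3, limit - 1, -3):
            codon = after.seq[s:s + 3]
            if codon in ("TAA", "TAG", "TGA"):
                break
            if codon in starts:
                rec = OrfConsequence(g.id, "start_gained", s,
                                     {"codon": codon, "extension_nt": new_start - s})
                out.append(rec)
                for other in genes:
                    o_start = other.start + shift if other.start >= pos + removed else other.start
                    o_end = other.end + shift if other.end > pos + removed else other.end
                    if other.id != g.id and o_start < new_start and o_end > s:
                        out.append(OrfConsequence(
                            g.id, "overlap_created", s,
                            {"overlaps": other.id, "overlap_nt": o_end - s}))
                break
    return out


# ---------------------------------------------------------------------------
# tandem duplications inside ORFs
# ---------------------------------------------------------------------------

@dataclass
class TandemDupRecord:
    length: int
    offset: int               # start of the duplicated unit within the ORF
    frameshift: bool
    premature_stop_codon: Optional[int]   # 0-based codon index in the mutant, or None
    lost_sequons: list        # 1-based Asn positions (wild-type numbering)


def analyze_tandem_dup(gene_before: str, gene_after: str) -> Optional[TandemDupRecord]:
    """Detect a tandem duplication by before/after ORF comparison.

    Reports the duplication length and (leftmost) offset, whether it shifts
    the reading frame, the resulting premature stop, and which downstream
    N-X-(S/T) sequons of the wild-type translation are no longer encoded in
    the mutant protein.
    """
    gene_before = gene_before.upper()
    gene_after = gene_after.upper()
    L = len(gene_after) - len(gene_before)
    if L <= 0:
        return None
    n = len(gene_before)
    hit = None
    for i in range(L, n + 1):   # leftmost insertion point of the tandem copy
        if gene_after == gene_before[:i] + gene_before[i - L:i] + gene_before[i:]:
            hit = i
            break
    if hit is None:
        return None
    offset = hit - L
    frameshift = L % 3 != 0
    prot_before = translate(gene_before)
    full_after = translate(gene_after)
    stop = full_after.find("*")
    premature = stop if (0 <= stop < (len(gene_after) // 3) - 1) else None
    prot_after = full_after if stop < 0 else full_after[:stop]
    fp_before = scan_sequons(prot_before.replace("*", "X"))
    dup_aa = offset // 3
    lost = []
    for p in fp_before.positions:
        if p <= dup_aa:
            continue
        motif = prot_before[p - 1:p + 2]
        if motif not in prot_after[dup_aa:]:
            lost.append(p)
    return TandemDupRecord(length=L, offset=offset, frameshift=frameshift,
                           premature_stop_codon=premature, lost_sequons=lost)
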