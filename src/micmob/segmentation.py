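"""Chunked pairwise whole-genome comparison into matchSEG/divSEG intervals.

Strategy: genome A is traversed in chunks (default 400 kb). Within a chunk,
exact unique 21-mers shared with genome B are chained collinearly; the gaps
between anchors are aligned with banded edit-distance alignment (edlib).
Alignment columns are classified by windowed identity (default: 95 % over
1 kb windows); maximal qualifying runs of at least 500 bp on the A side
become matchSEGs, everything else divSEGs. The next chunk restarts at the
start of the previous chunk's final matchSEG, and the per-chunk results are
stitched and deduplicated.

matchSEG/divSEG thresholds are classification decisions, configurable;
closely related strains typically show 97-99 % identity within matchSEGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import edlib
import numpy as np

from .core_io import ContractViolation, Genome

log = logging.getLogger(__name__)


@dataclass
class Segment:
    kind: str             # "matchSEG" or "divSEG"
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: Optional[float]   # percent over aligned columns; matchSEG only

    @property
    def length(self) -> int:
        return self.a_end - self.a_start

    def __post_init__(self):
        if self.kind not in ("matchSEG", "divSEG"):
            raise ContractViolation(f"bad segment kind {self.kind!r}")
        if self.identity is not None and not (0 <= self.identity <= 100):
            raise ContractViolation("identity outside [0,100]")


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _unique_kmers(seq: str, k: int) -> dict:
    counts: dict[str, int] = {}
    pos: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        counts[km] = counts.get(km, 0) + 1
        pos[km] = i
    return {km: p for km, p in pos.items() if counts[km] == 1 and "N" not in km}


def _chain_anchors(matches: list) -> list:
    """Longest collinear chain (strictly increasing in both coordinates).

    ``matches`` are (a_pos, b_pos) pairs sorted by a_pos. Ties broken by
    longest chain, then leftmost. O(n log n) patience chaining.
    """
    if not matches:
        return []
    import bisect
    tails: list[int] = []          # b_pos of smallest tail per chain length
    back: list[int] = [-1] * len(matches)
    idx_at: list[list[int]] = []
    for i, (_, b) in enumerate(matches):
        j = bisect.bisect_left(tails, b)
        if j == len(tails):
            tails.append(b)
            idx_at.append([i])
        else:
            tails[j] = b
            idx_at[j].append(i)
        back[i] = idx_at[j - 1][-1] if j > 0 else -1
    chain = []
    cur = idx_at[-1][-1]
    while cur != -1:
        chain.append(matches[cur])
        cur = back[cur]
    return chain[::-1]


def _merge_diagonal(chain: list, k: int) -> list:
    """Collapse chained k-mer anchors into maximal exact blocks
    [(a_start, b_start, length), ...], dropping anchors that would overlap a
    previous block inconsistently."""
    blocks = []
    for a, b in chain:
        if blocks:
            pa, pb, pl = blocks[-1]
            if a - pa == b - pb and a <= pa + pl:       # same diagonal, contiguous
                blocks[-1] = (pa, pb, a + k - pa)
                continue
            if a < pa + pl or b < pb + pl:              # overlapping, off-diagonal
                a_clip = max(a, pa + pl, pb + pl - (b - a))
                shift = a_clip - a
                if shift >= k:
                    continue
                blocks.append((a + shift, b + shift, k - shift))
                continue
        blocks.append((a, b, k))
    return blocks


# ---------------------------------------------------------------------------
# column construction
# ---------------------------------------------------------------------------

def _gap_columns(a_seq: str, b_seq: str):
    """Alignment columns for an inter-anchor gap as (a_step, b_step, match)."""
    cols = []
    if not a_seq and not b_seq:
        return cols
    if not a_seq:
        return [(0, 1, False)] * len(b_seq)
    if not b_seq:
        return [(1, 0, False)] * len(a_seq)
    res = edlib.align(a_seq, b_seq, task="path", mode="NW")
    cigar = res["cigar"] or ""
    i = j = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "=":
            for t in range(n):
                ok = a_seq[i + t] == b_seq[j + t] and a_seq[i + t] != "N"
                cols.append((1, 1, ok))
            i += n
            j += n
        elif ch == "X":
            cols.extend([(1, 1, False)] * n)
            i += n
            j += n
        elif ch == "D":      # consumes target (b)
            cols.extend([(0, 1, False)] * n)
            j += n
        elif ch == "I":      # consumes query (a)
            cols.extend([(1, 0, False)] * n)
            i += n
    return cols


def _classify_columns(cols, window_len: int, min_identity: float,
                      min_match_len: int, a0: int, b0: int) -> list:
    """Windowed-identity classification of alignment columns into segments."""
    n = len(cols)
    if n == 0:
        return []
    match = np.fromiter((c[2] for c in cols), dtype=float, count=n)
    w = min(window_len, n)
    c = np.concatenate([[0.0], np.cumsum(match)])
    # trailing-window mean at each column (window [i-w+1, i]), shrunk at the edge
    starts = np.maximum(0, np.arange(n) - w + 1)
    win_mean = (c[np.arange(n) + 1] - c[starts]) / (np.arange(n) + 1 - starts)
    # a column is match-eligible if ANY window containing it passes; using the
    # best of the trailing window ending at i+w-1 and the one ending at i
    # a column is eligible if either the trailing window ending at it or the
    # one it leads passes the identity threshold
    lead_idx = np.minimum(n - 1, np.arange(n) + w - 1)
    eligible = (win_mean >= min_identity / 100.0) | \
               (win_mean[lead_idx] >= min_identity / 100.0)

    a_steps = np.fromiter((c0 for c0, _, _ in cols), dtype=np.int64, count=n)
    b_steps = np.fromiter((c1 for _, c1, _ in cols), dtype=np.int64, count=n)
    a_off = np.concatenate([[0], np.cumsum(a_steps)]) + a0
    b_off = np.concatenate([[0], np.cumsum(b_steps)]) + b0

    segs = []
    i = 0
    while i < n:
        j = i
        flag = bool(eligible[i])
        while j < n and bool(eligible[j]) == flag:
            j += 1
        a_s, a_e = int(a_off[i]), int(a_off[j])
        b_s, b_e = int(b_off[i]), int(b_off[j])
        run_match = float(c[j] - c[i])
        if flag and (a_e - a_s) >= min_match_len:
            # trim terminal mismatch columns off a matchSEG
            ii, jj = i, j
            while ii < jj and not cols[ii][2]:
                ii += 1
            while jj > ii and not cols[jj - 1][2]:
                jj -= 1
            segs.append(Segment("matchSEG", int(a_off[ii]), int(a_off[jj]),
                                int(b_off[ii]), int(b_off[jj]),
                                100.0 * float(c[jj] - c[ii]) / max(1, jj - ii)))
            if ii > i:
                segs.insert(-1, Segment("divSEG", a_s, int(a_off[ii]),
                                        b_s, int(b_off[ii]), None))
            if jj < j:
                segs.append(Segment("divSEG", int(a_off[jj]), a_e,
                                    int(b_off[jj]), b_e, None))
        else:
            segs.append(Segment("divSEG", a_s, a_e, b_s, b_e, None))
        i = j
    return _stitch(segs)


def _stitch(segs: list) -> list:
    """Merge adjacent segments of the same kind (weighted identity)."""
    out: list[Segment] = []
    for s in segs:
        if s.a_end == s.a_start and s.b_end == s.b_start:
            continue
        if out and out[-1].kind == s.kind and out[-1].a_end == s.a_start:
            p = out[-1]
            ident = None
            if s.kind == "matchSEG":
                la, lb = max(1, p.length), max(1, s.length)
                ident = (p.identity * la + s.identity * lb) / (la + lb)
            out[-1] = Segment(s.kind, p.a_start, s.a_end, p.b_start, s.b_end, ident)
        else:
            out.append(s)
    return out


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def segment_genomes(genome_a: Genome, genome_b: Genome,
                    chunk_len: int = 400_000, k: int = 21,
                    window_len: int = 1_000, match_min_identity: float = 95.0,
                    min_match_len: int = 500) -> list:
    """Alternating matchSEG/divSEG tiling of genome A against genome B."""
    A, B = genome_a.seq, genome_b.seq
    if not A or not B:
        raise ContractViolation("both genomes must be non-empty")
    b_index = _unique_kmers(B, k)
    segments: list[Segment] = []
    a_cursor, b_cursor = 0, 0
    while a_cursor < len(A):
        chunk = A[a_cursor:a_cursor + chunk_len]
        final = a_cursor + chunk_len >= len(A)
        a_index = _unique_kmers(chunk, k)
        matches = sorted((a_cursor + ai, b_index[km])
                         for km, ai in a_index.items()
                         if km in b_index and b_index[km] >= b_cursor)
        chain = _chain_anchors(matches)
        blocks = _merge_diagonal(chain, k)
        if not blocks:
            log.info("no anchors in chunk at %d; whole chunk is divergent", a_cursor)
            segments.append(Segment("divSEG", a_cursor,
                                    min(len(A), a_cursor + chunk_len),
                                    b_cursor, b_cursor if not final else len(B),
                                    None))
            a_cursor += chunk_len
            continue
        cols = []
        a0 = a_cursor
        pa, pb = a_cursor, b_cursor
        for (ba, bb, bl) in blocks:
            cols.extend(_gap_columns(A[pa:ba], B[pb:bb]))
            cols.extend([(1, 1, True)] * bl)
            pa, pb = ba + bl, bb + bl
        chunk_a_end = min(len(A), a_cursor + chunk_len)
        b_tail_end = len(B) if final else pb
        cols.extend(_gap_columns(A[pa:chunk_a_end], B[pb:b_tail_end]))
        segs = _classify_columns(cols, window_len, match_min_identity,
                                 min_match_len, a0, b_cursor)
        match_idx = [i for i, s in enumerate(segs) if s.kind == "matchSEG"]
        last = match_idx[-1] if match_idx else None
        if final or last is None or segs[last].a_start <= a_cursor:
            # final chunk, anchorless chunk, or no forward progress possible
            segments.extend(segs)
            a_cursor = chunk_a_end
            b_cursor = pb
        else:
            # keep everything before the last matchSEG; restart the traversal
            # at the start of that matchSEG
            segments.extend(segs[:last])
            a_cursor = segs[last].a_start
            b_cursor = segs[last].b_start
    segments = _stitch(segments)
    _check_tiling(segments, len(A))
    return segments


def _check_tiling(segments: list, a_len: int) -> None:
    pos = 0
    for s in segments:
        if s.a_start != pos:
            raise ContractViolation(
                f"segments do not tile genome A: gap/overlap at {pos} vs {s.a_start}")
        pos = s.a_end
    if pos != a_len:
        raise ContractViolation(f"segments end at {pos}, genome A has {a_len}")


def ani(segments: list) -> Optional[float]:
    """Length-weighted mean matchSEG identity (percent); None if no matchSEG."""
    num = den = 0.0
    for s in segments:
        if s.kind == "matchSEG" and s.identity is not None:
            num += s.identity * s.length
            den += s.length
    return None if den == 0 else num / den


def segments_to_tsv(segments: list) -> str:
    lines = ["kind\ta_start\ta_end\tb_start\tb_end\tlength\tidentity"]
    for s in segments:
        ident = "" if s.identity is None else f"{s.identity:.3f}"
        lines.append(f"{s.kind}\t{s.a_start}\t{s.a_end}\t{s.b_start}\t{s.b_end}"
                     f"\t{s.length}\t{ident}")
    return "\n".join(lines) + "\n"
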