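"""N-glycosylation sequon scanning and fingerprint comparison.

A sequon is the tripeptide N-X-(S/T); by default X may not be proline, the
standard constraint on productive N-glycosylation. Sequon *fingerprints*
(the set of Asn positions) of homologous proteins are compared through a
sequence alignment: two sequons match when their Asn residues occupy the
same alignment column.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import ContractViolation

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequonFingerprint:
    protein_id: str
    positions: list       # 1-based residue index of each sequon's Asn
    count: int

    def __post_init__(self):
        if self.count != len(self.positions):
            raise ContractViolation("count must equal number of positions")


def scan_sequons(protein: str, exclude_proline_x: bool = True,
                 protein_id: str = "") -> SequonFingerprint:
    """All N-X-(S/T) sequon positions, left to right; overlaps allowed.

    Trailing stop symbols are ignored; input case is normalized. A
    non-amino-acid character raises an error naming its position.
    """
    seq = protein.upper().rstrip("*")
    for i, c in enumerate(seq):
        if c not in AA_ALPHABET:
            raise ContractViolation(
                f"non-amino-acid character {c!r} at position {i + 1}")
    positions = []
    for i in range(len(seq) - 2):
        if seq[i] != "N":
            continue
        if exclude_proline_x and seq[i + 1] == "P":
            continue
        if seq[i + 2] in "ST":
            positions.append(i + 1)
    return SequonFingerprint(protein_id=protein_id, positions=positions,
                             count=len(positions))


def _column_of_positions(aligned: str) -> dict:
    """Map 1-based residue index -> alignment column for one gapped row."""
    out = {}
    res = 0
    for col, c in enumerate(aligned):
        if c != "-":
            res += 1
            out[res] = col
    return out


def compare_fingerprints(proteins: list, alignment: list,
                         exclude_proline_x: bool = True) -> dict:
    """Matched/unique sequon report for aligned homologs.

    ``proteins`` is a list of (id, sequence); ``alignment`` the corresponding
    gapped rows of one multiple (or pairwise) alignment. Returns a dict with
    the per-protein fingerprints, the pairwise matched-count matrix, and the
    per-protein sequons found in no other homolog.
    """
    if len(proteins) != len(alignment):
        raise ContractViolation("one alignment row per protein required")
    ids = []
    col_sets = []
    fingerprints = {}
    for (pid, seq), row in zip(proteins, alignment):
        if row.replace("-", "") != seq.upper().rstrip("*"):
            raise ContractViolation(f"alignment row does not spell protein {pid!r}")
        fp = scan_sequons(seq, exclude_proline_x, protein_id=pid)
        colmap = _column_of_positions(row)
        ids.append(pid)
        col_sets.append({colmap[p] for p in fp.positions})
        fingerprints[pid] = fp
    n = len(ids)
    matrix = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            matrix[i][j] = len(col_sets[i] & col_sets[j]) if i != j else len(col_sets[i])
    unique = {}
    for i, pid in enumerate(ids):
        others = set().union(*(col_sets[j] for j in range(n) if j != i)) if n > 1 else set()
        inv = {v: k for k, v in _column_of_positions(alignment[i]).items()}
        unique[pid] = sorted(inv[c] for c in col_sets[i] - others)
    return {"ids": ids, "fingerprints": fingerprints,
            "matched_matrix": matrix, "unique_positions": unique}


def align_homologs(seqs: list) -> list:
    """Gapped rows for 2+ protein sequences (pairwise; center-star for >2).

    A convenience for fingerprint comparison; for publication-grade MSAs use
    a dedicated aligner and pass its rows to :func:`compare_fingerprints`.
    """
    from .clusters import _aligner
    if len(seqs) < 2:
        return list(seqs)
    if len(seqs) == 2:
        aln = _aligner().align(seqs[0], seqs[1])[0]
        a, b = str(aln[0]), str(aln[1])
        return [a, b]
    # center-star: align everything to the longest sequence
    center = max(range(len(seqs)), key=lambda i: len(seqs[i]))
    pair_rows = []
    for i, s in enumerate(seqs):
        if i == center:
            continue
        aln = _aligner().align(seqs[center], s)[0]
        pair_rows.append((i, str(aln[0]), str(aln[1])))
    # merge on the center sequence: each center residue is a master column,
    # with per-gap insert widths taken as the maximum over pairs
    m = len(seqs[center])
    insert = [0] * (m + 1)
    for _, c_row, _ in pair_rows:
        gap = run = 0
        res = 0
        for ch in c_row:
            if ch == "-":
                run += 1
            else:
                insert[res] = max(insert[res], run)
                run = 0
                res += 1
        insert[m] = max(insert[m], run)
    rows = [None] * len(seqs)
    rows[center] = "".join("-" * insert[r] + seqs[center][r] for r in range(m)) \
        + "-" * insert[m]
    for i, c_row, s_row in pair_rows:
        out = []
        res = 0
        chunk = ""
        pending = ""
        for c_ch, s_ch in zip(c_row, s_row):
            if c_ch == "-":
                pending += s_ch
            else:
                out.append(pending.rjust(insert[res], "-") if len(pending) <= insert[res]
                           else pending)
                out.append(s_ch)
                pending = ""
                res += 1
        out.append(pending.rjust(insert[m], "-") if len(pending) <= insert[m] else pending)
        rows[i] = "".join(out)
    width = max(len(r) for r in rows)
    rows = [r.ljust(width, "-") for r in rows]
    return rows
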