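"""Gene-cluster comparison, conserved-core extraction, split-gene detection.

Clusters are compared by all-vs-all global protein alignment (BLOSUM62,
affine gaps, free end gaps) plus gene-order analysis. Ortholog groups come
from reciprocal-best-hit links joined by single linkage; the *core* is the
set of groups represented in every input cluster, with split genes (one gene
in cluster A matched by two adjacent part-genes in cluster B) counting as a
single membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Align import PairwiseAligner, substitution_matrices

from .core_io import ContractViolation, GeneModel


@dataclass
class GeneCluster:
    genome_id: str
    genes: list                   # ordered GeneModel, translations required
    span: Optional[tuple] = None

    def __post_init__(self):
        for g in self.genes:
            if not g.translation:
                raise ContractViolation(f"gene {g.id!r} lacks a translation")
        if self.span is None and self.genes:
            self.span = (min(g.start for g in self.genes),
                         max(g.end for g in self.genes))

    def index_of(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.id == gene_id:
                return i
        raise KeyError(gene_id)


@dataclass
class HomologyLink:
    gene_a: str
    gene_b: str
    identity: float               # percent over aligned columns (no end gaps)
    coverage_a: float
    coverage_b: float
    a_span: tuple                 # aligned residue interval on protein A (0-based)
    b_span: tuple
    score: float
    reciprocal: bool = False


@dataclass
class CoreSet:
    groups: list                  # list of {genome_id: [gene ids]} dicts
    near_core: list               # groups missing exactly one cluster
    split_gene_calls: list        # (single_gene_id, [part1_id, part2_id])


_ALIGNER = None


def _aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        # free terminal gaps: partial-length homologs (split genes) align
        # without end-gap penalties
        a.end_gap_score = 0.0
        a.mode = "global"
        _ALIGNER = a
    return _ALIGNER


def align_proteins(a: str, b: str, id_a: str = "a", id_b: str = "b") -> HomologyLink:
    """Global affine-gap alignment; identity over columns excluding terminal
    gaps; coverage = aligned fraction of each protein."""
    a = a.upper().rstrip("*")
    b = b.upper().rstrip("*")
    aln = _aligner().align(a, b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    # strip terminal-gap columns
    lead = 0
    while ra[lead] == "-" or rb[lead] == "-":
        lead += 1
    trail = len(ra)
    while ra[trail - 1] == "-" or rb[trail - 1] == "-":
        trail -= 1
    core_a, core_b = ra[lead:trail], rb[lead:trail]
    cols = len(core_a)
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    a_aln = sum(1 for x in core_a if x != "-")
    b_aln = sum(1 for x in core_b if x != "-")
    a_lead = sum(1 for x in ra[:lead] if x != "-")
    b_lead = sum(1 for x in rb[:lead] if x != "-")
    return HomologyLink(
        gene_a=id_a, gene_b=id_b,
        identity=100.0 * matches / cols if cols else 0.0,
        coverage_a=a_aln / len(a) if a else 0.0,
        coverage_b=b_aln / len(b) if b else 0.0,
        a_span=(a_lead, a_lead + a_aln),
        b_span=(b_lead, b_lead + b_aln),
        score=float(aln.score))


def compare_clusters(query: GeneCluster, reference: GeneCluster,
                     min_identity: float = 30.0, min_coverage: float = 0.7
                     ) -> dict:
    """All-vs-all links above thresholds, reciprocal-best marking, and an
    order-conservation (synteny) statistic.

    ``min_coverage`` applies to the better-covered side, so a half-length
    part-gene linking a full-length gene is retained (split-gene evidence).
    """
    links = []
    for gq in query.genes:
        for gr in reference.genes:
            ln = align_proteins(gq.translation, gr.translation, gq.id, gr.id)
            if ln.identity >= min_identity and \
                    max(ln.coverage_a, ln.coverage_b) >= min_coverage:
                links.append(ln)
    best_q: dict[str, HomologyLink] = {}
    best_r: dict[str, HomologyLink] = {}
    for ln in links:
        key = (ln.identity, ln.score)
        if ln.gene_a not in best_q or key > (best_q[ln.gene_a].identity,
                                             best_q[ln.gene_a].score):
            best_q[ln.gene_a] = ln
        if ln.gene_b not in best_r or key > (best_r[ln.gene_b].identity,
                                             best_r[ln.gene_b].score):
            best_r[ln.gene_b] = ln
    for ln in links:
        ln.reciprocal = (best_q.get(ln.gene_a) is ln and best_r.get(ln.gene_b) is ln)
    # synteny: fraction of adjacent query pairs whose best partners are adjacent
    partner = {a: ln.gene_b for a, ln in best_q.items()}
    ref_pos = {g.id: i for i, g in enumerate(reference.genes)}
    adjacent = total = 0
    for g1, g2 in zip(query.genes, query.genes[1:]):
        p1, p2 = partner.get(g1.id), partner.get(g2.id)
        if p1 is None or p2 is None:
            continue
        total += 1
        if abs(ref_pos[p1] - ref_pos[p2]) == 1:
            adjacent += 1
    return {"links": links,
            "synteny": adjacent / total if total else 0.0}


def detect_split_genes(links: list, cluster_a: GeneCluster,
                       cluster_b: GeneCluster, min_combined_coverage: float = 0.8,
                       max_overlap_frac: float = 0.10,
                       max_intervening: int = 2) -> list:
    """(A; B1,B2) calls where two adjacent genes of cluster B align to
    distinct regions of one gene A of cluster A.

    B1/B2 must lie within ``max_intervening`` genes of each other, their
    aligned regions on A must overlap by less than ``max_overlap_frac`` of A,
    and together they must cover at least ``min_combined_coverage`` of A.
    Order of the parts is not required to mirror the regions on A.
    """
    by_a: dict[str, list] = {}
    for ln in links:
        by_a.setdefault(ln.gene_a, []).append(ln)
    calls = []
    for a_id, lns in by_a.items():
        a_len = len(next(g for g in cluster_a.genes if g.id == a_id)
                    .translation.rstrip("*"))
        for i in range(len(lns)):
            for j in range(len(lns)):
                if i >= j:
                    continue
                l1, l2 = lns[i], lns[j]
                if l1.gene_b == l2.gene_b:
                    continue
                p1 = cluster_b.index_of(l1.gene_b)
                p2 = cluster_b.index_of(l2.gene_b)
                if abs(p1 - p2) - 1 > max_intervening:
                    continue
                s1, e1 = l1.a_span
                s2, e2 = l2.a_span
                overlap = max(0, min(e1, e2) - max(s1, s2))
                if overlap >= max_overlap_frac * a_len:
                    continue
                covered = (e1 - s1) + (e2 - s2) - overlap
                if covered < min_combined_coverage * a_len:
                    continue
                parts = [l1.gene_b, l2.gene_b] if p1 < p2 else [l2.gene_b, l1.gene_b]
                calls.append((a_id, parts))
    return calls


def extract_core(clusters: list, min_identity: float = 30.0,
                 min_coverage: float = 0.7) -> CoreSet:
    """Ortholog groups present in every cluster (split parts count as one)."""
    if len(clusters) < 2:
        raise ContractViolation("need at least two clusters")
    owner = {}
    for c in clusters:
        for g in c.genes:
            if g.id in owner:
                raise ContractViolation(f"duplicate gene id {g.id!r}")
            owner[g.id] = c.genome_id
    parent: dict[str, str] = {gid: gid for gid in owner}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    split_calls = []
    for i in range(len(clusters)):
        for j in range(len(clusters)):
            if i == j:
                continue
            rep = compare_clusters(clusters[i], clusters[j],
                                   min_identity, min_coverage)
            for ln in rep["links"]:
                if ln.reciprocal:
                    union(ln.gene_a, ln.gene_b)
            if i < j:
                for a_id, parts in detect_split_genes(
                        rep["links"], clusters[i], clusters[j]):
                    split_calls.append((a_id, parts))
                    union(a_id, parts[0])
                    union(a_id, parts[1])
    groups_by_root: dict[str, dict] = {}
    for gid in owner:
        groups_by_root.setdefault(find(gid), {}).setdefault(owner[gid], []).append(gid)
    all_ids = [c.genome_id for c in clusters]
    core, near = [], []
    for members in groups_by_root.values():
        missing = [cid for cid in all_ids if cid not in members]
        if not missing:
            core.append(members)
        elif len(missing) == 1 and len(members) > 1:
            near.append(members)
    order = {c.genome_id: {g.id: k for k, g in enumerate(c.genes)} for c in clusters}
    key = lambda m: min(order[cid][g] for cid, gs in m.items() for g in gs
                        if cid == all_ids[0]) if all_ids[0] in m else 10**9
    core.sort(key=key)
    return CoreSet(groups=core, near_core=near, split_gene_calls=split_calls)
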