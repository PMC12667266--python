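"""Sequence/annotation data model and readers/writers shared by all stages.

Conventions
-----------
* All in-memory coordinates are 0-based half-open ``[start, end)``.
* Conversion to 1-based inclusive (GFF3) or 0-based half-open (BED) happens
  only at the format boundary.
* Circular replicons are stored linearly with ``topology == "circular"``;
  features that wrap the origin are represented as two sub-intervals.
* ``N`` never counts as a match in any identity computation anywhere in the
  package (conservative identity).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Malformed input file."""


class ContractViolation(ValueError):
    """An operation was handed arguments violating its preconditions."""


@dataclass
class GeneModel:
    """A single annotated feature (CDS, repeat_region, mobile_element, misc)."""

    id: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    kind: str = "CDS"
    product: str = ""
    translation: Optional[str] = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.start >= self.end:
            raise ContractViolation(
                f"feature {self.id!r}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ContractViolation(f"feature {self.id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    """A named DNA sequence (optionally circular) with an attached feature table."""

    id: str
    seq: str
    topology: str = "linear"
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ParseError(f"genome {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"genome {self.id!r}: non-DNA characters {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ContractViolation(f"bad topology {self.topology!r}")
        for f in self.features:
            if not (0 <= f.start < f.end <= len(self.seq)):
                raise ContractViolation(
                    f"feature {f.id!r} [{f.start},{f.end}) outside genome "
                    f"{self.id!r} of length {len(self.seq)}")

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin on circular genomes."""
        n = len(self.seq)
        if 0 <= start <= end <= n:
            return self.seq[start:end]
        if self.topology == "circular":
            return (self.seq * 2)[start % n: start % n + (end - start)]
        raise ContractViolation(f"[{start},{end}) outside linear genome of length {n}")


@dataclass
class DepthTrack:
    """Per-bin mean read depth along one genome."""

    genome_id: str
    bin_size: int
    depth: list

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ContractViolation("bin_size must be positive")
        if any(d < 0 for d in self.depth):
            raise ContractViolation("negative depth")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list:
    """Read a FASTA file into a list of :class:`Genome` (topology linear)."""
    path = Path(path)
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        genomes.append(Genome(id=rec.id, seq=seq))
    if not genomes and path.stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records found")
    return genomes


def read_protein_fasta(path) -> list:
    """Protein FASTA as (id, sequence) pairs (no DNA alphabet validation)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        out.append((rec.id, seq))
    return out


def write_fasta(genomes: Iterable[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

def _esc(value) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_gff3(genome: Genome, calls: Iterable[GeneModel], path=None) -> str:
    """Serialize feature calls as GFF3 (1-based inclusive coordinates).

    ``calls`` may be any objects exposing kind/start/end/strand/id and an
    optional ``attributes`` dict carrying evidence fields.
    """
    out = io.StringIO()
    out.write("##gff-version 3\n")
    out.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
    for c in calls:
        if not (0 <= c.start < c.end <= len(genome)):
            raise ContractViolation(
                f"call {getattr(c, 'id', '?')!r} [{c.start},{c.end}) outside "
                f"genome of length {len(genome)}")
        attrs = dict(getattr(c, "attributes", {}) or {})
        if getattr(c, "id", ""):
            attrs = {"ID": c.id, **attrs}
        attr_s = ";".join(f"{k}={_esc(v)}" for k, v in attrs.items()) or "."
        out.write("\t".join([
            genome.id, "micmob", c.kind,
            str(c.start + 1), str(c.end), ".", c.strand, ".", attr_s,
        ]) + "\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gff3(path) -> list:
    """Parse a GFF3 file back into :class:`GeneModel` records (0-based)."""
    feats = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ParseError(f"{path}: bad GFF3 line: {line[:60]!r}")
        attrs = {}
        if cols[8] != ".":
            for kv in cols[8].split(";"):
                if kv:
                    k, _, v = kv.partition("=")
                    attrs[k] = v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")
        feats.append(GeneModel(
            id=attrs.pop("ID", ""), start=int(cols[3]) - 1, end=int(cols[4]),
            strand=cols[6] if cols[6] in "+-" else "+", kind=cols[2],
            attributes=attrs))
    return feats


def write_bed(genome: Genome, calls: Iterable[GeneModel], path=None) -> str:
    out = io.StringIO()
    for c in calls:
        out.write(f"{genome.id}\t{c.start}\t{c.end}\t{getattr(c, 'id', '.') or '.'}"
                  f"\t0\t{c.strand}\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_bed(path) -> list:
    feats = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        feats.append(GeneModel(
            id=cols[3] if len(cols) > 3 and cols[3] != "." else f"bed_{i}",
            start=int(cols[1]), end=int(cols[2]),
            strand=cols[5] if len(cols) > 5 and cols[5] in "+-" else "+",
            kind="misc"))
    return feats


def read_genbank(path) -> list:
    """Minimal read-only GenBank support: sequence plus CDS / repeat_region."""
    genomes = []
    for rec in SeqIO.parse(str(path), "genbank"):
        feats = []
        for ft in rec.features:
            if ft.type not in ("CDS", "repeat_region", "mobile_element"):
                continue
            feats.append(GeneModel(
                id=ft.qualifiers.get("locus_tag", [ft.type])[0],
                start=int(ft.location.start), end=int(ft.location.end),
                strand="-" if ft.location.strand == -1 else "+",
                kind=ft.type,
                product=ft.qualifiers.get("product", [""])[0],
                translation=ft.qualifiers.get("translation", [None])[0]))
        genomes.append(Genome(id=rec.id, seq=str(rec.seq).upper(),
                              topology="circular" if rec.annotations.get("topology") == "circular" else "linear",
                              features=feats))
    return genomes


# ---------------------------------------------------------------------------
# Translation
# ---------------------------------------------------------------------------

#: start codons recoded to Met under each policy (position 0 only)
START_POLICIES = {
    "strict": frozenset({"ATG"}),
    "alt": frozenset({"ATG", "GTG", "TTG"}),
    "speculative": frozenset({"ATG", "GTG", "TTG", "ATA"}),
}


def translate(dna: str, table: int = 11, start_policy: str = "alt") -> str:
    """Translate a coding sequence under the bacterial/archaeal code.

    The first codon is recoded to Met when it is a recognized initiator under
    ``start_policy`` ("strict": ATG; "alt": +GTG/TTG; "speculative": +ATA).
    A single trailing stop is trimmed; internal stops are kept as ``*`` so
    callers can detect truncations. Codons containing N translate to ``X``
    when ambiguous.
    """
    dna = dna.upper()
    if len(dna) < 3:
        raise ContractViolation("need at least one codon")
    if start_policy not in START_POLICIES:
        raise ContractViolation(f"unknown start policy {start_policy!r}")
    trimmed = dna[: len(dna) - len(dna) % 3]
    prot = str(Seq(trimmed).translate(table=table))
    if prot.endswith("*"):
        prot = prot[:-1]
    if prot and trimmed[:3] in START_POLICIES[start_policy]:
        prot = "M" + prot[1:]
    return prot
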