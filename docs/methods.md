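# Methods

This note documents the models, detection rules, parameter choices and known
limitations of micmob. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Coordinate and identity conventions

All in-memory coordinates are 0-based half-open; conversion to 1-based
inclusive (GFF3) or 0-based half-open (BED) happens only in the writers.
Circular replicons are stored linearly with a topology flag; wrap-around
features are represented as ordered sub-intervals, and `Genome.slice` wraps.
An `N` base never counts as a match in any identity computation — a
conservative choice that slightly understates identity on ambiguous input
rather than overstating it.

Translation uses the bacterial/archaeal code (table 11). The genetic-code
table for ORF checks is an assumption: the organisms modeled are archaea and
table 11 is the standard choice for them. Start-codon policies: `strict`
(ATG), `alt` (ATG/GTG/TTG, the default — GTG and TTG initiate with Met), and
`speculative` (additionally ATA, which some archaeal genes may use; it is
opt-in because the evidence for it is weaker).

## Synthetic genomes and the truth ledger

Background sequence is i.i.d. at a configurable GC (default 0.33, the
genome-wide mean of the modeled chromosomes). No codon structure, repeat
families, GC skew or oligonucleotide bias is emulated: passing tests
demonstrate correct recovery of the planted geometry in that background,
not robustness to every repeat structure of real chromosomes. Planted ORFs
have a valid start, no internal stops and one stop; the background is not
guaranteed ORF-free and detectors do not assume it.

Default planted geometries are the study conditions of the modeled system:
221 bp direct repeats around a 12 kb (repeat-inclusive) island whose cargo
carries a miniature 6-ORF core; composite transposons with 25 bp ITRs, an
8 nt TSD outside the pair and none per element; two 9 nt microhomology
motifs placed 212 bp apart (start-to-start) in a recipient gene so that the
predicted integration produces 221 bp repeats; a 37 bp (frameshifting)
tandem duplication; a 31 kb duplication with a single inter-copy
substitution; strain pairs at 2 % per-base substitution divergence; mixed
populations at a stated carrier fraction. Scaled-down backgrounds (40–200 kb
rather than 1.7 Mb) are used in tests and in the acceptance script so the
whole desk-scale suite runs in well under a minute per scenario; the full
scale is supported.

Two generator details matter for exact-boundary assertions:

* **Clean boundaries.** Two to five background bases adjacent to each
  planted repeat/ITR/motif copy are forced to mismatch the corresponding
  flank of the other copy. Without this, a chance flanking match lets any
  seed-and-extend detector legitimately report a copy one or two bases
  longer than planted, which is an ambiguity of the sequence, not a detector
  error. Real data offers no such guarantee, so detectors never rely on it;
  it only makes `reported == planted` a meaningful test assertion.
* **Motif uniqueness.** The MMEJ plant redraws motifs until each occurs
  exactly once per genome (insertion junctions can create chance second
  copies). For motif lengths where uniqueness is combinatorially impossible
  at the genome size (4^L comparable to the genome length), planting fails
  explicitly rather than planting an ambiguous scenario.

Read simulation is uniform over the pooled DNA of a mixed population:
variant choice is weighted by carrier-fraction × genome length, which makes
the expected background depth equal `mean_depth` and the island depth equal
`carrier_fraction × mean_depth` exactly. Reads wrap the origin (the
chromosomes are circular), so expected coverage is uniform with no terminal
ramp. No sequencing-error model is applied; reads carry their true origin
so depth tracks need no mapper. Real-data use therefore requires an
externally produced depth file (bedGraph-style TSV).

## Direct-repeat islands and large duplications

Seeding uses exact shared 21-mers; each same-diagonal seed group is extended
once, ungapped, with X-drop scoring (match +1, mismatch −3, drop 12). The
best-scoring endpoints always fall on matching bases, so boundaries never
end in a mismatch. A pair is accepted if its cumulative inter-copy mismatch
fraction is ≤ `max_mismatch_frac` (default 0.02 — "near-identical"; the one
quantified large-duplication case in the modeled system showed a single
mismatch over 31 kb, and 2 % is comfortably below the matchSEG range while
far above chance). Contained pairs are suppressed in favor of maximal ones:
one call per biological element. Island calls additionally require the
repeat-inclusive span to fall within `island_len_range`
(default 1–100 kb). The island interval is reported repeat-inclusive and
the cargo interval repeat-exclusive, since span conventions differ between
descriptions; both are fields of the call.

Excision retains the upstream copy on the chromosome — the repeats are
near-identical so either scar is biologically plausible; fixing one makes
the operation deterministic. The circle is `cargo + downstream copy`,
marked circular. Sequence length is conserved exactly
(`len(chromosome) + len(circle) == len(genome)`), and integration at a
repeat copy is the exact inverse (the circle may be supplied in any
rotation; it is rotated so the repeat abuts the target copy).

## Transposons and composites

`find_itrs` compares the element's 5′ prefix with the reverse complement of
its 3′ suffix, anchored at both termini, and returns the longest length with
at most `max_mismatches` (default 4) whose innermost base matches; requiring
a matching inner base trims chance one-base extensions. The match-string
renders the left ITR with mismatches lowercased. TSD matching is exact-only:
the evidence for target-site duplications is exact flank identity, and
allowing mismatches would trade specificity for nothing the analyses need.
The composite rule: for an ordered pair of same-family elements (ungapped
ITR identity ≥ 70 %), neither element may have its own TSD and the
`tsd_len` (8) bases upstream of the first must equal those downstream of
the second. Elements flanked by individual TSDs moved separately and never
form a composite.

Element discovery is primarily annotation-guided (`annotate_element` on
known transposase loci); `scan_for_elements` offers seed-based de novo
discovery but is lower-confidence — with mismatched ITR copies the
seed-derived termini can shift by a few bases, so it guarantees overlapping
candidates, not exact boundaries.

## MMEJ junctions and coding consequences

Motif search enumerates maximal exact shared substrings within the MMEJ
length range (5–25 nt). Pairs are formed only from motifs occurring exactly
once in the donor and once in the recipient region (`unique_only`, default):
a motif repeated across the genome carries no breakpoint localization
signal, and the biological evidence modeled here is a pair of unique
motifs. `max_span` is interpreted as (maximum recipient span, maximum donor
span) — the recipient motifs must sit close together inside one gene (they
become the direct repeats), while the donor motifs may bracket a long
cargo. Pairs are ordered longest motif first, then leftmost.

The integration geometry cuts exactly at motif boundaries: the donor
contributes the cargo strictly between its motifs, and the recipient
segment from the start of motif 1 to the end of motif 2 (motif-inclusive)
appears twice, flanking the cargo. This is the one geometry that
reproduces island-bounding direct repeats of length
`inter-motif distance + motif length` and makes excision the exact inverse
of integration; alternatives (motif-exclusive duplication) would leave the
motifs unpaired in the product.

`orf_consequences` lifts plus-strand gene models linearly across a single
contiguous edit and compares translations. Classification: a divergence
confined to the last 10 residues of both forms is `cterm_replaced`
(reported with both terminal peptides) — deliberately checked before the
frameshift rule, because an edit at a gene's 3′ end replaces the terminus
rather than shifting the frame of the translated region; an in-gene edit of
length ≢ 0 (mod 3) is otherwise a `frameshift`; a shortened product is
`stop_gained`. Novel in-frame ATG/GTG/TTG (policy-dependent) starts inside
inserted sequence upstream of a gene are `start_gained`, with
`overlap_created` when the implied extension overlaps a neighboring gene.
Reverse-strand genes and genes whose start lies inside the edit are
reported as skipped, not fatal. Every reported consequence is re-derivable
by translating the stored before/after sequences; the tests do exactly
that.

`analyze_tandem_dup` finds the leftmost placement of a tandem duplication
turning the before-ORF into the after-ORF (equivalent placements exist when
the duplicated unit borders identical sequence; leftmost is reported),
flags frameshifts (length ≢ 0 mod 3), locates the resulting premature
stop, and lists wild-type sequons downstream of the duplication that are no
longer encoded in the truncated product.

## Segmentation

Within each chunk (default 400 kb) of genome A, exact 21-mers unique in both
sequences are chained by longest increasing subsequence (ties: longest
chain, then leftmost), merged into exact blocks, and inter-anchor gaps are
aligned with edlib (banded edit-distance DP). Alignment columns are
classified by windowed identity: a column is match-eligible when the 1 kb
window ending at it *or* the one it leads reaches ≥ 95 %; maximal eligible
runs of ≥ 500 bp on the A side, trimmed to matching end columns, become
matchSEGs. The 95 %/1 kb/500 bp values are classification decisions, not
measured facts: the observed identity inside matchSEGs of closely related
strain pairs is 97–99 %, so the threshold sits below the signal and far
above the ~25 % chance level; all three are configurable. Chunks restart at
the start of the previous chunk's last matchSEG; an anchorless chunk
becomes one divSEG and is logged, not an error. The a-side intervals tile
genome A exactly (checked as an internal invariant on every run). ANI is
summarized as the length-weighted mean matchSEG identity. Circular genomes
are compared as linearized; aligning the rotation ("point of ring opening")
is the caller's responsibility.

Pure-insertion junctions are ambiguous when inserted bases coincide with
flanking sequence; boundary placement may differ from a full-DP alignment
by a few bases, and the oracle-equivalence test accounts for that.

## Clusters and cores

Protein alignment is global with BLOSUM62, affine gaps (open −11,
extend −1) and free terminal gaps, so part-length homologs align without
end-gap penalties; identity is matches over aligned columns excluding
terminal gaps, coverage is the aligned fraction of each protein. Links
require identity ≥ 30 % and coverage ≥ 70 % on the better-covered side
(so a half-gene linking a full gene survives — split-gene evidence).
Ortholog groups are reciprocal best hits joined by single linkage; the core
is the set of groups with a member in every cluster, split parts counting
as one membership; groups missing exactly one cluster are reported as
near-core. Split-gene calls require two part-genes within ≤ 2 intervening
genes, aligned regions on the single gene overlapping < 10 % of it, and
combined coverage ≥ 80 %; part order is not constrained. The 80/10/2
thresholds are design choices for a phenomenon the source material
describes qualitatively.

## Sequons

A sequon is N-X-(S/T) with X ≠ P by default (the standard productive-sequon
constraint; a flag disables the proline rule for exact-motif replication).
Overlapping sequons are all reported. Fingerprint comparison maps each Asn
to its alignment column; two sequons match when their Asn residues share a
column. The matched-count matrix is symmetric with each protein's own count
on the diagonal. Fingerprints are rule-based counts; neural-network
glycosylation scoring is out of scope, so comparisons against
score-thresholded counts from such tools are approximate.

## Carriage estimation

The carrier fraction is mean region depth over a 10 %-trimmed mean of
outside-bin depths (trimming resists depth inflation from other repeats);
bins straddling a region boundary are excluded from both sides. The 95 % CI
is a seeded bootstrap over bins (default 1000 resamples). The estimator is
scale-invariant exactly and unbiased on the synthetic mixture model (tested
at f ∈ {0, 1/3, 1/2, 1} over 100 seeded replicates, mean within 2 SE).

## Numerical and degenerate-input choices

* Chaining and pair enumeration tie-breaks are deterministic (longest, then
  leftmost) so repeated runs are identical.
* Identical genomes segment to a single matchSEG at identity 100; an empty
  anchor set yields one divSEG per chunk.
* `ani` returns absent (None) when no matchSEG exists rather than 0.
* Bootstrap CIs are clamped to contain the point estimate (degenerate
  resamples at tiny bin counts).
* All generator and estimator randomness flows through numpy Generators
  seeded explicitly; library functions accept either a seed or a Generator.

## Known limitations

* No read mapper: real-data carriage estimation needs an external depth
  track. Junction-spanning read counting is not implemented.
* Gene liftover handles one contiguous edit and plus-strand genes;
  rearrangements and inversions are out of scope.
* De novo transposon discovery trades boundary exactness for not requiring
  annotations.
* Segmentation detects substitution/indel mosaics, not inversions or
  translocations.
* The synthetic background is i.i.d.; detector false-positive rates on real
  repeat-rich chromosomes are not characterized by this test suite.
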