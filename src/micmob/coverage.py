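"""Island-carriage estimation from relative read depth.

An unstable element present in only part of a population shows proportionally
reduced read depth: depth(region)/depth(background) estimates the fraction of
genome copies carrying the region. The background is a trimmed mean over
bins outside the region (robust to other repeats inflating depth), and the
confidence interval comes from a bin-level bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core_io import ContractViolation, DepthTrack, Genome


@dataclass
class CarrierEstimate:
    region: tuple
    depth_region: float
    depth_background: float
    fraction: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if self.fraction < 0:
            raise ContractViolation("fraction must be non-negative")


def depth_track(reads_or_path, genome: Genome, bin_size: int = 1_000) -> DepthTrack:
    """Per-bin mean depth from true-origin reads, or from a depth file.

    Reads are objects with an ``intervals`` attribute (lists of genomic
    intervals they cover); a path is parsed as bedGraph-style TSV
    (chrom, start, end, depth).
    """
    n = len(genome)
    cover = np.zeros(n + 1)
    if isinstance(reads_or_path, (str, Path)):
        for line in Path(reads_or_path).read_text().splitlines():
            if not line or line.startswith(("#", "track")):
                continue
            cols = line.split("\t")
            s, e, d = int(cols[1]), int(cols[2]), float(cols[3])
            cover[s] += d
            cover[min(e, n)] -= d
    else:
        for read in reads_or_path:
            for s, e in read.intervals:
                cover[max(0, s)] += 1
                cover[min(e, n)] -= 1
    per_base = np.cumsum(cover[:-1])
    nbins = -(-n // bin_size)
    depth = [float(per_base[i * bin_size:(i + 1) * bin_size].mean())
             for i in range(nbins)]
    return DepthTrack(genome_id=genome.id, bin_size=bin_size, depth=depth)


def estimate_carrier_fraction(track: DepthTrack, region: tuple,
                              trim: float = 0.1, n_boot: int = 1_000,
                              seed: int = 0) -> CarrierEstimate:
    """Fraction of genome copies carrying ``region`` (interval in bp).

    Bins straddling a region boundary are excluded from both sides; the
    background is a ``trim``-trimmed mean of the remaining outside bins.
    """
    bs = track.bin_size
    depth = np.asarray(track.depth, dtype=float)
    s, e = region
    region_idx = np.array([i for i in range(len(depth))
                           if i * bs >= s and (i + 1) * bs <= e])
    outside_idx = np.array([i for i in range(len(depth))
                            if (i + 1) * bs <= s or i * bs >= e])
    if len(region_idx) < 3:
        raise ContractViolation("region must span at least 3 full bins")
    if len(outside_idx) < 30:
        raise ContractViolation("background must span at least 30 bins")
    reg = depth[region_idx]
    bg = depth[outside_idx]
    bg_mean = float(stats.trim_mean(bg, trim))
    if bg_mean <= 0:
        raise ContractViolation("zero background depth")
    frac = float(reg.mean() / bg_mean)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        rb = rng.choice(reg, size=len(reg), replace=True)
        bb = rng.choice(bg, size=len(bg), replace=True)
        denom = stats.trim_mean(bb, trim)
        boots[b] = rb.mean() / denom if denom > 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return CarrierEstimate(region=region, depth_region=float(reg.mean()),
                           depth_background=bg_mean, fraction=frac,
                           ci_low=float(min(lo, frac)),
                           ci_high=float(max(hi, frac)))
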