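"""Peak-caller-free ChIP-seq occupancy quantification.

The pipeline quantifies transcription-factor binding without peak calling:

1. each mapped read (5' position + strand) is extended to the sonication
   fragment size (default 200 bp) towards 3';
2. per-position coverage is scaled by sequencing depth (division by the
   genome-wide mean, so every scaled track has mean 1);
3. the IP/input ratio is formed per replicate (with a pseudocount for
   zero-coverage positions);
4. replicate ratios are averaged position-wise (arithmetic mean first, log2
   afterwards for visualisation);
5. per-gene occupancy is the mean linear ratio in a fixed window (default
   300 bp) around the gene's TSS.

All coordinate arithmetic wraps on circular genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneRecord

__all__ = [
    "ReadSet",
    "CoverageTrack",
    "RatioTrack",
    "extend_reads",
    "coverage",
    "scale_track",
    "ratio_track",
    "mean_ratio_track",
    "mean_log2_track",
    "window_occupancy",
    "occupancy_table",
]


@dataclass
class ReadSet:
    """Mapped single-end reads: 5' coordinates plus strands on one genome."""

    positions: np.ndarray  # 0-based 5' coordinates
    strands: np.ndarray  # '+' / '-' per read
    genome_length: int
    label: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.strands = np.asarray(self.strands)
        if self.positions.shape != self.strands.shape:
            raise ValueError("positions and strands must have equal shape")
        if self.positions.size and (
            self.positions.min() < 0 or self.positions.max() >= self.genome_length
        ):
            raise ValueError("read positions outside [0, genome_length)")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class CoverageTrack:
    values: np.ndarray
    genome_length: int
    scaled: bool = False
    label: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome_length,):
            raise ValueError("track length does not match genome length")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")


@dataclass
class RatioTrack:
    """Linear IP/input ratio per position for one replicate."""

    values: np.ndarray
    genome_length: int
    replicate: str = ""
    condition: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome_length,):
            raise ValueError("track length does not match genome length")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("ratio values must be finite and non-negative")


def extend_reads(reads: ReadSet, fragment_length: int = 200) -> np.ndarray:
    """Extend 5'-anchored reads to fragment size towards 3'.

    Returns an (n, 2) array of half-open intervals. A + read at p becomes
    [p, p+L); a - read with 5' end at p becomes [p-L+1, p+1). Intervals may
    extend past the sequence bounds; :func:`coverage` wraps them.
    """
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    p = reads.positions
    fwd = reads.strands == "+"
    starts = np.where(fwd, p, p - fragment_length + 1)
    return np.stack([starts, starts + fragment_length], axis=1)


def coverage(intervals: np.ndarray, genome_length: int, circular: bool = True) -> CoverageTrack:
    """Per-position count of covering intervals. Sum equals total interval length."""
    intervals = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    diff = np.zeros(genome_length + 1, dtype=float)
    if intervals.size:
        lengths = intervals[:, 1] - intervals[:, 0]
        if (lengths < 0).any():
            raise ValueError("intervals must have start <= end")
        if (lengths > genome_length).any():
            raise ValueError("interval longer than genome")
        if circular:
            starts = intervals[:, 0] % genome_length
            ends = starts + lengths
            wrap = ends > genome_length
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, np.minimum(ends, genome_length), -1.0)
            if wrap.any():
                np.add.at(diff, np.zeros(wrap.sum(), dtype=np.int64), 1.0)
                np.add.at(diff, ends[wrap] - genome_length, -1.0)
        else:
            starts = np.clip(intervals[:, 0], 0, genome_length)
            ends = np.clip(intervals[:, 1], 0, genome_length)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, ends, -1.0)
    values = np.cumsum(diff[:-1])
    return CoverageTrack(values=values, genome_length=genome_length, scaled=False)


def scale_track(track: CoverageTrack) -> CoverageTrack:
    """Depth-normalise: divide by the genome-wide mean so the result has mean 1."""
    mean = track.values.mean()
    if mean <= 0:
        raise ValueError("cannot scale an all-zero coverage track")
    return CoverageTrack(
        values=track.values / mean,
        genome_length=track.genome_length,
        scaled=True,
        label=track.label,
    )


def ratio_track(
    ip: CoverageTrack,
    input_: CoverageTrack,
    pseudocount: float = 0.1,
    replicate: str = "",
    condition: str = "",
) -> RatioTrack:
    """Per-position (ip + eps) / (input + eps) on depth-scaled tracks."""
    if ip.genome_length != input_.genome_length:
        raise ValueError("IP and input tracks cover different genome lengths")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = (ip.values + pseudocount) / (input_.values + pseudocount)
    return RatioTrack(values=values, genome_length=ip.genome_length,
                      replicate=replicate, condition=condition)


def mean_ratio_track(ratios: list[RatioTrack]) -> np.ndarray:
    """Position-wise arithmetic mean of linear replicate ratios."""
    if not ratios:
        raise ValueError("need at least one replicate ratio track")
    lengths = {r.genome_length for r in ratios}
    if len(lengths) != 1:
        raise ValueError("replicate tracks cover different genome lengths")
    return np.mean([r.values for r in ratios], axis=0)


def mean_log2_track(ratios: list[RatioTrack]) -> np.ndarray:
    """log2 of the replicate-averaged linear ratio (average first, then log2)."""
    return np.log2(mean_ratio_track(ratios))


def _window_bounds(gene: GeneRecord, window: int, anchor: str) -> tuple[int, int]:
    if anchor == "centered":
        lo = gene.tss - window // 2
        return lo, lo + window
    if anchor == "upstream":
        if gene.strand == "+":
            return gene.tss - window, gene.tss
        return gene.tss + 1, gene.tss + 1 + window
    raise ValueError(f"anchor must be 'centered' or 'upstream', got {anchor!r}")


def window_occupancy(
    mean_ratio: np.ndarray,
    genes: list[GeneRecord],
    window: int = 300,
    anchor: str = "centered",
    circular: bool = True,
) -> pd.Series:
    """Mean linear ratio in a window around each gene's TSS (strand-agnostic).

    The default window is 300 bp centered on the TSS, i.e. [tss-150, tss+150).
    Returns a Series indexed by gene_id.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    mean_ratio = np.asarray(mean_ratio, dtype=float)
    n = mean_ratio.shape[0]
    out = {}
    for g in genes:
        if g.end > n or g.start < 0:
            raise ValueError(f"gene {g.gene_id} outside the coordinate space")
        lo, hi = _window_bounds(g, window, anchor)
        if circular:
            idx = np.arange(lo, hi) % n
            out[g.gene_id] = float(mean_ratio[idx].mean())
        else:
            lo, hi = max(lo, 0), min(hi, n)
            if hi <= lo:
                raise ValueError(f"gene {g.gene_id}: empty window on linear genome")
            out[g.gene_id] = float(mean_ratio[lo:hi].mean())
    return pd.Series(out, name="occupancy")


def occupancy_table(
    ip_readsets: dict[str, list[ReadSet]],
    input_readsets: dict[str, list[ReadSet]],
    genes: list[GeneRecord],
    fragment_length: int = 200,
    window: int = 300,
    pseudocount: float = 0.1,
    anchor: str = "centered",
    circular: bool = True,
) -> pd.DataFrame:
    """Run the full occupancy pipeline per condition.

    ``ip_readsets`` / ``input_readsets`` map condition name to a list of
    replicate ReadSets. Returns a wide table indexed by gene_id with one
    ``occ_<condition>`` column per condition.
    """
    if set(ip_readsets) != set(input_readsets):
        raise ValueError("IP and input conditions differ")
    cols = {}
    for condition, ip_reps in ip_readsets.items():
        in_reps = input_readsets[condition]
        if len(ip_reps) != len(in_reps):
            raise ValueError(f"{condition}: replicate counts differ between IP and input")
        ratios = []
        for i, (ip_rs, in_rs) in enumerate(zip(ip_reps, in_reps)):
            ip_cov = scale_track(coverage(extend_reads(ip_rs, fragment_length),
                                          ip_rs.genome_length, circular))
            in_cov = scale_track(coverage(extend_reads(in_rs, fragment_length),
                                          in_rs.genome_length, circular))
            ratios.append(ratio_track(ip_cov, in_cov, pseudocount,
                                      replicate=str(i), condition=condition))
        mean_track = mean_ratio_track(ratios)
        cols[f"occ_{condition}"] = window_occupancy(mean_track, genes, window, anchor, circular)
    return pd.DataFrame(cols)
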