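"""TSS-anchored positional analyses of promoter sequence.

Two analyses share the same strand-aware window extraction (default -150
to +50 relative to the TSS, position 0 = first transcribed base):

* per-position nucleotide enrichment of a target promoter set against a
  background promoter set (log2 ratio of pseudocounted frequencies);
* trinucleotide major-groove bendability profiles: each position is scored
  by a strand-symmetric trinucleotide scale, averaged across sequences,
  smoothed with a centered running mean and banded with a percentile
  bootstrap over sequences.

The published DNase-I-derived trinucleotide scales are not bundled; the
scale is a pluggable input (2-column TSV) and a synthetic toy scale is
provided for tests and demonstrations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import circular_slice, revcomp, sub_rng
from .genome import GeneRecord, Genome

__all__ = [
    "AnchoredSequenceSet",
    "TrinucleotideScale",
    "Profile",
    "extract_anchored",
    "positional_enrichment",
    "bendability_profile",
    "compare_profiles",
    "toy_scale",
]


@dataclass
class AnchoredSequenceSet:
    """Equal-length windows around TSSs, oriented so upstream is leftward."""

    sequences: list[str]
    offsets: np.ndarray  # relative position of each window column
    label: str = ""

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=int)
        w = self.offsets.size
        if any(len(s) != w for s in self.sequences):
            raise ValueError("all windows must match the offset grid length")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def window(self) -> int:
        return self.offsets.size


def extract_anchored(
    genome: Genome,
    genes: list[GeneRecord],
    from_pos: int = -150,
    to_pos: int = 50,
    label: str = "",
    on_overhang: str = "error",
) -> AnchoredSequenceSet:
    """Strand-aware TSS windows covering relative positions [from_pos, to_pos).

    Windows of minus-strand genes are reverse-complemented so that upstream
    is always to the left. Windows wrap on circular genomes; on linear
    genomes an overhanging window raises (``on_overhang='error'``) or drops
    the gene (``'skip'``).
    """
    if from_pos >= to_pos:
        raise ValueError("from_pos must be < to_pos")
    if on_overhang not in ("error", "skip"):
        raise ValueError("on_overhang must be 'error' or 'skip'")
    width = to_pos - from_pos
    n = len(genome)
    seqs = []
    for g in genes:
        if g.strand == "+":
            start = g.tss + from_pos
        else:
            start = g.tss - to_pos + 1
        if not genome.circular and (start < 0 or start + width > n):
            if on_overhang == "error":
                raise ValueError(f"window for {g.gene_id} overhangs the linear genome")
            continue
        window = circular_slice(genome.sequence, start, width)
        seqs.append(window if g.strand == "+" else revcomp(window))
    return AnchoredSequenceSet(
        sequences=seqs, offsets=np.arange(from_pos, to_pos), label=label
    )


def _base_counts(aset: AnchoredSequenceSet) -> np.ndarray:
    """(4, window) counts of A,C,G,T per position (other characters ignored)."""
    counts = np.zeros((4, aset.window))
    order = {b: i for i, b in enumerate("ACGT")}
    for seq in aset.sequences:
        for i, b in enumerate(seq.upper()):
            if b in order:
                counts[order[b], i] += 1
    return counts


def positional_enrichment(
    target: AnchoredSequenceSet,
    background: AnchoredSequenceSet,
    pseudocount: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Per-position, per-base log2 enrichment of target over background.

    Frequencies are computed from pseudocounted counts,
    f(i, b) = (c(i, b) + pi) / (n + 4 pi), then compared as
    log2(f_target / f_background). Raw (un-pseudocounted) frequency tables
    are returned alongside so alternative statistics can be layered on.
    """
    if target.window != background.window or not np.array_equal(
        target.offsets, background.offsets
    ):
        raise ValueError("target and background window geometry differ")
    result = {}
    freqs = {}
    for name, aset in (("target", target), ("background", background)):
        counts = _base_counts(aset)
        n_at_pos = counts.sum(axis=0)
        raw = np.divide(counts, n_at_pos, out=np.zeros_like(counts), where=n_at_pos > 0)
        result[f"freq_{name}"] = pd.DataFrame(
            raw.T, index=aset.offsets, columns=list("ACGT")
        )
        freqs[name] = (counts + pseudocount) / (n_at_pos + 4 * pseudocount)
    enr = np.log2(freqs["target"] / freqs["background"])
    result["enrichment"] = pd.DataFrame(enr.T, index=target.offsets, columns=list("ACGT"))
    return result


_TRINUCS = ["".join(t) for t in itertools.product("ACGT", repeat=3)]


def _tri_class(t: str) -> str:
    return min(t, revcomp(t))


@dataclass
class TrinucleotideScale:
    """Strand-symmetric trinucleotide -> bendability value mapping."""

    values: dict[str, float]
    name: str = "unnamed"

    def __post_init__(self):
        full = {}
        for t in _TRINUCS:
            cls = _tri_class(t)
            if cls in self.values:
                full[t] = float(self.values[cls])
            elif t in self.values:
                full[t] = float(self.values[t])
            else:
                raise ValueError(f"scale is missing trinucleotide class {cls}")
            if not np.isfinite(full[t]):
                raise ValueError(f"non-finite scale value for {t}")
        for t in _TRINUCS:
            if full[t] != full[revcomp(t)]:
                raise ValueError(f"scale not strand-symmetric at {t}/{revcomp(t)}")
        self.values = full

    def __getitem__(self, trinuc: str) -> float:
        return self.values[trinuc.upper()]

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "TrinucleotideScale":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["trinucleotide", "value"])
        return cls(
            values=dict(zip(df["trinucleotide"].str.upper(), df["value"])),
            name=name or str(path),
        )

    def to_tsv(self, path):
        rows = sorted({_tri_class(t) for t in _TRINUCS})
        with open(path, "w") as fh:
            fh.write(f"# trinucleotide bendability scale: {self.name}\n")
            for t in rows:
                fh.write(f"{t}\t{self.values[t]!r}\n")


def toy_scale() -> TrinucleotideScale:
    """Synthetic demonstration scale (NOT a published bendability scale).

    Value = -0.1 per A/T base in the trinucleotide, so A/T-rich steps read
    as rigid (more negative) and G/C-rich steps as flexible. Strand
    symmetric by construction.
    """
    vals = {t: -0.1 * sum(b in "AT" for b in t) for t in _TRINUCS}
    return TrinucleotideScale(values=vals, name="toy-synthetic")


@dataclass
class Profile:
    """TSS-anchored positional statistic with a confidence band."""

    positions: np.ndarray
    mean: np.ndarray  # smoothed per-position mean
    lower: np.ndarray
    upper: np.ndarray
    span: int
    n: int
    raw_mean: np.ndarray | None = None
    boot_curves: np.ndarray | None = field(default=None, repr=False)
    n_skipped: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions)
        for name in ("mean", "lower", "upper"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.positions.shape:
                raise ValueError(f"{name} does not match the position grid")
        if ((self.lower > self.mean + 1e-12) | (self.upper < self.mean - 1e-12)).any():
            raise ValueError("confidence bounds must bracket the mean")


def _running_mean(x: np.ndarray, span: int) -> np.ndarray:
    """Centered running mean of odd width `span`, window shrunk at edges.

    Works row-wise on 2-D input.
    """
    if span % 2 != 1 or span < 1:
        raise ValueError("span must be odd and >= 1")
    x = np.asarray(x, dtype=float)
    was_1d = x.ndim == 1
    x = np.atleast_2d(x)
    h = span // 2
    csum = np.cumsum(np.pad(x, ((0, 0), (1, 0))), axis=1)
    n = x.shape[1]
    idx_hi = np.minimum(np.arange(n) + h + 1, n)
    idx_lo = np.maximum(np.arange(n) - h, 0)
    out = (csum[:, idx_hi] - csum[:, idx_lo]) / (idx_hi - idx_lo)
    return out[0] if was_1d else out


def _per_sequence_values(
    windows: AnchoredSequenceSet, scale: TrinucleotideScale
) -> tuple[np.ndarray, int]:
    """(n_seq, window-2) matrix of scale values; NaN where a trinucleotide
    contains a non-ACGT base. Returns (matrix, number of skipped positions)."""
    if windows.window < 3:
        raise ValueError("window must span at least 3 bases")
    P = windows.window - 2
    V = np.full((len(windows), P), np.nan)
    for i, seq in enumerate(windows.sequences):
        s = seq.upper()
        for j in range(P):
            tri = s[j:j + 3]
            if all(b in "ACGT" for b in tri):
                V[i, j] = scale[tri]
    return V, int(np.isnan(V).sum())


def bendability_profile(
    windows: AnchoredSequenceSet,
    scale: TrinucleotideScale,
    span: int = 11,
    ci: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> Profile:
    """Smoothed mean bendability across sequences with a bootstrap band.

    Position i of each sequence is scored by the trinucleotide starting
    there (profile length = window - 2). The cross-sequence mean is
    smoothed with a centered running mean of width ``span``; the band is a
    percentile bootstrap over sequences (resample sequences with
    replacement, recompute the smoothed mean, take the ci quantiles).
    """
    V, n_skipped = _per_sequence_values(windows, scale)
    n = V.shape[0]
    if n == 0:
        raise ValueError("empty sequence set")
    valid = ~np.isnan(V)
    filled = np.nan_to_num(V)
    raw_mean = filled.sum(axis=0) / np.maximum(valid.sum(axis=0), 1)
    smoothed = _running_mean(raw_mean, span)

    rng = sub_rng(seed, "bendability-boot")
    weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)
    boot_sum = weights @ filled
    boot_cnt = weights @ valid
    boot_raw = boot_sum / np.maximum(boot_cnt, 1)
    boot_smoothed = _running_mean(boot_raw, span)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    lower = np.quantile(boot_smoothed, lo_q, axis=0)
    upper = np.quantile(boot_smoothed, hi_q, axis=0)
    # percentile band can exclude the point estimate in tiny samples
    lower, upper = np.minimum(lower, smoothed), np.maximum(upper, smoothed)
    return Profile(
        positions=windows.offsets[:-2],
        mean=smoothed,
        lower=lower,
        upper=upper,
        span=span,
        n=n,
        raw_mean=raw_mean,
        boot_curves=boot_smoothed,
        n_skipped=n_skipped,
    )


def compare_profiles(target: Profile, background: Profile) -> Profile:
    """Difference of smoothed means with a combined bootstrap band.

    Both profiles must carry their bootstrap curves (built on the same
    position grid); the band comes from independently pairing bootstrap
    replicates of the two sets.
    """
    if not np.array_equal(target.positions, background.positions):
        raise ValueError("profiles are on different position grids")
    diff = target.mean - background.mean
    if target.boot_curves is None or background.boot_curves is None:
        raise ValueError("both profiles need bootstrap curves for a combined band")
    nb = min(target.boot_curves.shape[0], background.boot_curves.shape[0])
    boot_diff = target.boot_curves[:nb] - background.boot_curves[:nb]
    lower = np.quantile(boot_diff, 0.025, axis=0)
    upper = np.quantile(boot_diff, 0.975, axis=0)
    lower, upper = np.minimum(lower, diff), np.maximum(upper, diff)
    return Profile(
        positions=target.positions,
        mean=diff,
        lower=lower,
        upper=upper,
        span=target.span,
        n=min(target.n, background.n),
        boot_curves=boot_diff,
    )
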