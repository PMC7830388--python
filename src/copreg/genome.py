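"""Genome and gene-annotation containers.

A :class:`Genome` is the single source of coordinates for the whole pipeline:
a (by default circular) chromosome plus non-overlapping gene records with
strand-aware transcription start sites (TSS). Coordinates are 0-based
half-open throughout; GFF3 export converts to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["GeneRecord", "Genome"]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 0-based half-open interval on one strand.

    The TSS is the first transcribed base on the gene's strand: ``start`` for
    + genes and ``end - 1`` for - genes.
    """

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: require start < end, got [{self.start}, {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Genome:
    name: str
    sequence: str
    circular: bool = True
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("genome sequence must be non-empty")
        n = len(self.sequence)
        last_end = -1
        for g in sorted(self.genes, key=lambda g: g.start):
            if g.start < 0 or g.end > n:
                raise ValueError(f"gene {g.gene_id} outside [0, {n})")
            if g.start < last_end:
                raise ValueError(f"gene {g.gene_id} overlaps a previous gene")
            last_end = g.end

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "Genome":
        return replace(self, sequence=sequence)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def intergenic_mask(self):
        """Boolean array, True where no gene body covers the position."""
        import numpy as np

        mask = np.ones(len(self.sequence), dtype=bool)
        for g in self.genes:
            mask[g.start:g.end] = False
        return mask

    def intergenic_sequences(self) -> list[str]:
        """Maximal runs of intergenic sequence (wrap-aware on circular genomes)."""
        import numpy as np

        mask = self.intergenic_mask()
        if mask.all():
            return [self.sequence]
        if not mask.any():
            return []
        n = len(mask)
        edges = np.flatnonzero(np.diff(mask.astype(int)))
        # runs of True in linear coordinates
        starts = [int(e) + 1 for e in edges if not mask[e]]
        ends = [int(e) + 1 for e in edges if mask[e]]
        if mask[0]:
            starts = [0] + starts
        if mask[-1]:
            ends = ends + [n]
        runs = list(zip(starts, ends))
        if self.circular and mask[0] and mask[-1] and len(runs) > 1:
            # merge the run touching the origin
            (s0, e0), (sl, el) = runs[0], runs[-1]
            runs = runs[1:-1] + [(sl, el + e0)]
            return [
                self.sequence[s:e] if e <= n else self.sequence[s:] + self.sequence[: e - n]
                for s, e in runs
            ]
        return [self.sequence[s:e] for s, e in runs]
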