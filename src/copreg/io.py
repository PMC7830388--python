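"""Readers and writers for the pipeline's plain-text interchange formats.

FASTA via Biopython, GFF3 via gffutils (1-based inclusive on disk, 0-based
half-open in memory), reads as 6-column BED with one record per read
(length-1 interval anchored at the 5' end), coverage tracks as bedGraph,
tables as TSV, motifs in minimal MEME text format, truth records as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chip_occupancy import ReadSet
from .genome import Genome, GeneRecord
from .motif import MotifModel
from .synthetic_data import PlantedSite, SyntheticTruth

__all__ = [
    "write_fasta", "read_fasta",
    "write_gff3", "read_gff3",
    "write_reads_bed", "read_reads_bed",
    "write_bedgraph",
    "write_counts", "read_counts", "write_sample_sheet", "read_sample_sheet",
    "write_truth", "read_truth",
    "write_meme", "read_meme",
]


def write_fasta(genome: Genome, path) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.name,
                    description=f"circular={genome.circular}")
    SeqIO.write([rec], str(path), "fasta")


def read_fasta(path, circular: bool = True) -> Genome:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected a single-sequence FASTA, got {len(records)} records")
    rec = records[0]
    if "circular=False" in (rec.description or ""):
        circular = False
    return Genome(name=rec.id, sequence=str(rec.seq).upper(), circular=circular)


def write_gff3(genome: Genome, path) -> None:
    """Genes as GFF3 `gene` features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {len(genome)}\n")
        for g in sorted(genome.genes, key=lambda g: g.start):
            fh.write(
                f"{genome.name}\tcopreg\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )


def read_gff3(path) -> list[GeneRecord]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for feat in db.features_of_type("gene", order_by="start"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(GeneRecord(gid, feat.start - 1, feat.end, feat.strand))
    return genes


def write_reads_bed(reads: ReadSet, path, chrom: str = "chr") -> None:
    """One record per read: 0-based half-open length-1 interval at the 5' end."""
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": reads.positions,
            "end": reads.positions + 1,
            "name": reads.label or "read",
            "score": 0,
            "strand": reads.strands,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_reads_bed(path, genome_length: int, label: str = "") -> ReadSet:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return ReadSet(
        positions=df["start"].to_numpy(),
        strands=df["strand"].to_numpy(),
        genome_length=genome_length,
        label=label or (df["name"].iloc[0] if len(df) else ""),
    )


def write_bedgraph(values: np.ndarray, path, chrom: str = "chr") -> None:
    """Run-length-compressed 4-column bedGraph (0-based half-open)."""
    values = np.asarray(values, dtype=float)
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{values[s]:.6g}\n")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_sample_sheet(conditions: pd.Series, path) -> None:
    df = pd.DataFrame({"sample": conditions.index, "condition": conditions.to_numpy()})
    df["replicate"] = df.groupby("condition").cumcount() + 1
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["condition"].to_numpy(), index=df["sample"], name="condition")


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "regulon_gene_ids": sorted(truth.regulon_gene_ids),
        "planted_sites": [
            {"position": s.position, "strand": s.strand, "sequence": s.sequence}
            for s in truth.planted_sites
        ],
        "log2_fold_changes": truth.log2_fold_changes,
        "chip_enrichment": truth.chip_enrichment,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        regulon_gene_ids=set(payload["regulon_gene_ids"]),
        planted_sites=[PlantedSite(**s) for s in payload["planted_sites"]],
        log2_fold_changes=payload["log2_fold_changes"],
        chip_enrichment=payload["chip_enrichment"],
    )


def write_meme(model: MotifModel, path, name: str = "MOTIF1") -> None:
    """Minimal MEME text format: version, alphabet, background, matrix."""
    bg = model.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {model.width} "
            f"nsites= 0 E= 0\n"
        )
        for col in model.theta.T:
            fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")


def read_meme(path) -> MotifModel:
    lines = Path(path).read_text().splitlines()
    bg = np.full(4, 0.25)
    theta_rows: list[list[float]] = []
    width = None
    it = iter(enumerate(lines))
    for i, line in it:
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
        if line.startswith("letter-probability matrix"):
            tokens = dict(zip(line.split()[2::2], line.split()[3::2]))
            width = int(tokens.get("w=", tokens.get("w", 0)) or line.split("w=")[1].split()[0])
            for row in lines[i + 1:i + 1 + width]:
                theta_rows.append([float(v) for v in row.split()])
            break
    if width is None:
        raise ValueError("no letter-probability matrix found")
    theta = np.array(theta_rows).T
    theta /= theta.sum(axis=0, keepdims=True)
    return MotifModel(width=width, theta=theta, background=bg / bg.sum(), gamma=0.5)
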