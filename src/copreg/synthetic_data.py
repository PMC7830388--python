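"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates a copper-shock regulon study on a small circular
archaeal chromosome: annotated genes, a degenerate binding motif planted
upstream of a chosen regulon, ChIP IP reads enriched around the planted
sites versus uniform input reads (replicated, two conditions), and
negative-binomial RNA-seq counts with planted fold inductions. A
:class:`SyntheticTruth` record makes recovery tests possible.

Every operation is a pure function of its inputs and seed; replicates use
independent sub-streams derived from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import IUPAC, revcomp, sub_rng
from .chip_occupancy import ReadSet
from .genome import Genome, GeneRecord

__all__ = [
    "Genome",
    "GeneRecord",
    "PlantedSite",
    "SyntheticTruth",
    "StudyData",
    "generate_genome",
    "plant_motif",
    "simulate_chip_reads",
    "simulate_counts",
    "simulate_study",
    "COPPER_CONSENSUS",
    "DEFAULT_EFFECT_SIZES",
]

# Minimal palindromic consensus of the copper-responsive regulator's binding site.
COPPER_CONSENSUS = "TTNNCAWWWTGNNAA"

# Planted log2 fold-change ladder spanning weak to very strong induction
# (~2-fold up to ~290-fold, the range seen for copper-shock regulons).
DEFAULT_EFFECT_SIZES = (1.0, 2.5, 6.14, 8.2)


@dataclass(frozen=True)
class PlantedSite:
    position: int  # genomic start of the realized site (0-based)
    strand: str  # strand of the target gene
    sequence: str  # realization as read on the gene's strand

    @property
    def center(self) -> int:
        return self.position + len(self.sequence) // 2


@dataclass
class SyntheticTruth:
    regulon_gene_ids: set[str]
    planted_sites: list[PlantedSite] = field(default_factory=list)
    log2_fold_changes: dict[str, float] = field(default_factory=dict)
    chip_enrichment: float = 1.0


@dataclass
class StudyData:
    """One complete synthetic study: genome + ChIP read sets + counts + truth."""

    genome: Genome
    truth: SyntheticTruth
    ip_readsets: dict[str, list[ReadSet]]
    input_readsets: dict[str, list[ReadSet]]
    counts: pd.DataFrame  # genes x samples
    conditions: pd.Series  # sample -> condition label


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def generate_genome(
    length: int,
    n_genes: int,
    min_intergenic: int = 200,
    gc: float = 0.5,
    seed: int = 0,
    gene_length_range: tuple[int, int] = (300, 600),
    circular: bool = True,
    name: str = "synthetic_chromosome",
) -> Genome:
    """Random circular genome with non-overlapping genes and guaranteed gaps.

    Genes are laid out sequentially with intergenic gaps of at least
    ``min_intergenic`` bases; leftover space is distributed randomly over the
    gaps. Strands are drawn independently per gene.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    gmin, gmax = gene_length_range
    if gmin < 1 or gmax < gmin:
        raise ValueError("invalid gene_length_range")
    if n_genes * (gmin + min_intergenic) > length:
        raise ValueError(
            f"cannot pack {n_genes} genes of >= {gmin} bp with {min_intergenic} bp "
            f"gaps into {length} bp"
        )
    rng = sub_rng(seed, "genome")
    sequence = _random_sequence(rng, length, gc)
    genes: list[GeneRecord] = []
    if n_genes > 0:
        budget = length - n_genes * min_intergenic
        lengths = rng.integers(gmin, gmax + 1, size=n_genes)
        if lengths.sum() > budget:
            # shrink draws proportionally towards the minimum so packing fits
            excess = lengths - gmin
            scale = (budget - n_genes * gmin) / max(excess.sum(), 1)
            lengths = gmin + np.floor(excess * scale).astype(int)
        spare = length - int(lengths.sum()) - n_genes * min_intergenic
        gaps = min_intergenic + rng.multinomial(spare, np.full(n_genes, 1.0 / n_genes))
        strands = rng.choice(["+", "-"], size=n_genes)
        pos = int(gaps[0])
        for i in range(n_genes):
            start, end = pos, pos + int(lengths[i])
            genes.append(GeneRecord(f"gene{i + 1:04d}", start, end, str(strands[i])))
            pos = end + int(gaps[(i + 1) % n_genes]) if i + 1 < n_genes else end
    return Genome(name=name, sequence=sequence, circular=circular, genes=genes)


def _realize_iupac(rng: np.random.Generator, consensus: str) -> str:
    out = []
    for code in consensus.upper():
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {code!r}")
        out.append(allowed[rng.integers(len(allowed))] if len(allowed) > 1 else allowed)
    return "".join(out)


def plant_motif(
    genome: Genome,
    consensus: str,
    target_gene_ids: set[str],
    offset_upstream: int = 30,
    seed: int = 0,
) -> tuple[Genome, list[PlantedSite]]:
    """Overwrite one consensus realization upstream of each target gene's TSS.

    The realized site occupies, on the gene's strand, the ``w`` bases ending
    ``offset_upstream`` bases 5' of the TSS. Degenerate consensus positions
    are drawn uniformly from their allowed bases. Raises if the site window
    would collide with any gene body.
    """
    rng = sub_rng(seed, "plant")
    w = len(consensus)
    n = len(genome)
    seq = list(genome.sequence)
    sites: list[PlantedSite] = []
    for gid in sorted(target_gene_ids):
        gene = genome.gene(gid)
        realization = _realize_iupac(rng, consensus)
        if gene.strand == "+":
            start = gene.tss - offset_upstream - w
            genomic = realization
        else:
            start = gene.tss + offset_upstream + 1
            genomic = revcomp(realization)
        if not genome.circular and (start < 0 or start + w > n):
            raise ValueError(f"{gid}: planted site outside linear genome")
        positions = [(start + k) % n for k in range(w)]
        for g in genome.genes:
            if any(g.start <= p < g.end for p in positions):
                raise ValueError(
                    f"{gid}: planted site at {start % n} collides with gene body {g.gene_id}"
                )
        for p, base in zip(positions, genomic):
            seq[p] = base
        sites.append(PlantedSite(position=start % n, strand=gene.strand, sequence=realization))
    return genome.with_sequence("".join(seq)), sites


def simulate_chip_reads(
    genome: Genome,
    sites: list[PlantedSite],
    n_reads: int = 50_000,
    enrichment: float = 20.0,
    site_halfwidth: int = 150,
    n_replicates: int = 3,
    seed: int = 0,
    condition: str = "",
) -> tuple[list[ReadSet], list[ReadSet]]:
    """Simulate replicate IP and input read sets (5' positions + strands).

    Input read starts are uniform over the circular genome. IP starts follow
    a mixture: with probability e*W / (e*W + (L - W)) uniform within the
    union of +/- site_halfwidth windows around site centers (W = union
    width, e = enrichment), else uniform over the rest of the genome --
    i.e. per-position read density is `enrichment`-fold higher inside site
    windows. enrichment=1 collapses to uniform.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    L = len(genome)
    in_window = np.zeros(L, dtype=bool)
    for s in sites:
        idx = np.arange(s.center - site_halfwidth, s.center + site_halfwidth) % L
        in_window[idx] = True
    window_pos = np.flatnonzero(in_window)
    bg_pos = np.flatnonzero(~in_window)
    W = window_pos.size
    p_site = (enrichment * W) / (enrichment * W + (L - W)) if W else 0.0

    ip_sets, input_sets = [], []
    for r in range(n_replicates):
        rng_ip = sub_rng(seed, condition, "ip", r)
        rng_in = sub_rng(seed, condition, "input", r)
        n_site = rng_ip.binomial(n_reads, p_site) if W else 0
        parts = []
        if n_site:
            parts.append(rng_ip.choice(window_pos, size=n_site, replace=True))
        if n_reads - n_site:
            pool = bg_pos if W else np.arange(L)
            parts.append(rng_ip.choice(pool, size=n_reads - n_site, replace=True))
        ip_pos = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        ip_pos = rng_ip.permutation(ip_pos)
        ip_sets.append(
            ReadSet(
                positions=ip_pos,
                strands=np.where(rng_ip.random(n_reads) < 0.5, "+", "-"),
                genome_length=L,
                label=f"{condition}_ip_rep{r + 1}".strip("_"),
            )
        )
        input_sets.append(
            ReadSet(
                positions=rng_in.integers(0, L, size=n_reads),
                strands=np.where(rng_in.random(n_reads) < 0.5, "+", "-"),
                genome_length=L,
                label=f"{condition}_input_rep{r + 1}".strip("_"),
            )
        )
    return ip_sets, input_sets


def site_mixture_weight(genome_length: int, n_sites: int, enrichment: float,
                        site_halfwidth: int) -> float:
    """Closed-form expected fraction of IP reads starting inside site windows."""
    W = n_sites * 2 * site_halfwidth
    return (enrichment * W) / (enrichment * W + (genome_length - W))


def simulate_counts(
    genome: Genome,
    truth: SyntheticTruth,
    base_mean: float = 500.0,
    dispersion: float = 0.05,
    n_replicates: int = 3,
    size_factors: list[float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial count matrix for a control vs copper-shock design.

    count(g, j) ~ NB(mean = sf_j * base_mean_g * 2**(log2FC_g * [j is shock]),
    Var = mu + dispersion * mu**2). dispersion=0 degenerates to Poisson.
    Returns (counts DataFrame genes x samples, condition labels per sample).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    n_samples = 2 * n_replicates
    if size_factors is None:
        size_factors = [1.0] * n_samples
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (n_samples,) or (size_factors <= 0).any():
        raise ValueError("size_factors must be positive, one per sample")
    samples = [f"control_{r + 1}" for r in range(n_replicates)] + [
        f"shock_{r + 1}" for r in range(n_replicates)
    ]
    conditions = pd.Series(
        ["control"] * n_replicates + ["copper_shock"] * n_replicates, index=samples
    )
    gene_ids = [g.gene_id for g in genome.genes]
    base = np.asarray(base_mean, dtype=float)
    base = np.full(len(gene_ids), float(base)) if base.ndim == 0 else base
    if base.shape != (len(gene_ids),):
        raise ValueError("base_mean must be scalar or one value per gene")
    lfc = np.array([truth.log2_fold_changes.get(g, 0.0) for g in gene_ids])
    counts = np.empty((len(gene_ids), n_samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        rng = sub_rng(seed, "counts", sample)
        shock = conditions.iloc[j] == "copper_shock"
        mu = size_factors[j] * base * np.exp2(lfc if shock else 0.0)
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_param = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(n_param, n_param / (n_param + mu))
    return pd.DataFrame(counts, index=gene_ids, columns=samples), conditions


def simulate_study(
    seed: int = 0,
    genome_length: int = 120_000,
    n_genes: int = 200,
    n_regulon: int = 10,
    consensus: str = COPPER_CONSENSUS,
    offset_upstream: int = 30,
    enrichment: float = 20.0,
    site_halfwidth: int = 150,
    n_reads: int = 50_000,
    n_chip_replicates: int = 3,
    base_mean: float = 500.0,
    dispersion: float = 0.05,
    n_rna_replicates: int = 3,
    effect_sizes: tuple[float, ...] = DEFAULT_EFFECT_SIZES,
    conditions: tuple[str, str] = ("control", "copper_shock"),
) -> StudyData:
    """Complete default study: genome, planted regulon, ChIP reads, counts.

    The regulon is a seeded random gene subset; planted log2 fold changes
    cycle through ``effect_sizes``. Binding is copper-independent: both
    conditions share the same sites and enrichment.
    """
    genome = generate_genome(genome_length, n_genes, seed=seed)
    rng = sub_rng(seed, "regulon-choice")
    regulon = sorted(
        rng.choice([g.gene_id for g in genome.genes], size=n_regulon, replace=False)
    )
    genome, sites = plant_motif(genome, consensus, set(regulon), offset_upstream, seed=seed)
    lfc = {gid: float(effect_sizes[i % len(effect_sizes)]) for i, gid in enumerate(regulon)}
    truth = SyntheticTruth(
        regulon_gene_ids=set(regulon),
        planted_sites=sites,
        log2_fold_changes=lfc,
        chip_enrichment=enrichment,
    )
    ip_sets, input_sets = {}, {}
    for cond in conditions:
        ip, inp = simulate_chip_reads(
            genome, sites, n_reads, enrichment, site_halfwidth,
            n_chip_replicates, seed=seed, condition=cond,
        )
        ip_sets[cond], input_sets[cond] = ip, inp
    counts, cond_labels = simulate_counts(
        genome, truth, base_mean, dispersion, n_rna_replicates, seed=seed
    )
    return StudyData(
        genome=genome,
        truth=truth,
        ip_readsets=ip_sets,
        input_readsets=input_sets,
        counts=counts,
        conditions=cond_labels,
    )
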