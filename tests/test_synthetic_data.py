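"""Generator contracts: determinism, packing, planted sites, read mixtures,
negative-binomial count moments."""

import re

import numpy as np
import pytest
from scipy import stats

from copreg import synthetic_data as sd
from copreg._utils import IUPAC, revcomp


class TestGenerateGenome:
    def test_empty_gene_list(self):
        g = sd.generate_genome(length=10_000, n_genes=0, seed=1)
        assert len(g.sequence) == 10_000
        assert g.genes == []

    def test_base_composition_matches_gc(self):
        g = sd.generate_genome(length=50_000, n_genes=20, gc=0.5, seed=7)
        gc = sum(b in "GC" for b in g.sequence) / len(g.sequence)
        assert abs(gc - 0.5) < 0.02  # ~3 sigma of a binomial at n=50k

    def test_determinism(self):
        a = sd.generate_genome(length=20_000, n_genes=10, seed=3)
        b = sd.generate_genome(length=20_000, n_genes=10, seed=3)
        assert a.sequence == b.sequence
        assert a.genes == b.genes

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            sd.generate_genome(length=1_000, n_genes=10, min_intergenic=200, seed=0)

    def test_intergenic_gaps_respected(self):
        g = sd.generate_genome(length=50_000, n_genes=30, min_intergenic=250, seed=5)
        genes = sorted(g.genes, key=lambda x: x.start)
        for a, b in zip(genes, genes[1:]):
            assert b.start - a.end >= 250
        # wraparound gap between last gene end and first gene start
        assert len(g) - genes[-1].end + genes[0].start >= 250

    def test_tss_definition(self):
        g = sd.generate_genome(length=30_000, n_genes=15, seed=9)
        for gene in g.genes:
            assert gene.tss == (gene.start if gene.strand == "+" else gene.end - 1)
            assert gene.start <= gene.tss < gene.end


class TestPlantMotif:
    def test_fixed_positions_of_consensus(self):
        g = sd.generate_genome(length=30_000, n_genes=15, seed=2)
        targets = {g.genes[i].gene_id for i in range(5)}
        _, sites = sd.plant_motif(g, sd.COPPER_CONSENSUS, targets, seed=2)
        fixed = {0: "T", 1: "T", 4: "C", 5: "A", 9: "T", 10: "G", 13: "A", 14: "A"}
        for site in sites:
            for pos, base in fixed.items():
                assert site.sequence[pos] == base
            for pos, code in enumerate(sd.COPPER_CONSENSUS):
                assert site.sequence[pos] in IUPAC[code]

    def test_empty_targets_is_noop(self):
        g = sd.generate_genome(length=20_000, n_genes=10, seed=4)
        g2, sites = sd.plant_motif(g, sd.COPPER_CONSENSUS, set(), seed=4)
        assert g2.sequence == g.sequence
        assert sites == []

    def test_regex_oracle_finds_every_planted_site(self):
        g = sd.generate_genome(length=40_000, n_genes=20, seed=6)
        targets = {x.gene_id for x in g.genes[:8]}
        g2, sites = sd.plant_motif(g, sd.COPPER_CONSENSUS, targets, seed=6)
        pattern = "".join(f"[{IUPAC[c]}]" for c in sd.COPPER_CONSENSUS)
        doubled = g2.sequence + g2.sequence  # wrap-aware search
        fwd = {m.start() % len(g2) for m in re.finditer(f"(?={pattern})", doubled)}
        rc_doubled = revcomp(doubled)
        rev = {
            (2 * len(g2) - m.start() - len(sd.COPPER_CONSENSUS)) % len(g2)
            for m in re.finditer(f"(?={pattern})", rc_doubled)
        }
        found = fwd | rev
        for site in sites:
            assert site.position in found

    def test_collision_with_gene_body_raises(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        genome = sd.Genome(
            name="t", sequence=seq,
            genes=[sd.GeneRecord("a", 1_000, 1_600, "+"),
                   sd.GeneRecord("b", 3_000, 3_600, "+")],
        )
        with pytest.raises(ValueError, match="collides"):
            # offset chosen so the site lands inside gene a's body
            sd.plant_motif(genome, sd.COPPER_CONSENSUS, {"b"}, offset_upstream=1_450)


class TestSimulateChipReads:
    def test_no_enrichment_is_uniform(self, small_genome):
        _, sites = sd.plant_motif(
            small_genome, sd.COPPER_CONSENSUS, {small_genome.genes[0].gene_id}, seed=1
        )
        ip, inp = sd.simulate_chip_reads(
            small_genome, sites, n_reads=50_000, enrichment=1.0, n_replicates=1, seed=1
        )
        ks = stats.ks_2samp(ip[0].positions, inp[0].positions)
        assert ks.pvalue > 0.01

    def test_mixture_weight_closed_form(self):
        g = sd.generate_genome(length=10_000, n_genes=2, min_intergenic=500, seed=3)
        g2, sites = sd.plant_motif(g, sd.COPPER_CONSENSUS, {g.genes[0].gene_id}, seed=3)
        n = 50_000
        ip, _ = sd.simulate_chip_reads(
            g2, sites, n_reads=n, enrichment=20.0, site_halfwidth=150,
            n_replicates=1, seed=3,
        )
        p = sd.site_mixture_weight(len(g2), 1, 20.0, 150)
        center = sites[0].center
        d = np.abs((ip[0].positions - center + len(g2) // 2) % len(g2) - len(g2) // 2)
        observed = (d < 150).mean()
        assert abs(observed - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_replicates_differ_but_conserve_read_count(self, small_genome):
        ip, inp = sd.simulate_chip_reads(
            small_genome, [], n_reads=5_000, enrichment=1.0, n_replicates=3, seed=5
        )
        assert all(len(r) == 5_000 for r in ip + inp)
        for i in range(3):
            for j in range(i + 1, 3):
                assert not np.array_equal(ip[i].positions, ip[j].positions)


class TestSimulateCounts:
    def _null_truth(self, genome):
        return sd.SyntheticTruth(regulon_gene_ids=set())

    def test_null_design_centered_at_one(self):
        g = sd.generate_genome(length=120_000, n_genes=200, seed=11)
        counts, cond = sd.simulate_counts(
            g, self._null_truth(g), base_mean=500, dispersion=0.05,
            n_replicates=3, seed=11,
        )
        shock = counts.loc[:, (cond == "copper_shock").to_numpy()].mean(axis=1)
        control = counts.loc[:, (cond == "control").to_numpy()].mean(axis=1)
        assert 0.8 <= (shock / control).median() <= 1.25

    def test_planted_fold_change_recovered(self):
        g = sd.generate_genome(length=30_000, n_genes=20, seed=12)
        gid = g.genes[0].gene_id
        truth = sd.SyntheticTruth(
            regulon_gene_ids={gid}, log2_fold_changes={gid: 6.14}
        )
        counts, cond = sd.simulate_counts(g, truth, base_mean=500, n_replicates=3, seed=12)
        shock = counts.loc[gid, (cond == "copper_shock").to_numpy()].mean()
        control = counts.loc[gid, (cond == "control").to_numpy()].mean()
        assert abs(np.log2(shock / control) - 6.14) < 0.5

    def test_poisson_limit_variance_equals_mean(self):
        g = sd.generate_genome(length=30_000, n_genes=20, seed=13)
        counts, _ = sd.simulate_counts(
            g, self._null_truth(g), base_mean=500, dispersion=0.0,
            n_replicates=500, seed=13,
        )
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert ((ratio >= 0.7) & (ratio <= 1.4)).all()

    def test_nb_moments_match_formula(self):
        g = sd.generate_genome(length=30_000, n_genes=20, seed=14)
        counts, _ = sd.simulate_counts(
            g, self._null_truth(g), base_mean=500, dispersion=0.1,
            n_replicates=500, seed=14,
        )
        mu = counts.mean(axis=1)
        expected_var = mu + 0.1 * mu**2
        ratio = counts.var(axis=1, ddof=1) / expected_var
        assert ((ratio > 0.7) & (ratio < 1.4)).all()

    def test_determinism(self):
        g = sd.generate_genome(length=20_000, n_genes=10, seed=15)
        t = self._null_truth(g)
        a, _ = sd.simulate_counts(g, t, seed=15)
        b, _ = sd.simulate_counts(g, t, seed=15)
        assert a.equals(b)
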