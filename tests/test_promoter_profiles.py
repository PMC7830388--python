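"""TSS-anchored windows, nucleotide enrichment, and trinucleotide
bendability profiles with bootstrap bands."""

import numpy as np
import pytest

from copreg import promoter_profiles as pp
from copreg._utils import revcomp
from copreg.genome import Genome, GeneRecord


def random_genome(seed, length=5_000, genes=()):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return Genome(name="t", sequence=seq, circular=True, genes=list(genes))


class TestExtractAnchored:
    def test_plus_strand_window_bounds(self):
        g = random_genome(0, genes=[GeneRecord("g", 1000, 1500, "+")])
        aset = pp.extract_anchored(g, g.genes, -150, 50)
        assert aset.sequences[0] == g.sequence[850:1050]
        assert aset.offsets[0] == -150 and aset.offsets[-1] == 49

    def test_unit_window_is_base_upstream(self):
        g = random_genome(1, genes=[GeneRecord("g", 1000, 1500, "+")])
        aset = pp.extract_anchored(g, g.genes, -1, 0)
        assert aset.sequences[0] == g.sequence[999]

    def test_minus_strand_matches_coordinate_walking_oracle(self):
        g = random_genome(2, genes=[GeneRecord("g", 1000, 1500, "-")])
        aset = pp.extract_anchored(g, g.genes, -150, 50)
        tss = 1499
        expected = ""
        for rel in range(-150, 50):
            base = g.sequence[(tss - rel) % len(g)]
            expected += revcomp(base)
        assert aset.sequences[0] == expected

    def test_circular_wrap(self):
        g = random_genome(3, genes=[GeneRecord("g", 50, 400, "+")])
        aset = pp.extract_anchored(g, g.genes, -150, 50)
        assert aset.sequences[0] == g.sequence[-100:] + g.sequence[:100]

    def test_linear_overhang_error_and_skip(self):
        g = random_genome(4, genes=[GeneRecord("g", 50, 400, "+")])
        g.circular = False
        with pytest.raises(ValueError, match="overhang"):
            pp.extract_anchored(g, g.genes, -150, 50)
        aset = pp.extract_anchored(g, g.genes, -150, 50, on_overhang="skip")
        assert len(aset) == 0


class TestPositionalEnrichment:
    def _aset(self, seqs, start=-5):
        return pp.AnchoredSequenceSet(
            sequences=seqs, offsets=np.arange(start, start + len(seqs[0]))
        )

    def test_identity_gives_zero(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(10)]
        res = pp.positional_enrichment(self._aset(seqs), self._aset(seqs))
        assert np.allclose(res["enrichment"].to_numpy(), 0.0)

    def test_hand_counted_enrichment(self):
        target = self._aset(["CA", "CA", "CA", "CA"], start=0)
        background = self._aset(["AA", "CA", "GA", "TA"], start=0)
        res = pp.positional_enrichment(target, background, pseudocount=1)
        # position 0: target C count 4 -> (4+1)/(4+4); background C 1 -> (1+1)/(4+4)
        assert res["enrichment"].loc[0, "C"] == pytest.approx(np.log2(5 / 2))
        assert res["enrichment"].loc[0, "A"] == pytest.approx(np.log2(1 / 2))
        assert res["freq_target"].loc[0, "C"] == 1.0

    def test_raw_frequencies_sum_to_one(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(7)]
        res = pp.positional_enrichment(self._aset(seqs), self._aset(seqs))
        assert np.allclose(res["freq_target"].sum(axis=1), 1.0)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(7)
        a = self._aset(["".join(rng.choice(list("ACGT"), size=15)) for _ in range(9)])
        b = self._aset(["".join(rng.choice(list("ACGT"), size=15)) for _ in range(12)])
        ab = pp.positional_enrichment(a, b)["enrichment"].to_numpy()
        ba = pp.positional_enrichment(b, a)["enrichment"].to_numpy()
        assert np.allclose(ab, -ba)

    def test_geometry_mismatch_raises(self):
        a = self._aset(["ACGT"], start=0)
        b = self._aset(["ACG"], start=0)
        with pytest.raises(ValueError):
            pp.positional_enrichment(a, b)


class TestTrinucleotideScale:
    def test_toy_scale_is_complete_and_strand_symmetric(self):
        scale = pp.toy_scale()
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    t = a + b + c
                    assert scale[t] == scale[revcomp(t)]

    def test_tsv_roundtrip(self, tmp_path):
        scale = pp.toy_scale()
        path = tmp_path / "scale.tsv"
        scale.to_tsv(path)
        back = pp.TrinucleotideScale.from_tsv(path)
        assert all(back[t] == pytest.approx(scale[t], abs=1e-12) for t in scale.values)

    def test_incomplete_scale_raises(self):
        with pytest.raises(ValueError, match="missing"):
            pp.TrinucleotideScale(values={"AAA": -0.3})


class TestBendabilityProfile:
    def test_homopolymer_gives_flat_profile_at_scale_value(self):
        aset = pp.AnchoredSequenceSet(["A" * 40] * 6, np.arange(-20, 20))
        prof = pp.bendability_profile(aset, pp.toy_scale(), n_boot=100, seed=0)
        assert np.allclose(prof.mean, pp.toy_scale()["AAA"])
        assert np.allclose(prof.lower, prof.mean) and np.allclose(prof.upper, prof.mean)

    def test_unsmoothed_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(11)]
        aset = pp.AnchoredSequenceSet(seqs, np.arange(-15, 15))
        scale = pp.toy_scale()
        prof = pp.bendability_profile(aset, scale, n_boot=100, seed=1)
        for j in range(28):
            expected = np.mean([scale[s[j:j + 3]] for s in seqs])
            assert prof.raw_mean[j] == pytest.approx(expected)

    def test_n_bases_skipped_and_counted(self):
        aset = pp.AnchoredSequenceSet(["ANAAAA", "AAAAAA"], np.arange(-3, 3))
        prof = pp.bendability_profile(aset, pp.toy_scale(), n_boot=50, seed=2)
        assert prof.n_skipped == 2  # the two trinucs overlapping the N
        assert np.isfinite(prof.mean).all()

    def test_reverse_complement_mirror(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(8)]
        aset = pp.AnchoredSequenceSet(seqs, np.arange(0, 40))
        rc_set = pp.AnchoredSequenceSet([revcomp(s) for s in seqs], np.arange(0, 40))
        a = pp.bendability_profile(aset, pp.toy_scale(), span=1, n_boot=50, seed=3)
        b = pp.bendability_profile(rc_set, pp.toy_scale(), span=1, n_boot=50, seed=3)
        assert np.allclose(a.raw_mean, b.raw_mean[::-1])

    def test_fixed_seed_reproducible_band(self):
        rng = np.random.default_rng(10)
        seqs = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(15)]
        aset = pp.AnchoredSequenceSet(seqs, np.arange(-25, 25))
        a = pp.bendability_profile(aset, pp.toy_scale(), seed=4)
        b = pp.bendability_profile(aset, pp.toy_scale(), seed=4)
        assert np.array_equal(a.lower, b.lower) and np.array_equal(a.upper, b.upper)

    def test_window_too_small_raises(self):
        aset = pp.AnchoredSequenceSet(["AC"], np.arange(0, 2))
        with pytest.raises(ValueError):
            pp.bendability_profile(aset, pp.toy_scale())


class TestCompareProfiles:
    def _profiles(self, seed=11, n_target=15, rigid=False):
        rng = np.random.default_rng(seed)

        def mkseq(rigid_block):
            s = list(rng.choice(list("ACGT"), size=200))
            if rigid_block:
                s[30:70] = rng.choice(list("AT"), size=40)  # -120..-80 in the window
            return "".join(s)

        t = pp.AnchoredSequenceSet(
            [mkseq(rigid) for _ in range(n_target)], np.arange(-150, 50)
        )
        b = pp.AnchoredSequenceSet(
            [mkseq(False) for _ in range(60)], np.arange(-150, 50)
        )
        scale = pp.toy_scale()
        return (
            pp.bendability_profile(t, scale, seed=1),
            pp.bendability_profile(b, scale, seed=2),
        )

    def test_self_difference_is_zero(self):
        t, _ = self._profiles()
        d = pp.compare_profiles(t, t)
        assert np.allclose(d.mean, 0.0)

    def test_planted_rigid_block_localized(self):
        t, b = self._profiles(rigid=True)
        d = pp.compare_profiles(t, b)
        min_pos = d.positions[np.argmin(d.mean)]
        assert -120 <= min_pos <= -80

    def test_difference_of_means_is_mean_of_differences(self):
        rng = np.random.default_rng(12)
        seqs_a = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(10)]
        seqs_b = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(10)]
        grid = np.arange(-30, 30)
        scale = pp.toy_scale()
        pa = pp.bendability_profile(
            pp.AnchoredSequenceSet(seqs_a, grid), scale, span=1, seed=5
        )
        pb = pp.bendability_profile(
            pp.AnchoredSequenceSet(seqs_b, grid), scale, span=1, seed=6
        )
        d = pp.compare_profiles(pa, pb)
        per_seq = np.mean(
            [
                [scale[a[j:j + 3]] - scale[b[j:j + 3]] for j in range(58)]
                for a, b in zip(seqs_a, seqs_b)
            ],
            axis=0,
        )
        assert np.allclose(d.mean, per_seq)

    def test_grid_mismatch_raises(self):
        t, _ = self._profiles()
        other = pp.bendability_profile(
            pp.AnchoredSequenceSet(["ACGTACGT"] * 3, np.arange(0, 8)),
            pp.toy_scale(),
            n_boot=50,
            seed=7,
        )
        with pytest.raises(ValueError):
            pp.compare_profiles(t, other)
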