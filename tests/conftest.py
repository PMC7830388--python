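import numpy as np
import pytest

from copreg import synthetic_data as sd
from copreg.genome import Genome


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """10-kb seeded genome with a handful of genes on both strands."""
    return sd.generate_genome(length=10_000, n_genes=8, min_intergenic=300, seed=42)


@pytest.fixture(scope="session")
def default_study() -> sd.StudyData:
    """One default synthetic study shared by read-only tests."""
    return sd.simulate_study(seed=7, effect_sizes=(2.5, 6.14, 8.2))


def make_planted_windows(seed: int, n: int = 30, length: int = 60,
                         shared_word: bool = True):
    """Random upstream-like windows each carrying a planted consensus site.

    Returns (sequences, planted word or list of words, planted offsets).
    """
    rng = np.random.default_rng(seed)
    word = sd._realize_iupac(rng, sd.COPPER_CONSENSUS)
    seqs, words, offsets = [], [], []
    for _ in range(n):
        s = "".join(rng.choice(list("ACGT"), size=length))
        w = word if shared_word else sd._realize_iupac(rng, sd.COPPER_CONSENSUS)
        j = int(rng.integers(0, length - len(w) + 1))
        seqs.append(s[:j] + w + s[j + len(w):])
        words.append(w)
        offsets.append(j)
    return seqs, (word if shared_word else words), offsets
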