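import numpy as np
import pytest

from dsrnakit.energetics import default_stack_table
from dsrnakit.fixtures import gen_transcriptome
from dsrnakit.seqio import Transcript


@pytest.fixture(scope="session")
def stack_table():
    return default_stack_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_transcriptome():
    return gen_transcriptome(n=20, length=500, gc=0.5, seed=7)


@pytest.fixture()
def hairpin_transcript():
    """A transcript whose middle 21-mer is the stem of a strong hairpin."""
    stem = "GCGCGCGCGCGCGCGCGCGCG"  # 21 nt, pairs with its revcomp downstream
    loop = "AAAAA"
    rc = stem.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    flank = "A" * 40
    seq = flank + stem + loop + rc + flank
    t = Transcript(id="hairpin", seq=seq)
    return t, 40, 40 + 21  # site interval of the stem


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))
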