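import numpy as np
import pytest
from hypothesis import settings

import sixma as sx

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MEME_TEXT = """\
MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

MOTIF WIDE41
letter-probability matrix: alength= 4 w= 41 nsites= 100 E= 3.3e-18
""" + "0.40 0.20 0.20 0.20\n" * 41 + """
MOTIF WEAK
letter-probability matrix: alength= 4 w= 5 nsites= 30 E= 0.2
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25
0.25 0.25 0.25 0.25

MOTIF ACCGATCSA
letter-probability matrix: alength= 4 w= 9 nsites= 20 E= 2.9e-2
0.91 0.03 0.03 0.03
0.03 0.91 0.03 0.03
0.03 0.91 0.03 0.03
0.03 0.03 0.91 0.03
0.91 0.03 0.03 0.03
0.03 0.03 0.03 0.91
0.03 0.91 0.03 0.03
0.05 0.45 0.45 0.05
0.91 0.03 0.03 0.03
"""


@pytest.fixture
def meme_file(tmp_path):
    path = tmp_path / "motifs.meme"
    path.write_text(MEME_TEXT)
    return path


@pytest.fixture
def fasta_writer(tmp_path):
    def write(name, entries):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, seq in entries:
                fh.write(f">{rec_id}\n{seq}\n")
        return path

    return write


@pytest.fixture(scope="session")
def small_dataset():
    """40 synthetic 41-nt windows with a strongly planted motif."""
    spec = sx.SyntheticSpec(n_pos=20, n_neg=20, motif_strength=1.0, seed=7)
    return sx.generate_dataset(spec)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    """Fast-to-compute nsd+binary features of the small planted dataset."""
    return sx.assemble_features(small_dataset, sx.EncoderConfig(subsets=("nsd", "binary")))
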