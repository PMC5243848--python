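import numpy as np
import pytest

from taxotyper.seqio import Msa, SequenceRecord


def make_msa(seqs, ids=None, taxa=None):
    """Build an Msa from a list of residue strings."""
    ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
    taxa = taxa or [None] * len(seqs)
    return Msa([
        SequenceRecord(id=i, residues=s, declared_taxon=t)
        for i, s, t in zip(ids, seqs, taxa)
    ])


def random_msa(rng, nseq, ncols, alphabet="ACGT"):
    return make_msa([
        "".join(rng.choice(list(alphabet), ncols)) for _ in range(nseq)
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def catalog():
    from taxotyper.oligotype import load_default_catalog

    return load_default_catalog()


@pytest.fixture(scope="session")
def small_complex():
    """A small simulated 3-clade complex shared across tests."""
    from taxotyper.simulate import SimulationConfig, simulate_complex

    cfg = SimulationConfig(
        seed=7, n_clades=3, strains_per_clade=5, gene_length_16s=400,
        rrna_copies=1, mlsa_loci=(("locA", 80), ("locB", 60)),
        inter_clade_divergence=0.10, within_clade_divergence=0.005,
        mislabel_rate=0.2,
    )
    return cfg, simulate_complex(cfg)
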