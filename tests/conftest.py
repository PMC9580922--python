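import matplotlib
import pytest

matplotlib.use("Agg")

from hsdfind import simulate as sim
from hsdfind.core import build_gene_records
from hsdfind.tabular_io import (
    read_fasta_lengths,
    read_signature_table,
    read_similarity_table,
)

BUNDLE_SEED = 7
BUNDLE_FAMILIES = 40


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A 40-family synthetic bundle covering every planting scenario."""
    outdir = tmp_path_factory.mktemp("bundle")
    families = sim.default_families(BUNDLE_FAMILIES, seed=BUNDLE_SEED)
    return sim.generate_dataset(families, BUNDLE_SEED, outdir)


@pytest.fixture(scope="session")
def bundle_hits(bundle):
    return read_similarity_table(bundle.similarity)


@pytest.fixture(scope="session")
def bundle_genes(bundle):
    signatures = read_signature_table(bundle.signatures)
    fasta_lengths = read_fasta_lengths(bundle.fasta)
    return build_gene_records(signatures, fasta_lengths)
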