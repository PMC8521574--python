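import numpy as np
import pytest

from evosig.orthogroups import SpeciesPanel
from evosig.trees import PhyloTree

# fixed 8-taxon geometry used for the selection-test calibration checks:
# focal terminal branch 0.3, outgroup OG
EIGHT_TAXON_NEWICK = (
    "((((F:0.3,A:0.15):0.1,(B:0.15,C:0.15):0.1):0.1,"
    "((D:0.15,E:0.15):0.1,G:0.2):0.1):0.1,OG:0.3);"
)


@pytest.fixture(scope="session")
def eight_taxon_tree():
    return PhyloTree.from_newick(EIGHT_TAXON_NEWICK, outgroup="OG")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return SpeciesPanel(
        species=("A", "B", "C", "D"), focal="A", outgroup="D"
    )


def random_protein_alignment(rng, n_taxa, n_cols, gap_rate=0.1, x_rate=0.0):
    from evosig.alignments import ProteinAlignment
    from evosig.codons import AMINO_ACIDS

    mat = rng.choice(list(AMINO_ACIDS), size=(n_taxa, n_cols))
    gaps = rng.random((n_taxa, n_cols)) < gap_rate
    mat[gaps] = "-"
    if x_rate:
        xs = rng.random((n_taxa, n_cols)) < x_rate
        mat[xs] = "X"
    return ProteinAlignment([f"t{i}" for i in range(n_taxa)], mat)
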