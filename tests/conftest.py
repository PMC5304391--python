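import numpy as np
import pytest

from uagscan import build_model, synth
from uagscan.genetic_codes import get_code
from uagscan.phylo_ml import SubstitutionModel
from uagscan.seqio import Tree, map_alignment_to_codons


@pytest.fixture(scope="session")
def standard_code():
    return get_code("standard")


@pytest.fixture(scope="session")
def uag_x():
    return get_code("uag_x")


@pytest.fixture(scope="session")
def poisson_model():
    """20-state equal-rates model: uniform exchangeabilities and frequencies."""
    R = np.ones((20, 20))
    np.fill_diagonal(R, 0.0)
    return SubstitutionModel(
        exchangeabilities=R, frequencies=np.full(20, 0.05), alpha=1.0, ncat=1
    )


@pytest.fixture(scope="session")
def small_tree():
    return Tree.from_newick("((A:0.12,B:0.08):0.05,(C:0.2,D:0.15):0.07);")


def make_scan_fixture(
    seed, n_taxa=12, n_background=500, n_reassigned=50, alpha=0.8,
    true_residue="L", code_name="uag_leu",
):
    """A matched tree/alignment/CDS fixture with a planted UAG reassignment."""
    tree = synth.random_tree(n_taxa, seed=seed)
    model = build_model(alpha=alpha)
    focal = tree.leaf_names[0]
    spec = synth.SimSpec(
        tree=tree, model=model, n_background_sites=n_background,
        n_reassigned_sites=n_reassigned, focal=focal,
        true_residue=true_residue, seed=seed,
    )
    aln, truth = synth.simulate_alignment(spec)
    cds_set, boundaries = synth.emit_cds_fixture(aln, truth, focal, seed=seed + 1)
    caln = map_alignment_to_codons(aln, cds_set, get_code(code_name))
    return {
        "tree": tree, "model": model, "focal": focal, "alignment": aln,
        "truth": truth, "cds": cds_set, "boundaries": boundaries, "caln": caln,
    }


@pytest.fixture(scope="session")
def scan_fixture():
    return make_scan_fixture(seed=20240917)
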