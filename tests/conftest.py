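import numpy as np
import pytest

from dupasym.family import read_gene_tree
from dupasym.synthetic_data import SimFamilySpec, generate_family, generate_species_tree

TOY4 = (
    "((a[&&NHX:S=a:GT=true_singleton],b[&&NHX:S=b:GT=true_singleton])"
    "n1[&&NHX:D=N:KS=0.5],(c[&&NHX:S=c:GT=true_singleton],"
    "d[&&NHX:S=d:GT=true_singleton])n2[&&NHX:D=N:KS=0.5])n0[&&NHX:D=N:KS=1.0];"
)


@pytest.fixture
def toy4_tree():
    """Balanced 4-leaf tree ((a,b),(c,d)) with Ks depths."""
    return read_gene_tree(TOY4, path=False)


@pytest.fixture(scope="session")
def species_tree6():
    return generate_species_tree(6, 0.3, 2)


@pytest.fixture
def small_family(species_tree6):
    """One moderately diverged family with an eligible duplication."""
    spec = SimFamilySpec(length=200, dup_edge="n03", rate_ratio=2.0,
                         seed=42, ka_ks_scale=0.3, family_id="fam_small")
    return generate_family(species_tree6, spec)


def tiny_pair_families(n, seed, rate_ratio=1.0, length=80):
    """Many minimal 3-taxon families with a terminal-edge duplication."""
    tree = generate_species_tree(3, 0.4, 7)
    leaf = sorted(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )[0]
    out = []
    for i in range(n):
        spec = SimFamilySpec(length=length, dup_edge=leaf, rate_ratio=rate_ratio,
                             seed=seed + i, ka_ks_scale=0.5,
                             family_id=f"tiny{i:04d}")
        out.append(generate_family(tree, spec))
    return out


@pytest.fixture(scope="session")
def neutral_cohort():
    return tiny_pair_families(300, seed=1000)
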