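import numpy as np
import pytest

from nitriscan.homology import ReferenceGene
from nitriscan.simulate import ImplantSpec, SimSpec, default_catalog, make_genome


@pytest.fixture(scope="session")
def catalog():
    return default_catalog(seed=42)


@pytest.fixture(scope="session")
def small_catalog():
    """Five families, enough for scan/synteny tests without the full cost."""
    full = default_catalog(seed=42)
    keep = {"ureA", "ureC", "utp", "dur3", "cynS"}
    return [g for g in full if g.family in keep]


@pytest.fixture(scope="session")
def implanted_genome(small_catalog):
    """One genome with known implants: dur3 x2 clustered, ureC, utp."""
    spec = SimSpec(
        seed=11, orfs_per_strain=40, genome_gc_target=0.40,
        codon_bias_strength=0.3,
        implants=[
            ImplantSpec("dur3", copies=2, gc_offset=0.10,
                        identity_to_ref=0.60, cluster_positions=[10, 13]),
            ImplantSpec("ureC", copies=1, identity_to_ref=0.90,
                        cluster_positions=[20]),
            ImplantSpec("utp", copies=1, identity_to_ref=0.35,
                        cluster_positions=[30]),
        ])
    return make_genome(spec, small_catalog, strain_id="SYN1")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# shared tree helpers (used by unit and acceptance tests)

def random_unrooted_tree(n_taxa, rng, blen_lo=0.05, blen_hi=0.5):
    """Random topology by sequential joining; trifurcating root (unrooted)."""
    from nitriscan.phylo.trees import Node, Tree
    nodes = [Node(f"T{i}", float(rng.uniform(blen_lo, blen_hi)))
             for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = Node("", float(rng.uniform(blen_lo, blen_hi)))
        p.add(nodes[int(i)])
        p.add(nodes[int(j)])
        nodes = [x for k, x in enumerate(nodes) if k not in (int(i), int(j))] + [p]
    root = Node("")
    for x in nodes:
        root.add(x)
    return Tree(root)


def tree_path_distances(tree):
    """(matrix, sorted labels) of leaf-to-leaf path lengths — additive by
    construction, the oracle for neighbor joining."""
    leaves = tree.leaves()

    def path(n):
        out, d = {}, 0.0
        while n is not None:
            out[id(n)] = d
            d += n.length
            n = n.parent
        return out

    paths = {l.name: path(l) for l in leaves}
    labels = sorted(paths)
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            pa, pb = paths[labels[a]], paths[labels[b]]
            common = set(pa) & set(pb)
            d[a, b] = d[b, a] = min(pa[c] for c in common) + min(pb[c] for c in common)
    return d, labels
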