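import numpy as np
import pytest

from azescan import phylo

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  CA AGLY A   2       3.000   1.000   0.000  0.60 10.00           C
ATOM      4  CA BGLY A   2       3.200   1.100   0.000  0.40 10.00           C
ATOM      5  CA  SER A   3       4.500   2.000   1.000  1.00 10.00           C
HETATM    6  N   SAH A 301       5.000   0.000   0.000  1.00 10.00           N
HETATM    7  CG  SAH A 301       5.000   0.000   2.900  1.00 10.00           C
HETATM    8  O   HOH A 401       9.000   9.000   9.000  1.00 10.00           O
END
"""


@pytest.fixture
def toy_pdb_text() -> str:
    return TOY_PDB


def random_additive_tree(n: int, rng: np.random.Generator) -> phylo.TreeNode:
    """A random unrooted tree with positive branch lengths; its leaf-to-leaf
    path-length matrix is additive by construction, so NJ must recover it."""
    pool = [phylo.TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
            for i in range(n)]
    while len(pool) > 3:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        parent = phylo.TreeNode(children=[b, a], length=float(rng.uniform(0.05, 1.0)))
        pool = [x for x in pool if x is not a and x is not b] + [parent]
    return phylo.TreeNode(children=pool)
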