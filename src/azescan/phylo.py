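"""Alignment trimming, p-distances, and bootstrapped neighbor-joining trees.

The dereplicated cluster representatives are related by a desk-scale
distance phylogeny: gappy alignment columns are removed by a gap-fraction
rule, pairwise p-distances are computed over mutually ungapped columns, and
an unrooted tree is built with the classic Saitou-Nei neighbor-joining
algorithm.  Edge support comes from a plain nonparametric bootstrap
(columns resampled with replacement, support = percentage of replicate
trees containing the same bipartition).

This is an intentionally simple, fully reproducible stand-in for
maximum-likelihood inference; an externally computed tree can be supplied
to the pipeline instead (``tree_path`` in the run configuration).
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError

GAP_CHARS = frozenset("-.")
DEFAULT_MAX_GAP_FRACTION = 0.5
DEFAULT_BOOTSTRAP_REPLICATES = 100


@dataclass
class Alignment:
    """A protein multiple sequence alignment (rows of equal length)."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ParameterError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ParameterError("duplicate sequence ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ParameterError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        return np.array([list(r) for r in self.rows], dtype="U1")


def read_fasta_alignment(path: str | Path) -> Alignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not ids:
        raise DataError(f"no records in {path}")
    return Alignment(ids=ids, rows=rows)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), 60):
                fh.write(row[i : i + 60] + "\n")


def align_sequences(seqs: dict[str, str]) -> Alignment:
    """Multiple sequence alignment via MAFFT (L-INS-i for high accuracy).

    Requires the ``mafft`` executable on PATH; raises :class:`DataError`
    otherwise.  Record order follows the input dict.
    """
    if len(seqs) < 2:
        raise ParameterError("need at least 2 sequences to align")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        with open(fasta, "w") as fh:
            for sid, seq in seqs.items():
                fh.write(f">{sid}\n{seq}\n")
        try:
            out = subprocess.run(
                ["mafft", "--maxiterate", "1000", "--localpair", "--quiet", str(fasta)],
                capture_output=True, text=True, check=True,
            )
        except (OSError, subprocess.CalledProcessError) as exc:
            raise DataError(f"mafft failed or is unavailable: {exc}") from exc
    ids, rows, cur = [], [], []
    for line in out.stdout.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur).upper())
                cur = []
            ids.append(line[1:].split()[0])
        else:
            cur.append(line.strip())
    if cur:
        rows.append("".join(cur).upper())
    order = {sid: i for i, sid in enumerate(seqs)}
    pairs = sorted(zip(ids, rows), key=lambda t: order.get(t[0], len(order)))
    return Alignment(ids=[p[0] for p in pairs], rows=[p[1] for p in pairs])


def trim_alignment(aln: Alignment, max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION) -> Alignment:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Columns with gap fraction <= the threshold are retained in order; an
    empty result raises :class:`DataError`.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ParameterError("max_gap_fraction must be in [0, 1]")
    m = aln.matrix()
    is_gap = np.isin(m, list(GAP_CHARS))
    keep = is_gap.mean(axis=0) <= max_gap_fraction
    if not keep.any():
        raise DataError("empty alignment: every column exceeds the gap-fraction threshold")
    rows = ["".join(r) for r in m[:, keep]]
    return Alignment(ids=list(aln.ids), rows=rows)


def protein_distance(aln: Alignment) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distance matrix over mutually ungapped columns.

    d(i, j) = 1 - identity over columns where neither row is gapped.  A pair
    with zero comparable columns raises :class:`DataError` naming the pair.
    """
    if aln.n_rows < 3:
        raise ParameterError("need at least 3 rows for a distance matrix")
    m = aln.matrix()
    ungapped = ~np.isin(m, list(GAP_CHARS))
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise DataError(
                    f"rows {aln.ids[i]!r} and {aln.ids[j]!r} share no ungapped columns"
                )
            matches = int((m[i, both] == m[j, both]).sum())
            d[i, j] = d[j, i] = 1.0 - matches / comparable
    return d, list(aln.ids)


@dataclass
class TreeNode:
    """Node of an unrooted tree serialized with a trifurcating root."""

    name: str = ""
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]

    def to_newick(self, with_support: bool = False) -> str:
        return self._newick(with_support, top=True) + ";"

    def _newick(self, with_support: bool, top: bool = False) -> str:
        if self.is_leaf:
            return f"{self.name}:{self.length:.10g}"
        inner = ",".join(c._newick(with_support) for c in self.children)
        label = ""
        if with_support and self.support is not None and not top:
            label = f"{self.support:g}"
        if top:
            return f"({inner}){label}"
        return f"({inner}){label}:{self.length:.10g}"

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial bipartitions, each encoded as the side NOT holding the
        lexicographically smallest leaf (a canonical form for unrooted trees)."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        bips: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if node is not self and 1 < len(below) < len(all_leaves) - 1:
                side = below if anchor not in below else all_leaves - below
                bips.add(side)
            return below

        walk(self)
        return bips


def nj_tree(dist: np.ndarray, ids: list[str]) -> TreeNode:
    """Classic Saitou-Nei neighbor joining on a symmetric distance matrix.

    On additive matrices the generating tree (topology and path lengths) is
    recovered exactly.  Negative branch lengths are clamped to zero with the
    deficit shifted onto the sibling branch, which preserves path lengths
    through the parent node.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[0] != d.shape[1] or len(ids) != n:
        raise ParameterError("distance matrix must be square and match the id list")
    if n < 3:
        raise ParameterError("need at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ParameterError("distance matrix is not symmetric")
    if np.any(np.diag(d) != 0):
        raise ParameterError("distance matrix diagonal must be zero")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n))
    dm = d.copy()

    while len(active) > 3:
        r = len(active)
        totals = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best, best_q = None, np.inf
        for ai in range(r):
            for bi in range(ai + 1, r):
                i, j = active[ai], active[bi]
                q = (r - 2) * dm[i, j] - totals[i] - totals[j]
                if q < best_q - 1e-15:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * dm[i, j] + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = dm[i, j] - li
        if li < 0:
            lj += li  # shift deficit to the sibling; path lengths unchanged
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length, nodes[j].length = li, lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # grow the matrix with the new node's distances
        new_idx = dm.shape[0]
        newrow = np.zeros((1, dm.shape[0]))
        dm = np.vstack([dm, newrow])
        dm = np.hstack([dm, np.zeros((dm.shape[0], 1))])
        for k in active:
            if k in (i, j):
                continue
            dm[new_idx, k] = dm[k, new_idx] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_idx]

    i, j, k = active
    li = 0.5 * (dm[i, j] + dm[i, k] - dm[j, k])
    lj = 0.5 * (dm[i, j] + dm[j, k] - dm[i, k])
    lk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def tree_path_lengths(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix of a tree (ids sorted)."""
    import itertools

    parents: dict[int, TreeNode | None] = {}

    def walk(node: TreeNode, parent: TreeNode | None) -> None:
        parents[id(node)] = parent
        for c in node.children:
            walk(c, node)

    walk(tree, None)
    leaves = tree.leaves()
    names = sorted(lf.name for lf in leaves)
    by_name = {lf.name: lf for lf in leaves}
    n = len(names)
    out = np.zeros((n, n))

    def path_to_root(node: TreeNode) -> list[TreeNode]:
        chain = [node]
        while parents[id(chain[-1])] is not None:
            chain.append(parents[id(chain[-1])])
        return chain

    for a, b in itertools.combinations(range(n), 2):
        pa = path_to_root(by_name[names[a]])
        pb = path_to_root(by_name[names[b]])
        seen = {id(x) for x in pa}
        lca = next(x for x in pb if id(x) in seen)
        dist = 0.0
        for x in pa:
            if x is lca:
                break
            dist += x.length
        for x in pb:
            if x is lca:
                break
            dist += x.length
        out[a, b] = out[b, a] = dist
    return out, names


def bootstrap_support(
    aln: Alignment,
    n_replicates: int = DEFAULT_BOOTSTRAP_REPLICATES,
    seed: int = 0,
) -> TreeNode:
    """NJ tree of ``aln`` with bootstrap support on internal edges.

    Alignment columns are resampled with replacement ``n_replicates`` times;
    the support of an internal edge is the percentage of replicate NJ trees
    containing the same leaf bipartition.  Fully reproducible for a fixed
    seed.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    d, ids = protein_distance(aln)
    main = nj_tree(d, ids)
    rng = np.random.default_rng(seed)
    m = aln.matrix()
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, aln.n_cols, size=aln.n_cols)
        rep_rows = ["".join(row) for row in m[:, cols]]
        rep_aln = Alignment(ids=list(aln.ids), rows=rep_rows)
        try:
            rd, rids = protein_distance(rep_aln)
        except DataError:
            continue  # a replicate may sample only mutually-gapped columns
        rep_tree = nj_tree(rd, rids)
        for bip in rep_tree.bipartitions():
            counts[bip] = counts.get(bip, 0) + 1

    all_leaves = frozenset(main.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        below = frozenset().union(*(annotate(c) for c in node.children))
        if node is not main and 1 < len(below) < len(all_leaves) - 1:
            side = below if anchor not in below else all_leaves - below
            node.support = 100.0 * counts.get(side, 0) / n_replicates
        return below

    annotate(main)
    return main
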