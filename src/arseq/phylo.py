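"""Poisson-corrected protein distances and neighbor-joining trees.

Distances follow the classic amino-acid pipeline: the observed proportion
of differing sites p per sequence pair (with pairwise deletion — columns
gapped or ambiguous in either sequence of the pair are excluded for that
pair only) is transformed to the expected number of substitutions per
site d = -ln(1 - p), assuming equal substitution rates across sites and
no back-substitution bias (the Poisson correction).  The tree is built by
Saitou-Nei neighbor joining on the Q-criterion, with negative branch
length estimates clamped to zero and ties broken by the smallest index
pair, and serialised as Newick with a trifurcating root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# residues treated as informative; everything else (gap '-', 'X', B, Z, U,
# O, '.') triggers pairwise deletion for the pair
_CANONICAL = set("ACDEFGHIKLMNPQRSTVWY")


class NoOverlapError(RuntimeError):
    """A sequence pair shares no usable (ungapped, unambiguous) column."""


@dataclass
class MsaView:
    """An existing multiple alignment (computed elsewhere) as equal-length rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path) -> "MsaView":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq))
        return cls(ids=ids, rows=rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    usable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and >= 0")
        self.matrix = m

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.ids) + "\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in self.matrix[i]) + "\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                fh.write(name + "  " + "  ".join(f"{x:.6f}" for x in self.matrix[i]) + "\n")


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return self.name or ""
        inner = ",".join(f"{c._nwk()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner}){self.name or ''}"


@dataclass
class UnrootedTree:
    """NJ result: a tree with a trifurcating root node."""

    root: TreeNode
    ids: list[str]

    def newick(self) -> str:
        return self.root.newick()

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Summed branch lengths between every leaf pair (additivity check)."""
        # distances from each node to all leaves below, assembled upward
        def collect(node: TreeNode) -> dict[str, float]:
            if node.is_leaf():
                return {node.name: 0.0}
            out: dict[str, float] = {}
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                d = {k: v + bl for k, v in collect(child).items()}
                below.append(d)
                out.update(d)
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for a, da in below[i].items():
                        for b, db in below[j].items():
                            key = (a, b) if a < b else (b, a)
                            paths[key] = da + db
            return out

        paths: dict[tuple[str, str], float] = {}
        collect(self.root)
        return paths


def pairwise_p_distance(msa: MsaView) -> tuple[np.ndarray, np.ndarray]:
    """Observed proportion of differing sites per pair, pairwise deletion.

    Returns (p matrix, usable-site count matrix).  For each pair, columns
    where either sequence carries a gap or an ambiguous residue are
    excluded; p is the fraction of the remaining columns that differ.
    """
    n = len(msa.ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    arrs = [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    ok = np.array([[c in _CANONICAL for c in r] for r in msa.rows])
    p = np.zeros((n, n))
    usable = np.zeros((n, n), dtype=int)
    for i in range(n):
        usable[i, i] = int(ok[i].sum())
        for j in range(i + 1, n):
            use = ok[i] & ok[j]
            m = int(use.sum())
            if m == 0:
                raise NoOverlapError(f"{msa.ids[i]} / {msa.ids[j]}: no usable sites")
            diff = int(np.count_nonzero((arrs[i] != arrs[j]) & use))
            p[i, j] = p[j, i] = diff / m
            usable[i, j] = usable[j, i] = m
    return p, usable


def poisson_correct(p: float | np.ndarray) -> float | np.ndarray:
    """Expected substitutions per site d = -ln(1 - p); requires p < 1."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr >= 1)):
        raise ValueError("p must lie in [0, 1)")
    d = -np.log1p(-arr)
    return float(d) if np.isscalar(p) or arr.ndim == 0 else d


def distance_matrix(msa: MsaView) -> DistanceMatrix:
    """Poisson-corrected distances with pairwise deletion."""
    p, usable = pairwise_p_distance(msa)
    return DistanceMatrix(ids=list(msa.ids), matrix=poisson_correct(p),
                          usable_sites=usable)


def nj_tree(dm: DistanceMatrix) -> UnrootedTree:
    """Saitou-Nei neighbor joining.

    At each step the pair (i, j) minimising
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)
    is joined; branch lengths to the new node follow the standard
    formulas, clamped to >= 0; ties on Q go to the smallest (i, j) index
    pair in the current matrix ordering.  The final three clusters are
    attached to a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least three taxa")
    d = dm.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node u to every other active k
        du = {k: 0.5 * (d[i, k] + d[j, k] - dij) for k in active if k not in (i, j)}
        # reuse slot i for u, deactivate j
        nodes[i] = new
        for k, v in du.items():
            d[i, k] = d[k, i] = max(v, 0.0)
        active.remove(j)
    a, b, c = active
    # three-point formulas for the final trifurcation
    va = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    vb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    vc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode(children=[
        (nodes[a], max(va, 0.0)),
        (nodes[b], max(vb, 0.0)),
        (nodes[c], max(vc, 0.0)),
    ])
    return UnrootedTree(root=root, ids=list(dm.ids))
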