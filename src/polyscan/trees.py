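"""Window genealogies: p-distances and the BIONJ agglomeration.

BIONJ is neighbor joining with variance-weighted distance updates
(Gascuel 1997). Ties in the pair-selection criterion are broken by the
smallest pair of tip indices, making the output newick reproducible.
Negative branch-length estimates are clamped to zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_popgen import MISSING, Window
from .phasing import HaplotypeMatrix

logger = logging.getLogger(__name__)


class Node:
    """A rooted-tree node; unrooted trees carry a trifurcating root."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out

    def newick(self, lengths: bool = True) -> str:
        return self._nwk(lengths) + ";"

    def _nwk(self, lengths: bool) -> str:
        if self.is_leaf:
            s = self.name or ""
        else:
            s = "(" + ",".join(c._nwk(lengths) for c in self.children) + ")"
        if lengths and self.parent is not None:
            s += f":{self.length:.10g}"
        return s


@dataclass
class Genealogy:
    """A tree over haplotype tips with a tip -> taxon map."""

    root: Node
    taxon_map: dict[str, str] = field(default_factory=dict)
    window: Window | None = None

    def tip_names(self) -> list[str]:
        return [l.name for l in self.root.leaves()]

    def newick(self, lengths: bool = True) -> str:
        return self.root.newick(lengths)


def parse_newick(text: str) -> Node:
    """Parse a newick string (names and optional branch lengths)."""
    import dendropy

    tree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(dn) -> Node:
        node = Node(
            name=dn.taxon.label if dn.taxon is not None else None,
            length=dn.edge.length if dn.edge.length is not None else 0.0,
        )
        for c in dn.child_nodes():
            node.add(convert(c))
        return node

    return convert(tree.seed_node)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def hamming_pdist(hm: HaplotypeMatrix) -> tuple[list[str], np.ndarray]:
    """Pairwise mismatch fraction between haplotypes over co-called SNPs.

    Pairs with zero shared called sites get distance 1 with a warning.
    Returns (tip labels, symmetric matrix).
    """
    if hm.n_slots < 3:
        raise ValueError("need >= 3 haplotypes")
    if hm.n_sites < 1:
        raise ValueError("need >= 1 SNP")
    labels = hm.tip_labels()
    H = hm.haps
    called = H != MISSING
    n = hm.n_slots
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            ns = int(shared.sum())
            if ns == 0:
                logger.warning("haplotypes %s/%s share no called sites", labels[i], labels[j])
                d = 1.0
            else:
                d = float(np.sum(H[i, shared] != H[j, shared]) / ns)
            D[i, j] = D[j, i] = d
    return labels, D


# ---------------------------------------------------------------------------
# BIONJ
# ---------------------------------------------------------------------------

def bionj(labels: list[str], dist: np.ndarray) -> Genealogy:
    """BIONJ tree from a distance matrix; returns an unrooted genealogy
    (trifurcating root node)."""
    D = np.array(dist, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if np.any(np.isnan(D)):
        raise ValueError("NaN distances")
    if n < 3:
        raise ValueError("need >= 3 tips")
    V = D.copy()  # variance matrix, initialised to distances
    nodes: list[Node] = [Node(name=l) for l in labels]
    # 'order' tracks the smallest original tip index under each active node,
    # used for deterministic tie-breaking.
    order = list(range(n))
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        S = sub.sum(axis=1)
        best = None  # (Q, tiebreak, ai, aj)
        for a in range(r):
            for b in range(a + 1, r):
                q = (r - 2) * sub[a, b] - S[a] - S[b]
                tie = tuple(sorted((order[idx[a]], order[idx[b]])))
                key = (q, tie)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = idx[a], idx[b]
        dij = D[i, j]
        bi = 0.5 * dij + (S[a] - S[b]) / (2 * (r - 2))
        bj = dij - bi
        u = Node()
        ci, cj = nodes[i], nodes[j]
        ci.length = max(bi, 0.0)
        cj.length = max(bj, 0.0)
        u.add(ci)
        u.add(cj)
        nodes.append(u)
        ui = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        others = [k for k in active if k not in (i, j)]
        vij = V[i, j]
        if vij > 0 and r > 2:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (2 * (r - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        for k in others:
            D[ui, k] = D[k, ui] = lam * (D[i, k] - bi) + (1 - lam) * (D[j, k] - bj)
            V[ui, k] = V[k, ui] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * vij
        order.append(min(order[i], order[j]))
        active = others + [ui]

    # join the final three nodes on a trifurcating root
    i, j, k = active
    root = Node()
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(ln, 0.0)
        root.add(node)
    return Genealogy(root)


def trees_for_windows(
    hm_by_window: list[tuple[Window, HaplotypeMatrix]],
    taxon_map: dict[str, str],
) -> list[tuple[Window, Genealogy]]:
    """One BIONJ genealogy per phased window; tips annotated with taxa.

    ``taxon_map`` maps sample names to taxa; tip labels are ``sample.slot``.
    Windows whose distance matrix is undefined (no polymorphic data) are
    skipped with a log entry.
    """
    out = []
    for window, hm in hm_by_window:
        try:
            labels, D = hamming_pdist(hm)
        except ValueError as exc:
            logger.warning("window %s skipped: %s", window, exc)
            continue
        if np.all(D == 0):
            logger.warning(
                "window %s:%d-%d has no variation; skipped",
                window.chrom, window.start, window.end,
            )
            continue
        g = bionj(labels, D)
        g.window = window
        g.taxon_map = {lab: taxon_map[lab.rsplit(".", 1)[0]] for lab in labels}
        out.append((window, g))
    return out


def tree_distance_matrix(gen: Genealogy) -> tuple[list[str], np.ndarray]:
    """Path-length distances between all tips (for additivity checks)."""
    leaves = gen.root.leaves()
    labels = [l.name for l in leaves]
    n = len(leaves)

    # depth and ancestry via parent pointers
    def path_to_root(node: Node) -> list[Node]:
        out = [node]
        while out[-1].parent is not None:
            out.append(out[-1].parent)
        return out

    D = np.zeros((n, n))
    paths = [path_to_root(l) for l in leaves]
    for i in range(n):
        for j in range(i + 1, n):
            pi = {id(x): k for k, x in enumerate(paths[i])}
            dist = 0.0
            node_j = paths[j]
            for x in node_j:
                if id(x) in pi:
                    dist += sum(y.length for y in paths[i][: pi[id(x)]])
                    break
                dist += x.length
            D[i, j] = D[j, i] = dist
    return labels, D
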