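"""Topology weighting over five taxa (four ingroups + outgroup).

For each window genealogy, the weighting of a taxon topology is the
fraction of tip combinations (one haplotype per taxon) whose induced,
outgroup-rooted subtree matches that topology. Trees are first simplified
by collapsing same-taxon monophyletic clades into multiplicity-carrying
tips, which leaves the weighting unchanged. Weightings are computed exactly
(integer counting) when the number of remaining tip combinations is at most
``exact_threshold``, and otherwise by Monte-Carlo sampling until the Wilson
confidence interval of every topology frequency is narrower than a target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_popgen import Window
from .trees import Genealogy, Node

logger = logging.getLogger(__name__)

DEFAULT_INGROUPS = ("arenosa2x", "arenosa4x", "lyrata2x", "lyrata4x")
DEFAULT_OUTGROUP = "outgroup"


# ---------------------------------------------------------------------------
# topology enumeration and classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonTopology:
    id: int
    canonical: str          # sorted-newick over ingroup taxon names
    clades: frozenset[frozenset[str]]
    outgroup: str

    def newick(self) -> str:
        return f"({self.canonical},{self.outgroup});"


def _canon(shape) -> str:
    if isinstance(shape, str):
        return shape
    return "(" + ",".join(sorted(_canon(c) for c in shape)) + ")"


def _clades(shape) -> set[frozenset[str]]:
    """All non-trivial clades (leaf-name sets of internal nodes)."""
    out: set[frozenset[str]] = set()

    def leafset(s) -> frozenset[str]:
        if isinstance(s, str):
            return frozenset([s])
        ls = frozenset().union(*(leafset(c) for c in s))
        if len(ls) > 1:
            out.add(ls)
        return ls

    leafset(shape)
    return out


def enumerate_topologies(
    ingroup_taxa: tuple[str, ...] = DEFAULT_INGROUPS,
    outgroup: str = DEFAULT_OUTGROUP,
) -> list[TaxonTopology]:
    """All distinct rooted binary topologies of the ingroup taxa.

    Count is (2n-3)!! for n ingroups (15 for n=4). Ids follow the sorted
    order of the canonical newick strings and are stable across runs.
    """
    taxa = list(ingroup_taxa)
    if len(set(taxa)) != len(taxa) or outgroup in taxa:
        raise ValueError("duplicate taxon names")
    shapes = [taxa[0]]
    for leaf in taxa[1:]:
        new_shapes = []
        for s in shapes:
            new_shapes.extend(_attach(s, leaf))
        shapes = new_shapes
    seen: dict[str, tuple] = {}
    for s in shapes:
        seen.setdefault(_canon(s), s)
    out = []
    for i, canon in enumerate(sorted(seen), start=1):
        out.append(
            TaxonTopology(i, canon, frozenset(_clades(seen[canon])), outgroup)
        )
    return out


def _attach(shape, leaf):
    """All rooted shapes obtained by attaching ``leaf`` onto ``shape``."""
    yield (shape, leaf)  # new root above everything
    if not isinstance(shape, str):
        left, right = shape
        for sub in _attach(left, leaf):
            yield (sub, right)
        for sub in _attach(right, leaf):
            yield (left, sub)


def classify_topologies(
    topologies: list[TaxonTopology],
    lyrata2x: str = "lyrata2x",
    lyrata4x: str = "lyrata4x",
    arenosa2x: str = "arenosa2x",
    arenosa4x: str = "arenosa4x",
) -> dict[int, str]:
    """Structural classes: species / introgression / ILS / other.

    * species: conspecifics are sisters — ((L2x,L4x),(A2x,A4x))
    * introgression: the two tetraploids form a clade
    * ILS: a diploid of one species forms a clade with the other species'
      tetraploid (and the topology is not introgression-classified)
    """
    tetra = frozenset([lyrata4x, arenosa4x])
    ils_a = frozenset([arenosa2x, lyrata4x])
    ils_b = frozenset([lyrata2x, arenosa4x])
    species = frozenset(
        [frozenset([lyrata2x, lyrata4x]), frozenset([arenosa2x, arenosa4x])]
    )
    out: dict[int, str] = {}
    for t in topologies:
        if species <= t.clades:
            out[t.id] = "species"
        elif tetra in t.clades:
            out[t.id] = "introgression"
        elif ils_a in t.clades or ils_b in t.clades:
            out[t.id] = "ils"
        else:
            out[t.id] = "other"
    return out


# ---------------------------------------------------------------------------
# tree simplification
# ---------------------------------------------------------------------------

class SimplifiedTree:
    """Unrooted tree whose tips carry a taxon and a multiplicity.

    Same-taxon monophyletic clades of the source genealogy are collapsed to
    single tips; the topology weighting is invariant under this collapse.
    """

    def __init__(
        self,
        adj: dict[int, set[int]],
        tip_taxon: dict[int, str],
        tip_mult: dict[int, int],
    ):
        self.adj = adj
        self.tip_taxon = tip_taxon
        self.tip_mult = tip_mult
        self._dist: np.ndarray | None = None
        self._tip_index: dict[int, int] = {t: i for i, t in enumerate(sorted(tip_taxon))}

    @property
    def tips_by_taxon(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for t in sorted(self.tip_taxon):
            out.setdefault(self.tip_taxon[t], []).append(t)
        return out

    def combination_count(self) -> int:
        """Number of distinct remaining tip combinations (one per taxon)."""
        c = 1
        for tips in self.tips_by_taxon.values():
            c *= len(tips)
        return c

    def total_weight(self) -> int:
        """Product over taxa of summed multiplicities (= product of group sizes)."""
        c = 1
        for tips in self.tips_by_taxon.values():
            c *= sum(self.tip_mult[t] for t in tips)
        return c

    def tip_distance(self, a: int, b: int) -> int:
        if self._dist is None:
            self._compute_dists()
        return int(self._dist[self._tip_index[a], self._tip_index[b]])

    def _compute_dists(self) -> None:
        tips = sorted(self.tip_taxon)
        n = len(tips)
        self._dist = np.zeros((n, n), dtype=np.int32)
        for i, src in enumerate(tips):
            # BFS over the unrooted tree
            depth = {src: 0}
            frontier = [src]
            while frontier:
                nxt = []
                for v in frontier:
                    for w in self.adj[v]:
                        if w not in depth:
                            depth[w] = depth[v] + 1
                            nxt.append(w)
                frontier = nxt
            for j, dst in enumerate(tips):
                self._dist[i, j] = depth[dst]


def _genealogy_to_graph(
    gen: Genealogy, taxon_map: dict[str, str]
) -> tuple[dict[int, set[int]], dict[int, str], dict[int, int]]:
    adj: dict[int, set[int]] = {}
    tip_taxon: dict[int, str] = {}
    counter = [0]
    ids: dict[int, int] = {}

    def nid(node: Node) -> int:
        key = id(node)
        if key not in ids:
            ids[key] = counter[0]
            adj[counter[0]] = set()
            counter[0] += 1
        return ids[key]

    stack = [gen.root]
    while stack:
        node = stack.pop()
        u = nid(node)
        if node.is_leaf:
            # accept tip-level keys or sample-level keys ('sample.slot' tips)
            taxon = taxon_map.get(node.name)
            if taxon is None and node.name and "." in node.name:
                taxon = taxon_map.get(node.name.rsplit(".", 1)[0])
            if taxon is None:
                raise ValueError(f"tip {node.name!r} has no taxon")
            tip_taxon[u] = taxon
        for c in node.children:
            v = nid(c)
            adj[u].add(v)
            adj[v].add(u)
            stack.append(c)
    return adj, tip_taxon, {t: 1 for t in tip_taxon}


def _suppress_degree2(adj, tip_taxon) -> None:
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v not in tip_taxon and len(adj[v]) == 2:
                a, b = adj[v]
                adj[a].discard(v)
                adj[b].discard(v)
                adj[a].add(b)
                adj[b].add(a)
                del adj[v]
                changed = True


def simplify_tree(gen: Genealogy, taxon_map: dict[str, str] | None = None) -> SimplifiedTree:
    """Collapse same-taxon monophyletic clades into multiplicity tips."""
    if taxon_map is None:
        taxon_map = gen.taxon_map
    adj, tip_taxon, tip_mult = _genealogy_to_graph(gen, taxon_map)
    _suppress_degree2(adj, tip_taxon)
    changed = True
    while changed:
        changed = False
        for v in list(adj):
            if v in tip_taxon or v not in adj:
                continue
            # group tip neighbours of v by taxon
            by_taxon: dict[str, list[int]] = {}
            for w in adj[v]:
                if w in tip_taxon:
                    by_taxon.setdefault(tip_taxon[w], []).append(w)
            for taxon, tips in by_taxon.items():
                if len(tips) >= 2:
                    keep, *drop = sorted(tips)
                    for d in drop:
                        tip_mult[keep] += tip_mult.pop(d)
                        del tip_taxon[d]
                        adj[v].discard(d)
                        del adj[d]
                    changed = True
            if v in adj and len(adj[v]) == 2 and v not in tip_taxon:
                a, b = adj[v]
                adj[a].discard(v)
                adj[b].discard(v)
                adj[a].add(b)
                adj[b].add(a)
                del adj[v]
                changed = True
    return SimplifiedTree(adj, tip_taxon, tip_mult)


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

@dataclass
class WeightingResult:
    window: Window | None
    weights: np.ndarray            # per topology id order
    mode: str                      # 'exact' | 'sampled'
    n_samples: int = 0
    ci_half_widths: np.ndarray | None = None
    seed: int | None = None
    exact_fractions: list[Fraction] | None = None


def _induced_topology_id(
    st: SimplifiedTree,
    out_tip: int,
    combo: dict[str, int],
    topo_ids: dict[str, int],
) -> int:
    """Id of the outgroup-rooted topology induced by one tip per taxon.

    Uses MRCA depths from the outgroup tip: depth(x, y) =
    (d(o,x) + d(o,y) - d(x,y)) / 2 in unit branch lengths. The deepest pair
    is always a true cherry of the induced topology, so iterated merging
    recovers the rooted shape.
    """
    units = [(taxon, tip) for taxon, tip in sorted(combo.items())]

    def depth(x: int, y: int) -> int:
        return st.tip_distance(out_tip, x) + st.tip_distance(out_tip, y) - st.tip_distance(x, y)

    while len(units) > 1:
        best = None
        for i in range(len(units)):
            for j in range(i + 1, len(units)):
                d = depth(units[i][1], units[j][1])
                if best is None or d > best[0]:
                    best = (d, i, j)
        _, i, j = best
        (ca, ta), (cb, tb) = units[i], units[j]
        merged = ("(" + ",".join(sorted([ca, cb])) + ")", ta)
        units = [u for k, u in enumerate(units) if k not in (i, j)] + [merged]
    return topo_ids[units[0][0]]


def exact_weighting(
    st: SimplifiedTree,
    topologies: list[TaxonTopology] | None = None,
    window: Window | None = None,
) -> WeightingResult:
    """Exact weighting by enumeration of all remaining tip combinations."""
    if topologies is None:
        topologies = enumerate_topologies()
    outgroup = topologies[0].outgroup
    topo_ids = {t.canonical: t.id for t in topologies}
    by_taxon = st.tips_by_taxon
    if outgroup not in by_taxon:
        raise ValueError(f"no {outgroup!r} tips in tree")
    ingroups = sorted(t for t in by_taxon if t != outgroup)
    counts = {t.id: 0 for t in topologies}
    total = 0
    for out_tip in by_taxon[outgroup]:
        w_out = st.tip_mult[out_tip]
        for tips in product(*(by_taxon[t] for t in ingroups)):
            combo = dict(zip(ingroups, tips))
            w = w_out
            for tip in tips:
                w *= st.tip_mult[tip]
            tid = _induced_topology_id(st, out_tip, combo, topo_ids)
            counts[tid] += w
            total += w
    assert total == st.total_weight()
    fracs = [Fraction(counts[t.id], total) for t in topologies]
    assert sum(fracs) == 1
    return WeightingResult(
        window,
        np.array([float(f) for f in fracs]),
        "exact",
        n_samples=total,
        exact_fractions=fracs,
    )


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k outside 0..n")
    z = norm.ppf(1 - (1 - conf) / 2)
    phat = k / n
    denom = 1 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return (lo, hi)


def sampled_weighting(
    st: SimplifiedTree,
    topologies: list[TaxonTopology] | None = None,
    ci_target: float = 0.05,
    conf: float = 0.95,
    seed: int = 0,
    batch: int = 100,
    window: Window | None = None,
    max_samples: int = 1_000_000,
) -> WeightingResult:
    """Monte-Carlo weighting: sample combinations until every topology's
    Wilson CI half-width is below ``ci_target``."""
    if topologies is None:
        topologies = enumerate_topologies()
    outgroup = topologies[0].outgroup
    topo_ids = {t.canonical: t.id for t in topologies}
    by_taxon = st.tips_by_taxon
    ingroups = sorted(t for t in by_taxon if t != outgroup)
    taxa = [outgroup] + ingroups
    rng = np.random.default_rng(seed)
    choices = {}
    for t in taxa:
        tips = by_taxon[t]
        mults = np.array([st.tip_mult[x] for x in tips], dtype=float)
        choices[t] = (tips, mults / mults.sum())
    counts = np.zeros(len(topologies), dtype=np.int64)
    n = 0
    while True:
        for _ in range(batch):
            out_tip = _draw(rng, *choices[outgroup])
            combo = {t: _draw(rng, *choices[t]) for t in ingroups}
            tid = _induced_topology_id(st, out_tip, combo, topo_ids)
            counts[tid - 1] += 1
        n += batch
        halves = np.array(
            [
                (hi - lo) / 2
                for lo, hi in (wilson_interval(int(k), n, conf) for k in counts)
            ]
        )
        if np.all(halves < ci_target) or n >= max_samples:
            break
    return WeightingResult(
        window, counts / n, "sampled", n_samples=n, ci_half_widths=halves, seed=seed
    )


def _draw(rng, tips, probs):
    return tips[int(rng.choice(len(tips), p=probs))]


def weight_tree(
    gen: Genealogy,
    taxon_map: dict[str, str] | None = None,
    topologies: list[TaxonTopology] | None = None,
    exact_threshold: int = 2000,
    ci_target: float = 0.05,
    conf: float = 0.95,
    seed: int = 0,
) -> WeightingResult:
    """Simplify, then weight exactly if the combination count allows,
    otherwise by sampling."""
    st = simplify_tree(gen, taxon_map)
    if st.combination_count() <= exact_threshold:
        return exact_weighting(st, topologies, window=gen.window)
    return sampled_weighting(
        st, topologies, ci_target=ci_target, conf=conf, seed=seed, window=gen.window
    )


# ---------------------------------------------------------------------------
# genome-wide profile and peak calling
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    summit_label: str
    max_weight: float
    threshold: float
    windows: list[str] = field(default_factory=list)


def weighting_profile(
    trees: list[tuple[Window, Genealogy]],
    taxon_map: dict[str, str] | None = None,
    thresholds: tuple[float, ...] = (0.5, 0.7),
    exact_threshold: int = 2000,
    ci_target: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[float, list[Peak]]]:
    """Per-window topology weights, class sums, and introgression peaks.

    A peak is a maximal run of consecutive windows whose introgression-class
    weight exceeds the threshold; the summit is the window with the largest
    class weight in the run.
    """
    topologies = enumerate_topologies()
    classes = classify_topologies(topologies)
    rows = []
    for window, gen in trees:
        res = weight_tree(
            gen, taxon_map, topologies, exact_threshold=exact_threshold,
            ci_target=ci_target, seed=seed,
        )
        row = {
            "chrom": window.chrom,
            "start": window.start,
            "end": window.end,
            "label": window.label or f"{window.chrom}:{window.start}",
            "mode": res.mode,
            "n_samples": res.n_samples,
        }
        for t, w in zip(topologies, res.weights):
            row[f"topo{t.id}"] = w
        for cls in ("species", "introgression", "ils", "other"):
            row[f"w_{cls}"] = float(
                sum(w for t, w in zip(topologies, res.weights) if classes[t.id] == cls)
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    peaks: dict[float, list[Peak]] = {}
    for thr in thresholds:
        peaks[thr] = _call_peaks(table, thr)
    return table, peaks


def _call_peaks(table: pd.DataFrame, threshold: float) -> list[Peak]:
    peaks: list[Peak] = []
    run: list[int] = []

    def flush():
        if not run:
            return
        sub = table.iloc[run]
        summit = sub["w_introgression"].idxmax()
        peaks.append(
            Peak(
                chrom=sub.iloc[0]["chrom"],
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                summit_label=str(table.loc[summit, "label"]),
                max_weight=float(sub["w_introgression"].max()),
                threshold=threshold,
                windows=[str(x) for x in sub["label"]],
            )
        )

    prev_chrom = None
    for i in range(len(table)):
        row = table.iloc[i]
        above = row["w_introgression"] > threshold
        if above and (not run or row["chrom"] == prev_chrom):
            run.append(i)
        elif above:
            flush()
            run = [i]
        else:
            flush()
            run = []
        prev_chrom = row["chrom"]
    flush()
    return peaks
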