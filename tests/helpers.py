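"""Shared test utilities: toy matrix builders and independent oracles."""

from __future__ import annotations

import itertools

import numpy as np

from polyscan.io_popgen import GenotypeMatrix, PopulationMap, VariantSite
from polyscan.phasing import enumerate_configurations, pairwise_ld
from polyscan.trees import Genealogy, Node
from polyscan.weighting import TaxonTopology

TAXA = ("lyrata2x", "lyrata4x", "arenosa2x", "arenosa4x")


def make_gm(dosage, ploidy, chrom="chr1", positions=None, samples=None):
    """GenotypeMatrix from a plain nested list (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n_sites, n_samples = dosage.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if isinstance(ploidy, int):
        ploidy = {s: ploidy for s in samples}
    elif isinstance(ploidy, (list, tuple)):
        ploidy = dict(zip(samples, ploidy))
    if positions is None:
        positions = [10 * (i + 1) for i in range(n_sites)]
    sites = [VariantSite(chrom, p, "A", "T") for p in positions]
    return GenotypeMatrix(sites, samples, ploidy, dosage)


def make_popmap(assignment):
    """PopulationMap from {pop: (taxon, [samples...])}."""
    sample_pop, pop_taxon = {}, {}
    for pop, (taxon, samples) in assignment.items():
        pop_taxon[pop] = taxon
        for s in samples:
            sample_pop[s] = pop
    return PopulationMap(sample_pop, pop_taxon)


def random_topology(tipnames, rng):
    """Random unrooted binary tree (trifurcating-root representation is fine
    for weighting; here we return a bifurcating seed)."""
    nodes = [Node(name=n, length=1.0) for n in tipnames]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        p = Node(length=1.0)
        p.add(nodes[i])
        p.add(nodes[j])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = Node()
    root.add(nodes[0])
    root.add(nodes[1])
    return root


def random_taxon_tree(rng, max_per_taxon=3, max_outgroup=2):
    """Random genealogy with 1..max_per_taxon tips per ingroup taxon."""
    tipnames, tm = [], {}
    sizes = {t: int(rng.integers(1, max_per_taxon + 1)) for t in TAXA}
    sizes["outgroup"] = int(rng.integers(1, max_outgroup + 1))
    for t, k in sizes.items():
        for i in range(k):
            nm = f"{t}-{i}"
            tipnames.append(nm)
            tm[nm] = t
    return Genealogy(random_topology(tipnames, rng), taxon_map=tm)


def dendropy_oracle_weights(
    newick: str, taxon_map: dict[str, str], topologies: list[TaxonTopology]
) -> np.ndarray:
    """Independent weighting oracle: enumerate all tip combinations and, for
    each, prune the tree with dendropy, reroot on the outgroup tip and read
    off the induced rooted topology."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    topo_ids = {t.canonical: t.id for t in topologies}
    outg = topologies[0].outgroup
    by_taxon: dict[str, list[str]] = {}
    for leaf in tree.leaf_node_iter():
        by_taxon.setdefault(taxon_map[leaf.taxon.label], []).append(leaf.taxon.label)
    ingroups = sorted(t for t in by_taxon if t != outg)
    counts = {t.id: 0 for t in topologies}
    total = 0
    for combo in itertools.product(by_taxon[outg], *(by_taxon[t] for t in ingroups)):
        sub = tree.extract_tree_with_taxa_labels(labels=combo)
        og = [l for l in sub.leaf_node_iter() if l.taxon.label == combo[0]][0]
        sub.reroot_at_edge(og.edge, update_bipartitions=False)

        def canon(node):
            if node.is_leaf():
                return taxon_map[node.taxon.label]
            kids = node.child_nodes()
            if len(kids) == 1:
                return canon(kids[0])
            return "(" + ",".join(sorted(canon(c) for c in kids)) + ")"

        root_kids = [
            c
            for c in sub.seed_node.child_nodes()
            if not (c.is_leaf() and c.taxon.label == combo[0])
        ]
        assert len(root_kids) == 1
        counts[topo_ids[canon(root_kids[0])]] += 1
        total += 1
    return np.array([counts[t.id] / total for t in topologies])


def brute_force_phase_optimum(gm, cap=60_000):
    """Exhaustive maximum of the mean pairwise-r^2 phasing objective.

    Returns (optimum, n_configurations) or (None, n) if above ``cap``.
    """
    samples = gm.samples
    ploidies = [gm.ploidy[s] for s in samples]
    n_slots = sum(ploidies)
    offsets = np.cumsum([0] + ploidies[:-1])
    per_site = []
    for i in range(gm.n_sites):
        opts = []
        it = itertools.product(
            *[
                enumerate_configurations(int(gm.dosage[i, j]), ploidies[j])
                for j in range(len(samples))
            ]
        )
        for cfgs in it:
            col = np.zeros(n_slots, dtype=np.int8)
            for j, cfg in enumerate(cfgs):
                for k in cfg:
                    col[offsets[j] + k] = 1
            opts.append(col)
        per_site.append(opts)
    total = int(np.prod([len(o) for o in per_site]))
    if total > cap:
        return None, total
    best = -1.0
    for combo in itertools.product(*per_site):
        H = np.array(combo).astype(float)  # sites x slots
        poly = [i for i in range(H.shape[0]) if H[i].min() != H[i].max()]
        if len(poly) < 2:
            obj = 0.0
        else:
            C = np.corrcoef(H[poly])
            obj = float(np.mean(C[np.triu_indices(len(poly), 1)] ** 2))
        best = max(best, obj)
    return best, total


def pair_metrics_brute_force(p_a, p_b, n_a, n_b, x_a, x_b):
    """Direct per-formula summation of the five divergence metrics.

    ``p_*`` allele freqs, ``n_*`` called allele counts per SNP; ``x_*`` lists
    of per-individual allele-frequency arrays per SNP (called only).
    """
    afd = float(np.mean([abs(a - b) for a, b in zip(p_a, p_b)]))
    dxy = float(np.mean([a * (1 - b) + b * (1 - a) for a, b in zip(p_a, p_b)]))
    fixed = sum(
        1 for a, b in zip(p_a, p_b) if (a == 1 and b == 0) or (a == 0 and b == 1)
    )
    hw_sum = hb_sum = 0.0
    rho_num = rho_den = 0.0
    for a, b, na, nb, xa, xb in zip(p_a, p_b, n_a, n_b, x_a, x_b):
        if na < 2 or nb < 2:
            continue
        hw = 0.5 * (2 * a * (1 - a) * na / (na - 1) + 2 * b * (1 - b) * nb / (nb - 1))
        hb = a * (1 - b) + b * (1 - a)
        hw_sum += hw
        hb_sum += hb
        ia, ib = len(xa), len(xb)
        n_tot = ia + ib
        if ia < 1 or ib < 1 or n_tot < 3:
            continue
        ma, mb = np.mean(xa), np.mean(xb)
        grand = (ia * ma + ib * mb) / n_tot
        msb = ia * (ma - grand) ** 2 + ib * (mb - grand) ** 2
        msw = (np.sum((xa - ma) ** 2) + np.sum((xb - mb) ** 2)) / (n_tot - 2)
        n0 = n_tot - (ia**2 + ib**2) / n_tot
        rho_num += msb - msw
        rho_den += msb + (n0 - 1) * msw
    fst = 1 - hw_sum / hb_sum if hb_sum > 0 else np.nan
    rho = rho_num / rho_den if rho_den > 0 else np.nan
    return afd, dxy, fst, rho, fixed
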