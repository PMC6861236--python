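"""Synthetic mixed-ploidy datasets with full ground truth.

A minimal structured coalescent generates one genealogy per genomic window:
five demes (two species, each with a diploid and an autotetraploid
population, plus an outgroup), population splits at configurable times, the
two whole-genome duplications modelled as daughter-population foundings,
optional continuous tetraploid-tetraploid migration and per-window
introgression pulses. Mutations are dropped under the infinite-sites model,
so every site is biallelic by construction. Tetraploids are tetrasomic:
four exchangeable lineages per individual.

Sweep-like signals are imposed afterwards by resampling target-group
haplotypes toward a high ALT frequency inside designated windows.

All times are in generations; all randomness flows from the scenario seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .io_popgen import (
    MISSING,
    GenotypeMatrix,
    PopulationMap,
    VariantSite,
    Window,
    write_bed,
    write_popmap,
    write_vcf,
)
from .phasing import HaplotypeMatrix, write_phased_vcf
from .trees import Genealogy, Node

logger = logging.getLogger(__name__)

TAXON_PLOIDY = {
    "lyrata2x": 2,
    "lyrata4x": 4,
    "arenosa2x": 2,
    "arenosa4x": 4,
    "outgroup": 2,
}


def default_samples() -> dict[str, list[tuple[str, int]]]:
    """taxon -> [(population, n_individuals), ...]"""
    return {
        "lyrata2x": [("LDA", 2), ("LDB", 2)],
        "lyrata4x": [("LTA", 2), ("LTB", 2)],
        "arenosa2x": [("ADA", 2)],
        "arenosa4x": [("ATA", 2)],
        "outgroup": [("OUT", 1)],
    }


@dataclass
class DemographyScenario:
    """Reference demography: species split at 931k generations, WGDs at 81k
    (lyrata) and 226k (arenosa) generations, mu = 3.7e-8 per bp per
    generation, bidirectional tetraploid migration 0.1 alleles/generation."""

    split_gen: float = 931_000.0
    wgd_lyrata_gen: float = 81_000.0
    wgd_arenosa_gen: float = 226_000.0
    outgroup_split_gen: float = 2_000_000.0
    ne: dict[str, float] = field(
        default_factory=lambda: {t: 30_000.0 for t in TAXON_PLOIDY}
    )
    ancestral_ne: float = 30_000.0
    migration: float = 0.1  # tetraploid<->tetraploid, alleles/generation
    mu: float = 3.7e-8
    seq_len: int = 400
    seed: int = 0
    samples: dict[str, list[tuple[str, int]]] = field(default_factory=default_samples)

    def __post_init__(self) -> None:
        if not (self.wgd_lyrata_gen < self.split_gen and self.wgd_arenosa_gen < self.split_gen):
            raise ValueError("WGD times must predate (be smaller than) the species split")
        if self.split_gen >= self.outgroup_split_gen:
            raise ValueError("outgroup split must be deeper than the species split")
        if self.migration < 0 or self.mu < 0:
            raise ValueError("rates must be >= 0")

    def popmap(self) -> PopulationMap:
        sample_pop: dict[str, str] = {}
        pop_taxon: dict[str, str] = {}
        for taxon, pops in self.samples.items():
            for pop, n_ind in pops:
                pop_taxon[pop] = taxon
                for i in range(1, n_ind + 1):
                    sample_pop[f"{pop}_{i}"] = pop
        return PopulationMap(sample_pop, pop_taxon)

    def sample_ploidy(self) -> dict[str, int]:
        pm = self.popmap()
        return {s: TAXON_PLOIDY[pm.taxon_of_sample(s)] for s in pm.sample_pop}


@dataclass
class IntrogressionPulse:
    """At ``time`` generations ago, a round(fraction * k) subset of the k
    recipient-taxon lineages jumps into the donor taxon's deme (backward in
    time); which lineages move is random, how many is deterministic."""

    donor: str
    recipient: str
    time: float = 5_000.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.donor not in TAXON_PLOIDY or self.recipient not in TAXON_PLOIDY:
            raise ValueError("unknown taxon in pulse")


@dataclass
class TruthSet:
    """Ground truth emitted next to a synthetic dataset."""

    haplotypes: HaplotypeMatrix | None = None
    sweep_windows: dict[str, tuple[str, float]] = field(default_factory=dict)
    introgressed_windows: dict[str, str] = field(default_factory=dict)  # label -> donor


class _Lineage:
    __slots__ = ("node", "time", "deme")

    def __init__(self, node: Node, time: float, deme: str):
        self.node = node
        self.time = time
        self.deme = deme


def simulate_genealogy(
    scenario: DemographyScenario,
    window_id: int,
    pulse: IntrogressionPulse | None = None,
) -> Genealogy:
    """One coalescent genealogy for a window; tips are ``sample.slot``."""
    rng = np.random.default_rng([scenario.seed, 7_919, window_id])
    if pulse is not None:
        merge_times = {
            "lyrata4x": scenario.wgd_lyrata_gen,
            "arenosa4x": scenario.wgd_arenosa_gen,
        }
        for taxon in (pulse.donor, pulse.recipient):
            if taxon in merge_times and pulse.time >= merge_times[taxon]:
                raise ValueError(
                    f"pulse at {pulse.time} into {taxon} postdates its founding"
                )

    pm = scenario.popmap()
    lineages: list[_Lineage] = []
    taxon_map: dict[str, str] = {}
    for sample, pop in pm.sample_pop.items():
        taxon = pm.pop_taxon[pop]
        for k in range(TAXON_PLOIDY[taxon]):
            name = f"{sample}.{k}"
            lineages.append(_Lineage(Node(name=name), 0.0, taxon))
            taxon_map[name] = taxon

    events: list[tuple[float, str]] = []
    if pulse is not None:
        events.append((pulse.time, "pulse"))
    events.append((scenario.wgd_lyrata_gen, "merge:lyrata4x:lyrata2x"))
    events.append((scenario.wgd_arenosa_gen, "merge:arenosa4x:arenosa2x"))
    events.append((scenario.split_gen, "merge:arenosa2x:lyrata2x"))
    events.append((scenario.outgroup_split_gen, "merge:outgroup:lyrata2x"))
    events.sort()

    def deme_ne(deme: str) -> float:
        if deme == "lyrata2x" and t >= scenario.split_gen:
            return scenario.ancestral_ne
        return scenario.ne[deme]

    t = 0.0
    ev_i = 0
    both_tetra_alive = True
    while len(lineages) > 1:
        by_deme: dict[str, list[int]] = {}
        for i, ln in enumerate(lineages):
            by_deme.setdefault(ln.deme, []).append(i)
        coal_rates = {
            d: len(ix) * (len(ix) - 1) / 2 / (2 * deme_ne(d))
            for d, ix in by_deme.items()
            if len(ix) >= 2
        }
        mig_rates: dict[tuple[str, str], float] = {}
        if scenario.migration > 0 and both_tetra_alive:
            for src, dst in (("lyrata4x", "arenosa4x"), ("arenosa4x", "lyrata4x")):
                k = len(by_deme.get(src, []))
                if k:
                    mig_rates[(src, dst)] = k * scenario.migration / (2 * scenario.ne[src])
        total = sum(coal_rates.values()) + sum(mig_rates.values())
        if total == 0:
            dt = np.inf
        else:
            dt = rng.exponential(1.0 / total)
        if ev_i < len(events) and t + dt >= events[ev_i][0]:
            t, action = events[ev_i]
            ev_i += 1
            if action == "pulse":
                assert pulse is not None
                recip = [ln for ln in lineages if ln.deme == pulse.recipient]
                n_mig = int(round(pulse.fraction * len(recip)))
                for i in rng.choice(len(recip), size=n_mig, replace=False):
                    recip[int(i)].deme = pulse.donor
            else:
                _, src, dst = action.split(":")
                for ln in lineages:
                    if ln.deme == src:
                        ln.deme = dst
                if src in ("lyrata4x", "arenosa4x"):
                    both_tetra_alive = False
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        chosen = None
        for d, rate in coal_rates.items():
            acc += rate
            if u < acc:
                chosen = ("coal", d)
                break
        if chosen is None:
            for (src, dst), rate in mig_rates.items():
                acc += rate
                if u < acc:
                    chosen = ("mig", src, dst)
                    break
        if chosen is None:  # numerical edge
            continue
        if chosen[0] == "coal":
            d = chosen[1]
            ix = by_deme[d]
            a, b = rng.choice(len(ix), size=2, replace=False)
            la, lb = lineages[ix[a]], lineages[ix[b]]
            parent = Node()
            la.node.length = t - la.time
            lb.node.length = t - lb.time
            parent.add(la.node)
            parent.add(lb.node)
            merged = _Lineage(parent, t, d)
            lineages = [
                ln for i, ln in enumerate(lineages) if i not in (ix[a], ix[b])
            ] + [merged]
        else:
            _, src, dst = chosen
            ix = by_deme[src]
            pick = int(rng.choice(len(ix)))
            lineages[ix[pick]].deme = dst

    root = lineages[0].node
    gen = Genealogy(root, taxon_map=taxon_map)
    return gen


def drop_mutations(
    gen: Genealogy, mu: float, seq_len: int, seed: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Infinite-sites mutations: Poisson(mu * L * branch) per branch.

    Returns (positions sorted ascending, tips x sites 0/1 matrix, tip names).
    """
    rng = np.random.default_rng(seed)
    tips = gen.root.leaves()
    tip_index = {t.name: i for i, t in enumerate(tips)}
    branch_tipsets: list[list[int]] = []
    n_mut_per_branch: list[int] = []

    def visit(node: Node) -> list[int]:
        below = (
            [tip_index[node.name]]
            if node.is_leaf
            else [i for c in node.children for i in visit(c)]
        )
        if node.parent is not None:
            k = int(rng.poisson(mu * seq_len * max(node.length, 0.0)))
            if k:
                branch_tipsets.append(below)
                n_mut_per_branch.append(k)
        return below

    visit(gen.root)
    s = int(sum(n_mut_per_branch))
    if s == 0:
        return np.zeros(0, dtype=np.int64), np.zeros((len(tips), 0), dtype=np.int8), [
            t.name for t in tips
        ]
    if s > seq_len:
        raise ValueError(
            f"{s} mutations exceed seq_len={seq_len}; infinite-sites needs more sites"
        )
    positions = np.sort(rng.choice(np.arange(1, seq_len + 1), size=s, replace=False))
    # assign mutations to positions in a deterministic shuffled order
    site_order = rng.permutation(s)
    haps = np.zeros((len(tips), s), dtype=np.int8)
    m = 0
    for tipset, k in zip(branch_tipsets, n_mut_per_branch):
        for _ in range(k):
            haps[tipset, site_order[m]] = 1
            m += 1
    return positions, haps, [t.name for t in tips]


def collapse_to_genotypes(
    positions: np.ndarray,
    haps: np.ndarray,
    tip_names: list[str],
    scenario: DemographyScenario,
    chrom: str = "chr1",
    offset: int = 0,
    randomise_phase: bool = False,
    seed: int = 0,
) -> tuple[GenotypeMatrix, HaplotypeMatrix]:
    """Sum per-sample haplotypes into dosages; keep true phase as truth.

    Tip names are ``sample.slot``; the slot order of the truth matrix follows
    the popmap sample order.
    """
    pm = scenario.popmap()
    ploidy = scenario.sample_ploidy()
    samples = list(pm.sample_pop)
    sites = [
        VariantSite(chrom, int(offset + p), "A", "T") for p in positions
    ]
    n_sites = len(sites)
    tipmap = {name: i for i, name in enumerate(tip_names)}
    rows = []
    for s in samples:
        for k in range(ploidy[s]):
            rows.append(tipmap[f"{s}.{k}"])
    hap_matrix = haps[rows, :].astype(np.int8)  # slots x sites
    if randomise_phase:
        rng = np.random.default_rng(seed)
        off = 0
        for s in samples:
            k = ploidy[s]
            for i in range(n_sites):
                rng.shuffle(hap_matrix[off : off + k, i])
            off += k
    dosage = np.zeros((n_sites, len(samples)), dtype=np.int16)
    off = 0
    for j, s in enumerate(samples):
        k = ploidy[s]
        dosage[:, j] = hap_matrix[off : off + k, :].sum(axis=0)
        off += k
    gm = GenotypeMatrix(sites, samples, ploidy, dosage)
    hm = HaplotypeMatrix(gm, hap_matrix, provenance="true")
    return gm, hm


def spike_sweep(
    gm: GenotypeMatrix,
    hm: HaplotypeMatrix,
    windows: list[Window],
    popmap: PopulationMap,
    target_group: str,
    target_freq: float,
    seed: int = 0,
) -> TruthSet:
    """Resample target-group haplotypes toward ALT frequency ``target_freq``
    inside the given windows (in place); other groups are untouched."""
    if not 0 < target_freq <= 1:
        raise ValueError("target_freq must be in (0, 1]")
    rng = np.random.default_rng(seed)
    targets = [
        s for s in gm.samples if popmap.taxon_of_sample(s) == target_group
    ] or popmap.pop_samples(target_group)
    if not targets:
        raise ValueError(f"no samples in target group {target_group!r}")
    truth = TruthSet()
    for w in windows:
        idx = gm.window_site_indices(w)
        if not idx:
            logger.warning("sweep window %s has no SNPs; skipped", w.label)
            continue
        for s in targets:
            j = gm.sample_index(s)
            rows = hm.sample_rows(s)
            k = gm.ploidy[s]
            for i in idx:
                if gm.dosage[i, j] == MISSING:
                    continue
                new = (rng.random(k) < target_freq).astype(np.int8)
                hm.haps[rows, i] = new
                gm.dosage[i, j] = int(new.sum())
        truth.sweep_windows[w.label or f"{w.chrom}:{w.start}"] = (
            target_group,
            target_freq,
        )
    return truth


def generate_dataset(
    scenario: DemographyScenario,
    n_windows: int,
    sweep_spec: dict[int, tuple[str, float]] | None = None,
    introgression_spec: dict[int, IntrogressionPulse] | None = None,
    out_dir: str | None = None,
    randomise_phase: bool = False,
) -> tuple[GenotypeMatrix, PopulationMap, list[Window], TruthSet]:
    """Simulate ``n_windows`` adjacent windows and (optionally) write
    VCF + popmap + window BED + truth tables to ``out_dir``.

    ``sweep_spec`` maps window index -> (target taxon, target ALT freq);
    ``introgression_spec`` maps window index -> pulse description.
    """
    sweep_spec = sweep_spec or {}
    introgression_spec = introgression_spec or {}
    pm = scenario.popmap()
    span = scenario.seq_len
    all_pos: list[np.ndarray] = []
    all_haps: list[np.ndarray] = []
    tip_names_ref: list[str] | None = None
    windows: list[Window] = []
    genealogies: list[Genealogy] = []
    for w in range(n_windows):
        pulse = introgression_spec.get(w)
        gen = simulate_genealogy(scenario, w, pulse=pulse)
        genealogies.append(gen)
        pos, haps, tip_names = drop_mutations(
            gen, scenario.mu, scenario.seq_len,
            seed=int(np.random.default_rng([scenario.seed, 104_729, w]).integers(2**31)),
        )
        if tip_names_ref is None:
            tip_names_ref = tip_names
        else:  # stable tip order across windows
            order = [tip_names.index(n) for n in tip_names_ref]
            haps = haps[order, :]
        all_pos.append(pos + w * span)
        all_haps.append(haps)
        windows.append(Window("chr1", w * span + 1, (w + 1) * span, "gene", f"g{w}"))

    positions = np.concatenate(all_pos)
    haps = np.concatenate(all_haps, axis=1) if all_haps else np.zeros((0, 0), np.int8)
    gm, hm = collapse_to_genotypes(
        positions, haps, tip_names_ref or [], scenario,
        randomise_phase=randomise_phase, seed=scenario.seed + 13,
    )
    truth = TruthSet(haplotypes=hm)
    for w, pulse in introgression_spec.items():
        truth.introgressed_windows[f"g{w}"] = pulse.donor
    for w, (taxon, freq) in sweep_spec.items():
        tr = spike_sweep(
            gm, hm, [windows[w]], pm, taxon, freq, seed=scenario.seed + 1000 + w
        )
        truth.sweep_windows.update(tr.sweep_windows)

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_vcf(gm, os.path.join(out_dir, "synthetic.vcf"))
        write_popmap(pm, os.path.join(out_dir, "popmap.tsv"))
        write_bed(windows, os.path.join(out_dir, "windows.bed"))
        write_phased_vcf(hm, os.path.join(out_dir, "truth_phase.vcf"))
        sweep_w = [w for w in windows if (w.label or "") in truth.sweep_windows]
        intro_w = [w for w in windows if (w.label or "") in truth.introgressed_windows]
        write_bed(sweep_w, os.path.join(out_dir, "truth_sweeps.bed"))
        write_bed(intro_w, os.path.join(out_dir, "truth_introgression.bed"))
        with open(os.path.join(out_dir, "truth_trees.nwk"), "w") as fh:
            for w, gen in zip(windows, genealogies):
                fh.write(f"{gen.newick()}\n")
    return gm, pm, windows, truth
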