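"""Heuristic phasing of mixed-ploidy genotypes within a SNP window.

Sites are processed in decreasing order of heterozygous-genotype count
(ties by ascending position). The first site gets the canonical
configuration (ALT alleles to the lowest-numbered haplotype slots). Each
subsequent site receives the configuration maximising the mean r^2 between
its haplotype column and all previously phased columns — searched
exhaustively over the site's joint sample configurations when that space is
small, otherwise by coordinate ascent over samples in fixed order. The
procedure is fully deterministic.
"""

from __future__ import annotations

import logging
from itertools import combinations, product

import numpy as np

from .io_popgen import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class HaplotypeMatrix:
    """Phased 0/1 haplotypes: ploidy(sample) rows per sample, one column per SNP."""

    def __init__(self, gm: GenotypeMatrix, haps: np.ndarray, provenance: str = "inferred"):
        self.samples = list(gm.samples)
        self.ploidy = dict(gm.ploidy)
        self.sites = list(gm.sites)
        self.slot_ids: list[tuple[str, int]] = []
        self.slot_offsets: dict[str, int] = {}
        off = 0
        for s in self.samples:
            self.slot_offsets[s] = off
            for k in range(self.ploidy[s]):
                self.slot_ids.append((s, k))
            off += self.ploidy[s]
        haps = np.asarray(haps, dtype=np.int8)
        if haps.shape != (off, len(self.sites)):
            raise ValueError(f"haps shape {haps.shape} != ({off}, {len(self.sites)})")
        self.haps = haps
        self.provenance = provenance
        self._check_dosage(gm)

    def _check_dosage(self, gm: GenotypeMatrix) -> None:
        for j, s in enumerate(self.samples):
            rows = self.sample_rows(s)
            for i in range(len(self.sites)):
                d = gm.dosage[i, j]
                col = self.haps[rows, i]
                if d == MISSING:
                    if not np.all(col == MISSING):
                        raise ValueError("missing genotype must phase to missing slots")
                elif int(np.sum(col == 1)) != int(d):
                    raise ValueError(
                        f"slot sum != dosage for sample {s} at site {i}"
                    )

    def sample_rows(self, sample: str) -> np.ndarray:
        off = self.slot_offsets[sample]
        return np.arange(off, off + self.ploidy[sample])

    @property
    def n_slots(self) -> int:
        return self.haps.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haps.shape[1]

    def tip_labels(self) -> list[str]:
        return [f"{s}.{k}" for s, k in self.slot_ids]

    def to_genotype_matrix(self) -> GenotypeMatrix:
        dosage = np.full((len(self.sites), len(self.samples)), MISSING, dtype=np.int16)
        for j, s in enumerate(self.samples):
            rows = self.sample_rows(s)
            sub = self.haps[rows, :]
            miss = np.any(sub == MISSING, axis=0)
            dosage[:, j] = np.sum(sub == 1, axis=0)
            dosage[miss, j] = MISSING
        return GenotypeMatrix(self.sites, self.samples, self.ploidy, dosage)


def enumerate_configurations(dosage: int, ploidy: int) -> list[tuple[int, ...]]:
    """All C(ploidy, dosage) slot subsets that can carry the ALT alleles."""
    if not 0 <= dosage <= ploidy:
        raise ValueError(f"dosage {dosage} outside 0..{ploidy}")
    return list(combinations(range(ploidy), dosage))


def pairwise_ld(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation of two 0/1 haplotype columns.

    MISSING slots are excluded pairwise; monomorphic columns (over the
    shared called slots) have LD 0 by convention.
    """
    m = (col_a != MISSING) & (col_b != MISSING)
    if int(m.sum()) < 2:
        logger.warning("fewer than 2 shared called slots; LD set to 0")
        return 0.0
    x = col_a[m].astype(float)
    y = col_b[m].astype(float)
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _mean_r2(col: np.ndarray, prev: np.ndarray) -> float:
    """Mean r^2 between ``col`` and each row of ``prev`` (fast path: no MISSING)."""
    if prev.size == 0:
        return 0.0
    if MISSING not in col and not np.any(prev == MISSING):
        x = col.astype(float)
        p = prev.astype(float)
        xc = x - x.mean()
        vx = np.mean(xc * xc)
        if vx == 0.0:
            return 0.0
        pc = p - p.mean(axis=1, keepdims=True)
        vp = np.mean(pc * pc, axis=1)
        cov = pc @ xc / len(x)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(vp > 0, cov * cov / (vp * vx), 0.0)
        return float(np.mean(r2))
    return float(np.mean([pairwise_ld(col, prev[i]) for i in range(prev.shape[0])]))


def _site_column(
    configs: list[tuple[int, ...] | None],
    offsets: list[int],
    ploidies: list[int],
    n_slots: int,
) -> np.ndarray:
    col = np.zeros(n_slots, dtype=np.int8)
    for j, cfg in enumerate(configs):
        off = offsets[j]
        if cfg is None:  # missing genotype
            col[off : off + ploidies[j]] = MISSING
        else:
            for k in cfg:
                col[off + k] = 1
    return col


def phase_window(
    gm_window: GenotypeMatrix,
    max_iter: int = 20,
    exhaustive_limit: int = 256,
    refine_iter: int = 3,
) -> HaplotypeMatrix:
    """Phase one window of genotypes by iterative LD maximisation.

    After the greedy sequential pass, up to ``refine_iter`` full sweeps
    revisit every site and re-optimise its configuration against all other
    columns (monotone coordinate ascent on the window objective)."""
    n_sites = gm_window.n_sites
    if n_sites < 1:
        raise ValueError("window must contain at least one SNP")
    samples = gm_window.samples
    ploidies = [gm_window.ploidy[s] for s in samples]
    offsets = list(np.cumsum([0] + ploidies[:-1]))
    n_slots = sum(ploidies)

    het_counts = []
    for i in range(n_sites):
        h = sum(
            1
            for j in range(len(samples))
            if gm_window.dosage[i, j] not in (MISSING, 0, ploidies[j])
        )
        het_counts.append(h)
    order = sorted(range(n_sites), key=lambda i: (-het_counts[i], gm_window.sites[i].pos))

    def site_options(i: int) -> tuple[list[list[tuple[int, ...] | None]], int]:
        per_sample: list[list[tuple[int, ...] | None]] = []
        n_joint = 1
        for j in range(len(samples)):
            d = int(gm_window.dosage[i, j])
            if d == MISSING:
                per_sample.append([None])
            else:
                per_sample.append(enumerate_configurations(d, ploidies[j]))
            n_joint *= len(per_sample[-1])
        return per_sample, n_joint

    def optimise_site(
        i: int, prev: np.ndarray, start: list[tuple[int, ...] | None] | None = None
    ) -> np.ndarray:
        """Best column for site i against reference columns ``prev``."""
        per_sample, n_joint = site_options(i)
        canonical = [opts[0] for opts in per_sample]
        if n_joint == 1 or prev.size == 0:
            return _site_column(canonical, offsets, ploidies, n_slots)
        if n_joint <= exhaustive_limit:
            best, best_obj = canonical, -1.0
            for joint in product(*per_sample):
                col = _site_column(list(joint), offsets, ploidies, n_slots)
                obj = _mean_r2(col, prev)
                if obj > best_obj + 1e-12:
                    best, best_obj = list(joint), obj
        else:
            best = list(start if start is not None else canonical)
            for _ in range(max_iter):
                changed = False
                for j in range(len(samples)):
                    if len(per_sample[j]) == 1:
                        continue
                    best_obj, best_cfg = -1.0, best[j]
                    for cfg in per_sample[j]:
                        trial = list(best)
                        trial[j] = cfg
                        col = _site_column(trial, offsets, ploidies, n_slots)
                        obj = _mean_r2(col, prev)
                        if obj > best_obj + 1e-12:
                            best_obj, best_cfg = obj, cfg
                    if best_cfg != best[j]:
                        best[j] = best_cfg
                        changed = True
                if not changed:
                    break
        return _site_column(best, offsets, ploidies, n_slots)

    def run_pass(order_: list[int]) -> np.ndarray:
        haps = np.zeros((n_slots, n_sites), dtype=np.int8)
        phased_cols: list[np.ndarray] = []
        for i in order_:
            col = optimise_site(
                i, np.array(phased_cols) if phased_cols else np.zeros((0, n_slots))
            )
            haps[:, i] = col
            phased_cols.append(col)
        # refinement sweeps: re-optimise each site against all other columns
        for _ in range(max(refine_iter, 0)):
            changed = False
            for i in order_:
                others = np.delete(np.arange(n_sites), i)
                if others.size == 0:
                    continue
                col = optimise_site(i, haps[:, others].T)
                if not np.array_equal(col, haps[:, i]):
                    # accept only strict improvements of the site objective
                    old = _mean_r2(haps[:, i], haps[:, others].T)
                    new = _mean_r2(col, haps[:, others].T)
                    if new > old + 1e-12:
                        haps[:, i] = col
                        changed = True
            if not changed:
                break
        return haps

    # two deterministic starts (greedy order and its reverse); keep the better
    haps = run_pass(order)
    if n_sites > 1:
        alt = run_pass(order[::-1])
        if _window_objective(alt) > _window_objective(haps) + 1e-12:
            haps = alt
    return HaplotypeMatrix(gm_window, haps, provenance="inferred")


def _window_objective(haps: np.ndarray) -> float:
    """Mean pairwise r^2 over polymorphic columns of a slot x site matrix."""
    poly = [
        i
        for i in range(haps.shape[1])
        if len({v for v in haps[:, i] if v != MISSING}) > 1
    ]
    if len(poly) < 2:
        return 0.0
    return float(
        np.mean(
            [pairwise_ld(haps[:, a], haps[:, b]) for a, b in combinations(poly, 2)]
        )
    )


def phasing_objective(hm: HaplotypeMatrix) -> float:
    """Mean pairwise r^2 over polymorphic site pairs (the quantity the
    heuristic maximises); 0.0 for windows with < 2 polymorphic sites."""
    poly = [
        i
        for i in range(hm.n_sites)
        if len({v for v in hm.haps[:, i] if v != MISSING}) > 1
    ]
    if len(poly) < 2:
        return 0.0
    vals = [
        pairwise_ld(hm.haps[:, a], hm.haps[:, b]) for a, b in combinations(poly, 2)
    ]
    return float(np.mean(vals))


def phase_randomise(hm: HaplotypeMatrix, seed: int) -> HaplotypeMatrix:
    """Reassign ALT alleles to uniformly random slot subsets (dosage preserved)."""
    rng = np.random.default_rng(seed)
    gm = hm.to_genotype_matrix()
    haps = np.zeros_like(hm.haps)
    for j, s in enumerate(hm.samples):
        rows = hm.sample_rows(s)
        k = hm.ploidy[s]
        for i in range(hm.n_sites):
            d = int(gm.dosage[i, j])
            if d == MISSING:
                haps[rows, i] = MISSING
            else:
                pick = rng.choice(k, size=d, replace=False)
                col = np.zeros(k, dtype=np.int8)
                col[pick] = 1
                haps[rows, i] = col
    return HaplotypeMatrix(gm, haps, provenance="randomised")


def phase_concordance(estimated: HaplotypeMatrix, truth: HaplotypeMatrix) -> float:
    """Fraction of correctly placed alleles, best over per-sample slot
    permutations (slots are exchangeable), averaged over samples."""
    from itertools import permutations

    if estimated.samples != truth.samples or estimated.n_sites != truth.n_sites:
        raise ValueError("haplotype matrices are not comparable")
    per_sample = []
    for s in estimated.samples:
        er = estimated.haps[estimated.sample_rows(s), :]
        tr = truth.haps[truth.sample_rows(s), :]
        called = (er != MISSING) & (tr != MISSING)
        total = int(called.sum())
        if total == 0:
            continue
        best = 0
        for perm in permutations(range(er.shape[0])):
            m = int(np.sum((er[list(perm), :] == tr) & called))
            best = max(best, m)
        per_sample.append(best / total)
    return float(np.mean(per_sample)) if per_sample else 1.0


def write_phased_vcf(hm: HaplotypeMatrix, path: str) -> None:
    """Phased-VCF-like export with pipe-separated GT fields (0|1|1|0)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyscan-phase\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(hm.samples)
            + "\n"
        )
        for i, site in enumerate(hm.sites):
            gts = []
            for s in hm.samples:
                vals = hm.haps[hm.sample_rows(s), i]
                gts.append("|".join("." if v == MISSING else str(int(v)) for v in vals))
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
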