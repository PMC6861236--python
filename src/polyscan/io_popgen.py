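"""Readers/writers for VCF, popmap, GFF3 and BED, plus the core genotype container.

Coordinates are 1-based inclusive internally (VCF/GFF convention); BED export
is 0-based half-open. Missing genotypes are a distinct state (``MISSING``),
never coerced to dosage 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage entry.
MISSING = -1

#: Taxon groups accepted in a popmap (four ingroups + outgroup).
KNOWN_TAXA = ("lyrata2x", "lyrata4x", "arenosa2x", "arenosa4x", "outgroup")


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class Window:
    """A 1-based inclusive genomic interval.

    ``kind`` is one of ``snp-count``, ``gene`` or ``fixed-bp``; ``label``
    carries the gene id (or a synthetic window id) where applicable.
    """

    chrom: str
    start: int
    end: int
    kind: str = "fixed-bp"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")


class GenotypeMatrix:
    """Sites x samples ALT-dosage matrix with per-sample ploidy.

    ``dosage[i, j]`` is the number of ALT alleles carried by sample ``j`` at
    site ``i`` (0..ploidy), or :data:`MISSING`.
    """

    def __init__(
        self,
        sites: Sequence[VariantSite],
        samples: Sequence[str],
        ploidy: dict[str, int],
        dosage: np.ndarray,
    ):
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(sites), len(samples)):
            raise ValueError(
                f"dosage shape {dosage.shape} != ({len(sites)}, {len(samples)})"
            )
        for s in samples:
            if s not in ploidy:
                raise ValueError(f"sample {s!r} has no ploidy")
            if ploidy[s] not in (2, 4):
                raise ValueError(f"sample {s!r}: unsupported ploidy {ploidy[s]}")
        pl = np.array([ploidy[s] for s in samples], dtype=np.int16)
        called = dosage != MISSING
        if np.any((dosage[called] < 0)) or np.any(dosage > pl[None, :]):
            raise ValueError("dosage outside 0..ploidy")
        self.sites = list(sites)
        self.samples = list(samples)
        self.ploidy = dict(ploidy)
        self.dosage = dosage

    # -- basic accessors -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def ploidy_array(self) -> np.ndarray:
        return np.array([self.ploidy[s] for s in self.samples], dtype=np.int16)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def site_positions(self, chrom: str) -> np.ndarray:
        return np.array(
            [s.pos for s in self.sites if s.chrom == chrom], dtype=np.int64
        )

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.chrom, None)
        return list(seen)

    def subset_sites(self, idx: Iterable[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            [self.sites[i] for i in idx], self.samples, self.ploidy, self.dosage[idx]
        )

    def window_site_indices(self, window: Window) -> list[int]:
        return [
            i
            for i, s in enumerate(self.sites)
            if s.chrom == window.chrom and window.start <= s.pos <= window.end
        ]


@dataclass
class PopulationMap:
    """sample -> population and population -> taxon lookups."""

    sample_pop: dict[str, str]
    pop_taxon: dict[str, str]

    def __post_init__(self) -> None:
        for pop, taxon in self.pop_taxon.items():
            if taxon not in KNOWN_TAXA:
                raise ValueError(f"population {pop!r}: unknown taxon {taxon!r}")
        for s, p in self.sample_pop.items():
            if p not in self.pop_taxon:
                raise ValueError(f"sample {s!r}: population {p!r} has no taxon")

    @property
    def populations(self) -> list[str]:
        return list(self.pop_taxon)

    def pop_samples(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_pop.items() if p == pop]

    def taxon_pops(self, taxon: str) -> list[str]:
        return [p for p, t in self.pop_taxon.items() if t == taxon]

    def taxon_of_sample(self, sample: str) -> str:
        return self.pop_taxon[self.sample_pop[sample]]

    def restrict_to(self, samples: Iterable[str]) -> "PopulationMap":
        keep = set(samples)
        sp = {s: p for s, p in self.sample_pop.items() if s in keep}
        pops = set(sp.values())
        return PopulationMap(sp, {p: t for p, t in self.pop_taxon.items() if p in pops})


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str, max_missing_frac: float = 0.10, min_dp: int = 5
) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Genotype calls with ``DP < min_dp`` are set missing; sites whose missing
    fraction (over samples) exceeds ``max_missing_frac`` are dropped. Ploidy
    is inferred per sample from GT arity and must be constant across sites.
    """
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    ploidy: dict[str, int] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(path)
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                continue
            row = np.full(len(samples), MISSING, dtype=np.int16)
            malformed = False
            for j, s in enumerate(samples):
                sm = rec.samples[s]
                gt = sm.get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                if len(gt) not in (2, 4):
                    logger.warning(
                        "%s:%d sample %s: GT arity %d not in {2,4}; site rejected",
                        rec.chrom, rec.pos, s, len(gt),
                    )
                    malformed = True
                    break
                if s in ploidy and ploidy[s] != len(gt):
                    raise ValueError(
                        f"sample {s!r}: inconsistent ploidy "
                        f"({ploidy[s]} vs {len(gt)} at {rec.chrom}:{rec.pos})"
                    )
                ploidy.setdefault(s, len(gt))
                if any(a is None for a in gt):
                    continue
                dp = sm.get("DP")
                if dp is not None and dp < min_dp:
                    continue
                row[j] = sum(1 for a in gt if a == 1)
            if malformed:
                continue
            miss_frac = np.mean(row == MISSING)
            if miss_frac > max_missing_frac:
                continue
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0]))
            rows.append(row)
    for s in samples:
        ploidy.setdefault(s, 2)  # sample missing everywhere: assume diploid
    dosage = (
        np.array(rows, dtype=np.int16)
        if rows
        else np.zeros((0, len(samples)), dtype=np.int16)
    )
    gm = GenotypeMatrix(sites, samples, ploidy, dosage)
    _check_sorted(gm)
    return gm


def _check_sorted(gm: GenotypeMatrix) -> None:
    last: dict[str, int] = {}
    for s in gm.sites:
        if s.chrom in last and s.pos <= last[s.chrom]:
            raise ValueError(f"sites not strictly increasing at {s.chrom}:{s.pos}")
        last[s.chrom] = s.pos


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write the matrix back out as an unphased, uncompressed VCF."""
    chrom_max: dict[str, int] = {}
    for s in gm.sites:
        chrom_max[s.chrom] = max(chrom_max.get(s.chrom, 0), s.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=polyscan\n")
        for chrom, mx in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={mx + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        pl = gm.ploidy_array
        for i, site in enumerate(gm.sites):
            gts = []
            for j in range(gm.n_samples):
                d = int(gm.dosage[i, j])
                k = int(pl[j])
                if d == MISSING:
                    gts.append("/".join(["."] * k))
                else:
                    gts.append("/".join(["0"] * (k - d) + ["1"] * d))
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# popmap
# ---------------------------------------------------------------------------

def read_popmap(path: str, vcf_samples: Sequence[str] | None = None) -> PopulationMap:
    """Read a tab-separated ``sample<TAB>population<TAB>taxon`` file.

    If ``vcf_samples`` is given, popmap entries absent from it are dropped
    with a warning. Duplicate samples are a hard error.
    """
    sample_pop: dict[str, str] = {}
    pop_taxon: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            sample, pop, taxon = parts
            if sample in sample_pop:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if taxon not in KNOWN_TAXA:
                raise ValueError(f"{path}:{lineno}: unknown taxon {taxon!r}")
            if pop in pop_taxon and pop_taxon[pop] != taxon:
                raise ValueError(f"{path}:{lineno}: population {pop!r} taxon conflict")
            if vcf_samples is not None and sample not in vcf_samples:
                logger.warning("popmap sample %s not in VCF; dropped", sample)
                continue
            sample_pop[sample] = pop
            pop_taxon[pop] = taxon
    return PopulationMap(sample_pop, pop_taxon)


def write_popmap(pm: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for s, p in pm.sample_pop.items():
            fh.write(f"{s}\t{p}\t{pm.pop_taxon[p]}\n")


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def gene_windows(
    gff_path: str, flank_bp: int = 0, known_chroms: set[str] | None = None
) -> list[Window]:
    """One window per GFF3 gene feature (span +/- ``flank_bp``).

    Overlapping windows are truncated at the midpoint of their overlap so
    the returned list is non-overlapping and sorted.
    """
    raw: list[Window] = []
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, start, end, attrs = parts[0], int(parts[3]), int(parts[4]), parts[8]
            if known_chroms is not None and chrom not in known_chroms:
                logger.warning("gene on unknown chrom %s skipped", chrom)
                continue
            label = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    label = kv[3:]
                    break
            raw.append(
                Window(chrom, max(1, start - flank_bp), end + flank_bp, "gene", label)
            )
    raw.sort(key=lambda w: (w.chrom, w.start, w.end))
    out: list[Window] = []
    for w in raw:
        if out and out[-1].chrom == w.chrom and w.start <= out[-1].end:
            prev = out[-1]
            mid = (w.start + prev.end) // 2  # split overlap at its midpoint
            out[-1] = Window(prev.chrom, prev.start, mid, "gene", prev.label)
            w = Window(w.chrom, mid + 1, w.end, "gene", w.label)
        out.append(w)
    return out


def snp_windows(gm: GenotypeMatrix, n_snps: int = 50) -> list[Window]:
    """Consecutive blocks of exactly ``n_snps`` SNPs per chromosome.

    A trailing block with fewer than ``n_snps`` SNPs is discarded.
    """
    if n_snps < 2:
        raise ValueError("n_snps must be >= 2")
    out: list[Window] = []
    for chrom in gm.chroms():
        pos = gm.site_positions(chrom)
        n_full = len(pos) // n_snps
        if n_full == 0:
            logger.warning("chrom %s has < %d SNPs; no windows", chrom, n_snps)
            continue
        for b in range(n_full):
            block = pos[b * n_snps : (b + 1) * n_snps]
            out.append(
                Window(chrom, int(block[0]), int(block[-1]), "snp-count",
                       f"{chrom}.w{b}")
            )
    return out


def write_bed(windows: Sequence[Window], path: str) -> None:
    """BED export: 0-based half-open."""
    with open(path, "w") as fh:
        for w in windows:
            label = w.label if w.label is not None else "."
            fh.write(f"{w.chrom}\t{w.start - 1}\t{w.end}\t{label}\n")


def read_bed(path: str, kind: str = "gene") -> list[Window]:
    out: list[Window] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            label = parts[3].strip() if len(parts) > 3 else None
            out.append(Window(chrom, start + 1, end, kind, label))
    return out
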