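"""Per-window divergence metrics between populations of arbitrary ploidy.

Five metrics per window and population pair:

* AFD   — mean over SNPs of |pA - pB|
* dXY   — mean over SNPs of pA(1-pB) + pB(1-pA)
* Fst   — Hudson-style ratio of sums, 1 - sum(Hw)/sum(Hb), with
  Hw the mean of the two unbiased within-population expected
  heterozygosities 2p(1-p) n/(n-1) (n = called allele count) and
  Hb = pA(1-pB) + pB(1-pA)
* Rho   — intraclass correlation on individual allele frequencies
  x = dosage/ploidy (one-way ANOVA, ratio of sums across SNPs), which is
  independent of ploidy level by construction
* fixed_diff — count of SNPs fixed for alternative alleles

Group-level metrics are unweighted means over the between-group population
pairs. Allele frequencies respect per-sample ploidy; missing genotypes only
shrink the denominators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_popgen import MISSING, GenotypeMatrix, PopulationMap, Window

logger = logging.getLogger(__name__)


@dataclass
class SiteFreqs:
    """Per-population allele frequencies and per-individual frequencies.

    Arrays are indexed by site (rows follow ``gm.sites``).
    """

    populations: list[str]
    p: dict[str, np.ndarray]          # ALT frequency; NaN if no called allele
    n_alleles: dict[str, np.ndarray]  # called allele count
    x: dict[str, np.ndarray]          # sites x individuals, dosage/ploidy, NaN missing


@dataclass
class PairWindowMetrics:
    pop_a: str
    pop_b: str
    window: Window
    n_snps: int
    afd: float
    dxy: float
    fst: float
    rho: float
    fixed_diff: int


@dataclass
class GroupWindowMetrics:
    group_a: str
    group_b: str
    window: Window
    n_snps: float
    afd: float
    dxy: float
    fst: float
    rho: float
    fixed_diff: float


def site_freqs(
    gm: GenotypeMatrix, popmap: PopulationMap, populations: list[str] | None = None
) -> SiteFreqs:
    """Compute p, called-allele counts and individual frequencies per population."""
    if populations is None:
        populations = popmap.populations
    pl = gm.ploidy_array.astype(float)
    dosage = gm.dosage.astype(float)
    called = gm.dosage != MISSING
    p: dict[str, np.ndarray] = {}
    n_alleles: dict[str, np.ndarray] = {}
    x: dict[str, np.ndarray] = {}
    for pop in populations:
        idx = [gm.sample_index(s) for s in popmap.pop_samples(pop)]
        if not idx:
            raise ValueError(f"population {pop!r} has no samples in matrix")
        sub_d = dosage[:, idx]
        sub_c = called[:, idx]
        sub_pl = pl[idx]
        alt = np.where(sub_c, sub_d, 0.0).sum(axis=1)
        tot = (sub_c * sub_pl[None, :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[pop] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        p[pop][tot == 0] = np.nan
        n_alleles[pop] = tot
        xi = np.where(sub_c, sub_d / sub_pl[None, :], np.nan)
        x[pop] = xi
    return SiteFreqs(list(populations), p, n_alleles, x)


def _rho_terms(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site one-way ANOVA numerator/denominator terms for Rho.

    Returns (MSB - MSW, MSB + (n0-1) MSW, valid mask). ``xa``/``xb`` are
    sites x individuals with NaN for missing.
    """
    na = np.sum(~np.isnan(xa), axis=1).astype(float)
    nb = np.sum(~np.isnan(xb), axis=1).astype(float)
    n_tot = na + nb
    valid = (na >= 1) & (nb >= 1) & (n_tot >= 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        ma = np.nansum(np.nan_to_num(xa, nan=0.0), axis=1) / np.maximum(na, 1)
        mb = np.nansum(np.nan_to_num(xb, nan=0.0), axis=1) / np.maximum(nb, 1)
        grand = (na * ma + nb * mb) / np.maximum(n_tot, 1)
        ssb = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
        ssw = np.nansum((xa - ma[:, None]) ** 2, axis=1) + np.nansum(
            (xb - mb[:, None]) ** 2, axis=1
        )
        msb = ssb / 1.0  # k - 1 = 1
        msw = np.where(n_tot > 2, ssw / (n_tot - 2), np.nan)
        n0 = (n_tot - (na**2 + nb**2) / n_tot) / 1.0
        num = msb - msw
        den = msb + (n0 - 1.0) * msw
    return num, den, valid


def pair_metrics(
    freqs: SiteFreqs,
    gm: GenotypeMatrix,
    window: Window,
    pop_a: str,
    pop_b: str,
) -> PairWindowMetrics:
    """All five metrics for one window and one population pair."""
    idx = np.array(gm.window_site_indices(window), dtype=int)
    nan_metrics = PairWindowMetrics(
        pop_a, pop_b, window, 0, np.nan, np.nan, np.nan, np.nan, 0
    )
    if idx.size == 0:
        return nan_metrics
    pa = freqs.p[pop_a][idx]
    pb = freqs.p[pop_b][idx]
    na = freqs.n_alleles[pop_a][idx]
    nb = freqs.n_alleles[pop_b][idx]
    informative = ~np.isnan(pa) & ~np.isnan(pb)
    if not informative.any():
        return nan_metrics
    pa, pb, na, nb = pa[informative], pb[informative], na[informative], nb[informative]
    n_snps = int(informative.sum())

    afd = float(np.mean(np.abs(pa - pb)))
    hb = pa * (1 - pb) + pb * (1 - pa)
    dxy = float(np.mean(hb))
    fixed = int(np.sum(((pa == 1) & (pb == 0)) | ((pa == 0) & (pb == 1))))

    # Fst: exclude SNPs where a population has a single called allele
    # (the n/(n-1) bias correction is undefined there).
    ok = (na >= 2) & (nb >= 2)
    if ok.any():
        hw = 0.5 * (
            2 * pa[ok] * (1 - pa[ok]) * na[ok] / (na[ok] - 1)
            + 2 * pb[ok] * (1 - pb[ok]) * nb[ok] / (nb[ok] - 1)
        )
        hb_ok = hb[ok]
        denom = float(np.sum(hb_ok))
        fst = 1.0 - float(np.sum(hw)) / denom if denom > 0 else np.nan
    else:
        fst = np.nan

    # Rho on individual allele frequencies.
    xa = freqs.x[pop_a][idx][informative]
    xb = freqs.x[pop_b][idx][informative]
    num, den, valid = _rho_terms(xa, xb)
    valid = valid & ok
    if valid.any() and np.nansum(den[valid]) > 0:
        rho = float(np.nansum(num[valid]) / np.nansum(den[valid]))
    else:
        rho = np.nan

    return PairWindowMetrics(pop_a, pop_b, window, n_snps, afd, dxy, fst, rho, fixed)


def group_metrics(
    freqs: SiteFreqs,
    gm: GenotypeMatrix,
    window: Window,
    group_a_pops: list[str],
    group_b_pops: list[str],
    group_a: str = "A",
    group_b: str = "B",
) -> GroupWindowMetrics:
    """Unweighted mean of pair metrics over all between-group pairs."""
    if not group_a_pops or not group_b_pops:
        raise ValueError("each group needs >= 1 population")
    pairs = []
    for a in group_a_pops:
        for b in group_b_pops:
            m = pair_metrics(freqs, gm, window, a, b)
            if m.n_snps == 0:
                logger.warning(
                    "pair (%s,%s) window %s:%d-%d: no informative SNPs; excluded",
                    a, b, window.chrom, window.start, window.end,
                )
                continue
            pairs.append(m)
    if not pairs:
        return GroupWindowMetrics(
            group_a, group_b, window, 0, np.nan, np.nan, np.nan, np.nan, np.nan
        )

    def mean(attr: str) -> float:
        vals = np.array([getattr(m, attr) for m in pairs], dtype=float)
        vals = vals[~np.isnan(vals)]
        return float(np.mean(vals)) if vals.size else np.nan

    return GroupWindowMetrics(
        group_a,
        group_b,
        window,
        mean("n_snps"),
        mean("afd"),
        mean("dxy"),
        mean("fst"),
        mean("rho"),
        mean("fixed_diff"),
    )


def scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    windows: list[Window],
    group_a_pops: list[str],
    group_b_pops: list[str],
    group_a: str = "A",
    group_b: str = "B",
) -> pd.DataFrame:
    """Windowed divergence scan; one row per window, deterministic order.

    Groups may be given as taxon names (resolved via the popmap) or as
    explicit population lists.
    """
    if not windows:
        logger.warning("empty window set; empty scan table")
    pops = sorted(set(group_a_pops) | set(group_b_pops))
    freqs = site_freqs(gm, popmap, pops)
    rows = []
    for w in windows:
        m = group_metrics(freqs, gm, w, group_a_pops, group_b_pops, group_a, group_b)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "label": w.label if w.label is not None else f"{w.chrom}:{w.start}",
                "n_snps": m.n_snps,
                "afd": m.afd,
                "dxy": m.dxy,
                "fst": m.fst,
                "rho": m.rho,
                "fixed_diff": m.fixed_diff,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "label", "n_snps",
            "afd", "dxy", "fst", "rho", "fixed_diff",
        ],
    )


def resolve_groups(
    popmap: PopulationMap, contrast: str
) -> tuple[list[str], list[str], str, str]:
    """Parse ``taxonA:taxonB`` (or comma-joined population lists) into groups."""
    left, _, right = contrast.partition(":")
    if not right:
        raise ValueError("contrast must be 'groupA:groupB'")

    def resolve(token: str) -> list[str]:
        pops = popmap.taxon_pops(token)
        if pops:
            return pops
        pops = [p for p in token.split(",") if p]
        for p in pops:
            if p not in popmap.pop_taxon:
                raise ValueError(f"unknown taxon or population {p!r}")
        return pops

    return resolve(left), resolve(right), left, right
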