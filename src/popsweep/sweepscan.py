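"""Windowed nucleotide diversity, pairwise Fst, and selected-region calling.

The scan follows the standard resequencing sweep-screen design: theta-pi
(per-bp pairwise nucleotide diversity) and pairwise Fst are computed in
100 kb windows sliding by 10 kb, and windows with Fst > 0.25 combined with
a pi ratio > 2 or < 0.5 are called as selected regions, which are then
merged and intersected with gene spans.

Estimators
----------
Per biallelic site with ``k`` alternate alleles among ``n`` called alleles,
the unbiased per-site diversity is ``2*(k/n)*(1-k/n)*n/(n-1)`` (the mean
pairwise-difference fraction); window pi sums sites and divides by the full
window length, so monomorphic bases contribute zero.

The default Fst estimator is Hudson's, as the ratio of averages
``sum(N)/sum(D)`` with per-site ``N = (p1-p2)^2 - p1(1-p1)/(n1-1) -
p2(1-p2)/(n2-1)`` and ``D = p1(1-p2) + p2(1-p1)`` — robust to rare variants
and the common choice for window scans.  The two-population
Weir-Cockerham variance-components estimator is available as an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SweepConfig",
    "WindowStat",
    "SweepRegion",
    "make_windows",
    "window_pi",
    "window_fst",
    "scan",
    "call_selected_regions",
    "intersect_genes",
    "venn_counts",
]


@dataclass
class SweepConfig:
    """Window geometry and selection thresholds for the sweep scan."""

    window_bp: int = 100_000
    step_bp: int = 10_000
    fst_min: float = 0.25
    pi_ratio_high: float = 2.0
    pi_ratio_low: float = 0.5
    min_sites_per_window: int = 10
    fst_estimator: str = "hudson"

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step_bp must not exceed window_bp")
        if not (self.pi_ratio_low < 1.0 < self.pi_ratio_high):
            raise ValueError("need pi_ratio_low < 1 < pi_ratio_high")
        if self.fst_estimator not in ("hudson", "weir_cockerham"):
            raise ValueError(f"unknown Fst estimator {self.fst_estimator!r}")


@dataclass
class WindowStat:
    """Per-window statistics for one ordered population comparison A vs B."""

    chrom: str
    start: int                      # 0-based half-open
    end: int
    n_sites: int
    pi_a: float
    pi_b: float
    fst: float | None               # None when undefined (no variation)
    pi_ratio: float | None          # pi_a / pi_b; inf if pi_b == 0 < pi_a
    eligible: bool = True
    selected: bool = False          # set by call_selected_regions


@dataclass
class SweepRegion:
    """A maximal run of threshold-passing windows."""

    chrom: str
    start: int
    end: int
    direction: str                  # "A" or "B": population with reduced pi
    n_windows: int
    gene_ids: list[str] = field(default_factory=list)


def make_windows(chrom_length: int, config: SweepConfig) -> list[tuple[int, int]]:
    """Full-length sliding windows [0, W), [S, S+W), ... within the chromosome."""
    if chrom_length < config.window_bp:
        logger.warning("chromosome length %d shorter than one window (%d)",
                       chrom_length, config.window_bp)
        return []
    n = (chrom_length - config.window_bp) // config.step_bp + 1
    return [(i * config.step_bp, i * config.step_bp + config.window_bp)
            for i in range(n)]


def _site_freqs(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count k, called allele count n) for a pop block."""
    called = genotypes >= 0
    n = 2 * called.sum(axis=0)
    k = np.where(called, genotypes, 0).sum(axis=0)
    return k.astype(float), n.astype(float)


def window_pi(genotypes: np.ndarray, window_bp: int) -> float:
    """Per-bp theta-pi of one population over the sites of one window.

    ``genotypes``: (n_samples, n_sites) diploid dosages with -1 missing.
    Sites with fewer than two called alleles are skipped.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if genotypes.size == 0:
        return 0.0
    k, n = _site_freqs(genotypes)
    ok = n >= 2
    if not ok.any():
        return 0.0
    k, n = k[ok], n[ok]
    p = k / n
    return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)) / window_bp)


def _hudson_components(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k1, n1 = _site_freqs(ga)
    k2, n2 = _site_freqs(gb)
    ok = (n1 >= 2) & (n2 >= 2)
    p1, p2 = k1[ok] / n1[ok], k2[ok] / n2[ok]
    num = ((p1 - p2) ** 2
           - p1 * (1 - p1) / (n1[ok] - 1)
           - p2 * (1 - p2) / (n2[ok] - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, ok


def _wc_components(ga: np.ndarray, gb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir-Cockerham (1984) per-site a and a+b+c for two populations."""
    blocks = []
    for g in (ga, gb):
        called = g >= 0
        n_ind = called.sum(axis=0).astype(float)          # diploid individuals
        k = np.where(called, g, 0).sum(axis=0).astype(float)
        het = ((g == 1) & called).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = k / (2 * n_ind)
            h = het / n_ind
        blocks.append((n_ind, p, h))
    (n1, p1, h1), (n2, p2, h2) = blocks
    ok = (n1 >= 1) & (n2 >= 1) & (n1 + n2 >= 2)
    n1, p1, h1, n2, p2, h2 = (x[ok] for x in (n1, p1, h1, n2, p2, h2))
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                         / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    tot = a + b + c
    good = np.isfinite(a) & np.isfinite(tot)
    return a[good], tot[good]


def window_fst(genotypes_a: np.ndarray, genotypes_b: np.ndarray,
               estimator: str = "hudson") -> float | None:
    """Pairwise Fst over the sites of one window; None when undefined.

    Hudson: ratio of averages sum(N)/sum(D).  ``weir_cockerham``: sum(a) /
    sum(a+b+c).  The value is reported raw and may be negative.
    """
    if estimator == "hudson":
        num, den, _ = _hudson_components(genotypes_a, genotypes_b)
        total_den = float(den.sum())
        if total_den == 0.0:
            return None
        return float(num.sum() / total_den)
    if estimator == "weir_cockerham":
        a, tot = _wc_components(genotypes_a, genotypes_b)
        total = float(tot.sum())
        if total == 0.0:
            return None
        return float(a.sum() / total)
    raise ValueError(f"unknown Fst estimator {estimator!r}")


def scan(genotypes: np.ndarray, positions: np.ndarray, chrom: str,
         chrom_length: int, pop_a: Sequence[int], pop_b: Sequence[int],
         config: SweepConfig | None = None) -> list[WindowStat]:
    """Windowed pi/Fst scan of one chromosome for the comparison A vs B.

    ``genotypes``: (n_samples, n_sites) dosage matrix (-1 missing);
    ``positions``: 1-based site positions, sorted; ``pop_a`` / ``pop_b``:
    row indices of the two populations.  A variant at position p belongs to
    the windows whose half-open span contains p - 1.  Windows with fewer
    than ``min_sites_per_window`` usable sites (or undefined Fst) are
    flagged ineligible.
    """
    config = config or SweepConfig()
    positions = np.asarray(positions)
    if positions.size and (np.diff(positions) < 0).any():
        raise ValueError("positions must be sorted")
    pop_a = np.asarray(pop_a, dtype=int)
    pop_b = np.asarray(pop_b, dtype=int)
    stats: list[WindowStat] = []
    pos0 = positions - 1
    for start, end in make_windows(chrom_length, config):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        ga = genotypes[np.ix_(pop_a, np.arange(lo, hi))]
        gb = genotypes[np.ix_(pop_b, np.arange(lo, hi))]
        n_sites = hi - lo
        pi_a = window_pi(ga, config.window_bp)
        pi_b = window_pi(gb, config.window_bp)
        fst = window_fst(ga, gb, config.fst_estimator) if n_sites else None
        if pi_b > 0:
            ratio = pi_a / pi_b
        elif pi_a > 0:
            ratio = math.inf
        else:
            ratio = None
        eligible = n_sites >= config.min_sites_per_window and fst is not None \
            and ratio is not None
        stats.append(WindowStat(chrom, start, end, n_sites, pi_a, pi_b,
                                fst, ratio, eligible))
    return stats


def _window_selected(w: WindowStat, config: SweepConfig) -> str | None:
    """Direction tag if the window passes all thresholds, else None."""
    if not w.eligible or w.fst is None or w.pi_ratio is None:
        return None
    if w.fst <= config.fst_min:
        return None
    if w.pi_ratio > config.pi_ratio_high:
        return "B"                   # denominator population lost diversity
    if w.pi_ratio < config.pi_ratio_low:
        return "A"
    return None


def call_selected_regions(stats: Sequence[WindowStat],
                          config: SweepConfig | None = None) -> list[SweepRegion]:
    """Merge threshold-passing windows into maximal selected regions.

    Overlapping or book-ended selected windows with the same direction are
    merged; the direction names the population with the reduced diversity.
    """
    config = config or SweepConfig()
    selected = []
    for w in stats:
        d = _window_selected(w, config)
        w.selected = d is not None
        if d is not None:
            selected.append((w, d))
    selected.sort(key=lambda t: (t[0].chrom, t[0].start))
    regions: list[SweepRegion] = []
    for w, d in selected:
        if regions and regions[-1].chrom == w.chrom \
                and regions[-1].direction == d and w.start <= regions[-1].end:
            regions[-1].end = max(regions[-1].end, w.end)
            regions[-1].n_windows += 1
        else:
            regions.append(SweepRegion(w.chrom, w.start, w.end, d, 1))
    return regions


def intersect_genes(regions: Sequence[SweepRegion], annotation
                    ) -> tuple[list[SweepRegion], set[str]]:
    """Attach overlapping gene ids to each region; return the deduplicated set.

    A gene is included iff its span overlaps the region by at least 1 bp
    under half-open interval intersection (bedtools-style).
    """
    all_genes: set[str] = set()
    for region in regions:
        ids = annotation.genes_overlapping(region.chrom, region.start, region.end)
        region.gene_ids = ids
        all_genes.update(ids)
    return list(regions), all_genes


def venn_counts(gene_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Counts of every exclusive region of the Venn partition.

    Keys are sorted tuples of set names; the value counts elements belonging
    to exactly those sets and no others.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two named sets")
    names = sorted(gene_sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(gene_sets[n] for n in combo))
            outside = set.union(set(), *(gene_sets[n] for n in names
                                         if n not in combo))
            counts[combo] = len(inside - outside)
    return counts
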