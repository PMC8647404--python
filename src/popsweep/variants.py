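"""VCF reading, GATK-style hard filtering, and SNP/InDel summaries.

The hard filters reproduce the standard post-HaplotypeCaller recipe:

1. SNPs within 5 bp of an InDel, and InDels within 10 bp of another InDel,
   are removed (bcftools ``varFilter -w 5 -W 10`` semantics, applied to the
   distance between VCF POS coordinates);
2. clustered variants — more than ``cluster_size`` (2) variants whose POS
   span fits a ``cluster_window_bp`` (5 bp) window — are all removed;
3. QUAL < 30; 4. QD < 2.0; 5. MQ < 40; 6. FS > 60.0.

Each removed record is tagged with the first rule that fired, in the order
above; proximity and cluster relations are evaluated against the full input
set, which makes the filter idempotent on its own passing set.

Summaries use the population-resequencing conventions: transitions are
A<->G and C<->T, everything else is a transversion; a sample-site genotype
counts as a heterozygous SNP call iff its two alleles differ and as a
homozygous SNP call iff both alleles are the alternate; the Het-ratio is
het / (het + hom) as a percentage.  Reported Ti/Tv and Het-ratio values are
truncated (not rounded) to two decimals — the convention the published
summary tables for this analysis follow.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "FilterConfig",
    "SnpSummary",
    "IndelSummary",
    "VariantList",
    "read_vcf",
    "write_vcf",
    "classify_substitution",
    "apply_hard_filters",
    "summarize_snps",
    "summarize_indels",
    "per_chromosome_counts",
    "truncate2",
]

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def truncate2(x: float) -> float:
    """Truncate to two decimals (floor), the printed-table convention."""
    return math.floor(x * 100 + 1e-9) / 100


@dataclass
class VariantRecord:
    """One biallelic VCF site (multi-allelic sites are split on read)."""

    chrom: str
    pos: int                       # 1-based
    ref: str
    alt: str
    qual: float | None = None
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None
    genotypes: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int8))

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError("ref and alt must be non-empty and differ")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def indel_length(self) -> int:
        """Signed length: insertions positive, deletions negative."""
        if self.is_snp:
            raise ValueError("indel_length undefined for a SNP")
        return len(self.alt) - len(self.ref)


class VariantList(list):
    """A list of :class:`VariantRecord` that remembers the sample names."""

    def __init__(self, records: Iterable[VariantRecord] = (),
                 samples: Sequence[str] = ()) -> None:
        super().__init__(records)
        self.samples = list(samples)


@dataclass
class FilterConfig:
    """Thresholds of the hard-filter recipe (defaults as published)."""

    snp_near_indel_bp: int = 5
    adjacent_indel_bp: int = 10
    cluster_size: int = 2
    cluster_window_bp: int = 5
    min_qual: float = 30.0
    min_qd: float = 2.0
    min_mq: float = 40.0
    max_fs: float = 60.0

    def __post_init__(self) -> None:
        for name in ("snp_near_indel_bp", "adjacent_indel_bp", "cluster_size",
                     "cluster_window_bp", "min_qual", "min_qd", "min_mq",
                     "max_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SnpSummary:
    """Transition/transversion and zygosity tallies for a SNP set."""

    n_transitions: int
    n_transversions: int
    n_het: int
    n_hom: int

    @property
    def ti_tv(self) -> float | None:
        if self.n_transversions == 0:
            return None
        return truncate2(self.n_transitions / self.n_transversions)

    @property
    def het_ratio(self) -> float | None:
        """Heterozygous percentage of all SNP genotype calls, truncated."""
        total = self.n_het + self.n_hom
        if total == 0:
            return None
        return truncate2(100.0 * self.n_het / total)


@dataclass
class IndelSummary:
    """Insertion/deletion, zygosity and length-spectrum tallies."""

    n_insertions: int
    n_deletions: int
    n_het: int
    n_hom: int
    length_spectrum: dict[int, int]
    scope: str = "genome"

    @property
    def total(self) -> int:
        return self.n_insertions + self.n_deletions


def read_vcf(path: str | Path) -> VariantList:
    """Read a VCF into :class:`VariantRecord` objects, in file order.

    Multi-allelic sites are split into one biallelic record per ALT allele:
    for the k-th ALT, each sample's genotype is the count of its alleles
    equal to k (other ALT alleles count as reference); genotypes with any
    missing allele stay missing (-1).
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    records = VariantList(samples=samples)
    for line_no, v in enumerate(vcf, start=1):
        try:
            alleles = np.array(v.genotypes, dtype=object)
            pairs = [(int(g[0]), int(g[1])) for g in alleles] if samples else []
            for k, alt in enumerate(v.ALT, start=1):
                gts = np.empty(len(pairs), dtype=np.int8)
                for i, (a, b) in enumerate(pairs):
                    gts[i] = -1 if (a < 0 or b < 0) else (a == k) + (b == k)
                records.append(VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                    qual=None if v.QUAL is None else float(v.QUAL),
                    qd=_info_float(v, "QD"), mq=_info_float(v, "MQ"),
                    fs=_info_float(v, "FS"), genotypes=gts,
                ))
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"malformed VCF record #{line_no} in {path}: {exc}") from exc
    return records


def _info_float(variant, key: str) -> float | None:
    value = variant.INFO.get(key)
    return None if value is None else float(value)


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(records: VariantList, path: str | Path,
              contigs: dict[str, int] | None = None) -> Path:
    """Write records back out as a minimal VCF v4.2 (pass-through)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=popsweep-variants\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for key, desc in (("QD", "Variant confidence normalized by depth"),
                          ("MQ", "RMS mapping quality"),
                          ("FS", "Phred-scaled strand-bias Fisher p")):
            fh.write(f'##INFO=<ID={key},Number=1,Type=Float,Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(records.samples) + "\n")
        for r in records:
            info = ";".join(f"{k}={v:.2f}" for k, v in
                            (("QD", r.qd), ("MQ", r.mq), ("FS", r.fs))
                            if v is not None) or "."
            qual = "." if r.qual is None else f"{r.qual:.2f}"
            gts = "\t".join(_GT_STR[int(g)] for g in r.genotypes)
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\t.\t"
                     f"{info}\tGT\t{gts}\n")
    return path


def classify_substitution(ref: str, alt: str) -> str:
    """Classify a single-base substitution as transition or transversion."""
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1 \
            or ref == alt:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}")
    return "transition" if (ref, alt) in TRANSITIONS else "transversion"


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    last: dict[str, int] = {}
    seen_order: list[str] = []
    for r in records:
        if r.chrom not in last:
            if r.chrom in seen_order:
                raise ValueError("records are not sorted by (chrom, pos)")
            seen_order.append(r.chrom)
        elif r.pos < last[r.chrom]:
            raise ValueError("records are not sorted by (chrom, pos)")
        last[r.chrom] = r.pos


def apply_hard_filters(
    records: Sequence[VariantRecord], config: FilterConfig | None = None,
) -> tuple[VariantList, list[tuple[VariantRecord, str]]]:
    """Apply the hard-filter recipe; returns (passing, removals).

    Removals carry the first reason that fired, rule order:
    ``snp_near_indel`` / ``adjacent_indel`` -> ``cluster`` -> ``QUAL`` ->
    ``QD`` -> ``MQ`` -> ``FS``.  A record missing a metric skips that
    metric's rule (logged).  Input must be sorted by (chrom, pos).
    """
    config = config or FilterConfig()
    _check_sorted(records)

    by_chrom: dict[str, list[int]] = defaultdict(list)
    for i, r in enumerate(records):
        by_chrom[r.chrom].append(i)

    reasons: dict[int, str] = {}

    # rule 1: proximity to InDels
    for chrom, idxs in by_chrom.items():
        indel_pos = np.array([records[i].pos for i in idxs if records[i].is_indel])
        for i in idxs:
            r = records[i]
            if indel_pos.size == 0:
                continue
            dist = np.abs(indel_pos - r.pos)
            if r.is_snp:
                if (dist <= config.snp_near_indel_bp).any():
                    reasons[i] = "snp_near_indel"
            else:
                # distance to *another* InDel: ignore self (distance 0 once)
                if (dist <= config.adjacent_indel_bp).sum() > 1 or \
                        ((dist <= config.adjacent_indel_bp) & (dist > 0)).any():
                    reasons[i] = "adjacent_indel"

    # rule 2: variant clusters (> cluster_size variants in a window)
    for chrom, idxs in by_chrom.items():
        pos = np.array([records[i].pos for i in idxs])
        k = config.cluster_size
        for a in range(len(pos) - k):
            if pos[a + k] - pos[a] <= config.cluster_window_bp:
                for b in range(a, a + k + 1):
                    reasons.setdefault(idxs[b], "cluster")

    # rules 3-6: per-record metric thresholds
    for i, r in enumerate(records):
        if i in reasons:
            continue
        for value, name, bad in ((r.qual, "QUAL", lambda v: v < config.min_qual),
                                 (r.qd, "QD", lambda v: v < config.min_qd),
                                 (r.mq, "MQ", lambda v: v < config.min_mq),
                                 (r.fs, "FS", lambda v: v > config.max_fs)):
            if value is None:
                logger.debug("site %s:%d lacks %s; rule skipped", r.chrom, r.pos, name)
                continue
            if bad(value):
                reasons[i] = name
                break

    samples = getattr(records, "samples", [])
    passing = VariantList((r for i, r in enumerate(records) if i not in reasons),
                          samples=samples)
    removals = [(records[i], reasons[i]) for i in sorted(reasons)]
    logger.info("hard filters: %d in, %d pass, %d removed",
                len(records), len(passing), len(removals))
    return passing, removals


def summarize_snps(records: Sequence[VariantRecord],
                   sample: int | None = None) -> SnpSummary:
    """Tally Ti/Tv and zygosity over SNP records.

    Zygosity is tallied per sample-site genotype call (het: the two alleles
    differ; hom: both are the alternate) and summed over samples, or
    restricted to one sample index when ``sample`` is given.
    """
    n_ti = n_tv = n_het = n_hom = 0
    for r in records:
        if not r.is_snp:
            raise ValueError(f"summarize_snps got a non-SNP at {r.chrom}:{r.pos}")
        if classify_substitution(r.ref, r.alt) == "transition":
            n_ti += 1
        else:
            n_tv += 1
        g = r.genotypes if sample is None else r.genotypes[sample:sample + 1]
        n_het += int((g == 1).sum())
        n_hom += int((g == 2).sum())
    return SnpSummary(n_ti, n_tv, n_het, n_hom)


def summarize_indels(records: Sequence[VariantRecord], annotation=None,
                     scope: str = "genome") -> IndelSummary:
    """Tally insertion/deletion counts, zygosity and the length spectrum.

    ``scope="CDS"`` keeps only InDels whose reference span overlaps a CDS
    interval of ``annotation`` (a :class:`popsweep.annotate.GenomeAnnotation`).
    """
    if scope not in ("genome", "CDS"):
        raise ValueError("scope must be 'genome' or 'CDS'")
    if scope == "CDS" and annotation is None:
        raise ValueError("CDS scope requires an annotation")
    n_ins = n_del = n_het = n_hom = 0
    spectrum: Counter = Counter()
    for r in records:
        if r.is_snp:
            raise ValueError(f"summarize_indels got a SNP at {r.chrom}:{r.pos}")
        if scope == "CDS":
            span = (r.pos - 1, r.pos - 1 + len(r.ref))
            if not annotation.overlaps_cds(r.chrom, *span):
                continue
        length = r.indel_length
        if length > 0:
            n_ins += 1
        else:
            n_del += 1
        spectrum[length] += 1
        n_het += int((r.genotypes == 1).sum())
        n_hom += int((r.genotypes == 2).sum())
    return IndelSummary(n_ins, n_del, n_het, n_hom, dict(spectrum), scope=scope)


def per_chromosome_counts(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """SNP and InDel counts per chromosome (rows partition the input)."""
    counts: dict[str, list[int]] = {}
    for r in records:
        row = counts.setdefault(r.chrom, [0, 0])
        row[0 if r.is_snp else 1] += 1
    return pd.DataFrame(
        [(c, n[0], n[1]) for c, n in counts.items()],
        columns=["chrom", "n_snps", "n_indels"],
    )
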