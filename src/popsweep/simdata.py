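"""Synthetic three-population genomic datasets with ground truth.

The generator emulates the design of a three-population resequencing study:
two genetically close populations (anadromous AP and sea SP) and one
diverged landlocked population (LP), ten diploid individuals each.  Per-site
population allele frequencies follow the Balding-Nichols model: an ancestral
frequency ``p`` is drawn per site and each population's frequency is drawn
from ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, whose expected fixation index against
the ancestral pool is approximately ``F``.  Genotypes are Hardy-Weinberg
(Binomial(2, p_pop)).  Selective sweeps are injected by pushing the target
population's major allele toward fixation inside chosen intervals, which
produces the low-diversity / high-differentiation signal that the sweep-scan
module is designed to detect.

A toy annotated genome is generated alongside the variants: every gene has a
valid ORF (ATG start, stop codon, length divisible by 3, no internal stops on
the coding strand), 1-3 exons, short UTR stubs and both strands represented,
so the annotation module can be exercised on every category it defines.

qPCR cycle-threshold (Ct) tables are simulated for the expression module:
``Ct = baseline - log2(relative expression) + noise`` with three
group-independent housekeeping genes and triplicate technical measurements.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_populations",
    "inject_sweep",
    "write_dataset",
    "simulate_qpcr",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
# codons excluding stops, fixed order for determinism
_CODING_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class SimConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of a synthetic three-population dataset.

    Defaults mirror the study design being emulated: three populations of
    ten diploid individuals, with the landlocked population carrying a much
    larger drift parameter than the two marine-connected ones (the observed
    topology clusters AP with SP and sets LP apart).  SNP density defaults
    to about one variant per 250 bp, in line with the roughly 3.2 M SNPs on
    an ~800 Mb genome reported for this kind of cohort, and ~37 % of
    variants are short InDels (the reported SNP:InDel proportion).
    """

    n_chromosomes: int = 1
    chrom_length: int = 500_000
    n_pops: int = 3
    samples_per_pop: int = 10
    drift_F: tuple[float, ...] = (0.02, 0.25, 0.03)
    snp_density: float = 0.004
    indel_fraction: float = 0.37
    sweep_intervals: list[tuple[str, int, int, str]] = field(default_factory=list)
    n_genes: int = 12
    metric_fail_fraction: float = 0.05
    missing_rate: float = 0.01
    pop_names: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_names is None:
            defaults = ("AP", "LP", "SP")
            if self.n_pops <= 3:
                self.pop_names = defaults[: self.n_pops]
            else:
                self.pop_names = defaults + tuple(
                    f"P{i}" for i in range(4, self.n_pops + 1)
                )
        if len(self.pop_names) != self.n_pops:
            raise SimConfigError("pop_names length must equal n_pops")
        if len(self.drift_F) != self.n_pops:
            raise SimConfigError("drift_F must give one value per population")
        for f in self.drift_F:
            if not (0.0 < f < 1.0):
                raise SimConfigError(f"drift_F must lie in (0, 1), got {f}")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise SimConfigError("chromosome count and length must be positive")
        if self.samples_per_pop < 1:
            raise SimConfigError("samples_per_pop must be positive")
        if not (0.0 <= self.indel_fraction <= 1.0):
            raise SimConfigError("indel_fraction must lie in [0, 1]")
        if self.snp_density <= 0:
            raise SimConfigError("snp_density must be positive")
        chroms = {f"chr{i + 1}" for i in range(self.n_chromosomes)}
        for chrom, start, end, pop in self.sweep_intervals:
            if chrom not in chroms:
                raise SimConfigError(f"sweep interval on unknown chromosome {chrom}")
            if not (0 <= start <= end <= self.chrom_length):
                raise SimConfigError(
                    f"sweep interval [{start}, {end}) outside chromosome bounds"
                )
            if pop not in self.pop_names:
                raise SimConfigError(f"sweep interval targets unknown population {pop}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class GeneModel:
    """One gene with a single transcript; coordinates 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]

    @property
    def transcript_id(self) -> str:
        return f"{self.gene_id}.t1"


@dataclass
class SimDataset:
    """Ground-truth bundle produced by :func:`simulate_populations`."""

    config: SimConfig
    reference: dict[str, np.ndarray]          # chrom -> char array
    chrom: np.ndarray                          # per site, chromosome name
    pos: np.ndarray                            # per site, 1-based position
    ref: list[str]
    alt: list[str]
    qual: np.ndarray
    qd: np.ndarray
    mq: np.ndarray
    fs: np.ndarray
    true_freqs: np.ndarray                     # (n_sites, n_pops) alt-allele freq
    genotypes: np.ndarray                      # (n_samples, n_sites), -1 missing
    sample_names: list[str]
    sample_pop: list[str]
    genes: list[GeneModel]
    true_sweeps: list[tuple[str, int, int, str]]
    seed: int

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def is_indel(self) -> np.ndarray:
        return np.array(
            [len(r) != len(a) for r, a in zip(self.ref, self.alt)], dtype=bool
        )

    def pop_samples(self, pop: str) -> np.ndarray:
        """Row indices of the samples belonging to ``pop``."""
        idx = np.array([i for i, p in enumerate(self.sample_pop) if p == pop])
        if idx.size == 0:
            raise KeyError(f"unknown population label {pop!r}")
        return idx

    def indel_length_spectrum(self) -> Counter:
        """Signed InDel lengths (insertions positive) -> counts."""
        spectrum: Counter = Counter()
        for r, a in zip(self.ref, self.alt):
            if len(r) != len(a):
                spectrum[len(a) - len(r)] += 1
        return spectrum


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str,
               slot_start: int, slot_end: int) -> GeneModel | None:
    """Lay out one gene inside a slot; returns None if the slot is too small."""
    n_exons = int(rng.integers(1, 4))
    n_codons = int(rng.integers(50, 150))       # incl. start and stop
    cds_len = 3 * n_codons
    introns = [int(rng.integers(80, 300)) for _ in range(n_exons - 1)]
    utr = 30
    span = cds_len + sum(introns) + 2 * utr
    if span > slot_end - slot_start - 20:
        return None
    offset = int(rng.integers(slot_start + 10, slot_end - span - 10))
    strand = "+" if rng.random() < 0.5 else "-"

    # split the CDS into n_exons genomic chunks, each >= 30 bp
    cuts = sorted(rng.integers(30, cds_len - 30, size=n_exons - 1).tolist()) \
        if n_exons > 1 else []
    pieces, prev = [], 0
    for c in cuts + [cds_len]:
        if c - prev < 30:               # keep chunks non-trivial
            c = prev + 30
        pieces.append(min(c, cds_len) - prev)
        prev = min(c, cds_len)
    pieces[-1] = cds_len - sum(pieces[:-1])
    if min(pieces) < 1:
        pieces = [cds_len]              # degenerate cut set -> single exon
        introns = []
        n_exons = 1

    cds_iv, exon_iv = [], []
    cursor = offset + utr
    for i, plen in enumerate(pieces):
        cds_iv.append((cursor, cursor + plen))
        cursor += plen
        if i < len(introns):
            cursor += introns[i]
    # UTR stubs extend the first and last exon beyond the CDS
    for i, (s, e) in enumerate(cds_iv):
        es = s - utr if i == 0 else s
        ee = e + utr if i == len(cds_iv) - 1 else e
        exon_iv.append((es, ee))
    return GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        start=exon_iv[0][0], end=exon_iv[-1][1],
        exons=exon_iv, cds=cds_iv,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _write_cds_sequence(rng: np.random.Generator, genome: np.ndarray,
                        gene: GeneModel) -> None:
    """Write a valid ORF into the gene's CDS intervals on the genome."""
    cds_len = sum(e - s for s, e in gene.cds)
    n_codons = cds_len // 3
    body = "".join(
        _CODING_CODONS[i]
        for i in rng.integers(0, len(_CODING_CODONS), size=n_codons - 2)
    )
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    coding = "ATG" + body + stop
    if gene.strand == "+":
        cursor = 0
        for s, e in gene.cds:
            genome[s:e] = list(coding[cursor:cursor + (e - s)])
            cursor += e - s
    else:
        cursor = 0
        for s, e in reversed(gene.cds):      # transcription order on '-'
            chunk = coding[cursor:cursor + (e - s)]
            genome[s:e] = list(_revcomp(chunk))
            cursor += e - s


def _simulate_metrics(rng: np.random.Generator, n: int,
                      fail_fraction: float) -> tuple[np.ndarray, ...]:
    """QUAL/QD/MQ/FS per site; a fraction of sites violates one threshold."""
    qual = np.round(rng.uniform(30.5, 900.0, size=n), 2)
    qd = np.round(rng.uniform(2.5, 35.0, size=n), 2)
    mq = np.round(rng.uniform(40.5, 60.0, size=n), 2)
    fs = np.round(rng.uniform(0.0, 55.0, size=n), 2)
    fail = rng.random(n) < fail_fraction
    which = rng.integers(0, 4, size=n)
    qual[fail & (which == 0)] = np.round(rng.uniform(5.0, 29.5, size=n), 2)[fail & (which == 0)]
    qd[fail & (which == 1)] = np.round(rng.uniform(0.1, 1.9, size=n), 2)[fail & (which == 1)]
    mq[fail & (which == 2)] = np.round(rng.uniform(20.0, 39.5, size=n), 2)[fail & (which == 2)]
    fs[fail & (which == 3)] = np.round(rng.uniform(61.0, 150.0, size=n), 2)[fail & (which == 3)]
    return qual, qd, mq, fs


def simulate_populations(config: SimConfig) -> SimDataset:
    """Generate a complete synthetic dataset under the Balding-Nichols model.

    Deterministic given ``config.seed``: the same configuration always yields
    the same reference, gene models, variants and genotypes.  Sweeps listed
    in ``config.sweep_intervals`` are injected before returning.
    """
    rng = np.random.default_rng(config.seed)
    reference: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []

    # reference sequence and gene models
    per_chrom = max(1, math.ceil(config.n_genes / config.n_chromosomes))
    gene_i = 0
    for chrom in config.chrom_names:
        genome = rng.choice(_BASES, size=config.chrom_length)
        n_here = min(per_chrom, config.n_genes - gene_i)
        if n_here > 0:
            slot = config.chrom_length // n_here
            for j in range(n_here):
                g = _make_gene(rng, f"gene{gene_i + 1:04d}", chrom,
                               j * slot, (j + 1) * slot)
                if g is not None:
                    _write_cds_sequence(rng, genome, g)
                    genes.append(g)
                    gene_i += 1
        reference[chrom] = genome

    # variant sites
    chrom_col, pos_col, refs, alts = [], [], [], []
    freqs = []
    for chrom in config.chrom_names:
        genome = reference[chrom]
        n_var = int(round(config.snp_density * config.chrom_length))
        n_var = min(n_var, config.chrom_length - 30)
        positions = np.sort(
            rng.choice(np.arange(1, config.chrom_length - 15), size=n_var,
                       replace=False)
        )
        is_indel = rng.random(n_var) < config.indel_fraction
        for p0, ind in zip(positions, is_indel):
            ref_base = str(genome[p0])
            if not ind:
                if rng.random() < 0.56:         # mild transition bias
                    alt_base = _TRANSITION[ref_base]
                else:
                    choices = [b for b in "ACGT"
                               if b != ref_base and b != _TRANSITION[ref_base]]
                    alt_base = choices[int(rng.integers(0, 2))]
                refs.append(ref_base)
                alts.append(alt_base)
            else:
                # truncated geometric lengths on 1..10, mononucleotide-heavy
                length = min(int(rng.geometric(0.5)), 10)
                if rng.random() < 0.5:          # insertion
                    ins = "".join(rng.choice(_BASES, size=length))
                    refs.append(ref_base)
                    alts.append(ref_base + ins)
                else:                            # deletion
                    refs.append(ref_base + "".join(genome[p0 + 1:p0 + 1 + length]))
                    alts.append(ref_base)
            chrom_col.append(chrom)
            pos_col.append(int(p0) + 1)         # VCF 1-based
        anc = rng.uniform(0.05, 0.95, size=n_var)
        pop_freq = np.empty((n_var, config.n_pops))
        for k, F in enumerate(config.drift_F):
            a = anc * (1.0 - F) / F
            b = (1.0 - anc) * (1.0 - F) / F
            pop_freq[:, k] = rng.beta(a, b)
        freqs.append(pop_freq)

    true_freqs = np.vstack(freqs) if freqs else np.zeros((0, config.n_pops))
    n_sites = len(pos_col)

    # genotypes under HWE, then missingness
    n_samples = config.n_pops * config.samples_per_pop
    genotypes = np.empty((n_samples, n_sites), dtype=np.int8)
    sample_names, sample_pop = [], []
    for k, pop in enumerate(config.pop_names):
        rows = slice(k * config.samples_per_pop, (k + 1) * config.samples_per_pop)
        genotypes[rows] = rng.binomial(
            2, true_freqs[:, k], size=(config.samples_per_pop, n_sites)
        ).astype(np.int8)
        for i in range(config.samples_per_pop):
            sample_names.append(f"{pop}_{i + 1}")
            sample_pop.append(pop)
    if config.missing_rate > 0:
        missing = rng.random(genotypes.shape) < config.missing_rate
        genotypes[missing] = -1

    qual, qd, mq, fs = _simulate_metrics(rng, n_sites, config.metric_fail_fraction)

    dataset = SimDataset(
        config=config, reference=reference,
        chrom=np.array(chrom_col), pos=np.array(pos_col, dtype=np.int64),
        ref=refs, alt=alts, qual=qual, qd=qd, mq=mq, fs=fs,
        true_freqs=true_freqs, genotypes=genotypes,
        sample_names=sample_names, sample_pop=sample_pop,
        genes=genes, true_sweeps=[], seed=config.seed,
    )
    for chrom, start, end, pop in config.sweep_intervals:
        dataset = inject_sweep(dataset, (chrom, start, end), pop)
    return dataset


def inject_sweep(dataset: SimDataset, interval: tuple[str, int, int],
                 target_pop: str, *, strength: float = 50.0,
                 minor_target: float = 0.02) -> SimDataset:
    """Push the target population's major allele toward fixation in a region.

    Inside ``interval`` the target population's allele frequencies are
    resampled from ``Beta(minor_target*K, (1-minor_target)*K)`` (K =
    ``strength``) mapped onto the minor allele, and the population's
    genotypes at those sites are regenerated.  Other populations are left
    untouched.  The interval is recorded in ``true_sweeps``.  Deterministic:
    the resampling RNG is derived from the dataset seed and the interval.
    """
    chrom, start, end = interval
    if target_pop not in dataset.config.pop_names:
        raise KeyError(f"unknown population label {target_pop!r}")
    if chrom not in dataset.config.chrom_names:
        raise SimConfigError(f"sweep interval on unknown chromosome {chrom}")
    if not (0 <= start <= end <= dataset.config.chrom_length):
        raise SimConfigError("sweep interval outside chromosome bounds")
    if start == end:
        return dataset

    k = dataset.config.pop_names.index(target_pop)
    rng = np.random.default_rng([dataset.seed & 0x7FFFFFFF, start, end, k])
    in_iv = (dataset.chrom == chrom) & (dataset.pos - 1 >= start) & (dataset.pos - 1 < end)
    idx = np.flatnonzero(in_iv)
    if idx.size:
        minor = rng.beta(minor_target * strength,
                         (1.0 - minor_target) * strength, size=idx.size)
        old = dataset.true_freqs[idx, k]
        new = np.where(old >= 0.5, 1.0 - minor, minor)
        dataset.true_freqs[idx, k] = new
        rows = dataset.pop_samples(target_pop)
        g = rng.binomial(2, new, size=(rows.size, idx.size)).astype(np.int8)
        if dataset.config.missing_rate > 0:
            g[rng.random(g.shape) < dataset.config.missing_rate] = -1
        dataset.genotypes[np.ix_(rows, idx)] = g
    dataset.true_sweeps.append((chrom, start, end, target_pop))
    return dataset


_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_dataset(dataset: SimDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``ref.fa``, ``genes.gff3``, ``variants.vcf`` and ``truth.json``.

    The VCF is v4.2 with a GT FORMAT field and QD/MQ/FS INFO metrics; the
    GFF3 carries gene/mRNA/exon/CDS features with correct phases.  Returns a
    name -> path mapping.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref": out / "ref.fa",
        "gff3": out / "genes.gff3",
        "vcf": out / "variants.vcf",
        "truth": out / "truth.json",
    }

    with open(paths["ref"], "w") as fh:
        for chrom in dataset.config.chrom_names:
            fh.write(f">{chrom}\n")
            seq = "".join(dataset.reference[chrom])
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in dataset.config.chrom_names:
            fh.write(f"##sequence-region {chrom} 1 {dataset.config.chrom_length}\n")
        for g in dataset.genes:
            t = g.transcript_id
            fh.write(f"{g.chrom}\tpopsweep\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            fh.write(f"{g.chrom}\tpopsweep\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={t};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tpopsweep\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={t}.exon{i + 1};Parent={t}\n")
            cds_order = g.cds if g.strand == "+" else list(reversed(g.cds))
            cum = 0
            phased = []
            for s, e in cds_order:
                phased.append((s, e, (3 - cum % 3) % 3))
                cum += e - s
            for i, (s, e, phase) in enumerate(
                    sorted(phased, key=lambda x: x[0])):
                fh.write(f"{g.chrom}\tpopsweep\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t{phase}\tID={t}.cds{i + 1};Parent={t}\n")

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=popsweep-simdata\n")
        for chrom in dataset.config.chrom_names:
            fh.write(f"##contig=<ID={chrom},length={dataset.config.chrom_length}>\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description='
                 '"Variant confidence normalized by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description='
                 '"RMS mapping quality">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description='
                 '"Phred-scaled strand-bias Fisher p">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.sample_names) + "\n")
        for j in range(dataset.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in dataset.genotypes[:, j])
            fh.write(
                f"{dataset.chrom[j]}\t{dataset.pos[j]}\t.\t{dataset.ref[j]}\t"
                f"{dataset.alt[j]}\t{dataset.qual[j]:.2f}\t.\t"
                f"QD={dataset.qd[j]:.2f};MQ={dataset.mq[j]:.2f};"
                f"FS={dataset.fs[j]:.2f}\tGT\t{gts}\n"
            )

    truth = {
        "seed": dataset.seed,
        "true_sweeps": [list(s) for s in dataset.true_sweeps],
        "pop_names": list(dataset.config.pop_names),
        "n_sites": dataset.n_sites,
        "n_missing_genotypes": int((dataset.genotypes == -1).sum()),
        "indel_length_spectrum": {
            str(k): v for k, v in sorted(dataset.indel_length_spectrum().items())
        },
        "true_freqs": [
            [round(float(x), 6) for x in row] for row in dataset.true_freqs
        ],
        "positions": [f"{c}:{p}" for c, p in zip(dataset.chrom, dataset.pos)],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths


def simulate_qpcr(groups: list[str], target_genes: list[str],
                  effect_sizes: dict[str, dict[str, float]], seed: int, *,
                  housekeeping: tuple[str, str, str] = ("actb", "rn18s", "gapdh"),
                  n_biological: int = 5, n_replicates: int = 3,
                  noise_sd: float = 0.15, baseline_ct: float = 22.0) -> pd.DataFrame:
    """Simulate a long-format qPCR Ct table.

    ``effect_sizes[gene][group]`` is the true expression fold change of
    ``gene`` in ``group`` relative to the first group (missing entries mean
    no change).  Each sample carries a loading offset (RNA input variation)
    common to all its genes, which the housekeeping normalization must
    cancel; all randomness scales with ``noise_sd`` so a zero-noise run is
    exactly deterministic arithmetic.  Five biological replicates per group
    and triplicate technical measurements by default.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if len(set(housekeeping)) < 3:
        raise ValueError("need three distinct housekeeping genes")
    if not target_genes:
        raise ValueError("need at least one target gene")
    if n_replicates < 1 or n_biological < 1:
        raise ValueError("replicate counts must be positive")

    rng = np.random.default_rng(seed)
    genes = list(housekeeping) + list(target_genes)
    # distinct per-gene baselines (housekeepers tend to be abundant)
    base = {g: baseline_ct + 2.0 * i for i, g in enumerate(genes)}
    rows = []
    for group in groups:
        for b in range(n_biological):
            sample = f"{group}_{b + 1}"
            load = float(rng.normal(0.0, noise_sd))
            for gene in genes:
                if gene in housekeeping:
                    fold = 1.0
                else:
                    fold = effect_sizes.get(gene, {}).get(group, 1.0)
                    if fold <= 0:
                        raise ValueError("fold changes must be positive")
                mu = base[gene] + load - math.log2(fold)
                for rep in range(n_replicates):
                    ct = mu + float(rng.normal(0.0, noise_sd))
                    rows.append((sample, group, gene, rep + 1, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "rep", "ct"])
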