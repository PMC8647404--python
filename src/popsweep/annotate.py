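"""Genomic-region and coding-effect annotation of variants.

Each variant is assigned one genomic region — CDS, splice site
(donor/acceptor/region), intron, intragenic, upstream/downstream (5 kb
flanks by default), or intergenic — and, within CDS, one coding effect using
the classic SnpEff category vocabulary (SYNONYMOUS_CODING,
NON_SYNONYMOUS_CODING, STOP_GAINED, FRAME_SHIFT, CODON_INSERTION, ...).

Conventions:

- coordinates are converted once at the boundary from 1-based VCF positions
  to the 0-based half-open intervals used internally;
- per transcript, region precedence is CDS > splice donor/acceptor >
  splice region > intron > intragenic; gene flanks and intergenic apply
  when no transcript feature is hit;
- splice donor = first 2 intronic bases after an exon (in transcription
  direction), acceptor = last 2 before the next exon, splice region =
  intronic bases 3-8 from either boundary plus the 3 exonic bases adjacent
  to a junction;
- across transcripts the single highest-severity call is reported
  (severity order below), because the published summary tables count each
  variant once;
- InDel codon alignment is judged after left-normalizing the InDel against
  the reference sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAnnotation",
    "Gene",
    "Transcript",
    "EffectCall",
    "load_annotation",
    "annotate_variant",
    "effect_table",
    "SEVERITY_ORDER",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _translate(codon: str) -> str:
    """One-letter amino acid (or ``*``) for a codon; standard genetic code."""
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table
        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE[codon.upper()]


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# Highest first.  Region labels double as effect labels for non-CDS calls.
SEVERITY_ORDER = [
    "EXON_DELETED",
    "FRAME_SHIFT",
    "STOP_GAINED",
    "STOP_LOST",
    "START_LOST",
    "CODON_CHANGE_PLUS_CODON_INSERTION",
    "CODON_CHANGE_PLUS_CODON_DELETION",
    "CODON_INSERTION",
    "CODON_DELETION",
    "NON_SYNONYMOUS_CODING",
    "SPLICE_SITE_ACCEPTOR",
    "SPLICE_SITE_DONOR",
    "SPLICE_SITE_REGION",
    "SYNONYMOUS_CODING",
    "SYNONYMOUS_STOP",
    "INTRON",
    "UPSTREAM",
    "DOWNSTREAM",
    "INTRAGENIC",
    "INTERGENIC",
]
_SEVERITY = {name: i for i, name in enumerate(SEVERITY_ORDER)}

CDS_EFFECTS = {
    "SYNONYMOUS_CODING", "NON_SYNONYMOUS_CODING", "SYNONYMOUS_STOP",
    "STOP_GAINED", "STOP_LOST", "START_LOST", "FRAME_SHIFT",
    "CODON_INSERTION", "CODON_DELETION", "CODON_CHANGE_PLUS_CODON_INSERTION",
    "CODON_CHANGE_PLUS_CODON_DELETION", "EXON_DELETED",
}


@dataclass
class Transcript:
    """One transcript: exons and CDS as sorted 0-based half-open intervals."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    flagged: bool = False          # CDS length not divisible by 3

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = -1
        for s, e in self.exons:
            if s < prev_end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons (genomic order)."""
        return [(self.exons[i][1], self.exons[i + 1][0])
                for i in range(len(self.exons) - 1)]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def coding_order_cds(self) -> list[tuple[int, int]]:
        """CDS intervals in transcription (5'->3') order."""
        return self.cds if self.strand == "+" else list(reversed(self.cds))

    def genomic_to_cds(self, pos0: int) -> int | None:
        """Map a genomic base to its 0-based index in the coding sequence."""
        offset = 0
        for s, e in self.coding_order_cds():
            if s <= pos0 < e:
                return offset + (pos0 - s if self.strand == "+" else e - 1 - pos0)
            offset += e - s
        return None


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class EffectCall:
    """The single region/effect assigned to one variant."""

    chrom: str
    pos: int                       # 1-based, as in the VCF
    ref: str
    alt: str
    region: str
    cds_effect: str | None = None
    gene_id: str | None = None
    transcript_id: str | None = None

    @property
    def label(self) -> str:
        """Effect label used for severity ranking and count tables."""
        return self.cds_effect if self.region == "CDS" else self.region

    @property
    def severity(self) -> int:
        return _SEVERITY[self.label]


class GenomeAnnotation:
    """Gene models plus derived interval indexes and the genome sequence."""

    def __init__(self, genes: list[Gene], sequences: dict[str, str],
                 flank_bp: int = 5000, splice_site_bp: int = 2,
                 splice_region_intron: tuple[int, int] = (3, 8),
                 splice_region_exon: int = 3) -> None:
        self.genes = {g.gene_id: g for g in genes}
        self.sequences = sequences
        self.flank_bp = flank_bp
        self.splice_site_bp = splice_site_bp
        self.splice_region_intron = splice_region_intron
        self.splice_region_exon = splice_region_exon
        self._cds_seq_cache: dict[str, str] = {}
        self._build_indexes()

    # -- index construction -------------------------------------------------

    def _build_indexes(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        for gene in self.genes.values():
            gt = self._gene_trees.setdefault(gene.chrom, IntervalTree())
            gt[gene.start:gene.end] = gene.gene_id
            tree = self._trees.setdefault(gene.chrom, IntervalTree())
            # gene span and strand-aware flanks
            tree[gene.start:gene.end] = ("INTRAGENIC", gene.gene_id, None)
            up = ("UPSTREAM" if gene.strand == "+" else "DOWNSTREAM")
            down = ("DOWNSTREAM" if gene.strand == "+" else "UPSTREAM")
            if gene.start > 0:
                tree[max(0, gene.start - self.flank_bp):gene.start] = \
                    (up, gene.gene_id, None)
            tree[gene.end:gene.end + self.flank_bp] = (down, gene.gene_id, None)
            for tx in gene.transcripts:
                self._index_transcript(tree, tx)

    def _index_transcript(self, tree: IntervalTree, tx: Transcript) -> None:
        for s, e in tx.cds:
            tree[s:e] = ("CDS", tx.gene_id, tx.transcript_id)
        k = self.splice_site_bp
        r_lo, r_hi = self.splice_region_intron
        ex = self.splice_region_exon
        for s, e in tx.introns:
            if e - s <= 0:
                continue
            left_site = ("SPLICE_SITE_DONOR" if tx.strand == "+"
                         else "SPLICE_SITE_ACCEPTOR")
            right_site = ("SPLICE_SITE_ACCEPTOR" if tx.strand == "+"
                          else "SPLICE_SITE_DONOR")
            tree[s:min(e, s + k)] = (left_site, tx.gene_id, tx.transcript_id)
            tree[max(s, e - k):e] = (right_site, tx.gene_id, tx.transcript_id)
            # intronic splice region: bases r_lo..r_hi from either boundary
            lo_s, lo_e = s + r_lo - 1, min(e, s + r_hi)
            hi_s, hi_e = max(s, e - r_hi), e - r_lo + 1
            if lo_e > lo_s:
                tree[lo_s:lo_e] = ("SPLICE_SITE_REGION", tx.gene_id, tx.transcript_id)
            if hi_e > hi_s:
                tree[hi_s:hi_e] = ("SPLICE_SITE_REGION", tx.gene_id, tx.transcript_id)
        # exonic splice-region bases adjacent to each junction
        for i, (s, e) in enumerate(tx.exons):
            if i > 0:
                tree[s:min(e, s + ex)] = ("SPLICE_SITE_REGION", tx.gene_id,
                                          tx.transcript_id)
            if i < len(tx.exons) - 1:
                tree[max(s, e - ex):e] = ("SPLICE_SITE_REGION", tx.gene_id,
                                          tx.transcript_id)
        for s, e in tx.introns:
            tree[s:e] = ("INTRON", tx.gene_id, tx.transcript_id)

    # -- queries ------------------------------------------------------------

    def overlaps_cds(self, chrom: str, start0: int, end0: int) -> bool:
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return any(tag == "CDS" for iv in tree.overlap(start0, end0)
                   for tag, _, _ in [iv.data])

    def genes_overlapping(self, chrom: str, start0: int, end0: int) -> list[str]:
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start0, end0)})

    def cds_sequence(self, tx: Transcript) -> str:
        """Coding-strand CDS sequence of a transcript (cached)."""
        if tx.transcript_id not in self._cds_seq_cache:
            chrom_seq = self.sequences[tx.chrom]
            parts = [chrom_seq[s:e] for s, e in tx.cds]
            seq = "".join(parts)
            if tx.strand == "-":
                seq = _revcomp(seq)
            self._cds_seq_cache[tx.transcript_id] = seq.upper()
        return self._cds_seq_cache[tx.transcript_id]


def load_annotation(gff3_path: str | Path, fasta_path: str | Path,
                    flank_bp: int = 5000) -> GenomeAnnotation:
    """Load gene models from GFF3 and sequence from FASTA.

    Expects gene / mRNA / exon / CDS features linked by ID/Parent
    attributes.  Transcripts whose CDS length is not divisible by 3 are
    flagged with a warning; CDS on a chromosome absent from the FASTA is an
    error.
    """
    fasta = Fasta(str(fasta_path))
    sequences = {name: str(fasta[name][:]).upper() for name in fasta.keys()}

    genes: dict[str, Gene] = {}
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}

    with open(gff3_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line {line_no}: {line!r}")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s, e = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attr["ID"]
                genes[gid] = Gene(gid, chrom, strand, s, e)
            elif ftype in ("mRNA", "transcript"):
                tx_meta[attr["ID"]] = {"gene": attr.get("Parent"),
                                       "chrom": chrom, "strand": strand}
            elif ftype == "exon":
                exons.setdefault(attr["Parent"], []).append((s, e))
            elif ftype == "CDS":
                if chrom not in sequences:
                    raise ValueError(
                        f"CDS on chromosome {chrom!r} absent from FASTA")
                cds.setdefault(attr["Parent"], []).append((s, e))

    for tid, meta in tx_meta.items():
        tx = Transcript(
            transcript_id=tid, gene_id=meta["gene"], chrom=meta["chrom"],
            strand=meta["strand"], exons=exons.get(tid, []),
            cds=cds.get(tid, []),
        )
        if tx.cds and tx.cds_length % 3 != 0:
            warnings.warn(f"transcript {tid}: CDS length {tx.cds_length} "
                          "not divisible by 3", stacklevel=2)
            tx.flagged = True
        gene = genes.get(meta["gene"])
        if gene is None:
            gene = Gene(meta["gene"] or tid, meta["chrom"], meta["strand"],
                        min(s for s, _ in tx.exons or tx.cds),
                        max(e for _, e in tx.exons or tx.cds))
            genes[gene.gene_id] = gene
        gene.transcripts.append(tx)

    return GenomeAnnotation(list(genes.values()), sequences, flank_bp=flank_bp)


# ---------------------------------------------------------------------------
# per-variant annotation
# ---------------------------------------------------------------------------

def _normalize_indel(ann: GenomeAnnotation, chrom: str, pos0: int,
                     ref: str, alt: str) -> tuple[int, str]:
    """Return (edit start, edited sequence) in left-normalized form.

    For an insertion the edit start is the 0-based genomic index *before*
    which the bases are inserted (i.e. insertion after the anchor base, so
    start = pos0 + 1); for a deletion it is the first deleted base.  The
    edited sequence is the inserted or deleted bases.  Left-shifts the edit
    while the base preceding it equals the last base of the edited
    sequence (standard VCF left-alignment).
    """
    seq = ann.sequences[chrom]
    if len(alt) > len(ref):          # insertion after anchor
        start = pos0 + 1
        edit = alt[len(ref):].upper()
    else:                            # deletion of ref[len(alt):]
        start = pos0 + len(alt)
        edit = ref[len(alt):].upper()
    while start > 0 and edit and seq[start - 1].upper() == edit[-1]:
        edit = edit[-1] + edit[:-1]
        start -= 1
    return start, edit


def _snp_cds_effect(ann: GenomeAnnotation, tx: Transcript, pos0: int,
                    alt: str) -> str:
    cds_seq = ann.cds_sequence(tx)
    idx = tx.genomic_to_cds(pos0)
    assert idx is not None
    base = alt.upper() if tx.strand == "+" else alt.upper().translate(_COMP)
    codon_i, within = divmod(idx, 3)
    old_codon = cds_seq[3 * codon_i:3 * codon_i + 3]
    if len(old_codon) < 3:           # flagged/truncated transcript
        return "NON_SYNONYMOUS_CODING"
    new_codon = old_codon[:within] + base + old_codon[within + 1:]
    old_aa, new_aa = _translate(old_codon), _translate(new_codon)
    if codon_i == 0 and old_codon == "ATG" and new_codon != "ATG":
        return "START_LOST"
    if old_aa == new_aa:
        return "SYNONYMOUS_STOP" if old_aa == "*" else "SYNONYMOUS_CODING"
    if new_aa == "*":
        return "STOP_GAINED"
    if old_aa == "*":
        return "STOP_LOST"
    return "NON_SYNONYMOUS_CODING"


def _indel_cds_effect(ann: GenomeAnnotation, tx: Transcript, pos0: int,
                      ref: str, alt: str) -> str:
    cds_seq = ann.cds_sequence(tx)
    n_codons = len(cds_seq) // 3
    start, edit = _normalize_indel(ann, tx.chrom, pos0, ref, alt)
    insertion = len(alt) > len(ref)

    if not insertion:
        del_span = (start, start + len(edit))
        for es, ee in tx.exons:
            if del_span[0] <= es and ee <= del_span[1]:
                return "EXON_DELETED"
        # CDS bases actually removed
        del_cds = [i for p in range(*del_span)
                   if (i := tx.genomic_to_cds(p)) is not None]
        if not del_cds:
            return "INTRON"          # shouldn't happen: caller checked CDS overlap
        del_cds.sort()
        n_del = len(del_cds)
        if n_del % 3 != 0:
            return "FRAME_SHIFT"
        first = del_cds[0]
        # stop-lost override: terminal stop codon removed
        if del_cds[-1] >= 3 * (n_codons - 1):
            return "STOP_LOST"
        aligned = first % 3 == 0
        if not aligned:
            # codon-change: check whether the re-joined codon becomes a stop
            new_seq = "".join(c for i, c in enumerate(cds_seq)
                              if i not in set(del_cds))
            c0 = (first // 3) * 3
            if new_seq[c0:c0 + 3] in _STOPS:
                return "STOP_GAINED"
            return "CODON_CHANGE_PLUS_CODON_DELETION"
        return "CODON_DELETION"

    # insertion: locate the insertion point in CDS coordinates
    ins_seq = edit if tx.strand == "+" else _revcomp(edit)
    if tx.strand == "+":
        cds_point = tx.genomic_to_cds(start)
        if cds_point is None:
            left = tx.genomic_to_cds(start - 1)
            cds_point = None if left is None else left + 1
    else:
        # inserting before genomic index `start` means inserting after the
        # base at start-1; in coding coordinates on '-', that is before the
        # cds index of start-1
        cds_point = tx.genomic_to_cds(start - 1)
        if cds_point is None:
            right = tx.genomic_to_cds(start)
            cds_point = None if right is None else right + 1
    if cds_point is None:
        return "INTRON"
    n_ins = len(ins_seq)
    if n_ins % 3 != 0:
        return "FRAME_SHIFT"
    new_seq = cds_seq[:cds_point] + ins_seq + cds_seq[cds_point:]
    first_codon = cds_point // 3
    affected = new_seq[3 * first_codon:3 * first_codon + n_ins + 3]
    terminal_codon = len(new_seq) // 3 - 1
    for off in range(0, len(affected) - 2, 3):
        if affected[off:off + 3] in _STOPS and first_codon + off // 3 < terminal_codon:
            return "STOP_GAINED"
    aligned = cds_point % 3 == 0
    return "CODON_INSERTION" if aligned else "CODON_CHANGE_PLUS_CODON_INSERTION"


def annotate_variant(variant, ann: GenomeAnnotation) -> EffectCall:
    """Assign the single highest-severity region/effect to one variant.

    ``variant`` is any object with chrom / pos (1-based) / ref / alt
    attributes, e.g. :class:`popsweep.variants.VariantRecord`.
    """
    chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref, variant.alt
    if chrom not in ann.sequences:
        raise ValueError(f"variant on unannotated chromosome {chrom!r}")
    if pos > len(ann.sequences[chrom]):
        raise ValueError(f"variant at {chrom}:{pos} beyond chromosome end")
    pos0 = pos - 1
    is_indel = len(ref) != len(alt)
    if is_indel and len(ref) > len(alt):
        span = (pos0 + len(alt), pos0 + len(ref))   # deleted bases
    else:
        span = (pos0, pos0 + 1)

    tree = ann._trees.get(chrom)
    hits = sorted(tree.overlap(*span), key=lambda iv: iv.begin) if tree else []

    candidates: list[EffectCall] = []
    per_tx: dict[str, list[str]] = {}
    gene_of_tx: dict[str, str] = {}
    gene_level: list[tuple[str, str]] = []
    for iv in hits:
        tag, gene_id, tx_id = iv.data
        if tx_id is None:
            gene_level.append((tag, gene_id))
        else:
            per_tx.setdefault(tx_id, []).append(tag)
            gene_of_tx[tx_id] = gene_id

    region_rank = {"CDS": 0, "SPLICE_SITE_DONOR": 1, "SPLICE_SITE_ACCEPTOR": 1,
                   "SPLICE_SITE_REGION": 2, "INTRON": 3}
    for tx_id, tags in per_tx.items():
        gene = ann.genes[gene_of_tx[tx_id]]
        tx = next(t for t in gene.transcripts if t.transcript_id == tx_id)
        best = min(tags, key=lambda t: region_rank[t])
        if best == "CDS":
            if is_indel:
                effect = _indel_cds_effect(ann, tx, pos0, ref, alt)
            else:
                effect = _snp_cds_effect(ann, tx, pos0, alt)
            if effect == "INTRON":
                candidates.append(EffectCall(chrom, pos, ref, alt, "INTRON",
                                             None, gene.gene_id, tx_id))
            else:
                candidates.append(EffectCall(chrom, pos, ref, alt, "CDS",
                                             effect, gene.gene_id, tx_id))
        else:
            candidates.append(EffectCall(chrom, pos, ref, alt, best, None,
                                         gene.gene_id, tx_id))

    # gene-level fallbacks: intragenic, then flanks
    order = {"INTRAGENIC": 0, "UPSTREAM": 1, "DOWNSTREAM": 2}
    for tag, gene_id in sorted(gene_level, key=lambda x: (order[x[0]], x[1])):
        candidates.append(EffectCall(chrom, pos, ref, alt, tag, None, gene_id))

    if not candidates:
        return EffectCall(chrom, pos, ref, alt, "INTERGENIC")
    return min(candidates, key=lambda c: (c.severity, c.gene_id or "",
                                          c.transcript_id or ""))


# ordered as in the published annotation tables
_TABLE_ROWS = [
    ("-", "INTERGENIC"), ("-", "INTRAGENIC"), ("-", "INTRON"),
    ("-", "UPSTREAM"), ("-", "DOWNSTREAM"),
    ("-", "SPLICE_SITE_ACCEPTOR"), ("-", "SPLICE_SITE_DONOR"),
    ("-", "SPLICE_SITE_REGION"),
    ("CDS", "START_LOST"), ("CDS", "SYNONYMOUS_CODING"),
    ("CDS", "NON_SYNONYMOUS_CODING"), ("CDS", "SYNONYMOUS_STOP"),
    ("CDS", "STOP_GAINED"), ("CDS", "STOP_LOST"),
    ("CDS", "FRAME_SHIFT"), ("CDS", "CODON_INSERTION"),
    ("CDS", "EXON_DELETED"), ("CDS", "CODON_DELETION"),
    ("CDS", "CODON_CHANGE_PLUS_CODON_DELETION"),
    ("CDS", "CODON_CHANGE_PLUS_CODON_INSERTION"),
]


def effect_table(calls: list[EffectCall]) -> pd.DataFrame:
    """Count calls per (region, type) in the published table layout."""
    counts: dict[tuple[str, str], int] = {row: 0 for row in _TABLE_ROWS}
    for call in calls:
        key = ("CDS", call.cds_effect) if call.region == "CDS" \
            else ("-", call.region)
        counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [(r, t, counts[(r, t)]) for r, t in counts],
        columns=["region", "type", "count"],
    )
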