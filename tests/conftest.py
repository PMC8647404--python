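"""Shared fixtures: a handcrafted annotated toy genome and a small
simulated dataset written to disk once per session."""

from __future__ import annotations

import numpy as np
import pytest

from popsweep.annotate import Gene, GenomeAnnotation, Transcript
from popsweep.simdata import SimConfig, simulate_populations, write_dataset

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def build_toy_genome():
    """A 30 kb chromosome with one two-exon plus-strand gene (gP) and one
    single-exon minus-strand gene (gM), with fully controlled codons.

    gP: exons [8000,8099) + [8200,8323), CDS [8030,8099) + [8200,8293)
        (162 bp = 54 codons; the exon junction falls on a codon boundary);
        codons 0..5 are ATG GCT CCA GTC GGA TGG, the last codon is TAA.
    gM: exon [20000,20200), CDS [20030,20168) (138 bp = 46 codons);
        codons 0,1 are ATG GGA, last codon TGA, written reverse-complemented.
    """
    L = 30_000
    seq = list(("ACGT" * (L // 4 + 1))[:L])

    codons = ["GCT"] * 54
    codons[:6] = ["ATG", "GCT", "CCA", "GTC", "GGA", "TGG"]
    codons[-1] = "TAA"
    coding_p = "".join(codons)
    cds_p = [(8030, 8099), (8200, 8293)]
    cursor = 0
    for s, e in cds_p:
        seq[s:e] = list(coding_p[cursor:cursor + e - s])
        cursor += e - s
    tx_p = Transcript("gP.t1", "gP", "c1", "+",
                      exons=[(8000, 8099), (8200, 8323)], cds=cds_p)
    gene_p = Gene("gP", "c1", "+", 8000, 8323, [tx_p])

    codons_m = ["GCT"] * 46
    codons_m[:2] = ["ATG", "GGA"]
    codons_m[-1] = "TGA"
    coding_m = "".join(codons_m)
    seq[20030:20168] = list(revcomp(coding_m))
    tx_m = Transcript("gM.t1", "gM", "c1", "-",
                      exons=[(20000, 20200)], cds=[(20030, 20168)])
    gene_m = Gene("gM", "c1", "-", 20000, 20200, [tx_m])

    sequence = "".join(seq)
    ann = GenomeAnnotation([gene_p, gene_m], {"c1": sequence})
    meta = {
        "length": L,
        "sequence": sequence,
        "coding_p": coding_p,
        "coding_m": coding_m,
        "genes": [gene_p, gene_m],
    }
    return ann, meta


@pytest.fixture(scope="session")
def toy():
    return build_toy_genome()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A 100 kb single-chromosome dataset with default study conditions,
    written to disk: (dataset, paths)."""
    cfg = SimConfig(chrom_length=100_000, n_genes=4, seed=11)
    ds = simulate_populations(cfg)
    paths = write_dataset(ds, tmp_path_factory.mktemp("simdata"))
    return ds, paths


def balding_nichols_genotypes(rng, n_sites, f_values, samples_per_pop):
    """Direct Balding-Nichols genotype sampler used as an independent
    data source in calibration tests (no simdata involvement)."""
    anc = rng.uniform(0.05, 0.95, size=n_sites)
    blocks = []
    for f in f_values:
        p = rng.beta(anc * (1 - f) / f, (1 - anc) * (1 - f) / f)
        blocks.append(rng.binomial(2, p, size=(samples_per_pop, n_sites)))
    return np.vstack(blocks).astype(np.int8)
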