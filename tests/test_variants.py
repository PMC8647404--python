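"""Hard filters, substitution classes, and Fig-1-style summaries."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsweep.variants import (
    FilterConfig,
    SnpSummary,
    VariantRecord,
    apply_hard_filters,
    classify_substitution,
    per_chromosome_counts,
    read_vcf,
    summarize_indels,
    summarize_snps,
)


def rec(pos, ref="A", alt="G", chrom="c1", qual=100.0, qd=20.0, mq=50.0,
        fs=1.0, gts=()):
    return VariantRecord(chrom, pos, ref, alt, qual, qd, mq, fs,
                         np.array(gts, dtype=np.int8))


class TestSubstitutionClass:
    def test_all_twelve_ordered_pairs(self):
        results = [classify_substitution(a, b)
                   for a, b in itertools.permutations("ACGT", 2)]
        assert results.count("transition") == 4
        assert results.count("transversion") == 8
        assert classify_substitution("A", "G") == "transition"
        assert classify_substitution("C", "A") == "transversion"

    @pytest.mark.parametrize("ref,alt", [("A", "A"), ("AT", "A"), ("N", "A")])
    def test_non_snp_rejected(self, ref, alt):
        with pytest.raises(ValueError):
            classify_substitution(ref, alt)


class TestHardFilters:
    def test_snp_near_indel(self):
        records = [rec(100), rec(103, ref="A", alt="AT")]
        passing, removals = apply_hard_filters(records)
        assert [(r.pos, why) for r, why in removals] == [(100, "snp_near_indel")]
        assert [r.pos for r in passing] == [103]

    def test_adjacent_indels_both_removed(self):
        records = [rec(100, ref="A", alt="AT"), rec(108, ref="CG", alt="C")]
        _, removals = apply_hard_filters(records)
        assert {(r.pos, why) for r, why in removals} == {
            (100, "adjacent_indel"), (108, "adjacent_indel")}

    def test_cluster_of_three_in_five_bp(self):
        records = [rec(200), rec(202), rec(204)]
        passing, removals = apply_hard_filters(records)
        assert not passing
        assert all(why == "cluster" for _, why in removals)

    @pytest.mark.parametrize("field,value,reason", [
        ("qual", 25.0, "QUAL"), ("qd", 1.5, "QD"),
        ("mq", 35.0, "MQ"), ("fs", 70.0, "FS"),
    ])
    def test_metric_thresholds(self, field, value, reason):
        r = rec(500, **{field: value})
        passing, removals = apply_hard_filters([r])
        assert not passing and removals[0][1] == reason

    def test_missing_metric_skips_rule(self):
        r = rec(500, qd=None)
        passing, removals = apply_hard_filters([r])
        assert len(passing) == 1 and not removals

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            apply_hard_filters([rec(200), rec(100)])

    def test_planted_fixture_matches_bruteforce_oracle(self):
        passing, removals = apply_hard_filters(_planted_fixture())
        removed_idx, reasons = _filter_oracle(_planted_fixture())
        assert {(r.chrom, r.pos) for r, _ in removals} == removed_idx
        assert {(r.chrom, r.pos): why for r, why in removals} == reasons
        assert len(passing) + len(removals) == 100

    @given(st.lists(st.tuples(st.integers(1, 3000), st.booleans(),
                              st.floats(0, 200), st.floats(0, 40),
                              st.floats(0, 70), st.floats(0, 100)),
                    min_size=0, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_conservation_and_idempotence(self, raw):
        seen = set()
        records = []
        for pos, indel, qual, qd, mq, fs in sorted(raw):
            if pos in seen:
                continue
            seen.add(pos)
            records.append(rec(pos, ref="A", alt="AT" if indel else "G",
                               qual=qual, qd=qd, mq=mq, fs=fs))
        passing, removals = apply_hard_filters(records)
        assert len(passing) + len(removals) == len(records)
        assert {id(r) for r in passing}.isdisjoint(
            {id(r) for r, _ in removals})
        again, removed_again = apply_hard_filters(passing)
        assert len(again) == len(passing) and not removed_again


def _planted_fixture():
    """100 sorted variants with planted violations of every rule."""
    rng = np.random.default_rng(1234)
    positions = np.sort(rng.choice(np.arange(10, 50_000, 7), size=95,
                                   replace=False))
    records = []
    for i, pos in enumerate(positions):
        kind = i % 10
        if kind == 0:
            records.append(rec(int(pos), ref="A", alt="AT"))       # InDel
        elif kind == 1:
            records.append(rec(int(pos), qual=float(rng.uniform(5, 29))))
        elif kind == 2:
            records.append(rec(int(pos), qd=float(rng.uniform(0.1, 1.9))))
        elif kind == 3:
            records.append(rec(int(pos), mq=float(rng.uniform(20, 39))))
        elif kind == 4:
            records.append(rec(int(pos), fs=float(rng.uniform(61, 150))))
        else:
            records.append(rec(int(pos)))
    # plant a cluster and a SNP-near-InDel pair at fresh positions
    extra = [rec(60_001), rec(60_003), rec(60_005),
             rec(60_050), rec(60_053, ref="G", alt="GTT")]
    return records + extra


def _filter_oracle(records, cfg=FilterConfig()):
    """Exhaustive independent rule-checker (quadratic, rule by rule)."""
    removed = {}
    n = len(records)
    for i, r in enumerate(records):                       # rule 1
        for j, o in enumerate(records):
            if i == j or o.chrom != r.chrom or not o.is_indel:
                continue
            d = abs(o.pos - r.pos)
            if r.is_snp and d <= cfg.snp_near_indel_bp:
                removed.setdefault(i, "snp_near_indel")
            if r.is_indel and d <= cfg.adjacent_indel_bp:
                removed.setdefault(i, "adjacent_indel")
    for combo in itertools.combinations(range(n), cfg.cluster_size + 1):
        chroms = {records[i].chrom for i in combo}
        if len(chroms) != 1:
            continue
        pos = [records[i].pos for i in combo]
        if max(pos) - min(pos) <= cfg.cluster_window_bp:  # rule 2
            for i in combo:
                removed.setdefault(i, "cluster")
    for i, r in enumerate(records):                       # rules 3-6
        if i in removed:
            continue
        if r.qual is not None and r.qual < cfg.min_qual:
            removed[i] = "QUAL"
        elif r.qd is not None and r.qd < cfg.min_qd:
            removed[i] = "QD"
        elif r.mq is not None and r.mq < cfg.min_mq:
            removed[i] = "MQ"
        elif r.fs is not None and r.fs > cfg.max_fs:
            removed[i] = "FS"
    keys = {(records[i].chrom, records[i].pos) for i in removed}
    reasons = {(records[i].chrom, records[i].pos): why
               for i, why in removed.items()}
    return keys, reasons


class TestSummaries:
    def test_titv_reproduces_printed_population_values(self):
        # the three populations' transition/transversion count pairs
        assert SnpSummary(1_783_585, 1_392_619, 0, 0).ti_tv == 1.28
        assert SnpSummary(1_855_653, 1_451_416, 0, 0).ti_tv == 1.27
        assert SnpSummary(1_800_730, 1_407_176, 0, 0).ti_tv == 1.27

    def test_het_ratio_reproduces_printed_population_values(self):
        assert SnpSummary(0, 1, 968_651, 2_207_553).het_ratio == 30.49
        assert SnpSummary(0, 1, 965_564, 2_341_505).het_ratio == 29.19
        assert SnpSummary(0, 1, 988_916, 2_218_990).het_ratio == 30.82

    def test_truncation_not_rounding(self):
        # 1855653/1451416 = 1.27851... rounds to 1.28 but truncates to 1.27
        assert SnpSummary(1_855_653, 1_451_416, 0, 0).ti_tv == 1.27

    def test_all_het_input(self):
        records = [rec(10, gts=[1, 1, 1]), rec(20, ref="C", alt="T",
                                               gts=[1, 1, 1])]
        assert summarize_snps(records).het_ratio == 100.00

    def test_zero_transversions_reported_absent(self):
        assert summarize_snps([rec(10)]).ti_tv is None

    def test_recount_matches_bruteforce(self, small_dataset):
        ds, paths = small_dataset
        records = read_vcf(paths["vcf"])
        snps = [r for r in records if r.is_snp]
        s = summarize_snps(snps)
        het = sum(int(g == 1) for r in snps for g in r.genotypes)
        hom = sum(int(g == 2) for r in snps for g in r.genotypes)
        assert (s.n_het, s.n_hom) == (het, hom)
        assert s.n_transitions + s.n_transversions == len(snps)

    def test_indel_signs_and_spectrum(self):
        ins = rec(10, ref="A", alt="AT")
        dele = rec(50, ref="ACGT", alt="A")
        s = summarize_indels([ins, dele])
        assert (s.n_insertions, s.n_deletions) == (1, 1)
        assert s.length_spectrum == {1: 1, -3: 1}

    def test_indel_spectrum_matches_generator_truth(self, small_dataset):
        ds, paths = small_dataset
        records = read_vcf(paths["vcf"])
        s = summarize_indels([r for r in records if r.is_indel])
        assert s.length_spectrum == dict(ds.indel_length_spectrum())

    def test_snp_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_indels([rec(10)])
        with pytest.raises(ValueError):
            summarize_snps([rec(10, ref="A", alt="AT")])


class TestPerChromosome:
    def test_counts_partition_input(self):
        records = [rec(10, chrom="c1"), rec(20, chrom="c1", ref="A", alt="AT"),
                   rec(5, chrom="c2")]
        table = per_chromosome_counts(records)
        assert table["n_snps"].sum() == 2
        assert table["n_indels"].sum() == 1
        assert len(table) == 2

    def test_empty_input(self):
        assert per_chromosome_counts([]).empty


class TestVcfReading:
    def test_multiallelic_site_split(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=c1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
            "c1\t42\t.\tA\tG,T\t99\t.\t.\tGT\t0/1\t1/2\t./.\n"
        )
        records = read_vcf(vcf)
        assert len(records) == 2
        first, second = records
        assert (first.ref, first.alt) == ("A", "G")
        assert (second.ref, second.alt) == ("A", "T")
        # sample 2 is 1/2: one allele of each alt; missing stays missing
        assert list(first.genotypes) == [1, 1, -1]
        assert list(second.genotypes) == [0, 1, -1]

    def test_missing_genotypes_match_truth(self, small_dataset):
        ds, paths = small_dataset
        import json
        truth = json.loads(paths["truth"].read_text())
        records = read_vcf(paths["vcf"])
        n_missing = sum(int((r.genotypes == -1).sum()) for r in records)
        assert n_missing == truth["n_missing_genotypes"]

    def test_split_invariance_of_summaries(self, tmp_path):
        """Summaries on a multi-allelic file equal those on a pre-split one."""
        header = ("##fileformat=VCFv4.2\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="G">\n'
                  "##contig=<ID=c1,length=1000>\n"
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")
        multi = tmp_path / "multi.vcf"
        multi.write_text(header + "c1\t10\t.\tA\tG,C\t99\t.\t.\tGT\t1/2\n")
        split = tmp_path / "split.vcf"
        split.write_text(header
                         + "c1\t10\t.\tA\tG\t99\t.\t.\tGT\t0/1\n"
                         + "c1\t10\t.\tA\tC\t99\t.\t.\tGT\t0/1\n")
        s1 = summarize_snps(read_vcf(multi))
        s2 = summarize_snps(read_vcf(split))
        assert s1 == s2
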