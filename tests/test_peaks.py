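"""Consensus building, CpG counting, annotation and coverage filtering."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbdmethyl.core import CountMatrix, GenomicInterval
from mbdmethyl.peaks import (
    PeakCall,
    assign_nearest_gene,
    build_consensus,
    classify_feature,
    count_cpg,
    filter_mean_coverage,
    filter_peak_calls,
    merge_intervals,
)


def iv(s, e, chrom="chr1"):
    return GenomicInterval(chrom, s, e)


class TestFilterPeakCalls:
    def test_strict_boundaries(self):
        calls = [
            PeakCall(iv(0, 10), "s1", 5.0, 0.001),
            PeakCall(iv(0, 10), "s1", 4.0, 0.001),
            PeakCall(iv(0, 10), "s1", 5.0, 0.01),
        ]
        kept = filter_peak_calls(calls, 4.0, 0.01)
        assert kept == [calls[0]]

    def test_empty_input(self):
        assert filter_peak_calls([], 4.0, 0.01) == []

    def test_matches_brute_force(self, rng):
        calls = [
            PeakCall(iv(i * 10, i * 10 + 5), "s", float(rng.uniform(0, 10)), float(rng.uniform(1e-6, 0.05)))
            for i in range(500)
        ]
        kept = filter_peak_calls(calls, 4.0, 0.01)
        brute = [c for c in calls if c.fold_enrichment > 4.0 and c.p_value < 0.01]
        assert kept == brute


def per_base_consensus_oracle(calls_by_sample, blacklist, min_support, genome_len):
    """Independent per-base coverage oracle on a small genome (one chrom)."""
    cov = np.zeros(genome_len, dtype=int)
    for ivs in calls_by_sample.values():
        mask = np.zeros(genome_len, dtype=bool)
        for i in ivs:
            mask[i.start : i.end] = True
        cov += mask
    keep = cov >= min_support
    # extract maximal runs, then drop any run overlapping blacklist
    out = []
    pos = 0
    while pos < genome_len:
        if keep[pos]:
            start = pos
            while pos < genome_len and keep[pos]:
                pos += 1
            run = GenomicInterval("chr1", start, pos)
            if not any(run.overlaps(b) for b in blacklist):
                out.append(run)
        else:
            pos += 1
    return out


class TestBuildConsensus:
    def test_three_sample_overlap(self):
        calls = {
            "s1": [iv(100, 200)],
            "s2": [iv(150, 250)],
            "s3": [iv(180, 220)],
        }
        got = build_consensus(calls, min_support=3)
        assert [(p.interval.start, p.interval.end, p.support) for p in got] == [(180, 200, 3)]

    def test_single_sample_yields_nothing(self):
        assert build_consensus({"s1": [iv(0, 1000)]}, min_support=3) == []

    def test_two_sample_support_insufficient(self):
        calls = {"s1": [iv(100, 200)], "s2": [iv(100, 200)]}
        assert build_consensus(calls, min_support=3) == []

    def test_blacklist_removal(self):
        calls = {s: [iv(100, 200)] for s in ("s1", "s2", "s3")}
        assert build_consensus(calls, [iv(190, 195)], min_support=3) == []
        kept = build_consensus(calls, [iv(300, 400)], min_support=3)
        assert len(kept) == 1

    def test_empty_sample_never_changes_consensus(self):
        calls = {"s1": [iv(0, 50)], "s2": [iv(10, 60)], "s3": [iv(20, 70)]}
        base = build_consensus(calls, min_support=3)
        with_empty = build_consensus({**calls, "s4": []}, min_support=3)
        assert [(p.interval, p.support) for p in base] == [
            (p.interval, p.support) for p in with_empty
        ]

    def test_mixed_chromosome_naming_rejected(self):
        calls = {"s1": [iv(0, 10, "chr1")], "s2": [iv(0, 10, "1")], "s3": [iv(0, 10, "chr1")]}
        with pytest.raises(ValueError, match="naming"):
            build_consensus(calls, min_support=1)

    def test_matches_per_base_oracle(self, rng):
        for trial in range(30):
            genome_len = int(rng.integers(500, 5000))
            n_samples = int(rng.integers(1, 9))
            calls = {}
            for s in range(n_samples):
                n = int(rng.integers(0, 12))
                ivs = []
                for _ in range(n):
                    start = int(rng.integers(0, genome_len - 20))
                    length = int(rng.integers(5, 300))
                    ivs.append(iv(start, min(start + length, genome_len)))
                calls[f"s{s}"] = ivs
            blacklist = [
                iv(int(b), int(b) + 40) for b in rng.integers(0, genome_len - 40, size=2)
            ]
            min_support = int(rng.integers(1, 5))
            got = build_consensus(calls, blacklist, min_support)
            want = per_base_consensus_oracle(calls, blacklist, min_support, genome_len)
            assert [p.interval for p in got] == want, f"trial {trial}"
            # support values match the oracle's max coverage over each run
            for p in got:
                cov = np.zeros(genome_len, dtype=int)
                for ivs in calls.values():
                    mask = np.zeros(genome_len, dtype=bool)
                    for i in ivs:
                        mask[i.start : i.end] = True
                    cov += mask
                assert p.support == cov[p.interval.start : p.interval.end].max()

    def test_output_disjoint_and_sorted(self, rng):
        calls = {
            f"s{s}": [iv(int(a), int(a) + 100) for a in rng.integers(0, 3000, size=15)]
            for s in range(5)
        }
        got = build_consensus(calls, min_support=2)
        spans = [(p.interval.start, p.interval.end) for p in got]
        assert spans == sorted(spans)
        assert all(spans[i][1] < spans[i + 1][0] for i in range(len(spans) - 1))


class TestCountCpg:
    def test_known_sequences(self, toy_fasta):
        ref, seqs = toy_fasta
        assert count_cpg(iv(0, 6, "chrA"), ref) == 2  # ACGCGT
        assert count_cpg(iv(0, 200, "chrC"), ref) == 0  # CCCC...

    def test_matches_regex_oracle(self, toy_fasta, rng):
        ref, seqs = toy_fasta
        seq = seqs["chrB"].upper()
        for _ in range(100):
            start = int(rng.integers(0, 4000))
            end = start + int(rng.integers(10, 900))
            got = count_cpg(iv(start, end, "chrB"), ref)
            # oracle: CG whose C is inside [start, end), G may extend past end
            want = sum(1 for m in re.finditer("CG", seq) if start <= m.start() < end)
            assert got == want

    def test_partition_additivity(self, toy_fasta, rng):
        ref, seqs = toy_fasta
        total = count_cpg(iv(0, len(seqs["chrB"]), "chrB"), ref)
        cuts = sorted(set([0, len(seqs["chrB"])] + list(rng.integers(1, len(seqs["chrB"]), size=7))))
        parts = sum(
            count_cpg(iv(a, b, "chrB"), ref) for a, b in zip(cuts[:-1], cuts[1:])
        )
        assert parts == total

    def test_out_of_bounds_rejected(self, toy_fasta):
        ref, seqs = toy_fasta
        with pytest.raises(ValueError, match="beyond contig"):
            count_cpg(iv(0, len(seqs["chrA"]) + 10, "chrA"), ref)


class TestClassifyFeature:
    def test_promoter_beats_exon(self, gene_models):
        # overlaps G1's TSS+-1kb and its first exon
        feature, _ = classify_feature(iv(9_500, 10_400), gene_models)
        assert feature == "promoter"

    def test_intron(self, gene_models):
        feature, _ = classify_feature(iv(12_000, 12_100), gene_models)
        assert feature == "intron"

    def test_strand_aware_tss_for_minus_gene(self, gene_models):
        # G2 is on -, so its TSS sits at the genebody end
        feature, _ = classify_feature(iv(60_500, 60_700), gene_models)
        assert feature == "promoter"

    def test_shore_within_1kb_downstream(self, gene_models):
        islands = [iv(30_000, 31_000)]
        _, status = classify_feature(iv(31_500, 31_600), gene_models, islands)
        assert status == "shore"
        _, status = classify_feature(iv(30_200, 30_300), gene_models, islands)
        assert status == "cpg_island"
        _, status = classify_feature(iv(40_000, 40_100), gene_models, islands)
        assert status == "open_sea"

    def test_gene_free_chromosome(self, gene_models):
        feature, status = classify_feature(iv(0, 100, "chr9"), gene_models, [])
        assert (feature, status) == ("intergenic", "open_sea")


class TestNearestGene:
    def test_overlap_gives_distance_zero(self, gene_models):
        assert assign_nearest_gene(iv(15_000, 15_100), gene_models) == ("G1", 0)

    def test_window_boundary(self, gene_models):
        only = [gene_models[0]]  # genebody ends at 20,000
        gene, d = assign_nearest_gene(iv(120_000, 120_010), only, window=100_000)
        assert (gene, d) == ("G1", 100_000)
        gene, d = assign_nearest_gene(iv(120_001, 120_011), only, window=100_000)
        assert gene == "intergenic" and d is None

    def test_matches_brute_force(self, gene_models, rng):
        def brute(region):
            best = None
            for gm in gene_models:
                gb = gm.genebody
                if gb.chrom != region.chrom:
                    continue
                if region.overlaps(gb):
                    d = 0
                elif gb.end <= region.start:
                    d = region.start - gb.end
                else:
                    d = gb.start - region.end
                if d <= 100_000 and (best is None or (d, gm.gene_id) < best):
                    best = (d, gm.gene_id)
            return ("intergenic", None) if best is None else (best[1], best[0])

        for _ in range(200):
            start = int(rng.integers(0, 200_000))
            region = iv(start, start + int(rng.integers(10, 5000)))
            assert assign_nearest_gene(region, gene_models) == brute(region)


class TestCoverageFilter:
    def _matrix(self, rows):
        regions = [iv(100 * i, 100 * i + 50) for i in range(len(rows))]
        return CountMatrix(regions, [f"s{j}" for j in range(len(rows[0]))], np.array(rows))

    def test_strict_boundary(self):
        m = self._matrix([[10, 10, 10], [11, 11, 11]])
        kept = filter_mean_coverage(m, 10.0)
        assert kept.region_ids == [m.region_ids[1]]

    def test_matches_brute_force(self, rng):
        counts = rng.integers(0, 40, size=(500, 10))
        m = self._matrix(counts.tolist())
        kept = filter_mean_coverage(m, 10.0)
        want = [m.region_ids[j] for j in range(500) if counts[j].mean() > 10.0]
        assert kept.region_ids == want


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.lists(st.tuples(st.integers(0, 900), st.integers(1, 150)), max_size=8),
        min_size=1,
        max_size=6,
    ),
    st.integers(1, 4),
)
def test_consensus_equals_oracle_property(sample_calls, min_support):
    """Sweep-line consensus equals per-base counting on arbitrary inputs."""
    calls = {
        f"s{k}": [GenomicInterval("chr1", a, min(a + l, 1000)) for a, l in ivs]
        for k, ivs in enumerate(sample_calls)
    }
    got = build_consensus(calls, min_support=min_support)
    want = per_base_consensus_oracle(calls, [], min_support, 1000)
    assert [p.interval for p in got] == want


def test_merge_intervals_is_union(rng):
    ivs = [iv(int(a), int(a) + int(l)) for a, l in zip(rng.integers(0, 500, 40), rng.integers(1, 80, 40))]
    merged = merge_intervals(ivs)
    mask = np.zeros(600, dtype=bool)
    for i in ivs:
        mask[i.start : i.end] = True
    covered = int(mask.sum())
    assert sum(len(m) for m in merged) == covered
    spans = [(m.start, m.end) for m in merged]
    assert spans == sorted(spans)
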