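"""Consensus methylated-region construction and annotation.

Per-sample MBD-capture peak calls (from an upstream caller) are filtered on
fold enrichment and p-value, fragmented at the union of all breakpoints,
scored by the number of distinct supporting samples, merged, screened
against a blacklist, and annotated with CpG counts, genomic feature class,
CpG-island status and nearest gene.  All thresholds printed as strict
inequalities are implemented strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import CountMatrix, GenomicInterval


@dataclass(frozen=True)
class PeakCall:
    """One peak call in one sample."""

    interval: GenomicInterval
    sample_id: str
    fold_enrichment: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be >= 0")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value must be in (0, 1]")


@dataclass
class GeneModel:
    """A gene body with strand-aware TSS and exon blocks."""

    gene_id: str
    genebody: GenomicInterval
    strand: str
    exons: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for e in self.exons:
            if e.chrom != self.genebody.chrom or e.start < self.genebody.start or e.end > self.genebody.end:
                raise ValueError(f"exon {e} outside genebody of {self.gene_id}")

    @property
    def tss(self) -> int:
        return self.genebody.start if self.strand == "+" else self.genebody.end - 1


@dataclass
class ConsensusPeak:
    """A consensus methylated region with support and annotation."""

    interval: GenomicInterval
    support: int
    cpg_count: Optional[int] = None
    feature: Optional[str] = None
    island_status: Optional[str] = None
    nearest_gene: Optional[str] = None
    distance_to_gene: Optional[int] = None


def filter_peak_calls(
    calls: Iterable[PeakCall], fe_min: float = 4.0, p_max: float = 0.01
) -> List[PeakCall]:
    """Retain calls with fold enrichment strictly above ``fe_min`` and
    p-value strictly below ``p_max``."""
    if fe_min < 0 or p_max <= 0:
        raise ValueError("thresholds must be positive")
    return [c for c in calls if c.fold_enrichment > fe_min and c.p_value < p_max]


def merge_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    """Union of intervals: overlapping or book-ended intervals are merged."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: (x.start, x.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def _check_naming(chroms: Iterable[str]) -> None:
    names = set(chroms)
    prefixed = {c for c in names if c.startswith("chr")}
    if prefixed and prefixed != names:
        raise ValueError(f"mixed chromosome naming schemes: {sorted(names)[:6]}")


def build_consensus(
    calls_by_sample: Dict[str, Sequence[GenomicInterval]],
    blacklist: Sequence[GenomicInterval] = (),
    min_support: int = 3,
) -> List[ConsensusPeak]:
    """Multi-sample interval intersection with a support rule.

    The genome is fragmented at the union of all interval breakpoints; a
    fragment's support is the number of distinct samples covering it (each
    sample's intervals are merged first, so stacked calls within one sample
    count once).  Fragments with support >= ``min_support`` are kept,
    adjacent kept fragments merged (support = max over parts), and merged
    regions overlapping the blacklist by >= 1 bp removed.
    """
    per_sample = {s: merge_intervals(ivs) for s, ivs in calls_by_sample.items() if ivs}
    all_chroms = [iv.chrom for ivs in per_sample.values() for iv in ivs]
    _check_naming(all_chroms + [b.chrom for b in blacklist])

    # sweep-line per chromosome: +1 at each sample-interval start, -1 at end
    events: Dict[str, List[Tuple[int, int]]] = {}
    for ivs in per_sample.values():
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, 1))
            events[iv.chrom].append((iv.end, -1))

    kept: List[ConsensusPeak] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        support = 0
        prev_pos = None
        fragments: List[Tuple[int, int, int]] = []  # start, end, support
        i = 0
        while i < len(ev):
            pos = ev[i][0]
            if prev_pos is not None and support > 0 and pos > prev_pos:
                fragments.append((prev_pos, pos, support))
            while i < len(ev) and ev[i][0] == pos:
                support += ev[i][1]
                i += 1
            prev_pos = pos
        # keep qualifying fragments, merge adjacency with max support
        run: Optional[List[int]] = None
        merged: List[Tuple[int, int, int]] = []
        for s, e, sup in fragments:
            if sup < min_support:
                continue
            if run is not None and s == run[1]:
                run[1] = e
                run[2] = max(run[2], sup)
            else:
                if run is not None:
                    merged.append(tuple(run))
                run = [s, e, sup]
        if run is not None:
            merged.append(tuple(run))
        for s, e, sup in merged:
            iv = GenomicInterval(chrom, s, e)
            if any(iv.overlaps(b) for b in blacklist):
                continue
            kept.append(ConsensusPeak(interval=iv, support=sup))
    return kept


def count_cpg(interval: GenomicInterval, reference) -> int:
    """Count CG dinucleotides assigned to the interval by C position.

    A CG is counted when its C lies in ``[start, end)``; the G may sit just
    beyond ``end`` (read from the reference), so a CG straddling a window
    boundary is counted exactly once in any partition into half-open
    windows.  Case-insensitive; ambiguous bases never match.

    ``reference`` is a mapping of contig name to sequence-like object
    supporting slicing (a ``pyfaidx.Fasta`` works directly).
    """
    contig = reference[interval.chrom]
    contig_len = len(contig)
    if interval.end > contig_len:
        raise ValueError(
            f"interval {interval.region_id} beyond contig end ({contig_len})"
        )
    stop = min(interval.end + 1, contig_len)
    seq = str(contig[interval.start : stop]).upper()
    n = 0
    limit = interval.end - interval.start  # C must lie within the interval
    pos = seq.find("CG")
    while pos != -1 and pos < limit:
        n += 1
        pos = seq.find("CG", pos + 1)
    # find may return a hit at limit or beyond; loop exits then
    return n


def classify_feature(
    interval: GenomicInterval,
    gene_models: Sequence[GeneModel],
    cpg_islands: Sequence[GenomicInterval] = (),
    promoter_flank: int = 1000,
    shore_flank: int = 1000,
) -> Tuple[str, str]:
    """Assign (feature, island_status) to a region.

    Feature precedence promoter > exon > intron > intergenic by any
    overlap; the promoter is TSS +/- ``promoter_flank`` (strand-aware TSS).
    Island status: cpg_island on overlap, shore within ``shore_flank`` of
    an island, else open_sea.  The two labels are independent.
    """
    feature = "intergenic"
    best = 4
    for gm in gene_models:
        if gm.genebody.chrom != interval.chrom:
            continue
        prom_start = max(0, gm.tss - promoter_flank)
        prom = GenomicInterval(gm.genebody.chrom, prom_start, gm.tss + promoter_flank + 1)
        if interval.overlaps(prom):
            rank = 1
        elif any(interval.overlaps(e) for e in gm.exons):
            rank = 2
        elif interval.overlaps(gm.genebody):
            rank = 3
        else:
            continue
        if rank < best:
            best = rank
    feature = {1: "promoter", 2: "exon", 3: "intron", 4: "intergenic"}[best]

    island_status = "open_sea"
    for isl in cpg_islands:
        if isl.chrom != interval.chrom:
            continue
        if interval.overlaps(isl):
            island_status = "cpg_island"
            break
        flank = GenomicInterval(
            isl.chrom, max(0, isl.start - shore_flank), isl.end + shore_flank
        )
        if interval.overlaps(flank):
            island_status = "shore"
    return feature, island_status


def assign_nearest_gene(
    interval: GenomicInterval,
    gene_models: Sequence[GeneModel],
    window: int = 100_000,
) -> Tuple[str, Optional[int]]:
    """Nearest-genebody assignment within ``window`` bp, else "intergenic".

    Overlap means distance 0.  Ties broken by smallest gap then
    lexicographic gene_id.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    best: Optional[Tuple[int, str]] = None
    for gm in gene_models:
        gb = gm.genebody
        if gb.chrom != interval.chrom:
            continue
        if interval.overlaps(gb):
            d = 0
        elif gb.end <= interval.start:
            d = interval.start - gb.end
        else:
            d = gb.start - interval.end
        if d > window:
            continue
        cand = (d, gm.gene_id)
        if best is None or cand < best:
            best = cand
    if best is None:
        return "intergenic", None
    return best[1], best[0]


def annotate_consensus(
    peaks: Sequence[ConsensusPeak],
    reference=None,
    gene_models: Sequence[GeneModel] = (),
    cpg_islands: Sequence[GenomicInterval] = (),
    window: int = 100_000,
) -> List[ConsensusPeak]:
    """Fill cpg_count, feature, island_status and nearest gene in place."""
    for p in peaks:
        if reference is not None:
            p.cpg_count = count_cpg(p.interval, reference)
        p.feature, p.island_status = classify_feature(p.interval, gene_models, cpg_islands)
        p.nearest_gene, p.distance_to_gene = assign_nearest_gene(p.interval, gene_models, window)
    return list(peaks)


def filter_mean_coverage(matrix: CountMatrix, threshold: float = 10.0) -> CountMatrix:
    """Keep regions whose mean methyl-capture count is strictly > threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    means = matrix.methyl_counts.mean(axis=1)
    return matrix.subset_regions(means > threshold)
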