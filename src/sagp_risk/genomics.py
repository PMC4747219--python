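"""Strand-aware promoter windows, ChIP-peak overlap tests and CNV summaries.

Proximal promoters are the -450/+50 bp window around the strand-aware TSS
(0-based half-open coordinates; for a minus-strand gene the TSS is the
interval end). A promoter "hits" a ChIP binding region (CBR) when they share
at least 1 bp. For divergent gene pairs whose promoter windows merge into a
single bidirectional promoter, an optional doubling rule counts one shared
overlapping CBR as two hits, reflecting a factor driving transcription in
both directions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .data_model import GenomicInterval


@dataclass
class PromoterWindow:
    gene_id: str
    interval: GenomicInterval
    tss_pos: int


@dataclass
class CnvGeneValue:
    gene_id: str
    mean_cnv: float
    n_snps: int


def promoter_window(
    gene: GenomicInterval,
    upstream: int = 450,
    downstream: int = 50,
    gene_id: str = "",
) -> PromoterWindow:
    """Proximal promoter around the strand-aware TSS, clipped at position 0."""
    if gene.strand == "+":
        tss = gene.start
        start, end = tss - upstream, tss + downstream
    else:
        tss = gene.end
        start, end = tss - downstream, tss + upstream
    start = max(start, 0)
    return PromoterWindow(
        gene_id=gene_id,
        interval=GenomicInterval(gene.chrom, start, end, gene.strand),
        tss_pos=tss,
    )


def _peak_trees(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end)
    return trees


def _hits(window: GenomicInterval, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(window.chrom)
    return bool(tree is not None and tree.overlap(window.start, window.end))


def intersect_replicate_peaks(
    replicates: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Higher-confidence CBRs: first-replicate peaks overlapping all replicates.

    A peak from the first replicate is kept (on its own coordinates) when it
    shares at least 1 bp with some peak in every other replicate.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    if len(replicates) == 1:
        return list(replicates[0])
    trees = [_peak_trees(r) for r in replicates[1:]]
    return [
        p for p in replicates[0] if all(_hits(p, t) for t in trees)
    ]


def cbr_overlap_test(
    promoters_a: Sequence[PromoterWindow],
    promoters_b: Sequence[PromoterWindow],
    peaks: Sequence[GenomicInterval],
    divergent_pairs_in_a: Sequence[tuple[str, str]] = (),
    doubling: bool = False,
) -> tuple[np.ndarray, float, float]:
    """Fisher's exact comparison of CBR-overlap frequencies between two sets.

    Divergent pairs in set A whose two promoter windows overlap each other
    are merged into one bidirectional-promoter unit; with ``doubling`` a hit
    on such a unit counts as 2 hits (the miss side stays one unit). Returns
    the 2x2 table [[hitsA, missA], [hitsB, missB]], the sample odds ratio and
    the two-sided Fisher p.
    """
    if not promoters_a or not promoters_b:
        raise ValueError("promoter sets must be non-empty")
    trees = _peak_trees(peaks)
    by_gene = {w.gene_id: w for w in promoters_a}
    merged: dict[str, tuple[GenomicInterval, bool]] = {}
    consumed: set[str] = set()
    for ga, gb in divergent_pairs_in_a:
        wa, wb = by_gene.get(ga), by_gene.get(gb)
        if wa is None or wb is None or not wa.interval.overlaps(wb.interval):
            continue
        union = GenomicInterval(
            wa.interval.chrom,
            min(wa.interval.start, wb.interval.start),
            max(wa.interval.end, wb.interval.end),
        )
        merged[f"{ga}|{gb}"] = (union, True)
        consumed.update((ga, gb))
    units: list[tuple[GenomicInterval, bool]] = list(merged.values())
    units += [
        (w.interval, False) for w in promoters_a if w.gene_id not in consumed
    ]

    hits_a = miss_a = 0
    for window, bidirectional in units:
        if _hits(window, trees):
            hits_a += 2 if (doubling and bidirectional) else 1
        else:
            miss_a += 1
    hits_b = sum(1 for w in promoters_b if _hits(w.interval, trees))
    miss_b = len(promoters_b) - hits_b

    table = np.array([[hits_a, miss_a], [hits_b, miss_b]], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (hits_a * miss_b) / (miss_a * hits_b) if miss_a * hits_b else np.inf
    if hits_a == 0 and hits_b == 0:
        return table, np.nan, 1.0
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return table, float(odds), p


def cnv_gene_value(
    gene: GenomicInterval,
    snps: Sequence[tuple[int, float]],
    gene_id: str = "",
) -> CnvGeneValue:
    """Mean copy-number over SNPs assigned to a gene.

    Assigned SNPs are those inside the gene interval plus the single nearest
    SNP strictly upstream and strictly downstream of it (when they exist).
    """
    if not snps:
        raise ValueError(f"gene {gene_id!r}: no SNPs on chromosome")
    positions = np.array([p for p, _ in snps])
    values = np.array([v for _, v in snps], dtype=float)
    inside = (positions >= gene.start) & (positions < gene.end)
    chosen = list(values[inside])
    upstream = positions < gene.start
    if upstream.any():
        chosen.append(values[upstream][np.argmax(positions[upstream])])
    downstream = positions >= gene.end
    if downstream.any():
        chosen.append(values[downstream][np.argmin(positions[downstream])])
    return CnvGeneValue(
        gene_id=gene_id, mean_cnv=float(np.mean(chosen)), n_snps=len(chosen)
    )


def cnv_matched_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon matched-pairs signed-rank test on per-gene CNV values.

    Exact null distribution for n <= 25 non-zero differences (tie-free),
    normal approximation otherwise; zero differences are dropped. All-zero
    differences return (0, 1): no evidence of any shift.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matched value vectors must have equal length")
    if len(a) < 6:
        raise ValueError("need at least 6 matched pairs")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
    return float(res.statistic), float(res.pvalue)
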