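"""Independent oracles shared across tests.

The brute-force query deliberately avoids the interval index and recomputes
the edge gap with a case split rather than the max() expression the package
uses, so index and arithmetic are both cross-checked.
"""

from __future__ import annotations

from hervprox.locus_store import GenomicInterval, HervLocus, QueryParams


def edge_gap(region: GenomicInterval, other: GenomicInterval) -> int:
    if other.start >= region.end:
        return other.start - region.end
    if region.start >= other.end:
        return region.start - other.end
    return 0


def brute_force_query(
    loci: list[HervLocus], region: GenomicInterval, params: QueryParams
) -> list[tuple[HervLocus, int]]:
    hits = []
    for locus in loci:
        if locus.interval.chrom != region.chrom:
            continue
        g = edge_gap(region, locus.interval)
        if g > params.max_distance:
            continue
        if locus.evalue > params.max_evalue:
            continue
        n = locus.interval.end - locus.interval.start
        if params.min_length is not None and n < params.min_length:
            continue
        if params.max_length is not None and n > params.max_length:
            continue
        hits.append((locus, g))
    return hits


def hit_key(hit: tuple[HervLocus, int]):
    locus, g = hit
    iv = locus.interval
    return (g, iv.chrom, iv.start, iv.end, iv.strand, locus.evalue, locus.source_id)
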