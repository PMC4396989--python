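"""Poly(A)-site preprocessing: clustering, low-read filtering, merging.

Three operations prepare raw cleavage evidence for testing:

1. cluster cleavage positions lying within a window (default 24 nt) into
   poly(A) sites — single-linkage along the chromosome, so any two output
   clusters are separated by more than the window;
2. drop sites supported by fewer than ``min_reads`` reads combined across
   the two samples (default 5), which removes outlier data points;
3. merge closely apposed sites (3'-UTR length difference within
   ``max_gap`` nt, typically 40 or 80) — a robustness step against
   clustering artifacts that split a single poly(A) site in two.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io import CleavageSiteRecord, TandemGene


@dataclass(frozen=True)
class SiteCluster:
    """A poly(A) site formed from clustered cleavage positions.

    ``position`` is the representative member: the one with the largest
    combined read count, ties resolved toward the most distal member in
    transcript orientation (largest coordinate on '+', smallest on '-').
    """

    chrom: str
    strand: str
    position: int
    count_sample1: int
    count_sample2: int
    members: tuple[int, ...]


def cluster_cleavage_sites(
    records: list[CleavageSiteRecord], window: int = 24
) -> list[SiteCluster]:
    """Single-linkage clustering of cleavage positions into poly(A) sites.

    Positions are sorted ascending; a new cluster starts whenever the gap to
    the previous position exceeds ``window`` nt. Counts are summed per
    sample over members. All records must share one (chrom, strand).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not records:
        return []
    keys = {(r.chrom, r.strand) for r in records}
    if len(keys) > 1:
        raise ValueError(
            f"cluster_cleavage_sites expects one (chrom, strand) per call, got {sorted(keys)}"
        )
    chrom, strand = next(iter(keys))
    recs = sorted(records, key=lambda r: r.position)
    clusters: list[SiteCluster] = []
    group: list[CleavageSiteRecord] = [recs[0]]
    for r in recs[1:]:
        if r.position - group[-1].position <= window:
            group.append(r)
        else:
            clusters.append(_finish_cluster(chrom, strand, group))
            group = [r]
    clusters.append(_finish_cluster(chrom, strand, group))
    return clusters


def _finish_cluster(chrom: str, strand: str, group: list[CleavageSiteRecord]) -> SiteCluster:
    c1 = sum(r.count_sample1 for r in group)
    c2 = sum(r.count_sample2 for r in group)
    # representative: max combined count; ties -> most distal in transcript
    # orientation (downstream-most cleavage position)
    distal_sign = 1 if strand == "+" else -1
    rep = max(group, key=lambda r: (r.count_sample1 + r.count_sample2,
                                    distal_sign * r.position))
    return SiteCluster(
        chrom=chrom,
        strand=strand,
        position=rep.position,
        count_sample1=c1,
        count_sample2=c2,
        members=tuple(r.position for r in group),
    )


def filter_low_read_sites(gene: TandemGene, min_reads: int = 5) -> TandemGene:
    """Drop sites with combined two-sample support below ``min_reads``.

    The comparison is strict (< min_reads), so a site with exactly
    ``min_reads`` reads is kept. Site order is preserved. The returned gene
    may have fewer than two sites, in which case ``is_testable`` is False.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = [
        j
        for j in range(gene.n_sites)
        if gene.counts_sample1[j] + gene.counts_sample2[j] >= min_reads
    ]
    if len(keep) == gene.n_sites:
        return gene
    return replace(
        gene,
        utr_lengths=tuple(gene.utr_lengths[j] for j in keep),
        counts_sample1=tuple(gene.counts_sample1[j] for j in keep),
        counts_sample2=tuple(gene.counts_sample2[j] for j in keep),
        site_positions=None if gene.site_positions is None
        else tuple(gene.site_positions[j] for j in keep),
    )


def merge_adjacent_sites(gene: TandemGene, max_gap: int = 40) -> TandemGene:
    """Merge closely apposed sites whose 3'-UTR lengths differ by <= max_gap nt.

    Merging is greedy left-to-right on the original lengths: a run extends
    while each consecutive gap is within ``max_gap`` (runs can therefore
    chain). Merged counts are summed per sample; the merged 3'-UTR length is
    the count-weighted mean of member lengths rounded to the nearest
    integer (plain mean if the run carries no reads). Total read counts are
    conserved, and all consecutive gaps in the output exceed ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if gene.n_sites <= 1:
        return gene
    runs: list[list[int]] = [[0]]
    for j in range(1, gene.n_sites):
        if gene.utr_lengths[j] - gene.utr_lengths[runs[-1][-1]] <= max_gap:
            runs[-1].append(j)
        else:
            runs.append([j])
    if all(len(run) == 1 for run in runs):
        return gene
    lengths, c1s, c2s = [], [], []
    for run in runs:
        w = [gene.counts_sample1[j] + gene.counts_sample2[j] for j in run]
        ls = [gene.utr_lengths[j] for j in run]
        if sum(w) > 0:
            merged_len = round(sum(wi * li for wi, li in zip(w, ls)) / sum(w))
        else:
            merged_len = round(sum(ls) / len(ls))
        lengths.append(merged_len)
        c1s.append(sum(gene.counts_sample1[j] for j in run))
        c2s.append(sum(gene.counts_sample2[j] for j in run))
    return replace(
        gene,
        utr_lengths=tuple(lengths),
        counts_sample1=tuple(c1s),
        counts_sample2=tuple(c2s),
        site_positions=None,
    )
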