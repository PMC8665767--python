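"""Isoform clustering, binning, masking, collapsing and the design matrix.

Mature isoforms are grouped into maximal non-overlapping, strand-specific
clusters (roughly genes; two genes overlapping on the same strand share a
cluster).  Each cluster is tiled with fixed-width bins anchored at its
5'-most coordinate, oriented 5' -> 3' along transcription.  A configurable
number of bins is masked at the start and end of each isoform to avoid
biases from promoter-proximal pausing and termination deceleration.
Mature isoforms that share both their (post-mask) start and end bins are
collapsed to a single distinguishable pre-RNA isoform, and the m x n
design matrix X records which isoform spans which bin: x[i, j] = 1 when
pre-RNA isoform j spans unmasked bin i, 0 otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome_io import CoverageTrack, GenomicInterval, MatureIsoform


@dataclass
class PreRNAIsoform:
    """A distinguishable unspliced transcription unit (unique TSS/PAS bin pair)."""

    id: str
    gene_id: str
    start_bin: int          # 5'-most spanned bin (transcription orientation)
    end_bin: int            # 3'-most spanned bin, inclusive
    unmasked_start: int     # first unmasked bin
    unmasked_end: int       # last unmasked bin, inclusive
    member_transcript_ids: tuple[str, ...]
    interval: GenomicInterval
    tss: int                # genomic coordinate of representative TSS
    pas: int

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class IsoformCluster:
    """A strand-specific group of overlapping isoforms with its bin grid."""

    chrom: str
    strand: str
    start: int
    end: int
    mature: list[MatureIsoform]
    bin_size: int = 0
    n_bins: int = 0
    mask5_bins: int = 0
    mask3_bins: int = 0
    isoforms: list[PreRNAIsoform] = field(default_factory=list)
    X: np.ndarray | None = None
    Y: np.ndarray | None = None

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def gene_ids(self) -> list[str]:
        return sorted({m.gene_id for m in self.mature})

    # --- bin geometry (bins indexed 5'->3' along transcription) -------

    def bin_of(self, pos: int) -> int:
        if self.strand == "+":
            return (pos - self.start) // self.bin_size
        return (self.end - 1 - pos) // self.bin_size

    def bin_interval(self, i: int) -> tuple[int, int]:
        """Genomic [start, end) of bin ``i``; edge bins may be truncated."""
        if self.strand == "+":
            s = self.start + i * self.bin_size
            return s, min(s + self.bin_size, self.end)
        e = self.end - i * self.bin_size
        return max(e - self.bin_size, self.start), e

    def bin_counts(self, coverage: CoverageTrack) -> np.ndarray:
        """Sense-strand read counts per bin, in transcription order."""
        vals = coverage.get(self.chrom, self.start, self.end, self.strand)
        pad = self.n_bins * self.bin_size - len(vals)
        if pad > 0:
            vals = np.concatenate([vals, np.zeros(pad)])
        if self.strand == "-":
            vals = vals[::-1]
        return vals.reshape(self.n_bins, self.bin_size).sum(axis=1)


def cluster_isoforms(isoforms: list[MatureIsoform]) -> list[IsoformCluster]:
    """Group isoforms by transitive same-strand genomic overlap."""
    clusters: list[IsoformCluster] = []
    by_key: dict[tuple[str, str], list[MatureIsoform]] = {}
    for iso in isoforms:
        by_key.setdefault((iso.chrom, iso.strand), []).append(iso)
    for (chrom, strand), members in sorted(by_key.items()):
        members.sort(key=lambda m: (m.interval.start, m.interval.end, m.transcript_id))
        current: list[MatureIsoform] = []
        cur_end = -1
        for iso in members:
            if current and iso.interval.start >= cur_end:
                clusters.append(
                    IsoformCluster(chrom, strand, current[0].interval.start, cur_end, current)
                )
                current, cur_end = [], -1
            current.append(iso)
            cur_end = max(cur_end, iso.interval.end)
        if current:
            clusters.append(
                IsoformCluster(chrom, strand, current[0].interval.start, cur_end, current)
            )
    return clusters


def bin_and_mask(
    cluster: IsoformCluster,
    bin_size: int = 250,
    mask5_bins: int = 1,
    mask3_bins: int = 4,
) -> IsoformCluster:
    """Tile the cluster with bins and record mask parameters."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    cluster.bin_size = bin_size
    cluster.mask5_bins = mask5_bins
    cluster.mask3_bins = mask3_bins
    cluster.n_bins = -((cluster.start - cluster.end) // bin_size)  # ceil division
    return cluster


def _masked_range(cluster: IsoformCluster, iso: MatureIsoform) -> tuple[int, int, int, int]:
    """(start_bin, end_bin, unmasked_start, unmasked_end) for one isoform."""
    b5 = cluster.bin_of(iso.tss)
    b3 = cluster.bin_of(iso.pas)
    lo, hi = b5 + cluster.mask5_bins, b3 - cluster.mask3_bins
    if lo > hi:
        warnings.warn(
            f"isoform {iso.transcript_id} shorter than its masks; "
            "keeping its single central bin unmasked"
        )
        mid = (b5 + b3) // 2
        lo = hi = mid
    return b5, b3, lo, hi


def collapse_isoforms(cluster: IsoformCluster) -> IsoformCluster:
    """Merge mature isoforms sharing post-mask start and end bins."""
    if cluster.bin_size <= 0:
        raise ValueError("bin_and_mask must be applied before collapsing")
    groups: dict[tuple, list[tuple[MatureIsoform, tuple]] ] = {}
    for iso in cluster.mature:
        key_bins = _masked_range(cluster, iso)
        groups.setdefault((iso.gene_id, key_bins[2], key_bins[3]), []).append((iso, key_bins))
    out = []
    for (gene_id, lo, hi), members in sorted(groups.items()):
        members.sort(key=lambda t: (-t[0].length, t[0].transcript_id))
        rep, (b5, b3, _, _) = members[0]
        out.append(
            PreRNAIsoform(
                id=f"{gene_id}:{lo}-{hi}",
                gene_id=gene_id,
                start_bin=b5,
                end_bin=b3,
                unmasked_start=lo,
                unmasked_end=hi,
                member_transcript_ids=tuple(sorted(m.transcript_id for m, _ in members)),
                interval=rep.interval,
                tss=rep.tss,
                pas=rep.pas,
            )
        )
    out.sort(key=lambda p: (p.unmasked_start, p.unmasked_end, p.id))
    cluster.isoforms = out
    return cluster


def build_design_matrix(cluster: IsoformCluster) -> np.ndarray:
    """m x n binary occupancy matrix; masked bins are zero even when spanned."""
    n = len(cluster.isoforms)
    X = np.zeros((cluster.n_bins, n), dtype=np.float64)
    for j, iso in enumerate(cluster.isoforms):
        X[iso.unmasked_start : iso.unmasked_end + 1, j] = 1.0
    cluster.X = X
    return X


def prepare_cluster(
    cluster: IsoformCluster,
    coverage: CoverageTrack | None = None,
    bin_size: int = 250,
    mask5_bins: int = 1,
    mask3_bins: int = 4,
) -> IsoformCluster:
    """bin_and_mask -> collapse -> design matrix (and bin counts if given)."""
    bin_and_mask(cluster, bin_size, mask5_bins, mask3_bins)
    collapse_isoforms(cluster)
    build_design_matrix(cluster)
    if coverage is not None:
        cluster.Y = cluster.bin_counts(coverage)
    return cluster


# ---------------------------------------------------------------------------
# TSS grouping and internal-TSS classification


def group_tss_within(isoforms: list[MatureIsoform], distance: int = 1000) -> list[MatureIsoform]:
    """Single-linkage group isoforms of one gene by TSS proximity.

    TSSs closer than ``distance`` are chained into one group; the longest
    isoform in each group (ties: lexicographically smallest transcript_id)
    represents it.
    """
    if not isoforms:
        return []
    ordered = sorted(isoforms, key=lambda m: (m.tss, m.transcript_id))
    groups: list[list[MatureIsoform]] = [[ordered[0]]]
    for iso in ordered[1:]:
        if iso.tss - groups[-1][-1].tss < distance:
            groups[-1].append(iso)
        else:
            groups.append([iso])
    reps = [
        min(g, key=lambda m: (-m.length, m.transcript_id))
        for g in groups
    ]
    return sorted(reps, key=lambda m: (m.tss, m.transcript_id))


def classify_internal_tss(
    gene_isoforms: list[MatureIsoform | PreRNAIsoform],
    dominant_tss: int,
    threshold: int = 1000,
) -> str:
    """'internal' when the dominant TSS is >= threshold bp downstream of the
    gene's 5'-most annotated TSS, else 'five_prime'."""
    strand = gene_isoforms[0].strand
    if strand == "+":
        five_most = min(iso.tss for iso in gene_isoforms)
        dist = dominant_tss - five_most
    else:
        five_most = max(iso.tss for iso in gene_isoforms)
        dist = five_most - dominant_tss
    return "internal" if dist >= threshold else "five_prime"
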