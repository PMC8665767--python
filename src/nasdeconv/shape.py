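"""Canonical shape-profile estimation and design-matrix adjustment.

Nascent RNA-seq read density along a transcription unit is typically
'U'-shaped even after pause and termination peaks are masked: elevated
near both ends, depressed through the gene body.  The profile is derived
empirically from reference isoforms that are long, well expressed and the
sole source of signal in their region.  Each reference is rescaled onto a
canonical [0, 1] axis (the first 3 kb to [0, 0.2], the last 3 kb to
[0.8, 1], the remainder stretched over (0.2, 0.8)), densities are pooled,
loess-smoothed, and scaled so the median over the interval is one.  The
fitted profile then replaces the 1-entries of each cluster's design
matrix with the relative density at the corresponding canonical position.
"""

from __future__ import annotations

import warnings

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .clusters import IsoformCluster, PreRNAIsoform
from .genome_io import CoverageTrack

EDGE_BP = 3000          # genomic extent mapped to each canonical edge segment
SHORT_ISOFORM_BP = 6000  # at or below this, the 0.75l/0.25l rule applies
PROFILE_FLOOR = 0.05
GRID_POINTS = 1000


class ShapeProfile:
    """Relative read density over the canonical [0, 1] axis, median 1."""

    def __init__(self, grid: np.ndarray, density: np.ndarray, span: float = 0.1):
        density = np.asarray(density, dtype=np.float64)
        if np.any(density <= 0):
            raise ValueError("profile densities must be positive")
        self.grid = np.asarray(grid, dtype=np.float64)
        self.density = density
        self.span = span

    @classmethod
    def flat(cls) -> "ShapeProfile":
        grid = np.linspace(0.0, 1.0, GRID_POINTS)
        return cls(grid, np.ones(GRID_POINTS))

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.density == 1.0))

    def __call__(self, u) -> np.ndarray:
        return np.interp(u, self.grid, self.density)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("u\tdensity\n")
            for u, d in zip(self.grid, self.density):
                fh.write(f"{u:.6f}\t{d:.6f}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "ShapeProfile":
        data = np.loadtxt(path, skiprows=1)
        return cls(data[:, 0], data[:, 1])


def map_to_canonical(offset_bp: float, l: int) -> float:
    """Map a base-pair offset from the TSS of an isoform of length ``l``
    onto the canonical [0, 1] axis."""
    if not (0 <= offset_bp < l):
        raise ValueError(f"offset {offset_bp} outside [0, {l})")
    if l > SHORT_ISOFORM_BP:
        if offset_bp < EDGE_BP:
            return 0.2 * offset_bp / EDGE_BP
        if offset_bp >= l - EDGE_BP:
            return 0.8 + 0.2 * (offset_bp - (l - EDGE_BP)) / EDGE_BP
        return 0.2 + 0.6 * (offset_bp - EDGE_BP) / (l - 2 * EDGE_BP)
    # short isoforms: first 0.75 l -> [0, 0.2], last 0.25 l -> [0.8, 1]
    cut = 0.75 * l
    if offset_bp < cut:
        return 0.2 * offset_bp / cut
    return 0.8 + 0.2 * (offset_bp - cut) / (0.25 * l)


def select_reference_isoforms(
    clusters: list[IsoformCluster],
    coverage: CoverageTrack,
    min_length: int = 10000,
    min_mean_density: float | None = None,
    isolation_bp: int = 5000,
) -> list[tuple[IsoformCluster, PreRNAIsoform]]:
    """Pick isoforms that are long, robustly expressed and the sole signal
    source in their region.

    Candidates must (i) be at least ``min_length`` bp, (ii) be the only
    isoform of their cluster, (iii) lie >= ``isolation_bp`` from any
    neighbouring cluster on either strand, and (iv) have mean unmasked-bin
    density at least ``min_mean_density`` (default: the top expression
    quartile among candidates passing i-iii).
    """
    # cluster extents per chromosome, both strands pooled, for isolation test
    extents: dict[str, list[tuple[int, int, int]]] = {}
    for idx, cl in enumerate(clusters):
        extents.setdefault(cl.chrom, []).append((cl.start, cl.end, idx))

    candidates = []
    for idx, cl in enumerate(clusters):
        if len(cl.isoforms) != 1:
            continue
        iso = cl.isoforms[0]
        if iso.length < min_length:
            continue
        isolated = True
        for s, e, other in extents[cl.chrom]:
            if other == idx:
                continue
            if s < cl.end + isolation_bp and e > cl.start - isolation_bp:
                isolated = False
                break
        if not isolated:
            continue
        if cl.Y is None:
            cl.Y = cl.bin_counts(coverage)
        sel = slice(iso.unmasked_start, iso.unmasked_end + 1)
        mean_density = float(cl.Y[sel].mean()) / cl.bin_size
        candidates.append((cl, iso, mean_density))

    if not candidates:
        return []
    if min_mean_density is None:
        densities = np.array([d for _, _, d in candidates])
        min_mean_density = float(np.quantile(densities, 0.75))
    refs = [(cl, iso) for cl, iso, d in candidates if d >= min_mean_density and d > 0]
    if len(refs) < 20:
        warnings.warn(f"only {len(refs)} reference isoforms selected for shape fitting")
    return refs


def fit_profile(
    references: list[tuple[IsoformCluster, PreRNAIsoform]],
    coverage: CoverageTrack,
    loess_span: float = 0.1,
) -> ShapeProfile:
    """Fit the canonical shape profile from reference isoforms.

    Each reference's unmasked bin densities are normalised by their own
    mean (scale-free), placed at the canonical positions of the bin
    midpoints, pooled across references, loess-smoothed and rescaled to
    median 1.  Fewer than 5 references yields the flat fallback profile.
    """
    if len(references) < 5:
        warnings.warn(
            f"{len(references)} reference isoforms (< 5); using flat profile"
        )
        return ShapeProfile.flat()

    us, ds = [], []
    for cl, iso in references:
        if cl.Y is None:
            cl.Y = cl.bin_counts(coverage)
        sel = np.arange(iso.unmasked_start, iso.unmasked_end + 1)
        dens = cl.Y[sel].astype(np.float64)
        mean = dens.mean()
        if mean <= 0:
            continue
        dens /= mean
        tss_axis = iso.start_bin * cl.bin_size + _tss_offset_in_bin(cl, iso)
        mids = (sel + 0.5) * cl.bin_size - tss_axis
        mids = np.clip(mids, 0, iso.length - 1)
        us.append([map_to_canonical(m, iso.length) for m in mids])
        ds.append(dens)
    u = np.concatenate(us)
    d = np.concatenate(ds)

    smoothed = lowess(d, u, frac=loess_span, return_sorted=True)
    grid = np.linspace(0.0, 1.0, GRID_POINTS)
    curve = np.interp(grid, smoothed[:, 0], smoothed[:, 1])
    if np.any(curve <= 0):
        warnings.warn("non-positive smoothed densities clipped to floor")
        curve = np.maximum(curve, PROFILE_FLOOR)
    curve = curve / np.median(curve)
    curve = np.maximum(curve, PROFILE_FLOOR)
    return ShapeProfile(grid, curve, span=loess_span)


def _tss_offset_in_bin(cluster: IsoformCluster, iso: PreRNAIsoform) -> float:
    """Offset of the isoform TSS within its bin, along the transcription axis."""
    if cluster.strand == "+":
        return (iso.tss - cluster.start) - iso.start_bin * cluster.bin_size
    return (cluster.end - 1 - iso.tss) - iso.start_bin * cluster.bin_size


def adjust_design_matrix(
    X: np.ndarray, profile: ShapeProfile, cluster: IsoformCluster
) -> np.ndarray:
    """Replace each 1-entry of X with the profile density at the canonical
    position of that bin's midpoint relative to the isoform's TSS."""
    Xp = X.astype(np.float64).copy()
    for j, iso in enumerate(cluster.isoforms):
        rows = np.flatnonzero(X[:, j])
        if rows.size == 0:
            continue
        tss_axis = iso.start_bin * cluster.bin_size + _tss_offset_in_bin(cluster, iso)
        mids = (rows + 0.5) * cluster.bin_size - tss_axis
        mids = np.clip(mids, 0, iso.length - 1)
        u = np.array([map_to_canonical(m, iso.length) for m in mids])
        Xp[rows, j] = X[rows, j] * profile(u)
    return Xp
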