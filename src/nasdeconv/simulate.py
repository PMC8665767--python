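"""Archetype-resampling simulator for nascent RNA-seq data.

Synthetic data are built in five steps: (1) template isoform annotations
are grouped into non-overlapping strand-specific clusters; (2) clusters
and inter-cluster distances are resampled with replacement until the
requested number of genes is placed; (3) each isoform is substituted by
the archetype closest to it in genomic length, keeping the TSS at its
original position relative to the cluster start; (4) a new abundance is
drawn for each isoform (log-normal by default); (5) per-base counts are
resampled from the archetype's counts in proportion to the simulated
abundance (Poisson thinning/amplification), with overlapping isoforms
contributing additively.

Archetypes here are themselves synthetic: single-isoform read-count
templates with a promoter-proximal pause peak, a 'U'-shaped gene body,
a 3' termination bump, divergent antisense signal upstream of the TSS
and negative-binomial per-base noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import os
import warnings

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GenomicInterval, MatureIsoform, write_gtf
from .shape import map_to_canonical

TEMPLATE_SEED = 735901          # fixed: the template is a fixed annotation set
CHROM_SIZE_CAP = 16_000_000
ANTISENSE_SPAN = 500            # bp of divergent signal upstream of the TSS
NB_DISPERSION = 5.0

# isoform-count distribution per template gene (1..6 isoforms)
ISOFORM_COUNT_P = (0.40, 0.25, 0.15, 0.10, 0.06, 0.04)
# probability that a non-first isoform starts at an internal TSS (>= 1 kb)
P_INTERNAL_TSS = 0.4


@dataclass
class Archetype:
    """A single-isoform read-count template (TSS at offset 0)."""

    id: str
    length: int
    sense: np.ndarray       # per-base counts over [0, length)
    antisense: np.ndarray   # per-base counts over offsets [-ANTISENSE_SPAN, 0)
    native_density: float   # mean per-base sense count over the gene body


def _body_shape(u: np.ndarray) -> np.ndarray:
    """Canonical U-shaped relative density over [0, 1]."""
    return 0.7 + 1.1 * np.exp(-((u / 0.12) ** 2)) + 0.8 * np.exp(-(((1 - u) / 0.10) ** 2))


def generate_archetypes(
    k: int = 62,
    length_range: tuple[int, int] = (1500, 50000),
    seed: int = 0,
) -> list[Archetype]:
    """Generate ``k`` synthetic archetypes with log-uniform lengths."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    out = []
    for i in range(k):
        length = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        d0 = float(np.exp(rng.uniform(np.log(0.5), np.log(5.0))))
        pos = np.arange(length)
        u = np.array([map_to_canonical(p, length) for p in pos])
        mu = d0 * _body_shape(u)
        # promoter-proximal pause peak within the first 500 bp
        pk_pos = rng.uniform(80, 300)
        pk_sd = rng.uniform(30, 80)
        mu += d0 * rng.uniform(8, 20) * np.exp(-(((pos - pk_pos) / pk_sd) ** 2))
        # 3' termination bump
        tp_pos = length - rng.uniform(100, 400)
        tp_sd = rng.uniform(100, 250)
        mu += d0 * rng.uniform(2, 6) * np.exp(-(((pos - tp_pos) / tp_sd) ** 2))
        sense = _nb_counts(mu, rng)
        # divergent antisense peak upstream of the TSS
        apos = np.arange(-ANTISENSE_SPAN, 0)
        ac = -rng.uniform(100, 250)
        amu = d0 * rng.uniform(4, 12) * np.exp(-(((apos - ac) / rng.uniform(40, 80)) ** 2))
        anti = _nb_counts(amu, rng)
        body = slice(min(500, length // 4), length - min(500, length // 4) or length)
        native = float(sense[body].mean())
        if native <= 0:
            native = max(float(sense.mean()), 1e-3)
        out.append(Archetype(f"A{i:03d}", length, sense, anti, native))
    return out


def _nb_counts(mu: np.ndarray, rng) -> np.ndarray:
    """Negative-binomial counts with mean mu and dispersion NB_DISPERSION."""
    r = NB_DISPERSION
    p = r / (r + np.maximum(mu, 1e-12))
    return rng.negative_binomial(r, p).astype(np.float64)


# ---------------------------------------------------------------------------
# template annotations


@dataclass
class TemplateCluster:
    """One template gene: isoform (tss_offset, length) pairs on a + axis."""

    isoforms: list[tuple[int, int]]     # (offset of TSS from cluster start, length)


def default_template(
    n_genes: int = 300, seed: int = TEMPLATE_SEED
) -> tuple[list[TemplateCluster], np.ndarray]:
    """Deterministic synthetic template: 1-6 isoforms per gene with
    staggered/nested TSS-PAS configurations, plus an empirical
    inter-cluster gap distribution."""
    rng = np.random.default_rng(seed)
    clusters = []
    for _ in range(n_genes):
        k = int(rng.choice(len(ISOFORM_COUNT_P), p=ISOFORM_COUNT_P)) + 1
        isoforms = [(0, _draw_length(rng))]
        for _j in range(1, k):
            if rng.random() < P_INTERNAL_TSS:
                off = int(rng.uniform(1000, 20000))
            else:
                off = int(rng.uniform(0, 900))
            isoforms.append((off, _draw_length(rng)))
        clusters.append(TemplateCluster(isoforms))
    gaps = rng.uniform(3000, 15000, size=n_genes).astype(int)
    return clusters, gaps


def _draw_length(rng) -> int:
    return int(np.exp(rng.uniform(np.log(2000), np.log(45000))))


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimulatedDataset:
    isoforms: list[MatureIsoform]       # annotations, one per placed transcript
    truth: pd.DataFrame                 # per-transcript true abundances
    coverage: CoverageTrack
    seed: int
    params: dict = field(default_factory=dict)
    contributions: list | None = None   # per-isoform placed count arrays (optional)


def simulate(
    archetypes: list[Archetype],
    n_genes: int = 1500,
    template: tuple[list[TemplateCluster], np.ndarray] | None = None,
    abundance_mu: float = 4.0,
    abundance_sigma: float = 1.2,
    seed: int = 0,
    keep_contributions: bool = False,
) -> SimulatedDataset:
    """Run the five-step simulation and return annotations, truth and counts."""
    rng = np.random.default_rng(seed)
    if template is None:
        template = default_template()
    tclusters, tgaps = template
    arch_lengths = np.array([a.length for a in archetypes])

    # -- plan placements (steps 1-4) ----------------------------------
    placements = []  # (gene_id, chrom, strand, [(tid, start, end, arch_idx, abundance)])
    chrom_idx, pos = 0, 0
    gi = 0
    while gi < n_genes:
        tc = tclusters[rng.integers(len(tclusters))]
        gap = int(tgaps[rng.integers(len(tgaps))])
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"SG{gi:05d}"
        rel = []
        for off, length in tc.isoforms:
            ai = int(np.argmin(np.abs(arch_lengths - length)))
            la = int(arch_lengths[ai])
            if la > 2 * length or length > 2 * la:
                warnings.warn(
                    f"no archetype within 2x of isoform length {length}; using nearest"
                )
            rel.append((off, la, ai))
        ext = max(off + la for off, la, _ in rel)
        pos += gap
        if pos + ext + ANTISENSE_SPAN >= CHROM_SIZE_CAP:
            chrom_idx += 1
            pos = gap
        chrom = f"sim{chrom_idx + 1}"
        start = pos
        iso_rows = []
        for j, (off, la, ai) in enumerate(rel):
            a = float(rng.lognormal(abundance_mu, abundance_sigma))
            if strand == "+":
                s, e = start + off, start + off + la
            else:
                s, e = start + (ext - off - la), start + (ext - off)
            iso_rows.append((f"{gene_id}.{j + 1}", s, e, ai, a))
        placements.append((gene_id, chrom, strand, iso_rows))
        pos = start + ext
        gi += 1

    # -- allocate tracks ----------------------------------------------
    coverage = CoverageTrack()
    chrom_ends: dict[str, int] = {}
    for _g, chrom, _s, rows in placements:
        end = max(r[2] for r in rows)
        chrom_ends[chrom] = max(chrom_ends.get(chrom, 0), end + ANTISENSE_SPAN + 1)
    for chrom, length in chrom_ends.items():
        coverage.add_chrom(chrom, length)

    # -- generate counts (step 5) -------------------------------------
    isoforms, truth_rows = [], []
    contributions = [] if keep_contributions else None
    for gene_id, chrom, strand, rows in placements:
        for tid, s, e, ai, a in rows:
            arch = archetypes[ai]
            scale = a / arch.native_density
            sense = rng.poisson(arch.sense * scale).astype(np.float64)
            anti = rng.poisson(arch.antisense * scale).astype(np.float64)
            anti_strand = "-" if strand == "+" else "+"
            if strand == "+":
                coverage.add_counts(chrom, "+", s, sense)
                a_start = s - ANTISENSE_SPAN
                avals = anti
            else:
                sense = sense[::-1]
                coverage.add_counts(chrom, "-", s, sense)
                a_start = e
                avals = anti[::-1]
            if a_start >= 0:
                coverage.add_counts(chrom, anti_strand, a_start, avals)
            if contributions is not None:
                contributions.append(
                    {"transcript_id": tid, "chrom": chrom, "strand": strand,
                     "start": s, "sense": sense,
                     "anti_start": a_start, "anti_strand": anti_strand, "anti": avals}
                )
            isoforms.append(
                MatureIsoform(tid, gene_id, GenomicInterval(chrom, s, e, strand))
            )
            iso = isoforms[-1]
            truth_rows.append(
                {"transcript_id": tid, "gene_id": gene_id, "chrom": chrom,
                 "start": s, "end": e, "strand": strand, "tss": iso.tss,
                 "length": e - s, "archetype": arch.id, "true_abundance": a}
            )
    truth = pd.DataFrame(truth_rows)
    return SimulatedDataset(
        isoforms=isoforms,
        truth=truth,
        coverage=coverage,
        seed=seed,
        params={
            "n_genes": n_genes,
            "abundance_mu": abundance_mu,
            "abundance_sigma": abundance_sigma,
            "n_archetypes": len(archetypes),
        },
        contributions=contributions,
    )


def export(dataset: SimulatedDataset, out_dir: str) -> dict[str, str]:
    """Write annotations (GTF), coverage (bedGraph pair) and the truth TSV."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gtf": os.path.join(out_dir, "annotations.gtf"),
        "plus": os.path.join(out_dir, "coverage_plus.bedgraph"),
        "minus": os.path.join(out_dir, "coverage_minus.bedgraph"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_gtf(dataset.isoforms, paths["gtf"])
    dataset.coverage.to_bedgraph(paths["plus"], paths["minus"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    return paths


# ---------------------------------------------------------------------------
# labelled TSS examples for classifier training


def make_tss_training_set(
    dataset: SimulatedDataset,
    negatives_per_positive: float = 1.0,
    min_tss_distance: int = 1500,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, str]]]:
    """Labelled feature vectors: positives at simulated isoform TSSs,
    negatives at gene-body/intergenic positions away from any TSS."""
    from .tss import extract_features

    rng = np.random.default_rng(seed)
    pos_sites = sorted({(r.chrom, r.tss, r.strand) for r in dataset.truth.itertuples()})
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, t, _s in pos_sites:
        tss_by_chrom.setdefault(chrom, []).append(t)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}

    def far_from_tss(chrom, p):
        arr = tss_by_chrom.get(chrom)
        if arr is None:
            return True
        i = np.searchsorted(arr, p)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - p) < min_tss_distance:
                return False
        return True

    n_neg = int(round(negatives_per_positive * len(pos_sites)))
    chroms = dataset.coverage.chroms
    neg_sites: list[tuple[str, int, str]] = []
    attempts = 0
    while len(neg_sites) < n_neg and attempts < 50 * n_neg:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        p = int(rng.integers(1000, dataset.coverage.chrom_length(chrom) - 1000))
        if far_from_tss(chrom, p):
            neg_sites.append((chrom, p, "+" if rng.random() < 0.5 else "-"))

    sites = list(pos_sites) + neg_sites
    labels = np.concatenate([np.ones(len(pos_sites)), np.zeros(len(neg_sites))])
    feats = np.stack(
        [extract_features(p, s, c, dataset.coverage) for c, p, s in sites]
    )
    return feats, labels, sites
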