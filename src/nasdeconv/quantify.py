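"""Constrained least-squares estimation of pre-RNA isoform abundances.

Per cluster, the observed bin counts Y are modelled as a non-negative
mixture of isoform occupancy columns: beta_hat = argmin ||Y - X beta||^2
subject to beta >= 0.  In linear mode the problem is solved exactly by
active-set NNLS; a bounded quasi-Newton route (L-BFGS-B with a zero
lower bound) is kept as a cross-check and carries the optional
log-space objective, sum over bins of
(log(y_i + c) - log((X beta)_i + c))^2, which corresponds to a
log-normal noise assumption (pseudocount c, default 1).

Estimates are normalised by total library depth (per million), summed
over isoforms to gene level, and the most abundant isoform per gene is
flagged as dominant.  A read-count-based (RCB) baseline — reads over a
region divided by region length, TPM-normalised — is provided for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, nnls

from .clusters import (
    IsoformCluster,
    MatureIsoform,
    cluster_isoforms,
    prepare_cluster,
)
from .genome_io import CoverageTrack
from .shape import ShapeProfile, adjust_design_matrix, fit_profile, select_reference_isoforms
from .tss import ConvTSSModel, call_cluster_isoforms, filter_design_matrix

GTOL = 1e-10
FTOL = 1e-14  # scipy's default (factr=1e7) stops far from the optimum on
              # large-count log objectives, whose per-iteration decrease is tiny
MAX_ITER = 1000


def _start_point(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-isoform mean of Y over its bins divided by the column's mean weight."""
    beta0 = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        rows = X[:, j] > 0
        if rows.any():
            beta0[j] = max(Y[rows].mean() / X[rows, j].mean(), 0.0)
        else:
            beta0[j] = 0.0
    return beta0


def estimate_abundance(
    X: np.ndarray,
    Y: np.ndarray,
    log_space: bool = False,
    pseudocount: float = 1.0,
    solver: str = "auto",
) -> np.ndarray:
    """Estimate non-negative isoform weights for one cluster.

    Rows of X with no occupied isoform (all-zero rows, e.g. fully masked
    bins) are dropped from the objective.  ``solver`` selects the linear
    route: 'auto' uses exact NNLS in linear mode, 'lbfgsb' forces the
    bounded quasi-Newton path (always used in log mode).
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("design matrix must have at least one column")
    if len(Y) != X.shape[0]:
        raise ValueError("Y length does not match design-matrix rows")
    rows = np.flatnonzero(np.abs(X).sum(axis=1) > 0)
    Xr, Yr = X[rows], Y[rows]
    if Xr.shape[0] == 0 or not np.any(Yr):
        return np.zeros(X.shape[1])

    if not log_space and solver in ("auto", "nnls"):
        beta, _ = nnls(Xr, Yr)
        return beta

    if log_space:
        # start from the exact linear solution: well-scaled and usually
        # close to the log-space optimum
        beta0, _ = nnls(Xr, Yr)
    else:
        beta0 = _start_point(Xr, Yr)
    if log_space:
        logy = np.log(Yr + pseudocount)

        def objective(b):
            mu = Xr @ b
            r = np.log(mu + pseudocount) - logy
            grad = 2.0 * Xr.T @ (r / (mu + pseudocount))
            return float(r @ r), grad

    else:

        def objective(b):
            r = Xr @ b - Yr
            return float(r @ r), 2.0 * Xr.T @ r

    res = minimize(
        objective,
        beta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * Xr.shape[1],
        options={"gtol": GTOL, "ftol": FTOL, "maxiter": MAX_ITER},
    )
    if not res.success and "ABNORMAL" in str(res.message):
        warnings.warn(f"optimizer did not converge: {res.message}; using best iterate")
    return np.maximum(res.x, 0.0)


def normalize(beta: np.ndarray, library_depth: float) -> np.ndarray:
    """Scale raw weights to per-million library depth units."""
    if library_depth <= 0:
        raise ValueError("library depth must be positive")
    return np.asarray(beta, dtype=np.float64) * 1e6 / library_depth


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class QuantifyConfig:
    bin_size: int = 250
    mask5_bins: int = 1
    mask3_bins: int = 4
    log_space: bool = True
    pseudocount: float = 1.0
    use_shape: bool = True
    use_tss: bool = True
    tss_threshold: float = 0.5
    shape_min_length: int = 10000
    shape_isolation_bp: int = 5000
    loess_span: float = 0.1


def quantify(
    isoforms: list[MatureIsoform],
    coverage: CoverageTrack,
    config: QuantifyConfig | None = None,
    tss_model=None,
    user_inactive: set[str] | None = None,
    shape_profile: ShapeProfile | None = None,
) -> pd.DataFrame:
    """Run the full deconvolution pipeline and return the abundance table.

    Columns: gene_id, pre_rna_isoform_id, member_transcript_ids, chrom,
    start, end, strand, raw_beta, normalized_abundance, is_dominant.
    """
    config = config or QuantifyConfig()
    clusters = cluster_isoforms(isoforms)
    for cl in clusters:
        prepare_cluster(cl, coverage, config.bin_size, config.mask5_bins, config.mask3_bins)

    if config.use_shape and shape_profile is None:
        refs = select_reference_isoforms(
            clusters, coverage,
            min_length=config.shape_min_length,
            isolation_bp=config.shape_isolation_bp,
        )
        shape_profile = fit_profile(refs, coverage, loess_span=config.loess_span)
    if not config.use_shape:
        shape_profile = None

    calls = None
    if config.use_tss or user_inactive:
        if config.use_tss:
            if tss_model is None:
                raise ValueError("TSS prediction requested but no trained model given")
            calls = call_cluster_isoforms(
                clusters, coverage, tss_model,
                threshold=config.tss_threshold, user_inactive=user_inactive,
            )

    depth = coverage.library_depth
    records = []
    for cl in clusters:
        if not cl.isoforms:
            continue
        X = cl.X
        keep = list(range(len(cl.isoforms)))
        if calls is not None:
            allowed = {i.id for i in cl.isoforms if calls[i.id].active}
            X, keep = filter_design_matrix(cl, allowed)
        elif user_inactive:
            allowed = {
                i.id for i in cl.isoforms
                if i.id not in user_inactive
                and not any(t in user_inactive for t in i.member_transcript_ids)
            }
            X, keep = filter_design_matrix(cl, allowed)
        beta = np.zeros(len(cl.isoforms))
        if X.shape[1] > 0:
            if shape_profile is not None and not shape_profile.is_flat:
                Xsub = adjust_design_matrix(
                    cl.X, shape_profile, cl
                )[:, keep]
            else:
                Xsub = X
            beta[keep] = estimate_abundance(
                Xsub, cl.Y, log_space=config.log_space, pseudocount=config.pseudocount
            )
        for iso, b in zip(cl.isoforms, beta):
            records.append(
                {
                    "gene_id": iso.gene_id,
                    "pre_rna_isoform_id": iso.id,
                    "member_transcript_ids": ",".join(iso.member_transcript_ids),
                    "chrom": iso.interval.chrom,
                    "start": iso.interval.start,
                    "end": iso.interval.end,
                    "strand": iso.strand,
                    "length": iso.length,
                    "tss": iso.tss,
                    "raw_beta": float(b),
                }
            )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["normalized_abundance"] = normalize(table["raw_beta"].to_numpy(), depth)
        table["is_dominant"] = False
        for _gene, idx in table.groupby("gene_id").groups.items():
            sub = table.loc[idx]
            table.loc[_dominant_index(sub), "is_dominant"] = True
    return table


def _dominant_index(sub: pd.DataFrame):
    """Max raw_beta; ties broken by longer isoform then lexicographic id."""
    ranked = sub.sort_values(
        ["raw_beta", "length", "pre_rna_isoform_id"],
        ascending=[False, False, True],
    )
    return ranked.index[0]


def aggregate_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Gene-level abundances (sums over member isoforms) with dominant calls."""
    rows = []
    for gene, sub in table.groupby("gene_id"):
        dom = sub.loc[_dominant_index(sub)]
        rows.append(
            {
                "gene_id": gene,
                "raw_beta": float(sub["raw_beta"].sum()),
                "normalized_abundance": float(sub["normalized_abundance"].sum())
                if "normalized_abundance" in sub
                else np.nan,
                "n_isoforms": len(sub),
                "dominant_isoform_id": dom["pre_rna_isoform_id"],
                "dominant_tss": int(dom["tss"]) if "tss" in sub else -1,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# read-count baseline


def _union_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def rcb_estimate(
    regions: list[dict],
    coverage: CoverageTrack,
    mode: str = "gene",
    trim5: int = 250,
    trim3: int = 1000,
    T: float | None = None,
) -> pd.DataFrame:
    """Read-count-based abundance: q_i = r_i * 1e6 / (f_i * T).

    ``regions`` carry 'id', 'chrom', 'strand' and either 'intervals'
    (gene mode: the union of annotated isoform spans) or 'start'/'end'
    (isoform mode).  In isoform mode, ``trim5`` bp downstream of the TSS
    and ``trim3`` bp upstream of the PAS are excluded before counting.
    T defaults to sum(r_g / f_g) over the given regions; pass the
    gene-level T to keep isoform-mode estimates on the gene TPM scale.
    """
    rows = []
    for reg in regions:
        chrom, strand = reg["chrom"], reg["strand"]
        if mode == "gene":
            ivs = _union_intervals(reg["intervals"])
        else:
            s, e = reg["start"], reg["end"]
            if strand == "+":
                s, e = s + trim5, e - trim3
            else:
                s, e = s + trim3, e - trim5
            ivs = [(s, e)] if e > s else []
        f = sum(e - s for s, e in ivs)
        if f <= 0:
            raise ValueError(f"region {reg['id']} has zero effective length")
        r = sum(coverage.region_sum(chrom, s, e, strand) for s, e in ivs)
        rows.append({"id": reg["id"], "reads": r, "length": f, "density": r / f})
    df = pd.DataFrame(rows)
    if T is None:
        T = float(df["density"].sum())
    df["abundance"] = 0.0 if T == 0 else df["density"] * 1e6 / T
    df.attrs["T"] = T
    return df


def gene_union_regions(isoforms: list[MatureIsoform]) -> list[dict]:
    """Per-gene union-of-isoform-span regions for gene-mode RCB."""
    by_gene: dict[str, list[MatureIsoform]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)
    regions = []
    for gene, members in sorted(by_gene.items()):
        regions.append(
            {
                "id": gene,
                "chrom": members[0].chrom,
                "strand": members[0].strand,
                "intervals": [(m.interval.start, m.interval.end) for m in members],
            }
        )
    return regions


def filter_by_expression_rank(
    gene_table: pd.DataFrame, top_fraction: float = 0.75,
    column: str = "normalized_abundance",
) -> pd.DataFrame:
    """Keep the top fraction of expressed (> 0) genes ranked by abundance."""
    expressed = gene_table[gene_table[column] > 0]
    if expressed.empty:
        return expressed
    n_keep = int(np.floor(top_fraction * len(expressed)))
    return expressed.sort_values(column, ascending=False).head(n_keep)
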