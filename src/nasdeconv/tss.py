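"""Active-TSS calling from bidirectional transcription signatures.

Active promoters in nascent RNA-seq data show a characteristic pattern:
a promoter-proximal pause peak on the sense strand and divergent
transcription on the antisense strand.  A pluggable binary classifier is
applied to a 42-dimensional feature vector (strand-specific read counts
in 21 bins of 51 bp centred on the candidate TSS, jointly z-scored), and
only isoforms whose TSS is called active are allowed non-zero weight in
the deconvolution.  Because the classifier inevitably misses some active
TSSs, isoforms with a high upstream polymerase ratio (UPR) and no nearby
active isoform are rescued.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._convnet import ConvNet1D
from .clusters import IsoformCluster, PreRNAIsoform
from .genome_io import CoverageTrack

N_BINS = 21
BIN_WIDTH = 51
WINDOW = N_BINS * BIN_WIDTH  # 1071 bp
UPR_THRESHOLD = 5.0
RESCUE_UPSTREAM_BP = 5000
RESCUE_DOWNSTREAM_BP = 6000


@dataclass
class TSSCall:
    position: int
    probability: float
    active: bool
    rescued: bool = False


@dataclass
class UPRStatistic:
    inside_density: float
    upstream_density: float
    ratio: float

    @property
    def eligible(self) -> bool:
        return self.ratio >= UPR_THRESHOLD


# ---------------------------------------------------------------------------
# features


def extract_features(
    tss: int, strand: str, chrom: str, coverage: CoverageTrack
) -> np.ndarray:
    """42-value z-scored feature vector around a candidate TSS.

    21 contiguous 51-bp bins centred on the TSS (the centre bin spans
    [tss-25, tss+26)), ordered 5' -> 3' along transcription, for the
    sense then the antisense strand.  Windows beyond chromosome edges are
    zero-padded.  If the 42 raw counts are constant, the vector is all
    zeros (sd = 0 convention), which downstream code treats as inactive.
    """
    half = WINDOW // 2  # 535
    window_start = tss - half
    anti_strand = "-" if strand == "+" else "+"
    sense = coverage.get(chrom, window_start, window_start + WINDOW, strand)
    anti = coverage.get(chrom, window_start, window_start + WINDOW, anti_strand)
    sense_bins = sense.reshape(N_BINS, BIN_WIDTH).sum(axis=1)
    anti_bins = anti.reshape(N_BINS, BIN_WIDTH).sum(axis=1)
    if strand == "-":
        sense_bins = sense_bins[::-1]
        anti_bins = anti_bins[::-1]
    raw = np.concatenate([sense_bins, anti_bins])
    sd = raw.std()
    if sd == 0:
        return np.zeros(2 * N_BINS)
    return (raw - raw.mean()) / sd


# ---------------------------------------------------------------------------
# classifier backends


class LogisticTSSModel:
    """Logistic-regression baseline over the 42 features (scikit-learn)."""

    def __init__(self, seed: int = 0, C: float = 1.0):
        from sklearn.linear_model import LogisticRegression

        self._clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
        self.trained = False

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "LogisticTSSModel":
        self._clf.fit(np.asarray(features), np.asarray(labels))
        self.trained = True
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self._clf.predict_proba(np.asarray(features))[:, 1]


class ConvTSSModel:
    """Small 1-D convolutional classifier (default backend).

    One convolutional layer over the two strand channels, ReLU,
    max-pooling, dropout, then a dense sigmoid output.
    """

    def __init__(
        self,
        filters: int = 16,
        kernel: int = 5,
        pool: int = 2,
        dropout: float = 0.3,
        seed: int = 0,
    ):
        self._net = ConvNet1D(
            n_channels=2, length=N_BINS, filters=filters, kernel=kernel,
            pool=pool, dropout=dropout, seed=seed,
        )

    @property
    def trained(self) -> bool:
        return self._net.trained

    def fit(self, features: np.ndarray, labels: np.ndarray, **kwargs) -> "ConvTSSModel":
        self._net.fit(features, labels, **kwargs)
        return self

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self._net.predict_proba(features)

    def save(self, path: str) -> None:
        self._net.save(path)

    @classmethod
    def load(cls, path: str) -> "ConvTSSModel":
        model = cls.__new__(cls)
        model._net = ConvNet1D.load(path)
        return model


def classify_tss(features: np.ndarray, model, threshold: float = 0.5) -> TSSCall:
    """Classify one candidate TSS; all-zero features bypass the model."""
    features = np.asarray(features, dtype=np.float64)
    if np.all(features == 0):
        return TSSCall(position=-1, probability=0.0, active=False)
    if not getattr(model, "trained", False):
        raise RuntimeError("TSS model is untrained; call fit() or load weights")
    prob = float(model.predict_proba(features.reshape(1, -1))[0])
    return TSSCall(position=-1, probability=prob, active=prob >= threshold)


# ---------------------------------------------------------------------------
# training-set construction from peak/read evidence (BED)


def build_training_set(
    candidates: list[tuple[str, int, str]],
    active_peaks: list[tuple[str, int, int, float]],
    cap_reads: list[tuple[str, int]],
    tss_proximity: int = 100,
    read_proximity: int = 25,
) -> tuple[list[tuple[str, int, str]], list[tuple[str, int, str]]]:
    """Label candidate TSSs from cap-analysis evidence.

    Positives: candidates overlapping a peak, keeping per peak the
    candidate with the maximum cap signal (cap reads within
    ``read_proximity``).  Negatives: candidates overlapping no peak and
    not within ``tss_proximity`` of a positive nor ``read_proximity`` of
    any cap read.  Candidates meeting neither rule are dropped.
    """
    reads_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in cap_reads:
        reads_by_chrom.setdefault(chrom, []).append(pos)
    reads_by_chrom = {c: np.sort(np.asarray(p)) for c, p in reads_by_chrom.items()}

    def cap_signal(chrom, pos):
        arr = reads_by_chrom.get(chrom)
        if arr is None:
            return 0
        lo = np.searchsorted(arr, pos - read_proximity, side="left")
        hi = np.searchsorted(arr, pos + read_proximity, side="right")
        return hi - lo

    per_peak: dict[int, tuple[float, tuple]] = {}
    in_peak = [False] * len(candidates)
    for ci, (chrom, pos, strand) in enumerate(candidates):
        for pi, (pchrom, pstart, pend, _score) in enumerate(active_peaks):
            if pchrom == chrom and pstart <= pos < pend:
                in_peak[ci] = True
                sig = cap_signal(chrom, pos)
                if pi not in per_peak or sig > per_peak[pi][0]:
                    per_peak[pi] = (sig, (chrom, pos, strand))
    positives = [cand for _sig, cand in per_peak.values()]
    pos_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos, _ in positives:
        pos_by_chrom.setdefault(chrom, []).append(pos)
    pos_by_chrom = {c: np.sort(np.asarray(p)) for c, p in pos_by_chrom.items()}

    def near(arr, pos, radius):
        if arr is None or len(arr) == 0:
            return False
        i = np.searchsorted(arr, pos)
        for j in (i - 1, i):
            if 0 <= j < len(arr) and abs(int(arr[j]) - pos) <= radius:
                return True
        return False

    negatives = []
    for ci, (chrom, pos, strand) in enumerate(candidates):
        if in_peak[ci]:
            continue
        if near(pos_by_chrom.get(chrom), pos, tss_proximity):
            continue
        if near(reads_by_chrom.get(chrom), pos, read_proximity):
            continue
        negatives.append((chrom, pos, strand))
    if not positives or not negatives:
        raise ValueError("training set needs both positive and negative examples")
    return positives, negatives


# ---------------------------------------------------------------------------
# UPR rescue


def _axis_window(tss: int, strand: str, lo: int, hi: int) -> tuple[int, int]:
    """Genomic [start, end) of transcription-axis offsets [lo, hi)."""
    if strand == "+":
        return tss + lo, tss + hi
    return tss - hi + 1, tss - lo + 1


def compute_upr(iso: PreRNAIsoform, coverage: CoverageTrack) -> UPRStatistic:
    """Upstream polymerase ratio: sense-strand density in [+0.5 kb, +2 kb)
    over density in [-3 kb, -0.5 kb) relative to the TSS."""
    chrom, strand, tss = iso.interval.chrom, iso.strand, iso.tss
    chrom_len = coverage.chrom_length(chrom) or None

    def density(lo, hi):
        s, e = _axis_window(tss, strand, lo, hi)
        s = max(s, 0)
        if chrom_len is not None:
            e = min(e, chrom_len)
        if e <= s:
            return 0.0
        return coverage.region_sum(chrom, s, e, strand) / (e - s)

    inside = density(500, 2000)
    upstream = density(-3000, -500)
    if upstream == 0:
        ratio = float("inf") if inside > 0 else 0.0
    else:
        ratio = inside / upstream
    return UPRStatistic(inside, upstream, ratio)


def rescue_isoforms(
    calls: dict[str, TSSCall],
    clusters: list[IsoformCluster],
    coverage: CoverageTrack,
    upr_threshold: float = UPR_THRESHOLD,
    upstream_bp: int = RESCUE_UPSTREAM_BP,
    downstream_bp: int = RESCUE_DOWNSTREAM_BP,
) -> dict[str, TSSCall]:
    """Re-admit classifier-missed isoforms with UPR >= threshold and no
    active isoform within 5 kb upstream / 6 kb downstream of their TSS
    (TSS-to-TSS, same strand).  Rescue only adds calls, never removes."""
    isoform_index = {
        iso.id: (cl, iso) for cl in clusters for iso in cl.isoforms
    }
    active_tss: dict[tuple[str, str], list[int]] = {}
    for iso_id, call in calls.items():
        if call.active and iso_id in isoform_index:
            _, iso = isoform_index[iso_id]
            active_tss.setdefault((iso.interval.chrom, iso.strand), []).append(iso.tss)
    for key in active_tss:
        active_tss[key] = np.sort(np.asarray(active_tss[key]))

    for iso_id, call in calls.items():
        if call.active or iso_id not in isoform_index:
            continue
        _, iso = isoform_index[iso_id]
        stat = compute_upr(iso, coverage)
        if stat.ratio < upr_threshold:
            continue
        s, e = _axis_window(iso.tss, iso.strand, -upstream_bp, downstream_bp + 1)
        nearby = active_tss.get((iso.interval.chrom, iso.strand))
        if nearby is not None:
            lo = np.searchsorted(nearby, s, side="left")
            hi = np.searchsorted(nearby, e - 1, side="right")
            if hi > lo:
                continue
        calls[iso_id] = TSSCall(call.position, call.probability, True, rescued=True)
    return calls


def filter_design_matrix(
    cluster: IsoformCluster, allowed: set[str]
) -> tuple[np.ndarray, list[int]]:
    """Drop design-matrix columns of disallowed isoforms.

    Returns the reduced matrix and the retained column indices; callers
    report exactly zero for removed isoforms.
    """
    keep = [j for j, iso in enumerate(cluster.isoforms) if iso.id in allowed]
    if cluster.X is None:
        raise ValueError("design matrix not built")
    if not keep and cluster.Y is not None and cluster.Y.sum() > 0:
        warnings.warn(
            f"all isoforms disallowed in expressed cluster "
            f"{cluster.chrom}:{cluster.start}-{cluster.end}{cluster.strand}"
        )
    return cluster.X[:, keep], keep


def call_cluster_isoforms(
    clusters: list[IsoformCluster],
    coverage: CoverageTrack,
    model,
    threshold: float = 0.5,
    rescue: bool = True,
    user_inactive: set[str] | None = None,
) -> dict[str, TSSCall]:
    """Classify every pre-RNA isoform TSS, apply UPR rescue, then apply a
    user-supplied inactive list (which always wins)."""
    calls: dict[str, TSSCall] = {}
    for cl in clusters:
        for iso in cl.isoforms:
            f = extract_features(iso.tss, iso.strand, cl.chrom, coverage)
            call = classify_tss(f, model, threshold)
            call.position = iso.tss
            calls[iso.id] = call
    if rescue:
        rescue_isoforms(calls, clusters, coverage)
    if user_inactive:
        for cl in clusters:
            for iso in cl.isoforms:
                if (
                    iso.id in user_inactive
                    or any(t in user_inactive for t in iso.member_transcript_ids)
                ):
                    c = calls[iso.id]
                    calls[iso.id] = TSSCall(c.position, c.probability, False, False)
    return calls
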