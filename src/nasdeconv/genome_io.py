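"""Reading and writing of genomic file formats.

Everything entering the pipeline is converted to a single coordinate
convention: 0-based, half-open intervals on explicit '+'/'-' strands.
GTF (1-based, closed) is converted on read.  Minus-strand coverage files
that encode counts as negative values (a common PRO-seq convention) are
absolute-valued on read.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation input; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MatureIsoform:
    """An annotated transcript span (exon structure discarded).

    ``tss`` and ``pas`` are the strand-aware 5' and 3' terminal bases:
    on '+' the TSS is ``start`` and the PAS is ``end - 1``; on '-' the
    TSS is ``end - 1`` and the PAS is ``start``.
    """

    transcript_id: str
    gene_id: str
    interval: GenomicInterval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def pas(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)


class CoverageTrack:
    """Strand-specific per-base read counts, one dense array per chromosome.

    All stored values are non-negative.  ``library_depth`` is the total
    mapped read count summed over both strands.
    """

    def __init__(self, dtype=np.float32):
        self._data: dict[str, dict[str, np.ndarray]] = {"+": {}, "-": {}}
        self.dtype = dtype
        self._warned_chroms: set[str] = set()

    # -- construction -------------------------------------------------

    def add_chrom(self, chrom: str, length: int) -> None:
        for s in STRANDS:
            arr = self._data[s].get(chrom)
            if arr is None:
                self._data[s][chrom] = np.zeros(length, dtype=self.dtype)
            elif len(arr) < length:
                grown = np.zeros(length, dtype=self.dtype)
                grown[: len(arr)] = arr
                self._data[s][chrom] = grown

    def add_counts(self, chrom: str, strand: str, start: int, values: np.ndarray) -> None:
        """Add per-base counts at [start, start+len(values))."""
        arr = self._data[strand].get(chrom)
        end = start + len(values)
        if arr is None or end > len(arr):
            new_len = max(end, 0 if arr is None else len(arr))
            grown = np.zeros(new_len, dtype=self.dtype)
            if arr is not None:
                grown[: len(arr)] = arr
            self._data[strand][chrom] = grown
            arr = grown
        arr[start:end] += np.asarray(values, dtype=self.dtype)

    # -- queries ------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        names = set(self._data["+"]) | set(self._data["-"])
        return sorted(names)

    def chrom_length(self, chrom: str) -> int:
        return max(
            (len(self._data[s][chrom]) for s in STRANDS if chrom in self._data[s]),
            default=0,
        )

    def get(self, chrom: str, start: int, end: int, strand: str) -> np.ndarray:
        """Per-base counts over [start, end); out-of-range bases are zero."""
        out = np.zeros(end - start, dtype=np.float64)
        arr = self._data[strand].get(chrom)
        if arr is None:
            if chrom not in self._warned_chroms:
                warnings.warn(
                    f"chromosome {chrom!r} absent from coverage; treated as zero"
                )
                self._warned_chroms.add(chrom)
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def region_sum(self, chrom: str, start: int, end: int, strand: str) -> float:
        return float(self.get(chrom, start, end, strand).sum())

    @property
    def library_depth(self) -> float:
        return float(
            sum(arr.sum() for s in STRANDS for arr in self._data[s].values())
        )

    # -- file I/O ------------------------------------------------------

    @classmethod
    def from_bigwig(cls, plus_path: str, minus_path: str, abs_minus: bool = True) -> "CoverageTrack":
        import pyBigWig

        track = cls()
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            bw = pyBigWig.open(path)
            try:
                for chrom, length in bw.chroms().items():
                    vals = np.nan_to_num(
                        np.asarray(bw.values(chrom, 0, length), dtype=np.float64)
                    )
                    if strand == "-" and abs_minus:
                        vals = np.abs(vals)
                    track.add_counts(chrom, strand, 0, vals)
            finally:
                bw.close()
        return track

    @classmethod
    def from_bedgraph(cls, plus_path: str, minus_path: str, abs_minus: bool = True) -> "CoverageTrack":
        track = cls()
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            # parse first, then allocate each chromosome once: growing the
            # arrays line by line would be quadratic in file size
            rows: list[tuple[str, int, int, float]] = []
            maxend: dict[str, int] = {}
            with open(path) as fh:
                for lineno, line in enumerate(fh, 1):
                    line = line.strip()
                    if not line or line.startswith(("track", "#", "browser")):
                        continue
                    fields = line.split("\t")
                    if len(fields) < 4:
                        raise AnnotationError(
                            f"{path}:{lineno}: bedGraph line has {len(fields)} fields"
                        )
                    chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    if strand == "-" and abs_minus:
                        value = abs(value)
                    if value != 0:
                        rows.append((chrom, start, end, value))
                        maxend[chrom] = max(maxend.get(chrom, 0), end)
            for chrom, end in maxend.items():
                track.add_chrom(chrom, end)
            for chrom, start, end, value in rows:
                track._data[strand][chrom][start:end] += np.asarray(value, dtype=track.dtype)
        return track

    def to_bedgraph(self, plus_path: str, minus_path: str) -> None:
        """Write run-length-encoded bedGraph files (zero runs omitted)."""
        for path, strand in ((plus_path, "+"), (minus_path, "-")):
            with open(path, "w") as fh:
                for chrom in self.chroms:
                    arr = self._data[strand].get(chrom)
                    if arr is None:
                        continue
                    vals = np.asarray(arr, dtype=np.float64)
                    # boundaries of constant runs
                    change = np.flatnonzero(np.diff(vals)) + 1
                    starts = np.concatenate(([0], change))
                    ends = np.concatenate((change, [len(vals)]))
                    for s, e in zip(starts, ends):
                        v = vals[s]
                        if v != 0:
                            fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# annotations


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attrs(text: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(text))


def read_annotations(path: str, format: str | None = None) -> list[MatureIsoform]:
    """Read transcript annotations from GTF (Ensembl dialect) or BED6/BED12.

    Each transcript yields one :class:`MatureIsoform`; exon structure is
    discarded because the pipeline models unspliced pre-RNA spans.  GTF
    coordinates (1-based closed) are converted to 0-based half-open.
    """
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = "BED" if ext == ".bed" else "GTF"
    format = format.upper()
    if format == "GTF":
        return _read_gtf(path)
    if format == "BED":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gtf(path: str) -> list[MatureIsoform]:
    spans: dict[str, list] = {}  # transcript_id -> [gene_id, chrom, strand, start, end]
    have_transcript_feature = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 fields, got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("transcript", "exon"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise AnnotationError(f"{path}:{lineno}: bad strand {strand!r}")
            a = _parse_gtf_attrs(attrs)
            tid = a.get("transcript_id")
            gid = a.get("gene_id")
            if tid is None:
                raise AnnotationError(f"{path}:{lineno}: missing transcript_id")
            if gid is None:
                raise AnnotationError(f"{path}:{lineno}: transcript without gene_id")
            if feature == "transcript":
                have_transcript_feature = True
                spans[tid] = [gid, chrom, strand, start0, end0]
            elif not have_transcript_feature or tid not in spans:
                # derive transcript span from exons when no transcript lines exist
                rec = spans.setdefault(tid, [gid, chrom, strand, start0, end0])
                rec[3] = min(rec[3], start0)
                rec[4] = max(rec[4], end0)
    return [
        MatureIsoform(tid, gid, GenomicInterval(chrom, s, e, strand))
        for tid, (gid, chrom, strand, s, e) in spans.items()
    ]


def _read_bed(path: str) -> list[MatureIsoform]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: BED needs >= 6 fields (chrom start end name score strand)"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if strand not in STRANDS:
                raise AnnotationError(f"{path}:{lineno}: bad strand {strand!r}")
            # BED carries no gene linkage; the name field serves as both ids
            out.append(MatureIsoform(name, name, GenomicInterval(chrom, start, end, strand)))
    return out


def write_gtf(isoforms: list[MatureIsoform], path: str, source: str = "nasdeconv") -> None:
    """Write transcript-level GTF (1-based closed on disk)."""
    with open(path, "w") as fh:
        for iso in isoforms:
            fh.write(
                f"{iso.chrom}\t{source}\ttranscript\t{iso.interval.start + 1}\t"
                f"{iso.interval.end}\t.\t{iso.strand}\t.\t"
                f'gene_id "{iso.gene_id}"; transcript_id "{iso.transcript_id}";\n'
            )


read_coverage = CoverageTrack.from_bigwig


def write_abundance_table(table: pd.DataFrame, path: str) -> None:
    """Write the isoform abundance table as headered TSV."""
    required = [
        "gene_id", "pre_rna_isoform_id", "member_transcript_ids", "chrom",
        "start", "end", "strand", "raw_beta", "normalized_abundance", "is_dominant",
    ]
    if table is None or len(table) == 0:
        raise ValueError("abundance table is empty; nothing to write")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table missing columns: {missing}")
    table[required].to_csv(path, sep="\t", index=False)
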