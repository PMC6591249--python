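"""Intron inference and size summaries from GTF annotations.

Transcripts are assembled from the ``exon`` features of a 9-column GTF
(Ensembl ``gene_biotype`` or GENCODE ``gene_type`` dialects); introns are
the gaps between consecutive exons of each transcript, kept in the GTF's
1-based closed coordinates, so intron k of a transcript with start-sorted
exons spans ``[exon_k.end + 1, exon_{k+1}.start - 1]``.  Sizes are
summarized on a log10 scale — intron-size distributions span orders of
magnitude, and the comparison of interest is the prevalence of short
introns.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GtfParseError",
    "TranscriptModel",
    "IntronRecord",
    "SizeSummary",
    "parse_gtf",
    "extract_introns",
    "intron_size_summary",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """A malformed GTF line, reported with its 1-based line number."""


@dataclass
class TranscriptModel:
    """One transcript: its exons (1-based closed intervals) and provenance."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = ""

    @property
    def sorted_exons(self) -> list[tuple[int, int]]:
        return sorted(self.exons)

    @property
    def span(self) -> int:
        ex = self.sorted_exons
        return ex[-1][1] - ex[0][0] + 1

    def has_overlapping_exons(self) -> bool:
        ex = self.sorted_exons
        return any(ex[i][1] >= ex[i + 1][0] for i in range(len(ex) - 1))


@dataclass(frozen=True)
class IntronRecord:
    """One inferred intron as a 1-based closed interval."""

    chrom: str
    strand: str
    start: int
    end: int
    gene_id: str
    supporting_transcript_count: int = 1

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SizeSummary:
    """Distributional summary of intron sizes (quartiles, log10 histogram)."""

    n_introns: int
    median: float
    q1: float
    q3: float
    log10_bin_edges: tuple[float, ...]
    log10_counts: tuple[int, ...]
    proportion_short: float
    short_cutoff: int


def _open_maybe_gzip(source: str | Path) -> IO[str]:
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _iter_lines(stream: str | Path | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, Path):
        with _open_maybe_gzip(stream) as fh:
            yield from fh
    elif isinstance(stream, str):
        if "\n" in stream or "\t" in stream:  # GTF text, not a path
            yield from stream.splitlines()
        else:
            with _open_maybe_gzip(stream) as fh:
                yield from fh
    else:
        yield from stream


def parse_gtf(stream: str | Path | IO[str] | Iterable[str]) -> list[TranscriptModel]:
    """Assemble transcript models from the exon features of a GTF.

    ``stream`` may be a path (``.gz`` accepted), an open text handle, or GTF
    text itself.  The gene biotype is read from ``gene_biotype`` (Ensembl)
    or ``gene_type`` (GENCODE), whichever is present; non-exon feature types
    are ignored.  Malformed lines raise :class:`GtfParseError` with the line
    number.
    """
    transcripts: dict[str, TranscriptModel] = {}
    for lineno, raw in enumerate(_iter_lines(stream), start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
            )
        chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
        if feature != "exon":
            continue
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as err:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from err
        if start < 1 or end < start:
            raise GtfParseError(f"line {lineno}: invalid interval {start}..{end}")
        if strand not in {"+", "-"}:
            raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
        attr = dict(_ATTR_RE.findall(attrs))
        tid = attr.get("transcript_id")
        if not tid:
            raise GtfParseError(f"line {lineno}: exon feature lacks transcript_id")
        gene_id = attr.get("gene_id", "")
        biotype = attr.get("gene_biotype", attr.get("gene_type", ""))
        model = transcripts.get(tid)
        if model is None:
            model = TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                biotype=biotype,
            )
            transcripts[tid] = model
        else:
            if (model.chrom, model.strand) != (chrom, strand):
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} spans multiple chrom/strand"
                )
            if not model.biotype and biotype:
                model.biotype = biotype
        model.exons.append((start, end))
    return list(transcripts.values())


def extract_introns(
    transcripts: Sequence[TranscriptModel],
    biotype_filter: str | None = "protein_coding",
    dedup: str = "per_gene",
) -> tuple[list[IntronRecord], list[tuple[str, str]]]:
    """Infer introns from transcript exon chains.

    ``dedup="per_gene"`` collapses identical intron coordinates within a
    gene, counting supporting transcripts; ``"per_transcript"`` keeps one
    record per transcript-intron occurrence.  Transcripts with overlapping
    exons are rejected, not silently fixed; the second return value lists
    ``(transcript_id, reason)`` rejections.
    """
    if dedup not in {"per_gene", "per_transcript"}:
        raise ValueError(f"unknown dedup mode {dedup!r}")
    rejected: list[tuple[str, str]] = []
    per_transcript: list[IntronRecord] = []
    for tr in transcripts:
        if biotype_filter is not None and tr.biotype != biotype_filter:
            continue
        if not tr.exons:
            rejected.append((tr.transcript_id, "no exons"))
            continue
        if tr.has_overlapping_exons():
            rejected.append((tr.transcript_id, "overlapping exons"))
            continue
        ex = tr.sorted_exons
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            start, end = e1 + 1, s2 - 1
            if start > end:  # abutting exons leave no intron
                continue
            per_transcript.append(
                IntronRecord(
                    chrom=tr.chrom,
                    strand=tr.strand,
                    start=start,
                    end=end,
                    gene_id=tr.gene_id,
                )
            )
    if dedup == "per_transcript":
        return per_transcript, rejected
    counts: dict[tuple[str, str, str, int, int], int] = {}
    for rec in per_transcript:
        key = (rec.gene_id, rec.chrom, rec.strand, rec.start, rec.end)
        counts[key] = counts.get(key, 0) + 1
    deduped = [
        IntronRecord(
            chrom=chrom,
            strand=strand,
            start=start,
            end=end,
            gene_id=gene_id,
            supporting_transcript_count=n,
        )
        for (gene_id, chrom, strand, start, end), n in counts.items()
    ]
    return deduped, rejected


def intron_size_summary(
    records: Sequence[IntronRecord], short_cutoff: int = 100, n_bins: int = 50
) -> SizeSummary:
    """Quartiles and a log10-size histogram of an intron set.

    Quantiles use linear interpolation on the sorted sizes; the histogram
    covers the observed log10 range with ``n_bins`` equal-width bins.
    ``proportion_short`` is the fraction of introns with
    ``size <= short_cutoff``.
    """
    if len(records) == 0:
        raise ValueError("no intron records to summarize")
    if short_cutoff < 1:
        raise ValueError("short_cutoff must be at least 1")
    sizes = np.array([r.size for r in records], dtype=float)
    q1, med, q3 = np.quantile(sizes, [0.25, 0.5, 0.75])
    log_sizes = np.log10(sizes)
    lo, hi = float(log_sizes.min()), float(log_sizes.max())
    if lo == hi:  # all sizes equal: one occupied bin of nominal width
        hi = lo + 1e-9
    counts, edges = np.histogram(log_sizes, bins=n_bins, range=(lo, hi))
    return SizeSummary(
        n_introns=int(sizes.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        log10_bin_edges=tuple(float(e) for e in edges),
        log10_counts=tuple(int(c) for c in counts),
        proportion_short=float(np.mean(sizes <= short_cutoff)),
        short_cutoff=int(short_cutoff),
    )
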