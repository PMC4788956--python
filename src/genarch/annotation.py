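"""Transcript structure parsing and gene-architecture metrics.

Transcripts are represented in UCSC genePred convention: 0-based, half-open
genomic coordinates, with the transcript span delimited by the first exon
start and last exon end.  Per-transcript metrics cover the genomic span
length (``l_tr``), summed exon/intron lengths (``l_ex``/``l_int``), exon and
intron counts and the derived averages and ratio.  Genes are reduced to
their single longest transcript (first-in-file wins ties), with the number
of annotated transcripts kept as the splice-variant count ``N_tr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

log = logging.getLogger(__name__)

#: L_tr threshold (nt) above which a gene counts as exceptionally long.
LONG_GENE_THRESHOLD = 200_000


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """One transcript's genomic structure: span plus ordered exon intervals.

    Coordinates are 0-based half-open.  The first exon starts at ``tx_start``
    and the last exon ends at ``tx_end`` (genePred convention).
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise AnnotationError(
                f"{self.transcript_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: transcript has no exons")
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise AnnotationError(f"{self.transcript_id}: empty exon ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted at ({s}, {e})"
                )
            if s < self.tx_start or e > self.tx_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exon ({s}, {e}) outside span"
                )
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise AnnotationError(
                f"{self.transcript_id}: span not delimited by first/last exon"
            )


@dataclass(frozen=True, slots=True)
class TranscriptMetrics:
    """Length/composition descriptors of one transcript (all lengths in nt).

    ``avg_int`` is None for single-exon transcripts (no introns), so that
    intron-average distributions exclude rather than zero-pad them.
    """

    l_tr: int
    l_ex: int
    l_int: int
    n_ex: int
    n_int: int
    avg_ex: float
    avg_int: float | None
    ratio_int_ex: float


@dataclass(frozen=True, slots=True)
class GeneSummary:
    """Per-gene reduction to the representative (longest) transcript."""

    gene_symbol: str
    L_tr: int
    N_tr: int
    representative_id: str
    metrics: TranscriptMetrics
    exceeds_200k: bool


def parse_annotation(
    stream: Iterable[str],
    format: str = "genepred",
    allowed_chroms: Sequence[str] | None = None,
) -> list[TranscriptModel]:
    """Parse a genePred/refFlat or GTF text stream into transcript models.

    Parameters
    ----------
    stream : iterable of lines (an open text file works).
    format : ``"genepred"`` (covers refFlat) or ``"gtf"``.
    allowed_chroms : optional whitelist of chromosome names; records on any
        other chromosome are dropped (e.g. nuclear-only analyses exclude
        ``chrM``).
    """
    if format == "genepred":
        transcripts = parse_genepred(stream)
    elif format == "gtf":
        transcripts = parse_gtf(stream)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    if allowed_chroms is not None:
        allowed = set(allowed_chroms)
        transcripts = [t for t in transcripts if t.chrom in allowed]
    return transcripts


def _parse_coord_list(field: str, lineno: int, what: str) -> list[int]:
    try:
        return [int(x) for x in field.rstrip(",").split(",") if x != ""]
    except ValueError:
        raise AnnotationError(f"line {lineno}: bad {what} list {field!r}") from None


def parse_genepred(stream: Iterable[str]) -> list[TranscriptModel]:
    """Parse genePred-with-name2 (gene symbol last) or refFlat (symbol first).

    The two layouts are distinguished by the strand column position:
    genePred has strand in column 3, refFlat in column 4.
    """
    out: list[TranscriptModel] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise AnnotationError(
                f"line {lineno}: expected >=11 tab-separated fields, got {len(fields)}"
            )
        if fields[2] in ("+", "-"):
            # name chrom strand txStart txEnd cdsStart cdsEnd exonCount starts ends geneSymbol
            name, chrom, strand = fields[0], fields[1], fields[2]
            tx_start_f, tx_end_f = fields[3], fields[4]
            exon_count_f, starts_f, ends_f = fields[7], fields[8], fields[9]
            symbol = fields[10]
        elif fields[3] in ("+", "-"):
            # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount starts ends
            symbol, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            tx_start_f, tx_end_f = fields[4], fields[5]
            exon_count_f, starts_f, ends_f = fields[8], fields[9], fields[10]
        else:
            raise AnnotationError(f"line {lineno}: no strand column found")
        try:
            tx_start, tx_end = int(tx_start_f), int(tx_end_f)
            exon_count = int(exon_count_f)
        except ValueError:
            raise AnnotationError(f"line {lineno}: non-integer coordinate field") from None
        starts = _parse_coord_list(starts_f, lineno, "exonStarts")
        ends = _parse_coord_list(ends_f, lineno, "exonEnds")
        if len(starts) != exon_count or len(ends) != exon_count:
            raise AnnotationError(
                f"line {lineno}: exonCount {exon_count} does not match "
                f"list lengths {len(starts)}/{len(ends)}"
            )
        try:
            out.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    exons=tuple(zip(starts, ends)),
                )
            )
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None
    return out


def _gtf_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def parse_gtf(stream: Iterable[str]) -> list[TranscriptModel]:
    """Parse GTF exon features into transcripts.

    GTF coordinates are 1-based inclusive and converted to 0-based half-open
    on read.  Gene symbol comes from ``gene_name`` when present, else
    ``gene_id``.
    """
    # transcript_id -> [symbol, chrom, strand, [exons]], in first-seen order
    acc: dict[str, list] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise AnnotationError(
                f"line {lineno}: expected 9 tab-separated GTF fields, got {len(fields)}"
            )
        if fields[2] != "exon":
            continue
        chrom, strand = fields[0], fields[6]
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError:
            raise AnnotationError(f"line {lineno}: non-integer GTF coordinates") from None
        attrs = _gtf_attributes(fields[8])
        tid = attrs.get("transcript_id")
        if not tid:
            raise AnnotationError(f"line {lineno}: exon without transcript_id")
        symbol = attrs.get("gene_name") or attrs.get("gene_id")
        if not symbol:
            raise AnnotationError(f"line {lineno}: exon without gene attribute")
        rec = acc.setdefault(tid, [symbol, chrom, strand, []])
        rec[3].append((start1 - 1, end1))
    out: list[TranscriptModel] = []
    for tid, (symbol, chrom, strand, exons) in acc.items():
        if not exons:
            raise AnnotationError(f"transcript {tid}: no exons")
        exons.sort()
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_symbol=symbol,
                chrom=chrom,
                strand=strand,
                tx_start=exons[0][0],
                tx_end=exons[-1][1],
                exons=tuple(exons),
            )
        )
    return out


def write_genepred(transcripts: Iterable[TranscriptModel], stream: IO[str]) -> None:
    """Write transcripts in the genePred-with-name2 dialect ``parse_genepred`` reads."""
    for t in transcripts:
        starts = ",".join(str(s) for s, _ in t.exons) + ","
        ends = ",".join(str(e) for _, e in t.exons) + ","
        stream.write(
            "\t".join(
                [
                    t.transcript_id,
                    t.chrom,
                    t.strand,
                    str(t.tx_start),
                    str(t.tx_end),
                    str(t.tx_start),
                    str(t.tx_end),
                    str(len(t.exons)),
                    starts,
                    ends,
                    t.gene_symbol,
                ]
            )
            + "\n"
        )


def compute_transcript_metrics(t: TranscriptModel) -> TranscriptMetrics:
    """Length and exon/intron composition of one transcript.

    ``l_tr`` is the genomic span, ``l_ex`` the summed exon length,
    ``l_int = l_tr − l_ex`` the summed intron length.
    """
    l_tr = t.tx_end - t.tx_start
    l_ex = sum(e - s for s, e in t.exons)
    l_int = l_tr - l_ex
    n_ex = len(t.exons)
    n_int = n_ex - 1
    return TranscriptMetrics(
        l_tr=l_tr,
        l_ex=l_ex,
        l_int=l_int,
        n_ex=n_ex,
        n_int=n_int,
        avg_ex=l_ex / n_ex,
        avg_int=(l_int / n_int) if n_int > 0 else None,
        ratio_int_ex=l_int / l_ex,
    )


def summarize_genes(transcripts: Sequence[TranscriptModel]) -> list[GeneSummary]:
    """Collapse transcripts to one summary per gene symbol.

    The representative transcript is the one with maximal span length; ties
    are broken by input order (first wins).  ``N_tr`` is the number of
    transcripts carrying the gene's symbol.
    """
    if not transcripts:
        raise ValueError("summarize_genes: empty transcript list")
    best: dict[str, tuple[int, TranscriptModel]] = {}
    counts: dict[str, int] = {}
    for t in transcripts:
        l_tr = t.tx_end - t.tx_start
        counts[t.gene_symbol] = counts.get(t.gene_symbol, 0) + 1
        cur = best.get(t.gene_symbol)
        if cur is None or l_tr > cur[0]:
            best[t.gene_symbol] = (l_tr, t)
    out = []
    for symbol, (l_tr, rep) in best.items():
        metrics = compute_transcript_metrics(rep)
        out.append(
            GeneSummary(
                gene_symbol=symbol,
                L_tr=metrics.l_tr,
                N_tr=counts[symbol],
                representative_id=rep.transcript_id,
                metrics=metrics,
                exceeds_200k=metrics.l_tr > LONG_GENE_THRESHOLD,
            )
        )
    return out


_TSV_HEADER = [
    "gene",
    "transcript",
    "chrom",
    "l_tr",
    "l_ex",
    "l_int",
    "n_ex",
    "n_int",
    "avg_ex",
    "avg_int",
    "ratio_int_ex",
    "N_tr",
]


def write_metrics_tsv(
    transcripts: Sequence[TranscriptModel], genes: Sequence[GeneSummary], stream: IO[str]
) -> None:
    """Per-transcript metrics table (one row per transcript, with the gene's N_tr)."""
    ntr = {g.gene_symbol: g.N_tr for g in genes}
    stream.write("\t".join(_TSV_HEADER) + "\n")
    for t in transcripts:
        m = compute_transcript_metrics(t)
        stream.write(
            "\t".join(
                [
                    t.gene_symbol,
                    t.transcript_id,
                    t.chrom,
                    str(m.l_tr),
                    str(m.l_ex),
                    str(m.l_int),
                    str(m.n_ex),
                    str(m.n_int),
                    f"{m.avg_ex:.4g}",
                    "NA" if m.avg_int is None else f"{m.avg_int:.4g}",
                    f"{m.ratio_int_ex:.6g}",
                    str(ntr.get(t.gene_symbol, 1)),
                ]
            )
            + "\n"
        )
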