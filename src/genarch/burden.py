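"""Somatic mutation catalogs: merge/dedup, transcript mapping, per-gene
counts and the mutation-count-vs-length linear fit.

Catalog records carry 1-based genomic positions (COSMIC convention).  A
record at position p is engulfed by a transcript with 0-based half-open
span [tx_start, tx_end) iff p-1 falls inside the span.  When several
transcripts engulf a position, the first one in annotation-file order takes
the count; per-gene counts then come from the representative (longest)
transcript only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, NamedTuple, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation import GeneSummary, TranscriptModel

log = logging.getLogger(__name__)


class MutationRecord(NamedTuple):
    """One somatic mutation event; position is 1-based (COSMIC convention).

    Positions are validated (>= 1, integral) when catalogs are loaded;
    catalogs run to millions of records, so this stays a plain tuple.
    """

    chrom: str
    pos: int
    source: str  # "coding" or "noncoding"


@dataclass(frozen=True, slots=True)
class DedupReport:
    """Tallies from merging and deduplicating mutation catalogs."""

    total_read: int
    unique_kept: int
    per_source_unique: dict[str, int]
    per_source_fraction: dict[str, float]


@dataclass(frozen=True, slots=True)
class GeneMutationCount:
    gene_symbol: str
    n_mutations: int
    L_tr: int
    N_tr: int


@dataclass(frozen=True, slots=True)
class BurdenFit:
    """OLS fit of per-gene mutation count on transcript length."""

    slope: float  # mutations per nt
    intercept: float  # mutations
    pearson_r: float
    n_genes: int

    @property
    def slope_per_kb(self) -> float:
        """Slope expressed as mutations per 1000 nt."""
        return self.slope * 1000.0


def _coerce_positions(raw: pd.Series, source: str) -> pd.Series:
    """Vectorized 1-based position validation; names the first bad line."""
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() | (num != np.floor(num)) | (num < 1)
    if bad.any():
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header row
        raise ValueError(f"{source}: unparseable position on line {lineno}: {raw.iloc[lineno - 2]!r}")
    return num.astype(np.int64)


def _positions_from_combined(col: pd.Series, source: str) -> tuple[pd.Series, pd.Series]:
    """Split a combined 'chrom:start-end' (or 'chrom:start') column.

    Multi-base/range variants are reduced to their start position.
    """
    parts = col.astype(str).str.split(":", n=1, expand=True)
    if parts.shape[1] < 2 or parts[1].isna().any():
        raise ValueError(f"{source}: combined position column lacks 'chrom:pos' values")
    chrom = parts[0]
    pos_str = parts[1].str.split("-", n=1).str[0]
    return chrom, _coerce_positions(pos_str, source)


def load_and_dedup(
    streams: Sequence[tuple[object, str]],
    chrom_col: str = "chromosome",
    pos_col: str = "position",
    combined_col: str | None = None,
) -> tuple[list[MutationRecord], DedupReport]:
    """Merge mutation TSV streams and keep one record per (chrom, position).

    Parameters
    ----------
    streams : sequence of ``(stream_or_path, source)`` pairs, read in order;
        the first occurrence of a (chrom, position) pair keeps its source.
    chrom_col, pos_col : column names holding chromosome and 1-based position.
    combined_col : alternatively, a single column holding ``chrom:start-end``
        values (COSMIC "Mutation genome position" style); overrides the
        two-column mapping.  Multi-base variants are reduced to their start.
    """
    frames = []
    total = 0
    for stream, source in streams:
        df = pd.read_csv(stream, sep="\t")
        if combined_col is not None:
            if combined_col not in df.columns:
                raise ValueError(f"{source}: missing required column {combined_col!r}")
            chrom, pos = _positions_from_combined(df[combined_col], source)
        else:
            for col in (chrom_col, pos_col):
                if col not in df.columns:
                    raise ValueError(f"{source}: missing required column {col!r}")
            chrom = df[chrom_col].astype(str)
            pos = _coerce_positions(df[pos_col], source)
        total += len(df)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos, "source": source}))
    merged = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos", "source"]
    )
    unique = merged.drop_duplicates(subset=["chrom", "pos"], keep="first")
    per_source = unique["source"].value_counts().to_dict()
    n_unique = len(unique)
    report = DedupReport(
        total_read=total,
        unique_kept=n_unique,
        per_source_unique={s: int(c) for s, c in per_source.items()},
        per_source_fraction={
            s: (int(c) / n_unique if n_unique else 0.0) for s, c in per_source.items()
        },
    )
    records = list(
        map(
            MutationRecord,
            unique["chrom"].tolist(),
            unique["pos"].tolist(),
            unique["source"].tolist(),
        )
    )
    return records, report


def assign_to_transcripts(
    records: Sequence[MutationRecord], transcripts: Sequence[TranscriptModel]
) -> tuple[dict[str, int], int]:
    """Map each mutation to the first engulfing transcript in file order.

    Returns ``(counts_by_transcript_id, n_unassigned)``; assigned plus
    unassigned always equals the number of input records.
    """
    # per-chromosome span arrays in annotation-file order
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for idx, t in enumerate(transcripts):
        by_chrom.setdefault(t.chrom, []).append((t.tx_start, t.tx_end, idx))

    pos_by_chrom: dict[str, list[int]] = {}
    for r in records:
        pos_by_chrom.setdefault(r.chrom, []).append(r.pos)

    counts = np.zeros(len(transcripts), dtype=np.int64)
    unassigned = 0
    for chrom, positions in pos_by_chrom.items():
        q = np.asarray(positions, dtype=np.int64) - 1  # 0-based query points
        spans = by_chrom.get(chrom)
        if not spans:
            unassigned += len(q)
            continue
        order = sorted(spans)  # by start
        starts = np.array([s for s, _, _ in order], dtype=np.int64)
        ends = np.array([e for _, e, _ in order], dtype=np.int64)
        idxs = np.array([i for _, _, i in order], dtype=np.int64)
        if np.all(starts[1:] >= ends[:-1]):
            # non-overlapping spans: each point hits at most one transcript
            j = np.searchsorted(starts, q, side="right") - 1
            hit = (j >= 0) & (q < ends[np.clip(j, 0, len(ends) - 1)])
            np.add.at(counts, idxs[j[hit]], 1)
            unassigned += int((~hit).sum())
        else:
            tree = IntervalTree()
            for s, e, i in spans:
                tree.addi(s, e, i)
            for point in q:
                hits = tree[int(point)]
                if hits:
                    counts[min(iv.data for iv in hits)] += 1
                else:
                    unassigned += 1
    out = {
        transcripts[i].transcript_id: int(c) for i, c in enumerate(counts) if c > 0
    }
    return out, unassigned


def counts_per_gene(
    tx_counts: dict[str, int],
    genes: Sequence[GeneSummary],
    include_zero: bool = False,
) -> list[GeneMutationCount]:
    """Per-gene mutation counts, taken from the representative transcript only.

    Counts assigned to alternate transcripts are dropped, not re-attributed.
    By default only genes with at least one mapped event are returned;
    ``include_zero=True`` keeps all genes.
    """
    out = []
    for g in genes:
        n = tx_counts.get(g.representative_id, 0)
        if n == 0 and not include_zero:
            continue
        out.append(
            GeneMutationCount(
                gene_symbol=g.gene_symbol, n_mutations=n, L_tr=g.L_tr, N_tr=g.N_tr
            )
        )
    return out


def fit_burden(counts: Sequence[GeneMutationCount]) -> BurdenFit:
    """OLS of mutation count on L_tr, with the Pearson correlation of the pairs."""
    if len(counts) < 3:
        raise ValueError("fit_burden: need at least 3 genes")
    x = np.array([c.L_tr for c in counts], dtype=float)
    y = np.array([c.n_mutations for c in counts], dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("fit_burden: non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("fit_burden: zero variance in transcript length")
    res = stats.linregress(x, y)
    # constant counts: flat line with an undefined correlation, reported as 0
    r = float(res.rvalue) if np.ptp(y) > 0 else 0.0
    return BurdenFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=r,
        n_genes=len(counts),
    )


@dataclass(frozen=True, slots=True)
class SpliceGroupSummary:
    """Five-number summary (plus mean) of mutation counts at one N_tr value."""

    N_tr: int
    n_genes: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    mean: float


def burden_by_splice_count(
    counts: Sequence[GeneMutationCount], min_group: int = 500
) -> list[SpliceGroupSummary]:
    """Mutation-count distribution per N_tr group with at least ``min_group`` genes."""
    groups: dict[int, list[int]] = {}
    for c in counts:
        groups.setdefault(c.N_tr, []).append(c.n_mutations)
    out = []
    for ntr in sorted(groups):
        vals = np.array(groups[ntr], dtype=float)
        if len(vals) < min_group:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        out.append(
            SpliceGroupSummary(
                N_tr=ntr,
                n_genes=len(vals),
                minimum=float(vals.min()),
                q1=float(q1),
                median=float(med),
                q3=float(q3),
                maximum=float(vals.max()),
                mean=float(vals.mean()),
            )
        )
    return out


def write_gene_counts_tsv(counts: Sequence[GeneMutationCount], stream: IO[str]) -> None:
    stream.write("gene\tn_mutations\tL_tr\tN_tr\n")
    for c in counts:
        stream.write(f"{c.gene_symbol}\t{c.n_mutations}\t{c.L_tr}\t{c.N_tr}\n")
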