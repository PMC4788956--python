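"""Synthetic annotation, gene-set and mutation-catalog generation.

The generator emulates the statistical structure the analysis pipeline
assumes: heavy-tailed (log-normal) exon and intron lengths, a zero-truncated
geometric splice-variant count coupled to exon count (so longer genes tend
to have more transcripts), a designated subset of "case" genes collected
into case pathways with controllable length and splice-count shifts, and
per-gene Poisson mutation catalogs whose rate is proportional to transcript
length.  Every generator is fully deterministic given the config seed, and
returns the planted per-gene truth for oracle tests.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GeneSummary, TranscriptModel, compute_transcript_metrics, write_genepred
from .burden import BurdenFit, assign_to_transcripts, counts_per_gene, fit_burden, load_and_dedup
from .pathways import GeneSetCollection, label_pathways, write_gmt

_CHROMS = tuple(f"chr{i}" for i in range(1, 23))
_GENE_GAP = 10_000


@dataclass(frozen=True, slots=True)
class SyntheticConfig:
    """Parameters of the synthetic genome/pathway/mutation generator.

    Defaults mirror the real-data setting the pipeline targets: a ~19k-gene
    universe with ~1.95 transcripts per gene, 186 pathways of which 15 are
    case (cancer-like) with 380 member genes, a 1.4x intron-length shift and
    +0.5 splice-count shift for case genes, and a somatic mutation rate of
    0.0032 events per nucleotide with 86.2% of records in the noncoding
    stream.
    """

    seed: int = 0
    n_genes: int = 19_219
    # architecture of the longest transcript
    exon_count_mean: float = 8.0  # geometric, support >= 1
    exon_log_mean: float = math.log(150.0)  # log-normal exon length (nt)
    exon_log_sd: float = 0.75
    intron_log_mean: float = math.log(2000.0)  # log-normal intron length (nt)
    intron_log_sd: float = 1.3
    # splice variants
    ntr_mean: float = 1.95  # zero-truncated geometric mean
    ntr_exon_coupling: float = 0.25  # relative exon-count increase per extra transcript
    # pathways
    n_pathways: int = 186
    pathway_size_lo: int = 25
    pathway_size_hi: int = 85
    n_case_pathways: int = 15
    n_case_genes: int = 380
    # planted case effects
    case_length_shift: float = 1.4  # multiplier on case-gene intron lengths
    case_ntr_shift: float = 0.5  # additive shift of the case N_tr mean
    case_length_shift_ntr: tuple[int, ...] | None = None  # restrict shift to these N_tr
    # mutation catalog
    mutation_rate_per_nt: float = 0.0032
    noncoding_fraction: float = 0.862
    duplicate_record_rate: float = 0.05

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.exon_count_mean < 1 or self.ntr_mean < 1:
            raise ValueError("geometric means must be >= 1")
        for name in ("exon_log_sd", "intron_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.pathway_size_lo <= self.pathway_size_hi):
            raise ValueError("need 0 < pathway_size_lo <= pathway_size_hi")
        if self.n_case_pathways > self.n_pathways:
            raise ValueError("n_case_pathways exceeds n_pathways")
        if self.n_case_genes > self.n_genes:
            raise ValueError("n_case_genes exceeds n_genes")
        if self.case_length_shift <= 0:
            raise ValueError("case_length_shift must be positive")
        if self.mutation_rate_per_nt < 0:
            raise ValueError("mutation_rate_per_nt must be >= 0")
        if not 0 <= self.noncoding_fraction <= 1:
            raise ValueError("noncoding_fraction must be in [0, 1]")
        if not 0 <= self.duplicate_record_rate <= 1:
            raise ValueError("duplicate_record_rate must be in [0, 1]")


#: named presets: the default genome-scale shape, the same shape with all
#: planted case effects switched off, and a small fast fixture
PRESETS: dict[str, SyntheticConfig] = {
    "full": SyntheticConfig(),
    "null": SyntheticConfig(case_length_shift=1.0, case_ntr_shift=0.0),
    "toy": SyntheticConfig(
        n_genes=300,
        exon_count_mean=4.0,
        n_pathways=12,
        pathway_size_lo=8,
        pathway_size_hi=20,
        n_case_pathways=3,
        n_case_genes=40,
    ),
}


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    # independent substreams for annotation / genesets / mutations
    return np.random.default_rng([cfg.seed, stream])


def _cumsum0(a: np.ndarray) -> np.ndarray:
    out = np.zeros(len(a) + 1, dtype=np.int64)
    np.cumsum(a, out=out[1:])
    return out


@dataclass(frozen=True, slots=True)
class Architecture:
    """Vectorized per-gene architecture sample (internal)."""

    symbols: list[str]
    is_case: np.ndarray
    ntr: np.ndarray
    n_ex: np.ndarray
    exon_lengths: np.ndarray  # flat, segmented by ex_offsets
    intron_lengths: np.ndarray  # flat, segmented by int_offsets
    ex_offsets: np.ndarray
    int_offsets: np.ndarray
    l_ex: np.ndarray
    l_int: np.ndarray
    l_tr: np.ndarray


def _sample_architecture(cfg: SyntheticConfig, rng: np.random.Generator) -> Architecture:
    n = cfg.n_genes
    symbols = [f"G{i:06d}" for i in range(n)]
    is_case = np.zeros(n, dtype=bool)
    if cfg.n_case_genes:
        is_case[rng.choice(n, size=cfg.n_case_genes, replace=False)] = True

    ntr = rng.geometric(1.0 / cfg.ntr_mean, size=n).astype(np.int64)
    if cfg.n_case_genes and cfg.case_ntr_shift != 0:
        ntr[is_case] = rng.geometric(
            1.0 / (cfg.ntr_mean + cfg.case_ntr_shift), size=int(is_case.sum())
        )

    # length/splice-count coupling: more transcripts -> more exons on average
    exon_mean = cfg.exon_count_mean * (1.0 + cfg.ntr_exon_coupling * (ntr - 1))
    n_ex = rng.geometric(1.0 / exon_mean).astype(np.int64)

    ex_offsets = _cumsum0(n_ex)
    exon_lengths = np.maximum(
        1, np.rint(rng.lognormal(cfg.exon_log_mean, cfg.exon_log_sd, int(n_ex.sum())))
    ).astype(np.int64)

    n_int = n_ex - 1
    int_offsets = _cumsum0(n_int)
    intron_lengths = np.maximum(
        1, np.rint(rng.lognormal(cfg.intron_log_mean, cfg.intron_log_sd, int(n_int.sum())))
    ).astype(np.int64)

    shifted = is_case.copy()
    if cfg.case_length_shift_ntr is not None:
        shifted &= np.isin(ntr, np.asarray(cfg.case_length_shift_ntr))
    if cfg.case_length_shift != 1.0 and shifted.any():
        per_intron_shifted = np.repeat(shifted, n_int)
        scaled = np.rint(intron_lengths[per_intron_shifted] * cfg.case_length_shift)
        intron_lengths[per_intron_shifted] = np.maximum(1, scaled).astype(np.int64)

    ex_cs = _cumsum0(exon_lengths)
    int_cs = _cumsum0(intron_lengths)
    l_ex = ex_cs[ex_offsets[1:]] - ex_cs[ex_offsets[:-1]]
    l_int = int_cs[int_offsets[1:]] - int_cs[int_offsets[:-1]]
    return Architecture(
        symbols=symbols,
        is_case=is_case,
        ntr=ntr,
        n_ex=n_ex,
        exon_lengths=exon_lengths,
        intron_lengths=intron_lengths,
        ex_offsets=ex_offsets,
        int_offsets=int_offsets,
        l_ex=l_ex,
        l_int=l_int,
        l_tr=l_ex + l_int,
    )


def _truth_frame(arch: Architecture) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": arch.symbols,
            "is_case": arch.is_case,
            "N_tr": arch.ntr,
            "n_ex": arch.n_ex,
            "l_ex": arch.l_ex,
            "l_int": arch.l_int,
            "L_tr": arch.l_tr,
        }
    )


def generate_annotation(
    cfg: SyntheticConfig,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Generate transcript models plus the planted per-gene truth table.

    Per gene, the longest transcript is built from sampled exon/intron
    lengths and written first; the remaining N_tr-1 alternates are exon
    sub-selections sharing the same genomic span.  Genes are laid end to
    end (with a fixed gap) across 22 synthetic chromosomes, so gene spans
    never overlap.
    """
    rng = _rng(cfg, 1)
    arch = _sample_architecture(cfg, rng)
    cursors = {c: 0 for c in _CHROMS}
    transcripts: list[TranscriptModel] = []
    for i, symbol in enumerate(arch.symbols):
        el = arch.exon_lengths[arch.ex_offsets[i] : arch.ex_offsets[i + 1]]
        il = arch.intron_lengths[arch.int_offsets[i] : arch.int_offsets[i + 1]]
        chrom = _CHROMS[i % len(_CHROMS)]
        tx_start = cursors[chrom] + _GENE_GAP
        rel_starts = np.zeros(len(el), dtype=np.int64)
        if len(el) > 1:
            rel_starts[1:] = np.cumsum(el[:-1] + il)
        starts = tx_start + rel_starts
        ends = starts + el
        exons = tuple(zip(starts.tolist(), ends.tolist()))
        tx_end = int(ends[-1])
        cursors[chrom] = tx_end
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(
            TranscriptModel(
                transcript_id=f"{symbol}.t1",
                gene_symbol=symbol,
                chrom=chrom,
                strand=strand,
                tx_start=int(tx_start),
                tx_end=tx_end,
                exons=exons,
            )
        )
        for alt in range(2, int(arch.ntr[i]) + 1):
            if len(exons) > 2:
                keep = np.ones(len(exons), dtype=bool)
                keep[1:-1] = rng.random(len(exons) - 2) < 0.5
                alt_exons = tuple(e for e, k in zip(exons, keep) if k)
            else:
                alt_exons = exons
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"{symbol}.t{alt}",
                    gene_symbol=symbol,
                    chrom=chrom,
                    strand=strand,
                    tx_start=int(tx_start),
                    tx_end=tx_end,
                    exons=alt_exons,
                )
            )
    return transcripts, _truth_frame(arch)


def generate_gene_summaries(
    cfg: SyntheticConfig,
) -> tuple[list[GeneSummary], pd.DataFrame]:
    """Fast path: per-gene summaries without materializing exon structures.

    Samples the identical architecture stream as :func:`generate_annotation`
    (same seed, same draws), so the returned summaries match what
    ``summarize_genes`` would produce on the generated annotation, at a
    fraction of the cost.  Used by replicated power/calibration studies.
    """
    rng = _rng(cfg, 1)
    arch = _sample_architecture(cfg, rng)
    from .annotation import LONG_GENE_THRESHOLD, TranscriptMetrics

    out = []
    for i, symbol in enumerate(arch.symbols):
        l_tr = int(arch.l_tr[i])
        l_ex = int(arch.l_ex[i])
        l_int = int(arch.l_int[i])
        n_ex = int(arch.n_ex[i])
        n_int = n_ex - 1
        metrics = TranscriptMetrics(
            l_tr=l_tr,
            l_ex=l_ex,
            l_int=l_int,
            n_ex=n_ex,
            n_int=n_int,
            avg_ex=l_ex / n_ex,
            avg_int=(l_int / n_int) if n_int else None,
            ratio_int_ex=l_int / l_ex,
        )
        out.append(
            GeneSummary(
                gene_symbol=symbol,
                L_tr=l_tr,
                N_tr=int(arch.ntr[i]),
                representative_id=f"{symbol}.t1",
                metrics=metrics,
                exceeds_200k=l_tr > LONG_GENE_THRESHOLD,
            )
        )
    return out, _truth_frame(arch)


def generate_genesets(
    cfg: SyntheticConfig, truth: pd.DataFrame
) -> tuple[GeneSetCollection, list[str]]:
    """Build a labelled pathway collection from the planted truth.

    Every case gene is dealt into at least one case pathway (so the
    partition of the universe reproduces the planted case/other split
    exactly); case pathways are padded to their target sizes with further
    case genes, and other pathways are sampled from the non-case pool.
    """
    rng = _rng(cfg, 2)
    case_pool = truth.loc[truth["is_case"], "gene"].tolist()
    other_pool = truth.loc[~truth["is_case"], "gene"].tolist()
    n_other_pathways = cfg.n_pathways - cfg.n_case_pathways
    if cfg.pathway_size_hi > len(other_pool):
        raise ValueError("pathway size exceeds non-case universe")
    if cfg.n_case_pathways and not case_pool:
        raise ValueError("case pathways requested but no case genes planted")

    sets: dict[str, frozenset[str]] = {}
    case_names: list[str] = []
    if cfg.n_case_pathways:
        dealt: list[list[str]] = [[] for _ in range(cfg.n_case_pathways)]
        order = rng.permutation(len(case_pool))
        for j, gi in enumerate(order):
            dealt[j % cfg.n_case_pathways].append(case_pool[gi])
        targets = rng.integers(
            cfg.pathway_size_lo, cfg.pathway_size_hi + 1, size=cfg.n_case_pathways
        )
        for p in range(cfg.n_case_pathways):
            members = set(dealt[p])
            want = int(targets[p])
            extra = [g for g in case_pool if g not in members]
            if len(members) < want and extra:
                n_pad = min(want - len(members), len(extra))
                pad = rng.choice(len(extra), size=n_pad, replace=False)
                members.update(extra[i] for i in pad)
            name = f"SYN_CANCER_PATHWAY_{p + 1:02d}"
            case_names.append(name)
            sets[name] = frozenset(members)
    sizes = rng.integers(cfg.pathway_size_lo, cfg.pathway_size_hi + 1, size=n_other_pathways)
    for p in range(n_other_pathways):
        idx = rng.choice(len(other_pool), size=int(sizes[p]), replace=False)
        sets[f"SYN_PATHWAY_{p + 1:03d}"] = frozenset(other_pool[i] for i in idx)
    collection = label_pathways(GeneSetCollection(sets=sets), case_names)
    return collection, case_names


def generate_mutations(
    cfg: SyntheticConfig, transcripts: list[TranscriptModel]
) -> dict[str, str]:
    """Generate coding/noncoding mutation catalog TSVs (as text).

    Per gene, the longest transcript receives a Poisson(rate * l_tr) number
    of events at positions uniform over its span (1-based).  Each event is
    assigned to the noncoding stream with probability
    ``noncoding_fraction``; duplicated records are injected at
    ``duplicate_record_rate`` to exercise deduplication.
    """
    if not transcripts:
        raise ValueError("generate_mutations: no transcripts")
    rng = _rng(cfg, 3)
    best: dict[str, TranscriptModel] = {}
    for t in transcripts:
        cur = best.get(t.gene_symbol)
        if cur is None or (t.tx_end - t.tx_start) > (cur.tx_end - cur.tx_start):
            best[t.gene_symbol] = t
    reps = list(best.values())
    l_tr = np.array([t.tx_end - t.tx_start for t in reps], dtype=np.int64)
    counts = rng.poisson(cfg.mutation_rate_per_nt * l_tr)
    total = int(counts.sum())
    gene_idx = np.repeat(np.arange(len(reps)), counts)
    starts = np.array([t.tx_start for t in reps], dtype=np.int64)[gene_idx]
    spans = l_tr[gene_idx]
    pos = starts + 1 + (rng.random(total) * spans).astype(np.int64)
    chroms = np.array([t.chrom for t in reps])[gene_idx]

    dup = rng.random(total) < cfg.duplicate_record_rate
    all_pos = np.concatenate([pos, pos[dup]])
    all_chroms = np.concatenate([chroms, chroms[dup]])
    noncoding = rng.random(len(all_pos)) < cfg.noncoding_fraction

    out = {}
    for source, mask in (("coding", ~noncoding), ("noncoding", noncoding)):
        df = pd.DataFrame({"chromosome": all_chroms[mask], "position": all_pos[mask]})
        out[source] = df.to_csv(sep="\t", index=False)
    return out


def write_fixture(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Emit a complete fixture directory: genePred, GMT, case list, catalogs, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcripts, truth = generate_annotation(cfg)
    collection, case_names = generate_genesets(cfg, truth)
    catalogs = generate_mutations(cfg, transcripts)
    paths = {
        "annotation": outdir / "annotation.genepred",
        "gmt": outdir / "pathways.gmt",
        "case_list": outdir / "case_pathways.txt",
        "coding": outdir / "mutations_coding.tsv",
        "noncoding": outdir / "mutations_noncoding.tsv",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["annotation"], "w") as fh:
        write_genepred(transcripts, fh)
    with open(paths["gmt"], "w") as fh:
        write_gmt(collection, fh)
    paths["case_list"].write_text("".join(n + "\n" for n in case_names))
    paths["coding"].write_text(catalogs["coding"])
    paths["noncoding"].write_text(catalogs["noncoding"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def length_grid_transcripts(
    n_genes: int, length_lo: int, length_hi: int, seed: int
) -> list[TranscriptModel]:
    """Single-exon transcripts with log-uniform span lengths, one per gene.

    Used by the mutation-burden parameter-recovery study: lengths are drawn
    log-uniformly on [length_lo, length_hi] and genes are laid out without
    overlap across the synthetic chromosomes.
    """
    rng = np.random.default_rng(seed)
    lengths = np.exp(
        rng.uniform(math.log(length_lo), math.log(length_hi), size=n_genes)
    ).astype(np.int64)
    lengths = np.clip(lengths, length_lo, length_hi)
    cursors = {c: 0 for c in _CHROMS}
    out = []
    for i, ln in enumerate(lengths):
        chrom = _CHROMS[i % len(_CHROMS)]
        tx_start = cursors[chrom] + _GENE_GAP
        tx_end = tx_start + int(ln)
        cursors[chrom] = tx_end
        out.append(
            TranscriptModel(
                transcript_id=f"G{i:05d}.t1",
                gene_symbol=f"G{i:05d}",
                chrom=chrom,
                strand="+",
                tx_start=tx_start,
                tx_end=tx_end,
                exons=((tx_start, tx_end),),
            )
        )
    return out


def burden_recovery_replicate(
    rate_per_nt: float,
    n_genes: int = 2000,
    length_lo: int = 1000,
    length_hi: int = 2_000_000,
    seed: int = 1,
) -> BurdenFit:
    """One end-to-end mutation-burden replicate on a synthetic catalog.

    Generates single-transcript genes with log-uniform lengths, a Poisson
    catalog at ``rate_per_nt`` split into coding/noncoding streams with
    duplicate records injected, then runs the full load -> dedup -> assign
    -> per-gene-count -> OLS pipeline and returns the fit.
    """
    transcripts = length_grid_transcripts(n_genes, length_lo, length_hi, seed)
    cfg = replace(PRESETS["full"], seed=seed, mutation_rate_per_nt=rate_per_nt)
    catalogs = generate_mutations(cfg, transcripts)
    records, _ = load_and_dedup(
        [
            (io.StringIO(catalogs["coding"]), "coding"),
            (io.StringIO(catalogs["noncoding"]), "noncoding"),
        ]
    )
    tx_counts, _ = assign_to_transcripts(records, transcripts)
    from .annotation import summarize_genes

    genes = summarize_genes(transcripts)
    counts = counts_per_gene(tx_counts, genes)
    return fit_burden(counts)
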