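"""Shared fixtures: lightweight gene/pathway factories and brute-force oracles."""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import pytest

from genarch.annotation import GeneSummary, TranscriptMetrics, TranscriptModel
from genarch.pathways import PathwaySummary


def make_gene(
    symbol: str,
    l_tr: float,
    ntr: int = 1,
    l_ex: float | None = None,
    n_ex: int = 2,
) -> GeneSummary:
    """Minimal GeneSummary for tests that only exercise per-gene metrics."""
    if l_ex is None:
        l_ex = min(200.0, l_tr)
    l_int = l_tr - l_ex
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
    return GeneSummary(
        gene_symbol=symbol,
        L_tr=l_tr,
        N_tr=ntr,
        representative_id=f"{symbol}.t1",
        metrics=metrics,
        exceeds_200k=l_tr > 200_000,
    )


def make_pathway_summary(
    name: str, label: str, mean_L_tr: float, mean_N_tr: float = 2.0
) -> PathwaySummary:
    return PathwaySummary(
        pathway_name=name,
        label=label,
        n_genes_matched=10,
        n_genes_unmatched=0,
        mean_L_tr=mean_L_tr,
        mean_N_tr=mean_N_tr,
        frac_Ntr_gt=0.0,
        frac_above_200k=0.0,
        missing=False,
    )


def enum_mwu_p_greater(x, y) -> float:
    """Brute-force one-sided Mann-Whitney p by enumerating all labelings."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)
    u_obs = sum(a > b for a in x for b in y)
    total = 0
    count = 0
    indices = range(len(pooled))
    for chosen in itertools.combinations(indices, n):
        chosen_set = set(chosen)
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in indices if i not in chosen_set]
        u = sum(a > b for a in xs for b in ys)
        total += 1
        if u >= u_obs:
            count += 1
    return count / total


def ease_oracle(k: int, n: int, K: int, N: int) -> float:
    """Exact-rational EASE p: hypergeometric upper tail of the decremented table."""
    if k <= 1:
        return 1.0
    N1, K1, n1 = N - 1, K - 1, n - 1
    total = comb(N1, n1)
    num = sum(
        comb(K1, i) * comb(N1 - K1, n1 - i)
        for i in range(k - 1, min(K1, n1) + 1)
        if n1 - i <= N1 - K1
    )
    return float(Fraction(num, total))


@pytest.fixture
def three_exon_transcript() -> TranscriptModel:
    return TranscriptModel(
        transcript_id="NM_1",
        gene_symbol="GENEA",
        chrom="chr1",
        strand="+",
        tx_start=0,
        tx_end=1000,
        exons=((0, 100), (400, 500), (900, 1000)),
    )
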