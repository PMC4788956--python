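"""Top-gene selection rules and EASE-score over-representation analysis.

The EASE score is DAVID's conservative variant of the one-tailed Fisher
exact test: one gene is removed from the list-hit cell before computing the
upper-tail hypergeometric probability, so pathways hit by a single list
gene are never significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneSummary
from .pathways import GeneSetCollection

log = logging.getLogger(__name__)

TOP_METRICS = ("l_ex", "l_tr")


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One pathway's hit counts and EASE p-value against the background."""

    pathway_name: str
    k_hits: int
    n_list: int
    K_bg: int
    N_bg: int
    p_ease: float
    significant: bool


def select_top_by_metric(
    genes: Sequence[GeneSummary], metric: str = "l_tr", k_sigma: float = 2.0
) -> list[str]:
    """Genes whose metric exceeds the median plus ``k_sigma`` sample SDs.

    Under normality the default k_sigma=2 keeps roughly the top 2.3% of
    genes.  Output is ordered by descending metric value.  A zero-variance
    metric yields an empty selection with a warning.
    """
    if metric not in TOP_METRICS:
        raise ValueError(f"unsupported top-gene metric {metric!r}")
    if len(genes) < 2:
        raise ValueError("select_top_by_metric: need at least 2 genes")
    values = np.array([getattr(g.metrics, metric) for g in genes], dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("select_top_by_metric: non-finite metric values")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn("select_top_by_metric: zero variance, empty selection", stacklevel=2)
        return []
    threshold = np.median(values) + k_sigma * sd
    selected = [(v, g.gene_symbol) for v, g in zip(values, genes) if v > threshold]
    selected.sort(key=lambda t: (-t[0], t[1]))
    return [sym for _, sym in selected]


def select_multi_splice(genes: Sequence[GeneSummary], threshold: int = 3) -> list[str]:
    """Genes with strictly more than ``threshold`` annotated transcripts."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return [g.gene_symbol for g in genes if g.N_tr > threshold]


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """EASE p-value for k list hits, list size n, K background hits, universe N.

    Computes the one-sided upper-tail Fisher exact p of the 2x2 table with
    the list-hit cell decremented by one, i.e. P(X >= k-1) for
    X ~ Hypergeom(N-1, K-1, n-1).  For k in {0, 1} the decrement removes
    the entire signal and p is exactly 1.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if n - k > N - K:
        raise ValueError(f"list misses exceed background misses: k={k} n={n} K={K} N={N}")
    if k <= 1:
        return 1.0
    # sf(k-2) = P(X > k-2) = P(X >= k-1)
    return float(stats.hypergeom.sf(k - 2, N - 1, K - 1, n - 1))


def enrich_gene_list(
    list_genes: set[str] | frozenset[str] | Sequence[str],
    c: GeneSetCollection,
    background: set[str] | frozenset[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """EASE enrichment of a gene list against every pathway in the collection.

    Pathway and list genes are intersected with the background universe
    first; list genes outside the background are dropped (count logged).
    Pathways with no background overlap are excluded.  Results are sorted
    ascending by p_ease (ties by name).
    """
    bg = frozenset(background)
    lst = frozenset(list_genes)
    effective = lst & bg
    dropped = len(lst) - len(effective)
    if dropped:
        log.info("enrich_gene_list: dropped %d list genes outside background", dropped)
    if not effective:
        raise ValueError("enrich_gene_list: no list genes in background")
    n = len(effective)
    N = len(bg)
    out: list[EnrichmentResult] = []
    for name, members in c.sets.items():
        members_bg = members & bg
        K = len(members_bg)
        if K == 0:
            continue
        k = len(effective & members_bg)
        p = ease_score(k, n, K, N)
        out.append(
            EnrichmentResult(
                pathway_name=name,
                k_hits=k,
                n_list=n,
                K_bg=K,
                N_bg=N,
                p_ease=p,
                significant=p < alpha,
            )
        )
    out.sort(key=lambda r: (r.p_ease, r.pathway_name))
    return out


def read_gene_list(stream) -> list[str]:
    """Read a one-symbol-per-line gene list."""
    return [line.strip() for line in stream if line.strip()]


def write_enrichment_tsv(results: Sequence[EnrichmentResult], stream: IO[str]) -> None:
    stream.write("pathway\tk\tn\tK\tN\tp_ease\tsignificant\n")
    for r in results:
        stream.write(
            f"{r.pathway_name}\t{r.k_hits}\t{r.n_list}\t{r.K_bg}\t{r.N_bg}\t"
            f"{r.p_ease:.6g}\t{int(r.significant)}\n"
        )
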