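"""One-sided Mann–Whitney comparisons, stratified decoupling tests,
binned case fractions, and the resampled pathway check.

All comparisons test the alternative "case values are stochastically
greater than other values".  The exact null distribution of the U
statistic is used for small tie-free samples; otherwise the normal
approximation with tie correction and continuity correction applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import IO, Sequence

import numpy as np
from scipy import stats

from .annotation import GeneSummary
from .pathways import PathwaySummary

log = logging.getLogger(__name__)

#: combined-sample-size cutoff at or below which (tie-free) the exact
#: enumeration p-value is used
EXACT_CUTOFF = 16

GENE_METRICS = ("l_tr", "l_ex", "l_int", "avg_int", "ratio_int_ex", "avg_ex")
PATHWAY_METRICS = ("mean_L_tr", "mean_N_tr")


@dataclass(frozen=True, slots=True)
class ComparisonResult:
    """Outcome of one case-vs-other rank comparison."""

    metric_name: str
    n_case: int
    n_other: int
    U: float
    p_one_sided: float
    mean_case: float
    mean_other: float
    median_case: float
    median_other: float


@dataclass(frozen=True, slots=True)
class SkippedComparison:
    """Placeholder returned when a stratum is too small to test."""

    metric_name: str
    n_case: int
    n_other: int
    reason: str


@dataclass(frozen=True, slots=True)
class StratumSpec:
    """A stratum for the decoupling tests.

    ``kind="fixed_Ntr"``: genes with exactly ``value`` transcripts; the
    compared metric is L_tr.  ``kind="Ltr_interval"``: genes with L_tr in
    the half-open interval ``value=(lo, hi)``; the compared metric is N_tr.
    """

    kind: str
    value: int | tuple[int, int]
    min_group_size: int = 5

    def __post_init__(self) -> None:
        if self.kind == "fixed_Ntr":
            if not isinstance(self.value, int) or self.value < 1:
                raise ValueError("fixed_Ntr stratum needs an integer value >= 1")
        elif self.kind == "Ltr_interval":
            lo, hi = self.value  # type: ignore[misc]
            if lo >= hi:
                raise ValueError("Ltr_interval stratum needs lo < hi")
        else:
            raise ValueError(f"unknown stratum kind {self.kind!r}")


@dataclass(frozen=True, slots=True)
class BinnedFraction:
    """One bin of the case-gene fraction curve (half-open bin [lo, hi))."""

    bin_lo: int
    bin_hi: int
    n_total: int
    n_case: int
    fraction: float | None
    below_min_n: bool = False


def _exact_u_counts(n: int, m: int) -> list[int]:
    """Number of rank configurations with each U value, by integer recurrence.

    ``counts[u]`` is the number of ways to interleave n x-values and m
    y-values (no ties) such that exactly u of the n*m pairs have x > y —
    equivalently the Gaussian-binomial coefficients of [n+m choose n]_q,
    via f(u; n, m) = f(u-m; n-1, m) + f(u; n, m-1).  Integer arithmetic
    throughout, so tail probabilities computed from it match brute-force
    enumeration bit-exactly.
    """
    size = n * m + 1
    # counts for (a, m) built up over a = 0..n; inner recursion on b = 0..m
    # realized as repeated prefix structure: f(u; a, b) = f(u-b; a-1, b) + f(u; a, b-1)
    prev = {(0, b): [1] + [0] * (size - 1) for b in range(m + 1)}
    for a in range(1, n + 1):
        row: dict[int, list[int]] = {0: [1 if u == 0 else 0 for u in range(size)]}
        for b in range(1, m + 1):
            cur = [0] * size
            shifted = prev[(a - 1, b)]
            left = row[b - 1]
            for u in range(size):
                cur[u] = (shifted[u - b] if u >= b else 0) + left[u]
            row[b] = cur
        prev = {(a, b): row[b] for b in range(m + 1)}
    return prev[(n, m)]


def exact_mwu_p_greater(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact one-sided Mann–Whitney p (alternative: x greater), tie-free input.

    Returns ``(U, p)`` where p = P(U >= u_obs) under the exact permutation
    null, computed as a ratio of integers.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    n, m = len(xa), len(ya)
    u_obs = int((xa[:, None] > ya[None, :]).sum())
    counts = _exact_u_counts(n, m)
    ways_ge = sum(counts[u_obs:])
    return float(u_obs), ways_ge / comb(n + m, n)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_greater(
    x: Sequence[float],
    y: Sequence[float],
    metric_name: str = "",
    exact_cutoff: int = EXACT_CUTOFF,
) -> ComparisonResult:
    """One-sided Mann–Whitney test of "x stochastically greater than y".

    Uses the exact enumeration p-value when the combined sample size is at
    most ``exact_cutoff`` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if len(xa) == 0 or len(ya) == 0:
        raise ValueError("mann_whitney_greater: empty sample")
    if len(xa) + len(ya) <= exact_cutoff and not _has_ties(xa, ya):
        u, p = exact_mwu_p_greater(xa, ya)
    else:
        res = stats.mannwhitneyu(xa, ya, alternative="greater", method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        metric_name=metric_name,
        n_case=len(xa),
        n_other=len(ya),
        U=u,
        p_one_sided=min(p, 1.0),
        mean_case=float(xa.mean()),
        mean_other=float(ya.mean()),
        median_case=float(np.median(xa)),
        median_other=float(np.median(ya)),
    )


def _gene_metric_values(genes: Sequence[GeneSummary], metric: str) -> np.ndarray:
    if metric not in GENE_METRICS:
        raise ValueError(f"unknown gene metric {metric!r}")
    vals = [getattr(g.metrics, metric) for g in genes]
    kept = [v for v in vals if v is not None]
    dropped = len(vals) - len(kept)
    if dropped:
        log.info("compare_gene_metric: dropped %d missing %s values", dropped, metric)
    return np.asarray(kept, dtype=float)


def compare_gene_metric(
    case_genes: Sequence[GeneSummary],
    other_genes: Sequence[GeneSummary],
    metric: str = "l_tr",
) -> ComparisonResult:
    """Case-vs-other comparison of one per-gene architecture metric.

    Metric values come from each gene's representative (longest) transcript;
    missing values (e.g. avg_int of single-exon genes) are dropped.
    """
    x = _gene_metric_values(case_genes, metric)
    y = _gene_metric_values(other_genes, metric)
    if len(x) == 0 or len(y) == 0:
        raise ValueError(f"compare_gene_metric: all {metric} values missing in a group")
    return mann_whitney_greater(x, y, metric_name=metric)


def compare_pathway_averages(
    summaries: Sequence[PathwaySummary], metric: str = "mean_L_tr"
) -> ComparisonResult:
    """Case-vs-other comparison over per-pathway average metrics."""
    if metric not in PATHWAY_METRICS:
        raise ValueError(f"unknown pathway metric {metric!r}")
    x = [getattr(s, metric) for s in summaries if s.label == "case" and not s.missing]
    y = [getattr(s, metric) for s in summaries if s.label == "other" and not s.missing]
    if not x or not y:
        raise ValueError("compare_pathway_averages: need >=1 non-missing case and other summary")
    return mann_whitney_greater(x, y, metric_name=metric)


def stratified_comparison(
    case_genes: Sequence[GeneSummary],
    other_genes: Sequence[GeneSummary],
    stratum: StratumSpec,
) -> ComparisonResult | SkippedComparison:
    """Decoupling test within one stratum.

    fixed_Ntr strata compare L_tr between case and other genes that have
    exactly the given number of transcripts; Ltr_interval strata compare
    N_tr between genes whose L_tr falls in the half-open interval.
    Returns ``SkippedComparison`` when either group is smaller than
    ``stratum.min_group_size``.
    """
    if stratum.kind == "fixed_Ntr":
        sel = lambda g: g.N_tr == stratum.value  # noqa: E731
        metric = "L_tr"
        value = lambda g: float(g.L_tr)  # noqa: E731
        name = f"L_tr|N_tr={stratum.value}"
    else:
        lo, hi = stratum.value  # type: ignore[misc]
        sel = lambda g: lo <= g.L_tr < hi  # noqa: E731
        metric = "N_tr"
        value = lambda g: float(g.N_tr)  # noqa: E731
        name = f"N_tr|L_tr=[{lo},{hi})"
    x = [value(g) for g in case_genes if sel(g)]
    y = [value(g) for g in other_genes if sel(g)]
    if len(x) < stratum.min_group_size or len(y) < stratum.min_group_size:
        return SkippedComparison(
            metric_name=name,
            n_case=len(x),
            n_other=len(y),
            reason=f"group below min_group_size={stratum.min_group_size}",
        )
    return mann_whitney_greater(x, y, metric_name=name)


def default_strata(
    ntr_values: Sequence[int] = tuple(range(1, 11)),
    ltr_bin_width: int = 25_000,
    ltr_max: int = 200_000,
    min_group_size: int = 5,
) -> list[StratumSpec]:
    """The default stratification grid: N_tr 1..10 and 25k-wide L_tr bins."""
    strata = [StratumSpec("fixed_Ntr", v, min_group_size) for v in ntr_values]
    strata += [
        StratumSpec("Ltr_interval", (lo, lo + ltr_bin_width), min_group_size)
        for lo in range(0, ltr_max, ltr_bin_width)
    ]
    return strata


def binned_case_fraction(
    genes: Sequence[GeneSummary],
    case_symbols: set[str] | frozenset[str],
    axis: str = "L_tr",
    bin_width: int = 3000,
    min_bin_n: int | None = None,
) -> list[BinnedFraction]:
    """Fraction of case-pathway genes per half-open bin along L_tr or N_tr.

    L_tr bins are [k*w, (k+1)*w); the N_tr axis uses one bin per integer
    value.  Bins with fewer than ``min_bin_n`` genes are flagged, not
    dropped.  Empty bins between occupied ones are reported with fraction
    None.
    """
    if axis == "L_tr":
        if bin_width <= 0:
            raise ValueError("bin_width must be positive")
        key = lambda g: int(g.L_tr // bin_width)  # noqa: E731
        bounds = lambda k: (k * bin_width, (k + 1) * bin_width)  # noqa: E731
    elif axis == "N_tr":
        key = lambda g: int(g.N_tr)  # noqa: E731
        bounds = lambda k: (k, k + 1)  # noqa: E731
    else:
        raise ValueError(f"unknown axis {axis!r}")
    totals: dict[int, int] = {}
    cases: dict[int, int] = {}
    for g in genes:
        k = key(g)
        totals[k] = totals.get(k, 0) + 1
        if g.gene_symbol in case_symbols:
            cases[k] = cases.get(k, 0) + 1
    if not totals:
        return []
    out = []
    for k in range(min(totals), max(totals) + 1):
        lo, hi = bounds(k)
        n_total = totals.get(k, 0)
        n_case = cases.get(k, 0)
        out.append(
            BinnedFraction(
                bin_lo=lo,
                bin_hi=hi,
                n_total=n_total,
                n_case=n_case,
                fraction=(n_case / n_total) if n_total > 0 else None,
                below_min_n=(min_bin_n is not None and n_total < min_bin_n),
            )
        )
    return out


def resampled_pathway_comparison(
    summaries: Sequence[PathwaySummary],
    metric: str = "mean_L_tr",
    n_iter: int = 999,
    seed: int = 0,
) -> float:
    """Empirical p for the case-pathway mean by resampling other pathways.

    Draws ``n_iter`` samples of size |case| from the other-labelled
    summaries (without replacement within a draw) and compares the mean of
    the chosen per-pathway metric against the observed case mean, with an
    add-one pseudocount so p is never zero.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    if metric not in PATHWAY_METRICS:
        raise ValueError(f"unknown pathway metric {metric!r}")
    case_vals = np.array(
        [getattr(s, metric) for s in summaries if s.label == "case" and not s.missing]
    )
    other_vals = np.array(
        [getattr(s, metric) for s in summaries if s.label == "other" and not s.missing]
    )
    if len(case_vals) < 1:
        raise ValueError("need at least one case pathway")
    if len(other_vals) < len(case_vals):
        raise ValueError("fewer other pathways than case pathways")
    observed = case_vals.mean()
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_iter):
        draw = rng.choice(other_vals, size=len(case_vals), replace=False)
        if draw.mean() >= observed:
            n_ge += 1
    return (1 + n_ge) / (n_iter + 1)


def write_comparisons_tsv(
    results: Sequence[ComparisonResult | SkippedComparison], stream: IO[str]
) -> None:
    stream.write(
        "metric\tn_case\tn_other\tU\tp_one_sided\tmean_case\tmean_other\t"
        "median_case\tmedian_other\tstatus\n"
    )
    for r in results:
        if isinstance(r, SkippedComparison):
            stream.write(
                f"{r.metric_name}\t{r.n_case}\t{r.n_other}\tNA\tNA\tNA\tNA\tNA\tNA\t"
                f"SKIPPED:{r.reason}\n"
            )
        else:
            stream.write(
                f"{r.metric_name}\t{r.n_case}\t{r.n_other}\t{r.U:g}\t{r.p_one_sided:.6g}\t"
                f"{r.mean_case:.6g}\t{r.mean_other:.6g}\t{r.median_case:.6g}\t"
                f"{r.median_other:.6g}\tOK\n"
            )


def write_binned_fractions_tsv(bins: Sequence[BinnedFraction], stream: IO[str]) -> None:
    stream.write("bin_lo\tbin_hi\tn_total\tn_case\tfraction\tbelow_min_n\n")
    for b in bins:
        frac = "NA" if b.fraction is None else f"{b.fraction:.6g}"
        stream.write(
            f"{b.bin_lo}\t{b.bin_hi}\t{b.n_total}\t{b.n_case}\t{frac}\t{int(b.below_min_n)}\n"
        )
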