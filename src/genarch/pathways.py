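"""Gene-set collections (GMT), case/other pathway labelling and pathway summaries.

A collection is a KEGG-style set of named pathways.  A subset of pathways is
labelled ``case`` (e.g. the cancer pathways); all genes of the annotation
universe found in at least one case pathway form the case gene group, every
other annotated gene — whether in another pathway or in none — forms the
comparison group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

from .annotation import GeneSummary

log = logging.getLogger(__name__)

CASE = "case"
OTHER = "other"

#: Default substrings (lower-cased) used to pick cancer pathways by name
#: when no explicit case list is supplied; mirrors KEGG naming.
DEFAULT_CASE_NAME_HINTS = (
    "cancer",
    "leukemia",
    "melanoma",
    "glioma",
    "carcinoma",
)


@dataclass
class GeneSetCollection:
    """Ordered named gene sets with case/other labels (default: all other)."""

    sets: dict[str, frozenset[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
        for name in self.sets:
            self.labels.setdefault(name, OTHER)

    def case_names(self) -> list[str]:
        return [n for n in self.sets if self.labels[n] == CASE]

    def case_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for name in self.case_names():
            out |= self.sets[name]
        return frozenset(out)


@dataclass(frozen=True, slots=True)
class PathwaySummary:
    """Aggregate architecture metrics of the genes matched in one pathway.

    ``missing`` is True when no pathway gene is present in the annotation;
    such summaries are excluded from downstream comparisons.
    """

    pathway_name: str
    label: str
    n_genes_matched: int
    n_genes_unmatched: int
    mean_L_tr: float | None
    mean_N_tr: float | None
    frac_Ntr_gt: float | None
    frac_above_200k: float | None
    missing: bool


def parse_gmt(stream: Iterable[str]) -> GeneSetCollection:
    """Parse GMT text: one set per line, ``name TAB description TAB gene...``.

    Duplicate genes within a line are collapsed; a duplicate pathway name or
    a line with fewer than three fields is an error.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 fields, got {len(fields)}")
        name = fields[0]
        if name in sets:
            raise ValueError(f"GMT line {lineno}: duplicate pathway name {name!r}")
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValueError(f"GMT line {lineno}: pathway {name!r} has no genes")
        sets[name] = genes
    return GeneSetCollection(sets=sets)


def write_gmt(c: GeneSetCollection, stream: IO[str]) -> None:
    for name, genes in c.sets.items():
        stream.write("\t".join([name, c.labels[name]] + sorted(genes)) + "\n")


def label_pathways(c: GeneSetCollection, case_names: Sequence[str]) -> GeneSetCollection:
    """Return a copy of the collection with the named pathways labelled case."""
    missing = [n for n in case_names if n not in c.sets]
    if missing:
        raise ValueError(f"unknown case pathway names: {', '.join(sorted(missing))}")
    labels = {name: (CASE if name in set(case_names) else OTHER) for name in c.sets}
    return GeneSetCollection(sets=dict(c.sets), labels=labels)


def label_pathways_by_name(
    c: GeneSetCollection, hints: Sequence[str] = DEFAULT_CASE_NAME_HINTS
) -> GeneSetCollection:
    """Heuristic labelling: pathways whose name contains a hint become case."""
    case = [n for n in c.sets if any(h in n.lower() for h in hints)]
    return label_pathways(c, case)


def read_case_list(stream: Iterable[str]) -> list[str]:
    """Read a plain-text case-pathway list, one name per line."""
    return [line.strip() for line in stream if line.strip()]


def partition_genes(
    c: GeneSetCollection, genes: Sequence[GeneSummary]
) -> tuple[list[GeneSummary], list[GeneSummary]]:
    """Split the annotation universe into case-pathway genes and all the rest.

    The "other" group is the full remaining universe (including genes in no
    pathway), so the two lists always partition the input exactly.
    """
    if not genes:
        raise ValueError("partition_genes: empty gene universe")
    case_symbols = c.case_genes()
    case = [g for g in genes if g.gene_symbol in case_symbols]
    other = [g for g in genes if g.gene_symbol not in case_symbols]
    return case, other


def summarize_pathways(
    c: GeneSetCollection,
    genes: Sequence[GeneSummary],
    ntr_threshold: int = 3,
    length_threshold: int = 200_000,
) -> list[PathwaySummary]:
    """Per-pathway means of L_tr / N_tr and threshold-exceedance fractions.

    Pathway genes absent from the annotation are skipped and tallied in
    ``n_genes_unmatched`` (total also logged).  A pathway with no matched
    gene yields a ``missing`` summary rather than an error.
    """
    if ntr_threshold < 1:
        raise ValueError("ntr_threshold must be >= 1")
    by_symbol = {g.gene_symbol: g for g in genes}
    out: list[PathwaySummary] = []
    total_unmatched = 0
    for name, members in c.sets.items():
        matched = [by_symbol[s] for s in sorted(members) if s in by_symbol]
        unmatched = len(members) - len(matched)
        total_unmatched += unmatched
        if not matched:
            out.append(
                PathwaySummary(
                    pathway_name=name,
                    label=c.labels[name],
                    n_genes_matched=0,
                    n_genes_unmatched=unmatched,
                    mean_L_tr=None,
                    mean_N_tr=None,
                    frac_Ntr_gt=None,
                    frac_above_200k=None,
                    missing=True,
                )
            )
            continue
        ltr = np.array([g.L_tr for g in matched], dtype=float)
        ntr = np.array([g.N_tr for g in matched], dtype=float)
        out.append(
            PathwaySummary(
                pathway_name=name,
                label=c.labels[name],
                n_genes_matched=len(matched),
                n_genes_unmatched=unmatched,
                mean_L_tr=float(ltr.mean()),
                mean_N_tr=float(ntr.mean()),
                frac_Ntr_gt=float((ntr > ntr_threshold).mean()),
                frac_above_200k=float((ltr > length_threshold).mean()),
                missing=False,
            )
        )
    if total_unmatched:
        log.info("summarize_pathways: %d set genes absent from annotation", total_unmatched)
    return out


def write_pathway_summaries(
    summaries: Sequence[PathwaySummary], stream: IO[str], sort_key: str = "mean_L_tr"
) -> None:
    """Write the pathway summary TSV sorted ascending by the chosen column."""
    cols = [
        "pathway",
        "label",
        "n_matched",
        "n_unmatched",
        "mean_L_tr",
        "mean_N_tr",
        "frac_Ntr_gt",
        "frac_above_200k",
    ]
    if sort_key not in ("mean_L_tr", "mean_N_tr", "frac_Ntr_gt", "frac_above_200k"):
        raise ValueError(f"unsupported sort key {sort_key!r}")
    order = sorted(
        summaries,
        key=lambda s: (getattr(s, sort_key) is None, getattr(s, sort_key) or 0.0),
    )
    stream.write("\t".join(cols) + "\n")
    for s in order:
        stream.write(
            "\t".join(
                [
                    s.pathway_name,
                    s.label,
                    str(s.n_genes_matched),
                    str(s.n_genes_unmatched),
                    "NA" if s.mean_L_tr is None else f"{s.mean_L_tr:.2f}",
                    "NA" if s.mean_N_tr is None else f"{s.mean_N_tr:.4f}",
                    "NA" if s.frac_Ntr_gt is None else f"{s.frac_Ntr_gt:.4f}",
                    "NA" if s.frac_above_200k is None else f"{s.frac_above_200k:.4f}",
                ]
            )
            + "\n"
        )
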