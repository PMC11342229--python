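"""Per-category reciprocal D analyses and cytonuclear enrichment tests.

Gene categories follow the CyMIRA scheme: NOT (non-organelle-targeted),
MTNI/MTI/MTEC (mitochondrial-targeted non-interacting / interacting /
enzyme-complex) and PTNI/PTI/PTEC (the plastid equivalents). The
enzyme-complex sets are subsets of the interacting sets, so the MTI/PTI
analyses include their MTEC/PTEC members; "All" is every gene.

The maternal-bias hypothesis predicts an excess of E-overwrites-C
signal specifically in genes whose products sit in jointly encoded
cytonuclear enzyme complexes. Two lines of evidence are computed: the
reciprocal bootstrap D per category and direction (Holm-corrected as
one family), and Fisher tests of whether a focal category's *ratio of
HGF topologies to species-tree topologies* is shifted relative to the
non-organelle-targeted baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dstat import BootstrapConfig, DStatError, DStatResult, bootstrap_D, holm_adjust
from .site_patterns import SitePatternCounts
from .topology import E_OVER_C, C_OVER_E, SPECIES, TopologyCounts, enumerate_topologies

#: Reporting order; membership below. MTEC/PTEC are nested in MTI/PTI.
REPORT_CATEGORIES: Tuple[str, ...] = (
    "All", "NOT", "MTNI", "MTI", "MTEC", "PTNI", "PTI", "PTEC",
)


def genes_in_category(category: str, assignment: Mapping[str, str]) -> List[str]:
    """Gene ids belonging to a reporting category (handles nesting)."""
    if category == "All":
        return list(assignment)
    if category == "MTI":
        members = {"MTI", "MTEC"}
    elif category == "PTI":
        members = {"PTI", "PTEC"}
    else:
        members = {category}
    return [g for g, c in assignment.items() if c in members]


@dataclass(frozen=True)
class CategoryRun:
    category: str
    n_genes: int
    results: Dict[str, Optional[DStatResult]]  # direction -> result
    skipped_reason: Optional[str] = None
    flags: Tuple[str, ...] = ()


def run_category_dstats(
    counts_by_direction: Mapping[str, Sequence[SitePatternCounts]],
    assignment: Mapping[str, str],
    cfg: BootstrapConfig,
    categories: Sequence[str] = REPORT_CATEGORIES,
) -> List[CategoryRun]:
    """Bootstrap D per category and direction, Holm-corrected as a family.

    ``counts_by_direction`` maps "MAT"/"PAT" to per-gene counts;
    ``assignment`` maps every gene id to its most specific category.
    Empty categories are skipped with a reason; single-gene categories
    run but carry a degenerate-bootstrap flag from the D machinery.
    """
    by_dir_by_gene = {
        d: {c.gene_id: c for c in clist} for d, clist in counts_by_direction.items()
    }
    runs: List[CategoryRun] = []
    for category in categories:
        gene_ids = genes_in_category(category, assignment)
        results: Dict[str, Optional[DStatResult]] = {}
        if not gene_ids:
            runs.append(CategoryRun(category, 0, {}, skipped_reason="no_genes"))
            continue
        flags: List[str] = []
        if len(gene_ids) == 1:
            flags.append("single_gene_bootstrap_degenerate")
        for direction, by_gene in by_dir_by_gene.items():
            subset = [by_gene[g] for g in gene_ids if g in by_gene]
            if not subset:
                results[direction] = None
                continue
            try:
                results[direction] = bootstrap_D(subset, cfg)
            except DStatError:
                results[direction] = None
                flags.append(f"no_informative_sites:{direction}")
        runs.append(CategoryRun(category, len(gene_ids), results, flags=tuple(flags)))

    # Holm across the whole family of reported category x direction tests
    keyed: List[Tuple[int, str]] = []
    pvals: List[float] = []
    for i, run in enumerate(runs):
        for direction, res in run.results.items():
            if res is not None and np.isfinite(res.p_one_tailed):
                keyed.append((i, direction))
                pvals.append(res.p_one_tailed)
    if pvals:
        adjusted = holm_adjust(pvals)
        for (i, direction), p_adj in zip(keyed, adjusted):
            run = runs[i]
            res = run.results[direction]
            run.results[direction] = DStatResult(
                **{**res.__dict__, "p_holm": float(p_adj)}
            )
    return runs


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows (focal, baseline), columns (HGF-topology, reference)."""

    focal_hgf: int
    focal_ref: int
    baseline_hgf: int
    baseline_ref: int

    def __post_init__(self) -> None:
        cells = (self.focal_hgf, self.focal_ref, self.baseline_hgf, self.baseline_ref)
        if any(c < 0 for c in cells):
            raise ValueError("negative cell count")

    def as_list(self) -> List[List[int]]:
        return [[self.focal_hgf, self.focal_ref], [self.baseline_hgf, self.baseline_ref]]


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher's exact p (probability-mass rule).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.
    """
    t = table.as_list()
    if sum(t[0]) == 0 or sum(t[1]) == 0:
        raise ValueError("empty margin")
    # an all-zero column is fine: no signal, p = 1
    return float(stats.fisher_exact(t)[1])


@dataclass(frozen=True)
class EnrichmentResult:
    focal: str
    baseline: str
    label: str  # E_OVER_C or C_OVER_E
    table: ContingencyTable
    p: float


def topology_enrichment(
    category_counts: TopologyCounts,
    baseline_counts: TopologyCounts,
    labels: Sequence[str] = (E_OVER_C, C_OVER_E),
    focal_name: str = "focal",
    baseline_name: str = "NOT",
) -> List[EnrichmentResult]:
    """Fisher tests for HGF-topology enrichment in a focal category.

    For each directional HGF topology the 2x2 table opposes the HGF
    count to the *species-tree* count, focal category vs baseline:
    the tested quantity is the ratio of biased-HGF trees to concordant
    trees, which is insensitive to how many ILS/other trees a category
    happens to contain.
    """
    letter_of = {t.category: t.letter for t in enumerate_topologies()
                 if t.category in (E_OVER_C, C_OVER_E, SPECIES)}
    results: List[EnrichmentResult] = []
    for label in labels:
        if label not in (E_OVER_C, C_OVER_E):
            raise ValueError(f"unsupported enrichment label: {label}")
        table = ContingencyTable(
            focal_hgf=category_counts.counts[letter_of[label]],
            focal_ref=category_counts.counts[letter_of[SPECIES]],
            baseline_hgf=baseline_counts.counts[letter_of[label]],
            baseline_ref=baseline_counts.counts[letter_of[SPECIES]],
        )
        results.append(
            EnrichmentResult(
                focal=focal_name,
                baseline=baseline_name,
                label=label,
                table=table,
                p=fisher_two_sided(table),
            )
        )
    return results
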