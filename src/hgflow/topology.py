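"""The 15 rooted five-taxon gene-tree topologies and HGF-vs-ILS tests.

With the outgroup fixed as root, a gene tree is identified by the shape
of its four-leaf ingroup subtree; there are exactly 15 rooted binary
topologies on four labelled leaves. Identity is canonical: the ingroup
is serialized as nested sets with lexicographically sorted children, so
child order, branch lengths and supports never matter.

Biologically meaningful topologies (species tree
((E_SUB,E_DIP),(C_SUB,C_DIP)) and the gene-flow / ILS alternatives) get
named categories; the conventional letters A-O are cosmetic display
labels and can be remapped. The default letter table anchors the
topologies identified in the source data set (A = species tree,
L = E-overwrites-C, M = C-overwrites-E, F = reciprocal exchange,
K = tetraploids-sister + diploids-sister, N/H = a subgenome sister to
the opposing diploid, I/O = diploids-sister caterpillars).

Under pure ILS the tetraploids-sister arrangements are no more likely
than their counterparts, so an excess of the HGF topologies (L, M, F)
over the paired ILS topologies (default pairing L:N, M:H, F:K,
configurable) indicates gene flow; the excess is tested with binomial,
chi-square and Fisher tests with Holm correction within each family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .dstat import holm_adjust
from .io_model import GeneTree, IngroupNode, TreeError

INGROUP_ROLES = ("E_SUB", "C_SUB", "E_DIP", "C_DIP")

SPECIES = "SPECIES"
E_OVER_C = "E_OVER_C"
C_OVER_E = "C_OVER_E"
RECIPROCAL = "RECIPROCAL"
ILS_TETRA_SISTER = "ILS_TETRA_SISTER"
ILS_SUB_OPP_DIP = "ILS_SUB_OPP_DIP"
ILS_DIPS_SISTER = "ILS_DIPS_SISTER"
OTHER = "OTHER"


def canonical_id(node: IngroupNode) -> str:
    """Order-invariant serialization of an ingroup subtree."""
    if isinstance(node, str):
        return node
    return "(" + ",".join(sorted(canonical_id(c) for c in node)) + ")"


@dataclass(frozen=True)
class TopologyLabel:
    canonical: str
    letter: str
    category: str


def _t(*args):
    """Shorthand: nested tuples for topology literals."""
    return tuple(a if isinstance(a, (str, tuple)) else _t(*a) for a in args)


# Default letter table. Letters beyond the anchored ones (A, F, K, L, M,
# N, H, I, O) are arbitrary display choices and remappable via the
# `letters` argument of enumerate_topologies.
_DEFAULT_STRUCTURES: Dict[str, IngroupNode] = {
    "A": (("E_SUB", "E_DIP"), ("C_SUB", "C_DIP")),   # species tree
    "B": ((("E_SUB", "E_DIP"), "C_SUB"), "C_DIP"),
    "C": ((("E_SUB", "E_DIP"), "C_DIP"), "C_SUB"),
    "D": ((("C_SUB", "C_DIP"), "E_SUB"), "E_DIP"),
    "E": ((("C_SUB", "C_DIP"), "E_DIP"), "E_SUB"),
    "F": (("E_SUB", "C_DIP"), ("C_SUB", "E_DIP")),   # reciprocal exchange
    "G": ((("E_SUB", "C_DIP"), "E_DIP"), "C_SUB"),
    "H": ((("E_SUB", "C_DIP"), "C_SUB"), "E_DIP"),   # E_SUB sister to C_DIP
    "I": ((("E_DIP", "C_DIP"), "E_SUB"), "C_SUB"),   # diploids sister
    "J": ((("C_SUB", "E_DIP"), "C_DIP"), "E_SUB"),
    "K": (("E_SUB", "C_SUB"), ("E_DIP", "C_DIP")),   # tetra + dips sister
    "L": ((("E_SUB", "C_SUB"), "E_DIP"), "C_DIP"),   # E overwrites C
    "M": ((("E_SUB", "C_SUB"), "C_DIP"), "E_DIP"),   # C overwrites E
    "N": ((("C_SUB", "E_DIP"), "E_SUB"), "C_DIP"),   # C_SUB sister to E_DIP
    "O": ((("E_DIP", "C_DIP"), "C_SUB"), "E_SUB"),   # diploids sister
}

_CATEGORY_BY_LETTER: Dict[str, str] = {
    "A": SPECIES,
    "L": E_OVER_C,
    "M": C_OVER_E,
    "F": RECIPROCAL,
    "K": ILS_TETRA_SISTER,
    "N": ILS_SUB_OPP_DIP,
    "H": ILS_SUB_OPP_DIP,
    "I": ILS_DIPS_SISTER,
    "O": ILS_DIPS_SISTER,
}

#: HGF topology letter -> ILS counterpart letters used by the abundance tests.
DEFAULT_PAIRING: Dict[str, Tuple[str, ...]] = {
    "L": ("N",),
    "M": ("H",),
    "F": ("K",),
}


def _all_rooted_shapes(leaves: Sequence[str]) -> List[IngroupNode]:
    """All rooted binary shapes on labelled leaves (duplicates possible)."""
    if len(leaves) == 1:
        return [leaves[0]]
    shapes: List[IngroupNode] = []
    n = len(leaves)
    # split leaves into two non-empty subsets; fix leaves[0] on the left
    # to halve the symmetric duplicates (dedup happens on canonical ids).
    rest = list(leaves[1:])
    for mask in range(2 ** (n - 1)):
        left = [leaves[0]] + [rest[i] for i in range(n - 1) if mask >> i & 1]
        right = [rest[i] for i in range(n - 1) if not mask >> i & 1]
        if not right:
            continue
        for lsub in _all_rooted_shapes(left):
            for rsub in _all_rooted_shapes(right):
                shapes.append((lsub, rsub))
    return shapes


def enumerate_topologies(
    letters: Optional[Mapping[str, IngroupNode]] = None,
) -> List[TopologyLabel]:
    """The 15 rooted ingroup topologies, lettered and categorized.

    ``letters`` optionally remaps letter -> ingroup structure (nested
    tuples of the four ingroup roles); it must cover all 15 topologies.
    Categories attach to structures, not letters.
    """
    structures = dict(letters) if letters is not None else dict(_DEFAULT_STRUCTURES)
    canon_all = {canonical_id(s) for s in _all_rooted_shapes(INGROUP_ROLES)}
    assert len(canon_all) == 15
    by_canon = {canonical_id(s): letter for letter, s in structures.items()}
    if set(by_canon) != canon_all or len(by_canon) != 15:
        raise ValueError("letter table must map the 15 topologies bijectively")
    category_of = {
        canonical_id(_DEFAULT_STRUCTURES[l]): cat
        for l, cat in _CATEGORY_BY_LETTER.items()
    }
    out = [
        TopologyLabel(
            canonical=canon,
            letter=by_canon[canon],
            category=category_of.get(canon, OTHER),
        )
        for canon in sorted(canon_all)
    ]
    return sorted(out, key=lambda t: t.letter)


_ENUM_CACHE: Optional[Dict[str, TopologyLabel]] = None


def _label_index() -> Dict[str, TopologyLabel]:
    global _ENUM_CACHE
    if _ENUM_CACHE is None:
        _ENUM_CACHE = {t.canonical: t for t in enumerate_topologies()}
    return _ENUM_CACHE


def canonicalize(tree: GeneTree) -> TopologyLabel:
    """Look up a gene tree's canonical topology label.

    The GeneTree invariants already guarantee a binary four-leaf
    ingroup, so this is total on valid trees.
    """
    canon = canonical_id(tree.ingroup)
    try:
        return _label_index()[canon]
    except KeyError as exc:  # pragma: no cover - unreachable for valid trees
        raise TreeError(f"unclassifiable:{canon}") from exc


@dataclass(frozen=True)
class TopologyCounts:
    """Per-letter counts over a gene set at one support threshold."""

    counts: Dict[str, int]
    support_threshold: float
    n_classified: int
    n_filtered: int

    def total(self) -> int:
        return self.n_classified

    def by_category(self) -> Dict[str, int]:
        cats: Dict[str, int] = {}
        labels = {t.letter: t.category for t in enumerate_topologies()}
        for letter, n in self.counts.items():
            cats[labels[letter]] = cats.get(labels[letter], 0) + n
        return cats


def count_topologies(
    trees: Iterable[GeneTree], support_threshold: float = 0.0
) -> TopologyCounts:
    """Tally topology letters, filtering trees on minimum ingroup support.

    A tree is counted only if *all* its ingroup internal supports are
    >= the threshold (inclusive); with a threshold of 0 no filtering
    happens. Trees lacking support labels fail any positive threshold.
    """
    if not 0.0 <= support_threshold <= 100.0:
        raise ValueError("support_threshold must be in [0, 100]")
    counts = {t.letter: 0 for t in enumerate_topologies()}
    n_filtered = 0
    n_classified = 0
    for tree in trees:
        if support_threshold > 0:
            min_sup = tree.min_support()
            if min_sup is None or min_sup < support_threshold:
                n_filtered += 1
                continue
        counts[canonicalize(tree).letter] += 1
        n_classified += 1
    return TopologyCounts(
        counts=counts,
        support_threshold=support_threshold,
        n_classified=n_classified,
        n_filtered=n_filtered,
    )


@dataclass(frozen=True)
class AbundanceTest:
    comparison: str  # e.g. "L_vs_N"
    test: str        # binomial | chisquare | fisher
    statistic: float
    p_raw: float
    p_holm: Optional[float] = None
    skipped_reason: Optional[str] = None


def test_hgf_abundance(
    counts: TopologyCounts,
    pairing: Optional[Mapping[str, Sequence[str]]] = None,
    alternative: str = "two-sided",
) -> List[AbundanceTest]:
    """Test each HGF topology's count against its ILS counterparts.

    For HGF count h and counterpart mean c (counterpart counts averaged
    when several are paired): a binomial test of h successes in h+c
    trials at p=0.5; a chi-square goodness-of-fit of equal expected
    counts across the HGF label and its counterparts; and Fisher's exact
    test on [[h, total-h], [c_sum, total-c_sum]]. Holm correction is
    applied within each test family across comparisons.
    """
    pairing = dict(pairing) if pairing is not None else dict(DEFAULT_PAIRING)
    known = {t.letter for t in enumerate_topologies()}
    results: List[AbundanceTest] = []
    total = counts.total()
    for hgf, cps in pairing.items():
        cps = tuple(cps)
        if hgf not in known or any(c not in known for c in cps):
            raise ValueError(f"pairing names unknown letters: {hgf}:{cps}")
        name = f"{hgf}_vs_{'+'.join(cps)}"
        h = counts.counts[hgf]
        cp_counts = [counts.counts[c] for c in cps]
        c_sum = sum(cp_counts)
        c_mean = c_sum / len(cps)
        if h + c_sum == 0:
            for test in ("binomial", "chisquare", "fisher"):
                results.append(
                    AbundanceTest(name, test, float("nan"), float("nan"),
                                  skipped_reason="zero_totals")
                )
            continue
        n_binom = int(round(h + c_mean))
        binom = stats.binomtest(min(h, n_binom), n_binom, 0.5, alternative=alternative)
        results.append(AbundanceTest(name, "binomial", float(h), binom.pvalue))
        observed = np.array([h] + cp_counts, dtype=float)
        chi = stats.chisquare(observed)
        results.append(AbundanceTest(name, "chisquare", float(chi.statistic), float(chi.pvalue)))
        table = [[h, total - h], [c_sum, total - c_sum]]
        _, p_fisher = stats.fisher_exact(table, alternative=alternative)
        results.append(AbundanceTest(name, "fisher", float(h), float(p_fisher)))

    # Holm within each family of comparisons
    adjusted: List[AbundanceTest] = []
    for test_name in ("binomial", "chisquare", "fisher"):
        fam = [r for r in results if r.test == test_name and r.skipped_reason is None]
        if fam:
            adj = holm_adjust([r.p_raw for r in fam])
            fam = [
                AbundanceTest(r.comparison, r.test, r.statistic, r.p_raw, p_holm=a)
                for r, a in zip(fam, adj)
            ]
        fam += [r for r in results if r.test == test_name and r.skipped_reason]
        adjusted.extend(fam)
    return adjusted
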