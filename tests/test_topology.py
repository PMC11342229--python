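"""Topology enumeration, canonical classification and abundance tests."""

from itertools import permutations

import numpy as np
import pytest
from scipy import stats

from hgflow.io_model import GeneTree
from hgflow.topology import (
    C_OVER_E,
    DEFAULT_PAIRING,
    E_OVER_C,
    ILS_TETRA_SISTER,
    INGROUP_ROLES,
    RECIPROCAL,
    SPECIES,
    TopologyCounts,
    canonical_id,
    canonicalize,
    count_topologies,
    enumerate_topologies,
)
from hgflow.topology import test_hgf_abundance as run_abundance_tests


def oracle_enumeration():
    """Independent route to the 15 shapes: join leaves pairwise.

    Repeatedly merge two elements of the working set until one tree
    remains; deduplicate canonical forms. Written without reusing the
    package's recursive generator.
    """
    seen = set()

    def grow(items):
        if len(items) == 1:
            seen.add(canonical_id(items[0]))
            return
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                merged = (items[i], items[j])
                rest = [items[k] for k in range(len(items)) if k not in (i, j)]
                grow(rest + [merged])

    grow(list(INGROUP_ROLES))
    return seen


def tree_of(ingroup, supports=(100.0, 100.0)):
    return GeneTree(gene_id="t", ingroup=ingroup, supports=supports)


def random_topology(rng):
    """Random rooted binary shape via sequential joins (not shape-uniform:
    balanced shapes arise from two join orders, caterpillars from one)."""
    items = [str(r) for r in rng.permutation(INGROUP_ROLES)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = (items[i], items[j])
        items = [items[k] for k in range(len(items)) if k not in (i, j)]
        items.append(merged)
    return items[0]


def uniform_topology(rng):
    """Uniform draw over the 15 shapes: a uniform leaf permutation maps
    2 of 24 orders onto each caterpillar and 8 of 24 onto each balanced
    shape, so choosing the shape class 12/15 vs 3/15 makes every
    topology equally likely."""
    a, b, c, d = (str(r) for r in rng.permutation(INGROUP_ROLES))
    if rng.random() < 12 / 15:
        return (((a, b), c), d)
    return ((a, b), (c, d))


class TestEnumeration:
    def test_exactly_fifteen_distinct(self):
        labels = enumerate_topologies()
        assert len(labels) == 15
        assert len({t.canonical for t in labels}) == 15
        assert sorted(t.letter for t in labels) == [chr(ord("A") + i) for i in range(15)]

    def test_matches_bruteforce_oracle(self):
        assert {t.canonical for t in enumerate_topologies()} == oracle_enumeration()

    def test_unique_named_categories(self):
        cats = [t.category for t in enumerate_topologies()]
        for unique in (SPECIES, E_OVER_C, C_OVER_E, RECIPROCAL, ILS_TETRA_SISTER):
            assert cats.count(unique) == 1

    def test_bad_letter_table_rejected(self):
        with pytest.raises(ValueError):
            enumerate_topologies(letters={"A": (("E_SUB", "E_DIP"), ("C_SUB", "C_DIP"))})


class TestCanonicalize:
    @pytest.mark.parametrize(
        "ingroup,category",
        [
            ((("E_SUB", "E_DIP"), ("C_SUB", "C_DIP")), SPECIES),
            (((("E_SUB", "C_SUB"), "E_DIP"), "C_DIP"), E_OVER_C),
            (((("E_SUB", "C_SUB"), "C_DIP"), "E_DIP"), C_OVER_E),
            ((("E_SUB", "C_DIP"), ("C_SUB", "E_DIP")), RECIPROCAL),
            ((("E_DIP", "E_SUB"), ("C_DIP", "C_SUB")), SPECIES),  # rotated
            ((("C_SUB", "C_DIP"), ("E_SUB", "E_DIP")), SPECIES),  # swapped
        ],
    )
    def test_category_lookup(self, ingroup, category):
        assert canonicalize(tree_of(ingroup)).category == category

    def test_total_on_random_trees(self):
        rng = np.random.default_rng(7)
        known = {t.canonical for t in enumerate_topologies()}
        for _ in range(2000):
            label = canonicalize(tree_of(random_topology(rng)))
            assert label.canonical in known

    def test_uniform_random_topologies_are_uniform(self):
        """Uniform shape draws give each of the 15 labels frequency ~1/15."""
        rng = np.random.default_rng(123)
        letters = [canonicalize(tree_of(uniform_topology(rng))).letter
                   for _ in range(15000)]
        observed = [letters.count(chr(ord("A") + i)) for i in range(15)]
        assert stats.chisquare(observed).pvalue > 0.001


class TestCounting:
    def test_counts_without_filter(self):
        trees = [tree_of((("E_SUB", "E_DIP"), ("C_SUB", "C_DIP")))] * 3
        counts = count_topologies(trees, support_threshold=0)
        assert counts.counts["A"] == 3
        assert counts.total() == 3

    def test_low_support_excluded(self):
        t = tree_of((("E_SUB", "E_DIP"), ("C_SUB", "C_DIP")), supports=(95.0, 60.0))
        counts = count_topologies([t], support_threshold=80)
        assert counts.total() == 0
        assert counts.n_filtered == 1

    def test_threshold_inclusive(self):
        t = tree_of((("E_SUB", "E_DIP"), ("C_SUB", "C_DIP")), supports=(80.0, 80.0))
        assert count_topologies([t], support_threshold=80).total() == 1

    def test_filtering_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        trees = [
            tree_of(random_topology(rng),
                    supports=tuple(rng.uniform(30, 100, size=2)))
            for _ in range(200)
        ]
        prev = None
        for thr in (0, 50, 70, 80, 95, 100):
            counts = count_topologies(trees, support_threshold=thr)
            if prev is not None:
                assert all(counts.counts[k] <= prev[k] for k in counts.counts)
            prev = counts.counts


def make_counts(**letter_counts):
    base = {t.letter: 0 for t in enumerate_topologies()}
    base.update(letter_counts)
    return TopologyCounts(
        counts=base, support_threshold=0.0,
        n_classified=sum(base.values()), n_filtered=0,
    )


class TestAbundance:
    def test_balanced_binomial_is_one(self):
        res = run_abundance_tests(make_counts(L=10, N=10), pairing={"L": ["N"]})
        binom = next(r for r in res if r.test == "binomial")
        assert binom.p_raw == pytest.approx(1.0)

    def test_eight_vs_two_binomial(self):
        # exact two-sided binomial: sum over k in {0,1,2,8,9,10} at p=0.5
        res = run_abundance_tests(make_counts(L=8, N=2), pairing={"L": ["N"]})
        binom = next(r for r in res if r.test == "binomial")
        assert round(binom.p_raw, 3) == 0.109

    def test_zero_totals_skipped(self):
        res = run_abundance_tests(make_counts(A=5), pairing={"L": ["N"]})
        assert all(r.skipped_reason == "zero_totals" for r in res)

    def test_default_pairing_on_observed_counts(self):
        """Published genome-wide counts: all three HGF excesses significant."""
        counts = make_counts(A=3651, L=316, N=37, M=289, H=34, F=198, K=81,
                             B=478, C=278, D=474, E=629, G=89, I=19, J=68, O=31)
        res = run_abundance_tests(counts, pairing=DEFAULT_PAIRING)
        tested = [r for r in res if r.skipped_reason is None]
        assert len(tested) == 9  # 3 comparisons x 3 test families
        assert all(r.p_holm < 0.05 for r in tested)

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            run_abundance_tests(make_counts(L=1), pairing={"Z": ["L"]})
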