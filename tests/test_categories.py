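"""Category-wise D runs, Fisher's exact test and topology enrichment."""

from dataclasses import replace
from math import comb

import numpy as np
import pytest

from hgflow.categories import (
    ContingencyTable,
    fisher_two_sided,
    genes_in_category,
    run_category_dstats,
    topology_enrichment,
)
from hgflow.dstat import BootstrapConfig
from hgflow.site_patterns import MAT_QUARTET, PAT_QUARTET, count_patterns
from hgflow.simulate import SimulationParams, simulate_dataset
from hgflow.topology import C_OVER_E, E_OVER_C
from tests.test_topology import make_counts


def fisher_oracle(table):
    """Brute-force two-sided Fisher: enumerate tables with fixed margins."""
    a, b = table.focal_hgf, table.focal_ref
    c, d = table.baseline_hgf, table.baseline_ref
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(k):
        return comb(c1, k) * comb(n - c1, r1 - k) / comb(n, r1)

    p_obs = prob(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_no_signal_table(self):
        assert fisher_two_sided(ContingencyTable(0, 10, 0, 10)) == pytest.approx(1.0)

    def test_identical_rows_give_one(self):
        assert fisher_two_sided(ContingencyTable(4, 44, 4, 44)) == pytest.approx(1.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="empty margin"):
            fisher_two_sided(ContingencyTable(0, 0, 3, 5))

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            cells = rng.integers(0, 12, size=4)
            t = ContingencyTable(*map(int, cells))
            try:
                got = fisher_two_sided(t)
            except ValueError:
                continue
            assert got == pytest.approx(fisher_oracle(t), abs=1e-9)

    def test_invariant_to_row_and_column_swap(self):
        t = ContingencyTable(4, 24, 261, 3070)
        swapped = ContingencyTable(3070, 261, 24, 4)
        assert fisher_two_sided(t) == pytest.approx(fisher_two_sided(swapped))


class TestEnrichment:
    def test_published_cytonuclear_ratios(self):
        """HGF-vs-species-tree ratios, focal category vs NOT baseline.

        PTEC: 4 E-over-C, 1 C-over-E, 24 species trees; MTEC: 3/3/32;
        NOT: 261 E-over-C, 238 C-over-E, 3070 species trees.
        """
        not_counts = make_counts(A=3070, L=261, M=238)
        ptec = make_counts(A=24, L=4, M=1)
        mtec = make_counts(A=32, L=3, M=3)
        p_ptec = {r.label: r.p for r in topology_enrichment(ptec, not_counts)}
        p_mtec = {r.label: r.p for r in topology_enrichment(mtec, not_counts)}
        assert round(p_ptec[E_OVER_C], 3) == 0.274
        assert round(p_ptec[C_OVER_E], 3) == 1.0
        assert round(p_mtec[E_OVER_C], 3) == 0.752
        assert round(p_mtec[C_OVER_E], 3) == 0.737

    def test_focal_equals_baseline(self):
        counts = make_counts(A=100, L=10, M=8)
        for r in topology_enrichment(counts, counts):
            assert r.p == pytest.approx(1.0)

    def test_tables_recorded(self):
        res = topology_enrichment(
            make_counts(A=24, L=4, M=1), make_counts(A=3070, L=261, M=238)
        )
        t = next(r.table for r in res if r.label == E_OVER_C)
        assert t.as_list() == [[4, 24], [261, 3070]]


class TestCategoryMembership:
    def test_enzyme_complexes_nested_in_interacting(self):
        assignment = {"g1": "MTI", "g2": "MTEC", "g3": "PTI", "g4": "PTEC", "g5": "NOT"}
        assert sorted(genes_in_category("MTI", assignment)) == ["g1", "g2"]
        assert sorted(genes_in_category("PTI", assignment)) == ["g3", "g4"]
        assert genes_in_category("MTEC", assignment) == ["g2"]
        assert len(genes_in_category("All", assignment)) == 5

    def test_partition_conserves_gene_count(self):
        rng = np.random.default_rng(3)
        cats = ["NOT", "MTNI", "MTI", "MTEC", "PTNI", "PTI", "PTEC"]
        assignment = {f"g{i}": cats[rng.integers(len(cats))] for i in range(200)}
        top_level = ["NOT", "MTNI", "MTI", "PTNI", "PTI"]
        total = sum(len(genes_in_category(c, assignment)) for c in top_level)
        assert total == 200


class TestCategoryDstats:
    def test_hgf_confined_to_tagged_category(self):
        """Only PTEC genes carry maternal HGF: PTEC significant, NOT null."""
        hgf, _, _, _ = simulate_dataset(SimulationParams(n_genes=60, f_mat=0.8, seed=21))
        null, _, _, _ = simulate_dataset(SimulationParams(n_genes=300, seed=22))
        genes, assignment = [], {}
        for i, g in enumerate(hgf):
            gid = f"ptec{i:04d}"
            genes.append((gid, g))
            assignment[gid] = "PTEC"
        for i, g in enumerate(null):
            gid = f"not{i:04d}"
            genes.append((gid, g))
            assignment[gid] = "NOT"
        counts = {
            d: [replace(count_patterns(g, q), gene_id=gid) for gid, g in genes]
            for d, q in (("MAT", MAT_QUARTET), ("PAT", PAT_QUARTET))
        }
        runs = run_category_dstats(
            counts, assignment, BootstrapConfig(n_reps=500, seed=9),
            categories=("All", "NOT", "PTEC"),
        )
        by_cat = {r.category: r for r in runs}
        ptec = by_cat["PTEC"].results["MAT"]
        not_ = by_cat["NOT"].results["MAT"]
        assert ptec.ci_low > 0
        assert not_.ci_low <= 0 <= not_.ci_high

    def test_empty_category_skipped(self):
        al, _, _, _ = simulate_dataset(SimulationParams(n_genes=10, seed=1))
        counts = {
            d: [count_patterns(g, q) for g in al]
            for d, q in (("MAT", MAT_QUARTET), ("PAT", PAT_QUARTET))
        }
        assignment = {g.gene_id: "NOT" for g in al}
        runs = run_category_dstats(counts, assignment, BootstrapConfig(n_reps=50, seed=2))
        by_cat = {r.category: r for r in runs}
        assert by_cat["PTEC"].skipped_reason == "no_genes"
        assert by_cat["NOT"].n_genes == 10

    def test_single_gene_category_flagged(self):
        al, _, _, _ = simulate_dataset(SimulationParams(n_genes=2, seed=1))
        counts = {
            d: [count_patterns(g, q) for g in al]
            for d, q in (("MAT", MAT_QUARTET), ("PAT", PAT_QUARTET))
        }
        assignment = {al[0].gene_id: "MTEC", al[1].gene_id: "NOT"}
        runs = run_category_dstats(counts, assignment, BootstrapConfig(n_reps=50, seed=2))
        mtec = next(r for r in runs if r.category == "MTEC")
        assert "single_gene_bootstrap_degenerate" in mtec.flags

    def test_holm_family_applied(self):
        al, _, _, _ = simulate_dataset(SimulationParams(n_genes=50, f_mat=0.5, seed=33))
        counts = {
            d: [count_patterns(g, q) for g in al]
            for d, q in (("MAT", MAT_QUARTET), ("PAT", PAT_QUARTET))
        }
        assignment = {g.gene_id: "NOT" for g in al}
        runs = run_category_dstats(counts, assignment, BootstrapConfig(n_reps=200, seed=3),
                                   categories=("All", "NOT"))
        for run in runs:
            for res in run.results.values():
                if res is not None and np.isfinite(res.p_one_tailed):
                    assert res.p_holm is not None
                    assert res.p_holm >= res.p_one_tailed
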