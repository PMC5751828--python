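"""Tables, taxonomy collapse, normalization, top-genera ranking, rarefaction, I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nichepair.datamodel import (
    AbundanceTable,
    DegenerateSampleError,
    FormatError,
    TaxonomyMap,
    ValidationError,
    collapse_to_genus,
    default_rarefaction_depth,
    rarefy,
    to_relative_abundance,
    top_genera_union,
)
from nichepair.io import (
    read_abundance_table,
    read_metadata,
    read_taxonomy_map,
    read_tree,
    write_abundance_table,
    write_metadata,
    write_taxonomy_map,
    write_tree,
)
from nichepair.synthetic import CohortSpec, generate_cohort, generate_random_tree

from conftest import make_table


class TestAbundanceTableIO:
    def test_parse_counts_tsv(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\tg1\tg2\ns1\t5\t5\ns2\t0\t10\n")
        t = read_abundance_table(p, site="NS")
        assert t.data.sum(axis=1).tolist() == [10.0, 10.0]
        assert t.sample_ids == ["s1", "s2"] and t.taxon_ids == ["g1", "g2"]

    def test_round_trip_is_byte_stable(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text("sample_id\tg1\tg2\ns1\t5\t5\ns2\t0\t10\n")
        t1 = read_abundance_table(p1, site="NS")
        write_abundance_table(t1, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_entry_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\tg1\ns1\t-3\n")
        with pytest.raises(ValidationError, match="negative"):
            read_abundance_table(p, site="NS")

    def test_duplicate_sample_ids_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("sample_id\tg1\ns1\t1\ns1\t2\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_abundance_table(p, site="NS")

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sums to"):
            make_table([[0.5, 0.4]], mode="proportions")

    def test_metadata_round_trip(self, tmp_path, small_cohort):
        cohort, _ = small_cohort
        p = tmp_path / "meta.csv"
        write_metadata(cohort.metadata, p)
        back = read_metadata(p)
        assert back["icu_use"].tolist() == cohort.metadata["icu_use"].tolist()
        assert back["age_months"].tolist() == cohort.metadata["age_months"].tolist()

    def test_taxonomy_map_round_trip(self, tmp_path):
        tm = TaxonomyMap({"o1": "Staphylococcus", "o2": ""})
        p = tmp_path / "tax.tsv"
        write_taxonomy_map(tm, p)
        back = read_taxonomy_map(p)
        assert back.genus_of("o1") == "Staphylococcus"
        assert back.genus_of("o2") == "Unclassified"

    def test_tree_round_trip(self, tmp_path):
        tree = generate_random_tree(["A", "B", "C", "D"], seed=5)
        p = tmp_path / "t.nwk"
        write_tree(tree, p)
        back = read_tree(p)
        assert sorted(back.leaf_names) == ["A", "B", "C", "D"]
        d1 = {t.name: t.accumulate_to_ancestor(tree.tree) for t in tree.tree.tips()}
        d2 = {t.name: t.accumulate_to_ancestor(back.tree) for t in back.tree.tips()}
        for name in d1:
            assert d1[name] == pytest.approx(d2[name], abs=1e-9)


class TestCollapse:
    def test_additive_collapse(self):
        t = make_table([[3, 4, 5]], taxa=["o1", "o2", "o3"])
        tm = TaxonomyMap({"o1": "Staph", "o2": "Staph", "o3": "Morax"})
        c = collapse_to_genus(t, tm)
        assert c.data.iloc[0].to_dict() == {"Staph": 7.0, "Morax": 5.0}

    def test_identity_map_preserves_table(self):
        t = make_table([[1, 2], [3, 4]], taxa=["o1", "o2"])
        tm = TaxonomyMap({"o1": "g1", "o2": "g2"})
        c = collapse_to_genus(t, tm)
        assert np.array_equal(c.matrix, t.matrix)

    def test_random_collapse_matches_accumulation_oracle(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(0, 50, size=(10, 20))
        otus = [f"o{j}" for j in range(20)]
        genera = [f"g{k}" for k in range(6)]
        assignment = {o: genera[rng.integers(0, 6)] for o in otus}
        t = make_table(mat, taxa=otus)
        c = collapse_to_genus(t, TaxonomyMap(assignment))
        # oracle: accumulate column sums genus by genus
        for g in set(assignment.values()):
            expected = sum(mat[:, j] for j, o in enumerate(otus) if assignment[o] == g)
            assert np.array_equal(c.data[g].to_numpy(), expected)

    def test_unmapped_otu_needs_bucket(self):
        t = make_table([[1]], taxa=["oX"])
        with pytest.raises(KeyError):
            collapse_to_genus(t, TaxonomyMap({}, allow_unclassified=False))
        c = collapse_to_genus(t, TaxonomyMap({}, allow_unclassified=True))
        assert c.taxon_ids == ["Unclassified"]

    def test_collapse_commutes_with_normalization(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(1, 30, size=(6, 8))
        otus = [f"o{j}" for j in range(8)]
        tm = TaxonomyMap({o: f"g{j % 3}" for j, o in enumerate(otus)})
        t = make_table(mat, taxa=otus)
        a = to_relative_abundance(collapse_to_genus(t, tm))
        b = collapse_to_genus(to_relative_abundance(t), tm)
        assert np.allclose(a.matrix, b.matrix, atol=1e-15)


class TestRelativeAbundance:
    def test_simple_normalization(self):
        t = to_relative_abundance(make_table([[2, 2, 4]]))
        assert t.matrix.tolist() == [[0.25, 0.25, 0.5]]
        assert t.mode == "proportions"

    def test_single_taxon_corner(self):
        t = to_relative_abundance(make_table([[7]]))
        assert t.matrix.tolist() == [[1.0]]

    def test_zero_row_names_sample(self):
        with pytest.raises(DegenerateSampleError, match="s1"):
            to_relative_abundance(make_table([[1, 1], [0, 0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1000), min_size=4, max_size=4),
                    min_size=1, max_size=6))
    def test_rows_sum_to_one(self, rows):
        mat = np.asarray(rows, dtype=float)
        if (mat.sum(axis=1) == 0).any():
            return
        rel = to_relative_abundance(make_table(mat))
        assert np.allclose(rel.matrix.sum(axis=1), 1.0, atol=1e-12)


class TestTopGenera:
    def test_identical_tables_give_exactly_n_top(self):
        rng = np.random.default_rng(1)
        mat = rng.dirichlet(np.ones(12), size=5)
        t = make_table(mat, mode="proportions", taxa=[f"g{j}" for j in range(12)])
        genera, truncated = top_genera_union(t, t, n_top=10)
        assert len(genera) == 10 and not truncated

    def test_disjoint_rankings_give_double(self):
        ns = make_table([[0.7, 0.3, 0.0, 0.0]], mode="proportions",
                        taxa=["a", "b", "c", "d"])
        npa = make_table([[0.0, 0.0, 0.6, 0.4]], mode="proportions",
                         taxa=["a", "b", "c", "d"])
        genera, _ = top_genera_union(ns, npa, n_top=2)
        assert sorted(genera) == ["a", "b", "c", "d"]

    def test_matches_sort_and_union_oracle(self):
        rng = np.random.default_rng(8)
        taxa = [f"g{j:02d}" for j in range(15)]
        ns = make_table(rng.dirichlet(np.ones(15), size=30), mode="proportions", taxa=taxa)
        npa = make_table(rng.dirichlet(np.ones(15), size=30), mode="proportions", taxa=taxa)
        genera, _ = top_genera_union(ns, npa, n_top=5)
        # oracle: rank by per-site totals, union, order by combined totals
        ns_tot = ns.data.sum(axis=0)
        npa_tot = npa.data.sum(axis=0)
        top_ns = set(ns_tot.sort_values(ascending=False).index[:5])
        top_npa = set(npa_tot.sort_values(ascending=False).index[:5])
        union = top_ns | top_npa
        combined = (ns_tot + npa_tot)[sorted(union)]
        expected = list(combined.sort_values(ascending=False).index)
        assert genera == expected

    def test_invariant_to_sample_and_column_order(self):
        rng = np.random.default_rng(4)
        taxa = [f"g{j}" for j in range(8)]
        mat_ns = rng.dirichlet(np.ones(8), size=10)
        mat_npa = rng.dirichlet(np.ones(8), size=10)
        ns = make_table(mat_ns, mode="proportions", taxa=taxa)
        npa = make_table(mat_npa, mode="proportions", taxa=taxa)
        ref, _ = top_genera_union(ns, npa, 4)
        perm_rows = rng.permutation(10)
        perm_cols = rng.permutation(8)
        ns2 = AbundanceTable(ns.data.iloc[perm_rows, perm_cols], site="NS", mode="proportions")
        npa2 = AbundanceTable(npa.data.iloc[perm_rows, perm_cols], site="NPA", mode="proportions")
        out, _ = top_genera_union(ns2, npa2, 4)
        assert out == ref

    def test_short_table_flags_truncation(self):
        t = make_table([[0.6, 0.4]], mode="proportions", taxa=["a", "b"])
        genera, truncated = top_genera_union(t, t, n_top=10)
        assert genera and truncated


class TestRarefy:
    def test_full_depth_keeps_row(self):
        t = make_table([[30, 20, 50]])
        out, dropped = rarefy(t, depth=100, seed=0)
        assert dropped == []
        assert out.matrix.tolist() == [[30.0, 20.0, 50.0]]

    def test_single_taxon_support(self):
        out, _ = rarefy(make_table([[1000, 0]]), depth=100, seed=1)
        assert out.matrix.tolist() == [[100.0, 0.0]]

    def test_row_sums_equal_depth_and_seeded_repeatability(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.integers(0, 400, size=(8, 5)))
        out1, dropped = rarefy(t, depth=300, seed=7)
        out2, _ = rarefy(t, depth=300, seed=7)
        assert np.array_equal(out1.matrix, out2.matrix)
        assert np.all(out1.matrix.sum(axis=1) == 300)
        totals = t.data.sum(axis=1)
        assert dropped == [s for s in t.sample_ids if totals[s] < 300]

    def test_subsample_matches_hypergeometric_mean(self):
        row = np.array([[60, 30, 10]])
        t = make_table(row)
        depth = 20
        draws = np.array([
            rarefy(t, depth, seed=s)[0].matrix[0] for s in range(1000)
        ])
        expected = depth * row[0] / row.sum()
        se = np.sqrt(
            depth * (row[0] / row.sum()) * (1 - row[0] / row.sum())
            * (row.sum() - depth) / (row.sum() - 1) / 1000
        )
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 5 * se + 1e-9)

    def test_depth_validation(self):
        with pytest.raises(ValueError):
            rarefy(make_table([[5]]), depth=0, seed=0)

    def test_default_depth_is_min_retained(self):
        t = make_table([[1500, 0], [0, 2500], [100, 100]])
        assert default_rarefaction_depth(t, floor=1000) == 1500
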