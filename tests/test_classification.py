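"""Fast/intermediate/slow classes, shared counts and the species network."""

import math

import numpy as np
import pytest

from kaks.classification import (
    build_species_network,
    classify_by_ka,
    edges_to_frame,
    shared_class_counts,
)


def _classes(table):
    return dict(zip(table["gene_id"], table["class"]))


class TestClassifyByKa:
    def test_ten_genes_one_per_class(self):
        genes = [(f"g{i}", 0.01 * (i + 1)) for i in range(10)]
        cls = _classes(classify_by_ka(genes))
        assert cls["g0"] == "slow" and cls["g9"] == "fast"
        assert sum(v == "intermediate" for v in cls.values()) == 1

    def test_twenty_genes_centered_window(self):
        genes = [(f"g{i:02d}", float(i)) for i in range(20)]
        table = classify_by_ka(genes, cutoff=0.10)
        by_rank = dict(zip(table["rank"], table["class"]))
        assert [by_rank[r] for r in (1, 2)] == ["slow", "slow"]
        assert [by_rank[r] for r in (10, 11)] == ["intermediate", "intermediate"]
        assert [by_rank[r] for r in (19, 20)] == ["fast", "fast"]
        assert sum(c == "unclassified" for c in by_rank.values()) == 14

    def test_na_sorts_to_slow_end(self):
        genes = [("gNA", math.nan)] + [(f"g{i}", 0.1 + 0.01 * i) for i in range(11)]
        table = classify_by_ka(genes)
        row = table[table["gene_id"] == "gNA"].iloc[0]
        assert row["rank"] == 1 and row["class"] == "slow" and row["ka"] == 0.0

    def test_order_invariance(self, rng):
        genes = [(f"g{i:03d}", float(v)) for i, v in enumerate(rng.uniform(0, 1, 50))]
        base = _classes(classify_by_ka(genes))
        shuffled = list(genes)
        rng.shuffle(shuffled)
        assert _classes(classify_by_ka(shuffled)) == base

    def test_class_sizes_exact(self, rng):
        for n in (30, 47, 100):
            genes = [(f"g{i:03d}", float(v)) for i, v in enumerate(rng.uniform(0, 1, n))]
            table = classify_by_ka(genes, cutoff=0.10)
            k = n // 10
            counts = table["class"].value_counts()
            assert counts["slow"] == counts["fast"] == counts["intermediate"] == k

    def test_rank_is_permutation(self, rng):
        genes = [(f"g{i}", float(v)) for i, v in enumerate(rng.uniform(0, 1, 30))]
        table = classify_by_ka(genes)
        assert sorted(table["rank"]) == list(range(1, 31))

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            classify_by_ka([("a", 1.0), ("b", 2.0)])

    def test_duplicate_ids_error(self):
        genes = [("dup", 0.1)] * 2 + [(f"g{i}", 0.2 + i * 0.1) for i in range(10)]
        with pytest.raises(ValueError, match="duplicate"):
            classify_by_ka(genes)


def _species_table(species, fast, slow, universe):
    genes = []
    for g in universe:
        cls = "fast" if g in fast else ("slow" if g in slow else "unclassified")
        genes.append({"species_id": species, "gene_id": g, "ka": 0.0, "rank": 0, "class": cls})
    import pandas as pd

    return pd.DataFrame(genes)


class TestSharedClassCounts:
    def test_intersection_examples(self):
        uni = [f"g{i}" for i in range(10)]
        tables = {
            "sp1": _species_table("sp1", {"g0", "g1", "g2"}, set(), uni),
            "sp2": _species_table("sp2", {"g1", "g2", "g3"}, set(), uni),
            "sp3": _species_table("sp3", {"g1", "g4"}, set(), uni),
        }
        assert shared_class_counts(tables, "fast", ["sp1", "sp2"]) == 2
        assert shared_class_counts(tables, "fast", ["sp1", "sp2", "sp3"]) == 1
        assert shared_class_counts(tables, "slow") == 0

    def test_monotone_in_species_added(self):
        uni = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(5)
        tables = {
            f"sp{j}": _species_table(
                f"sp{j}", set(rng.choice(uni, 8, replace=False)), set(), uni
            )
            for j in range(4)
        }
        species = list(tables)
        prev = None
        for k in range(1, 5):
            count = shared_class_counts(tables, "fast", species[:k])
            if prev is not None:
                assert count <= prev
            prev = count

    def test_unknown_species(self):
        with pytest.raises(ValueError, match="unknown"):
            shared_class_counts({}, "fast", ["nope"])


class TestSpeciesNetwork:
    def _three_species(self):
        uni = [f"g{i}" for i in range(20)]
        return {
            "A": _species_table("A", {"g0", "g1"}, {"g10", "g11"}, uni),
            "B": _species_table("B", {"g0", "g2"}, {"g10", "g12"}, uni),
            "C": _species_table("C", {"g5"}, {"g15"}, uni),
        }

    def test_coefficients(self):
        edges = build_species_network(self._three_species())
        df = edges_to_frame(edges)
        ab_fast = df.query("species_a == 'A' and species_b == 'B' and `class` == 'fast'")
        assert ab_fast["coefficient"].iloc[0] == pytest.approx(1 / 20)
        ab_both = df.query("species_a == 'A' and species_b == 'B' and `class` == 'both'")
        assert ab_both["coefficient"].iloc[0] == pytest.approx(2 / 20)

    def test_identical_species_coefficient(self):
        uni = [f"g{i}" for i in range(10)]
        t = _species_table("X", {"g0"}, {"g9"}, uni)
        tables = {s: t.assign(species_id=s) for s in ("X", "Y", "Z")}
        edges = build_species_network(tables)
        for e in edges:
            if e.cls == "fast":
                assert e.coefficient == pytest.approx(1 / 10)

    def test_disjoint_pair_contributes_no_edge(self):
        import pandas as pd

        uni1 = [f"a{i}" for i in range(10)]
        uni2 = [f"b{i}" for i in range(10)]
        tables = {
            "A": _species_table("A", {"a0"}, set(), uni1),
            "B": _species_table("B", {"a0"}, set(), uni1),
            "C": _species_table("C", {"b0"}, set(), uni2),
        }
        df = edges_to_frame(build_species_network(tables))
        assert set(map(tuple, df[["species_a", "species_b"]].values)) == {("A", "B")}

    def test_per_species_top2_retention_bound(self, rng):
        uni = [f"g{i}" for i in range(30)]
        tables = {}
        for j in range(5):
            fast = set(rng.choice(uni, 6, replace=False))
            slow = set(rng.choice([g for g in uni if g not in fast], 6, replace=False))
            tables[f"sp{j}"] = _species_table(f"sp{j}", fast, slow, uni)
        df = edges_to_frame(build_species_network(tables))
        retained = df[df["retained"]]
        # an edge is retained when either endpoint ranks it top-2, so a
        # species can touch at most 2 self-marked + marks by the 4 others
        for cls in ("fast", "slow", "both"):
            sub = retained[retained["class"] == cls]
            marks = {}
            for _, row in sub.iterrows():
                for sp in (row["species_a"], row["species_b"]):
                    marks[sp] = marks.get(sp, 0) + 1
            assert all(v <= 4 + 2 for v in marks.values())
        assert len(retained) < len(df)

    def test_per_pair_top_class_retention(self):
        edges = build_species_network(self._three_species(), retention="per_pair_top_class")
        df = edges_to_frame(edges)
        retained = df[df["retained"]]
        pairs = retained.groupby(["species_a", "species_b"]).size()
        assert (pairs == 1).all()
        assert set(retained["class"]) <= {"fast", "slow"}

    def test_needs_three_species(self):
        with pytest.raises(ValueError):
            build_species_network({"A": None, "B": None})
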